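"""Multi-channel volume processing.

Linear spectral unmixing, intensity-filter segmentation into connected
bacterial objects, and assignment of objects to crypt regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import measure

__all__ = [
    "VoxelVolume",
    "EmissionSpectraMatrix",
    "SegmentedObject",
    "CryptRegion",
    "linear_unmix",
    "segment_channel",
    "assign_objects_to_crypts",
    "signal_to_background",
]


@dataclass
class VoxelVolume:
    """Channels-first 3D intensity grid with physical voxel size.

    ``data`` has shape (C, Z, Y, X); ``voxel_size`` is (dz, dy, dx) in µm.
    Physical coordinates follow the centre-of-voxel convention:
    coord = origin + (index + 0.5) * voxel_size.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float]
    channel_names: list[str]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)  # (z, y, x) µm

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError("data must be (C, Z, Y, X)")
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError("channel count must equal len(channel_names)")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("all voxel sizes must be positive")

    def channel(self, name: str) -> np.ndarray:
        if name not in self.channel_names:
            raise KeyError(
                f"no channel {name!r}; have {list(self.channel_names)}"
            )
        return self.data[self.channel_names.index(name)]


class CollinearSpectraError(ValueError):
    """Spectra matrix is rank deficient; names the collinear fluorophores."""


@dataclass
class EmissionSpectraMatrix:
    """Detection-channel × fluorophore emission weights.

    Columns are normalized to unit sum on construction (set
    ``normalize=False`` to keep raw weights). All-zero columns are invalid.
    """

    weights: np.ndarray
    fluorophore_names: list[str]
    normalize: bool = True
    channel_names: list[str] | None = None

    def __post_init__(self) -> None:
        W = np.asarray(self.weights, dtype=float)
        if W.ndim != 2:
            raise ValueError("weights must be 2D (channels × fluorophores)")
        if W.shape[1] != len(self.fluorophore_names):
            raise ValueError("fluorophore count mismatch")
        if np.any(W < 0):
            raise ValueError("spectra weights must be non-negative")
        colsum = W.sum(axis=0)
        dead = np.flatnonzero(colsum == 0)
        if len(dead):
            names = [self.fluorophore_names[i] for i in dead]
            raise ValueError(f"all-zero spectra column(s) for {names}")
        if self.normalize:
            W = W / colsum
        self.weights = W
        self._check_rank()

    def _check_rank(self) -> None:
        W = self.weights
        if np.linalg.matrix_rank(W) < W.shape[1]:
            # name near-parallel column pairs to make the error actionable
            norms = np.linalg.norm(W, axis=0)
            cos = (W.T @ W) / np.outer(norms, norms)
            pairs = [
                (self.fluorophore_names[i], self.fluorophore_names[j])
                for i in range(W.shape[1])
                for j in range(i + 1, W.shape[1])
                if cos[i, j] > 1 - 1e-9
            ]
            raise CollinearSpectraError(
                f"spectra matrix is rank deficient; collinear fluorophores: "
                f"{pairs or self.fluorophore_names}"
            )


@dataclass
class SegmentedObject:
    """One connected bacterial aggregate in a single channel."""

    object_id: int
    channel: str
    voxel_count: int
    voxels: np.ndarray            # (n, 3) int (z, y, x) indices
    centroid_um: tuple[float, float, float]   # (x, y, z) physical µm
    mean_intensity: float
    crypt_id: int | None = None

    def __post_init__(self) -> None:
        if self.voxel_count != len(self.voxels):
            raise ValueError("voxel_count must equal len(voxels)")


@dataclass
class CryptRegion:
    """Cylindrical stand-in for one crypt: axis through (x, y), +z into tissue."""

    crypt_id: int
    center_xy: tuple[float, float]     # µm
    lateral_radius: float              # µm
    luminal_opening_z: float = 0.0     # µm
    axis: tuple[float, float, float] = (0.0, 0.0, 1.0)

    def __post_init__(self) -> None:
        if self.lateral_radius <= 0:
            raise ValueError("lateral_radius must be positive")


def linear_unmix(
    volume: VoxelVolume, spectra: EmissionSpectraMatrix
) -> tuple[VoxelVolume, np.ndarray]:
    """Per-voxel least-squares removal of fluorescent spectral overlap.

    Solves ``spectra.weights @ a = observed`` for every voxel, clamps
    negative abundances to zero, and returns the unmixed volume (fluorophore
    axis replacing the channel axis) together with the per-voxel residual
    norm of the unconstrained solution as a QC map.
    """
    W = spectra.weights
    C = volume.data.shape[0]
    if W.shape[0] != C:
        raise ValueError(
            f"spectra has {W.shape[0]} channels but volume has {C}"
        )
    if W.shape[1] > C:
        raise ValueError("need at least as many channels as fluorophores")
    obs = volume.data.reshape(C, -1)
    sol, *_ = np.linalg.lstsq(W, obs, rcond=None)
    residual = np.linalg.norm(obs - W @ sol, axis=0)
    abund = np.clip(sol, 0.0, None).reshape((W.shape[1],) + volume.data.shape[1:])
    out = VoxelVolume(
        data=abund,
        voxel_size=volume.voxel_size,
        channel_names=list(spectra.fluorophore_names),
        origin=volume.origin,
    )
    return out, residual.reshape(volume.data.shape[1:])


def segment_channel(
    volume: VoxelVolume,
    channel: str,
    intensity_threshold: float,
    min_voxels: int = 1,
    connectivity: int = 26,
    weighted_centroid: bool = False,
) -> list[SegmentedObject]:
    """Intensity-filter segmentation of one channel.

    Connected components (26-connectivity by default, 6 available) of the
    super-threshold mask ``intensity > threshold``; components smaller than
    ``min_voxels`` are discarded. Centroids are reported in physical µm
    under the centre-of-voxel convention; unweighted by default, intensity
    weighted if requested.
    """
    if intensity_threshold <= 0:
        raise ValueError("intensity_threshold must be positive")
    if min_voxels < 1:
        raise ValueError("min_voxels must be >= 1")
    if connectivity not in (6, 26):
        raise ValueError("connectivity must be 6 or 26")
    img = volume.channel(channel)
    mask = img > intensity_threshold
    labels = measure.label(mask, connectivity=3 if connectivity == 26 else 1)
    dz, dy, dx = volume.voxel_size
    oz, oy, ox = volume.origin
    objects: list[SegmentedObject] = []
    oid = 0
    for region in measure.regionprops(labels, intensity_image=img):
        if region.num_pixels < min_voxels:
            continue
        coords = region.coords  # (n, 3) z,y,x
        if weighted_centroid:
            w = img[tuple(coords.T)].astype(float)
            cz, cy, cx = (coords * w[:, None]).sum(0) / w.sum()
        else:
            cz, cy, cx = coords.mean(axis=0)
        centroid_um = (
            ox + (cx + 0.5) * dx,
            oy + (cy + 0.5) * dy,
            oz + (cz + 0.5) * dz,
        )
        objects.append(
            SegmentedObject(
                object_id=oid,
                channel=channel,
                voxel_count=int(region.num_pixels),
                voxels=coords.copy(),
                centroid_um=centroid_um,
                mean_intensity=float(region.intensity_mean),
            )
        )
        oid += 1
    return objects


def assign_objects_to_crypts(
    objects: list[SegmentedObject], regions: list[CryptRegion]
) -> dict[int, int | None]:
    """Assign each object to the nearest crypt axis in (x, y).

    An object belongs to the region whose axis is closest to its centroid,
    provided the lateral distance is within that region's radius; otherwise
    it is unassigned (None). Exact ties go to the smaller crypt_id.
    """
    ids = [r.crypt_id for r in regions]
    if len(set(ids)) != len(ids):
        raise ValueError("crypt regions must have distinct ids")
    out: dict[int, int | None] = {}
    for obj in objects:
        x, y, _ = obj.centroid_um
        best: tuple[float, int] | None = None
        for r in regions:
            d = float(np.hypot(x - r.center_xy[0], y - r.center_xy[1]))
            if d > r.lateral_radius:
                continue
            if best is None or d < best[0] - 1e-9 or (
                abs(d - best[0]) <= 1e-9 and r.crypt_id < best[1]
            ):
                best = (d, r.crypt_id)
        out[obj.object_id] = None if best is None else best[1]
        obj.crypt_id = out[obj.object_id]
    return out


def signal_to_background(
    objects: list[SegmentedObject], background_level: float
) -> np.ndarray:
    """Per-object mean intensity over a scalar background level."""
    if background_level <= 0:
        raise ValueError("background_level must be positive")
    return np.array([o.mean_intensity / background_level for o in objects])
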