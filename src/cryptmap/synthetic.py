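"""Synthetic mucosa generator.

Produces crypt landscapes (jittered lattices), spatially clustered
colonization with community-type labels, per-crypt taxon abundances,
rendered multi-channel voxel volumes with full ground truth, and
staining-QC tables — all reproducible from a single integer seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _sstats

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "make_crypt_lattice",
    "simulate_colonization",
    "sample_crypt_abundances",
    "place_bacteria_and_render",
    "simulate_gel_slab",
    "simulate_dataset",
    "ground_truth_to_records",
    "brute_force_clusters",
    "DEFAULT_TAXA",
    "DEFAULT_ARCHETYPES",
]

DEFAULT_TAXA = ("Bacteroidetes", "Clostridia", "Bacilli")

#: Six community-type abundance archetypes (mean voxel counts per taxon).
#: A is unenriched; B Clostridia-rich; C and F Bacilli-rich (different
#: magnitudes); D Bacteroidetes+Clostridia; E Bacteroidetes-rich.
DEFAULT_ARCHETYPES: dict[str, dict[str, float]] = {
    "A": {"Bacteroidetes": 8, "Clostridia": 8, "Bacilli": 8},
    "B": {"Bacteroidetes": 25, "Clostridia": 420, "Bacilli": 20},
    "C": {"Bacteroidetes": 20, "Clostridia": 25, "Bacilli": 320},
    "D": {"Bacteroidetes": 520, "Clostridia": 400, "Bacilli": 25},
    "E": {"Bacteroidetes": 640, "Clostridia": 35, "Bacilli": 20},
    "F": {"Bacteroidetes": 45, "Clostridia": 40, "Bacilli": 1300},
}

DEFAULT_DEPTH_MEANS = {"Bacteroidetes": 45.0, "Clostridia": 28.0, "Bacilli": 15.0}
DEFAULT_DEPTH_SDS = {"Bacteroidetes": 5.0, "Clostridia": 5.0, "Bacilli": 5.0}


class InvalidConfigError(ValueError):
    """Raised when a SimulationConfig violates its invariants."""


@dataclass
class SimulationConfig:
    """Parameters of the synthetic mucosa.

    All randomness derives from ``rng_seed``; independent sub-streams are
    spawned per stage so adding a stage never perturbs another.
    """

    lattice_nx: int = 10
    lattice_ny: int = 10
    crypt_pitch: float = 75.0            # µm, centre-to-centre
    lattice_geometry: str = "hex"        # "hex" or "square"
    position_jitter_sd: float = 4.0      # µm
    seed_fraction: float = 0.05
    spread_prob: float = 0.5
    n_spread_rounds: int = 2
    type_archetypes: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_ARCHETYPES.items()}
    )
    type_spatial_coupling: float = 1.0
    abundance_noise_sd: float = 0.3      # log-scale
    taxon_depth_means: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DEPTH_MEANS)
    )
    taxon_depth_sds: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DEPTH_SDS)
    )
    crypt_depth: float = 60.0            # µm
    crypt_radius: float = 20.0           # µm, lateral extent used in rendering
    cluster_threshold: float = 150.0     # µm, defines true spatial clusters
    mixing_matrix: np.ndarray | None = None   # channels × fluorophores
    noise_sd: float = 0.0                # intensity units
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.0)  # (dz, dy, dx) µm
    blob_intensity: float = 100.0
    stained_ratio_mean: float = 200.0
    stained_ratio_sd: float = 30.0
    background_level: float = 10.0
    sample_id: str = "S1"
    condition: str = "NA"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.lattice_nx < 1 or self.lattice_ny < 1:
            raise InvalidConfigError("lattice dimensions must be >= 1")
        if self.crypt_pitch <= 0:
            raise InvalidConfigError("crypt_pitch must be positive")
        if self.crypt_depth <= 0 or self.crypt_radius <= 0:
            raise InvalidConfigError("crypt_depth and crypt_radius must be positive")
        if self.position_jitter_sd < 0 or self.abundance_noise_sd < 0:
            raise InvalidConfigError("noise SDs must be non-negative")
        for name, p in (
            ("seed_fraction", self.seed_fraction),
            ("spread_prob", self.spread_prob),
            ("type_spatial_coupling", self.type_spatial_coupling),
        ):
            if not 0.0 <= p <= 1.0:
                raise InvalidConfigError(f"{name} must be in [0, 1], got {p}")
        if self.lattice_geometry not in ("hex", "square"):
            raise InvalidConfigError("lattice_geometry must be 'hex' or 'square'")
        taxa = self.taxa
        for label, arch in self.type_archetypes.items():
            if set(arch) != set(taxa):
                raise InvalidConfigError(
                    f"archetype {label!r} does not cover the taxon set {taxa}"
                )
            if any(v < 0 for v in arch.values()):
                raise InvalidConfigError(f"archetype {label!r} has negative entries")
        for t in taxa:
            if self.taxon_depth_sds.get(t, 1.0) <= 0:
                raise InvalidConfigError(f"depth sd for {t!r} must be positive")
        if self.mixing_matrix is not None:
            M = np.asarray(self.mixing_matrix, dtype=float)
            if M.ndim != 2 or np.any(M < 0) or np.any(M.sum(axis=0) <= 0):
                raise InvalidConfigError(
                    "mixing_matrix must be 2D, non-negative, with at least one "
                    "positive entry per column"
                )

    @property
    def taxa(self) -> tuple[str, ...]:
        first = next(iter(self.type_archetypes.values()))
        return tuple(first.keys())

    @property
    def type_labels(self) -> tuple[str, ...]:
        return tuple(self.type_archetypes.keys())

    def rng_streams(self, names: Sequence[str]) -> dict[str, np.random.Generator]:
        """Named independent generators derived from ``rng_seed``."""
        children = np.random.SeedSequence(self.rng_seed).spawn(len(names))
        return {n: np.random.default_rng(c) for n, c in zip(names, children)}

    def replace(self, **kw) -> "SimulationConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class GroundTruth:
    """Everything the generator knows; the oracle for the analysis modules."""

    centers: np.ndarray                      # (n, 2) µm
    colonized: np.ndarray                    # (n,) bool
    type_labels: np.ndarray                  # (n,) object; None where empty
    counts: pd.DataFrame | None = None       # n × taxa integer voxel counts
    depths: pd.DataFrame | None = None       # n × taxa µm; NaN where count == 0
    cluster_labels: np.ndarray | None = None  # (n,) int; -1 where not colonized
    objects: dict[str, list[np.ndarray]] | None = None  # channel -> voxel lists
    object_crypts: dict[str, list[int]] | None = None   # channel -> crypt index
    clipped_blobs: int = 0

    @property
    def n_crypts(self) -> int:
        return len(self.centers)


# ---------------------------------------------------------------------------
# lattice and colonization
# ---------------------------------------------------------------------------

def make_crypt_lattice(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Jittered hexagonal (or square) lattice of crypt centres, in µm.

    Returns an ``(nx * ny, 2)`` array of (x, y). Hexagonal packing offsets
    odd rows by half a pitch and compresses row spacing by sqrt(3)/2.
    """
    if rng is None:
        rng = config.rng_streams(["lattice"])["lattice"]
    nx, ny, pitch = config.lattice_nx, config.lattice_ny, config.crypt_pitch
    ix, iy = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    x = ix.astype(float) * pitch
    y = iy.astype(float) * pitch
    if config.lattice_geometry == "hex":
        x = x + (iy % 2) * pitch / 2.0
        y = iy.astype(float) * pitch * np.sqrt(3.0) / 2.0
    centers = np.column_stack([x.ravel(), y.ravel()])
    if config.position_jitter_sd > 0:
        centers = centers + rng.normal(0.0, config.position_jitter_sd, centers.shape)
    return centers


def simulate_colonization(
    centers: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    return_sources: bool = False,
):
    """Seed-and-spread contact process over the crypt lattice.

    Seeds are Bernoulli(``seed_fraction``); for ``n_spread_rounds`` each
    colonized crypt colonizes each empty neighbour (centre distance
    <= 1.5 * pitch) with probability ``spread_prob``. Community-type labels
    are drawn uniformly from the archetypes at seeds and copied from the
    spreading source with probability ``type_spatial_coupling``.

    Returns ``(colonized, type_labels)`` where ``type_labels`` is an object
    array with ``None`` at uncolonized crypts. With ``return_sources=True``
    a third array gives, for each colonized crypt, the index of the crypt it
    was colonized from (itself for seeds; -1 where uncolonized).
    """
    centers = np.asarray(centers, dtype=float)
    if len(centers) == 0:
        raise ValueError("centers must be non-empty")
    if rng is None:
        rng = config.rng_streams(["colonization"])["colonization"]
    n = len(centers)
    labels = np.asarray(config.type_labels, dtype=object)

    colonized = rng.random(n) < config.seed_fraction
    type_labels = np.full(n, None, dtype=object)
    type_labels[colonized] = rng.choice(labels, size=int(colonized.sum()))
    sources = np.where(colonized, np.arange(n), -1)

    # neighbour lists once; lattice sizes stay small enough for O(n^2)
    reach = 1.5 * config.crypt_pitch
    d2 = ((centers[:, None, :] - centers[None, :, :]) ** 2).sum(-1)
    neighbour = (d2 <= reach**2) & ~np.eye(n, dtype=bool)

    for _ in range(config.n_spread_rounds):
        frontier = np.flatnonzero(colonized)
        newly: dict[int, int] = {}
        for src in frontier:
            for tgt in np.flatnonzero(neighbour[src]):
                if colonized[tgt] or tgt in newly:
                    continue
                if rng.random() < config.spread_prob:
                    newly[tgt] = src
        for tgt, src in newly.items():
            colonized[tgt] = True
            sources[tgt] = src
            if rng.random() < config.type_spatial_coupling:
                type_labels[tgt] = type_labels[src]
            else:
                type_labels[tgt] = rng.choice(labels)
    if return_sources:
        return colonized, type_labels, sources
    return colonized, type_labels


def brute_force_clusters(centers: np.ndarray, threshold: float) -> np.ndarray:
    """O(n^2) union-find connected components of the <=threshold graph.

    Deliberately independent of the KD-tree implementation in
    :mod:`cryptmap.biogeography`; serves as its oracle.
    """
    centers = np.asarray(centers, dtype=float)
    n = len(centers)
    parent = list(range(n))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    d2 = ((centers[:, None, :] - centers[None, :, :]) ** 2).sum(-1)
    edges = np.argwhere(np.triu(d2 <= threshold * threshold, k=1))
    for i, j in edges:
        ra, rb = find(int(i)), find(int(j))
        if ra != rb:
            parent[rb] = ra
    roots: dict[int, int] = {}
    out = np.empty(n, dtype=int)
    for i in range(n):
        r = find(i)
        out[i] = roots.setdefault(r, len(roots))
    return out


# ---------------------------------------------------------------------------
# abundances and depths
# ---------------------------------------------------------------------------

def sample_crypt_abundances(
    type_label: str,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> dict[str, int]:
    """Lognormal-noised voxel counts around the type archetype.

    counts = round(exp(log(mean + 1) + Normal(0, abundance_noise_sd))) - 1,
    clamped at zero — multiplicative noise that keeps counts non-negative
    and preserves exact zeros.
    """
    if type_label not in config.type_archetypes:
        raise KeyError(f"unknown community type {type_label!r}")
    if rng is None:
        rng = config.rng_streams(["abundance"])["abundance"]
    arch = config.type_archetypes[type_label]
    out: dict[str, int] = {}
    for taxon in config.taxa:
        mean = float(arch[taxon])
        if mean == 0.0:
            # exact zeros are structural, not noisy
            out[taxon] = 0
            continue
        draw = np.exp(np.log(mean + 1.0) + rng.normal(0.0, config.abundance_noise_sd))
        out[taxon] = max(int(round(draw)) - 1, 0)
    return out


def _sample_depth(
    taxon: str, config: SimulationConfig, rng: np.random.Generator, size: int = 1
) -> np.ndarray:
    """Truncated-normal depths in [0, crypt_depth] µm."""
    mu = float(config.taxon_depth_means[taxon])
    sd = float(config.taxon_depth_sds[taxon])
    a, b = (0.0 - mu) / sd, (config.crypt_depth - mu) / sd
    return _sstats.truncnorm.rvs(a, b, loc=mu, scale=sd, size=size, random_state=rng)


# ---------------------------------------------------------------------------
# volume rendering
# ---------------------------------------------------------------------------

#: 7-voxel plus-shaped blob (centre + 6 face neighbours).
_BLOB_OFFSETS = np.array(
    [[0, 0, 0], [1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]],
    dtype=int,
)


def place_bacteria_and_render(
    ground_truth: GroundTruth,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
):
    """Render the colonized landscape into a multi-channel voxel volume.

    Bacteria are 7-voxel blobs placed laterally within ``crypt_radius`` of
    their crypt centre at truncated-Gaussian depths per taxon; the number of
    blobs per crypt/taxon approximates the ground-truth voxel count.
    Fluorophore stacks are mixed into detection channels via
    ``mixing_matrix`` (identity if None) and Gaussian noise is added.
    Ground-truth per-object voxel lists are recorded before mixing/noise;
    blobs touching (26-adjacency) are merged into one object. Blobs falling
    outside the volume are clipped and counted in ``clipped_blobs``.

    Returns a :class:`cryptmap.volumes.VoxelVolume` and updates
    ``ground_truth.objects`` in place.
    """
    from .volumes import VoxelVolume  # local import: avoid cycle at import time

    if rng is None:
        rng = config.rng_streams(["render"])["render"]
    gt = ground_truth
    taxa = config.taxa
    dz, dy, dx = config.voxel_size

    pad = config.crypt_radius + 3 * max(dy, dx)
    x0 = float(gt.centers[:, 0].min()) - pad
    y0 = float(gt.centers[:, 1].min()) - pad
    x1 = float(gt.centers[:, 0].max()) + pad
    y1 = float(gt.centers[:, 1].max()) + pad
    shape = (
        int(np.ceil(config.crypt_depth / dz)) + 2,
        int(np.ceil((y1 - y0) / dy)) + 1,
        int(np.ceil((x1 - x0) / dx)) + 1,
    )
    fluor = np.zeros((len(taxa),) + shape, dtype=float)

    # per taxon: voxel -> blob-group id, with union-find over group ids so
    # touching blobs collapse into one ground-truth object
    owner: dict[str, dict[tuple, int]] = {t: {} for t in taxa}
    parent: dict[str, list[int]] = {t: [] for t in taxa}
    group_crypt: dict[str, list[int]] = {t: [] for t in taxa}
    clipped = 0

    def _find(t: str, a: int) -> int:
        p = parent[t]
        while p[a] != a:
            p[a] = p[p[a]]
            a = p[a]
        return a

    counts = gt.counts if gt.counts is not None else None
    for ci in np.flatnonzero(gt.colonized):
        cx, cy = gt.centers[ci]
        for ti, taxon in enumerate(taxa):
            n_vox = int(counts.iloc[ci][taxon]) if counts is not None else 0
            if n_vox <= 0:
                continue
            n_blobs = max(1, int(round(n_vox / len(_BLOB_OFFSETS))))
            depths = _sample_depth(taxon, config, rng, size=n_blobs)
            for b in range(n_blobs):
                r = config.crypt_radius * np.sqrt(rng.random())
                th = rng.random() * 2 * np.pi
                bx, by, bz_um = cx + r * np.cos(th), cy + r * np.sin(th), depths[b]
                iz = int(bz_um / dz)
                iy = int((by - y0) / dy)
                ix = int((bx - x0) / dx)
                vox = _BLOB_OFFSETS + np.array([iz, iy, ix])
                inside = (
                    (vox[:, 0] >= 0) & (vox[:, 0] < shape[0])
                    & (vox[:, 1] >= 0) & (vox[:, 1] < shape[1])
                    & (vox[:, 2] >= 0) & (vox[:, 2] < shape[2])
                )
                if not inside.all():
                    clipped += 1
                    vox = vox[inside]
                if len(vox) == 0:
                    continue
                fluor[ti][tuple(vox.T)] = config.blob_intensity
                gid = len(parent[taxon])
                parent[taxon].append(gid)
                group_crypt[taxon].append(int(ci))
                own = owner[taxon]
                for (z, y, x) in map(tuple, vox):
                    for nz in (z - 1, z, z + 1):
                        for ny in (y - 1, y, y + 1):
                            for nx_ in (x - 1, x, x + 1):
                                g = own.get((nz, ny, nx_))
                                if g is not None:
                                    ra, rb = _find(taxon, gid), _find(taxon, g)
                                    if ra != rb:
                                        parent[taxon][rb] = ra
                    own[(z, y, x)] = gid

    gt_objects: dict[str, list[np.ndarray]] = {}
    object_crypts: dict[str, list[int]] = {}
    for t in taxa:
        groups: dict[int, list[tuple]] = {}
        for vox_idx, gid in owner[t].items():
            groups.setdefault(_find(t, gid), []).append(vox_idx)
        gt_objects[t] = [np.array(sorted(v), dtype=int) for v in groups.values()]
        object_crypts[t] = [group_crypt[t][root] for root in groups.keys()]
    gt.objects = gt_objects
    gt.object_crypts = object_crypts
    gt.clipped_blobs = clipped

    M = config.mixing_matrix
    if M is None:
        data = fluor.copy()
        channel_names = list(taxa)
    else:
        M = np.asarray(M, dtype=float)
        if M.shape[1] != len(taxa):
            raise InvalidConfigError(
                f"mixing_matrix has {M.shape[1]} fluorophore columns, "
                f"expected {len(taxa)}"
            )
        data = np.tensordot(M, fluor, axes=(1, 0))
        channel_names = [f"ch{i}" for i in range(M.shape[0])]
    if config.noise_sd > 0:
        data = data + rng.normal(0.0, config.noise_sd, data.shape)

    vol = VoxelVolume(
        data=data,
        voxel_size=config.voxel_size,
        channel_names=channel_names,
        origin=(0.0, y0, x0),
    )
    return vol, gt.objects


# ---------------------------------------------------------------------------
# gel-slab staining QC
# ---------------------------------------------------------------------------

def simulate_gel_slab(
    n_cells: int,
    staining_efficiency: Callable[[np.ndarray], np.ndarray],
    config: SimulationConfig | None = None,
    depth_max: float = 600.0,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Cells at uniform depths with depth-dependent staining success.

    Each cell at depth d is stained with probability ``staining_efficiency(d)``,
    drawing its signal-to-background ratio from the bright "stained"
    distribution; otherwise the ratio sits at background level (~1).
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    cfg = config or SimulationConfig()
    if rng is None:
        rng = cfg.rng_streams(["gel"])["gel"]
    depth = rng.uniform(0.0, depth_max, n_cells)
    eff = np.asarray(staining_efficiency(depth), dtype=float)
    if eff.shape != depth.shape:
        eff = np.broadcast_to(eff, depth.shape).copy()
    if np.any((eff < 0) | (eff > 1)):
        raise ValueError("staining efficiency must map depths into [0, 1]")
    stained = rng.random(n_cells) < eff
    ratio = np.where(
        stained,
        np.clip(rng.normal(cfg.stained_ratio_mean, cfg.stained_ratio_sd, n_cells), 1e-6, None),
        np.clip(rng.normal(1.0, 0.2, n_cells), 1e-6, None),
    )
    background = cfg.background_level
    return pd.DataFrame(
        {
            "cell_id": np.arange(n_cells),
            "depth_um": depth,
            "hcr_signal": ratio * background,
            "background": background,
            "reference_detected": True,
            "true_stained": stained,
        }
    )


# ---------------------------------------------------------------------------
# full tabular scene
# ---------------------------------------------------------------------------

def simulate_dataset(config: SimulationConfig) -> GroundTruth:
    """Lattice + colonization + abundances + depths + true spatial clusters."""
    streams = config.rng_streams(["lattice", "colonization", "abundance", "depth"])
    centers = make_crypt_lattice(config, streams["lattice"])
    colonized, type_labels = simulate_colonization(centers, config, streams["colonization"])

    taxa = config.taxa
    n = len(centers)
    counts = pd.DataFrame(0, index=np.arange(n), columns=list(taxa), dtype=int)
    depths = pd.DataFrame(np.nan, index=np.arange(n), columns=list(taxa))
    for ci in np.flatnonzero(colonized):
        c = sample_crypt_abundances(type_labels[ci], config, streams["abundance"])
        for taxon in taxa:
            counts.loc[ci, taxon] = c[taxon]
            if c[taxon] > 0:
                depths.loc[ci, taxon] = _sample_depth(
                    taxon, config, streams["depth"], size=1
                )[0]

    cluster_labels = np.full(n, -1, dtype=int)
    idx = np.flatnonzero(colonized)
    if len(idx):
        cluster_labels[idx] = brute_force_clusters(
            centers[idx], config.cluster_threshold
        )
    return GroundTruth(
        centers=centers,
        colonized=colonized,
        type_labels=type_labels,
        counts=counts,
        depths=depths,
        cluster_labels=cluster_labels,
    )


def ground_truth_to_records(gt: GroundTruth, config: SimulationConfig) -> pd.DataFrame:
    """Flatten a GroundTruth into the crypt-record table schema.

    Columns: crypt_id, sample_id, condition, x_um, y_um, per-taxon
    ``count_*`` / ``depth_*``, and eubacterial ``count_total`` /
    ``depth_total`` (count-weighted mean depth).
    """
    taxa = config.taxa
    rows = []
    for ci in range(gt.n_crypts):
        row: dict = {
            "crypt_id": ci,
            "sample_id": config.sample_id,
            "condition": config.condition,
            "x_um": gt.centers[ci, 0],
            "y_um": gt.centers[ci, 1],
        }
        total = 0
        wdepth = 0.0
        for taxon in taxa:
            c = int(gt.counts.iloc[ci][taxon]) if gt.counts is not None else 0
            d = float(gt.depths.iloc[ci][taxon]) if gt.depths is not None else np.nan
            row[f"count_{taxon}"] = c
            row[f"depth_{taxon}"] = d
            total += c
            if c > 0 and np.isfinite(d):
                wdepth += c * d
        row["count_total"] = total
        row["depth_total"] = wdepth / total if total > 0 else np.nan
        rows.append(row)
    return pd.DataFrame(rows)
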