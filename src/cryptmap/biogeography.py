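"""Per-crypt and tissue-scale spatial metrics.

Taxon volumes and centre-of-mass depths, signed depth differences between
taxa within a crypt, colonized-crypt density per field of view, and
distance-threshold spatial clustering of colonized crypts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .volumes import CryptRegion, SegmentedObject

__all__ = [
    "SpatialClusterLabeling",
    "taxon_volume",
    "com_depth",
    "com_depth_from_objects",
    "delta_cm",
    "colonized_density",
    "spatial_clusters",
    "cluster_size_summary",
]


@dataclass
class SpatialClusterLabeling:
    """Partition of colonized crypts into distance-threshold clusters."""

    crypt_ids: np.ndarray       # ids of the clustered (colonized) crypts
    labels: np.ndarray          # same length; cluster id per crypt
    threshold: float            # µm
    inclusive: bool = True      # edge rule: distance <= threshold (else <)

    @property
    def n_clusters(self) -> int:
        return len(np.unique(self.labels))

    def sizes(self) -> pd.Series:
        """Cluster id -> number of member crypts."""
        return pd.Series(self.labels).value_counts().sort_index()

    def per_crypt_sizes(self) -> np.ndarray:
        """Size of each crypt's own cluster, aligned with ``crypt_ids``."""
        counts = np.bincount(self.labels)
        return counts[self.labels]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "crypt_id": self.crypt_ids,
                "cluster_id": self.labels,
                "cluster_size": self.per_crypt_sizes(),
            }
        )


def taxon_volume(record: pd.Series | dict, taxon: str) -> int:
    """Stored voxel count of a taxon in one crypt record."""
    key = f"count_{taxon}"
    if key not in record:
        raise KeyError(f"unknown taxon {taxon!r} (no column {key!r})")
    return int(record[key])


def com_depth(record: pd.Series | dict, taxon: str) -> float:
    """Centre-of-mass depth of a taxon in one crypt record (µm).

    Undefined (NaN) when the taxon has no voxels in the crypt; callers
    exclude such crypts downstream.
    """
    if taxon_volume(record, taxon) == 0:
        return float("nan")
    return float(record[f"depth_{taxon}"])


def com_depth_from_objects(
    objects: list[SegmentedObject], region: CryptRegion
) -> float:
    """Pooled-centroid depth of a set of objects along the crypt axis.

    Objects are pooled with voxel-count weights; the pooled centroid is
    projected onto the region's axis direction and referenced to the
    luminal opening. Deeper = larger.
    """
    if not objects:
        raise ValueError("need at least one object to compute a depth")
    w = np.array([o.voxel_count for o in objects], dtype=float)
    cents = np.array([o.centroid_um for o in objects])  # (n, 3) x,y,z
    pooled = (cents * w[:, None]).sum(axis=0) / w.sum()
    axis = np.asarray(region.axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    ref = np.array([region.center_xy[0], region.center_xy[1], region.luminal_opening_z])
    return float(np.dot(pooled - ref, axis))


def delta_cm(record: pd.Series | dict, taxon_a: str, taxon_b: str) -> float:
    """Signed depth difference com_depth(A) - com_depth(B) within one crypt.

    Positive means A sits deeper than B. NaN when either taxon is absent.
    """
    da, db = com_depth(record, taxon_a), com_depth(record, taxon_b)
    return da - db


def colonized_density(
    records: pd.DataFrame,
    fov_edge: float = 425.0,
    colonization_min: int = 1,
    origin: tuple[float, float] | None = None,
) -> tuple[np.ndarray, float, float]:
    """Colonized crypts per field-of-view tile.

    Tiles the (x, y) plane into half-open ``fov_edge`` squares anchored at
    ``origin`` (bounding-box minimum by default), counts crypts with
    eubacterial voxel count >= ``colonization_min`` per tile containing at
    least one crypt, and returns (per-tile counts, mean, SD).
    """
    if fov_edge <= 0:
        raise ValueError("fov_edge must be positive")
    if len(records) == 0:
        return np.array([], dtype=int), float("nan"), float("nan")
    x = records["x_um"].to_numpy(dtype=float)
    y = records["y_um"].to_numpy(dtype=float)
    if origin is None:
        origin = (float(x.min()), float(y.min()))
    ix = np.floor((x - origin[0]) / fov_edge).astype(int)
    iy = np.floor((y - origin[1]) / fov_edge).astype(int)
    colonized = records["count_total"].to_numpy() >= colonization_min
    tiles: dict[tuple[int, int], int] = {}
    for i, j, c in zip(ix, iy, colonized):
        tiles[(i, j)] = tiles.get((i, j), 0) + int(c)
    counts = np.array([tiles[k] for k in sorted(tiles)], dtype=int)
    sd = float(counts.std(ddof=1)) if len(counts) > 1 else 0.0
    return counts, float(counts.mean()), sd


def spatial_clusters(
    xy: np.ndarray,
    crypt_ids: np.ndarray | None = None,
    threshold: float = 150.0,
    inclusive: bool = True,
) -> SpatialClusterLabeling:
    """Distance-threshold clustering of colonized crypt centres.

    Two crypts belong to the same cluster when connected by a chain of
    pairwise (x, y) distances <= ``threshold`` (or strictly < when
    ``inclusive=False``). Implemented with a KD-tree neighbour query plus
    sparse connected components; singletons form size-1 clusters.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    xy = np.asarray(xy, dtype=float).reshape(-1, 2)
    n = len(xy)
    if crypt_ids is None:
        crypt_ids = np.arange(n)
    crypt_ids = np.asarray(crypt_ids)
    if n == 0:
        return SpatialClusterLabeling(crypt_ids, np.array([], dtype=int), threshold, inclusive)
    tree = cKDTree(xy)
    pairs = np.array(sorted(tree.query_pairs(r=threshold)), dtype=int).reshape(-1, 2)
    if not inclusive and len(pairs):
        d = np.linalg.norm(xy[pairs[:, 0]] - xy[pairs[:, 1]], axis=1)
        pairs = pairs[d < threshold]
    data = np.ones(len(pairs))
    graph = coo_matrix(
        (data, (pairs[:, 0], pairs[:, 1])), shape=(n, n)
    )
    _, labels = connected_components(graph, directed=False)
    # relabel by first appearance for determinism across scipy versions
    order: dict[int, int] = {}
    labels = np.array([order.setdefault(l, len(order)) for l in labels])
    return SpatialClusterLabeling(crypt_ids, labels, threshold, inclusive)


def cluster_size_summary(labeling: SpatialClusterLabeling) -> dict:
    """Median and central-75% interval of cluster size.

    Primary statistics weight each *crypt* by the size of its own cluster
    (so "75% of crypts sit in clusters between lo and hi"); the per-cluster
    view is reported alongside. Percentiles use linear interpolation.
    """
    if len(labeling.labels) == 0:
        raise ValueError("empty labeling")
    per_crypt = labeling.per_crypt_sizes().astype(float)
    lo, med, hi = np.percentile(per_crypt, [12.5, 50.0, 87.5])
    per_cluster = labeling.sizes().to_numpy(dtype=float)
    clo, cmed, chi = np.percentile(per_cluster, [12.5, 50.0, 87.5])
    return {
        "per_crypt": {"median": float(med), "p12.5": float(lo), "p87.5": float(hi)},
        "per_cluster": {"median": float(cmed), "p12.5": float(clo), "p87.5": float(chi)},
        "n_crypts": int(len(per_crypt)),
        "n_clusters": int(labeling.n_clusters),
    }
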