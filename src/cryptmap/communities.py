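"""Community typing of crypt microbiota.

Z-scored taxon abundances are clustered by cosine-similarity hierarchical
agglomeration (average linkage), the tree is cut into k types (A, B, ...),
clustering quality is scored with silhouettes, and the spatial arrangement
of types is summarized through nearest-neighbour distances.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "TypeAssignment",
    "zscore_by_taxon",
    "cosine_distance",
    "hca",
    "cut_tree",
    "assign_types",
    "silhouette_scores",
    "nn_type_distances",
    "type_clustering_permutation_test",
]


@dataclass
class TypeAssignment:
    """Community-type label per crypt plus the tree it came from."""

    crypt_ids: np.ndarray
    labels: np.ndarray                  # object array of type letters
    linkage: np.ndarray                 # scipy linkage matrix
    k: int
    silhouette: np.ndarray | None = None
    flagged: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"crypt_id": self.crypt_ids, "type": self.labels})
        if self.silhouette is not None:
            df["silhouette"] = self.silhouette
        return df


def zscore_by_taxon(matrix: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Column-wise Z scoring of the crypt × taxon abundance matrix.

    Each column is centred to mean 0 and scaled to sample SD 1 (n-1
    denominator). Zero-variance columns become all-zeros and are returned
    in the flag list. Raises on a single-row matrix (SD undefined).
    """
    if len(matrix) < 2:
        raise ValueError("Z scoring needs at least 2 rows")
    vals = matrix.to_numpy(dtype=float)
    mean = vals.mean(axis=0)
    sd = vals.std(axis=0, ddof=1)
    flagged = [c for c, s in zip(matrix.columns, sd) if s == 0]
    safe_sd = np.where(sd == 0, 1.0, sd)
    z = (vals - mean) / safe_sd
    z[:, sd == 0] = 0.0
    return pd.DataFrame(z, index=matrix.index, columns=matrix.columns), flagged


def cosine_distance(u: np.ndarray, v: np.ndarray) -> float:
    """1 - cosine similarity, in [0, 2].

    Zero vectors have no direction: distance 0 to another zero vector, 1 to
    anything else (the indifferent value).
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 and nv == 0:
        return 0.0
    if nu == 0 or nv == 0:
        return 1.0
    return float(np.clip(1.0 - np.dot(u, v) / (nu * nv), 0.0, 2.0))


def _cosine_pdist(X: np.ndarray) -> np.ndarray:
    """Condensed cosine distance matrix honouring the zero-vector rules."""
    norms = np.linalg.norm(X, axis=1)
    zero = norms == 0
    safe = np.where(zero, 1.0, norms)
    Xn = X / safe[:, None]
    sim = np.clip(Xn @ Xn.T, -1.0, 1.0)
    D = 1.0 - sim
    D[zero, :] = 1.0
    D[:, zero] = 1.0
    D[np.ix_(zero, zero)] = 0.0
    np.fill_diagonal(D, 0.0)
    return squareform(D, checks=False)


def hca(z_matrix: pd.DataFrame | np.ndarray, axis: str = "crypts",
        method: str = "average") -> np.ndarray:
    """Agglomerative clustering of crypts (rows) or taxa (columns).

    Cosine distance with average linkage (UPGMA) by default. SciPy's
    implementation is deterministic (lowest-index merge first). Merge
    heights are checked to be non-decreasing.
    """
    X = z_matrix.to_numpy(dtype=float) if isinstance(z_matrix, pd.DataFrame) else np.asarray(z_matrix, float)
    if axis == "taxa":
        X = X.T
    elif axis != "crypts":
        raise ValueError("axis must be 'crypts' or 'taxa'")
    if X.shape[0] < 2:
        raise ValueError("need at least 2 items to cluster")
    Z = hierarchy.linkage(_cosine_pdist(X), method=method)
    if np.any(np.diff(Z[:, 2]) < -1e-10):
        raise RuntimeError("non-monotone linkage heights")
    return Z


def cut_tree(linkage: np.ndarray, k: int = 6,
             crypt_ids: np.ndarray | None = None) -> TypeAssignment:
    """Cut the tree into exactly k groups labelled A, B, ... by size.

    Labels are ordered by cluster size descending; ties broken by the
    smallest member position.
    """
    n = linkage.shape[0] + 1
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    if crypt_ids is None:
        crypt_ids = np.arange(n)
    raw = hierarchy.cut_tree(linkage, n_clusters=k).ravel()
    order = sorted(
        np.unique(raw),
        key=lambda c: (-int((raw == c).sum()), int(np.flatnonzero(raw == c)[0])),
    )
    letters = _type_letters(k)
    mapping = {c: letters[i] for i, c in enumerate(order)}
    labels = np.array([mapping[c] for c in raw], dtype=object)
    return TypeAssignment(crypt_ids=np.asarray(crypt_ids), labels=labels,
                          linkage=linkage, k=k)


def _type_letters(k: int) -> list[str]:
    base = list(string.ascii_uppercase)
    if k <= len(base):
        return base[:k]
    return base + [f"Z{i}" for i in range(k - len(base))]


def assign_types(
    matrix: pd.DataFrame,
    k: int = 6,
    method: str = "average",
    crypt_ids: np.ndarray | None = None,
) -> TypeAssignment:
    """Full typing pipeline: Z score, cluster, cut, score silhouettes.

    Rows that are all-zero after Z scoring (crypts sitting exactly at every
    column mean) have undefined cosine direction; they are assigned to the
    nearest cluster centroid (Euclidean, in Z space) post hoc and flagged.
    """
    z, _ = zscore_by_taxon(matrix)
    X = z.to_numpy(dtype=float)
    zero_rows = np.flatnonzero(np.linalg.norm(X, axis=1) == 0)
    good = np.flatnonzero(np.linalg.norm(X, axis=1) > 0)
    if crypt_ids is None:
        crypt_ids = np.asarray(matrix.index)
    if len(good) < 2:
        raise ValueError("fewer than 2 crypts with non-degenerate profiles")
    Z = hca(X[good], method=method)
    sub = cut_tree(Z, k=min(k, len(good)))
    labels = np.full(len(X), None, dtype=object)
    labels[good] = sub.labels
    if len(zero_rows):
        cents = {
            lab: X[good][sub.labels == lab].mean(axis=0)
            for lab in np.unique(sub.labels)
        }
        labs = sorted(cents)
        for i in zero_rows:
            d = [np.linalg.norm(X[i] - cents[l]) for l in labs]
            labels[i] = labs[int(np.argmin(d))]
    assignment = TypeAssignment(
        crypt_ids=np.asarray(crypt_ids), labels=labels, linkage=Z, k=sub.k,
        flagged=zero_rows,
    )
    if len(np.unique(labels[good])) >= 2:
        assignment.silhouette = silhouette_scores(X, labels)[0]
    return assignment


def silhouette_scores(
    X: np.ndarray | pd.DataFrame, labels: np.ndarray
) -> tuple[np.ndarray, float]:
    """Silhouette values under cosine distance.

    Standard a(i)/b(i) definition; members of singleton clusters score 0,
    as do points where both a and b vanish. Returns (per-point values,
    mean).
    """
    X = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("silhouette needs at least 2 clusters")
    D = squareform(_cosine_pdist(X), checks=False)
    n = len(X)
    s = np.zeros(n)
    for i in range(n):
        same = (labels == labels[i])
        n_same = same.sum()
        if n_same == 1:
            s[i] = 0.0
            continue
        a = D[i, same].sum() / (n_same - 1)
        b = min(
            D[i, labels == other].mean() for other in uniq if other != labels[i]
        )
        denom = max(a, b)
        s[i] = 0.0 if denom == 0 else (b - a) / denom
    return s, float(s.mean())


def nn_type_distances(
    xy: np.ndarray,
    labels: np.ndarray,
    exclude_types: tuple[str, ...] = ("A",),
) -> pd.DataFrame:
    """Median nearest-neighbour distance between community types.

    For each crypt i and each target type T, d(i, T) is the distance to the
    nearest crypt of type T (excluding i itself). Entry (S, T) of the
    returned matrix is the median of d(i, T) over crypts i of type S. A
    type with a single member has an undefined same-type entry (NaN).
    Types in ``exclude_types`` (the unenriched type by default) are dropped
    before any distance is computed.
    """
    xy = np.asarray(xy, dtype=float).reshape(-1, 2)
    labels = np.asarray(labels, dtype=object)
    if len(xy) != len(labels):
        raise ValueError("positions and labels must align")
    keep = np.array([l not in exclude_types for l in labels])
    xy, labels = xy[keep], labels[keep]
    types = sorted(set(labels.tolist()))
    D = squareform(pdist(xy))
    np.fill_diagonal(D, np.inf)
    out = pd.DataFrame(np.nan, index=types, columns=types, dtype=float)
    for s in types:
        rows = np.flatnonzero(labels == s)
        for t in types:
            cols = np.flatnonzero(labels == t)
            vals = []
            for i in rows:
                d = D[i, cols]
                d = d[np.isfinite(d)]
                if len(d):
                    vals.append(d.min())
            if vals:
                out.loc[s, t] = float(np.median(vals))
    return out


def _same_cross_stat(D: np.ndarray, labels: np.ndarray) -> float:
    """median(same-type NN distance) - median(cross-type NN distance)."""
    same_d, cross_d = [], []
    for i in range(len(labels)):
        same = (labels == labels[i])
        same[i] = False
        cross = labels != labels[i]
        if same.any():
            same_d.append(D[i, same].min())
        if cross.any():
            cross_d.append(D[i, cross].min())
    if not same_d or not cross_d:
        return float("nan")
    return float(np.median(same_d) - np.median(cross_d))


def type_clustering_permutation_test(
    xy: np.ndarray,
    labels: np.ndarray,
    n_permutations: int = 500,
    rng: np.random.Generator | None = None,
    exclude_types: tuple[str, ...] = ("A",),
) -> dict:
    """Label-permutation test for spatial clustering of community types.

    Statistic: median same-type NN distance minus median cross-type NN
    distance (negative when like types sit together). One-sided p-value is
    the fraction of label permutations with a statistic at least as small,
    with the +1 correction.
    """
    if rng is None:
        rng = np.random.default_rng()
    xy = np.asarray(xy, dtype=float).reshape(-1, 2)
    labels = np.asarray(labels, dtype=object)
    keep = np.array([l not in exclude_types for l in labels])
    xy, labels = xy[keep], labels[keep]
    if len(set(labels.tolist())) < 2:
        raise ValueError("need at least 2 types for a permutation test")
    D = squareform(pdist(xy))
    observed = _same_cross_stat(D, labels)
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(labels)
        if _same_cross_stat(D, perm) <= observed:
            count += 1
    p = (count + 1) / (n_permutations + 1)
    return {"statistic": observed, "p_value": p, "n_permutations": n_permutations}
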