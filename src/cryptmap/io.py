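"""File plumbing: TSV tables, YAML configs, JSON ground truth, TIFF volumes."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .qc import ProbeTaxonMatrix
from .synthetic import GroundTruth, SimulationConfig
from .volumes import VoxelVolume

__all__ = [
    "load_config",
    "save_config",
    "read_table",
    "write_table",
    "read_probe_matrix",
    "write_ground_truth",
    "read_ground_truth",
    "write_volume",
    "read_volume",
]

_TSV_KW = dict(sep="\t", index=False, float_format="%.6g")


def load_config(path: str | Path) -> SimulationConfig:
    """SimulationConfig from a YAML (or JSON) mapping of field names."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    if "mixing_matrix" in raw and raw["mixing_matrix"] is not None:
        raw["mixing_matrix"] = np.asarray(raw["mixing_matrix"], dtype=float)
    if "voxel_size" in raw:
        raw["voxel_size"] = tuple(raw["voxel_size"])
    return SimulationConfig(**raw)


def save_config(config: SimulationConfig, path: str | Path) -> None:
    d = dict(config.__dict__)
    if d.get("mixing_matrix") is not None:
        d["mixing_matrix"] = np.asarray(d["mixing_matrix"]).tolist()
    d["voxel_size"] = list(d["voxel_size"])
    d["type_archetypes"] = {k: dict(v) for k, v in d["type_archetypes"].items()}
    d["taxon_depth_means"] = dict(d["taxon_depth_means"])
    d["taxon_depth_sds"] = dict(d["taxon_depth_sds"])
    Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


def read_table(path: str | Path) -> pd.DataFrame:
    # "NA" is a condition label (unexposed), not a missing value
    return pd.read_csv(path, sep="\t", keep_default_na=False,
                       na_values=["", "nan", "NaN"])


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, **_TSV_KW)


def read_probe_matrix(path: str | Path) -> ProbeTaxonMatrix:
    """Probe × taxon TSV with a 'probe' id column and a 'pmp_taxon' column."""
    df = pd.read_csv(path, sep="\t")
    if "probe" not in df.columns or "pmp_taxon" not in df.columns:
        raise ValueError("probe matrix needs 'probe' and 'pmp_taxon' columns")
    pmp = dict(zip(df["probe"], df["pmp_taxon"]))
    values = df.drop(columns=["pmp_taxon"]).set_index("probe")
    return ProbeTaxonMatrix(values=values, pmp=pmp)


def write_ground_truth(gt: GroundTruth, path: str | Path) -> None:
    d = {
        "centers": gt.centers.tolist(),
        "colonized": gt.colonized.astype(int).tolist(),
        "type_labels": [t if t is None else str(t) for t in gt.type_labels],
        "cluster_labels": None if gt.cluster_labels is None else gt.cluster_labels.tolist(),
        "counts": None if gt.counts is None else gt.counts.to_dict(orient="list"),
        "depths": None
        if gt.depths is None
        else {c: [None if not np.isfinite(v) else v for v in gt.depths[c]] for c in gt.depths},
        "clipped_blobs": gt.clipped_blobs,
    }
    if gt.objects is not None:
        d["objects"] = {t: [v.tolist() for v in vs] for t, vs in gt.objects.items()}
        d["object_crypts"] = gt.object_crypts
    Path(path).write_text(json.dumps(d))


def read_ground_truth(path: str | Path) -> GroundTruth:
    d = json.loads(Path(path).read_text())
    counts = None if d["counts"] is None else pd.DataFrame(d["counts"])
    depths = None
    if d["depths"] is not None:
        depths = pd.DataFrame(
            {c: [np.nan if v is None else v for v in vs] for c, vs in d["depths"].items()}
        )
    gt = GroundTruth(
        centers=np.asarray(d["centers"], dtype=float),
        colonized=np.asarray(d["colonized"], dtype=bool),
        type_labels=np.asarray(d["type_labels"], dtype=object),
        counts=counts,
        depths=depths,
        cluster_labels=None
        if d["cluster_labels"] is None
        else np.asarray(d["cluster_labels"], dtype=int),
        clipped_blobs=d.get("clipped_blobs", 0),
    )
    if "objects" in d:
        gt.objects = {
            t: [np.asarray(v, dtype=int) for v in vs] for t, vs in d["objects"].items()
        }
        gt.object_crypts = d.get("object_crypts")
    return gt


def write_volume(volume: VoxelVolume, path: str | Path) -> None:
    """Channel-first TIFF with voxel size and channel names in metadata."""
    meta = {
        "axes": "CZYX",
        "voxel_size_um": list(volume.voxel_size),
        "channel_names": list(volume.channel_names),
        "origin_um": list(volume.origin),
    }
    tifffile.imwrite(
        path,
        volume.data.astype(np.float32),
        photometric="minisblack",
        metadata=meta,
    )


def read_volume(
    path: str | Path,
    voxel_size: tuple[float, float, float] | None = None,
    channel_names: list[str] | None = None,
) -> VoxelVolume:
    """Read a channel-first TIFF volume; CLI flags override metadata."""
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
    if data.ndim == 3:
        data = data[None]
    vs = voxel_size or tuple(meta.get("voxel_size_um", (1.0, 1.0, 1.0)))
    names = channel_names or list(
        meta.get("channel_names", [f"ch{i}" for i in range(data.shape[0])])
    )
    origin = tuple(meta.get("origin_um", (0.0, 0.0, 0.0)))
    return VoxelVolume(data=data, voxel_size=vs, channel_names=names, origin=origin)
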