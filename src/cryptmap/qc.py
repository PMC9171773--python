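"""Staining quality control.

Sensitivity of amplified in situ staining from gel-slab experiments,
signal-to-background ECDFs, and selection of an orthogonal probe set from
a probe × taxon tagging matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ProbeTaxonMatrix",
    "Ecdf",
    "sensitivity",
    "ratio_ecdf",
    "select_probe_set",
]


def sensitivity(
    records: pd.DataFrame,
    ratio_threshold: float = 20.0,
    depth_max: float = 600.0,
) -> float:
    """Fraction of reference-detected cells with S/B ratio >= threshold.

    Only cells at depth <= ``depth_max`` and flagged as detected by the
    reference stain are eligible; raises if none are.
    """
    eligible = records[
        (records["depth_um"] <= depth_max) & records["reference_detected"]
    ]
    if len(eligible) == 0:
        raise ValueError("no eligible cells (depth filter / reference stain)")
    ratio = eligible["hcr_signal"] / eligible["background"]
    return float((ratio >= ratio_threshold).mean())


class Ecdf:
    """Right-continuous empirical CDF, evaluable at arbitrary points."""

    def __init__(self, values) -> None:
        values = np.asarray(values, dtype=float).ravel()
        if len(values) == 0:
            raise ValueError("ECDF needs at least one value")
        self.x = np.sort(values)
        self.n = len(self.x)

    def __call__(self, q):
        q = np.asarray(q, dtype=float)
        out = np.searchsorted(self.x, q, side="right") / self.n
        return float(out) if out.ndim == 0 else out

    def steps(self) -> pd.DataFrame:
        """The step points (x, F(x)) as a table for plotting/export."""
        return pd.DataFrame({"value": self.x, "cdf": np.arange(1, self.n + 1) / self.n})


def ratio_ecdf(records: pd.DataFrame | np.ndarray) -> Ecdf:
    """ECDF of signal-to-background ratios.

    Accepts a stain-record table (uses hcr_signal/background) or a bare
    array of ratios.
    """
    if isinstance(records, pd.DataFrame):
        vals = (records["hcr_signal"] / records["background"]).to_numpy()
    else:
        vals = np.asarray(records, dtype=float)
    return Ecdf(vals)


@dataclass
class ProbeTaxonMatrix:
    """Percent of cells tagged, probes × taxa, with designated PMPs.

    ``pmp`` maps each probe (row) to the taxon (column) with which it is
    perfectly homologous.
    """

    values: pd.DataFrame                 # rows = probes, cols = taxa, percent
    pmp: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = self.values.to_numpy(dtype=float)
        if np.any((v < 0) | (v > 100)):
            raise ValueError("tagging percentages must lie in [0, 100]")
        for probe in self.values.index:
            taxon = self.pmp.get(probe)
            if taxon is None or taxon not in self.values.columns:
                raise ValueError(f"probe {probe!r} lacks a valid PMP designation")

    def off_targets(self, probe: str) -> pd.Series:
        row = self.values.loc[probe]
        return row.drop(self.pmp[probe])


def select_probe_set(
    matrix: ProbeTaxonMatrix,
    pmp_min: float = 84.0,
    offtarget_max: float = 5.0,
    exceptions: set[tuple[str, str]] | None = None,
    required_taxa: list[str] | None = None,
) -> dict:
    """Select one admissible probe per target taxon.

    A probe is admissible iff its PMP entry >= ``pmp_min`` and every
    off-target entry <= ``offtarget_max``, except for explicitly documented
    (probe, taxon) exceptions (small known cross-reactions). When several
    admissible probes share a PMP taxon, the one with the smaller maximum
    off-target wins. Raises if any required taxon ends up uncovered,
    listing the failing entries.
    """
    if not (0 <= pmp_min <= 100 and 0 <= offtarget_max <= 100):
        raise ValueError("thresholds must be percentages in [0, 100]")
    exceptions = exceptions or set()
    admissible: dict[str, dict] = {}
    rejected: dict[str, list[str]] = {}
    for probe in matrix.values.index:
        taxon = matrix.pmp[probe]
        reasons = []
        pmp_val = float(matrix.values.loc[probe, taxon])
        if pmp_val < pmp_min:
            reasons.append(f"PMP {taxon}={pmp_val:g}% < {pmp_min:g}%")
        offs = matrix.off_targets(probe)
        bad = offs[(offs > offtarget_max)]
        bad = bad[[t not in {e[1] for e in exceptions if e[0] == probe} for t in bad.index]]
        for t, v in bad.items():
            reasons.append(f"off-target {t}={v:g}% > {offtarget_max:g}%")
        if reasons:
            rejected[probe] = reasons
        else:
            admissible[probe] = {
                "pmp_taxon": taxon,
                "pmp_percent": pmp_val,
                "max_offtarget": float(offs.max()) if len(offs) else 0.0,
                "exceptions_applied": sorted(
                    t for (p, t) in exceptions if p == probe and t in offs.index
                    and offs[t] > offtarget_max
                ),
            }
    selected: dict[str, str] = {}
    for probe, info in sorted(admissible.items()):
        taxon = info["pmp_taxon"]
        cur = selected.get(taxon)
        if cur is None or info["max_offtarget"] < admissible[cur]["max_offtarget"]:
            selected[taxon] = probe
    required = required_taxa if required_taxa is not None else sorted(
        set(matrix.pmp.values())
    )
    missing = [t for t in required if t not in selected]
    if missing:
        detail = {
            probe: reasons
            for probe, reasons in rejected.items()
            if matrix.pmp[probe] in missing
        }
        raise ValueError(
            f"no admissible probe for taxa {missing}; failing entries: {detail}"
        )
    return {
        "selected": selected,
        "admissible": admissible,
        "rejected": rejected,
        "pmp_min": pmp_min,
        "offtarget_max": offtarget_max,
    }
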