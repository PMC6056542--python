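"""Reporter-assay quantification: delta-FU with the not-detected rule, and
relative activity versus a wild-type control.

Fluorescence units are read at OD600 = 1 under induced and uninduced
conditions; the promoter signal is deltaFU = FU_induced - FU_uninduced.
A measurement is "not detected" (ND) when deltaFU is negative or zero, or
when the replicate standard deviation of deltaFU exceeds deltaFU itself.
No arithmetic is ever performed on ND values: they propagate.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

ND_REASONS = ("none", "negative_or_zero", "sd_exceeds")


@dataclass(frozen=True)
class ReporterMeasurement:
    """Induced/uninduced fluorescence at OD600 = 1 with replicate SD of deltaFU."""

    strain_label: str
    fu_induced: float
    fu_uninduced: float
    sd: float
    n_replicates: int = 3

    def __post_init__(self) -> None:
        if self.fu_induced < 0 or self.fu_uninduced < 0:
            raise ValueError(f"{self.strain_label}: fluorescence must be >= 0")
        if self.sd < 0:
            raise ValueError(f"{self.strain_label}: negative sd")
        if self.n_replicates < 1:
            raise ValueError(f"{self.strain_label}: n_replicates must be >= 1")


@dataclass(frozen=True)
class DeltaFUResult:
    """deltaFU value or the ND sentinel (``delta_fu is None``)."""

    delta_fu: Optional[float]
    nd_reason: str = "none"

    def __post_init__(self) -> None:
        if self.nd_reason not in ND_REASONS:
            raise ValueError(f"unknown nd_reason: {self.nd_reason!r}")
        if (self.delta_fu is None) != (self.nd_reason != "none"):
            raise ValueError("delta_fu is ND exactly when nd_reason is set")

    @property
    def is_nd(self) -> bool:
        return self.delta_fu is None


def delta_fu(m: ReporterMeasurement) -> DeltaFUResult:
    """deltaFU = FU_induced - FU_uninduced, with the ND rule.

    ND when deltaFU <= 0 (both the negative and the zero case), or when the
    replicate SD exceeds deltaFU.
    """
    d = m.fu_induced - m.fu_uninduced
    if d <= 0:
        return DeltaFUResult(None, "negative_or_zero")
    if m.sd > d:
        return DeltaFUResult(None, "sd_exceeds")
    return DeltaFUResult(d)


def relative_activity(mutant: DeltaFUResult, wildtype: DeltaFUResult) -> Optional[float]:
    """Promoter activity as a percentage of the wild-type control (100%).

    Ratio of condition means: 100 * deltaFU_mutant / deltaFU_wildtype.
    An ND mutant propagates as None; an ND (or non-positive) wild type is an
    error because the reference point is undefined.
    """
    if wildtype.is_nd or wildtype.delta_fu <= 0:
        raise ValueError("wild-type deltaFU is ND or non-positive")
    if mutant.is_nd:
        return None
    return 100.0 * mutant.delta_fu / wildtype.delta_fu


def read_measurements(path: str | os.PathLike) -> list[ReporterMeasurement]:
    """Read a TSV with columns strain_label, fu_induced, fu_uninduced, sd[, n]."""
    df = pd.read_csv(path, sep="\t")
    required = {"strain_label", "fu_induced", "fu_uninduced", "sd"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"measurement TSV missing columns: {sorted(missing)}")
    out = []
    for row in df.itertuples():
        out.append(
            ReporterMeasurement(
                strain_label=str(row.strain_label),
                fu_induced=float(row.fu_induced),
                fu_uninduced=float(row.fu_uninduced),
                sd=float(row.sd),
                n_replicates=int(getattr(row, "n", 3)),
            )
        )
    return out


def results_table(
    measurements: Sequence[ReporterMeasurement], wildtype_label: Optional[str] = None
) -> pd.DataFrame:
    """deltaFU/ND table, plus a relative-activity column when a wild-type
    row is named.  ND entries are written as the string ``ND``."""
    results = {m.strain_label: delta_fu(m) for m in measurements}
    wt = None
    if wildtype_label is not None:
        if wildtype_label not in results:
            raise ValueError(f"wild-type row {wildtype_label!r} not found")
        wt = results[wildtype_label]
    rows = []
    for m in measurements:
        res = results[m.strain_label]
        row = {
            "strain_label": m.strain_label,
            "delta_fu": "ND" if res.is_nd else res.delta_fu,
            "nd_reason": res.nd_reason,
        }
        if wt is not None:
            rel = relative_activity(res, wt)
            row["relative_activity_pct"] = "ND" if rel is None else rel
        rows.append(row)
    return pd.DataFrame(rows)


def write_results(
    measurements: Sequence[ReporterMeasurement],
    path: str | os.PathLike,
    wildtype_label: Optional[str] = None,
) -> None:
    results_table(measurements, wildtype_label).to_csv(path, sep="\t", index=False)
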