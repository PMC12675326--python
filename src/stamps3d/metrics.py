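"""Regional reduction of strain/pressure fields to study metrics.

The study's measures of interest are, per trial, the regional *peak*
values (maximum valid node per region, plus a global maximum), reduced
across the repeated-measures design as medians: per participant the
median across repeats, across the cohort the median (and 25th-75th IQR)
of those per-participant medians.  Repeatability is the coefficient of
variation across a participant's repeats, summarised as the median CV
per condition.

Peaks default to the single maximum node; a percentile-peak option
exists for robustness studies but is off by default.  The CV uses the
sample (n-1) standard deviation — material at three repeats.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import EmptyStrainField
from .mask import RegionAssignment
from .regions import ALL_LABELS, GLOBAL, REGIONS
from .strain import StrainField

__all__ = [
    "TrialRecord",
    "regional_peaks",
    "build_study_table",
    "summarize_medians",
    "repeatability_cv",
]


@dataclass
class TrialRecord:
    """Regional peak measures for one participant x condition x repeat."""

    participant: str
    condition: str
    repeat: int
    peaks_pct: Mapping[str, float]
    ppp_kpa: Mapping[str, float] = dc_field(default_factory=dict)
    invalid_fraction: Mapping[str, float] = dc_field(default_factory=dict)

    def __post_init__(self):
        if self.repeat < 1:
            raise ValueError("repeat index must be >= 1")
        bad = set(self.peaks_pct) - set(ALL_LABELS)
        if bad:
            raise ValueError(f"unknown region labels: {sorted(bad)}")
        for v in self.peaks_pct.values():
            if np.isfinite(v) and v < 0:
                raise ValueError("peaks must be >= 0")


def regional_peaks(strain: StrainField, assignment: RegionAssignment,
                   value: str = "S_MAG",
                   percentile: float | None = None) -> dict[str, float]:
    """Per-region peak of a strain measure over valid nodes.

    ``global`` is the maximum over all valid nodes.  Regions containing
    no valid node are reported as NaN (missing) — never zero.  With
    ``percentile`` set, the peak becomes that percentile of the region's
    node values instead of the maximum.
    """
    vals = np.asarray(getattr(strain, value), dtype=float)
    valid = strain.valid & np.isfinite(vals)
    if not valid.any():
        raise EmptyStrainField("no valid nodes")
    labels = assignment.labels

    def peak(x):
        return float(np.percentile(x, percentile)) if percentile is not None \
            else float(np.max(x))

    out: dict[str, float] = {}
    for region in REGIONS:
        sel = valid & (labels == region)
        out[region] = peak(vals[sel]) if sel.any() else float("nan")
    out[GLOBAL] = peak(vals[valid & (labels != "outside")])
    return out


def region_invalid_fractions(strain: StrainField,
                             assignment: RegionAssignment) -> dict[str, float]:
    """Fraction of each region's nodes that failed correlation/strain fitting."""
    labels = assignment.labels
    out = {}
    for region in REGIONS:
        sel = labels == region
        out[region] = float(1.0 - strain.valid[sel].mean()) if sel.any() else float("nan")
    inside = labels != "outside"
    out[GLOBAL] = float(1.0 - strain.valid[inside].mean()) if inside.any() else float("nan")
    return out


def build_study_table(records: list[TrialRecord]) -> pd.DataFrame:
    """Assemble trial records into the long-format study table.

    One row per participant x condition x repeat x region; duplicate
    trial keys are rejected.
    """
    keys = [(r.participant, r.condition, r.repeat) for r in records]
    if len(set(keys)) != len(keys):
        raise ValueError("duplicate participant/condition/repeat records")
    rows = []
    for r in records:
        for region, v in r.peaks_pct.items():
            rows.append((r.participant, r.condition, r.repeat, region, v,
                         r.ppp_kpa.get(region, np.nan),
                         r.invalid_fraction.get(region, np.nan)))
    return pd.DataFrame(rows, columns=["participant", "condition", "repeat",
                                       "region", "peak_smag_pct", "ppp_kpa",
                                       "invalid_fraction"])


def _participant_medians(table: pd.DataFrame, value_col: str) -> pd.DataFrame:
    return (table.dropna(subset=[value_col])
            .groupby(["region", "condition", "participant"], sort=False)[value_col]
            .median().reset_index())


def summarize_medians(table: pd.DataFrame, value_col: str = "peak_smag_pct",
                      pooled: bool = False) -> pd.DataFrame:
    """Cohort summary per region x condition: median and IQR.

    Two-stage by default: median across each participant's repeats, then
    the median and 25th-75th percentile range of those per-participant
    medians.  ``pooled=True`` instead pools every repeat of every
    participant into one sample.  Cells with no data propagate as NaN
    with a zero count.
    """
    if pooled:
        per = table.dropna(subset=[value_col]).rename(columns={value_col: "val"})
    else:
        per = _participant_medians(table, value_col).rename(columns={value_col: "val"})
    g = per.groupby(["region", "condition"], sort=False)["val"]
    out = g.agg(median="median",
                iqr_lo=lambda x: x.quantile(0.25),
                iqr_hi=lambda x: x.quantile(0.75),
                n="count").reset_index()
    # preserve the full region x condition grid, missing cells as NaN
    regions = [r for r in list(ALL_LABELS) if r in set(table.region)]
    conditions = list(dict.fromkeys(table.condition))
    grid = pd.MultiIndex.from_product([regions, conditions],
                                      names=["region", "condition"]).to_frame(index=False)
    out = grid.merge(out, on=["region", "condition"], how="left")
    out["n"] = out["n"].fillna(0).astype(int)
    return out


def repeatability_cv(table: pd.DataFrame, value_col: str = "peak_smag_pct"):
    """Coefficient of variation across repeats, and its per-condition median.

    CV = 100 * sample SD / mean over one participant/condition/region's
    repeats.  Cells with zero mean or fewer than two repeats are reported
    missing.  Returns ``(cell_cv, condition_median_cv)`` where the second
    is the median CV across all participants and regions per condition.
    """
    def cv(x):
        x = x.dropna()
        if len(x) < 2 or x.mean() == 0:
            return np.nan
        return 100.0 * x.std(ddof=1) / x.mean()

    cell = (table.groupby(["condition", "region", "participant"], sort=False)[value_col]
            .apply(cv).rename("cv_pct").reset_index())
    cond = cell.groupby("condition", sort=False)["cv_pct"].median()
    return cell, cond
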