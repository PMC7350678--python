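"""Replicate-performance quality control.

For every metabolite, the relative fold change of each replicate against the
arithmetic mean of the non-missing replicates of the same condition is
computed:

    f(m, s) = I(m, s) / mean_{s' in condition(s)} I(m, s')

With this denominator the fold changes of a complete condition average to
exactly 1 per metabolite, so when replicates perform comparably the per-sample
means of all metabolites' fold changes are centred around 1. Samples whose
mean deviates by more than a configurable factor (default 2-fold, on a log2
scale) are flagged as candidates for removal. Missing intensities contribute
no fold change at all — they are excluded from both numerator rows and the
denominator mean, never zero-filled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .sample_design import SampleDesign
from .table_io import MeasurementTable


@dataclass
class QCReport:
    fold_changes: pd.DataFrame  # compound, sample_id, condition, fold_change
    per_sample_mean: pd.Series  # sample_id -> mean fold change
    flagged_samples: list[str] = field(default_factory=list)


def replicate_fold_changes(table: MeasurementTable, design: SampleDesign) -> QCReport:
    """Compute per-metabolite relative fold changes within conditions.

    Conditions with a single replicate are skipped with a warning; at least
    one condition must have two or more replicates.
    """
    meta = design.frame.set_index("sample_id")["condition"]
    counts = design.replicates_per_condition()
    singles = list(counts.index[counts < 2])
    if singles:
        warnings.warn(
            f"conditions with a single replicate are skipped in QC: {singles}",
            stacklevel=2,
        )
    usable = set(counts.index[counts >= 2])
    if not usable:
        raise ValidationError("QC needs at least one condition with >= 2 replicates")

    data = table.data.copy()
    data["condition"] = data["sample_id"].map(meta)
    data = data[data["condition"].isin(usable)]
    data = data.dropna(subset=["intensity"])

    denom = data.groupby(["compound", "condition"], sort=False)["intensity"].transform("mean")
    with np.errstate(divide="ignore", invalid="ignore"):
        data = data.assign(fold_change=data["intensity"] / denom)
    data = data[np.isfinite(data["fold_change"])]

    fold = data[["compound", "sample_id", "condition", "fold_change"]].reset_index(drop=True)
    per_sample = fold.groupby("sample_id", sort=False)["fold_change"].mean()
    per_sample = per_sample.reindex([s for s in table.samples if s in set(fold["sample_id"])])
    return QCReport(fold, per_sample)


def flag_outlier_samples(report: QCReport, tolerance: float = 2.0) -> list[str]:
    """Flag samples whose mean fold change deviates more than ``tolerance``-fold
    from 1 (symmetric on a log2 scale). The report's flagged list is updated."""
    if tolerance <= 1 and np.isfinite(tolerance):
        raise ValidationError("tolerance must be > 1 (a fold-change factor)")
    if not np.isfinite(tolerance):
        report.flagged_samples = []
        return []
    limit = np.log2(tolerance)
    means = report.per_sample_mean
    flagged = list(means.index[np.abs(np.log2(means)) > limit])
    report.flagged_samples = flagged
    return flagged
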