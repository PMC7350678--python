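"""Intensity normalisation: external correction (cell counts / protein),
internal-standard normalisation, and Total Peak Sum.

Each strategy computes a per-sample factor c_s and applies it in one of two
modes:

absolute
    I' = I / c_s — changes the dimension of the intensities (e.g. "peak area
    per million cells").
relative
    I' = (I / c_s) * mean(c) — the arithmetic mean of the factors over all
    included samples; intensities keep their dimension and the samples are
    brought to comparable levels.

Missing values stay missing under every normalisation; they are never
rescaled to zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

from .errors import ValidationError
from .sample_design import SampleDesign
from .table_io import MeasurementTable

MODES = ("off", "absolute", "relative")


@dataclass(frozen=True)
class NormalisationConfig:
    external_mode: str = "off"
    internal_mode: str = "off"
    internal_standards: tuple[str, ...] = ()
    internal_timing: str = "before_external"  # or "after_external"
    total_peak_sum: bool = False
    total_peak_sum_mode: str = "relative"

    def __post_init__(self) -> None:
        for mode in (self.external_mode, self.internal_mode):
            if mode not in MODES:
                raise ValidationError(f"normalisation mode {mode!r} not in {MODES}")
        if self.internal_timing not in ("before_external", "after_external"):
            raise ValidationError(f"bad internal_timing {self.internal_timing!r}")
        if (self.internal_mode != "off") != bool(self.internal_standards):
            raise ValidationError(
                "internal standards must be given exactly when internal "
                "normalisation is enabled"
            )
        if self.total_peak_sum and self.internal_mode != "off":
            raise ValidationError(
                "Total Peak Sum and internal-standard normalisation are "
                "mutually exclusive"
            )


def _apply_factors(table: MeasurementTable, factors: pd.Series, mode: str
                   ) -> MeasurementTable:
    if mode == "off":
        return table
    if (factors <= 0).any() or factors.isna().any():
        bad = sorted(factors.index[(factors <= 0) | factors.isna()])
        raise ValidationError(f"non-positive or missing normalisation factor for {bad}")
    out = table.copy()
    scale = out.data["sample_id"].map(factors)
    if scale.isna().any():
        bad = sorted(out.data.loc[scale.isna(), "sample_id"].unique())
        raise ValidationError(f"no normalisation factor for samples {bad}")
    out.data["intensity"] = out.data["intensity"] / scale
    if mode == "relative":
        out.data["intensity"] = out.data["intensity"] * factors.mean()
    elif mode != "absolute":
        raise ValidationError(f"unknown normalisation mode {mode!r}")
    return out


def external_correct(table: MeasurementTable, design: SampleDesign, mode: str
                     ) -> MeasurementTable:
    """Divide intensities by the per-sample correction value from the sample
    table (absolute), optionally rescaling by the mean correction value
    (relative)."""
    if mode == "off":
        return table
    factors = design.frame.set_index("sample_id")["correction_value"]
    if factors.isna().any():
        bad = sorted(factors.index[factors.isna()])
        raise ValidationError(f"correction value missing for samples {bad}")
    factors = factors.astype(float)
    return _apply_factors(table, factors.loc[factors.index.intersection(
        table.samples)].reindex(table.samples), mode)


def internal_correct(table: MeasurementTable, standards, mode: str
                     ) -> MeasurementTable:
    """Normalise by the per-sample sum of the selected internal standards.

    Multiple standards are summed, so the factor is dominated by the abundant
    ones. A standard missing in a sample contributes nothing to that sample's
    sum (with a warning); a sample where every standard is missing is a hard
    error. The standards stay in the table and are normalised too.
    """
    if mode == "off":
        return table
    standards = list(standards)
    present = set(table.compounds)
    absent = [s for s in standards if s not in present]
    if absent:
        raise ValidationError(f"internal standards not found in the data: {absent}")
    rows = table.data[table.data["compound"].isin(standards)]
    if rows["intensity"].isna().any():
        gone = sorted(rows.loc[rows["intensity"].isna(), "sample_id"].unique())
        warnings.warn(
            f"internal standard missing in samples {gone}; it contributes 0 to "
            "their normalisation sum", stacklevel=2,
        )
    factors = rows.groupby("sample_id")["intensity"].sum(min_count=1)
    factors = factors.reindex(table.samples)
    empty = factors.index[factors.isna()]
    if len(empty):
        raise ValidationError(
            f"every internal standard is missing in samples {sorted(empty)}"
        )
    return _apply_factors(table, factors, mode)


def total_peak_sum(table: MeasurementTable, mode: str) -> MeasurementTable:
    """Normalise by the per-sample sum over all compounds of the non-missing
    intensities ("Total Peak Sum")."""
    if mode == "off":
        return table
    factors = table.data.groupby("sample_id")["intensity"].sum(min_count=1)
    factors = factors.reindex(table.samples)
    empty = factors.index[factors.isna()]
    if len(empty):
        raise ValidationError(f"samples with no measured intensity at all: {sorted(empty)}")
    return _apply_factors(table, factors, mode)


def apply_normalisation(table: MeasurementTable, design: SampleDesign,
                        config: NormalisationConfig) -> MeasurementTable:
    """Run the configured corrections in the configured order."""
    steps = []
    internal = ("internal", lambda t: internal_correct(
        t, config.internal_standards, config.internal_mode))
    external = ("external", lambda t: external_correct(
        t, design, config.external_mode))
    if config.internal_timing == "before_external":
        steps += [internal, external]
    else:
        steps += [external, internal]
    if config.total_peak_sum:
        steps.append(("total_peak_sum",
                      lambda t: total_peak_sum(t, config.total_peak_sum_mode)))
    for _, step in steps:
        table = step(table)
    return table
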