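"""Stable-isotope tracing support: isotopologue label parsing, grouping, and
mass isotopomer distributions (MIDs).

Isotopologues are supplied in the compound names as a trailing suffix of the
form ``"<name> +<n>"`` — e.g. ``"Lactate +3"`` for the species of lactate with
a mass shift of 3 Da. An unsuffixed name is the unlabelled species M+0. Only a
trailing ``" +<integer>"`` is consumed, so names with internal plus signs
(``"NAD+ +5"``) keep them. Mass shifts up to M+30 are accepted.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .table_io import MeasurementTable

MAX_SHIFT = 30

_SUFFIX_RE = re.compile(r"^(?P<base>.*\S)\s\+(?P<shift>\d+)$")


def parse_isotopologue_label(label: str) -> tuple[str, int]:
    """Split a compound label into (base name, mass shift).

    ``"Glucose +6"`` -> ``("Glucose", 6)``; a label without the trailing
    suffix is the unlabelled species, shift 0. Shifts beyond M+30 are a hard
    error.
    """
    match = _SUFFIX_RE.match(str(label))
    if not match:
        return str(label), 0
    shift = int(match.group("shift"))
    if shift > MAX_SHIFT:
        raise ValidationError(
            f"isotopologue shift +{shift} in {label!r} exceeds the M+{MAX_SHIFT} limit"
        )
    return match.group("base"), shift


@dataclass
class IsotopologueGroup:
    """One base compound with its isotopologue intensities.

    ``intensities`` is a long frame (sample_id, shift, intensity); shifts not
    present in the data are simply absent (not zero-filled).
    """

    base_compound: str
    intensities: pd.DataFrame

    @property
    def max_shift(self) -> int:
        return int(self.intensities["shift"].max())

    @property
    def shifts(self) -> list[int]:
        return sorted(self.intensities["shift"].unique())

    @property
    def samples(self) -> list[str]:
        return list(dict.fromkeys(self.intensities["sample_id"]))

    def vector(self, sample_id: str, length: int | None = None) -> np.ndarray:
        """Dense intensity vector over shifts 0..length-1 for one sample;
        shifts absent from the data and missing values appear as NaN."""
        length = (self.max_shift + 1) if length is None else length
        out = np.full(length, np.nan)
        rows = self.intensities[self.intensities["sample_id"] == sample_id]
        out[rows["shift"].to_numpy()] = rows["intensity"].to_numpy()
        return out


def group_isotopologues(table: MeasurementTable) -> list[IsotopologueGroup]:
    """Group records into one IsotopologueGroup per base compound.

    Grouping is a lossless partition of the records: flattening the groups
    recovers the original (compound, sample, intensity) set.
    """
    parsed = [parse_isotopologue_label(c) for c in table.data["compound"]]
    data = table.data.assign(
        base=[b for b, _ in parsed], shift=[s for _, s in parsed]
    )
    dup = data.duplicated(subset=["base", "shift", "sample_id"])
    if dup.any():
        bad = sorted(
            (data.loc[dup, "base"] + " +" + data.loc[dup, "shift"].astype(str)).unique()
        )
        raise ValidationError(f"duplicate isotopologue records for: {bad}")
    groups = []
    for base, rows in data.groupby("base", sort=False):
        groups.append(
            IsotopologueGroup(
                base,
                rows[["sample_id", "shift", "intensity"]].reset_index(drop=True),
            )
        )
    return groups


def relative_mid(group: IsotopologueGroup, sample_id: str) -> np.ndarray:
    """Fractional MID for one sample: intensity / sum of non-missing
    intensities, with missing isotopologues contributing 0.

    Raises when every isotopologue is missing for the sample (the MID is
    undefined; the caller drops the sample from relative plots with a
    warning). The returned vector spans shifts 0..max_shift and sums to 1.
    """
    vec = group.vector(sample_id)
    if np.isnan(vec).all():
        raise ValidationError(
            f"all isotopologues of {group.base_compound!r} are missing in "
            f"sample {sample_id!r}; relative MID undefined"
        )
    filled = np.nan_to_num(vec, nan=0.0)
    total = filled.sum()
    if total == 0:
        raise ValidationError(
            f"zero total intensity for {group.base_compound!r} in sample "
            f"{sample_id!r}; relative MID undefined"
        )
    return filled / total


def tracing_tables(groups: list[IsotopologueGroup]) -> pd.DataFrame:
    """Long export frame (base, shift, sample, intensity, fraction); the
    fraction is NaN wherever the sample's MID is undefined."""
    frames = []
    for group in groups:
        rows = group.intensities.copy()
        rows.insert(0, "compound", group.base_compound)
        totals = rows.dropna(subset=["intensity"]).groupby("sample_id")["intensity"].sum()
        rows["fraction"] = (
            rows["intensity"].fillna(0.0)
            / rows["sample_id"].map(totals)
        )
        rows.loc[rows["intensity"].isna() & rows["sample_id"].map(totals).isna(),
                 "fraction"] = np.nan
        frames.append(rows)
    return pd.concat(frames, ignore_index=True)[
        ["compound", "shift", "sample_id", "intensity", "fraction"]
    ]
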