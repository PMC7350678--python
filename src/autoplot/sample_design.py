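"""Sample-table template generation, loading and replicate averaging.

The sample table maps each measured file (sample id) to the condition it
belongs to, the display order and colour of that condition on plots, optional
experimental (biological) and technical (measurement) replicate labels, an
optional external correction value (cell count, protein amount, ...) and an
include flag. Colours may be given in hex notation (``#FFAA25``) or as one of
the standard R colour names, resolved through a bundled name-to-hex table.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .table_io import MeasurementTable

#: Bit-exact template headers (documented in the README).
TEMPLATE_COLUMNS = (
    "sample_id",
    "condition",
    "order",
    "colour",
    "experimental_replicate",
    "technical_replicate",
    "correction_value",
    "include",
)

_HEX_RE = re.compile(r"^#[0-9A-Fa-f]{6}([0-9A-Fa-f]{2})?$")


@lru_cache(maxsize=1)
def r_colour_map() -> dict[str, str]:
    """Standard R colour names -> hex, from the bundled static table."""
    with resources.files("autoplot").joinpath("data/r_colours.csv").open() as fh:
        frame = pd.read_csv(fh)
    return dict(zip(frame["name"].str.lower(), frame["hex"]))


def resolve_colour(value: str) -> str:
    """Accept '#RRGGBB' hex as-is; resolve R colour names via the bundled map."""
    value = str(value).strip()
    if _HEX_RE.match(value):
        return value.upper()
    hexval = r_colour_map().get(value.lower())
    if hexval is None:
        raise ValidationError(
            f"unknown colour {value!r}: use hex notation (e.g. #FFAA25) "
            "or a standard R colour name"
        )
    return hexval


@dataclass
class SampleDesign:
    """Validated per-sample annotations, one row per included sample.

    ``frame`` columns follow TEMPLATE_COLUMNS; rows with include=False have
    already been dropped. Condition display order is the rank given in the
    ``order`` column (ties broken by first appearance).
    """

    frame: pd.DataFrame

    @property
    def samples(self) -> list[str]:
        return list(self.frame["sample_id"])

    @property
    def conditions(self) -> list[str]:
        """Conditions in display order."""
        firsts = (
            self.frame.reset_index(drop=True)
            .groupby("condition", sort=False)
            .agg(order=("order", "min"), appear=("condition", lambda s: s.index[0]))
        )
        return list(firsts.sort_values(["order", "appear"]).index)

    def condition_of(self, sample_id: str) -> str:
        row = self.frame.loc[self.frame["sample_id"] == sample_id]
        if row.empty:
            raise ValidationError(f"sample {sample_id!r} is not in the design")
        return row["condition"].iloc[0]

    @property
    def colours(self) -> dict[str, str | None]:
        """Condition -> explicit colour (first one given), or None."""
        out: dict[str, str | None] = {}
        for cond in self.conditions:
            vals = self.frame.loc[self.frame["condition"] == cond, "colour"].dropna()
            out[cond] = vals.iloc[0] if len(vals) else None
        return out

    @property
    def has_replicate_levels(self) -> bool:
        return (
            self.frame["experimental_replicate"].notna().all()
            and self.frame["technical_replicate"].notna().all()
        )

    def replicates_per_condition(self) -> pd.Series:
        return self.frame.groupby("condition", sort=False)["sample_id"].count()


def make_template(table: MeasurementTable, path) -> Path:
    """Write a sample-table template with one row per sample, in input order.

    The condition column is left blank for the user to fill in; order defaults
    to the sample's position and include to True.
    """
    path = Path(path)
    samples = table.samples
    frame = pd.DataFrame(
        {
            "sample_id": samples,
            "condition": ["" for _ in samples],
            "order": range(1, len(samples) + 1),
            "colour": ["" for _ in samples],
            "experimental_replicate": ["" for _ in samples],
            "technical_replicate": ["" for _ in samples],
            "correction_value": ["" for _ in samples],
            "include": [True for _ in samples],
        }
    )
    if path.suffix.lower() in (".xls", ".xlsx"):
        frame.to_excel(path, index=False)
    else:
        frame.to_csv(path, index=False)
    return path


_TRUTHY = {"true", "1", "yes", "y", "t"}
_FALSY = {"false", "0", "no", "n", "f"}


def _parse_bool(value, default=True) -> bool:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return default
    if isinstance(value, bool):
        return value
    text = str(value).strip().lower()
    if text == "":
        return default
    if text in _TRUTHY:
        return True
    if text in _FALSY:
        return False
    raise ValidationError(f"include flag {value!r} is not a recognised boolean")


def _optional_text(value):
    if value is None:
        return None
    text = str(value).strip()
    if text == "" or text.lower() in ("nan", "na"):
        return None
    # keep integer-looking replicate ids tidy ("1.0" from Excel -> "1")
    if re.fullmatch(r"\d+\.0", text):
        text = text[:-2]
    return text


def load_design(path, table: MeasurementTable) -> SampleDesign:
    """Read the user-edited sample table and validate it against the data.

    Hard errors: a data sample missing from the design, an empty condition,
    an unknown colour, a non-positive correction value, or partially filled
    replicate columns. A design row for a sample absent from the data only
    warns (it is ignored).
    """
    path = Path(path)
    if path.suffix.lower() in (".xls", ".xlsx"):
        raw = pd.read_excel(path, sheet_name=0, dtype=object)
    else:
        raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    raw.columns = [str(c).strip().lower() for c in raw.columns]
    missing_cols = [c for c in TEMPLATE_COLUMNS if c not in raw.columns]
    if missing_cols:
        raise ValidationError(f"sample table is missing columns: {missing_cols}")

    rows = []
    for _, row in raw.iterrows():
        sample_id = str(row["sample_id"]).strip()
        include = _parse_bool(row["include"])
        condition = _optional_text(row["condition"])
        if include and condition is None:
            raise ValidationError(f"condition missing for sample {sample_id!r}")
        colour = _optional_text(row["colour"])
        corr = _optional_text(row["correction_value"])
        order = _optional_text(row["order"])
        rows.append(
            {
                "sample_id": sample_id,
                "condition": condition,
                "order": int(float(order)) if order is not None else len(rows) + 1,
                "colour": resolve_colour(colour) if colour is not None else None,
                "experimental_replicate": _optional_text(row["experimental_replicate"]),
                "technical_replicate": _optional_text(row["technical_replicate"]),
                "correction_value": float(corr) if corr is not None else None,
                "include": include,
            }
        )
    frame = pd.DataFrame(rows)

    data_samples = set(table.samples)
    design_samples = set(frame["sample_id"])
    orphans = design_samples - data_samples
    if orphans:
        import warnings

        warnings.warn(f"sample table rows without data are ignored: {sorted(orphans)}",
                      stacklevel=2)
        frame = frame[frame["sample_id"].isin(data_samples)]
    unmatched = data_samples - design_samples
    if unmatched:
        raise ValidationError(
            f"samples present in the data but missing from the sample table: "
            f"{sorted(unmatched)}"
        )
    if frame["sample_id"].duplicated().any():
        dup = sorted(frame.loc[frame["sample_id"].duplicated(), "sample_id"])
        raise ValidationError(f"sample table lists samples more than once: {dup}")

    frame = frame[frame["include"]].reset_index(drop=True)
    if frame.empty:
        raise ValidationError("all samples are excluded; nothing to process")
    bad_corr = frame["correction_value"].dropna() <= 0
    if bad_corr.any():
        raise ValidationError("correction values must be > 0")
    exp_filled = frame["experimental_replicate"].notna()
    tech_filled = frame["technical_replicate"].notna()
    for name, filled in (("experimental_replicate", exp_filled),
                         ("technical_replicate", tech_filled)):
        if filled.any() and not filled.all():
            raise ValidationError(
                f"{name} column is partially filled: give it for every included "
                "sample or for none"
            )
    return SampleDesign(frame)


def average_technical(table: MeasurementTable, design: SampleDesign
                      ) -> tuple[MeasurementTable, SampleDesign]:
    """Average technical (measurement) replicates within each experimental
    replicate: one record per (compound, condition, experimental replicate),
    the arithmetic mean over non-missing technical values; all-missing stays
    missing. Returns the collapsed table and a matching collapsed design.
    """
    if not design.has_replicate_levels:
        raise ValidationError(
            "averaging technical replicates requires both replicate columns "
            "filled for every included sample"
        )
    meta = design.frame.set_index("sample_id")
    data = table.data[table.data["sample_id"].isin(meta.index)].copy()
    data["condition"] = data["sample_id"].map(meta["condition"])
    data["exp_rep"] = data["sample_id"].map(meta["experimental_replicate"])
    data["pseudo"] = data["condition"] + "__" + data["exp_rep"]

    grouped = (
        data.groupby(["compound", "pseudo"], sort=False)
        .agg(
            rt=("rt", "first"),
            intensity=("intensity", lambda s: s.mean()),  # skipna: all-NaN -> NaN
            condition=("condition", "first"),
            exp_rep=("exp_rep", "first"),
        )
        .reset_index()
    )
    new_data = grouped.rename(columns={"pseudo": "sample_id"})[
        ["compound", "rt", "sample_id", "intensity"]
    ]

    first_rows = (
        design.frame.assign(pseudo=design.frame["condition"] + "__"
                            + design.frame["experimental_replicate"])
        .groupby("pseudo", sort=False)
        .first()
        .reset_index()
    )
    new_design = pd.DataFrame(
        {
            "sample_id": first_rows["pseudo"],
            "condition": first_rows["condition"],
            "order": first_rows["order"],
            "colour": first_rows["colour"],
            "experimental_replicate": first_rows["experimental_replicate"],
            "technical_replicate": None,
            "correction_value": first_rows["correction_value"],
            "include": True,
        }
    )
    order = list(new_design["sample_id"])
    return (
        MeasurementTable(new_data, table.dialect, table.metadata, order),
        SampleDesign(new_design),
    )
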