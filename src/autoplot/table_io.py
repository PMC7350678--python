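"""Read quantified compound-intensity tables in five dialects into one canonical
long-form table, and write restructured output tables.

The five supported layouts are the vendor exports and generic layouts commonly
produced by targeted LC-MS quantification software:

``tracefinder``
    Long list with essential columns Compound, Filename, Area and optional
    Actual RT, Formula, Adduct and m/z columns (kept as per-compound metadata).
``compound_discoverer``
    Wide matrix with Compound and "RT [min]" columns; sample columns follow the
    pattern ``"Area: <filename>.raw (F<number>)"`` (or ``"Norm. Area: ..."``)
    and the filename becomes the sample id.
``compounds_in_columns``
    Samples along rows (sample names in the first column, header ignored),
    metabolites in the remaining columns.
``other_list``
    Exactly four columns in fixed order — Metabolite, RT, Filename, Area —
    further columns are ignored.
``other_matrix``
    Metabolite and RT in the first two columns, samples in the rest.

Missing values (empty cells and the tokens "NA", "NaN", "N/F", "N/A") are kept
missing end to end: they are represented as NaN internally and exported as empty
cells, never imputed or zero-filled.
"""

from __future__ import annotations

import csv
import re
import shutil
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DialectError, ValidationError

DIALECTS = (
    "tracefinder",
    "compound_discoverer",
    "compounds_in_columns",
    "other_list",
    "other_matrix",
)

#: Tokens always treated as missing, matched after stripping whitespace.
BASE_MISSING_TOKENS = frozenset({"", "NA", "NaN", "N/F", "N/A"})

_CD_SAMPLE_RE = re.compile(r"^(?:Norm\. )?Area: (?P<name>.+?)\.raw \(F\d+\)$")

#: TraceFinder optional columns carried into per-compound metadata.
_TF_META_COLUMNS = (
    "actual rt",
    "formula",
    "adduct",
    "m/z (apex)",
    "m/z (delta (ppm))",
    "m/z (delta)",
)


@dataclass(frozen=True)
class MissingPolicy:
    """How raw cell values are mapped onto intensities or MISSING.

    Parameters
    ----------
    tokens
        Text values treated as missing; always includes the base token set.
    zeros_as_missing
        For the compounds_in_columns dialect only: treat numeric 0 as missing
        instead of keeping it as an explicit zero.
    threshold
        For compound_discoverer and other_matrix: values below this intensity
        are treated as missing. The threshold itself passes (``value >=
        threshold`` is kept).
    """

    tokens: frozenset[str] = BASE_MISSING_TOKENS
    zeros_as_missing: bool = False
    threshold: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "tokens", frozenset(self.tokens) | BASE_MISSING_TOKENS)
        if self.threshold is not None and self.threshold < 0:
            raise ValidationError("missing-value threshold must be >= 0")


@dataclass
class MeasurementTable:
    """Canonical long-form measurement table.

    ``data`` has columns ``compound`` (display name, may carry an isotopologue
    suffix), ``rt`` (minutes, NaN when absent), ``sample_id`` and ``intensity``
    (non-negative float, NaN = missing). ``metadata`` holds optional per-compound
    extras (formula, adduct, m/z) keyed by compound.
    """

    data: pd.DataFrame
    dialect: str
    metadata: pd.DataFrame | None = None
    sample_order: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sample_order:
            self.sample_order = list(dict.fromkeys(self.data["sample_id"]))

    @property
    def samples(self) -> list[str]:
        return list(self.sample_order)

    @property
    def compounds(self) -> list[str]:
        return list(dict.fromkeys(self.data["compound"]))

    @property
    def n_missing(self) -> int:
        return int(self.data["intensity"].isna().sum())

    def wide(self) -> pd.DataFrame:
        """Compound x sample intensity matrix (NaN = missing)."""
        return (
            self.data.pivot_table(
                index="compound", columns="sample_id", values="intensity",
                aggfunc="first", dropna=False, sort=False,
            )
            .reindex(index=self.compounds, columns=self.samples)
        )

    def copy(self) -> "MeasurementTable":
        return MeasurementTable(
            self.data.copy(),
            self.dialect,
            None if self.metadata is None else self.metadata.copy(),
            list(self.sample_order),
        )


def classify_value(raw, policy: MissingPolicy, dialect: str,
                   context: str = "") -> float:
    """Map one raw cell value to an intensity or NaN (missing).

    Token in the policy's missing set -> missing. Numeric zero -> missing only
    for compounds_in_columns with ``zeros_as_missing``. Values below the policy
    threshold (compound_discoverer / other_matrix) -> missing; the threshold
    itself is kept. Non-numeric text outside the token set is a hard error.
    """
    if raw is None:
        return np.nan
    if isinstance(raw, str):
        text = raw.strip()
        if text in policy.tokens:
            return np.nan
        # accept comma decimal separators from European exports
        try:
            value = float(text.replace(",", ".", 1)) if text.count(",") == 1 and "." not in text else float(text)
        except ValueError:
            raise ValidationError(
                f"non-numeric value {raw!r} is not a recognised missing token"
                + (f" ({context})" if context else "")
            ) from None
    else:
        if isinstance(raw, float) and np.isnan(raw):
            return np.nan
        value = float(raw)
    if not np.isfinite(value):
        return np.nan
    if value == 0 and dialect == "compounds_in_columns" and policy.zeros_as_missing:
        return np.nan
    if (
        policy.threshold is not None
        and dialect in ("compound_discoverer", "other_matrix")
        and value < policy.threshold
    ):
        return np.nan
    if value < 0:
        raise ValidationError(
            f"negative intensity {value!r}" + (f" ({context})" if context else "")
        )
    return value


def _sniff_delimiter(path: Path) -> str:
    sample = path.read_text(errors="replace")[:65536]
    try:
        return csv.Sniffer().sniff(sample, delimiters=",;\t").delimiter
    except csv.Error:
        return ","


def _read_raw(path: Path, delimiter: str | None = None) -> pd.DataFrame:
    """Read csv/tsv/txt/xls(x) with one header row; all cells as objects."""
    path = Path(path)
    if not path.exists():
        raise DialectError(f"input file not found: {path}")
    suffix = path.suffix.lower()
    if suffix in (".xls", ".xlsx"):
        frame = pd.read_excel(path, sheet_name=0, dtype=object)
    elif suffix in (".csv", ".tsv", ".txt"):
        sep = delimiter or ("\t" if suffix == ".tsv" else _sniff_delimiter(path))
        frame = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False,
                            skip_blank_lines=True)
    else:
        raise DialectError(f"unsupported file extension {suffix!r} for {path}")
    frame.columns = [str(c) for c in frame.columns]
    return frame


def _norm_header(name: str) -> str:
    return re.sub(r"\s+", " ", str(name)).strip().lower()


def _find_column(frame: pd.DataFrame, wanted: str, dialect: str) -> str:
    for col in frame.columns:
        if _norm_header(col) == _norm_header(wanted):
            return col
    raise DialectError(f"{dialect}: essential column {wanted!r} is missing")


def _strip_raw(sample: str) -> str:
    sample = str(sample).strip()
    return sample[:-4] if sample.lower().endswith(".raw") else sample


def _parse_rt(raw) -> float:
    if raw is None:
        return np.nan
    text = str(raw).strip()
    if text in BASE_MISSING_TOKENS:
        return np.nan
    try:
        return float(text.replace(",", ".", 1)) if text.count(",") == 1 and "." not in text else float(text)
    except ValueError:
        raise DialectError(f"retention time {raw!r} is not numeric") from None


def parse_input(path, dialect: str, policy: MissingPolicy | None = None,
                delimiter: str | None = None) -> MeasurementTable:
    """Parse one input file into the canonical long-form MeasurementTable.

    Wide layouts are melted to long form; the record count of a wide input is
    exactly n_compounds x n_samples (missing cells become missing records,
    never dropped).
    """
    if dialect not in DIALECTS:
        raise DialectError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    policy = policy or MissingPolicy()
    frame = _read_raw(Path(path), delimiter)
    parser = {
        "tracefinder": _parse_tracefinder,
        "compound_discoverer": _parse_compound_discoverer,
        "compounds_in_columns": _parse_compounds_in_columns,
        "other_list": _parse_other_list,
        "other_matrix": _parse_other_matrix,
    }[dialect]
    table = parser(frame, policy)
    _check_duplicates(table)
    return table


def _check_duplicates(table: MeasurementTable) -> None:
    """Duplicate compound names are only legal when RT can disambiguate."""
    dup = table.data.duplicated(subset=["compound", "rt", "sample_id"])
    if dup.any():
        bad = sorted(table.data.loc[dup, "compound"].unique())
        raise DialectError(
            "duplicated compound names cannot be disambiguated "
            f"(same name, RT and sample): {bad}"
        )


def _long_records(compounds, rts, sample_ids, intensities, dialect,
                  metadata=None, sample_order=None) -> MeasurementTable:
    data = pd.DataFrame(
        {
            "compound": compounds,
            "rt": rts,
            "sample_id": sample_ids,
            "intensity": intensities,
        }
    ).reset_index(drop=True)
    if (data["compound"].astype(str).str.strip() == "").any():
        raise DialectError(f"{dialect}: compound names cannot contain empty values")
    data["compound"] = data["compound"].astype(str).str.strip()
    data["sample_id"] = data["sample_id"].astype(str).str.strip()
    return MeasurementTable(data, dialect, metadata, sample_order or [])


def _parse_tracefinder(frame: pd.DataFrame, policy: MissingPolicy) -> MeasurementTable:
    col_compound = _find_column(frame, "Compound", "tracefinder")
    col_file = _find_column(frame, "Filename", "tracefinder")
    col_area = _find_column(frame, "Area", "tracefinder")
    norm = {_norm_header(c): c for c in frame.columns}
    rt_col = norm.get("actual rt")
    intensities = [
        classify_value(v, policy, "tracefinder", context=f"row {i + 2}, column Area")
        for i, v in enumerate(frame[col_area])
    ]
    rts = ([_parse_rt(v) for v in frame[rt_col]] if rt_col is not None
           else [np.nan] * len(frame))
    meta_cols = [norm[c] for c in _TF_META_COLUMNS if c in norm]
    metadata = None
    if meta_cols:
        metadata = (
            frame[[col_compound] + meta_cols]
            .drop_duplicates(subset=[col_compound])
            .rename(columns={col_compound: "compound"})
            .set_index("compound")
        )
    return _long_records(
        frame[col_compound], rts, frame[col_file].map(_strip_raw), intensities,
        "tracefinder", metadata,
    )


def _parse_compound_discoverer(frame: pd.DataFrame, policy: MissingPolicy) -> MeasurementTable:
    col_compound = _find_column(frame, "Compound", "compound_discoverer")
    col_rt = _find_column(frame, "RT [min]", "compound_discoverer")
    sample_cols = [(c, m.group("name")) for c in frame.columns
                   if (m := _CD_SAMPLE_RE.match(str(c).strip()))]
    if not sample_cols:
        raise DialectError(
            'compound_discoverer: no sample columns matching '
            '"Area: <filename>.raw (F<number>)" were found'
        )
    norm = {_norm_header(c): c for c in frame.columns}
    meta_cols = [norm[c] for c in ("molecular weight", "mass", "formula") if c in norm]
    metadata = None
    if meta_cols:
        metadata = (
            frame[[col_compound] + meta_cols]
            .drop_duplicates(subset=[col_compound])
            .rename(columns={col_compound: "compound"})
            .set_index("compound")
        )
    records = []
    for i, row in frame.iterrows():
        rt = _parse_rt(row[col_rt])
        for col, sample in sample_cols:
            records.append(
                (
                    row[col_compound],
                    rt,
                    sample,
                    classify_value(row[col], policy, "compound_discoverer",
                                   context=f"row {i + 2}, column {col!r}"),
                )
            )
    compounds, rts, sample_ids, intensities = zip(*records) if records else ((), (), (), ())
    return _long_records(list(compounds), list(rts), list(sample_ids),
                         list(intensities), "compound_discoverer", metadata,
                         sample_order=[s for _, s in sample_cols])


def _parse_compounds_in_columns(frame: pd.DataFrame, policy: MissingPolicy) -> MeasurementTable:
    if frame.shape[1] < 2:
        raise DialectError(
            "compounds_in_columns: need a sample column plus at least one metabolite column"
        )
    sample_col = frame.columns[0]
    metabolite_cols = list(frame.columns[1:])
    records = []
    for i, row in frame.iterrows():
        sample = _strip_raw(row[sample_col])
        for col in metabolite_cols:
            records.append(
                (
                    col,
                    np.nan,
                    sample,
                    classify_value(row[col], policy, "compounds_in_columns",
                                   context=f"row {i + 2}, column {col!r}"),
                )
            )
    compounds, rts, sample_ids, intensities = zip(*records) if records else ((), (), (), ())
    return _long_records(list(compounds), list(rts), list(sample_ids),
                         list(intensities), "compounds_in_columns")


def _parse_other_list(frame: pd.DataFrame, policy: MissingPolicy) -> MeasurementTable:
    if frame.shape[1] < 4:
        raise DialectError(
            "other_list: expects 4 columns in fixed order (Metabolite, RT, Filename, Area)"
        )
    if frame.shape[1] > 4:
        warnings.warn("other_list: ignoring extra columns beyond the first four",
                      stacklevel=2)
    col_m, col_rt, col_f, col_a = frame.columns[:4]
    intensities = [
        classify_value(v, policy, "other_list", context=f"row {i + 2}, column Area")
        for i, v in enumerate(frame[col_a])
    ]
    return _long_records(
        frame[col_m], [_parse_rt(v) for v in frame[col_rt]],
        frame[col_f].map(_strip_raw), intensities, "other_list",
    )


def _parse_other_matrix(frame: pd.DataFrame, policy: MissingPolicy) -> MeasurementTable:
    if frame.shape[1] < 3:
        raise DialectError(
            "other_matrix: expects Metabolite and RT columns followed by sample columns"
        )
    col_m, col_rt = frame.columns[:2]
    sample_cols = list(frame.columns[2:])
    records = []
    for i, row in frame.iterrows():
        rt = _parse_rt(row[col_rt])
        for col in sample_cols:
            records.append(
                (
                    row[col_m],
                    rt,
                    _strip_raw(col),
                    classify_value(row[col], policy, "other_matrix",
                                   context=f"row {i + 2}, column {col!r}"),
                )
            )
    compounds, rts, sample_ids, intensities = zip(*records) if records else ((), (), (), ())
    return _long_records(list(compounds), list(rts), list(sample_ids),
                         list(intensities), "other_matrix",
                         sample_order=[_strip_raw(c) for c in sample_cols])


def merge_duplicate_names(table: MeasurementTable) -> MeasurementTable:
    """Disambiguate duplicated compound names by appending the retention time.

    Names occurring with more than one distinct RT become ``"name@RT"`` with RT
    to two decimals; unique names are left untouched. A duplicate without an RT
    is a hard error because nothing can tell the species apart.
    """
    data = table.data
    n_rts = data.groupby("compound", sort=False)["rt"].nunique(dropna=True)
    duplicated = set(n_rts.index[n_rts > 1])
    if not duplicated:
        return table
    missing_rt = data["compound"].isin(duplicated) & data["rt"].isna()
    if missing_rt.any():
        bad = sorted(data.loc[missing_rt, "compound"].unique())
        raise DialectError(
            f"duplicated compound names with missing RT cannot be merged: {bad}"
        )
    out = table.copy()
    mask = out.data["compound"].isin(duplicated)
    out.data.loc[mask, "compound"] = (
        out.data.loc[mask, "compound"]
        + "@"
        + out.data.loc[mask, "rt"].map(lambda r: f"{r:.2f}")
    )
    return out


def serialise_input(table: MeasurementTable, dialect: str, path) -> Path:
    """Write a MeasurementTable back out in one of the five input dialects.

    Missing intensities become empty cells. Used for round-trip checks and by
    the fixture generator.
    """
    path = Path(path)
    data = table.data
    if dialect == "tracefinder":
        frame = pd.DataFrame(
            {
                "Compound": data["compound"],
                "Filename": data["sample_id"],
                "Area": data["intensity"],
                "Actual RT": data["rt"],
            }
        )
    elif dialect == "other_list":
        frame = pd.DataFrame(
            {
                "Metabolite": data["compound"],
                "RT": data["rt"],
                "Filename": data["sample_id"],
                "Area": data["intensity"],
            }
        )
    elif dialect == "compound_discoverer":
        wide = table.wide()
        rt = data.groupby("compound", sort=False)["rt"].first().reindex(wide.index)
        frame = pd.DataFrame({"Compound": wide.index, "RT [min]": rt.values})
        for k, sample in enumerate(wide.columns, start=1):
            frame[f"Area: {sample}.raw (F{k})"] = wide[sample].values
    elif dialect == "other_matrix":
        wide = table.wide()
        rt = data.groupby("compound", sort=False)["rt"].first().reindex(wide.index)
        frame = pd.DataFrame({"Metabolite": wide.index, "RT": rt.values})
        for sample in wide.columns:
            frame[sample] = wide[sample].values
    elif dialect == "compounds_in_columns":
        wide = table.wide().T  # samples in rows
        frame = wide.reset_index().rename(columns={"sample_id": "Sample"})
    else:
        raise DialectError(f"unknown dialect {dialect!r}")
    if path.suffix.lower() in (".xls", ".xlsx"):
        frame.to_excel(path, index=False)
    else:
        frame.to_csv(path, index=False)
    return path


def write_structured_tables(table: MeasurementTable, design, out_dir,
                            input_path=None, design_path=None) -> list[Path]:
    """Export the cleaned long table, the wide matrix and a per-condition
    mean/SD/n summary as CSV and XLSX; copy the cleaned input and sample table
    into an ``Inputs`` subfolder so a run can be repeated later.
    """
    out_dir = Path(out_dir)
    tables_dir = out_dir / "Tables"
    inputs_dir = out_dir / "Inputs"
    try:
        tables_dir.mkdir(parents=True, exist_ok=True)
        inputs_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise ValidationError(f"cannot create output directory {out_dir}: {exc}") from exc

    cond = design.frame.set_index("sample_id")["condition"]
    annotated = table.data.copy()
    annotated["condition"] = annotated["sample_id"].map(cond)

    wide = table.wide().reset_index()
    rt = table.data.groupby("compound", sort=False)["rt"].first()
    wide.insert(1, "RT", wide["compound"].map(rt).values)
    wide = wide.rename(columns={"compound": "Metabolite"})
    present = annotated.dropna(subset=["intensity"])
    summary = (
        present.groupby(["compound", "condition"], sort=False)["intensity"]
        .agg(mean="mean", sd=lambda s: s.std(ddof=1), n="count")
        .reset_index()
    )

    written: list[Path] = []
    for name, frame, index in (
        ("data_long", annotated, False),
        ("data_matrix", wide, False),
        ("summary_per_condition", summary, False),
    ):
        csv_path = tables_dir / f"{name}.csv"
        frame.to_csv(csv_path, index=index)
        xlsx_path = tables_dir / f"{name}.xlsx"
        frame.to_excel(xlsx_path, index=index)
        written += [csv_path, xlsx_path]

    cleaned = inputs_dir / "cleaned_input.csv"
    serialise_input(table, "other_list", cleaned)
    written.append(cleaned)
    if input_path is not None and Path(input_path).exists():
        written.append(Path(shutil.copy(input_path, inputs_dir / Path(input_path).name)))
    if design_path is not None and Path(design_path).exists():
        written.append(Path(shutil.copy(design_path, inputs_dir / Path(design_path).name)))
    else:
        sample_table = inputs_dir / "sample_table.csv"
        design.frame.to_csv(sample_table, index=False)
        written.append(sample_table)
    return written
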