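"""End-to-end pipeline: parse -> design -> normalise -> QC -> (tracing ->
natural-abundance correction) -> stats -> plots -> tables -> zip.

The run is driven by a RunConfig (loadable from YAML). Every stage logs one
line with the record counts going in and out, warnings accumulate into the
run report, and the results zip is written only after all stages succeed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import matplotlib.pyplot as plt
import pandas as pd
import yaml

from . import qc as qc_mod
from . import table_io
from .errors import StageError, ValidationError
from .isotope_correction import TracerSpec, correct_group, parse_formula
from .normalisation import NormalisationConfig, apply_normalisation
from .plotting import (FilenameSanitizer, PlotSpec, bundle_results,
                       render_metabolite, render_tracing_group)
from .sample_design import SampleDesign, average_technical, load_design
from .stats import compare_groups, comparison_plan
from .table_io import MeasurementTable, MissingPolicy
from .tracing import group_isotopologues, tracing_tables

MAX_UPLOAD_BYTES = 25 * 1024 * 1024  # matches the original app's upload cap


@dataclass
class RunConfig:
    input_path: str
    dialect: str
    sample_table: str
    out_dir: str = "autoplot_results"
    missing_policy: MissingPolicy = field(default_factory=MissingPolicy)
    normalisation: NormalisationConfig = field(default_factory=NormalisationConfig)
    qc: bool = True
    qc_tolerance: float = 2.0
    tracing: bool = False
    correction: bool = False
    formula_table: str | None = None
    tracer: TracerSpec = field(default_factory=TracerSpec)
    carbon_only: bool = True
    plot: PlotSpec = field(default_factory=PlotSpec)
    tracing_plots: tuple[str, ...] = ("stacked_absolute", "stacked_relative")
    max_upload_bytes: int = MAX_UPLOAD_BYTES

    def __post_init__(self) -> None:
        if self.correction and not self.tracing:
            raise ValidationError("natural-abundance correction requires tracing mode")
        if self.correction and self.formula_table is None:
            raise ValidationError("correction requires a compound-to-formula table")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        policy = MissingPolicy(
            tokens=frozenset(raw.get("missing", {}).get("tokens", ())),
            zeros_as_missing=raw.get("missing", {}).get("zeros_as_missing", False),
            threshold=raw.get("missing", {}).get("threshold"),
        )
        internal = raw.get("internal", {})
        norm = NormalisationConfig(
            external_mode=raw.get("external", {}).get("mode", "off"),
            internal_mode=internal.get("mode", "off"),
            internal_standards=tuple(internal.get("standards", ())),
            internal_timing=internal.get("timing", "before_external"),
            total_peak_sum=bool(raw.get("total_peak_sum", False)),
        )
        tracer_raw = raw.get("tracer", {})
        correction_raw = raw.get("correction", {})
        plot = PlotSpec(**raw.get("plot", {}))
        return cls(
            input_path=raw["input"],
            dialect=raw["dialect"],
            sample_table=raw["sample_table"],
            out_dir=raw.get("out_dir", "autoplot_results"),
            missing_policy=policy,
            normalisation=norm,
            qc=raw.get("qc", True),
            qc_tolerance=raw.get("qc_tolerance", 2.0),
            tracing=raw.get("tracing", False),
            correction=bool(correction_raw.get("enabled", False)),
            formula_table=correction_raw.get("formula_table"),
            tracer=TracerSpec(tracer_raw.get("element", "C13"),
                              tracer_raw.get("purity", 1.0)),
            carbon_only=correction_raw.get("carbon_only", True),
            plot=plot,
            tracing_plots=tuple(raw.get("tracing_plots",
                                        ("stacked_absolute", "stacked_relative"))),
            max_upload_bytes=raw.get("max_upload_bytes", MAX_UPLOAD_BYTES),
        )


@dataclass
class RunResult:
    out_dir: Path
    zip_path: Path
    table: MeasurementTable
    design: SampleDesign
    qc_report: qc_mod.QCReport | None
    plot_paths: list[Path]
    log: list[str]
    warnings: list[str]


def _load_formulas(path) -> dict[str, dict[str, int]]:
    path = Path(path)
    if path.suffix.lower() in (".xls", ".xlsx"):
        frame = pd.read_excel(path, sheet_name=0, dtype=object)
    else:
        frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    if frame.shape[1] < 2:
        raise ValidationError("formula table needs two columns: compound, formula")
    compound_col, formula_col = frame.columns[:2]
    return {
        str(row[compound_col]).strip(): parse_formula(row[formula_col])
        for _, row in frame.iterrows()
        if str(row[formula_col]).strip()
    }


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute the full workflow. Any stage failure aborts with a
    stage-named StageError; the zip only appears after every stage
    succeeded."""
    log: list[str] = []
    collected: list[str] = []
    out_dir = Path(config.out_dir)
    plots_dir = out_dir / "Plots"
    tables_dir = out_dir / "Tables"
    inputs_dir = out_dir / "Inputs"

    def stage(name: str, func, *args, **kwargs):
        try:
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                result = func(*args, **kwargs)
            for w in caught:
                collected.append(f"{name}: {w.message}")
            return result
        except ValidationError as exc:
            raise StageError(f"stage {name!r} failed: {exc}") from exc
        except table_io.DialectError as exc:
            raise StageError(f"stage {name!r} failed: {exc}") from exc

    # --- validate & parse -------------------------------------------------
    input_path = Path(config.input_path)
    if not input_path.exists():
        raise StageError(f"stage 'parse' failed: input {input_path} not found")
    size = input_path.stat().st_size
    if size > config.max_upload_bytes:
        raise StageError(
            f"stage 'parse' failed: input is {size} bytes, above the "
            f"{config.max_upload_bytes}-byte limit"
        )
    table = stage("parse", table_io.parse_input, input_path, config.dialect,
                  config.missing_policy)
    table = stage("parse", table_io.merge_duplicate_names, table)
    log.append(f"parse: {len(table.data)} records, {len(table.compounds)} "
               f"compounds, {len(table.samples)} samples ({table.n_missing} missing)")

    # --- sample design ----------------------------------------------------
    design = stage("design", load_design, config.sample_table, table)
    table.data = table.data[table.data["sample_id"].isin(design.samples)].reset_index(drop=True)
    table.sample_order = [s for s in table.sample_order if s in set(design.samples)]
    log.append(f"design: {len(design.samples)} included samples, "
               f"{len(design.conditions)} conditions")

    # --- normalisation + QC ----------------------------------------------
    norm = config.normalisation
    if norm.internal_timing == "after_external":
        table = stage("normalise", apply_normalisation, table, design,
                      replace(norm, internal_mode="off", internal_standards=(),
                              total_peak_sum=False))
        qc_report = _run_qc(stage, table, design, config, log)
        if norm.internal_mode != "off" or norm.total_peak_sum:
            table = stage("normalise", apply_normalisation, table, design,
                          replace(norm, external_mode="off"))
    else:
        table = stage("normalise", apply_normalisation, table, design, norm)
        qc_report = _run_qc(stage, table, design, config, log)
    log.append(f"normalise: external={norm.external_mode} "
               f"internal={norm.internal_mode} ({norm.internal_timing}) "
               f"total_peak_sum={norm.total_peak_sum}")

    # --- technical replicate averaging -----------------------------------
    if design.has_replicate_levels:
        table, design = stage("average_technical", average_technical, table, design)
        log.append(f"average_technical: collapsed to {len(design.samples)} "
                   "experimental replicates")

    plots_dir.mkdir(parents=True, exist_ok=True)
    plot_paths: list[Path] = []
    fig = plt.figure()
    namer = FilenameSanitizer()
    try:
        if config.tracing:
            plot_paths += _tracing_stage(stage, table, design, config, plots_dir,
                                         tables_dir, fig, namer, log)
        else:
            plot_paths += _quantitative_stage(stage, table, design, config,
                                              plots_dir, tables_dir, fig, namer, log)
    finally:
        plt.close(fig)

    # --- tables, QC export, zip ------------------------------------------
    stage("tables", table_io.write_structured_tables, table, design, out_dir,
          input_path=config.input_path, design_path=config.sample_table)
    if qc_report is not None:
        tables_dir.mkdir(parents=True, exist_ok=True)
        qc_report.fold_changes.to_csv(tables_dir / "qc_fold_changes.csv", index=False)
    report_path = out_dir / "run_report.txt"
    report_path.write_text(
        "\n".join(log + [f"warning: {w}" for w in collected]) + "\n"
    )
    zip_path = stage("bundle", bundle_results, plots_dir, tables_dir,
                     inputs_dir, out_dir / "results.zip")
    log.append(f"bundle: {zip_path}")
    return RunResult(out_dir, zip_path, table, design, qc_report, plot_paths,
                     log, collected)


def _run_qc(stage, table, design, config, log):
    if not config.qc:
        return None
    counts = design.replicates_per_condition()
    if (counts < 2).all():
        log.append("qc: skipped (no condition with >= 2 replicates)")
        return None
    report = stage("qc", qc_mod.replicate_fold_changes, table, design)
    flagged = stage("qc", qc_mod.flag_outlier_samples, report, config.qc_tolerance)
    log.append(f"qc: {len(report.fold_changes)} fold changes, "
               f"{len(flagged)} flagged samples {flagged or ''}".rstrip())
    return report


def _quantitative_stage(stage, table, design, config, plots_dir, tables_dir,
                        fig, namer, log) -> list[Path]:
    meta = design.frame.set_index("sample_id")
    data = table.data.copy()
    data["condition"] = data["sample_id"].map(meta["condition"])
    data["experimental_replicate"] = data["sample_id"].map(
        meta["experimental_replicate"])
    paths = []
    for compound, rows in data.groupby("compound", sort=False):
        path = stage("plots", render_metabolite, compound, rows, config.plot,
                     design, plots_dir, filename=namer(compound), fig=fig)
        if path is not None:
            paths.append(path)
    log.append(f"plots: {len(paths)} metabolite plots "
               f"({config.plot.plot_type}, {config.plot.format})")
    if config.plot.stats_mode:
        _export_stats(data, design, config, tables_dir)
        log.append("stats: exported statistics table")
    return paths


def _export_stats(data, design, config, tables_dir) -> None:
    tables_dir.mkdir(parents=True, exist_ok=True)
    pairs = comparison_plan(design.conditions, config.plot.stats_mode,
                            config.plot.stats_reference)
    rows = []
    for compound, sub in data.groupby("compound", sort=False):
        for a, b in pairs:
            res = compare_groups(
                sub.loc[sub["condition"] == a, "intensity"],
                sub.loc[sub["condition"] == b, "intensity"],
                test=config.plot.stats_test, compound=compound,
                group_a=a, group_b=b, display_style=config.plot.stats_style,
            )
            if res is not None:
                rows.append(res.__dict__)
    pd.DataFrame(rows).to_csv(tables_dir / "statistics.csv", index=False)


def _tracing_stage(stage, table, design, config, plots_dir, tables_dir,
                   fig, namer, log) -> list[Path]:
    groups = stage("tracing", group_isotopologues, table)
    log.append(f"tracing: {len(groups)} isotopologue groups")
    if config.correction:
        formulas = stage("correction", _load_formulas, config.formula_table)
        corrected = []
        for group in groups:
            if group.base_compound not in formulas:
                collected_msg = (f"no formula for {group.base_compound!r}; "
                                 "compound left uncorrected")
                warnings.warn(collected_msg, stacklevel=2)
                corrected.append(group)
                continue
            new_group, _ = stage("correction", correct_group, group,
                                 formulas[group.base_compound], config.tracer,
                                 carbon_only=config.carbon_only)
            corrected.append(new_group)
        groups = corrected
        log.append(f"correction: tracer {config.tracer.element} "
                   f"purity {config.tracer.purity}, carbon_only={config.carbon_only}")
    paths = []
    for plot_type in config.tracing_plots:
        spec = replace(config.plot, plot_type=plot_type)
        suffix = "_absolute" if plot_type == "stacked_absolute" else "_relative"
        for group in groups:
            path = stage("plots", render_tracing_group, group, spec, design,
                         plots_dir,
                         filename=namer(group.base_compound + suffix), fig=fig)
            if path is not None:
                paths.append(path)
    log.append(f"plots: {len(paths)} tracing plots ({', '.join(config.tracing_plots)})")
    tables_dir.mkdir(parents=True, exist_ok=True)
    tracing_tables(groups).to_csv(tables_dir / "tracing_long.csv", index=False)
    return paths
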