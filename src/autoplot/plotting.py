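"""Per-metabolite plot rendering and result bundling.

One image per metabolite: bar (mean + SD), univariate scatter (points with
mean + SD), violin (density + median, needs >= 5 replicate measurements per
condition), box (median, quartiles, 1.5 x IQR whiskers, needs >= 10),
replicate-comparison variants (points or bars grouped by experimental
replicate), and stacked isotopologue bars (absolute intensities or relative,
normalised to 100%, M+0 at the bottom of the stack). Rendering is headless
and deterministic; filenames are the sanitised compound names and everything
is finally packed into a zip with Plots/, Tables/ and Inputs/ folders.
"""

from __future__ import annotations

import re
import zipfile
from dataclasses import dataclass, field, replace
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .errors import ValidationError
from .palettes import quantitative_colours, tracing_colours
from .sample_design import SampleDesign
from .stats import compare_groups, comparison_plan

PLOT_TYPES = (
    "bar", "points", "violin", "box", "replicate_points", "replicate_bars",
    "stacked_absolute", "stacked_relative",
)
FORMATS = ("jpg", "pdf", "png", "svg")

_FORBIDDEN = ':;<>/\\|?*"'
_SANITIZE_RE = re.compile("[" + re.escape(_FORBIDDEN) + "]")


@dataclass(frozen=True)
class PlotSpec:
    """Declarative description of one rendered plot."""

    plot_type: str = "bar"
    hollow: bool = False
    overlay_points: bool = False
    width: float = 4.0
    height: float = 4.0
    dpi: int = 150
    format: str = "png"
    x_text_angle: int = 45
    title_size: float = 12.0
    axis_size: float = 10.0
    tick_size: float = 9.0
    x_title: str = ""
    y_title: str = "Peak area"
    name_prefix: str = ""
    name_suffix: str = ""
    legend_instead_of_x: bool = False
    show_n: bool = False
    stats_mode: str | None = None  # all_pairwise | vs_reference | None
    stats_reference: str | None = None
    stats_test: str = "t_equal_var"
    stats_style: str = "symbols"
    tracing_scale: str = "short"

    def __post_init__(self) -> None:
        if self.plot_type not in PLOT_TYPES:
            raise ValidationError(f"unknown plot type {self.plot_type!r}")
        if self.format not in FORMATS:
            raise ValidationError(f"unknown output format {self.format!r}")
        if self.x_text_angle not in (0, 45, 90):
            raise ValidationError("x_text_angle must be 0, 45 or 90 degrees")


def available_plot_types(design: SampleDesign) -> set[str]:
    """Plot types legal for this design: bar and points always; violin from 5
    and box from 10 replicate measurements per condition; replicate variants
    only when experimental replicates are defined."""
    available = {"bar", "points"}
    min_reps = int(design.replicates_per_condition().min())
    if min_reps >= 5:
        available.add("violin")
    if min_reps >= 10:
        available.add("box")
    if design.frame["experimental_replicate"].notna().all():
        available |= {"replicate_points", "replicate_bars"}
    return available


class FilenameSanitizer:
    """Sanitise compound names into unique, filesystem-safe file stems."""

    def __init__(self) -> None:
        self._used: dict[str, int] = {}

    def __call__(self, compound: str) -> str:
        stem = _SANITIZE_RE.sub("_", str(compound)).strip()
        if not stem:
            stem = "compound"
        count = self._used.get(stem.lower(), 0) + 1
        self._used[stem.lower()] = count
        return stem if count == 1 else f"{stem}_{count}"


def sanitize_filename(compound: str) -> str:
    """One-off sanitisation (no cross-run uniqueness bookkeeping)."""
    return FilenameSanitizer()(compound)


def _style_axes(ax, spec: PlotSpec, title: str) -> None:
    ax.set_title(f"{spec.name_prefix}{title}{spec.name_suffix}",
                 fontsize=spec.title_size)
    ax.set_xlabel(spec.x_title, fontsize=spec.axis_size)
    ax.set_ylabel(spec.y_title, fontsize=spec.axis_size)
    ax.tick_params(labelsize=spec.tick_size)
    ha = {0: "center", 45: "right", 90: "center"}[spec.x_text_angle]
    for label in ax.get_xticklabels():
        label.set_rotation(spec.x_text_angle)
        label.set_horizontalalignment(ha)


def _group_values(data: pd.DataFrame, conditions: list[str]) -> list[np.ndarray]:
    return [
        data.loc[data["condition"] == cond, "intensity"].dropna().to_numpy()
        for cond in conditions
    ]


def _condition_colours(design: SampleDesign) -> list[str]:
    conditions = design.conditions
    defaults = quantitative_colours(len(conditions))
    explicit = design.colours
    return [explicit.get(c) or defaults[i] for i, c in enumerate(conditions)]


def _annotate_stats(ax, spec: PlotSpec, conditions, groups) -> None:
    pairs = comparison_plan(conditions, spec.stats_mode, spec.stats_reference)
    finite = np.concatenate([g for g in groups if len(g)]) if any(len(g) for g in groups) else np.array([0.0])
    top = float(np.nanmax(finite)) if len(finite) else 1.0
    step = 0.08 * (top if top > 0 else 1.0)
    y = top + step
    index = {c: i for i, c in enumerate(conditions)}
    for a, b in pairs:
        result = compare_groups(groups[index[a]], groups[index[b]],
                                test=spec.stats_test, group_a=a, group_b=b,
                                display_style=spec.stats_style)
        text = result.display if result is not None else "n/a"
        xa, xb = index[a], index[b]
        ax.plot([xa, xa, xb, xb], [y, y + step / 3, y + step / 3, y],
                lw=0.8, color="black")
        ax.text((xa + xb) / 2, y + step / 3, text, ha="center",
                va="bottom", fontsize=spec.tick_size)
        y += step * 1.5


def render_metabolite(compound: str, data: pd.DataFrame, spec: PlotSpec,
                      design: SampleDesign, out_dir, filename: str | None = None,
                      fig=None) -> Path | None:
    """Render one metabolite's plot and return the written path.

    ``data`` is the long frame for this compound with columns sample_id,
    condition, intensity and (for replicate plots) experimental_replicate.
    A compound with no measured value is skipped (returns None). Passing a
    ``fig`` reuses the figure across calls, which matters when rendering
    hundreds of compounds.
    """
    if spec.plot_type not in available_plot_types(design):
        raise ValidationError(
            f"plot type {spec.plot_type!r} is not available for this design "
            f"(allowed: {sorted(available_plot_types(design))})"
        )
    values = data["intensity"].dropna()
    if values.empty:
        import warnings

        warnings.warn(f"no data for {compound!r}; plot skipped", stacklevel=2)
        return None
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    owned = fig is None
    if fig is None:
        fig = plt.figure(figsize=(spec.width, spec.height))
    else:
        fig.clf()
        fig.set_size_inches(spec.width, spec.height)
    try:
        ax = fig.add_subplot(111)
        conditions = design.conditions
        colours = _condition_colours(design)
        groups = _group_values(data, conditions)
        x = np.arange(len(conditions))

        if spec.plot_type in ("bar", "points"):
            means = [g.mean() if len(g) else np.nan for g in groups]
            sds = [g.std(ddof=1) if len(g) > 1 else 0.0 for g in groups]
            if spec.plot_type == "bar":
                ax.bar(x, means, yerr=sds, capsize=3,
                       color="none" if spec.hollow else colours,
                       edgecolor=colours if spec.hollow else "black",
                       linewidth=1.2 if spec.hollow else 0.5)
            else:
                ax.errorbar(x, means, yerr=sds, fmt="_", color="black",
                            capsize=4, markersize=18, zorder=3)
            if spec.plot_type == "points" or spec.overlay_points:
                for i, g in enumerate(groups):
                    jitter = np.linspace(-0.15, 0.15, num=len(g)) if len(g) > 1 else [0.0]
                    ax.plot(i + np.asarray(jitter), g, "o", ms=4,
                            color=colours[i], mec="black", mew=0.3, zorder=4)
        elif spec.plot_type == "violin":
            parts = ax.violinplot([g for g in groups], positions=x,
                                  showmedians=True, showextrema=False)
            for body, colour in zip(parts["bodies"], colours):
                body.set_facecolor("none" if spec.hollow else colour)
                body.set_edgecolor(colour if spec.hollow else "black")
                body.set_alpha(1.0 if spec.hollow else 0.8)
            parts["cmedians"].set_color("black")
        elif spec.plot_type == "box":
            boxes = ax.boxplot([g for g in groups], positions=x, whis=1.5,
                               patch_artist=not spec.hollow, widths=0.6)
            if not spec.hollow:
                for patch, colour in zip(boxes["boxes"], colours):
                    patch.set_facecolor(colour)
        elif spec.plot_type in ("replicate_points", "replicate_bars"):
            if "experimental_replicate" not in data.columns:
                raise ValidationError("replicate plots need experimental_replicate")
            _render_replicates(ax, data, spec, conditions, colours)
        else:  # stacked_* handled by render_tracing_group
            raise ValidationError(
                f"{spec.plot_type!r} applies to grouped isotopologue data; "
                "use render_tracing_group"
            )

        if spec.plot_type in ("bar", "points", "violin", "box"):
            if spec.overlay_points and spec.plot_type in ("violin", "box"):
                for i, g in enumerate(groups):
                    jitter = np.linspace(-0.15, 0.15, num=len(g)) if len(g) > 1 else [0.0]
                    ax.plot(i + np.asarray(jitter), g, "o", ms=3, color="black",
                            zorder=4)
            if spec.stats_mode:
                _annotate_stats(ax, spec, conditions, groups)
            labels = list(conditions)
            if spec.show_n:
                labels = [f"{c}\n(n={len(g)})" for c, g in zip(labels, groups)]
            ax.set_xticks(x)
            if spec.legend_instead_of_x:
                ax.set_xticklabels([""] * len(x))
                handles = [plt.Rectangle((0, 0), 1, 1, color=c) for c in colours]
                ax.legend(handles, labels, fontsize=spec.tick_size, frameon=False)
            else:
                ax.set_xticklabels(labels)
        _style_axes(ax, spec, compound)
        fig.tight_layout()
        stem = filename if filename is not None else sanitize_filename(compound)
        path = out_dir / f"{stem}.{spec.format}"
        fig.savefig(path, dpi=spec.dpi, format=spec.format)
        return path
    finally:
        if owned:
            plt.close(fig)


def _render_replicates(ax, data: pd.DataFrame, spec: PlotSpec,
                       conditions, colours) -> None:
    """Replicate-comparison plots: one x position per condition, experimental
    replicates side by side within it."""
    reps = sorted(data["experimental_replicate"].dropna().unique())
    n = max(len(reps), 1)
    width = 0.8 / n
    for i, cond in enumerate(conditions):
        for k, rep in enumerate(reps):
            vals = data.loc[
                (data["condition"] == cond)
                & (data["experimental_replicate"] == rep), "intensity"
            ].dropna().to_numpy()
            if not len(vals):
                continue
            pos = i - 0.4 + width * (k + 0.5)
            if spec.plot_type == "replicate_bars":
                ax.bar(pos, vals.mean(), width=width * 0.9,
                       yerr=vals.std(ddof=1) if len(vals) > 1 else 0.0,
                       color=colours[i], edgecolor="black", linewidth=0.4)
            else:
                ax.plot([pos] * len(vals), vals, "o", ms=4, color=colours[i],
                        mec="black", mew=0.3)
    ax.set_xticks(np.arange(len(conditions)))
    ax.set_xticklabels(conditions)


def render_tracing_group(group, spec: PlotSpec, design: SampleDesign, out_dir,
                         filename: str | None = None, fig=None) -> Path | None:
    """Stacked isotopologue bars for one base compound, one bar per condition
    (mean over the condition's samples), M+0 at the bottom.

    ``stacked_absolute`` stacks mean intensities; ``stacked_relative``
    normalises each bar to 100%. Missing isotopologues draw as zero-height
    segments but stay missing in exported tables.
    """
    if spec.plot_type not in ("stacked_absolute", "stacked_relative"):
        raise ValidationError("render_tracing_group needs a stacked_* plot type")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    meta = design.frame.set_index("sample_id")["condition"]
    rows = group.intensities.copy()
    rows["condition"] = rows["sample_id"].map(meta)
    rows = rows.dropna(subset=["condition"])
    if rows["intensity"].dropna().empty:
        import warnings

        warnings.warn(f"no data for {group.base_compound!r}; plot skipped",
                      stacklevel=2)
        return None
    conditions = [c for c in design.conditions if c in set(rows["condition"])]
    shifts = list(range(group.max_shift + 1))
    colours = tracing_colours(spec.tracing_scale, group.max_shift)

    # mean per (condition, shift) over samples, missing as absent
    mat = np.zeros((len(shifts), len(conditions)))
    for j, cond in enumerate(conditions):
        sub = rows[rows["condition"] == cond].dropna(subset=["intensity"])
        means = sub.groupby("shift")["intensity"].mean()
        for shift, value in means.items():
            mat[int(shift), j] = value
    if spec.plot_type == "stacked_relative":
        totals = mat.sum(axis=0)
        totals[totals == 0] = 1.0
        mat = 100.0 * mat / totals

    owned = fig is None
    if fig is None:
        fig = plt.figure(figsize=(spec.width, spec.height))
    else:
        fig.clf()
        fig.set_size_inches(spec.width, spec.height)
    try:
        ax = fig.add_subplot(111)
        x = np.arange(len(conditions))
        bottom = np.zeros(len(conditions))
        for shift in shifts:
            ax.bar(x, mat[shift], bottom=bottom, color=colours[shift],
                   edgecolor="white", linewidth=0.3, label=f"M+{shift}")
            bottom += mat[shift]
        ax.set_xticks(x)
        ax.set_xticklabels(conditions)
        handles, labels = ax.get_legend_handles_labels()
        ax.legend(handles[::-1], labels[::-1], fontsize=max(spec.tick_size - 2, 5),
                  loc="center left", bbox_to_anchor=(1.0, 0.5), frameon=False)
        y_title = spec.y_title if spec.plot_type == "stacked_absolute" else "Relative peak area (%)"
        _style_axes(ax, replace(spec, y_title=y_title), group.base_compound)
        fig.tight_layout()
        stem = filename if filename is not None else sanitize_filename(group.base_compound)
        path = out_dir / f"{stem}.{spec.format}"
        fig.savefig(path, dpi=spec.dpi, format=spec.format)
        return path
    finally:
        if owned:
            plt.close(fig)


def bundle_results(plots_dir, tables_dir, inputs_dir, zip_path) -> Path:
    """Pack Plots/, Tables/ and Inputs/ into one zip with a deterministic
    (sorted) member order and fixed timestamps, so identical runs produce
    identical archives."""
    zip_path = Path(zip_path)
    members: list[tuple[str, Path]] = []
    for arc, directory in (("Plots", plots_dir), ("Tables", tables_dir),
                           ("Inputs", inputs_dir)):
        directory = Path(directory)
        if directory.is_dir():
            for path in sorted(directory.rglob("*")):
                if path.is_file():
                    members.append((f"{arc}/{path.relative_to(directory)}", path))
    if not members:
        raise ValidationError("nothing to bundle: no plots, tables or inputs found")
    members.sort(key=lambda m: m[0])
    with zipfile.ZipFile(zip_path, "w", zipfile.ZIP_DEFLATED) as archive:
        for arcname, path in members:
            info = zipfile.ZipInfo(arcname, date_time=(1980, 1, 1, 0, 0, 0))
            info.compress_type = zipfile.ZIP_DEFLATED
            info.external_attr = 0o644 << 16
            archive.writestr(info, path.read_bytes())
    return zip_path
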