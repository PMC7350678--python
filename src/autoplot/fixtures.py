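"""Synthetic dataset generation for every input dialect.

The generator emulates the two study designs the tool targets:

* a quantitative targeted LC-MS experiment — by default 99 metabolites over 5
  conditions with 4 experimental replicates, log-normal peak areas with
  per-condition effect multipliers, and missing values injected preferentially
  into low-abundance compounds (where real detection limits bite);
* a stable-isotope tracing experiment — by default 38 base compounds over 4
  conditions in triplicate, where each compound's measured isotopologue vector
  is the forward model ``correction_matrix @ true_MID`` scaled by abundance
  and multiplicative noise, so the natural-abundance correction stage has a
  known ground truth to recover.

Everything is driven by one integer seed; the same spec and seed produce
byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .isotope_correction import TracerSpec, build_correction_matrix
from .table_io import MeasurementTable, serialise_input


@dataclass
class FixtureSpec:
    """Parameters of one synthetic dataset."""

    n_compounds: int = 99
    n_conditions: int = 5
    n_experimental_replicates: int = 4
    n_technical_replicates: int = 1
    tracing: bool = False
    tracing_carbon_range: tuple[int, int] = (3, 10)
    missing_rate: float = 0.05
    effect_sizes: tuple[float, ...] | None = None  # per-condition multipliers
    tracer_purity: float = 0.99
    noise_sigma: float = 0.1
    abundance_sigma: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tracing:
            # tracing study defaults: 38 compounds, 4 time points, triplicates
            if self.n_compounds == 99:
                self.n_compounds = 38
            if self.n_conditions == 5:
                self.n_conditions = 4
            if self.n_experimental_replicates == 4:
                self.n_experimental_replicates = 3

    @property
    def conditions(self) -> list[str]:
        return [f"cond{i + 1}" for i in range(self.n_conditions)]

    @property
    def multipliers(self) -> np.ndarray:
        if self.effect_sizes is not None:
            return np.asarray(self.effect_sizes, dtype=float)
        return 1.5 ** np.arange(self.n_conditions)


@dataclass
class Fixture:
    """A generated dataset plus its ground truth."""

    table: MeasurementTable
    design_frame: pd.DataFrame
    formula_frame: pd.DataFrame | None = None
    true_mids: dict | None = None  # (compound, condition) -> MID vector
    carbon_counts: dict | None = None
    paths: dict = field(default_factory=dict)


def _sample_names(spec: FixtureSpec) -> list[tuple[str, str, str, str]]:
    """(sample_id, condition, experimental replicate, technical replicate)."""
    out = []
    for cond in spec.conditions:
        for e in range(1, spec.n_experimental_replicates + 1):
            if spec.n_technical_replicates > 1:
                for t in range(1, spec.n_technical_replicates + 1):
                    out.append((f"{cond}_r{e}_t{t}", cond, str(e), str(t)))
            else:
                out.append((f"{cond}_r{e}", cond, str(e), "1"))
    return out


def _design_frame(spec: FixtureSpec, samples, rng) -> pd.DataFrame:
    conditions = spec.conditions
    order = {c: i + 1 for i, c in enumerate(conditions)}
    return pd.DataFrame(
        {
            "sample_id": [s for s, _, _, _ in samples],
            "condition": [c for _, c, _, _ in samples],
            "order": [order[c] for _, c, _, _ in samples],
            "colour": "",
            "experimental_replicate": [e for _, _, e, _ in samples],
            "technical_replicate": [t for _, _, _, t in samples],
            "correction_value": np.round(rng.uniform(0.8, 1.2, len(samples)), 4),
            "include": True,
        }
    )


def _inject_missing(frame: pd.DataFrame, spec: FixtureSpec, rank_pct, rng) -> None:
    """Blank a fixed fraction of cells, weighted toward low-abundance
    compounds (3:2:1 across abundance tertiles). ``rank_pct`` is the per-row
    percentile rank of the compound's base abundance."""
    if spec.missing_rate <= 0:
        return
    n_missing = int(round(spec.missing_rate * len(frame)))
    if n_missing == 0:
        return
    rank_pct = np.asarray(rank_pct, dtype=float)
    weight = np.where(rank_pct <= 1 / 3, 3.0, np.where(rank_pct <= 2 / 3, 2.0, 1.0))
    prob = weight / weight.sum()
    idx = rng.choice(len(frame), size=min(n_missing, len(frame)), replace=False,
                     p=prob)
    frame.loc[frame.index[idx], "intensity"] = np.nan


def generate_quantitative(spec: FixtureSpec, rng: np.random.Generator) -> Fixture:
    samples = _sample_names(spec)
    compounds = [f"Metabolite{i + 1:03d}" for i in range(spec.n_compounds)]
    abundance = np.exp(rng.normal(np.log(1e6), spec.abundance_sigma,
                                  spec.n_compounds))
    rts = np.round(rng.uniform(0.5, 15.0, spec.n_compounds), 2)
    multipliers = dict(zip(spec.conditions, spec.multipliers))

    rank_pct = pd.Series(abundance).rank(pct=True).to_numpy()
    rows = []
    ranks = []
    for i, compound in enumerate(compounds):
        for sample_id, cond, _, _ in samples:
            noise = np.exp(rng.normal(0.0, spec.noise_sigma))
            rows.append((compound, rts[i], sample_id,
                         abundance[i] * multipliers[cond] * noise))
            ranks.append(rank_pct[i])
    frame = pd.DataFrame(rows, columns=["compound", "rt", "sample_id", "intensity"])
    _inject_missing(frame, spec, ranks, rng)
    table = MeasurementTable(frame, "other_list",
                             sample_order=[s for s, _, _, _ in samples])
    return Fixture(table, _design_frame(spec, samples, rng))


def generate_tracing(spec: FixtureSpec, rng: np.random.Generator) -> Fixture:
    samples = _sample_names(spec)
    lo, hi = spec.tracing_carbon_range
    carbon_counts = {
        f"Metabolite{i + 1:03d}": int(rng.integers(lo, hi + 1))
        for i in range(spec.n_compounds)
    }
    abundance = np.exp(rng.normal(np.log(1e6), spec.abundance_sigma,
                                  spec.n_compounds))
    rts = np.round(rng.uniform(0.5, 15.0, spec.n_compounds), 2)
    tracer = TracerSpec("C13", spec.tracer_purity)

    true_mids: dict = {}
    rows = []
    for i, (compound, n_c) in enumerate(carbon_counts.items()):
        formula = {"C": n_c, "H": 2 * n_c, "O": max(n_c // 2, 1)}
        cm = build_correction_matrix(formula, tracer, max_shift=n_c,
                                     carbon_only=True)
        for cond in spec.conditions:
            # labelling grows with condition index (time-course style)
            alpha = np.ones(n_c + 1)
            alpha[0] = 5.0 / (1 + spec.conditions.index(cond))
            mid = rng.dirichlet(alpha)
            true_mids[(compound, cond)] = mid
            expected = cm.matrix @ mid
            for sample_id, scond, _, _ in samples:
                if scond != cond:
                    continue
                noise = np.exp(rng.normal(0.0, spec.noise_sigma))
                scale = abundance[i] * noise
                for shift in range(n_c + 1):
                    label = compound if shift == 0 else f"{compound} +{shift}"
                    rows.append((label, rts[i], sample_id,
                                 scale * expected[shift]))
    frame = pd.DataFrame(rows, columns=["compound", "rt", "sample_id", "intensity"])
    if spec.missing_rate > 0:
        _inject_missing(frame, spec, np.full(len(frame), 0.5), rng)
    table = MeasurementTable(frame, "other_list",
                             sample_order=[s for s, _, _, _ in samples])
    formula_frame = pd.DataFrame(
        {
            "compound": list(carbon_counts),
            "formula": [f"C{n}H{2 * n}O{max(n // 2, 1)}"
                        for n in carbon_counts.values()],
        }
    )
    return Fixture(table, _design_frame(spec, samples, rng), formula_frame,
                   true_mids, carbon_counts)


def generate_fixture(spec: FixtureSpec, dialect: str = "other_list",
                     out_dir=None) -> Fixture:
    """Generate a dataset, optionally writing it to disk in the requested
    dialect together with a pre-filled sample table (and, for tracing, a
    compound-to-formula table)."""
    rng = np.random.default_rng(spec.seed)
    fixture = (generate_tracing if spec.tracing else generate_quantitative)(spec, rng)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        input_path = out_dir / f"input_{dialect}.csv"
        serialise_input(fixture.table, dialect, input_path)
        design_path = out_dir / "sample_table.csv"
        fixture.design_frame.to_csv(design_path, index=False)
        fixture.paths = {"input": input_path, "design": design_path,
                         "dialect": dialect}
        if fixture.formula_frame is not None:
            formula_path = out_dir / "formulas.csv"
            fixture.formula_frame.to_csv(formula_path, index=False)
            fixture.paths["formulas"] = formula_path
    return fixture
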