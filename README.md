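# autoplot

Process and visualise quantified metabolite tables from targeted LC-MS
experiments — as a Python library and a small command-line tool.

After peak detection, integration and identification, a metabolomics
experiment is a compound × sample intensity table. Turning that table into
per-metabolite figures and clean summary tables usually means hours of
copy-and-paste: associating files to conditions, averaging replicates,
normalising by cell counts or internal standards, and plotting each compound
by hand. `autoplot` automates that second half of the analysis. It reads the
table in any of five common layouts, attaches a user-edited sample design,
normalises, quality-checks the replicates, handles stable-isotope tracing
data (including natural-abundance correction), and writes one
publication-style plot per metabolite plus restructured tables, all bundled
into a zip.

## What it computes

**Normalisation.** With a per-sample factor $c_s$ (a cell count, protein
amount, internal-standard sum or Total Peak Sum), intensities are corrected
absolutely, $I' = I/c_s$, or relatively, $I' = (I/c_s)\cdot\bar c$, which
keeps the scale of the data while equalising samples. Missing values stay
missing throughout — nothing is imputed or zero-filled.

**Replicate QC.** For metabolite $m$ in sample $s$ of a condition with
replicate set $R$, the relative fold change is

$$f(m,s) = \frac{I(m,s)}{\tfrac{1}{|R|}\sum_{r\in R} I(m,r)},$$

so each metabolite's fold changes average to exactly 1 within a complete
condition; a sample whose mean over all metabolites drifts from 1 beyond a
chosen factor is flagged.

**Isotopologue handling.** Compounds named `"Lactate +3"` are parsed as the
M+3 species of lactate (shifts up to M+30), grouped per base compound and
shown as stacked bars, absolute or normalised to 100% (the mass isotopomer
distribution, MID).

**Natural-abundance correction.** Naturally occurring heavy isotopes
(¹³C ≈ 1.1%, plus ²H, ¹⁵N, ¹⁸O, ³⁴S, …) inflate M+n signals independently of
any tracer: a 3-carbon molecule shows ~3% natural M+1, a 10-carbon molecule
~10%. From each compound's sum formula, a correction matrix $A$ is built
whose column $j$ is the mass-shift distribution of a molecule with $j$
tracer atoms labelled (tracer purity included); the measured vector
$m = Ax$ is then inverted for the tracer-derived intensities $x$ by
non-negative least squares.

**Statistics.** Two-sample $t$ test (pooled variance) or Wilcoxon rank-sum,
all pairwise or against a reference condition, drawn on the plots as star
symbols or numeric p-values. Raw p-values only — no multiple-testing
correction is applied.

## Worked example

```python
from autoplot import (FixtureSpec, PlotSpec, RunConfig, generate_fixture,
                      run_pipeline)

# a synthetic 10-compound experiment: 5 conditions, 3 replicates
fix = generate_fixture(
    FixtureSpec(n_compounds=10, n_conditions=5, n_experimental_replicates=3,
                missing_rate=0.05, seed=21),
    dialect="other_list", out_dir="demo")

result = run_pipeline(RunConfig(
    input_path=str(fix.paths["input"]), dialect="other_list",
    sample_table=str(fix.paths["design"]), out_dir="demo_results",
    plot=PlotSpec(plot_type="bar", overlay_points=True)))
print("\n".join(result.log))
```

prints

```
parse: 150 records, 10 compounds, 15 samples (8 missing)
design: 15 included samples, 5 conditions
qc: 142 fold changes, 0 flagged samples
normalise: external=off internal=off (before_external) total_peak_sum=False
average_technical: collapsed to 15 experimental replicates
plots: 10 metabolite plots (bar, png)
bundle: demo_results/results.zip
```

— 150 parsed records (10 compounds × 15 samples) of which 8 were injected as
missing; every metabolite's fold-change distribution centred on 1 with no
replicate flagged; one bar plot per compound; and a zip with `Plots/`,
`Tables/` (long table, compound × sample matrix, per-condition mean/SD/n
summary, QC fold changes) and `Inputs/` (the cleaned input plus the sample
table, enough to repeat the run later).

The same flow is available from the shell:

```bash
autoplot fixture --out demo --seed 21
autoplot template --input demo/input_other_list.csv --dialect other_list
autoplot run --config cfg.yaml
```

The sample-table headers are bit-exact between the template and the loader:
`sample_id, condition, order, colour, experimental_replicate,
technical_replicate, correction_value, include`. Colours accept hex
(`#FFAA25`) or standard R colour names (`tomato`).

For tracing data set `tracing: true` in the config, and for
natural-abundance correction supply a two-column compound → formula table
plus `tracer: {element: C13, purity: 0.99}`.

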