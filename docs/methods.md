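# Methods

This note documents the models and procedures implemented in `autoplot`, the
defaults and why they were chosen, what the synthetic-data generator does and
does not emulate, and the package's known limitations.

## Input dialects and the missing-value policy

All five supported layouts are normalised into one long-form table of
(compound, retention time, sample, intensity) records. The parsing contracts:

* **tracefinder** — long list; essential columns `Compound`, `Filename`,
  `Area`; `Actual RT`, `Formula`, `Adduct` and the `m/z` columns are carried
  as per-compound metadata. Header matching is case-insensitive and
  whitespace-tolerant.
* **compound_discoverer** — wide; `Compound` and `RT [min]` plus sample
  columns matching `"Area: <file>.raw (F<k>)"` or `"Norm. Area: …"`; the
  file name (minus `.raw`) becomes the sample id.
* **compounds_in_columns** — samples in rows; every column after the first is
  a metabolite, so stray annotation columns become (nonsense) metabolites by
  construction — the format has no way to tell them apart.
* **other_list** — exactly four columns in fixed order (metabolite, RT,
  file, area); extras are ignored with a warning.
* **other_matrix** — metabolite and RT columns, then one column per sample.

Delimiters (comma / semicolon / tab) are sniffed for text files; a single
comma in an otherwise numeric cell is accepted as a decimal separator, which
covers semicolon-separated European exports. Excel files are read from the
first sheet and must have a single header row.

Empty cells and the tokens `NA`, `NaN`, `N/F`, `N/A` are missing. Zeros are
kept as explicit zeros unless the compounds-in-columns option
`zeros_as_missing` is set. An intensity threshold (compound_discoverer and
other_matrix only) treats values *below* it as missing; the threshold itself
passes, reading "must be reached" inclusively. Missing values are never
imputed or zero-filled anywhere in the pipeline: they are excluded from
means, sums, fold changes and MIDs, and are exported as empty cells.

Duplicated compound names are resolved by appending the retention time as
`name@RT` with two decimals (a readable, collision-free convention; the
format of the merge is otherwise arbitrary). A duplicate without an RT is an
error, since nothing can distinguish the species.

## Sample design

The sample table (template generated by the package, then edited by the
user) carries per sample: condition, display order, colour, experimental and
technical replicate labels, an external correction value and an include
flag. Colours are hex strings or standard R colour names resolved through a
bundled 657-entry lookup table, so no R runtime is needed. Condition order
ties are broken by first appearance. Excluded samples are dropped from every
computation but the raw input is still copied to `Inputs/` unmodified, so a
run can always be repeated from its own outputs.

Technical (measurement) replicates are averaged within each experimental
(biological) replicate using the arithmetic mean over non-missing values;
an all-missing group stays missing. The mean (rather than, say, the median)
is the natural choice for instrument replicates of the same extract, whose
variation is multiplicative noise around a common level.

## Normalisation

Three factor families, each applied absolutely ($I' = I/c_s$) or relatively
($I' = (I/c_s)\,\bar c$ with $\bar c$ the arithmetic mean of the factors over
included samples):

* **external** — the user-supplied correction value (cell count, protein);
* **internal** — the per-sample sum of selected internal-standard compounds
  (so abundant standards dominate; a standard missing in a sample
  contributes zero with a warning, and a sample where *all* standards are
  missing is an error); the standards remain in the table and are
  themselves normalised;
* **Total Peak Sum** — the per-sample sum of all non-missing intensities,
  for experiments without a representative standard. All detected rows,
  including isotopologue rows and internal standards, enter the sum; with
  heavy labelling one may prefer an internal standard instead.

Internal normalisation runs before or after external correction as
configured (`internal_timing`); the two orders genuinely differ whenever
relative modes meet unequal factors, and the run report records the
effective order. Relative mode with constant factors is the identity, and
relative Total Peak Sum conserves the grand total exactly — both are tested
invariants. No log transformation, scaling or other massaging is applied:
the data are shown as measured.

## Replicate quality control

Fold changes $f(m,s) = I(m,s) / \operatorname{mean}_{r}\,I(m,r)$ are
computed per metabolite within each condition (conditions with a single
replicate are skipped). The arithmetic-mean denominator makes the
per-metabolite mean of fold changes exactly 1 on complete data, so the
distribution of all metabolites' fold changes per sample should centre on 1;
the per-sample mean is the QC summary. Samples are flagged when
$|\log_2(\text{mean})|$ exceeds $\log_2(\text{tolerance})$; the default
tolerance of 2 is deliberately permissive (a sample's mean can only approach
2 asymptotically when it is uniformly 2× its partners, since it drags its
own denominator up — with $n$ replicates the ceiling is $2n/(n+1)$), so
flagging a uniform 2× sample requires lowering the tolerance to ~1.5. QC
runs after external normalisation and before internal normalisation when the
internal step is timed `after_external`, otherwise after all normalisation;
this is a package choice, documented rather than asserted as anyone else's
behaviour.

## Isotopologue grouping and natural-abundance correction

Labels ending in `" +<n>"` are isotopologues of the base compound with a
mass shift of $n$ Da; only a trailing space-plus-integer is consumed, so
names with internal plus signs (`NAD+`) survive. Shifts run to M+30.
Grouping is a lossless partition; shifts absent from the data are stored as
absent (not zero) but render as zero-height stack segments, with M+0 at the
bottom of each stack. Relative MIDs divide by the sum of non-missing
intensities, treating missing isotopologues as zero contribution; an
all-missing (compound, sample) pair has no MID and is dropped from relative
plots with a warning.

Correction is classical low-resolution matrix deconvolution built from the
compound's elemental formula (elements C, H, N, O, P, S; P has no stable
heavy isotope and contributes nothing; Si/Cl/Br are rejected, so GC-MS
derivatives are out of scope). For a tracer with purity $p$ and a molecule
with $j$ of its $N$ tracer atoms nominally labelled, the predicted mass-shift
distribution is the convolution of: a Binomial$(j, p)$ for the labelled
positions (impurity shifts mass down), a Binomial$(N-j, a)$ at natural
abundance $a$ for the remaining tracer atoms, and — unless `carbon_only` —
the independent polynomial convolution of every other element's isotopes,
which handles +2 Da species (¹⁸O, ³⁴S) exactly rather than by a
binomial-per-shift approximation. Stacking these distributions as columns
gives the correction matrix $A$; the measured vector is inverted by
non-negative least squares (`scipy.optimize.nnls`), which unlike a plain
matrix inverse cannot produce negative intensities. Missing isotopologue
entries enter the solver as zeros with a warning and the affected compounds
are flagged in the export.

Defaults: `carbon_only=True`, appropriate for high-resolution Orbitrap-style
data where non-tracer isotopes are mass-resolved away from the tracer
shifts — and consistent with treating a 10-carbon molecule's natural M+1 as
$10 \times 0.011 \times 0.989^9 \approx 9.96\%$, i.e. the absolute M+1
fraction (the strict ratio to M+0 would be 11.1%). The isotope table pins
¹³C at 1.1% and uses standard IUPAC abundances for ²H (0.0115%), ¹⁵N
(0.364%), ¹⁷O/¹⁸O (0.038% / 0.205%) and ³³S/³⁴S (0.75% / 4.21%); it is
user-overridable. Resolution-dependent correction (taking the mass
analyser's resolving power as input) is deliberately not implemented.

## Statistics

The $t$ test uses pooled variance (equal variances assumed); "Wilcoxon"
means the two-sample rank-sum (Mann–Whitney) test, since conditions are
independent groups — exact null distribution for ≤8 per group without ties,
normal approximation with continuity correction otherwise. Comparisons are
all pairwise or versus a reference condition; groups with fewer than two
non-missing values are skipped and annotated `n/a`. Symbols follow the
conventional four-star thresholds (0.05 / 0.01 / 0.001 / 0.0001); numeric
display uses three significant figures with a `<0.001` floor. **No
multiple-testing correction is applied** — with many metabolites × many
pairs, the raw p-values on the plots are descriptive, not confirmatory.

## Plotting

Bar and scatter plots show mean ± sample standard deviation ($n-1$
denominator). Violin plots (Silverman-bandwidth density, median) require ≥5
replicate measurements per condition and box plots (median, quartiles by
linear interpolation, whiskers at the most extreme value within 1.5×IQR)
require ≥10 — below that the summaries mislead. Replicate-comparison
variants split each condition by experimental replicate. Output formats are
jpg/pdf/png/svg at configurable size and dpi; filenames are the compound
names with filesystem-hostile characters (`: ; < > / \ | ? * "`) replaced by
underscores and numeric suffixes on collision. Default quantitative colours
are Paul Tol's qualitative schemes; tracing stacks use two fixed scales
(short: 8 colours to M+7, a saturation/value-boosted rainbow; long: grey
M+0 plus 5 hue blocks × 3 shades to M+15, cycling beyond). The exact hex
values are pinned in this package and follow the described construction, not
any other tool's bytes. Rendering is headless (`Agg`), embeds no timestamps,
and the final zip (`Plots/`, `Tables/`, `Inputs/`) is written with sorted
member order and fixed timestamps, so identical runs produce identical
archives. The zip is only written after every stage has succeeded.

## Synthetic data

The generator emulates the two study shapes the tool targets, and its
defaults are those designs: quantitative — 99 compounds, 5 conditions, 4
experimental replicates; tracing — 38 base compounds, 4 conditions,
triplicates. Peak areas are log-normal (median 10⁶, σ=1.5 across compounds)
with per-condition effect multipliers (default 1.5-fold steps) and
multiplicative per-measurement noise (σ=0.1); a 5% default missing rate is
injected with 3:2:1 odds across low/mid/high abundance tertiles, mimicking
detection-limit censoring. Tracing intensities are the exact forward model
`correction_matrix @ true_MID` (tracer purity 0.99) scaled by abundance and
noise, so the correction stage has known ground truth; labelling increases
across conditions like a time course. What the generator does **not**
emulate: retention-time drift, correlated (batch) effects, heteroscedastic
detector noise, peak-integration failures that censor independently of
abundance, and chemical constraints among metabolites. Tests passing on
these fixtures therefore validate the arithmetic and the contracts, not the
behaviour of any instrument.

Scale choices in the test suite are the package's own: the stress check runs
1000 compounds × 5 conditions × 3 replicates end to end (the untargeted
regime), statistical calibration uses 1000 null simulations, and MID
recovery uses 100 random distributions over 3–10 carbons at purities
0.95–1.0.

## Numerical choices and degenerate inputs

* NNLS returns exact zeros at active constraints; recovered MIDs are
  renormalised before comparison when the measured vector carries noise.
* An all-zero measured vector corrects to all zeros without error.
* Correction-matrix columns sum to ≤1; truncated tail mass (shifts beyond
  the observed range) is simply lost, so corrected totals can slightly
  exceed measured totals.
* Identical groups in the $t$ test (zero pooled variance) return $t=0$,
  $p=1$ rather than NaN.
* Empty inputs (header-only files) parse to empty tables without error;
  compounds with no measured value are skipped at plot time with a warning.
* The 25 MB input cap mirrors the hosted original and is configurable; it
  is a hosting artefact, not a scientific constraint.

## Limitations

Discrete x-axes only (no numeric time/concentration axes), no grouped or
nested condition layouts, condition names must be unique, no dual-tracer
deconvolution, no positional isotopomer or flux analysis, no
resolution-dependent correction, and no correction for Si/Cl/Br-containing
derivatives. Parsing starts from quantified tables; raw or mzML files,
peak detection and identification are out of scope.
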