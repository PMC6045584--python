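# Methods

## Scope and data model

The package analyses plate-based chemosensitivity screens: a panel of
cell lines, each screened in replicate against a small-molecule library
laid out as dose titrations on 384-well plates, with viability read out
as end-point luminescence. Inputs are long-format CSV/TSV tables
(reads: `cell_line, replicate, plate_id, well, luminescence`; layout:
`plate_id, well, role, compound_id, conc_nM`), with well roles
`compound`, `dmso`, `positive`, `empty`. Wells are validated against
16×24 geometry (`A1`..`P24`) and stored 0-based. Parsing is independent
of row order and line endings; score matrices (cell line × drug, first
column `cell_line`) round-trip through text at full double precision,
with missing values as empty cells. The plate map is never assumed: an
explicit layout file is required, because compound/control positions
are an experimental choice the reads file cannot encode.

## Normalisation and quality control

Surviving fraction is per-plate: SF = luminescence / median(same-plate
DMSO wells). A zero or absent DMSO median is an error, not a silent
NaN. SF > 1 (wells brighter than the DMSO median) is retained — clipping
before curve fitting would discard information; clipping happens only
inside the AUC integrands.

Two per-cell-line gates decide inclusion, both strict inequalities:

- **Replicate reproducibility.** Pearson r for every unordered
  replicate pair over shared (compound, dose) keys, missing entries
  excluded pairwise; the gate uses the median pairwise r > 0.7. The
  median (rather than the minimum) is robust to a single bad pair;
  callers wanting the stricter rule can gate on `min(pairwise_pearson)`
  themselves.
- **Dynamic range.** Z′ = 1 − 3(σ₊+σ₋)/|μ₊−μ₋| per (replicate, plate),
  with sample (ddof=1) standard deviations, DMSO wells as the negative
  population and designated maximum-kill wells as the positive one;
  gate: median Z′ > 0.3. Z′ is undefined without two control
  populations, so the layout schema requires `positive` wells and the
  simulator creates them; whether a real screen used a toxic compound
  or an empty-well proxy is an input decision, not something the code
  guesses.

Excluded lines are reported with the failing criterion and never
fitted; they do not appear in score matrices.

## Dose-response model and fitting

Survival is modelled as the three-parameter log-logistic curve with the
lower asymptote fixed at zero, SF(c) = d/(1+(c/e)^b) — the standard
"LL.3" choice for viability data normalised to vehicle, where complete
kill drives the signal to background. Replicate observations are pooled
without averaging (each replicate point is one residual) and fitted by
ordinary least squares with bounds b ∈ [0.1, 10], d ∈ [0, 1.5],
e ∈ [c_min/100, 100·c_max]. Initialisation is multi-start: e at every
distinct tested dose × b ∈ {0.5, 1, 2}, d at the maximum observed SF
clipped to [0.5, 1.5]; the lowest-RSS solution wins, ties broken by the
smaller slope. Solver tolerances are 1e-13; a start that exhausts its
evaluation budget is still accepted as a candidate because for
degenerate data (e.g. near-complete kill at every dose, where d and e
trade off along a ridge) the solver reaches an excellent plateau
without formally satisfying the tolerance. `converged=False` — and
missing downstream scores rather than sentinel numbers — occurs only
when every start fails outright. Genuinely flat data (SF ≈ 1
everywhere) fit cleanly with d ≈ 1 and produce AUC = 1, the correct
"no effect" score.

On noise-free 8-dose data the fit recovers (b, d, e) to ~1e-15 relative
error; under 10% multiplicative lognormal noise with 3 replicates the
estimated unscaled AUC preserves the true sensitivity ranking across a
50-line panel with Spearman ρ ≈ 0.99 (both re-measured by
`scripts/acceptance.py`).

## AUC scoring

Both scores integrate on the natural-log dose axis, normalised by
L = ln(c_max/c_min), so they are dimensionless mean quantities in
[0, 1] regardless of the tested range, and invariant to rescaling all
concentrations by a common factor:

- unscaled: AUC_u = (1/L)∫ clip(SF, 0, 1) d ln c — mean survival, the
  complement of activity area measured against reference activity 0;
- scaled: with a(c) = clip(1−SF, 0, 1) and A_ref = max(0, a(c_min)),
  AUC_s = 1 − (1/L)∫ max(0, a(c) − A_ref) d ln c — only activity beyond
  the lowest-dose baseline counts, so a drug already maximally active
  at the bottom of the titration (or a dose-flat toxicity) scores 1.

When a(c_min) = 0 the two definitions coincide; AUC_s ≥ AUC_u always.
Quadrature is adaptive (`scipy.integrate.quad`, absolute tolerance
1e-6, 200 subdivisions); agreement with a 10⁵-point trapezoid oracle is
~4e-7 worst-case over wide random parameter draws.

Robust Z standardises the **unscaled** AUC per drug column across the
panel: Z = (AUC − median)/(1.4826·MAD), the normal-consistent MAD
convention. Columns with MAD = 0 become missing with a warning;
columns need ≥3 observed values. Z is invariant to shifting or
positively rescaling a column.

## Association statistics

All p values are deliberately uncorrected — the screen-resource
convention is to flag candidate associations per marker/drug pair;
panel-wide scans need multiplicity control downstream (the CLI prints
this caveat, and the proteomics report carries reference
Benjamini–Hochberg q-values in a clearly separate column).

- **Mann–Whitney U** (two-sided): exact null when min(n₁,n₂) ≤ 8 with
  tie-free data, otherwise the tie-corrected normal approximation
  without continuity correction (so exchangeable groups give exactly
  p = 1). The reported U is the classic min(U₁, U₂). Verified against
  full enumeration of all C(n,k) label assignments for n ≤ 10.
- **Spearman** with average ranks and the t-approximation p; incomplete
  pairs dropped, ≥3 required.
- **Sensitivity ranks**: rank 1 = most negative Z; ties share the
  minimum rank; missing scores stay unranked.
- **Curve comparison ANOVA**: additive two-factor fixed-effects model
  SF ~ cell line + dose (both categorical, no interaction), p for the
  cell-line main effect from the classical sums-of-squares
  decomposition (statsmodels OLS + anova_lm, type 2 — identical to the
  classical decomposition for the balanced designs required here).
  Requiring ≥2 observations per (dataset, dose) keeps the residual an
  honest replicate error rather than lack-of-fit. The additive model is
  one design choice among several defensible ones; adding an
  interaction term changes the residual df and is left to the caller.
- **Foci positivity**: a cell is positive when its nuclear focus count
  strictly exceeds the threshold (default 5, i.e. "more than five");
  per-replicate positive fractions are compared between two conditions
  by the two-sided equal-variance Student t-test.

## Proteomics differential filter

Per protein: Welch's unequal-variance t (Welch–Satterthwaite df,
two-sided) on log2 LFQ values, with Δ = mean(B) − mean(A). The mean is
used for Δ for consistency with the mean-based test; a median-based
effect can be computed from the returned per-group values if preferred.
Missing values are excluded per protein with no imputation; fewer than
two observed values in either group skips the protein with a recorded
reason. Significance requires p < 0.05 AND |Δ| > 3, both strict —
the effect-size gate is what holds false positives near zero when
thousands of null proteins are tested at raw p < 0.05 (measured: recall
1.0 of 30 proteins spiked at Δ = 4, σ = 0.5, n = 3/group over 1000
nulls, with 0 false positives). Significant proteins are ranked by |Δ|
descending within the over- and under-expressed sets.

## Synthetic data: what it emulates, and what it does not

The generator is the package's study-condition definition, not a
tuning knob. Defaults: the 8-point titration 0.5, 1, 5, 10, 50, 100,
500, 1000 nM; 3 replicates; base luminescence 1000 RLU; multiplicative
lognormal read noise with σ = 0.1 (≈10% CV, typical for end-point
luminescence viability reads, whose noise scales with signal — hence
multiplicative, not additive); 16 DMSO and 16 positive-control wells
per plate; positive controls at 2% residual signal (98% kill — a
realistic maximum-kill control that keeps Z′ informative without
saturating at zero). True (b, d, e) draws: b ~ U(0.8, 2.5),
d ~ U(0.92, 1.05), log-uniform ED50 from the lowest dose to 10× the
top dose, spanning profound sensitivity through near-inactivity.
Genotype effects divide the ED50 of targeted drugs by a configured fold
for a configured fraction of lines. For the designed 30-fold effect in
6/20 lines, the resulting Mann–Whitney p fluctuates between ~0.003 and
~0.2 across seeds — an honest reflection of the limited power of a
20-line panel against a potency distribution spanning four orders of
magnitude.

True AUCs are computed by dense (10⁵-point) trapezoid quadrature on the
true parameters in the simulator module itself — an oracle path that
never touches the fitting/scoring code, so pipeline-vs-truth
comparisons are genuinely two-route.

The fixture bundle hard-codes a six-line panel with an HR-defective
hypersensitive analogue (PARPi ED50 2 nM), a resistant revertant
analogue (50 µM), four intermediate lines, three PARPi-like drugs
sharing per-line potency, and one kinase-inhibitor control drug that
every line responds to (so replicate correlations stay informative even
for PARPi-resistant lines), at σ = 0.05.

Not modelled, deliberately: spatial/edge plate artifacts, inter-day
batch effects, plate-to-plate drift, cell-seeding-count variation, and
dose-dispensing error. Passing tests therefore demonstrate correctness
of the analysis chain under well-behaved noise, not robustness to the
systematic artifacts a real screening campaign must additionally QC.

## Problem sizes and numerical choices

The test suite and acceptance script use panels of 1–50 cell lines,
1–4 drugs, 3 replicates, and proteome matrices of ~1000 proteins —
sizes at which every stage's behaviour is already fully exercised while
a complete run takes well under a minute per stage. Quadrature
tolerance 1e-6 absolute; solver tolerances 1e-13 with 2000-evaluation
budget per start; fit tie-break by smaller slope; degenerate inputs
(no DMSO wells, zero MAD, single-class labels, mismatched dose grids,
all-missing columns) raise informative errors or produce flagged
missing values as documented per function, never silent sentinels.
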