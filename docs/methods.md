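# Methods

This note documents the models, estimators and numerical choices behind
`tracefate`, and what the synthetic-data generators do and do not emulate.

## 1. Natural-abundance correction

**Model.** Only carbon isotopes are modelled. A molecule with `j` tracer
carbons out of `N` has each of its `N−j` remaining carbons carrying a
natural ¹³C independently with probability `p13` (default 0.0107,
configurable everywhere it appears). The observed mass shift is therefore
`j + Binomial(N−j, p13)`, giving the lower-triangular column-stochastic
matrix

    C[i, j] = C(N−j, i−j) · p13^(i−j) · (1−p13)^(N−i),   i ≥ j.

The entries are computed from the closed form via `scipy.special.comb`
rather than a pmf routine, which keeps the matrix exact at `p13 = 0` and
stable for subnormal `p13`.

**Correction.** Given measured intensities `y` (normalised to sum 1), the
corrected MID solves `min ‖C·x − y‖` subject to `x ≥ 0`
(`scipy.optimize.nnls`), then renormalises. The unconstrained triangular
solve with negatives clipped (`solve_clip`) is retained as a cross-check
path; on noiseless data both return the true MID to < 1e−8 (property
tested against an independently coded polynomial-convolution forward
model). NNLS is the default because clipping can redistribute mass
incorrectly when noise drives small fractions negative.

**Not modelled:** N/H/O/S isotopes, tracer impurity (a purity parameter
would pre-convolve the tracer channel; labelling is assumed 100 % pure),
spectral-resolution effects, positional (isotopomer) information.

## 2. First-turn TCA labelling model

Three fractions parameterise the stationary first-turn labelling state:

| parameter | meaning | range | preset (parental / mesenchymal) |
|---|---|---|---|
| `f_pyr` | fraction of the pyruvate pool that is tracer-derived (M+3 under U-¹³C₆ glucose) | [0,1] | 0.8 / 0.8 |
| `g_pdh` | fraction of citrate acetyl units supplied by labelled pyruvate via PDH | [0,1] | 0.3 / 0.6 |
| `q_gln` | fraction of the glutamate pool derived directly from glutamine | [0,1] | 0.7 / 0.5 |
| `d_lac` | lactate dilution relative to pyruvate | [0,1] | 0 |

Under the glucose tracer: pyruvate M+3 = `f_pyr`; lactate M+3 =
`f_pyr(1−d_lac)`; citrate, α-ketoglutarate and malate M+2 =
`g_pdh·f_pyr`; glutamate M+2 = `g_pdh·f_pyr·(1−q_gln)`; the remainder sits
at M+0. Under the glutamine tracer only glutamate is labelled (M+5 =
`q_gln`). Consequences used by the analysis:

* the (glutamate M+2)/(pyruvate M+3) ratio equals `g_pdh(1−q_gln)` — a
  PDH-activity proxy strictly increasing in `g_pdh`;
* the model is exactly invertible from paired tracer arms
  (`recover_flux_params`), which closes the generator → pipeline →
  estimate loop in the tests.

The presets were chosen once so that the qualitative
mesenchymal-vs-parental pattern (more glucose carbon in the TCA cycle,
lower glycolysis/OXPHOS ratio) emerges by default; the true magnitudes in
the motivating experiments exist only as figures and were never used for
calibration.

**Deliberate simplifications:** single-turn only (no M+4 species from a
second TCA turn), no pyruvate-carboxylase (anaplerotic) M+3 citrate, no
reductive carboxylation, no exchange fluxes. A green recovery test
therefore establishes that the estimators invert *this* model, not that
they would resolve multi-turn isotopologue patterns in real data.

**Noise model.** Each replicate's smeared MID is scaled by a lognormal
abundance (log-SD 0.2 around 10⁶ counts) and each isotopologue is
multiplied by unit-mean lognormal noise with coefficient of variation
`noise_cv` (default presets 0; 0.05 in the demo pipeline, matching typical
LC-MS technical variation), floored at zero. All draws flow through one
seeded `numpy.random.Generator`.

## 3. Group comparisons

`student_t_compare` is a pooled-variance two-sample Student t
(df = n₁+n₂−2, two-tailed), the test named by the source study's methods;
Welch's variant sits behind `welch=True` and is used for the sensitivity
report in the screen benchmark. The t statistic is oriented
first-group-minus-second; the fold-change is second-over-first. Zero
pooled variance with equal means returns t=0, p=1; with unequal means
p=0 flagged `degenerate`. Fractions are reported in [0,1]; percentage
axes are presentation-layer ×100.

## 4. Consistency screens

Per model, metabolite fold-change = mean(mesenchymal)/mean(parental) on
raw abundances and p from the Student t on raw values (log-scale option
behind a flag); gene log2-FC = mean difference of log2 expression, BH-FDR
within each model over all genes (not pooled across models). "Absolute
fold-change > T" is applied two-sidedly (FC > T or FC < 1/T). A hit must
pass thresholds in **every** model with a consistent direction
(`require_same_direction=True` by default, the stricter reading).
Metabolites with an all-zero parental condition have undefined FC; they
are flagged and excluded from ranking rather than silently dropped.

With three models the intersection rule compounds a per-model α = 0.05 to
≈ 1.25×10⁻⁴ per feature before the FC gate, which is why 100 null
simulations of 400 features have a median hit count of 0.

**Detectability ceiling of the unmoderated t.** With the microarray
design's 3 replicates per condition, the pooled t has df = 4 and its
two-sided p cannot realistically fall below ~10⁻⁷ even for an 8-fold
planted change — after BH adjustment over thousands of genes this never
clears the 10⁻⁵ FDR gate. (The original analysis used a moderated
(limma-style) t, which is out of scope here.) The synthetic expression
world therefore uses 5 replicates per condition (σ = 0.15 log2 units),
where the planted 8-fold *PDK4* loss is recovered and *PDK1–3* remain
unflagged. This is a property of the estimator, not a tuning decision.

**Published-supplement benchmark.** The real metabolomics supplement is an
external binary spreadsheet that cannot be redistributed with this
package. The benchmark in the test suite instead runs the exact filter on
a synthetic stand-in planted with the published hit *structure* — 10
consistent metabolites out of 400, 5 of them annotated amino acid or
peptide (using the five published metabolite names) — so a green test
certifies the filter logic against generator ground truth, not agreement
with the published measurements.

## 5. Survival analysis

* **Median split:** high iff expression strictly above the cohort median;
  ties at the median go to the low stratum (fixed convention; it only
  matters for discretised expression values).
* **Kaplan-Meier:** `lifelines.KaplanMeierFitter` behind the `km_curve`
  surface (product-limit; censoring shrinks the risk set without a step).
* **Cox:** single binary covariate; Newton's method on the partial
  likelihood with Efron's tie approximation; SE from the observed
  information. Implemented in-package (the estimator is small, and the
  calibration tests need ~10³ fast fits); `lifelines.CoxPHFitter` serves
  as an independent oracle in the tests, alongside a brute-force grid
  maximisation of a hand-written partial likelihood. A monotone
  likelihood (complete separation) is detected when the Newton step
  diverges or the information degenerates; the estimate is clamped to
  |log HR| ≤ 15, flagged, and a warning is raised. Breslow ties were not
  implemented: Efron is the common default and no consumer requests
  Breslow.
* **Meta-analysis:** fixed-effect inverse-variance combination (the
  described procedure — combining per-study values and standard errors);
  DerSimonian–Laird random effects behind `random_effects=True` since the
  originating analysis does not name its model. The fixed-effect identity
  `combined se ≤ min per-study se` is property-tested.

The survival generator draws exponential event times with hazard
`baseline · true_hr^[low]` and independent exponential censoring —
proportional hazards holds exactly, so consistency tests check the
estimator, not robustness to PH violations. Defaults (150
patients/cohort, 3 cohorts, baseline 0.02 events/month, censoring
0.01/month, true HR 2) give event fractions (~60–70 %) typical of
published lung-adenocarcinoma cohorts.

## 6. Pipeline determinism

`run_all` derives every stage seed from the root seed by fixed offsets;
CSVs are written with a fixed float format (`%.10g`) and newline
convention, so identical seeds give byte-identical statistical outputs
(asserted in the acceptance suite). The manifest records the package
version, seed, thresholds and SHA-256 checksums of the simulated input
tables.

## 7. Known limitations

* No positional isotopomer or multi-turn information; the labelling model
  is diagnostic, not a flux-fitting (EMU/cumomer) system.
* Screens assume equal replicate counts per condition within a model and
  independence across features; no imputation beyond the zero-abundance
  rule.
* The expression generator plants mean shifts with homoscedastic Gaussian
  noise on the log2 scale — no probe effects, batch structure or
  variance–mean dependence, so moderated-variance methods cannot be
  meaningfully compared against it.
* Survival cohorts are endpoint-agnostic; real cohorts mix overall and
  recurrence-free survival, which the math ignores by design.
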