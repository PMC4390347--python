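# Methods

This note documents the statistical model behind `trapscreen`, the
choices made where the design was genuinely open, and what the synthetic
tests do and do not establish about real screens.

## Screen model and statistics

A screen consists of mutant ESC clones (one per trapped gene by default)
and wild-type replicate samples, each measured in duplicate wells at a
0-Gy reference dose and one or more irradiation doses. Each well yields
dead-cell and total-cell luminescence (RLU) from the cytotoxicity assay
and, for mutant clones, β-gal reporter luminescence. Live signal is
always derived as `total − dead`; it is never a stored measurement.

**Viability.** `%viability = (total − dead)/total`; duplicates are
averaged at the %viability level (averaging raw RLU first is available as
an option, and the two commute only when duplicate totals are equal);
ΔV = V_d − V_0 per clone and dose contrast. The null is the sample mean
and n−1 SD of the wild-type replicate ΔV values, fitted separately per
dose contrast because chance variability grows with dose. Clones are
scored with Z = (ΔV − μ_wt)/σ_wt and two-tailed normal p-values; the
normalisation to wild type is this centering itself — there is no second
subtraction step. Direction is the sign of (ΔV − μ_wt), not of raw ΔV, so
a clone that merely tracks wild-type drift is not called directional.

**Expression.** E = β-gal/live per well, duplicates averaged at the
normalised-expression level, r = E_d/E_0, x = log₁₀ r (base 10
throughout: a 2.76-fold change is 0.44 log units). Wells with no live
signal are excluded from expression analysis with a log message. Because
wild-type cells carry no reporter, the null (μ, σ) is estimated from the
clone population itself by the robust consensus estimator below, per dose
contrast. Z, p and hit calls then use the same machinery as viability.

**p-values.** `2·Φ(−|z|)` is computed with the scipy survival function,
accurate far past |z| = 6. A finite z never yields p = 0: results carry a
`log10_p` column, and the table writer renders p/q values below 1e-300 as
the explicit sentinel `<1e-300` rather than a silent zero.

**Enrichment.** For hits pooled per category across doses, each gene set
is intersected (case-insensitively — mouse symbol capitalisation varies
across annotation sources) with the screen background before its
population count K is taken. Terms with K < 3 or overlap k < 2 are
removed *before* adjustment, so the Benjamini–Hochberg family is exactly
the set of terms actually tested. The statistic is the one-sided
hypergeometric tail P(X ≥ k); depletion is not tested. Annotations are
counted flat from the GMT file; no ontology-graph propagation is applied.

## The robust null estimator

The expression null must be estimated in the presence of true hits,
which are outliers by construction. The estimator keeps the RANSAC
skeleton — `n_iterations` seeded random draws of `min_sample` values
propose candidate locations — but scores each candidate by the SD of the
`⌈min_consensus_fraction·n⌉` points nearest its mean and lets the
tightest such majority win. This is a minimum-variance-subset (1-D MCD)
objective; plain inlier *counting* against a scale estimated from the
contaminated sample fails under heavy one-sided contamination, because
the inflated scale lets mid-position candidates straddle both modes and
win the count. The winning subset seeds a reweighting loop: inliers
within `inlier_threshold` (default 2.5) robust-scale units of the current
location are refit, with the in-loop scale corrected by the fixed
truncated-normal consistency factor at ±threshold, iterated to a fixed
point (≤ 20 rounds; the map is contractive on normal data).

The reported σ is the consensus SD corrected at the *empirical* kept
fraction f, i.e. divided by the truncated-normal SD factor at
c = Φ⁻¹((1+f)/2), clipped to [2.0, threshold]. The empirical correction
makes σ agree with the full-sample SD wherever the fixed point settles on
clean data; the floor at c = 2.0 (≈ 4.6% exclusion) stops genuine outlier
removal — which is not normal-tail truncation — from inflating σ. This
correction is applied only to the reported value, never inside the loop,
where it would feed contamination back into the band width.

Behaviour, measured at n = 400 with σ = 0.3 and one-sided contamination
offset +1.5 (the test suite re-runs these): location bias ≤ ~0.02
for contamination 0–30% (the naive mean drifts as 1.5·fraction); on clean
data μ and σ match the plain sample moments within 0.02. A
`RobustFitError` is raised when the stable consensus covers less than
`min_consensus_fraction` of the data — e.g. for Cauchy-tailed samples at
a demanded fraction of 0.9 — signalling that no normal-consistent
majority exists and a trimmed estimate should be considered instead.
Hyperparameters (2000 iterations, minimal samples of 5, threshold 2.5,
fraction 0.5, fixed seed) are defaults sized for ~400-point 1-D problems
and are exposed in `RansacConfig`.

## Synthetic screens

The generator's defaults are the original study's conditions: 386 clones,
22 wild-type replicate samples, duplicates, doses (0, 0.5, 4) Gy, mean
wild-type viability 0.6. The wild-type ΔV null — mean −1.5% / SD 6.7% at
0.5 Gy, −2.7% / 8.0% at 4 Gy — and the log₁₀-ratio null SDs (0.14,
0.19) are back-derived from the published hit tables: since
Z = (x − μ)/σ is affine in the printed statistic, least squares of
printed Z on printed x recovers σ and μ per dose with residuals < 0.001
(viability) and < 10⁻⁴ (expression), limited only by print rounding.

Per well, viability is `base + clone baseline + dose systematic +
planted effect + well noise`, clipped to [0.02, 0.98] (clipping logged);
the dose-systematic SD is calibrated so the *duplicate-averaged* ΔV null
has exactly the configured SD after the well-noise contribution
(2·w²/n_dup) is accounted for. RLU mapping multiplies a per-well
lognormal gain (CV 10%) into both dead and total signals — luminescence
gain varies per well, the within-well dead/total ratio does not — so the
drawn viability is preserved exactly and the convergence of simulated
ΔV moments to their configured values is exact rather than approximate.
β-gal RLU is live RLU × a lognormal per-clone baseline × 10^(dose
systematic + planted effect + well noise); the log-ratio SD calibration
accounts for the duplicate-averaged reporter noise to first order
(residual error < 0.5% relative, far below the sampling noise of any test
herein). Wild-type units run through the identical model minus reporter
and effects, making wild-type and null-clone ΔV exchangeable by
construction. The default well-noise split reproduces duplicate
concordances near the study's reported values (viability r ≈ 0.7–0.8,
β-gal r ≈ 0.99).

All draws derive from a single seed through fixed per-stage substreams,
so a config snapshot regenerates byte-identical fixtures and editing one
stage's parameters leaves other stages' draws unchanged.

**What the generator does not emulate:** plate-position (edge) effects,
between-day batch structure, dose–response curvature across validation
doses, mechanistic survival models, or multi-clone genes (available but
off by default). Passing tests therefore validate the statistical
machinery under the stated noise model, not robustness to spatial or
batch artefacts in real plates.

## Calibration of hit calling at small control counts

With the null estimated from n wild-type replicates, the statistic
(ΔV − μ̂)/σ̂ is √(1+1/n)·t with n−1 degrees of freedom, not standard
normal. At the study's n = 22, the normal p < 0.01 cut-off has an exact
two-sided type-I rate of 2·P(t₂₁ > z₀.₉₉₅/√(23/22)) ≈ 0.020 — double
nominal. This is a property of the published procedure, not an
implementation artefact, and the planted-effect experiments at the
study's scale verify the empirical false-call rate against this exact
t-based value. The calibration experiment that checks the calling rule
itself (10 000 null tests at α = 0.01 inside the exact binomial 95% CI)
therefore scales the control count with the screen (2000 wild-type
replicates), so that it measures the rule's nominal calibration rather
than the small-n inflation already characterised analytically. The
expression side estimates its null from ~380 clones and is close to
nominally calibrated; the robust-σ floor makes it mildly conservative
(empirical false-call rate ≈ 0.007–0.010 at α = 0.01) when ~10% of the
population carries planted effects.

Experiment sizes used by the test suite and acceptance script — 10 000
clone-dose tests for calibration, 50 replicate screens with 20 planted
genes per effect category (1000 trials per category), 25 replicates per
contamination level — were chosen so that each estimated rate resolves
its validation bound with comfortable power.

## Degenerate inputs and numerical edge cases

Wells with dead > total RLU are excluded and logged at load (QC flag);
wells with zero total signal are dropped from viability; wells with no
live signal are dropped from expression. A constant control sample
raises a degenerate-null error rather than emitting infinite Z. GMT
lines with fewer than three fields fail with their line number.
Ties in the consensus objective break toward the smaller consensus SD;
enrichment output sorts by (q, p, term id) for deterministic order.

## Known limitations

* The duplicate correlations reported for the original screen (0.72
  viability, 0.98 β-gal) depend on its unpublished raw well data; the
  generator reproduces them only as orders of magnitude, and which metric
  they were computed on is not documented.
* Whether the original analysis pooled wild-type nulls across doses is
  not stated; per-dose nulls are implemented because the back-derived
  scales differ (0.067 vs 0.080).
* The original RANSAC variant and its hyperparameters are undocumented;
  the estimator here is a declared design, validated by its published
  internal consistency (Table-row residuals) and by simulation, not by
  equivalence to the original code.
* Enrichment q-values depend on the annotation release; only the filter
  semantics and the statistic are validated, not any specific term list.
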