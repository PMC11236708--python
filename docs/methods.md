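# Methods

`capsmeta` implements the quantitative synthesis of evidence on
cannabis-associated psychotic symptoms (CAPS): transient hallucinations,
paranoia and/or delusions during cannabis intoxication, studied through
three lenses — observational surveys of recreational users, experimental
THC-challenge studies, and safety data from medicinal-cannabis trials.
The package has two analysis arms: *rates* (what fraction of exposed
individuals report CAPS) and *predictors* (how strongly a factor — a THC
dose, a psychiatric liability, age — shifts CAPS severity, expressed as
Cohen's d).

## Effect-size harmonization

Studies report their evidence in incompatible forms; everything is mapped
to a standardized mean difference d with an analytic sampling variance
before pooling.

| input | point estimate | variance |
|---|---|---|
| group means/SDs | d = (M_E − M_C)/SD_P, SD_P the Cohen pooled SD | (n_E+n_C)/(n_E·n_C) + d²/2(n_E+n_C) |
| paired means/SDs | d = (M_T1 − M_T2)/√(SD₁² + SD₂² − 2r·SD₁SD₂) | (1/n + d²/2n)·2(1−r) |
| t statistic | d = t·√(1/n_E + 1/n_C) | as group means |
| F (1 df) | \|d\| = √F·√(1/n_E + 1/n_C), sign supplied | as group means |
| correlation | d = 2r/√(1−r²) | 4·var(r)/(1−r²)³, var(r) = (1−r²)²/(n−1) |
| p-value only | invert the two-sided two-sample t-test | as group means |

Decisions behind the table:

- **Pooled SD**: the Cohen form √(((n_E−1)SD_E² + (n_C−1)SD_C²)/(n_E+n_C−2)),
  the textbook default consistent with the variance used for d.
- **Paired variance**: Borenstein's paired-design companion to the
  difference-score denominator. The pre/post correlation defaults to
  r = 0.5 analysis-wide; sensitivity reruns use 0.3 and 0.7. With equal
  SDs, d is strictly increasing in r (the denominator √(2(1−r))·SD shrinks),
  so the sweep brackets the main analysis.
- **p-only rows**: |t| = t⁻¹(1 − p/2) at df = n_E+n_C−2, computed as
  `t.isf(p/2)` to stay exact for very small p. Results published only as
  "not significant" enter with the conservative P = 1, i.e. d = 0 exactly
  — a deliberate bias toward the null. A direction of "0" with p < 1 is
  rejected rather than silently signed.
- **Regression coefficients** are routed through the correlation transform
  and assume the coefficient was standardized upstream; this is the one
  conversion whose exact provenance must be asserted by the user.
- No small-sample (Hedges) correction by default, matching the Cohen's d
  common metric; `hedges_g=True` applies J = 1 − 3/(4·df − 1).
- Repeated post-THC assessments use the earliest timepoint
  (`select_timepoint`), ties broken by input order.

Positive d always means more CAPS under the exposure of interest.

## Rates

Per-study rates R = X/N carry exact Clopper–Pearson intervals (beta
quantiles, via statsmodels; closed at the boundaries). Pooling treats
each transformed rate as an effect size:

- **raw scale** (default): y = p̂, v = p(1−p)/n, with p clamped to
  [1/(4n), 1−1/(4n)] inside the variance so boundary counts stay usable;
- **logit scale** (flag): y = log((x+½)/(n−x+½)),
  v = 1/(x+½) + 1/(n−x+½); estimates and bounds are inverse-logit
  transformed, so they always land in (0, 1).

The raw scale is the default because it yields the symmetric
percentage-point intervals this literature reports. Neither scale is
unbiased for *rare* events under heterogeneity: raw-scale
inverse-variance weighting over-weights zero-count studies (downward
bias), and the continuity-corrected logit back-transform drifts upward.
For rates around 1–2% the two bracket the truth; results there should be
read with that in mind.

## Pooling models

Three model classes map onto the dependence structure, chosen
automatically from `sample_id` (`choose_model`):

- **Aggregation** (all estimates from one sample): inverse-variance mean
  whose variance uses the full quadratic form under compound-symmetry
  correlation ρ = 0.5 between constituent estimates — for k equal-variance
  estimates, v(1 + (k−1)ρ)/k.
- **Random effects** (independent samples): d_i ~ N(μ, v_i + τ²). τ² by
  REML (default) or DerSimonian–Laird; the pooled mean uses weights
  1/(v_i + τ̂²); Wald normal intervals (not Knapp–Hartung), matching the
  symmetric CIs this literature prints.
- **Multilevel** (mixture): three-level model with random intercepts at
  the sample and estimate levels, marginal covariance
  V_j = diag(v_ij + σ²_w) + σ²_b·11′ per cluster, fitted by restricted
  maximum likelihood. Sherman–Morrison keeps each cluster O(size).
  `tau2` reports σ²_b + σ²_w and both components are exposed. A layout
  with every cluster of size 1 carries no within/between information and
  delegates to the random-effects fit.

Heterogeneity: Q about the fixed-effect mean against χ²(k−1), and
I² = max(0, (Q−df)/Q)·100, with I² > 30 read as moderate and > 50 as
substantial. Pooling requires k ≥ 2; single-estimate classes are reported
unpooled, never silently dropped.

Numerical choices: the scalar REML search is bounded on
[0, 10·(max v_i + var(d))] with `xatol = 1e-10` — the bound includes the
raw dispersion of the estimates so that τ² is never truncated in
high-heterogeneity models (observational CAPS models reach I² ≈ 98%).
The bivariate three-level search starts deterministically at the DL
estimate split evenly and is bounded the same way. REML failure falls
back to DL with a logged warning.

## Publication bias and influence

- **Egger's test** (effect models, k ≥ 6): OLS of d_i/se_i on 1/se_i,
  two-sided test of the intercept — algebraically the 1/v-weighted
  regression of d on se. Models below six estimates are refused.
- **Peters' test** (rate models, same k ≥ 6 rule, adopted for the same
  small-k instability): WLS of the log-odds of the rate on 1/n with
  weights n·p̂(1−p̂), ½ continuity corrections at boundary counts.
- **Trim-and-fill** (triggered at p < 0.05, or on demand): the
  Duval–Tweedie iteration with the L0 rank estimator by default (R0
  available). The iteration trims the k₀ most extreme studies on the
  non-missing side, re-estimates the center by fixed-effect weighting of
  the trimmed set, and repeats until k₀ stabilizes; mirror-image studies
  are then filled and the random-effects model refit (same τ² estimator
  as the parent). `side="auto"` fills opposite the sign of the Egger
  asymmetry (skew about the fixed-effect mean when k < 6). The
  implementation reproduces `metafor::trimfill` estimate-for-estimate on
  shared datasets.
- **Leave-one-out** (k ≥ 3): k refits in input order, each omitting one
  estimate.
- **Outliers**: a study is flagged when its 95% CI lies entirely outside
  the pooled 95% CI; the re-pooled result omits flagged studies. This is
  the operational reading of "deviates from the pooled estimate" used by
  the influence toolkits this field cites.

A known limitation, quantified in our simulations: at realistic
suppression intensities (8 of 30 studies removed one-sidedly from a
funnel with n between 10 and 300), trim-and-fill detects suppression
(k₀ > 0) in roughly 80–95% of replicates and the joint event "detected
and adjusted closer to the generating mean" occurs in only ~75% —
identical to metafor's behaviour on the same data. Trim-and-fill is a
sensitivity analysis, not an unbiased corrector.

## Pipeline rules

Per predictor class: convert → choose model → pool → heterogeneity →
Egger (k ≥ 6) → trim-and-fill (p_Egger < 0.05) → leave-one-out and
outlier re-pool. Rates pool per design (intoxication-level profiles) and
full-blown psychotic episodes pool separately across designs. Reported
p-values are uncorrected for multiple testing (the convention of this
literature); `results_to_frame(..., adjust_p=True)` adds a
Benjamini–Hochberg column. Conversion failures are row-logged; every
input row ends in exactly one of a pooled model, the unpooled-singles
report, or the rejection log. The pipeline is a pure function of
(evidence, configuration): reruns are byte-identical.

## Synthetic evidence generator

`synthetic_data` produces evidence bases with known ground truth so every
stage is testable without external data. Its defaults encode the study
conditions of the CAPS literature: per-design true rates 19.4%
(observational), 21% (experimental), 1.5% (medicinal) with logit-scale
between-study SD 0.6 (matching the substantial heterogeneity of
observational rate models); full-episode rate 0.52% drawn from larger
cohorts; per-class true effects
{single-dose THC 0.70, THC dose–response 0.42, medicinal cannabis 0.14,
bipolar disorder 0.80, dopamine activity 0.40, age −0.20, female gender
−0.09} with between-study τ² = 0.04; 12 studies per class; study sizes
log-normal (median ≈ 90); a quarter of samples contribute two dependent
estimates sharing a sample-level random effect (intra-sample correlation
0.5, aligned with the aggregation model's ρ); and a statistic mix of
means (35%), paired means (25%), t (15%), F (5%), correlation (10%) and
p-only (10%). Age and gender classes are spread across observational,
experimental and quasi-experimental designs so triangulation is
exercisable.

Reported statistics are computed *exactly* from the drawn group
summaries (t from the pooled-SD test, F = t², r from the realized d, p
from the exact t-test), so conversion can be validated row-by-row
against stored truth. Censoring replaces rows with realized p above
`censor_alpha` by the bare "P > α" report (P = 1 input); selection
retains studies with probability min(1, 2·expit(−s·(p − 0.05))), a
logistic taper that is the identity at s = 0.

What the generator does **not** emulate: correlated predictors within a
study, non-normal outcome scales, digitization error from
figure-extracted estimates, time-varying effects across repeated
assessments, and design-specific measurement instruments. Passing tests
therefore demonstrate correctness of the statistical machinery under the
assumed model, not robustness to those real-data features.

## Problem sizes

Simulation-based tests use sizes chosen to make Monte-Carlo error small
relative to the tolerances tested: 2,000 replicates for test size, 500
studies for random-effects recovery, 10 × (40 clusters × 3) for
multilevel component recovery, 200 replicates for the suppression
analysis, and exhaustive enumeration up to n = 50 for interval coverage.
The acceptance script runs the full pipeline on one generated evidence
base (~170 rows) in a few seconds.
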