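# Methods

## Measurement model

All estimators treat GWAS summary statistics as noisy measurements of
latent per-variant effects: for instrument *j*,

```
beta_X_j ~ Normal(xi_j, sigma_X_j^2)          (exposure side)
beta_Y_j ~ Normal(theta * xi_j + alpha_j, sigma_Y_j^2)   (outcome side)
```

with the two sides independent (two-sample design, no overlapping
participants), `theta` the causal effect of one SD of the exposure on the
outcome (log-odds for binary outcomes), and `alpha_j` a horizontal-
pleiotropy offset — zero for a valid instrument. Exposure effects are
expressed per SD of the exposure; `scale_to_sd` divides beta and SE by the
trait SD when an input is on a raw scale.

## Harmonization

Outcome records are aligned to the exposure's effect allele: swapped
alleles invert the beta's sign and complement the effect-allele frequency;
opposite-strand reports (A<->T, C<->G recoding) are detected and recoded.
Palindromic variants (A/T, G/C) cannot be strand-resolved from alleles;
the default policy infers strand from allele frequency when both sides
have EAF and both minor-allele frequencies are <= 0.42, and drops the
variant otherwise. The 0.42 cut is the conventional compromise between
losing variants and risking a wrong strand call near EAF 0.5; it is
configurable. Every variant of the input intersection receives exactly
one provenance flag, so `|intersection| = kept + dropped` always holds and
a run log can account for every decision.

Instruments absent from an outcome study are recovered through a local
proxy table (variant, proxy, r², allele mapping); the highest-r² proxy at
r² >= 0.8 is substituted with alleles mapped through the table. An
unresolvable instrument is reported, never silently dropped.

## Instrument construction

Cis instruments are variants on the anchor chromosome within a window of
±5 Mb around the gene body (inclusive ends, 1-based positions), at
p < 5×10⁻⁸ (strict). Clumping is greedy by ascending p (ties broken
lexicographically by variant id for determinism): the smallest-p variant
is retained and all remaining variants with r² >= 0.1 against it *within
10,000 kb* are pruned; pairs farther apart are never pruned, and distance
alone never prunes. This reproduces the parameterisation of standard
clumping tools. No instrument-strength (F-statistic) filter is applied.

## Estimators

* **IVW.** Ratio form `sum(w_j r_j)/sum(w_j)` with first-order weights
  `w_j = (sigma_Y_j / |beta_X_j|)^-2`; identical to the zero-intercept WLS
  slope with weights `sigma_Y_j^-2`. Fixed-effect SE `(sum w_j)^-1/2`;
  the primary multiplicative random-effects model inflates it by
  `sqrt(phi)`, `phi = max(1, Q/(J-1))`. The floor at 1 means
  heterogeneity can only widen intervals. P-values are standard normal.
  The floor together with normal reference makes the test slightly
  conservative at small J (its size sits just below the nominal 0.05 at
  J = 13); this is the convention of the standard MR toolchains and is
  kept deliberately.
* **Maximum likelihood.** The latent `xi_j` are profiled analytically,
  leaving `l(theta) = -1/2 * sum (beta_Y_j - theta*beta_X_j)^2 /
  (sigma_Y_j^2 + theta^2 sigma_X_j^2)`; Brent minimisation from the
  fixed-effect IVW start, SE from the numerical curvature at the optimum.
  Non-convergence raises with diagnostics rather than returning garbage.
* **Weighted median.** Ratios sorted ascending; standardized cumulative
  weights `s_j = (sum_{k<=j} w_k - w_j/2)/sum w`; linear interpolation at
  s = 0.5. SE from a parametric bootstrap (default 1,000 replicates)
  resampling both sides from their sampling distributions; the seed is
  mandatory so results are reproducible.
* **MR-Egger.** Pairs are first oriented so every `beta_X_j > 0` (Egger is
  not orientation-invariant; a fixed convention is required). WLS with
  intercept, weights `sigma_Y_j^-2`, inference from t(J-2), residual
  heterogeneity with the same multiplicative floor. The intercept
  estimates average directional pleiotropy; its two-sided t-test is
  reported as P_pleiotropy.
* **MR-PRESSO.** Observed residual sum built from leave-one-out IVW
  slopes so each variant is scored against a fit it did not influence;
  the null distribution is simulated parametrically (default 1,000 draws,
  seed required). Empirical p-values carry the (r+1)/(n+1) correction, so
  the smallest attainable p is 1/(n_sim+1). Outliers are variants with
  per-term p below 0.05/J (Bonferroni); the corrected estimate is IVW-MRE
  on the remainder; the distortion test compares the raw-vs-corrected
  shift with the shift from removing equally many variants at random
  (two-sided on the absolute shift). J >= 4 is required so each
  leave-one-out slope rests on at least three variants.

## Multivariable MR and mediation

`mvmr_fit` regresses `beta_Y` on the K exposure columns jointly (zero
intercept, weights `sigma_Y^-2`), with the same overdispersion floor on
`Q/(J-K)` and normal p-values; a rank-deficient exposure matrix raises an
error naming the collinear columns. With K = 1 the fit reduces exactly to
univariable random-effects IVW.

The two-step network decomposition multiplies the exposure→mediator
effect `a` by the mediator→outcome effect `b`; by default `b` comes from
the joint (mediator + exposure) multivariable fit — the network form —
with a configuration switch to the univariable estimate, since either
reading is defensible. The proportion mediated `a*b/theta_total` is
reported in percent with a delta-method 95% CI treating the three inputs
as independent; a Monte-Carlo propagation CI is available behind a flag.
The delta CI is accurate when the total effect is estimated with small
relative error; when `se(total)/total` is large the ratio distribution is
heavy-tailed and neither a delta nor a normal-theory interval is reliable
(the Monte-Carlo option shows this directly). A zero total effect leaves
the proportion undefined and is reported as such. Attenuation on
adjustment is the bare percentage `100*(1 - adjusted/total)` without a CI.

## Synthetic data generator

`generate_pair` draws instrument effects `xi_j ~ Normal(0.35, 0.05^2)` —
a strong cis-pQTL architecture — and per-variant sampling noise whose
default scales follow the nominal sample sizes of the emulated data
sources via `se ≈ 1/sqrt(n * 2f(1-f))`: 0.0088 for a 30,931-person
protein GWAS on the exposure side and 0.0076 on the log-odds scale for a
~61k-case/~124k-control outcome GWAS. Pleiotropy models: `balanced`
(zero-mean offsets), `directional` (a fixed offset on a controlled
fraction of instruments), plus gross outliers injected by adding a large
offset to a random subset. Binary-outcome effects are generated directly
on the log-odds scale; a liability-threshold layer would add nothing the
estimators could see. Records carry consistent alleles, frequencies and
p-values, and always pass input validation; a truth record stores every
latent quantity, so recovery tests need no hidden state.

`generate_mediation_scenario` adds a mediator with its own instruments:
`beta_M = a*xi + eta`, `beta_Y = theta_direct*xi + b*(a*xi + eta)`, so the
total exposure→outcome effect is `theta_direct + a*b` by construction.
Two shipped presets calibrate this chain to the emulated study's two
headline configurations, which are mutually inconsistent under a single
linear chain and therefore kept separate:

* `apoB_reversal` — `theta_direct = ln 0.84`, `a = 0.049`, `b` chosen so
  the total effect is `ln 1.09`: the univariable estimate is positive
  while the mediator-adjusted direct effect is negative (the sign
  reversal).
* `apoB_mediation` — `a = 0.049`, `b = 0.51`, total `ln 1.09`: the true
  proportion mediated is 29.0%.

`generate_ld_fixture` produces block-diagonal r² structure with the block
lead carrying the smallest p, so clumping fixtures have construction-
implied truth. The fixture does not correlate the *betas* of variants
within a block (only their r² entries); this is sufficient for testing
selection logic but does not emulate the joint sampling distribution of
correlated variants — one reason fixture results say nothing about
fine-mapping behaviour on real data. Other deliberate omissions: no
realistic allele-frequency spectrum, no exposure/outcome sample overlap,
no genome-wide null background.

## Simulation studies and their conditions

The calibration module fixes the study conditions used by the test suite
and the acceptance script:

* **Null calibration / consistency.** J = 13 instruments at the default
  (sample-size-derived) noise scales; 2,000 null replicates for type-I
  error, 1,000 replicates at theta = 0.1 for consistency.
* **Weighted-median breakdown sweep.** J = 20 equal-effect instruments
  (`xi_sd = 0`, so every instrument carries the same weight and an
  invalid fraction of instruments is an invalid fraction of weight), true
  effect 0.1, directional offset 0.1, invalid-weight fractions 30%-60% in
  5% steps, 1,000 replicates each. The sweep uses high-precision
  instruments (`sigma = 0.002` on both sides): the breakdown point is a
  large-sample property of the invalid-weight fraction, and shrinking the
  sampling noise ensures the measured boundary reflects that property
  rather than finite-sample scatter. With these conditions the absolute
  bias stays below 0.01 up to 45% and jumps an order of magnitude at 50%.
* **MR-PRESSO detection.** Ten clean instruments plus one whose Wald
  ratio sits at 1.0 against a background effect of 0.1, with noise 0.012
  chosen so the outlier's own residual is ~26 sigma while the distortion
  it induces on clean variants' leave-one-out residuals stays within
  their null spread — i.e. the test is asked to find the outlier, not to
  condemn the bystanders.
* **Mediation recovery.** 1,000 replicates of the `apoB_mediation`
  scenario; the mean recovered proportion and the delta-CI coverage of
  the true 29.0% are both measured.

## Numerical conventions

Empirical p-values never reach zero ((r+1)/(n+1) correction). All
Monte-Carlo procedures take explicit seeds; per-analysis seeds inside the
pipeline are derived deterministically from the study seed and the cell's
labels, so adding an analysis does not shift the seeds of others. Report
files are written with fixed float formatting, making whole-study runs
byte-reproducible. Ties in clumping are broken lexicographically;
duplicate variant ids within a file keep the smallest-p row.

## Known limitations

The pipeline assumes summary statistics on additive scales with correct
SEs; it does not model winner's curse in instrument selection, weak-
instrument bias beyond the NOME approximation (no second-order weights,
no I²_GX diagnostics), sample overlap, or LD-aware joint estimation.
Mode-based and penalised estimators, Steiger filtering and multivariable
PRESSO are out of scope.
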