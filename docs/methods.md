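# Methods

## The model

Each study contributes one Pearson correlation r between the heights of
spouses, computed on N couples. Analysis happens on the
variance-stabilized Fisher scale, z = artanh(r), whose sampling
distribution is close to normal with a variance that depends only on
the couples count:

    z_i ~ N(zeta_i, v_i),    v_i = 1/(N_i - 3).

True effects vary across the literature, and studies are not
independent: the same research group publishes several estimates, and
several estimates come from the same country. The marginal model is
therefore a meta-regression with two *crossed* random intercepts,

    z = X beta + Z_a u + Z_c w + e,
    u ~ N(0, sigma2_author I),   w ~ N(0, sigma2_country I),
    e ~ N(0, diag(v)),

where X contains an intercept, a binary western indicator (UN M49
regions Europe 150, Northern America 021, Australia/New Zealand 053;
Japan non-western by convention), and publication year centered at the
analyzed dataset's mean (the centering constant is stored in the fit
metadata). Crossed, not nested: an author group can publish from more
than one country and a country hosts many groups.

## Estimation

Variance components are estimated by REML. At any candidate
(sigma2_author, sigma2_country) the fixed effects are the GLS solution
and drop out; the restricted objective is

    l_R = -1/2 [ (k-p) log 2pi + log|V| + log|X'V^-1 X|
                 - log|X'X| + r'V^-1 r ],

with V the marginal covariance and r the GLS residual. The
+log|X'X|/2 term makes the value invariant to reparameterization of
the fixed effects and directly comparable to metafor's `rma.mv`, which
the test suite uses as an external cross-check (agreement to ~1e-6 in
coefficients, SEs, variance components and log-likelihood on a
40-study table).

Numerical choices:

* optimization on the log-variance scale by Nelder–Mead
  (xatol/fatol 1e-10 on the objective), started from a
  DerSimonian–Laird-style method-of-moments value split evenly across
  components — deterministic, no seeds;
* the 0 boundary of each component handled explicitly: every subset of
  components is pinned at zero and the remainder re-optimized; the best
  of the interior and boundary candidates is returned, and interior
  optima below 1e-10 are snapped to the boundary;
* V is dense (k up to a few hundred) and factorized by Cholesky; a
  non-finite objective returns -inf rather than raising, and a stalled
  optimizer yields `converged=False` rather than an exception;
* a guard against false convergence profiles the restricted likelihood
  for each component on a multiplicative grid around the estimate
  (re-optimizing the other); `profile_ok` is false if any profiled
  point beats the reported optimum by more than 1e-6. Components at
  the boundary are probed on an absolute grid, where a decreasing
  profile counts as a boundary maximum.

Inference is Wald-normal on the z scale (no Knapp–Hartung adjustment,
matching the toolchain the original analysis used); confidence
intervals are formed on the z scale and the endpoints mapped through
tanh, so r-scale intervals always lie in (-1, 1). Subgroup estimates
(western-only, non-western-only) come from separate intercept-only
fits, the reading most consistent with df = k_subgroup - 1 in the
published subgroup heterogeneity statistics; constant moderators in a
subgroup are dropped with a warning rather than breaking the design
matrix.

## Sample-size recovery

Publications that omit N are handled by the transform module:

* from a reported SE of r: N = ((1-r^2)/SE)^2 + 2, rounded
  half-away-from-zero;
* from a significance category: t in {1.96, 2.58, 3.59} for p < .05 /
  .01 / .001, df = t^2 (1-r^2)/r^2, N = df + 1 rounded *down* — the
  category only bounds the evidence, so the recovered N is a lower
  limit and flooring preserves that reading;
* median imputation across companion studies (even counts: mean of the
  central pair, rounded half-away-from-zero);
* several correlations from one source can be pooled by sample-size
  weights on the z scale and back-transformed (an r-scale average is
  available behind a switch for sensitivity analysis).

All recovered Ns are integers; both rounding rules are configurable.
Records keep a provenance flag, but weighting never down-weights
imputed records: the weight is always 1/(N-3) with the final N.

## Heterogeneity and bias diagnostics

Cochran's Q is the weighted residual sum of squares from the
*fixed-effects* weighted LS fit on the same moderator design as the
mixed model (df = k - p); that convention is what makes df = 151 for
154 effects and three coefficients. The multilevel I² sums the
variance components over themselves plus the Higgins–Thompson typical
sampling variance v~ = (k-1) Sum(w) / ((Sum w)^2 - Sum w^2); per-factor
shares are reported alongside the total. Funnel asymmetry uses the
Begg–Mazumdar rank correlation: Kendall tau-b between
(z_i - z_pooled)/sqrt(v_i - v_pooled) and v_i, with the tie-corrected
normal p (an exact permutation p is available for k <= 8; by default
the test runs against the intercept-only pooled estimate, with a flag
to use the full model's residuals instead).

A calibration caveat the test suite documents deliberately: under a
symmetric-funnel null with realistic spread in N, the rank test is
*conservative* — the standardized deviates share the pooled estimate
and are mutually negatively correlated, which shrinks the null spread
of tau to roughly 0.8 of the normal-approximation variance. Measured
type-I error is about 2–4% at nominal 5% (metafor's `ranktest` shows
the same behavior under the identical null). The suite asserts the
property that actually holds: the test never rejects above nominal.

## The synthetic generator

`simulate_studies` runs the model generatively: country effects, then
author effects, then per-study true z including moderators, then an
observation. Two observation modes: `z_approx` draws the Fisher-z
value directly at its nominal variance; `couple_level` simulates N
height pairs from a bivariate normal (178 ± 7 cm by 165 ± 6 cm by
default) at correlation tanh(z_true) and takes the sample Pearson r.
The two modes agree in pooled estimates to < 0.005 z units at N >= 50
(tested over 100 replicates at the default design).

Defaults are the design of the meta-analysis this package
re-implements: 154 studies in 91 author groups and 43 countries (20
western), publication years uniform on 1899–2016, couples counts
log-uniform on [20, 2000], true pooled effect artanh(0.23), western
contrast +0.038, year slope +0.00003 per year. Variance components
were sized once so the multilevel I² is ~93% at this design: the
typical sampling variance under the default N distribution is
~0.00237, giving a total sigma2 of ~0.0315, split 2:1 between author
(0.021) and country (0.0105) on the reasoning that methodological
variation between research groups exceeds between-country variation.

Seeding: one master `SeedSequence` spawns a design stream, a
cluster-effect stream, and one stream per study, so enlarging a
simulation never perturbs earlier draws. Author and study counts are
partitioned randomly with at-least-one constraints unless explicit
per-country/per-author counts are supplied.

What the generator does *not* emulate — and therefore what passing
tests cannot show about the historical literature: the real table's
skewed N distribution (a few cohorts above 10,000 couples dominate the
weights and its Q), the asymmetry in heterogeneity between western and
non-western subgroups, any publication-bias mechanism, correlated or
systematically varying measurement methods (measured vs self-reported
height), and the actual geographic sampling pattern. Synthetic
country assignments reuse real M49 codes but are exchangeable within
the western/non-western split.

`recovery_experiment` repeats simulate-and-fit and reports bias, RMSE
and 95% CI coverage. Coverage is defined only for fixed effects (the
fit carries Wald SEs for beta, not for the variance components, whose
Wald intervals would be misleading near the boundary; their rows
report bias/RMSE with NaN coverage). At the default design over 200
replicates the pooled-effect bias is below 0.01 z units and CI
coverage sits in the low-to-mid 90s; variance components show the
expected small positive bias at this cluster count, documented rather
than asserted away.

## Problem sizes used by the shipped experiments

The packaged tests and the acceptance script size their simulations to
what the inferential statement needs: single-fit checks run at k = 40
or the full 154-study design; the recovery experiment uses 200
replicates at the full design; the Begg calibration uses 1000
replicates of k = 50; homogeneity calibration uses 200 replicates of
k = 30. These are the package's chosen experiment sizes and are stated
here so results can be reproduced exactly.

## Known limitations

* The deposited study table of the original meta-analysis is not
  packaged; replication-style checks run against a labelled synthetic
  stand-in with the published values as generative truth, so those
  checks validate the machinery, and single-draw point estimates land
  within sampling error of — not on — the published numbers.
* Robust/clustered variances, Knapp–Hartung, Egger regression,
  trim-and-fill, selection models, Bayesian estimation and
  correlated-outcome models are out of scope.
* The western/non-western split is the crude two-way geography the
  original rule defines; the packaged M49 table covers the three
  western regions exhaustively and the commonly sampled non-western
  countries, raising a validation error for codes it cannot resolve.
* Fisher-z pooling of several correlations from one source assumes the
  underlying samples are independent.
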