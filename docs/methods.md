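# Methods

## The synthetic registry

The generator emulates a full calendar year of an adult (≥16 y) binational
ICU registry: 125 ICUs across four hospital classes — metropolitan,
private, rural/regional, tertiary — holding patient shares of
16.9/32.8/6.4/43.8% and roughly 94,000 admissions in total.

**Site structure.** Annual volumes are lognormal within class, with class
medians (520/983/326/1500) and spreads taken from the class volume
quartiles, a floor of 150 admissions, and a cap of 2900. Two identities
are imposed exactly rather than left to sampling noise: class patient
totals hit their share quotas, and volumes sit at evenly spaced quantiles
of the class distribution (systematic sampling). One global dispersion
factor is then solved (Brent's method) so the *patient-weighted* mean
annual volume equals 1192 — the quantity a patient-level demographic table
reports. Each site's admission count equals its annual volume.

**Covariates.** Age is truncated normal (16–110 y, mean 61.7, SD 17.5);
APACHE III is a truncated, integer-rounded skew-normal (0–299, mean 54.6,
SD 25.7); the ANZROD death risk is logit-normal with its mean tied
linearly to standardized APACHE III (correlation ≈ 0.7) so risk adjustment
has signal; pre-ICU days are lognormal (median 0.4, mean 1.5, capped at
60); ventilation on day 1 follows a severity-tilted logistic; ICU death is
Bernoulli with probability proportional to ANZROD; the remaining flags
(male 58.3%, renal failure 5.0%, limitation 5.2%, arrest 3.4%) are
independent Bernoulli; the 30-level diagnostic group has geometrically
decaying frequencies. Location parameters are centred on their targets by
one large internal calibration draw (n = 200,000, fixed internal seed)
that is part of the configuration definition, not of the user's random
stream.

**LOS.** Each patient gets `eta = x'beta − c + u_i`, with
`u_i ~ N(0, tau²)` and LOS drawn so that `E[LOS | x, u] = exp(eta)`:

* lognormal noise (default): `log LOS = eta − sigma²/2 + sigma·z`;
* gamma noise (option): shape `k` (default 1.7), scale `exp(eta)/k` —
  same conditional mean, different shape, built specifically to
  misspecify the log-normal LMM and induce estimator discordance.

LOS is truncated at 180 days. The marginal target (mean 3.2 d, median
1.8 d) fixes, via the lognormal moment equations, `mu = ln 1.8` and a
total log-scale variance `2·ln(3.2/1.8) ≈ 1.151`; that budget is split as
`tau² = 0.05` (between-ICU), a covariate share of ≈ 0.27 (set by the
default effect sizes, e.g. +0.25 log-days per SD of APACHE III, +0.45 for
ventilation, −0.45 for ICU death, so the true-model patient-level R² is
≈ 0.23), and the remainder `sigma² ≈ 0.80` as residual. The centring
constant `c` and the exact residual share come from the calibration draw,
using the empirical `E[exp(x'beta − c)]` so the marginal mean is hit even
though the covariate signal is not exactly Gaussian. With 125 sites the
patient-weighted mean of the drawn `u_i` would wander by ±0.03 on the log
scale between seeds, so the default configuration weight-centres the site
effects (`Σ volume_i·u_i = 0`); recovery-study configurations keep `u_i`
i.i.d. instead, since there the estimand is `tau²` itself.

What the generator does *not* emulate: diagnosis-specific LOS profiles,
informative missingness (covariates can be blanked but the mechanism is
uniform), death as a censoring process, within-year admission dynamics,
and any real correlation between hospital class and casemix beyond the
configured class effects. Passing tests therefore demonstrate that the
estimators and interval machinery behave correctly under a controlled,
realistic-moment data process — not that any particular real cohort meets
the models' assumptions.

## Estimation

**LMM.** `log LOS` with an ICU random intercept, maximum likelihood (not
REML, so information criteria are comparable across fixed-effect sets),
via `statsmodels MixedLM`. Random intercepts are reported as posterior
modes (BLUPs) with conditional prediction SEs
`sqrt(tau²·sigma²/(sigma² + n_i·tau²))`; these are the SEs the downstream
±1.96·SE intervals use, and they ignore fixed-effect estimation
uncertainty by construction.

**GLMM (gaussian family, log link).** No installed package fits this
family/link with a random intercept, so the Laplace-approximated marginal
likelihood is maximized directly. For each value of `(log sigma²,
log tau²)` the conditional modes are found by a joint penalized
Gauss-Newton over `(beta, u)` — the augmented normal equations assembled
with per-site segment sums, never forming the n×m indicator matrix —
followed by a per-site 1-d Newton polish of the modes; the Laplace
objective adds the site-wise `−½·log` curvature terms. The outer 2-d
search is Nelder-Mead (derivative-free: finite-difference gradients of a
profiled objective are unreliable near the optimum), bounded on the log
scale, capped at 500 outer iterations, started from the LMM fit (`beta`
shifted by `+sigma²_LMM/2` on the intercept). Non-convergence is flagged
on the result and by the pipeline, never silent. With a single site or
`tau²` pinned to zero the fit reduces exactly to exp-link nonlinear least
squares (verified against scipy's independent Levenberg-Marquardt solver
to < 1e-4 relative).

**Predictions and R².** FE predictions use `x'beta` only — quality
metrics must not adjust away the site effect they are trying to measure;
RE adds the site intercept. GLMM day-scale predictions are `exp(eta)`,
hence strictly positive. LMM predictions are reported on the log scale
only: because `exp{E(ln Y)} ≠ E(Y)`, a day-scale back-transformation would
need a smearing-type correction, which is deliberately out of scope —
requesting LMM predictions in days raises an error rather than silently
returning geometric-scale values. R² is the squared Pearson correlation
of observed vs predicted (patient level, or on within-ICU means), which
is scale-consistent but has the known quirk of scoring anti-correlated
predictions as 1; split-sample validation allocates whole ICUs 60/40 (by
site count; the fraction is configurable) and uses RE predictions
in-sample, FE out-of-sample, so the development-validation R² gap carries
a structural component of about `tau²/Var(log LOS)`.

**Complete cases.** Rows with any missing model covariate are dropped at
fit time with the count logged; no imputation. ANZROD is floored at 1e-4
before taking logs (a floor on a covariate, not a shift parameter on the
response). The default interaction list — ventilation × log ANZROD, ICU
death × log ANZROD, hospital class × APACHE III — is an explicit,
swappable default, and the synthetic generator deliberately uses *no*
interactions, so model and generator never share unstated structure.

## Quality metrics and BCa intervals

Per ICU: OMELOS `mean(obs) − mean(pred)`, arithmetic RALOSR
`mean(obs)/mean(pred)` (both from GLMM day-scale FE predictions), and
geometric RALOSR `exp(mean(log obs) − mean(pred_log))` (from LMM log-scale
FE predictions). The bootstrap resamples (observed, predicted) pairs
within each ICU; the model is fitted once, not per replicate — refitting
a mixed model inside every bootstrap replicate would change the estimand
(to one including fixed-effect uncertainty) at three orders of magnitude
more cost. BCa follows the standard construction: bias term
`z0 = Phi⁻¹(#{theta* < theta}/B)`, acceleration from the jackknife
third-moment formula; degenerate bootstrap distributions yield a
zero-width interval, an infinite `z0` falls back to the percentile
interval with a warning, and ICUs with fewer than two patients get a
flagged zero-width Wald fallback. One master seed spawns a per-ICU child
stream keyed on the ICU id, so results do not depend on iteration order.
Site-RE intervals are Wald (`±1.96·SE`), matching how predicted random
effects are conventionally displayed.

## Rank confidence sets

Estimates and SEs are treated as independent Gaussians — the same
abstraction as feeding a rank-inference package a column of point
estimates and SEs. Ratio metrics enter on the log scale (log point
estimate, SE from the bootstrap distribution of the log ratio), where the
Gaussian approximation is defensible. For unit `i`, a Monte-Carlo
critical value `c_i` covers all `N−1` studentized differences
`(θ_j−θ_i)/sqrt(s_i²+s_j²)` jointly with probability 1−α; units whose
lower/upper difference bound clears zero are counted as confidently
better/worse, giving `rank ∈ [1+#better, N−#worse]`. Marginal sets use
per-unit `c_i`; simultaneous sets one `c` over all pairs. Both kinds
share the same Gaussian draws (default 10,000), so marginal ⊆
simultaneous holds on every seed, and only single-step critical values
are used (no stepdown), making the sets conservative — coverage at or
above nominal, verified by the included simulation harness. Tied
estimates with zero SE are rejected with an instruction to jitter rather
than silently ordered. The default orientation ranks the lowest adjusted
LOS first and is configurable.

## Concordance reporting

Agreement between two rankings is Kendall's tau-b (tie-corrected;
primary) with Spearman's rho as secondary — the qualitative claim
"rankings disagree" is made quantitative. Flag counts report how many
ICUs' 95% CIs fall entirely below/above the metric's null (0 for
differences and REs, 1 for ratios), with boundary-touching intervals
counted as not excluded. All display functions return the exact plotted
table so tests never parse images; densities are Gaussian-kernel with
Silverman bandwidth.

## Problem sizes and numerical choices

The test suite runs the full calibrated registry once (125 ICUs, ~94k
patients) for calibration and invariant checks, and uses 40-ICU × 150-300
patient registries for the statistical studies: 50 replicates for
parameter recovery, 1000 simulations (B = 400) for BCa coverage of an
exponential mean, 200 simulations of a 20-unit near-tied scenario (2000
rank draws) for rank-set coverage, and 20 seeds for null calibration of
the flagging rates — sizes chosen so each study's Monte-Carlo SE is well
inside the asserted bands. Null-calibration runs score the metrics
against the generator's *true* fixed-effect predictions: the question
asked there is whether the bootstrap intervals are calibrated, and the
single-fit bootstrap design already fixes predictions, so estimating them
would conflate two error sources.

Tolerances: inner Gauss-Newton steps stop at 1e-11 relative, the outer
Nelder-Mead at 1e-4 on log-variance coordinates; linear predictors are
clipped at ±700 before exponentiation; BCa quantiles use linear
interpolation; rank-set critical values use the conservative "higher"
quantile.

## Known limitations

* The GLMM likelihood is a Laplace approximation; with very small sites
  or extreme skew the variance components inherit its bias (observed
  < 5% at 40 sites × 300 patients).
* Conditional RE SEs ignore fixed-effect uncertainty; with many small
  sites the Wald RE intervals are mildly anticonservative.
* BCa inherits bootstrap failure modes for heavy-tailed statistics at
  small n (the Wald/percentile fallbacks are flagged, not hidden).
* Rank sets assume independent Gaussian estimate errors; metrics derived
  from one fitted model share estimation error across ICUs, which the
  construction ignores (conservatism of the single-step bound works in
  the opposite direction).
* Poisson- and gamma-family GLMMs, crossed/nested random slopes, and
  day-scale retransformation of LMM predictions are out of scope.
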