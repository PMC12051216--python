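# Methods

`trajrecur` implements a two-stage analysis of long-run glycemia and
recurrent heart-failure hospitalization in type 2 diabetes, exercised
end to end on synthetic cohorts: (1) a latent class growth model
(LCGM) with cubic B-spline mean trajectories clusters irregularly
sampled HbA1c series on a weeks-since-diagnosis axis; (2) a power-law
nonhomogeneous Poisson process (NHPP), observed only inside
per-subject windows, links the classes (and baseline risk factors) to
recurrent hospitalization intensity and yields horizon risk
predictions evaluated by ROC/AUC after balanced down-sampling.

## Time axis and baseline construction

All times are fractional weeks since the date of diabetes diagnosis
(DDD); calendar dates convert as day-difference / 7 without rounding.
When a subject's diagnosis year matches the year of their first HbA1c
record, the DDD is that record's date; otherwise it is drawn uniformly
over the days of the diagnosis year (365 or 366 — leap years draw over
366). The per-subject observation window for events is
`L = max(0, weeks(truncation date − DDD))`, `R = weeks(end of
follow-up − DDD)`: covariate histories are complete only from the
truncation date onward, so events before `L` are treated as
unobserved rather than absent.

## Latent class growth model

Subject *i* in class *k* has

    y_i ~ N( B_i beta_k ,  sigma_b_k^2 J + sigma_e^2 I )

with `B_i` the cubic B-spline design matrix at the subject's
observation times, a class-specific random-intercept SD `sigma_b_k`
(honouring per-subgroup heterogeneity) and a shared residual SD
`sigma_e` (keeping the M-step well conditioned). Mixing proportions
`pi` are constant (no covariates in the membership submodel). The
compound-symmetric covariance is handled by the rank-1 Woodbury
identity, so every per-subject likelihood evaluation is O(n_i).

Fitting is EM over class labels and random intercepts jointly: the
E-step computes responsibilities by log-sum-exp and intercept
posteriors in closed form; the M-step updates `beta_k` by
responsibility-weighted GLS and the variance components by moment
updates, giving a monotone (generalized EM) log-likelihood ascent.
Convergence is `|Δloglik| < 1e-6 × N` or 500 iterations; `sigma_e` is
floored at 1e-4 to prevent degenerate spikes and `sigma_b_k` at 0.

Initialization matters for K around 8: responsibilities come from
k-means on per-subject *profile features* — each subject's
observations ridge-projected onto the model basis with shrinkage
toward the pooled mean curve, evaluated at a handful of grid times
that track the data density (interior-knot positions). This
"longitudinal k-means" start separates classes by level and shape.
Summary-statistic features (mean, slope, SD) were much weaker: EM
frequently converged to merged-class optima in which one component
absorbed two levels with an inflated intercept SD. The first start
uses the best of ten k-means seedings; restarts use single random
seedings; the best final log-likelihood wins. A single fit defaults
to five starts; the model-selection scans default to ten, because a
BIC comparison across K is only as good as the worst-optimized fit
in it — with fewer starts the BIC curve across K showed
local-optimum non-monotonicity (a truth-initialized K=8 fit beating
the scan's own K=8 value).

Classes are reported in descending-`pi` order (ties broken by the
first spline coefficient) so that fits are comparable across runs.
Posterior membership, single-series assignment (ties to the lower
class index), and mean-trajectory prediction follow directly.

## Spline bases and model selection

Bases are clamped cubic B-splines on `[0, max pooled time]`; the
dimension is `n_interior + degree + 1`. Two interior-knot placements
are supported: *equidistant* (equal widths) and *equipotent* (equal
data counts: pooled-time quantiles `j/(n_interior+1)`). Pooling all
subjects' times for the quantiles matches the data-point reading of
equipotency; tied quantiles collapse to unique values with a warning.
Prediction times outside the boundary are clamped — the late axis
(beyond ~1,300 weeks) is sparsely observed and extrapolating
unpenalized splines there is unstable.

Model selection alternates two BIC scans until the triple (knot
count, strategy, class count) repeats (or a round cap of 5 is hit):
knot counts {5, 10, ..., 40} × both strategies at fixed K, then K = 1..10
at fixed knots. The class-count scan supports two scores: a 10-fold
cross-validated BIC — held-out marginal log-likelihood with the
penalty computed on the held-out subject count, so rankings are
driven by the held-out likelihood — and a plain single-fit BIC, which
is far cheaper and selects the same K on well-separated data. Ties
always go to the smaller model, and to equidistant placement between
strategies. Fold assignment is subject-level and seeded.

## Window-observed NHPP

The event intensity for covariates `x` is

    lambda(t|x) = (beta/eta) (t/eta)^(beta-1) exp(x' gamma)

with scale `eta` (weeks), shape `beta` (beta = 1 is the homogeneous
process) and log hazard ratios `gamma`. `gamma` carries no intercept:
`eta` absorbs the baseline level and an intercept would be
unidentified against it. Covariates are time-fixed within a window.
Each subject contributes `sum log lambda(t_j|x) − [Lambda(R|x) −
Lambda(L|x)]`; maximization runs on the unconstrained scale
`(log eta, log beta, gamma)` by L-BFGS with the analytic gradient, and
the covariance of the estimates is the inverse observed information
(central-difference Hessian of the gradient). Hazard ratios are
`exp(gamma)` with 95% Wald intervals and two-sided Wald p-values.

Simulation uses the exponential time-transform property: cumulative
Exp(1) draws are mapped through `Lambda^{-1}(u|x) =
eta (u exp(−x'gamma))^{1/beta}`, starting from `Lambda(L|x)` and
truncating at `R`. Residual diagnostics invert it: gaps
`Lambda(T_j|x) − Lambda(T_{j−1}|x)` with the origin at the window left
bound `L` (not 0 — pre-window events are unobserved, a deliberate
divergence from the untruncated definition of the process, which
starts the clock at diagnosis). Under the true parameters the gaps of
the *untruncated* process are Exp(1). On short windows the complete
observed gaps are length-biased low (a gap is observed only if it
fits inside the window); the estimator of the Exp(1) mean that
remains correct under this right-censoring is total transformed
exposure over the number of events (`residual_mean`), the
censored-exponential MLE, whose expectation is 1 at any truncation
severity. Tests check exact Exp(1)-ness in an effectively untruncated
regime (windows holding ~40 expected events, first five gaps only)
and the censoring-aware mean at realistic truncation.

## Prediction protocol

The horizon risk at start `s` over `h` weeks is `p = 1 −
exp(−[Lambda(s+h|x) − Lambda(s|x)])`; horizons are 26, 52 and 104
weeks. Because events are rare, evaluation first balances the cohort:
all cases are kept and an equal number of controls is sampled without
replacement; a stratified split then takes `floor(0.8 × n_group)` of
each group for training. A subject's observed label over `(s, s+h]`
uses events up to the window end when the window closes before `s+h`
(exclusion of such subjects is available as a switch; the default
keeps them, labelling with what was observed). ROC curves sweep all
distinct predicted probabilities; the AUC is the Mann–Whitney rank
statistic with ties counted half, which equals the trapezoidal area
under the swept curve exactly.

## Synthetic cohorts

The generator emulates the registry structure the analysis was
designed for. Defaults are the published study conditions:

- Eight classes with proportions from the published class sizes
  (counts over 194,258 subjects; low stable = 22.2%). Two published
  summaries of the proportions disagree for one class (one set sums
  to 102%); the per-class counts, which sum exactly to the cohort
  size, are used.
- Class mean trajectories start at the published baseline HbA1c means
  (6.27 ... 11.60%) and follow the published qualitative shapes via
  four primitives: stable, linear drift (saturating at 25 years),
  exponential sharp decline (rate 0.02/week to a near-normal floor),
  and damped sinusoid for the volatile classes.
- Volatile classes use amplitude 1.5% HbA1c (a free choice, flagged
  here), periods 700/900 weeks and damping 1,000 weeks. The source
  describes volatility only qualitatively; the periods were fixed by
  an a-priori structural criterion — the class mean must lie
  (approximately) inside the cubic-spline families the selection
  procedure scans, quantified as best-approximation RMS error well
  below the residual SD in a 10-equipotent-knot basis (≤ 0.04% at
  these settings) — which is also the fluctuation scale visible on a
  2,500-week axis. Oscillations much faster than the knot spacing
  would place the truth outside every candidate model, which is not
  the regime a recovery test should probe.
- Random-intercept SD 0.2%, residual SD 0.3%; measurements clipped to
  the physiological range [3, 25]%.
- Visits: first at week 0, then truncated-exponential gaps (mean 26
  weeks, bounds [4, 104]) to a follow-up drawn Uniform(150, 2,500)
  weeks — reproducing the order of magnitude of the published
  per-class measurement counts and observation periods.
- Windows: `L = max(0, followup − 416)`, `R = followup`, mimicking a
  truncated covariate-availability period of ~8 years.
- Events: NHPP with shape beta = 1.3 and class effects equal to the
  published hazard ratios (0.79 ... 2.88, low stable as reference),
  applied through class-indicator covariates. The scale eta = 6,000
  weeks is calibrated so that ~6.7% of subjects have any event inside
  their window — the published cohort's case share (per-class shares
  then span roughly 3–12%, matching the published gradient). The
  recovery simulations for the event model itself use denser settings
  (eta = 400, windows (0, 520] or (0, 800]) so the likelihood surface
  is well identified at desk scale.
- Class-conditional covariates (age, sex, ethnicity, prior
  complications, medications) are independent Bernoulli/normal draws
  at the published per-class prevalences.

What the generator does *not* emulate: registry artifacts (duplicate
records, coding errors), within-class covariate correlation (only
marginal class rates are published), medication effects on the event
process, and time-varying covariates. Passing recovery tests
therefore show the pipeline is correct under its own assumptions at
registry-like signal strength, not that the published real-data
estimates are reproducible — the registry itself is access-restricted.

## Problem sizes and numerical choices

Recovery checks run at desk scale, chosen so each stage's sampling
error is well inside its tolerance: residual diagnostics at 2,000
subjects, hazard-ratio recovery at 5,000, the 8-class LCGM fit at
4,000 (10 equipotent interior knots, 5 EM starts), class-count
selection at 2,000 over K ∈ {6..10} with single-fit BIC. The full
10-fold CV grid is supported but is a configuration choice. Matching
of fitted to generating classes uses minimal RMS mean-trajectory
distance on the data-dense span 0–800 weeks.

Known limitations: no penalized smoothing (knot count is the only
smoothness control); no random slopes or class-specific residual
variances; no frailty in the event process; Wald rather than profile
intervals; the CV-BIC convention under cross-validation is one of two
defensible readings (the other — refitting on held-out data — is not
implemented).
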