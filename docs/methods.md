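# Methods

## The model

A bolus intravenous injection delivers tracer to an organ through two
sequential stochastic stages: transit/distribution through the organ's blood
pool, and washout from the perfused tissue.  Modelling each stage as a
gamma-distributed residence time and adding them (densities add by
convolution) gives the gamma-distribution convolution (GDC) time-activity
model

    GDC(a, b, alpha, beta; tau)
        = GD(a, b; tau) (*) GD(alpha, beta; tau)
        = b^a beta^alpha / Gamma(a + alpha)
          * exp(-b tau) * tau^(a+alpha-1)
          * 1F1[alpha, a + alpha, (b - beta) tau],        tau > 0,

with `1F1` Kummer's confluent hypergeometric function (standard convention
`M(A, B, z)`).  `a, b` describe the fast delivery component (`b` per
minute), `alpha, beta` the washout component; `alpha < 1` makes the washout
density strictly decreasing, which is what "washout" means.  Two reductions
anchor the implementation: `a = alpha = 1` gives the Bateman (biexponential
convolution) density, and `b = beta` gives a single gamma density
`GD(a + alpha, b)`.

A fitted time-activity curve (TAC) adds two non-kinetic quantities: an
arrival offset `t_A` (the tracer reaches the organ some fraction of a minute
after injection) and a scale `S` equating the TAC area to `S` times the unit
density area — i.e. the total counts the region would collect from
injection to infinity absent decay.

Mean residence times add under convolution:

    MRT_total_from_injection = t_A + a/b + alpha/beta.

Organ residence excludes `t_A` (tracer cannot reside in an organ it has not
reached): the reported quantities are `MRT_fast = a/b` (delivery/mixing,
~0.7-1.1 min for the bundled cases) and `MRT_WO = alpha/beta` (washout,
~210-700 min).

## Numerical evaluation

The printed closed form pairs `exp(-b tau)` with a 1F1 whose argument
`(b - beta) tau` is large and positive for clinical parameters; the product
is finite but each factor overflows within the 89-min acquisition.  All
evaluation therefore uses the Kummer transformation
`1F1(A, B, z) = exp(z) 1F1(B-A, B, -z)` so the hypergeometric argument is
always negative (bounded, algebraically decaying) and the gamma-variate
prefactor is assembled in log space.  `scipy.special.hyp1f1` on this path
agrees with 50-digit arbitrary-precision evaluation to better than 1e-12
relative out to tau = 2000 min for clinical parameter ranges (asserted in
the test suite against mpmath).

Frame expectations integrate the density over each frame with 3-point
Gauss-Legendre quadrature (default) or a cheaper midpoint rule.  The two
agree to <0.1% from about the fifth one-minute frame on; near the activity
peak (frames 2-4) the midpoint rule deviates by up to ~2%, which is why
Gauss-Legendre is the default.  Physical decay multiplies the density by
`2^(-t/half_life)` clocked from injection (decay does not wait for tracer
arrival); the default half-life is 360.4 min (Tc-99m, 6.007 h).

Quadrature for the numeric MRT oracle splits `[0, inf)` at
1, 10, 100, 1e3, 1e4 minutes (the integrands combine minute-scale peaks
with multi-hour tails) and applies adaptive quadrature per segment at 1e-9
absolute tolerance.

At `tau = 0` the density is 0 by the printed branch; a bare gamma density
with shape < 1 diverges at the origin and is capped at the largest finite
float with a warning (frame integrals never evaluate the endpoint).
The Bateman density switches to its `b = beta` limit formula when
`|b - beta| < 1e-8 b` to avoid catastrophic cancellation.

## Fitting

Counting data are Poisson, so the fit criterion is the Poisson negative
log-likelihood `sum(M_i - O_i ln M_i)` (a Pearson chi-square option is
provided).  Minimization is Nelder-Mead over
`(t_A, ln a, ln b, ln alpha, ln beta, ln S)`; the log parameterization
enforces positivity and makes the simplex tolerance a relative one.  `t_A`
is bounded to `[0, 1)` min by a quadratic penalty.  `alpha >= 1` is
reported with a warning, not clipped: a non-monotone "washout" is a finding
about the data, not a fitting failure.

Internally the minimized quantity is the loss shifted by its attainable
minimum (the Poisson half-deviance `sum(M - O - O ln(M/O))`, assembled with
`log1p`).  This matters: the raw NLL has magnitude ~1e7 for clinical
counts, so float64 cannot resolve loss differences below ~1e-9 relative —
exactly the depth of the flattest likelihood direction (below).  The
shifted loss is zero at the optimum and keeps full precision there; the
minimizer is unchanged.

Identifiability drives the optimizer design.  The likelihood is
near-degenerate along a `(t_A, a, b)` ridge: with one-minute frames,
making arrival earlier while sharpening the delivery component changes the
noiseless curve by only ~1e-5 relative (this is also why fitted `a` and `b`
are correlated at r ~ 0.999 across cases).  Three devices resolve it:

1. restarts explore a geometric ladder of delivery shapes `a` at fixed
   `a/b` (local jitter cannot cross between ridge segments);
2. the best candidates are polished by repeated simplex cycles until the
   relative loss improvement stalls (configurable stop, default demands
   improvement below float resolution);
3. the loss is profiled over `t_A` — nine grid points, re-optimizing the
   other five parameters with warm-started continuation along the grid —
   and the fit re-polished from the profile minimum.

With all three, noiseless round trips recover all six parameters to ~1e-7 %
for every bundled case.  For Poisson-noise data the ridge degeneracy is
broken by the noise itself and the profile changes nothing (verified:
identical recovered values with and without), so batch studies disable it
(`FitConfig(profile_t_A=False)`) for speed.

Starting values are data-driven: `t_A` from a ramp-deficit closed form on
the first two frame counts (`t_A = (1-R) - sqrt(R^2+R)`, `R = C1/C2`,
clipped to `[0, 1)`; within 0.3 min of truth for all bundled cases), `S`
from total counts (decay-compensated on average when decay is on), `beta`
from the log-linear tail slope with `alpha0 = 0.9`, and `b` from the peak
position with `a0 = 1.5`.

### Goodness-of-fit metrics

For observed `O` and fitted `M` over `n` frames with `p = 6` parameters:

* fit error % = `100 RMS(O - M) / mean(O)`;
* corrected fit error % = fit error inflated by `sqrt(n/(n-p))`;
* noise % = `100 sqrt(mean(1/M_i))` (RMS per-frame relative Poisson SD);
* misregistration % = `sqrt(max(corrected^2 - noise^2, 0))` — the residual
  systematic discrepancy beyond counting noise;
* `1 - R^2` from the Pearson correlation of `O` with `M`.

These are reconstructions of conventional definitions; they are exposed and
documented rather than treated as reference values.

## The synthetic-data generator

The generator's defaults are the bundled study conditions: nine clinical
parameter sets (three patients x left lobe / right lobe / total thyroid),
89 consecutive one-minute frames, total-curve scales `S` of 2.0-6.6 million
counts, independent per-frame Poisson draws around the model expectation,
and no physical decay (noise is injected at the larger undecayed count
level, and the study then cross-checks the decay-corrected model).  One
master seed spawns an independent stream per (case, replicate).

What the generator does *not* emulate: TAC-image misregistration (patient
motion, ROI drift — the clinical fits show ~0.8-1% systematic residual
beyond noise), dead time, scatter, attenuation, background from outside the
ROI, and frame-timing jitter.  Passing recovery tests therefore demonstrate
self-consistency of the estimator under ideal counting statistics, not
robustness to those effects.

## The recovery study

Ten Poisson replicates per case are refit and summarized per parameter as:
the mean over cases of the within-case CV; the accuracy error
`100 (mean simulated - clinical mean) / clinical mean`; and a paired
two-tailed t-test of per-case replicate means against the generating
values.  Fit-error agreement is tested on Fisher z-transformed TAC-model
correlations.  Refits warm-start at the generating parameters with the
batch fit configuration; as noted above this is purely a runtime choice —
cold-started deep fits give the same recovered values.

A quantitative caveat documented here because it shapes expectations: the
Fisher-information (Cramer-Rao) bound for the within-case CV of `MRT_WO`
under these exact conditions is 2.3-9.4% per case (mean ~4.9% over the nine
cases), dominated by the tail-extrapolation variance of `beta`; the study
measures a mean CV of ~4.5%, i.e. the maximum-likelihood refit essentially
achieves the bound.  Within-case CVs well below ~3% are not attainable for
the ratio `alpha/beta` by any unbiased refit of this design, since even
perfectly correlated `alpha`-`beta` errors leave `CV(alpha/beta) >=
|CV(beta) - CV(alpha)|`.  Accuracy, by contrast, is tight: `alpha` recovers
to ~0.04% and the grand-mean `MRT_WO` to well under 1%.

## Washout comparators

Four washout-only models are fitted on the 5-89 min window (washout models
are maximal at their start, so fitting must begin well after the peak;
5 min is the conventional earliest start):

* OLS and `1/C(t)^2`-weighted biexponential
  (`MRT = (A1/l1^2 + A2/l2^2)/(A1/l1 + A2/l2)`), started from curve
  stripping, with a monoexponential fallback when the two rates or
  amplitudes degenerate;
* OLS gamma variate `K t^(alpha-1) e^(-beta t)` (`MRT = alpha/beta`) by
  nonlinear least squares started from the log-linearized solution;
* a Tikhonov-regularized gamma variate: ridge regression on the
  log-linearized model with standardized regressors, penalty excluded from
  the intercept, and the ridge strength scanned log-uniformly over
  1e-6...1e2 (60 points) to minimize the relative standard error of `beta`
  from the ridge sandwich covariance.  This is a deliberately simple
  estimator built around the published selection rule (minimum relative
  error of `beta`); adaptively regularized gamma-variate fitters in the
  literature differ in the regularized functional and variance formula, so
  results should be read as representative of the class, not of any
  specific prior implementation.

Washout fits consume decay-corrected counts by construction when the
synthetic battery is generated without decay; a flag on the CLI level is
unnecessary because decay handling lives in the forward model.

On the synthetic battery the biexponential MRTs are systematically short of
the generating `alpha/beta` (the instant-mixing assumption borrows early
redistribution into elimination), while the mean of the direct and
regularized gamma-variate MRTs tracks the truth best — the comparative
pattern the model comparison is designed to expose.

## Problem sizes and runtimes

Defaults were chosen so the full reference study (9 cases x 10 replicates,
89 frames) runs in a few minutes on one CPU: batch refits use the
statistically matched fast configuration (~2-10 s per fit), noiseless
reference fits the full-precision configuration (~5-15 s per fit).  The
Poisson dispersion property test uses 200 replicates of one case.

## Known limitations

* The `(t_A, a, b)` ridge means individual delivery-phase parameters are
  weakly identified from one-minute frames even though `a/b` is stable;
  interpret `a` and `b` jointly, not separately.
* Fitted `beta` (hence `MRT_WO`) extrapolates a ~90-min window to a
  multi-hour tail; its few-percent sampling variability is an information
  limit of the design, not an optimizer deficiency.
* The washout comparison uses a synthetic battery generated by the GDC
  model itself, which favours the gamma-variate comparators structurally;
  conclusions about biexponential bias mirror, but cannot replace, analysis
  of real data.
* No dead-time, scatter, attenuation or partial-volume corrections;
  single-isotope decay only.
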