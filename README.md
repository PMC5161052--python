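# gdctac

Gamma-distribution-convolution (GDC) modelling of bolus-injection
time-activity curves (TACs) from dynamic nuclear-medicine imaging.

## The problem

After a peripheral intravenous bolus, the activity recorded over an organ
region of interest first rises (tracer delivery through the blood pool) and
then decays over hours (tissue washout).  Conventional washout-only models
(biexponentials, gamma variates) are maximal at their start, so they cannot
describe the early curve at all and need very long acquisitions to pin down
washout rates.  Modelling the whole curve as the convolution of two gamma
densities — a fast delivery component `GD(a, b)` and a slow washout
component `GD(alpha, beta)` with `alpha < 1` — yields a closed-form density

    GDC(tau) = b^a beta^alpha / Gamma(a+alpha)
               * e^(-b tau) * tau^(a+alpha-1)
               * 1F1[alpha, a+alpha, (b-beta) tau],    tau > 0,

(`1F1` = Kummer's confluent hypergeometric function) that fits the entire
TAC from a single ROI and ~90 min of one-minute frames.  Mean residence
times then come for free, because MRTs add under convolution:

    MRT_total_from_injection = t_A + a/b + alpha/beta,

where `t_A` is the arrival offset (not part of organ residence),
`MRT_fast = a/b` quantifies delivery/mixing and `MRT_WO = alpha/beta` the
physiologically interesting washout time.

The package is for tracer-kinetics researchers and medical physicists who
want to fit this model to framed count data, use fitted models as realistic
simulation templates, quantify estimator precision by Monte Carlo, and
benchmark simpler washout-only models against it.

## What's inside

| module | contents |
|---|---|
| `gdctac.densities`  | gamma, Bateman and GDC densities; MRT calculus; numeric first-moment oracle |
| `gdctac.tac_model`  | framed forward model (optional physical decay), clinical frame grid, nine bundled thyroid parameter sets |
| `gdctac.fitting`    | Poisson-loss Nelder-Mead estimation of the six parameters; goodness-of-fit metrics |
| `gdctac.simulation` | Poisson TAC simulator; 9 x 10 parameter-recovery study; paired statistics |
| `gdctac.washout`    | OLS/WLS biexponential and OLS/Tikhonov gamma-variate washout comparators; CV(interpolation), CV(rmse) |
| `gdctac.io` / `gdctac.cli` | TAC CSV round trip, result documents, `gdctac` command line |

See `docs/methods.md` for the model, numerics, and design decisions.

## Worked example

Simulate one Poisson-noise TAC from bundled case 2T (total thyroid,
patient 2) and fit it back:

```sh
gdctac simulate --case 2T --seed 7 --out tac_2T.csv
gdctac fit tac_2T.csv --no-decay --seed 0 --out fit_2T.json
```

`fit_2T.json` (abridged, as printed by the run above):

```json
{
  "params": {
    "t_A": 0.32862357238678686,
    "a": 1.0650254625028548,
    "b": 1.170336515881495,
    "alpha": 0.9000091879060143,
    "beta": 0.002641194394529985,
    "S": 6651368.943933902
  },
  "mrt_fast_min": 0.910016433778177,
  "mrt_wo_min": 340.7584045195491,
  "fit_err_pct": 0.7510953301416111,
  "corrected_fit_err_pct": 0.7777696979376171,
  "noise_pct": 0.7429106768534665,
  "misregistration_pct": 0.23023776676969485,
  "one_minus_r2_pct": 0.19676428199167928,
  "converged": true
}
```

Reading the numbers: the generating parameters were
`t_A = 0.307, a = 1.127, b = 1.203, alpha = 0.8998, beta = 0.002652,
S = 6.625e6`; one noisy realization recovers the washout MRT as
`alpha/beta = 340.8 min` against a generating `339.3 min` (+0.4%), with the
delivery time `a/b = 0.91 min` — thyroid blood-pool mixing lasts about a
minute, washout about five-and-a-half hours.  The fit error (0.75%) sits at
the expected Poisson noise level (0.74%), so the model residual beyond
counting noise (misregistration, 0.23%) is essentially nil — as it should
be when the data come from the model itself.  Individual delivery
parameters (`a`, `b`) move more than their ratio: they sit on a
near-degenerate likelihood ridge (see `docs/methods.md`).

The nine bundled parameter sets and their MRTs:

```sh
gdctac fixtures --out params.csv
```

The Monte Carlo recovery study (10 Poisson replicates per case, no decay)
and the washout-model comparison:

```sh
gdctac recover --reps 10 --seed 1 --no-decay --out recovery.csv
gdctac washout-compare tac_2T.csv --models ols_e2,wls_e2,ols_gv,tk_gv \
    --gdc-mrts 339.3 --out washout.csv
```

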