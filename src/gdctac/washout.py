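"""Washout-only comparator models fitted on a late post-peak window.

Washout models are maximal at their start and strictly decreasing, so they
can only be fitted after the activity peak — here from the 5th to the 89th
minute by default.  Four comparators are provided:

* ``OLS_E2``  — biexponential ``A1 exp(-lam1 t) + A2 exp(-lam2 t)`` by
  ordinary least squares;
* ``WLS_E2``  — the same model weighted by ``1/C(t)^2`` (relative-error
  weighting, favouring the late samples that carry the half-life);
* ``OLS_GV``  — single gamma variate ``K t^(alpha-1) exp(-beta t)`` by
  nonlinear least squares on counts;
* ``TK_GV``   — the gamma variate fitted on the log-linearized model
  ``ln C = ln K + (alpha-1) ln t - beta t`` with a Tikhonov (ridge) penalty
  whose strength is chosen to minimize the relative standard error of the
  washout rate ``beta``.

Mean residence times: ``(A1/lam1^2 + A2/lam2^2) / (A1/lam1 + A2/lam2)`` for
the biexponential and ``alpha/beta`` for the gamma variate.

The ``TK_GV`` scheme here is a deliberately simple regularized estimator
built around the minimum-relative-error-of-beta selection rule; published
adaptively regularized gamma-variate fitters differ in the regularized
functional and variance estimate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .tac_model import TimeActivityCurve

__all__ = [
    "E2Params",
    "GVParams",
    "WashoutFit",
    "fit_e2",
    "fit_gv",
    "e2_mrt",
    "gv_mrt",
    "cv_interpolation",
    "cv_rmse",
    "WASHOUT_WINDOW",
]

#: default fitting window (minutes): washout models start at >= 5 min
WASHOUT_WINDOW = (5.0, 89.0)


@dataclass(frozen=True)
class E2Params:
    """Biexponential amplitudes (counts/min) and rates (per min), lam1 >= lam2."""

    A1: float
    A2: float
    lam1: float
    lam2: float

    def __post_init__(self) -> None:
        if self.A1 < 0 or self.A2 < 0 or max(self.A1, self.A2) == 0:
            raise ValueError("amplitudes must be >= 0 with at least one positive")
        if self.lam1 <= 0 or self.lam2 <= 0:
            raise ValueError("rates must be positive")
        if self.lam1 < self.lam2:
            raise ValueError("convention requires lam1 >= lam2")


@dataclass(frozen=True)
class GVParams:
    """Gamma-variate scale K, shape alpha_w and rate beta_w (model K t^(a-1) e^(-bt))."""

    K: float
    alpha_w: float
    beta_w: float

    def __post_init__(self) -> None:
        if self.K <= 0 or self.alpha_w <= 0 or self.beta_w <= 0:
            raise ValueError("all gamma-variate parameters must be positive")


@dataclass(frozen=True)
class WashoutFit:
    """One fitted washout comparator: parameters, MRT and fitting window."""

    model_id: str  # OLS_E2 | WLS_E2 | OLS_GV | TK_GV
    params: E2Params | GVParams
    mrt_wo: float
    window: tuple[float, float]
    converged: bool = True


def e2_mrt(p: E2Params) -> float:
    """MRT of a biexponential: amplitude-weighted mean of the two 1/lam."""
    num = p.A1 / p.lam1**2 + p.A2 / p.lam2**2
    den = p.A1 / p.lam1 + p.A2 / p.lam2
    return num / den


def gv_mrt(p: GVParams) -> float:
    """MRT of a gamma variate: the gamma-density mean ``alpha/beta``."""
    return p.alpha_w / p.beta_w


def _window_samples(
    tac: TimeActivityCurve, window: tuple[float, float]
) -> tuple[np.ndarray, np.ndarray]:
    lo, hi = window
    t = tac.frame_mid
    mask = (t >= lo) & (t <= hi)
    if mask.sum() < 6:
        raise ValueError("need at least 6 frames in the fitting window")
    y = tac.counts[mask] / tac.frame_duration[mask]  # counts/min
    if np.any(y <= 0):
        raise ValueError("washout fitting requires positive counts in the window")
    return t[mask], y


def _strip_init(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float]:
    """Curve-stripping starting values: peel the slow tail, then the fast rest."""
    n = len(t)
    tail = slice(n // 2, n)
    s2, i2 = np.polyfit(t[tail], np.log(y[tail]), 1)
    lam2 = max(-s2, 1e-5)
    A2 = np.exp(i2)
    resid = y - A2 * np.exp(-lam2 * t)
    head = resid[: max(n // 4, 3)] > 0
    if head.sum() >= 2:
        th = t[: max(n // 4, 3)][head]
        rh = resid[: max(n // 4, 3)][head]
        s1, i1 = np.polyfit(th, np.log(rh), 1)
        lam1 = max(-s1, lam2 * 3)
        A1 = np.exp(i1)
    else:
        lam1, A1 = lam2 * 10, 0.1 * A2
    return A1, A2, lam1, lam2


def fit_e2(
    tac: TimeActivityCurve,
    window: tuple[float, float] = WASHOUT_WINDOW,
    weighting: str = "ols",
) -> WashoutFit:
    """Least-squares biexponential washout fit on the given window.

    ``weighting='ols'`` minimizes unweighted squared residuals;
    ``'inverse_square'`` weights by ``1/C(t)^2`` (each residual divided by
    the observed value).  Near-degenerate fits (rate ratio ~1, which makes
    the amplitude split arbitrary) fall back to a monoexponential with a
    warning.
    """
    if weighting not in ("ols", "inverse_square"):
        raise ValueError(f"unknown weighting {weighting!r}")
    t, y = _window_samples(tac, window)
    A1, A2, lam1, lam2 = _strip_init(t, y)
    x0 = np.log(np.maximum([A1, A2, lam1, lam2], 1e-12))

    w = 1.0 / y if weighting == "inverse_square" else np.ones_like(y)

    def resid(x: np.ndarray) -> np.ndarray:
        a1, a2, l1, l2 = np.exp(x)
        return (a1 * np.exp(-l1 * t) + a2 * np.exp(-l2 * t) - y) * w

    sol = optimize.least_squares(resid, x0, method="lm", max_nfev=20000)
    a1, a2, l1, l2 = np.exp(sol.x)
    if l1 < l2:  # enforce lam1 >= lam2 by swapping components
        a1, a2, l1, l2 = a2, a1, l2, l1
    model_id = "OLS_E2" if weighting == "ols" else "WLS_E2"
    if l1 / l2 < 1.05 or min(a1, a2) / (a1 + a2) < 1e-6:
        warnings.warn(
            "biexponential degenerate (rate ratio ~ 1 or amplitude collapse); "
            "falling back to a monoexponential",
            RuntimeWarning,
            stacklevel=2,
        )
        s, i = np.polyfit(t, np.log(y), 1)
        lam = max(-s, 1e-6)
        params = E2Params(A1=0.0, A2=float(np.exp(i)), lam1=lam * 1.0001, lam2=lam)
        return WashoutFit(model_id, params, 1.0 / lam, window, converged=False)
    params = E2Params(A1=float(a1), A2=float(a2), lam1=float(l1), lam2=float(l2))
    return WashoutFit(model_id, params, float(e2_mrt(params)), window)


def _linearized_design(t: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones_like(t), np.log(t), t])


def _ridge_gv(
    t: np.ndarray, logy: np.ndarray, lam_r: float
) -> tuple[np.ndarray, float, float]:
    """Ridge fit of ln C = c0 + c1 ln t + c2 t; returns (coef, beta_hat, sd_beta).

    The non-intercept columns are standardized before penalization (the two
    regressors live on very different scales); the penalty excludes the
    intercept.  The variance of beta_hat comes from the usual ridge sandwich
    covariance with the residual variance estimated at the penalized fit.
    """
    X = _linearized_design(t)
    mu = X[:, 1:].mean(axis=0)
    sd = X[:, 1:].std(axis=0)
    Xs = X.copy()
    Xs[:, 1:] = (X[:, 1:] - mu) / sd
    n, p = Xs.shape
    D = np.diag([0.0, 1.0, 1.0])
    A = Xs.T @ Xs + lam_r * D
    A_inv = np.linalg.inv(A)
    coef_s = A_inv @ Xs.T @ logy
    resid = logy - Xs @ coef_s
    sigma2 = float(resid @ resid) / max(n - p, 1)
    cov = sigma2 * (A_inv @ (Xs.T @ Xs) @ A_inv)
    # unscale: beta = -c2 / sd_t
    beta_hat = -coef_s[2] / sd[1]
    sd_beta = np.sqrt(max(cov[2, 2], 0.0)) / sd[1]
    coef = np.array(
        [
            coef_s[0] - np.sum(coef_s[1:] * mu / sd),
            coef_s[1] / sd[0],
            coef_s[2] / sd[1],
        ]
    )
    return coef, float(beta_hat), float(sd_beta)


def fit_gv(
    tac: TimeActivityCurve,
    window: tuple[float, float] = WASHOUT_WINDOW,
    method: str = "ols",
) -> WashoutFit:
    """Gamma-variate washout fit ``K t^(alpha-1) exp(-beta t)``.

    ``method='ols'``: nonlinear least squares on counts, started from the
    log-linearized solution.  ``method='tk'``: ridge-penalized linearized
    fit whose penalty strength is scanned log-uniformly over 1e-6 ... 1e2
    (60 points) to minimize the relative standard error ``sd(beta)/beta``
    of the washout rate.
    """
    if method not in ("ols", "tk"):
        raise ValueError(f"unknown method {method!r}")
    t, y = _window_samples(tac, window)
    logy = np.log(y)

    if method == "tk":
        best = None
        for lam_r in np.logspace(-6, 2, 60):
            coef, beta_hat, sd_beta = _ridge_gv(t, logy, lam_r)
            if beta_hat <= 0:
                continue
            rel = sd_beta / beta_hat
            if best is None or rel < best[0]:
                best = (rel, coef, beta_hat)
        if best is None:
            coef, beta_hat, _ = _ridge_gv(t, logy, 0.0)
            params = GVParams(
                K=float(np.exp(coef[0])),
                alpha_w=float(coef[1] + 1.0),
                beta_w=max(beta_hat, 1e-12),
            )
            return WashoutFit("TK_GV", params, gv_mrt(params), window, converged=False)
        _, coef, beta_hat = best
        alpha_w = coef[1] + 1.0
        if alpha_w <= 0:
            return WashoutFit(
                "TK_GV",
                GVParams(K=float(np.exp(coef[0])), alpha_w=1e-6, beta_w=beta_hat),
                1e-6 / beta_hat,
                window,
                converged=False,
            )
        params = GVParams(
            K=float(np.exp(coef[0])), alpha_w=float(alpha_w), beta_w=float(beta_hat)
        )
        return WashoutFit("TK_GV", params, gv_mrt(params), window)

    # OLS: nonlinear least squares started from the unpenalized linearization
    coef, beta0, _ = _ridge_gv(t, logy, 0.0)
    x0 = np.array(
        [coef[0], np.log(max(coef[1] + 1.0, 1e-3)), np.log(max(beta0, 1e-6))]
    )

    def resid(x: np.ndarray) -> np.ndarray:
        lnK, ln_alpha, ln_beta = x
        alpha_w, beta_w = np.exp(ln_alpha), np.exp(ln_beta)
        return np.exp(lnK + (alpha_w - 1.0) * np.log(t) - beta_w * t) - y

    sol = optimize.least_squares(resid, x0, method="lm", max_nfev=20000)
    lnK, ln_alpha, ln_beta = sol.x
    params = GVParams(
        K=float(np.exp(lnK)),
        alpha_w=float(np.exp(ln_alpha)),
        beta_w=float(np.exp(ln_beta)),
    )
    return WashoutFit("OLS_GV", params, gv_mrt(params), window, converged=sol.success)


def cv_interpolation(per_patient) -> float:
    """Interpolation quality of whole-organ MRTs between lobe MRTs (%).

    For each patient with left-lobe, right-lobe and total-organ MRTs, the
    distance to interpolation is ``d = MRT_total - min(MRT_L, MRT_R)`` and
    the interpolation interval is ``ii = |MRT_L - MRT_R|``.  Returns
    ``100 * SD(d) / mean(ii)`` with the sample (n-1) standard deviation.
    """
    rows = []
    for rec in per_patient:
        if isinstance(rec, dict):
            L, R, T = rec["mrt_L"], rec["mrt_R"], rec["mrt_T"]
        else:
            L, R, T = rec
        rows.append((L, R, T))
    if len(rows) < 2:
        raise ValueError("need at least 2 patients")
    d = np.array([T - min(L, R) for L, R, T in rows])
    ii = np.array([abs(L - R) for L, R, T in rows])
    if np.any(ii == 0):
        raise ValueError("interpolation interval is zero for some patient")
    return float(100.0 * np.std(d, ddof=1) / np.mean(ii))


def cv_rmse(method_mrts, gdc_mrts) -> float:
    """CV of the RMS difference between a method's MRTs and reference MRTs (%)."""
    m = np.asarray(method_mrts, dtype=float)
    g = np.asarray(gdc_mrts, dtype=float)
    if m.shape != g.shape:
        raise ValueError("method and reference vectors must have equal length")
    if len(g) < 1 or g.mean() <= 0:
        raise ValueError("reference MRTs must be non-empty with positive mean")
    return float(100.0 * np.sqrt(np.mean((m - g) ** 2)) / np.mean(g))
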