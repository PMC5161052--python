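"""Monte Carlo TAC simulation and parameter-recovery studies.

The recovery study mirrors the package's core self-consistency check: each
clinical parameter set generates noiseless expected frame counts on the
clinical 89 x 1-min grid, Poisson counting noise is injected to produce
``reps_per_case`` independent replicate TACs, each replicate is refit with
the GDC model, and the recovered parameters are compared with the generating
("clinical") values.  Physical decay is not simulated by default: that keeps
the injected Poisson noise at the larger, undecayed count level and makes the
study a cross-check of the decay-corrected clinical fits.

Reported per parameter (t_A, a, b, alpha, beta, S, MRT_WO, MRT_fast):

* precision  — the mean over cases of the within-case CV across replicates;
* accuracy   — 100 * (mean simulated - clinical mean) / clinical mean;
* a paired two-tailed t-test (per-case replicate means vs clinical values)
  for zero difference.

Fit-error agreement between simulation and clinic is tested on Fisher
z-transformed TAC-model correlations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .fitting import FitConfig, FitResult, fit_gdc
from .tac_model import (
    ClinicalCase,
    DecayConfig,
    GDCParams,
    TimeActivityCurve,
    clinical_frames,
    expected_counts,
)

__all__ = [
    "RecoveryStudyConfig",
    "RecoveryStudySummary",
    "simulate_tac",
    "run_recovery_study",
    "paired_tests",
    "fisher_z_compare",
]

#: quantities tracked by the recovery study
STUDY_QUANTITIES = ("t_A", "a", "b", "alpha", "beta", "S", "MRT_WO", "MRT_fast")


def simulate_tac(
    p: GDCParams,
    frames: TimeActivityCurve | None = None,
    decay: DecayConfig = DecayConfig(),
    seed: int | np.random.Generator | np.random.SeedSequence = 0,
) -> TimeActivityCurve:
    """One Poisson-noise realization of the GDC forward model.

    Frame counts are independent Poisson draws around the expected counts
    (non-integer means are valid Poisson intensities; the draws are
    integers).  Reproducible for a given seed.
    """
    if frames is None:
        frames = clinical_frames()
    M = expected_counts(p, frames, decay)
    if np.any(M > 1e12):
        raise ValueError("expected counts exceed 1e12; refusing to simulate")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    return frames.with_counts(rng.poisson(M).astype(float))


# fit configuration tuned for replicate refits: the generating parameters
# provide the warm start, the t_A profile (a noiseless-identifiability
# device) is skipped, and the simplex tolerance sits two orders below the
# statistical parameter uncertainty
_STUDY_FIT_CFG = FitConfig(n_restarts=1, profile_t_A=False, xtol=1e-6, max_iter=3000)


@dataclass
class RecoveryStudyConfig:
    """Configuration of the Monte Carlo parameter-recovery study.

    Defaults are the package's reference study: the nine clinical parameter
    sets, ten Poisson replicates each, the 89 x 1-min clinical frame grid and
    no physical decay.  ``warm_start`` starts each refit at the generating
    parameters (the refits measure within-case recovery, and the noisy
    likelihood optimum does not depend on the start); ``inject_noise=False``
    turns the study into a deterministic refit consistency check.
    """

    cases: list[ClinicalCase] | None = None
    reps_per_case: int = 10
    decay: DecayConfig = field(default_factory=lambda: DecayConfig(enabled=False))
    seed: int = 0
    fit_cfg: FitConfig = field(default_factory=lambda: _STUDY_FIT_CFG)
    frames: TimeActivityCurve | None = None
    warm_start: bool = True
    inject_noise: bool = True

    def __post_init__(self) -> None:
        if self.reps_per_case < 2:
            raise ValueError("reps_per_case must be >= 2")


@dataclass
class RecoveryStudySummary:
    """Per-parameter precision/accuracy table plus replicate-level detail.

    ``table`` has one row per quantity with columns ``clinical_mean``,
    ``sim_mean``, ``mean_within_case_cv_pct``, ``accuracy_err_pct`` and
    ``p_no_difference``.  ``replicates`` holds every recovered fit;
    ``per_case`` the per-case replicate means and CVs.  ``fit_error_fisher_p``
    is the paired-t p-value on Fisher-z transformed TAC-model correlations
    (simulation vs clinical), when clinical correlations are available.
    """

    table: pd.DataFrame
    replicates: pd.DataFrame
    per_case: pd.DataFrame
    n_nonconverged: int
    fit_error_fisher_p: float | None
    seed: int

    @property
    def mean_cv_mrt_wo_pct(self) -> float:
        return float(self.table.loc["MRT_WO", "mean_within_case_cv_pct"])

    @property
    def grand_mean_mrt_wo(self) -> float:
        return float(self.replicates["MRT_WO"].mean())


def _quantities(p: GDCParams) -> dict[str, float]:
    return {
        "t_A": p.t_A,
        "a": p.a,
        "b": p.b,
        "alpha": p.alpha,
        "beta": p.beta,
        "S": p.S,
        "MRT_WO": p.alpha / p.beta,
        "MRT_fast": p.a / p.b,
    }


def run_recovery_study(cfg: RecoveryStudyConfig) -> RecoveryStudySummary:
    """Run the Monte Carlo recovery study and summarize precision/accuracy.

    One master seed spawns an independent random stream per (case,
    replicate), so any replicate can be regenerated in isolation.
    Non-converged refits are excluded from the summary with their count
    reported.
    """
    from .tac_model import generate_fixture_params

    cases = cfg.cases if cfg.cases is not None else generate_fixture_params()
    frames = cfg.frames if cfg.frames is not None else clinical_frames()
    master = np.random.SeedSequence(cfg.seed)
    streams = master.spawn(len(cases) * cfg.reps_per_case)

    rows = []
    n_bad = 0
    for ci, case in enumerate(cases):
        M = expected_counts(case.params, frames, cfg.decay)
        for rep in range(cfg.reps_per_case):
            ss = streams[ci * cfg.reps_per_case + rep]
            if cfg.inject_noise:
                rng = np.random.default_rng(ss)
                tac = frames.with_counts(rng.poisson(M).astype(float))
            else:
                tac = frames.with_counts(M.copy())
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                res = fit_gdc(
                    tac,
                    cfg.decay,
                    cfg.fit_cfg,
                    x0=case.params if cfg.warm_start else None,
                )
            if not res.converged:
                n_bad += 1
                continue
            row = {"case": case.case_id, "rep": rep}
            row.update(_quantities(res.params))
            row["fit_err_pct"] = res.fit_err_pct
            row["one_minus_r2_pct"] = res.one_minus_r2_pct
            rows.append(row)
    replicates = pd.DataFrame(rows)
    if replicates.empty:
        raise RuntimeError("no replicate fit converged")

    clinical = pd.DataFrame(
        [{"case": c.case_id, **_quantities(c.params)} for c in cases]
    ).set_index("case")

    grp = replicates.groupby("case")
    per_case_mean = grp[list(STUDY_QUANTITIES)].mean()
    per_case_cv = 100.0 * grp[list(STUDY_QUANTITIES)].std(ddof=1) / per_case_mean
    per_case = per_case_mean.join(per_case_cv, lsuffix="_mean", rsuffix="_cv_pct")

    table_rows = {}
    for q in STUDY_QUANTITIES:
        clin = clinical[q]
        simm = per_case_mean[q].reindex(clin.index)
        if len(clin) >= 3:
            tests = paired_tests(clin.to_numpy(), simm.to_numpy())
        else:  # too few cases for a paired test
            tests = {"t_p_two_tailed": float("nan")}
        table_rows[q] = {
            "clinical_mean": float(clin.mean()),
            "sim_mean": float(replicates[q].mean()),
            "mean_within_case_cv_pct": float(per_case_cv[q].mean()),
            "accuracy_err_pct": 100.0
            * (replicates[q].mean() - clin.mean())
            / clin.mean(),
            "p_no_difference": tests["t_p_two_tailed"],
        }
    table = pd.DataFrame(table_rows).T

    fisher_p = None
    clin_r = _clinical_correlations(cases)
    if clin_r is not None and "one_minus_r2_pct" in replicates:
        sim_r = np.sqrt(1.0 - grp["one_minus_r2_pct"].mean() / 100.0)
        sim_r = sim_r.reindex(clinical.index).to_numpy()
        # perfect correlations (noiseless refits) have no finite Fisher z
        if np.all(np.abs(clin_r) < 1) and np.all(np.abs(sim_r) < 1):
            fisher_p = fisher_z_compare(clin_r, sim_r)

    return RecoveryStudySummary(
        table=table,
        replicates=replicates,
        per_case=per_case,
        n_nonconverged=n_bad,
        fit_error_fisher_p=fisher_p,
        seed=cfg.seed,
    )


def _clinical_correlations(cases) -> np.ndarray | None:
    """TAC-model Pearson r per clinical case, if the cases carry fit metrics."""
    try:
        return np.sqrt(1.0 - np.array([c.one_minus_r2_pct for c in cases]) / 100.0)
    except AttributeError:
        return None


def paired_tests(clinical, sim_means) -> dict[str, float | bool]:
    """Paired two-tailed t-test and exact Wilcoxon signed-rank p-values.

    Both compare per-case clinical values with per-case simulation means.
    All-zero differences return p = 1 by convention; non-zero differences
    with zero spread make the t statistic undefined and are flagged
    ``degenerate`` (p = nan).
    """
    c = np.asarray(clinical, dtype=float)
    s = np.asarray(sim_means, dtype=float)
    if c.shape != s.shape or c.ndim != 1:
        raise ValueError("inputs must be equal-length 1-d vectors")
    if len(c) < 3:
        raise ValueError("need at least 3 pairs")
    d = s - c
    if np.all(d == 0):
        return {"t_p_two_tailed": 1.0, "wilcoxon_p": 1.0, "degenerate": False}
    if np.std(d, ddof=1) == 0:
        return {
            "t_p_two_tailed": float("nan"),
            "wilcoxon_p": float("nan"),
            "degenerate": True,
        }
    t_res = stats.ttest_rel(s, c)
    method = "exact" if len(c) <= 25 and not np.any(d == 0) else "auto"
    w_res = stats.wilcoxon(s, c, method=method)
    return {
        "t_p_two_tailed": float(t_res.pvalue),
        "wilcoxon_p": float(w_res.pvalue),
        "degenerate": False,
    }


def fisher_z_compare(r_clinical, r_sim) -> float:
    """Paired two-tailed t-test on Fisher z-transformed correlations.

    ``z = atanh(r)`` variance-stabilizes Pearson correlations so the paired
    t-test applies; returns the two-tailed p-value (1.0 for identical
    vectors by convention).
    """
    rc = np.asarray(r_clinical, dtype=float)
    rs = np.asarray(r_sim, dtype=float)
    if np.any(np.abs(rc) >= 1) or np.any(np.abs(rs) >= 1):
        raise ValueError("correlations must lie strictly inside (-1, 1)")
    zc, zs = np.arctanh(rc), np.arctanh(rs)
    d = zs - zc
    if np.all(d == 0):
        return 1.0
    return float(stats.ttest_rel(zs, zc).pvalue)
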