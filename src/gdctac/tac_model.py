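"""Forward model: expected framed counts from a scaled, offset GDC density.

A time-activity curve (TAC) records the counts collected in an organ region
of interest during each acquisition frame.  The forward model here is

    M_i = S * integral over frame i of GDC(t - t_A) * D(t) dt,

where ``S`` is the total-counts scale (the TAC area when decay is off),
``t_A`` the arrival offset, and ``D(t) = 2^(-t/half_life)`` the physical
radionuclide decay factor (identity when decay is disabled).  Fitting the
decay-bearing model to raw counts yields decay-corrected kinetics directly
from the convolution parameters.

The clinical acquisition layout emulated throughout the package is 89
consecutive one-minute frames, frame ``i`` covering ``[i-1, i)`` minutes from
injection.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .densities import GDCShape, InvalidParameterError, gdc_density

__all__ = [
    "DecayConfig",
    "GDCParams",
    "TimeActivityCurve",
    "clinical_frames",
    "expected_counts",
    "decay_factor",
    "ClinicalCase",
    "generate_fixture_params",
    "load_clinical_table",
]

#: physical half-life of Tc-99m in minutes (6.007 h)
TC99M_HALF_LIFE_MIN = 360.4


@dataclass(frozen=True)
class DecayConfig:
    """Physical-decay switch for the forward model."""

    enabled: bool = False
    half_life: float = TC99M_HALF_LIFE_MIN

    def __post_init__(self) -> None:
        if not (self.half_life > 0):
            raise InvalidParameterError(
                f"half_life must be positive, got {self.half_life}"
            )


@dataclass(frozen=True)
class GDCParams:
    """The six fitted quantities of one scaled, time-offset GDC model.

    ``t_A`` (min) is the tracer arrival offset, ``shape`` holds
    (a, b, alpha, beta), and ``S`` is the scale factor equating the TAC area
    to ``S`` times the (unit) GDC area — i.e. the total counts the region
    would collect from injection to infinity absent decay.
    """

    t_A: float
    shape: GDCShape
    S: float

    def __post_init__(self) -> None:
        if self.t_A < 0:
            raise InvalidParameterError(f"t_A must be >= 0, got {self.t_A}")
        if not (self.S > 0 and np.isfinite(self.S)):
            raise InvalidParameterError(f"S must be positive, got {self.S}")

    @classmethod
    def from_values(
        cls, t_A: float, a: float, b: float, alpha: float, beta: float, S: float
    ) -> "GDCParams":
        return cls(t_A=t_A, shape=GDCShape.from_values(a, b, alpha, beta), S=S)

    def as_array(self) -> np.ndarray:
        """(t_A, a, b, alpha, beta, S) as a flat vector."""
        s = self.shape
        return np.array([self.t_A, s.a, s.b, s.alpha, s.beta, self.S])

    @property
    def a(self) -> float:
        return self.shape.a

    @property
    def b(self) -> float:
        return self.shape.b

    @property
    def alpha(self) -> float:
        return self.shape.alpha

    @property
    def beta(self) -> float:
        return self.shape.beta


PARAM_NAMES = ("t_A", "a", "b", "alpha", "beta", "S")


@dataclass
class TimeActivityCurve:
    """Framed count series with frame timing metadata.

    ``frame_start`` and ``frame_duration`` are in minutes from injection;
    frame ``i`` covers the half-open interval
    ``[frame_start[i], frame_start[i] + frame_duration[i])``.  ``counts`` are
    totals collected per frame (not rates).
    """

    frame_start: np.ndarray
    frame_duration: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.frame_start = np.asarray(self.frame_start, dtype=float)
        self.frame_duration = np.asarray(self.frame_duration, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        n = len(self.frame_start)
        if len(self.frame_duration) != n or len(self.counts) != n:
            raise ValueError("frame_start, frame_duration and counts must align")
        if np.any(np.diff(self.frame_start) <= 0):
            raise ValueError("frame_start must be strictly increasing")
        if np.any(self.frame_duration <= 0):
            raise ValueError("frame durations must be positive")
        overlap = self.frame_start[1:] < (
            self.frame_start[:-1] + self.frame_duration[:-1] - 1e-9
        )
        if np.any(overlap):
            raise ValueError("frames must not overlap")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def n_frames(self) -> int:
        return len(self.frame_start)

    @property
    def frame_mid(self) -> np.ndarray:
        return self.frame_start + 0.5 * self.frame_duration

    @property
    def frame_end(self) -> np.ndarray:
        return self.frame_start + self.frame_duration

    def with_counts(self, counts: np.ndarray) -> "TimeActivityCurve":
        return TimeActivityCurve(
            frame_start=self.frame_start.copy(),
            frame_duration=self.frame_duration.copy(),
            counts=np.asarray(counts, dtype=float),
        )


def clinical_frames(n_frames: int = 89, frame_duration: float = 1.0) -> TimeActivityCurve:
    """The clinical acquisition layout: ``n_frames`` consecutive equal frames.

    Returns a :class:`TimeActivityCurve` with zero counts, usable as a frame
    grid for the forward model and simulators.
    """
    start = np.arange(n_frames, dtype=float) * frame_duration
    return TimeActivityCurve(
        frame_start=start,
        frame_duration=np.full(n_frames, frame_duration),
        counts=np.zeros(n_frames),
    )


def decay_factor(t, decay: DecayConfig) -> np.ndarray | float:
    """``2^(-t/half_life)`` when decay is enabled, else 1."""
    if not decay.enabled:
        return np.ones_like(np.asarray(t, dtype=float)) if np.ndim(t) else 1.0
    return np.exp2(-np.asarray(t, dtype=float) / decay.half_life)


# 3-point Gauss-Legendre nodes/weights on [-1, 1]
_GL3_NODES = np.array([-math.sqrt(0.6), 0.0, math.sqrt(0.6)])
_GL3_WEIGHTS = np.array([5.0 / 9.0, 8.0 / 9.0, 5.0 / 9.0])


def expected_counts(
    p: GDCParams,
    frames: TimeActivityCurve,
    decay: DecayConfig = DecayConfig(),
    method: str = "gauss3",
) -> np.ndarray:
    """Expected counts per frame under the (optionally decayed) GDC model.

    ``method='gauss3'`` integrates the density over each frame with 3-point
    Gauss-Legendre quadrature (the density changes rapidly near its peak
    within the first frames); ``method='midpoint'`` uses the cheaper
    midpoint-times-duration rule.  Decay is clocked from injection (t = 0),
    not from arrival: physical decay does not wait for the tracer.
    """
    start = frames.frame_start
    dur = frames.frame_duration
    if method == "gauss3":
        # nodes shape (n_frames, 3)
        t = start[:, None] + 0.5 * dur[:, None] * (1.0 + _GL3_NODES[None, :])
        w = 0.5 * dur[:, None] * _GL3_WEIGHTS[None, :]
        dens = gdc_density(p.shape, (t - p.t_A).ravel()).reshape(t.shape)
        integrand = dens * np.asarray(decay_factor(t.ravel(), decay)).reshape(t.shape)
        return p.S * np.sum(w * integrand, axis=1)
    if method == "midpoint":
        t = frames.frame_mid
        dens = gdc_density(p.shape, t - p.t_A)
        return p.S * dur * dens * decay_factor(t, decay)
    raise ValueError(f"unknown frame integration method: {method!r}")


@dataclass(frozen=True)
class ClinicalCase:
    """One clinical parameter set (patient + region label) with fit metrics.

    ``case_id`` encodes patient number and region: L/R for left/right thyroid
    lobe, T for the summed total-thyroid region.  The goodness-of-fit columns
    are as reported for the original clinical regressions.
    """

    case_id: str
    params: GDCParams
    fit_err_pct: float
    noise_pct: float
    one_minus_r2_pct: float


def load_clinical_table() -> pd.DataFrame:
    """The bundled table of the nine clinical GDC parameter sets."""
    ref = importlib.resources.files("gdctac").joinpath("data/clinical_params.csv")
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path)


def generate_fixture_params() -> list[ClinicalCase]:
    """The nine clinical GDC parameter sets (cases 1L ... 3T).

    These are the study conditions for every simulation in the package:
    thyroid-lobe and total-thyroid kinetics with total-curve scales of
    roughly 2-6.6 million counts over the 89-minute acquisition.
    """
    df = load_clinical_table()
    cases = []
    for row in df.itertuples(index=False):
        cases.append(
            ClinicalCase(
                case_id=row.case,
                params=GDCParams.from_values(
                    t_A=row.t_A_min,
                    a=row.a,
                    b=row.b_per_min,
                    alpha=row.alpha,
                    beta=row.beta_per_min,
                    S=row.S_counts,
                ),
                fit_err_pct=row.fit_err_pct,
                noise_pct=row.noise_pct,
                one_minus_r2_pct=row.one_minus_r2_pct,
            )
        )
    return cases
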