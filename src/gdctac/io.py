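"""Reading and writing TAC files, fit results and run configuration.

TACs travel as delimited text with the header
``frame,t_start_min,duration_min,counts`` — one row per acquisition frame,
sorted by frame index.  Fit results serialize to JSON documents carrying
every fitted quantity and metric at full precision.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .fitting import FitResult
from .tac_model import TimeActivityCurve

__all__ = [
    "read_tac",
    "write_tac",
    "fit_result_to_dict",
    "write_fit_result",
    "load_run_config",
    "TacParseError",
]

TAC_COLUMNS = ("frame", "t_start_min", "duration_min", "counts")


class TacParseError(ValueError):
    """Raised when a TAC file violates the expected layout."""


def read_tac(path) -> TimeActivityCurve:
    """Read a TAC CSV, validating layout, ordering and count signs."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise TacParseError(f"{path}: cannot parse ({exc})") from exc
    missing = [c for c in TAC_COLUMNS if c not in df.columns]
    if missing:
        raise TacParseError(f"{path}: missing columns {missing}")
    for col in TAC_COLUMNS:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax()) + 2  # header + 1-based
            raise TacParseError(f"{path}: non-numeric value in {col!r} at line {row}")
        if vals.isna().any():
            row = int(vals.isna().idxmax()) + 2
            raise TacParseError(f"{path}: empty cell in {col!r} at line {row}")
        df[col] = vals
    frames = df["frame"].to_numpy()
    if np.any(np.diff(frames) <= 0):
        row = int(np.argmax(np.diff(frames) <= 0)) + 3
        raise TacParseError(f"{path}: frame indices not strictly increasing at line {row}")
    if (df["counts"] < 0).any():
        row = int((df["counts"] < 0).idxmax()) + 2
        raise TacParseError(f"{path}: negative counts at line {row}")
    start = df["t_start_min"].to_numpy(dtype=float)
    dur = df["duration_min"].to_numpy(dtype=float)
    gaps = start[1:] - (start[:-1] + dur[:-1])
    if np.any(np.abs(gaps) > 1e-9):
        warnings.warn(
            f"{path}: timing gaps between frames (largest {np.max(np.abs(gaps)):.3g} min)",
            RuntimeWarning,
            stacklevel=2,
        )
    try:
        return TimeActivityCurve(
            frame_start=start, frame_duration=dur, counts=df["counts"].to_numpy(float)
        )
    except ValueError as exc:
        raise TacParseError(f"{path}: {exc}") from exc


def write_tac(tac: TimeActivityCurve, path) -> None:
    """Write a TAC as CSV (round-trips with :func:`read_tac`)."""
    df = pd.DataFrame(
        {
            "frame": np.arange(1, tac.n_frames + 1),
            "t_start_min": tac.frame_start,
            "duration_min": tac.frame_duration,
            "counts": tac.counts,
        }
    )
    df.to_csv(path, index=False, float_format="%.10g")


def fit_result_to_dict(res: FitResult) -> dict:
    p = res.params
    return {
        "params": {
            "t_A": p.t_A,
            "a": p.a,
            "b": p.b,
            "alpha": p.alpha,
            "beta": p.beta,
            "S": p.S,
        },
        "mrt_fast_min": p.a / p.b,
        "mrt_wo_min": p.alpha / p.beta,
        "loss_value": res.loss_value,
        "fit_err_pct": res.fit_err_pct,
        "corrected_fit_err_pct": res.corrected_fit_err_pct,
        "noise_pct": res.noise_pct,
        "misregistration_pct": res.misregistration_pct,
        "one_minus_r2_pct": res.one_minus_r2_pct,
        "converged": res.converged,
        "n_evaluations": res.n_evaluations,
    }


def write_fit_result(res: FitResult, path) -> None:
    Path(path).write_text(json.dumps(fit_result_to_dict(res), indent=2) + "\n")


#: recognized run-configuration keys and their coercions
_RUN_CONFIG_KEYS = {
    "decay": bool,
    "half_life_min": float,
    "loss": str,
    "window_start_min": float,
    "window_end_min": float,
    "restarts": int,
    "seed": int,
    "verbosity": str,
}


def load_run_config(path) -> dict:
    """Load a flat key-value YAML run configuration; unknown keys rejected."""
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        return {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: run config must be a flat mapping")
    out = {}
    for key, val in raw.items():
        if key not in _RUN_CONFIG_KEYS:
            raise ValueError(f"{path}: unknown config key {key!r}")
        out[key] = _RUN_CONFIG_KEYS[key](val)
    return out
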