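"""Behavioral psychophysics: d′ and log-modulus logistic psychometric fits.

A go/no-go harmonics-discrimination session is a table of trials with the
stimulus Δonset (ms), a lick outcome, and an optogenetic-light flag.
Response rate versus Δonset is fit with a logistic function after the
log-modulus transform x = sign(Δ)·log10(1 + |Δ|), which linearizes the wide
Δonset range while keeping the sign; the midpoint (behavioral threshold)
and growth-rate slope are estimated by binomial maximum likelihood.  The
half-max Δonset is the back-transformed |Δ| at the 50% response rate, and
the fractional broadening under cortical inactivation compares light-on and
control half-max values per session.

d′ uses the equal-variance Gaussian convention z(hit) − z(false alarm) with
rate clipping to avoid infinite quantiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import norm


def log_modulus(delta_ms: np.ndarray) -> np.ndarray:
    """Signed log transform: sign(x) * log10(1 + |x|)."""
    delta_ms = np.asarray(delta_ms, dtype=float)
    return np.sign(delta_ms) * np.log10(1.0 + np.abs(delta_ms))


def inverse_log_modulus(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return np.sign(x) * (10.0 ** np.abs(x) - 1.0)


def dprime(hit_rate: float, fa_rate: float, clip: float = 0.01) -> float:
    """Equal-variance Gaussian d′ = z(hit) − z(fa) with rate clipping.

    Rates are clipped to [clip, 1 − clip]; with N trials a conventional
    choice is clip = 1/(2N).
    """
    if not 0 < clip < 0.5:
        raise ValueError("clip must be in (0, 0.5)")
    h = float(np.clip(hit_rate, clip, 1.0 - clip))
    f = float(np.clip(fa_rate, clip, 1.0 - clip))
    return float(norm.ppf(h) - norm.ppf(f))


@dataclass
class PsychometricFit:
    """Logistic fit on the log-modulus scale for one condition."""

    midpoint: float  # log-modulus units
    slope: float
    half_max_delta_ms: float
    response_rates: pd.Series  # index: delta_onset_ms
    n_trials: int
    success: bool


def _neg_log_lik(params, x, licked):
    mid, slope = params
    z = slope * (x - mid)
    # log(p) and log(1-p) via logaddexp for numerical stability
    logp = -np.logaddexp(0.0, -z)
    log1mp = -np.logaddexp(0.0, z)
    return -(logp[licked].sum() + log1mp[~licked].sum())


def fit_logistic(x: np.ndarray, licked: np.ndarray) -> tuple[float, float, bool]:
    """Binomial-MLE logistic fit p = 1/(1 + exp(-slope*(x - midpoint)))."""
    x = np.asarray(x, dtype=float)
    licked = np.asarray(licked, dtype=bool)
    if licked.all() or (~licked).all():
        return float("nan"), float("nan"), False
    best = None
    for slope0 in (1.0, 4.0, -1.0, -4.0):
        res = minimize(
            _neg_log_lik,
            x0=np.array([float(np.median(x)), slope0]),
            args=(x, licked),
            method="Nelder-Mead",
            options={"xatol": 1e-7, "fatol": 1e-10, "maxiter": 2000},
        )
        if best is None or res.fun < best.fun:
            best = res
    return float(best.x[0]), float(best.x[1]), bool(best.success)


def trim_unmotivated(
    trials: pd.DataFrame,
    lick_col: str = "lick",
    run_length: int = 10,
) -> pd.DataFrame:
    """Drop leading/trailing runs of >= ``run_length`` consecutive misses.

    Emulates excluding session phases where the animal was not engaged.
    """
    licks = trials[lick_col].to_numpy(dtype=bool)
    n = licks.size
    start, end = 0, n
    i = 0
    while i < n and not licks[i]:
        i += 1
    if i >= run_length:
        start = i
    j = n
    while j > 0 and not licks[j - 1]:
        j -= 1
    if n - j >= run_length:
        end = j
    return trials.iloc[start:end]


def fit_psychometric(
    trials: pd.DataFrame,
    delta_col: str = "delta_onset_ms",
    lick_col: str = "lick",
    led_col: str = "led",
    trim: bool = True,
    first_n: int | None = 250,
) -> dict[str, PsychometricFit]:
    """Per-condition (control / light-on) psychometric fits for one session.

    Optionally trims unmotivated leading/trailing stretches and caps the
    analysis at the first ``first_n`` trials.  Returns fits keyed
    ``"control"`` and (if light trials exist) ``"led"``.
    """
    df = trials
    if trim:
        df = trim_unmotivated(df, lick_col=lick_col)
    if first_n is not None:
        df = df.iloc[:first_n]
    if df[delta_col].nunique() < 2:
        raise ValueError("need at least 2 distinct delta onsets")
    out: dict[str, PsychometricFit] = {}
    conditions = {"control": ~df[led_col].astype(bool)}
    if df[led_col].astype(bool).any():
        conditions["led"] = df[led_col].astype(bool)
    for name, mask in conditions.items():
        sub = df[mask]
        x = log_modulus(sub[delta_col].to_numpy())
        licked = sub[lick_col].to_numpy(dtype=bool)
        mid, slope, ok = fit_logistic(x, licked)
        half = float(abs(inverse_log_modulus(mid))) if np.isfinite(mid) else float("nan")
        rates = sub.groupby(delta_col)[lick_col].mean()
        out[name] = PsychometricFit(
            midpoint=mid,
            slope=slope,
            half_max_delta_ms=half,
            response_rates=rates,
            n_trials=int(mask.sum()),
            success=ok,
        )
    return out


def broadening(fits: dict[str, PsychometricFit]) -> float:
    """Fractional widening of the half-max Δonset under inactivation.

    (half_max_led − half_max_control) / half_max_control for one session.
    """
    if "led" not in fits:
        return float("nan")
    c = fits["control"].half_max_delta_ms
    l = fits["led"].half_max_delta_ms
    if not (np.isfinite(c) and np.isfinite(l)) or c == 0:
        return float("nan")
    return (l - c) / c


def session_summary(per_session_fits: list[dict[str, PsychometricFit]]) -> dict:
    """Group summary: mean half-max per condition plus two broadening reports.

    ``broadening_per_session`` averages the per-session fractional widening;
    ``broadening_of_means`` recomputes it from the group-mean half-max
    values.  The two differ whenever sessions are heterogeneous.
    """
    ctrl = np.array([f["control"].half_max_delta_ms for f in per_session_fits])
    led = np.array(
        [f["led"].half_max_delta_ms for f in per_session_fits if "led" in f]
    )
    per = np.array([broadening(f) for f in per_session_fits])
    per = per[np.isfinite(per)]
    out = {
        "half_max_control_ms": float(np.nanmean(ctrl)),
        "half_max_led_ms": float(np.nanmean(led)) if led.size else float("nan"),
        "broadening_per_session": float(per.mean()) if per.size else float("nan"),
    }
    if led.size and np.isfinite(out["half_max_control_ms"]) and out["half_max_control_ms"] != 0:
        out["broadening_of_means"] = (
            out["half_max_led_ms"] - out["half_max_control_ms"]
        ) / out["half_max_control_ms"]
    return out
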