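"""Per-ROI calcium-trace processing and single-cell response statistics.

Covers the standard two-photon analysis chain: ring-background (neuropil)
subtraction, per-trial ΔF/F normalization with an additive denominator
offset guarding against dim baselines, area-under-curve response amplitudes,
a two-criterion significance test (single-trial and trial-mean threshold
crossings of minimum duration), ROC-based threshold calibration, the
coincidence-preference index CI = (C - S)/(C + S), the linearity index
LI = (H - S)/(H + S) with negative amplitudes clipped to zero, and tonal
receptive-field metrics (CF and BW70).

Cell-type-specific significance thresholds (in baseline-SD multiples)
default to pyramidal 3.3, SOM 1.6, PV 2.6.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

CELL_TYPE_THRESHOLD_K = {"pyr": 3.3, "som": 1.6, "pv": 2.6}

DFF_OFFSET = 20.0  # a.u. added to the ΔF/F denominator
NEUROPIL_R = 0.9
BRIGHTNESS_MIN = 0.03


class NoBaselineVarianceError(ValueError):
    """Raised when a baseline SD of zero makes thresholding undefined."""


@dataclass
class RoiSession:
    """Fluorescence traces plus trial alignment for one imaging session.

    ``f_cell`` and ``f_bg`` are (n_rois, n_frames) arrays in raw a.u.;
    ``coords`` is (n_rois, 2) in µm; ``trials`` has columns
    ``stim_id`` and ``onset_frame``.
    """

    f_cell: np.ndarray
    f_bg: np.ndarray
    coords: np.ndarray
    frame_rate: float
    trials: pd.DataFrame
    cell_type: str = "pyr"

    def __post_init__(self) -> None:
        if self.f_cell.shape != self.f_bg.shape:
            raise ValueError("f_cell and f_bg must have identical shapes")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be > 0")
        if (self.trials["onset_frame"] >= self.f_cell.shape[1]).any():
            raise ValueError("trial onset frame beyond trace end")

    @property
    def n_rois(self) -> int:
        return self.f_cell.shape[0]

    def save(self, path: str) -> None:
        import h5py

        with h5py.File(path, "w") as h:
            h.create_dataset("traces_cell", data=self.f_cell)
            h.create_dataset("traces_bg", data=self.f_bg)
            h.create_dataset("coords", data=self.coords)
            h.attrs["frame_rate"] = self.frame_rate
            h.attrs["cell_type"] = self.cell_type
            tr = h.create_group("trials")
            tr.create_dataset(
                "stim_id", data=np.array(self.trials["stim_id"], dtype="S")
            )
            tr.create_dataset("onset_frame", data=self.trials["onset_frame"].to_numpy())

    @classmethod
    def load(cls, path: str) -> "RoiSession":
        import h5py

        with h5py.File(path, "r") as h:
            trials = pd.DataFrame(
                {
                    "stim_id": [s.decode() for s in h["trials/stim_id"][()]],
                    "onset_frame": h["trials/onset_frame"][()],
                }
            )
            return cls(
                f_cell=h["traces_cell"][()],
                f_bg=h["traces_bg"][()],
                coords=h["coords"][()],
                frame_rate=float(h.attrs["frame_rate"]),
                trials=trials,
                cell_type=str(h.attrs.get("cell_type", "pyr")),
            )


def neuropil_correct(
    session: RoiSession,
    r: float = NEUROPIL_R,
    brightness_min: float = BRIGHTNESS_MIN,
) -> tuple[np.ndarray, np.ndarray]:
    """Subtract scaled background: F = F_cell - r * F_bg.

    Returns the corrected traces and an inclusion mask that keeps only ROIs
    whose mean raw fluorescence is at least ``brightness_min`` (fractional)
    brighter than their background ring.
    """
    if not 0 <= r <= 1:
        raise ValueError("r must be in [0, 1]")
    f = session.f_cell - r * session.f_bg
    include = session.f_cell.mean(axis=1) >= (1.0 + brightness_min) * session.f_bg.mean(axis=1)
    return f, include


def trial_dff(
    f: np.ndarray,
    onset_frames: np.ndarray,
    frame_rate: float,
    pre_s: float = 1.0,
    post_s: float = 3.0,
    offset: float = DFF_OFFSET,
) -> np.ndarray:
    """Trial-aligned ΔF/F: (F - F0) / (F0 + offset), F0 = per-trial baseline mean.

    Returns an array of shape (n_trials, n_pre + n_post) where the baseline
    window is the ``pre_s`` seconds preceding each sound onset.  The offset
    enters the denominator only (guard against dim baselines).
    """
    f = np.asarray(f, dtype=float)
    onset_frames = np.asarray(onset_frames, dtype=int)
    n_pre = int(round(pre_s * frame_rate))
    n_post = int(round(post_s * frame_rate))
    if np.any(onset_frames - n_pre < 0) or np.any(onset_frames + n_post > f.size):
        raise ValueError("trial window extends beyond the trace")
    out = np.empty((onset_frames.size, n_pre + n_post))
    for i, on in enumerate(onset_frames):
        seg = f[on - n_pre : on + n_post]
        f0 = seg[:n_pre].mean()
        if f0 + offset <= 0:
            raise NoBaselineVarianceError("degenerate baseline: F0 + offset <= 0")
        out[i] = (seg - f0) / (f0 + offset)
    return out


def response_amplitude(
    dff_trials: np.ndarray,
    frame_rate: float,
    window_s: float = 1.0,
    baseline_frames: int = 0,
    mode: str = "auc",
) -> tuple[np.ndarray, float]:
    """Response amplitude per trial and its trial mean.

    ``auc`` integrates the (already baseline-subtracted) ΔF/F trapezoidally
    over ``window_s`` after onset, yielding ΔF/F·s.  ``charge`` integrates
    the negative-going part of the signal over the same window and flips the
    sign, for voltage-clamp EPSC charge.  ``baseline_frames`` locates the
    onset within each row.
    """
    dff_trials = np.atleast_2d(np.asarray(dff_trials, dtype=float))
    n_win = int(round(window_s * frame_rate))
    if baseline_frames + n_win > dff_trials.shape[1]:
        raise ValueError("response window extends beyond the trial window")
    seg = dff_trials[:, baseline_frames : baseline_frames + n_win]
    if mode == "auc":
        per_trial = np.trapezoid(seg, dx=1.0 / frame_rate, axis=1)
    elif mode == "charge":
        per_trial = -np.trapezoid(np.minimum(seg, 0.0), dx=1.0 / frame_rate, axis=1)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return per_trial, float(per_trial.mean())


def _longest_run(mask: np.ndarray) -> int:
    if not mask.any():
        return 0
    padded = np.concatenate(([False], mask, [False]))
    d = np.diff(padded.astype(np.int8))
    return int(np.max(np.flatnonzero(d == -1) - np.flatnonzero(d == 1)))


def test_significance(
    dff_trials: np.ndarray,
    frame_rate: float,
    threshold_k: float,
    baseline_frames: int,
    min_dur_s: float = 0.5,
    trial_fraction: float = 0.5,
) -> tuple[bool, dict]:
    """Two-criterion excitation test on trial-aligned ΔF/F.

    The threshold is ``threshold_k`` times the pooled baseline SD.  A cell is
    significant iff (1) more than ``trial_fraction`` of single trials exceed
    the threshold consecutively for at least ``min_dur_s`` after onset, AND
    (2) the trial-averaged trace does as well.
    """
    dff_trials = np.atleast_2d(np.asarray(dff_trials, dtype=float))
    base = dff_trials[:, :baseline_frames]
    sd = float(base.std())
    if sd == 0.0:
        raise NoBaselineVarianceError("baseline SD is zero")
    thr = threshold_k * sd
    n_min = int(round(min_dur_s * frame_rate))
    post = dff_trials[:, baseline_frames:]
    runs = np.array([_longest_run(tr > thr) for tr in post])
    frac = float(np.mean(runs >= n_min))
    crit1 = frac > trial_fraction
    mean_run = _longest_run(post.mean(axis=0) > thr)
    crit2 = mean_run >= n_min
    return bool(crit1 and crit2), {
        "threshold": thr,
        "baseline_sd": sd,
        "trial_pass_fraction": frac,
        "single_trial_criterion": bool(crit1),
        "mean_trace_criterion": bool(crit2),
        "mean_trace_run_frames": mean_run,
    }


def calibrate_threshold(
    scores: np.ndarray, labels: np.ndarray, tpr_target: float = 0.90
) -> tuple[float, dict]:
    """ROC threshold calibration to a target true-positive rate.

    Sweeps cutoffs (midpoints between consecutive distinct scores) and,
    among cutoffs whose TPR is at least ``tpr_target``, picks the one with
    the lowest false-positive rate, breaking ties toward the highest TPR; a
    run of equivalent cutoffs (e.g. across a separation gap) resolves to its
    midpoint.  If no cutoff attains the target, the lowest cutoff (boundary)
    is returned with a warning flag.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if not (labels.any() and (~labels).any()):
        raise ValueError("both label classes must be present")
    pos, neg = scores[labels], scores[~labels]
    uniq = np.unique(scores)
    cuts = (uniq[:-1] + uniq[1:]) / 2.0
    cuts = np.concatenate(([uniq[0] - 1.0], cuts, [uniq[-1] + 1.0]))
    tpr = (pos[None, :] > cuts[:, None]).mean(axis=1)
    fpr = (neg[None, :] > cuts[:, None]).mean(axis=1)
    ok = tpr >= tpr_target
    if not ok.any():
        return float(cuts[0]), {"tpr": float(tpr[0]), "fpr": float(fpr[0]), "attained": False}
    best_fpr = fpr[ok].min()
    ok &= fpr == best_fpr
    best_tpr = tpr[ok].max()
    ok &= tpr == best_tpr
    idx = np.flatnonzero(ok)
    # equivalent adjacent cutoffs delimit a score gap; return its midpoint
    lo_cut, hi_cut = cuts[idx[0]], cuts[idx[-1]]
    lo_edge = uniq[np.searchsorted(uniq, lo_cut) - 1] if lo_cut > uniq[0] - 0.5 else lo_cut
    hi_edge = uniq[np.searchsorted(uniq, hi_cut)] if hi_cut < uniq[-1] + 0.5 else hi_cut
    thr = float((lo_edge + hi_edge) / 2.0)
    return thr, {"tpr": float(best_tpr), "fpr": float(best_fpr), "attained": True}


def coincidence_index(c: float, s: float) -> float:
    """CI = (C - S)/(C + S) after clipping negative amplitudes to 0.

    C is the coincident-harmonics amplitude, S the shifted-harmonics
    amplitude.  Returns NaN (undefined sentinel) when both clip to zero;
    callers drop sentinels from pooled statistics.
    """
    c, s = max(float(c), 0.0), max(float(s), 0.0)
    if c + s == 0.0:
        return float("nan")
    return (c - s) / (c + s)


def linearity_index(h: float, s_linear: float) -> float:
    """LI = (H - S)/(H + S) with negative amplitudes clipped to 0.

    H is the multi-tone (harmonic) response, S the linear sum of component
    tone responses.  0 = linear, negative = sublinear, positive =
    supralinear.  NaN sentinel when both clip to zero.
    """
    h, s = max(float(h), 0.0), max(float(s_linear), 0.0)
    if h + s == 0.0:
        return float("nan")
    return (h - s) / (h + s)


def pool_ci(
    indices: pd.DataFrame,
    shifts: tuple = (-30.0, -15.0, 15.0, 30.0),
    value_col: str = "ci",
) -> np.ndarray:
    """Pool per-(ROI, F0, Δonset) CI values at ±15 and ±30 ms, dropping sentinels.

    ±45 ms comparisons are excluded by default.
    """
    m = indices["delta_onset"].isin(shifts)
    vals = indices.loc[m, value_col].to_numpy(dtype=float)
    return vals[np.isfinite(vals)]


def average_li_over_shifts(
    li_by_shift: dict[float, float], shifts: tuple = (-30.0, -15.0, 15.0, 30.0)
) -> float:
    """Whole-cell convention: average LI over the ±15 and ±30 ms onset shifts."""
    vals = [li_by_shift[s] for s in shifts if s in li_by_shift and np.isfinite(li_by_shift[s])]
    if not vals:
        return float("nan")
    return float(np.mean(vals))


def _gauss_log2(x, a, mu, sigma):
    return a * np.exp(-((x - mu) ** 2) / (2 * sigma**2))


def fit_gaussian_tuning(
    freqs_hz: np.ndarray, amplitudes: np.ndarray
) -> tuple[float, float, float]:
    """Least-squares Gaussian over log2(frequency); returns (amp, mu_log2, sigma_log2)."""
    x = np.log2(np.asarray(freqs_hz, float))
    y = np.clip(np.asarray(amplitudes, float), 0.0, None)
    if y.max() <= 0:
        raise ValueError("no positive amplitude to fit")
    p0 = (y.max(), x[int(np.argmax(y))], 1.0)
    bounds = ([0.0, x.min() - 2, 0.05], [np.inf, x.max() + 2, 10.0])
    popt, _ = curve_fit(_gauss_log2, x, y, p0=p0, bounds=bounds, maxfev=10_000)
    return tuple(float(v) for v in popt)


@dataclass(frozen=True)
class TuningMetrics:
    cf_hz: float
    bw70_octaves: float
    threshold_level_db: float


def tuning_metrics(
    amplitudes: np.ndarray,
    significant: np.ndarray,
    freqs_hz: np.ndarray,
    levels_db: np.ndarray,
    bw_level_db: float = 70.0,
    fit_threshold_fraction: float = 0.5,
) -> TuningMetrics | None:
    """Characteristic frequency and 70 dB bandwidth from a tone response grid.

    ``amplitudes`` and ``significant`` are (n_levels, n_freqs).  The
    threshold intensity is the lowest level with any significant response;
    CF is the best frequency at that level.  When the threshold intensity is
    the lowest tested level (the true threshold may lie below it), CF is the
    geometric mean of the best frequency and the mean of a Gaussian fit at
    that level.  BW70 (octaves) averages the empirical span of significant
    frequencies at ``bw_level_db`` with the span where a Gaussian fit exceeds
    ``fit_threshold_fraction`` of its peak.  Returns None when no tone
    response is significant.
    """
    amplitudes = np.asarray(amplitudes, dtype=float)
    significant = np.asarray(significant, dtype=bool)
    freqs_hz = np.asarray(freqs_hz, dtype=float)
    levels_db = np.asarray(levels_db, dtype=float)
    if not significant.any():
        return None
    order = np.argsort(levels_db)
    levels_db, amplitudes, significant = levels_db[order], amplitudes[order], significant[order]
    sig_levels = np.flatnonzero(significant.any(axis=1))
    i_thr = int(sig_levels[0])
    thr_level = float(levels_db[i_thr])
    row = np.where(significant[i_thr], amplitudes[i_thr], -np.inf)
    best = float(freqs_hz[int(np.argmax(row))])
    if i_thr == 0:
        try:
            _, mu, _ = fit_gaussian_tuning(freqs_hz, amplitudes[i_thr])
            cf = float(2.0 ** ((np.log2(best) + mu) / 2.0))
        except (ValueError, RuntimeError):
            cf = best
    else:
        cf = best

    i70 = int(np.argmin(np.abs(levels_db - bw_level_db)))
    sig70 = significant[i70]
    log_f = np.log2(freqs_hz)
    if sig70.any():
        # bin-inclusive span: each tested frequency stands for one grid step,
        # so the range spans half a step beyond the outermost significant tones
        step = float(np.mean(np.diff(np.sort(log_f))))
        emp_bw = float(log_f[sig70].max() - log_f[sig70].min()) + step
    else:
        emp_bw = 0.0
    try:
        a, mu, sigma = fit_gaussian_tuning(freqs_hz, amplitudes[i70])
        # width where the Gaussian exceeds the fractional threshold of its peak
        fit_bw = float(2.0 * sigma * np.sqrt(2.0 * np.log(1.0 / fit_threshold_fraction)))
    except (ValueError, RuntimeError):
        fit_bw = emp_bw
    return TuningMetrics(
        cf_hz=cf, bw70_octaves=(emp_bw + fit_bw) / 2.0, threshold_level_db=thr_level
    )


def session_response_table(
    session: RoiSession,
    threshold_k: float | None = None,
    pre_s: float = 1.0,
    post_s: float = 3.0,
    window_s: float = 1.0,
    offset: float = DFF_OFFSET,
    r: float = NEUROPIL_R,
    brightness_min: float = BRIGHTNESS_MIN,
) -> pd.DataFrame:
    """Full per-(ROI, stimulus) response table for a session.

    Runs neuropil correction, per-trial ΔF/F, amplitude quantification and
    the two-criterion significance test, returning one row per included
    ROI x stimulus with columns ``roi``, ``stim_id``, ``amplitude``,
    ``significant`` and the per-trial amplitudes.
    """
    if threshold_k is None:
        threshold_k = CELL_TYPE_THRESHOLD_K[session.cell_type]
    f, include = neuropil_correct(session, r=r, brightness_min=brightness_min)
    n_pre = int(round(pre_s * session.frame_rate))
    rows = []
    stim_groups = session.trials.groupby("stim_id", sort=True)
    for roi in range(session.n_rois):
        if not include[roi]:
            continue
        for stim_id, grp in stim_groups:
            dff = trial_dff(
                f[roi], grp["onset_frame"].to_numpy(), session.frame_rate,
                pre_s=pre_s, post_s=post_s, offset=offset,
            )
            per_trial, mean_amp = response_amplitude(
                dff, session.frame_rate, window_s=window_s, baseline_frames=n_pre
            )
            sig, _ = test_significance(
                dff, session.frame_rate, threshold_k, baseline_frames=n_pre
            )
            rows.append(
                {
                    "roi": roi,
                    "stim_id": stim_id,
                    "amplitude": mean_amp,
                    "significant": sig,
                    "trial_amplitudes": per_trial,
                }
            )
    return pd.DataFrame(rows)
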