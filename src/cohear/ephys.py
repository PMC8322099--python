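"""Spike-train PSTHs, evoked-response quantification, and optogenetic
suppression kinetics.

PSTHs use half-open uniform bins (default 10 ms), trial-averaged rates in
Hz, optional baseline subtraction (default window 200 ms before sound
onset) and an optional three-bin moving average for display only.  Evoked
responses sum the positive-going PSTH over a response window.  Suppression
kinetics at light onset are quantified on fine-binned (0.5 ms) PSTHs
normalized to the pre-light spontaneous rate by fitting

    r(t) = 1                                        for t < latency
    r(t) = floor + (1 - floor) * exp(-(t - latency)/tau)   for t >= latency
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit


@dataclass
class PsthResult:
    bin_edges: np.ndarray  # ms
    rate: np.ndarray  # Hz (or baseline-subtracted Hz)
    n_trials: int
    baseline_rate: float | None = None
    counts: np.ndarray | None = None  # raw summed counts per bin

    @property
    def bin_centers(self) -> np.ndarray:
        return (self.bin_edges[:-1] + self.bin_edges[1:]) / 2.0


def compute_psth(
    spike_times: list[np.ndarray],
    bin_ms: float = 10.0,
    t_range: tuple[float, float] = (-200.0, 500.0),
    baseline_window: tuple[float, float] | None = None,
    smooth_bins: int | None = None,
) -> PsthResult:
    """Trial-averaged PSTH in Hz over half-open bins [lo, hi).

    ``baseline_window`` (ms) subtracts the mean rate within it;
    ``smooth_bins`` applies a centered moving average (visualization only —
    quantify on the unsmoothed result).
    """
    if bin_ms <= 0:
        raise ValueError("bin_ms must be > 0")
    lo, hi = t_range
    edges = np.arange(lo, hi + bin_ms / 2, bin_ms)
    counts = np.zeros(edges.size - 1)
    for trial in spike_times:
        c, _ = np.histogram(np.asarray(trial, dtype=float), bins=edges)
        counts += c
    n_trials = max(1, len(spike_times))
    rate = counts / n_trials / (bin_ms / 1000.0)
    baseline = None
    if baseline_window is not None:
        b = (edges[:-1] >= baseline_window[0]) & (edges[:-1] < baseline_window[1])
        baseline = float(rate[b].mean())
        rate = rate - baseline
    if smooth_bins is not None and smooth_bins > 1:
        kernel = np.ones(smooth_bins) / smooth_bins
        rate = np.convolve(rate, kernel, mode="same")
    return PsthResult(
        bin_edges=edges, rate=rate, n_trials=len(spike_times),
        baseline_rate=baseline, counts=counts,
    )


def evoked_response(
    psth: PsthResult,
    window_ms: tuple[float, float] = (0.0, 150.0),
    normalize_to: float | None = None,
) -> float:
    """Sum of positive-going PSTH bins within the window, optionally normalized.

    Returns NaN when ``normalize_to`` is zero (undefined sentinel).
    """
    lo, hi = window_ms
    starts = psth.bin_edges[:-1]
    if lo < psth.bin_edges[0] or hi > psth.bin_edges[-1]:
        raise ValueError("window extends beyond the PSTH range")
    m = (starts >= lo) & (starts < hi)
    val = float(np.clip(psth.rate[m], 0.0, None).sum())
    if normalize_to is not None:
        if normalize_to == 0:
            return float("nan")
        val /= normalize_to
    return val


def _suppression_model(t, latency, tau, floor):
    r = np.ones_like(t)
    after = t >= latency
    r[after] = floor + (1.0 - floor) * np.exp(-(t[after] - latency) / tau)
    return r


@dataclass
class SuppressionFit:
    latency_ms: float
    tau_ms: float
    floor: float
    rmse: float
    success: bool


def suppression_kinetics(
    t_ms: np.ndarray,
    normalized_rate: np.ndarray,
    latency_bounds: tuple[float, float] = (0.0, 50.0),
    tau_bounds: tuple[float, float] = (0.1, 500.0),
) -> SuppressionFit:
    """Fit the single-exponential suppression model to a normalized fine PSTH.

    ``normalized_rate`` is the rate divided by the pre-light spontaneous
    rate; times are relative to light onset.  Initialization grids over
    candidate latencies.  Non-decaying data (late rate not below 1) yields
    a failure sentinel with diagnostics rather than a spurious fit.
    """
    t = np.asarray(t_ms, dtype=float)
    y = np.asarray(normalized_rate, dtype=float)
    late = y[t > t.max() * 0.5]
    if late.size == 0 or late.mean() >= 0.95:
        return SuppressionFit(float("nan"), float("nan"), float("nan"), float("nan"), False)
    best = None
    for lat0 in np.linspace(latency_bounds[0], min(latency_bounds[1], t.max() / 2), 6):
        try:
            popt, _ = curve_fit(
                _suppression_model,
                t,
                y,
                p0=(lat0, 20.0, max(0.0, float(late.mean()))),
                bounds=(
                    [latency_bounds[0], tau_bounds[0], 0.0],
                    [latency_bounds[1], tau_bounds[1], 1.0],
                ),
                maxfev=5000,
            )
        except RuntimeError:
            continue
        rmse = float(np.sqrt(np.mean((_suppression_model(t, *popt) - y) ** 2)))
        if best is None or rmse < best[1]:
            best = (popt, rmse)
    if best is None:
        return SuppressionFit(float("nan"), float("nan"), float("nan"), float("nan"), False)
    (lat, tau, floor), rmse = best
    return SuppressionFit(float(lat), float(tau), float(floor), rmse, True)
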