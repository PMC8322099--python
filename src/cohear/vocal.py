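"""Harmonic analysis of vocalization audio: syllables, contours, F0 matching.

The pipeline mirrors a standard bioacoustic workflow for mouse vocalizations:

1. Syllables are detected where the absolute amplitude exceeds a high
   multiple of the baseline-noise SD, with onsets/offsets extended to a
   lower-multiple crossing and fixed margins added.
2. Each syllable's spectrogram is cleaned (per-column detrending along the
   frequency axis, 3x3 median filter, Frangi ridge enhancement), thresholded
   relative to the syllable maximum, and flood-filled into connected
   time-frequency contours; short components are rejected as noise.
3. Short time segments are matched against harmonic templates over a grid of
   candidate fundamentals.  The match quality for a candidate F0 is

       EF = sqrt( (1/n) * sum_f ((f*F0 - F_real) / F_real)^2 )

   where f is the harmonic order assigned to each observed component
   frequency F_real and n is the number of components in the segment.  A
   segment with EF below a threshold (default 0.5) is judged harmonic.

The harmonic order per component is f = round(F_real/F0) clipped to >= 1,
which per component is the integer minimizing its term of the sum, so grid
minimization over F0 with this assignment equals the exhaustive minimum over
grid x order assignments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal
from skimage.filters import frangi


class NoBaselineError(ValueError):
    """Raised when the baseline-noise SD cannot be estimated (constant audio)."""


@dataclass(frozen=True)
class Syllable:
    """One detected vocal syllable with margins included in ``samples``."""

    onset: float  # s, margin-inclusive start
    offset: float  # s, margin-inclusive end
    samples: np.ndarray
    sample_rate: float
    core_onset: float  # s, boundary-criterion crossing
    core_offset: float
    source_id: str = ""


@dataclass(frozen=True)
class SpectroContour:
    """One flood-fill-connected time-frequency component of a syllable.

    ``weights`` carries the raw spectrogram magnitude at each pixel so that
    representative frequencies are power-weighted, undoing the spatial
    spread the ridge-enhancement halo introduces.
    """

    time_bins: np.ndarray  # int bin indices
    freq_bins: np.ndarray
    times_s: np.ndarray  # bin centers, absolute within the recording
    freqs_hz: np.ndarray
    time_resolution_ms: float
    weights: np.ndarray | None = None
    ridge_times_s: np.ndarray | None = None  # one per occupied time bin
    ridge_freqs_hz: np.ndarray | None = None  # peak-interpolated frequency

    @property
    def duration_ms(self) -> float:
        return (self.time_bins.max() - self.time_bins.min() + 1) * self.time_resolution_ms

    def frequency_at(self, t_lo: float, t_hi: float) -> float | None:
        """Mean ridge frequency over the half-open window [t_lo, t_hi) s.

        Uses the peak-interpolated ridge track when available (sub-bin
        accuracy), falling back to a power-weighted pixel mean.
        """
        if self.ridge_times_s is not None:
            m = (self.ridge_times_s >= t_lo) & (self.ridge_times_s < t_hi)
            if m.any():
                return float(self.ridge_freqs_hz[m].mean())
            return None
        m = (self.times_s >= t_lo) & (self.times_s < t_hi)
        if not m.any():
            return None
        if self.weights is None or self.weights[m].sum() == 0:
            return float(self.freqs_hz[m].mean())
        return float(np.average(self.freqs_hz[m], weights=self.weights[m]))


@dataclass(frozen=True)
class HarmonicSegment:
    """A short time segment with its best-matching fundamental."""

    t_center: float  # s
    observed_freqs: np.ndarray  # Hz
    orders: np.ndarray  # harmonic order per component
    n: int
    best_f0: float
    ef: float
    is_harmonic: bool


@dataclass(frozen=True)
class F0Summary:
    """Probability-normalized F0-usage histogram with percentile summary."""

    bin_edges: np.ndarray
    probabilities: np.ndarray
    median: float
    p10: float
    p90: float
    n_segments: int


def default_f0_grid(lo: float = 1000.0, hi: float = 10_000.0, step: float = 50.0) -> np.ndarray:
    """Candidate-F0 grid spanning the vocal range, 50 Hz resolution by default."""
    return np.arange(lo, hi + step / 2, step)


def detect_syllables(
    audio: np.ndarray,
    sample_rate: float,
    detect_k: float = 10.0,
    bound_k: float = 5.0,
    margin_ms: float = 15.0,
    baseline: slice | None = None,
    source_id: str = "",
) -> list[Syllable]:
    """Detect syllables by amplitude threshold crossings.

    A candidate region is any contiguous run where ``|audio|`` exceeds
    ``bound_k`` times the baseline-noise SD; it is emitted as a syllable iff
    it also contains a sample exceeding ``detect_k`` SD.  Margins of
    ``margin_ms`` are added on both ends (clipped to the recording) and
    regions whose margin-extended intervals overlap are merged.

    Baseline SD is estimated from ``baseline`` (default: the leading 50 ms).
    """
    audio = np.asarray(audio, dtype=float)
    if audio.size == 0:
        raise ValueError("audio must be non-empty")
    if not detect_k >= bound_k > 0:
        raise ValueError("require detect_k >= bound_k > 0")
    if baseline is None:
        baseline = slice(0, max(2, int(round(0.05 * sample_rate))))
    sd = float(np.std(audio[baseline]))
    if sd == 0.0:
        raise NoBaselineError("baseline segment has zero SD; cannot set thresholds")

    above = np.abs(audio) > bound_k * sd
    if not above.any():
        return []
    padded = np.concatenate(([False], above, [False]))
    d = np.diff(padded.astype(np.int8))
    run_starts = np.flatnonzero(d == 1)
    run_ends = np.flatnonzero(d == -1)  # exclusive

    detect_level = detect_k * sd
    margin = int(round(margin_ms / 1000.0 * sample_rate))
    intervals: list[tuple[int, int, int, int]] = []  # (lo, hi, core_lo, core_hi)
    for lo, hi in zip(run_starts, run_ends):
        if np.max(np.abs(audio[lo:hi])) > detect_level:
            intervals.append((max(0, lo - margin), min(audio.size, hi + margin), lo, hi))
    if not intervals:
        return []
    # merge overlapping margin-extended intervals
    merged = [intervals[0]]
    for lo, hi, clo, chi in intervals[1:]:
        mlo, mhi, mclo, mchi = merged[-1]
        if lo <= mhi:
            merged[-1] = (mlo, max(mhi, hi), mclo, max(mchi, chi))
        else:
            merged.append((lo, hi, clo, chi))
    return [
        Syllable(
            onset=lo / sample_rate,
            offset=hi / sample_rate,
            samples=audio[lo:hi].copy(),
            sample_rate=sample_rate,
            core_onset=clo / sample_rate,
            core_offset=chi / sample_rate,
            source_id=source_id,
        )
        for lo, hi, clo, chi in merged
    ]


def _spectrogram(samples: np.ndarray, sample_rate: float, time_resolution_ms: float):
    hop = max(1, int(round(sample_rate * time_resolution_ms / 1000.0)))
    win = 2 * hop
    if samples.size < win:
        return None
    f, t, z = signal.stft(
        samples,
        fs=sample_rate,
        window="hann",
        nperseg=win,
        noverlap=win - hop,
        boundary=None,
        padded=False,
    )
    return f, t, np.abs(z)


def extract_contours(
    syllable: Syllable,
    time_resolution_ms: float = 1.0,
    detrend_window_hz: float = 4000.0,
    power_threshold: float = 0.05,
    min_duration_ms: float = 7.0,
    use_frangi: bool = True,
    frangi_sigmas: tuple = (1, 2, 3),
) -> list[SpectroContour]:
    """Trace time-frequency contours in one syllable's spectrogram.

    Processing per the pipeline described in the module docstring; the
    power threshold is a fraction of the processed image's maximum.  The
    Frangi ridge filter can be bypassed (``use_frangi=False``) for ablation.
    """
    spec = _spectrogram(syllable.samples, syllable.sample_rate, time_resolution_ms)
    if spec is None:
        return []
    f, t, s_raw = spec
    if s_raw.max() == 0:
        return []
    df = f[1] - f[0]
    wbins = max(1, int(round(detrend_window_hz / df)))
    s = s_raw - ndimage.uniform_filter1d(s_raw, size=wbins, axis=0, mode="nearest")
    s = ndimage.median_filter(s, size=(3, 3), mode="nearest")
    detrended = s
    if use_frangi:
        s = frangi(s, sigmas=frangi_sigmas, black_ridges=False)
    if s.max() <= 0:
        return []
    # the ridge filter rings around a bright line, producing faint parallel
    # ghosts where the detrended power is non-positive; gate them out
    mask = (s > power_threshold * s.max()) & (detrended > 0)
    labels, n_lab = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    contours: list[SpectroContour] = []
    for lab in range(1, n_lab + 1):
        fb, tb = np.nonzero(labels == lab)
        dur = (tb.max() - tb.min() + 1) * time_resolution_ms
        if dur < min_duration_ms:
            continue
        # sub-bin ridge track: per occupied time bin, quadratic (log-parabolic)
        # interpolation of the raw magnitude around the brightest contour pixel
        ridge_t, ridge_f = [], []
        for col in np.unique(tb):
            rows = fb[tb == col]
            peak = rows[np.argmax(s_raw[rows, col])]
            freq = f[peak]
            if 0 < peak < f.size - 1:
                a, b, c = s_raw[peak - 1 : peak + 2, col]
                if a > 0 and b > 0 and c > 0:
                    la, lb, lc = np.log(a), np.log(b), np.log(c)
                    denom = la - 2 * lb + lc
                    if denom < 0:
                        freq = f[peak] + 0.5 * (la - lc) / denom * df
            ridge_t.append(t[col])
            ridge_f.append(freq)
        contours.append(
            SpectroContour(
                time_bins=tb,
                freq_bins=fb,
                times_s=syllable.onset + t[tb],
                freqs_hz=f[fb],
                time_resolution_ms=time_resolution_ms,
                weights=s_raw[fb, tb],
                ridge_times_s=syllable.onset + np.array(ridge_t),
                ridge_freqs_hz=np.array(ridge_f),
            )
        )
    return contours


def harmonic_orders(freqs: np.ndarray, f0: float | np.ndarray) -> np.ndarray:
    """Harmonic order per observed frequency: round(F_real/F0), at least 1."""
    return np.maximum(1, np.round(np.asarray(freqs, float) / f0)).astype(int)


def evaluate_ef(freqs: np.ndarray, f0: float, orders: np.ndarray | None = None) -> float:
    """Root-mean-square relative mismatch between f*F0 and the observed freqs."""
    freqs = np.asarray(freqs, dtype=float)
    if orders is None:
        orders = harmonic_orders(freqs, f0)
    rel = (orders * f0 - freqs) / freqs
    return float(np.sqrt(np.mean(rel**2)))


def match_harmonic_template(
    freqs: np.ndarray, f0_grid: np.ndarray
) -> tuple[float, float, np.ndarray]:
    """Best-matching F0 on the grid and its EF (plus the order assignment).

    Per candidate F0 each component is assigned the order minimizing its own
    relative-mismatch term; two components may share an order (the sum runs
    over components, not template orders).
    """
    freqs = np.asarray(freqs, dtype=float)
    f0_grid = np.asarray(f0_grid, dtype=float)
    if freqs.size == 0:
        raise ValueError("segment must contain at least one component")
    if np.any(freqs <= 0):
        raise ValueError("observed frequencies must be positive")
    if f0_grid.size == 0:
        raise ValueError("f0_grid must be non-empty")
    orders = np.maximum(1, np.round(freqs[None, :] / f0_grid[:, None]))
    rel = (orders * f0_grid[:, None] - freqs[None, :]) / freqs[None, :]
    ef = np.sqrt(np.mean(rel**2, axis=1))
    # exact EF ties occur at subharmonics of the true fundamental; prefer
    # the highest tied candidate so an in-grid F0/2 never wins over F0
    i = int(np.flatnonzero(ef == ef.min())[-1])
    return float(f0_grid[i]), float(ef[i]), orders[i].astype(int)


def segment_and_match(
    contours: list[SpectroContour],
    segment_width_ms: float = 1.4,
    f0_grid: np.ndarray | None = None,
    threshold: float = 0.5,
    keep_all: bool = False,
) -> list[HarmonicSegment]:
    """Match harmonic templates in consecutive time segments.

    Each segment of width ``segment_width_ms`` collects the simultaneous
    contour frequencies (one per contour: its mean frequency within the
    segment) and runs the template match.  Segments with EF below
    ``threshold`` are returned; ``keep_all=True`` keeps the rest too,
    flagged non-harmonic.
    """
    if segment_width_ms <= 0:
        raise ValueError("segment_width_ms must be > 0")
    if not contours:
        return []
    if f0_grid is None:
        f0_grid = default_f0_grid()
    w = segment_width_ms / 1000.0
    t_lo = min(c.times_s.min() for c in contours)
    t_hi = max(c.times_s.max() for c in contours)
    n_seg = max(1, int(np.ceil((t_hi - t_lo) / w + 1e-12)))
    out: list[HarmonicSegment] = []
    for k in range(n_seg):
        lo = t_lo + k * w
        freqs = [c.frequency_at(lo, lo + w) for c in contours]
        freqs = np.array([f for f in freqs if f is not None])
        if freqs.size == 0:
            continue
        best_f0, ef, orders = match_harmonic_template(freqs, f0_grid)
        seg = HarmonicSegment(
            t_center=lo + w / 2,
            observed_freqs=freqs,
            orders=orders,
            n=freqs.size,
            best_f0=best_f0,
            ef=ef,
            is_harmonic=ef < threshold,
        )
        if seg.is_harmonic or keep_all:
            out.append(seg)
    return out


def analyze_recording(
    audio: np.ndarray,
    sample_rate: float,
    time_resolution_ms: float = 1.0,
    f0_grid: np.ndarray | None = None,
    threshold: float = 0.5,
    **detect_kwargs,
) -> list[HarmonicSegment]:
    """End-to-end: detect syllables, trace contours, match harmonic templates."""
    segments: list[HarmonicSegment] = []
    for syl in detect_syllables(audio, sample_rate, **detect_kwargs):
        contours = extract_contours(syl, time_resolution_ms=time_resolution_ms)
        segments.extend(segment_and_match(contours, f0_grid=f0_grid, threshold=threshold))
    return segments


def f0_usage_summary(
    segments: list[HarmonicSegment], bin_edges: np.ndarray | None = None
) -> F0Summary | None:
    """F0-usage histogram (probabilities summing to 1) and percentile summary.

    Only harmonic segments contribute.  Returns None when there are none.
    """
    f0s = np.array([s.best_f0 for s in segments if s.is_harmonic])
    if f0s.size == 0:
        return None
    if bin_edges is None:
        bin_edges = np.arange(1000.0, 10_250.0, 250.0)
    counts, edges = np.histogram(f0s, bins=bin_edges)
    p10, med, p90 = np.percentile(f0s, [10, 50, 90])
    return F0Summary(
        bin_edges=edges,
        probabilities=counts / f0s.size,
        median=float(med),
        p10=float(p10),
        p90=float(p90),
        n_segments=int(f0s.size),
    )
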