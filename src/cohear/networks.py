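"""Noise correlations and matched-control pair construction.

Noise correlation between two simultaneously recorded ROIs is the Pearson
correlation of their trial-to-trial response residuals: per stimulus, the
across-trial mean amplitude is subtracted, residuals are concatenated over
stimuli and trials, and the pair's coefficient is computed on the two
residual vectors.  Elevated noise correlation within putative subnetworks
is benchmarked against three matched-control pair sets: distance-matched
random pairs (3 per target pair), and noise-SD- or SNR-matched pairs (the
2 closest-statistic ROIs per member, giving 2 x 2 = 4 control pairs).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import mannwhitneyu


def noise_correlation(trial_amplitudes: np.ndarray) -> np.ndarray:
    """Pairwise noise-correlation matrix from (n_rois, n_stimuli, n_trials) amplitudes.

    Residuals remove the per-ROI, per-stimulus trial mean; ROIs with
    zero-variance residuals get NaN rows/columns (undefined sentinel).
    """
    a = np.asarray(trial_amplitudes, dtype=float)
    if a.ndim != 3:
        raise ValueError("expected (n_rois, n_stimuli, n_trials) array")
    resid = a - a.mean(axis=2, keepdims=True)
    flat = resid.reshape(a.shape[0], -1)
    sd = flat.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(flat)
    r[sd == 0, :] = np.nan
    r[:, sd == 0] = np.nan
    return r


def residual_vectors(trial_amplitudes: np.ndarray) -> np.ndarray:
    """Mean-subtracted residuals concatenated over stimuli and trials."""
    a = np.asarray(trial_amplitudes, dtype=float)
    resid = a - a.mean(axis=2, keepdims=True)
    return resid.reshape(a.shape[0], -1)


@dataclass(frozen=True)
class PairSample:
    roi_a: int
    roi_b: int
    category: str
    r: float
    distance: float


def _pair_distance(coords: np.ndarray, i: int, j: int) -> float:
    return float(np.linalg.norm(coords[i] - coords[j]))


def matched_control_pairs(
    target_pairs: list[tuple[int, int]],
    coords: np.ndarray,
    mode: str = "distance",
    stats: np.ndarray | None = None,
    n_distance_controls: int = 3,
    n_stat_neighbors: int = 2,
    tolerance: float = 0.10,
    max_widenings: int = 2,
    seed: int = 0,
    strict: bool = False,
) -> list[tuple[int, int]]:
    """Control pairs matched on distance or on a per-ROI statistic.

    ``distance`` mode draws, per target pair, ``n_distance_controls`` random
    same-field pairs whose separation is within ``tolerance`` (fractional)
    of the target's; the tolerance doubles up to ``max_widenings`` times if
    too few candidates exist (or raises when ``strict``).  ``sd``/``snr``
    mode takes, per target ROI, the ``n_stat_neighbors`` ROIs closest in
    ``stats`` (baseline-ΔF/F SD or peak-amplitude SNR) and returns all
    cross combinations (2 x 2 = 4 per target pair by default).
    """
    rng = np.random.default_rng(seed)
    n = coords.shape[0]
    controls: list[tuple[int, int]] = []
    if mode == "distance":
        all_pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
        all_d = np.array([_pair_distance(coords, i, j) for i, j in all_pairs])
        for a, b in target_pairs:
            d0 = _pair_distance(coords, a, b)
            tol = tolerance
            for attempt in range(max_widenings + 1):
                cand = [
                    k
                    for k in range(len(all_pairs))
                    if abs(all_d[k] - d0) <= tol * d0 and all_pairs[k] != (min(a, b), max(a, b))
                ]
                if len(cand) >= n_distance_controls:
                    break
                if attempt == max_widenings:
                    if strict:
                        raise ValueError(
                            f"not enough distance-matched candidates for pair ({a}, {b})"
                        )
                    break
                tol *= 2.0
            if len(cand) == 0:
                continue
            pick = rng.choice(len(cand), size=min(n_distance_controls, len(cand)), replace=False)
            controls.extend(all_pairs[cand[k]] for k in pick)
    elif mode in ("sd", "snr"):
        if stats is None:
            raise ValueError(f"{mode} mode requires per-ROI stats")
        stats = np.asarray(stats, dtype=float)
        for a, b in target_pairs:
            nbrs = {}
            for roi in (a, b):
                order = np.argsort(np.abs(stats - stats[roi]))
                order = order[(order != a) & (order != b)]
                nbrs[roi] = order[:n_stat_neighbors]
            for i in nbrs[a]:
                for j in nbrs[b]:
                    if i != j:
                        controls.append((min(i, j), max(i, j)))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return controls


def pair_samples(
    pairs: list[tuple[int, int]],
    r_matrix: np.ndarray,
    coords: np.ndarray,
    category: str,
) -> list[PairSample]:
    """Attach r and distance to each pair, dropping NaN-sentinel correlations."""
    out = []
    for a, b in pairs:
        r = r_matrix[a, b]
        if not np.isfinite(r):
            continue
        out.append(PairSample(a, b, category, float(r), _pair_distance(coords, a, b)))
    return out


def spatial_distance_stats(
    coords: np.ndarray, labels: dict[str, list[tuple[int, int]]]
) -> tuple[dict[str, np.ndarray], dict[str, dict]]:
    """Per-category pairwise-distance samples plus rank-sum comparisons.

    ``labels`` maps category name to a list of ROI index pairs; categories
    with fewer than one pair get a None sentinel.  Returns the distance
    samples and, for every category pair, a two-sided Mann-Whitney test.
    """
    samples: dict[str, np.ndarray] = {}
    for cat, pairs in labels.items():
        if len(pairs) < 1:
            samples[cat] = None
            continue
        samples[cat] = np.array([_pair_distance(coords, a, b) for a, b in pairs])
    tests: dict[str, dict] = {}
    cats = [c for c, v in samples.items() if v is not None and v.size >= 2]
    for i, c1 in enumerate(cats):
        for c2 in cats[i + 1 :]:
            u, p = mannwhitneyu(samples[c1], samples[c2], alternative="two-sided")
            tests[f"{c1}_vs_{c2}"] = {"u": float(u), "p": float(p)}
    return samples, tests


def all_pairs_within(labels: np.ndarray, value) -> list[tuple[int, int]]:
    """All index pairs whose label equals ``value``."""
    idx = np.flatnonzero(np.asarray(labels) == value)
    return [(int(idx[i]), int(idx[j])) for i in range(idx.size) for j in range(i + 1, idx.size)]


def pairs_across(labels: np.ndarray, values: list) -> list[tuple[int, int]]:
    """All index pairs whose two labels are distinct members of ``values``."""
    labels = np.asarray(labels)
    idx = np.flatnonzero(np.isin(labels, values))
    return [
        (int(i), int(j))
        for k, i in enumerate(idx)
        for j in idx[k + 1 :]
        if labels[i] != labels[j]
    ]
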