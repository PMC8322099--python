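"""Population-level geometry and clustering of Δonset response profiles.

Response profiles of all responsive ROI-sound pairs are normalized per pair
to their maximum across Δonset conditions (non-significant entries zeroed
first, as de-noising), stacked into a conditions x pairs matrix, and
analyzed three ways: PCA of the condition ensemble patterns, pairwise
Euclidean distance (normalized by sqrt(n_pairs), making it comparable
across population sizes) and Pearson correlation between condition rows,
and non-negative matrix factorization into k = 3 response templates
(negative-shift-, positive-shift-, and coincidence-preferring).  Each pair
is assigned to the template with the dominating NMF coefficient; pairs
whose dominant coefficient carries less than half the total coefficient
mass are labeled "others".

A permutation test quantifies whether coincidence-preferring memberships
overlap across fundamental frequencies more than chance: set labels are
re-drawn uniformly over the responsive-cell universe preserving set sizes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist
from scipy.stats import chi2_contingency
from sklearn.decomposition import NMF, PCA

CLUSTER_NAMES = ("negative_shift", "positive_shift", "coincidence")


@dataclass
class PopulationMatrix:
    """conditions x pairs matrix of max-normalized response amplitudes.

    ``conditions`` labels rows (Δonset values or condition names);
    ``pair_labels`` carries one row of metadata per column (roi, F0, area,
    mouse — whatever the caller tracked).
    """

    matrix: np.ndarray
    conditions: np.ndarray
    pair_labels: pd.DataFrame

    @property
    def n_pairs(self) -> int:
        return self.matrix.shape[1]


def build_population_matrix(
    responses: pd.DataFrame,
    conditions: np.ndarray,
    condition_col: str = "delta_onset",
    amplitude_col: str = "amplitude",
    significant_col: str = "significant",
    group_cols: tuple = ("roi",),
) -> PopulationMatrix:
    """Assemble the normalized conditions x pairs matrix from a response table.

    One column per group (e.g. ROI-F0 pair) that has a significant
    excitatory response in at least one condition.  Non-significant
    amplitudes are zeroed, negatives clipped, and each column divided by its
    maximum.  Groups whose normalizer is zero are excluded.
    """
    conditions = np.asarray(conditions)
    cols, labels = [], []
    for key, grp in responses.groupby(list(group_cols), sort=True):
        if not grp[significant_col].any():
            continue
        grp = grp.set_index(condition_col)
        try:
            amps = grp.loc[conditions, amplitude_col].to_numpy(dtype=float)
            sig = grp.loc[conditions, significant_col].to_numpy(dtype=bool)
        except KeyError as e:
            raise ValueError(f"group {key} is missing condition {e}") from e
        amps = np.clip(amps, 0.0, None)
        amps[~sig] = 0.0
        if amps.max() <= 0:
            continue
        cols.append(amps / amps.max())
        labels.append(key if isinstance(key, tuple) else (key,))
    if not cols:
        raise ValueError("no responsive groups to include")
    return PopulationMatrix(
        matrix=np.column_stack(cols),
        conditions=conditions,
        pair_labels=pd.DataFrame(labels, columns=list(group_cols)),
    )


def pca_project(pm: PopulationMatrix, n_components: int = 3) -> tuple[np.ndarray, np.ndarray]:
    """PCA of condition ensemble patterns (conditions = observations).

    Returns (scores, explained_variance_ratio).  Rank-deficient matrices
    yield fewer components than requested.
    """
    n_cond = pm.matrix.shape[0]
    if n_cond < n_components:
        raise ValueError("need at least n_components conditions")
    k = min(n_components, n_cond, pm.n_pairs)
    pca = PCA(n_components=k)
    scores = pca.fit_transform(pm.matrix)
    return scores, pca.explained_variance_ratio_


def pairwise_geometry(
    pm: PopulationMatrix,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Condition-by-condition distance and correlation structure.

    Returns ``(D, R, mean_d, mean_r)``: normalized Euclidean distances
    D[i, j] = ||row_i - row_j|| / sqrt(n_pairs), Pearson correlations across
    pairs, and the per-condition off-diagonal means of each.  Constant rows
    make their correlations NaN (undefined sentinel).
    """
    x = pm.matrix
    if x.shape[0] < 2:
        raise ValueError("need at least 2 conditions")
    d = squareform(pdist(x, metric="euclidean")) / np.sqrt(pm.n_pairs)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x)
    const = x.std(axis=1) == 0
    r[const, :] = np.nan
    r[:, const] = np.nan
    np.fill_diagonal(r, 1.0)
    off = ~np.eye(x.shape[0], dtype=bool)
    mean_d = np.array([d[i, off[i]].mean() for i in range(x.shape[0])])
    mean_r = np.array([np.nanmean(r[i, off[i]]) for i in range(x.shape[0])])
    return d, r, mean_d, mean_r


@dataclass
class ClusterAssignment:
    """NMF cluster labels per ROI-sound pair plus the fitted templates."""

    assignments: pd.DataFrame  # columns: pair metadata + cluster, dominant_fraction
    templates: np.ndarray  # (n_conditions, k)
    template_labels: tuple[str, ...]
    reconstruction_error: float


def _label_templates(templates: np.ndarray, conditions: np.ndarray) -> tuple[str, ...]:
    """Name each template by the Δonset at which it peaks (ties → coincidence)."""
    labels = []
    for k in range(templates.shape[1]):
        col = templates[:, k]
        peak = col.max()
        at_peak = np.asarray(conditions, dtype=float)[np.isclose(col, peak)]
        if np.any(at_peak == 0):
            labels.append("coincidence")
        elif at_peak[np.argmin(np.abs(at_peak))] < 0:
            labels.append("negative_shift")
        else:
            labels.append("positive_shift")
    return tuple(labels)


def assign_from_coefficients(
    h: np.ndarray, labels: tuple[str, ...], dominance: float = 0.5
) -> tuple[np.ndarray, np.ndarray]:
    """Cluster label per pair from NMF coefficients.

    ``h`` is (k, n_pairs).  A pair joins the cluster of its largest
    coefficient unless that coefficient is less than ``dominance`` of the
    coefficient sum, in which case it is labeled ``"others"``.
    Returns (cluster labels, dominant fractions).
    """
    total = h.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total > 0, h.max(axis=0) / total, 0.0)
    dominant = h.argmax(axis=0)
    cluster = np.where(frac >= dominance, np.array(labels, dtype=object)[dominant], "others")
    return cluster, frac


def nmf_cluster_assign(
    pm: PopulationMatrix,
    k: int = 3,
    n_restarts: int = 100,
    seed: int = 0,
    dominance: float = 0.5,
    max_iter: int = 1000,
) -> ClusterAssignment:
    """Cluster pair response profiles by best-of-restarts NMF.

    The conditions x pairs matrix is factorized as W H (W: conditions x k
    templates, H: k x pairs coefficients) with multiplicative updates and
    random non-negative initialization; the restart with the lowest
    reconstruction error wins.  Each pair is assigned to the template of its
    largest coefficient; if that coefficient is less than ``dominance`` of
    the coefficient sum the pair is labeled ``"others"``.
    """
    x = pm.matrix
    if x.min() < 0:
        raise ValueError("population matrix must be nonnegative")
    if x.max() == 0:
        raise ValueError("population matrix is all zero")
    rng = np.random.default_rng(seed)
    best = None
    for restart_seed in rng.integers(0, 2**31 - 1, size=n_restarts):
        model = NMF(
            n_components=k,
            init="random",
            solver="mu",
            max_iter=max_iter,
            random_state=int(restart_seed),
            tol=1e-6,
        )
        w = model.fit_transform(x)
        if best is None or model.reconstruction_err_ < best[0]:
            best = (model.reconstruction_err_, w, model.components_)
    err, w, h = best
    labels = _label_templates(w, pm.conditions)
    cluster, frac = assign_from_coefficients(h, labels, dominance)
    out = pm.pair_labels.copy()
    out["cluster"] = cluster
    out["dominant_fraction"] = frac
    return ClusterAssignment(
        assignments=out,
        templates=w,
        template_labels=labels,
        reconstruction_error=float(err),
    )


def coincidence_fraction(
    assignments: pd.DataFrame,
    group_col: str,
    cluster_col: str = "cluster",
    include_others: bool = True,
) -> tuple[pd.Series, dict]:
    """Fraction of coincidence-preferring pairs per group, with a χ² test.

    The denominator includes "others" by default (all clustered pairs);
    ``include_others=False`` restricts it to pairs inside named clusters.
    For exactly two groups a 2x2 χ² proportion comparison is returned.
    """
    df = assignments
    if not include_others:
        df = df[df[cluster_col] != "others"]
    groups = df.groupby(group_col, sort=True)
    if groups.ngroups == 0:
        raise ValueError("no groups present")
    frac = groups[cluster_col].apply(lambda s: float((s == "coincidence").mean()))
    stats: dict = {}
    if groups.ngroups == 2:
        tab = np.array(
            [
                [(g[cluster_col] == "coincidence").sum(), (g[cluster_col] != "coincidence").sum()]
                for _, g in groups
            ]
        )
        if tab.sum(axis=1).min() > 0 and tab.sum(axis=0).min() > 0:
            chi2, p, dof, _ = chi2_contingency(tab)
            stats = {"chi2": float(chi2), "p": float(p), "dof": int(dof)}
    return frac, stats


def overlap_permutation_test(
    memberships: list[set],
    universe: set,
    n_perm: int = 10_000,
    seed: int = 0,
) -> tuple[int, np.ndarray, float]:
    """Is cross-set membership overlap larger than chance?

    The observed statistic counts universe elements belonging to at least
    two membership sets.  The null redraws each set uniformly at random from
    the universe, preserving its size; the p-value uses the add-one
    correction p = (1 + #{null >= observed}) / (1 + n_perm), so p is always
    in (0, 1].
    """
    if len(memberships) < 2:
        raise ValueError("need at least 2 membership sets")
    uni = np.array(sorted(universe))
    if uni.size == 0:
        raise ValueError("universe must be non-empty")
    for m in memberships:
        if not set(m) <= universe:
            raise ValueError("membership sets must lie within the universe")
    counts = np.zeros(uni.size, dtype=int)
    idx = {v: i for i, v in enumerate(uni)}
    for m in memberships:
        for v in m:
            counts[idx[v]] += 1
    observed = int((counts >= 2).sum())
    sizes = [len(m) for m in memberships]
    rng = np.random.default_rng(seed)
    # vectorized null: per permutation and set, a uniform size-preserving redraw
    c = np.zeros((n_perm, uni.size), dtype=np.int16)
    rows = np.arange(n_perm)[:, None]
    for sz in sizes:
        if sz == 0:
            continue
        keys = rng.random((n_perm, uni.size))
        chosen = np.argpartition(keys, sz - 1, axis=1)[:, :sz]
        c[rows, chosen] += 1
    null = (c >= 2).sum(axis=1)
    p = (1.0 + np.sum(null >= observed)) / (1.0 + n_perm)
    return observed, null, float(p)
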