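"""Ensemble-analysis tests: population-matrix assembly, PCA against an
eigendecomposition oracle, geometry metric properties, NMF planted-partition
recovery, and the overlap permutation test."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from cohear import ensemble, synth

DELTAS = np.array([-45.0, -30.0, -15.0, 0.0, 15.0, 30.0, 45.0])


def _response_table(amplitudes, significant):
    """(n_rois, n_conditions) arrays -> long-format response table."""
    rows = []
    for roi in range(amplitudes.shape[0]):
        for j, d in enumerate(DELTAS):
            rows.append(
                {
                    "roi": roi,
                    "delta_onset": d,
                    "amplitude": amplitudes[roi, j],
                    "significant": bool(significant[roi, j]),
                }
            )
    return pd.DataFrame(rows)


def _synthetic_pm(n_per_kind=20, trial_noise_sd=0.0, seed=0):
    cfg = synth.PopulationConfig(
        f0s=(4000.0,),
        n_per_archetype=(
            ("negative_shift", n_per_kind),
            ("positive_shift", n_per_kind),
            ("coincidence", n_per_kind),
            ("nonresponsive", 0),
        ),
        trial_noise_sd=trial_noise_sd,
        seed=seed,
    )
    amps, truth, stim, w = synth.generate_trial_amplitudes(cfg)
    mean_amp = amps.mean(axis=2)
    rows = []
    for roi in range(mean_amp.shape[0]):
        for s in range(mean_amp.shape[1]):
            rows.append(
                {
                    "roi": roi,
                    "delta_onset": stim.delta_onset[s],
                    "amplitude": mean_amp[roi, s],
                    "significant": w.iloc[s, roi] > 0,
                }
            )
    pm = ensemble.build_population_matrix(pd.DataFrame(rows), DELTAS)
    planted = truth.loc[pm.pair_labels.roi, "archetype"].to_numpy()
    return pm, planted


class TestPopulationMatrix:
    def test_uniform_significant_responses_give_all_ones(self):
        amps = np.full((4, 7), 0.3)
        pm = ensemble.build_population_matrix(
            _response_table(amps, np.ones((4, 7), bool)), DELTAS
        )
        assert np.array_equal(pm.matrix, np.ones((7, 4)))

    def test_single_significant_condition_is_one_hot(self):
        amps = np.full((3, 7), 0.5)
        sig = np.zeros((3, 7), bool)
        for roi in range(3):
            sig[roi, roi + 1] = True
        pm = ensemble.build_population_matrix(_response_table(amps, sig), DELTAS)
        assert np.array_equal(pm.matrix, np.eye(7)[:, 1:4])

    def test_matches_hand_computed_oracle(self):
        rng = np.random.default_rng(7)
        amps = rng.uniform(-0.1, 1.0, (5, 7))
        sig = rng.random((5, 7)) < 0.6
        sig[:, 0] = True  # guarantee inclusion
        pm = ensemble.build_population_matrix(_response_table(amps, sig), DELTAS)
        oracle = []
        for roi in range(5):
            v = np.clip(amps[roi], 0, None)
            v[~sig[roi]] = 0.0
            oracle.append(v / v.max())
        assert np.allclose(pm.matrix, np.column_stack(oracle))

    def test_nonresponsive_rois_excluded(self):
        amps = np.full((2, 7), 0.4)
        sig = np.ones((2, 7), bool)
        sig[1] = False
        pm = ensemble.build_population_matrix(_response_table(amps, sig), DELTAS)
        assert pm.n_pairs == 1


class TestPca:
    def test_identical_rows_give_zero_scores(self):
        pm = ensemble.PopulationMatrix(
            np.ones((7, 10)), DELTAS, pd.DataFrame({"roi": range(10)})
        )
        scores, _ = ensemble.pca_project(pm)
        assert np.allclose(scores, 0.0)

    def test_single_axis_variation_loads_pc1(self):
        base = np.ones((7, 10))
        base += np.outer(np.linspace(-1, 1, 7), np.ones(10))
        pm = ensemble.PopulationMatrix(base, DELTAS, pd.DataFrame({"roi": range(10)}))
        _, evr = ensemble.pca_project(pm)
        assert evr[0] == pytest.approx(1.0)

    def test_scores_match_eigendecomposition_oracle(self):
        rng = np.random.default_rng(8)
        x = rng.uniform(0, 1, (7, 50))
        pm = ensemble.PopulationMatrix(x, DELTAS, pd.DataFrame({"roi": range(50)}))
        scores, _ = ensemble.pca_project(pm, n_components=3)
        xc = x - x.mean(axis=0)
        evals, evecs = np.linalg.eigh(xc.T @ xc)
        order = np.argsort(evals)[::-1][:3]
        oracle = xc @ evecs[:, order]
        for k in range(3):  # sign of each principal axis is arbitrary
            assert np.allclose(scores[:, k], oracle[:, k], atol=1e-9) or np.allclose(
                scores[:, k], -oracle[:, k], atol=1e-9
            )


class TestPairwiseGeometry:
    def test_identical_conditions(self):
        pm = ensemble.PopulationMatrix(
            np.ones((3, 5)), DELTAS[:3], pd.DataFrame({"roi": range(5)})
        )
        d, r, mean_d, _ = ensemble.pairwise_geometry(pm)
        assert np.allclose(d, 0.0) and np.allclose(mean_d, 0.0)

    def test_unit_one_hot_closed_form(self):
        x = np.array([[1.0, 0.0], [0.0, 1.0]])
        pm = ensemble.PopulationMatrix(x, DELTAS[:2], pd.DataFrame({"roi": range(2)}))
        d, _, _, _ = ensemble.pairwise_geometry(pm)
        assert d[0, 1] == pytest.approx(1.0)  # sqrt(2)/sqrt(2)

    def test_metric_axioms(self):
        rng = np.random.default_rng(9)
        x = rng.uniform(0, 1, (7, 20))
        pm = ensemble.PopulationMatrix(x, DELTAS, pd.DataFrame({"roi": range(20)}))
        d, _, _, _ = ensemble.pairwise_geometry(pm)
        assert np.allclose(d, d.T) and np.allclose(np.diag(d), 0.0)
        for i in range(7):
            for j in range(7):
                for k in range(7):
                    assert d[i, j] <= d[i, k] + d[k, j] + 1e-12

    def test_column_duplication_invariance(self):
        rng = np.random.default_rng(10)
        x = rng.uniform(0, 1, (7, 15))
        pm1 = ensemble.PopulationMatrix(x, DELTAS, pd.DataFrame({"roi": range(15)}))
        pm2 = ensemble.PopulationMatrix(
            np.hstack([x, x]), DELTAS, pd.DataFrame({"roi": range(30)})
        )
        d1, _, _, _ = ensemble.pairwise_geometry(pm1)
        d2, _, _, _ = ensemble.pairwise_geometry(pm2)
        assert np.allclose(d1, d2)

    def test_constant_row_correlation_sentinel(self):
        x = np.vstack([np.ones(10), np.random.default_rng(11).uniform(0, 1, (2, 10))])
        pm = ensemble.PopulationMatrix(x, DELTAS[:3], pd.DataFrame({"roi": range(10)}))
        _, r, _, _ = ensemble.pairwise_geometry(pm)
        assert np.isnan(r[0, 1]) and np.isnan(r[2, 0])

    def test_matches_direct_recomputation(self):
        rng = np.random.default_rng(12)
        x = rng.uniform(0, 1, (5, 12))
        pm = ensemble.PopulationMatrix(x, DELTAS[:5], pd.DataFrame({"roi": range(12)}))
        d, r, _, _ = ensemble.pairwise_geometry(pm)
        for i in range(5):
            for j in range(5):
                assert d[i, j] == pytest.approx(
                    np.linalg.norm(x[i] - x[j]) / np.sqrt(12), abs=1e-12
                )
                if i != j:
                    assert r[i, j] == pytest.approx(np.corrcoef(x[i], x[j])[0, 1])


class TestNmfClustering:
    def test_noiseless_planted_partition_recovered_exactly(self):
        pm, planted = _synthetic_pm(n_per_kind=15, trial_noise_sd=0.0, seed=1)
        ca = ensemble.nmf_cluster_assign(pm, n_restarts=5, seed=0)
        assert adjusted_rand_score(planted, ca.assignments.cluster) == 1.0
        # template identities map onto the planted archetypes, not just groups
        assert (ca.assignments.cluster == planted).all()

    def test_dominance_rule_labels_weak_pairs_others(self):
        h = np.array([[0.4, 0.8], [0.35, 0.1], [0.25, 0.1]])
        cluster, frac = ensemble.assign_from_coefficients(
            h, ("negative_shift", "positive_shift", "coincidence")
        )
        assert cluster[0] == "others" and frac[0] == pytest.approx(0.4)
        assert cluster[1] == "negative_shift" and frac[1] == pytest.approx(0.8)

    def test_same_seed_is_deterministic(self):
        pm, _ = _synthetic_pm(n_per_kind=8, trial_noise_sd=0.2, seed=2)
        a = ensemble.nmf_cluster_assign(pm, n_restarts=3, seed=5)
        b = ensemble.nmf_cluster_assign(pm, n_restarts=3, seed=5)
        assert a.assignments.cluster.tolist() == b.assignments.cluster.tolist()
        assert a.reconstruction_error == b.reconstruction_error

    def test_more_restarts_never_worse(self):
        pm, _ = _synthetic_pm(n_per_kind=8, trial_noise_sd=0.3, seed=3)
        e1 = ensemble.nmf_cluster_assign(pm, n_restarts=1, seed=4).reconstruction_error
        e5 = ensemble.nmf_cluster_assign(pm, n_restarts=5, seed=4).reconstruction_error
        assert e5 <= e1 + 1e-12

    def test_all_zero_matrix_rejected(self):
        pm = ensemble.PopulationMatrix(
            np.zeros((7, 4)), DELTAS, pd.DataFrame({"roi": range(4)})
        )
        with pytest.raises(ValueError):
            ensemble.nmf_cluster_assign(pm, n_restarts=1, seed=0)


class TestCoincidenceFraction:
    def test_all_coincidence(self):
        df = pd.DataFrame({"area": ["A2"] * 5, "cluster": ["coincidence"] * 5})
        frac, _ = ensemble.coincidence_fraction(df, "area")
        assert frac["A2"] == 1.0

    def test_planted_fraction_within_binomial_ci(self):
        rng = np.random.default_rng(13)
        n = 400
        clusters = np.where(rng.random(n) < 0.25, "coincidence", "negative_shift")
        df = pd.DataFrame({"area": ["A1"] * n, "cluster": clusters})
        frac, _ = ensemble.coincidence_fraction(df, "area")
        assert abs(frac["A1"] - 0.25) < 3 * np.sqrt(0.25 * 0.75 / n)

    def test_two_group_chi_square(self):
        df = pd.DataFrame(
            {
                "area": ["A1"] * 100 + ["A2"] * 100,
                "cluster": ["coincidence"] * 10 + ["others"] * 90
                + ["coincidence"] * 30 + ["others"] * 70,
            }
        )
        frac, stats = ensemble.coincidence_fraction(df, "area")
        assert frac["A2"] / frac["A1"] == pytest.approx(3.0)
        assert stats["p"] < 0.01


class TestOverlapPermutation:
    def test_disjoint_cover_gives_zero_overlap(self):
        universe = set(range(60))
        sets = [set(range(0, 20)), set(range(20, 40)), set(range(40, 60))]
        obs, null, p = ensemble.overlap_permutation_test(sets, universe, n_perm=500, seed=0)
        assert obs == 0
        assert p > 0.99

    def test_identical_sets_are_maximally_significant(self):
        universe = set(range(500))
        m = set(range(20))
        obs, null, p = ensemble.overlap_permutation_test(
            [m, m, m], universe, n_perm=1000, seed=1
        )
        assert obs == 20
        assert p == pytest.approx(1.0 / 1001.0)

    def test_p_always_positive(self):
        universe = set(range(30))
        sets = [set(range(10)), set(range(5, 15))]
        _, _, p = ensemble.overlap_permutation_test(sets, universe, n_perm=200, seed=2)
        assert 0.0 < p <= 1.0

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            ensemble.overlap_permutation_test([set(), set()], set(), n_perm=10, seed=0)
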