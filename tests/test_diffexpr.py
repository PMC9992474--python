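import numpy as np
import pytest
from scipy import stats

import _brute
from conftest import make_matrix
from keygenes import (
    PhenotypeTable,
    adjust_bh,
    collapse_probes,
    filter_degs,
    fit_moderated_t,
    log2_quantile_normalize,
    simulate_expression_dataset,
)
from keygenes.diffexpr import DEResult


class TestQuantileNormalize:
    def test_two_column_hand_example(self):
        X = make_matrix(np.array([[1.0, 4.0], [2.0, 5.0], [3.0, 6.0]]))
        out = log2_quantile_normalize(X).values
        np.testing.assert_allclose(out[:, 0], [2.5, 3.5, 4.5])
        np.testing.assert_allclose(out[:, 1], [2.5, 3.5, 4.5])

    def test_identical_columns_are_fixed_point(self):
        col = np.array([1.0, 5.0, 2.0, 9.0])
        X = make_matrix(np.column_stack([col, col, col]))
        np.testing.assert_allclose(log2_quantile_normalize(X).values, X.values)

    def test_tie_rule_matches_limma_reference(self):
        # frozen from limma::normalizeQuantiles on this exact matrix
        X = make_matrix(np.array([[1, 3, 2], [1, 4, 8], [2, 5, 4], [5, 6, 9]], dtype=float))
        expected = np.array(
            [
                [2.5, 2.0, 2.0],
                [2.5, 3.0, 5.0],
                [5.0, 5.0, 3.0],
                [20 / 3, 20 / 3, 20 / 3],
            ]
        )
        np.testing.assert_allclose(log2_quantile_normalize(X).values, expected)

    def test_sorted_columns_identical_after_normalization(self, rng):
        X = make_matrix(rng.normal(8, 2, size=(40, 5)))
        out = np.sort(log2_quantile_normalize(X).values, axis=0)
        for j in range(1, out.shape[1]):
            np.testing.assert_allclose(out[:, j], out[:, 0], atol=1e-12)

    def test_log2_rejects_nonpositive(self):
        X = make_matrix(np.array([[1.0, -2.0], [3.0, 4.0]]))
        with pytest.raises(ValueError, match="nonpositive"):
            log2_quantile_normalize(X, already_logged=False)


class TestModeratedT:
    def test_matches_limma_reference_values(self, limma_fixture):
        """Hyperparameters, t and p agree with limma 3.58.1 lmFit+eBayes."""
        X, labels = limma_fixture
        de = fit_moderated_t(X, labels)
        assert de.d0 == pytest.approx(4.985471, abs=1e-5)
        assert de.s02 == pytest.approx(0.4383382, abs=1e-6)
        expected_t = [
            3.4899947587, -3.2983965326, 1.9389252961, 0.1435119440,
            -1.0736667632, 0.1208709649, -2.8477253804, -1.1627231313,
        ]
        expected_p = [
            6.8471388328e-03, 9.2738875813e-03, 8.4507063251e-02, 8.8905277644e-01,
            3.1095784509e-01, 9.0645295877e-01, 1.9190484150e-02, 2.7489075975e-01,
        ]
        np.testing.assert_allclose(de.mod_t, expected_t, rtol=1e-7)
        np.testing.assert_allclose(de.p, expected_p, rtol=1e-7)

    def test_d0_zero_recovers_ordinary_t(self, limma_fixture):
        X, labels = limma_fixture
        de = fit_moderated_t(X, labels, d0_override=0.0)
        t_ref, p_ref = stats.ttest_ind(X.values[:, :3], X.values[:, 3:], axis=1, equal_var=True)
        np.testing.assert_allclose(de.mod_t, t_ref, rtol=1e-10)
        np.testing.assert_allclose(de.p, p_ref, rtol=1e-10)

    def test_d0_infinite_pins_all_variances_to_prior(self, limma_fixture):
        X, labels = limma_fixture
        de = fit_moderated_t(X, labels, d0_override=np.inf)
        # all genes share the prior variance, so t is proportional to log2fc / 1
        se = np.sqrt(de.s02 * (1 / 3 + 1 / 3))
        np.testing.assert_allclose(de.mod_t, de.log2fc / se, rtol=1e-12)

    def test_all_zero_variance_is_degenerate(self):
        X = make_matrix(np.ones((5, 6)))
        labels = PhenotypeTable(X.sample_ids, [1, 1, 1, 0, 0, 0])
        with pytest.raises(ValueError, match="zero"):
            fit_moderated_t(X, labels)

    def test_null_type_one_error_rate(self):
        """Under delta=0 the moderated-t p-values are calibrated at the 5% level."""
        rng = np.random.default_rng(5)
        X = make_matrix(rng.normal(8.0, 1.0, size=(5000, 40)))
        labels = PhenotypeTable(X.sample_ids, [1] * 20 + [0] * 20)
        de = fit_moderated_t(X, labels)
        frac = float(np.mean(de.p < 0.05))
        assert 0.04 <= frac <= 0.06

    def test_requires_two_samples_per_class(self):
        X = make_matrix(np.random.default_rng(0).normal(size=(4, 3)))
        labels = PhenotypeTable(X.sample_ids, [1, 0, 0])
        with pytest.raises(ValueError, match="2 samples"):
            fit_moderated_t(X, labels)


class TestAdjustBH:
    def test_hand_step_up_example(self):
        np.testing.assert_allclose(adjust_bh([0.01, 0.04, 0.03, 0.02]), [0.04] * 4)

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(adjust_bh([0.37]), [0.37])

    def test_identical_values_unchanged(self):
        np.testing.assert_allclose(adjust_bh([0.5] * 100), [0.5] * 100)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            adjust_bh([0.5, 1.5])

    def test_agrees_with_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(99)
        for _ in range(1000):
            p = rng.random(rng.integers(1, 40))
            np.testing.assert_allclose(adjust_bh(p), _brute.brute_bh(p), atol=1e-12)


class TestCollapseProbes:
    def test_minimum_adjusted_p_wins(self):
        X = make_matrix(np.array([[1.0, 2.0], [3.0, 4.0]]), prefix_g="p")
        out = collapse_probes(X, {"p0": "G", "p1": "G"}, {"p0": 0.2, "p1": 0.01})
        assert out.feature_ids == ["G"]
        np.testing.assert_allclose(out.values[0], [3.0, 4.0])

    def test_one_probe_per_gene_is_relabel(self):
        X = make_matrix(np.arange(4.0).reshape(2, 2), prefix_g="p")
        out = collapse_probes(X, {"p0": "GA", "p1": "GB"}, {"p0": 0.5, "p1": 0.5})
        assert out.feature_ids == ["GA", "GB"]
        np.testing.assert_allclose(out.values, X.values)

    def test_adj_p_tie_broken_by_raw_p(self):
        X = make_matrix(np.array([[1.0], [2.0]]), prefix_g="p")
        out = collapse_probes(
            X, {"p0": "G", "p1": "G"}, {"p0": 0.05, "p1": 0.05}, {"p0": 0.02, "p1": 0.01}
        )
        np.testing.assert_allclose(out.values[0], [2.0])

    def test_full_tie_broken_by_probe_id(self):
        X = make_matrix(np.array([[1.0], [2.0]]), prefix_g="p")
        out = collapse_probes(X, {"p0": "G", "p1": "G"}, {"p0": 0.05, "p1": 0.05})
        np.testing.assert_allclose(out.values[0], [1.0])  # p0 < p1 lexicographically

    def test_unmapped_probes_dropped(self):
        X = make_matrix(np.arange(4.0).reshape(2, 2), prefix_g="p")
        out = collapse_probes(X, {"p0": "G"}, {"p0": 0.5})
        assert out.feature_ids == ["G"]


class TestFilterDegs:
    def _result(self, genes, lfc, adj):
        n = len(genes)
        return DEResult(genes, np.array(lfc), np.zeros(n), np.array(adj), np.array(adj), 1.0, 1.0)

    def test_boundary_lfc_excluded(self):
        de = self._result(["a", "b"], [1.0, 1.01], [0.001, 0.001])
        up, down = filter_degs(de)
        assert up == {"b"} and down == set()

    def test_zero_adjp_cut_empties_both(self):
        de = self._result(["a"], [3.0], [1e-10])
        assert filter_degs(de, adjp_cut=0.0) == (set(), set())

    def test_sign_symmetry(self):
        rng = np.random.default_rng(3)
        lfc = rng.normal(0, 2, 50)
        adj = rng.random(50)
        de = self._result([f"g{i}" for i in range(50)], lfc, adj)
        neg = self._result([f"g{i}" for i in range(50)], -lfc, adj)
        up, down = filter_degs(de)
        up2, down2 = filter_degs(neg)
        assert up == down2 and down == up2

    def test_planted_genes_recovered(self):
        """delta=3 planted genes pass the DEG filter nearly completely."""
        X, labels, probe_map, truth = simulate_expression_dataset(
            200, 30, 30, de_fraction=0.1, delta=3.0, sigma=0.5, dup_probe_rate=0.1, seed=8
        )
        Xn = log2_quantile_normalize(X)
        de_probe = fit_moderated_t(Xn, labels)
        adj = dict(zip(de_probe.feature_ids, de_probe.adj_p))
        raw = dict(zip(de_probe.feature_ids, de_probe.p))
        Xg = collapse_probes(Xn, probe_map, adj, raw)
        de = fit_moderated_t(Xg, labels)
        up, down = filter_degs(de)
        planted = set(truth.de_genes)
        assert len((up | down) & planted) >= 0.95 * len(planted)
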