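import itertools

import numpy as np
import pytest
from scipy import stats

from keygenes import (
    km_estimate,
    logrank_test,
    median_dichotomize,
    simulate_expression_dataset,
    simulate_meta_table,
    simulate_ppi_network,
    simulate_survival,
)
from conftest import make_matrix


class TestExpressionDataset:
    def test_bookkeeping(self):
        X, phen, probe_map, truth = simulate_expression_dataset(
            200, 30, 30, de_fraction=0.1, delta=2.0, sigma=0.5, dup_probe_rate=0.1, seed=1
        )
        assert len(truth.de_genes) == 20
        assert len(X.feature_ids) >= 200
        assert len(X.sample_ids) == 60
        assert set(probe_map.values()) == {f"G{i:05d}" for i in range(200)}
        # alternating shift signs: both directions planted
        shifts = np.array(list(truth.de_genes.values()))
        assert (shifts > 0).any() and (shifts < 0).any()

    def test_null_case_has_no_planted_genes(self):
        *_, truth = simulate_expression_dataset(50, 10, 10, 0.1, delta=0.0, seed=2)
        assert truth.de_genes == {}

    def test_seed_determinism(self):
        a = simulate_expression_dataset(60, 10, 10, 0.1, seed=7)
        b = simulate_expression_dataset(60, 10, 10, 0.1, seed=7)
        np.testing.assert_array_equal(a[0].values, b[0].values)
        assert a[2] == b[2]

    @pytest.mark.parametrize(
        "kwargs", [dict(n_genes=5), dict(n_case=0), dict(de_fraction=1.5), dict(sigma=0.0)]
    )
    def test_invalid_arguments(self, kwargs):
        base = dict(n_genes=50, n_case=10, n_control=10, de_fraction=0.1, delta=1.0, sigma=0.5)
        base.update(kwargs)
        with pytest.raises(ValueError):
            simulate_expression_dataset(**base)


class TestPPINetwork:
    def test_planted_clique_edges_all_present(self):
        genes = [f"G{i}" for i in range(50)]
        net, truth = simulate_ppi_network(genes, 0.02, [genes[:6]], seed=7)
        edge_set = {(a, b) for a, b, _ in net.edges}
        for a, b in itertools.combinations(sorted(genes[:6]), 2):
            assert (a.upper(), b.upper()) in edge_set
        assert truth.clique_genes == [set(g.upper() for g in genes[:6])]

    def test_zero_background_gives_clique_plus_isolates(self):
        genes = [f"G{i}" for i in range(10)]
        net, _ = simulate_ppi_network(genes, 0.0, [genes[:6]], seed=1)
        assert net.number_of_edges() == 15
        assert net.number_of_nodes() == 10

    def test_confidences_survive_070_filter(self):
        genes = [f"G{i}" for i in range(20)]
        net, _ = simulate_ppi_network(genes, 0.3, seed=3)
        assert all(c > 0.70 for *_, c in net.edges)

    def test_seed_determinism(self):
        genes = [f"G{i}" for i in range(30)]
        a, _ = simulate_ppi_network(genes, 0.05, seed=9)
        b, _ = simulate_ppi_network(genes, 0.05, seed=9)
        assert a.edges == b.edges

    def test_small_clique_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            simulate_ppi_network(["A", "B", "C"], 0.1, [["A", "B"]], seed=0)


class TestMetaTable:
    def test_exact_frequency_recovery(self):
        table = simulate_meta_table(["A", "B"], 10, {"A": 4, "B": 2}, seed=5)
        counts = {}
        for _, g in table.records:
            counts[g] = counts.get(g, 0) + 1
        assert counts == {"A": 4, "B": 2}

    def test_all_zero_frequencies_empty(self):
        assert len(simulate_meta_table(["A"], 5, {"A": 0}, seed=1)) == 0

    def test_seed_determinism(self):
        a = simulate_meta_table(["A", "B", "C"], 12, {"A": 3, "B": 7, "C": 1}, seed=4)
        b = simulate_meta_table(["A", "B", "C"], 12, {"A": 3, "B": 7, "C": 1}, seed=4)
        assert a.records == b.records

    def test_frequency_above_study_count_rejected(self):
        with pytest.raises(ValueError):
            simulate_meta_table(["A"], 3, {"A": 4}, seed=0)


class TestSurvival:
    def _expr(self, n, seed=0):
        rng = np.random.default_rng(seed)
        return make_matrix(rng.normal(0, 1, size=(1, n)))

    def test_zero_censoring_gives_all_events(self):
        X = self._expr(50)
        surv = simulate_survival(X, {"g0": 0.5}, censor_rate=0.0, seed=1)
        assert surv.event.sum() == 50

    def test_censor_rate_approximately_achieved(self):
        X = self._expr(4000, seed=2)
        surv = simulate_survival(X, {"g0": 0.3}, censor_rate=0.3, seed=2)
        assert abs(1.0 - surv.event.mean() - 0.3) < 0.05

    def test_seed_determinism(self):
        X = self._expr(30)
        a = simulate_survival(X, {"g0": 1.0}, censor_rate=0.2, seed=11)
        b = simulate_survival(X, {"g0": 1.0}, censor_rate=0.2, seed=11)
        np.testing.assert_array_equal(a.time, b.time)
        np.testing.assert_array_equal(a.event, b.event)

    def test_invalid_baseline(self):
        with pytest.raises(ValueError):
            simulate_survival(self._expr(10), {}, baseline_hazard=0.0, seed=0)

    def test_missing_hazard_gene(self):
        with pytest.raises(ValueError, match="absent"):
            simulate_survival(self._expr(10), {"nope": 1.0}, seed=0)

    def test_null_beta_logrank_p_uniform(self):
        """With beta=0 the median-split log-rank p-value is ~ Uniform(0,1)."""
        pvals = []
        for rep in range(100):
            X = self._expr(60, seed=rep)
            surv = simulate_survival(X, {"g0": 0.0}, censor_rate=0.0, seed=1000 + rep)
            groups = median_dichotomize(X, "g0")
            _, p = logrank_test(surv, groups)
            pvals.append(p)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_km_from_simulated_exponential_decreasing(self):
        X = self._expr(100, seed=3)
        surv = simulate_survival(X, {"g0": 0.0}, censor_rate=0.2, seed=3)
        times, s = km_estimate(surv)
        assert np.all(np.diff(s) <= 1e-12)
        assert s[0] <= 1.0
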