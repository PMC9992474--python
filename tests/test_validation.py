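import numpy as np
import pytest

from conftest import make_matrix
from keygenes import (
    PhenotypeTable,
    SurvivalTable,
    cox_univariate,
    km_estimate,
    logrank_test,
    median_dichotomize,
    per_gene_auc_loocv,
    simulate_survival,
)
from keygenes.validation import delong_ci, mann_whitney_auc

# Reference values for the fixtures below were frozen from R:
# pROC 1.19 (ci.auc method="delong") and survival 3.8 (coxph ties="breslow",
# survdiff, survfit).
DELONG_SCORES_CASE = np.array([0.9, 0.5, 0.85, 0.3, 0.7])
DELONG_SCORES_CTRL = np.array([0.1, 0.4, 0.35, 0.8, 0.2])

COX_TIME = np.array([5, 8, 8, 12, 15, 20, 22, 30, 31, 40], dtype=float)
COX_EVENT = np.array([1, 1, 1, 0, 1, 1, 0, 1, 0, 0])
COX_X = np.array([2.0, 1.5, 1.8, 0.5, 1.2, 0.7, 1.0, 0.3, 0.8, 0.1])


class TestAUC:
    def test_perfect_separation(self):
        assert mann_whitney_auc([3, 4], [1, 2]) == 1.0

    def test_three_quarters_by_pair_enumeration(self):
        assert mann_whitney_auc([2, 4], [1, 3]) == 0.75

    def test_ties_counted_half(self):
        assert mann_whitney_auc([1.0], [1.0]) == 0.5

    def test_delong_matches_pROC_reference(self):
        auc, lo, hi = delong_ci(DELONG_SCORES_CASE, DELONG_SCORES_CTRL)
        assert auc == pytest.approx(0.8, abs=1e-12)
        assert lo == pytest.approx(0.4963636851, abs=1e-9)
        assert hi == pytest.approx(1.0, abs=1e-12)  # clipped at 1

    def test_sign_symmetry_on_tie_free_data(self, rng):
        x = rng.normal(size=30)
        y = np.concatenate([np.ones(15), np.zeros(15)]).astype(int)
        a1 = mann_whitney_auc(x[y == 1], x[y == 0])
        a2 = mann_whitney_auc(-x[y == 1], -x[y == 0])
        assert a1 + a2 == pytest.approx(1.0)


class TestPerGeneAUCLoocv:
    def _fixture(self, row, labels):
        X = make_matrix(np.asarray(row, dtype=float).reshape(1, -1))
        return X, PhenotypeTable(X.sample_ids, labels)

    def test_separable_gene_scores_one(self):
        rng = np.random.default_rng(1)
        row = np.concatenate([rng.normal(10, 0.1, 10), rng.normal(0, 0.1, 10)])
        X, labels = self._fixture(row, [1] * 10 + [0] * 10)
        result = per_gene_auc_loocv(X, labels, "g0")
        assert result.auc == 1.0
        assert result.ci_low <= result.auc <= result.ci_high

    def test_constant_gene_returns_half_with_warning(self):
        X, labels = self._fixture([5.0] * 10, [1] * 5 + [0] * 5)
        with pytest.warns(UserWarning, match="constant"):
            result = per_gene_auc_loocv(X, labels, "g0")
        assert result.auc == 0.5
        assert (result.ci_low, result.ci_high) == (0.5, 0.5)

    def test_loocv_matches_raw_expression_auc_when_separable(self):
        """Held-out logistic scores preserve the raw-expression ordering on
        cleanly separable data, so the AUCs coincide."""
        rng = np.random.default_rng(2)
        row = np.concatenate([rng.normal(4, 1, 15), rng.normal(0, 1, 15)])
        X, labels = self._fixture(row, [1] * 15 + [0] * 15)
        result = per_gene_auc_loocv(X, labels, "g0")
        raw = mann_whitney_auc(row[:15], row[15:])
        assert result.auc == pytest.approx(raw, abs=0.02)

    def test_missing_gene_rejected(self):
        X, labels = self._fixture([1.0, 2.0, 3.0, 4.0], [1, 1, 0, 0])
        with pytest.raises(KeyError):
            per_gene_auc_loocv(X, labels, "nope")


class TestMedianDichotomize:
    def test_even_count_split(self):
        X = make_matrix(np.array([[1.0, 2.0, 3.0, 4.0]]))
        groups = median_dichotomize(X, "g0")
        assert [groups[s] for s in X.sample_ids] == ["low", "low", "high", "high"]

    def test_odd_count_at_median_goes_low(self):
        X = make_matrix(np.array([[1.0, 2.0, 3.0]]))
        groups = median_dichotomize(X, "g0")
        assert [groups[s] for s in X.sample_ids] == ["low", "low", "high"]

    def test_constant_gene_single_group_warns(self):
        X = make_matrix(np.array([[2.0, 2.0, 2.0]]))
        with pytest.warns(UserWarning, match="constant"):
            groups = median_dichotomize(X, "g0")
        assert set(groups.values()) == {"low"}


class TestKaplanMeier:
    def test_hand_product_limit_example(self):
        surv = SurvivalTable(["a", "b", "c"], [1, 2, 3], [1, 0, 1])
        times, s = km_estimate(surv)
        np.testing.assert_array_equal(times, [1, 3])
        np.testing.assert_allclose(s, [2 / 3, 0.0])

    def test_no_events_survival_stays_one(self):
        surv = SurvivalTable(["a", "b"], [5, 9], [0, 0])
        times, s = km_estimate(surv)
        assert len(times) == 0

    def test_all_events_no_censoring_is_empirical_survival(self, rng):
        t = np.sort(rng.exponential(10, size=12))
        surv = SurvivalTable([f"s{i}" for i in range(12)], t, np.ones(12, dtype=int))
        times, s = km_estimate(surv)
        expected = 1.0 - np.arange(1, 13) / 12.0
        np.testing.assert_allclose(s, expected, atol=1e-10)

    def test_non_increasing(self, rng):
        t = rng.exponential(10, size=40)
        e = rng.integers(0, 2, size=40)
        e[0] = 1
        surv = SurvivalTable([f"s{i}" for i in range(40)], t, e)
        _, s = km_estimate(surv)
        assert np.all(np.diff(s) <= 1e-12)


class TestLogRank:
    def test_matches_survdiff_reference(self):
        surv = SurvivalTable([f"s{i}" for i in range(10)], COX_TIME, COX_EVENT)
        groups = {f"s{i}": ("a" if i < 5 else "b") for i in range(10)}
        chi2, p = logrank_test(surv, groups)
        assert chi2 == pytest.approx(7.2781954887, abs=1e-8)
        assert p == pytest.approx(6.9796616147e-03, rel=1e-8)

    def test_identical_groups_null(self):
        surv = SurvivalTable(
            [f"s{i}" for i in range(8)], [1, 2, 3, 4, 1, 2, 3, 4], [1, 1, 0, 1, 1, 1, 0, 1]
        )
        groups = {f"s{i}": ("a" if i < 4 else "b") for i in range(8)}
        chi2, p = logrank_test(surv, groups)
        assert chi2 == pytest.approx(0.0, abs=1e-10)
        assert p == pytest.approx(1.0, abs=1e-10)

    def test_label_swap_invariance(self, rng):
        t = rng.exponential(10, size=30)
        e = np.ones(30, dtype=int)
        surv = SurvivalTable([f"s{i}" for i in range(30)], t, e)
        g1 = {f"s{i}": ("a" if i % 2 else "b") for i in range(30)}
        g2 = {f"s{i}": ("b" if i % 2 else "a") for i in range(30)}
        assert logrank_test(surv, g1) == pytest.approx(logrank_test(surv, g2))

    def test_no_events_warns(self):
        surv = SurvivalTable(["a", "b"], [1, 2], [0, 0])
        with pytest.warns(UserWarning, match="no events"):
            chi2, p = logrank_test(surv, {"a": "x", "b": "y"})
        assert (chi2, p) == (0.0, 1.0)


class TestCoxUnivariate:
    def test_matches_coxph_breslow_reference(self):
        surv = SurvivalTable([f"s{i}" for i in range(10)], COX_TIME, COX_EVENT)
        loghr, se, p = cox_univariate(surv, COX_X)
        assert loghr == pytest.approx(3.2746717869, abs=1e-7)
        assert se == pytest.approx(1.4712843772, abs=1e-7)
        assert p == pytest.approx(2.6032727107e-02, rel=1e-6)

    def test_agrees_with_lifelines_on_tie_free_data(self, rng):
        """Independent route: lifelines CoxPHFitter on tie-free times (where
        Breslow and Efron coincide) gives the same estimate."""
        import pandas as pd
        from lifelines import CoxPHFitter

        x = rng.normal(size=80)
        t = rng.exponential(np.exp(-0.8 * x))
        surv = SurvivalTable([f"s{i}" for i in range(80)], t, np.ones(80, dtype=int))
        loghr, se, _ = cox_univariate(surv, x)
        cph = CoxPHFitter()
        cph.fit(pd.DataFrame({"T": t, "E": 1, "x": x}), "T", "E")
        assert loghr == pytest.approx(float(cph.params_["x"]), abs=1e-5)
        assert se == pytest.approx(float(cph.standard_errors_["x"]), abs=1e-4)

    def test_constant_covariate_rejected(self):
        surv = SurvivalTable(["a", "b", "c"], [1, 2, 3], [1, 1, 1])
        with pytest.raises(ValueError, match="constant"):
            cox_univariate(surv, np.array([2.0, 2.0, 2.0]))

    def test_no_events_rejected(self):
        surv = SurvivalTable(["a", "b"], [1, 2], [0, 0])
        with pytest.raises(ValueError, match="event"):
            cox_univariate(surv, np.array([1.0, 2.0]))

    def test_null_covariate_estimates_near_zero(self):
        """beta=0 truth: estimates concentrate near zero over replicates."""
        hits = 0
        for rep in range(50):
            rng = np.random.default_rng(300 + rep)
            x = rng.normal(size=300)
            X = make_matrix(x.reshape(1, -1))
            surv = simulate_survival(X, {"g0": 0.0}, censor_rate=0.1, seed=600 + rep)
            loghr, _, _ = cox_univariate(surv, x)
            hits += abs(loghr) < 0.2
        assert hits >= 48
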