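import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from asoanfis.evaluation import (
    benchmark_suite,
    confusion_metrics,
    paired_significance,
    regression_metrics,
    split_holdout,
)


class TestSplitHoldout:
    def test_paper_proportions_158(self):
        split = split_holdout(158, 0.7, seed=0)
        assert len(split.train_idx) == 110
        assert len(split.val_idx) == 48

    def test_disjoint_and_covering(self):
        split = split_holdout(57, 0.7, seed=1)
        merged = np.sort(np.concatenate([split.train_idx, split.val_idx]))
        np.testing.assert_array_equal(merged, np.arange(57))

    def test_same_seed_same_split(self):
        s1 = split_holdout(100, 0.7, seed=7)
        s2 = split_holdout(100, 0.7, seed=7)
        np.testing.assert_array_equal(s1.train_idx, s2.train_idx)

    @pytest.mark.parametrize("frac", [0.0, 1.0, 1.3])
    def test_degenerate_fraction_raises(self, frac):
        with pytest.raises(ValueError):
            split_holdout(10, frac, seed=0)


class TestRegressionMetrics:
    def test_perfect_prediction(self, rng):
        y = rng.random(20)
        m = regression_metrics(y, y)
        assert m == {"rmse": 0.0, "mae": 0.0, "r2": 1.0}

    def test_mean_predictor_r2_zero(self, rng):
        y = rng.random(50)
        m = regression_metrics(np.full(50, y.mean()), y)
        assert m["r2"] == pytest.approx(0.0, abs=1e-12)

    def test_hand_computation(self):
        m = regression_metrics(np.array([1.0, 2.0, 5.0]), np.array([1.0, 2.0, 3.0]))
        assert m["rmse"] == pytest.approx(np.sqrt(4 / 3))
        assert m["mae"] == pytest.approx(2 / 3)
        assert m["r2"] == pytest.approx(-1.0)

    def test_zero_variance_obs_flagged(self):
        with pytest.warns(UserWarning, match="zero variance"):
            m = regression_metrics(np.array([1.0, 2.0]), np.array([3.0, 3.0]))
        assert np.isnan(m["r2"])

    @given(st.integers(0, 2**32 - 1))
    @settings(deadline=None, max_examples=50)
    def test_mae_never_exceeds_rmse(self, seed):
        r = np.random.default_rng(seed)
        pred, obs = r.standard_normal(20), r.standard_normal(20)
        m = regression_metrics(pred, obs)
        assert m["mae"] <= m["rmse"] + 1e-12


def wilcoxon_enumeration(a, b):
    """Oracle: exact two-sided signed-rank p by enumerating all sign patterns."""
    d = np.asarray(a, float) - np.asarray(b, float)
    d = d[d != 0]
    n = d.size
    ranks = np.argsort(np.argsort(np.abs(d))) + 1.0
    # midranks for ties
    absd = np.abs(d)
    for v in np.unique(absd):
        sel = absd == v
        ranks[sel] = ranks[sel].mean()
    w_plus = ranks[d > 0].sum()
    stat = min(w_plus, ranks[d < 0].sum())
    count = 0
    total = 0
    for signs in itertools.product([0, 1], repeat=n):
        wp = sum(r for s, r in zip(signs, ranks) if s)
        wm = ranks.sum() - wp
        total += 1
        if min(wp, wm) <= stat + 1e-12:
            count += 1
    return stat, count / total


class TestPairedSignificance:
    def test_identical_errors_degenerate(self):
        with pytest.warns(UserWarning, match="zero"):
            V, p = paired_significance(np.ones(6), np.ones(6))
        assert p == 1.0

    def test_one_sided_differences_exact_p(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        b = a + np.array([0.5, 0.6, 0.7, 0.8, 0.9, 1.0])
        V, p = paired_significance(a, b)
        assert p == pytest.approx(2 / 64)

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(5):
            a = rng.standard_normal(10)
            b = a + rng.standard_normal(10) * 0.5
            V, p = paired_significance(a, b)
            V_or, p_or = wilcoxon_enumeration(a, b)
            assert p == pytest.approx(p_or, abs=1e-10)

    def test_enumeration_matches_up_to_n12(self, rng):
        a = rng.standard_normal(12)
        b = a + rng.standard_normal(12)
        _, p = paired_significance(a, b)
        _, p_or = wilcoxon_enumeration(a, b)
        assert p == pytest.approx(p_or, abs=1e-10)

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            paired_significance(np.ones(3), np.zeros(3))


class TestConfusionMetrics:
    def test_perfect_prediction(self):
        y = np.repeat(np.arange(1, 7), 10)
        rep = confusion_metrics(y, y)
        assert rep.overall_accuracy == 1.0
        assert rep.kappa == pytest.approx(1.0)
        assert all(v == 1.0 for v in rep.producers_accuracy.values())

    def test_two_class_hand_computation(self):
        truth = np.array([0] * 50 + [1] * 50)
        pred = np.concatenate([np.repeat(0, 40), np.repeat(1, 10), np.repeat(0, 5), np.repeat(1, 45)])
        rep = confusion_metrics(truth, pred)
        np.testing.assert_array_equal(rep.matrix, [[40, 10], [5, 45]])
        assert rep.overall_accuracy == pytest.approx(0.85)
        # pe = (50*45 + 50*55) / 100^2 = 0.5 -> kappa = 0.35 / 0.5 = 0.7
        assert rep.kappa == pytest.approx(0.7)
        assert rep.producers_accuracy[0] == pytest.approx(0.8)
        assert rep.users_accuracy[0] == pytest.approx(40 / 45)

    def test_matches_sklearn(self, rng):
        truth = rng.integers(0, 4, 300)
        pred = rng.integers(0, 4, 300)
        rep = confusion_metrics(truth, pred)
        from sklearn.metrics import cohen_kappa_score, confusion_matrix

        np.testing.assert_array_equal(rep.matrix, confusion_matrix(truth, pred))
        assert rep.kappa == pytest.approx(cohen_kappa_score(truth, pred))

    def test_random_predictions_kappa_near_zero(self, rng):
        truth = np.repeat(np.arange(6), 200)
        pred = rng.integers(0, 6, truth.size)
        rep = confusion_metrics(truth, pred)
        assert abs(rep.kappa) < 0.1

    def test_unseen_label_raises(self):
        with pytest.raises(ValueError, match="registry"):
            confusion_metrics([1, 2], [1, 9], labels=[1, 2])


@pytest.fixture(scope="module")
def easy_report():
    rng = np.random.default_rng(0)
    X = rng.random((600, 8))
    y = 5 * X[:, 0] + 5 * X[:, 1] + 5 * X[:, 2] + 0.01 * rng.standard_normal(600)
    table = pd.DataFrame(X, columns=list("abcdefgh"))
    table["agb"] = y
    kwargs = dict(
        seed=0,
        n_trees=60,
        svr_grid={"svr__C": [10, 100], "svr__gamma": [0.1, 1]},
        asoanfis_kwargs=dict(n_rules=2, n_atoms=8, n_iterations=15, polish="light"),
    )
    return table, kwargs, benchmark_suite(table, {"all": list("abcdefgh")}, **kwargs)


class TestBenchmarkSuite:
    def test_every_model_explains_easy_linear_data(self, easy_report):
        _, _, report = easy_report
        assert set(report.metrics.index.get_level_values("model")) == {
            "ASO-ANFIS",
            "SVR",
            "MLP",
            "RF",
            "RS",
        }
        r2 = report.metrics["r2"].droplevel("feature_set")
        # random-subspace trees carry an irreducible feature-exclusion bias,
        # so the ensemble plateaus below the other models on smooth truths
        assert (r2.drop("RS") > 0.9).all()
        assert r2["RS"] > 0.75

    def test_identical_seeds_identical_reports(self, easy_report):
        table, kwargs, report = easy_report
        again = benchmark_suite(table, {"all": list("abcdefgh")}, **kwargs)
        pd.testing.assert_frame_equal(report.metrics, again.metrics)
        pd.testing.assert_frame_equal(report.significance, again.significance)

    def test_significance_entries_for_each_benchmark(self, easy_report):
        _, _, report = easy_report
        assert set(report.significance.index.get_level_values("model")) == {
            "SVR",
            "MLP",
            "RF",
            "RS",
        }
        assert (report.significance["p_value"] <= 1.0).all()

    def test_constant_feature_degenerates_gracefully(self):
        rng = np.random.default_rng(1)
        table = pd.DataFrame({"flat": np.ones(60), "agb": rng.random(60)})
        report = benchmark_suite(
            table,
            {"flat": ["flat"]},
            seed=1,
            n_trees=20,
            svr_grid={"svr__C": [1], "svr__gamma": [0.1]},
            asoanfis_kwargs=dict(n_rules=1, n_atoms=4, n_iterations=5, polish="none"),
        )
        assert (report.metrics["r2"] < 0.5).all()
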