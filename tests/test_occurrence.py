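"""Balanced occurrence forest, AUC, and the GLM comparator."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import plumbsdm as p
from plumbsdm.occurrence_model import _sens_spec


def pair_counting_auc(scores, labels):
    """Exhaustive oracle: fraction of positive-negative pairs correctly
    ordered, ties counted one half."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    pos = scores[labels]
    neg = scores[~labels]
    total = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                total += 1.0
            elif sp == sn:
                total += 0.5
    return total / (len(pos) * len(neg))


class TestAuc:
    def test_worked_example(self):
        assert p.auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == pytest.approx(0.75)
        assert pair_counting_auc([0.1, 0.4, 0.35, 0.8],
                                 [0, 0, 1, 1]) == pytest.approx(0.75)

    def test_perfect_and_all_ties(self):
        assert p.auc([1, 2, 3, 4], [0, 0, 1, 1]) == 1.0
        assert p.auc([0.5] * 6, [0, 1, 0, 1, 0, 1]) == 0.5

    def test_matches_pair_counting_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = rng.integers(4, 31)
            scores = np.round(rng.random(n), 2)  # rounding forces ties
            labels = rng.integers(0, 2, n).astype(bool)
            if labels.all() or not labels.any():
                continue
            assert p.auc(scores, labels) == pytest.approx(
                pair_counting_auc(scores, labels), abs=1e-12
            )

    def test_one_class_absent(self):
        with pytest.raises(p.UndefinedMetricError):
            p.auc([0.1, 0.9], [1, 1])

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        n = 25
        scores = rng.random(n)
        labels = np.r_[np.ones(5, bool), rng.integers(0, 2, n - 5).astype(bool)]
        base = p.auc(scores, labels)
        for f in (lambda s: 3 * s + 1, np.exp, lambda s: s**3):
            assert p.auc(f(scores), labels) == pytest.approx(base, abs=1e-12)


class TestBalance:
    def _records(self, n_pres, n_abs, seed=0):
        rng = np.random.default_rng(seed)
        n = n_pres + n_abs
        df = pd.DataFrame({
            "trap_id": [f"T{i}" for i in range(n)],
            "count": np.r_[rng.integers(1, 9, n_pres), np.zeros(n_abs, int)],
            "cov": rng.normal(size=n),
        })
        df["presence"] = df["count"] >= 1
        return df

    def test_97_of_669_absences(self):
        """97 presences against 669 absences -> 97 + 97 records."""
        bal = p.balance(self._records(97, 669), seed=0)
        assert bal.n_per_class == 97
        assert bal.records["presence"].sum() == 97
        assert (~bal.records["presence"]).sum() == 97

    def test_already_balanced_is_identity(self):
        df = self._records(50, 50)
        bal = p.balance(df, seed=1)
        assert len(bal.records) == 100
        assert set(bal.records["trap_id"]) == set(df["trap_id"])

    def test_deterministic_and_equal_counts(self):
        df = self._records(30, 200)
        a = p.balance(df, seed=7).records
        b = p.balance(df, seed=7).records
        pd.testing.assert_frame_equal(a, b)
        assert a["presence"].sum() == (~a["presence"]).sum()

    def test_excludes_incomplete_and_requires_both_classes(self):
        df = self._records(10, 10)
        df["complete"] = [True] * 15 + [False] * 5
        assert p.balance(df, seed=0).records["complete"].all()
        df2 = self._records(5, 5)
        df2.loc[df2["presence"], "complete"] = False
        df2.loc[~df2["presence"], "complete"] = True
        with pytest.raises(ValueError):
            p.balance(df2, seed=0)


def _tabular_records(n, seed, signal=3.0, noise=1.0):
    """Tabular benchmark: presence driven by a noisy linear signal."""
    rng = np.random.default_rng(seed)
    x1 = rng.normal(size=n)
    x2 = rng.normal(size=n)
    logit = signal * x1 + noise * rng.normal(size=n)
    pres = logit > 0
    return pd.DataFrame({
        "trap_id": [f"T{i}" for i in range(n)],
        "count": pres.astype(int), "presence": pres, "x1": x1, "x2": x2,
    })


class TestFitOccurrence:
    def test_strong_signal_high_oob_auc(self):
        bal = p.balance(_tabular_records(200, seed=1, noise=0.1), seed=1)
        fit = p.fit_occurrence(bal, covariates=["x1", "x2"],
                               config=p.ForestConfig(n_trees=200, seed=1))
        assert fit.oob["auc"] > 0.95
        assert fit.importance.iloc[0]["covariate"] == "x1"

    def test_permuted_labels_null_auc(self):
        df = _tabular_records(200, seed=2, noise=0.1)
        rng = np.random.default_rng(2)
        df["presence"] = rng.permutation(df["presence"].to_numpy())
        df["count"] = df["presence"].astype(int)
        bal = p.balance(df, seed=2)
        fit = p.fit_occurrence(bal, covariates=["x1", "x2"],
                               config=p.ForestConfig(n_trees=200, seed=2))
        assert 0.4 <= fit.oob["auc"] <= 0.6

    def test_metrics_in_range_and_importance_complete(self):
        bal = p.balance(_tabular_records(120, seed=3), seed=3)
        fit = p.fit_occurrence(bal, covariates=["x1", "x2"],
                               config=p.ForestConfig(n_trees=100, seed=3))
        for k in ("sensitivity", "specificity", "auc"):
            assert 0.0 <= fit.oob[k] <= 1.0
        assert sorted(fit.importance["covariate"]) == ["x1", "x2"]

    def test_pooled_oob_mode(self):
        bal = p.balance(_tabular_records(120, seed=4), seed=4)
        fit = p.fit_occurrence(
            bal, covariates=["x1", "x2"],
            config=p.ForestConfig(n_trees=100, seed=4,
                                  oob_aggregation="pooled"))
        assert 0.0 <= fit.oob["sensitivity"] <= 1.0

    def test_all_missing_covariate_rejected(self):
        df = _tabular_records(50, seed=5)
        df["x2"] = np.nan
        bal = p.balance(df, seed=5)
        with pytest.raises(ValueError, match="all-missing"):
            p.fit_occurrence(bal, covariates=["x1", "x2"])


@pytest.fixture(scope="module")
def fit():
    bal = p.balance(_tabular_records(150, seed=6, noise=0.1), seed=6)
    return p.fit_occurrence(bal, covariates=["x1", "x2"],
                            config=p.ForestConfig(n_trees=50, seed=6))


class TestPredictSuitability:

    def test_vote_fraction_definition(self, fit):
        """Suitability equals the exact fraction of trees voting presence."""
        X = np.array([[2.0, 0.0], [-2.0, 0.0], [0.05, 0.3]])
        suit = p.predict_suitability(fit, X)
        votes = np.array([t.predict(X) for t in fit.trees])
        np.testing.assert_allclose(suit, votes.mean(axis=0))

    def test_unanimous_votes_hit_bounds(self):
        """All trees voting presence gives 1.0; all voting absence 0.0."""
        x = np.r_[np.linspace(-3, -1, 30), np.linspace(1, 3, 30)]
        pres = x > 0
        df = pd.DataFrame({"trap_id": range(60), "count": pres.astype(int),
                           "presence": pres, "x1": x})
        bal = p.balance(df, seed=12)
        fit = p.fit_occurrence(bal, covariates=["x1"],
                               config=p.ForestConfig(n_trees=25, seed=12))
        # every tree's split threshold lies inside the (-1, 1) margin
        suit = p.predict_suitability(fit, np.array([[10.0], [-10.0]]))
        assert suit[0] == 1.0
        assert suit[1] == 0.0

    def test_bounds_and_input_forms(self, fit):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(40, 2))
        s_mat = p.predict_suitability(fit, X)
        s_df = p.predict_suitability(
            pd.DataFrame(X, columns=["x1", "x2"]).pipe(lambda d: d), None
        ) if False else p.predict_suitability(
            fit, pd.DataFrame(X, columns=["x1", "x2"]))
        s_dict = p.predict_suitability(
            fit, {"x1": X[:, 0].reshape(8, 5), "x2": X[:, 1].reshape(8, 5)})
        assert ((s_mat >= 0) & (s_mat <= 1)).all()
        np.testing.assert_allclose(s_mat, s_df)
        np.testing.assert_allclose(s_mat, s_dict.ravel())
        assert s_dict.shape == (8, 5)

    def test_missing_covariate_named(self, fit):
        with pytest.raises(KeyError, match="x2"):
            p.predict_suitability(fit, {"x1": np.zeros(3)})


class TestGlmComparator:
    def test_slope_recovery_within_2se(self):
        """Single covariate equal to the true logit: slope ~ 1 at n=500."""
        rng = np.random.default_rng(8)
        x = rng.normal(size=500)
        pres = rng.random(500) < 1 / (1 + np.exp(-x))
        df = pd.DataFrame({"trap_id": range(500), "count": pres.astype(int),
                           "presence": pres, "x1": x})
        bal = p.balance(df, seed=8)
        glm = p.fit_occurrence_glm(bal, covariates=["x1"], seed=8)
        slope, se = glm.params["x1"], glm.bse["x1"]
        assert abs(slope - 1.0) <= 2 * se

    def test_intercept_only_predicts_half(self):
        rng = np.random.default_rng(9)
        pres = np.r_[np.ones(50, bool), np.zeros(50, bool)]
        df = pd.DataFrame({"trap_id": range(100), "count": pres.astype(int),
                           "presence": pres, "x1": rng.normal(size=100)})
        bal = p.balance(df, seed=9)
        glm = p.fit_occurrence_glm(bal, covariates=["x1"], seed=9)
        prob = glm.model.predict()
        assert prob.mean() == pytest.approx(0.5, abs=0.05)

    def test_forest_beats_glm_on_nonlinear_benchmark(self):
        """XOR-style interaction: the forest captures it, the GLM cannot."""
        rng = np.random.default_rng(10)
        n = 300
        x1, x2 = rng.normal(size=n), rng.normal(size=n)
        pres = (x1 > 0) ^ (x2 > 0)
        df = pd.DataFrame({"trap_id": range(n), "count": pres.astype(int),
                           "presence": pres, "x1": x1, "x2": x2})
        bal = p.balance(df, seed=10)
        forest = p.fit_occurrence(bal, covariates=["x1", "x2"],
                                  config=p.ForestConfig(n_trees=200, seed=10))
        glm = p.fit_occurrence_glm(bal, covariates=["x1", "x2"], seed=10)
        assert glm.cv["auc"] <= forest.oob["auc"]
        assert forest.oob["auc"] > 0.8

    def test_separation_flagged(self):
        x = np.r_[np.full(20, -2.0), np.full(20, 2.0)]
        pres = x > 0
        df = pd.DataFrame({"trap_id": range(40), "count": pres.astype(int),
                           "presence": pres, "x1": x})
        bal = p.balance(df, seed=11)
        with pytest.warns(UserWarning, match="separation"):
            glm = p.fit_occurrence_glm(bal, covariates=["x1"], seed=11)
        assert glm.separation_flag


def test_sens_spec_helper():
    pred = np.array([True, True, False, False, True])
    lab = np.array([True, False, True, False, True])
    sens, spec = _sens_spec(pred, lab)
    assert sens == pytest.approx(2 / 3)
    assert spec == pytest.approx(1 / 2)
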