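import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import cohen_kappa_score

from pembropred.errors import DomainError, InputError, UndefinedStatisticError
from pembropred.personalization import (NormalizationBounds,
                                        PersonalizationModel, classify_gamma,
                                        impute, knn_estimate, knn_rule_k,
                                        loo_cross_validate,
                                        max_threshold_kappa, normalize,
                                        pearson_screen, roc_auc,
                                        train_gamma_tree)


def _cov_frame(**columns) -> pd.DataFrame:
    df = pd.DataFrame(columns)
    if "center" not in df:
        df["center"] = "A"
    df.index = [f"p{i}" for i in range(len(df))]
    return df


class TestNormalize:
    @pytest.mark.parametrize("x, lo, hi, expected", [
        (5.0, 5.0, 10.0, 0.0), (10.0, 5.0, 10.0, 1.0), (7.5, 5.0, 10.0, 0.5),
        (12.0, 5.0, 10.0, 1.4),     # queries outside the range are not clipped
    ])
    def test_min_max(self, x, lo, hi, expected):
        assert normalize(x, lo, hi) == pytest.approx(expected)

    def test_degenerate_bounds_rejected(self):
        with pytest.raises(DomainError):
            normalize(1.0, 5.0, 5.0)

    def test_training_values_land_in_unit_interval(self):
        df = _cov_frame(baseline_sod=[10.0, 55.0, 100.0])
        bounds = NormalizationBounds.fit(df, ("baseline_sod",))
        x = bounds.transform(df, ("baseline_sod",))["baseline_sod"]
        assert x.min() == 0.0 and x.max() == 1.0
        # denormalizing restores the training values exactly
        lo, hi = bounds.pooled["baseline_sod"]
        assert np.allclose(x * (hi - lo) + lo, df["baseline_sod"])

    def test_per_center_bounds(self):
        df = _cov_frame(baseline_sod=[10.0, 20.0, 100.0, 200.0],
                        center=["A", "A", "B", "B"])
        bounds = NormalizationBounds.fit(df, ("baseline_sod",))
        assert bounds.bounds_for("baseline_sod", "A") == (10.0, 20.0)
        assert bounds.bounds_for("baseline_sod", "B") == (100.0, 200.0)
        # unseen center falls back to pooled bounds
        assert bounds.bounds_for("baseline_sod", "C") == (10.0, 200.0)


class TestImpute:
    def test_continuous_mean_and_binary_zero(self):
        df = _cov_frame(breslow=[2.0, np.nan, 4.0], nodular=[1.0, np.nan, 0.0])
        out, values = impute(df)
        assert list(out["breslow"]) == [2.0, 3.0, 4.0]
        assert list(out["nodular"]) == [1.0, 0.0, 0.0]
        assert values["breslow"] == 3.0 and values["nodular"] == 0.0

    def test_no_missing_is_identity(self):
        df = _cov_frame(breslow=[1.0, 2.0], age=[60.0, 70.0])
        out, _ = impute(df)
        pd.testing.assert_frame_equal(out, df)

    def test_all_missing_rejected(self):
        with pytest.raises(InputError):
            impute(_cov_frame(breslow=[np.nan, np.nan]))


class TestKnn:
    @pytest.mark.parametrize("n, k", [(54, 7), (100, 10), (1, 1), (3, 1)])
    def test_sqrt_rule(self, n, k):
        assert knn_rule_k(n) == k

    def test_mean_of_k_nearest(self):
        x = np.array([[0.1], [0.2], [0.9]])
        y = np.array([1.0, 2.0, 3.0])
        assert knn_estimate(x, y, [0.15], 2) == pytest.approx(1.5)
        assert knn_estimate(x, y, [0.5], 3) == pytest.approx(2.0)  # k = n
        assert knn_estimate(x, y, [0.88], 1) == pytest.approx(3.0)

    def test_distance_ties_broken_by_training_order(self):
        x = np.array([[0.0], [2.0], [-2.0]])     # last two equidistant from 0
        y = np.array([0.0, 10.0, 20.0])
        assert knn_estimate(x, y, [0.0], 2) == pytest.approx(5.0)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.lists(st.integers(-500, 500).map(lambda v: v / 100.0),
                    min_size=1, max_size=10, unique=True))
    def test_k1_on_training_point_returns_own_y(self, xs):
        x = np.array(xs).reshape(-1, 1)
        y = np.arange(len(xs), dtype=float)
        for i, q in enumerate(xs):
            assert knn_estimate(x, y, [q], 1) == y[i]

    def test_k_bounds_validated(self):
        with pytest.raises(DomainError):
            knn_estimate(np.array([[0.0]]), np.array([1.0]), [0.0], 2)


class TestGammaTree:
    def test_perfectly_separable(self):
        rng = np.random.default_rng(0)
        breslow = np.concatenate([rng.uniform(0.5, 3.9, 10),
                                  rng.uniform(4.1, 20, 10)])
        nodular = rng.integers(0, 2, 20).astype(float)
        labels = np.where(breslow > 4.0, 0.005, 0.003269)
        feats = pd.DataFrame({"breslow": breslow, "nodular": nodular})
        tree = train_gamma_tree(feats, labels)
        assert np.all(classify_gamma(tree, feats) == labels)

    def test_single_class_warns_and_is_constant(self):
        feats = pd.DataFrame({"breslow": [1.0, 2.0, 3.0], "nodular": [0, 1, 0]})
        with pytest.warns(UserWarning):
            tree = train_gamma_tree(feats, np.full(3, 0.005))
        assert np.all(classify_gamma(tree, feats) == 0.005)

    def test_at_least_majority_class_accuracy(self):
        rng = np.random.default_rng(1)
        feats = pd.DataFrame({"breslow": rng.uniform(0.5, 20, 30),
                              "nodular": rng.integers(0, 2, 30).astype(float)})
        labels = np.where(rng.random(30) < 0.3, 0.005, 0.003269)
        tree = train_gamma_tree(feats, labels)
        acc = np.mean(classify_gamma(tree, feats) == labels)
        majority = max(np.mean(labels == 0.005), np.mean(labels == 0.003269))
        # the depth-2 tree can always fall back to the majority leaf, and must
        # do at least as well as the best brute-force single split
        best_split = majority
        for f in ("breslow", "nodular"):
            for thr in np.unique(feats[f]):
                for hi_label in (0.005, 0.003269):
                    lo_label = 0.005 if hi_label == 0.003269 else 0.003269
                    pred = np.where(feats[f] > thr, hi_label, lo_label)
                    best_split = max(best_split, np.mean(pred == labels))
        assert acc >= majority
        assert acc >= best_split - 1e-12


class TestLooCrossValidation:
    def test_identical_patients_predict_common_value(self):
        df = _cov_frame(baseline_sod=[50.0] * 6, breslow=[2.0] * 6,
                        nodular=[0.0] * 6)
        ln_a = pd.Series([3.5] * 6, index=df.index)
        gamma = pd.Series([0.005, 0.003269] * 3, index=df.index)
        loo = loo_cross_validate(df, ln_a, gamma)
        assert np.allclose(loo["ln_a_pem"], 3.5)

    def test_held_out_outlier_label_never_leaks(self):
        df = _cov_frame(baseline_sod=[10.0, 11.0, 12.0, 13.0, 14.0],
                        breslow=[1.0, 1.1, 1.2, 1.3, 1.4],
                        nodular=[0.0] * 5)
        ln_a = pd.Series([3.0, 3.0, 3.0, 3.0, 9.0], index=df.index)
        gamma = pd.Series([0.005, 0.003269, 0.005, 0.003269, 0.005],
                          index=df.index)
        loo = loo_cross_validate(df, ln_a, gamma)
        # the outlier's own extreme label must come only from the others
        assert loo["ln_a_pem"].iloc[-1] == pytest.approx(3.0)

    def test_removing_distant_nonneighbor_changes_nothing(self):
        sod = [1.0, 2.0, 3.0, 4.0, 100.0, 101.0]
        df = _cov_frame(baseline_sod=sod, breslow=[1.0] * 6, nodular=[0.0] * 6)
        y = pd.Series([1.0, 2.0, 3.0, 4.0, 8.0, 9.0], index=df.index)
        gamma = pd.Series([0.005, 0.003269] * 3, index=df.index)
        model_full = PersonalizationModel.fit(df, y, gamma, k=2)
        model_minus = PersonalizationModel.fit(df.drop(index="p5"),
                                               y.drop(index="p5"),
                                               gamma.drop(index="p5"), k=2)
        query = df.loc[["p0"]]
        assert model_full.predict_ln_a_pem(query) == pytest.approx(
            model_minus.predict_ln_a_pem(query))

    def test_too_small_cohort_rejected(self):
        df = _cov_frame(baseline_sod=[1.0, 2.0], breslow=[1.0, 2.0],
                        nodular=[0.0, 1.0])
        with pytest.raises(InputError):
            loo_cross_validate(df, pd.Series([1.0, 2.0], index=df.index),
                               pd.Series([0.005, 0.003269], index=df.index))


class TestScreening:
    @pytest.mark.parametrize("x, y, r", [
        ((1, 2, 3), (2, 4, 6), 1.0),
        ((1, 2, 3), (6, 4, 2), -1.0),
        ((-1, 0, 1), (1, -2, 1), 0.0),
    ])
    def test_pearson(self, x, y, r):
        got, _ = pearson_screen(x, y)
        assert got == pytest.approx(r, abs=1e-12)

    def test_pearson_zero_variance_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            pearson_screen((1, 1, 1), (1, 2, 3))

    def test_roc_auc_perfect_and_inverted(self):
        assert roc_auc((0.1, 0.2, 0.8, 0.9), (0, 0, 1, 1)) == 1.0
        assert roc_auc((0.1, 0.2, 0.8, 0.9), (1, 1, 0, 0)) == 0.0
        assert roc_auc((0.5, 0.5, 0.5, 0.5), (0, 1, 0, 1)) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            roc_auc((0.1, 0.9), (1, 1))
        with pytest.raises(UndefinedStatisticError):
            max_threshold_kappa((0.1, 0.9), (0, 0))

    def test_perfect_separation_max_kappa(self):
        assert max_threshold_kappa((0.1, 0.2, 0.8, 0.9),
                                   (0, 0, 1, 1)) == pytest.approx(1.0)

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            scores = rng.normal(size=10)
            labels = rng.integers(0, 2, 10)
            if labels.min() == labels.max():
                continue
            got = max_threshold_kappa(scores, labels)
            brute = max(
                cohen_kappa_score((scores >= t).astype(int), labels)
                for t in np.concatenate((np.unique(scores),
                                         [scores.min() - 1, scores.max() + 1])))
            assert got == pytest.approx(brute, abs=1e-12)
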