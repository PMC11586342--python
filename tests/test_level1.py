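"""First-level screening: chi-square, Pearson, Lasso, elastic net, union."""

import numpy as np
import pytest

from srpnet import (
    FeatureTable,
    LabelVector,
    MethodScore,
    chi_square_scores,
    enet_select,
    lasso_select,
    pearson_scores,
    union_candidates,
)


def make_table(cols: dict, kinds: dict | None = None, normalized=False) -> FeatureTable:
    names = list(cols)
    return FeatureTable(
        values=np.column_stack([np.asarray(cols[n], dtype=float) for n in names]),
        feature_names=names,
        feature_kinds=[(kinds or {}).get(n, "continuous") for n in names],
        normalized=normalized,
    )


class TestChiSquare:
    def test_hand_computed_2x2(self):
        # observed [[10,20],[20,10]]: all expected counts 15,
        # chi2 = 4 * 25/15 = 6.6667, df 1, p ~ 0.00983
        x = np.repeat([0, 0, 1, 1], [10, 20, 20, 10])
        y = np.repeat([0, 1, 0, 1], [10, 20, 20, 10])
        t = make_table({"f": x}, kinds={"f": "binary"})
        labels = LabelVector(codes=y, category_names=["neg", "pos"])
        score = chi_square_scores(t, labels, alpha=0.05)
        assert score.statistic[0] == pytest.approx(6.6667, abs=1e-4)
        assert score.p_values[0] == pytest.approx(0.00983, abs=1e-5)
        assert score.kept[0]  # p = 0.0098 <= 0.05

    def test_identical_distribution_scores_zero(self):
        x = np.tile([0, 1], 20)
        y = np.repeat([0, 1], 20)
        t = make_table({"f": x}, kinds={"f": "binary"})
        labels = LabelVector(codes=y, category_names=["a", "b"])
        score = chi_square_scores(t, labels)
        assert score.statistic[0] == 0.0
        assert not score.kept[0]

    def test_continuous_column_skipped_with_warning(self):
        rng = np.random.default_rng(0)
        t = make_table({"cont": rng.random(40)})
        labels = LabelVector(codes=rng.integers(0, 2, 40), category_names=["a", "b"])
        with pytest.warns(UserWarning, match="cont"):
            score = chi_square_scores(t, labels)
        assert not score.kept[0]
        assert score.p_values[0] == 1.0

    def test_matches_scipy_without_correction(self):
        from scipy.stats import chi2_contingency

        rng = np.random.default_rng(5)
        x = rng.integers(0, 3, 200)
        y = (x + rng.integers(0, 3, 200)) % 3
        t = make_table({"f": x}, kinds={"f": "ordinal"})
        labels = LabelVector(codes=y, category_names=list("abc"))
        score = chi_square_scores(t, labels)
        obs = np.zeros((3, 3))
        np.add.at(obs, (x, y), 1)
        ref = chi2_contingency(obs, correction=False)
        assert score.statistic[0] == pytest.approx(ref.statistic)
        assert score.p_values[0] == pytest.approx(ref.pvalue)

    def test_type_one_calibration_on_null_features(self):
        """p <= 0.05 keep-rate is ~5% when features are label-independent."""
        rng = np.random.default_rng(2024)
        n, n_features = 2_000, 500
        labels = LabelVector(
            codes=rng.choice(5, size=n, p=[0.71, 0.14, 0.10, 0.03, 0.02]),
            category_names=list("abcde"),
        )
        t = FeatureTable(
            values=rng.integers(0, 2, (n, n_features)).astype(float),
            feature_names=[f"null{j}" for j in range(n_features)],
            feature_kinds=["binary"] * n_features,
        )
        score = chi_square_scores(t, labels, alpha=0.05)
        rate = score.kept.mean()
        assert rate == pytest.approx(0.05, abs=0.02)


class TestPearson:
    def test_perfect_linear_and_inverse(self):
        t = make_table({"up": [1, 2, 3], "down": [6, 4, 2]})
        labels = LabelVector(codes=np.array([0, 1, 2]), category_names=list("abc"))
        score = pearson_scores(t, labels)
        assert score.statistic[0] == pytest.approx(1.0)
        assert score.statistic[1] == pytest.approx(-1.0)
        assert score.kept.all()

    def test_constant_column_dropped_with_warning(self):
        t = make_table({"const": [5, 5, 5], "x": [1, 2, 3]})
        labels = LabelVector(codes=np.array([0, 1, 2]), category_names=list("abc"))
        with pytest.warns(UserWarning, match="const"):
            score = pearson_scores(t, labels)
        assert score.statistic[0] == 0.0
        assert not score.kept[0]

    def test_threshold_applied_to_absolute_value(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 3, 500)
        weak = rng.random(500)  # uncorrelated
        strong = -(y + 0.1 * rng.random(500))  # strongly negative
        t = make_table({"weak": weak, "strong": strong})
        labels = LabelVector(codes=y, category_names=list("abc"))
        score = pearson_scores(t, labels, tau=0.5)
        assert not score.kept[0]
        assert score.kept[1]


@pytest.fixture
def regression_toy():
    """y equals x1 exactly; x2, x3 are noise (n = 100)."""
    rng = np.random.default_rng(42)
    n = 100
    y = rng.integers(0, 2, n)
    x1 = y.astype(float)
    x2, x3 = rng.random(n), rng.random(n)
    table = make_table({"x1": x1, "x2": x2, "x3": x3}, normalized=True)
    labels = LabelVector(codes=y, category_names=["a", "b"])
    return table, labels


class TestLasso:
    def test_dominant_feature_kept_on_toy(self, regression_toy):
        table, labels = regression_toy
        score = lasso_select(table, labels, lam=0.01)
        assert "x1" in score.kept_names

    def test_huge_penalty_empties_the_kept_set(self, regression_toy):
        table, labels = regression_toy
        score = lasso_select(table, labels, lam=1e6)
        assert score.kept_names == []

    def test_zero_penalty_matches_ols(self, regression_toy):
        from sklearn.linear_model import LinearRegression

        table, labels = regression_toy
        score = lasso_select(table, labels, lam=1e-12)
        ols = LinearRegression().fit(table.values, labels.codes.astype(float))
        np.testing.assert_allclose(score.statistic, ols.coef_, atol=1e-4)

    def test_kept_set_size_non_increasing_in_penalty(self, regression_toy):
        table, labels = regression_toy
        sizes = [
            len(lasso_select(table, labels, lam=lam).kept_names)
            for lam in [1e-4, 1e-3, 1e-2, 1e-1, 1.0]
        ]
        assert sizes == sorted(sizes, reverse=True)

    def test_cv_default_selects_dominant_feature(self, regression_toy):
        table, labels = regression_toy
        score = lasso_select(table, labels, seed=0)
        assert "x1" in score.kept_names

    def test_requires_normalized_table(self, regression_toy):
        table, labels = regression_toy
        raw = FeatureTable(
            values=table.values * 10,
            feature_names=table.feature_names,
            feature_kinds=table.feature_kinds,
            normalized=False,
        )
        with pytest.raises(ValueError, match="normalized"):
            lasso_select(raw, labels)


class TestElasticNet:
    def test_mix_one_equals_lasso(self, regression_toy):
        table, labels = regression_toy
        lam = 0.01
        lasso = lasso_select(table, labels, lam=lam)
        enet = enet_select(table, labels, lam=lam, mix=1.0)
        np.testing.assert_allclose(enet.statistic, lasso.statistic, atol=1e-8)

    def test_mix_zero_is_ridge_with_tolerance_rule(self, regression_toy):
        table, labels = regression_toy
        score = enet_select(table, labels, lam=0.01, mix=0.0)
        # ridge keeps everything above tolerance: generically no exact zeros
        assert len(score.kept_names) == 3

    def test_mix_out_of_range_rejected(self, regression_toy):
        table, labels = regression_toy
        with pytest.raises(ValueError, match="mix"):
            enet_select(table, labels, lam=0.1, mix=1.5)


class TestUnion:
    def test_union_of_kept_sets_in_column_order(self, regression_toy):
        table, labels = regression_toy

        def fake(method, kept_names):
            kept = np.array([n in kept_names for n in table.feature_names])
            return MethodScore(
                method=method,
                feature_names=list(table.feature_names),
                statistic=np.zeros(3),
                kept=kept,
            )

        report = union_candidates(
            [fake("chi2", {"x3", "x1"}), fake("pearson", {"x1", "x2"}),
             fake("lasso", set()), fake("enet", set())],
            table,
        )
        assert report.candidate_set == ["x1", "x2", "x3"]

    def test_each_kept_set_within_candidates(self, regression_toy):
        from srpnet import select_level1

        table, labels = regression_toy
        report = select_level1(table, labels, seed=0)
        for score in report.scores.values():
            assert set(score.kept_names) <= set(report.candidate_set)
        assert set(report.candidate_set) <= set(table.feature_names)

    def test_empty_union_errors(self, regression_toy):
        table, _ = regression_toy

        def empty(method):
            return MethodScore(
                method=method,
                feature_names=list(table.feature_names),
                statistic=np.zeros(3),
                kept=np.zeros(3, dtype=bool),
            )

        with pytest.raises(ValueError, match="relax"):
            union_candidates([empty(m) for m in ("chi2", "pearson", "lasso", "enet")], table)
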