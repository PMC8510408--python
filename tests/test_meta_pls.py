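"""Meta-analysis statistics: summaries, one-hot designs, NIPALS PLS, VIP."""

import numpy as np
import pytest

from bilemix import (
    MetaRecord,
    fit_pls,
    gen_meta_table,
    group_summary,
    one_hot_encode,
    vip_scores,
    welch_t_test,
)
from bilemix.errors import DomainError, SchemaError
from bilemix.meta_pls import PlsModel


def records_from(values, group):
    return [MetaRecord(response=v, categories={"grp": group}) for v in values]


class TestGroupSummary:
    def test_intestinal_segment_ratios(self):
        # literature bile-salt composition percentages by gut segment
        recs = (
            records_from([88.00, 75.00], "ileum_conjugated")
            + records_from([11.79, 25.00], "ileum_unconjugated")
            + records_from([0.30, 5.00, 9.00], "duodenum_unconjugated")
        )
        out = group_summary(recs, "grp").set_index("group")
        assert round(out.loc["ileum_conjugated", "mean"]) == 82
        assert round(out.loc["ileum_unconjugated", "mean"]) == 18
        assert round(out.loc["duodenum_unconjugated", "mean"]) == 5

    def test_constant_group_and_counts(self):
        out = group_summary(records_from([4.0, 4.0, 4.0], "a"), "grp")
        assert out.loc[0, "mean"] == 4.0
        assert out.loc[0, "sd"] == 0.0
        assert out.loc[0, "n"] == 3

    def test_singleton_group_sd_undefined(self):
        out = group_summary(records_from([2.5], "solo"), "grp")
        assert np.isnan(out.loc[0, "sd"])

    def test_sample_sd_uses_n_minus_one(self):
        out = group_summary(records_from([1.0, 2.0, 3.0], "a"), "grp")
        assert out.loc[0, "sd"] == pytest.approx(1.0)


LEVELS = {"bs_type": ["PC", "PU", "SC", "SU"]}


class TestOneHot:
    def test_single_level_row(self):
        X, names = one_hot_encode(
            [MetaRecord(response=1.0, categories={"bs_type": "PC"})], LEVELS
        )
        assert names == ["bs_type=PC", "bs_type=PU", "bs_type=SC", "bs_type=SU"]
        assert X.tolist() == [[1.0, 0.0, 0.0, 0.0]]

    def test_mixture_pair_sets_both_indicators(self):
        X, _ = one_hot_encode(
            [MetaRecord(response=1.0, categories={"bs_type": "PU:PC"})], LEVELS
        )
        assert X.tolist() == [[1.0, 1.0, 0.0, 0.0]]

    def test_pair_rows_raise_design_rank(self):
        singles = [
            MetaRecord(response=1.0, categories={"bs_type": lvl})
            for lvl in ("PC", "PU", "SC", "SU")
        ]
        X1, _ = one_hot_encode(singles, LEVELS)
        pairs = singles + [
            MetaRecord(response=1.0, categories={"bs_type": ("PC", "SU")})
        ]
        X2, _ = one_hot_encode(pairs, LEVELS)
        # single-level rows sum to 1 so carry a rank deficiency pairs break
        assert np.linalg.matrix_rank(X2 - X2.mean(0)) > np.linalg.matrix_rank(
            X1 - X1.mean(0)
        )

    def test_numeric_columns_appended_unchanged(self):
        rec = MetaRecord(
            response=1.0, categories={"bs_type": "SC"}, numerics={"temperature": 310.15}
        )
        X, names = one_hot_encode([rec], LEVELS, ["temperature"])
        assert names[-1] == "temperature"
        assert X[0, -1] == 310.15

    def test_unseen_level_names_offender(self):
        recs = [MetaRecord(response=1.0, categories={"bs_type": "ZZ"})]
        with pytest.raises(SchemaError, match="'ZZ'"):
            one_hot_encode(recs, LEVELS)

    def test_empty_records_rejected(self):
        with pytest.raises(SchemaError):
            one_hot_encode([], LEVELS)


def random_design(n=40, p=5, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    y = X @ rng.normal(size=p) + 0.1 * rng.normal(size=n)
    return X, y


class TestFitPls:
    def test_planted_single_column_signal(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(60, 6))
        j = 3
        y = (X[:, j] - X[:, j].mean()) / X[:, j].std(ddof=1)
        model = fit_pls(X, y, n_components=1)
        assert np.argmax(np.abs(model.coefficients)) == j
        assert np.argmax(vip_scores(model).vip) == j

    def test_full_component_fit_matches_ols(self):
        X, y = random_design()
        model = fit_pls(X, y, n_components=X.shape[1])
        Xs = (X - X.mean(0)) / X.std(0, ddof=1)
        ys = (y - y.mean()) / y.std(ddof=1)
        ols = np.linalg.lstsq(Xs, ys, rcond=None)[0]
        assert np.allclose(model.coefficients, ols, atol=1e-8)

    def test_predictions_match_sklearn(self):
        sklearn_pls = pytest.importorskip("sklearn.cross_decomposition")
        X, y = random_design(seed=7)
        model = fit_pls(X, y, n_components=2)
        ref = sklearn_pls.PLSRegression(n_components=2, scale=True).fit(X, y)
        assert np.allclose(
            model.predict(X), ref.predict(X).ravel(), atol=1e-8
        )

    def test_scores_mutually_orthogonal(self):
        X, y = random_design(seed=3)
        T = fit_pls(X, y, n_components=4).scores
        gram = T.T @ T
        off = gram - np.diag(np.diag(gram))
        assert np.max(np.abs(off)) < 1e-8

    def test_prediction_invariant_to_column_rescaling(self):
        X, y = random_design(seed=5)
        scales = np.array([2.0, 0.1, 30.0, 1.0, 5.0])
        shifts = np.array([-3.0, 0.0, 100.0, 2.0, 0.0])
        m1 = fit_pls(X, y, n_components=2)
        m2 = fit_pls(X * scales + shifts, y, n_components=2)
        assert np.allclose(m1.predict(X), m2.predict(X * scales + shifts), atol=1e-8)

    def test_constant_response_rejected(self):
        X, _ = random_design()
        with pytest.raises(SchemaError):
            fit_pls(X, np.ones(X.shape[0]), n_components=1)

    def test_zero_variance_column_rejected(self):
        X, y = random_design()
        X[:, 2] = 4.2
        with pytest.raises(SchemaError, match="zero-variance"):
            fit_pls(X, y, n_components=1)

    def test_rank_exhaustion_warns_and_reduces(self):
        rng = np.random.default_rng(2)
        base = rng.normal(size=(30, 2))
        X = np.column_stack([base, base @ [[1.0, 2.0], [0.5, -1.0]]])
        y = base @ [1.0, -1.0] + 0.01 * rng.normal(size=30)
        with pytest.warns(UserWarning, match="rank"):
            model = fit_pls(X, y, n_components=4)
        assert model.n_components < 4


class TestVip:
    def test_sum_of_squares_equals_p(self):
        for seed in range(3):
            X, y = random_design(seed=seed)
            for a in (1, 2, 5):
                report = vip_scores(fit_pls(X, y, n_components=a))
                assert np.sum(report.vip**2) == pytest.approx(X.shape[1], abs=1e-9)

    def test_equal_weights_give_unit_vip(self):
        p = 4
        w = np.full((p, 1), 0.5)
        model = PlsModel(
            n_components=1,
            x_means=np.zeros(p),
            x_scales=np.ones(p),
            y_mean=0.0,
            y_scale=1.0,
            weights=w,
            scores=np.ones((10, 1)),
            x_loadings=w,
            y_loadings=np.array([1.0]),
            coefficients=np.full(p, 0.5),
        )
        assert np.allclose(vip_scores(model).vip, 1.0)

    def test_planted_secondary_conjugated_effect_recovered(self):
        ds = gen_meta_table(
            level_effects={"bs_type": {"PC": 0.0, "PU": 0.0, "SC": -2.0, "SU": 0.0}},
            noise_sd=0.3,
            n=100,
            seed=11,
        )
        X, names = one_hot_encode(ds.data, {"bs_type": ["PC", "PU", "SC", "SU"]})
        y = np.array([r.response for r in ds.data])
        model = fit_pls(X, y, n_components=2, names=names)
        report = vip_scores(model)
        top = report.as_frame().iloc[0]
        assert top["variable"] == "bs_type=SC"
        assert top["coefficient"] < 0


class TestWelch:
    def test_identical_samples(self):
        a = [1.0, 2.0, 3.0]
        t, df, p = welch_t_test(a, a, tail="right")
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(0.5)

    def test_large_separation(self):
        rng = np.random.default_rng(0)
        b = rng.normal(size=10)
        _, _, p = welch_t_test(b + 100.0, b, tail="right")
        assert p < 1e-6

    def test_two_sided_doubles_one_sided_at_symmetry(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(1.0, 1, 12), rng.normal(0.0, 1, 9)
        t, _, p_right = welch_t_test(a, b, tail="right")
        _, _, p_two = welch_t_test(a, b, tail="two")
        assert t > 0
        assert p_two == pytest.approx(2 * p_right, rel=1e-10)

    def test_power_at_one_sd_gap(self):
        # two literature categories, one-sd mean gap, unbalanced counts
        rng = np.random.default_rng(5)
        hits = 0
        n_rep = 500
        for _ in range(n_rep):
            a = rng.normal(1.0, 1.0, 28)
            b = rng.normal(0.0, 1.0, 16)
            _, _, p = welch_t_test(a, b, tail="right")
            hits += p < 0.05
        assert hits / n_rep >= 0.80

    def test_small_samples_rejected(self):
        with pytest.raises(DomainError):
            welch_t_test([1.0], [1.0, 2.0])
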