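"""Classifier contracts: probability outputs, feature selection behavior,
the hand-computed shrunken-centroid arithmetic, and grid conventions."""

import numpy as np
import pandas as pd
import pytest

from panelgrid import clf
from panelgrid.clf import default_grids, pam_delta_grid, pam_score, train
from conftest import make_expr


def separable_cohort(rng, n_feat=10, n_per_class=12, shift=3.0):
    x = rng.normal(8.0, 1.0, size=(n_feat, 2 * n_per_class))
    x[:3, :n_per_class] += shift
    return make_expr(x, n_per_class)


@pytest.fixture(scope="module")
def cohort():
    return separable_cohort(np.random.default_rng(0))


@pytest.fixture(scope="module")
def specs():
    return default_grids()


PARAMS = {
    "EN-0.10": 0.1, "EN-0.50": 0.1, "EN-0.90": 0.1, "LDA": 3,
    "PAM": 0.5, "RF-1": None, "SVM": 1.0, "XGBoost": 50,
}


@pytest.mark.parametrize("method", list(PARAMS))
def test_probabilities_valid_and_complementary(method, cohort, specs):
    model = train(specs[method], cohort, cohort.feature_ids, PARAMS[method], seed=1)
    p = model.predict_proba(cohort)
    assert np.all((p.values >= 0) & (p.values <= 1))
    assert set(model.selected_feature_ids) <= set(cohort.feature_ids)
    # training AUC sanity floor on separable data
    from panelgrid.cveval import auc

    assert auc(p.values, cohort.labels) >= 0.5


@pytest.mark.parametrize("method", ["RF-1", "XGBoost"])
def test_seeded_training_is_deterministic(method, cohort, specs):
    a = train(specs[method], cohort, cohort.feature_ids, PARAMS[method], seed=3)
    b = train(specs[method], cohort, cohort.feature_ids, PARAMS[method], seed=3)
    pd.testing.assert_series_equal(a.predict_proba(cohort), b.predict_proba(cohort))


def test_lda_saturates_on_separated_data(specs):
    rng = np.random.default_rng(1)
    expr = separable_cohort(rng, shift=6.0)
    model = train(specs["LDA"], expr, expr.feature_ids, 3)
    p = model.predict_proba(expr).values
    case = expr.case_mask
    assert np.all(p[case] > 0.99) and np.all(p[~case] < 0.01)


def test_missing_prediction_features_signalled(cohort, specs):
    model = train(specs["LDA"], cohort, cohort.feature_ids, 2)
    reduced = cohort.subset_features(cohort.feature_ids[5:])
    with pytest.raises(ValueError, match="missing"):
        model.predict_proba(reduced)


def test_empty_panel_rejected(cohort, specs):
    with pytest.raises(ValueError, match="empty panel"):
        train(specs["LDA"], cohort, [], 1)


class TestPAM:
    def test_zero_shrinkage_keeps_all_features(self, cohort, specs):
        model = train(specs["PAM"], cohort, cohort.feature_ids, 0.0)
        assert model.selected_feature_ids == cohort.feature_ids

    def test_total_shrinkage_collapses_to_priors(self, specs):
        rng = np.random.default_rng(2)
        expr = separable_cohort(rng)
        model = train(specs["PAM"], expr, expr.feature_ids, 1e6)
        assert model.selected_feature_ids == []
        p = model.predict_proba(expr).values
        # balanced priors: every sample scores exactly 1/2
        np.testing.assert_allclose(p, 0.5, atol=1e-12)

    def test_midpoint_sample_probability_half(self):
        # symmetric centroids, equal priors -> midpoint is undecidable
        x = np.array(
            [[1.0, 1.0, -1.0, -1.0], [2.0, 2.0, -2.0, -2.0]]
        ) + np.array([[0.1, -0.1, 0.1, -0.1], [0.1, -0.1, 0.1, -0.1]])
        expr = make_expr(x, 2)
        model = train(default_grids()["PAM"], expr, expr.feature_ids, 0.0)
        mid = np.zeros(2)
        _, probs = pam_score(mid, model)
        np.testing.assert_allclose(probs, [0.5, 0.5], atol=1e-12)

    def test_hand_computed_discriminants(self):
        """2 features x 2 classes, 2 samples per class, delta = 0.5: the
        full chain d -> soft-threshold -> shrunken centroids -> delta_k is
        checked against a by-hand evaluation."""
        # class means per feature: case (+1), control (-1); within-class sd
        # arranged so s = [1, 1]; equal priors, n = 4
        x = np.array(
            [
                [2.0, 0.0, -2.0, 0.0],  # case mean 1, control mean -1
                [0.0, 2.0, 0.0, -2.0],
            ]
        )
        expr = make_expr(x, 2)
        model = train(default_grids()["PAM"], expr, expr.feature_ids, 0.5)
        st = model.state
        # by hand: overall = 0; s_i = sqrt(sum (x - mean)^2 / (n-2))
        #        = sqrt((1+1+1+1)/2) = sqrt(2); s0 = median = sqrt(2)
        # m_k = sqrt(1/2 - 1/4) = 0.5; denom = 0.5 * 2 sqrt(2) = sqrt(2)
        # d_ik = +-1/sqrt(2) ~ 0.7071; d' = +-(0.7071 - 0.5) = +-0.2071
        # shrunken centroid = 0 + sqrt(2) * d' = +-0.29289
        c_expected = (np.sqrt(2) - 1) / np.sqrt(2) * np.sqrt(2) / np.sqrt(2)
        expect = 1 - 1 / np.sqrt(2) * 0.5 * 2  # = 1 - sqrt(2)/2 ~ 0.29289
        np.testing.assert_allclose(
            st["shrunk_centroids"],
            np.array([[expect, -expect], [expect, -expect]]),
            atol=1e-12,
        )
        # delta_k at x = (1, 1): sum over features of
        # (x_i - c'_ik)^2 / (s_i + s0)^2 - 2 log(1/2), (s+s0)^2 = 8
        for xi, want_case_smaller in [(np.array([1.0, 1.0]), True)]:
            d0 = ((xi - expect) ** 2).sum() / 8 - 2 * np.log(0.5)
            d1 = ((xi + expect) ** 2).sum() / 8 - 2 * np.log(0.5)
            delta, probs = pam_score(xi, model)
            np.testing.assert_allclose(delta, [d0, d1], atol=1e-12)
            assert (probs[0] > 0.5) == want_case_smaller

    def test_delta_grid_spans_zero_to_max(self, cohort):
        grid = pam_delta_grid(cohort, cohort.feature_ids)
        assert grid[-1] == 0.0 and grid[0] > 0
        assert list(grid) == sorted(grid, reverse=True)


def test_en_sparsity_monotone_in_alpha(specs):
    """At matched penalty, the more lasso-like mix never keeps more
    features (checked over random instances)."""
    rng = np.random.default_rng(5)
    wins = 0
    trials = 40
    for _ in range(trials):
        expr = separable_cohort(rng, n_feat=20, shift=1.0)
        lam = 0.3
        n10 = len(train(specs["EN-0.10"], expr, expr.feature_ids, lam).selected_feature_ids)
        n90 = len(train(specs["EN-0.90"], expr, expr.feature_ids, lam).selected_feature_ids)
        if n90 <= n10:
            wins += 1
    assert wins / trials >= 0.95


def test_en_and_pam_selection_monotone_in_regularization(specs):
    rng = np.random.default_rng(6)
    expr = separable_cohort(rng, n_feat=30, shift=1.5)
    for method, grid in [
        ("EN-0.50", [3.0, 0.3, 0.03]),
        ("PAM", [4.0, 1.0, 0.0]),
    ]:
        sizes = [
            len(train(specs[method], expr, expr.feature_ids, g).selected_feature_ids)
            for g in grid
        ]
        assert sizes == sorted(sizes)  # fewer features at stronger shrinkage


@pytest.mark.parametrize("method", ["EN-0.50", "LDA", "PAM", "SVM"])
def test_model_text_dump_is_self_describing(method, cohort, specs):
    model = train(specs[method], cohort, cohort.feature_ids, PARAMS[method])
    text = clf.model_to_text(model)
    assert text.startswith(f"method\t{method}")
    assert f"panel_size\t{len(cohort.feature_ids)}" in text
    for f in model.selected_feature_ids:
        assert f in text


class TestDefaultGrids:
    def test_rf_untuned(self, specs):
        assert specs["RF-1"].tuning_grid == []

    def test_grid_orientations(self, specs):
        assert specs["EN-0.10"].tuning_grid[0] > specs["EN-0.10"].tuning_grid[-1]
        assert specs["SVM"].tuning_grid[0] < specs["SVM"].tuning_grid[-1]
        assert specs["XGBoost"].tuning_grid[0] < specs["XGBoost"].tuning_grid[-1]
        assert specs["LDA"].tuning_grid[0] == 1

    def test_en_alphas_fixed(self, specs):
        for a in (0.10, 0.50, 0.90):
            assert specs[f"EN-{a:.2f}"].fixed_params["alpha"] == a
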