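"""Cross-validation machinery: fold stratification, AUC pair-counting
oracle, confusion metrics, one-SE selection, optimism correction, and the
flat-vs-nested bias structure."""

import numpy as np
import pandas as pd
import pytest

from panelgrid import cveval
from panelgrid.clf import ClassifierSpec, default_grids
from panelgrid.cveval import (
    auc,
    bias_correct,
    confusion_metrics,
    make_folds,
    nested_cv,
    select_param,
    tune_flat,
)
from panelgrid.simdata import SimConfig, simulate_cohort
from conftest import make_expr


def brute_force_auc(scores, labels):
    cases = [s for s, l in zip(scores, labels) if l == "AR"]
    controls = [s for s, l in zip(scores, labels) if l == "NR"]
    total = 0.0
    for c in cases:
        for d in controls:
            total += 1.0 if c > d else (0.5 if c == d else 0.0)
    return total / (len(cases) * len(controls))


class TestAUC:
    def test_perfect_and_tied(self):
        assert auc([0.9, 0.8, 0.1, 0.2], ["AR", "AR", "NR", "NR"]) == 1.0
        assert auc([0.5] * 6, ["AR"] * 3 + ["NR"] * 3) == 0.5

    def test_worked_example(self):
        assert auc([0.9, 0.4, 0.6], ["AR", "AR", "NR"]) == 0.5

    def test_single_class_signalled(self):
        with pytest.raises(ValueError, match="single class"):
            auc([0.1, 0.9], ["AR", "AR"])

    def test_matches_pair_counting_oracle_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            n = int(rng.integers(4, 30))
            n_case = int(rng.integers(1, n))
            labels = ["AR"] * n_case + ["NR"] * (n - n_case)
            # discretized scores force ties regularly
            scores = np.round(rng.uniform(size=n), 1)
            assert auc(scores, labels) == pytest.approx(
                brute_force_auc(scores, labels), abs=1e-12
            )


class TestConfusionMetrics:
    def test_all_called_case(self):
        m = confusion_metrics([1.0] * 6, ["AR"] * 3 + ["NR"] * 3)
        assert m["sensitivity"] == 1.0 and m["specificity"] == 0.0

    def test_perfect_scores(self):
        m = confusion_metrics([1, 0, 1, 0], ["AR", "NR", "AR", "NR"])
        assert m["error"] == 0.0

    def test_direct_count_example(self):
        scores = [0.6, 0.4, 0.9, 0.2, 0.7, 0.1]
        labels = ["AR", "AR", "AR", "NR", "NR", "NR"]
        m = confusion_metrics(scores, labels)
        assert m["sensitivity"] == pytest.approx(2 / 3)
        assert m["specificity"] == pytest.approx(2 / 3)
        assert m["error"] == pytest.approx(1 / 3)


class TestMakeFolds:
    def test_exact_balance_for_study_design(self):
        labels = pd.Series(
            ["AR"] * 24 + ["NR"] * 24, index=[f"s{i}" for i in range(48)]
        )
        for seed in range(5):
            plan = make_folds(labels, k=8, m=5, seed=seed)
            assert len(plan.assignments) == 5
            for a in plan.assignments:
                ct = pd.crosstab(a, labels)
                assert (ct == 3).all().all()

    def test_partitions_differ_and_are_deterministic(self):
        labels = pd.Series(
            ["AR"] * 16 + ["NR"] * 16, index=[f"s{i}" for i in range(32)]
        )
        p1 = make_folds(labels, k=8, m=2, seed=4)
        p2 = make_folds(labels, k=8, m=2, seed=4)
        for a, b in zip(p1.assignments, p2.assignments):
            pd.testing.assert_series_equal(a, b)
        assert not p1.assignments[0].equals(p1.assignments[1])

    def test_degenerate_folds_of_two(self):
        labels = pd.Series(["AR"] * 8 + ["NR"] * 8, index=[f"s{i}" for i in range(16)])
        plan = make_folds(labels, k=8, m=1, seed=0)
        sizes = plan.assignments[0].value_counts()
        assert (sizes == 2).all()

    def test_small_class_rejected(self):
        labels = pd.Series(["AR"] * 4 + ["NR"] * 24)
        with pytest.raises(ValueError):
            make_folds(labels, k=8)


class TestSelection:
    def test_single_value_grid(self):
        grid = [1.0]
        fg = np.array([[0.8], [0.9]])
        assert select_param(grid, [0.85], fg, "auc", "one_se") == 0

    def test_one_se_picks_more_regularized(self):
        # grid ordered most -> least regularized; means 0.89 then 0.90,
        # SE at best 0.02 -> both within one SE -> first (more regularized)
        grid = ["strong", "weak"]
        fold = np.array([[0.89, 0.88], [0.89, 0.92]])
        means = fold.mean(axis=0)
        assert select_param(grid, means, fold, "auc", "one_se") == 0
        assert select_param(grid, means, fold, "auc", "extreme") == 1

    def test_one_se_for_minimized_error(self):
        grid = ["strong", "weak"]
        fold = np.array([[0.13, 0.07], [0.11, 0.13]])
        means = fold.mean(axis=0)  # [0.12, 0.10]; SE at best 0.03
        assert select_param(grid, means, fold, "error", "one_se") == 0


class TestBiasCorrect:
    def test_no_optimism_when_folds_agree(self):
        fg = pd.DataFrame({"a": [0.9, 0.8], "b": [0.7, 0.6]})
        corrected, b = bias_correct(fg, "a", 0.85, "auc")
        assert b == 0.0 and corrected == 0.85

    def test_hand_example(self):
        fg = pd.DataFrame({"a": [0.9, 0.8], "b": [0.7, 0.9]})
        corrected, b = bias_correct(fg, "a", 0.85, "auc")
        assert b == pytest.approx(0.05)
        assert corrected == pytest.approx(0.80)

    def test_error_direction(self):
        fg = pd.DataFrame({"a": [0.10, 0.20], "b": [0.20, 0.10]})
        corrected, b = bias_correct(fg, "a", 0.15, "error")
        assert b == pytest.approx(0.05)
        assert corrected == pytest.approx(0.20)

    def test_missing_entries_signalled(self):
        fg = pd.DataFrame({"a": [0.9, np.nan]})
        with pytest.raises(ValueError):
            bias_correct(fg, "a", 0.9, "auc")


def _null_cohort(seed, n_feat=100, n_per_class=16):
    cfg = SimConfig(
        n_case=n_per_class, n_control=n_per_class, n_probesets=n_feat,
        de_fraction=0.0, seed=seed,
    )
    _, expr, _, _ = simulate_cohort(cfg, probe_level=False)
    return expr


class TestFlatVsNested:
    def test_null_nested_unbiased_flat_optimistic(self):
        """On label-independent data, nested CV stays within 2 SE of 0.5
        while tuned flat CV shows positive mean optimism over seeds."""
        flat_aucs, nested_aucs, ses = [], [], []
        spec = default_grids()["PAM"]
        for seed in range(10):
            expr = _null_cohort(seed)
            plan = cveval.make_folds(expr.labels, k=8, m=1, seed=seed)
            ctx = cveval.build_fold_context(expr, plan, ["FDR50"])
            flat = tune_flat(spec, expr, "FDR50", plan, context=ctx)
            nested = nested_cv(spec, expr, "FDR50", plan, context=ctx)
            flat_aucs.append(flat.estimate.metrics["auc"])
            nested_aucs.append(nested.estimate.metrics["auc"])
            ses.append(nested.estimate.se["auc"])
        mean_nested = np.mean(nested_aucs)
        pooled_se = np.mean(ses) / np.sqrt(len(ses))
        assert abs(mean_nested - 0.5) <= 2 * np.mean(ses)
        assert np.mean(flat_aucs) - np.mean(nested_aucs) > 0

    def test_rf_flat_equals_nested_exactly(self):
        cfg = SimConfig(n_case=8, n_control=8, n_probesets=80, seed=21)
        _, expr, _, _ = simulate_cohort(cfg, probe_level=False)
        plan = cveval.make_folds(expr.labels, k=8, m=2, seed=2)
        ctx = cveval.build_fold_context(expr, plan, ["FDR50"])
        spec = default_grids()["RF-1"]
        flat = tune_flat(spec, expr, "FDR50", plan, context=ctx)
        nested = nested_cv(spec, expr, "FDR50", plan, context=ctx)
        pd.testing.assert_frame_equal(
            flat.estimate.per_fold, nested.estimate.per_fold
        )


def test_no_leakage_from_test_fold_labels():
    """Permuting a test fold's labels leaves the training-fold DE table and
    panels untouched."""
    cfg = SimConfig(n_case=8, n_control=8, n_probesets=60, seed=31)
    _, expr, _, _ = simulate_cohort(cfg, probe_level=False)
    plan = cveval.make_folds(expr.labels, k=8, m=1, seed=1)
    ctx = cveval.build_fold_context(expr, plan, ["FDR50"])
    train_ids, test_ids = plan.folds(0)[0]
    flipped = expr.labels.copy()
    flipped.loc[test_ids] = flipped.loc[test_ids].map({"AR": "NR", "NR": "AR"})
    expr_flipped = type(expr)(expr.values, flipped)
    ctx2 = cveval.build_fold_context(expr_flipped, plan, ["FDR50"])
    fd, fd2 = ctx[(0, 0)], ctx2[(0, 0)]
    pd.testing.assert_frame_equal(fd.de.table, fd2.de.table)
    assert fd.panels["FDR50"].feature_ids == fd2.panels["FDR50"].feature_ids


def test_tune_flat_recovers_signal_with_one_se(midsize_cohort):
    """On planted-signal data the tuned flat estimate lands in a high-AUC
    regime and the one-SE pick is at least as regularized as the extreme."""
    cfg, expr, truth, _ = midsize_cohort
    sub = expr  # 2,000 features, 24+24
    plan = cveval.make_folds(sub.labels, k=8, m=1, seed=7)
    ctx = cveval.build_fold_context(sub, plan, ["FDR50"])
    spec = default_grids()["PAM"]
    one_se = tune_flat(spec, sub, "FDR50", plan, context=ctx, selection="one_se")
    extreme = tune_flat(spec, sub, "FDR50", plan, context=ctx, selection="extreme")
    assert one_se.estimate.metrics["auc"] > 0.85
    assert one_se.selected_param >= extreme.selected_param  # larger delta


def test_run_grid_small_cartesian(small_cohort):
    """A 2 x 2 x 2 grid enumerates 8 combinations with a full score row per
    sample, and the score matrix is the per-partition mean of held-out
    probabilities."""
    cfg, coll, expr, truth, annot = small_cohort
    import panelgrid.prefilter as pf

    datasets = {
        "ECMR": pf.ecmr(expr).analysis_matrix(expr),
        "BI2005": pf.bi2005(expr).analysis_matrix(expr),
    }
    plan = cveval.make_folds(expr.labels, k=8, m=2, seed=5)
    specs = {k: v for k, v in default_grids().items() if k in ("PAM", "RF-1")}
    res = cveval.run_grid(
        datasets, ["FDR50", "FC0.5.TOP50"], specs, plan, nested=False
    )
    assert len(res.table) == 8
    assert res.score_matrix.shape == (48, 8)
    assert res.score_matrix.notna().all().all()
    assert ((res.score_matrix >= 0) & (res.score_matrix <= 1)).all().all()
    assert (res.table["status"] == "ok").all()
    # flat AUC well above chance on planted-signal data for PAM arms
    pam_rows = res.table[res.table["method"] == "PAM"]
    assert (pam_rows["flat_auc"] > 0.7).all()
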