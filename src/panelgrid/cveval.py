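"""Cross-validated model tuning and performance estimation.

Implements multiple-partition stratified k-fold cross-validation in two
modes: *flat* CV, where the same folds serve parameter tuning and
performance estimation (optimistically biased after selection), and
*nested* CV, where tuning happens entirely inside inner folds of each outer
training set so the outer estimate is unbiased.  Within every training
fold the differential-expression table and the ranking-rule panel are
recomputed from the training samples only — the held-out fold never leaks
into feature selection.

Model selection uses either the extreme value of the cross-validated
metric or the one-standard-error rule (among grid values within one SE of
the best, take the most regularized; grids are ordered most -> least
regularized).  A fold-wise optimism estimate adapted from the classical
classification-error bias correction is available for AUC, error,
sensitivity and specificity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from . import clf as _clf
from .clf import ClassifierSpec, TrainedModel, pam_delta_grid, train
from .de import DEResult, moderated_t
from .panels import Panel, apply_rule
from .simdata import CASE_LABEL, ExpressionMatrix

METRICS = ("auc", "error", "sensitivity", "specificity")
_MAXIMIZED = {"auc": True, "error": False, "sensitivity": True, "specificity": True}


@dataclass
class FoldPlan:
    k: int
    m: int
    assignments: list[pd.Series]  # per partition: sample id -> fold index
    seed: int

    def folds(self, partition: int) -> list[tuple[list[str], list[str]]]:
        """(train_ids, test_ids) for every fold of one partition."""
        a = self.assignments[partition]
        out = []
        for f in range(self.k):
            test = list(a.index[a == f])
            trainv = list(a.index[a != f])
            out.append((trainv, test))
        return out


def make_folds(labels: pd.Series, k: int = 8, m: int = 5, seed: int = 0) -> FoldPlan:
    """Stratified fold plans: within each class, shuffle by a seeded stream
    and deal round-robin into k folds, once per partition.  Per-fold class
    counts differ by at most one from perfect balance (exactly 3+3 for the
    24+24, k=8 design)."""
    classes = labels.unique()
    for c in classes:
        if (labels == c).sum() < k:
            raise ValueError(f"class {c!r} has fewer samples than k={k}")
    assignments = []
    for part in range(m):
        rng = np.random.Generator(
            np.random.PCG64(np.random.SeedSequence([int(seed), part]))
        )
        assign = pd.Series(-1, index=labels.index, dtype=int)
        for c in classes:
            ids = list(labels.index[labels == c])
            rng.shuffle(ids)
            for pos, sid in enumerate(ids):
                assign[sid] = pos % k
        assignments.append(assign)
    return FoldPlan(k, m, assignments, seed)


def auc(scores, labels) -> float:
    """Mann-Whitney AUC: concordant case-control pairs plus half credit for
    ties, over all case x control pairs."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray([lab == CASE_LABEL for lab in labels])
    n1 = int(y.sum())
    n0 = int((~y).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("undefined AUC: fold contains a single class")
    r = rankdata(s)
    return float((r[y].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def confusion_metrics(scores, labels, threshold: float = 0.5) -> dict[str, float]:
    """Error, sensitivity and specificity at the probability threshold
    (score >= threshold classifies as case)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray([lab == CASE_LABEL for lab in labels])
    pred = s >= threshold
    tp = int((pred & y).sum())
    tn = int((~pred & ~y).sum())
    fp = int((pred & ~y).sum())
    fn = int((~pred & y).sum())
    return {
        "error": (fp + fn) / len(s),
        "sensitivity": tp / (tp + fn) if (tp + fn) else np.nan,
        "specificity": tn / (tn + fp) if (tn + fp) else np.nan,
    }


def _fold_metrics(scores, labels) -> dict[str, float]:
    out = {"auc": auc(scores, labels)}
    out.update(confusion_metrics(scores, labels))
    return out


@dataclass
class PerformanceEstimate:
    mode: str  # "flat" | "nested"
    metrics: dict[str, float]
    se: dict[str, float]
    per_fold: pd.DataFrame  # (partition, fold) x metric
    selected_param: object = None
    bias_corrected: dict[str, float] | None = None
    partial: bool = False  # some folds missing


def _aggregate(per_fold: pd.DataFrame, mode: str, selected_param=None) -> PerformanceEstimate:
    means = per_fold.mean(axis=0, skipna=True).to_dict()
    n = len(per_fold)
    ses = (per_fold.std(axis=0, ddof=1, skipna=True) / np.sqrt(n)).to_dict()
    partial = bool(per_fold.isna().any().any())
    return PerformanceEstimate(mode, means, ses, per_fold, selected_param, None, partial)


def _model_seed(plan_seed: int, partition: int, fold: int) -> int:
    return int((plan_seed * 1_000_003 + partition * 8_191 + fold * 131 + 17) % (2**31))


# --- per-fold context: DE table and rule panels from training samples only --


@dataclass
class FoldData:
    train_expr: ExpressionMatrix
    test_expr: ExpressionMatrix
    de: DEResult
    panels: dict[str, Panel]


def build_fold_context(
    expr: ExpressionMatrix,
    plan: FoldPlan,
    rules: Sequence[str],
    rule_params: dict | None = None,
) -> dict[tuple[int, int], FoldData]:
    """Compute, for every (partition, fold), the training-fold DE table and
    the panel of each requested rule.  Shared across classifiers."""
    rule_params = rule_params or {}
    ctx: dict[tuple[int, int], FoldData] = {}
    for p in range(plan.m):
        for f, (train_ids, test_ids) in enumerate(plan.folds(p)):
            tr = expr.subset_samples(train_ids)
            te = expr.subset_samples(test_ids)
            de_res = moderated_t(tr)
            panels = {
                r: apply_rule(r, de_res, tr, **rule_params.get(r, {}))
                for r in rules
            }
            ctx[(p, f)] = FoldData(tr, te, de_res, panels)
    return ctx


def _resolve_grid(
    spec: ClassifierSpec, expr: ExpressionMatrix, rule: str, rule_params=None
) -> list:
    """Tuning grid for a spec.  RF's empty grid becomes the single untuned
    configuration; PAM's shrinkage grid spans 0 .. max|d| of the panel the
    rule produces on the data handed to the tuner (training samples only in
    nested CV)."""
    if spec.tuning_grid:
        return list(spec.tuning_grid)
    if spec.method == "PAM":
        de_res = moderated_t(expr)
        panel = apply_rule(rule, de_res, expr, **((rule_params or {}).get(rule, {})))
        if len(panel) == 0:
            raise ValueError("empty panel: cannot build PAM shrinkage grid")
        return pam_delta_grid(expr, panel.feature_ids)
    return [None]  # untuned (RF)


@dataclass
class TuneResult:
    selected_param: object
    estimate: PerformanceEstimate
    grid: list
    grid_means: pd.Series  # mean tuning metric per grid value
    fold_grid: pd.DataFrame  # (partition, fold) x grid value, tuning metric
    scores: pd.DataFrame  # samples x partitions, held-out scores at selection


def select_param(
    grid: list, grid_means: np.ndarray, fold_grid: np.ndarray, metric: str, rule: str
) -> int:
    """Index of the selected grid value under ``rule`` in {extreme, one_se}.

    Grids are ordered most -> least regularized, so the one-SE rule takes
    the earliest candidate whose mean lies within one standard error of the
    best."""
    maximize = _MAXIMIZED[metric]
    means = np.asarray(grid_means, dtype=float)
    valid = ~np.isnan(means)
    if not valid.any():
        raise ValueError("no grid value produced a valid CV estimate")
    if maximize:
        best = int(np.nanargmax(means))
    else:
        best = int(np.nanargmin(means))
    if rule == "extreme" or len(grid) == 1:
        return best
    if rule != "one_se":
        raise ValueError(f"unknown selection rule: {rule}")
    col = fold_grid[:, best]
    col = col[~np.isnan(col)]
    se = float(np.std(col, ddof=1) / np.sqrt(len(col))) if len(col) > 1 else 0.0
    if maximize:
        cand = np.where(valid & (means >= means[best] - se))[0]
    else:
        cand = np.where(valid & (means <= means[best] + se))[0]
    return int(cand[0])


def tune_flat(
    spec: ClassifierSpec,
    expr: ExpressionMatrix,
    rule: str,
    plan: FoldPlan,
    metric: str = "auc",
    selection: str = "one_se",
    context: dict | None = None,
    rule_params: dict | None = None,
) -> TuneResult:
    """Flat cross-validated tuning: every grid value is scored on the same
    k*m held-out folds (training-fold DE + panel recomputed per fold), then
    the extreme or one-SE rule picks the parameter.  The returned estimate
    is the flat (biased-after-selection) CV performance at the selection."""
    if metric not in METRICS:
        raise ValueError(f"unknown metric: {metric}")
    grid = _resolve_grid(spec, expr, rule, rule_params)
    if context is None:
        context = build_fold_context(expr, plan, [rule], rule_params)
    keys = [(p, f) for p in range(plan.m) for f in range(plan.k)]
    fold_grid = np.full((len(keys), len(grid)), np.nan)
    all_metrics: list[list[dict | None]] = [[None] * len(grid) for _ in keys]
    score_rows: dict[tuple[int, int], dict[int, pd.Series]] = {}
    for ki, key in enumerate(keys):
        fd = context[key]
        panel = fd.panels[rule]
        if len(panel) == 0:
            continue  # fold recorded as missing
        p, f = key
        seed = _model_seed(plan.seed, p, f)
        for gi, gv in enumerate(grid):
            try:
                model = train(spec, fd.train_expr, panel.feature_ids, gv, seed=seed)
                scores = model.predict_proba(fd.test_expr)
            except ValueError:
                continue
            mets = _fold_metrics(scores, fd.test_expr.labels)
            all_metrics[ki][gi] = mets
            fold_grid[ki, gi] = mets[metric]
            score_rows.setdefault(key, {})[gi] = scores
    grid_means = np.nanmean(
        np.where(np.isnan(fold_grid), np.nan, fold_grid), axis=0
    )
    sel = select_param(grid, grid_means, fold_grid, metric, selection)
    per_fold = pd.DataFrame(
        [
            all_metrics[ki][sel] if all_metrics[ki][sel] is not None
            else {mname: np.nan for mname in METRICS}
            for ki in range(len(keys))
        ],
        index=pd.MultiIndex.from_tuples(keys, names=["partition", "fold"]),
    )[list(METRICS)]
    estimate = _aggregate(per_fold, "flat", grid[sel])
    scores = pd.DataFrame(np.nan, index=expr.sample_ids, columns=range(plan.m))
    for (p, f), by_grid in score_rows.items():
        if sel in by_grid:
            scores.loc[by_grid[sel].index, p] = by_grid[sel].to_numpy()
    return TuneResult(
        grid[sel],
        estimate,
        grid,
        pd.Series(grid_means, index=[str(g) for g in grid]),
        pd.DataFrame(
            fold_grid,
            index=pd.MultiIndex.from_tuples(keys, names=["partition", "fold"]),
            columns=[str(g) for g in grid],
        ),
        scores,
    )


def bias_correct(
    fold_grid: pd.DataFrame,
    selected_column: str,
    estimate: float,
    metric: str = "auc",
) -> tuple[float, float]:
    """Fold-wise optimism correction of a flat CV estimate.

    B = mean over folds of (fold's best grid value - fold's value at the
    overall selection), clipped at zero from below; corrected estimate =
    estimate - B for maximized metrics, estimate + B for error.  Returns
    (corrected, B)."""
    if fold_grid.isna().any().any():
        raise ValueError("missing fold entries; cannot bias-correct")
    maximize = _MAXIMIZED[metric]
    vals = fold_grid.to_numpy(dtype=float)
    at_sel = fold_grid[selected_column].to_numpy(dtype=float)
    per_fold_best = vals.max(axis=1) if maximize else vals.min(axis=1)
    b = float(np.mean(per_fold_best - at_sel)) if maximize else float(
        np.mean(at_sel - per_fold_best)
    )
    b = max(b, 0.0)
    corrected = estimate - b if maximize else estimate + b
    return corrected, b


@dataclass
class NestedResult:
    estimate: PerformanceEstimate
    fold_params: dict[tuple[int, int], object]
    scores: pd.DataFrame  # samples x partitions, outer held-out scores


def nested_cv(
    spec: ClassifierSpec,
    expr: ExpressionMatrix,
    rule: str,
    plan_outer: FoldPlan,
    inner_k: int = 8,
    inner_m: int = 1,
    metric: str = "auc",
    selection: str = "one_se",
    rule_params: dict | None = None,
    context: dict | None = None,
) -> NestedResult:
    """Nested CV: per outer fold, tune on the outer-training samples with
    inner folds, refit at the selection on the full outer-training set, and
    score the outer test fold.  Untuned specs (empty grid, non-PAM) skip the
    inner loop, so their flat and nested per-fold results coincide by
    construction."""
    if context is None:
        context = build_fold_context(expr, plan_outer, [rule], rule_params)
    tuned = bool(spec.tuning_grid) or spec.method == "PAM"
    keys = [(p, f) for p in range(plan_outer.m) for f in range(plan_outer.k)]
    rows = []
    fold_params: dict[tuple[int, int], object] = {}
    scores = pd.DataFrame(np.nan, index=expr.sample_ids, columns=range(plan_outer.m))
    for p, f in keys:
        fd = context[(p, f)]
        panel = fd.panels[rule]
        if len(panel) == 0:
            rows.append({mname: np.nan for mname in METRICS})
            continue
        if tuned:
            inner_seed = _model_seed(plan_outer.seed, p, f) % (2**20)
            inner_plan = make_folds(
                fd.train_expr.labels, k=inner_k, m=inner_m, seed=inner_seed
            )
            try:
                inner = tune_flat(
                    spec, fd.train_expr, rule, inner_plan,
                    metric=metric, selection=selection, rule_params=rule_params,
                )
                param = inner.selected_param
            except ValueError:
                rows.append({mname: np.nan for mname in METRICS})
                continue
        else:
            param = None
        fold_params[(p, f)] = param
        seed = _model_seed(plan_outer.seed, p, f)
        model = train(spec, fd.train_expr, panel.feature_ids, param, seed=seed)
        s = model.predict_proba(fd.test_expr)
        scores.loc[s.index, p] = s.to_numpy()
        rows.append(_fold_metrics(s, fd.test_expr.labels))
    per_fold = pd.DataFrame(
        rows, index=pd.MultiIndex.from_tuples(keys, names=["partition", "fold"])
    )[list(METRICS)]
    return NestedResult(_aggregate(per_fold, "nested"), fold_params, scores)


# --- full method grid -------------------------------------------------------


@dataclass
class GridResult:
    table: pd.DataFrame  # one row per combination
    score_matrix: pd.DataFrame  # samples x combination label (flat CV scores)
    nested_score_matrix: pd.DataFrame | None
    final_panels: dict[str, list[str]]  # combination label -> selected features


def run_grid(
    datasets: dict[str, ExpressionMatrix],
    rules: Sequence[str],
    specs: dict[str, ClassifierSpec],
    plan: FoldPlan,
    metric: str = "auc",
    selection: str = "one_se",
    nested: bool = False,
    inner_k: int = 8,
    inner_m: int = 1,
    rule_params: dict | None = None,
) -> GridResult:
    """The full cartesian grid: every pre-filter analysis data set x every
    ranking rule x every classifier configuration.

    Per combination this reports the flat CV estimate at the tuned
    parameter (with its fold-wise optimism correction), optionally the
    nested CV estimate, the final model trained on all samples at the
    selection, and the held-out probability-of-case score of every sample
    averaged over partitions — 48 samples x 200 combinations = 9,600 scores
    in the full design."""
    rows = []
    flat_scores: dict[str, pd.Series] = {}
    nested_scores: dict[str, pd.Series] = {}
    final_panels: dict[str, list[str]] = {}
    sample_ids = None
    for pf_name, expr in datasets.items():
        if sample_ids is None:
            sample_ids = expr.sample_ids
        context = build_fold_context(expr, plan, rules, rule_params)
        de_full = moderated_t(expr)
        for rule in rules:
            panel_full = apply_rule(
                rule, de_full, expr, **((rule_params or {}).get(rule, {}))
            )
            for mname, spec in specs.items():
                label = f"{pf_name}|{rule}|{mname}"
                row = {"prefilter": pf_name, "rule": rule, "method": mname,
                       "rule_panel_size": len(panel_full)}
                try:
                    tuned = tune_flat(
                        spec, expr, rule, plan, metric=metric,
                        selection=selection, context=context,
                        rule_params=rule_params,
                    )
                except ValueError as exc:
                    row["status"] = f"failed: {exc}"
                    rows.append(row)
                    continue
                row["status"] = "ok"
                row["selected_param"] = tuned.selected_param
                for met in METRICS:
                    row[f"flat_{met}"] = tuned.estimate.metrics[met]
                    row[f"flat_{met}_se"] = tuned.estimate.se[met]
                if not tuned.fold_grid.isna().any().any():
                    corrected, b = bias_correct(
                        tuned.fold_grid, str(tuned.selected_param),
                        tuned.estimate.metrics[metric], metric,
                    )
                    row[f"corrected_{metric}"] = corrected
                    row["optimism"] = b
                flat_scores[label] = tuned.scores.mean(axis=1)
                if nested:
                    nres = nested_cv(
                        spec, expr, rule, plan, inner_k=inner_k,
                        inner_m=inner_m, metric=metric, selection=selection,
                        rule_params=rule_params, context=context,
                    )
                    for met in METRICS:
                        row[f"nested_{met}"] = nres.estimate.metrics[met]
                        row[f"nested_{met}_se"] = nres.estimate.se[met]
                    nested_scores[label] = nres.scores.mean(axis=1)
                # final model on all samples at the selected parameter
                if len(panel_full) > 0:
                    final = train(
                        spec, expr, panel_full.feature_ids,
                        tuned.selected_param, seed=_model_seed(plan.seed, 0, 0),
                    )
                    final_panels[label] = final.selected_feature_ids
                    row["n_features_final"] = len(final.selected_feature_ids)
                rows.append(row)
    table = pd.DataFrame(rows)
    score_matrix = pd.DataFrame(flat_scores, index=sample_ids)
    nested_matrix = (
        pd.DataFrame(nested_scores, index=sample_ids) if nested else None
    )
    return GridResult(table, score_matrix, nested_matrix, final_panels)
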