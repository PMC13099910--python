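"""Eight classifier configurations behind one contract: train on
(expression, labels, panel), return probability of the case class.

Configurations (one tuned parameter each; everything else fixed):

===========  =============================  =========================================
name         algorithm                      tuned parameter (grid most->least
                                            regularized)
===========  =============================  =========================================
EN-0.10      elastic-net logistic (a=0.10)  penalty strength lambda, descending
EN-0.50      elastic-net logistic (a=0.50)  lambda, descending
EN-0.90      elastic-net logistic (a=0.90)  lambda, descending
LDA          linear discriminant            n = number of top-FDR panel features
PAM          nearest shrunken centroids     shrinkage threshold delta, descending
RF-1         random forest (500 trees)      none (untuned)
SVM          linear-kernel SVM              cost C in 2^-5 .. 2^5, ascending
XGBoost      gradient boosting (depth 2)    boosting rounds, ascending
===========  =============================  =========================================

EN and PAM perform additional feature selection (non-zero coefficients /
surviving features); LDA selects its top-n input; SVM, RF and XGBoost keep
the full input panel.  SVM probabilities come from a Platt-style logistic
map fitted on the training decision values; any monotone calibration
preserves AUC.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.svm import SVC
from xgboost import XGBClassifier

from .simdata import ExpressionMatrix

METHOD_NAMES = ("EN-0.10", "EN-0.50", "EN-0.90", "LDA", "PAM", "RF-1", "SVM", "XGBoost")


@dataclass
class ClassifierSpec:
    method: str
    tuned_param_name: str | None
    tuning_grid: list  # ordered most -> least regularized; empty for RF
    fixed_params: dict = field(default_factory=dict)


@dataclass
class TrainedModel:
    spec: ClassifierSpec
    param_value: Any
    panel_ids: list[str]
    selected_feature_ids: list[str]
    state: dict = field(default_factory=dict)

    def predict_proba(self, expr: ExpressionMatrix) -> pd.Series:
        return _PREDICTORS[self.spec.method.split("-")[0]](self, expr)


def default_grids(panel_size: int = 50) -> dict[str, ClassifierSpec]:
    """Shipped parameter grids.  ``panel_size`` caps the LDA top-n grid."""
    lambdas = list(np.logspace(1, -4, 30))  # descending: most regularized first
    svm_costs = [2.0**k for k in range(-5, 6)]
    xgb_rounds = [10, 25, 50, 100, 200, 300]
    n_max = max(1, min(50, panel_size))
    specs = {
        "EN-0.10": ClassifierSpec("EN-0.10", "lambda", list(lambdas), {"alpha": 0.10}),
        "EN-0.50": ClassifierSpec("EN-0.50", "lambda", list(lambdas), {"alpha": 0.50}),
        "EN-0.90": ClassifierSpec("EN-0.90", "lambda", list(lambdas), {"alpha": 0.90}),
        "LDA": ClassifierSpec("LDA", "n_features", list(range(1, n_max + 1))),
        "PAM": ClassifierSpec("PAM", "delta", []),  # grid built per panel at fit time
        "RF-1": ClassifierSpec(
            "RF-1", None, [], {"ntree": 500, "mtry": "sqrt", "nodesize": 1}
        ),
        "SVM": ClassifierSpec("SVM", "cost", svm_costs),
        "XGBoost": ClassifierSpec(
            "XGBoost", "n_rounds", xgb_rounds, {"max_depth": 2, "learning_rate": 0.1}
        ),
    }
    return specs


def pam_delta_grid(expr: ExpressionMatrix, panel_ids: Sequence[str], n: int = 30) -> list[float]:
    """Shrinkage grid 0 .. max |d_ik| (descending = most regularized
    first), matching the span of the standardized centroid differences."""
    stats = _pam_stats(expr, list(panel_ids))
    dmax = float(np.max(np.abs(stats["d"]))) if stats["d"].size else 1.0
    grid = np.linspace(0.0, dmax, n)
    return list(grid[::-1])  # large delta (strong shrinkage) first


# --- shrunken centroids (native implementation) -----------------------------


def _pam_stats(expr: ExpressionMatrix, panel_ids: list[str]) -> dict:
    x = expr.values.loc[panel_ids].to_numpy(dtype=float)  # features x samples
    case = expr.case_mask
    n = x.shape[1]
    groups = [case, ~case]
    nk = np.array([g.sum() for g in groups], dtype=float)
    overall = x.mean(axis=1)
    centroids = np.column_stack([x[:, g].mean(axis=1) for g in groups])
    # pooled within-class standard deviation per feature
    ss = sum(((x[:, g] - x[:, g].mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
             for g in groups)
    s = np.sqrt(ss / (n - 2))
    s0 = float(np.median(s))
    mk = np.sqrt(1.0 / nk - 1.0 / n)
    denom = (mk[None, :]) * (s + s0)[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(denom > 0, (centroids - overall[:, None]) / denom, 0.0)
    priors = nk / n
    return {
        "overall": overall, "centroids": centroids, "s": s, "s0": s0,
        "mk": mk, "d": d, "priors": priors, "classes": ["case", "control"],
    }


def _pam_shrink(stats: dict, delta: float) -> tuple[np.ndarray, np.ndarray]:
    d = stats["d"]
    dprime = np.sign(d) * np.maximum(np.abs(d) - delta, 0.0)
    shrunk = (
        stats["overall"][:, None]
        + stats["mk"][None, :] * (stats["s"] + stats["s0"])[:, None] * dprime
    )
    return dprime, shrunk


def pam_score(x: np.ndarray, model: "TrainedModel") -> tuple[np.ndarray, np.ndarray]:
    """Class discriminant scores and probabilities for one sample vector
    over the model's panel features.

    delta_k(x) = sum_i (x_i - c'_ik)^2 / (s_i + s0)^2 - 2 log prior_k;
    probability proportional to exp(-delta_k / 2).
    """
    st = model.state
    scale = (st["s"] + st["s0"]) ** 2
    diffs = (x[:, None] - st["shrunk_centroids"]) ** 2 / scale[:, None]
    delta = diffs.sum(axis=0) - 2.0 * np.log(st["priors"])
    w = np.exp(-(delta - delta.min()) / 2.0)
    return delta, w / w.sum()


# --- training ----------------------------------------------------------------


def _standardize_fit(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    sd = np.where(sd == 0, 1.0, sd)
    return (x - mean) / sd, mean, sd


def train(
    spec: ClassifierSpec,
    expr: ExpressionMatrix,
    panel_ids: Sequence[str],
    param_value=None,
    seed: int = 0,
) -> TrainedModel:
    """Fit one configuration on the panel features of ``expr``.

    ``param_value`` is the single tuned parameter (ignored for RF-1); any
    standardization uses the training samples only.  ``seed`` fixes the
    subsampling streams of RF and XGBoost.
    """
    panel_ids = list(panel_ids)
    if not panel_ids:
        raise ValueError("empty panel")
    y = expr.case_mask.astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes required for training")
    x = expr.values.loc[panel_ids].to_numpy(dtype=float).T  # samples x features
    method = spec.method
    state: dict = {}
    selected = panel_ids

    if method.startswith("EN"):
        lam = float(param_value)
        alpha = spec.fixed_params.get("alpha", 0.5)
        xs, mean, sd = _standardize_fit(x)
        # sklearn C = 1 / (n * lambda) reproduces the 1/n-scaled elastic-net
        # objective with penalty strength lambda
        c = 1.0 / (len(y) * lam)
        model = LogisticRegression(
            solver="saga", l1_ratio=alpha, C=c, max_iter=1000, tol=1e-3,
        )
        model.fit(xs, y)
        coef = model.coef_.ravel()
        selected = [f for f, w in zip(panel_ids, coef) if w != 0.0]
        state = {"model": model, "mean": mean, "sd": sd}
    elif method == "LDA":
        n_feat = int(param_value)
        selected = panel_ids[: max(1, n_feat)]
        xs = expr.values.loc[selected].to_numpy(dtype=float).T
        model = LinearDiscriminantAnalysis(solver="svd")
        model.fit(xs, y)
        state = {"model": model}
    elif method == "PAM":
        delta = float(param_value)
        stats = _pam_stats(expr, panel_ids)
        dprime, shrunk = _pam_shrink(stats, delta)
        surviving = np.any(dprime != 0.0, axis=1)
        selected = [f for f, keep in zip(panel_ids, surviving) if keep]
        state = {
            "s": stats["s"], "s0": stats["s0"], "priors": stats["priors"],
            "shrunk_centroids": shrunk, "delta": delta, "surviving": surviving,
        }
    elif method == "RF-1":
        model = RandomForestClassifier(
            n_estimators=int(spec.fixed_params.get("ntree", 500)),
            max_features="sqrt",
            random_state=seed,
            n_jobs=1,
        )
        model.fit(x, y)
        state = {"model": model}
    elif method == "SVM":
        cost = float(param_value)
        xs, mean, sd = _standardize_fit(x)
        model = SVC(kernel="linear", C=cost)
        model.fit(xs, y)
        dec = model.decision_function(xs)
        # Platt-style monotone logistic map from decision values to
        # probability of case, fitted on the training fold
        cal = LogisticRegression(C=1e3, max_iter=1000)
        cal.fit(dec.reshape(-1, 1), y)
        state = {"model": model, "mean": mean, "sd": sd, "calibrator": cal}
    elif method == "XGBoost":
        rounds = int(param_value)
        model = XGBClassifier(
            n_estimators=rounds,
            max_depth=int(spec.fixed_params.get("max_depth", 2)),
            learning_rate=float(spec.fixed_params.get("learning_rate", 0.1)),
            subsample=1.0,
            colsample_bytree=1.0,
            reg_lambda=1.0,
            objective="binary:logistic",
            eval_metric="logloss",
            random_state=seed,
            n_jobs=1,
            verbosity=0,
        )
        model.fit(x, y)
        state = {"model": model}
    else:
        raise ValueError(f"unknown method: {method}")
    return TrainedModel(spec, param_value, panel_ids, selected, state)


# --- prediction --------------------------------------------------------------


def _extract(model: TrainedModel, expr: ExpressionMatrix, ids: list[str]) -> np.ndarray:
    missing = [f for f in ids if f not in expr.values.index]
    if missing:
        raise ValueError(f"features missing from prediction data: {missing[:5]}")
    return expr.values.loc[ids].to_numpy(dtype=float).T


def _predict_en(model: TrainedModel, expr: ExpressionMatrix) -> pd.Series:
    x = _extract(model, expr, model.panel_ids)
    xs = (x - model.state["mean"]) / model.state["sd"]
    p = model.state["model"].predict_proba(xs)[:, 1]
    return pd.Series(p, index=expr.sample_ids)


def _predict_lda(model: TrainedModel, expr: ExpressionMatrix) -> pd.Series:
    x = _extract(model, expr, model.selected_feature_ids)
    p = model.state["model"].predict_proba(x)[:, 1]
    return pd.Series(p, index=expr.sample_ids)


def _predict_pam(model: TrainedModel, expr: ExpressionMatrix) -> pd.Series:
    x = _extract(model, expr, model.panel_ids)
    probs = [pam_score(row, model)[1][0] for row in x]
    return pd.Series(probs, index=expr.sample_ids)


def _predict_sk(model: TrainedModel, expr: ExpressionMatrix) -> pd.Series:
    x = _extract(model, expr, model.panel_ids)
    p = model.state["model"].predict_proba(x)[:, 1]
    return pd.Series(p, index=expr.sample_ids)


def _predict_svm(model: TrainedModel, expr: ExpressionMatrix) -> pd.Series:
    x = _extract(model, expr, model.panel_ids)
    xs = (x - model.state["mean"]) / model.state["sd"]
    dec = model.state["model"].decision_function(xs)
    p = model.state["calibrator"].predict_proba(dec.reshape(-1, 1))[:, 1]
    return pd.Series(p, index=expr.sample_ids)


def model_to_text(model: TrainedModel) -> str:
    """Self-describing text dump of a trained model (method, tuned
    parameter, panel, selected features, and the per-feature coefficients
    or shrunken centroids where the method exposes them)."""
    lines = [
        f"method\t{model.spec.method}",
        f"tuned_param\t{model.spec.tuned_param_name}\t{model.param_value}",
        f"panel_size\t{len(model.panel_ids)}",
        f"selected_features\t{','.join(model.selected_feature_ids)}",
    ]
    method = model.spec.method
    if method.startswith("EN"):
        coef = model.state["model"].coef_.ravel()
        for f, w in zip(model.panel_ids, coef):
            if w != 0.0:
                lines.append(f"coef\t{f}\t{w:.6g}")
    elif method == "SVM":
        coef = model.state["model"].coef_.ravel()
        for f, w in zip(model.panel_ids, coef):
            lines.append(f"coef\t{f}\t{w:.6g}")
    elif method == "PAM":
        cent = model.state["shrunk_centroids"]
        for f, (c_case, c_ctrl) in zip(model.panel_ids, cent):
            lines.append(f"centroid\t{f}\t{c_case:.6g}\t{c_ctrl:.6g}")
    elif method == "LDA":
        coef = model.state["model"].coef_.ravel()
        for f, w in zip(model.selected_feature_ids, coef):
            lines.append(f"coef\t{f}\t{w:.6g}")
    return "\n".join(lines) + "\n"


_PREDICTORS = {
    "EN": _predict_en,
    "LDA": _predict_lda,
    "PAM": _predict_pam,
    "RF": _predict_sk,
    "SVM": _predict_svm,
    "XGBoost": _predict_sk,
}
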