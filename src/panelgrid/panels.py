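"""Ranking-and-filtering rules that turn a differential-expression table
into a candidate feature panel.

Five rule sets with pragmatic thresholds (top 50; panel size 50-500; FDR
cuts 0.05 and 0.10; absolute log2 fold-change cut 0.5):

* **FDR50** — top 50 features by FDR.
* **COMBO0.05** — all features at FDR < 0.05, padded to at least 50 with
  the next-most-significant features and truncated to at most 500.
* **FDR0.10.FC0.5** — FDR < 0.10 intersected with |log2 FC| >= 0.5
  (boundary inclusive, separately for up- and down-regulation).
* **FC0.5.TOP50** — |log2 FC| >= 0.5 first, then the 50 lowest FDR.
* **FDR0.10.RFE50** — FDR < 0.10, then a one-shot linear-SVM weight
  ranking (cost 1, features standardized on the training samples) keeping
  the 50 largest absolute weights; all inputs are returned when 50 or fewer
  pass the FDR cut.

FDR cuts are strict (<); the fold-change cut is inclusive (>=).  All rules
are deterministic given their inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .de import DEResult
from .simdata import ExpressionMatrix

RULE_NAMES = ("FDR50", "COMBO0.05", "FDR0.10.FC0.5", "FC0.5.TOP50", "FDR0.10.RFE50")


@dataclass
class Panel:
    rule: str
    feature_ids: list[str]
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.feature_ids)


def _sig_order(de: DEResult) -> list[str]:
    """Significance ordering: fdr, then p, then |logFC| descending, then id."""
    t = de.table
    key = pd.DataFrame(
        {
            "fdr": t["fdr"],
            "p": t["p"],
            "neg_abs_lfc": -t["logFC"].abs(),
        },
        index=t.index,
    )
    key["id"] = key.index
    return list(key.sort_values(["fdr", "p", "neg_abs_lfc", "id"]).index)


def rule_fdr50(de: DEResult, top: int = 50, **_) -> Panel:
    if len(de) == 0:
        raise ValueError("empty differential-expression table")
    order = _sig_order(de)
    return Panel("FDR50", order[:top], {"top": top, "n_input": len(de)})


def rule_combo(
    de: DEResult, fdr_cut: float = 0.05, min_n: int = 50, max_n: int = 500, **_
) -> Panel:
    if len(de) == 0:
        raise ValueError("empty differential-expression table")
    order = _sig_order(de)
    n_sig = int((de.table["fdr"] < fdr_cut).sum())
    n_keep = min(max(n_sig, min_n), max_n, len(order))
    return Panel(
        "COMBO0.05",
        order[:n_keep],
        {"fdr_cut": fdr_cut, "n_significant": n_sig, "min_n": min_n, "max_n": max_n},
    )


def rule_fdr_fc(de: DEResult, fdr_cut: float = 0.10, lfc_cut: float = 0.5, **_) -> Panel:
    if len(de) == 0:
        raise ValueError("empty differential-expression table")
    t = de.table
    mask = (t["fdr"] < fdr_cut) & (t["logFC"].abs() >= lfc_cut)
    order = [f for f in _sig_order(de) if mask[f]]
    return Panel(
        "FDR0.10.FC0.5",
        order,
        {"fdr_cut": fdr_cut, "lfc_cut": lfc_cut, "n_pass": len(order)},
    )


def rule_fc_top50(de: DEResult, lfc_cut: float = 0.5, top: int = 50, **_) -> Panel:
    if len(de) == 0:
        raise ValueError("empty differential-expression table")
    t = de.table
    mask = t["logFC"].abs() >= lfc_cut
    order = [f for f in _sig_order(de) if mask[f]]
    return Panel(
        "FC0.5.TOP50",
        order[:top],
        {"lfc_cut": lfc_cut, "top": top, "n_pass_fc": int(mask.sum())},
    )


def svm_weights(
    expr: ExpressionMatrix, feature_ids: list[str], cost: float = 1.0
) -> pd.Series:
    """Absolute linear-SVM coefficients for the given features, after
    per-feature standardization on the supplied samples (the scale=TRUE
    contract)."""
    x = expr.values.loc[feature_ids].to_numpy(dtype=float).T  # samples x features
    y = expr.case_mask.astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes required for the SVM weight step")
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    xs = (x - mean) / sd
    model = SVC(kernel="linear", C=cost)
    model.fit(xs, y)
    return pd.Series(np.abs(model.coef_.ravel()), index=feature_ids, name="svm_weight")


def rule_fdr_rfe50(
    de: DEResult,
    expr: ExpressionMatrix,
    fdr_cut: float = 0.10,
    top: int = 50,
    cost: float = 1.0,
    **_,
) -> Panel:
    if len(de) == 0:
        raise ValueError("empty differential-expression table")
    t = de.table
    candidates = [f for f in _sig_order(de) if t.loc[f, "fdr"] < fdr_cut]
    if not candidates:
        return Panel(
            "FDR0.10.RFE50", [], {"fdr_cut": fdr_cut, "top": top, "n_pass_fdr": 0}
        )
    weights = svm_weights(expr, candidates, cost=cost)
    # order by weight descending, ties by fdr then id
    order = sorted(
        candidates, key=lambda f: (-weights[f], t.loc[f, "fdr"], f)
    )
    return Panel(
        "FDR0.10.RFE50",
        order[:top],
        {
            "fdr_cut": fdr_cut,
            "top": top,
            "cost": cost,
            "n_pass_fdr": len(candidates),
        },
    )


def apply_rule(
    rule: str, de: DEResult, expr: ExpressionMatrix | None = None, **params
) -> Panel:
    """Dispatch by rule name; RFE50 additionally needs expression + labels
    for the SVM weight step."""
    if rule == "FDR50":
        return rule_fdr50(de, **params)
    if rule == "COMBO0.05":
        return rule_combo(de, **params)
    if rule == "FDR0.10.FC0.5":
        return rule_fdr_fc(de, **params)
    if rule == "FC0.5.TOP50":
        return rule_fc_top50(de, **params)
    if rule == "FDR0.10.RFE50":
        if expr is None:
            raise ValueError("FDR0.10.RFE50 requires expression data")
        return rule_fdr_rfe50(de, expr, **params)
    raise ValueError(f"unknown ranking rule: {rule}")
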