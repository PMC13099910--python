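"""Unsupervised pre-filters that reduce the probe-set space before any
class comparison.

Five strategies, from permissive to restrictive:

* **ECMR** — keep the half of features with the largest inter-quartile
  range (classes pooled; the filter is label-blind).
* **PVAC** — keep probe-sets whose probe-level profiles agree across
  arrays, scored as the share of the row-centered block's variance captured
  by its first principal direction.
* **BI2005** — clamp log2 values below 5 up to 5, then keep features whose
  clamped maximum is at least 7.25.
* **FARMS-style informative/non-informative call** — a penalized one-factor
  model fitted to each probe block by alternating least squares; a set is
  informative when the factor explains enough of the probe variance.  The
  selection contract of the original Bayesian factor-analysis filter is
  preserved with a simpler, fully documented statistic.
* **PROOF1** — an ordered conjunction of configurable rules (expression
  cutoffs, annotation whitelists, within-class robustness), standing in for
  a semi-automated biologically motivated filter.

Every filter is deterministic given its input and parameters; ties break on
lexicographic feature id.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .simdata import CASE_LABEL, ExpressionMatrix, ProbeLevelCollection, ProbeLevelSet


@dataclass
class PrefilterResult:
    method: str
    retained_ids: list[str]
    scores: pd.Series  # per-feature criterion value
    params: dict
    # BI2005 defines its own analysis matrix (clamped); others pass through
    matrix: ExpressionMatrix | None = None

    def analysis_matrix(self, expr: ExpressionMatrix) -> ExpressionMatrix:
        """The analysis data set this filter defines: retained features of
        the (possibly transformed) matrix."""
        base = self.matrix if self.matrix is not None else expr
        return base.subset_features(self.retained_ids)


def ecmr(expr: ExpressionMatrix, retain_fraction: float = 0.5) -> PrefilterResult:
    """Empirical central mass range filter: top-IQR half of all features."""
    if expr.values.shape[1] < 4:
        raise ValueError("IQR pre-filter needs >= 4 samples")
    q75 = expr.values.quantile(0.75, axis=1)
    q25 = expr.values.quantile(0.25, axis=1)
    iqr = q75 - q25
    n_keep = int(np.floor(retain_fraction * len(iqr)))
    # sort by IQR descending, ties by id ascending
    order = sorted(iqr.index, key=lambda f: (-iqr[f], f))
    retained = sorted(order[:n_keep])
    return PrefilterResult(
        "ECMR", retained, iqr, {"retain_fraction": retain_fraction}
    )


def bi2005(
    expr: ExpressionMatrix,
    clamp_floor: float = 5.0,
    max_threshold: float = 7.25,
) -> PrefilterResult:
    """Clamp low values to the floor, keep features whose clamped maximum
    reaches the threshold (boundary inclusive)."""
    clamped = expr.values.clip(lower=clamp_floor)
    maxima = clamped.max(axis=1)
    retained = sorted(maxima.index[maxima >= max_threshold])
    return PrefilterResult(
        "BI2005",
        retained,
        maxima,
        {"clamp_floor": clamp_floor, "max_threshold": max_threshold},
        matrix=ExpressionMatrix(clamped, expr.labels),
    )


def pvac_score(block: ProbeLevelSet) -> float:
    """Share of a row-centered probe block's variance on its first
    principal direction across arrays; 1 for a rank-one (perfectly
    consistent) block, ~1/min(probes, arrays) for independent probe noise."""
    x = np.asarray(block.values, dtype=float)
    if x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need >= 2 probes and >= 2 arrays")
    centered = x - x.mean(axis=1, keepdims=True)
    sv = np.linalg.svd(centered, compute_uv=False)
    total = np.sum(sv**2)
    if total == 0.0:
        return 1.0
    return float(sv[0] ** 2 / total)


def pvac(
    collection: ProbeLevelCollection | None, threshold: float = 0.5
) -> PrefilterResult:
    if collection is None or len(collection) == 0:
        raise ValueError("probe-level data required for the PVAC pre-filter")
    scores = pd.Series(
        {b.probeset_id: pvac_score(b) for b in collection}, name="pvac"
    )
    retained = sorted(scores.index[scores >= threshold])
    return PrefilterResult("PVAC", retained, scores, {"threshold": threshold})


def farms_score(
    block: ProbeLevelSet,
    ridge: float = 0.1,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> float:
    """Informativeness of a probe block under a penalized one-factor model.

    Fits value(p, j) = mean_p + loading_p * z_j + eps by alternating least
    squares with a quadratic (ridge) penalty on the loadings, then scores
    var(loading * z) / (var(loading * z) + mean residual variance).  Returns
    0.0 (non-informative) if the fit does not converge within ``max_iter``.
    """
    x = np.asarray(block.values, dtype=float)
    if x.shape[0] < 2:
        raise ValueError("need >= 2 probes")
    centered = x - x.mean(axis=1, keepdims=True)
    n_probes, n_arrays = centered.shape
    # first right singular vector as starting factor; the factor is kept at
    # unit norm each sweep to pin down the scale indeterminacy of the
    # bilinear fit
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    z = vt[0]
    fitted = np.zeros_like(centered)
    converged = False
    for _ in range(max_iter):
        lam = centered @ z / (z @ z + ridge)
        denom = lam @ lam
        if denom == 0.0:
            return 0.0
        z = centered.T @ lam / denom
        norm = np.linalg.norm(z)
        if norm == 0.0:
            return 0.0
        z /= norm
        lam = centered @ z / (z @ z + ridge)
        new_fitted = np.outer(lam, z)
        delta = float(np.max(np.abs(new_fitted - fitted)))
        fitted = new_fitted
        if delta < tol:
            converged = True
            break
    if not converged:
        return 0.0
    signal_var = float(np.var(fitted))
    resid_var = float(np.mean((centered - fitted) ** 2))
    if signal_var + resid_var == 0.0:
        return 1.0
    return signal_var / (signal_var + resid_var)


def farms_ini(block: ProbeLevelSet, threshold: float = 0.5) -> bool:
    """Informative / non-informative call for one probe-set."""
    return farms_score(block) >= threshold


def farms(
    collection: ProbeLevelCollection | None, threshold: float = 0.5
) -> PrefilterResult:
    if collection is None or len(collection) == 0:
        raise ValueError("probe-level data required for the FARMS-style pre-filter")
    scores = pd.Series(
        {b.probeset_id: farms_score(b) for b in collection}, name="farms"
    )
    retained = sorted(scores.index[scores >= threshold])
    return PrefilterResult("FARMS", retained, scores, {"threshold": threshold})


# --- PROOF1 rule chain ------------------------------------------------------


@dataclass
class ExpressionCutoffRule:
    """Keep features where >= ``min_fraction`` of samples reach ``cutoff``."""

    cutoff: float
    min_fraction: float

    def apply(self, expr: ExpressionMatrix, annotation: pd.DataFrame | None) -> pd.Series:
        frac = (expr.values >= self.cutoff).mean(axis=1)
        return frac >= self.min_fraction


@dataclass
class AnnotationWhitelistRule:
    """Keep features whose annotation ``field`` is one of ``allowed``."""

    field: str
    allowed: Sequence[str]

    def apply(self, expr: ExpressionMatrix, annotation: pd.DataFrame | None) -> pd.Series:
        if annotation is None or self.field not in annotation.columns:
            raise ValueError(f"annotation field {self.field!r} unavailable")
        allowed = set(self.allowed)
        ok = annotation[self.field].isin(allowed)
        return pd.Series(
            [bool(ok.get(f, False)) for f in expr.feature_ids],
            index=expr.feature_ids,
        )


@dataclass
class RobustnessRule:
    """Keep features whose within-class coefficient of variation (on the
    log2 scale) stays below ``max_cv`` in both classes."""

    max_cv: float

    def apply(self, expr: ExpressionMatrix, annotation: pd.DataFrame | None) -> pd.Series:
        case = expr.case_mask
        keep = pd.Series(True, index=expr.feature_ids)
        for mask in (case, ~case):
            sub = expr.values.loc[:, mask]
            mean = sub.mean(axis=1)
            sd = sub.std(axis=1, ddof=1)
            cv = sd / mean.abs().replace(0.0, np.nan)
            keep &= (cv <= self.max_cv).fillna(False)
        return keep


ProofRule = ExpressionCutoffRule | AnnotationWhitelistRule | RobustnessRule


def default_proof1_rules() -> list[ProofRule]:
    """Shipped default chain: a moderately high expression floor plus a
    within-class stability requirement, sized to retain on the order of 10%
    of a default synthetic cohort."""
    return [
        ExpressionCutoffRule(cutoff=9.0, min_fraction=0.75),
        RobustnessRule(max_cv=0.25),
    ]


def proof1(
    expr: ExpressionMatrix,
    annotation: pd.DataFrame | None = None,
    rules: Sequence[ProofRule] | None = None,
) -> PrefilterResult:
    if rules is None:
        rules = default_proof1_rules()
    if not rules:
        raise ValueError("PROOF1 requires a non-empty rule chain")
    passed = pd.Series(True, index=expr.feature_ids)
    stage_counts = []
    for rule in rules:
        if not isinstance(rule, (ExpressionCutoffRule, AnnotationWhitelistRule, RobustnessRule)):
            raise ValueError(f"unknown rule type: {type(rule).__name__}")
        passed &= rule.apply(expr, annotation).reindex(expr.feature_ids).fillna(False)
        stage_counts.append(int(passed.sum()))
    retained = sorted(passed.index[passed])
    return PrefilterResult(
        "PROOF1",
        retained,
        passed.astype(int),
        {"rules": [type(r).__name__ for r in rules], "stage_counts": stage_counts},
    )


def run_all(
    expr: ExpressionMatrix,
    collection: ProbeLevelCollection | None = None,
    annotation: pd.DataFrame | None = None,
    pvac_threshold: float = 0.5,
    farms_threshold: float = 0.5,
    proof1_rules: Sequence[ProofRule] | None = None,
) -> dict[str, PrefilterResult]:
    """All five filters on one cohort (PVAC/FARMS only when probe-level data
    are supplied)."""
    results = {
        "ECMR": ecmr(expr),
        "BI2005": bi2005(expr),
        "PROOF1": proof1(expr, annotation, proof1_rules),
    }
    if collection is not None:
        results["PVAC"] = pvac(collection, pvac_threshold)
        results["FARMS"] = farms(collection, farms_threshold)
    return results


def overlap_table(results: Sequence[PrefilterResult], all_ids: Sequence[str] | None = None) -> dict:
    """Union/intersection/pairwise-overlap accounting across filters."""
    if len(results) < 2:
        raise ValueError("need >= 2 pre-filter results")
    sets = {r.method: set(r.retained_ids) for r in results}
    union = set().union(*sets.values())
    inter = set.intersection(*sets.values())
    pairwise = {}
    methods = list(sets)
    for i, a in enumerate(methods):
        for b in methods[i + 1 :]:
            pairwise[(a, b)] = len(sets[a] & sets[b])
    unique = {
        m: len(sets[m] - set().union(*(sets[o] for o in methods if o != m)))
        for m in methods
    }
    out = {
        "sizes": {m: len(s) for m, s in sets.items()},
        "union": len(union),
        "intersection": len(inter),
        "pairwise": pairwise,
        "unique": unique,
    }
    if all_ids is not None:
        out["excluded_by_all"] = len(set(all_ids) - union)
    return out
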