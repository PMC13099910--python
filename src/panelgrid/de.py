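"""Moderated two-group differential expression.

Per feature g, with pooled residual variance s_g^2 on d_g = n - 2 degrees
of freedom, the residual variances are modelled as scaled F draws around a
prior (d0, s0^2).  The prior is estimated by the standard method of moments
on log s_g^2 (matching the mean and variance of the log residual variances
to the moments a log-F distribution implies), the per-feature variance is
shrunk to

    s~_g^2 = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g)

and the moderated statistic t_g = logFC_g / (s~_g * sqrt(1/n1 + 1/n2)) is
referred to a t distribution on d0 + d_g degrees of freedom.  Benjamini-
Hochberg step-up adjustment turns the two-sided p-values into FDR values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .simdata import CASE_LABEL, ExpressionMatrix


@dataclass
class DEResult:
    table: pd.DataFrame  # per-feature statistics, original feature order
    d0: float  # prior degrees of freedom
    s0_2: float  # prior variance

    def __len__(self) -> int:
        return len(self.table)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.table.index)


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("need a non-empty 1-d p-value vector")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton iteration, as used by the
    standard empirical-Bayes variance-prior fit)."""
    if x <= 0:
        return np.inf
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of the (d0, s0^2) variance prior on log s^2.

    With z = log(s^2), E[z] and Var[z] under the scaled-F model are
    digamma/trigamma expressions in d0 and df; matching the empirical
    moments gives d0 via a trigamma inversion and s0^2 in closed form.
    Returns (inf, exp(mean)) when the residual spread is no larger than the
    sampling spread (no feature-specific variance component).
    """
    s2 = np.asarray(s2, dtype=float)
    pos = s2[s2 > 0]
    if pos.size == 0:
        raise ValueError("all residual variances are zero")
    floor = pos.min() * 1e-6
    z = np.log(np.maximum(s2, floor))
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1)) if e.size > 1 else 0.0
    evar = e_var - float(special.polygamma(1, df / 2.0))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_2 = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s0_2 = float(np.exp(e_mean))
    return d0, s0_2


def moderated_t(
    expr: ExpressionMatrix,
    d0_override: float | None = None,
    s0_2_override: float | None = None,
) -> DEResult:
    """Two-group moderated t-test over all features of ``expr``.

    logFC is case minus control on the log2 scale.  ``d0_override`` /
    ``s0_2_override`` replace the estimated prior (0 weight disables
    shrinkage entirely, recovering the ordinary pooled t).
    """
    case = expr.case_mask
    n1 = int(case.sum())
    n2 = int((~case).sum())
    if n1 < 2 or n2 < 2:
        raise ValueError("both classes need >= 2 samples")
    x = expr.values.to_numpy(dtype=float)
    xc = x[:, case]
    xn = x[:, ~case]
    mean_case = xc.mean(axis=1)
    mean_control = xn.mean(axis=1)
    logfc = mean_case - mean_control
    df = n1 + n2 - 2
    s2 = ((xc.var(axis=1, ddof=1) * (n1 - 1)) + (xn.var(axis=1, ddof=1) * (n2 - 1))) / df

    if d0_override is None:
        d0, s0_2 = fit_variance_prior(s2, df)
    else:
        d0 = float(d0_override)
        s0_2 = float(s0_2_override) if s0_2_override is not None else float(np.mean(s2))

    if np.isinf(d0):
        s2_shrunk = np.full_like(s2, s0_2)
        df_total = np.inf
    elif d0 == 0.0:
        s2_shrunk = s2
        df_total = df
    else:
        s2_shrunk = (d0 * s0_2 + df * s2) / (d0 + df)
        df_total = d0 + df
    denom = np.sqrt(s2_shrunk * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = np.where(denom > 0, logfc / denom, 0.0)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t_mod))
    else:
        p = 2.0 * stats.t.sf(np.abs(t_mod), df_total)
    p = np.clip(p, 0.0, 1.0)
    fdr = bh_adjust(p)
    table = pd.DataFrame(
        {
            "mean_case": mean_case,
            "mean_control": mean_control,
            "logFC": logfc,
            "s2": s2,
            "df_residual": float(df),
            "t_mod": t_mod,
            "p": p,
            "fdr": fdr,
            "direction": np.where(logfc > 0, "Up", "Down"),
        },
        index=expr.values.index,
    )
    return DEResult(table, float(d0), float(s0_2))


def fold_change_from_means(mean_case: float, mean_control: float) -> tuple[float, str]:
    """Natural-scale fold-change magnitude and direction from log2 group
    means: (2^|diff|, 'Up' if case mean is higher else 'Down')."""
    if not (np.isfinite(mean_case) and np.isfinite(mean_control)):
        raise ValueError("group means must be finite")
    diff = mean_case - mean_control
    return float(2.0 ** abs(diff)), ("Up" if diff > 0 else "Down")


def volcano_table(de: DEResult, fdr_cut: float = 0.05) -> pd.DataFrame:
    """logFC vs -log10 p with a significance flag, ready for plotting."""
    t = de.table
    with np.errstate(divide="ignore"):
        neglog = -np.log10(t["p"].to_numpy())
    return pd.DataFrame(
        {
            "logFC": t["logFC"],
            "neg_log10_p": neglog,
            "significant": t["fdr"] < fdr_cut,
        },
        index=t.index,
    )


def row_standardize(expr: ExpressionMatrix, feature_ids=None) -> pd.DataFrame:
    """Center and unit-scale each feature row (constant rows become zeros);
    the transform behind row-standardized cluster heatmaps."""
    values = expr.values if feature_ids is None else expr.values.loc[list(feature_ids)]
    x = values.to_numpy(dtype=float)
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, (x - mean) / sd, 0.0)
    return pd.DataFrame(z, index=values.index, columns=values.columns)
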