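"""Cross-panel aggregation and biological reporting.

Collects the final feature panels of every (pre-filter, rule, classifier)
combination into a binary inclusion matrix, ranks features by how often
they recur, summarizes them with group means and natural-scale fold-
changes, summarizes the sample x combination probability matrix, and runs
hypergeometric over-representation analysis of candidate gene lists
against GMT gene-set collections with Benjamini-Hochberg correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .de import DEResult, bh_adjust, fold_change_from_means
from .simdata import CASE_LABEL

UNANNOTATED = "---"


@dataclass
class InclusionMatrix:
    matrix: pd.DataFrame  # features x combination labels, 0/1
    counts: pd.Series
    fractions: pd.Series

    @property
    def n_combinations(self) -> int:
        return self.matrix.shape[1]


def build_inclusion(panels: dict[str, list[str]]) -> InclusionMatrix:
    """Binary features x combinations matrix over the union of all final
    panel members (features never selected do not appear)."""
    if not panels:
        raise ValueError("need at least one panel")
    features = sorted(set().union(*[set(v) for v in panels.values()]))
    mat = pd.DataFrame(0, index=features, columns=list(panels), dtype=int)
    for label, members in panels.items():
        mat.loc[sorted(set(members)), label] = 1
    counts = mat.sum(axis=1)
    fractions = counts / mat.shape[1]
    return InclusionMatrix(mat, counts, fractions)


def frequency_filter(incl: InclusionMatrix, min_fraction: float = 0.25) -> list[str]:
    """Features recurring in at least ``min_fraction`` of combinations,
    ordered by count descending then id."""
    keep = incl.fractions[incl.fractions >= min_fraction]
    return sorted(keep.index, key=lambda f: (-incl.counts[f], f))


def gene_summary(
    incl: InclusionMatrix, de: DEResult, annotation: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Recurring-feature summary: gene symbol/title, group means, natural-
    scale fold-change magnitude with direction, and inclusion count and
    fraction, ordered by count descending."""
    rows = []
    t = de.table
    for f in incl.matrix.index:
        if f in t.index:
            mc, mn = float(t.loc[f, "mean_case"]), float(t.loc[f, "mean_control"])
            fc, direction = fold_change_from_means(mc, mn)
        else:
            mc = mn = fc = np.nan
            direction = ""
        if annotation is not None and f in annotation.index:
            symbol = annotation.loc[f, "gene_symbol"]
            title = annotation.loc[f, "gene_title"]
        else:
            symbol = title = UNANNOTATED
        rows.append(
            {
                "feature_id": f,
                "gene_symbol": symbol,
                "gene_title": title,
                "mean_case": round(mc, 2) if np.isfinite(mc) else np.nan,
                "mean_control": round(mn, 2) if np.isfinite(mn) else np.nan,
                "fold_change": round(fc, 2) if np.isfinite(fc) else np.nan,
                "direction": direction,
                "count": int(incl.counts[f]),
                "fraction": round(float(incl.fractions[f]), 2),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "feature_id", "gene_symbol", "gene_title", "mean_case",
            "mean_control", "fold_change", "direction", "count", "fraction",
        ],
    )
    return df.sort_values(
        ["count", "feature_id"], ascending=[False, True]
    ).reset_index(drop=True)


def score_summaries(
    score_matrix: pd.DataFrame, labels: pd.Series, threshold: float = 0.5
) -> pd.DataFrame:
    """Per-sample score distribution across combinations, flagging samples
    whose median probability-of-case falls on the wrong side of the
    threshold for their true class."""
    med = score_matrix.median(axis=1)
    q1 = score_matrix.quantile(0.25, axis=1)
    q3 = score_matrix.quantile(0.75, axis=1)
    lab = labels.loc[score_matrix.index]
    is_case = lab == CASE_LABEL
    discordant = np.where(is_case, med < threshold, med >= threshold)
    return pd.DataFrame(
        {
            "class": lab,
            "median": med,
            "iqr": q3 - q1,
            "frac_called_case": (score_matrix >= threshold).mean(axis=1),
            "discordant": discordant,
        },
        index=score_matrix.index,
    )


def enrich(
    gene_list,
    universe,
    sets: dict[str, list[str]],
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``gene_list`` in each gene
    set, against ``universe`` (sets are intersected with the universe
    first).

    Per set of size K in a universe of N, with n candidate genes of which k
    land in the set, p is the upper-tail probability of >= k overlaps.  The
    gene ratio is k over the number of candidate genes mapped to any set;
    BH adjustment runs across all tested sets.
    """
    universe = set(universe)
    mapped = set(gene_list) & universe
    if not mapped:
        raise ValueError("no candidate genes map to the universe")
    trimmed = {name: set(members) & universe for name, members in sets.items()}
    in_any = mapped & set().union(*trimmed.values()) if trimmed else set()
    denom = max(len(in_any), 1)
    rows = []
    for name, members in trimmed.items():
        k = len(mapped & members)
        big_k = len(members)
        p = float(hypergeom.sf(k - 1, len(universe), big_k, len(mapped)))
        rows.append(
            {
                "set": name,
                "overlap": k,
                "set_size": big_k,
                "gene_ratio": k / denom,
                "p": min(p, 1.0),
            }
        )
    df = pd.DataFrame(rows)
    df["fdr"] = bh_adjust(df["p"].to_numpy())
    return df.sort_values(["p", "set"]).reset_index(drop=True)
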