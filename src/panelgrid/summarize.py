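"""RMA-style probe-set summarization.

Quantile normalization equalizes the value distribution across arrays, then
Tukey's median polish sweeps probe (row) and array (column) effects out of
each probe-set block; the per-array summary is the overall effect plus the
array's column effect.  The convolution background-correction step of the
full RMA recipe is deliberately not part of this module: inputs here are
already on the log2 scale.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .simdata import (
    CASE_LABEL,
    ExpressionMatrix,
    ProbeLevelCollection,
    ProbeLevelSet,
)


def quantile_normalize(matrix: np.ndarray | pd.DataFrame) -> np.ndarray | pd.DataFrame:
    """Map every column onto the across-column mean of sorted values.

    Ties within a column receive the mean of the reference distribution over
    their rank span (dense mid-rank convention), so columns with tied values
    still end up with the same multiset as untied columns up to tie
    averaging.
    """
    is_df = isinstance(matrix, pd.DataFrame)
    x = matrix.to_numpy(dtype=float) if is_df else np.asarray(matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 1 or x.shape[1] < 2:
        raise ValueError("need a features x arrays matrix with >= 2 arrays")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values in input")
    order = np.argsort(x, axis=0, kind="stable")
    reference = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    n = x.shape[0]
    ranks = np.empty(n, dtype=np.intp)
    for j in range(x.shape[1]):
        col = x[:, j]
        ranks[order[:, j]] = np.arange(n)
        mapped = reference[ranks]
        # average the reference over spans of tied input values
        uniq, inv = np.unique(col, return_inverse=True)
        if len(uniq) < n:
            sums = np.bincount(inv, weights=mapped, minlength=len(uniq))
            counts = np.bincount(inv, minlength=len(uniq))
            mapped = (sums / counts)[inv]
        out[:, j] = mapped
    if is_df:
        return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)
    return out


def median_polish(
    values: np.ndarray, max_iter: int = 10, tol: float = 0.01
) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    """Tukey's median polish of a probes x arrays block.

    Alternately sweeps row then column medians out of the residuals until
    the largest absolute change falls below ``tol`` or ``max_iter`` full
    sweeps.  Returns (overall, row_effects, col_effects, residuals).
    """
    z = np.asarray(values, dtype=float).copy()
    if z.ndim != 2 or z.size == 0:
        raise ValueError("need a non-empty 2-d block")
    nr, nc = z.shape
    overall = 0.0
    row = np.zeros(nr)
    col = np.zeros(nc)
    for _ in range(max_iter):
        rmed = np.median(z, axis=1)
        z -= rmed[:, None]
        row += rmed
        cmed_of_row = np.median(row)
        row -= cmed_of_row
        overall += cmed_of_row

        cmed = np.median(z, axis=0)
        z -= cmed[None, :]
        col += cmed
        rmed_of_col = np.median(col)
        col -= rmed_of_col
        overall += rmed_of_col
        delta = max(np.max(np.abs(rmed)), np.max(np.abs(cmed)))
        if delta < tol:
            break
    return overall, row, col, z


def median_polish_summarize(
    block: ProbeLevelSet, max_iter: int = 10, tol: float = 0.01
) -> np.ndarray:
    """Per-array summary of one probe-set: overall + column effects."""
    overall, _, col, _ = median_polish(block.values, max_iter=max_iter, tol=tol)
    return overall + col


def summarize_collection(
    collection: ProbeLevelCollection,
    labels: pd.Series,
    normalize: bool = True,
    max_iter: int = 10,
    tol: float = 0.01,
) -> ExpressionMatrix:
    """Quantile-normalize all probes jointly, then polish each probe-set.

    ``labels`` must cover the collection's arrays; the result is the
    features x samples matrix every downstream stage consumes.
    """
    if len(collection) == 0:
        raise ValueError("empty probe-level collection")
    arrays = collection.arrays
    for block in collection:
        if block.arrays != arrays:
            raise ValueError("all blocks must share the identical array list")
    stacked = np.vstack([b.values for b in collection])
    if normalize:
        stacked = quantile_normalize(stacked)
    summaries = []
    offset = 0
    for block in collection:
        k = len(block.probe_ids)
        chunk = stacked[offset : offset + k]
        overall, _, col, _ = median_polish(chunk, max_iter=max_iter, tol=tol)
        summaries.append(overall + col)
        offset += k
    values = pd.DataFrame(
        np.vstack(summaries),
        index=[b.probeset_id for b in collection],
        columns=arrays,
    )
    return ExpressionMatrix(values, labels.loc[arrays])
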