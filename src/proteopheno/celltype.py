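"""Cell-type specificity calls and set enrichment.

A gene is called specific to a cell type when that cell type carries more
than 50% (strictly) of the gene's sum-total expression.  Enrichment of a
target protein set against the platform background is the ratio of
specific-gene fractions (fold change) with a hypergeometric upper-tail
p-value: the probability of drawing at least the observed number of
specific genes in a sample of the target's size from the background
composition.  Fisher's one-sided exact test on the same 2x2 table gives
the identical tail and is exposed as an alias.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["CellTypeCall", "EnrichmentResult", "assign_specificity", "enrichment"]


@dataclass
class EnrichmentResult:
    cell_type: str
    target_specific: int
    target_size: int
    background_specific: int
    background_size: int
    fold_change: float
    p: float
    flag: str = ""


def assign_specificity(expression: pd.DataFrame) -> pd.DataFrame:
    """Per-gene expression shares and the >50% specificity call.

    expression: genes x cell types, nonnegative.  Returns a frame with one
    share column per cell type and a 'call' column holding the specific
    cell type or 'none' (all-zero genes are 'none' with a flag).
    """
    if expression.shape[1] < 2:
        raise ValueError("need at least 2 cell types")
    if (expression.to_numpy() < 0).any():
        raise ValueError("expression must be nonnegative")
    totals = expression.sum(axis=1)
    shares = expression.div(totals.replace(0.0, np.nan), axis=0)
    call = pd.Series("none", index=expression.index, dtype=object)
    flag = pd.Series("", index=expression.index, dtype=object)
    nonzero = totals > 0
    top = shares.loc[nonzero].max(axis=1)
    argtop = shares.loc[nonzero].idxmax(axis=1)
    # strict "more than 50%": a share of exactly one half (up to float
    # rounding of the normalization) is not specific
    call.loc[nonzero] = np.where(top > 0.5 + 1e-9, argtop, "none")
    flag.loc[~nonzero] = "zero_expression"
    out = shares.fillna(0.0).copy()
    out["call"] = call
    out["flag"] = flag
    return out


def enrichment(
    target_genes,
    background_genes,
    calls: pd.DataFrame,
    cell_type: str,
) -> EnrichmentResult:
    """Fold-change and hypergeometric enrichment of ``cell_type``-specific
    genes in the target set relative to the background.

    target must be a subset of background; calls must cover the background
    (the 'call' column of :func:`assign_specificity`).
    """
    target = pd.Index(target_genes).unique()
    background = pd.Index(background_genes).unique()
    if not target.isin(background).all():
        raise ValueError("target genes must be a subset of the background")
    missing = background.difference(calls.index)
    if len(missing):
        raise ValueError(f"calls missing for background genes: {list(missing)[:5]}")
    spec = calls.loc[background, "call"] == cell_type
    K = int(spec.sum())  # specific in background
    N = len(background)
    n = len(target)
    k = int(spec.loc[target].sum())  # specific in target
    if K == 0:
        return EnrichmentResult(cell_type, k, n, K, N, np.nan, np.nan, flag="no_specific_in_background")
    fc = (k / n) / (K / N)
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return EnrichmentResult(cell_type, k, n, K, N, fc, p)


# identical upper tail; provided for users who think in terms of the 2x2 table
def fisher_enrichment(target_genes, background_genes, calls, cell_type) -> EnrichmentResult:
    res = enrichment(target_genes, background_genes, calls, cell_type)
    if res.flag:
        return res
    table = np.array(
        [
            [res.target_specific, res.target_size - res.target_specific],
            [
                res.background_specific - res.target_specific,
                (res.background_size - res.target_size)
                - (res.background_specific - res.target_specific),
            ],
        ]
    )
    _, p = stats.fisher_exact(table, alternative="greater")
    res.p = float(p)
    return res
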