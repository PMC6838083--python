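"""geNorm and NormFinder stability rankings, for comparison with the
clique-based selection.

Both operate on averaged Cq values treated directly as log2-scale
expression (100 % efficiency), so a "log ratio" of two genes is simply the
difference of their Cq values.

**geNorm** scores gene j with M_j, the average over all partner genes k of
the across-sample SD of (Cq_j - Cq_k); the gene with the largest M is
removed and M recomputed, until two genes remain — these form the
(unordered) best pair.  Lower M = more stable.

**NormFinder** fits a two-way model to sample-centred Cq values: for each
gene and group it estimates an intra-group variance and an inter-group
bias, shrinks the bias towards zero in proportion to its sampling noise,
and scores each gene with the group-average of |shrunken bias| plus its
posterior SD.  Lower = more stable.  Unlike geNorm it uses the group
labels, and partially accounts for compositionality through the per-sample
centring.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cq_data import CqDataError, CqMatrix

__all__ = ["StabilityRanking", "genorm_rank", "normfinder_rank",
           "compare_selections"]


@dataclass
class StabilityRanking:
    """Per-gene stability values and the induced ranking (best first).

    ``table`` has columns ``gene, stability, rank``; ``ranking`` lists genes
    most-stable first.  For geNorm the first two entries form an unordered
    best pair (reported alphabetically, both with rank 1) and
    ``exclusion_trace`` records the stepwise removal order (worst first).
    """

    method: str
    table: pd.DataFrame
    ranking: list[str]
    exclusion_trace: list[str] | None = None


def _values_frame(matrix) -> pd.DataFrame:
    if isinstance(matrix, CqMatrix):
        return matrix.values
    return pd.DataFrame(matrix)


def _genorm_m(values: pd.DataFrame, strict: bool) -> pd.Series:
    """M value of every gene: mean over partners of SD of pairwise differences.

    Pairwise-complete samples are used per pair; ``strict`` refuses missing
    cells instead.
    """
    if strict and values.isna().any().any():
        raise CqDataError("missing Cq values (strict mode)")
    genes = list(values.columns)
    arr = values.to_numpy(dtype=float)
    m = {}
    for j, gj in enumerate(genes):
        sds = []
        for k, gk in enumerate(genes):
            if k == j:
                continue
            d = arr[:, j] - arr[:, k]
            d = d[~np.isnan(d)]
            if len(d) >= 2:
                sds.append(np.std(d, ddof=1))
        if not sds:
            raise CqDataError(
                f"gene {gj!r} shares fewer than 2 complete samples with "
                "every partner")
        m[gj] = float(np.mean(sds))
    return pd.Series(m)


def genorm_rank(matrix, strict: bool = False) -> StabilityRanking:
    """geNorm stepwise stability ranking.

    Repeatedly removes the gene with the largest M (ties broken by removing
    the lexicographically last gene) and recomputes M on the remainder until
    two genes are left.  The reported stability of each gene is its M at the
    step of its removal; the final two genes share the M of the 2-gene set
    (which is just the SD of their difference) and are tied best.
    """
    values = _values_frame(matrix)
    if values.shape[1] < 3:
        raise CqDataError("geNorm needs at least 3 genes")
    remaining = values.copy()
    removal: list[str] = []
    stability: dict[str, float] = {}
    while remaining.shape[1] > 2:
        m = _genorm_m(remaining, strict)
        worst_value = m.max()
        worst = max(g for g in m.index if m[g] == worst_value)
        stability[worst] = float(m[worst])
        removal.append(worst)
        remaining = remaining.drop(columns=[worst])
    m_final = _genorm_m(remaining, strict)
    pair = sorted(remaining.columns)
    for g in pair:
        stability[g] = float(m_final[g])

    ranking = pair + removal[::-1]
    ranks = {g: (1 if g in pair else i + 1)
             for i, g in enumerate(ranking)}
    table = pd.DataFrame({
        "gene": ranking,
        "stability": [stability[g] for g in ranking],
        "rank": [ranks[g] for g in ranking],
    })
    return StabilityRanking(method="geNorm", table=table, ranking=ranking,
                            exclusion_trace=removal)


def normfinder_rank(matrix, groups=None, strict: bool = False) -> StabilityRanking:
    """NormFinder model-based stability values (two-group design).

    The model needs a complete matrix; missing cells are imputed with the
    mean of the same gene within the same group (``strict`` refuses missing
    cells instead).  Each group must have at least 3 samples for the
    variance estimates to be defined.
    """
    if isinstance(matrix, CqMatrix):
        values = matrix.values
        if groups is None:
            groups = matrix.groups
    else:
        values = pd.DataFrame(matrix)
        if groups is None:
            raise CqDataError("group labels are required for NormFinder")
    groups = pd.Series(np.asarray(groups), index=values.index)
    levels = list(dict.fromkeys(groups))
    if len(levels) != 2:
        raise CqDataError(
            f"NormFinder (grouped variant) requires exactly 2 groups, "
            f"got {levels!r}")
    n_genes = values.shape[1]
    if n_genes < 3:
        raise CqDataError("NormFinder needs at least 3 genes")

    if values.isna().any().any():
        if strict:
            raise CqDataError("missing Cq values (strict mode)")
        values = values.copy()
        for level in levels:
            mask = (groups == level).to_numpy()
            sub = values.loc[mask]
            if sub.notna().sum().min() == 0:
                gene = sub.columns[sub.notna().sum() == 0][0]
                raise CqDataError(
                    f"gene {gene!r} has no usable value in group {level!r}")
            values.loc[mask] = sub.fillna(sub.mean())

    genes = list(values.columns)
    k = 2
    # centre each sample across genes: removes the compositional loading
    y = values.to_numpy(dtype=float)
    y = y - y.mean(axis=1, keepdims=True)

    ybar = np.empty((k, n_genes))
    s2 = np.empty((k, n_genes))
    n_g = np.empty(k, dtype=int)
    for gi, level in enumerate(levels):
        sub = y[(groups == level).to_numpy()]
        n_g[gi] = sub.shape[0]
        if n_g[gi] < 3:
            raise CqDataError(
                f"group {level!r} has fewer than 3 complete samples")
        ybar[gi] = sub.mean(axis=0)
        s2[gi] = sub.var(axis=0, ddof=1)

    # unbiased per-gene, per-group variance: centring across n genes makes
    # the naive variances correlated, corrected by the n/(n-2) factor
    n = n_genes
    sigma2 = (s2 - s2.sum(axis=1, keepdims=True) / (n * (n - 1))) * n / (n - 2)
    sigma2 = np.maximum(sigma2, 0.0)

    d = ybar - ybar.mean(axis=0, keepdims=True)  # inter-group bias, sums to 0
    samp_var = sigma2 / n_g[:, None]
    gamma2 = (d ** 2).sum() / ((n - 1) * (k - 1)) - samp_var.mean()
    gamma2 = max(gamma2, 0.0)

    if gamma2 > 0:
        shrink = gamma2 / (gamma2 + samp_var)
    else:
        shrink = np.zeros_like(samp_var)
    d_tilde = d * shrink
    post_var = samp_var * shrink
    rho = (np.abs(d_tilde) + np.sqrt(post_var)).mean(axis=0)

    order = np.lexsort((genes, rho))
    ranking = [genes[i] for i in order]
    table = pd.DataFrame({
        "gene": ranking,
        "stability": rho[order],
        "rank": np.arange(1, n_genes + 1),
    })
    return StabilityRanking(method="NormFinder", table=table, ranking=ranking)


def compare_selections(selection, rankings: list[StabilityRanking]) -> pd.DataFrame:
    """Positions of the clique-selected genes within each stability ranking.

    For each ranking, reports the rank of every selected gene and the size
    of the overlap between the selection and the ranking's top-k, with k the
    selection size.
    """
    selected = list(selection.selected)
    k = len(selected)
    rows = []
    for ranking in rankings:
        pos = {g: i + 1 for i, g in enumerate(ranking.ranking)}
        top_k = set(ranking.ranking[:k])
        overlap = len(top_k & set(selected))
        for gene in selected:
            rows.append({
                "method": ranking.method,
                "gene": gene,
                "rank": pos.get(gene, np.nan),
                "selection_size": k,
                "top_k_overlap": overlap,
            })
    return pd.DataFrame(rows)
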