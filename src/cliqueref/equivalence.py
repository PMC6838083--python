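"""Pairwise equivalence tests on Cq differences (log-scale expression ratios).

RT-qPCR data are compositional: the total RNA input is fixed, so only
*ratios* between genes are interpretable.  On the Cq (log2) scale the ratio
of two genes' expressions is the difference ``d = Cq_a - Cq_b``.  A pair of
genes is declared stable between two biological groups when the between-group
difference of ``d`` is *equivalent to zero* within a margin of ``delta``
cycles, established by the two one-sided tests (TOST) procedure:

* H0(lower): effect <= -delta, tested with t = (estimate + delta)/se;
* H0(upper): effect >= +delta, tested with t = (estimate - delta)/se;
* p_tost = max of the two one-sided p-values.

``p_tost <= alpha`` is exactly equivalent to the (1 - 2*alpha) confidence
interval of the effect lying inside [-delta, +delta].  The test assumes
Gaussian Cq values with equal group variances (pooled two-sample t, df =
n1 + n2 - 2); a Welch variant is available but not the default.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .cq_data import CqDataError, CqMatrix

__all__ = [
    "PairDifferenceSeries",
    "EquivalenceResult",
    "fold_change",
    "pair_differences",
    "tost_pvalue",
    "tost_pair",
    "all_pairs",
]


def fold_change(delta: float) -> float:
    """Expression fold change corresponding to ``delta`` cycles.

    Assumes 100 % amplification efficiency, i.e. one cycle = a factor 2:
    a margin of 0.5 Cq corresponds to a 2**0.5 ~ 1.414 fold change.
    """
    return float(2.0 ** delta)


@dataclass
class PairDifferenceSeries:
    """Per-sample Cq differences for one gene pair, with group labels."""

    gene_a: str
    gene_b: str
    d: np.ndarray
    groups: np.ndarray
    group_levels: tuple[str, str]

    @property
    def n_per_group(self) -> tuple[int, int]:
        return (int(np.sum(self.groups == self.group_levels[0])),
                int(np.sum(self.groups == self.group_levels[1])))

    @property
    def testable(self) -> bool:
        n1, n2 = self.n_per_group
        return n1 >= 2 and n2 >= 2


@dataclass
class EquivalenceResult:
    """TOST result for one gene pair.

    ``estimate`` is mean(d | group 2) - mean(d | group 1) in cycles; the CI
    is the (1 - 2*alpha)-level interval dual to the test.
    """

    gene_a: str
    gene_b: str
    delta: float
    estimate: float
    se: float
    df: float
    ci_low: float
    ci_high: float
    p_tost: float
    n1: int
    n2: int
    alpha: float


def _two_group_levels(matrix: CqMatrix) -> tuple[str, str]:
    levels = matrix.group_levels()
    if len(levels) != 2:
        raise CqDataError(
            f"equivalence testing requires exactly 2 groups, got {levels!r}"
        )
    return (levels[0], levels[1])


def pair_differences(matrix: CqMatrix, gene_a: str,
                     gene_b: str) -> PairDifferenceSeries:
    """Per-sample differences Cq(gene_a) - Cq(gene_b).

    Samples missing either gene are excluded (complete-pairs analysis).
    """
    for g in (gene_a, gene_b):
        if g not in matrix.values.columns:
            raise CqDataError(f"gene {g!r} not present in matrix")
    levels = _two_group_levels(matrix)
    a = matrix.values[gene_a].to_numpy(dtype=float)
    b = matrix.values[gene_b].to_numpy(dtype=float)
    ok = ~(np.isnan(a) | np.isnan(b))
    return PairDifferenceSeries(
        gene_a=gene_a, gene_b=gene_b,
        d=(a - b)[ok],
        groups=matrix.groups.to_numpy()[ok],
        group_levels=levels,
    )


def tost_pvalue(estimate, se, df, delta):
    """Vectorised TOST p-value max(p_lower, p_upper).

    Degenerate ``se == 0``: p = 0 when |estimate| < delta (perfectly
    demonstrated equivalence), p = 1 otherwise.
    """
    estimate = np.asarray(estimate, dtype=float)
    se = np.asarray(se, dtype=float)
    df = np.asarray(df, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_lower = (estimate + delta) / se
        t_upper = (estimate - delta) / se
        p_lower = stats.t.sf(t_lower, df)
        p_upper = stats.t.cdf(t_upper, df)
        p = np.maximum(p_lower, p_upper)
    degenerate = se == 0
    if np.any(degenerate):
        p = np.where(degenerate,
                     np.where(np.abs(estimate) < delta, 0.0, 1.0), p)
    return p if p.ndim else float(p)


def tost_pair(series: PairDifferenceSeries, delta: float,
              alpha: float = 0.05,
              variance_mode: str = "pooled") -> EquivalenceResult | None:
    """Equivalence test of the between-group shift of one pair's differences.

    Returns ``None`` when the pair is untestable (fewer than two usable
    samples in either group).  ``alpha`` only sets the level of the reported
    confidence interval, ``1 - 2*alpha``; the p-value does not depend on it.
    """
    if delta <= 0:
        raise ValueError("delta must be > 0")
    if not series.testable:
        return None
    lev1, lev2 = series.group_levels
    d1 = series.d[series.groups == lev1]
    d2 = series.d[series.groups == lev2]
    n1, n2 = len(d1), len(d2)
    estimate = float(np.mean(d2) - np.mean(d1))

    if variance_mode == "pooled":
        df = n1 + n2 - 2
        sp2 = (np.sum((d1 - d1.mean()) ** 2)
               + np.sum((d2 - d2.mean()) ** 2)) / df
        se = float(np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2)))
    elif variance_mode == "welch":
        v1 = np.var(d1, ddof=1) / n1
        v2 = np.var(d2, ddof=1) / n2
        se = float(np.sqrt(v1 + v2))
        df = ((v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
              if se > 0 else n1 + n2 - 2)
    else:
        raise ValueError(f"unknown variance_mode {variance_mode!r}")

    p = tost_pvalue(estimate, se, df, delta)
    tcrit = stats.t.ppf(1.0 - alpha, df) if se > 0 else 0.0
    return EquivalenceResult(
        gene_a=series.gene_a, gene_b=series.gene_b, delta=float(delta),
        estimate=estimate, se=se, df=float(df),
        ci_low=estimate - tcrit * se, ci_high=estimate + tcrit * se,
        p_tost=float(p), n1=n1, n2=n2, alpha=alpha,
    )


def all_pairs(matrix: CqMatrix, delta: float, alpha: float = 0.05,
              variance_mode: str = "pooled") -> pd.DataFrame:
    """TOST over all G*(G-1)/2 gene pairs.

    Returns one row per unordered pair with columns ``gene_a, gene_b,
    estimate, se, df, ci_low, ci_high, p_tost, n1, n2, testable``.
    Untestable pairs (insufficient complete samples in a group) are kept with
    ``testable = False`` and NaN statistics — distinct from p = 1.
    """
    genes = matrix.genes
    if len(genes) < 2:
        raise CqDataError("need at least 2 genes")
    _two_group_levels(matrix)
    rows = []
    for a, b in combinations(genes, 2):
        series = pair_differences(matrix, a, b)
        res = tost_pair(series, delta, alpha=alpha, variance_mode=variance_mode)
        if res is None:
            n1, n2 = series.n_per_group
            rows.append({"gene_a": a, "gene_b": b, "estimate": np.nan,
                         "se": np.nan, "df": np.nan, "ci_low": np.nan,
                         "ci_high": np.nan, "p_tost": np.nan,
                         "n1": n1, "n2": n2, "testable": False})
        else:
            rows.append({"gene_a": a, "gene_b": b, "estimate": res.estimate,
                         "se": res.se, "df": res.df, "ci_low": res.ci_low,
                         "ci_high": res.ci_high, "p_tost": res.p_tost,
                         "n1": res.n1, "n2": res.n2, "testable": True})
    out = pd.DataFrame(rows)
    out.attrs["delta"] = float(delta)
    out.attrs["alpha"] = float(alpha)
    return out


def write_pairs(pairs: pd.DataFrame, path) -> None:
    """Write the pairwise TOST table as TSV."""
    pairs.to_csv(path, sep="\t", index=False)
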