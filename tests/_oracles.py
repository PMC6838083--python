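"""Independent brute-force / literal-transcription oracles used by the tests.

These deliberately avoid the package's own code paths: clique enumeration by
exhaustive subset search, and NormFinder/geNorm statistics written as plain
formula-by-formula loops.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def brute_force_maximal_cliques(nodes, edges):
    """All inclusion-maximal cliques by enumerating every node subset.

    ``edges`` is a set of frozensets.  Intended for graphs of <= ~14 nodes.
    """
    nodes = list(nodes)
    edge_set = {frozenset(e) for e in edges}

    def is_clique(subset):
        return all(frozenset((a, b)) in edge_set
                   for a, b in combinations(subset, 2))

    cliques = []
    for r in range(1, len(nodes) + 1):
        for subset in combinations(nodes, r):
            if is_clique(subset):
                cliques.append(set(subset))
    maximal = [c for c in cliques
               if not any(c < other for other in cliques)]
    out = [tuple(sorted(c)) for c in maximal]
    out.sort(key=lambda c: (-len(c), c))
    return out


def genorm_m_oracle(values):
    """geNorm M by explicit loops: M_j = mean over k != j of the
    across-sample SD of (Cq_j - Cq_k)."""
    genes = list(values.columns)
    m = {}
    for gj in genes:
        sds = []
        for gk in genes:
            if gk == gj:
                continue
            diff = values[gj].to_numpy() - values[gk].to_numpy()
            diff = diff[~np.isnan(diff)]
            sds.append(float(np.std(diff, ddof=1)))
        m[gj] = float(np.mean(sds))
    return m


def normfinder_oracle(values, groups):
    """Literal transcription of the grouped NormFinder computation.

    Steps, written out one formula at a time:
      1. centre each sample across the n genes;
      2. per group g and gene i: mean ybar_gi and naive variance s2_gi;
      3. de-bias the variances (centring across n genes correlates them):
         sigma2_gi = (s2_gi - sum_i' s2_gi' / (n (n-1))) * n / (n-2), >= 0;
      4. inter-group bias d_gi = ybar_gi - mean_g ybar_gi;
      5. between-gene bias variance gamma2 = sum d^2 / ((n-1)(k-1))
         minus the mean sampling variance sigma2_gi / n_g, >= 0;
      6. shrink: d~ = d * gamma2 / (gamma2 + sigma2/n_g);
      7. stability rho_i = mean over groups of
         |d~_gi| + sqrt((sigma2_gi / n_g) * gamma2 / (gamma2 + sigma2/n_g)).
    """
    genes = list(values.columns)
    n = len(genes)
    levels = list(dict.fromkeys(groups))
    assert len(levels) == 2
    k = 2

    y = values.to_numpy(dtype=float).copy()
    for row in range(y.shape[0]):
        y[row, :] = y[row, :] - y[row, :].mean()

    groups = np.asarray(groups)
    ybar = np.zeros((k, n))
    s2 = np.zeros((k, n))
    n_g = np.zeros(k, dtype=int)
    for gi, level in enumerate(levels):
        sub = y[groups == level]
        n_g[gi] = len(sub)
        for i in range(n):
            ybar[gi, i] = sub[:, i].mean()
            s2[gi, i] = sub[:, i].var(ddof=1)

    sigma2 = np.zeros((k, n))
    for gi in range(k):
        total = s2[gi].sum()
        for i in range(n):
            sigma2[gi, i] = max(
                0.0, (s2[gi, i] - total / (n * (n - 1))) * n / (n - 2))

    d = np.zeros((k, n))
    for i in range(n):
        centre = ybar[:, i].mean()
        for gi in range(k):
            d[gi, i] = ybar[gi, i] - centre

    samp = np.zeros((k, n))
    for gi in range(k):
        for i in range(n):
            samp[gi, i] = sigma2[gi, i] / n_g[gi]
    gamma2 = max(0.0, (d ** 2).sum() / ((n - 1) * (k - 1)) - samp.mean())

    rho = {}
    for i, gene in enumerate(genes):
        terms = []
        for gi in range(k):
            if gamma2 > 0:
                w = gamma2 / (gamma2 + samp[gi, i])
            else:
                w = 0.0
            terms.append(abs(d[gi, i] * w) + np.sqrt(samp[gi, i] * w))
        rho[gene] = float(np.mean(terms))
    return rho
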