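"""Simulation-based choice of the per-pair rejection cutoff.

A single equivalence test is run at a per-pair cutoff far above 0.05 (the
study-level error is controlled on *cliques*, not edges).  The cutoff is
calibrated so that, under a null in which **no** pair of genes is truly
equivalent, the probability of the graph containing any clique of three or
more nodes stays below a target family-wise level (default 0.05).

The default null is the *fence* configuration: gene ``g`` receives a
between-group expression shift of ``g * delta`` cycles, so every adjacent
pair of genes sits exactly on the equivalence boundary — the least
favourable arrangement for producing false edges — and no pair is truly
equivalent at margin ``delta``.  Residual noise is i.i.d. Gaussian, scaled
so that within-group pairwise Cq differences have standard deviation
``residual_sd`` (each cell gets ``residual_sd / sqrt(2)``).

Calibration uses common random numbers: the per-pair p-values are simulated
once, each simulated dataset is reduced to its *critical cutoff* (the
smallest cutoff at which a 3-clique appears, i.e. the minimum over gene
triples of the largest of the three pairwise p-values), and the spurious-
clique probability at any cutoff c is then the fraction of critical cutoffs
strictly below c — exactly monotone in c and reproducible under a fixed
seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .cq_data import CqMatrix
from .equivalence import tost_pvalue, pair_differences

__all__ = [
    "CalibrationSpec",
    "CalibrationResult",
    "simulate_null_dataset",
    "spurious_clique_probability",
    "calibrate_cutoff",
    "estimate_residual_sd",
]

_CHUNK = 512  # simulations per block; fixed so results are seed-reproducible


@dataclass(frozen=True)
class CalibrationSpec:
    """Parameters of the Monte-Carlo cutoff calibration.

    ``residual_sd`` is the within-group SD, in cycles, of *pairwise Cq
    differences* under the null (about sqrt(2) times the per-gene
    inter-individual SD).  The default 1.0 corresponds to mid-range
    per-gene variability of roughly 0.7 cycles.
    """

    n_genes: int
    group_sizes: tuple[int, int]
    delta: float = 0.5
    residual_sd: float = 1.0
    n_sim: int = 10_000
    target_fwer: float = 0.05
    seed: int = 0
    null_model: str = "fence"
    grid_resolution: float = 0.001

    def __post_init__(self) -> None:
        if self.n_genes < 3:
            raise ValueError("n_genes must be >= 3")
        if self.n_sim < 1:
            raise ValueError("n_sim must be >= 1")
        if not (0 < self.target_fwer < 1):
            raise ValueError("target_fwer must be in (0, 1)")
        if min(self.group_sizes) < 2:
            raise ValueError("each group needs at least 2 samples")
        if self.null_model != "fence":
            raise ValueError(
                f"unknown null model {self.null_model!r}; 'fence' is the "
                "only built-in null"
            )


@dataclass
class CalibrationResult:
    """Calibrated cutoff with its Monte-Carlo uncertainty."""

    cutoff: float
    achieved_fwer: float
    mc_se: float
    n_sim: int
    seed: int
    success: bool
    spec: CalibrationSpec


def _fence_effects(spec: CalibrationSpec) -> np.ndarray:
    """Group-2 shift of gene g is g * delta: adjacent pairs sit at the
    boundary, all pairs differ by a non-zero multiple of delta."""
    return np.arange(spec.n_genes, dtype=float) * spec.delta


def simulate_null_dataset(spec: CalibrationSpec,
                          replicate_seed: int | None = None) -> CqMatrix:
    """One simulated samples x genes Cq matrix under the fence null."""
    rng = np.random.default_rng(
        spec.seed if replicate_seed is None else replicate_seed)
    n1, n2 = spec.group_sizes
    effects = _fence_effects(spec)
    cell_sd = spec.residual_sd / np.sqrt(2.0)
    base = 20.0
    x1 = base + rng.normal(0.0, cell_sd, (n1, spec.n_genes))
    x2 = base + effects[None, :] + rng.normal(0.0, cell_sd, (n2, spec.n_genes))
    genes = [f"G{i + 1:02d}" for i in range(spec.n_genes)]
    samples = [f"S{i + 1:03d}" for i in range(n1 + n2)]
    values = pd.DataFrame(np.vstack([x1, x2]),
                          index=pd.Index(samples, name="sample"),
                          columns=genes)
    groups = pd.Series(["group1"] * n1 + ["group2"] * n2,
                       index=values.index, name="group")
    return CqMatrix(values=values, groups=groups)


def _pair_indices(n_genes: int):
    ia, ib = np.triu_indices(n_genes, 1)
    pair_of = np.full((n_genes, n_genes), -1, dtype=int)
    pair_of[ia, ib] = np.arange(len(ia))
    triples = np.array(list(combinations(range(n_genes), 3)), dtype=int)
    t01 = pair_of[triples[:, 0], triples[:, 1]]
    t02 = pair_of[triples[:, 0], triples[:, 2]]
    t12 = pair_of[triples[:, 1], triples[:, 2]]
    return ia, ib, (t01, t02, t12)


def _critical_cutoffs(spec: CalibrationSpec, seed: int) -> np.ndarray:
    """Per-simulation minimal cutoff at which a 3-clique appears.

    For one simulated dataset this is min over gene triples of the largest
    of the three pairwise TOST p-values; a 3-clique exists at cutoff c iff
    this critical value is < c (edges require p < c, strictly).
    """
    rng = np.random.default_rng(seed)
    n1, n2 = spec.group_sizes
    g = spec.n_genes
    df = n1 + n2 - 2
    effects = _fence_effects(spec)
    cell_sd = spec.residual_sd / np.sqrt(2.0)
    ia, ib, (t01, t02, t12) = _pair_indices(g)
    crit = np.empty(spec.n_sim)

    done = 0
    while done < spec.n_sim:
        m = min(_CHUNK, spec.n_sim - done)
        x1 = rng.normal(0.0, cell_sd, (m, n1, g))
        x2 = effects[None, None, :] + rng.normal(0.0, cell_sd, (m, n2, g))
        mu1 = x1.mean(axis=1)
        mu2 = x2.mean(axis=1)
        c1 = x1 - mu1[:, None, :]
        c2 = x2 - mu2[:, None, :]
        ss1 = np.einsum("mig,mih->mgh", c1, c1)
        ss2 = np.einsum("mig,mih->mgh", c2, c2)
        ss = ss1 + ss2
        # variance of d = x_a - x_b from the pooled cross-product matrix
        var_d = (ss[:, ia, ia] + ss[:, ib, ib] - 2.0 * ss[:, ia, ib]) / df
        se = np.sqrt(np.maximum(var_d, 0.0) * (1.0 / n1 + 1.0 / n2))
        est = (mu2[:, ia] - mu2[:, ib]) - (mu1[:, ia] - mu1[:, ib])
        p = tost_pvalue(est, se, df, spec.delta)
        tri = np.maximum(p[:, t01], p[:, t02])
        np.maximum(tri, p[:, t12], out=tri)
        crit[done:done + m] = tri.min(axis=1)
        done += m
    return crit


def spurious_clique_probability(spec: CalibrationSpec, cutoff: float,
                                seed: int | None = None) -> float:
    """Fraction of null simulations whose graph contains a >= 3-node clique."""
    if not (0 <= cutoff <= 1):
        raise ValueError("cutoff must be in [0, 1]")
    if cutoff == 0:
        return 0.0
    crit = _critical_cutoffs(spec, spec.seed if seed is None else seed)
    return float(np.mean(crit < cutoff))


def calibrate_cutoff(spec: CalibrationSpec) -> CalibrationResult:
    """Largest grid cutoff keeping the spurious-clique probability at or
    below ``target_fwer``.

    The grid runs from ``grid_resolution`` to 1.0 in ``grid_resolution``
    steps.  When even the smallest grid cutoff exceeds the target, the
    result is flagged unsuccessful and reports the achieved probability at
    that smallest cutoff.
    """
    crit = np.sort(_critical_cutoffs(spec, spec.seed))
    res = spec.grid_resolution
    grid = np.round(np.arange(res, 1.0 + res / 2, res), 10)
    counts = np.searchsorted(crit, grid, side="left")  # c_i < cutoff, strict
    fwer = counts / spec.n_sim
    ok = np.flatnonzero(fwer <= spec.target_fwer)
    if len(ok):
        idx = ok[-1]
        cutoff = float(grid[idx])
        achieved = float(fwer[idx])
        success = True
    else:
        cutoff = float(grid[0])
        achieved = float(fwer[0])
        success = False
    mc_se = float(np.sqrt(achieved * (1.0 - achieved) / spec.n_sim))
    return CalibrationResult(cutoff=cutoff, achieved_fwer=achieved,
                             mc_se=mc_se, n_sim=spec.n_sim, seed=spec.seed,
                             success=success, spec=spec)


def estimate_residual_sd(matrix: CqMatrix) -> float:
    """Pooled within-group SD of pairwise Cq differences from real data.

    Root-mean-square across all gene pairs of the pooled within-group SD of
    d = Cq_a - Cq_b; used as the data-informed ``residual_sd`` of the
    calibration null.
    """
    genes = matrix.genes
    groups = matrix.groups.to_numpy()
    levels = list(dict.fromkeys(groups))
    ss_total = 0.0
    df_total = 0
    for i, a in enumerate(genes):
        for b in genes[i + 1:]:
            series = pair_differences(matrix, a, b)
            for level in levels:
                d = series.d[series.groups == level]
                if len(d) >= 2:
                    ss_total += float(np.sum((d - d.mean()) ** 2))
                    df_total += len(d) - 1
    if df_total == 0:
        raise ValueError("not enough complete pairs to estimate residual SD")
    return float(np.sqrt(ss_total / df_total))
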