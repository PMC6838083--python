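"""Synthetic replicate-level Cq data with known ground truth.

The generator emulates the structure of a two-group RT-qPCR reference-gene
experiment:

``Cq(s, g, r) = baseline_g + group_effect_g * [s in group 2] + loading_s
               + individual_(s,g) + analytical_(s,g,r)``

* ``baseline_g`` — per-gene expression level (cycles, default U[14, 30]);
* ``group_effect_g`` — between-group expression change; a *planted set* of
  genes shares one common effect (they are truly mutually equivalent), all
  other genes get effects differing pairwise, and from the planted effect,
  by at least the design spacing;
* ``loading_s`` — per-sample compositional shift common to all genes of the
  sample (fixed RNA input); invisible to any ratio-based statistic;
* ``individual`` — inter-individual biological noise;
* ``analytical`` — per-replicate technical noise (default SD 0.1 cycles);
* sporadic outliers (a large shift on a single replicate) and failures
  (late or undetected amplification) at configurable rates.

Noise defaults decompose observed per-gene Cq SDs of ~0.3-0.6 cycles, with
technical replicate SD around 0.1, as seen in typical LCL panels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .cq_data import RawCqTable

__all__ = ["SyntheticSpec", "generate", "study_scale_preset",
           "planted_preset", "write_long_csv", "write_truth"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Ground-truth parameterisation of a synthetic Cq experiment."""

    n_genes: int = 30
    group_sizes: tuple[int, int] = (14, 26)
    baseline_cq: tuple[float, ...] | None = None  # None: drawn uniformly
    baseline_range: tuple[float, float] = (14.0, 30.0)
    group_effects: tuple[float, ...] | None = None  # None: built from spacing
    planted_set: tuple[int, ...] = ()
    effect_spacing: float = 1.0  # used when group_effects is None
    sample_loading_sd: float = 0.5
    inter_individual_sd: float = 0.2
    analytical_sd: float = 0.1
    n_replicates: int = 3
    outlier_rate: float = 0.0
    outlier_magnitude: float = 5.0
    failure_rate: float = 0.0
    max_cq: float = 32.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 2:
            raise ValueError("n_genes must be >= 2")
        if any(i < 0 or i >= self.n_genes for i in self.planted_set):
            raise ValueError("planted_set indices out of range")
        if len(set(self.planted_set)) != len(self.planted_set):
            raise ValueError("planted_set indices must be unique")
        if self.group_effects is not None:
            eff = np.asarray(self.group_effects, dtype=float)
            if len(eff) != self.n_genes:
                raise ValueError("group_effects must have one entry per gene")
            planted = eff[list(self.planted_set)]
            if len(planted) and not np.all(planted == planted[0]):
                raise ValueError("planted genes must share one common effect")
            others = [eff[i] for i in range(self.n_genes)
                      if i not in self.planted_set]
            pool = others + ([planted[0]] if len(planted) else [])
            if len(set(pool)) != len(others) + (1 if len(planted) else 0):
                raise ValueError(
                    "non-planted effects must differ pairwise and from the "
                    "planted effect")


def _default_effects(spec: SyntheticSpec) -> np.ndarray:
    """Planted genes share effect 0; the others get +/- k * spacing."""
    effects = np.zeros(spec.n_genes)
    mags = []
    k = 1
    while len(mags) < spec.n_genes:
        mags.extend([k * spec.effect_spacing, -k * spec.effect_spacing])
        k += 1
    it = iter(mags)
    for i in range(spec.n_genes):
        if i not in spec.planted_set:
            effects[i] = next(it)
    return effects


def generate(spec: SyntheticSpec) -> tuple[RawCqTable, dict]:
    """Simulate a replicate-level Cq table plus its ground-truth record.

    A fixed seed yields a bit-identical table.  The truth record stores the
    realised baselines, effects, loadings, individual noise, and the
    positions of injected outliers and failures, so downstream checks never
    have to re-derive what was planted.
    """
    rng = np.random.default_rng(spec.seed)
    n1, n2 = spec.group_sizes
    n_samples = n1 + n2
    g, r = spec.n_genes, spec.n_replicates

    baseline = (np.asarray(spec.baseline_cq, dtype=float)
                if spec.baseline_cq is not None
                else rng.uniform(*spec.baseline_range, g))
    effects = (np.asarray(spec.group_effects, dtype=float)
               if spec.group_effects is not None else _default_effects(spec))
    in_group2 = np.array([0] * n1 + [1] * n2)
    loading = rng.normal(0.0, spec.sample_loading_sd, n_samples)
    individual = rng.normal(0.0, spec.inter_individual_sd, (n_samples, g))
    analytical = rng.normal(0.0, spec.analytical_sd, (n_samples, g, r))

    cq = (baseline[None, :, None]
          + (effects[None, :] * in_group2[:, None])[:, :, None]
          + loading[:, None, None]
          + individual[:, :, None]
          + analytical)

    outliers = rng.random((n_samples, g, r)) < spec.outlier_rate
    cq = cq + outliers * spec.outlier_magnitude

    failures = rng.random((n_samples, g, r)) < spec.failure_rate
    late = rng.random((n_samples, g, r)) < 0.5  # late detection vs none
    fail_cq = rng.uniform(spec.max_cq + 0.5, 40.0, (n_samples, g, r))
    cq = np.where(failures & late, fail_cq, cq)
    cq = np.where(failures & ~late, np.nan, cq)

    genes = [f"G{i + 1:02d}" for i in range(g)]
    samples = [f"S{i + 1:03d}" for i in range(n_samples)]
    groups = ["control"] * n1 + ["patient"] * n2

    records = pd.DataFrame({
        "sample": np.repeat(samples, g * r),
        "group": np.repeat(groups, g * r),
        "gene": np.tile(np.repeat(genes, r), n_samples),
        "replicate": np.tile(np.arange(1, r + 1), n_samples * g),
        "cq": cq.ravel(),
    })
    table = RawCqTable(records)

    truth = {
        "spec": asdict(spec),
        "genes": genes,
        "samples": samples,
        "groups": groups,
        "planted_genes": [genes[i] for i in spec.planted_set],
        "baseline_cq": baseline.tolist(),
        "group_effects": effects.tolist(),
        "loading": loading.tolist(),
        "individual": individual.tolist(),
        "outliers": [[samples[s], genes[j], int(k + 1)]
                     for s, j, k in zip(*np.nonzero(outliers))],
        "failures": [[samples[s], genes[j], int(k + 1),
                      "late" if late[s, j, k] else "undetected"]
                     for s, j, k in zip(*np.nonzero(failures))],
    }
    return table, truth


def study_scale_preset(seed: int = 0) -> SyntheticSpec:
    """A study-scale preset: 30 candidate genes, 14 + 26 samples,
    triplicates, 7 planted stable genes, sporadic outliers and failures.

    Decoy effects are spaced 0.6 cycles (just beyond the 0.5-cycle margin)
    and baselines kept within 14-24 cycles so that differential shifts do
    not interact with the late-detection failure rule; genes that amplify
    near the detection limit are exercised through ``failure_rate`` instead.
    """
    return SyntheticSpec(
        n_genes=30,
        group_sizes=(14, 26),
        baseline_range=(14.0, 24.0),
        planted_set=tuple(range(7)),
        effect_spacing=0.6,
        sample_loading_sd=0.5,
        inter_individual_sd=0.2,
        analytical_sd=0.1,
        n_replicates=3,
        outlier_rate=0.01,
        outlier_magnitude=5.0,
        failure_rate=0.005,
        seed=seed,
    )


def planted_preset(n_genes: int = 15, n_planted: int = 6,
                   seed: int = 0) -> SyntheticSpec:
    """Parameter-recovery preset: a planted stable set among decoys whose
    effects are spaced 1.0 cycle apart, at study-scale noise."""
    return SyntheticSpec(
        n_genes=n_genes,
        group_sizes=(14, 26),
        baseline_range=(14.0, 24.0),
        planted_set=tuple(range(n_planted)),
        effect_spacing=1.0,
        sample_loading_sd=0.5,
        inter_individual_sd=0.2,
        analytical_sd=0.1,
        n_replicates=3,
        outlier_rate=0.01,
        outlier_magnitude=5.0,
        failure_rate=0.005,
        seed=seed,
    )


def write_long_csv(table: RawCqTable, path: str | Path) -> None:
    """Write the replicate-level table in the long CSV dialect; undetected
    replicates are stored as 'Undetermined'."""
    out = table.data.copy()
    out["cq"] = out["cq"].map(
        lambda v: "Undetermined" if pd.isna(v) else f"{v:.6g}")
    out.to_csv(path, index=False)


def write_truth(truth: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(truth, indent=2, sort_keys=True),
                          encoding="utf-8")
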