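import numpy as np
import pandas as pd
import pytest

from cliqueref import (CqMatrix, RawCqTable, average_triplicates, generate,
                       planted_preset)


def long_table(triplicates, groups=None):
    """Build a RawCqTable from {(sample, gene): (cq, ...)} dicts.

    ``groups`` maps sample -> group; defaults to splitting samples in two
    halves (control / patient) in first-seen order.
    """
    samples = list(dict.fromkeys(s for s, _ in triplicates))
    if groups is None:
        half = max(1, len(samples) // 2)
        groups = {s: ("control" if i < half else "patient")
                  for i, s in enumerate(samples)}
    rows = []
    for (sample, gene), values in triplicates.items():
        for i, v in enumerate(values, start=1):
            rows.append({"sample": sample, "group": groups[sample],
                         "gene": gene, "replicate": i,
                         "cq": np.nan if v is None else float(v)})
    return RawCqTable(pd.DataFrame(rows))


def matrix_from_values(values, groups):
    """CqMatrix from a plain samples x genes array/frame and group labels."""
    values = pd.DataFrame(values)
    values.index = [f"S{i + 1:03d}" for i in range(len(values))]
    values.index.name = "sample"
    return CqMatrix(values=values,
                    groups=pd.Series(list(groups), index=values.index,
                                     name="group"))


def random_matrix(rng, n_genes=6, n1=6, n2=8, effect_scale=0.5,
                  noise_sd=0.3):
    """Random two-group Cq matrix with gene-specific group effects."""
    baseline = rng.uniform(15, 30, n_genes)
    effects = rng.normal(0, effect_scale, n_genes)
    in2 = np.array([0] * n1 + [1] * n2)
    x = (baseline[None, :] + effects[None, :] * in2[:, None]
         + rng.normal(0, noise_sd, (n1 + n2, n_genes)))
    return matrix_from_values(
        pd.DataFrame(x, columns=[f"G{i + 1:02d}" for i in range(n_genes)]),
        ["control"] * n1 + ["patient"] * n2)


@pytest.fixture(scope="session")
def planted_truth():
    """One planted 6-of-15 synthetic dataset with its ground truth."""
    table, truth = generate(planted_preset(seed=42))
    return table, truth


@pytest.fixture(scope="session")
def planted_matrix(planted_truth):
    table, _ = planted_truth
    return average_triplicates(table)
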