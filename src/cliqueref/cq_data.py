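"""Reading, triplicate quality control and summarising of RT-qPCR Cq tables.

Cq (quantification cycle) values are log2-scale proxies of RNA abundance:
one cycle less means roughly twice as much template, assuming 100 %
amplification efficiency.  Reactions are typically run as technical
triplicates; this module applies two standard QC rules before any analysis:

* **failure rule** — a triplicate is labelled *failed* when any replicate is
  undetected or crosses the detection threshold after ``max_cq`` cycles
  (default 32); failed triplicates yield no averaged Cq.
* **outlier rule** — when the standard deviation of a non-failed triplicate
  exceeds ``sd_threshold`` cycles (default 0.5), the single replicate with
  the greatest absolute deviation from the triplicate mean is dropped (once,
  never iterated) and the mean of the remainder is emitted.

The failure rule is applied first: a late replicate fails the whole
triplicate rather than being rescued by the outlier rule.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "UNDETECTED_MARKERS",
    "CqDataError",
    "RawCqTable",
    "CqMatrix",
    "VariabilitySummary",
    "read_cq_table",
    "flag_failures",
    "average_triplicates",
    "variability_summary",
    "write_matrix",
    "write_qc",
]

#: Case-insensitive cell contents treated as "no amplification detected".
UNDETECTED_MARKERS = frozenset({"", "na", "nd", "undetermined"})

_LONG_COLUMNS = ("sample", "group", "gene", "replicate", "cq")


class CqDataError(ValueError):
    """Raised for malformed or inconsistent Cq input."""


def _sep_for(path: str | Path) -> str:
    return "\t" if str(path).lower().endswith((".tsv", ".tab", ".txt")) else ","


def _parse_cq(raw: str, where: str) -> float:
    token = str(raw).strip()
    if token.lower() in UNDETECTED_MARKERS:
        return np.nan
    try:
        value = float(token)
    except ValueError:
        raise CqDataError(
            f"non-numeric Cq value {raw!r} at {where} is not a recognised "
            f"undetected marker (accepted markers, case-insensitive: "
            f"empty cell, 'NA', 'ND', 'Undetermined')"
        ) from None
    if value <= 0:
        raise CqDataError(f"Cq value {value} at {where} must be positive")
    return value


@dataclass
class RawCqTable:
    """Long-format replicate-level Cq records.

    ``data`` has columns ``sample, group, gene, replicate, cq``; an
    undetected replicate is stored with ``cq = NaN``.  Sample and gene order
    is first-seen order of the source.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in _LONG_COLUMNS if c not in self.data.columns]
        if missing:
            raise CqDataError(f"missing columns: {missing}")
        dup = self.data.duplicated(subset=["sample", "gene", "replicate"])
        if dup.any():
            row = self.data.loc[dup.idxmax()]
            raise CqDataError(
                "duplicate record for (sample, gene, replicate) = "
                f"({row['sample']!r}, {row['gene']!r}, {row['replicate']!r})"
            )
        grp = self.data.groupby("sample", sort=False)["group"].nunique()
        bad = grp[grp > 1]
        if len(bad):
            raise CqDataError(
                f"sample {bad.index[0]!r} is assigned to more than one group"
            )

    @property
    def samples(self) -> list[str]:
        return list(dict.fromkeys(self.data["sample"]))

    @property
    def genes(self) -> list[str]:
        return list(dict.fromkeys(self.data["gene"]))

    @property
    def groups(self) -> pd.Series:
        """Group label per sample, in first-seen sample order."""
        g = self.data.drop_duplicates("sample").set_index("sample")["group"]
        return g.reindex(self.samples)


@dataclass
class CqMatrix:
    """Samples x genes matrix of averaged Cq values.

    ``values`` is a DataFrame (rows = samples, columns = genes) with ``NaN``
    marking triplicates that failed QC or were absent; ``groups`` maps each
    sample to its group label; ``qc`` (optional) is the per-triplicate QC
    table produced by :func:`average_triplicates`.
    """

    values: pd.DataFrame
    groups: pd.Series
    qc: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.groups.index):
            self.groups = self.groups.reindex(self.values.index)
        if self.groups.isna().any():
            missing = self.groups.index[self.groups.isna()][0]
            raise CqDataError(f"sample {missing!r} has no group label")
        finite = self.values.to_numpy(dtype=float)
        present = ~np.isnan(finite)
        if present.any() and not (finite[present] > 0).all():
            raise CqDataError("all present Cq values must be finite and > 0")

    @property
    def genes(self) -> list[str]:
        return list(self.values.columns)

    @property
    def samples(self) -> list[str]:
        return list(self.values.index)

    def group_levels(self) -> list[str]:
        return list(dict.fromkeys(self.groups))


@dataclass
class VariabilitySummary:
    """Intra-assay and inter-individual variability, both in cycles.

    ``intra_assay``: one row per (sample, gene) — SD of the raw technical
    replicates of non-failed triplicates with at least two replicates.
    ``inter_individual``: one row per (gene, group) — SD of the averaged Cq
    across the samples of the group (``NaN`` when fewer than two samples
    have a value: undefined, not zero).
    """

    intra_assay: pd.DataFrame
    inter_individual: pd.DataFrame


def read_cq_table(path: str | Path, dialect: str = "long",
                  sep: str | None = None) -> RawCqTable | CqMatrix:
    """Read a Cq table from CSV/TSV.

    ``dialect='long'`` expects columns ``sample, group, gene, replicate, cq``
    (one row per technical replicate) and returns a :class:`RawCqTable`.
    ``dialect='wide'`` expects one row per sample with a ``sample`` and
    ``group`` column plus one column per gene of pre-averaged Cq, and
    returns a :class:`CqMatrix` (without QC records).
    """
    path = Path(path)
    if not path.exists():
        raise CqDataError(f"no such file: {path}")
    sep = sep or _sep_for(path)
    with open(path, newline="", encoding="utf-8") as fh:
        header = next(csv.reader(fh, delimiter=sep))
    header = [h.strip() for h in header]
    lowered = [h.lower() for h in header]
    seen: set[str] = set()
    for name in lowered:
        if name in seen:
            raise CqDataError(f"duplicated column name {name!r}")
        seen.add(name)

    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    df.columns = lowered

    if dialect == "long":
        unknown = [c for c in df.columns if c not in _LONG_COLUMNS]
        if unknown:
            raise CqDataError(f"unknown columns in long table: {unknown}")
        missing = [c for c in _LONG_COLUMNS if c not in df.columns]
        if missing:
            raise CqDataError(f"missing columns in long table: {missing}")
        try:
            rep = df["replicate"].astype(int)
        except ValueError as exc:
            raise CqDataError(f"non-integer replicate index: {exc}") from None
        if (rep < 1).any():
            raise CqDataError("replicate indices must be >= 1")
        cq = [
            _parse_cq(v, f"(sample={s}, gene={g}, replicate={r})")
            for v, s, g, r in zip(df["cq"], df["sample"], df["gene"], rep)
        ]
        out = pd.DataFrame({
            "sample": df["sample"].str.strip(),
            "group": df["group"].str.strip(),
            "gene": df["gene"].str.strip(),
            "replicate": rep.to_numpy(),
            "cq": np.asarray(cq, dtype=float),
        })
        return RawCqTable(out)

    if dialect == "wide":
        for col in ("sample", "group"):
            if col not in df.columns:
                raise CqDataError(f"missing column {col!r} in wide table")
        gene_cols = [c for c in df.columns if c not in ("sample", "group")]
        if not gene_cols:
            raise CqDataError("wide table has no gene columns")
        samples = df["sample"].str.strip()
        if samples.duplicated().any():
            raise CqDataError(
                f"duplicate sample {samples[samples.duplicated()].iloc[0]!r}"
            )
        # preserve the original header capitalisation for gene names
        orig = {l: h for l, h in zip(lowered, header)}
        values = pd.DataFrame(index=pd.Index(samples, name="sample"))
        for col in gene_cols:
            values[orig[col]] = [
                _parse_cq(v, f"(sample={s}, gene={orig[col]})")
                for v, s in zip(df[col], samples)
            ]
        groups = pd.Series(df["group"].str.strip().to_numpy(),
                           index=values.index, name="group")
        return CqMatrix(values=values, groups=groups)

    raise CqDataError(f"unknown dialect {dialect!r} (expected 'long' or 'wide')")


def _triplicate_arrays(table: RawCqTable):
    """Stack replicates into (n_triplicates, n_rep_slots) arrays.

    Returns (keys DataFrame with sample/gene, values V with NaN for absent
    slots, detected-record mask ``has``, undetected mask ``undet``, and the
    replicate index of each slot).
    """
    df = table.data
    rep_levels = np.sort(df["replicate"].unique())
    key = pd.MultiIndex.from_arrays([df["sample"], df["gene"]])
    cells = key.drop_duplicates()
    cell_pos = pd.Series(np.arange(len(cells)), index=cells)
    rows = cell_pos.loc[key].to_numpy()
    cols = np.searchsorted(rep_levels, df["replicate"].to_numpy())

    V = np.full((len(cells), len(rep_levels)), np.nan)
    has = np.zeros_like(V, dtype=bool)
    V[rows, cols] = df["cq"].to_numpy()
    has[rows, cols] = True
    undet = has & np.isnan(V)
    keys = pd.DataFrame({"sample": cells.get_level_values(0),
                         "gene": cells.get_level_values(1)})
    return keys, V, has, undet, rep_levels


def flag_failures(table: RawCqTable, max_cq: float = 32.0) -> pd.DataFrame:
    """Label each triplicate failed when any replicate is undetected or late.

    Returns one row per (sample, gene) with a boolean ``failed`` column:
    ``failed`` is true iff at least one replicate is undetected or has
    ``cq > max_cq`` (strictly later than ``max_cq`` cycles).
    """
    keys, V, has, undet, _ = _triplicate_arrays(table)
    late = np.where(np.isnan(V), False, V > max_cq)
    out = keys.copy()
    out["failed"] = undet.any(axis=1) | late.any(axis=1)
    return out


def average_triplicates(table: RawCqTable, sd_threshold: float = 0.5,
                        max_cq: float = 32.0,
                        failures: pd.DataFrame | None = None) -> CqMatrix:
    """Average technical replicates into a samples x genes Cq matrix.

    Failed triplicates (see :func:`flag_failures`) produce a missing cell.
    For each remaining triplicate the outlier rule is applied exactly once:
    if the sample SD (n-1 denominator) exceeds ``sd_threshold``, the single
    replicate with the greatest absolute deviation from the mean is dropped
    (ties broken by dropping the larger replicate index) and the mean of the
    remaining values is emitted.

    The returned matrix carries a ``qc`` table with one row per triplicate:
    ``sample, gene, failed, dropped_replicate, raw_sd, n_used``.
    """
    keys, V, has, undet, rep_levels = _triplicate_arrays(table)
    if failures is None:
        failures = flag_failures(table, max_cq=max_cq)
    fail_map = failures.set_index(["sample", "gene"])["failed"]
    failed = fail_map.loc[
        pd.MultiIndex.from_frame(keys[["sample", "gene"]])
    ].to_numpy(dtype=bool)

    n_raw = np.count_nonzero(~np.isnan(V), axis=1)
    mean_raw = _nan_mean(V)
    raw_sd = _nan_sd(V)

    work = V.copy()
    work[failed, :] = np.nan

    dropped = np.full(len(keys), -1)
    needs_drop = (~failed) & (n_raw >= 2) & (raw_sd > sd_threshold)
    if needs_drop.any():
        dev = np.abs(work - mean_raw[:, None])
        dev = np.where(np.isnan(dev), -np.inf, dev)
        # argmax on the reversed axis picks the *last* slot among ties,
        # i.e. the larger replicate index
        rev = dev[:, ::-1]
        drop_col = dev.shape[1] - 1 - np.argmax(rev, axis=1)
        idx = np.flatnonzero(needs_drop)
        work[idx, drop_col[idx]] = np.nan
        dropped[idx] = rep_levels[drop_col[idx]]

    n_used = np.count_nonzero(~np.isnan(work), axis=1)
    mean_used = _nan_mean(work)

    qc = keys.copy()
    qc["failed"] = failed
    qc["dropped_replicate"] = np.where(dropped > 0, dropped, np.nan)
    qc["raw_sd"] = raw_sd
    qc["n_used"] = n_used

    samples = table.samples
    genes = table.genes
    values = pd.DataFrame(np.nan, index=pd.Index(samples, name="sample"),
                          columns=genes)
    srow = {s: i for i, s in enumerate(samples)}
    gcol = {g: j for j, g in enumerate(genes)}
    arr = values.to_numpy()
    arr[[srow[s] for s in keys["sample"]],
        [gcol[g] for g in keys["gene"]]] = mean_used
    values.iloc[:, :] = arr
    return CqMatrix(values=values, groups=table.groups, qc=qc)


def _nan_mean(V: np.ndarray) -> np.ndarray:
    """Row-wise mean ignoring NaN; NaN for empty rows (no warning)."""
    n = np.count_nonzero(~np.isnan(V), axis=1)
    total = np.nansum(V, axis=1)
    return np.where(n > 0, total / np.where(n > 0, n, 1), np.nan)


def _nan_sd(V: np.ndarray) -> np.ndarray:
    """Row-wise sample SD (n-1 denominator) ignoring NaN; NaN when n < 2."""
    n = np.count_nonzero(~np.isnan(V), axis=1)
    mean = _nan_mean(V)
    ss = np.nansum((V - mean[:, None]) ** 2, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        sd = np.sqrt(ss / np.where(n > 1, n - 1, -1))
    return np.where(n > 1, sd, np.nan)


def variability_summary(table: RawCqTable,
                        matrix: CqMatrix | None = None) -> VariabilitySummary:
    """Intra-assay (replicate) and inter-individual (group) SDs in cycles."""
    if matrix is None:
        matrix = average_triplicates(table)
    keys, V, has, undet, _ = _triplicate_arrays(table)
    failures = flag_failures(table)
    failed = failures.set_index(["sample", "gene"])["failed"].loc[
        pd.MultiIndex.from_frame(keys[["sample", "gene"]])
    ].to_numpy(dtype=bool)
    sd = _nan_sd(V)
    intra = keys.copy()
    intra["sd"] = np.where(failed, np.nan, sd)
    intra = intra[~failed & ~np.isnan(sd)].reset_index(drop=True)

    rows = []
    for group in matrix.group_levels():
        sub = matrix.values.loc[matrix.groups == group]
        n = sub.notna().sum(axis=0)
        s = sub.std(axis=0, ddof=1)
        for gene in matrix.genes:
            rows.append({
                "gene": gene, "group": group,
                "sd": s[gene] if n[gene] >= 2 else np.nan,
                "n": int(n[gene]),
            })
    inter = pd.DataFrame(rows)
    return VariabilitySummary(intra_assay=intra, inter_individual=inter)


def write_matrix(matrix: CqMatrix, path: str | Path) -> None:
    """Write a CqMatrix as a wide CSV (sample, group, one column per gene)."""
    out = matrix.values.copy()
    out.insert(0, "group", matrix.groups)
    out.to_csv(path, index=True, index_label="sample")


def write_qc(qc: pd.DataFrame, path: str | Path) -> None:
    """Write the per-triplicate QC table as TSV."""
    qc.to_csv(path, sep="\t", index=False)
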