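"""Domain types and delimited-matrix IO shared by all pipeline stages.

The three matrix kinds (binary genotypes with missing entries, raw hash-antibody
counts, CLR-normalized hash expression) are stored cells-in-rows /
features-in-columns.  Genotype entries live in {0, 1, missing}; missingness is
represented internally as ``numpy.nan`` in a float array.  The canonical text
dialect writes tab-separated values with an unnamed barcode index column and
``NA`` for missing entries; ``NA``, the empty string and ``.`` are accepted on
read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("snacs")

NA_TOKENS = ("NA", "", ".")

#: reserved (non-sample) demultiplexing labels
MULTIPLET = "multiplet"
NO_CALL = "no_call"
FILTERED = "filtered"
RESERVED_LABELS = frozenset({MULTIPLET, NO_CALL, FILTERED})

ROUNDS = ("round1", "round2", "plus_doubletd")


class SnacsError(Exception):
    """Base class for validation and parse errors raised by this package."""


class ParseError(SnacsError):
    pass


class ValidationError(SnacsError):
    pass


class AlignmentError(SnacsError):
    pass


def _check_unique(ids: Sequence[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        seen, dups = set(), []
        for x in ids:
            if x in seen:
                dups.append(x)
            seen.add(x)
        raise ValidationError(f"duplicate {what}: {sorted(set(dups))[:5]}")


@dataclass
class GenotypeMatrix:
    """Cells x SNPs ternary matrix; entries 0 (wildtype), 1 (mutated) or NaN."""

    cell_ids: list[str]
    snp_ids: list[str]
    values: np.ndarray  # float64, nan = missing

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.cell_ids), len(self.snp_ids)):
            raise ValidationError(
                f"genotype shape {self.values.shape} inconsistent with "
                f"{len(self.cell_ids)} cells x {len(self.snp_ids)} SNPs"
            )
        _check_unique(self.cell_ids, "cell ids")
        _check_unique(self.snp_ids, "SNP ids")
        obs = self.values[~np.isnan(self.values)]
        if obs.size and not np.isin(obs, (0.0, 1.0)).all():
            bad = obs[~np.isin(obs, (0.0, 1.0))][0]
            raise ValidationError(f"genotype entries must be 0/1/missing; found {bad!r}")

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.cell_ids, columns=self.snp_ids)

    def subset_cells(self, keep: Sequence[str]) -> "GenotypeMatrix":
        idx = {c: i for i, c in enumerate(self.cell_ids)}
        rows = [idx[c] for c in keep]
        return GenotypeMatrix(list(keep), list(self.snp_ids), self.values[rows])

    def subset_snps(self, keep: Sequence[str]) -> "GenotypeMatrix":
        idx = {s: j for j, s in enumerate(self.snp_ids)}
        cols = [idx[s] for s in keep]
        return GenotypeMatrix(list(self.cell_ids), list(keep), self.values[:, cols])


@dataclass
class HashCounts:
    """Cells x hash-antibodies raw count matrix (one column per parent sample)."""

    cell_ids: list[str]
    hash_ids: list[str]
    counts: np.ndarray  # nonnegative integers

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.cell_ids), len(self.hash_ids)):
            raise ValidationError("hash count shape inconsistent with id lists")
        _check_unique(self.cell_ids, "cell ids")
        _check_unique(self.hash_ids, "hash ids")
        if self.counts.size == 0:
            raise ValidationError("no cells: empty hash count matrix")
        if np.isnan(np.asarray(self.counts, dtype=float)).any():
            raise ValidationError("hash counts contain missing values")
        if not np.equal(np.mod(self.counts, 1), 0).all():
            raise ValidationError("hash counts must be integers")
        if (self.counts < 0).any():
            raise ValidationError("hash counts must be nonnegative")
        self.counts = self.counts.astype(np.int64)

    @property
    def n_samples(self) -> int:
        """Number of multiplexed parent samples (= number of hashes)."""
        return len(self.hash_ids)

    def align_to(self, cell_ids: Sequence[str]) -> "HashCounts":
        """Reorder rows to the given barcode order (e.g. the genotype matrix's)."""
        idx = {c: i for i, c in enumerate(self.cell_ids)}
        missing = [c for c in cell_ids if c not in idx]
        if missing:
            raise AlignmentError(f"barcodes absent from hash matrix: {missing[:5]}")
        rows = [idx[c] for c in cell_ids]
        return HashCounts(list(cell_ids), list(self.hash_ids), self.counts[rows])


@dataclass
class HashExpression:
    """Cells x hashes CLR-normalized expression (finite reals)."""

    cell_ids: list[str]
    hash_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.cell_ids), len(self.hash_ids)):
            raise ValidationError("hash expression shape inconsistent with id lists")
        if self.values.size and not np.isfinite(self.values).all():
            raise ValidationError("hash expression must be finite")

    def column(self, hash_id: str) -> np.ndarray:
        return self.values[:, self.hash_ids.index(hash_id)]

    def subset_cells(self, keep: Sequence[str]) -> "HashExpression":
        idx = {c: i for i, c in enumerate(self.cell_ids)}
        rows = [idx[c] for c in keep]
        return HashExpression(list(keep), list(self.hash_ids), self.values[rows])


@dataclass
class SnacsConfig:
    """Tunable thresholds of the demultiplexing algorithm.

    Defaults are the algorithm's published operating point: 40% missingness
    filters, 95th-percentile background threshold (75th in the refinement
    round), top k=3 SNPs per pairwise comparison, 5-NN imputation, t-test
    split p-value 1e-5, minimum cluster size 2, >50% cluster-to-hash rule,
    100-cell small-sample fallback trigger and narrow-segment width.
    """

    missing_thresh_snp: float = 0.40
    missing_thresh_cell: float = 0.40
    background_pct: float = 95.0
    refine_pct: float = 75.0
    k_top_snps: int = 3
    knn_k: int = 5
    split_pvalue: float = 1e-5
    min_cluster_size: int = 2
    cluster_assign_frac: float = 0.5
    min_cells_per_hash: int = 100
    narrow_segment_max: int = 100
    bandwidth_step: float = 0.25
    cbs_alpha: float = 0.01
    cbs_nperm: int = 1000
    pseudocount: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("missing_thresh_snp", "missing_thresh_cell",
                     "cluster_assign_frac", "bandwidth_step"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValidationError(f"{name}={v} must lie in (0, 1)")
        for name in ("background_pct", "refine_pct"):
            v = getattr(self, name)
            if not 0.0 < v < 100.0:
                raise ValidationError(f"{name}={v} must lie in (0, 100)")
        if self.k_top_snps < 1:
            raise ValidationError("k_top_snps must be >= 1")
        if self.knn_k < 1:
            raise ValidationError("knn_k must be >= 1")
        if self.min_cluster_size < 1:
            raise ValidationError("min_cluster_size must be >= 1")

    @classmethod
    def from_mapping(cls, mapping: dict) -> "SnacsConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**mapping)


@dataclass
class DemuxCall:
    """Final per-cell label with round provenance.

    ``label`` is a hash id for a sample assignment, or one of the reserved
    labels ``multiplet`` / ``no_call`` / ``filtered``.
    """

    cell_id: str
    label: str
    round: str = "round1"

    def __post_init__(self) -> None:
        if self.round not in ROUNDS:
            raise ValidationError(f"unknown round {self.round!r}")

    @property
    def is_sample(self) -> bool:
        return self.label not in RESERVED_LABELS


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _sniff_sep(path: Path, dialect: str | None) -> str:
    if dialect:
        return {"tsv": "\t", "csv": ","}.get(dialect, dialect)
    with open(path) as fh:
        head = fh.readline()
    return "," if head.count(",") > head.count("\t") else "\t"


def read_genotype_matrix(path: str | Path, dialect: str | None = None) -> GenotypeMatrix:
    """Read a cells x SNPs 0/1/NA matrix from delimited text.

    The header row carries SNP ids and the first column cell barcodes.
    Accepted missing tokens: ``NA``, empty, ``.``. Any other non-0/1 entry is
    a parse error naming its row and column.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    sep = _sniff_sep(path, dialect)
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str,
                     keep_default_na=False, skipinitialspace=True)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ParseError(f"{path}: no cells or no SNPs")
    values = np.full(df.shape, np.nan)
    arr = df.to_numpy()
    for i in range(arr.shape[0]):
        for j in range(arr.shape[1]):
            tok = arr[i, j].strip()
            if tok in NA_TOKENS:
                continue
            if tok == "0":
                values[i, j] = 0.0
            elif tok == "1":
                values[i, j] = 1.0
            else:
                raise ParseError(
                    f"{path}: invalid genotype {tok!r} at cell "
                    f"{df.index[i]!r}, SNP {df.columns[j]!r}"
                )
    return GenotypeMatrix(list(df.index.astype(str)), list(df.columns.astype(str)), values)


def write_genotype_matrix(G: GenotypeMatrix, path: str | Path, sep: str = "\t") -> None:
    df = G.to_frame()
    out = df.map(lambda v: "NA" if np.isnan(v) else str(int(v)))
    out.to_csv(path, sep=sep)


def read_hash_counts(path: str | Path, dialect: str | None = None) -> HashCounts:
    """Read a cells x hash-antibodies nonnegative integer count matrix."""
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    sep = _sniff_sep(path, dialect)
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.shape[0] == 0:
        raise ParseError(f"{path}: no cells")
    counts = df.to_numpy()
    try:
        return HashCounts(list(df.index.astype(str)), list(df.columns.astype(str)), counts)
    except ValidationError as e:
        raise ValidationError(f"{path}: {e}") from e


def write_hash_counts(H: HashCounts, path: str | Path, sep: str = "\t") -> None:
    pd.DataFrame(H.counts, index=H.cell_ids, columns=H.hash_ids).to_csv(path, sep=sep)


def read_hash_expression(path: str | Path, dialect: str | None = None) -> HashExpression:
    path = Path(path)
    sep = _sniff_sep(path, dialect)
    df = pd.read_csv(path, sep=sep, index_col=0)
    return HashExpression(list(df.index.astype(str)), list(df.columns.astype(str)),
                          df.to_numpy(dtype=float))


def write_hash_expression(E: HashExpression, path: str | Path, sep: str = "\t") -> None:
    pd.DataFrame(E.values, index=E.cell_ids, columns=E.hash_ids).to_csv(path, sep=sep)


def calls_to_frame(calls: Iterable[DemuxCall]) -> pd.DataFrame:
    """Pivot a flat call list into a cell_id x round label table."""
    recs: dict[str, dict[str, str]] = {}
    order: list[str] = []
    for c in calls:
        row = recs.setdefault(c.cell_id, {})
        if c.round in row:
            raise ValidationError(f"duplicate call for cell {c.cell_id!r} round {c.round}")
        if not row:
            order.append(c.cell_id)
        row[c.round] = c.label
    rounds = [r for r in ROUNDS if any(r in row for row in recs.values())]
    df = pd.DataFrame(
        [[recs[cid].get(r, "") for r in rounds] for cid in order],
        index=pd.Index(order, name="cell_id"), columns=rounds,
    )
    return df


def write_demux_calls(calls: Iterable[DemuxCall], path: str | Path, sep: str = "\t") -> None:
    """Write calls as a delimited table with one column per computed round."""
    df = calls_to_frame(list(calls))
    if df.empty:
        Path(path).write_text("cell_id" + "\n")
        return
    df.to_csv(path, sep=sep)


def read_demux_calls(path: str | Path, sep: str = "\t") -> list[DemuxCall]:
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)
    calls = []
    for cid, row in df.iterrows():
        for rnd in df.columns:
            if row[rnd]:
                calls.append(DemuxCall(str(cid), row[rnd], rnd))
    return calls
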