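"""Data containers and TSV readers/writers.

All pipeline stages exchange a small set of validated containers: a genes x
samples :class:`ExpressionMatrix` of relative expression values (log2 ratios to
a basal/control state), a :class:`SampleMetadata` table driving partitioning
and time-series detection, plain gene-id sets, a directed gold-standard pair
set, and a directed :class:`Network` edge list.

File formats are deliberately minimal: tab-separated text with a header row
for matrices and metadata, one id per line (``#`` comments allowed) for gene
lists, two tab-separated columns for gold-standard pairs, and TSV or SIF for
networks.  Identifiers are matched case-sensitively and exactly; AGI locus
ids are conventionally written in a fixed case and silent normalization would
hide real mismatches.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Tokens accepted as a missing expression value on input (case-insensitive).
#: Missing values are always written back out as "NA".
MISSING_TOKENS = frozenset({"", "na"})

#: Reserved partition label for the pooled leftover samples.
COMBINED_REST = "combined_rest"


class ValidationError(ValueError):
    """An input file or container violates a structural invariant."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of relative expression (log2 ratio) values.

    ``data`` is a float DataFrame indexed by gene id with sample ids as
    columns.  NaN marks a missing measurement; missing values are only legal
    before :func:`kinmeta.partition.filter_missing` has been applied.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene ids: {dups}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dups}")
        self.data = self.data.astype(float)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_missing(self) -> int:
        return int(self.data.isna().to_numpy().sum())

    def subset_genes(self, gene_ids: Iterable[str]) -> "ExpressionMatrix":
        keep = [g for g in self.gene_ids if g in set(gene_ids)]
        return ExpressionMatrix(self.data.loc[keep])

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[:, list(sample_ids)])


@dataclass
class SampleMetadata:
    """Per-sample annotations: experiment, tissue, stage, time, replicates.

    ``table`` is indexed by sample id with columns ``experiment_id``,
    ``tissue``, ``dev_stage``, ``time_hours``, ``replicate_group``,
    ``treatment``.  ``time_hours`` is NaN for samples without a time
    coordinate; an experiment counts as time-series as soon as any of its
    samples carries a time.
    """

    table: pd.DataFrame

    REQUIRED = ("experiment_id", "tissue")
    OPTIONAL = ("dev_stage", "time_hours", "replicate_group", "treatment")

    def __post_init__(self) -> None:
        t = self.table.copy()
        if t.index.has_duplicates:
            dups = t.index[t.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids in metadata: {dups}")
        for col in self.REQUIRED:
            if col not in t.columns:
                raise ValidationError(f"metadata missing required column {col!r}")
        for col in self.OPTIONAL:
            if col not in t.columns:
                t[col] = np.nan if col == "time_hours" else ""
        t["time_hours"] = pd.to_numeric(t["time_hours"], errors="coerce")
        if (t["time_hours"].dropna() < 0).any():
            bad = t.index[t["time_hours"] < 0].tolist()
            raise ValidationError(f"negative time_hours for samples {bad}")
        for col in ("experiment_id", "tissue", "dev_stage", "replicate_group", "treatment"):
            t[col] = t[col].fillna("").astype(str)
        self.table = t

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def require_samples(self, sample_ids: Iterable[str]) -> None:
        missing = sorted(set(sample_ids) - set(self.sample_ids))
        if missing:
            raise ValidationError(f"samples absent from metadata: {missing}")

    def is_time_series(self, experiment_id: str) -> bool:
        rows = self.table[self.table["experiment_id"] == experiment_id]
        return bool(rows["time_hours"].notna().any())

    def time_series_experiments(self) -> list[str]:
        return [
            e
            for e in self.table["experiment_id"].unique()
            if self.is_time_series(e)
        ]

    def experiment_samples(self, experiment_id: str) -> list[str]:
        return list(self.table.index[self.table["experiment_id"] == experiment_id])

    def subset(self, sample_ids: Sequence[str]) -> "SampleMetadata":
        return SampleMetadata(self.table.loc[list(sample_ids)].copy())


@dataclass(frozen=True)
class GoldStandard:
    """Directed benchmark set of curated TF -> target pairs."""

    pairs: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        if not self.pairs:
            raise ValidationError("gold standard is empty")
        for tf, tg in self.pairs:
            if not tf or not tg:
                raise ValidationError("gold standard contains an empty id")
            if tf == tg:
                raise ValidationError(f"gold standard self pair: {tf}")

    def __len__(self) -> int:
        return len(self.pairs)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return pair in self.pairs


@dataclass(frozen=True)
class Edge:
    """One directed TF -> target edge with its meta statistics."""

    tf_id: str
    target_id: str
    significance_level: int
    meta_chisq: float
    meta_p: float
    mean_r: float


@dataclass
class Network:
    """Directed TF -> target edge list (no self edges, no duplicates)."""

    edges: list[Edge] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        for e in self.edges:
            if e.tf_id == e.target_id:
                raise ValidationError(f"self edge: {e.tf_id}")
            key = (e.tf_id, e.target_id)
            if key in seen:
                raise ValidationError(f"duplicate edge: {key}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.edges)

    @property
    def pair_set(self) -> set[tuple[str, str]]:
        return {(e.tf_id, e.target_id) for e in self.edges}

    @property
    def node_ids(self) -> set[str]:
        nodes: set[str] = set()
        for e in self.edges:
            nodes.add(e.tf_id)
            nodes.add(e.target_id)
        return nodes


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def _parse_cell(token: str, path: Path, row: int, col: int) -> float:
    if token.strip().lower() in MISSING_TOKENS:
        return math.nan
    try:
        return float(token)
    except ValueError:
        raise ValidationError(
            f"{path}: non-numeric cell {token!r} at row {row}, column {col}"
        ) from None


def read_expression_matrix(path: str | Path) -> ExpressionMatrix:
    """Read a genes x samples TSV: header row of sample ids, first column gene ids.

    Empty cells and ``NA`` (any case) are recorded as missing.  Duplicate
    gene or sample ids and ragged rows raise :class:`ValidationError`.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ValidationError(f"{path}: empty file") from None
        sample_ids = header[1:]
        if not sample_ids:
            raise ValidationError(f"{path}: header has no sample columns")
        width = len(header)
        gene_ids: list[str] = []
        rows: list[list[float]] = []
        for i, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != width:
                raise ValidationError(
                    f"{path}: ragged row {i}: {len(row)} fields, expected {width}"
                )
            gene_ids.append(row[0])
            rows.append(
                [_parse_cell(tok, path, i, j + 2) for j, tok in enumerate(row[1:])]
            )
    if not gene_ids:
        raise ValidationError(f"{path}: no gene rows")
    data = pd.DataFrame(rows, index=gene_ids, columns=sample_ids, dtype=float)
    return ExpressionMatrix(data)


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write a matrix TSV with 6-significant-digit reals; missing as ``NA``."""
    df = matrix.data.copy()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", na_rep="NA", float_format="%.6g")


def read_sample_metadata(path: str | Path) -> SampleMetadata:
    """Read the sample annotation TSV (sample_id, experiment_id, tissue, ...)."""
    path = Path(path)
    table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "sample_id" not in table.columns:
        raise ValidationError(f"{path}: metadata missing required column 'sample_id'")
    table = table.set_index("sample_id")
    table = table.mask(table == "")
    try:
        return SampleMetadata(table)
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from None


def write_sample_metadata(metadata: SampleMetadata, path: str | Path) -> None:
    df = metadata.table.copy()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t", na_rep="")


def read_gene_list(path: str | Path) -> set[str]:
    """Read a one-id-per-line gene list; ``#`` starts a comment line."""
    path = Path(path)
    ids: set[str] = set()
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        ids.add(line.split("\t")[0])
    if not ids:
        raise ValidationError(f"{path}: gene list is empty")
    return ids


def write_gene_list(ids: Iterable[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(sorted(ids)) + "\n")


def read_gold_standard(path: str | Path) -> GoldStandard:
    """Read a two-column TF<TAB>target TSV into a deduplicated directed pair set."""
    path = Path(path)
    pairs: set[tuple[str, str]] = set()
    for i, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 2:
            raise ValidationError(f"{path}: line {i} has fewer than two columns")
        tf, target = fields[0].strip(), fields[1].strip()
        if tf == target:
            raise ValidationError(f"{path}: line {i} is a self pair ({tf})")
        pairs.add((tf, target))
    if not pairs:
        raise ValidationError(f"{path}: gold standard file is empty")
    return GoldStandard(frozenset(pairs))


def write_gold_standard(gold: GoldStandard, path: str | Path) -> None:
    lines = [f"{tf}\t{tg}" for tf, tg in sorted(gold.pairs)]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# network output
# ---------------------------------------------------------------------------

_NETWORK_COLUMNS = (
    "tf_id",
    "target_id",
    "significance_level",
    "meta_chisq",
    "meta_p",
    "mean_r",
)


def write_network(network: Network, path: str | Path, format: str = "tsv") -> None:
    """Write an edge list as TSV (all attributes) or SIF (``tf regulates target``)."""
    path = Path(path)
    if format == "tsv":
        lines = ["\t".join(_NETWORK_COLUMNS)]
        for e in network.edges:
            lines.append(
                f"{e.tf_id}\t{e.target_id}\t{e.significance_level}"
                f"\t{e.meta_chisq:.6g}\t{e.meta_p:.6g}\t{e.mean_r:.6g}"
            )
        path.write_text("\n".join(lines) + "\n")
    elif format == "sif":
        lines = [f"{e.tf_id}\tregulates\t{e.target_id}" for e in network.edges]
        path.write_text("\n".join(lines) + ("\n" if lines else ""))
    else:
        raise ValueError(f"unknown network format {format!r}")


def read_network(path: str | Path) -> Network:
    """Read back a network TSV written by :func:`write_network`."""
    df = pd.read_csv(path, sep="\t", dtype={"tf_id": str, "target_id": str})
    missing = set(_NETWORK_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: network TSV missing columns {sorted(missing)}")
    edges = [
        Edge(
            tf_id=row.tf_id,
            target_id=row.target_id,
            significance_level=int(row.significance_level),
            meta_chisq=float(row.meta_chisq),
            meta_p=float(row.meta_p),
            mean_r=float(row.mean_r),
        )
        for row in df.itertuples(index=False)
    ]
    return Network(edges)
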