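"""Data preparation and sample partitioning.

Preparation mirrors a standard compendium workflow: average replicate
columns, drop genes with any missing measurement, and keep only genes that
are differentially expressed somewhere (max |log2 ratio| at or above a
threshold; 1.0 = two-fold by default).  Partitioning splits the samples by
tissue, experiment type, or developmental stage; every label with at least
``min_size`` samples becomes its own dataset and everything smaller is pooled
into a single ``combined_rest`` group, so partition count k becomes the
number of datasets entering the meta-analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import COMBINED_REST, ExpressionMatrix, SampleMetadata, ValidationError

SCHEMES = ("tissue", "experiment", "dev_stage")

_SCHEME_COLUMN = {
    "tissue": "tissue",
    "experiment": "experiment_id",
    "dev_stage": "dev_stage",
}


@dataclass
class PartitionSet:
    """Disjoint sample groups for one partitioning scheme."""

    scheme: str
    partitions: list[tuple[str, list[str]]]
    min_size: int

    def __post_init__(self) -> None:
        seen: set[str] = set()
        labels = [label for label, _ in self.partitions]
        if len(labels) != len(set(labels)):
            raise ValidationError("duplicate partition labels")
        for label, samples in self.partitions:
            overlap = seen & set(samples)
            if overlap:
                raise ValidationError(f"partitions overlap on samples {sorted(overlap)}")
            seen.update(samples)
            if label != COMBINED_REST and len(samples) < self.min_size:
                raise ValidationError(
                    f"partition {label!r} has {len(samples)} samples < min_size {self.min_size}"
                )

    @property
    def k(self) -> int:
        return len(self.partitions)

    @property
    def labels(self) -> list[str]:
        return [label for label, _ in self.partitions]

    @property
    def sizes(self) -> list[int]:
        return [len(samples) for _, samples in self.partitions]

    @property
    def total_samples(self) -> int:
        return sum(self.sizes)


def filter_missing(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Drop every gene with a missing measurement in any sample."""
    keep = matrix.data.notna().all(axis=1)
    if not keep.any():
        raise ValidationError("filter_missing removed every gene")
    return ExpressionMatrix(matrix.data.loc[keep])


def _replicate_groups(metadata: SampleMetadata) -> pd.Series:
    """Effective replicate-group key per sample (singletons for unlabeled)."""
    groups = metadata.table["replicate_group"].copy()
    unlabeled = groups == ""
    groups[unlabeled] = pd.Series(groups.index, index=groups.index)[unlabeled]
    return groups


def average_replicates(matrix: ExpressionMatrix, metadata: SampleMetadata) -> ExpressionMatrix:
    """Average replicate columns; one output column per replicate group.

    Samples sharing a ``replicate_group`` are measurements of the same
    condition; their per-gene mean becomes a single column named by the
    group.  Samples without a group pass through unchanged under their own
    sample id.  A group that spans two experiments is a metadata error.
    """
    metadata.require_samples(matrix.sample_ids)
    meta = metadata.subset(matrix.sample_ids)
    groups = _replicate_groups(meta)
    span = meta.table.groupby(groups)["experiment_id"].nunique()
    bad = span.index[span > 1].tolist()
    if bad:
        raise ValidationError(f"replicate groups spanning experiments: {bad}")
    # preserve first-appearance column order
    order = list(dict.fromkeys(groups))
    averaged = matrix.data.T.groupby(groups, sort=False).mean().T
    return ExpressionMatrix(averaged.loc[:, order])


def averaged_metadata(metadata: SampleMetadata) -> SampleMetadata:
    """Collapse metadata to one record per replicate group.

    Companion to :func:`average_replicates`: the averaged matrix's columns
    are replicate-group ids, and this returns the matching annotation table
    (annotations taken from the group's first sample; times are averaged,
    which is the identity for true replicates measured at one time).
    """
    groups = _replicate_groups(metadata)
    t = metadata.table
    rows = []
    for gid in dict.fromkeys(groups):
        members = t.loc[groups[groups == gid].index]
        rec = members.iloc[0].copy()
        times = members["time_hours"].dropna()
        rec["time_hours"] = float(times.mean()) if len(times) else np.nan
        rec.name = gid
        rows.append(rec)
    return SampleMetadata(pd.DataFrame(rows))


def differential_filter(
    matrix: ExpressionMatrix,
    metadata: SampleMetadata | None = None,
    threshold: float = 1.0,
) -> set[str]:
    """Genes whose max |log2 ratio| over all samples reaches ``threshold``.

    The boundary is inclusive (>=), matching an "at least two-fold" reading
    of differential expression.  Returns the retained gene-id set.
    """
    if threshold < 0:
        raise ValueError(f"threshold must be nonnegative, got {threshold}")
    peak = matrix.data.abs().max(axis=1)
    return set(peak.index[peak >= threshold])


def partition(metadata: SampleMetadata, scheme: str, min_size: int = 9) -> PartitionSet:
    """Split samples by ``scheme`` label with a minimum group size.

    Labels with at least ``min_size`` samples become named partitions
    (descending size, ties by label, for a stable deterministic order);
    everything else lands in a single ``combined_rest`` partition.  Samples
    without a label under the scheme (e.g. no developmental-stage record) go
    to ``combined_rest`` as well.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; expected one of {SCHEMES}")
    col = _SCHEME_COLUMN[scheme]
    labels = metadata.table[col].fillna("")
    if (labels == COMBINED_REST).any():
        raise ValidationError(
            f"label {COMBINED_REST!r} is reserved for the pooled leftover group"
        )
    counts = labels[labels != ""].value_counts()
    named = sorted(
        (label for label, n in counts.items() if n >= min_size),
        key=lambda label: (-counts[label], label),
    )
    if not named:
        raise ValidationError(
            f"no {scheme} group reaches min_size={min_size} "
            f"(largest is {int(counts.max()) if len(counts) else 0})"
        )
    parts: list[tuple[str, list[str]]] = []
    assigned: set[str] = set()
    for label in named:
        samples = sorted(labels.index[labels == label])
        parts.append((label, samples))
        assigned.update(samples)
    rest = sorted(set(labels.index) - assigned)
    if rest:
        parts.append((COMBINED_REST, rest))
    return PartitionSet(scheme=scheme, partitions=parts, min_size=min_size)
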