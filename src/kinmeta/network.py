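"""Network assembly from ranked pairs, plus the end-to-end pipeline.

Two target-selection rules are supported: a fixed number of top-ranked
targets per TF (top-k, typically 50 or 75), or a consensus cutoff keeping
every pair significant in at least a given number of partitions (with nine
partitions, cutoffs of 9/8/7 give small/medium/large networks).  The
consensus rule is the better-performing default.  A single-dataset Pearson
baseline (edges where r exceeds 0.75 or 0.70 over the unpartitioned data) is
included for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import Edge, ExpressionMatrix, Network, SampleMetadata, ValidationError
from .kinetics import KineticParams, transform_tf_profiles
from .meta import (
    DEFAULT_ALPHA,
    MetaPair,
    _corr_rows,
    combine_pairs,
    compute_pair_stats,
    rank_pairs,
    right_tailed_p,
)
from .partition import (
    PartitionSet,
    average_replicates,
    averaged_metadata,
    differential_filter,
    filter_missing,
    partition,
)


def select_targets(
    ranked: list[MetaPair],
    method: str = "level_cutoff",
    param: int = 8,
) -> list[MetaPair]:
    """Pick edges from a ranked pair list.

    ``top_k``: at most ``param`` targets per TF, in rank order.
    ``level_cutoff``: every pair whose significance level is at least
    ``param`` ("at least" is the only reading consistent with a cutoff equal
    to the partition count).
    """
    if param <= 0:
        raise ValueError(f"param must be positive, got {param}")
    if method == "top_k":
        taken: dict[str, int] = {}
        out = []
        for m in ranked:
            if taken.get(m.tf_id, 0) < param:
                out.append(m)
                taken[m.tf_id] = taken.get(m.tf_id, 0) + 1
        return out
    if method == "level_cutoff":
        return [m for m in ranked if m.significance_level >= param]
    raise ValueError(f"unknown selection method {method!r}")


def build_network(edges: list[MetaPair]) -> Network:
    """Materialize selected pairs as a validated directed network."""
    return Network(
        [
            Edge(
                tf_id=m.tf_id,
                target_id=m.gene_id,
                significance_level=m.significance_level,
                meta_chisq=m.chisq,
                meta_p=m.meta_p,
                mean_r=m.mean_r,
            )
            for m in edges
        ]
    )


def single_dataset_network(
    matrix: ExpressionMatrix,
    tf_set: set[str],
    r_cutoff: float = 0.75,
) -> Network:
    """Pearson-cutoff baseline on the unpartitioned matrix.

    Edges are TF -> gene pairs with correlation strictly above ``r_cutoff``
    over all samples taken as one dataset; self pairs are excluded.  Each
    edge carries its single-dataset right-tailed p-value (significance level
    1 if p < 0.01, else 0).
    """
    if not 0.0 < r_cutoff < 1.0:
        raise ValueError(f"r_cutoff must lie in (0, 1), got {r_cutoff}")
    tfs = [g for g in matrix.gene_ids if g in tf_set]
    if not tfs:
        raise ValueError("no TF ids present in the matrix")
    genes = np.array(matrix.gene_ids)
    n = len(matrix.sample_ids)
    r = _corr_rows(
        matrix.data.loc[tfs].to_numpy(dtype=float), matrix.data.to_numpy(dtype=float)
    )
    edges = []
    for i, tf in enumerate(tfs):
        hits = np.where(r[i] > r_cutoff)[0]
        for j in hits:
            if genes[j] == tf:
                continue
            rij = float(r[i, j])
            p = right_tailed_p(rij, n) if n >= 3 else float("nan")
            edges.append(
                Edge(
                    tf_id=tf,
                    target_id=str(genes[j]),
                    significance_level=int(p < DEFAULT_ALPHA) if np.isfinite(p) else 0,
                    meta_chisq=float(-2.0 * np.log(max(p, 1e-300))) if np.isfinite(p) else 0.0,
                    meta_p=p,
                    mean_r=rij,
                )
            )
    return Network(edges)


# ---------------------------------------------------------------------------
# pipeline orchestration
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """Every knob of the end-to-end run, with the working defaults.

    Defaults: tissue partitioning with minimum group size 9, two-fold
    differential-expression filter, per-dataset alpha 0.01, consensus cutoff
    8, kinetic lag transform on with (K_t, K_p) = (2.0, 1.0) per hour.
    """

    scheme: str = "tissue"
    min_size: int = 9
    de_threshold: float = 1.0
    alpha: float = DEFAULT_ALPHA
    method: str = "level_cutoff"
    param: int = 8
    transform: bool = True
    kinetic_params: KineticParams = field(
        default_factory=lambda: KineticParams(k_t=2.0, k_p=1.0, gamma=1.0)
    )

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        kp = d.pop("kinetic_params", None)
        cfg = cls(**d)
        if kp is not None:
            cfg = replace(cfg, kinetic_params=KineticParams(**kp))
        return cfg


@dataclass
class PipelineResult:
    """All intermediates of one pipeline run, exportable for inspection."""

    network: Network
    ranked: list[MetaPair]
    pair_stats: pd.DataFrame
    partitions: PartitionSet
    matrix: ExpressionMatrix  # prepared + transformed matrix actually correlated
    retained_genes: set[str]


def run_meta_pipeline(
    matrix: ExpressionMatrix,
    metadata: SampleMetadata,
    tf_set: set[str],
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Deterministic composition of the full method.

    Stages: average replicates -> drop genes with missing values ->
    differential-expression filter -> partition samples -> kinetic lag
    transform of TF rows in time-series blocks -> per-partition correlation
    statistics -> Fisher meta-combination -> rank -> select -> network.
    """
    config = config or PipelineConfig()
    if not tf_set:
        raise ValidationError("TF set is empty")
    metadata.require_samples(matrix.sample_ids)

    prepared = average_replicates(matrix, metadata)
    meta_avg = averaged_metadata(metadata.subset(matrix.sample_ids))
    prepared = filter_missing(prepared)
    retained = differential_filter(prepared, meta_avg, config.de_threshold)
    if not retained:
        raise ValidationError("differential filter removed every gene")
    prepared = prepared.subset_genes(retained)

    parts = partition(meta_avg, config.scheme, config.min_size)

    if config.transform:
        prepared = transform_tf_profiles(
            prepared, tf_set, config.kinetic_params, meta_avg
        )

    pair_stats = compute_pair_stats(prepared, tf_set, parts)
    metapairs = combine_pairs(pair_stats, k=parts.k, alpha=config.alpha)
    ranked = rank_pairs(metapairs)
    selected = select_targets(ranked, config.method, config.param)
    return PipelineResult(
        network=build_network(selected),
        ranked=ranked,
        pair_stats=pair_stats,
        partitions=parts,
        matrix=prepared,
        retained_genes=retained,
    )
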