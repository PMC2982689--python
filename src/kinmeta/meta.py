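"""Co-expression statistics and Fisher inverse-chi-square meta-analysis.

For each TF-gene pair and each dataset partition, the Pearson correlation r
over the partition's samples is converted to a right-tailed p-value via the
exact t transform  t = r sqrt((n-2)/(1-r^2))  with n-2 degrees of freedom
(n = samples in the partition).  Right-tailed means only positive
co-expression — activation — counts as evidence.

Partitions are treated as independent datasets, so their p-values combine by
Fisher's inverse-chi-square method:  chi2 = -2 sum ln p_i  follows a central
chi-square with 2k degrees of freedom under the null (k = number of
partitions), giving a single meta p-value per pair.  Alongside it we count
the pair's *significance level*: the number of partitions with p < 0.01.
Pairs are ranked by significance level first and meta chi-square second —
with equal degrees of freedom everywhere, chi-square and meta p-value give
the same order, and the chi-square stays numerically distinguishable where
meta p-values underflow.

No multiple-testing correction is applied: the consensus requirement
(recurring significance across independent partitions) is itself the
false-positive control.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix
from .partition import PartitionSet

#: Floor applied to p-values before the log so the chi-square stays finite.
P_FLOOR = 1e-300

#: Per-dataset significance threshold for the consensus count.
DEFAULT_ALPHA = 0.01


@dataclass(frozen=True)
class MetaPair:
    """Combined evidence for one directed TF -> gene pair across partitions."""

    tf_id: str
    gene_id: str
    significance_level: int
    chisq: float
    meta_p: float
    mean_r: float


def pearson_r(x, y) -> float:
    """Product-moment correlation of two equal-length profiles (n >= 3)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("profiles must be 1-D and of equal length")
    if len(x) < 3:
        raise ValueError(f"need at least 3 observations, got {len(x)}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant profile")
    r = float(np.corrcoef(x, y)[0, 1])
    return float(np.clip(r, -1.0, 1.0))


def right_tailed_p(r: float, n: int) -> float:
    """P(correlation >= r under no association), exact t transform.

    ``n`` is the number of conditions the correlation was computed over;
    the t statistic has n-2 degrees of freedom.  r = +1/-1 return the 0/1
    limits.
    """
    if n < 3:
        raise ValueError(f"need n >= 3, got {n}")
    if not -1.0 <= r <= 1.0:
        raise ValueError(f"correlation must lie in [-1, 1], got {r}")
    if r >= 1.0:
        return 0.0
    if r <= -1.0:
        return 1.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(stats.t.sf(t, df=n - 2))


def fisher_chisq(pvals, floor: float = P_FLOOR) -> float:
    """Fisher's combined statistic chi2 = -2 sum ln p_i.

    p-values of exactly zero are clamped to ``floor`` so the statistic is
    finite; NaN (undefined correlation in a partition) counts as p = 1,
    contributing no evidence.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("fisher_chisq needs at least one p-value")
    p = np.where(np.isnan(p), 1.0, p)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    p = np.clip(p, floor, 1.0)
    return float(-2.0 * np.sum(np.log(p)))


def meta_p(chisq: float, k: int) -> float:
    """Survival probability of chi-square with 2k df at ``chisq`` (k datasets)."""
    if k < 1:
        raise ValueError(f"need at least one dataset, got k={k}")
    if chisq < 0:
        raise ValueError(f"chi-square statistic must be nonnegative, got {chisq}")
    return float(stats.chi2.sf(chisq, df=2 * k))


def significance_level(pvals, alpha: float = DEFAULT_ALPHA) -> int:
    """Count of partitions with p strictly below ``alpha`` (NaN = not significant)."""
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    p = np.asarray(pvals, dtype=float)
    return int(np.sum(p < alpha))  # NaN compares False


# ---------------------------------------------------------------------------
# vectorized per-partition pair statistics
# ---------------------------------------------------------------------------


def _corr_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-by-row correlation matrix (len(a) x len(b)); NaN for constant rows."""
    n = a.shape[1]
    ac = a - a.mean(axis=1, keepdims=True)
    bc = b - b.mean(axis=1, keepdims=True)
    sa = np.sqrt((ac * ac).sum(axis=1))
    sb = np.sqrt((bc * bc).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (ac @ bc.T) / np.outer(sa, sb)
    r[~np.isfinite(r)] = np.nan
    np.clip(r, -1.0, 1.0, out=r)
    return r


def compute_pair_stats(
    matrix: ExpressionMatrix,
    tf_set: set[str],
    partitions: PartitionSet,
) -> pd.DataFrame:
    """Per-partition r and right-tailed p for every TF x gene pair.

    Returns a long DataFrame with columns (tf_id, gene_id, partition, n, r,
    p); self pairs are excluded before statistics, and a constant profile in
    a partition yields r = NaN and p = NaN there (downstream it counts as
    non-significant and contributes ln 1 = 0 to the chi-square).
    """
    tfs = [g for g in matrix.gene_ids if g in tf_set]
    if not tfs:
        raise ValueError("no TF ids present in the matrix")
    genes = matrix.gene_ids
    gene_arr = np.array(genes)
    self_mask = np.array(tfs)[:, None] == gene_arr[None, :]
    frames = []
    for label, samples in partitions.partitions:
        sub = matrix.data.loc[:, samples].to_numpy(dtype=float)
        n = len(samples)
        tf_block = matrix.data.loc[tfs, samples].to_numpy(dtype=float)
        r = _corr_rows(tf_block, sub)
        if n >= 3:
            with np.errstate(invalid="ignore", divide="ignore"):
                t = r * np.sqrt((n - 2) / (1.0 - r * r))
            p = stats.t.sf(t, df=n - 2)
            p = np.where(np.isnan(r), np.nan, p)
            # r = +/-1 gives t = +/-inf; sf handles the limits
        else:
            p = np.full_like(r, np.nan)
        keep = ~self_mask.ravel()
        frames.append(
            pd.DataFrame(
                {
                    "tf_id": np.repeat(tfs, len(genes))[keep],
                    "gene_id": np.tile(genes, len(tfs))[keep],
                    "partition": label,
                    "n": n,
                    "r": r.ravel()[keep],
                    "p": p.ravel()[keep],
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def combine_pairs(
    pair_stats: pd.DataFrame,
    k: int,
    alpha: float = DEFAULT_ALPHA,
) -> list[MetaPair]:
    """Fold per-partition statistics into one :class:`MetaPair` per pair."""
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    wide = pair_stats.pivot(index=["tf_id", "gene_id"], columns="partition")
    p_wide = wide["p"]
    p = p_wide.to_numpy(dtype=float)
    r = wide["r"].to_numpy(dtype=float)
    p_safe = np.clip(np.where(np.isnan(p), 1.0, p), P_FLOOR, 1.0)
    chisq = -2.0 * np.log(p_safe).sum(axis=1)
    metap = stats.chi2.sf(chisq, df=2 * k)
    level = np.sum(p < alpha, axis=1)
    finite = np.isfinite(r)
    counts = finite.sum(axis=1)
    mean_r = np.where(
        counts > 0, np.nansum(np.where(finite, r, 0.0), axis=1) / np.maximum(counts, 1), 0.0
    )
    return [
        MetaPair(
            tf_id=tf,
            gene_id=gene,
            significance_level=int(level[i]),
            chisq=float(chisq[i]),
            meta_p=float(metap[i]),
            mean_r=float(mean_r[i]),
        )
        for i, (tf, gene) in enumerate(p_wide.index)
    ]


def rank_pairs(metapairs: list[MetaPair]) -> list[MetaPair]:
    """Rank descending by significance level, then chi-square, then ids.

    The lexicographic (tf_id, gene_id) tail makes full ties deterministic.
    """
    return sorted(
        metapairs,
        key=lambda m: (-m.significance_level, -m.chisq, m.tf_id, m.gene_id),
    )
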