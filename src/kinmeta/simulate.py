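"""Synthetic multi-tissue expression compendium with planted regulons.

The generator emulates the kind of compendium the method is built for: many
experiments across several tissues, a fraction of them time courses under
abiotic stress, with a known set of TF -> target regulations planted by the
kinetic lag model itself.  Every stage of the pipeline — preparation,
partitioning, the lag transform, meta-statistics, network assembly and
benchmark evaluation — is therefore testable end to end with full knowledge
of the truth.

Layout: each tissue holds enough experiments of ``len(time_grid)`` samples
to reach ``samples_per_tissue``.  In a time-series tissue the first
experiment is a stress time course (samples annotated with hours on the
grid); all other experiments are steady-state collections of independent
conditions.  TF stress responses are smooth random sums of one or two
decaying pulses a (t/tau) e^{1 - t/tau}; each active target is the exact
analytic lag-model response to its TF's profile, times multiplicative
log-space noise e^{sigma Z} (expression values are log ratios).  In
steady-state experiments an active target tracks its TF's per-sample level
with the same multiplicative noise.  Inactive tissues and background genes
are independent noise around zero.

What this does *not* emulate: array-platform/probe artifacts, batch
effects, correlated background structure, or repression (responses are
activator-signed, matching the right-tailed statistics).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    ExpressionMatrix,
    GoldStandard,
    SampleMetadata,
    write_expression_matrix,
    write_gene_list,
    write_gold_standard,
    write_sample_metadata,
)
from .kinetics import KineticParams, fit_stepwise_linear, solve_target_profile

_DEV_STAGES = ("seedling", "vegetative", "flowering")


@dataclass
class SimConfig:
    """Study conditions of a simulated compendium.

    The defaults are a desk-scale analogue of a multi-experiment stress
    compendium: 9 tissue groups (so the consensus count runs over 9
    datasets), 12 samples per tissue, half the tissues carrying a stress
    time course on a typical 0-24 h design, regulons active in every tissue,
    15% multiplicative noise, and lag-model rates (K_t, K_p) = (2, 1) per
    hour with gamma = 2 (unit steady-state gain).
    """

    n_tfs: int = 20
    n_targets_per_tf: int = 10
    n_background_genes: int = 500
    k_tissues: int = 9
    samples_per_tissue: int = 12
    time_series_fraction: float = 0.5
    time_grid: tuple[float, ...] = (0.0, 1.0, 3.0, 6.0, 12.0, 24.0)
    k_t: float = 2.0
    k_p: float = 1.0
    gamma: float = 2.0
    noise_sd: float = 0.15
    active_fraction: float = 1.0
    background_sd: float = 0.5
    steady_tf_sd: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_tfs", "n_targets_per_tf", "k_tissues", "samples_per_tissue"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_background_genes < 0:
            raise ValueError("n_background_genes must be nonnegative")
        for name in ("time_series_fraction", "active_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.noise_sd < 0 or self.background_sd <= 0:
            raise ValueError("noise/background scales must be valid")
        if self.samples_per_tissue < 3:
            raise ValueError("samples_per_tissue must be at least 3 for correlations")
        if len(self.time_grid) < 2 or np.any(np.diff(self.time_grid) <= 0):
            raise ValueError("time_grid must be strictly increasing with >= 2 points")

    @property
    def params(self) -> KineticParams:
        return KineticParams(k_t=self.k_t, k_p=self.k_p, gamma=self.gamma)


@dataclass
class RegulonTruth:
    """Planted regulatory truth of one simulated compendium."""

    pairs: set[tuple[str, str]]
    activity: dict[str, set[str]] = field(default_factory=dict)  # tf -> active tissues
    tf_ids: list[str] = field(default_factory=list)

    def as_gold_standard(self) -> GoldStandard:
        return GoldStandard(frozenset(self.pairs))


def _pulse(t: np.ndarray, amp: float, tau: float) -> np.ndarray:
    """Smooth stress response: 0 at onset, peak ``amp`` at t = tau, decay."""
    return amp * (t / tau) * np.exp(1.0 - t / tau)


def _random_tf_course(rng: np.random.Generator, t: np.ndarray) -> np.ndarray:
    n_pulses = int(rng.integers(1, 3))
    out = np.zeros_like(t)
    for _ in range(n_pulses):
        amp = rng.uniform(1.5, 3.0)
        tau = rng.uniform(2.0, 8.0)
        out += _pulse(t, amp, tau)
    return out


def _mult_noise(rng: np.random.Generator, values: np.ndarray, sd: float) -> np.ndarray:
    if sd == 0:
        return values.copy()
    return values * np.exp(rng.normal(0.0, sd, size=values.shape))


def simulate_compendium(
    config: SimConfig,
) -> tuple[ExpressionMatrix, SampleMetadata, RegulonTruth]:
    """Generate (matrix, metadata, truth), fully reproducible from the seed.

    Uses numpy's default PCG64 generator, which is specified and portable
    across platforms for a fixed seed.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    grid = np.asarray(cfg.time_grid, dtype=float)
    n_grid = len(grid)
    exps_per_tissue = max(1, int(np.ceil(cfg.samples_per_tissue / n_grid)))

    tf_ids = [f"TF{i + 1:03d}" for i in range(cfg.n_tfs)]
    target_ids = {
        tf: [f"TG{i + 1:03d}_{j + 1:02d}" for j in range(cfg.n_targets_per_tf)]
        for i, tf in enumerate(tf_ids)
    }
    bg_ids = [f"BG{i + 1:04d}" for i in range(cfg.n_background_genes)]
    gene_ids = tf_ids + [g for tf in tf_ids for g in target_ids[tf]] + bg_ids

    tissues = [f"tissue{j + 1:02d}" for j in range(cfg.k_tissues)]
    n_ts_tissues = int(round(cfg.time_series_fraction * cfg.k_tissues))
    ts_tissues = set(rng.choice(tissues, size=n_ts_tissues, replace=False))

    # exact per-TF activity count so consensus levels are predictable
    n_active = int(round(cfg.active_fraction * cfg.k_tissues))
    activity = {
        tf: set(rng.choice(tissues, size=n_active, replace=False)) for tf in tf_ids
    }

    meta_rows = []
    columns: dict[str, np.ndarray] = {}
    n_genes = len(gene_ids)
    gene_pos = {g: i for i, g in enumerate(gene_ids)}

    for j, tissue in enumerate(tissues):
        stage = _DEV_STAGES[j % len(_DEV_STAGES)]
        for e in range(exps_per_tissue):
            exp_id = f"E{j + 1:02d}{chr(ord('a') + e)}"
            is_ts = tissue in ts_tissues and e == 0
            n_samples = n_grid if is_ts else min(
                n_grid, cfg.samples_per_tissue - e * n_grid
            ) or n_grid
            sample_ids = [f"{exp_id}_s{s + 1:02d}" for s in range(n_samples)]
            block = rng.normal(0.0, cfg.background_sd, size=(n_genes, n_samples))

            if is_ts:
                times = grid
                for tf in tf_ids:
                    clean = _random_tf_course(rng, times)
                    block[gene_pos[tf]] = _mult_noise(rng, clean, cfg.noise_sd)
                    profile = fit_stepwise_linear(times, clean)
                    theo = solve_target_profile(profile, cfg.params, eval_times=times)
                    if tissue in activity[tf]:
                        for tg in target_ids[tf]:
                            block[gene_pos[tg]] = _mult_noise(
                                rng, theo.values, cfg.noise_sd
                            )
            else:
                times = np.full(n_samples, np.nan)
                for tf in tf_ids:
                    levels = rng.normal(0.0, cfg.steady_tf_sd, size=n_samples)
                    block[gene_pos[tf]] = levels
                    if tissue in activity[tf]:
                        for tg in target_ids[tf]:
                            block[gene_pos[tg]] = _mult_noise(
                                rng, levels, cfg.noise_sd
                            )

            for s, sid in enumerate(sample_ids):
                meta_rows.append(
                    {
                        "sample_id": sid,
                        "experiment_id": exp_id,
                        "tissue": tissue,
                        "dev_stage": stage,
                        "time_hours": times[s] if is_ts else np.nan,
                        "replicate_group": "",
                        "treatment": "stress",
                    }
                )
                columns[sid] = block[:, s]

    data = pd.DataFrame(columns, index=gene_ids)
    matrix = ExpressionMatrix(data)
    meta = SampleMetadata(pd.DataFrame(meta_rows).set_index("sample_id"))
    truth = RegulonTruth(
        pairs={(tf, tg) for tf in tf_ids for tg in target_ids[tf]},
        activity=activity,
        tf_ids=tf_ids,
    )
    return matrix, meta, truth


#: Default training time course: a damped oscillatory induction-relaxation
#: design (hours / log2-ratio values).  An oscillating forcing probes the lag
#: dynamics at several phases, and the target's zero crossings are timed
#: precisely on a ratio scale, which makes the two turnover rates jointly
#: identifiable from a single 8-point course — a monotone single-pulse
#: induction leaves (K_t, K_p) on a flat trade-off ridge at realistic noise.
TRAINING_TIMES = (0.0, 1.0, 2.0, 4.0, 5.0, 7.0, 9.0, 12.0)
TRAINING_TF_COURSE = (0.0, 3.0, -2.0, 1.5, -1.0, 0.5, 0.0, 0.0)


def simulate_training_pair(
    params: KineticParams,
    times=None,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """One clean TF time course and its noisy exact kinetic target.

    The underlying TF curve is fixed (:data:`TRAINING_TF_COURSE` on
    :data:`TRAINING_TIMES` by default; linearly resampled onto custom
    ``times``); the seed controls only the multiplicative noise on the
    target, so different seeds share the same underlying curves.  Mirrors
    the classic training setup of a literature-known regulator-target pair
    measured along one designed stress time course.
    """
    if times is None:
        t = np.asarray(TRAINING_TIMES, dtype=float)
        tf_values = np.asarray(TRAINING_TF_COURSE, dtype=float)
    else:
        t = np.asarray(times, dtype=float)
        tf_values = np.interp(
            np.clip(t, TRAINING_TIMES[0], TRAINING_TIMES[-1]),
            TRAINING_TIMES,
            TRAINING_TF_COURSE,
        )
    rng = np.random.default_rng(seed)
    profile = fit_stepwise_linear(t, tf_values)
    target_exact = solve_target_profile(profile, params, eval_times=t).values
    return tf_values, _mult_noise(rng, target_exact, noise_sd)


def null_meta_calibration(
    n_pairs: int = 5000,
    k: int = 9,
    n_samples: int = 12,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Meta p-values and significance levels for independent null pairs.

    Draws ``n_pairs`` independent profile pairs in each of ``k`` simulated
    partitions of ``n_samples`` standard-normal samples and pushes them
    through the package's correlation -> right-tailed p -> Fisher
    combination path.  Under this null the meta p-value must be uniform on
    [0, 1] and P(level >= 1) = 1 - (1 - alpha)^k.

    Returns (meta_p values, significance levels), each of length n_pairs.
    """
    from scipy import stats as _stats

    from .meta import DEFAULT_ALPHA, P_FLOOR

    rng = np.random.default_rng(seed)
    r = np.empty((n_pairs, k))
    for j in range(k):
        x = rng.standard_normal((n_pairs, n_samples))
        y = rng.standard_normal((n_pairs, n_samples))
        xc = x - x.mean(axis=1, keepdims=True)
        yc = y - y.mean(axis=1, keepdims=True)
        r[:, j] = (xc * yc).sum(axis=1) / np.sqrt(
            (xc * xc).sum(axis=1) * (yc * yc).sum(axis=1)
        )
    t = r * np.sqrt((n_samples - 2) / (1.0 - r * r))
    p = _stats.t.sf(t, df=n_samples - 2)
    chisq = -2.0 * np.log(np.clip(p, P_FLOOR, 1.0)).sum(axis=1)
    metap = _stats.chi2.sf(chisq, df=2 * k)
    levels = (p < DEFAULT_ALPHA).sum(axis=1)
    return metap, levels


def write_simulation(
    out_dir: str | Path,
    matrix: ExpressionMatrix,
    metadata: SampleMetadata,
    truth: RegulonTruth,
) -> dict[str, Path]:
    """Write matrix/metadata/TF-list/truth files for CLI consumption."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": out / "matrix.tsv",
        "metadata": out / "metadata.tsv",
        "tfs": out / "tfs.txt",
        "truth": out / "truth_pairs.tsv",
    }
    write_expression_matrix(matrix, paths["matrix"])
    write_sample_metadata(metadata, paths["metadata"])
    write_gene_list(truth.tf_ids, paths["tfs"])
    write_gold_standard(truth.as_gold_standard(), paths["truth"])
    return paths
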