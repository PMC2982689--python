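# Methods

## Problem and model

`kinmeta` predicts directed transcription-factor (TF) → target regulations
from a heterogeneous expression compendium (relative expression, log2 ratio
to a basal/control state).  Two ideas are combined:

1. **A kinetic time-lag model.**  A TF acts on targets only through its
   protein, so target mRNA lags TF mRNA.  Writing first-order balances for
   translation/turnover of the regulator protein and for activated
   transcription/turnover of the target mRNA, and eliminating the
   unmeasured protein concentration, yields a single linear second-order
   ODE for the relative mRNA levels R′ (TF) and T′ (target):

       d²T′/dt² + (K_p + K_t) dT′/dt + K_p K_t T′ = γ R′(t),
       T′(0) = 0,  dT′/dt(0) = 0,

   with K_t the target-mRNA turnover rate (1/h), K_p the regulator-protein
   turnover rate (1/h) and γ = K_act·K_tran·R_m,basal/T_m,basal a lumped
   gain (1/h²) that fixes the amplitude but not the shape of the response.
   In every time-series experiment each TF's measured profile is
   interpolated stepwise-linearly, the ODE is solved in closed form, and
   the resulting *theoretical target profile* is substituted for the TF's
   row before any correlation is computed.  A genuinely interacting pair
   thereby becomes coherent in time.

2. **Consensus across tissue partitions.**  Samples are partitioned by
   tissue (or experiment, or developmental stage); each partition is an
   independent dataset.  Per partition, each TF–gene pair receives a
   Pearson correlation r over the partition's samples and the exact
   right-tailed p-value of t = r√((n−2)/(1−r²)) with n−2 degrees of
   freedom.  Partitions combine by Fisher's inverse-χ² method,
   χ² = −2Σ ln pᵢ ~ χ²(2k) under the null (k = number of partitions).  The
   pair's *significance level* is the number of partitions with p < 0.01.
   Pairs rank by level, then meta χ² (equivalent to meta p at equal
   degrees of freedom, but numerically stable where meta p underflows),
   then lexicographically by ids.

Networks are cut either by a consensus level cutoff ("significant in ≥ m
of k partitions"; with k = 9, cutoffs 9/8/7 give small/medium/large
networks) or as a fixed top-k per TF.  A single-dataset Pearson baseline
(r > 0.75 or 0.70 over the unpartitioned data) is provided for comparison.
Evaluation counts directed exact-id matches against a curated gold
standard; the confirmed ratio divides by network size only.

## Analytic solution and numerics

On each interval [tᵢ, tᵢ₊₁] with local time τ = t − tᵢ and forcing
αᵢ + βᵢτ (local intercept), the solution is

    T′(τ) = Aᵢ e^(−K_p τ) + Bᵢ e^(−K_t τ) + Cᵢ + Dᵢ τ,
    Dᵢ = βᵢ γ / (K_p K_t),   Cᵢ = (αᵢ γ − (K_p + K_t) Dᵢ) / (K_p K_t),

with Aᵢ, Bᵢ fixed by the rest initial conditions at the first knot and by
continuity of T′ and dT′/dt at every interior knot (forward propagation,
one 2×2 solve per interval).  Numerical choices:

- **Local-time convention.**  Exponentials are evaluated in τ = t − tᵢ,
  never in absolute time, so late intervals stay well conditioned.
- **Repeated-root degeneracy.**  When |K_p − K_t| < 1e−8·max(K_p, K_t) the
  two-exponential basis cancels catastrophically; the solver switches to
  the exact repeated-root basis {e^(−Kτ), τe^(−Kτ)}.
- **Oracle check.**  The analytic solution is verified against an
  independent LSODA integration of the ODE (rtol 1e−10) over randomized
  rates and profiles; agreement is required at rtol 1e−6.
- **γ-linearity.**  The solution is exactly linear in γ; Pearson
  correlation is scale-invariant, so the default γ = 1 is harmless for
  network inference.

p-values are floored at 1e−300 before the log so Fisher's statistic stays
finite.  A constant profile within a partition has no defined correlation;
its p is treated as 1 (no evidence) and the pair is retained elsewhere.
Self pairs are excluded before statistics.  No multiple-testing correction
is applied: the consensus count across independent partitions is itself
the false-positive control (FDR control would be a natural extension).

## Rate estimation (`learn_params`)

Only K_t and K_p shape the response, so only they are estimated, by
bounded nonlinear least squares on a known training pair's time course:
the TF course is interpolated, the ODE solved per candidate (K_t, K_p),
and the deviation from the measured target minimized in log-rate space
over (1e−3, 1e2)²/h, multi-started from a 4×4 log-spaced grid (ftol
1e−10).  With `fix_gamma` (default) the target is normalized to unit
maximum and the residual amplitude is profiled out analytically per
candidate, making the estimate exactly invariant to rescaling the target;
γ is reported as 1.  Residuals are weighted by reciprocal measured
amplitude, floored at 2% of the peak — the approximate maximum-likelihood
weighting for multiplicative noise on a ratio scale, where points near
zero are measured precisely.

Two caveats are inherent to the model, not the optimizer:

- The ODE is exactly symmetric under exchanging K_p and K_t, so the pair
  is identifiable only up to that swap.  Estimates are returned in the
  canonical order K_t ≥ K_p (mRNA typically turns over faster than the
  protein).
- Identifiability depends strongly on the training course.  An asymptotic
  information analysis (Jacobian of the solution with respect to the
  log-rates under multiplicative noise) shows that a smooth single-pulse
  induction leaves (K_t, K_p) on a flat trade-off ridge: at 10% noise and
  8 time points the shape-constrained standard deviation of the log-rates
  is ≈ 0.2–0.7, far too large to resolve the rates.  The default training
  course is therefore a *damped oscillatory induction–relaxation design*
  (log2-ratios 0, 3, −2, 1.5, −1, 0.5, 0, 0 at 0, 1, 2, 4, 5, 7, 9, 12 h):
  an oscillating forcing probes the lag dynamics at several phases and the
  response's zero crossings are timed precisely on a ratio scale, bringing
  the asymptotic sd down to ≈ 0.04 and making 15%-accurate recovery
  routine.  With a monotone real-world training pair the fitted rates
  should be treated as an effective time-lag scale, not as measured
  turnover rates.

One global (K_t, K_p) pair is used for all TFs, as learned from a single
designated training pair; per-TF rates can be passed explicitly if
desired.  The working default (K_t, K_p) = (2.0, 1.0)/h corresponds to
mRNA and protein half-lives of ≈ 21 and 42 minutes — fast, stress-scale
turnover.  The transform applies only to experiments carrying time
annotations; TF profiles in steady-state samples enter correlation
untransformed (the only self-consistent treatment of a mixed compendium).

## Data preparation and partitioning

Pipeline order: average replicate columns → drop genes with any missing
value → keep genes with max |log2 ratio| ≥ 1.0 somewhere (two-fold;
"differentially expressed at least once" is a qualitative criterion with
no standard formula, so the threshold is an explicit, configurable
convention) → partition.  Boundaries are inclusive ("at least") both for
the threshold and for the minimum partition size (default 9 samples).
Labels below the size floor pool into one reserved `combined_rest`
partition, which counts as a dataset in the meta-analysis; a real tissue
named `combined_rest` is rejected.  Samples without a developmental-stage
record fall into `combined_rest` under that scheme.  The level cutoff is
read as "at least m of k" — a cutoff equal to k can be met, never
exceeded.  When both selection rules are requested, the consensus rule
wins; rank-tied blocks truncate after the lexicographic tie-break.

## Synthetic compendium

`simulate_compendium` emulates the intended input: k tissues (default 9,
12 samples each), half the tissues carrying a stress time course on a
0–24 h grid (0, 1, 3, 6, 12, 24 h, a typical abiotic-stress design), the
rest steady-state condition collections.  TF responses in time courses
are sums of 1–2 random decaying pulses a(t/τ)e^(1−t/τ); each active
target is the *exact* analytic lag-model response to its TF's clean
course, times multiplicative log-space noise e^(σZ) (default σ = 0.15).
In steady-state experiments active targets track their TF's per-sample
level with the same noise.  Regulons are active in an exact number of
tissues (round(active_fraction·k)), so consensus levels are predictable.
Background genes and inactive-tissue targets are independent noise around
zero.  Randomness uses numpy's seeded PCG64 generator, portable across
platforms.

Not emulated: probe/platform artifacts, batch effects, correlated
background co-expression, repression (responses are activator-signed to
match the right-tailed statistics), and missing-value patterns beyond
what the preparation stage needs.  Passing recovery tests therefore
demonstrates internal consistency of the full pipeline under the model's
own assumptions — not performance on real arrays, where co-expressed
non-targets, tissue-specific regulation and unmodelled noise lower
precision substantially.

## Problem sizes used in tests

The packaged experiments run at desk scale, chosen to exercise every code
path with comfortable statistical margins: 20 TFs × 10 targets + 500
background genes over 9 tissues for regulon recovery; 200 replicates for
rate recovery; 5,000 pairs for null calibration; 200 randomized draws for
the ODE oracle.

## Known limitations

- Right-tailed statistics detect activation only; a two-sided mode exists
  (`two_sided` p would double-count repression) but is off by default.
- The method cannot distinguish true targets from co-expressed
  non-targets; consensus across tissues reduces but does not remove this.
- One global rate pair ignores TF-to-TF variation in protein stability.
- The differential-expression and correlation cutoffs are conventions;
  results should be read relative to them.
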