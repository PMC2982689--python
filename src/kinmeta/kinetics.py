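"""Chemical-kinetics time-lag model linking a TF's mRNA to its targets' mRNA.

A TF acts on its targets only after its transcript is translated and the
protein reaches the nucleus, so a target's mRNA response lags the TF's.  Two
coupled first-order kinetic balances — translation/turnover of the regulator
protein and activated transcription/turnover of the target mRNA — collapse,
after eliminating the unmeasured protein concentration, into one linear
second-order ODE for the relative (fold-change minus one) mRNA levels:

    d2T'/dt2 + (K_p + K_t) dT'/dt + K_p K_t T' = gamma * R'(t)

with R'(t) the TF's relative mRNA level, K_t the target-mRNA turnover rate,
K_p the regulator-protein turnover rate (both 1/hour), and gamma a lumped
gain that sets the amplitude but not the shape of the response.  At stress
onset both T' and its derivative are zero.

The measured TF profile is interpolated by a stepwise-linear function, which
makes the ODE solvable in closed form on each interval:

    T'(tau) = A_i e^{-K_p tau} + B_i e^{-K_t tau} + C_i + D_i tau

(tau = t - t_i, local to the interval; the local-time convention keeps the
exponentials well conditioned at late times).  A_i, B_i follow from the
initial conditions and from continuity of T' and dT'/dt at each knot; C_i,
D_i are the polynomial particular solution, D_i = beta_i gamma / (K_p K_t)
and C_i = (alpha_i gamma - (K_p + K_t) D_i) / (K_p K_t) with alpha_i the
interval's local intercept.

The theoretical target profile computed this way is substituted for the TF's
own measured profile in every time-series experiment before correlation, so
that a genuinely interacting TF-target pair becomes coherent in time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .io import ExpressionMatrix, SampleMetadata, ValidationError

#: Relative |K_p - K_t| gap below which the repeated-root closed form is used.
_REPEATED_ROOT_RTOL = 1e-8

#: Bounds (1/hour) for the turnover-rate search in :func:`learn_params`.
RATE_BOUNDS = (1e-3, 1e2)

#: Relative-amplitude floor on the regression weights in :func:`learn_params`.
WEIGHT_FLOOR_FRACTION = 0.02


class ConvergenceError(RuntimeError):
    """The nonlinear regression failed to converge from every start."""


@dataclass(frozen=True)
class KineticParams:
    """Turnover rates and lumped gain of the lag model.

    k_t : target mRNA turnover rate, 1/hour.
    k_p : regulator protein turnover rate, 1/hour.
    gamma : lumped gain K_act*K_tran*R_m,basal/T_m,basal, 1/hour^2.  Scales
        the response amplitude only; Pearson correlation is scale-invariant,
        so gamma = 1 is the working default.
    """

    k_t: float
    k_p: float
    gamma: float = 1.0

    def __post_init__(self) -> None:
        for name in ("k_t", "k_p", "gamma"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be positive and finite, got {v}")


@dataclass
class StepwiseProfile:
    """Continuous piecewise-linear interpolant of a measured TF profile.

    On [t_i, t_{i+1}] the profile is alpha_i + beta_i * t (global-time
    coefficients).  It passes exactly through the measured values at the
    knots.
    """

    knots: np.ndarray
    alpha: np.ndarray
    beta: np.ndarray

    @property
    def n_intervals(self) -> int:
        return len(self.knots) - 1

    def __call__(self, t: np.ndarray | float) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        i = self._interval_index(t)
        return self.alpha[i] + self.beta[i] * t

    def _interval_index(self, t: np.ndarray) -> np.ndarray:
        if np.any(t < self.knots[0]) or np.any(t > self.knots[-1]):
            raise ValueError(
                f"time outside knot range [{self.knots[0]}, {self.knots[-1]}]"
            )
        return np.clip(
            np.searchsorted(self.knots, t, side="right") - 1, 0, self.n_intervals - 1
        )


@dataclass
class TheoreticalProfile:
    """Piecewise analytic solution T'(t) of the lag ODE.

    Coefficient rows are (A_i, B_i, C_i, D_i) in the interval-local time
    convention tau = t - t_i.  With distinct rates the basis is
    {e^{-K_p tau}, e^{-K_t tau}}; in the repeated-root degeneracy
    K_p == K_t it is {e^{-K tau}, tau e^{-K tau}} and B_i multiplies
    tau e^{-K tau}.
    """

    knots: np.ndarray
    coeffs: np.ndarray  # (n_intervals, 4)
    params: KineticParams
    repeated_root: bool
    eval_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    values: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __call__(self, t: np.ndarray | float) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        scalar = t.ndim == 0
        t = np.atleast_1d(t)
        i = self._interval_index(t)
        tau = t - self.knots[i]
        A, B, C, D = (self.coeffs[i, j] for j in range(4))
        kp, kt = self.params.k_p, self.params.k_t
        if self.repeated_root:
            out = (A + B * tau) * np.exp(-kp * tau) + C + D * tau
        else:
            out = A * np.exp(-kp * tau) + B * np.exp(-kt * tau) + C + D * tau
        return out[0] if scalar else out

    def derivative(self, t: np.ndarray | float) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, dtype=float))
        i = self._interval_index(t)
        tau = t - self.knots[i]
        A, B, C, D = (self.coeffs[i, j] for j in range(4))
        kp, kt = self.params.k_p, self.params.k_t
        if self.repeated_root:
            e = np.exp(-kp * tau)
            return (B - kp * (A + B * tau)) * e + D
        return -kp * A * np.exp(-kp * tau) - kt * B * np.exp(-kt * tau) + D

    def _interval_index(self, t: np.ndarray) -> np.ndarray:
        eps = 1e-9 * max(1.0, abs(float(self.knots[-1])))
        if np.any(t < self.knots[0] - eps) or np.any(t > self.knots[-1] + eps):
            raise ValueError(
                f"eval time outside knot range [{self.knots[0]}, {self.knots[-1]}]"
            )
        return np.clip(
            np.searchsorted(self.knots, t, side="right") - 1, 0, len(self.knots) - 2
        )


def fit_stepwise_linear(times, values) -> StepwiseProfile:
    """Exact piecewise-linear interpolant through (times, values).

    Times must be strictly increasing with at least two points; the
    coefficients on each interval are determined by the two adjacent
    measurements.
    """
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.ndim != 1 or t.shape != v.shape:
        raise ValueError("times and values must be 1-D and of equal length")
    if len(t) < 2:
        raise ValueError(f"need at least 2 time points, got {len(t)}")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing (no duplicates)")
    if not (np.all(np.isfinite(t)) and np.all(np.isfinite(v))):
        raise ValueError("times and values must be finite")
    beta = np.diff(v) / np.diff(t)
    alpha = v[:-1] - beta * t[:-1]
    return StepwiseProfile(knots=t, alpha=alpha, beta=beta)


def solve_target_profile(
    profile: StepwiseProfile,
    params: KineticParams,
    eval_times=None,
) -> TheoreticalProfile:
    """Solve the lag ODE analytically for a stepwise-linear TF profile.

    Integrates forward interval by interval from rest (T' = dT'/dt = 0 at
    the first knot), choosing A_i, B_i on each interval so that the value
    and derivative are continuous at every knot.
    """
    kp, kt, gamma = params.k_p, params.k_t, params.gamma
    repeated = abs(kp - kt) < _REPEATED_ROOT_RTOL * max(kp, kt)
    knots = profile.knots
    n = profile.n_intervals
    coeffs = np.zeros((n, 4))
    value, deriv = 0.0, 0.0  # rest at stress onset
    kk = kp * kt
    for i in range(n):
        # forcing in local time: alpha_loc + beta * tau
        alpha_loc = profile.alpha[i] + profile.beta[i] * knots[i]
        beta = profile.beta[i]
        D = beta * gamma / kk
        C = (alpha_loc * gamma - (kp + kt) * D) / kk
        u = value - C
        w = deriv - D
        if repeated:
            A = u
            B = w + kp * A
        else:
            A = (w + kt * u) / (kt - kp)
            B = u - A
        coeffs[i] = (A, B, C, D)
        dt = knots[i + 1] - knots[i]
        if repeated:
            e = np.exp(-kp * dt)
            value = (A + B * dt) * e + C + D * dt
            deriv = (B - kp * (A + B * dt)) * e + D
        else:
            ep, et = np.exp(-kp * dt), np.exp(-kt * dt)
            value = A * ep + B * et + C + D * dt
            deriv = -kp * A * ep - kt * B * et + D
    theo = TheoreticalProfile(
        knots=knots, coeffs=coeffs, params=params, repeated_root=repeated
    )
    if eval_times is not None:
        theo.eval_times = np.asarray(eval_times, dtype=float)
        theo.values = theo(theo.eval_times)
    return theo


@dataclass
class FitDiagnostics:
    """Outcome of the nonlinear regression in :func:`learn_params`."""

    cost: float
    n_starts: int
    n_converged: int
    residual_norm: float
    scale: float


def _model_curve(kt: float, kp: float, profile: StepwiseProfile, times: np.ndarray) -> np.ndarray:
    params = KineticParams(k_t=kt, k_p=kp, gamma=1.0)
    return solve_target_profile(profile, params)(times)


def learn_params(
    tf_values,
    target_values,
    times,
    fix_gamma: bool = True,
) -> tuple[KineticParams, FitDiagnostics]:
    """Estimate (K_t, K_p) by nonlinear regression on a known TF-target pair.

    The TF profile is interpolated stepwise-linearly and the lag ODE solved
    for candidate rates; the squared deviation from the measured target
    profile is minimized by bounded least squares in log-rate space, with
    multi-start from a 4x4 log-spaced grid over ``RATE_BOUNDS``.

    With ``fix_gamma`` (default) the target is normalized to unit maximum
    response and the remaining amplitude is profiled out analytically per
    candidate — gamma sets magnitude, not shape, so it is not a free shape
    parameter and is reported as 1.  Without it gamma is fitted jointly.
    Either way the estimate is invariant to rescaling the target.

    Residuals are weighted by the reciprocal measured amplitude (floored at
    2% of the peak), matching the multiplicative error structure of relative
    expression data: points where the response passes through zero are
    measured precisely on a ratio scale and carry strong timing information.

    The ODE is symmetric under swapping K_p and K_t, so the pair is
    identifiable only up to that exchange; estimates are returned in the
    canonical order K_t >= K_p (mRNA typically turns over faster than
    protein).
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(target_values, dtype=float)
    if len(t) < 4:
        raise ValueError(f"need at least 4 time points, got {len(t)}")
    if np.ptp(y) == 0:
        raise ValueError("target profile is constant; rates are unidentifiable")
    profile = fit_stepwise_linear(t, tf_values)

    if fix_gamma:
        y_fit = y / np.max(np.abs(y))
    else:
        y_fit = y

    peak = np.max(np.abs(y_fit))
    weights = 1.0 / np.maximum(np.abs(y_fit), WEIGHT_FLOOR_FRACTION * peak)

    lo, hi = np.log(RATE_BOUNDS[0]), np.log(RATE_BOUNDS[1])

    def residuals(x: np.ndarray) -> np.ndarray:
        kt, kp = np.exp(x[0]), np.exp(x[1])
        m = _model_curve(kt, kp, profile, t)
        if fix_gamma:
            wm = weights * m
            mm = float(wm @ wm)
            s = float(wm @ (weights * y_fit)) / mm if mm > 0 else 0.0
        else:
            s = np.exp(x[2])
        return weights * (s * m - y_fit)

    grid = np.log(np.geomspace(RATE_BOUNDS[0], RATE_BOUNDS[1], 4))
    best = None
    n_converged = 0
    for g_kt in grid:
        for g_kp in grid:
            x0 = [g_kt, g_kp] if fix_gamma else [g_kt, g_kp, 0.0]
            bounds = ([lo] * 2, [hi] * 2) if fix_gamma else ([lo, lo, -50.0], [hi, hi, 50.0])
            try:
                res = least_squares(
                    residuals, x0, bounds=bounds, ftol=1e-10, xtol=1e-12, gtol=1e-10
                )
            except Exception:
                continue
            if not res.success:
                continue
            n_converged += 1
            if best is None or res.cost < best.cost:
                best = res
    if best is None:
        raise ConvergenceError("nonlinear regression failed from every start")

    kt_hat, kp_hat = float(np.exp(best.x[0])), float(np.exp(best.x[1]))
    if kt_hat < kp_hat:  # canonical order under the swap symmetry
        kt_hat, kp_hat = kp_hat, kt_hat
    if fix_gamma:
        gamma_hat = 1.0
        m = _model_curve(kt_hat, kp_hat, profile, t)
        mm = float(m @ m)
        scale = float(m @ y_fit) / mm if mm > 0 else 0.0
    else:
        gamma_hat = float(np.exp(best.x[2]))
        scale = gamma_hat
    diag = FitDiagnostics(
        cost=float(best.cost),
        n_starts=len(grid) ** 2,
        n_converged=n_converged,
        residual_norm=float(np.linalg.norm(best.fun)),
        scale=scale,
    )
    return KineticParams(k_t=kt_hat, k_p=kp_hat, gamma=gamma_hat), diag


def transform_tf_profiles(
    matrix: ExpressionMatrix,
    tf_set: set[str],
    params: KineticParams,
    metadata: SampleMetadata,
) -> ExpressionMatrix:
    """Replace TF rows by theoretical target profiles in time-series blocks.

    Within each experiment that carries time annotations, every TF's
    measured values (ordered by time) are interpolated, the lag ODE solved,
    and the theoretical target profile evaluated at the same times written
    back over the TF's row.  Non-TF rows, non-time-series experiments and
    untimed samples are untouched; a compendium with no time series passes
    through unchanged.  TFs absent from the matrix are warned about and
    skipped.
    """
    metadata.require_samples(matrix.sample_ids)
    missing = sorted(tf_set - set(matrix.gene_ids))
    if missing:
        warnings.warn(
            f"{len(missing)} TF ids absent from matrix, skipped: {missing[:5]}...",
            stacklevel=2,
        )
    tfs = [g for g in matrix.gene_ids if g in tf_set]
    out = matrix.data.copy()
    meta = metadata.subset(matrix.sample_ids)
    for exp in meta.time_series_experiments():
        rows = meta.table[
            (meta.table["experiment_id"] == exp) & meta.table["time_hours"].notna()
        ]
        if len(rows) < 2:
            continue
        order = rows["time_hours"].sort_values().index
        times = rows.loc[order, "time_hours"].to_numpy(dtype=float)
        if np.any(np.diff(times) <= 0):
            raise ValidationError(
                f"experiment {exp!r} has duplicate time points; "
                "average replicates before the kinetic transform"
            )
        for tf in tfs:
            v = out.loc[tf, order].to_numpy(dtype=float)
            if np.any(np.isnan(v)):
                continue  # missing values are handled by the upstream filter
            profile = fit_stepwise_linear(times, v)
            theo = solve_target_profile(profile, params, eval_times=times)
            out.loc[tf, order] = theo.values
    return ExpressionMatrix(out)
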