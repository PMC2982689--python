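import numpy as np
import pandas as pd
import pytest
from scipy.integrate import solve_ivp

from kinmeta import (
    ExpressionMatrix,
    KineticParams,
    SampleMetadata,
    fit_stepwise_linear,
    learn_params,
    simulate_training_pair,
    solve_target_profile,
    transform_tf_profiles,
)
from kinmeta.simulate import TRAINING_TIMES


def integrate_lag_ode(profile, params, eval_times):
    """Independent numerical oracle: integrate the lag ODE as a 1st-order system."""

    def rhs(t, y):
        return [
            y[1],
            params.gamma * float(profile(t))
            - (params.k_p + params.k_t) * y[1]
            - params.k_p * params.k_t * y[0],
        ]

    knots = profile.knots
    y = np.array([0.0, 0.0])
    out = {float(knots[0]): 0.0}
    times = np.asarray(eval_times, dtype=float)
    for i in range(len(knots) - 1):
        seg = times[(times > knots[i]) & (times <= knots[i + 1])]
        t_eval = np.unique(np.concatenate([seg, [knots[i + 1]]]))
        sol = solve_ivp(
            rhs,
            (knots[i], knots[i + 1]),
            y,
            t_eval=t_eval,
            rtol=1e-10,
            atol=1e-12,
            method="LSODA",
        )
        for t, v in zip(sol.t, sol.y[0]):
            out[float(t)] = float(v)
        y = sol.y[:, -1]
    return np.array([out[float(t)] for t in times])


class TestStepwiseFit:
    def test_single_interval(self):
        p = fit_stepwise_linear([0.0, 1.0], [0.0, 2.0])
        assert p.alpha[0] == pytest.approx(0.0)
        assert p.beta[0] == pytest.approx(2.0)

    def test_constant_profile(self):
        p = fit_stepwise_linear([0.0, 1.0, 2.0], [3.5, 3.5, 3.5])
        assert np.allclose(p.beta, 0.0)
        assert np.allclose(p.alpha, 3.5)

    def test_hand_interpolation(self):
        p = fit_stepwise_linear([0.0, 1.0, 3.0], [1.0, 2.0, 0.0])
        assert (p.alpha[0], p.beta[0]) == pytest.approx((1.0, 1.0))
        assert (p.alpha[1], p.beta[1]) == pytest.approx((3.0, -1.0))

    def test_interpolates_measurements_exactly(self):
        rng = np.random.default_rng(3)
        t = np.sort(rng.uniform(0, 24, 7))
        v = rng.normal(0, 2, 7)
        p = fit_stepwise_linear(t, v)
        assert np.allclose(p(t), v, atol=1e-12)

    @pytest.mark.parametrize(
        "times,values,msg",
        [
            ([0.0, 0.0, 1.0], [1, 2, 3], "strictly increasing"),
            ([0.0], [1.0], "at least 2"),
        ],
    )
    def test_invalid_inputs(self, times, values, msg):
        with pytest.raises(ValueError, match=msg):
            fit_stepwise_linear(times, values)


class TestSolveTargetProfile:
    def test_zero_forcing_zero_response(self):
        p = fit_stepwise_linear([0, 2, 5], [0.0, 0.0, 0.0])
        theo = solve_target_profile(p, KineticParams(2.0, 1.0, 1.0), [0, 1, 2, 3, 5])
        assert np.allclose(theo.values, 0.0, atol=1e-14)

    def test_single_interval_closed_form(self):
        # constant forcing alpha=1: T = (g/KpKt)[1 - (Kt e^{-Kp t} - Kp e^{-Kt t})/(Kt-Kp)]
        p = fit_stepwise_linear([0.0, 10.0], [1.0, 1.0])
        theo = solve_target_profile(p, KineticParams(k_t=2.0, k_p=1.0, gamma=2.0), [1.0])
        assert theo.values[0] == pytest.approx(0.39958, abs=1e-5)

    def test_stationary_limit_constant_forcing(self):
        c, params = 1.7, KineticParams(k_t=2.0, k_p=0.8, gamma=1.3)
        p = fit_stepwise_linear([0.0, 200.0], [c, c])
        theo = solve_target_profile(p, params, [200.0])
        assert theo.values[0] == pytest.approx(
            params.gamma * c / (params.k_p * params.k_t), rel=1e-9
        )

    def test_matches_numerical_integration_randomized(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            t = np.sort(rng.uniform(0, 24, rng.integers(3, 8)))
            t[0] = 0.0
            v = rng.normal(0, 2, len(t))
            params = KineticParams(*np.exp(rng.uniform(np.log(0.05), np.log(5), 3)))
            profile = fit_stepwise_linear(t, v)
            theo = solve_target_profile(profile, params, eval_times=t)
            ref = integrate_lag_ode(profile, params, t)
            assert np.allclose(theo.values, ref, rtol=1e-6, atol=1e-9)

    def test_repeated_root_degeneracy(self):
        t = np.array([0.0, 1.0, 4.0, 9.0])
        v = np.array([0.0, 2.0, -1.0, 0.5])
        profile = fit_stepwise_linear(t, v)
        params = KineticParams(k_t=1.3, k_p=1.3, gamma=1.0)
        theo = solve_target_profile(profile, params, eval_times=t)
        assert theo.repeated_root
        ref = integrate_lag_ode(profile, params, t)
        assert np.allclose(theo.values, ref, rtol=1e-6, atol=1e-9)
        # nearly-degenerate rates agree with the exactly-degenerate form
        near = solve_target_profile(
            profile, KineticParams(1.3 * (1 + 1e-7), 1.3, 1.0), eval_times=t
        )
        assert np.allclose(near.values, theo.values, rtol=1e-5)

    def test_continuity_at_interior_knots(self):
        rng = np.random.default_rng(5)
        t = np.sort(rng.uniform(0, 20, 6))
        t[0] = 0.0
        profile = fit_stepwise_linear(t, rng.normal(0, 2, 6))
        theo = solve_target_profile(profile, KineticParams(2.0, 0.7, 1.5))
        for ti in t[1:-1]:
            below, above = ti - 1e-12, ti + 1e-12
            assert abs(theo(below) - theo(above)) < 1e-9
            assert abs(theo.derivative(below) - theo.derivative(above)) < 1e-9

    def test_gamma_linearity(self):
        t = np.array([0.0, 1.0, 3.0, 6.0, 12.0])
        profile = fit_stepwise_linear(t, [0.0, 2.0, 1.0, -0.5, 0.0])
        base = solve_target_profile(profile, KineticParams(2.0, 1.0, 1.0), t).values
        for n in (3.0, 0.25, 7.5):
            scaled = solve_target_profile(profile, KineticParams(2.0, 1.0, n), t).values
            assert np.allclose(scaled, n * base, rtol=1e-12)

    def test_causal_lag_for_step_increase(self):
        # step forcing from onset: response starts at 0, rises, peaks later
        t_dense = np.linspace(0, 10, 400)
        profile = fit_stepwise_linear([0.0, 10.0], [2.0, 2.0])
        theo = solve_target_profile(profile, KineticParams(2.0, 1.0, 1.0))
        vals = theo(t_dense)
        assert vals[0] == pytest.approx(0.0, abs=1e-14)
        assert np.argmax(vals) > 0
        assert vals[1] > 0  # strictly rising after onset

    def test_eval_outside_range_rejected(self):
        profile = fit_stepwise_linear([0.0, 5.0], [1.0, 1.0])
        theo = solve_target_profile(profile, KineticParams(1.0, 2.0, 1.0))
        with pytest.raises(ValueError, match="outside"):
            theo(6.0)

    def test_invalid_rates_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            KineticParams(k_t=-1.0, k_p=1.0)
        with pytest.raises(ValueError, match="positive"):
            KineticParams(k_t=1.0, k_p=1.0, gamma=0.0)


class TestLearnParams:
    def test_noiseless_round_trip(self):
        true = KineticParams(k_t=2.0, k_p=1.0, gamma=1.0)
        tf, tg = simulate_training_pair(true, noise_sd=0.0, seed=0)
        est, diag = learn_params(tf, tg, TRAINING_TIMES)
        assert est.k_t == pytest.approx(2.0, rel=1e-3)
        assert est.k_p == pytest.approx(1.0, rel=1e-3)
        assert diag.cost < 1e-12

    def test_scale_invariance_of_estimates(self):
        true = KineticParams(k_t=1.5, k_p=0.6, gamma=1.0)
        tf, tg = simulate_training_pair(true, noise_sd=0.05, seed=7)
        est1, _ = learn_params(tf, tg, TRAINING_TIMES)
        est2, _ = learn_params(tf, 5.0 * tg, TRAINING_TIMES)
        assert est2.k_t == pytest.approx(est1.k_t, rel=1e-6)
        assert est2.k_p == pytest.approx(est1.k_p, rel=1e-6)

    def test_flat_target_rejected(self):
        tf = np.array([0.0, 1.0, 2.0, 1.0, 0.0])
        with pytest.raises(ValueError, match="constant"):
            learn_params(tf, np.zeros(5), [0, 1, 2, 3, 4])

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="at least 4"):
            learn_params([0, 1, 2], [0, 1, 2], [0, 1, 2])


def _ts_matrix_and_meta():
    times = [0.0, 1.0, 3.0, 6.0, 12.0]
    samples = [f"t{i}" for i in range(5)] + ["c1", "c2", "c3"]
    rng = np.random.default_rng(0)
    data = pd.DataFrame(
        rng.normal(0, 1, (3, 8)), index=["TF1", "g1", "g2"], columns=samples
    )
    data.loc["TF1", samples[:5]] = [0.0, 2.0, 1.5, 0.5, 0.0]
    meta = pd.DataFrame(
        {
            "experiment_id": ["E1"] * 5 + ["E2"] * 3,
            "tissue": ["root"] * 8,
            "time_hours": times + [np.nan] * 3,
        },
        index=pd.Index(samples, name="sample_id"),
    )
    return ExpressionMatrix(data), SampleMetadata(meta), np.asarray(times)


class TestTransformTfProfiles:
    def test_no_time_series_identity(self, small_matrix):
        meta = pd.DataFrame(
            {
                "experiment_id": ["E1"] * 4,
                "tissue": ["root"] * 4,
                "time_hours": [np.nan] * 4,
            },
            index=pd.Index(small_matrix.sample_ids, name="sample_id"),
        )
        out = transform_tf_profiles(
            small_matrix,
            {"At1g01010"},
            KineticParams(2.0, 1.0, 1.0),
            SampleMetadata(meta),
        )
        pd.testing.assert_frame_equal(out.data, small_matrix.data)

    def test_tf_row_equals_solver_output(self):
        matrix, metadata, times = _ts_matrix_and_meta()
        params = KineticParams(2.0, 1.0, 1.0)
        out = transform_tf_profiles(matrix, {"TF1"}, params, metadata)
        profile = fit_stepwise_linear(times, [0.0, 2.0, 1.5, 0.5, 0.0])
        expected = solve_target_profile(profile, params, eval_times=times).values
        got = out.data.loc["TF1"].to_numpy()[:5]
        assert np.allclose(got, expected, atol=1e-12)

    def test_non_tf_rows_and_steady_columns_unchanged(self):
        matrix, metadata, _ = _ts_matrix_and_meta()
        out = transform_tf_profiles(
            matrix, {"TF1"}, KineticParams(2.0, 1.0, 1.0), metadata
        )
        pd.testing.assert_frame_equal(
            out.data.loc[["g1", "g2"]], matrix.data.loc[["g1", "g2"]]
        )
        assert (
            out.data.loc["TF1", ["c1", "c2", "c3"]]
            == matrix.data.loc["TF1", ["c1", "c2", "c3"]]
        ).all()

    def test_missing_tf_warned_and_skipped(self):
        matrix, metadata, _ = _ts_matrix_and_meta()
        with pytest.warns(UserWarning, match="absent"):
            out = transform_tf_profiles(
                matrix, {"TF1", "TF_ghost"}, KineticParams(2.0, 1.0, 1.0), metadata
            )
        assert "TF_ghost" not in out.gene_ids
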