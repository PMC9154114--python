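"""Kernels, covariances, msd limits, and the log-derivative curve."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from tempertrack.models import (
    Model,
    ModelSpec,
    ParamVector,
    beta_curve,
    covariance_matrix,
    first_moment,
    msd,
    position_covariance,
    velocity_kernel,
)

from conftest import example_specs


def kernel_double_integral(spec: ModelSpec, t: float, t2: float) -> float:
    """Independent oracle: integrate the velocity kernel twice.

    Uses the change of variables that reduces the stationary double
    integral to 1-D pieces, J(s) = ∫₀^s (s−u)·k(u) du, with adaptive
    quadrature absorbing the integrable τ^{2H−2} singularity:
    ∫₀ᵗ∫₀ᵗ' k(|t₁−t₂|) = J(t) + J(t') − J(|t−t'|).
    """

    def J(s: float) -> float:
        if s == 0:
            return 0.0
        val, _ = quad(
            lambda u: (s - u) * float(velocity_kernel(spec, u)),
            0.0,
            s,
            points=[0.0],
            limit=200,
        )
        return val

    return J(t) + J(t2) - J(abs(t - t2))


class TestVelocityKernel:
    def test_model_d_at_zero_lag_is_mean_squared_velocity(self):
        spec = ModelSpec(Model.D, ParamVector(gamma=2.0, v_m2=4.0, v_d=0.0))
        assert velocity_kernel(spec, 0.0) == pytest.approx(4.0)

    def test_b_with_huge_tempering_time_reduces_to_a(self):
        a = ModelSpec(Model.A, ParamVector(H=0.76, D_H=39.01, v_d=0.0))
        # exp(−τ/τ*) differs from 1 by τ/τ* itself, so τ* must exceed
        # τ/tolerance for the reduction to hold at 1e−9 relative
        b = ModelSpec(Model.B, ParamVector(H=0.76, D_H=39.01, v_d=0.0, tau_star=1e12))
        for tau in (0.1, 1.0, 10.0):
            assert velocity_kernel(b, tau) == pytest.approx(
                float(velocity_kernel(a, tau)), rel=1e-9
            )

    def test_c_without_tempering_exponent_equals_a(self):
        a = ModelSpec(Model.A, ParamVector(H=0.76, D_H=39.01, v_d=0.0))
        c = ModelSpec(Model.C, ParamVector(H=0.76, D_H=39.01, v_d=0.0, tau_star=4.0, mu=0.0))
        taus = np.array([0.05, 0.5, 5.0, 25.0])
        np.testing.assert_allclose(velocity_kernel(c, taus), velocity_kernel(a, taus))

    def test_zero_lag_rejected_for_singular_kernels(self):
        spec = ModelSpec(Model.A, ParamVector(H=0.76, D_H=1.0, v_d=0.0))
        with pytest.raises(ValueError):
            velocity_kernel(spec, 0.0)

    def test_brownian_limit_defers_to_covariance_forms(self):
        spec = ModelSpec(Model.A, ParamVector(H=0.5, D_H=1.0, v_d=0.0))
        with pytest.raises(ValueError, match="delta"):
            velocity_kernel(spec, 1.0)


class TestPositionCovariance:
    def test_brownian_covariance_is_2d_min(self):
        spec = ModelSpec(Model.A, ParamVector(H=0.5, D_H=1.0, v_d=0.0))
        assert position_covariance(spec, 2.0, 3.0) == pytest.approx(4.0)
        assert position_covariance(spec, 3.0, 2.0) == pytest.approx(4.0)

    @pytest.mark.parametrize("model_id", ["A", "B", "C", "D"])
    def test_closed_form_matches_kernel_double_integration(self, model_id):
        """Covariances are the double integral of the velocity kernels."""
        spec = example_specs()[model_id]
        for t, t2 in [(3.0, 5.0), (30.0, 30.0), (1.0, 12.0)]:
            oracle = kernel_double_integral(spec, t, t2)
            closed = float(position_covariance(spec, t, t2))
            assert closed == pytest.approx(oracle, rel=1e-5)

    def test_wt_msd_matches_double_integration_at_30min(self, wt_y_spec):
        oracle = kernel_double_integral(wt_y_spec, 30.0, 30.0)
        assert float(msd(wt_y_spec, 30.0)) == pytest.approx(oracle, rel=1e-5)

    @pytest.mark.parametrize("model_id", ["A", "B", "C", "D"])
    def test_symmetry(self, model_id):
        spec = example_specs()[model_id]
        t = np.array([[0.5], [7.0], [21.0]])
        np.testing.assert_allclose(
            position_covariance(spec, t, t.T), position_covariance(spec, t.T, t)
        )

    def test_diagonal_equals_centered_msd(self):
        for spec in example_specs().values():
            t = np.array([0.5, 3.0, 17.0])
            np.testing.assert_allclose(
                position_covariance(spec, t, t), msd(spec, t, centered=True)
            )

    def test_nesting_b_and_c_reduce_to_a_elementwise(self):
        grid = np.linspace(0.25, 30.0, 40)
        a = ModelSpec(Model.A, ParamVector(H=0.76, D_H=39.01, v_d=0.0))
        b = ModelSpec(Model.B, ParamVector(H=0.76, D_H=39.01, v_d=0.0, tau_star=1e9))
        c = ModelSpec(Model.C, ParamVector(H=0.76, D_H=39.01, v_d=0.0, tau_star=4.0, mu=0.0))
        Ca = covariance_matrix(a, grid, jitter=0)
        np.testing.assert_allclose(covariance_matrix(b, grid, jitter=0), Ca, atol=1e-6 * Ca.max())
        np.testing.assert_allclose(covariance_matrix(c, grid, jitter=0), Ca, atol=1e-12 * Ca.max())

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(
        H=st.floats(0.55, 0.95),
        model_id=st.sampled_from(["A", "B", "C"]),
        tau=st.floats(0.5, 25.0),
        mu=st.floats(0.0, 3.5),
    )
    def test_kernel_integral_consistency_random_draws(self, H, model_id, tau, mu):
        """Closed forms track the kernel double integral across the prior range."""
        params = dict(H=H, D_H=10.0, v_d=0.0)
        if model_id in ("B", "C"):
            params["tau_star"] = tau
        if model_id == "C":
            params["mu"] = mu
        spec = ModelSpec(Model(model_id), ParamVector(**params))
        oracle = kernel_double_integral(spec, 2.0, 6.0)
        assert float(position_covariance(spec, 2.0, 6.0)) == pytest.approx(oracle, rel=1e-4)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        H=st.floats(0.05, 0.95),
        model_id=st.sampled_from(["A", "B", "C", "D"]),
        tau=st.floats(0.5, 25.0),
        mu=st.floats(0.0, 3.5),
    )
    def test_covariance_matrices_factorize(self, H, model_id, tau, mu):
        """Valid parameters give (jittered) positive-definite matrices."""
        if model_id == "D":
            spec = ModelSpec(Model.D, ParamVector(gamma=max(tau, 0.5), v_m2=25.0, v_d=0.0))
        else:
            params = dict(H=H, D_H=10.0, v_d=0.0)
            if model_id in ("B", "C"):
                params["tau_star"] = tau
            if model_id == "C":
                params["mu"] = mu
            spec = ModelSpec(Model(model_id), ParamVector(**params))
        grid = np.linspace(1 / 12, 30.0, 120)
        np.linalg.cholesky(covariance_matrix(spec, grid))  # raises on failure


class TestMsd:
    def test_brownian_msd_is_2dt(self):
        spec = ModelSpec(Model.A, ParamVector(H=0.5, D_H=1.0, v_d=0.0))
        assert float(msd(spec, 3.0)) == pytest.approx(6.0)

    def test_ou_ballistic_and_diffusive_regimes(self):
        spec = ModelSpec(Model.D, ParamVector(gamma=1.0, v_m2=4.0, v_d=0.0))
        t_small, t_large = 1e-3, 1e3
        assert float(msd(spec, t_small)) == pytest.approx(4.0 * t_small**2, rel=1e-3)
        assert float(msd(spec, t_large)) == pytest.approx(2 * 4.0 * t_large, rel=5e-3)

    def test_non_central_adds_squared_drift(self, wt_y_spec):
        t = 10.0
        assert float(msd(wt_y_spec, t, centered=False)) == pytest.approx(
            float(msd(wt_y_spec, t, centered=True)) + (7.4 * t) ** 2
        )

    def test_negative_time_rejected(self, wt_y_spec):
        with pytest.raises(ValueError):
            msd(wt_y_spec, -1.0)


class TestBetaCurve:
    def test_fbm_beta_is_flat_2h(self):
        spec = ModelSpec(Model.A, ParamVector(H=0.76, D_H=39.01, v_d=0.0))
        np.testing.assert_allclose(beta_curve(spec, np.linspace(0.1, 30, 50)), 1.52)

    def test_tempered_beta_reaches_normal_diffusion(self):
        spec = ModelSpec(Model.B, ParamVector(H=0.76, D_H=39.01, v_d=0.0, tau_star=1.0))
        assert float(beta_curve(spec, np.array([100.0]))[0]) == pytest.approx(1.0, abs=0.05)

    @pytest.mark.parametrize("model_id", ["B", "C"])
    def test_tempering_makes_beta_non_increasing(self, model_id):
        spec = example_specs()[model_id]
        beta = beta_curve(spec, np.linspace(0.2, 60.0, 200))
        assert np.all(np.diff(beta) <= 1e-9)

    def test_beta_matches_finite_difference_of_msd(self):
        spec = ModelSpec(Model.B, ParamVector(H=0.8, D_H=5.0, v_d=0.0, tau_star=2.0))
        t = np.array([0.5, 2.0, 10.0, 50.0])
        h = 1e-5
        fd = (np.log(msd(spec, t * (1 + h))) - np.log(msd(spec, t * (1 - h)))) / (
            np.log(1 + h) - np.log(1 - h)
        )
        np.testing.assert_allclose(beta_curve(spec, t), fd, atol=1e-4)

    def test_zero_time_rejected(self, wt_y_spec):
        with pytest.raises(ValueError):
            beta_curve(wt_y_spec, np.array([0.0, 1.0]))


class TestFirstMomentAndSpecs:
    def test_drift_scales_linearly(self, wt_y_spec):
        assert float(first_moment(wt_y_spec, 10.0)) == pytest.approx(74.0)

    def test_no_drift_and_sign(self):
        spec = ModelSpec(Model.A, ParamVector(H=0.6, D_H=1.0, v_d=0.0))
        assert float(first_moment(spec, 5.0)) == 0.0
        neg = ModelSpec(Model.A, ParamVector(H=0.6, D_H=1.0, v_d=-3.0))
        assert float(first_moment(neg, 2.0)) == pytest.approx(-6.0)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(H=1.2, D_H=1.0, v_d=0.0),
            dict(H=0.6, D_H=-1.0, v_d=0.0),
            dict(H=0.6, D_H=1.0),  # missing v_d
        ],
    )
    def test_invalid_model_a_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ModelSpec(Model.A, ParamVector(**kwargs))

    def test_theta_roundtrip(self):
        spec = ModelSpec.from_theta("C", [0.8, 10.0, 1.0, 3.0, 2.0])
        np.testing.assert_allclose(spec.theta(), [0.8, 10.0, 1.0, 3.0, 2.0])
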