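import numpy as np
import pytest

from hiernorm.dynamics import (
    Edge,
    FixedPointError,
    HierarchySpec,
    contrast_response,
    jacobian,
    normalization_rates,
    rate_nonlinearity,
    rhs,
    simulate,
    solve_fixed_point,
    two_area,
)
from hiernorm.network import RingGeometry, Stimulus, input_drive
from hiernorm.params import AreaParameters, GainState, ParameterRangeWarning


class TestRateNonlinearity:
    @pytest.mark.parametrize("v,expected", [(0.0, 0.0), (-3.0, 0.0), (2.0, 4.0)])
    def test_hard_rectify_square(self, v, expected):
        assert rate_nonlinearity(v, 0.0) == pytest.approx(expected)

    def test_nonnegative_and_monotone(self):
        v = np.linspace(-3, 3, 301)
        for s in (0.0, 0.1, 1.0):
            r = rate_nonlinearity(v, s)
            assert np.all(r >= 0)
            assert np.all(np.diff(r) >= -1e-12)

    def test_smoothing_converges_to_hard(self):
        v = np.linspace(-2, 2, 41)
        hard = rate_nonlinearity(v, 0.0)
        for s, tol in ((1e-2, 2e-4), (1e-4, 2e-8)):
            assert np.max(np.abs(rate_nonlinearity(v, s) - hard)) < tol

    def test_negative_smoothing_rejected(self):
        with pytest.raises(ValueError):
            rate_nonlinearity(1.0, -0.1)


class TestFixedPointOracle:
    """With unit gains and identity recurrence the solved fixed point must
    reproduce the divisive-normalization equation exactly in both areas."""

    @pytest.fixture(scope="class")
    def ident_spec(self):
        return two_area(geometry=RingGeometry(16), identity_recurrence=True)

    @pytest.mark.parametrize("contrast", [0, 3, 6, 12, 25, 50, 100])
    def test_normalization_identity(self, ident_spec, contrast):
        g = ident_spec.areas[0].geometry
        z = input_drive(Stimulus(contrast, 90.0), g, 40.0)
        st = solve_fixed_point(ident_spec, {"V1": z}, check_stability=False)
        a1, a2 = ident_spec.areas
        assert np.max(np.abs(
            st.rates("V1") - normalization_rates(z, a1.params.sigma, a1.N)
        )) < 1e-10
        z2 = ident_spec.edges[0].W_ff @ st.rates("V1")
        assert np.max(np.abs(
            st.rates("V2") - normalization_rates(z2, a2.params.sigma, a2.N)
        )) < 1e-10

    def test_semisaturation_at_sigma(self):
        """Uniform drive equal to sigma gives rates of exactly one half."""
        spec = two_area(geometry=RingGeometry(4), identity_recurrence=True)
        sigma = spec.areas[0].params.sigma
        z = np.full(4, sigma)
        st = solve_fixed_point(spec, {"V1": z}, check_stability=False)
        assert np.allclose(st.rates("V1"), 0.5, atol=1e-12)

    def test_zero_drive_silent(self, ident_spec):
        st = solve_fixed_point(
            ident_spec, {"V1": np.zeros(16)}, check_stability=False
        )
        assert np.allclose(st.rates("V1"), 0.0)
        assert np.allclose(st.rates("V2"), 0.0)


class TestRhs:
    def test_zero_state_derivatives(self, small_spec):
        x = np.zeros(small_spec.n_states)
        dx = rhs(small_spec, x, {"V1": np.zeros(16)})
        p = small_spec.areas[0].params
        # q relaxes to the (zero) rate: no motion
        assert np.allclose(dx[small_spec.state_slice("V1", "q")], 0.0)
        # the pool state is pulled up by the semisaturation source
        expected = p.pool_rate * 0.25 * p.sigma**2 / p.tau_u
        assert np.allclose(dx[small_spec.state_slice("V1", "u")], expected)

    def test_fixed_point_annihilates_rhs(self, small_spec, small_drive,
                                         small_fixed_point):
        dx = rhs(small_spec, small_fixed_point.x, small_drive)
        assert np.max(np.abs(dx)) < 1e-9

    def test_dimension_mismatch_raises(self, small_spec):
        with pytest.raises(ValueError):
            rhs(small_spec, np.zeros(3), {"V1": np.zeros(16)})


class TestJacobian:
    def test_matches_finite_differences(self, small_spec, small_drive,
                                        small_fixed_point):
        J = jacobian(small_spec, small_fixed_point.x, small_drive)
        rng = np.random.default_rng(0)
        h = 1e-6
        for _ in range(5):
            v = rng.standard_normal(small_spec.n_states)
            v /= np.linalg.norm(v)
            fd = (
                rhs(small_spec, small_fixed_point.x + h * v, small_drive)
                - rhs(small_spec, small_fixed_point.x - h * v, small_drive)
            ) / (2 * h)
            an = J @ v
            scale = max(1.0, np.max(np.abs(an)))
            assert np.max(np.abs(fd - an)) / scale < 1e-5

    def test_stable_at_default_half_contrast(self, small_fixed_point):
        assert small_fixed_point.stable is True

    def test_decoupled_areas_give_block_diagonal_jacobian(self):
        g = RingGeometry(8)
        base = two_area(geometry=g)
        zero_edge = Edge(lower="V1", higher="V2",
                         W_fb=np.zeros((8, 8)), gamma=1.0)
        spec = HierarchySpec(areas=base.areas, edges=(zero_edge,))
        z = {"V1": input_drive(Stimulus(50.0, 90.0), g, 40.0)}
        st = solve_fixed_point(spec, z, check_stability=False)
        J = jacobian(spec, st.x, z)
        n1 = 4 * 8
        assert np.allclose(J[:n1, n1:], 0.0)
        assert np.allclose(J[n1:, :n1], 0.0)

    def test_frozen_gain_removes_modulator_influence(self, small_spec,
                                                     small_drive,
                                                     small_fixed_point):
        J = jacobian(small_spec, small_fixed_point.x, small_drive,
                     frozen_gain=True)
        sy = small_spec.state_slice("V1", "y")
        sa = small_spec.state_slice("V1", "a")
        assert np.allclose(J[sy, sa], 0.0)


class TestSimulate:
    def test_constant_at_spontaneous_fixed_point(self, small_spec):
        z0 = {"V1": np.zeros(16)}
        st = solve_fixed_point(small_spec, z0, check_stability=False)
        sol = simulate(small_spec, z0, x0=st.x, duration=50.0)
        assert np.max(np.abs(sol.y[:, -1] - st.x)) < 1e-6

    def test_ramped_onset_reaches_fixed_point(self, small_spec, small_drive,
                                              small_fixed_point):
        rest = solve_fixed_point(small_spec, {"V1": np.zeros(16)},
                                 check_stability=False)
        sol = simulate(small_spec, small_drive, x0=rest.x, duration=3000.0,
                       onset_ramp=200.0)
        assert np.max(np.abs(sol.y[:, -1] - small_fixed_point.x)) < 1e-6

    def test_convergence_from_different_initial_states(self, small_spec,
                                                       small_drive,
                                                       small_fixed_point):
        rng = np.random.default_rng(3)
        fp = small_fixed_point.x
        x0a = fp + 0.05 * rng.standard_normal(small_spec.n_states)
        x0b = fp + 0.2 * rng.standard_normal(small_spec.n_states)
        sa = simulate(small_spec, small_drive, x0=x0a, duration=3000.0)
        sb = simulate(small_spec, small_drive, x0=x0b, duration=3000.0)
        assert np.max(np.abs(sa.y[:, -1] - sb.y[:, -1])) < 1e-6

    def test_invalid_duration(self, small_spec):
        with pytest.raises(ValueError):
            simulate(small_spec, {"V1": np.zeros(16)}, duration=0.0)


class TestGains:
    def test_with_gains_scalar_and_dict(self, small_spec):
        sp = small_spec.with_gains(beta=1.5, gamma={"V2": 0.5})
        assert sp.areas[0].beta == 1.5
        assert sp.edges[0].gamma == 0.5

    def test_out_of_range_warns(self):
        with pytest.warns(ParameterRangeWarning):
            GainState(beta=3.0)
        with pytest.warns(ParameterRangeWarning):
            GainState(gamma=1.5)

    def test_negative_gains_rejected(self):
        with pytest.raises(ValueError):
            GainState(beta=-0.1)

    def test_feedback_gain_never_decreases_peak_rates(self, small_spec):
        g = small_spec.areas[0].geometry
        z = {"V1": input_drive(Stimulus(50.0, 90.0), g, 40.0)}
        prev = solve_fixed_point(
            small_spec.with_gains(gamma=0.9), z, check_stability=False
        ).rates("V2").max()
        for gm in (1.0, 1.05, 1.1):
            cur = solve_fixed_point(small_spec.with_gains(gamma=gm), z,
                                    check_stability=False).rates("V2").max()
            assert cur >= prev - 1e-9
            prev = cur

    def test_low_gamma_low_contrast_solves(self, small_spec):
        g = small_spec.areas[0].geometry
        z = {"V1": input_drive(Stimulus(3.0, 90.0), g, 40.0)}
        st = solve_fixed_point(small_spec.with_gains(gamma=0.1), z,
                               check_stability=False)
        assert st.residual < 1e-12


class TestContrastResponse:
    def test_monotone_and_saturating(self, small_spec):
        table = contrast_response(small_spec, [0, 3, 6, 12, 25, 50, 100])
        for area in ("V1", "V2"):
            r = table[table.area == area].sort_values("contrast_pct").rate.values
            assert r[0] == pytest.approx(0.0, abs=1e-12)
            assert np.all(np.diff(r) >= -1e-9)
            # saturating: relative growth slows at high contrast
            assert r[-1] / r[-2] < r[3] / r[2]


class TestAreaParameters:
    def test_defaults(self):
        p = AreaParameters()
        assert p.tau_y == p.tau_u == p.tau_a == p.tau_q == 1.0
        assert p.alpha == 10.0 and p.sigma == 0.07

    def test_invalid_tau(self):
        with pytest.raises(ValueError):
            AreaParameters(tau_y=0.0)

    def test_sigma_range_warning(self):
        with pytest.warns(ParameterRangeWarning):
            AreaParameters(sigma=0.2)
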