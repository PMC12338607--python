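import numpy as np
import pytest

from hiernorm.dynamics import Edge, HierarchySpec, solve_fixed_point, two_area
from hiernorm.network import RingGeometry, Stimulus, input_drive
from hiernorm.noise import NoiseSpec, build_stochastic_system
from hiernorm.spectra import psd
from hiernorm.subspace import (
    CovariancePartition,
    SubsetSamplingSpec,
    augmented_covariance,
    band_covariance,
    dimensionality,
    frequency_resolved_communication,
    population_rate_observables,
    rate_covariance,
    stationary_covariance,
    subset_averaged_performance,
    subspace_analysis,
)


def _random_psd_cov(rng, n_s, n_t, rank=None):
    """Random joint covariance; optionally with rank-limited coupling."""
    d = n_s + n_t
    A = rng.standard_normal((d, 2 * d))
    C = A @ A.T / (2 * d)
    if rank is not None:
        # rebuild target as a rank-limited linear map of source plus noise
        Cs = C[:n_s, :n_s]
        B = rng.standard_normal((n_s, rank)) @ rng.standard_normal((rank, n_t))
        Ct = B.T @ Cs @ B
        C = np.block([[Cs, Cs @ B], [B.T @ Cs, Ct]])
    return 0.5 * (C + C.T)


class TestStationaryCovariance:
    def test_lyapunov_residual(self, tiny_system):
        C = augmented_covariance(tiny_system)
        J, L = tiny_system.J_aug, tiny_system.L_aug
        M = L @ L.T
        resid = np.linalg.norm(J @ C + C @ J.T + M) / np.linalg.norm(M)
        assert resid < 1e-10

    def test_block_solver_matches_full_augmented_solve(self, tiny_system):
        C_fast = stationary_covariance(tiny_system)
        C_full = augmented_covariance(tiny_system)
        n = tiny_system.n_circuit
        assert np.allclose(C_fast, C_full[:n, :n], atol=1e-10)

    def test_symmetric_psd(self, tiny_system):
        C = stationary_covariance(tiny_system)
        assert np.allclose(C, C.T)
        assert np.min(np.linalg.eigvalsh(C)) > -1e-12


class TestSubspaceAnalysis:
    def test_independent_target_gives_zero_performance(self):
        rng = np.random.default_rng(0)
        Cs = _random_psd_cov(rng, 6, 0)
        Ct = _random_psd_cov(rng, 5, 0)
        C = np.block([[Cs, np.zeros((6, 5))], [np.zeros((5, 6)), Ct]])
        part = CovariancePartition(C, np.arange(6), np.arange(6, 11))
        res = subspace_analysis(part)
        assert np.allclose(res.performance, 0.0, atol=1e-12)
        assert res.full_performance == pytest.approx(0.0, abs=1e-12)
        assert res.dimensionality == 0

    @pytest.mark.parametrize("rank", [1, 3])
    def test_noiseless_linear_map_fully_predicted(self, rank):
        rng = np.random.default_rng(1)
        n_s, n_t = 8, 6
        C = _random_psd_cov(rng, n_s, n_t, rank=rank)
        part = CovariancePartition(C, np.arange(n_s), np.arange(n_s, n_s + n_t))
        res = subspace_analysis(part)
        assert res.full_performance == pytest.approx(1.0, abs=1e-8)
        assert dimensionality(
            res.performance, criterion="rank", eigvals=res.eigvals, rank_rtol=1e-8
        ) == rank

    def test_performance_curve_monotone_and_bounded(self):
        rng = np.random.default_rng(2)
        for seed in range(5):
            C = _random_psd_cov(np.random.default_rng(seed), 7, 6)
            part = CovariancePartition(C, np.arange(7), np.arange(7, 13))
            res = subspace_analysis(part)
            assert np.all(np.diff(res.performance) >= -1e-12)
            assert res.performance[0] == 0.0
            assert res.performance[-1] <= res.full_performance + 1e-10
            assert 0.0 <= res.full_performance <= 1.0 + 1e-12

    def test_error_identity_two_code_paths(self):
        """1 - eps_i/eps_0 computed from the reduced-rank readout directly
        must equal the eigenvalue form of the performance curve."""
        rng = np.random.default_rng(3)
        C = _random_psd_cov(rng, 9, 7)
        part = CovariancePartition(C, np.arange(9), np.arange(9, 16))
        res = subspace_analysis(part)
        C1, C2, C3 = part.C1, part.C2, part.C3
        eps0 = np.trace(C2)
        for i in range(0, 8):
            B = res.rrr_readout(i)
            eps_i = np.trace(C2 + B.T @ C1 @ B - 2.0 * B.T @ C3)
            direct = 1.0 - eps_i / eps0
            assert direct == pytest.approx(res.performance[i], abs=1e-10)

    def test_monte_carlo_regression_oracle(self):
        """Sample-based ordinary least squares on draws from the model
        covariance reproduces the analytic performance curve."""
        rng = np.random.default_rng(4)
        n_s, n_t = 8, 6
        C = _random_psd_cov(rng, n_s, n_t)
        part = CovariancePartition(C, np.arange(n_s), np.arange(n_s, n_s + n_t))
        analytic = subspace_analysis(part)
        n_samp = 400_000
        X = rng.multivariate_normal(np.zeros(n_s + n_t), C, size=n_samp,
                                    method="cholesky")
        s, t = X[:, :n_s], X[:, n_s:]
        C1 = s.T @ s / n_samp
        C3 = s.T @ t / n_samp
        C2 = t.T @ t / n_samp
        B = np.linalg.solve(C1, C3)
        C2_hat = C3.T @ B
        w, V = np.linalg.eigh(0.5 * (C2_hat + C2_hat.T))
        w = np.maximum(w[::-1], 0.0)
        perf = np.concatenate([[0.0], np.cumsum(w)]) / np.trace(C2)
        assert np.max(np.abs(perf - analytic.performance)) < 0.01


class TestDimensionality:
    def test_single_dominant_dimension(self):
        assert dimensionality(np.array([0.0, 1.0, 1.0, 1.0])) == 1

    def test_zero_curve(self):
        assert dimensionality(np.zeros(5)) == 0

    def test_rank_criterion_matches_rank_of_cross_covariance(self):
        rng = np.random.default_rng(5)
        C = _random_psd_cov(rng, 8, 6, rank=2)
        part = CovariancePartition(C, np.arange(8), np.arange(8, 14))
        res = subspace_analysis(part)
        rank_c3 = np.linalg.matrix_rank(part.C3, tol=1e-8)
        assert dimensionality(
            res.performance, criterion="rank", eigvals=res.eigvals, rank_rtol=1e-8
        ) == rank_c3


class TestSubsetAveraging:
    @pytest.fixture(scope="class")
    def joint_cov(self, tiny_system):
        C, _ = rate_covariance(tiny_system, ["V1", "V2"])
        return C

    def test_single_repeat_reports_zero_sem(self, joint_cov):
        samp = SubsetSamplingSpec(subset_size=3, n_repeats=1, seed=0)
        res = subset_averaged_performance(
            joint_cov, np.arange(8), np.arange(8, 16), samp
        )
        assert res["full_performance_sem"] == 0.0
        assert np.allclose(res["performance_sem"], 0.0)

    def test_seed_determinism(self, joint_cov):
        samp = SubsetSamplingSpec(subset_size=3, n_repeats=6, seed=11)
        a = subset_averaged_performance(joint_cov, np.arange(8),
                                        np.arange(8, 16), samp)
        b = subset_averaged_performance(joint_cov, np.arange(8),
                                        np.arange(8, 16), samp)
        assert a["full_performance_mean"] == b["full_performance_mean"]
        assert np.array_equal(a["dimensionality"], b["dimensionality"])

    def test_oversized_subset_rejected(self, joint_cov):
        samp = SubsetSamplingSpec(subset_size=5, n_repeats=2, seed=0)
        with pytest.raises(ValueError):
            subset_averaged_performance(joint_cov, np.arange(8), np.arange(8),
                                        samp)


class TestBandCovariance:
    def test_symmetric_output(self, tiny_system):
        E = population_rate_observables(tiny_system, "V1")
        sp = psd(tiny_system, np.arange(2.0, 100.0, 2.0), E)
        C = band_covariance(sp, 40.0)
        assert np.allclose(C, C.T, atol=1e-12)

    def test_out_of_grid_frequency_rejected(self, tiny_system):
        E = population_rate_observables(tiny_system, "V1")
        sp = psd(tiny_system, np.arange(2.0, 100.0, 2.0), E)
        with pytest.raises(ValueError):
            band_covariance(sp, 500.0)

    def test_band_integral_recovers_covariance(self, tiny_system):
        """Wiener-Khinchin: twice the one-sided integral of Re S equals the
        stationary covariance of the observables."""
        E = population_rate_observables(tiny_system, "V1")
        freqs = np.linspace(0.0, 5000.0, 20001)
        sp = psd(tiny_system, freqs, E)
        integral = 2.0 * np.trapezoid(sp.S.real, freqs, axis=0)
        C = E @ stationary_covariance(tiny_system) @ E.T
        assert np.max(np.abs(integral - C)) / np.max(np.abs(C)) < 0.01

    def test_uncoupled_areas_vanishing_cross_block(self):
        g = RingGeometry(8)
        base = two_area(geometry=g)
        spec = HierarchySpec(areas=base.areas,
                             edges=(Edge("V1", "V2", np.zeros((8, 8))),))
        z = {"V1": input_drive(Stimulus(50.0, 90.0), g, 40.0)}
        st = solve_fixed_point(spec, z, check_stability=False)
        sys = build_stochastic_system(spec, st, NoiseSpec(), z)
        E = np.vstack([
            population_rate_observables(sys, "V1"),
            population_rate_observables(sys, "V2"),
        ])
        sp = psd(sys, np.arange(2.0, 50.0, 2.0), E)
        C = band_covariance(sp, 20.0)
        assert np.allclose(C[:8, 8:], 0.0, atol=1e-18)


class TestFrequencyResolved:
    def test_uncoupled_areas_communicate_nothing(self):
        g = RingGeometry(8)
        base = two_area(geometry=g)
        spec = HierarchySpec(areas=base.areas,
                             edges=(Edge("V1", "V2", np.zeros((8, 8))),))
        z = {"V1": input_drive(Stimulus(50.0, 90.0), g, 40.0)}
        st = solve_fixed_point(spec, z, check_stability=False)
        sys = build_stochastic_system(spec, st, NoiseSpec(), z)
        samp = SubsetSamplingSpec(subset_size=4, n_repeats=3, seed=0)
        res = frequency_resolved_communication(
            sys, "V1", "V2", np.arange(5.0, 50.0, 5.0), samp
        )
        assert np.allclose(res["performance_mean"], 0.0, atol=1e-10)

    def test_coupled_system_has_frequency_structure(self, tiny_system):
        samp = SubsetSamplingSpec(subset_size=4, n_repeats=5, seed=0)
        res = frequency_resolved_communication(
            tiny_system, "V1", "V2", np.arange(5.0, 100.0, 5.0), samp
        )
        assert np.all(res["performance_mean"] >= 0.0)
        assert np.all(res["performance_mean"] <= 1.0)
        assert res["performance_mean"].std() > 0.0
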