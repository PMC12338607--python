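"""Stationary covariance and communication-subspace analytics.

The stationary covariance of the linearized stochastic circuit solves the
Lyapunov equation ``J C + C Jᵀ = −L D Lᵀ`` on the augmented system (circuit
states plus noise-filter states); the filter states are then integrated out
by taking the circuit block.  Communication subspaces between a source and
a target subpopulation are obtained by reduced-rank regression on the
model covariance: with ``C1 = E[ssᵀ]``, ``C2 = E[ttᵀ]``, ``C3 = E[stᵀ]``,
the optimal linear readout is ``B_opt = C1⁻¹C3``, the predicted target
covariance ``Ĉ2 = C3ᵀC1⁻¹C3``, and the rank-i prediction performance is
the share of target variance explained by the top i eigenvectors of Ĉ2,
``Performance(i) = Σ_{j≤i} λ_j / Tr C2``.

The frequency decomposition replaces the covariance by the real part of
the cross-spectral density at a single frequency (the narrowband limit of
the Wiener-Khinchin integral, constant prefactor dropped), yielding
prediction performance and dimensionality as functions of frequency.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve_continuous_lyapunov, solve_sylvester

from .dynamics import HierarchySpec, rect
from .noise import StochasticSystem
from .spectra import SpectralResult, psd

__all__ = [
    "CovariancePartition",
    "SubspaceResult",
    "SubsetSamplingSpec",
    "stationary_covariance",
    "rate_covariance",
    "population_rate_observables",
    "subspace_analysis",
    "dimensionality",
    "subset_averaged_performance",
    "band_covariance",
    "frequency_resolved_communication",
]


def stationary_covariance(system: StochasticSystem) -> np.ndarray:
    """Circuit-state stationary covariance from the Lyapunov equation.

    Exploits the block-triangular structure of the augmented system: the
    noise-filter block is an uncoupled OU process, so its covariance and the
    cross block are solved first (a Sylvester equation), then the circuit
    block solves a standard Lyapunov equation.  The result is symmetrized
    and checked against the defining equation.
    """
    J = system.J
    n = system.n_circuit
    tau_n = system.noise.tau_noise
    K = np.diag(1.0 / system.tau_state)
    # OU filter covariance: amp^2 / (2 tau_n)
    C_ss = np.diag(system.ou_amp**2 / (2.0 * tau_n))
    # J C_xs - C_xs / tau_n = -K C_ss
    C_xs = solve_sylvester(J, -np.eye(n) / tau_n, -K @ C_ss)
    M = K @ C_xs.T
    C_xx = solve_continuous_lyapunov(J, -(M + M.T))
    return 0.5 * (C_xx + C_xx.T)


def augmented_covariance(system: StochasticSystem) -> np.ndarray:
    """Full augmented-state covariance (circuit + filter states), assembled
    from the block solves (filter block, cross block, circuit block)."""
    J = system.J
    n = system.n_circuit
    tau_n = system.noise.tau_noise
    K = np.diag(1.0 / system.tau_state)
    C_ss = np.diag(system.ou_amp**2 / (2.0 * tau_n))
    C_xs = solve_sylvester(J, -np.eye(n) / tau_n, -K @ C_ss)
    M = K @ C_xs.T
    C_xx = solve_continuous_lyapunov(J, -(M + M.T))
    C_xx = 0.5 * (C_xx + C_xx.T)
    return np.block([[C_xx, C_xs], [C_xs.T, C_ss]])


def population_rate_observables(
    system: StochasticSystem, area: str, indices: np.ndarray | None = None
) -> np.ndarray:
    """Observation matrix mapping state deviations to principal-cell
    firing-rate deviations (slope ``2⌊y*⌋`` at the fixed point)."""
    spec = system.spec
    y = system.fixed_point.get(area, "y")
    n = y.size
    indices = np.arange(n) if indices is None else np.asarray(indices)
    E = np.zeros((indices.size, spec.n_states))
    sl = spec.state_slice(area, "y")
    slope = 2.0 * rect(y, spec.smoothing)
    for k, i in enumerate(indices):
        E[k, sl][i] = slope[i]
    return E


def rate_covariance(system: StochasticSystem, areas: list[str] | None = None):
    """Covariance of principal-cell rate fluctuations, concatenated over
    ``areas`` (default: all areas in order).  Returns ``(C, index)`` where
    ``index`` maps (area, neuron) to the row of ``C``."""
    areas = areas or [a.name for a in system.spec.areas]
    E = np.vstack([population_rate_observables(system, a) for a in areas])
    C_x = stationary_covariance(system)
    C = E @ C_x @ E.T
    index = [(a, i) for a in areas for i in range(system.spec.area(a).n)]
    return 0.5 * (C + C.T), index


@dataclass
class CovariancePartition:
    """Source/target partition of a joint covariance matrix."""

    C0: np.ndarray
    source_idx: np.ndarray
    target_idx: np.ndarray

    def __post_init__(self) -> None:
        self.source_idx = np.asarray(self.source_idx, dtype=int)
        self.target_idx = np.asarray(self.target_idx, dtype=int)

    @property
    def C1(self) -> np.ndarray:
        return self.C0[np.ix_(self.source_idx, self.source_idx)]

    @property
    def C2(self) -> np.ndarray:
        return self.C0[np.ix_(self.target_idx, self.target_idx)]

    @property
    def C3(self) -> np.ndarray:
        return self.C0[np.ix_(self.source_idx, self.target_idx)]


@dataclass
class SubspaceResult:
    """Reduced-rank-regression summary of one source->target partition."""

    B_opt: np.ndarray
    C2_hat: np.ndarray
    eigvals: np.ndarray
    eigvecs: np.ndarray
    performance: np.ndarray  # performance(i), i = 0..rank
    full_performance: float
    dimensionality: int

    def rrr_readout(self, rank: int) -> np.ndarray:
        """Rank-constrained readout ``B_opt V(i) V(i)ᵀ``."""
        V = self.eigvecs[:, :rank]
        return self.B_opt @ V @ V.T


def _pinv_psd(C: np.ndarray, rcond: float = 1e-12, ridge: float | None = None):
    w, V = np.linalg.eigh(0.5 * (C + C.T))
    wmax = float(np.max(w)) if w.size else 0.0
    if ridge is not None and wmax > 0:
        w = w + ridge * wmax
    keep = w > rcond * max(wmax, 0.0)
    inv = np.zeros_like(w)
    inv[keep] = 1.0 / w[keep]
    return (V * inv[None, :]) @ V.T


def subspace_analysis(
    partition: CovariancePartition,
    rcond: float = 1e-12,
    ridge: float | None = None,
    performance_fraction: float = 0.95,
) -> SubspaceResult:
    """Reduced-rank regression on exact (model) covariances.

    The source covariance is inverted with a symmetric pseudo-inverse
    (relative eigenvalue cutoff ``rcond``); an optional relative ``ridge``
    stabilizes user-supplied noisy covariances.
    """
    C1, C2, C3 = partition.C1, partition.C2, partition.C3
    C1_inv = _pinv_psd(C1, rcond=rcond, ridge=ridge)
    B_opt = C1_inv @ C3
    C2_hat = C3.T @ C1_inv @ C3
    C2_hat = 0.5 * (C2_hat + C2_hat.T)
    w, V = np.linalg.eigh(C2_hat)
    order = np.argsort(w)[::-1]
    w, V = np.maximum(w[order], 0.0), V[:, order]
    tr_c2 = float(np.trace(C2))
    if tr_c2 <= 0:
        perf = np.zeros(w.size + 1)
        full = 0.0
    else:
        perf = np.concatenate([[0.0], np.cumsum(w)]) / tr_c2
        full = float(np.trace(C2_hat)) / tr_c2
    dim = dimensionality(perf, full_performance=full, fraction=performance_fraction)
    return SubspaceResult(
        B_opt=B_opt,
        C2_hat=C2_hat,
        eigvals=w,
        eigvecs=V,
        performance=perf,
        full_performance=full,
        dimensionality=dim,
    )


def dimensionality(
    performance: np.ndarray,
    full_performance: float | None = None,
    criterion: str = "fraction",
    fraction: float = 0.95,
    eigvals: np.ndarray | None = None,
    rank_rtol: float = 1e-10,
) -> int:
    """Communication-subspace dimensionality from a performance curve.

    ``criterion='fraction'`` (default): smallest rank reaching ``fraction``
    of the full-rank performance.  ``criterion='rank'``: number of
    eigenvalues above ``rank_rtol`` times the largest (requires ``eigvals``).
    """
    if criterion == "rank":
        if eigvals is None:
            raise ValueError("rank criterion requires eigvals")
        if eigvals.size == 0 or eigvals.max() <= 0:
            return 0
        return int(np.sum(eigvals > rank_rtol * eigvals.max()))
    performance = np.asarray(performance, dtype=float)
    full = performance[-1] if full_performance is None else full_performance
    if full <= 0:
        return 0
    return int(np.searchsorted(performance, fraction * full - 1e-15))


@dataclass(frozen=True)
class SubsetSamplingSpec:
    """Protocol for subset-averaged subspace analyses."""

    subset_size: int = 30
    n_repeats: int = 25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.subset_size < 1 or self.n_repeats < 1:
            raise ValueError("subset_size and n_repeats must be >= 1")


def _draw_subsets(rng, n_source: int, n_target: int, k: int, within: bool):
    if within:
        if 2 * k > n_source:
            raise ValueError(
                f"subset_size {k} too large for disjoint draws from {n_source}"
            )
        perm = rng.permutation(n_source)
        return perm[:k], perm[k : 2 * k]
    if k > n_source or k > n_target:
        raise ValueError(f"subset_size {k} exceeds population size")
    return (
        np.sort(rng.permutation(n_source)[:k]),
        np.sort(rng.permutation(n_target)[:k]),
    )


def subset_averaged_performance(
    C0: np.ndarray,
    source_pop: np.ndarray,
    target_pop: np.ndarray,
    sampling: SubsetSamplingSpec,
    performance_fraction: float = 0.95,
):
    """Mean +/- SEM performance curve and dimensionality over random subsets.

    ``source_pop`` and ``target_pop`` are index arrays into ``C0``.  When the
    two populations are identical (within-area analysis) each repeat draws
    *disjoint* source and target subsets.  Fully deterministic given the
    sampling seed.  Returns a dict with mean/sem arrays and per-repeat
    dimensionality.
    """
    source_pop = np.asarray(source_pop, dtype=int)
    target_pop = np.asarray(target_pop, dtype=int)
    within = source_pop.size == target_pop.size and np.array_equal(
        source_pop, target_pop
    )
    rng = np.random.default_rng(sampling.seed)
    k = sampling.subset_size
    curves = np.empty((sampling.n_repeats, k + 1))
    fulls = np.empty(sampling.n_repeats)
    dims = np.empty(sampling.n_repeats, dtype=int)
    for r in range(sampling.n_repeats):
        si, ti = _draw_subsets(rng, source_pop.size, target_pop.size, k, within)
        part = CovariancePartition(C0, source_pop[si], target_pop[ti])
        res = subspace_analysis(part, performance_fraction=performance_fraction)
        curves[r] = res.performance
        fulls[r] = res.full_performance
        dims[r] = res.dimensionality
    sem = lambda x: (
        np.std(x, axis=0, ddof=1) / np.sqrt(sampling.n_repeats)
        if sampling.n_repeats > 1
        else np.zeros(np.shape(x)[1:])
    )
    return {
        "performance_mean": curves.mean(axis=0),
        "performance_sem": sem(curves),
        "full_performance_mean": float(fulls.mean()),
        "full_performance_sem": float(np.atleast_1d(sem(fulls[:, None]))[0]),
        "dimensionality_mean": float(dims.mean()),
        "dimensionality_sem": float(np.atleast_1d(sem(dims[:, None].astype(float)))[0]),
        "dimensionality": dims,
    }


def band_covariance(
    spectral: SpectralResult, f_star: float, interpolate: bool = True
) -> np.ndarray:
    """Frequency-specific covariance: ``Re S(f*)``, symmetrized.

    The narrowband filtering argument gives ``C(0)|_{f*} ∝ Re S(f*)``; the
    constant bandwidth prefactor is dropped since the subspace analytics are
    scale-invariant.
    """
    freqs = spectral.freqs
    if f_star < freqs[0] or f_star > freqs[-1]:
        raise ValueError(f"f_star={f_star} outside the spectral grid")
    k = int(np.searchsorted(freqs, f_star))
    if np.isclose(freqs[min(k, freqs.size - 1)], f_star) or not interpolate:
        k = min(k, freqs.size - 1)
        S = spectral.S[k]
    else:
        w = (f_star - freqs[k - 1]) / (freqs[k] - freqs[k - 1])
        S = (1.0 - w) * spectral.S[k - 1] + w * spectral.S[k]
    C = S.real
    return 0.5 * (C + C.T)


def frequency_resolved_communication(
    system: StochasticSystem,
    source: str,
    target: str,
    freqs: np.ndarray,
    sampling: SubsetSamplingSpec,
    performance_fraction: float = 0.95,
):
    """Prediction performance and dimensionality versus frequency.

    Computes the rate cross-spectral density of the source and target
    principal populations, then runs the subset-averaged subspace analysis on
    ``Re S(f)`` at every frequency of ``freqs``.  Returns a dict of arrays
    (mean and SEM of full performance and dimensionality per frequency).
    """
    spec = system.spec
    E_s = population_rate_observables(system, source)
    E_t = population_rate_observables(system, target)
    E = np.vstack([E_s, E_t]) if source != target else E_s
    sp = psd(system, np.asarray(freqs, dtype=float), E)
    n_s = E_s.shape[0]
    if source == target:
        src_idx = tgt_idx = np.arange(n_s)
    else:
        src_idx = np.arange(n_s)
        tgt_idx = np.arange(n_s, n_s + E_t.shape[0])
    out = {
        "freqs": np.asarray(freqs, dtype=float),
        "performance_mean": [],
        "performance_sem": [],
        "dimensionality_mean": [],
        "dimensionality_sem": [],
    }
    for k in range(sp.freqs.size):
        C = sp.S[k].real
        C = 0.5 * (C + C.T)
        res = subset_averaged_performance(
            C, src_idx, tgt_idx, sampling, performance_fraction
        )
        out["performance_mean"].append(res["full_performance_mean"])
        out["performance_sem"].append(res["full_performance_sem"])
        out["dimensionality_mean"].append(res["dimensionality_mean"])
        out["dimensionality_sem"].append(res["dimensionality_sem"])
    for key in list(out):
        out[key] = np.asarray(out[key])
    return out
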