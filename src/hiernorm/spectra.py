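"""Closed-form spectra of the linearized stochastic circuit.

The cross-spectral density of the stationary linear response is evaluated
by the resolvent formula

    S(ω) = (iωI − J)⁻¹ M(ω) (−iωI − Jᵀ)⁻¹,

where ``M(ω)`` is the (diagonal) effective forcing density: the
multiplicative-noise floor plus the analytically integrated
Ornstein-Uhlenbeck synaptic term.  A single eigendecomposition of the
circuit Jacobian makes the whole frequency grid cheap for any small set
of observables (single neurons, firing-rate readouts, per-area LFP
sums).

All public interfaces use frequencies in Hz; internally time is in ms.
Densities are two-sided, per Hz, so that the full-axis integral of the
density equals the stationary covariance (Wiener-Khinchin).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dynamics import HierarchySpec, rect
from .noise import StochasticSystem, extrinsic_cross_density, lfp_weights

__all__ = [
    "SpectralResult",
    "CoherencePair",
    "psd",
    "lfp_psd",
    "coherence",
    "normalize_power",
    "find_spectral_peak",
    "highfreq_slope",
    "membrane_observables",
    "rate_observables",
]


@dataclass
class SpectralResult:
    """Cross-spectral density matrices on a frequency grid.

    ``S[k]`` is the Hermitian density matrix of the observables at
    ``freqs[k]`` (two-sided, per Hz).  Only nonnegative frequencies are
    stored; ``S(-f)`` is the complex conjugate.
    """

    freqs: np.ndarray
    S: np.ndarray
    labels: tuple[str, ...] = ()
    meta: dict = field(default_factory=dict)

    def auto(self, i: int = 0) -> np.ndarray:
        """Real auto-spectrum of observable ``i``."""
        return self.S[:, i, i].real


@dataclass
class CoherencePair:
    freqs: np.ndarray
    kappa: np.ndarray
    i: int
    j: int


def _eig_cache(system: StochasticSystem):
    cache = getattr(system, "_eig_cache", None)
    if cache is None:
        lam, V = np.linalg.eig(system.J)
        Vinv = np.linalg.inv(V)
        cache = (lam, V, Vinv)
        system._eig_cache = cache
    return cache


def membrane_observables(
    spec: HierarchySpec, channels: list[tuple[str, int]]
) -> tuple[np.ndarray, tuple[str, ...]]:
    """Unit readouts of principal-cell membrane potentials."""
    E = np.zeros((len(channels), spec.n_states))
    labels = []
    for k, (area, idx) in enumerate(channels):
        E[k, spec.state_slice(area, "y")][idx] = 1.0
        labels.append(f"{area}[{idx}]")
    return E, tuple(labels)


def rate_observables(
    system: StochasticSystem, channels: list[tuple[str, int]]
) -> tuple[np.ndarray, tuple[str, ...]]:
    """Firing-rate readouts: membrane deviations scaled by the rate slope
    ``dy+/dy = 2⌊y*⌋`` at the fixed point."""
    spec = system.spec
    E = np.zeros((len(channels), spec.n_states))
    labels = []
    for k, (area, idx) in enumerate(channels):
        y = system.fixed_point.get(area, "y")
        slope = 2.0 * rect(y[idx], spec.smoothing)
        E[k, spec.state_slice(area, "y")][idx] = slope
        labels.append(f"{area}+[{idx}]")
    return E, tuple(labels)


def psd(
    system: StochasticSystem,
    freqs: np.ndarray,
    E: np.ndarray | None = None,
    labels: tuple[str, ...] = (),
    meta: dict | None = None,
) -> SpectralResult:
    """Cross-spectral density of linear observables ``E @ x``.

    ``E`` defaults to the identity over all circuit states (use sparingly:
    the cost per frequency scales with the number of observables).
    """
    freqs = np.asarray(freqs, dtype=float)
    if np.any(freqs < 0):
        raise ValueError("frequencies must be >= 0")
    if E is None:
        E = np.eye(system.n_circuit)
    E = np.atleast_2d(np.asarray(E, dtype=float))
    lam, V, Vinv = _eig_cache(system)
    EV = E.astype(complex) @ V
    omegas = 2.0 * np.pi * (freqs / 1000.0)  # rad per ms
    forcing = system.forcing_density(omegas)  # (nf, n) diagonal density
    m = E.shape[0]
    out = np.empty((freqs.size, m, m), dtype=complex)
    for k, w in enumerate(omegas):
        A = (EV / (1j * w - lam)[None, :]) @ Vinv  # = E (iwI - J)^-1
        out[k] = (A * forcing[k][None, :]) @ A.conj().T
    out /= 1000.0  # per-ms -> per-Hz density
    return SpectralResult(freqs=freqs, S=out, labels=tuple(labels), meta=meta or {})


def lfp_psd(
    system: StochasticSystem,
    freqs: np.ndarray,
    include_extrinsic: bool = True,
) -> SpectralResult:
    """Per-area LFP cross-spectra: summed principal membrane potentials,
    plus (optionally) the flat extrinsic cross-spectral term."""
    spec = system.spec
    areas = [a.name for a in spec.areas]
    E = np.stack([lfp_weights(spec, a) for a in areas])
    res = psd(system, freqs, E, labels=tuple(areas), meta={"kind": "lfp"})
    if include_extrinsic:
        res.S = res.S + extrinsic_cross_density(system.noise, len(areas))[None, :, :]
    return res


def coherence(spectral: SpectralResult, i: int, j: int) -> CoherencePair:
    """Magnitude-squared coherence ``|S_ij|² / (S_ii S_jj)``."""
    s_ii = spectral.S[:, i, i].real
    s_jj = spectral.S[:, j, j].real
    bad = (s_ii <= 0) | (s_jj <= 0)
    if np.any(bad):
        f_bad = spectral.freqs[np.argmax(bad)]
        raise ValueError(f"coherence undefined: zero auto-spectrum at {f_bad} Hz")
    kappa = np.abs(spectral.S[:, i, j]) ** 2 / (s_ii * s_jj)
    return CoherencePair(freqs=spectral.freqs, kappa=kappa, i=i, j=j)


def normalize_power(power: np.ndarray, baseline: np.ndarray) -> np.ndarray:
    """Contrast-normalized power ``(power − baseline)/(power + baseline)``.

    The baseline is conventionally the spontaneous (0% contrast) spectrum on
    the same frequency grid.
    """
    power = np.asarray(power, dtype=float)
    baseline = np.asarray(baseline, dtype=float)
    if power.shape != baseline.shape:
        raise ValueError("power and baseline must share the same grid")
    if np.any(baseline <= 0):
        raise ValueError("baseline power must be positive")
    return (power - baseline) / (power + baseline)


def find_spectral_peak(
    freqs: np.ndarray,
    power: np.ndarray,
    band: tuple[float, float] | None = None,
):
    """Interior spectral peak in a band, with 3-point quadratic refinement.

    Returns ``(peak_freq_hz, peak_height)`` or ``None`` when the maximum sits
    at a band edge without an interior local maximum.  Interpolation is
    quadratic in log power (log-quadratic peaks are exact for resonances in
    log coordinates near the maximum).
    """
    freqs = np.asarray(freqs, dtype=float)
    power = np.asarray(power, dtype=float)
    if band is not None:
        mask = (freqs >= band[0]) & (freqs <= band[1])
        if mask.sum() < 3:
            raise ValueError(f"band {band} contains fewer than 3 grid points")
        freqs, power = freqs[mask], power[mask]
    k = int(np.argmax(power))
    if k == 0 or k == power.size - 1:
        return None
    use_log = np.all(power[k - 1 : k + 2] > 0)
    p = np.log(power[k - 1 : k + 2]) if use_log else power[k - 1 : k + 2]
    denom = p[0] - 2.0 * p[1] + p[2]
    if denom >= 0:  # not concave: no interior quadratic peak
        return None
    shift = 0.5 * (p[0] - p[2]) / denom
    shift = float(np.clip(shift, -1.0, 1.0))
    f_peak = freqs[k] + shift * (freqs[min(k + 1, freqs.size - 1)] - freqs[k])
    h = p[1] - 0.25 * (p[0] - p[2]) * shift
    height = float(np.exp(h)) if use_log else float(h)
    return float(f_peak), height


def highfreq_slope(
    freqs: np.ndarray, power: np.ndarray, f_range: tuple[float, float]
) -> float:
    """Least-squares log-log slope of the power spectrum over ``f_range``."""
    freqs = np.asarray(freqs, dtype=float)
    power = np.asarray(power, dtype=float)
    mask = (freqs >= f_range[0]) & (freqs <= f_range[1])
    if mask.sum() < 10:
        raise ValueError(f"need >= 10 grid points in {f_range}, got {mask.sum()}")
    if np.any(power[mask] <= 0):
        raise ValueError("power must be positive over the fit range")
    slope, _ = np.polyfit(np.log(freqs[mask]), np.log(power[mask]), 1)
    return float(slope)


def default_frequency_grid(
    f_min: float = 0.5, f_max: float = 1000.0, df: float = 0.5
) -> np.ndarray:
    return np.arange(f_min, f_max + 0.5 * df, df)
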