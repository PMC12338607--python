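"""Stochastic forcing, LFP observation, and the Euler-Maruyama oracle.

The circuit receives low-pass filtered (Ornstein-Uhlenbeck) synaptic
noise in every membrane equation, one auxiliary filter state per
membrane state.  Its variance has an additive component
(``synaptic_amp``) and a signal-dependent component proportional to the
fixed-point firing rate of the state (``mult_amp * rate*``, the
frozen-coefficient small-noise treatment consistent with linearization
around the fixed point).  A further *extrinsic* source models
long-range correlated measurement noise: it contaminates only the LFP
observation, never the dynamics.

Conventions (time in ms): each OU filter obeys
``tau_noise ds = -s dt + amp dW`` with
``amp = sqrt(synaptic_amp^2 + (mult_amp * rate*)^2)``, and feeds its
membrane equation as ``tau_v dv/dt = f(x) + s``.  Wiener increments are
independent (identity diffusion correlation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dynamics import (
    HierarchySpec,
    NetworkState,
    jacobian,
    rate_nonlinearity,
    rect,
    rhs,
)

__all__ = [
    "NoiseSpec",
    "StochasticSystem",
    "build_stochastic_system",
    "simulate_sde",
    "lfp_weights",
]


@dataclass(frozen=True)
class NoiseSpec:
    """Noise amplitudes and the LFP contamination model.

    All amplitudes are in the membrane-potential units of the circuit;
    ``tau_noise`` is in ms.  ``extrinsic_corr`` is the pairwise correlation
    of the extrinsic LFP noise across areas.
    """

    synaptic_amp: float = 1.0
    tau_noise: float = 1.0
    mult_amp: float = 0.5
    modulator_frac: float = 1.0
    extrinsic_amp: float = 0.05
    extrinsic_corr: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.synaptic_amp, self.mult_amp, self.extrinsic_amp) < 0:
            raise ValueError("noise amplitudes must be >= 0")
        if self.tau_noise <= 0:
            raise ValueError("tau_noise must be > 0")
        if not (0.0 <= self.extrinsic_corr <= 1.0):
            raise ValueError("extrinsic_corr must lie in [0, 1]")


class StabilityError(RuntimeError):
    pass


def _tau_vector(spec: HierarchySpec) -> np.ndarray:
    tau = np.empty(spec.n_states)
    for a in spec.areas:
        p = a.params
        for var, t in (("y", p.tau_y), ("u", p.tau_u), ("a", p.tau_a), ("q", p.tau_q)):
            tau[spec.state_slice(a.name, var)] = t
    return tau


def _state_rates(spec: HierarchySpec, x: np.ndarray) -> np.ndarray:
    """Fixed-point firing rate of every state under its own F-I curve."""
    s = spec.smoothing
    r = np.empty(spec.n_states)
    for a in spec.areas:
        r[spec.state_slice(a.name, "y")] = rate_nonlinearity(
            x[spec.state_slice(a.name, "y")], s
        )
        for var in ("u", "a", "q"):
            sl = spec.state_slice(a.name, var)
            r[sl] = rect(x[sl], s)
    return r


@dataclass
class StochasticSystem:
    """Linearized circuit plus its noise model.

    ``J`` is the circuit Jacobian at the fixed point; the augmented system
    appends one OU filter state per membrane equation:

        d[dx; s] = [[J, K], [0, -I/tau_n]] [dx; s] dt + [[B_mult, 0], [0, A]] dW

    with ``K = diag(1/tau_state)``, ``A = (synaptic_amp/tau_n) I`` and
    ``B_mult = diag(mult_amp * rate* / tau_state)``.  The diffusion
    correlation of the Wiener increments is the identity.
    """

    spec: HierarchySpec
    z_ext: dict
    fixed_point: NetworkState
    noise: NoiseSpec
    J: np.ndarray
    tau_state: np.ndarray
    rate_fp: np.ndarray
    frozen_gain: bool = False

    @property
    def n_circuit(self) -> int:
        return self.spec.n_states

    @property
    def n_aug(self) -> int:
        return 2 * self.spec.n_states

    @property
    def state_noise_scale(self) -> np.ndarray:
        """Relative synaptic-noise amplitude per state: principal cells at 1,
        modulator populations at ``modulator_frac``."""
        m = np.full(self.n_circuit, self.noise.modulator_frac)
        for a in self.spec.areas:
            m[self.spec.state_slice(a.name, "y")] = 1.0
        return m

    @property
    def ou_amp(self) -> np.ndarray:
        """Per-state OU drive amplitude: additive plus rate-dependent part."""
        return self.state_noise_scale * np.sqrt(
            self.noise.synaptic_amp**2 + (self.noise.mult_amp * self.rate_fp) ** 2
        )

    @property
    def J_aug(self) -> np.ndarray:
        n = self.n_circuit
        J = np.zeros((2 * n, 2 * n))
        J[:n, :n] = self.J
        J[:n, n:] = np.diag(1.0 / self.tau_state)
        J[n:, n:] = -np.eye(n) / self.noise.tau_noise
        return J

    @property
    def L_aug(self) -> np.ndarray:
        n = self.n_circuit
        L = np.zeros((2 * n, 2 * n))
        L[n:, n:] = np.diag(self.ou_amp / self.noise.tau_noise)
        return L

    @property
    def D(self) -> np.ndarray:
        return np.eye(self.n_aug)

    def forcing_density(self, omega: np.ndarray) -> np.ndarray:
        """Effective (diagonal) input spectral density onto the circuit
        states at angular frequency ``omega`` (rad/ms): the OU-filtered
        synaptic noise (additive plus rate-dependent variance), with the
        filter states integrated out analytically."""
        omega = np.atleast_1d(np.asarray(omega, dtype=float))
        lp = 1.0 / (1.0 + (omega * self.noise.tau_noise) ** 2)
        return lp[:, None] * (self.ou_amp**2 / self.tau_state**2)[None, :]


def build_stochastic_system(
    spec: HierarchySpec,
    fixed_point: NetworkState,
    noise: NoiseSpec,
    z_ext: dict,
    frozen_gain: bool = False,
) -> StochasticSystem:
    """Assemble the linearized stochastic system at a solved fixed point.

    Raises :class:`StabilityError` (reporting the offending eigenvalue) if
    the augmented system is not stable.
    """
    J = jacobian(spec, fixed_point.x, z_ext, frozen_gain=frozen_gain)
    system = StochasticSystem(
        spec=spec,
        z_ext=z_ext,
        fixed_point=fixed_point,
        noise=noise,
        J=J,
        tau_state=_tau_vector(spec),
        rate_fp=_state_rates(spec, fixed_point.x),
        frozen_gain=frozen_gain,
    )
    eigs = np.linalg.eigvals(J)
    worst = eigs[np.argmax(eigs.real)]
    if worst.real >= 0:
        raise StabilityError(
            f"linearized circuit is unstable: eigenvalue {worst:.6g} (1/ms)"
        )
    return system


def lfp_weights(spec: HierarchySpec, area: str) -> np.ndarray:
    """LFP readout vector: the sum of principal-cell membrane potentials."""
    if area not in {a.name for a in spec.areas}:
        raise KeyError(f"unknown area {area!r}")
    w = np.zeros(spec.n_states)
    w[spec.state_slice(area, "y")] = 1.0
    return w


def extrinsic_cross_density(noise: NoiseSpec, n_areas: int) -> np.ndarray:
    """Flat (white) cross-spectral density of the extrinsic LFP noise."""
    c = noise.extrinsic_corr
    corr = (1.0 - c) * np.eye(n_areas) + c * np.ones((n_areas, n_areas))
    return noise.extrinsic_amp**2 * corr


def simulate_sde(
    system: StochasticSystem,
    duration: float = 1000.0,
    dt: float = 0.01,
    seed: int | None = None,
    subsample: int = 10,
    nonlinear: bool = False,
):
    """Euler-Maruyama sample paths of the stochastic circuit.

    Integrates the augmented linear system (default) or the full nonlinear
    dynamics with the same frozen-coefficient noise, starting at the fixed
    point.  Returns ``(times_ms, deviations)`` where ``deviations`` has one
    row per retained sample and columns over the *circuit* states (the OU
    filter states are dropped), measured relative to the fixed point.

    Reproducible bitwise for a given seed; raises on divergence with the
    time of the first non-finite state.
    """
    if dt <= 0 or duration <= 0:
        raise ValueError("dt and duration must be > 0")
    tau_min = float(np.min(system.tau_state))
    if dt > tau_min / 10.0:
        raise ValueError(f"dt={dt} too coarse; need dt <= tau_min/10 = {tau_min/10}")
    rng = np.random.default_rng(system.noise.seed if seed is None else seed)
    n = system.n_circuit
    n_steps = int(round(duration / dt))
    keep = n_steps // subsample
    out = np.empty((keep, n), dtype=float)
    times = (np.arange(keep) + 1) * (dt * subsample)

    sq = np.sqrt(dt)
    a_ou = system.ou_amp / system.noise.tau_noise
    inv_tau = 1.0 / system.tau_state
    tau_n = system.noise.tau_noise
    J = system.J
    xs = np.zeros(n)  # circuit deviation (linear) or absolute state (nonlinear)
    if nonlinear:
        xs = system.fixed_point.x.copy()
    s = np.zeros(n)
    k = 0
    spec, z_ext = system.spec, system.z_ext
    for step in range(n_steps):
        dw = rng.standard_normal(n)
        if nonlinear:
            drift = rhs(spec, xs, z_ext) + s * inv_tau
        else:
            drift = J @ xs + s * inv_tau
        xs = xs + dt * drift
        s = s + dt * (-s / tau_n) + sq * a_ou * dw
        if (step + 1) % subsample == 0:
            if not np.all(np.isfinite(xs)):
                raise RuntimeError(
                    f"SDE diverged at t={(step + 1) * dt:.4g} ms (non-finite state)"
                )
            out[k] = xs
            k += 1
    if nonlinear:
        out -= system.fixed_point.x[None, :]
    return times, out
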