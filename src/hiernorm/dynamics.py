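"""Four-cell-type circuit dynamics, fixed points, and linearization.

Each modeled area holds four ring populations: principal cells ``y``
(excitatory output), excitatory modulators ``u``, inhibitory modulators
``a`` (setting the recurrent gain ``1/(1+a+)``), and inhibitory
interneurons ``q`` (a low-passed copy of the principal firing rate that
gates the feedback drive).  Membrane dynamics, with ``⌊v⌋ = max(v, 0)``
and firing rates ``y+ = ⌊y⌋²``, ``u+ = ⌊u⌋``, ``a+ = ⌊a⌋``, ``q+ = ⌊q⌋``:

    τ_y dy/dt = −y + (β/2) z + [W y + Σ_e (γ_e/2)(W_e y_e+) ⊙ q+] / (1 + a+)
    τ_u du/dt = ρ (u+ + σ/2) (√(σ²/4 + (N y+) ⊙ u+²) − u)
    τ_a da/dt = −a + Σ_e ½ W_e y_e+ + u+ + a ⊙ u+ + α du/dt
    τ_q dq/dt = −q + ⌊y⌋

where ``z`` is the input drive (external for the bottom area, the
feedforward rate projection ``W_eᵀ y_lower+`` otherwise), ``W`` the
recurrent matrix, ``W_e`` the feedback matrix of each edge and ``N`` the
uniform normalization pool.  At β = γ = 1 with identity recurrence this
system's fixed point *is* the normalization equation,
``y+ = z² / (σ² + N z²)``, exactly — the modulator equations are
constructed from that steady state (see docs/methods.md for the
derivation): the pool signal satisfies ``u+ = n/2`` with
``n² = σ² + N z²``, giving recurrent gain ``1 − n/2`` and therefore
``y = z/n``; the q-gate shuts the feedback drive off wherever the
principal cell is silent, so the identity survives arbitrary nonnegative
feedback.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import ndtr

from .network import Connectivity, RingGeometry
from .params import AreaParameters, warn_if_outside

__all__ = [
    "Area",
    "Edge",
    "HierarchySpec",
    "NetworkState",
    "FixedPointError",
    "rate_nonlinearity",
    "two_area",
    "three_area",
    "rhs",
    "jacobian",
    "simulate",
    "solve_fixed_point",
    "normalization_rates",
    "contrast_response",
]

_SQRT2PI = np.sqrt(2.0 * np.pi)


def _phi(t):
    return np.exp(-0.5 * t * t) / _SQRT2PI


# -- rectification nonlinearities -------------------------------------------
# Hard forms are used for fixed points (they make the normalization identity
# exact); the Gaussian-smoothed forms are the expected rectified response
# under additive Gaussian jitter of width `smoothing` and are everywhere
# differentiable.  Derivative convention at the kink of the hard forms is the
# smoothing -> 0 limit: step(0) = 1/2.


def rect(v, smoothing: float = 0.0):
    """Rectified-linear response ``⌊v⌋``, optionally Gaussian smoothed."""
    v = np.asarray(v, dtype=float)
    if smoothing <= 0.0:
        return np.maximum(v, 0.0)
    t = v / smoothing
    return v * ndtr(t) + smoothing * _phi(t)


def drect(v, smoothing: float = 0.0):
    v = np.asarray(v, dtype=float)
    if smoothing <= 0.0:
        return np.where(v > 0, 1.0, np.where(v < 0, 0.0, 0.5))
    return ndtr(v / smoothing)


def rate_nonlinearity(v, smoothing: float = 0.0):
    """Principal-cell firing rate: rectify-and-square, optionally smoothed.

    For ``smoothing = 0`` this is ``⌊v⌋²``; for ``smoothing = s > 0`` it is
    the Gaussian-rectification form ``E[⌊v + ε⌋²]`` with ``ε ~ N(0, s²)``,
    which is everywhere differentiable and converges to the hard form as
    ``s → 0``.
    """
    if smoothing < 0:
        raise ValueError("smoothing must be >= 0")
    v = np.asarray(v, dtype=float)
    if smoothing == 0.0:
        return np.maximum(v, 0.0) ** 2
    t = v / smoothing
    return (v * v + smoothing * smoothing) * ndtr(t) + v * smoothing * _phi(t)


def drate_nonlinearity(v, smoothing: float = 0.0):
    """Derivative of :func:`rate_nonlinearity`; equals ``2 rect(v)``."""
    return 2.0 * rect(v, smoothing)


# -- circuit specification ---------------------------------------------------


@dataclass(frozen=True)
class Area:
    """One cortical area: geometry, intrinsic parameters, recurrence, pool."""

    name: str
    geometry: RingGeometry
    params: AreaParameters
    W_rec: np.ndarray
    N: np.ndarray
    beta: float = 1.0

    def __post_init__(self) -> None:
        n = self.geometry.n_neurons
        if self.W_rec.shape != (n, n) or self.N.shape != (n, n):
            raise ValueError(f"area {self.name}: matrix shapes must be ({n},{n})")
        warn_if_outside("beta", float(np.mean(self.beta)))

    @property
    def n(self) -> int:
        return self.geometry.n_neurons


@dataclass(frozen=True)
class Edge:
    """A reciprocal connection: feedforward ``lower -> higher`` with weights
    ``W_fbᵀ`` and feedback ``higher -> lower`` with weights ``W_fb`` and gain
    ``gamma``.  One object per reciprocal pair guarantees the transpose
    relation by construction."""

    lower: str
    higher: str
    W_fb: np.ndarray
    gamma: float = 1.0

    def __post_init__(self) -> None:
        warn_if_outside("gamma", float(np.mean(self.gamma)))

    @property
    def W_ff(self) -> np.ndarray:
        return self.W_fb.T


class FixedPointError(RuntimeError):
    """Newton refinement failed; carries the best residual achieved."""

    def __init__(self, msg: str, residual: float):
        super().__init__(msg)
        self.residual = residual


@dataclass(frozen=True)
class HierarchySpec:
    """An ordered hierarchy of areas plus reciprocal inter-areal edges."""

    areas: tuple[Area, ...]
    edges: tuple[Edge, ...]
    smoothing: float = 0.0

    def __post_init__(self) -> None:
        names = [a.name for a in self.areas]
        if len(set(names)) != len(names):
            raise ValueError("area names must be unique")
        order = {n: i for i, n in enumerate(names)}
        for e in self.edges:
            if e.lower not in order or e.higher not in order:
                raise ValueError(f"edge references unknown area {e.lower}/{e.higher}")
            if order[e.lower] >= order[e.higher]:
                raise ValueError("edges must point from a lower to a higher area")

    # ---- state-vector bookkeeping: blocks [y, u, a, q] per area, in order
    @property
    def n_per_area(self) -> tuple[int, ...]:
        return tuple(a.n for a in self.areas)

    @property
    def n_states(self) -> int:
        return 4 * sum(self.n_per_area)

    def area(self, name: str) -> Area:
        for a in self.areas:
            if a.name == name:
                return a
        raise KeyError(name)

    def _offset(self, name: str) -> int:
        off = 0
        for a in self.areas:
            if a.name == name:
                return off
            off += 4 * a.n
        raise KeyError(name)

    def state_slice(self, name: str, var: str) -> slice:
        idx = {"y": 0, "u": 1, "a": 2, "q": 3}[var]
        n = self.area(name).n
        off = self._offset(name) + idx * n
        return slice(off, off + n)

    def with_gains(
        self,
        beta: float | dict[str, float] | None = None,
        gamma: float | dict[str, float] | None = None,
    ) -> "HierarchySpec":
        """Return a copy with new input / feedback gains.

        ``beta`` may be a scalar (all areas) or a dict by area name; ``gamma``
        a scalar (all edges) or a dict keyed by the edge's higher-area name.
        """
        areas = self.areas
        edges = self.edges
        if beta is not None:
            bmap = beta if isinstance(beta, dict) else {a.name: beta for a in areas}
            areas = tuple(
                replace(a, beta=bmap.get(a.name, a.beta)) for a in areas
            )
        if gamma is not None:
            gmap = (
                gamma if isinstance(gamma, dict) else {e.higher: gamma for e in edges}
            )
            edges = tuple(
                replace(e, gamma=gmap.get(e.higher, e.gamma)) for e in edges
            )
        return replace(self, areas=areas, edges=edges)


@dataclass
class NetworkState:
    """State vector of a hierarchy with convenient per-population views."""

    spec: HierarchySpec
    x: np.ndarray
    residual: float = np.nan
    stable: bool | None = None

    def get(self, area: str, var: str) -> np.ndarray:
        return self.x[self.spec.state_slice(area, var)]

    def rates(self, area: str) -> np.ndarray:
        """Principal-cell firing rates ``y+`` of one area."""
        return rate_nonlinearity(self.get(area, "y"), self.spec.smoothing)


# -- builders ----------------------------------------------------------------


def _default_area(
    name: str, geometry: RingGeometry, conn: Connectivity, params: AreaParameters,
    beta: float, w_rec: np.ndarray,
) -> Area:
    return Area(
        name=name, geometry=geometry, params=params, W_rec=w_rec, N=conn.N_1,
        beta=beta,
    )


def two_area(
    geometry: RingGeometry | None = None,
    conn: Connectivity | None = None,
    params: AreaParameters | None = None,
    beta: float = 1.0,
    gamma: float = 1.0,
    identity_recurrence: bool = False,
    smoothing: float = 0.0,
) -> HierarchySpec:
    """Default reciprocally connected two-area (V1 <-> V2) hierarchy."""
    geometry = geometry or RingGeometry()
    conn = conn or Connectivity.default(geometry)
    params = params or AreaParameters()
    eye = np.eye(geometry.n_neurons)
    w1 = eye if identity_recurrence else conn.W_11
    w2 = eye if identity_recurrence else conn.W_22
    v1 = _default_area("V1", geometry, conn, params, beta, w1)
    v2 = _default_area("V2", geometry, conn, params, beta, w2)
    edge = Edge(lower="V1", higher="V2", W_fb=conn.W_12, gamma=gamma)
    return HierarchySpec(areas=(v1, v2), edges=(edge,), smoothing=smoothing)


def three_area(
    gamma_v4: float = 1.0,
    gamma_v5: float = 1.0,
    geometry: RingGeometry | None = None,
    conn: Connectivity | None = None,
    params: AreaParameters | None = None,
    beta: float = 1.0,
    smoothing: float = 0.0,
) -> HierarchySpec:
    """V1 reciprocally connected to V4 and V5; no direct V4-V5 connection.

    V4 and V5 are built with *identical* recurrent, feedforward, and feedback
    parameters, so any communication asymmetry is attributable to the feedback
    gains alone.
    """
    geometry = geometry or RingGeometry()
    conn = conn or Connectivity.default(geometry)
    params = params or AreaParameters()
    v1 = _default_area("V1", geometry, conn, params, beta, conn.W_11)
    v4 = _default_area("V4", geometry, conn, params, beta, conn.W_22)
    v5 = _default_area("V5", geometry, conn, params, beta, conn.W_22.copy())
    e4 = Edge(lower="V1", higher="V4", W_fb=conn.W_12, gamma=gamma_v4)
    e5 = Edge(lower="V1", higher="V5", W_fb=conn.W_12.copy(), gamma=gamma_v5)
    return HierarchySpec(areas=(v1, v4, v5), edges=(e4, e5), smoothing=smoothing)


# -- right-hand side and Jacobian -------------------------------------------


def _drive_terms(spec: HierarchySpec, per_area: dict, z_ext: dict):
    """Input drive z_k, and feedback drives (gain-scaled and fixed-1/2)."""
    z = {}
    fb_y = {}  # Σ (γ/2) W_fb y_high+
    fb_a = {}  # Σ (1/2) W_fb y_high+
    for a in spec.areas:
        z[a.name] = np.array(z_ext.get(a.name, np.zeros(a.n)), dtype=float).copy()
        fb_y[a.name] = np.zeros(a.n)
        fb_a[a.name] = np.zeros(a.n)
    for e in spec.edges:
        r2_low = per_area[e.lower]["r2y"]
        r2_high = per_area[e.higher]["r2y"]
        z[e.higher] += e.W_ff @ r2_low
        f = e.W_fb @ r2_high
        fb_y[e.lower] += 0.5 * e.gamma * f
        fb_a[e.lower] += 0.5 * f
    return z, fb_y, fb_a


def _unpack(spec: HierarchySpec, x: np.ndarray) -> dict:
    s = spec.smoothing
    per = {}
    for a in spec.areas:
        y = x[spec.state_slice(a.name, "y")]
        u = x[spec.state_slice(a.name, "u")]
        av = x[spec.state_slice(a.name, "a")]
        q = x[spec.state_slice(a.name, "q")]
        per[a.name] = {
            "y": y, "u": u, "a": av, "q": q,
            "r1y": rect(y, s), "r2y": rate_nonlinearity(y, s),
            "r1u": rect(u, s), "r1a": rect(av, s), "r1q": rect(q, s),
        }
    return per


def rhs(spec: HierarchySpec, x: np.ndarray, z_ext: dict[str, np.ndarray]) -> np.ndarray:
    """Time derivative of the full state vector (time in ms)."""
    x = np.asarray(x, dtype=float)
    if x.shape != (spec.n_states,):
        raise ValueError(f"state must have shape ({spec.n_states},), got {x.shape}")
    per = _unpack(spec, x)
    z, fb_y, fb_a = _drive_terms(spec, per, z_ext)
    out = np.empty_like(x)
    for a in spec.areas:
        p = a.params
        d = per[a.name]
        g = 1.0 / (1.0 + d["r1a"])
        Ey = (
            -d["y"]
            + 0.5 * a.beta * z[a.name]
            + g * (a.W_rec @ d["y"] + fb_y[a.name] * d["r1q"])
        ) / p.tau_y
        pool = np.sqrt(0.25 * p.sigma**2 + (a.N @ d["r2y"]) * d["r1u"] ** 2)
        Eu = p.pool_rate * (d["r1u"] + 0.5 * p.sigma) * (pool - d["u"]) / p.tau_u
        Ea = (
            -d["a"] + fb_a[a.name] + d["r1u"] + d["a"] * d["r1u"]
        ) / p.tau_a + (p.alpha / p.tau_a) * Eu
        Eq = (-d["q"] + d["r1y"]) / p.tau_q
        out[spec.state_slice(a.name, "y")] = Ey
        out[spec.state_slice(a.name, "u")] = Eu
        out[spec.state_slice(a.name, "a")] = Ea
        out[spec.state_slice(a.name, "q")] = Eq
    return out


def jacobian(
    spec: HierarchySpec,
    x: np.ndarray,
    z_ext: dict[str, np.ndarray],
    frozen_gain: bool = False,
) -> np.ndarray:
    """Analytic Jacobian of :func:`rhs` at ``x``.

    ``frozen_gain=True`` removes the influence of the inhibitory modulators
    on the principal cells (the recurrent gain is pinned at its operating
    value), the minimal surgery that deletes dynamic normalization while
    keeping the operating point.
    """
    x = np.asarray(x, dtype=float)
    s = spec.smoothing
    per = _unpack(spec, x)
    z, fb_y, fb_a = _drive_terms(spec, per, z_ext)
    n_tot = spec.n_states
    J = np.zeros((n_tot, n_tot))
    sl = {
        (a.name, v): spec.state_slice(a.name, v)
        for a in spec.areas
        for v in "yuaq"
    }
    deriv = {}
    for a in spec.areas:
        d = per[a.name]
        deriv[a.name] = {
            "d1y": drect(d["y"], s), "d2y": drate_nonlinearity(d["y"], s),
            "d1u": drect(d["u"], s), "d1a": drect(d["a"], s),
            "d1q": drect(d["q"], s),
        }
    for a in spec.areas:
        p = a.params
        d = per[a.name]
        dv = deriv[a.name]
        g = 1.0 / (1.0 + d["r1a"])
        sy, su, sa, sq = (sl[(a.name, v)] for v in "yuaq")
        eye = np.eye(a.n)

        # principal cells
        J[sy, sy] = (-eye + g[:, None] * a.W_rec) / p.tau_y
        if not frozen_gain:
            drive = a.W_rec @ d["y"] + fb_y[a.name] * d["r1q"]
            J[sy, sa] = np.diag(-drive * g * g * dv["d1a"]) / p.tau_y
        J[sy, sq] = np.diag(g * fb_y[a.name] * dv["d1q"]) / p.tau_y

        # excitatory modulators (pool)
        pool = np.sqrt(0.25 * p.sigma**2 + (a.N @ d["r2y"]) * d["r1u"] ** 2)
        w_u = p.pool_rate * (d["r1u"] + 0.5 * p.sigma)
        Ju_y = (
            (w_u * d["r1u"] ** 2 / (2.0 * pool))[:, None]
            * a.N
            * dv["d2y"][None, :]
            / p.tau_u
        )
        J[su, sy] = Ju_y
        Ju_u = np.diag(
            p.pool_rate * dv["d1u"] * (pool - d["u"])
            + w_u * ((a.N @ d["r2y"]) * d["r1u"] * dv["d1u"] / pool - 1.0)
        ) / p.tau_u
        J[su, su] = Ju_u

        # inhibitory modulators
        J[sa, sy] = (p.alpha / p.tau_a) * Ju_y
        J[sa, su] = np.diag((1.0 + d["a"]) * dv["d1u"]) / p.tau_a + (
            p.alpha / p.tau_a
        ) * Ju_u
        J[sa, sa] = (-eye + np.diag(d["r1u"])) / p.tau_a

        # interneurons
        J[sq, sy] = np.diag(dv["d1y"]) / p.tau_q
        J[sq, sq] = -eye / p.tau_q

    # inter-areal couplings
    for e in spec.edges:
        lo, hi = e.lower, e.higher
        a_lo, a_hi = spec.area(lo), spec.area(hi)
        d_lo, d_hi = per[lo], per[hi]
        dv_lo, dv_hi = deriv[lo], deriv[hi]
        g_lo = 1.0 / (1.0 + d_lo["r1a"])
        g_hi = 1.0 / (1.0 + d_hi["r1a"])
        # feedforward: z_high depends on y_low
        J[sl[(hi, "y")], sl[(lo, "y")]] += (
            0.5 * a_hi.beta * (e.W_ff * dv_lo["d2y"][None, :])
        ) / a_hi.params.tau_y
        # feedback into principal cells of the lower area
        J[sl[(lo, "y")], sl[(hi, "y")]] += (
            (g_lo * d_lo["r1q"] * 0.5 * e.gamma)[:, None]
            * e.W_fb
            * dv_hi["d2y"][None, :]
        ) / a_lo.params.tau_y
        # feedback into inhibitory modulators of the lower area
        J[sl[(lo, "a")], sl[(hi, "y")]] += (
            0.5 * e.W_fb * dv_hi["d2y"][None, :]
        ) / a_lo.params.tau_a
    return J


# -- fixed points ------------------------------------------------------------


def normalization_rates(z: np.ndarray, sigma: float, N: np.ndarray) -> np.ndarray:
    """Analytic normalization: ``y+ = z² / (σ² + N z²)`` elementwise."""
    z = np.asarray(z, dtype=float)
    return z**2 / (sigma**2 + N @ z**2)


def _analytic_seed(spec: HierarchySpec, z_ext: dict[str, np.ndarray]) -> np.ndarray:
    """Exact fixed point for β=γ=1 / identity recurrence / uniform pools,
    used as the Newton seed elsewhere.  Drives propagate up the hierarchy
    through the normalization equation; modulators follow their steady-state
    relations."""
    x = np.zeros(spec.n_states)
    rates = {}
    z_eff = {}
    for a in spec.areas:
        z = np.array(z_ext.get(a.name, np.zeros(a.n)), dtype=float) * float(
            np.mean(a.beta)
        )
        for e in spec.edges:
            if e.higher == a.name:
                z = z + e.W_ff @ rates[e.lower]
        z_eff[a.name] = z
        sigma = a.params.sigma
        nvec = np.sqrt(sigma**2 + a.N @ z**2)
        y = z / nvec
        rates[a.name] = y**2
        x[spec.state_slice(a.name, "y")] = y
        x[spec.state_slice(a.name, "u")] = nvec / 2.0
        x[spec.state_slice(a.name, "q")] = np.maximum(y, 0.0)
    # second pass: inhibitory modulators need the higher area's rates
    for a in spec.areas:
        fb = np.zeros(a.n)
        for e in spec.edges:
            if e.lower == a.name:
                fb += 0.5 * (e.W_fb @ rates[e.higher])
        u = x[spec.state_slice(a.name, "u")]
        x[spec.state_slice(a.name, "a")] = (fb + u) / (1.0 - u)
    return x


def _newton(spec, z_ext, x0, tol, max_iter):
    x = x0.copy()
    f = rhs(spec, x, z_ext)
    best = np.max(np.abs(f))
    for _ in range(max_iter):
        if best < tol:
            break
        J = jacobian(spec, x, z_ext)
        try:
            dx = np.linalg.solve(J, -f)
        except np.linalg.LinAlgError:
            dx = np.linalg.lstsq(J, -f, rcond=None)[0]
        lam = 1.0
        for _ in range(40):
            x_try = x + lam * dx
            f_try = rhs(spec, x_try, z_ext)
            r_try = np.max(np.abs(f_try))
            if r_try < best or r_try < tol:
                x, f, best = x_try, f_try, r_try
                break
            lam *= 0.5
        else:
            break
    return x, best


def solve_fixed_point(
    spec: HierarchySpec,
    z_ext: dict[str, np.ndarray],
    tol: float = 1e-12,
    max_iter: int = 200,
    check_stability: bool = True,
    x0: np.ndarray | None = None,
) -> NetworkState:
    """Fixed point of the hierarchy for the given external drive.

    The analytic normalization point (or a caller-provided warm start
    ``x0``) seeds a damped Newton iteration on ``rhs = 0``; when β = γ = 1
    and the recurrent matrices are the identity the analytic seed itself is
    the solution and Newton terminates immediately.  If the direct solve
    stalls, a transient integration pulls the iterate into the fixed point's
    basin before polishing.  Local stability (all Jacobian eigenvalues with
    negative real part) is reported on the returned state, flagged but not
    raised.
    """
    if x0 is not None:
        x, res = _newton(spec, z_ext, np.asarray(x0, dtype=float), tol, max_iter)
        if res < tol:
            state = NetworkState(spec=spec, x=x, residual=res)
            if check_stability:
                eigs = np.linalg.eigvals(jacobian(spec, x, z_ext))
                state.stable = bool(np.max(eigs.real) < 0.0)
            return state
    x0 = _analytic_seed(spec, z_ext)
    x, res = _newton(spec, z_ext, x0, tol, max_iter)
    if res >= tol:
        # warm-start Newton from the tail of a transient integration; the
        # analytic seed is exact only for identity recurrence, and plain
        # damped Newton can stall across the rectification kinks
        from scipy.integrate import solve_ivp

        x_try = x0
        for duration in (300.0, 1500.0):
            sol = solve_ivp(
                lambda t, v: rhs(spec, v, z_ext),
                (0.0, duration),
                x_try,
                method="LSODA",
                jac=lambda t, v: jacobian(spec, v, z_ext),
                rtol=1e-8,
                atol=1e-11,
            )
            x_try = sol.y[:, -1]
            x, res = _newton(spec, z_ext, x_try, tol, max_iter)
            if res < tol:
                break
        if res >= tol:
            raise FixedPointError(
                f"Newton did not reach tol={tol:g}; best residual {res:.3e}", res
            )
    state = NetworkState(spec=spec, x=x, residual=res)
    if check_stability:
        eigs = np.linalg.eigvals(jacobian(spec, x, z_ext))
        state.stable = bool(np.max(eigs.real) < 0.0)
    return state


# -- deterministic integration ----------------------------------------------


def simulate(
    spec: HierarchySpec,
    z_ext: dict[str, np.ndarray],
    x0: np.ndarray | None = None,
    duration: float = 200.0,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "LSODA",
    t_eval: np.ndarray | None = None,
    onset_ramp: float = 0.0,
):
    """Integrate the deterministic dynamics for ``duration`` ms.

    ``onset_ramp > 0`` scales the external drive linearly from zero over the
    first ``onset_ramp`` ms.  Instantaneous large-contrast steps can throw
    the strongly amplifying circuit outside the fixed point's basin of
    attraction (see docs/methods.md); a ramped onset, like a real stimulus
    onset transient, keeps the trajectory on the stable branch.

    Returns the scipy solution object (``t`` in ms, ``y`` the state
    trajectory).  Raises a ``RuntimeError`` naming the first bad time if the
    state leaves the finite range.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    x0 = np.zeros(spec.n_states) if x0 is None else np.asarray(x0, dtype=float)

    def scaled(t):
        if onset_ramp <= 0.0:
            return z_ext
        s = min(t / onset_ramp, 1.0)
        return {k: s * v for k, v in z_ext.items()}

    def f(t, x):
        dx = rhs(spec, x, scaled(t))
        if not np.all(np.isfinite(dx)):
            raise RuntimeError(f"non-finite state derivative at t={t:.6g} ms")
        return dx

    def jac(t, x):
        return jacobian(spec, x, scaled(t))

    sol = __import__("scipy.integrate", fromlist=["solve_ivp"]).solve_ivp(
        f, (0.0, duration), x0, method=method, jac=jac, rtol=rtol, atol=atol,
        t_eval=t_eval,
    )
    if not sol.success:
        raise RuntimeError(f"integration failed: {sol.message}")
    return sol


# -- contrast response -------------------------------------------------------


def contrast_response(
    spec: HierarchySpec,
    contrasts,
    orientation: float = 90.0,
    tuning_half_width: float = 40.0,
    mode: str = "max",
):
    """Fixed-point firing rate versus contrast, per area.

    ``mode='max'`` reports the maximally responsive principal neuron (the
    convention used for coherence pairs); ``mode='mean'`` the population mean.
    Returns a pandas DataFrame with columns contrast_pct, area, rate.
    """
    import pandas as pd

    from .network import Stimulus, input_drive

    bottom = spec.areas[0]
    rows = []
    for c in contrasts:
        z = input_drive(Stimulus(c, orientation), bottom.geometry, tuning_half_width)
        state = solve_fixed_point(spec, {bottom.name: z}, check_stability=False)
        for a in spec.areas:
            r = state.rates(a.name)
            val = float(r.max()) if mode == "max" else float(r.mean())
            rows.append({"contrast_pct": float(c), "area": a.name, "rate": val})
    return pd.DataFrame(rows)
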