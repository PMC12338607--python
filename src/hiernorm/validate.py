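"""Internal oracle triangle: fixed point, Lyapunov covariance, analytic
spectra, and stochastic simulation must agree with each other.

Checks are run on a reduced ring (fast) but with the calibrated default
parameters otherwise.
"""

from __future__ import annotations

import numpy as np

from .config import default_config, build_circuit
from .dynamics import solve_fixed_point, normalization_rates, rhs, two_area
from .network import RingGeometry, Stimulus, input_drive
from .noise import build_stochastic_system, simulate_sde
from .spectra import psd
from .subspace import augmented_covariance, stationary_covariance

__all__ = ["run_validation"]


def run_validation(cfg: dict | None = None, n_neurons: int = 16,
                   sde_duration: float = 2000.0) -> dict:
    cfg = cfg or default_config()
    cfg = {**cfg, "circuit": {**cfg["circuit"], "n_neurons": n_neurons}}
    report = {}

    # 1. normalization fixed point, identity recurrence
    spec_id = two_area(
        geometry=RingGeometry(n_neurons), identity_recurrence=True
    )
    g = spec_id.areas[0].geometry
    errs = []
    for c in (0.0, 3.0, 6.0, 12.0, 25.0, 50.0, 100.0):
        z = input_drive(Stimulus(c, cfg["stimulus"]["orientation"]), g,
                        cfg["circuit"]["tuning_half_width"])
        st = solve_fixed_point(spec_id, {"V1": z}, check_stability=False)
        a1 = spec_id.areas[0]
        errs.append(np.max(np.abs(
            st.rates("V1") - normalization_rates(z, a1.params.sigma, a1.N)
        )))
        z2 = spec_id.edges[0].W_ff @ st.rates("V1")
        a2 = spec_id.areas[1]
        errs.append(np.max(np.abs(
            st.rates("V2") - normalization_rates(z2, a2.params.sigma, a2.N)
        )))
    report["fixed_point"] = {"max_abs_error": float(max(errs)),
                             "ok": max(errs) < 1e-10}

    # default circuit at 50% contrast
    spec, noise = build_circuit(cfg)
    z = input_drive(Stimulus(50.0, cfg["stimulus"]["orientation"]),
                    spec.areas[0].geometry, cfg["circuit"]["tuning_half_width"])
    st = solve_fixed_point(spec, {"V1": z})
    report["fp_residual"] = {"residual": float(st.residual), "stable": st.stable,
                             "ok": st.residual < 1e-10 and bool(st.stable)}
    sys = build_stochastic_system(spec, st, noise, {"V1": z})

    # 2. Lyapunov residual on the augmented system
    C_aug = augmented_covariance(sys)
    J, L = sys.J_aug, sys.L_aug
    M = L @ L.T
    resid = np.linalg.norm(J @ C_aug + C_aug @ J.T + M) / np.linalg.norm(M)
    report["lyapunov"] = {"relative_residual": float(resid), "ok": resid < 1e-10}

    # 3. Wiener-Khinchin: integral of the analytic spectrum = covariance
    C = stationary_covariance(sys)
    idx = np.concatenate([
        np.arange(*spec.state_slice("V1", "y").indices(spec.n_states))[:4],
        np.arange(*spec.state_slice("V2", "y").indices(spec.n_states))[:4],
    ])
    E = np.zeros((idx.size, spec.n_states))
    E[np.arange(idx.size), idx] = 1.0
    freqs = np.linspace(0.0, 5000.0, 20001)
    S = psd(sys, freqs, E)
    integral = 2.0 * np.trapezoid(S.S.real, freqs, axis=0)  # two-sided
    C_blk = C[np.ix_(idx, idx)]
    rel = np.max(np.abs(integral - C_blk)) / np.max(np.abs(C_blk))
    report["wiener_khinchin"] = {"max_rel_error": float(rel), "ok": rel < 0.01}

    # 4. SDE oracle: empirical covariance vs Lyapunov solution
    times, paths = simulate_sde(sys, duration=sde_duration, dt=0.01,
                                subsample=10)
    burn = paths.shape[0] // 10
    dev = paths[burn:]
    C_emp = dev.T @ dev / dev.shape[0]
    err = np.linalg.norm(C_emp - C) / np.linalg.norm(C)
    report["sde_covariance"] = {"rel_frobenius_error": float(err),
                                "ok": err < 0.10}
    return report
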