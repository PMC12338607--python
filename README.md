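# hiernorm

Hierarchical recurrent normalization circuits: ring-network models of
reciprocally connected visual cortical areas (V1↔V2, or V1↔V4/V5) that
implement divisive normalization dynamically, with closed-form
linear-response observables — power spectra, inter-areal coherence,
stationary covariance, and communication-subspace analytics — validated
against a stochastic simulation oracle.

The package is for computational neuroscientists studying how top-down
feedback and normalization shape inter-areal communication: how
contrast and gain move oscillatory peaks in LFP power and coherence,
and how the same linearized fluctuations define low-dimensional
communication subspaces between areas.

## The model

Each area is a 72-neuron orientation ring with four cell types:
principal cells **y** (rates y⁺ = ⌊y⌋²), excitatory modulators **u**,
inhibitory modulators **a** (setting the recurrent gain 1/(1+a⁺)), and
interneurons **q** that gate the feedback drive:

    τ_y ẏ = −y + (β/2) z + [W y + (γ/2)(W_fb y_high⁺) ⊙ q⁺] / (1 + a⁺)

with modulator dynamics constructed so that, at balanced gains
(β = γ = 1) and identity recurrence, the fixed point is *exactly* the
divisive normalization equation in every area:

    y⁺ = z² / (σ² + N z²),        σ = 0.07, N = uniform pool.

Around the stable fixed point the circuit is linearized; the
cross-spectral density follows the resolvent formula
S(ω) = (iωI − J)⁻¹ L D Lᵀ (−iωI − Jᵀ)⁻¹, coherence is
κ_ij = |S_ij|²/(S_ii S_jj), the stationary covariance C(0) solves
J C + C Jᵀ = −L D Lᵀ, and communication subspaces come from
reduced-rank regression on model covariances: B_opt = C1⁻¹C3,
Ĉ2 = C3ᵀC1⁻¹C3, Performance(i) = Σ_{j≤i} λ_j / Tr C2.  The model and
all conventions are documented in `docs/methods.md`.

## Worked example

```python
import numpy as np
from hiernorm import two_area, solve_fixed_point, input_drive, Stimulus
from hiernorm.noise import NoiseSpec, build_stochastic_system
from hiernorm.spectra import lfp_psd, normalize_power, find_spectral_peak

spec = two_area()                       # default calibrated V1<->V2 circuit
g = spec.areas[0].geometry
z50 = {"V1": input_drive(Stimulus(50.0, 90.0), g)}
state = solve_fixed_point(spec, z50)
print(f"V1 peak rate {state.rates('V1').max():.3f}, "
      f"V2 peak rate {state.rates('V2').max():.3f}, stable={state.stable}")

noise = NoiseSpec()
system = build_stochastic_system(spec, state, noise, z50)
freqs = np.arange(1.0, 1001.0, 1.0)
p50 = lfp_psd(system, freqs, include_extrinsic=False).auto(0)

z0 = {"V1": np.zeros(g.n_neurons)}
rest = solve_fixed_point(spec, z0)
base = lfp_psd(build_stochastic_system(spec, rest, noise, z0),
               freqs, include_extrinsic=False).auto(0)
peak = find_spectral_peak(freqs, normalize_power(p50, base), band=(5, 150))
print(f"normalized V1 power peaks at {peak[0]:.1f} Hz (height {peak[1]:.2f})")
```

prints

```
V1 peak rate 3.033, V2 peak rate 3.786, stable=True
normalized V1 power peaks at 21.0 Hz (height 0.85)
```

The V1/V2 rates show the hierarchy's contrast gain (V2 saturates harder
and earlier than V1), and the normalized spectrum shows the
contrast-driven resonance of the normalization loop; its peak moves to
higher frequencies as contrast or feedback gain rises, while coherence
between the maximally firing V1 and V2 neurons peaks in the gamma band
(≈46 Hz at 50% contrast).

## Command line

```bash
hiernorm crf --out out/               # contrast-response + Naka-Rushton fits
hiernorm spectra --sweep contrast     # normalized V1 power spectra
hiernorm coherence --sweep gamma      # V1-V2 coherence vs feedback gain
hiernorm subspace --contrast 100      # within/inter-areal communication
hiernorm freqcomm                     # frequency-resolved communication
hiernorm three-area --gamma-v4 0.25 --gamma-v5 1.0
hiernorm validate                     # internal consistency checks
```

All commands accept `--config file.yaml` (merged over the defaults),
`--out`, and `--seed`, and write CSV/JSON outputs plus a run manifest.

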