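# Methods

## The circuit model

`hiernorm` models a hierarchy of visual cortical areas (V1↔V2, or
V1↔V4 and V1↔V5) as reciprocally connected ring networks that implement
divisive normalization *dynamically*, through recurrent amplification
controlled by modulator cells.  Each area holds four cell types on a
common 72-neuron orientation ring (180°-periodic): principal cells
**y**, excitatory modulators **u**, inhibitory modulators **a**
(which set the recurrent gain), and inhibitory interneurons **q**
(which gate the feedback drive).  With ⌊v⌋ = max(v, 0), firing rates
are y⁺ = ⌊y⌋², u⁺ = ⌊u⌋, a⁺ = ⌊a⌋, q⁺ = ⌊q⌋ — each cell type has its
own F-I curve.  The membrane dynamics of one area are

    τ_y ẏ = −y + (β/2) z + [W y + Σ_e (γ_e/2)(W_e y_e⁺) ⊙ q⁺] / (1 + a⁺)
    τ_u u̇ = ρ (u⁺ + σ/2) ⊙ (√(σ²/4 + (N y⁺) ⊙ u⁺²) − u)
    τ_a ȧ = −a + Σ_e ½ W_e y_e⁺ + u⁺ + a ⊙ u⁺ + α u̇
    τ_q q̇ = −q + ⌊y⌋

where z is the input drive (for V1 the stimulus contrast in [0,1] times
the raised-cosine tuning-curve value; for a higher area the feedforward
rate projection W_eᵀ y_lower⁺), W the center-surround recurrent matrix
with unit spectral radius, W_e the nonnegative symmetric feedback matrix
of each inter-areal edge (the feedforward matrix is its transpose,
hence identical), and N the uniform normalization pool
(ones / n_neurons).  β is the input gain, γ the feedback gain; the
feedback routed to the inhibitory modulators and the modulator input
share are both pinned at ½, so β and γ set *relative* gains.

### Exact normalization fixed point

The modulator equations are constructed from the steady state they must
enforce.  At β = γ = 1 with identity recurrence, write
n² = σ² + N z² (uniform over the ring for the uniform pool).  Then the
fixed point satisfies, exactly:

- u⁺ = n/2 — the u population tracks half the norm of the
  normalization pool (the u-equation's bracket vanishes iff
  u⁺²(1 − N y⁺) = σ²/4, which is algebraically equivalent);
- a = (f ⊙ ⌊y⌋ + … )/(1−u⁺): from the a-equation,
  a⁺ = (n + f z/n)/(2 − n) where f is the feedback drive;
- the recurrent gain becomes 1/(1+a⁺), and substituting into the
  y-equation yields y = z/n, i.e. **y⁺ = z²/(σ² + N z²)** — the
  divisive normalization equation — in every area simultaneously
  (for a higher area, with z the realized feedforward drive).

The q⁺ gate on the feedback drive is what makes the identity survive
arbitrary nonnegative feedback matrices: wherever a principal cell is
silent its gate is closed, so off-bump neurons receive no feedback
excitation and remain exactly silent.  Away from the balanced point
(β, γ ≠ 1, ring recurrence) the fixed point is found by damped Newton
iteration seeded by the analytic point (with an integrate-then-polish
fallback), to a residual below 1e-12, and local stability is checked by
the Jacobian eigenvalues.

Design notes on the reconstruction: the recurrent drive is linear in
the membrane potential (this is what makes "maximum eigenvalue of W set
to one" the right stability normalization, and what allows the
recurrent loop to amplify weak inputs as strongly as normalization
requires: the loop gain is 1 − n/2, so the amplification is 1/n); the
pool-rate factor ρ (u⁺ + σ/2), with the structural constant ρ = 2, sets
how fast the normalization pool tracks its target without affecting any
fixed point — it is the main determinant of the resonance frequencies
discussed below.  The α u̇ term gives the inhibitory modulators a
phase-advanced copy of the pool velocity; it is strongly stabilizing.

### Parameters

| parameter | default | units | meaning |
|---|---|---|---|
| τ_y, τ_u, τ_a, τ_q | 1 | ms | intrinsic time constants |
| α | 10 | — | derivative coupling u̇ → a |
| σ | 0.07 | — | semisaturation constant |
| β | 1 | — | input gain (per area) |
| γ | 1 | — | feedback gain (per edge) |
| ρ (pool_rate) | 2 | — | pool tracking rate factor |
| tuning half-width | 40 | deg | raised-cosine support |
| recurrent DoG σ_E/σ_I | 45/90 | deg | center-surround widths |
| surround strength | 0.5 | — | inhibitory lobe amplitude |
| feedback width / row sum | 15 / 0.75 | deg / — | inter-areal kernel |

Gains and intrinsic parameters outside the tested stability ranges
(γ ∈ [0, 1.1], β ∈ [0, 2.5], α ∈ [7.5, 50], σ ∈ [0.035, 0.14]) raise a
warning, not an error.  The connectivity scales were calibrated once,
jointly, against the qualitative spectral phenomenology (gamma-band
resonance growing with contrast, ~10 Hz peak at low contrast and weak
feedback, 1/f⁴ tail) and then frozen; they are exposed in the YAML
config.

## Noise model and analytic observables

Each membrane equation receives Ornstein-Uhlenbeck (low-pass filtered)
synaptic noise through its own auxiliary filter state
(τ_noise = 1 ms).  The filter's drive variance has an additive part
(synaptic_amp = 1) and a signal-dependent part proportional to the
state's fixed-point firing rate (mult_amp = 0.5, frozen-coefficient
small-noise treatment).  Folding the rate-dependent term into the
filtered source (rather than injecting it white) is what preserves the
observed 1/f⁴ high-frequency tail: one factor 1/f² from the synaptic
filter, one from the membrane.  Extrinsic measurement noise
(amplitude 0.05, inter-areal correlation 0.5) is added only to the LFP
observation — never to the dynamics — as a flat cross-spectral term.

Linearizing at the fixed point gives dx = J x dt + L dW.  The analytic
observables are:

- **Cross-spectral density** S(f) = (2πif·I − J)⁻¹ M(f) (−2πif·I − Jᵀ)⁻¹,
  with M(f) the diagonal effective forcing density (OU filter states
  integrated out analytically).  One eigendecomposition of J serves the
  whole frequency grid.  Densities are two-sided per Hz, so the
  full-axis integral equals the stationary covariance (Wiener-Khinchin,
  verified to < 1% in the tests).
- **Coherence** κ_ij(f) = |S_ij|²/(S_ii S_jj), reported between the
  maximally firing V1 and V2 neurons; the extrinsic term is excluded
  for single-neuron coherence by default.
- **Stationary covariance** from the Lyapunov equation, solved in
  blocks (filter block, Sylvester cross block, circuit block) so the
  cost stays at the circuit dimension.
- **LFP proxy**: the summed principal-cell membrane potentials of an
  area; normalized power uses (p − b)/(p + b) against the 0%-contrast
  baseline.

The Euler-Maruyama simulator integrates the same augmented system
(linearized by default, full nonlinear drift optionally) and serves as
the empirical oracle: spectra, Lyapunov covariance, and simulation must
agree pairwise.  The default oracle run uses an 8-neuron ring and
320 s of model time at dt = 0.02 ms; the slowest collective mode of the
calibrated circuit has a ~170 ms correlation time, which sets the
averaging time needed for ~5% Monte-Carlo error.

## Communication subspaces

Fluctuations are read out as principal-cell firing rates (slope 2⌊y*⌋
at the fixed point).  For a source population s and target population t
with covariances C1, C2 and cross-covariance C3, the optimal linear
readout is B_opt = C1⁻¹C3 (symmetric pseudo-inverse, relative cutoff
1e-12; optional ridge for user-supplied covariances), the predicted
target covariance Ĉ2 = C3ᵀC1⁻¹C3, and the rank-i prediction performance
is Σ_{j≤i} λ_j / Tr C2 over the sorted eigenvalues of Ĉ2.  Subset
averaging follows the 30-source/30-target, 25-repeat protocol with
disjoint draws for within-area partitions; SEM uses the unbiased sample
standard deviation.  Dimensionality is reported by default as the
smallest rank reaching 95% of the full-rank performance; the
eigenvalue-rank criterion is available and equals the rank of C3
whenever C1 is full rank.

The frequency decomposition substitutes Re S(f) (the narrowband limit
of the covariance, constant prefactor dropped) for the covariance and
repeats the analysis per frequency, giving communication efficacy and
dimensionality as functions of frequency.

## What the defaults reproduce, and what they do not

With the single frozen calibration the model reproduces: the exact
normalization fixed point; contrast-response functions whose
semisaturation contrast decreases and exponent increases up the
hierarchy; a low-frequency (~10-13 Hz) normalized-power peak at low
contrast and weak feedback that vanishes at high feedback gain; a 1/f⁴
high-frequency tail; inter-areal coherence peaks that move from the
beta band into the gamma band (≈24 → 46 Hz) as contrast rises;
feedback-gain routing of inter-areal communication (including the exact
three-area symmetry); and normalized-power peak heights that are
non-monotonic in contrast.

Known quantitative departures of the reconstruction, measured and left
uncorrected rather than tuned away:

- The V1 *power* peak at 50% contrast sits near 21 Hz (the local pool
  resonance); the 40-60 Hz resonance of the inter-areal loop is
  expressed in the coherence spectra but does not dominate the V1 LFP.
- Peak coherence and peak communication keep growing toward 100%
  contrast instead of maximizing near 40%; the inter-areal coupling of
  the reconstruction strengthens monotonically with contrast.
- At 100% contrast the inter-areal communication subspace is *higher*
  dimensional (~4) than the within-area one (~2): within-area
  fluctuations are dominated by two collective modes.
- Removing dynamic normalization (freezing the recurrent gain at its
  operating value) destabilizes the circuit outright above ~3%
  contrast — normalization is load-bearing for stability here, so the
  "no-normalization" spectral control has no stable operating point to
  probe at mid contrast.
- Instantaneous large-contrast steps from rest can escape the fixed
  point's basin (the inter-areal excitatory transient outruns the
  modulators); `simulate(..., onset_ramp=200.0)` ramps the stimulus on
  and tracks the stable branch.  All linear-response analyses are local
  and unaffected.

## Numerical choices

Hard rectifications are used for fixed points (they make the
normalization identity exact); the kink derivative convention is the
Gaussian-smoothing limit (slope ½ at zero), which is also what central
finite differences measure.  A smoothed Gaussian-rectification variant
(everywhere differentiable) is available through the `smoothing`
parameter.  Newton uses step-halving damping, max 200 iterations,
tolerance 1e-12 in the max norm.  Deterministic integration uses LSODA
with rtol 1e-8/atol 1e-10 and the analytic Jacobian.  Spectral peaks
are refined by three-point quadratic interpolation in log power;
interior-peak detection rejects band-edge maxima.  Frequency grids:
1-1000 Hz at 1 Hz for spectra, 2-100 Hz at 2 Hz for the frequency-
resolved subspace analyses, 0-5 kHz for Wiener-Khinchin integrals.
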