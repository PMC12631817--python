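# Methods

This note documents the models behind `uspt`, the choices that were
genuinely open when it was built, and what its synthetic validation does and
does not show about real data.

## 1. Upconversion rate equations (`uspt.photophysics`)

### Model

The particle is three concentric layers: an Er³⁺-doped core (cation
fractions x_Yb, x_Er of a lattice with ρ_c ≈ 13.9 lanthanide sites nm⁻³), a
pure-Yb interior shell, and an optically inert outer shell of thickness t.
Populations are mean-field densities: two Yb levels in each of two
compartments (core, interior shell) and five effective Er levels, with
⁴F₇/₂ collapsed into the green level 4 (it relaxes orders of magnitude
faster than everything else) and ²H₁₁/₂/⁴S₃/₂ merged.

Kinetics, all per nm³ and second:

| process | form | direction |
|---|---|---|
| pumping | σφ·N_Yb0 (both compartments) | Yb₀→Yb₁ |
| Yb decay | N_Yb1/τ_Yb | Yb₁→Yb₀ |
| migration + IET | (k_mig·x_Yb + k_IET)(N_Yb1^shell − N_Yb1^core) | shell↔core |
| ETU-1/2/3 | c_i·N_Yb1·N_Er,j | Er 0→2, 2→4, 1→3 |
| BET | c_BET·N_Er4·N_Yb0 | Er₄→Er₁, Yb₀→Yb₁ |
| CR | c_CR·N_Er4·N_Er0 | Er₄+Er₀→2 Er₁ |
| Er decay | N_i/τ_i with branching b₄₃ (4→3) and b₂₁ (2→1) | down-ladder |
| surface quench | k_s0·e^(−t/λ_s) on shell Yb₁ and Er 1, 3, 4 | →ground |

BET and ETU-3 are implemented in their thermodynamically consistent
directions (Er₄+Yb₀→Er₁+Yb₁; Yb₁+Er₁→Yb₀+Er₃): together they drain the
green level into the ⁴F₉/₂ red level, which is what produces the rising
red-to-green ratio with sensitizer content and power. Every transfer term
moves one quantum per event, so compartment Yb totals and the Er total are
conserved identically; solvers work in reduced (excited-only) coordinates,
making conservation exact rather than approximate.

Green emission is the radiative fraction (1−b₄₃) of level-4 decay, red the
level-3 decay, both scaled by core volume; intensities are per particle on
an arbitrary photon scale.

### Parameters

No fitted rate-constant set ships with the model. The default preset uses
order-of-magnitude literature values for β-NaREF₄ Yb/Er systems (σ = 1.2e-20
cm², τ_Yb = 1 ms, τ_Er = 2/2/0.5/0.4 ms, ETU coefficients 30–70 nm³ s⁻¹,
k_mig = 2×10⁴ s⁻¹, k_s0 = 10⁴ s⁻¹, λ_s = 1 nm) and was screened once, before
freezing, against the qualitative trend suite (monotone S-shaped doping
curve, slope softening with doping, R/G non-decreasing in doping and power,
shell saturation near five decay lengths). Two structural choices matter for
the trends: the ETU-3 conversion of the Er₁ reservoir must be *unsaturated*
(c₃·N_Yb1 below the Er₁ removal rate) so the red chain gains an extra power
order, and the Er₁-feeding channels must be dominated by CR (whose partner,
ground-state Er, barely depletes) rather than BET (whose partner, ground-
state Yb, depletes ~40% over the power range and would bend R/G downward).
Only trends should be read off this preset, never absolute photon rates.

### Numerics

Stiff BDF integration (rtol 1e-8, atol 1e-14·ρ_c) to 50 lifetimes, then
damped Newton (step halving, ≤50 iterations) on the reduced system to
residual max|dN/dt|·τ/ρ_c < 1e-10. The Newton root and a 400-lifetime
integration agree to 1e-8 on a (x_Yb, ρ) grid. Power-dependence slopes are
unweighted least squares on log₁₀ I vs log₁₀ ρ over the lowest decade of the
grid, the standard convention for upconversion power studies. Decay
lifetimes are mono-exponential fits over the 50%→1% tail window.

## 2. EMCCD simulation and photometry (`uspt.imaging`)

Forward model per frame: expected photons from rate×exposure×QE distributed
over an integrated (erf) 2-D Gaussian PSF (default σ = 1.3 px at 160 nm/px)
plus uniform background; Poisson shot noise; EM multiplication as a gamma
variate with shape = electron count and scale = gain (the standard
approximation carrying the √2 excess-noise factor); Gaussian read noise;
ADU conversion with offset, clipping at 16 bits with a saturation mask. A
`noiseless` mode returns expectations, making the bookkeeping exactly
invertible for calibration tests.

Inverse: LoG blob detection on the temporal mean frame (threshold defaults
to 5× the MAD-based pixel noise), sub-pixel refinement by local Gaussian
least squares, then aperture photometry: (ADU−offset)·e/ADU ÷ (gain·QE),
3σ aperture minus 5–7σ annulus background, divided by exposure and by the
enclosed-energy fraction 1−exp(−r²/2σ²) of the aperture. The estimate is
gain- and exposure-invariant by construction; the photon-transfer curve is
linear with slope 1.00 ± 0.02 over 10²–10⁵ photons s⁻¹ and the end-to-end
bias is below 3%. Channel filters are treated as ideal (no crosstalk), and
there is no drift or flat-field correction — the module is a photon-budget
testbed, not a microscope model.

## 3. Trajectory hidden-Markov analysis (`uspt.transport`)

### Displacement model and fitting

Hidden states are D (pure diffusion) or DT (diffusion + constant drift);
a displacement in state k is N(v_k·Δt, 2D_k·Δt·I₂). Baum–Welch EM runs in
log space (numba kernels) with closed-form M-steps; the likelihood is
checked to be non-decreasing every iteration and any violation beyond 1e-8
raises. Initialization is k-means on step vectors plus five seeded
perturbations. Viterbi decoding breaks ties toward the lowest state index
and matches exhaustive enumeration on randomized small cases. Candidate
models are the nine multisets of {D, DT} with 1–3 states; the evidence is
the BIC-type score logL − (p/2)·log n (p = 1 per D state, 3 per DT state,
K(K−1) transition + K−1 initial parameters), with normalized exponentiated
scores as model probabilities and ties resolved toward simpler models.

**Persistence constraint.** Localization error added to positions makes
consecutive observed displacements anti-correlated (lag-1 correlation
−σ²/(2DΔt+2σ²), about −0.45 at the default settings). An unconstrained
displacement HMM exploits this with a spurious fast-oscillating two-state
solution that can sit ~100 nats above the motion structure. Motion states
that flip faster than the frame interval are physically unresolvable, so
the M-step constrains self-transition probabilities to ≥ 0.5 (the
constrained maximizer of the expected complete-data log-likelihood, so EM
monotonicity is preserved).

### Cohort pipeline

Per-trajectory evidence cannot justify three states at realistic noise: at
σ_loc = 30 nm and 600 frames even fits initialized at the generating
parameters gain only ~14 nats from the third state against a ~19-nat BIC
increment, because per-step assignment is uncertain. The pipeline therefore
separates three concerns:

1. **Selection** runs on the pooled cohort: trajectories are rotated into
   their axon frames (+x anterograde) and each candidate is fitted once
   with shared parameters, paying its complexity penalty once against the
   pooled displacement count. On control cohorts the D,DT,DT model then
   wins with near-unit probability. Per-trajectory selection remains
   available and is reported alongside when requested.
2. **Estimation** runs on 3-frame block displacements: block noise variance
   equals single-step noise variance while drift triples, and the block
   span (0.15 s) stays far below the ~1 s state dwell. At full resolution
   even decoding with the *true* parameters leaves +0.05 µm/s step-speed
   biases; at 3-frame blocks the same oracle is nearly unbiased.
3. **Per-trajectory refits** re-estimate each trajectory's state parameters
   by MAP-EM anchored on the pooled fit (Gaussian prior on drifts,
   inverse-gamma on diffusion coefficients, both centred on pooled values
   and weak enough that a few dozen displacements dominate). The priors
   only prevent a state from abandoning its cohort role on trajectories
   that barely visit it.

### Speed and transition estimators

A directed state's speed is the magnitude of the mean block displacement
over Viterbi segment *interiors* (segments ≥ 3 blocks, one block trimmed
per side): localization noise cancels in the mean, and boundary blocks —
the ones assigned partly on their own value — are excluded. The diffusive
state, which has no drift parameter, reports the mean step speed
√(πD/Δt_frame) of its de-noised process, with D estimated from the
within-segment variance of deep interiors of long segments (≥ 6 blocks,
two trimmed per side) after three exact corrections: per-segment mean
removal (a misassigned directed run then contributes scatter but no
drift), the MA(1) small-sample term that mean removal of anti-correlated
steps induces (2σ²/n per axis), and the localization variance itself. When
σ_loc is unknown the variance-plus-twice-lag-1-autocovariance estimator is
used instead (no σ needed, modest upward contamination bias). Cohort
speeds are unweighted means over trajectories — each trajectory is one
biological replicate; speed SDs are across-trajectory. Pooled transition
matrices are row-normalized Viterbi transition counts at block resolution.

**Known bias.** Trajectories whose drawn directed speed is unresolvable
(|v|·Δt below the noise scale) produce no directed segments; the detected
subset is faster than the cohort, which leaves the directed cohort means
sitting ≈ +0.02 µm/s high at the default conditions. A Tobit-style
censored-normal correction overcorrects (detection is not a sharp
threshold) and is not applied. The diffusive-state D̂ absorbs σ²/Δt when
uncorrected; the known-σ subtraction removes it, and the residual bias of
the fitted D̂ at small D is quantified in the test suite.

## 4. Synthetic cohorts (`uspt.synthdata`)

The control preset encodes the reference study conditions: 60 trajectories
× 600 frames at 20 fps, 30 nm localization noise, three states (diffusive,
anterograde, retrograde) with cohort-mean speeds 0.24/0.54/0.56 µm/s and
across-trajectory SDs 0.14/0.27/0.28 µm/s. Per-trajectory speeds are drawn
from truncated normals re-centred so the post-truncation mean equals the
target, by Latin-hypercube (stratified inverse-CDF) sampling: marginals are
unchanged but the realized cohort mean is pinned to the target instead of
wandering by SD/√n ≈ 0.035 µm/s, which would otherwise dominate any
recovery comparison. The diffusive state's speed fixes its D via
√(πD/Δt); directed speeds are drift magnitudes at a within-state
D = 0.002 µm²/s.

The transition matrix is strongly diagonal (dwells ≈ 1–1.7 s) with the
diffusion→retrograde entry the smallest off-diagonal by a decisive margin —
only this rank order, not the numbers, is constrained by the phenomenon
being emulated — and with anterograde and retrograde balanced in stationary
occupancy (0.41/0.30/0.29, so that per-trajectory speed heterogeneity leaks
into the shared diffusive state symmetrically and cancels); the asymmetry
A→R > R→A encodes anterograde transport as the gateway to retrograde runs. Axons are straight lines at random
orientations; drug presets rescale speeds (inhibitor: directed to 0.5× the
diffusive speed; stimulant: ×1.4 everywhere) and weaken persistence while
increasing anterograde↔retrograde exchange. Every generator is a pure
function of (preset, seed) via spawned seed sequences; cohorts are
bit-reproducible and ship a ground-truth table sufficient to score recovery
without re-simulation.

What the synthetic cohorts do *not* contain: curved axons with varying
local tangents (a curved-axon generator would label by local tangent, but
the default is straight), within-run speed fluctuation, blinking or
localization-precision heterogeneity, trajectory-linking errors, or gaps.
Passing recovery tests here shows the inference machinery is calibrated
under the stated noise model, not that real recordings meet that model.

## 5. Problem sizes and runtime

Validation sizes were chosen so the full suite and the acceptance script
each run in a few minutes on one CPU: the acceptance cohort is 60×600
frames (the scale of a tracking session), condition cohorts 30×600,
parameter-recovery suites 50 replicates × 2000 steps, imaging calibrations
40–100 synthetic particles. The heavy kernels (forward–backward, Viterbi)
are numba-compiled; a full cohort analysis takes ~1 minute.
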