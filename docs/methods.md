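# Methods

## Model

`v1field` simulates stimulus-driven activity in layer 2/3 of primary visual
cortex as a planar neural field with a discrete representation of
orientation. Four sub-populations u_i(x, y, t), i ∈ {0°, 45°, 90°, 135°},
evolve on a periodic square [-L, L)² (defaults L = 30, N = 128 grid points
per side, hypercolumn separation Λ = 2π) according to

    τ ∂u_i/∂t = − Σ_j ρ_ij u_j
                + Σ_j k_ij I_j (1 + β_inp J_j)
                + S(u_i) ⋆ [g_ex w_Eloc + g_in w_I]
                + [S(u_i)(1 + β_rec J_i)] ⋆ g_ex w_Elat

with τ = 10 ms, within/between-population decay ρ_same = 1 / ρ_cross = 0.1,
input gains k1 = 2.8 (stimulated orientation) and k2 = 1.4 (others), and the
zero-at-rest sigmoid S(u) = 1/(1+e^(−μu+θ)) − 1/(1+e^θ) with μ = 2.3,
θ = 5.6. μk1 > θ > μk2, so only the stimulated sub-population is driven
above threshold; the all-zero resting state is always a solution and is the
only stable one without input. Convolutions are periodic and computed
spectrally (real FFTs on the stacked population array); the map modulation
of the long-range term multiplies the convolved field at the presynaptic
site, so the operation remains a single convolution.

The stimulus is a localized circular oriented input: radial profile 1 inside
the 0.7Λ plateau, Gaussian-ring falloff of width 0.3Λ outside, ramped
linearly over t ∈ [20, 120] ms. The feedforward footprint (FFF) radius used
by all area metrics is the half-maximum radius of this profile,
r_FF = (0.7 + 0.3·√(2 ln 2))Λ ≈ 1.05Λ. The plateau edge (0.7Λ) is not a
sensible footprint boundary here: the supra-threshold skirt of the input
extends ≈ 40% beyond it, so selectivity confined to the cortical footprint
would still cover ≈ 1.6 plateau areas; the half-height contour is also the
standard way the extent of a cortical point-spread function is reported.

## Connectivity

The lateral profile is radially symmetric: a local excitatory Gaussian bump
w_Eloc = h(r, 0, RW_ex·Λ), long-range excitatory rings
w_Elat = χ(Λ)h(r, Λ, RW_ex·Λ) + χ(2Λ)h(r, 2Λ, RW_ex·Λ) with exponential
amplitude envelope χ(r) = e^(−r/ζΛ) (ζ = 0.625), and broad Gaussian
inhibition w_I = g(r, RW_in·Λ) (RW_in = 0.55, unit plane integral). Widths
are fractions of Λ. B_E normalizes the combined excitatory profile to unit
plane integral (closed-form ring zero-modes via erf). The complete profile
is w = P[B_E(w_Eloc + w_Elat) + (C−1)w_I]; C = 0 balances excitatory and
inhibitory masses, the default C = −0.4 gives net inhibition. Gains
g_ex = B_E·P and g_in = P(C−1) (signed; negative means inhibition).

The overall scaling P is fixed by a spectral calibration: the radial
Fourier transform of w/P (numeric Hankel transform for the rings, closed
form for the Gaussians) is maximized over wavenumbers — the peak sits at
the ring-spacing mode k ≈ 2π/Λ — and P is chosen so this maximum equals a
reference value p_ref. This keeps the recurrent gain at the
pattern-forming mode constant while RW_ex, C, ... vary, so input and
threshold parameters never need re-tuning. The default p_ref = 8 was
calibrated once, before the quantitative analyses, against the qualitative
operating contract: at (RW_ex = 0.25, β_rec = 0, C = −0.4) the response is
an above-threshold multi-bump pattern confined near the FFF; at β_rec = 0.9
the (stable) selective activation extends well outside the FFF; at
C = −0.2 with β_rec = 0.9 the activation destabilizes. The calibration
window satisfying all three spans roughly p_ref ∈ [6, 10].

Note the profile is pointwise non-positive at short range for every P
(w(0) < 0 with the default widths): bumps are input-driven and shaped by
the rings, not locally self-amplifying.

## Orientation preference map

Maps are grown by a Hebbian-like rule on the model's own converged
responses: each step presents a random orientation at a random location
(β_rec = 0), integrates to a converged localized state, and reinforces the
stimulated component where the model responded,

    J_i ← clip(J_i + H_a · I_i · (1 − ⟨|J| ⋆ G⟩_[0,1]) · u_i_fin, −1, 1),

with learning rate H_a = 0.05 and smoothing kernel G of width 0.6Λ. The
saturation term uses the smoothed *total* component magnitude Σ_i |J_i|
(local map structure of any orientation), which makes domains of different
orientations mutually exclusive; saturating each component independently
produces mutually independent, overlapping component maps with no
orientation tiling. Convergence is monitored as a pinwheel count per
checkpoint (stable from ≈ 800 steps at the default learning rate on the
64² grid).

Post-processing follows the standard treatment of orientation maps as a
complex field: the doubled-angle composite z = Σ_i J_i e^(2iθ_i) is
band-pass filtered with a raised-cosine annulus centered on 2π/Λ
(fractional half-width 0.5; removes the footprint-scale common mode and
pixel noise), and components are re-derived as the projections
J_i = ½Re(z e^(−2iθ_i)), which enforces exact orthogonal-component
consistency (J_90 = −J_0). Amplitudes are then rescaled so the 80th
percentile of |J| saturates at the rectification bound — the amplitude
convention of a fully converged map, whose learning stalls only once local
structure saturates everywhere. Maps learned on a 64² grid are Fourier
up-sampled to the 128² simulation grid (the map is band-limited, so this is
exact).

`synthetic_map` is a fast spectral stand-in: band-limited complex Gaussian
noise with the same annular spectrum, projected to components with the same
amplitude convention. It shares the learned maps' summary statistics
(annular spectral peak, equal orientation representation, pinwheel density)
but none of their provenance; tests that need map realism use the learned
generator.

What the generators do *not* emulate: anisotropies and boundary effects of
real imaged maps, species-specific pinwheel statistics, and any coupling
between map development and the specific connectivity parameters being
swept. Passing tests therefore show internal consistency of the model
pipeline, not fidelity to any particular animal's map.

## VSD-like signal and metrics

The optical signal passes presynaptic rates through the connection
profiles, sums populations, and blurs with a Gaussian of width
σ_OI = 0.075Λ:

    OI = [Σ_i S(u_i) ⋆ (B_E w_Eloc − p_I w_I + (1−e^(−t/τ_lat)) B_E w_Elat (1+β_rec J_i))] ⋆ g(σ_OI)

with p_I = 0.177 (15%/85% inhibition/excitation contribution split; the
excitatory components carry the B_E normalization so the split holds) and
τ_lat = 240 ms, a post-processing timescale for the build-up of the
lateral contribution. From four oriented runs: Act = mean of the four OI
maps (each normalized by its spatial maximum), D1 = OI_0 − OI_90,
D2 = OI_45 − OI_135, Pref = ½·atan2(D2, D1) in [0°, 180°),
Sel = √(D1² + D2²).

Thresholds are fractions of the final-time FFF means (η_Act = 0.2,
η_Sel = 0.5); areas are supra-threshold pixel counts × cell area;
fraction-correct is the share of the selective region whose preference is
within ±30° of the map. Radial profiles are annular means (bins one grid
cell wide, fit range r ≤ 3Λ) about the stimulus center, summarized by
decreasing Naka-Rushton fits NR(r) = R_max(1 − rⁿ/(rⁿ + r50ⁿ))
(least squares, bounds R_max, r50 > 0, 0 < n ≤ 50, initialized at the
profile maximum, the half-max radius and n = 4).

## Tuning of effective lateral connections

Orientation is axial; all circular statistics double the angle. Tuning
curves are 8-bin weighted pixel-count histograms of the composite
preference over [−90°, 90°), max-normalized; tuning strength κ is a
least-squares von Mises fit with a free amplitude (so the normalization
convention does not bias κ), κ ∈ [0, 50]. The effective-connection
weighting at a location is the total excitatory radial profile with the
long-range part multiplied by (1 + β_rec J_{i*}), i* the component of the
local preference. Locations with local Gaussian-weighted tuning κ < 1
(width 0.25Λ) are excluded as pinwheel neighbourhoods. The anatomical band
for mean κ is [0.7, 1.2].

## Numerical choices

- Integrator: fixed-step classical RK4 (default dt = 1 ms; the shipped
  analyses pass dt = 2 ms after verifying three-decimal agreement of all
  battery metrics with dt = 1) with an adaptive scipy RK45 option
  (rtol 1e−6, atol 1e−8). The fixed-step path is the default because the
  map-learning loop and parameter sweeps need thousands of short
  integrations and the dynamics' stiffness is set by τ and the calibrated
  recurrent gain, not by the error estimator.
- Unbounded activation is flagged, never raised: either |u| exceeding a
  hard cap (100), or supra-threshold activity appearing beyond 2.2Λ from
  the stimulus center (legitimate responses stay within ≈ r_FF + Λ; the
  sigmoid bounds amplitudes, so the instability manifests as spread).
  Flagged runs are excluded from quantification.
- Kernels are sampled at minimum-image distances on the periodic grid;
  discrete zero modes are checked against the analytic plane integrals
  (warn at 1%, fail at 5% drift).
- Degenerate inputs: zero-selectivity pixels have undefined preference
  (NaN) and are excluded from histograms; all-zero weight fields, empty
  pass bands, and sub-threshold fit inputs raise errors.
- Problem sizes: the test suite learns maps at 800 steps on 64² and runs
  batteries at 64² (dt = 2 ms); the acceptance script learns at 1600 steps
  on 64² and runs batteries on the full 128² grid. These schedules were
  chosen so a map's pinwheel count is stable across checkpoints while a
  full analysis completes on a laptop-class single core in minutes.

## Known limitations

- The reference value matched by the scaling constant P in the original
  formulation is not recoverable; the spectral-peak calibration with the
  frozen default p_ref = 8 is this package's own reproducible contract.
- Per-location Naka-Rushton selectivity exponents concentrate around 4–7.
  The decay width is dominated by the stimulus edge passed through the
  sigmoid; steeper per-location values (n ≈ 10–15) would require abrupt
  collective termination of the outermost bump ring, a mechanism that is
  weak here because the connectivity is pointwise non-positive at short
  range (no local bistability) for every admissible P. Correspondingly,
  inside the anatomical κ band the normalized selective area sits slightly
  above 1.05 and the exponent ratio slightly below 1.3, so the strict
  four-mask operating region on the (RW_ex, β_rec) grid is empty at the
  default thresholds even though every individual regime boundary
  (confinement at defaults, spread at reduced inhibition, spurious
  selectivity at small RW_ex, κ monotonicity, exponent-spread contraction)
  reproduces.
- Maps are generated, not imported; file-format pass-through of measured
  maps is untested against real data.
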