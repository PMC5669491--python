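# v1field

Neural field model of orientation-selective lateral spread in primary
visual cortex (V1, layer 2/3).

Voltage-sensitive dye imaging shows that a small oriented stimulus evokes
orientation-*selective* activation only within its retinotopic footprint,
while the activation that spreads far beyond the footprint — carried by
long-range horizontal connections — stays unselective, even though those
connections are anatomically biased toward iso-orientation targets. This
package implements a planar neural field model built to reconcile these
observations: it simulates the stimulus-driven dynamics, converts the
activity to a VSD-like optical signal, and quantifies how selectivity
decays with cortical distance as a function of the connectivity's
clustering, orientation bias, and excitation/inhibition balance.

## Model

Four sub-populations u_i(x, y, t), one per encoded orientation
i ∈ {0°, 45°, 90°, 135°}, evolve on a periodic cortical sheet:

    τ ∂u_i/∂t = − Σ_j ρ_ij u_j                               (decay)
                + Σ_j k_ij I_j (1 + β_inp J_j)               (oriented input)
                + S(u_i) ⋆ (g_ex w_Eloc + g_in w_I)          (local recurrence)
                + [S(u_i)(1 + β_rec J_i)] ⋆ g_ex w_Elat      (long-range rings)

The lateral connectivity has a local excitatory bump (width RW_ex·Λ),
excitatory rings clustered at the hypercolumn separations Λ and 2Λ, and
broad inhibition; a constant C sets the excitation/inhibition balance
(C = 0 balanced, default −0.4). J_i are the components of a synthetic
orientation preference map, grown by a Hebbian rule on the model's own
responses; they modulate the inputs (β_inp = 0.25) and, with strength
β_rec ∈ [0, 1], the long-range connections. The analysis pipeline mirrors
the imaging workflow: OI signal → general activation Act / preference
Pref / selectivity Sel → threshold areas, von Mises tuning strength κ of
effective connections (anatomical band κ ∈ [0.7, 1.2]), and decreasing
Naka-Rushton fits NR(r) = R_max(1 − rⁿ/(rⁿ + r50ⁿ)) of the radial decay.

## Worked example

Run the four-orientation battery at one non-pinwheel map location with the
default parameters (RW_ex = 0.25, β_rec = 0, C = −0.4):

```python
import v1field as vf
from v1field.orientation_map import synthetic_map, sample_locations
from v1field.experiments import run_battery

dom = vf.Domain(L=30.0, N=64)
omap = synthetic_map(dom, seed=7)
loc = sample_locations(omap, 1, seed=11)[0]
metrics = run_battery(loc, omap, vf.ConnectivityParams(), vf.ModelParams(),
                      dom, t_final=550.0, dt=2.0)
print(f"normalized selective area  : {metrics.a_sel_normalized:.2f}")
print(f"fraction correct (±30°)    : {metrics.fraction_correct:.2f}")
print(f"Naka-Rushton n_Act         : {metrics.n_act:.2f}")
print(f"Naka-Rushton n_Sel         : {metrics.n_sel:.2f}")
print(f"steepness ratio n_Sel/n_Act: {metrics.exponent_ratio:.2f}")
```

prints

```
normalized selective area  : 1.02
fraction correct (±30°)    : 0.87
Naka-Rushton n_Act         : 3.86
Naka-Rushton n_Sel         : 6.23
steepness ratio n_Sel/n_Act: 1.62
```

The selective activation covers about one feedforward-footprint area
(confined), 87% of it carries the orientation of the underlying map, and
selectivity falls off with distance much more steeply (n_Sel = 6.2) than
the general activation (n_Act = 3.9) — the imaging phenomenology the model
was built to capture. Raising β_rec spreads selective activation outward
and lowers n_Sel; reducing inhibition (C → −0.2) with strong β_rec
destabilizes the response, which the integrator flags as unbounded
activation.

A thin CLI wraps the same machinery: `v1field make-map`, `simulate`,
`battery`, `kappa-grid`, `sweep` (see `--help`).

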