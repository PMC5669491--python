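"""Conversion of model output to a VSD-like optical signal and its metrics.

The optical imaging (OI) signal models what voltage-sensitive dye imaging
reads out from superficial cortex: presynaptic firing rates S(u_i) are
passed through the excitatory and inhibitory connection profiles (with an
85%/15% excitation/inhibition contribution split, i.e. an inhibition weight
p_I = 0.15/0.85 ≈ 0.177), summed across sub-populations, and blurred by a
Gaussian of width σ_OI representing optical diffusion.  The contribution of
the long-range rings builds up on a slower timescale τ_lat (post-processing
only; the dynamics itself has no delays).

From four oriented OI maps the pipeline derives the general activation Act,
difference maps D1/D2, preference Pref and selectivity Sel, threshold areas,
angularly averaged radial profiles, and decreasing Naka-Rushton fits whose
exponent n quantifies how sharply activation/selectivity decays with
distance from the stimulus center.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.fft as sfft
from scipy.optimize import least_squares

from .connectivity import GriddedKernels, gaussian2d
from .domain import Domain
from .orientation_map import OrientationMap
from .simulator import ORIENTATIONS, SimulationResult, sigmoid

__all__ = [
    "P_I",
    "TAU_LAT",
    "SIGMA_OI_FRAC",
    "compute_oi",
    "SelectivityMaps",
    "act_pref_sel",
    "AreaMetrics",
    "activation_areas",
    "RadialProfile",
    "radial_profile",
    "NakaRushtonFit",
    "naka_rushton",
    "fit_naka_rushton",
]

#: Inhibition weighting in the optical signal, from the assumed 15%/85%
#: inhibition/excitation contribution split (0.15/0.85 = 0.1765, printed and
#: used as 0.177).
P_I = 0.177

#: Slow build-up timescale (ms) of the long-range component of the signal.
TAU_LAT = 240.0

#: Optical diffusion width as a fraction of Λ.
SIGMA_OI_FRAC = 0.075


def compute_oi(
    result: SimulationResult,
    kernels: GriddedKernels,
    omap: OrientationMap | None,
    t: float | None = None,
    p_i: float = P_I,
    tau_lat: float | None = TAU_LAT,
    sigma_oi_frac: float = SIGMA_OI_FRAC,
) -> np.ndarray:
    """VSD-like optical signal for one simulation snapshot.

    OI = [Σ_i S(u_i) ⋆ (B_E·w_Eloc - p_I·w_I) + (S(u_i)(1+β_rec·J_i)) ⋆ ramp·B_E·w_Elat]
         ⋆ g(σ_OI),
    with ramp = 1 - e^(-t/τ_lat) (or 1 when ``tau_lat`` is None, the
    stationary form).  The excitatory components carry the B_E
    normalization (unit total excitatory mass) and w_I is the unit-mass
    inhibitory Gaussian, so that the p_I = 0.177 weighting yields the
    assumed 85%/15% excitation/inhibition contribution split; the recurrent
    gains g_ex/g_in play no role in the optical mixing.
    """
    if t is None:
        t = float(result.times[-1])
    ti = int(np.argmin(np.abs(result.times - t)))
    if abs(result.times[ti] - t) > 1e-6:
        raise ValueError(f"no snapshot at t={t}; available: {result.times}")
    u = result.u[ti]
    dom = result.domain
    if omap is not None and omap.domain.N != dom.N:
        raise ValueError("map/simulation provenance mismatch: different grids")
    p = result.params
    s = sigmoid(u, p.mu, p.theta)
    ramp = 1.0 if tau_lat is None else 1.0 - np.exp(-result.times[ti] / tau_lat)

    b_e = kernels.profile.B_E
    spec_fix = b_e * kernels.spec_eloc - p_i * kernels.spec_i
    f = sfft.rfft2(s, axes=(-2, -1))
    total = sfft.irfft2(f * spec_fix, s=u.shape[-2:], axes=(-2, -1)).sum(axis=0)
    if omap is not None and p.beta_rec > 0.0:
        mod = s * (1.0 + p.beta_rec * omap.J)
        f_lat = sfft.rfft2(mod, axes=(-2, -1))
    else:
        f_lat = f
    total += (ramp * b_e) * sfft.irfft2(
        f_lat * kernels.spec_elat, s=u.shape[-2:], axes=(-2, -1)
    ).sum(axis=0)

    lam = kernels.profile.params.Lambda
    g = gaussian2d(dom.radius_origin, sigma_oi_frac * lam)
    spec_g = sfft.rfft2(g) * dom.cell_area
    return sfft.irfft2(sfft.rfft2(total) * spec_g, s=u.shape[-2:])


@dataclass
class SelectivityMaps:
    """General activation, difference maps, preference and selectivity."""

    act: np.ndarray
    d1: np.ndarray
    d2: np.ndarray
    pref: np.ndarray  # degrees in [0, 180)
    sel: np.ndarray


def act_pref_sel(oi: dict[int, np.ndarray], normalize: bool = True) -> SelectivityMaps:
    """Derive Act/Pref/Sel from the four oriented OI maps.

    Each OI map is first normalized by its spatial maximum (removing
    inter-simulation gain differences); then Act is their mean,
    D1 = OI_0 - OI_90, D2 = OI_45 - OI_135, Pref = ½·atan2(D2, D1) mapped to
    [0°, 180°) and Sel = √(D1² + D2²).  ``normalize=False`` skips the
    per-map scaling (differences of raw signals).
    """
    if sorted(oi) != list(ORIENTATIONS):
        raise ValueError(f"need OI maps for orientations {ORIENTATIONS}")
    normed = {}
    for k, v in oi.items():
        m = float(np.max(v))
        if normalize and m <= 0.0:
            raise ValueError(f"OI map for orientation {k} has non-positive spatial max")
        normed[k] = v / m if normalize else np.asarray(v, dtype=float)
    act = sum(normed.values()) / 4.0
    d1 = normed[0] - normed[90]
    d2 = normed[45] - normed[135]
    pref = np.degrees(0.5 * np.arctan2(d2, d1)) % 180.0
    sel = np.hypot(d1, d2)
    return SelectivityMaps(act=act, d1=d1, d2=d2, pref=pref, sel=sel)


def display_scale(field: np.ndarray, final_field: np.ndarray) -> np.ndarray:
    """Scale a time snapshot relative to 1.1× the final-time field maximum.

    Display convention for Act/Sel time courses: panels show the evolution
    relative to the final state with a 10% headroom.  Quantitative metrics
    (thresholds, areas, radial fits) always use the unscaled fields.
    """
    return np.asarray(field, dtype=float) / (1.1 * float(np.max(final_field)))


@dataclass
class AreaMetrics:
    """Threshold areas of the general and orientation-selective activation."""

    t_act: float
    t_sel: float
    a_act: float
    a_sel: float
    r_ff: float
    a_ff: float
    a_sel_normalized: float  # A_sel / (π r_FF²)
    a_sel_outside_ff: float
    fraction_correct: float


def activation_areas(
    maps: SelectivityMaps,
    domain: Domain,
    center: tuple[float, float],
    r_ff: float,
    omap: OrientationMap | None = None,
    eta_act: float = 0.2,
    eta_sel: float = 0.5,
    match_tolerance_deg: float = 30.0,
) -> AreaMetrics:
    """Threshold areas and orientation agreement of the final-time maps.

    Thresholds are fractions (η_Act = 0.2, η_Sel = 0.5) of the mean Act/Sel
    inside the feedforward footprint; areas are supra-threshold pixel counts
    times cell area.  ``fraction_correct`` is the share of the selective
    region whose preference is within ±30° of the map's composite
    preference.
    """
    r = domain.radius_from(center)
    inside = r < r_ff
    act_ff = float(maps.act[inside].mean())
    sel_ff = float(maps.sel[inside].mean())
    if act_ff <= 0.0 or sel_ff <= 0.0:
        raise ValueError("degenerate threshold: zero mean activation/selectivity in the FFF")
    t_act = eta_act * act_ff
    t_sel = eta_sel * sel_ff
    area = domain.cell_area
    sup_act = maps.act > t_act
    sup_sel = maps.sel > t_sel
    a_act = float(sup_act.sum() * area)
    a_sel = float(sup_sel.sum() * area)
    a_ff = float(np.pi * r_ff**2)
    a_out = float((sup_sel & ~inside).sum() * area)

    if omap is not None and sup_sel.any():
        map_pref = omap.preference()
        d = np.abs((maps.pref - map_pref + 90.0) % 180.0 - 90.0)
        ok = d[sup_sel] <= match_tolerance_deg
        frac = float(np.mean(ok[~np.isnan(d[sup_sel])])) if np.any(~np.isnan(d[sup_sel])) else 0.0
    else:
        frac = float("nan")
    return AreaMetrics(
        t_act=t_act,
        t_sel=t_sel,
        a_act=a_act,
        a_sel=a_sel,
        r_ff=r_ff,
        a_ff=a_ff,
        a_sel_normalized=a_sel / a_ff,
        a_sel_outside_ff=a_out,
        fraction_correct=frac,
    )


@dataclass
class RadialProfile:
    """Annular-bin means of a field about a center point."""

    r: np.ndarray  # bin centers
    values: np.ndarray


def radial_profile(
    field_2d: np.ndarray,
    domain: Domain,
    center: tuple[float, float],
    r_max: float | None = None,
) -> RadialProfile:
    """Angular average of a field in annular bins one grid cell wide."""
    r = domain.radius_from(center)
    h = domain.h
    bins = np.floor(r / h).astype(int)
    n_bins = bins.max() + 1
    sums = np.bincount(bins.ravel(), weights=np.asarray(field_2d, float).ravel(), minlength=n_bins)
    counts = np.bincount(bins.ravel(), minlength=n_bins)
    vals = sums / np.maximum(counts, 1)
    centers = h * (np.arange(n_bins) + 0.5)
    if r_max is not None:
        keep = centers <= r_max
        centers, vals = centers[keep], vals[keep]
    return RadialProfile(r=centers, values=vals)


@dataclass
class NakaRushtonFit:
    r_max: float
    r50: float
    n: float
    residual: float
    converged: bool = True

    def __call__(self, r):
        return naka_rushton(r, self.r_max, self.r50, self.n)


def naka_rushton(r, r_max, r50, n):
    """Decreasing Naka-Rushton function NR(r) = R_max·(1 - rⁿ/(rⁿ + r50ⁿ)).

    NR(0) = R_max, NR(r50) = R_max/2, monotonically decaying to zero; the
    exponent n > 0 sets the steepness of the transition.
    """
    r = np.asarray(r, dtype=float)
    with np.errstate(over="ignore"):
        rn = np.power(r, n)
        return r_max * (1.0 - rn / (rn + r50**n))


def fit_naka_rushton(profile: RadialProfile, n_max: float = 50.0) -> NakaRushtonFit:
    """Least-squares Naka-Rushton fit to a radial decay profile.

    Initialization: R_max at the profile maximum, r50 at the half-max
    radius, n = 4; positivity bounds with n ∈ (0, n_max].
    """
    r, y = profile.r, profile.values
    if np.count_nonzero(y) < 5:
        raise ValueError("need at least 5 nonzero profile bins for a fit")
    y_max = float(y.max())
    below = np.where(y < 0.5 * y_max)[0]
    r50_0 = float(r[below[0]]) if below.size else float(r[-1] / 2.0)

    def resid(p):
        return naka_rushton(r, *p) - y

    sol = least_squares(
        resid,
        x0=[y_max, max(r50_0, 1e-3), 4.0],
        bounds=([1e-12, 1e-6, 1e-3], [np.inf, np.inf, n_max]),
    )
    r_max, r50, n = sol.x
    return NakaRushtonFit(
        r_max=float(r_max),
        r50=float(r50),
        n=float(n),
        residual=float(np.sqrt(2.0 * sol.cost)),
        converged=bool(sol.success),
    )
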