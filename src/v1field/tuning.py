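"""Orientation tuning of map regions and of effective lateral connections.

Orientation is an axial quantity (period 180°); all circular statistics are
done on the doubled-angle circle and halved on output.  Tuning curves are
eight-bin weighted pixel-count histograms over [-90°, 90°), normalized to a
maximum of 1, and tuning strength is the concentration κ of a least-squares
von Mises fit (with a free amplitude so the normalization convention does
not bias κ).  The anatomical band κ ∈ [0.7, 1.2] comes from population-level
tracing of lateral connections in V1 L2/3.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.special import i0

from .connectivity import ConnectivityParams, ConnectivityProfile, build_profile
from .orientation_map import OrientationMap, ANGLES_DEG

__all__ = [
    "TuningCurve",
    "VonMisesFit",
    "von_mises",
    "weighted_orientation_histogram",
    "fit_von_mises",
    "local_kappa",
    "effective_tuning_kappa",
    "kappa_grid",
    "KappaGrid",
    "ANATOMICAL_KAPPA_BAND",
]

#: κ range reported by population-level tracing of lateral connections.
ANATOMICAL_KAPPA_BAND = (0.7, 1.2)

KAPPA_MAX = 50.0
N_BINS = 8


def von_mises(x, mu, kappa):
    """Von Mises density e^(κ cos(x-μ)) / (2π I0(κ)) on the circle (radians).

    κ = 0 is the uniform density 1/(2π); larger κ concentrates the density
    around μ.  Integrates to 1 over any 2π interval.
    """
    if kappa < 0:
        raise ValueError("kappa must be nonnegative")
    x = np.asarray(x, dtype=float)
    return np.exp(kappa * np.cos(x - mu)) / (2.0 * np.pi * i0(kappa))


@dataclass
class TuningCurve:
    """Max-normalized weighted pixel counts in 8 orientation bins [-90°, 90°)."""

    bin_centers: np.ndarray  # degrees
    counts: np.ndarray  # normalized, max 1
    total_weight: float = 0.0


@dataclass
class VonMisesFit:
    kappa: float
    mu_pref: float  # degrees in [0, 180)
    amplitude: float
    residual: float
    converged: bool = True


def _bin_edges() -> np.ndarray:
    return np.linspace(-90.0, 90.0, N_BINS + 1)


def weighted_orientation_histogram(
    omap: OrientationMap, weights: np.ndarray
) -> TuningCurve:
    """Weighted histogram of the composite preference in 8 orientation bins.

    ``weights`` is a nonnegative field on the map's grid; pixels with
    undefined preference (zero selectivity) are ignored.  Counts are
    normalized so the maximum bin is 1.
    """
    weights = np.asarray(weights, dtype=float)
    if weights.shape != omap.J.shape[1:]:
        raise ValueError("weight field must match the map grid")
    if np.any(weights < 0):
        raise ValueError("weights must be nonnegative")
    total = float(weights.sum())
    if total == 0.0:
        raise ValueError("empty histogram: all-zero weight field")
    pref = omap.preference()
    valid = ~np.isnan(pref)
    # Map [0, 180) to [-90, 90).
    p = pref[valid]
    p = np.where(p >= 90.0, p - 180.0, p)
    w = weights[valid]
    counts, _ = np.histogram(p, bins=_bin_edges(), weights=w)
    m = counts.max()
    if m == 0.0:
        raise ValueError("empty histogram: no weighted pixels with defined preference")
    centers = 0.5 * (_bin_edges()[:-1] + _bin_edges()[1:])
    return TuningCurve(bin_centers=centers, counts=counts / m, total_weight=float(w.sum()))


def fit_von_mises(curve: TuningCurve) -> VonMisesFit:
    """Least-squares von Mises fit (free amplitude) to a tuning curve.

    Orientations are doubled onto the full circle before fitting; the fitted
    location is halved back to [0°, 180°).  κ is bounded to [0, 50] to keep
    the optimizer stable on near-delta curves.
    """
    if np.count_nonzero(curve.counts) < 3:
        raise ValueError("need at least 3 nonzero bins for a meaningful fit")
    x2 = np.radians(2.0 * curve.bin_centers)
    y = curve.counts

    def model(p):
        a, mu2, kappa = p
        return a * von_mises(x2, mu2, kappa)

    mu0 = x2[int(np.argmax(y))]
    best = None
    for kappa0 in (0.5, 2.0, 8.0):
        a0 = y.max() * 2.0 * np.pi * i0(kappa0) / np.exp(kappa0)
        try:
            sol = least_squares(
                lambda p: model(p) - y,
                x0=[a0, mu0, kappa0],
                bounds=([0.0, -2.0 * np.pi, 0.0], [np.inf, 2.0 * np.pi, KAPPA_MAX]),
            )
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        return VonMisesFit(kappa=np.nan, mu_pref=np.nan, amplitude=np.nan,
                           residual=np.inf, converged=False)
    a, mu2, kappa = best.x
    mu_pref = (np.degrees(mu2) / 2.0) % 180.0
    return VonMisesFit(
        kappa=float(kappa),
        mu_pref=float(mu_pref),
        amplitude=float(a),
        residual=float(np.sqrt(2.0 * best.cost)),
        converged=bool(best.success),
    )


def local_kappa(
    omap: OrientationMap, index: tuple[int, int], sigma_loc_frac: float = 0.25
) -> float:
    """Local tuning strength at a grid location (Gaussian spatial weighting).

    Used both to exhibit the strong local tuning of linear zones and to
    exclude pinwheel neighbourhoods (κ < 1) when sampling analysis
    locations.
    """
    from .connectivity import gaussian2d

    center = omap.domain.node_xy(index)
    r = omap.domain.radius_from(center)
    weights = gaussian2d(r, sigma_loc_frac * omap.Lambda)
    curve = weighted_orientation_histogram(omap, weights)
    return fit_von_mises(curve).kappa


def _component_index(omap: OrientationMap, index: tuple[int, int]) -> int:
    """Index of the encoded orientation nearest the local composite preference."""
    pref = omap.preference()[index]
    if np.isnan(pref):
        raise ValueError("location has undefined preference (pinwheel center)")
    d = np.abs((ANGLES_DEG - pref + 90.0) % 180.0 - 90.0)
    return int(np.argmin(d))


def effective_tuning_kappa(
    omap: OrientationMap,
    index: tuple[int, int],
    profile: ConnectivityProfile,
    beta_rec: float,
) -> float:
    """Tuning strength κ of the effective lateral connections from a location.

    The weighting field is the total excitatory radial profile centered at
    the location, with the long-range rings multiplied by
    (1 + β_rec·J_{i*}) where i* is the component of the local preference;
    κ comes from the weighted orientation histogram and its von Mises fit.
    """
    center = omap.domain.node_xy(index)
    r = omap.domain.radius_from(center)
    i_star = _component_index(omap, index)
    weights = profile.w_eloc(r) + profile.w_elat(r) * (1.0 + beta_rec * omap.J[i_star])
    weights = np.clip(weights, 0.0, None)
    curve = weighted_orientation_histogram(omap, weights)
    return fit_von_mises(curve).kappa


@dataclass
class KappaGrid:
    """Mean effective-tuning κ over map locations on a (RW_ex, β_rec) grid."""

    rw_ex: np.ndarray
    beta_rec: np.ndarray
    mean_kappa: np.ndarray  # (len(rw_ex), len(beta_rec))
    band_mask: np.ndarray  # mean κ inside the anatomical band
    locations: list[tuple[int, int]] = field(default_factory=list)
    band: tuple[float, float] = ANATOMICAL_KAPPA_BAND

    def contours(self) -> dict[float, list[np.ndarray]]:
        """Iso-κ contour polylines for the two band boundaries.

        Polylines are in (rw_ex, beta_rec) coordinates.
        """
        from skimage.measure import find_contours

        out: dict[float, list[np.ndarray]] = {}
        for level in self.band:
            lines = find_contours(self.mean_kappa, level)
            conv = []
            for ln in lines:
                rw = np.interp(ln[:, 0], np.arange(len(self.rw_ex)), self.rw_ex)
                br = np.interp(ln[:, 1], np.arange(len(self.beta_rec)), self.beta_rec)
                conv.append(np.column_stack([rw, br]))
            out[level] = conv
        return out


def kappa_grid(
    omap: OrientationMap,
    rw_ex_values,
    beta_rec_values,
    n_locations: int = 50,
    seed: int = 0,
    conn_params: ConnectivityParams | None = None,
) -> KappaGrid:
    """Mean effective-connection tuning κ over a (RW_ex, β_rec) grid.

    κ is averaged over ``n_locations`` non-pinwheel map locations (local
    κ >= 1 criterion) shared across all grid cells; the band mask marks
    cells whose mean κ lies in the anatomical range [0.7, 1.2].
    """
    from .orientation_map import sample_locations

    rw_ex_values = np.asarray(rw_ex_values, dtype=float)
    beta_rec_values = np.asarray(beta_rec_values, dtype=float)
    base = conn_params if conn_params is not None else ConnectivityParams()
    locs = sample_locations(omap, n_locations, seed=seed)
    mean_k = np.empty((len(rw_ex_values), len(beta_rec_values)))
    from dataclasses import replace as _replace

    for i, rw in enumerate(rw_ex_values):
        profile = build_profile(_replace(base, rw_ex=float(rw)))
        for j, br in enumerate(beta_rec_values):
            ks = [effective_tuning_kappa(omap, loc, profile, float(br)) for loc in locs]
            mean_k[i, j] = float(np.mean(ks))
    lo, hi = ANATOMICAL_KAPPA_BAND
    return KappaGrid(
        rw_ex=rw_ex_values,
        beta_rec=beta_rec_values,
        mean_kappa=mean_k,
        band_mask=(mean_k >= lo) & (mean_k <= hi),
        locations=locs,
    )
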