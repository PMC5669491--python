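"""Synthetic orientation preference maps for the four-orientation model.

A map is four component fields J_i(x, y) in [-1, 1], one per encoded
orientation.  Maps are grown by a Hebbian-like rule operating on converged
model output: localized inputs of random orientation are presented at random
locations, and the stimulated component is reinforced where the model
responded, with a saturation term that protects regions that already carry
structure.  A converged map has linear zones and pinwheels, represents all
four orientations in equal proportion, and its spectral power concentrates
in an annulus at the hypercolumn wavenumber 2π/Λ.

A fast spectral generator (`synthetic_map`) produces maps with the same
summary statistics directly from band-limited noise, for use where the full
learning schedule is not needed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.fft as sfft

from .connectivity import ConnectivityProfile, GriddedKernels, gaussian2d, grid_kernels
from .domain import Domain

__all__ = [
    "OrientationMap",
    "MapLearningConfig",
    "learn_map",
    "band_filter",
    "composite",
    "spectral_power",
    "sample_locations",
    "pinwheel_count",
    "synthetic_map",
    "resample_map",
]

ANGLES_DEG = np.array([0.0, 45.0, 90.0, 135.0])


@dataclass
class OrientationMap:
    """Four component fields J_i on a periodic grid plus the length scale Λ."""

    domain: Domain
    J: np.ndarray  # (4, N, N), values in [-1, 1]
    Lambda: float = 2.0 * np.pi
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.J = np.asarray(self.J, dtype=float)
        if self.J.shape != (4, self.domain.N, self.domain.N):
            raise ValueError("J must have shape (4, N, N)")

    def complex_field(self) -> np.ndarray:
        """Doubled-angle vector sum Σ_i J_i e^(2iθ_i) = (J0-J90) + i(J45-J135)."""
        return (self.J[0] - self.J[2]) + 1j * (self.J[1] - self.J[3])

    def preference(self) -> np.ndarray:
        """Composite preferred orientation in degrees, [0, 180); NaN where untuned."""
        z = self.complex_field()
        pref = np.degrees(np.angle(z)) / 2.0 % 180.0
        pref[np.abs(z) == 0.0] = np.nan
        return pref

    def selectivity(self) -> np.ndarray:
        """Composite selectivity magnitude (resultant length), >= 0."""
        return np.abs(self.complex_field())


def composite(omap: OrientationMap) -> tuple[np.ndarray, np.ndarray]:
    """Composite (preference, selectivity) fields of a map."""
    return omap.preference(), omap.selectivity()


@dataclass(frozen=True)
class MapLearningConfig:
    """Schedule and smoothing parameters of the Hebbian map-learning rule.

    ``h_a`` is the learning rate; ``sigma_g`` the width of the saturation
    smoothing kernel G as a fraction of Λ; ``steps`` the number of stimulus
    presentations; ``check_every`` the cadence of the pinwheel-count
    convergence trace.  ``t_learn``/``dt`` control the per-presentation
    simulation (fixed-step RK4 run to a converged localized state).
    """

    h_a: float = 0.05
    sigma_g: float = 0.6
    steps: int = 6400
    check_every: int = 1600
    seed: int = 0
    t_learn: float = 200.0
    dt: float = 1.0
    filter_halfwidth: float = 0.5

    def __post_init__(self) -> None:
        if self.h_a <= 0:
            raise ValueError("learning rate h_a must be positive")
        if self.steps < 1:
            raise ValueError("steps must be >= 1")


def learn_map(
    config: MapLearningConfig,
    domain: Domain,
    kernels: GriddedKernels | ConnectivityProfile,
    model_params=None,
    apply_filter: bool = True,
) -> OrientationMap:
    """Grow an orientation map with the Hebbian-like learning rule.

    Starting from J_i = 0, each step presents a localized input of random
    orientation at a random grid location, integrates the model (with
    β_rec = 0) to a converged state, and updates the stimulated component:

        J_i <- clip( J_i + H_a · I_i · (1 - <|J| ⋆ G>_[0,1]) · u_i_fin, -1, 1 )

    The saturation term measures existing local *map* structure — the
    smoothed total component magnitude Σ_i |J_i| — so regions already
    committed to some orientation are modified less than structureless
    regions.  This makes iso-orientation domains of different orientations
    mutually exclusive, which is what gives the composite map its
    orientation tiling.  The converged map is band-pass filtered around the
    hypercolumn wavenumber.  Steps whose dynamics do not remain bounded are
    skipped with a warning.
    """
    from .simulator import ModelParams, ORIENTATIONS, StimulusSpec, _RHS, _integrate_rk4

    if isinstance(kernels, ConnectivityProfile):
        kernels = grid_kernels(kernels, domain)
    lam = kernels.profile.params.Lambda
    params = model_params if model_params is not None else ModelParams()
    params = replace(params, beta_rec=0.0)

    rng = np.random.default_rng(config.seed)
    J = np.zeros((4, domain.N, domain.N))
    spec_g = sfft.rfft2(gaussian2d(domain.radius_origin, config.sigma_g * lam)) * domain.cell_area

    trace: list[tuple[int, int]] = []
    skipped = 0
    t_eval = np.array([config.t_learn])
    for n in range(config.steps):
        j_idx = int(rng.integers(4))
        iy, ix = rng.integers(domain.N, size=2)
        center = domain.node_xy((int(iy), int(ix)))
        stim = StimulusSpec(
            orientation=ORIENTATIONS[j_idx],
            center=center,
            Lambda=lam,
            t_final=config.t_learn,
        )
        f = _RHS(params, domain, kernels, J, stim)
        from .simulator import SPREAD_RADIUS_FRAC

        far = domain.radius_from(center) > SPREAD_RADIUS_FRAC * lam
        _, u, unbounded = _integrate_rk4(
            f, np.zeros_like(J), t_eval, config.dt,
            spread_threshold=params.theta / params.mu,
            spread_mask=far,
        )
        if unbounded:
            skipped += 1
            warnings.warn(f"learning step {n}: unbounded dynamics, step skipped", stacklevel=2)
            continue
        u_fin = u[-1, j_idx]
        i_field = stim.radial_profile(domain.radius_from(center))
        structure = np.abs(J).sum(axis=0)
        smooth = np.clip(
            sfft.irfft2(sfft.rfft2(structure) * spec_g, s=(domain.N, domain.N)), 0.0, 1.0
        )
        J[j_idx] = np.clip(J[j_idx] + config.h_a * i_field * (1.0 - smooth) * u_fin, -1.0, 1.0)
        if (n + 1) % config.check_every == 0:
            omap_now = OrientationMap(domain=domain, J=J.copy(), Lambda=lam)
            trace.append((n + 1, pinwheel_count(omap_now)))

    if not np.any(J):
        raise RuntimeError("map learning failed: all components zero after full schedule")

    omap = OrientationMap(
        domain=domain,
        J=J,
        Lambda=lam,
        provenance={
            "seed": config.seed,
            "steps": config.steps,
            "h_a": config.h_a,
            "sigma_g": config.sigma_g,
            "t_learn": config.t_learn,
            "dt": config.dt,
            "skipped_steps": skipped,
            "pinwheel_trace": trace,
        },
    )
    if apply_filter:
        omap = band_filter(omap, halfwidth=config.filter_halfwidth)
    return omap


def band_filter(
    omap: OrientationMap,
    k0: float | None = None,
    halfwidth: float = 0.5,
    saturate_percentile: float | None = 80.0,
) -> OrientationMap:
    """Band-pass each component in an annulus around the hypercolumn wavenumber.

    The filtering operates on the doubled-angle composite field
    z = Σ_i J_i e^(2iθ_i): the pass band is a raised-cosine annulus centered
    on ``k0`` (default 2π/Λ, the map's regular length scale) with fractional
    half-width ``halfwidth``, which removes the DC offset — in a partially
    converged learned map dominated by a common mode at the
    stimulus-footprint scale — and pixel-scale noise while preserving the
    Λ-periodic structure.  Components are then re-derived as the projections
    J_i = ½·Re(z e^(-2iθ_i)), which makes orthogonal components exactly
    consistent (J_90 = -J_0); the independent learning of the four
    components leaves an inconsistent residual that carries no composite
    orientation signal and is discarded here.

    ``saturate_percentile`` sets the amplitude convention: components are
    rescaled so that the given percentile of |J| maps to 1 and re-rectified
    to [-1, 1].  This reproduces the saturated-domain statistics of a fully
    converged map, whose learning stalls only once local structure saturates
    across iso-orientation domains.  Pass None to skip.
    """
    if k0 is None:
        k0 = 2.0 * np.pi / omap.Lambda
    w = halfwidth * k0
    if w <= 0:
        raise ValueError("empty pass band: halfwidth * k0 must be positive")
    kk = omap.domain.k_radial
    n = omap.domain.N
    dist = np.abs(kk - k0)
    H = np.where(dist <= w, 0.5 * (1.0 + np.cos(np.pi * dist / w)), 0.0)
    if not np.any(H > 0):
        raise ValueError("empty pass band: no grid wavenumbers inside the annulus")
    z_f = sfft.ifft2(sfft.fft2(omap.complex_field()) * H)
    theta2 = np.radians(2.0 * ANGLES_DEG)
    J_f = np.stack([0.5 * np.real(z_f * np.exp(-1j * t)) for t in theta2])
    if saturate_percentile is not None:
        scale = np.percentile(np.abs(J_f), saturate_percentile)
        if scale > 0:
            J_f = J_f / scale
    J_f = np.clip(J_f, -1.0, 1.0)
    prov = dict(omap.provenance)
    prov["band_filter"] = {
        "k0": float(k0),
        "halfwidth": float(halfwidth),
        "saturate_percentile": saturate_percentile,
    }
    return OrientationMap(domain=omap.domain, J=J_f, Lambda=omap.Lambda, provenance=prov)


def spectral_power(
    z: np.ndarray, domain: Domain
) -> tuple[np.ndarray, np.ndarray, float, np.ndarray]:
    """Radially binned spectral power of a field on the periodic grid.

    Returns ``(k_centers, power, k_peak, power2d)`` where ``power`` is the
    mean power per annular wavenumber bin normalized by its peak value (the
    DC bin is excluded from the peak search).  A constant field yields a
    degenerate flat curve with a warning.
    """
    z = np.asarray(z)
    p2 = np.abs(sfft.fft2(z)) ** 2
    kk = domain.k_radial
    dk = np.pi / domain.L  # fundamental wavenumber
    bins = np.round(kk / dk).astype(int)
    n_bins = bins.max() + 1
    sums = np.bincount(bins.ravel(), weights=p2.ravel(), minlength=n_bins)
    counts = np.bincount(bins.ravel(), minlength=n_bins)
    power = sums / np.maximum(counts, 1)
    k_centers = dk * np.arange(n_bins)
    if np.all(power[1:] == 0.0):
        warnings.warn("degenerate spectrum: field is constant", stacklevel=2)
        return k_centers, np.zeros_like(power), 0.0, p2
    i_peak = 1 + int(np.argmax(power[1:]))
    power = power / power[i_peak]
    return k_centers, power, float(k_centers[i_peak]), p2


def pinwheel_count(omap: OrientationMap) -> int:
    """Count pinwheels as unit windings of the doubled-angle field.

    The winding number of arg(z), z the doubled-angle composite field, is
    accumulated around each grid plaquette (periodic); plaquettes with a
    +/-2π net winding contain a pinwheel.
    """
    phi = np.angle(omap.complex_field())

    def wrapped_diff(a, b):
        return np.angle(np.exp(1j * (b - a)))

    right = np.roll(phi, -1, axis=1)
    down = np.roll(phi, -1, axis=0)
    diag = np.roll(np.roll(phi, -1, axis=0), -1, axis=1)
    w = (
        wrapped_diff(phi, right)
        + wrapped_diff(right, diag)
        + wrapped_diff(diag, down)
        + wrapped_diff(down, phi)
    )
    return int(np.sum(np.abs(w) > np.pi))


def sample_locations(
    omap: OrientationMap,
    n: int,
    seed: int = 0,
    kappa_min: float = 1.0,
    sigma_loc_frac: float = 0.25,
    max_tries_factor: int = 40,
) -> list[tuple[int, int]]:
    """Sample ``n`` analysis locations away from pinwheels.

    Candidate pixels are drawn uniformly; a candidate is accepted when the
    local orientation tuning (Gaussian-weighted histogram of width
    ``sigma_loc_frac``·Λ, von Mises fit) has κ >= ``kappa_min``, which
    excludes pinwheel neighbourhoods.  Deterministic under a fixed seed.
    """
    from .tuning import local_kappa

    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    accepted: list[tuple[int, int]] = []
    tries = 0
    max_tries = max_tries_factor * n
    while len(accepted) < n and tries < max_tries:
        iy, ix = (int(v) for v in rng.integers(omap.domain.N, size=2))
        tries += 1
        kap = local_kappa(omap, (iy, ix), sigma_loc_frac=sigma_loc_frac)
        if kap >= kappa_min:
            accepted.append((iy, ix))
    if len(accepted) < n:
        if len(accepted) / tries < 0.05:
            raise RuntimeError(
                "map-quality error: fewer than 5% of candidate locations pass the "
                f"pinwheel-exclusion criterion (kappa >= {kappa_min})"
            )
        raise RuntimeError("could not find enough non-pinwheel locations")
    return accepted


def synthetic_map(
    domain: Domain,
    Lambda: float = 2.0 * np.pi,
    seed: int = 0,
    halfwidth: float = 0.5,
    saturate_percentile: float = 80.0,
) -> OrientationMap:
    """Fast synthetic map from band-limited complex Gaussian noise.

    A complex Gaussian random field with a raised-cosine annular spectrum at
    the hypercolumn wavenumber 2π/Λ yields a doubled-angle field z with
    realistic linear zones and pinwheels; the components are its projections
    J_i = Re(z e^(-2iθ_i)), rescaled to the same saturated-domain amplitude
    convention as the learned maps.  This generator shares the
    learned maps' summary statistics (single annular spectral peak, equal
    orientation representation, pinwheels) but not their provenance: it is a
    spectral stand-in, not the Hebbian learning procedure.
    """
    rng = np.random.default_rng(seed)
    n = domain.N
    noise = rng.normal(size=(n, n)) + 1j * rng.normal(size=(n, n))
    k0 = 2.0 * np.pi / Lambda
    w = halfwidth * k0
    kk = domain.k_radial
    dist = np.abs(kk - k0)
    H = np.where(dist <= w, 0.5 * (1.0 + np.cos(np.pi * dist / w)), 0.0)
    z = sfft.ifft2(sfft.fft2(noise) * H)
    theta2 = np.radians(2.0 * ANGLES_DEG)
    J = np.stack([np.real(z * np.exp(-1j * t)) for t in theta2])
    J = J / np.percentile(np.abs(J), saturate_percentile)
    return OrientationMap(
        domain=domain,
        J=np.clip(J, -1.0, 1.0),
        Lambda=Lambda,
        provenance={"generator": "synthetic_spectral", "seed": seed},
    )


def resample_map(omap: OrientationMap, new_domain: Domain) -> OrientationMap:
    """Resample a map onto a finer/coarser grid of the same physical domain.

    Fourier zero-padding/truncation; exact for the band-limited maps
    produced here.  The physical half-width L must match.
    """
    if abs(new_domain.L - omap.domain.L) > 1e-12:
        raise ValueError("resampling requires the same physical domain size L")
    n_old, n_new = omap.domain.N, new_domain.N
    if n_new == n_old:
        return omap
    J_new = np.empty((4, n_new, n_new))
    for i in range(4):
        F = sfft.fftshift(sfft.fft2(omap.J[i]))
        if n_new > n_old:
            pad = (n_new - n_old) // 2
            F2 = np.pad(F, pad)
        else:
            cut = (n_old - n_new) // 2
            F2 = F[cut : cut + n_new, cut : cut + n_new]
        J_new[i] = np.real(sfft.ifft2(sfft.ifftshift(F2))) * (n_new / n_old) ** 2
    prov = dict(omap.provenance)
    prov["resampled_from_N"] = n_old
    return OrientationMap(
        domain=new_domain, J=np.clip(J_new, -1.0, 1.0), Lambda=omap.Lambda, provenance=prov
    )
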