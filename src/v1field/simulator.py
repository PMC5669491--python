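"""Four-sub-population neural field dynamics on the periodic cortical sheet.

Each sub-population u_i(x, y, t) carries one of the four encoded orientations
{0, 45, 90, 135} degrees.  The membrane potential obeys

    τ ∂u_i/∂t = - Σ_j ρ_ij u_j                                (decay)
                + Σ_j k_ij I_j (1 + β_inp J_j)                (input)
                + S(u_i) ⋆ [g_ex w_Eloc + g_in w_I]           (local recurrence)
                + [S(u_i)(1 + β_rec J_i)] ⋆ g_ex w_Elat       (long-range)

with S a zero-at-rest sigmoid, ⋆ periodic spatial convolution computed
spectrally, and J_i the orientation-preference component maps.  The map
modulation of the long-range term multiplies the convolved field at the
presynaptic site so the operation stays a true convolution.  g_in is the
signed inhibitory gain (negative for net inhibition), so the local kernel
g_ex·w_Eloc + g_in·w_I is the standard excitation-minus-inhibition profile.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.fft as sfft

from .connectivity import ConnectivityProfile, GriddedKernels, grid_kernels, ring
from .domain import Domain

__all__ = [
    "ModelParams",
    "StimulusSpec",
    "SimulationResult",
    "sigmoid",
    "input_field",
    "rhs",
    "integrate",
    "ORIENTATIONS",
]

ORIENTATIONS = (0, 45, 90, 135)

#: Divergence cap: |u| beyond this value flags the run as unbounded
#: activation (a valid model outcome in the reduced-inhibition regime).
U_CAP = 100.0


@dataclass(frozen=True)
class ModelParams:
    """Dynamical parameters of the neural field equations.

    ``tau`` is the membrane timescale in ms; ``rho_same``/``rho_cross``
    weight the linear decay within/between sub-populations; ``k1``/``k2``
    are the input gains for the stimulated/non-stimulated sub-population
    (μ·k1 > θ supra-threshold, μ·k2 < θ sub-threshold); ``mu``/``theta``
    set the sigmoid; ``beta_inp``/``beta_rec`` are the map-modulation
    strengths of the inputs and of the long-range recurrent connections.
    """

    tau: float = 10.0
    rho_same: float = 1.0
    rho_cross: float = 0.1
    k1: float = 2.8
    k2: float = 1.4
    mu: float = 2.3
    theta: float = 5.6
    beta_inp: float = 0.25
    beta_rec: float = 0.0

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if not (self.mu > 0 and self.theta > 0):
            raise ValueError("mu and theta must be positive")
        if not self.mu * self.k1 > self.theta:
            raise ValueError("supra-threshold contract violated: mu*k1 must exceed theta")
        if not self.mu * self.k2 < self.theta:
            raise ValueError("sub-threshold contract violated: mu*k2 must be below theta")
        if not 0.0 <= self.beta_rec <= 1.0:
            raise ValueError("beta_rec must lie in [0, 1]")


def sigmoid(u, mu: float = 2.3, theta: float = 5.6):
    """Normalized firing-rate sigmoid S(u) = 1/(1+e^(-μu+θ)) - 1/(1+e^θ).

    S(0) = 0 by construction, so the all-zero resting state is always a
    solution of the field equations; S is bounded above by 1 - 1/(1+e^θ).
    """
    u = np.asarray(u, dtype=float)
    with np.errstate(over="ignore"):  # exp overflow at very negative u -> S = 0
        return 1.0 / (1.0 + np.exp(-mu * u + theta)) - 1.0 / (1.0 + np.exp(theta))


@dataclass(frozen=True)
class StimulusSpec:
    """Localized circular oriented stimulus.

    The radial input profile is 1 inside the feedforward footprint (plateau
    of radius 0.7Λ) and decays as a Gaussian ring of width 0.3Λ outside.
    The amplitude ramps linearly from 0 to 1 over ``ramp`` (ms).
    """

    orientation: int = 0
    center: tuple[float, float] = (0.0, 0.0)
    amplitude: float = 1.0
    Lambda: float = 2.0 * np.pi
    plateau_frac: float = 0.7
    edge_frac: float = 0.3
    ramp: tuple[float, float] = (20.0, 120.0)
    t_final: float = 600.0
    snapshot_dt: float = 25.0

    def __post_init__(self) -> None:
        if self.orientation not in ORIENTATIONS:
            raise ValueError(f"orientation must be one of {ORIENTATIONS}")
        if not self.ramp[0] < self.ramp[1] <= self.t_final:
            raise ValueError("require ramp start < ramp end <= t_final")

    @property
    def plateau_radius(self) -> float:
        """Radius of the full-amplitude input plateau (0.7Λ)."""
        return self.plateau_frac * self.Lambda

    @property
    def r_ff(self) -> float:
        """Feedforward-footprint radius: the half-maximum of the input.

        The cortical footprint of a localized stimulus is delimited where
        the point-spread-matched input falls to half its peak, i.e. at
        plateau + edge·√(2 ln 2) ≈ 1.05Λ with the default fractions.
        """
        return (self.plateau_frac + self.edge_frac * np.sqrt(2.0 * np.log(2.0))) * self.Lambda

    def radial_profile(self, r: np.ndarray) -> np.ndarray:
        """Input footprint: 1 on the plateau, Gaussian ring falloff outside."""
        rp = self.plateau_radius
        edge = ring(r, rp, self.edge_frac * self.Lambda)
        return np.where(r < rp, 1.0, edge)

    def ramp_factor(self, t: float) -> float:
        t0, t1 = self.ramp
        return float(np.clip((t - t0) / (t1 - t0), 0.0, 1.0))

    @property
    def snapshot_times(self) -> np.ndarray:
        times = np.arange(0.0, self.t_final, self.snapshot_dt)
        return np.append(times, self.t_final)


def input_field(
    stim: StimulusSpec,
    domain: Domain,
    params: ModelParams,
    J: np.ndarray | None,
    t: float | None = None,
) -> np.ndarray:
    """Per-population input fields Σ_j k_ij I_j (1 + β_inp J_stim).

    Returns a (4, N, N) array.  Only the stimulated orientation's input
    field I_j is active; it drives its own sub-population with gain k1 and
    the other three with gain k2, spatially modulated by the stimulated
    component map.  If ``t`` is given the linear onset ramp is applied,
    otherwise the full-amplitude field is returned.
    """
    if abs(stim.center[0]) > domain.L or abs(stim.center[1]) > domain.L:
        raise ValueError("stimulus center lies outside the domain")
    r = domain.radius_from(stim.center)
    base = stim.radial_profile(r)
    j_idx = ORIENTATIONS.index(stim.orientation)
    if J is not None:
        base = base * (1.0 + params.beta_inp * J[j_idx])
    gains = np.full(4, params.k2)
    gains[j_idx] = params.k1
    out = stim.amplitude * gains[:, None, None] * base[None, :, :]
    if t is not None:
        out = out * stim.ramp_factor(t)
    return out


class _RHS:
    """Precomputed right-hand side of the field equations on one domain."""

    def __init__(
        self,
        params: ModelParams,
        domain: Domain,
        kernels: GriddedKernels,
        J: np.ndarray | None,
        stim: StimulusSpec,
    ):
        self.params = params
        self.domain = domain
        self.stim = stim
        prof = kernels.profile
        # Local recurrent kernel spectrum: excitation minus inhibition.
        self.spec_local = prof.g_ex * kernels.spec_eloc + prof.g_in * kernels.spec_i
        self.spec_lat = prof.g_ex * kernels.spec_elat
        self.J = J
        if J is not None and params.beta_rec > 0.0:
            self.mod_rec = 1.0 + params.beta_rec * J
        else:
            self.mod_rec = None
        self.input_full = input_field(stim, domain, params, J, t=None)
        # Decay matrix: -[(rho_same - rho_cross)·u_i + rho_cross·Σ_j u_j].
        self.rho_diag = params.rho_same - params.rho_cross
        self.n_eval = 0

    def __call__(self, t: float, u: np.ndarray) -> np.ndarray:
        self.n_eval += 1
        p = self.params
        s = sigmoid(u, p.mu, p.theta)
        if self.mod_rec is None:
            f = sfft.rfft2(s, axes=(-2, -1))
            conv = sfft.irfft2(
                f * (self.spec_local + self.spec_lat), s=u.shape[-2:], axes=(-2, -1)
            )
        else:
            f = sfft.rfft2(s, axes=(-2, -1))
            f_mod = sfft.rfft2(s * self.mod_rec, axes=(-2, -1))
            conv = sfft.irfft2(f * self.spec_local, s=u.shape[-2:], axes=(-2, -1))
            conv += sfft.irfft2(f_mod * self.spec_lat, s=u.shape[-2:], axes=(-2, -1))
        decay = self.rho_diag * u + p.rho_cross * u.sum(axis=0, keepdims=True)
        drive = self.input_full * self.stim.ramp_factor(t)
        return (-decay + drive + conv) / p.tau


def rhs(
    u: np.ndarray,
    t: float,
    params: ModelParams,
    domain: Domain,
    kernels: GriddedKernels,
    J: np.ndarray | None,
    stim: StimulusSpec,
) -> np.ndarray:
    """One evaluation of the field-equation time derivative (4, N, N)."""
    if not np.all(np.isfinite(u)):
        raise FloatingPointError("NaN/Inf in state passed to rhs")
    return _RHS(params, domain, kernels, J, stim)(t, u)


@dataclass
class SimulationResult:
    """Time-resolved membrane-potential fields for one oriented stimulus."""

    domain: Domain
    stim: StimulusSpec
    params: ModelParams
    times: np.ndarray
    u: np.ndarray  # (n_times, 4, N, N)
    unbounded: bool
    diagnostics: dict = field(default_factory=dict)

    @property
    def u_final(self) -> np.ndarray:
        return self.u[-1]

    def convergence_metric(self, window: float = 50.0) -> float:
        """Max absolute field change over the trailing ``window`` ms."""
        t_end = self.times[-1]
        idx = np.where(self.times >= t_end - window)[0]
        if len(idx) < 2:
            return float("nan")
        seg = self.u[idx]
        return float(np.max(np.abs(seg[-1] - seg[0])))


#: Radius (in units of Λ) beyond which supra-threshold activity marks the
#: run as unbounded spread.  Legitimate responses — the stimulated footprint
#: plus ring-driven bumps — stay within ≈ r_FF + Λ of the stimulus center;
#: the spreading instability escapes this neighbourhood and keeps growing.
SPREAD_RADIUS_FRAC = 2.2


def _integrate_rk4(
    f: _RHS,
    u0: np.ndarray,
    t_eval: np.ndarray,
    dt: float,
    spread_threshold: float | None = None,
    spread_mask: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Fixed-step classical RK4 with snapshot capture and instability flags.

    Two flags mark the unbounded-activation regime: |u| beyond the hard cap
    (numerical blow-up), or supra-threshold activity appearing inside
    ``spread_mask`` — the far field of the stimulus (the sigmoid bounds the
    amplitude, so the instability manifests as activation escaping across
    the sheet).  Flagged runs return early with the last state replicated
    into the remaining snapshots.
    """
    u = u0.copy()
    t = 0.0
    snaps = [u0.copy()] if t_eval[0] == 0.0 else []
    next_i = len(snaps)
    t_end = t_eval[-1]
    unbounded = False
    check_every = max(1, int(round(10.0 / dt)))  # spread check every ~10 ms
    n_step = 0
    while t < t_end - 1e-9:
        step = min(dt, t_end - t)
        k1 = f(t, u)
        k2 = f(t + 0.5 * step, u + 0.5 * step * k1)
        k3 = f(t + 0.5 * step, u + 0.5 * step * k2)
        k4 = f(t + step, u + step * k3)
        u = u + (step / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        t += step
        n_step += 1
        m = float(np.max(np.abs(u)))
        if not np.isfinite(m) or m > U_CAP:
            unbounded = True
            u = np.clip(np.nan_to_num(u, nan=U_CAP, posinf=U_CAP, neginf=-U_CAP), -U_CAP, U_CAP)
        elif (
            spread_threshold is not None
            and spread_mask is not None
            and n_step % check_every == 0
            and bool(np.any(u.max(axis=0)[spread_mask] > spread_threshold))
        ):
            unbounded = True
        if unbounded:
            while next_i < len(t_eval):
                snaps.append(u.copy())
                next_i += 1
            break
        while next_i < len(t_eval) and t >= t_eval[next_i] - 1e-9:
            snaps.append(u.copy())
            next_i += 1
    return np.asarray(t_eval[: len(snaps)]), np.stack(snaps), unbounded


def integrate(
    params: ModelParams,
    domain: Domain,
    profile: ConnectivityProfile | GriddedKernels,
    omap=None,
    stim: StimulusSpec | None = None,
    method: str = "rk4",
    dt: float = 1.0,
    rtol: float = 1e-6,
    atol: float = 1e-8,
    snapshot_times: np.ndarray | None = None,
    u0: np.ndarray | None = None,
) -> SimulationResult:
    """Integrate the field equations from rest under one oriented stimulus.

    ``method`` is either "rk4" (fixed-step classical Runge-Kutta, step ``dt``
    ms — the fast default) or "rk45" (adaptive scipy RK45 with ``rtol``/
    ``atol``).  Divergence beyond the cap is flagged as unbounded activation
    and returned, not raised: it is a valid model outcome in the
    reduced-inhibition regime.
    """
    if stim is None:
        stim = StimulusSpec()
    kernels = (
        profile
        if isinstance(profile, GriddedKernels)
        else grid_kernels(profile, domain)
    )
    J = None if omap is None else np.asarray(omap.J if hasattr(omap, "J") else omap)
    f = _RHS(params, domain, kernels, J, stim)
    t_eval = np.asarray(snapshot_times if snapshot_times is not None else stim.snapshot_times)
    if u0 is None:
        u0 = np.zeros((4, domain.N, domain.N))
    else:
        u0 = np.asarray(u0, dtype=float).copy()

    if method == "rk4":
        far = domain.radius_from(stim.center) > SPREAD_RADIUS_FRAC * stim.Lambda
        times, u, unbounded = _integrate_rk4(
            f, u0, t_eval, dt,
            spread_threshold=params.theta / params.mu,
            spread_mask=far,
        )
    elif method == "rk45":
        from scipy.integrate import solve_ivp

        shape = u0.shape

        def fun(t, y):
            return f(t, y.reshape(shape)).ravel()

        def blowup(t, y):
            return U_CAP - float(np.max(np.abs(y)))

        blowup.terminal = True
        sol = solve_ivp(
            fun,
            (0.0, stim.t_final),
            u0.ravel(),
            method="RK45",
            t_eval=t_eval,
            rtol=rtol,
            atol=atol,
            events=blowup,
        )
        unbounded = bool(sol.t_events[0].size)
        times = sol.t
        u = sol.y.T.reshape(-1, *shape)
        if unbounded and len(times) < len(t_eval):
            # Pad with the capped last state so downstream code sees full shape.
            pad = np.clip(u[-1] if len(u) else u0, -U_CAP, U_CAP)
            extra = len(t_eval) - len(times)
            u = np.concatenate([u, np.repeat(pad[None], extra, axis=0)])
            times = t_eval
        far = domain.radius_from(stim.center) > SPREAD_RADIUS_FRAC * stim.Lambda
        if len(u) and bool(
            np.any(u.max(axis=1)[:, far] > params.theta / params.mu)
        ):
            unbounded = True
    else:
        raise ValueError(f"unknown method {method!r}")

    return SimulationResult(
        domain=domain,
        stim=stim,
        params=params,
        times=np.asarray(times),
        u=u,
        unbounded=unbounded,
        diagnostics={"n_eval": f.n_eval, "max_abs_u": float(np.max(np.abs(u)))},
    )
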