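"""Per-location oriented batteries and operating-region parameter sweeps.

A "battery" presents the four stimulus orientations at one map location,
converts each converged response to the optical signal, and quantifies the
selective activation (threshold areas, orientation agreement with the map,
Naka-Rushton decay exponents).  A sweep repeats batteries over a grid of
(RW_ex, β_rec, C), averages the metrics over locations, and intersects four
boolean masks — selective area confined near the footprint, correct
orientation, steep selectivity decay, and the anatomical tuning band — into
the model's operating region.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace

import numpy as np

from .connectivity import ConnectivityParams, build_profile, grid_kernels
from .domain import Domain
from .orientation_map import OrientationMap, sample_locations
from .simulator import ORIENTATIONS, ModelParams, StimulusSpec, integrate
from .tuning import ANATOMICAL_KAPPA_BAND, kappa_grid
from . import vsd

__all__ = [
    "BatteryMetrics",
    "run_battery",
    "SweepConfig",
    "OperatingRegionSummary",
    "sweep",
    "report",
]


@dataclass
class BatteryMetrics:
    """Metrics from one four-orientation battery at one map location."""

    location: tuple[int, int]
    center: tuple[float, float]
    unstable_orientations: list[int]
    a_act: float = np.nan
    a_sel: float = np.nan
    a_sel_normalized: float = np.nan
    a_sel_outside_ff: float = np.nan
    fraction_correct: float = np.nan
    n_act: float = np.nan
    n_sel: float = np.nan

    @property
    def unstable(self) -> bool:
        return bool(self.unstable_orientations)

    @property
    def exponent_ratio(self) -> float:
        return self.n_sel / self.n_act


def run_battery(
    location: tuple[int, int],
    omap: OrientationMap,
    conn_params: ConnectivityParams,
    model_params: ModelParams | None = None,
    domain: Domain | None = None,
    t_final: float = 550.0,
    method: str = "rk4",
    dt: float = 1.0,
    fit_r_max_frac: float = 3.0,
) -> BatteryMetrics:
    """Run four oriented simulations at a map location and quantify them.

    Returns NaN metrics with the offending orientations listed when any
    simulation hits the unbounded-activation cap — diverged fields are
    flagged, never quantified.
    """
    domain = domain if domain is not None else omap.domain
    params = model_params if model_params is not None else ModelParams()
    profile = build_profile(conn_params)
    kernels = grid_kernels(profile, domain)
    center = domain.node_xy(location)
    lam = conn_params.Lambda

    oi: dict[int, np.ndarray] = {}
    unstable: list[int] = []
    r_ff = 0.7 * lam
    for ori in ORIENTATIONS:
        stim = StimulusSpec(orientation=ori, center=center, Lambda=lam, t_final=t_final,
                            snapshot_dt=t_final)
        r_ff = stim.r_ff
        res = integrate(params, domain, kernels, omap, stim, method=method, dt=dt)
        if res.unbounded:
            unstable.append(ori)
            continue
        oi[ori] = vsd.compute_oi(res, kernels, omap, t=t_final)

    metrics = BatteryMetrics(location=location, center=center, unstable_orientations=unstable)
    if unstable:
        return metrics

    maps = vsd.act_pref_sel(oi)
    areas = vsd.activation_areas(maps, domain, center, r_ff, omap=omap)
    r_max = fit_r_max_frac * lam
    prof_act = vsd.radial_profile(maps.act, domain, center, r_max=r_max)
    prof_sel = vsd.radial_profile(maps.sel, domain, center, r_max=r_max)
    fit_act = vsd.fit_naka_rushton(prof_act)
    fit_sel = vsd.fit_naka_rushton(prof_sel)

    metrics.a_act = areas.a_act
    metrics.a_sel = areas.a_sel
    metrics.a_sel_normalized = areas.a_sel_normalized
    metrics.a_sel_outside_ff = areas.a_sel_outside_ff
    metrics.fraction_correct = areas.fraction_correct
    metrics.n_act = fit_act.n
    metrics.n_sel = fit_sel.n
    return metrics


@dataclass
class SweepConfig:
    """Grid, thresholds and schedule for an operating-region sweep."""

    rw_ex_values: tuple = (0.10, 0.15, 0.20, 0.25, 0.30, 0.35, 0.40)
    beta_rec_values: tuple = tuple(np.round(np.arange(0.0, 1.01, 0.1), 2))
    c_values: tuple = (-0.6, -0.4, -0.2)
    n_locations: int = 5
    seed: int = 0
    max_a_sel_normalized: float = 1.05
    min_fraction_correct: float = 0.85
    min_exponent_ratio: float = 1.3
    kappa_band: tuple[float, float] = ANATOMICAL_KAPPA_BAND
    t_final: float = 550.0
    dt: float = 1.0
    method: str = "rk4"
    base_conn: ConnectivityParams = field(default_factory=ConnectivityParams)
    base_model: ModelParams = field(default_factory=ModelParams)

    def __post_init__(self) -> None:
        if min(self.max_a_sel_normalized, self.min_fraction_correct, self.min_exponent_ratio) <= 0:
            raise ValueError("thresholds must be positive")


@dataclass
class OperatingRegionSummary:
    """Metric grids over (C, RW_ex, β_rec) with operating-region masks.

    Metric arrays have shape (n_C, n_RW_ex, n_beta_rec); masks are boolean
    with the same shape (the κ band is independent of C and broadcast).
    ``coverage`` is, per C, the fraction of the permissible RW_ex range
    (0.1, 0.55) for which some β_rec puts the cell in the combined region.
    """

    config: SweepConfig
    mean_a_sel_normalized: np.ndarray
    mean_fraction_correct: np.ndarray
    mean_n_sel: np.ndarray
    mean_n_act: np.ndarray
    mean_exponent_ratio: np.ndarray
    spread_n_sel: np.ndarray
    unstable_count: np.ndarray
    mask_area: np.ndarray
    mask_orientation: np.ndarray
    mask_steep: np.ndarray
    mask_kappa: np.ndarray
    mask_combined: np.ndarray
    coverage: np.ndarray  # per C
    kappa_mean: np.ndarray  # (n_RW_ex, n_beta_rec)
    locations: list[tuple[int, int]] = field(default_factory=list)
    per_location: dict = field(default_factory=dict)


def sweep(config: SweepConfig, omap: OrientationMap, domain: Domain | None = None,
          progress: bool = False) -> OperatingRegionSummary:
    """Run batteries over the (C, RW_ex, β_rec) grid and build the masks.

    Locations are sampled once (non-pinwheel criterion) and reused across
    all cells so that cell-to-cell differences reflect parameters, not
    location draw.  Cells where every location destabilizes are marked
    unstable and excluded from all masks.
    """
    domain = domain if domain is not None else omap.domain
    rws, brs, cs = (np.asarray(v, float) for v in
                    (config.rw_ex_values, config.beta_rec_values, config.c_values))
    locs = sample_locations(omap, config.n_locations, seed=config.seed)

    kgrid = kappa_grid(omap, rws, brs, n_locations=max(50, config.n_locations),
                       seed=config.seed, conn_params=config.base_conn)

    shape = (len(cs), len(rws), len(brs))
    out = {k: np.full(shape, np.nan) for k in
           ("asn", "fc", "nsel", "nact", "ratio", "spread")}
    unstable_count = np.zeros(shape, dtype=int)
    per_location: dict = {}

    for ic, c in enumerate(cs):
        for ir, rw in enumerate(rws):
            cp = replace(config.base_conn, rw_ex=float(rw), C=float(c))
            for ib, br in enumerate(brs):
                mp = replace(config.base_model, beta_rec=float(br))
                cell = []
                for loc in locs:
                    m = run_battery(loc, omap, cp, mp, domain,
                                    t_final=config.t_final, method=config.method,
                                    dt=config.dt)
                    cell.append(m)
                per_location[(float(c), float(rw), float(br))] = cell
                stable = [m for m in cell if not m.unstable]
                unstable_count[ic, ir, ib] = sum(len(m.unstable_orientations) for m in cell)
                if stable:
                    out["asn"][ic, ir, ib] = np.mean([m.a_sel_normalized for m in stable])
                    out["fc"][ic, ir, ib] = np.mean([m.fraction_correct for m in stable])
                    out["nsel"][ic, ir, ib] = np.mean([m.n_sel for m in stable])
                    out["nact"][ic, ir, ib] = np.mean([m.n_act for m in stable])
                    out["ratio"][ic, ir, ib] = np.mean(
                        [m.exponent_ratio for m in stable])
                    out["spread"][ic, ir, ib] = (max(m.n_sel for m in stable)
                                                 - min(m.n_sel for m in stable))
                if progress:
                    print(f"C={c:+.2f} RW_ex={rw:.2f} beta_rec={br:.2f} "
                          f"n_sel={out['nsel'][ic, ir, ib]:.2f} "
                          f"unstable={unstable_count[ic, ir, ib]}", flush=True)

    no_flag = unstable_count == 0
    with np.errstate(invalid="ignore"):
        mask_area = no_flag & (out["asn"] <= config.max_a_sel_normalized)
        mask_orient = np.nan_to_num(out["fc"], nan=-1.0) >= config.min_fraction_correct
        mask_steep = np.nan_to_num(out["ratio"], nan=-1.0) >= config.min_exponent_ratio
    mask_kappa = np.broadcast_to(kgrid.band_mask[None, :, :], shape).copy()
    combined = mask_area & mask_orient & mask_steep & mask_kappa

    drw = float(rws[1] - rws[0]) if len(rws) > 1 else 0.05
    coverage = np.array([
        combined[ic].any(axis=1).sum() * drw / (0.55 - 0.10) for ic in range(len(cs))
    ])
    return OperatingRegionSummary(
        config=config,
        mean_a_sel_normalized=out["asn"],
        mean_fraction_correct=out["fc"],
        mean_n_sel=out["nsel"],
        mean_n_act=out["nact"],
        mean_exponent_ratio=out["ratio"],
        spread_n_sel=out["spread"],
        unstable_count=unstable_count,
        mask_area=mask_area,
        mask_orientation=mask_orient,
        mask_steep=mask_steep,
        mask_kappa=mask_kappa,
        mask_combined=combined,
        coverage=coverage,
        kappa_mean=kgrid.mean_kappa,
        locations=locs,
        per_location=per_location,
    )


def _map_checksum(omap: OrientationMap) -> str:
    return hashlib.sha256(np.ascontiguousarray(omap.J).tobytes()).hexdigest()


def report(summary: OperatingRegionSummary, out_dir, omap: OrientationMap | None = None) -> dict:
    """Write per-cell CSV, mask rasters, heatmap figures and a run manifest."""
    import pathlib

    import h5py
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import pandas as pd

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = summary.config
    rows = []
    for ic, c in enumerate(cfg.c_values):
        for ir, rw in enumerate(cfg.rw_ex_values):
            for ib, br in enumerate(cfg.beta_rec_values):
                rows.append({
                    "C": c, "rw_ex": rw, "beta_rec": br,
                    "a_sel_normalized": summary.mean_a_sel_normalized[ic, ir, ib],
                    "fraction_correct": summary.mean_fraction_correct[ic, ir, ib],
                    "n_sel": summary.mean_n_sel[ic, ir, ib],
                    "n_act": summary.mean_n_act[ic, ir, ib],
                    "exponent_ratio": summary.mean_exponent_ratio[ic, ir, ib],
                    "spread_n_sel": summary.spread_n_sel[ic, ir, ib],
                    "unstable_count": summary.unstable_count[ic, ir, ib],
                    "in_operating_region": bool(summary.mask_combined[ic, ir, ib]),
                })
    df = pd.DataFrame(rows)
    df.to_csv(out / "sweep_cells.csv", index=False, float_format="%.6g")

    with h5py.File(out / "masks.h5", "w") as f:
        for name in ("mask_area", "mask_orientation", "mask_steep", "mask_kappa",
                     "mask_combined"):
            f.create_dataset(name, data=getattr(summary, name))
        f.create_dataset("kappa_mean", data=summary.kappa_mean)
        f.attrs["rw_ex_values"] = list(cfg.rw_ex_values)
        f.attrs["beta_rec_values"] = list(cfg.beta_rec_values)
        f.attrs["c_values"] = list(cfg.c_values)

    for ic, c in enumerate(cfg.c_values):
        fig, axes = plt.subplots(1, 3, figsize=(12, 3.4))
        extent = (min(cfg.beta_rec_values), max(cfg.beta_rec_values),
                  min(cfg.rw_ex_values), max(cfg.rw_ex_values))
        for ax, grid, title in zip(
            axes,
            (summary.mean_a_sel_normalized[ic], summary.mean_fraction_correct[ic],
             summary.mean_exponent_ratio[ic]),
            ("normalized selective area", "fraction correct", "n_Sel / n_Act"),
        ):
            im = ax.imshow(grid, origin="lower", aspect="auto", extent=extent)
            ax.contour(summary.kappa_mean, levels=list(cfg.kappa_band), colors="w",
                       extent=extent, origin="lower")
            ax.set_xlabel(r"$\beta_{rec}$")
            ax.set_ylabel(r"$RW_{ex}$")
            ax.set_title(f"{title} (C={c})")
            fig.colorbar(im, ax=ax)
        fig.tight_layout()
        fig.savefig(out / f"sweep_C{c:+.2f}.png", dpi=120)
        plt.close(fig)

    manifest = {
        "seed": cfg.seed,
        "rw_ex_values": list(map(float, cfg.rw_ex_values)),
        "beta_rec_values": list(map(float, cfg.beta_rec_values)),
        "c_values": list(map(float, cfg.c_values)),
        "n_locations": cfg.n_locations,
        "locations": [list(map(int, l)) for l in summary.locations],
        "thresholds": {
            "max_a_sel_normalized": cfg.max_a_sel_normalized,
            "min_fraction_correct": cfg.min_fraction_correct,
            "min_exponent_ratio": cfg.min_exponent_ratio,
            "kappa_band": list(cfg.kappa_band),
        },
        "t_final": cfg.t_final,
        "coverage_rw_ex": list(map(float, summary.coverage)),
    }
    if omap is not None:
        manifest["map_checksum_sha256"] = _map_checksum(omap)
        manifest["map_provenance"] = {
            k: v for k, v in omap.provenance.items() if not isinstance(v, np.ndarray)
        }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
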