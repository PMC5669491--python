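"""HDF5 persistence for maps, kernels and simulation snapshots."""

from __future__ import annotations

import json

import h5py
import numpy as np

from .domain import Domain
from .orientation_map import OrientationMap
from .simulator import SimulationResult

__all__ = ["save_map", "load_map", "save_result", "save_kernels"]


def save_map(omap: OrientationMap, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("J", data=omap.J)
        f.attrs["Lambda"] = omap.Lambda
        f.attrs["L"] = omap.domain.L
        f.attrs["N"] = omap.domain.N
        f.attrs["provenance"] = json.dumps(omap.provenance, default=str)


def load_map(path) -> OrientationMap:
    with h5py.File(path, "r") as f:
        J = f["J"][...]
        dom = Domain(L=float(f.attrs["L"]), N=int(f.attrs["N"]))
        prov = json.loads(f.attrs.get("provenance", "{}"))
        return OrientationMap(domain=dom, J=J, Lambda=float(f.attrs["Lambda"]), provenance=prov)


def save_result(result: SimulationResult, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("u", data=result.u)
        f.create_dataset("times", data=result.times)
        f.attrs["L"] = result.domain.L
        f.attrs["N"] = result.domain.N
        f.attrs["unbounded"] = result.unbounded
        f.attrs["orientation"] = result.stim.orientation
        f.attrs["center"] = list(result.stim.center)
        f.attrs["params"] = json.dumps(vars(result.params).copy(), default=str)
        f.attrs["diagnostics"] = json.dumps(result.diagnostics, default=str)


def save_kernels(kernels, path) -> None:
    with h5py.File(path, "w") as f:
        for name in ("w_eloc", "w_elat", "w_i"):
            f.create_dataset(name, data=getattr(kernels, name))
        p = kernels.profile
        f.attrs["B_E"] = p.B_E
        f.attrs["P"] = p.P
        f.attrs["params"] = json.dumps(vars(p.params).copy(), default=str)
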