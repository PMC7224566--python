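"""Serialization: HDF5 checkpoints, legacy-VTK structured grids and point
clouds, flat YAML configs with schema validation, and run manifests.

HDF5 round-trips are bit-exact; VTK files are ASCII legacy format (readable
by standard viewers) at declared precision.  2D states are written as
z-degenerate structured grids.
"""

from __future__ import annotations

import hashlib
import json
import time as _time
from dataclasses import dataclass, field as dc_field, asdict

import h5py
import numpy as np
import yaml

from .fields import Grid, SimulationState

__all__ = ["write_state_h5", "read_state_h5", "write_vtk", "read_vtk",
           "write_point_cloud_vtk", "load_config", "validate_config",
           "RunManifest", "ConfigError"]


class ConfigError(ValueError):
    """Invalid or unknown configuration key/value."""


# --------------------------------------------------------------------------
# HDF5 checkpoints
# --------------------------------------------------------------------------

def write_state_h5(state: SimulationState, path) -> None:
    """Checkpoint a simulation state (bit-exact round trip)."""
    with h5py.File(path, "w") as f:
        g = state.grid
        f.attrs["shape"] = g.shape
        f.attrs["lengths"] = g.lengths
        f.attrs["periodic"] = [int(p) for p in g.periodic]
        f.attrs["time"] = state.time
        f.create_dataset("phi", data=state.phi)
        f.create_dataset("p", data=state.p)
        for i, comp in enumerate(state.u):
            f.create_dataset(f"u{i}", data=comp)
        if state.psi is not None:
            for i, comp in enumerate(state.psi):
                f.create_dataset(f"psi{i}", data=comp)
        if state.F is not None:
            for i, row in enumerate(state.F):
                for j, comp in enumerate(row):
                    f.create_dataset(f"F{i}{j}", data=comp)


def read_state_h5(path) -> SimulationState:
    with h5py.File(path, "r") as f:
        grid = Grid(tuple(int(v) for v in f.attrs["shape"]),
                    tuple(float(v) for v in f.attrs["lengths"]),
                    tuple(bool(v) for v in f.attrs["periodic"]))
        d = grid.ndim
        phi = f["phi"][...]
        p = f["p"][...]
        u = [f[f"u{i}"][...] for i in range(d)]
        psi = None
        F = None
        if "psi0" in f:
            psi = [f[f"psi{i}"][...] for i in range(2)]
        else:
            F = [[f[f"F{i}{j}"][...] for j in range(d)] for i in range(d)]
        return SimulationState(grid, phi, u, p, F=F, psi=psi,
                               time=float(f.attrs["time"]))


# --------------------------------------------------------------------------
# legacy VTK (ASCII)
# --------------------------------------------------------------------------

def _as3d(arr: np.ndarray) -> np.ndarray:
    return arr[:, :, None] if arr.ndim == 2 else arr


def write_vtk(state: SimulationState, path, precision: int = 9) -> None:
    """Write phi, p and u on a STRUCTURED_POINTS legacy-VTK ASCII grid."""
    g = state.grid
    shape3 = tuple(g.shape) + (1,) * (3 - g.ndim)
    spacing3 = tuple(g.spacing) + (1.0,) * (3 - g.ndim)
    fmt = f"%.{precision}g"
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\n")
        f.write(f"clotflow fields t={state.time}\n")
        f.write("ASCII\nDATASET STRUCTURED_POINTS\n")
        f.write(f"DIMENSIONS {shape3[0]} {shape3[1]} {shape3[2]}\n")
        f.write("ORIGIN 0 0 0\n")
        f.write(f"SPACING {spacing3[0]} {spacing3[1]} {spacing3[2]}\n")
        npts = int(np.prod(shape3))
        f.write(f"POINT_DATA {npts}\n")

        def scalars(name, arr):
            f.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
            flat = _as3d(arr).ravel(order="F")
            f.write("\n".join(fmt % v for v in flat))
            f.write("\n")

        scalars("phi", state.phi)
        scalars("p", state.p)
        f.write("VECTORS velocity double\n")
        comps = [_as3d(c).ravel(order="F") for c in state.u]
        while len(comps) < 3:
            comps.append(np.zeros_like(comps[0]))
        for vals in zip(*comps):
            f.write(" ".join(fmt % v for v in vals) + "\n")


def read_vtk(path) -> dict:
    """Minimal reader for the files produced by :func:`write_vtk` (format
    conformance check and lightweight round trips)."""
    with open(path) as f:
        lines = f.read().splitlines()
    if not lines[0].startswith("# vtk DataFile"):
        raise ValueError("not a legacy VTK file")
    if lines[2].strip() != "ASCII":
        raise ValueError("expected ASCII encoding")
    if lines[3].split()[-1] != "STRUCTURED_POINTS":
        raise ValueError("expected STRUCTURED_POINTS")
    dims = tuple(int(v) for v in lines[4].split()[1:])
    spacing = tuple(float(v) for v in lines[6].split()[1:])
    npts = int(np.prod(dims))
    out = {"dimensions": dims, "spacing": spacing, "fields": {}}
    k = 8
    while k < len(lines):
        tok = lines[k].split()
        if not tok:
            k += 1
            continue
        if tok[0] == "SCALARS":
            name = tok[1]
            vals = []
            k += 2
            while len(vals) < npts:
                vals.extend(float(v) for v in lines[k].split())
                k += 1
            out["fields"][name] = np.array(vals).reshape(dims, order="F")
        elif tok[0] == "VECTORS":
            name = tok[1]
            vals = []
            k += 1
            while len(vals) < npts:
                vals.append([float(v) for v in lines[k].split()])
                k += 1
            arr = np.array(vals)
            out["fields"][name] = [arr[:, i].reshape(dims, order="F")
                                   for i in range(3)]
        else:
            k += 1
    return out


def write_point_cloud_vtk(positions: np.ndarray, path, radii=None,
                          states=None, precision: int = 9) -> None:
    """Write a platelet ensemble as legacy-VTK POLYDATA points."""
    fmt = f"%.{precision}g"
    n = len(positions)
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\nclotflow platelets\n")
        f.write("ASCII\nDATASET POLYDATA\n")
        f.write(f"POINTS {n} double\n")
        for row in positions:
            f.write(" ".join(fmt % v for v in row) + "\n")
        if radii is not None or states is not None:
            f.write(f"POINT_DATA {n}\n")
        if radii is not None:
            f.write("SCALARS radius double 1\nLOOKUP_TABLE default\n")
            f.write("\n".join(fmt % v for v in radii) + "\n")
        if states is not None:
            f.write("SCALARS state int 1\nLOOKUP_TABLE default\n")
            f.write("\n".join(str(int(v)) for v in states) + "\n")


# --------------------------------------------------------------------------
# configs
# --------------------------------------------------------------------------

_SCHEMA = {
    "scenario": str,       # channel | vessel | permeation | shear_cell | aneurysm
    "grid": list,          # node counts per axis
    "domain": list,        # extents per axis
    "h_s": float, "h_c": float,
    "vf": float,
    "max_inlet": float,
    "plate_amplitude": float, "plate_omega": float,
    "rho1": float, "rho2": float, "eta1": float, "eta2": float,
    "lambda_e0": float, "sigma": float, "h": float, "gamma": float,
    "tau": float, "kappa_s": float, "kappa_c": float, "a_f": float,
    "rho_Fbg": float, "fibrin_log_base": float,
    "dt": float, "t_end": float, "seed": int,
    "permeability_mode": str, "lambda_e_mode": str,
    "freeze_phase": bool, "freeze_deformation": bool,
    "R0": float, "amp": float, "x0": float, "width": float,
    "mean_inlet": float, "period": float, "steady": bool,
    "output_times": list,
}

_POSITIVE = {"h_s", "h_c", "vf", "rho1", "rho2", "eta1", "eta2", "h",
             "gamma", "tau", "kappa_s", "kappa_c", "a_f", "rho_Fbg",
             "dt", "t_end", "R0", "width", "period"}


def validate_config(cfg: dict) -> dict:
    """Check keys against the flat schema; unknown keys are errors (this
    catches typos like kappa_s vs kappa_c misspellings)."""
    if "scenario" not in cfg:
        raise ConfigError("missing required key 'scenario'")
    for key, val in cfg.items():
        if key not in _SCHEMA:
            raise ConfigError(f"unknown configuration key {key!r}")
        want = _SCHEMA[key]
        if want is float and isinstance(val, (int, float)) \
                and not isinstance(val, bool):
            val = float(val)
        elif not isinstance(val, want):
            raise ConfigError(
                f"key {key!r} expects {want.__name__}, got {type(val).__name__}")
        if key in _POSITIVE and val <= 0:
            raise ConfigError(f"key {key!r} must be > 0, got {val}")
        cfg[key] = val
    return cfg


def load_config(path) -> dict:
    with open(path) as f:
        cfg = yaml.safe_load(f)
    if not isinstance(cfg, dict):
        raise ConfigError("config must be a flat mapping")
    return validate_config(cfg)


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:16]


# --------------------------------------------------------------------------
# run manifest
# --------------------------------------------------------------------------

@dataclass
class RunManifest:
    """Provenance record of one run; written even on abort."""

    config_hash: str
    seed: int
    code_version: str
    start_time: float = dc_field(default_factory=_time.time)
    end_time: float = 0.0
    files: list = dc_field(default_factory=list)
    diagnostics: dict = dc_field(default_factory=dict)
    aborted: bool = False
    abort_reason: str = ""

    def add_file(self, path) -> None:
        self.files.append(str(path))

    def finalize(self, path, diagnostics: dict = None, aborted: bool = False,
                 reason: str = "") -> None:
        self.end_time = _time.time()
        self.aborted = aborted
        self.abort_reason = reason
        if diagnostics:
            self.diagnostics = diagnostics
        with open(path, "w") as f:
            json.dump(asdict(self), f, indent=2)
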