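"""Geometry, initial-condition and boundary-forcing generators.

Every virtual experiment starts from one of these generators: a rectangular
channel with a shell-core thrombus on the lower wall, a penalized circular
vessel with a semi-spherical thrombus, the permeation chamber, the
oscillatory-shear cell, and an idealized fusiform aneurysm with platelet
deposition sites.  Generators are pure functions of their configuration:
identical inputs give bit-identical states.

Curved lumens (circular vessel, aneurysm) are realized on the structured grid
by volume penalization: nodes outside the lumen carry a large Darcy drag
(kappa_wall) and are pinned to zero velocity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import Callable, Optional

import numpy as np

from .fields import Grid, SimulationState
from .materials import MaterialParams
from .solver import BCSet

__all__ = ["Scenario", "DepositionSite", "tanh_profile", "make_channel",
           "make_circular_vessel", "make_permeation_channel",
           "make_shear_cell", "make_aneurysm", "pulsatile_waveform"]


@dataclass
class Scenario:
    """A ready-to-run configuration: geometry + state factory + BCs."""

    name: str
    grid: Grid
    params: MaterialParams
    bcs: BCSet
    state_factory: Callable
    core_mask: Optional[np.ndarray] = None
    shell_mask: Optional[np.ndarray] = None
    wall_mask: Optional[np.ndarray] = None
    rigid_mask: Optional[np.ndarray] = None
    body_force: Optional[list] = None
    probes: tuple = ()
    meta: dict = dc_field(default_factory=dict)

    def initial_state(self) -> SimulationState:
        return self.state_factory()


def tanh_profile(signed_distance: np.ndarray, h: float) -> np.ndarray:
    """Equilibrium interface profile phi = (1 + tanh(d / (sqrt(2) h))) / 2.

    ``signed_distance`` is positive in blood, negative inside the thrombus.
    """
    return 0.5 * (1.0 + np.tanh(signed_distance / (math.sqrt(2.0) * h)))


# --------------------------------------------------------------------------
# rectangular channel with a shell-core thrombus (2D psi / 3D F)
# --------------------------------------------------------------------------

def make_channel(h_s: float, h_c: float, grid: Grid,
                 material: MaterialParams, max_inlet: float = 0.75,
                 formulation: str = None) -> Scenario:
    """Channel {0 <= x <= 6, 0 <= y <= 2} with a semicircular shell-core
    thrombus centered on the lower wall at x = 3.

    A 3D grid extrudes the same geometry in z with periodic boundaries
    (deformation carried by F); a 2D grid uses the potential formulation.
    The inlet is parabolic with the given maximum.
    """
    if not (0 < h_c < h_s):
        raise ValueError("need 0 < h_c < h_s")
    H = grid.lengths[1]
    if h_s >= H:
        raise ValueError("clot larger than channel")
    X = grid.meshgrid()
    x, y = X[0], X[1]
    r = np.sqrt((x - 3.0) ** 2 + y**2)
    phi0 = tanh_profile(r - h_s, material.h)
    core_mask = r < h_c
    shell_mask = (r >= h_c) & (r < h_s)
    parab = y * (H - y) / (H / 2.0) ** 2  # 1 at mid-height, 0 at walls

    def velocity_values(t, g):
        # dirichlet nodes: inlet face keeps the profile, walls stay zero
        vals = [np.zeros(g.shape) for _ in range(g.ndim)]
        vals[0][...] = max_inlet * parab
        if g.ndim == 2:
            vals[0][:, 0] = 0.0
            vals[0][:, -1] = 0.0
        else:
            vals[0][:, 0, :] = 0.0
            vals[0][:, -1, :] = 0.0
        return vals

    if grid.ndim == 2:
        kinds = (("inflow", "outflow"), ("wall", "wall"))
    else:
        kinds = (("inflow", "outflow"), ("wall", "wall"),
                 ("periodic", "periodic"))
    bcs = BCSet(kinds, velocity_values)
    if formulation is None:
        formulation = "psi" if grid.ndim == 2 else "F"

    def factory():
        st = SimulationState.uniform_blood(grid, formulation=formulation)
        st.phi = phi0.copy()
        st.u[0] = max_inlet * parab * phi0
        return st

    return Scenario("channel", grid, material, bcs, factory,
                    core_mask=core_mask, shell_mask=shell_mask,
                    probes=((1.5, 1.0), (3.0, 1.5), (4.5, 1.0)),
                    meta={"h_s": h_s, "h_c": h_c, "max_inlet": max_inlet})


# --------------------------------------------------------------------------
# circular vessel (penalized) with a semi-spherical shell-core thrombus
# --------------------------------------------------------------------------

def make_circular_vessel(h_s: float, h_c: float, grid: Grid,
                         material: MaterialParams, max_inlet: float = 0.75,
                         clot_x: float = None) -> Scenario:
    """Circular vessel of unit diameter (length = grid x-extent) with a
    semi-spherical thrombus sitting on the wall."""
    if grid.ndim != 3:
        raise ValueError("circular vessel is a 3D scenario")
    if not (0 < h_c < h_s <= 0.5):
        raise ValueError("need 0 < h_c < h_s <= vessel radius 0.5")
    x, y, z = grid.meshgrid()
    cy = grid.lengths[1] / 2.0
    cz = grid.lengths[2] / 2.0
    rad = np.sqrt((y - cy) ** 2 + (z - cz) ** 2)
    R = 0.5
    wall_mask = rad >= R
    if clot_x is None:
        clot_x = grid.lengths[0] * 0.3
    # clot centered on the bottom of the lumen wall
    r_clot = np.sqrt((x - clot_x) ** 2 + (y - (cy - R)) ** 2 + (z - cz) ** 2)
    phi0 = tanh_profile(r_clot - h_s, material.h)
    phi0[wall_mask] = 1.0  # outside lumen: treated as free of thrombus
    core_mask = (r_clot < h_c) & ~wall_mask
    shell_mask = (r_clot >= h_c) & (r_clot < h_s) & ~wall_mask
    parab = np.clip(1.0 - (rad / R) ** 2, 0.0, None)  # Hagen-Poiseuille

    def velocity_values(t, g):
        vals = [np.zeros(g.shape) for _ in range(g.ndim)]
        vals[0][...] = max_inlet * parab
        vals[0][:, 0, :] = 0.0
        vals[0][:, -1, :] = 0.0
        vals[0][:, :, 0] = 0.0
        vals[0][:, :, -1] = 0.0
        return vals

    kinds = (("inflow", "outflow"), ("wall", "wall"), ("wall", "wall"))
    bcs = BCSet(kinds, velocity_values)

    def factory():
        st = SimulationState.uniform_blood(grid, formulation="F")
        st.phi = phi0.copy()
        st.u[0] = max_inlet * parab * phi0
        st.u[0][wall_mask] = 0.0
        return st

    return Scenario("circular_vessel", grid, material, bcs, factory,
                    core_mask=core_mask, shell_mask=shell_mask,
                    wall_mask=wall_mask,
                    meta={"h_s": h_s, "h_c": h_c, "max_inlet": max_inlet,
                          "radius": R, "clot_x": clot_x})


# --------------------------------------------------------------------------
# permeation chamber
# --------------------------------------------------------------------------

def make_permeation_channel(vf: float, grid: Grid, material: MaterialParams,
                            max_inlet: float = 1.0, clot_extent=(2.5, 3.5)
                            ) -> Scenario:
    """Channel-filling uniform clot block for the permeability calibration.

    Domain {0<=x<=6, 0<=y<=2 (walls), z periodic}.  The block spans the full
    cross-section over ``clot_extent`` with uniform phi = 1 - vf inside
    (one_minus_phi convention), smoothed by the tanh profile at its axial
    faces.
    """
    if not (0.0 < vf < 1.0):
        raise ValueError("vf must lie in (0, 1)")
    X = grid.meshgrid()
    x, y = X[0], X[1]
    H = grid.lengths[1]
    x1, x2 = clot_extent
    # signed axial distance to the block (negative inside)
    d = np.maximum(x1 - x, x - x2)
    phi0 = 1.0 - vf * (1.0 - tanh_profile(d, material.h))
    parab = y * (H - y) / (H / 2.0) ** 2

    def velocity_values(t, g):
        vals = [np.zeros(g.shape) for _ in range(g.ndim)]
        vals[0][...] = max_inlet * parab
        if g.ndim == 2:
            vals[0][:, 0] = 0.0
            vals[0][:, -1] = 0.0
        else:
            vals[0][:, 0, :] = 0.0
            vals[0][:, -1, :] = 0.0
        return vals

    if grid.ndim == 2:
        kinds = (("inflow", "outflow"), ("wall", "wall"))
    else:
        kinds = (("inflow", "outflow"), ("wall", "wall"),
                 ("periodic", "periodic"))
    bcs = BCSet(kinds, velocity_values)

    def factory():
        st = SimulationState.uniform_blood(
            grid, formulation="psi" if grid.ndim == 2 else "F")
        st.phi = phi0.copy()
        st.u[0] = max_inlet * parab
        return st

    return Scenario("permeation", grid, material, bcs, factory,
                    meta={"vf": vf, "clot_extent": clot_extent,
                          "max_inlet": max_inlet})


# --------------------------------------------------------------------------
# oscillatory shear cell
# --------------------------------------------------------------------------

def make_shear_cell(vf: float, grid: Grid, material: MaterialParams,
                    plate_amplitude: float = 0.2,
                    plate_omega: float = 1.2 * math.pi,
                    slab_extent=(1.0, 5.0)) -> Scenario:
    """Plate-gap cell {0<=x<=6 (periodic), 0<=y<=1} with a thrombus slab.

    The slab spans the gap over ``slab_extent`` at uniform volume fraction
    ``vf`` (phi = 1 - vf inside); the upper plate moves at
    v = plate_amplitude * sin(plate_omega * t), the lower plate is no-slip.
    Works on 2D grids and on 3D grids with a periodic z axis.
    """
    if not (0.0 < vf < 1.0):
        raise ValueError("vf must lie in (0, 1)")
    if not grid.periodic[0]:
        raise ValueError("shear cell needs a periodic x axis")
    X = grid.meshgrid()
    x = X[0]
    x1, x2 = slab_extent
    d = np.maximum(x1 - x, x - x2)
    phi0 = 1.0 - vf * (1.0 - tanh_profile(d, material.h))

    def velocity_values(t, g):
        vals = [np.zeros(g.shape) for _ in range(g.ndim)]
        vp = plate_amplitude * math.sin(plate_omega * t)
        if g.ndim == 2:
            vals[0][:, -1] = vp
        else:
            vals[0][:, -1, :] = vp
        return vals

    if grid.ndim == 2:
        kinds = (("periodic", "periodic"), ("wall", "wall"))
    else:
        kinds = (("periodic", "periodic"), ("wall", "wall"),
                 ("periodic", "periodic"))
    bcs = BCSet(kinds, velocity_values)

    def factory():
        # F-primary even in 2D: the identity potential psi = (y, -x) is not
        # periodic in x, so the curl formulation cannot wrap the shear cell
        st = SimulationState.uniform_blood(grid, formulation="F")
        st.phi = phi0.copy()
        return st

    return Scenario("shear_cell", grid, material, bcs, factory,
                    meta={"vf": vf, "amplitude": plate_amplitude,
                          "omega": plate_omega, "slab_extent": slab_extent})


# --------------------------------------------------------------------------
# idealized fusiform aneurysm
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class DepositionSite:
    """Thrombogenic wall patch: axial interval and angular sector on the
    lumen surface, with a capture radius for platelet contact."""

    x_interval: tuple
    angle_interval: tuple  # radians, angle measured around the vessel axis
    capture_radius: float = 0.06
    lumen: tuple = None    # (cy, cz, radius_fn) of the host vessel

    def contains(self, x: float, angle: float) -> bool:
        x1, x2 = self.x_interval
        a1, a2 = self.angle_interval
        ang = (angle - a1) % (2.0 * math.pi)
        width = (a2 - a1) % (2.0 * math.pi)
        if width == 0.0:
            width = 2.0 * math.pi
        return (x1 <= x <= x2) and (ang <= width)


def pulsatile_waveform(t, coefficients=None, period: float = 1.0):
    """Periodic inlet scale factor from a truncated Fourier series.

    ``coefficients = (a0, [(a_k, b_k), ...])``:
    f(t) = a0 + sum_k a_k cos(2 pi k t / T) + b_k sin(2 pi k t / T).
    The mean over one period is a0; the default harmonics give a systolic
    peak of roughly three times the mean with a positive diastolic floor.
    """
    if period <= 0:
        raise ValueError("period must be > 0")
    if coefficients is None:
        coefficients = (1.0, [(0.0, 1.35), (-0.55, 0.0)])
    a0, harmonics = coefficients
    t = np.asarray(t, dtype=float)
    out = np.full(t.shape, float(a0))
    for k, (ak, bk) in enumerate(harmonics, start=1):
        w = 2.0 * math.pi * k / period
        out = out + ak * np.cos(w * t) + bk * np.sin(w * t)
    return float(out) if out.ndim == 0 else out


def lumen_radius(x, R0: float, amp: float, x0: float, width: float):
    """Axisymmetric fusiform bulge R(x) = R0 (1 + amp exp(-(x-x0)^2/w^2))."""
    return R0 * (1.0 + amp * np.exp(-((x - x0) ** 2) / width**2))


def make_aneurysm(grid: Grid, material: MaterialParams,
                  R0: float = 0.22, amp: float = 1.0, x0: float = None,
                  width: float = 1.0, mean_inlet: float = 0.4,
                  waveform_coefficients=None, period: float = 1.0,
                  steady: bool = False, initial_phi=None):
    """Penalized axisymmetric fusiform aneurysm with three deposition sites
    (proximal neck, distal neck, bottom).  Returns (Scenario, [sites]).

    With amp = 0 the geometry degenerates to the straight circular vessel.
    The pulsatile inlet scales a parabolic profile by the Fourier waveform;
    ``steady=True`` freezes the waveform at its mean (used for the
    steady-versus-pulsatile embolization comparison).
    """
    if grid.ndim != 3:
        raise ValueError("aneurysm is a 3D scenario")
    L = grid.lengths[0]
    if x0 is None:
        x0 = L / 2.0
    if R0 * (1.0 + amp) >= min(grid.lengths[1], grid.lengths[2]) / 2.0:
        raise ValueError("bulge does not fit in the cross-section")
    if amp >= L / 4.0:
        raise ValueError("bulge amplitude must be < vessel length / 4")
    x, y, z = grid.meshgrid()
    cy = grid.lengths[1] / 2.0
    cz = grid.lengths[2] / 2.0
    rad = np.sqrt((y - cy) ** 2 + (z - cz) ** 2)
    R = lumen_radius(x, R0, amp, x0, width)
    wall_mask = rad >= R
    parab = np.clip(1.0 - (rad / R0) ** 2, 0.0, None)

    def velocity_values(t, g):
        scale = (1.0 if steady else
                 pulsatile_waveform(t, waveform_coefficients, period))
        vals = [np.zeros(g.shape) for _ in range(g.ndim)]
        vals[0][...] = mean_inlet * scale * parab
        vals[0][:, 0, :] = 0.0
        vals[0][:, -1, :] = 0.0
        vals[0][:, :, 0] = 0.0
        vals[0][:, :, -1] = 0.0
        return vals

    kinds = (("inflow", "outflow"), ("wall", "wall"), ("wall", "wall"))
    bcs = BCSet(kinds, velocity_values)

    def factory():
        st = SimulationState.uniform_blood(grid, formulation="F")
        if initial_phi is not None:
            st.phi = np.array(initial_phi, dtype=float)
            st.phi[wall_mask] = 1.0
        st.u[0] = mean_inlet * parab * st.phi
        st.u[0][wall_mask] = 0.0
        return st

    neck_half = 0.35 * width
    Rfn = lambda xq: lumen_radius(np.asarray(xq), R0, amp, x0, width)  # noqa: E731
    lum = (cy, cz, Rfn)
    sites = [
        DepositionSite((x0 - width - neck_half, x0 - width + neck_half),
                       (0.0, 2.0 * math.pi), lumen=lum),
        DepositionSite((x0 + width - neck_half, x0 + width + neck_half),
                       (0.0, 2.0 * math.pi), lumen=lum),
        # bottom of the bulge: lower angular sector only
        DepositionSite((x0 - 0.5 * width, x0 + 0.5 * width),
                       (math.pi + math.pi / 3.0, 2.0 * math.pi - math.pi / 3.0),
                       lumen=lum),
    ]
    scen = Scenario("aneurysm", grid, material, bcs, factory,
                    wall_mask=wall_mask,
                    meta={"R0": R0, "amp": amp, "x0": x0, "width": width,
                          "mean_inlet": mean_inlet, "period": period,
                          "steady": steady})
    return scen, sites


# --------------------------------------------------------------------------
# config-driven construction
# --------------------------------------------------------------------------

def from_config(cfg: dict):
    """Build a Scenario (and sites for the aneurysm) from a flat config
    mapping (see :mod:`clotflow.io` for the schema)."""
    mat_keys = ("rho1", "rho2", "eta1", "eta2", "lambda_e0", "sigma", "h",
                "gamma", "tau", "kappa_s", "kappa_c", "a_f", "rho_Fbg",
                "fibrin_log_base")
    mat = MaterialParams(**{k: cfg[k] for k in mat_keys if k in cfg})
    name = cfg["scenario"]
    shape = tuple(cfg.get("grid", (64, 24)))
    if name == "channel":
        domain = tuple(cfg.get("domain", (6.0, 2.0, 1.0)[:len(shape)]))
        periodic = (False, False, True)[:len(shape)]
        grid = Grid(shape, domain, periodic=periodic)
        return make_channel(cfg.get("h_s", 0.8), cfg.get("h_c", 0.6), grid,
                            mat, max_inlet=cfg.get("max_inlet", 0.75))
    if name == "vessel":
        domain = tuple(cfg.get("domain", (6.0, 1.0, 1.0)))
        grid = Grid(shape, domain)
        return make_circular_vessel(cfg.get("h_s", 0.5), cfg.get("h_c", 0.3),
                                    grid, mat,
                                    max_inlet=cfg.get("max_inlet", 0.75))
    if name == "permeation":
        domain = tuple(cfg.get("domain", (6.0, 2.0, 1.0)[:len(shape)]))
        periodic = (False, False, True)[:len(shape)]
        grid = Grid(shape, domain, periodic=periodic)
        return make_permeation_channel(cfg.get("vf", 0.33), grid, mat,
                                       max_inlet=cfg.get("max_inlet", 1.0))
    if name == "shear_cell":
        domain = tuple(cfg.get("domain", (6.0, 1.0, 1.0)[:len(shape)]))
        periodic = (True, False, True)[:len(shape)]
        grid = Grid(shape, domain, periodic=periodic)
        return make_shear_cell(
            cfg.get("vf", 0.3419), grid, mat,
            plate_amplitude=cfg.get("plate_amplitude", 0.2),
            plate_omega=cfg.get("plate_omega", 1.2 * math.pi))
    if name == "aneurysm":
        domain = tuple(cfg.get("domain", (6.0, 1.0, 1.0)))
        grid = Grid(shape, domain)
        return make_aneurysm(grid, mat, R0=cfg.get("R0", 0.22),
                             amp=cfg.get("amp", 1.0),
                             x0=cfg.get("x0", None),
                             width=cfg.get("width", 1.0),
                             mean_inlet=cfg.get("mean_inlet", 0.4),
                             period=cfg.get("period", 1.0),
                             steady=cfg.get("steady", False))
    raise ValueError(f"unknown scenario {name!r}")
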