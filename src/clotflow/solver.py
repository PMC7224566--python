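"""Time integration of the coupled phase-field / flow / elasticity system.

One operator-split cycle advances, in order:

1. the Eulerian deformation gradient F (or its 2D potential psi) by an
   explicit SSP-RK2 transport step with entropy-viscosity stabilization,
2. the Cahn-Hilliard phase equation by a semi-implicit constant-coefficient
   scheme, with the fourth-order operator factored into two second-order
   Helmholtz solves,
3. the momentum/continuity pair by a semi-implicit velocity-correction
   (projection) step; the stiff Darcy drag is integrated pointwise implicitly.

All implicit operators have constant coefficients and are LU-factorized once
per run.  Variable viscosity and density are handled by the standard
constant-coefficient splitting: the implicit step uses the maximal kinematic
viscosity, the pointwise remainder is explicit.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field as dc_field, replace
from typing import Callable, Optional

import numpy as np
import pandas as pd

from .energetics import (double_well_derivative, drag_coefficient,
                         elastic_stress, surface_tension_force, total_energy,
                         bulk_volume_fraction, _tr_FtF_minus_I)
from .fields import Grid, SimulationState, deriv, div, grad, integrate, laplacian
from .linsolve import FactorizedHelmholtz, VariableCoeffPoisson
from .materials import (MaterialParams, elastic_modulus_field,
                        mixture_property, permeability_field)

__all__ = ["SolverConfig", "BCSet", "Stepper", "Trajectory", "CFLError",
           "PhaseBoundsError", "advance_deformation", "advance_psi",
           "entropy_viscosity"]


class CFLError(RuntimeError):
    """Advective CFL number exceeded the configured limit."""


class PhaseBoundsError(RuntimeError):
    """Phase field left the admissible window (mass-conserving scheme aborts
    rather than clipping)."""


@dataclass(frozen=True)
class SolverConfig:
    """Numerical parameters of the operator-split scheme."""

    dt: float = 2e-3
    t_end: float = 1.0
    splitting_order: int = 1
    pressure_tol: float = 5e-3      # dimensionless divergence criterion
    helmholtz_tol: float = 1e-10    # residual check on direct solves
    c_E: float = 1.0                # entropy-viscosity residual constant
    c_max: float = 0.5              # first-order viscosity cap constant
    stabilization: bool = True
    cfl_limit: float = 1.0
    max_projection_iters: int = 20
    freeze_phase: bool = False
    freeze_deformation: bool = False
    kappa_wall: float = 1e-8        # volume-penalization permeability
    permeability_mode: str = "shell_core"
    lambda_e_mode: str = "constant"
    phi_warn_band: tuple = (-0.05, 1.05)
    phi_abort_band: tuple = (-0.2, 1.2)

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.splitting_order not in (1, 2):
            raise ValueError("splitting order must be 1 or 2")
        for tol in (self.pressure_tol,):
            if not (0.0 < tol <= 1e-2):
                raise ValueError("tolerances must lie in (0, 1e-2]")

    def with_(self, **kw) -> "SolverConfig":
        return replace(self, **kw)


@dataclass
class BCSet:
    """Boundary descriptors per axis side.

    ``velocity_kinds[axis] = (lo, hi)`` with kinds 'wall', 'inflow',
    'outflow' or 'periodic'.  Dirichlet values (walls, inflow, moving plates)
    come from ``velocity_values(t, grid) -> [component fields]``; only the
    values on dirichlet nodes are used.  Pressure is zero at outflow faces
    and zero-Neumann elsewhere; the phase field is zero-Neumann everywhere.
    """

    velocity_kinds: tuple
    velocity_values: Optional[Callable] = None

    def matrix_kinds_velocity(self) -> tuple:
        table = {"wall": "dirichlet", "inflow": "dirichlet",
                 "outflow": "neumann", "periodic": "periodic"}
        return tuple((table[lo], table[hi]) for lo, hi in self.velocity_kinds)

    def matrix_kinds_pressure(self) -> tuple:
        table = {"wall": "neumann", "inflow": "neumann",
                 "outflow": "dirichlet", "periodic": "periodic"}
        return tuple((table[lo], table[hi]) for lo, hi in self.velocity_kinds)

    def has_outflow(self) -> bool:
        return any("outflow" in pair for pair in self.velocity_kinds)

    def inflow_faces(self) -> list:
        out = []
        for a, (lo, hi) in enumerate(self.velocity_kinds):
            if lo == "inflow":
                out.append((a, 0))
            if hi == "inflow":
                out.append((a, -1))
        return out


# --------------------------------------------------------------------------
# entropy-viscosity stabilized transport of F / psi
# --------------------------------------------------------------------------

def entropy_viscosity(f: np.ndarray, u, grid: Grid,
                      c_E: float = 1.0, c_max: float = 0.5) -> np.ndarray:
    """Pointwise artificial viscosity nu_E for a transported scalar.

    nu_E = min(c_max * h * |u|, c_E * h^2 * |R| / ||E - mean E||_inf) with
    entropy E = f^2/2 and residual R = u . (grad E - f grad f), the entropy
    commutation defect of the spatial discretization.  R vanishes at O(h^2)
    for smooth resolved fields (the scheme stays near second order) and is
    O(1) at grid-scale fronts, where the first-order cap engages.
    """
    h = min(grid.spacing)
    E = 0.5 * f**2
    R = np.zeros(grid.shape)
    for a in range(grid.ndim):
        R += u[a] * (deriv(E, grid, a, bc="extrap")
                     - f * deriv(f, grid, a, bc="extrap"))
    norm = np.max(np.abs(E - np.mean(E)))
    if norm < 1e-3 * max(1.0, float(E.max())):
        # nearly uniform field: nothing to stabilize
        return np.zeros(grid.shape)
    umag = np.sqrt(sum(c**2 for c in u))
    nu_max = c_max * h * umag
    nu_res = c_E * h**2 * np.abs(R) / norm
    return np.minimum(nu_max, nu_res)


def _transport_rhs(comp: np.ndarray, u, grid: Grid, nu, source=None):
    """-u.grad(comp) + source + div(nu grad comp), extrapolating ghosts."""
    out = np.zeros(grid.shape) if source is None else source.copy()
    for a in range(grid.ndim):
        d = deriv(comp, grid, a, bc="extrap")
        out -= u[a] * d
        if nu is not None:
            out += deriv(nu * d, grid, a, bc="extrap")
    return out


def _check_cfl(u, grid: Grid, dt: float, limit: float) -> float:
    umax = max(float(np.max(np.abs(c))) for c in u)
    cfl = dt * umax / min(grid.spacing)
    if cfl >= limit:
        raise CFLError(
            f"advective CFL {cfl:.3f} >= {limit} (dt = {dt}, max|u| = {umax:.3g})")
    return cfl


def advance_deformation(F, u, dt: float, grid: Grid,
                        config: SolverConfig = SolverConfig(),
                        inflow_faces=()) -> list:
    """One SSP-RK2 step of dF/dt + u.grad F = (grad u) F.

    Entropy-viscosity diffusion is added componentwise; rows of F stay
    discretely divergence-free up to the stencil commutation error.  F = I is
    imposed on inflow faces; zero-normal-gradient ghosts elsewhere.
    """
    _check_cfl(u, grid, dt, config.cfl_limit)
    d = grid.ndim
    gu = [[deriv(u[i], grid, j, bc="extrap2") for j in range(d)]
          for i in range(d)]

    def rhs(Fc):
        out = [[None] * d for _ in range(d)]
        for i in range(d):
            for j in range(d):
                src = np.zeros(grid.shape)
                for k in range(d):
                    src += gu[i][k] * Fc[k][j]
                nu = None
                if config.stabilization:
                    nu = entropy_viscosity(Fc[i][j], u, grid,
                                           config.c_E, config.c_max)
                out[i][j] = _transport_rhs(Fc[i][j], u, grid, nu, src)
        return out

    def axpy(Fa, Fb, w):
        return [[Fa[i][j] + w * Fb[i][j] for j in range(d)] for i in range(d)]

    k1 = rhs(F)
    F1 = axpy(F, k1, dt)
    k2 = rhs(F1)
    Fn = [[0.5 * (F[i][j] + F1[i][j] + dt * k2[i][j]) for j in range(d)]
          for i in range(d)]
    for axis, side in inflow_faces:
        sl = [slice(None)] * d
        sl[axis] = side
        for i in range(d):
            for j in range(d):
                Fn[i][j][tuple(sl)] = 1.0 if i == j else 0.0
    return Fn


def advance_psi(psi, u, dt: float, grid: Grid,
                config: SolverConfig = SolverConfig()) -> list:
    """One SSP-RK2 step of the 2D potential advection d psi/dt + u.grad psi = 0."""
    if grid.ndim != 2:
        raise ValueError("psi transport is 2D only")
    _check_cfl(u, grid, dt, config.cfl_limit)

    def rhs(pc):
        out = []
        for comp in pc:
            nu = None
            if config.stabilization:
                nu = entropy_viscosity(comp, u, grid,
                                       config.c_E, config.c_max)
            out.append(_transport_rhs(comp, u, grid, nu))
        return out

    k1 = rhs(psi)
    p1 = [psi[k] + dt * k1[k] for k in range(2)]
    k2 = rhs(p1)
    return [0.5 * (psi[k] + p1[k] + dt * k2[k]) for k in range(2)]


# --------------------------------------------------------------------------
# the coupled stepper
# --------------------------------------------------------------------------

class Stepper:
    """Holds the factorized operators and material fields for one run and
    advances a :class:`SimulationState` by full operator-split cycles."""

    def __init__(self, grid: Grid, params: MaterialParams,
                 config: SolverConfig, bcs: BCSet,
                 core_mask=None, shell_mask=None, wall_mask=None,
                 body_force=None, rigid_mask=None) -> None:
        self.grid = grid
        self.params = params
        self.config = config
        self.bcs = bcs
        self.core_mask = core_mask
        self.shell_mask = shell_mask
        self.wall_mask = wall_mask
        self.rigid_mask = rigid_mask
        self.body_force = body_force
        dt = config.dt

        # constant-coefficient implicit operators
        nu_bar = max(params.eta1 / params.rho1, params.eta2 / params.rho2,
                     params.eta1 / params.rho2, params.eta2 / params.rho1)
        self.nu_bar = nu_bar
        self.rho0 = min(params.rho1, params.rho2)
        vel_kinds = bcs.matrix_kinds_velocity()
        self.op_velocity = FactorizedHelmholtz(grid, 1.0 / dt, nu_bar, vel_kinds)
        self.op_pressure = FactorizedHelmholtz(
            grid, 0.0, 1.0, bcs.matrix_kinds_pressure())
        self.op_pressure_var = None  # built lazily for stiff-drag runs

        lam = params.mixing_lambda
        if lam > 0 and not config.freeze_phase:
            S = max(2.0 * math.sqrt(lam / (dt * params.tau)),
                    lam * params.gamma / params.h**2)
            disc = math.sqrt(max((S / lam) ** 2 - 4.0 / (dt * params.tau * lam),
                                 0.0))
            alpha = 0.5 * (S / lam + disc)
            beta = 0.5 * (S / lam - disc)
            self._S = S
            self.op_ch1 = FactorizedHelmholtz(grid, alpha, 1.0, "neumann")
            self.op_ch2 = FactorizedHelmholtz(grid, beta, 1.0, "neumann")
        else:
            self._S = 0.0
            self.op_ch1 = self.op_ch2 = None


    # -- material fields ----------------------------------------------------
    def _material_fields(self, phi: np.ndarray):
        cached = getattr(self, "_matcache", None)
        if cached is not None and cached[0] is phi:
            return cached[1]
        p = self.params
        eta = mixture_property(phi, p.eta1, p.eta2)
        rho = mixture_property(phi, p.rho1, p.rho2)
        kappa = permeability_field(phi, p, mode=self.config.permeability_mode,
                                   core_mask=self.core_mask,
                                   shell_mask=self.shell_mask)
        lam_e = elastic_modulus_field(phi, p, mode=self.config.lambda_e_mode)
        out = (eta, rho, kappa, lam_e)
        self._matcache = (phi, out)
        return out

    # -- phase sub-step ------------------------------------------------------
    def advance_phase(self, phi: np.ndarray, u, F, lam_e) -> np.ndarray:
        """Semi-implicit Cahn-Hilliard step (two Helmholtz solves).

        Conserves the trapezoid integral of phi exactly in closed domains
        (zero-Neumann chemical potential, impermeable walls).
        """
        p, cfg, grid = self.params, self.config, self.grid
        lam, dt = p.mixing_lambda, cfg.dt
        adv = div([u[a] * phi for a in range(grid.ndim)], grid, bc="odd")
        explicit = (lam * p.gamma * double_well_derivative(phi, p.h)
                    - self._S * phi)
        if F is not None:
            explicit = explicit + 0.5 * lam_e * _tr_FtF_minus_I(F)
        r = (phi / dt - adv
             + p.tau * laplacian(explicit, grid, bc="mirror"))
        w = self.op_ch1.solve(-r / (p.tau * lam))
        phi_new = self.op_ch2.solve(-w)
        lo, hi = float(phi_new.min()), float(phi_new.max())
        b_lo, b_hi = cfg.phi_abort_band
        if lo < b_lo or hi > b_hi:
            raise PhaseBoundsError(
                f"phi range [{lo:.3f}, {hi:.3f}] outside abort band "
                f"[{b_lo}, {b_hi}]; refine dt or interface resolution")
        w_lo, w_hi = cfg.phi_warn_band
        if lo < w_lo or hi > w_hi:
            warnings.warn(f"phi overshoot: range [{lo:.3f}, {hi:.3f}]",
                          RuntimeWarning, stacklevel=2)
        return phi_new

    # -- flow sub-step -------------------------------------------------------
    def advance_flow(self, u, p_field, phi, F, t_new: float):
        """Velocity-correction projection step; returns (u, p, max_div)."""
        grid, cfg, prm = self.grid, self.config, self.params
        dt = cfg.dt
        d = grid.ndim
        eta, rho, kappa, lam_e = self._material_fields(phi)

        # explicit momentum sources
        if F is not None and np.any(lam_e > 0):
            S_el = elastic_stress(F, phi, lam_e)
            f_el = [sum(deriv(S_el[i][j], grid, j, bc="extrap")
                        for j in range(d)) for i in range(d)]
        else:
            f_el = [0.0] * d
        if prm.sigma > 0:
            f_st = surface_tension_force(phi, prm.mixing_lambda, grid)
        else:
            f_st = [0.0] * d

        grad_eta = grad(eta, grid, bc="mirror")
        coef = drag_coefficient(phi, eta, kappa)
        if self.wall_mask is not None:
            coef = coef + self.wall_mask * (eta / cfg.kappa_wall)
        damp = 1.0 / (1.0 + dt * coef / rho)
        beta = dt * damp / rho

        stiff = float(np.max(dt * coef / rho)) > 0.05
        if stiff and self.op_pressure_var is None:
            if not (cfg.freeze_phase or self.config.permeability_mode
                    in ("shell_core", "free")):
                warnings.warn("stiff drag with evolving phase: projection "
                              "operator frozen at the current drag field",
                              RuntimeWarning, stacklevel=2)
            self.op_pressure_var = VariableCoeffPoisson(
                grid, beta, self.bcs.matrix_kinds_pressure())

        bc_vals = (self.bcs.velocity_values(t_new, grid)
                   if self.bcs.velocity_values is not None else None)
        if stiff:
            # pressure force through the harmonic-mean face mobilities
            pcorr = self.op_pressure_var.corrections(p_field)
        else:
            gp = grad(p_field, grid, bc="mirror")

        # combined drag-damped force increment (pressure, elastic, capillary,
        # body): applying it through the mobility beta recovers the Darcy
        # balance c u = f - grad p for arbitrarily small permeability
        finc = []
        for i in range(d):
            force = f_el[i] + f_st[i]
            if self.body_force is not None:
                force = force + self.body_force[i]
            inc = beta * force
            inc = inc - (pcorr[i] if stiff else beta * gp[i])
            finc.append(inc)

        ustar = []
        for i in range(d):
            ui = u[i]
            adv = np.zeros(grid.shape)
            for j in range(d):
                adv += u[j] * deriv(ui, grid, j, bc="extrap")
            lap_u = laplacian(ui, grid, bc="mirror")
            visc_exp = eta * lap_u
            for j in range(d):
                visc_exp += grad_eta[j] * deriv(ui, grid, j, bc="extrap")
            rhs = ui / dt - adv + visc_exp / rho - self.nu_bar * lap_u
            # dirichlet values shifted so the force increment added below
            # leaves the boundary values exact
            dval = None if bc_vals is None else bc_vals[i] - finc[i]
            ustar.append(self.op_velocity.solve(rhs, dirichlet_values=dval))

        for i in range(d):
            ustar[i] = damp * ustar[i] + finc[i]
        if self.wall_mask is not None:
            for c in ustar:
                c[self.wall_mask] = 0.0
        if bc_vals is not None:
            m = self.op_velocity.dirichlet_mask
            for i in range(d):
                ustar[i][m] = bc_vals[i][m]

        # projection: drag-consistent variable-coefficient operator when the
        # drag is stiff (the pressure correction inside the clot must be
        # damped exactly like the velocity), constant-coefficient otherwise
        p_new = p_field.copy()
        max_div = np.inf
        scale = (max(float(np.max(np.abs(c))) for c in ustar) + 1e-30)
        for _ in range(cfg.max_projection_iters):
            dvg = div(ustar, grid, bc="odd")
            max_div = float(np.max(np.abs(dvg)))
            if max_div * min(grid.spacing) / scale < cfg.pressure_tol:
                break
            if stiff:
                dp = self.op_pressure_var.solve(dvg)
                gdp = self.op_pressure_var.corrections(dp)
                ustar = [ustar[i] - gdp[i] for i in range(d)]
            else:
                dp = self.op_pressure.solve(-(self.rho0 / dt) * dvg)
                gdp = grad(dp, grid, bc="mirror")
                ustar = [ustar[i] - (dt / self.rho0) * gdp[i]
                         for i in range(d)]
            if bc_vals is not None:
                m = self.op_velocity.dirichlet_mask
                for i in range(d):
                    ustar[i][m] = bc_vals[i][m]
            if self.wall_mask is not None:
                for c in ustar:
                    c[self.wall_mask] = 0.0
            p_new = p_new + dp
        dvg = div(ustar, grid, bc="odd")
        max_div = float(np.max(np.abs(dvg)))
        self.last_div_criterion = max_div * min(grid.spacing) / scale
        return ustar, p_new, max_div

    # -- full cycle ----------------------------------------------------------
    def step(self, state: SimulationState) -> dict:
        """One operator-split cycle; mutates ``state`` and returns diagnostics."""
        cfg, grid = self.config, self.grid
        dt = cfg.dt
        cfl = _check_cfl(state.u, grid, dt, cfg.cfl_limit)
        t_new = state.time + dt

        # 1. deformation transport
        if not cfg.freeze_deformation:
            if state.psi is not None:
                state.psi = advance_psi(state.psi, state.u, dt, grid, cfg)
            else:
                state.F = advance_deformation(
                    state.F, state.u, dt, grid, cfg,
                    inflow_faces=self.bcs.inflow_faces())

        F = state.deformation_gradient()

        # 2. phase update (rigid regions, if any, keep their phase frozen)
        if not cfg.freeze_phase and self.op_ch1 is not None:
            _, _, _, lam_e = self._material_fields(state.phi)
            phi_new = self.advance_phase(state.phi, state.u, F, lam_e)
            if self.rigid_mask is not None:
                phi_new[self.rigid_mask] = state.phi[self.rigid_mask]
            state.phi = phi_new

        # 3. flow update
        u_new, p_new, max_div = self.advance_flow(
            state.u, state.p, state.phi, F, t_new)
        state.u = u_new
        state.p = p_new
        state.time = t_new

        e_mix, e_el = total_energy(state, self.params, parts=True)
        return {"time": t_new, "cfl": cfl, "max_div": max_div,
                "div_criterion": self.last_div_criterion,
                "energy_mixing": e_mix, "energy_elastic": e_el,
                "energy": e_mix + e_el,
                "vf": bulk_volume_fraction(state.phi, grid),
                "phi_min": float(state.phi.min()),
                "phi_max": float(state.phi.max())}


@dataclass
class Trajectory:
    """Snapshots at requested output times plus per-step diagnostics."""

    snapshots: list
    diagnostics: pd.DataFrame
    final: SimulationState
    aborted: bool = False
    abort_reason: str = ""


def run(scenario, config: SolverConfig, output_times=(),
        probes=(), progress: bool = False) -> Trajectory:
    """Integrate a scenario to ``config.t_end``.

    ``scenario`` is any object exposing ``initial_state()``, ``params``,
    ``bcs`` and optional ``core_mask/shell_mask/wall_mask/rigid_mask/
    body_force`` attributes (see :mod:`clotflow.scenarios`).  Deterministic
    given configuration and seed.
    """
    state = scenario.initial_state()
    stepper = Stepper(
        state.grid, scenario.params, config, scenario.bcs,
        core_mask=getattr(scenario, "core_mask", None),
        shell_mask=getattr(scenario, "shell_mask", None),
        wall_mask=getattr(scenario, "wall_mask", None),
        rigid_mask=getattr(scenario, "rigid_mask", None),
        body_force=getattr(scenario, "body_force", None))
    records = []
    snaps = []
    out_times = sorted(output_times)
    next_out = 0
    nsteps = int(round(config.t_end / config.dt))
    aborted = False
    reason = ""
    for k in range(nsteps):
        try:
            rec = stepper.step(state)
        except (CFLError, PhaseBoundsError, RuntimeError) as exc:
            aborted = True
            reason = str(exc)
            break
        for ax, pt in enumerate(probes):
            idx = [int(round(c / dxi)) for c, dxi
                   in zip(pt, state.grid.spacing)]
            while len(idx) < state.grid.ndim:  # 2D probe on a 3D grid: mid-plane
                idx.append(state.grid.shape[len(idx)] // 2)
            rec[f"probe{ax}_u"] = float(state.u[0][tuple(idx)])
        records.append(rec)
        while next_out < len(out_times) and state.time >= out_times[next_out] - 1e-12:
            snaps.append(state.copy())
            next_out += 1
    diag = pd.DataFrame.from_records(records)
    return Trajectory(snaps, diag, state, aborted=aborted, abort_reason=reason)
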