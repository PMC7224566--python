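"""Virtual oscillatory-shear rheometry and elastic-modulus calibration.

A plate-gap cell containing a thrombus slab is driven by a sinusoidal upper
plate.  The recorded torque(stress)-displacement loops are reduced to the
phase angle and the storage/loss moduli by the ellipse relations

    delta = asin(4 A_r / (pi dTs dd)),
    G'  = (dTs/dd) cos(delta),     G'' = (dTs/dd) sin(delta),

with A_r the loop area and dTs, dd PEAK-TO-PEAK amplitudes (only with that
convention does the formula recover delta exactly for an ellipse, since the
ellipse area is (pi/4) dTs dd sin(delta)).  A Kelvin-Voigt closure

    G'' = 2 pi f (eta1 + lambda_s G')

turns each loop into a relaxation time lambda_s = [G''/(2 pi f) - eta1]/G'.
Simulated lambda_s(VF) points are mapped to fibrinogen concentration by
inverting the fibrin volume-fraction relation, fitted log-log, extrapolated
to the 1-6 mg/mL range, and compared against the relaxation-time curve of the
printed experimental moduli fits G' = 10 c^2.6 Pa, G'' = 0.7 c^1.7 Pa to
select the elastic shear modulus.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .fields import Grid, SimulationState
from .materials import MaterialParams, invert_fibrin_volume_fraction
from .scenarios import make_shear_cell
from .solver import SolverConfig, Stepper
from .units import RHEOMETRY_SCALES, ScaleRegistry

__all__ = ["RheometryConfig", "LoopRecord", "ModuliResult",
           "run_oscillatory_shear", "loop_area", "loop_moduli",
           "kelvin_voigt_loss", "extract_relaxation_time",
           "experimental_fits", "experimental_relaxation_time",
           "calibrate_lambda_e", "run_calibration"]


@dataclass(frozen=True)
class RheometryConfig:
    """Configuration of one virtual oscillatory-shear experiment
    (nondimensional units; the scale registry converts at the boundary)."""

    vf: float = 0.3419
    plate_amplitude: float = 0.2
    plate_omega: float = 1.2 * math.pi
    grid_shape: tuple = (96, 32)
    domain: tuple = (6.0, 1.0)
    slab_extent: tuple = (1.0, 5.0)
    steps_per_cycle: int = 800
    discard_cycles: int = 3
    average_cycles: int = 3
    contact_threshold: float = None  # default: phi < 1 - vf/2
    drift_tolerance: float = 0.05
    scales: ScaleRegistry = RHEOMETRY_SCALES

    def __post_init__(self) -> None:
        if self.plate_omega <= 0:
            raise ValueError("drive frequency must be > 0")
        if self.average_cycles < 2 or self.discard_cycles < 1:
            raise ValueError("need >= 2 recorded cycles after >= 1 discarded")
        if self.steps_per_cycle < 64:
            raise ValueError("need >= 64 samples per cycle")

    @property
    def patch_threshold(self) -> float:
        """Contact-patch rule: a plate node belongs to the thrombus contact
        where phi < threshold.  The default 1 - vf/2 marks nodes whose local
        thrombus fraction exceeds half the slab's bulk value (a fixed 0.5
        would miss every slab with vf < 0.5)."""
        if self.contact_threshold is not None:
            return self.contact_threshold
        return 1.0 - 0.5 * self.vf

    @property
    def frequency(self) -> float:
        """Drive frequency in cycles per nondimensional time unit."""
        return self.plate_omega / (2.0 * math.pi)

    @property
    def period(self) -> float:
        return 1.0 / self.frequency

    @property
    def dt(self) -> float:
        return self.period / self.steps_per_cycle


@dataclass
class LoopRecord:
    """Uniformly sampled plate displacement and wall-traction series covering
    an integer number of recorded cycles."""

    time: np.ndarray
    displacement: np.ndarray
    traction: np.ndarray
    samples_per_cycle: int
    config: RheometryConfig = None

    def __post_init__(self) -> None:
        n = len(self.time)
        if len(self.displacement) != n or len(self.traction) != n:
            raise ValueError("series lengths differ")
        if self.samples_per_cycle < 64:
            raise ValueError("need >= 64 samples per cycle")
        if n % self.samples_per_cycle != 0:
            raise ValueError("record does not cover an integer number of cycles")

    @property
    def n_cycles(self) -> int:
        return len(self.time) // self.samples_per_cycle

    def cycle_averaged(self) -> tuple:
        """(displacement, traction) of the phase-averaged closed loop."""
        m = self.samples_per_cycle
        d = self.displacement.reshape(self.n_cycles, m).mean(axis=0)
        T = self.traction.reshape(self.n_cycles, m).mean(axis=0)
        return d, T

    def cycle_drift(self) -> float:
        """Relative L2 distance between consecutive cycle loops."""
        m = self.samples_per_cycle
        T = self.traction.reshape(self.n_cycles, m)
        num = np.linalg.norm(T[-1] - T[0])
        den = np.linalg.norm(T[-1] - T[-1].mean()) + 1e-300
        return float(num / den)

    def to_csv(self, path) -> None:
        pd.DataFrame({"time": self.time, "displacement": self.displacement,
                      "traction": self.traction}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, samples_per_cycle: int) -> "LoopRecord":
        df = pd.read_csv(path)
        return cls(df["time"].to_numpy(), df["displacement"].to_numpy(),
                   df["traction"].to_numpy(), samples_per_cycle)


@dataclass(frozen=True)
class ModuliResult:
    """Loop-derived viscoelastic quantities (nondimensional unless noted)."""

    A_r: float
    dTs: float
    dd: float
    delta: float
    Gp: float
    Gpp: float
    lambda_s: float          # nondimensional relaxation time
    lambda_s_seconds: float = float("nan")

    def __post_init__(self) -> None:
        if not (0.0 <= self.delta <= math.pi / 2 + 1e-12):
            raise ValueError("phase angle must lie in [0, pi/2]")
        if self.Gp < 0 or self.Gpp < 0:
            raise ValueError("moduli must be nonnegative")


# --------------------------------------------------------------------------
# loop analysis
# --------------------------------------------------------------------------

def loop_area(record) -> float:
    """Unsigned shoelace area of the cycle-averaged closed loop."""
    if isinstance(record, LoopRecord):
        d, T = record.cycle_averaged()
    else:
        d, T = record
        if len(d) != len(T):
            raise ValueError("displacement/traction length mismatch")
    a = 0.5 * np.sum(d * np.roll(T, -1) - np.roll(d, -1) * T)
    return float(abs(a))


def loop_moduli(A_r: float, dTs: float, dd: float) -> tuple:
    """(delta, G', G'') from loop area and peak-to-peak amplitudes."""
    arg = 4.0 * A_r / (math.pi * dTs * dd)
    if arg > 1.0 + 1e-9:
        raise ValueError(
            f"sin(delta) argument {arg:.4f} > 1: dTs and dd must be "
            "peak-to-peak amplitudes (not half-amplitudes)")
    delta = math.asin(min(arg, 1.0))
    ratio = dTs / dd
    return delta, ratio * math.cos(delta), ratio * math.sin(delta)


def kelvin_voigt_loss(f: float, eta1: float, lambda_s: float,
                      Gp: float) -> float:
    """Kelvin-Voigt loss modulus G'' = 2 pi f (eta1 + lambda_s G')."""
    if f <= 0:
        raise ValueError("frequency must be > 0")
    return 2.0 * math.pi * f * (eta1 + lambda_s * Gp)


def extract_relaxation_time(Gp: float, Gpp: float, f: float,
                            eta1: float) -> float:
    """lambda_s = [G''/(2 pi f) - eta1] / G', the algebraic inverse of
    :func:`kelvin_voigt_loss`.  May be negative if G'' < 2 pi f eta1 (the
    response is less lossy than the pure fluid); returned as-is with a
    warning in that case."""
    if Gp == 0:
        raise ValueError("storage modulus must be nonzero")
    lam = (Gpp / (2.0 * math.pi * f) - eta1) / Gp
    if lam < 0:
        warnings.warn(f"negative relaxation time {lam:.3g}: loss modulus "
                      "below the pure-fluid floor", RuntimeWarning,
                      stacklevel=2)
    return lam


def experimental_fits(c_Fbg) -> tuple:
    """Experimental power-law moduli of fibrin gels (Pa):
    G' = 10 c^2.6, G'' = 0.7 c^1.7 with c in mg/mL."""
    c = np.asarray(c_Fbg, dtype=float)
    if np.any(c <= 0):
        raise ValueError("c_Fbg must be > 0")
    Gp = 10.0 ** (2.6 * np.log10(c) + math.log10(10.0))
    Gpp = 10.0 ** (1.7 * np.log10(c) + math.log10(0.7))
    if np.isscalar(c_Fbg):
        return float(Gp), float(Gpp)
    return Gp, Gpp


def experimental_relaxation_time(c_Fbg, f_hz: float = 0.5,
                                 eta1_pa_s: float = 1e-3):
    """Relaxation time (seconds) implied by the experimental moduli fits."""
    Gp, Gpp = experimental_fits(c_Fbg)
    return (Gpp / (2.0 * math.pi * f_hz) - eta1_pa_s) / Gp


# --------------------------------------------------------------------------
# the virtual experiment
# --------------------------------------------------------------------------

def _plate_traction(state: SimulationState, params: MaterialParams,
                    lambda_e_nd: float, threshold: float) -> float:
    """Area-averaged tangential traction on the thrombus contact patch of the
    upper plate: viscous shear (one-sided, second order) plus the elastic
    shear stress component."""
    grid = state.grid
    dy = grid.spacing[1]
    u = state.u[0]
    dudy = (3.0 * u[:, -1] - 4.0 * u[:, -2] + u[:, -3]) / (2.0 * dy)
    phi_top = state.phi[:, -1]
    from .materials import mixture_property
    eta_top = mixture_property(phi_top, params.eta1, params.eta2)
    F = state.deformation_gradient()
    b_xy = sum(F[0][k][:, -1] * F[1][k][:, -1] for k in range(2))
    tau = eta_top * dudy + lambda_e_nd * (1.0 - phi_top) * b_xy
    patch = phi_top < threshold
    if not np.any(patch):
        patch = np.ones_like(patch, dtype=bool)
    return float(tau[patch].mean())


def run_oscillatory_shear(config: RheometryConfig, material: MaterialParams,
                          solver_overrides: dict = None) -> LoopRecord:
    """Simulate the plate-gap cell and record the torque-displacement loops.

    The plate displacement is the analytic integral of the prescribed
    velocity, d(t) = (A/omega)(1 - cos(omega t)); the traction is the
    area-averaged tangential stress on the contact patch (phi < threshold on
    the upper plate), including viscous and elastic contributions.
    """
    grid = Grid(config.grid_shape, config.domain, periodic=(True, False))
    scen = make_shear_cell(config.vf, grid, material,
                           plate_amplitude=config.plate_amplitude,
                           plate_omega=config.plate_omega,
                           slab_extent=config.slab_extent)
    # the measurement window is a few strain cycles at ~5% amplitude: the
    # volume-fraction field is frozen (deformation is carried by F), which
    # keeps the conservative phase scheme out of the loop entirely
    overrides = {"dt": config.dt, "permeability_mode": "free",
                 "lambda_e_mode": "constant", "freeze_phase": True}
    if solver_overrides:
        overrides.update(solver_overrides)
    cfg = SolverConfig(**overrides)
    stepper = Stepper(grid, material, cfg, scen.bcs)
    state = scen.initial_state()

    A, om = config.plate_amplitude, config.plate_omega
    n_total = (config.discard_cycles + config.average_cycles) \
        * config.steps_per_cycle
    n_skip = config.discard_cycles * config.steps_per_cycle
    times, disp, trac = [], [], []
    for k in range(n_total):
        stepper.step(state)
        if k >= n_skip:
            t = state.time
            times.append(t)
            disp.append((A / om) * (1.0 - math.cos(om * t)))
            trac.append(_plate_traction(state, material, material.lambda_e0,
                                        config.patch_threshold))
    rec = LoopRecord(np.asarray(times), np.asarray(disp), np.asarray(trac),
                     config.steps_per_cycle, config=config)
    drift = rec.cycle_drift()
    if drift > config.drift_tolerance:
        warnings.warn(
            f"transient not decayed: cycle-to-cycle loop drift {drift:.3f} "
            f"> {config.drift_tolerance}", RuntimeWarning, stacklevel=2)
    return rec


def analyze_record(record: LoopRecord, config: RheometryConfig,
                   eta1_nd: float) -> ModuliResult:
    """Reduce a loop record to (delta, G', G'', lambda_s)."""
    d, T = record.cycle_averaged()
    A_r = loop_area((d, T))
    dTs = float(T.max() - T.min())
    dd = float(d.max() - d.min())
    delta, Gp, Gpp = loop_moduli(A_r, dTs, dd)
    lam_nd = extract_relaxation_time(Gp, Gpp, config.frequency, eta1_nd)
    lam_s = lam_nd * config.scales.time
    return ModuliResult(A_r, dTs, dd, delta, Gp, Gpp, lam_nd,
                        lambda_s_seconds=lam_s)


# --------------------------------------------------------------------------
# calibration against the experimental fits
# --------------------------------------------------------------------------

def calibrate_lambda_e(candidates_pa, sim_points, c_range=(1.0, 6.0),
                       f_hz: float = 0.5, eta1_pa_s: float = 1e-3,
                       n_grid: int = 25) -> dict:
    """Select the elastic shear modulus whose simulated relaxation-time line
    best matches the experimental curve.

    ``sim_points`` maps each candidate (Pa) to a list of
    (c_Fbg [mg/mL], lambda_s [s]) pairs (>= 2 per candidate).  Each set is
    fitted as log10(lambda_s) = a log10(c) + b and extrapolated to
    ``c_range``; the candidate minimizing the mean squared log10-distance to
    the experimental relaxation-time curve is returned, with its fit.
    """
    cg = np.logspace(math.log10(c_range[0]), math.log10(c_range[1]), n_grid)
    lam_exp = experimental_relaxation_time(cg, f_hz, eta1_pa_s)
    if np.any(lam_exp <= 0):
        raise ValueError("experimental relaxation-time curve is not positive "
                         "on the requested range")
    log_exp = np.log10(lam_exp)
    rows = []
    for le in candidates_pa:
        pts = sim_points[le]
        if len(pts) < 2:
            raise ValueError(
                f"need >= 2 simulated (c, lambda_s) points per candidate; "
                f"lambda_e = {le} has {len(pts)}")
        c = np.array([p[0] for p in pts], dtype=float)
        lam = np.array([p[1] for p in pts], dtype=float)
        if np.any(lam <= 0):
            raise ValueError("simulated relaxation times must be positive "
                             "for the log-log fit")
        slope, intercept = np.polyfit(np.log10(c), np.log10(lam), 1)
        mse = float(np.mean((slope * np.log10(cg) + intercept - log_exp) ** 2))
        rows.append({"lambda_e_pa": float(le), "slope": float(slope),
                     "intercept": float(intercept), "mse_log10": mse})
    table = pd.DataFrame(rows)
    best = table.loc[table["mse_log10"].idxmin()]
    return {"selected_lambda_e_pa": float(best["lambda_e_pa"]),
            "slope": float(best["slope"]),
            "intercept": float(best["intercept"]),
            "table": table}


def run_calibration(candidates_pa=(0.22, 0.44, 0.67, 0.89),
                    vf_levels=(0.3419, 0.5219),
                    grid_shape=(96, 32), steps_per_cycle: int = 500,
                    rho_ratio: float = 2.0, eta_ratio: float = 2.0,
                    scales: ScaleRegistry = RHEOMETRY_SCALES,
                    h: float = 0.08, solver_overrides: dict = None,
                    verbose: bool = False) -> dict:
    """End-to-end elastic-modulus calibration.

    For each candidate modulus (Pa) and slab volume fraction, run the
    oscillatory-shear cell, extract the relaxation time from the loop moduli,
    map VF -> fibrinogen concentration by inverting the fibrin relation, fit
    and extrapolate log-log, and select against the experimental curve.
    Material conditions follow the oscillatory-shear parameter table:
    density ratio 2, viscosity ratio 2, fluid kinematic viscosity 1e-6 m^2/s.
    """
    eta1_nd = scales.viscosity_to_nondim(1e-3)  # 1e-6 m^2/s * 1000 kg/m^3
    sim_points = {}
    loops = {}
    for le_pa in candidates_pa:
        le_nd = scales.modulus_to_nondim(le_pa)
        pts = []
        for vf in vf_levels:
            material = MaterialParams(
                rho1=1.0, rho2=rho_ratio, eta1=eta1_nd,
                eta2=eta_ratio * eta1_nd, lambda_e0=le_nd, h=h,
                sigma=1e-3, tau=1e-6, a_f=1.0)
            cfg = RheometryConfig(vf=vf, grid_shape=grid_shape,
                                  steps_per_cycle=steps_per_cycle,
                                  scales=scales)
            rec = run_oscillatory_shear(cfg, material,
                                        solver_overrides=solver_overrides)
            res = analyze_record(rec, cfg, eta1_nd)
            c = invert_fibrin_volume_fraction(vf)
            pts.append((c, res.lambda_s_seconds))
            loops[(le_pa, vf)] = (rec, res)
            if verbose:
                print(f"lambda_e = {le_pa} Pa, VF = {vf}: delta = "
                      f"{res.delta:.3f}, G' = {res.Gp:.3f}, G'' = "
                      f"{res.Gpp:.3f}, lambda_s = {res.lambda_s_seconds:.4g} s")
        sim_points[le_pa] = pts
    sel = calibrate_lambda_e(candidates_pa, sim_points)
    sel["sim_points"] = sim_points
    sel["loops"] = loops
    return sel
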