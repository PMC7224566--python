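"""Constitutive closures for the blood/thrombus mixture.

Pure functions of the phase field and composition: Davies' fibrous-medium
permeability, the empirical fibrin volume-fraction relation, the mixing-energy
density / surface-tension link, linear mixture blends for density and
viscosity, and the calibrated Kelvin-Voigt relaxation-time relation.

Conventions
-----------
phi = 1 is flowing blood, phi = 0 is thrombus; 0 < phi < 1 is interfacial
mixture.  ``rho1, eta1`` are blood properties (phi = 1); ``rho2, eta2`` are
thrombus properties (phi = 0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "MaterialParams",
    "Composition",
    "davies_permeability",
    "fibrin_volume_fraction",
    "invert_fibrin_volume_fraction",
    "mixing_energy_density",
    "mixture_property",
    "calibrated_relaxation_time",
    "elastic_modulus_field",
    "permeability_field",
    "FREE_FLOW_KAPPA",
]

#: Sentinel permeability for pure blood: large enough that the Darcy drag is
#: negligible, finite so the drag term stays well defined.
FREE_FLOW_KAPPA = 1e12


@dataclass(frozen=True)
class MaterialParams:
    """Constitutive constants of one blood/thrombus system (nondimensional
    unless a scale registry is used at the boundary).

    Defaults follow the channel deformation runs: density ratio 2, viscosity
    ratio 1, elastic shear modulus 0.5, weak surface tension 1e-3 with
    interface thickness 0.04, shell/core permeabilities 1e-2 / 1e-4.
    """

    rho1: float = 1.0
    rho2: float = 2.0
    eta1: float = 0.15
    eta2: float = 0.15
    lambda_e0: float = 0.5
    sigma: float = 1e-3
    h: float = 0.04
    gamma: float = 1.0
    tau: float = 1e-5
    kappa_s: float = 1e-2
    kappa_c: float = 1e-4
    a_f: float = 1.0
    rho_Fbg: float = 1400.0  # fibrinogen molecular density, mg/mL (1.4 g/mL)
    fibrin_log_base: float = 10.0

    def __post_init__(self) -> None:
        for name in ("rho1", "rho2", "eta1", "eta2", "h", "gamma", "tau",
                     "kappa_s", "kappa_c", "a_f", "rho_Fbg"):
            v = getattr(self, name)
            if not v > 0:
                raise ValueError(f"MaterialParams.{name} must be > 0, got {v}")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.lambda_e0 < 0:
            raise ValueError("lambda_e0 must be >= 0")
        if not math.isfinite(self.rho2 / self.rho1):
            raise ValueError("density ratio must be finite")
        if not math.isfinite(self.eta2 / self.eta1):
            raise ValueError("viscosity ratio must be finite")
        if self.fibrin_log_base not in (10.0, math.e):
            raise ValueError("fibrin_log_base must be 10 or e")

    @property
    def mixing_lambda(self) -> float:
        """Mixing energy density lambda = 3 sigma h / (2 sqrt(2))."""
        return mixing_energy_density(self.sigma, self.h)

    def with_(self, **kwargs) -> "MaterialParams":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class Composition:
    """Local biochemical composition of the thrombus."""

    c_Fbg: float = 1.0    # fibrinogen concentration, mg/mL
    c_plat: float = 0.0   # platelet number density, 1/volume
    psi_f: float = 0.0    # fibrin solid volume fraction
    psi_p: float = 0.0    # platelet volume-fraction contribution

    def __post_init__(self) -> None:
        if self.c_Fbg < 0:
            raise ValueError("c_Fbg must be >= 0")
        if not (0.0 <= self.psi_f < 1.0):
            raise ValueError("psi_f must lie in [0, 1)")
        if self.psi_p < 0:
            raise ValueError("psi_p must be >= 0")


def davies_permeability(psi_f, a_f: float = 1.0):
    """Davies' empirical permeability of a fibrous medium.

    kappa / a_f^2 = [16 psi_f^1.5 (1 + 56 psi_f^3)]^-1 with ``a_f`` the fiber
    radius.  Strictly decreasing in ``psi_f``; diverges in the dilute limit.
    """
    psi = np.asarray(psi_f, dtype=float)
    if np.any(psi <= 0.0) or np.any(psi > 1.0):
        raise ValueError("davies_permeability requires 0 < psi_f <= 1 "
                         "(the dilute limit psi_f -> 0 diverges)")
    if a_f <= 0:
        raise ValueError("fiber radius a_f must be > 0")
    out = a_f**2 / (16.0 * psi**1.5 * (1.0 + 56.0 * psi**3))
    return float(out) if np.isscalar(psi_f) else out


def fibrin_volume_fraction(c_Fbg, rho_Fbg: float = 1400.0,
                           log_base: float = 10.0):
    """Fibrin solid volume fraction from fibrinogen concentration (mg/mL).

    Psi_f = c_Fbg / [rho_Fbg (0.015 log(c_Fbg) + 0.13)].  The logarithm base
    is a configuration switch (companion relations are written base-10, which
    is the default).
    """
    c = np.asarray(c_Fbg, dtype=float)
    if np.any(c <= 0.0):
        raise ValueError("c_Fbg must be > 0")
    if rho_Fbg <= 0:
        raise ValueError("rho_Fbg must be > 0")
    logc = np.log10(c) if log_base == 10.0 else np.log(c) / math.log(log_base)
    bracket = 0.015 * logc + 0.13
    if np.any(bracket <= 0.0):
        # base-10: bracket = 0 at c = 10^(-0.13/0.015) ~ 2.2e-9 mg/mL
        cmin = log_base ** (-0.13 / 0.015)
        raise ValueError(
            f"fibrin volume fraction undefined for c_Fbg <= {cmin:.3g} mg/mL "
            "(empirical relation valid only above this concentration)")
    out = c / (rho_Fbg * bracket)
    return float(out) if np.isscalar(c_Fbg) else out


def invert_fibrin_volume_fraction(psi_f: float, rho_Fbg: float = 1400.0,
                                  log_base: float = 10.0,
                                  c_range=(1e-3, 1000.0)) -> float:
    """Fibrinogen concentration (mg/mL) producing a given fibrin volume
    fraction, by monotone bisection of :func:`fibrin_volume_fraction`.

    There is no closed-form inverse.  The default bracket spans the
    physiological-to-gel range used by the calibrations.
    """
    lo, hi = c_range
    f_lo = fibrin_volume_fraction(lo, rho_Fbg, log_base) - psi_f
    f_hi = fibrin_volume_fraction(hi, rho_Fbg, log_base) - psi_f
    if f_lo * f_hi > 0:
        raise ValueError(
            f"psi_f = {psi_f:.4g} is not attainable for c_Fbg in "
            f"[{lo:g}, {hi:g}] mg/mL (valid psi_f range is "
            f"[{fibrin_volume_fraction(lo, rho_Fbg, log_base):.4g}, "
            f"{fibrin_volume_fraction(hi, rho_Fbg, log_base):.4g}])")
    return float(brentq(
        lambda c: fibrin_volume_fraction(c, rho_Fbg, log_base) - psi_f,
        lo, hi, xtol=1e-12, rtol=1e-12))


def mixing_energy_density(sigma: float, h: float) -> float:
    """Mixing energy density lambda = (3 / (2 sqrt(2))) sigma h.

    Links the Cahn-Hilliard energy coefficient to the physical surface
    tension ``sigma`` for an equilibrium tanh interface of thickness ``h``.
    """
    if h <= 0:
        raise ValueError("interface thickness h must be > 0")
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    return 3.0 * sigma * h / (2.0 * math.sqrt(2.0))


def mixture_property(phi, v_blood: float, v_thrombus: float):
    """Linear blend of a bulk property across the interface.

    Returns v_thrombus + phi (v_blood - v_thrombus): the blood value at
    phi = 1 and the thrombus value at phi = 0.  phi is clamped to [0, 1] for
    property evaluation only (overshoots must not produce negative densities).
    """
    phi_c = np.clip(phi, 0.0, 1.0)
    out = v_thrombus + phi_c * (v_blood - v_thrombus)
    return float(out) if np.isscalar(phi) else out


def calibrated_relaxation_time(c_Fbg):
    """Calibrated Kelvin-Voigt relaxation time (seconds).

    lambda_s = 10^(-0.7172 log10(c_Fbg) - 1.1140), the log-log linear fit of
    the oscillatory-shear calibration at the selected elastic shear modulus.
    Strictly decreasing in fibrinogen concentration.
    """
    c = np.asarray(c_Fbg, dtype=float)
    if np.any(c <= 0.0):
        raise ValueError("c_Fbg must be > 0")
    out = 10.0 ** (-0.7172 * np.log10(c) - 1.1140)
    return float(out) if np.isscalar(c_Fbg) else out


def elastic_modulus_field(phi_field, params: MaterialParams,
                          mode: str = "constant"):
    """Elastic shear modulus field lambda_e(x).

    mode = "constant": lambda_e0 wherever there is thrombus (phi < 1), zero in
    pure blood.  mode = "via_relaxation": map local thrombus volume fraction
    (1 - phi) -> c_Fbg (inverse of the fibrin relation) -> lambda_s ->
    lambda_e = eta2 / lambda_s, using the Kelvin-Voigt definition
    lambda_s = eta2 / lambda_e.  Nonnegative; identically zero where phi = 1.
    """
    phi = np.asarray(phi_field, dtype=float)
    vf = np.clip(1.0 - phi, 0.0, 1.0)
    if mode == "constant":
        return params.lambda_e0 * (vf > 0.0)
    if mode == "via_relaxation":
        out = np.zeros_like(vf)
        mask = vf > 1e-9
        if np.any(mask):
            vmax = float(vf[mask].max())
            grid_v, grid_c = _vf_to_c_table(params.rho_Fbg,
                                            params.fibrin_log_base)
            if vmax > grid_v[-1]:
                raise ValueError(
                    f"volume fraction {vmax:.4g} exceeds the invertible range "
                    f"(max {grid_v[-1]:.4g}) of the fibrin relation")
            c = np.interp(vf[mask], grid_v, grid_c)
            out[mask] = params.eta2 / calibrated_relaxation_time(c)
        return out
    raise ValueError(f"unknown elastic modulus mode {mode!r}")


_VF_TO_C_CACHE: dict = {}


def _vf_to_c_table(rho_Fbg: float, log_base: float, n: int = 512):
    """Monotone (psi_f, c) interpolation table for fast field inversion."""
    key = (rho_Fbg, log_base, n)
    if key not in _VF_TO_C_CACHE:
        c = np.logspace(-3, 3, n)
        v = fibrin_volume_fraction(c, rho_Fbg, log_base)
        order = np.argsort(v)
        _VF_TO_C_CACHE[key] = (v[order], c[order])
    return _VF_TO_C_CACHE[key]


def permeability_field(phi_field, params: MaterialParams,
                       mode: str = "shell_core", core_mask=None,
                       shell_mask=None):
    """Permeability field kappa(x).

    mode = "shell_core": kappa_c in the core mask, kappa_s in the shell mask,
    free-flow sentinel elsewhere (pure blood, where the (1 - phi) prefactor
    kills the drag anyway).  mode = "davies": local volume fraction (1 - phi)
    interpreted as fibrin fraction and pushed through Davies' equation.
    mode = "free": no porous drag anywhere (a thrombus that translates with
    the flow, e.g. the oscillatory-shear cell, where the drag's stationary-
    skeleton assumption does not apply).
    """
    phi = np.asarray(phi_field, dtype=float)
    if mode == "free":
        return np.full(phi.shape, FREE_FLOW_KAPPA)
    if mode == "shell_core":
        if shell_mask is None:
            # no clot masks given: free flow everywhere
            return np.full(phi.shape, FREE_FLOW_KAPPA)
        if params.kappa_c > params.kappa_s:
            raise ValueError("shell-core mode requires kappa_c <= kappa_s")
        kappa = np.full(phi.shape, FREE_FLOW_KAPPA)
        kappa[np.asarray(shell_mask)] = params.kappa_s
        if core_mask is not None:
            kappa[np.asarray(core_mask)] = params.kappa_c
        return kappa
    if mode == "davies":
        vf = np.clip(1.0 - phi, 0.0, 1.0)
        kappa = np.full(phi.shape, FREE_FLOW_KAPPA)
        mask = vf > 1e-6
        if np.any(mask):
            kappa[mask] = davies_permeability(vf[mask], params.a_f)
        return np.minimum(kappa, FREE_FLOW_KAPPA)
    raise ValueError(f"unknown permeability mode {mode!r}")
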