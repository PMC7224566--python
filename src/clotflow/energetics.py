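"""Energy functional and momentum source terms of the phase-field model.

The free energy of the blood-thrombus mixture is

    E = int [ lambda/2 |grad phi|^2 + lambda/(2 h^2) phi^2 (phi-1)^2 ]
      + int [ lambda_e/2 tr(F^T F - I) ],

a Cahn-Hilliard mixing part plus a neo-Hookean elastic part carried by the
Eulerian deformation gradient F.  This module provides the pointwise and
differential operators derived from E that feed the momentum and phase
equations: the chemical potential, the elastic and capillary stresses, and
the Darcy-Brinkman drag of the porous clot.
"""

from __future__ import annotations

import numpy as np

from .fields import Grid, deriv, grad, integrate, laplacian
from .materials import MaterialParams

__all__ = [
    "double_well_derivative", "chemical_potential", "elastic_stress",
    "surface_tension_force", "darcy_drag", "total_energy",
    "bulk_volume_fraction", "curl_potential_to_F",
]


def double_well_derivative(phi: np.ndarray, h: float) -> np.ndarray:
    """g1(phi) = phi (phi - 1)(2 phi - 1) / h^2.

    Exact cubic derivative of the double-well potential phi^2(phi-1)^2/(2h^2);
    roots at 0, 1/2, 1 and antisymmetric about phi = 1/2.
    """
    if h <= 0:
        raise ValueError("interface thickness h must be > 0")
    return phi * (phi - 1.0) * (2.0 * phi - 1.0) / h**2


def _tr_FtF_minus_I(F) -> np.ndarray:
    d = len(F)
    out = -float(d) * np.ones(F[0][0].shape)
    for i in range(d):
        for j in range(d):
            out += F[i][j] ** 2
    return out


def chemical_potential(phi: np.ndarray, F, params: MaterialParams,
                       grid: Grid, lambda_e=None) -> np.ndarray:
    """Free-energy potential mu1 = -lambda Lap(phi) + lambda gamma g1(phi)
    + (lambda_e / 2) tr(F^T F - I).

    The lambda*gamma mobility factor multiplies the double-well term exactly
    as in the governing equations.  Zero-Neumann phase boundary stencils.
    """
    if F is not None and F[0][0].shape != phi.shape:
        raise ValueError("phi and F live on different grids")
    lam = params.mixing_lambda
    le = params.lambda_e0 if lambda_e is None else lambda_e
    mu = (-lam * laplacian(phi, grid, bc="mirror")
          + lam * params.gamma * double_well_derivative(phi, params.h))
    if F is not None:
        mu = mu + 0.5 * le * _tr_FtF_minus_I(F)
    return mu


def elastic_stress(F, phi: np.ndarray, lambda_e) -> list:
    """Neo-Hookean stress lambda_e (1 - phi)(F F^T - I).

    Symmetric; vanishes where F = I or phi = 1.  ``lambda_e`` may be a scalar
    or a field.
    """
    d = len(F)
    pref = lambda_e * (1.0 - phi)
    out = [[None] * d for _ in range(d)]
    for i in range(d):
        for j in range(i, d):
            s = np.zeros(phi.shape)
            for k in range(d):
                s += F[i][k] * F[j][k]
            if i == j:
                s -= 1.0
            out[i][j] = pref * s
            if j != i:
                out[j][i] = out[i][j]
    return out


def surface_tension_force(phi: np.ndarray, lam: float, grid: Grid) -> list:
    """Capillary body force -lambda div(grad phi (x) grad phi)."""
    g = grad(phi, grid, bc="mirror")
    d = grid.ndim
    force = []
    for i in range(d):
        f = np.zeros(phi.shape)
        for j in range(d):
            f -= deriv(lam * g[i] * g[j], grid, j, bc="mirror")
        force.append(f)
    return force


def darcy_drag(u, phi: np.ndarray, eta, kappa) -> list:
    """Porous drag -eta(phi)(1 - phi) u / kappa(phi).

    Pointwise antiparallel to u; vanishes in pure blood (phi = 1) and in the
    free-flow limit kappa -> infinity.
    """
    kappa = np.asarray(kappa, dtype=float)
    if np.any(kappa <= 0):
        raise ValueError("kappa must be strictly positive")
    coef = eta * (1.0 - phi) / kappa
    return [-coef * comp for comp in u]


def drag_coefficient(phi: np.ndarray, eta, kappa) -> np.ndarray:
    """Positive drag coefficient eta(phi)(1-phi)/kappa used semi-implicitly."""
    kappa = np.asarray(kappa, dtype=float)
    if np.any(kappa <= 0):
        raise ValueError("kappa must be strictly positive")
    return eta * (1.0 - phi) / kappa


def total_energy(state, params: MaterialParams, lambda_e=None,
                 parts: bool = False):
    """Total free energy (mixing + elastic) by trapezoid quadrature."""
    grid = state.grid
    lam = params.mixing_lambda
    g = grad(state.phi, grid, bc="mirror")
    gradsq = np.zeros(grid.shape)
    for c in g:
        gradsq += c**2
    mixing = (0.5 * lam * gradsq
              + (0.5 * lam / params.h**2)
              * state.phi**2 * (state.phi - 1.0)**2)
    F = state.deformation_gradient()
    le = params.lambda_e0 if lambda_e is None else lambda_e
    elastic = 0.5 * le * _tr_FtF_minus_I(F)
    e_mix = integrate(mixing, grid)
    e_el = integrate(elastic, grid)
    if parts:
        return e_mix, e_el
    return e_mix + e_el


def bulk_volume_fraction(phi: np.ndarray, grid: Grid,
                         convention: str = "one_minus_phi") -> float:
    """Domain-averaged thrombus volume fraction.

    ``one_minus_phi`` (default) averages (1 - phi), consistent with
    phi in [0, 1]; ``as_printed`` averages (1 - phi)/2, the normalization of
    a [-1, 1] phase convention, retained for cross-checks.
    """
    vol = float(np.prod(grid.lengths))
    if convention == "one_minus_phi":
        return integrate(1.0 - phi, grid) / vol
    if convention == "as_printed":
        return integrate((1.0 - phi) / 2.0, grid) / vol
    raise ValueError(f"unknown VF convention {convention!r}")


def curl_potential_to_F(psi, grid: Grid) -> list:
    """2D deformation gradient from the vector potential: F = curl(psi).

    Row i of F is (d psi_i / dy, -d psi_i / dx), which makes every row
    discretely divergence-free up to stencil commutation error.
    """
    if grid.ndim != 2:
        raise ValueError("the psi potential formulation is 2D only")
    F = []
    for comp in psi:
        F.append([deriv(comp, grid, 1, bc="extrap"),
                  -deriv(comp, grid, 0, bc="extrap")])
    return F
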