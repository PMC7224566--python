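"""Structured-grid data model and discrete differential operators.

Uniform node-centered grids in 2D or 3D, second-order centered finite
differences with ghost-layer boundary handling, and trapezoid quadrature.
The gradient convention used everywhere is (grad u)_ij = d u_i / d x_j.

Ghost modes
-----------
``periodic``  wrap-around.
``mirror``    even reflection about the boundary node (zero normal gradient).
``odd``       odd reflection about the boundary node (value pinned at node).
``extrap``    linear extrapolation (outflow-like, keeps one-sided slope).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Sequence

import numpy as np

__all__ = ["Grid", "SimulationState", "pad_axis", "deriv", "grad", "div",
           "laplacian", "integrate", "trapezoid_weights"]


@dataclass(frozen=True)
class Grid:
    """Uniform structured grid.

    ``shape`` is the node count per axis (>= 4 per non-degenerate axis);
    ``lengths`` the domain extent per axis, with node (0, 0, 0) at the domain
    minimum corner.  On a periodic axis the duplicate end node is excluded,
    so spacing = L/n there and L/(n-1) on a bounded axis.
    """

    shape: tuple
    lengths: tuple
    periodic: tuple = None

    def __post_init__(self) -> None:
        shape = tuple(int(n) for n in self.shape)
        lengths = tuple(float(v) for v in self.lengths)
        periodic = self.periodic
        if periodic is None:
            periodic = (False,) * len(shape)
        periodic = tuple(bool(p) for p in periodic)
        if len(lengths) != len(shape) or len(periodic) != len(shape):
            raise ValueError("shape, lengths, periodic must have equal length")
        if len(shape) not in (2, 3):
            raise ValueError("only 2D and 3D grids are supported")
        if any(n < 4 for n in shape):
            raise ValueError("need at least 4 nodes per axis")
        if any(v <= 0 for v in lengths):
            raise ValueError("axis extents must be positive")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "lengths", lengths)
        object.__setattr__(self, "periodic", periodic)

    @property
    def ndim(self) -> int:
        return len(self.shape)

    @property
    def spacing(self) -> tuple:
        return tuple(
            L / n if per else L / (n - 1)
            for n, L, per in zip(self.shape, self.lengths, self.periodic))

    def coords(self, axis: int) -> np.ndarray:
        n, L, per = self.shape[axis], self.lengths[axis], self.periodic[axis]
        dx = L / n if per else L / (n - 1)
        return np.arange(n) * dx

    def meshgrid(self):
        return np.meshgrid(*[self.coords(a) for a in range(self.ndim)],
                           indexing="ij")

    def zeros(self) -> np.ndarray:
        return np.zeros(self.shape)

    @property
    def cell_volume(self) -> float:
        return float(np.prod(self.spacing))


def pad_axis(f: np.ndarray, axis: int, mode_lo: str, mode_hi: str) -> np.ndarray:
    """Add one ghost layer on each side of ``axis`` according to ghost modes."""
    def ghost(side_mode: str, lo: bool) -> np.ndarray:
        sl = [slice(None)] * f.ndim
        if side_mode == "periodic":
            sl[axis] = slice(-1, None) if lo else slice(0, 1)
            return f[tuple(sl)]
        if side_mode == "mirror":
            sl[axis] = slice(1, 2) if lo else slice(-2, -1)
            return f[tuple(sl)]
        if side_mode == "odd":
            sl[axis] = slice(1, 2) if lo else slice(-2, -1)
            inner = f[tuple(sl)]
            sl[axis] = slice(0, 1) if lo else slice(-1, None)
            bnd = f[tuple(sl)]
            return 2.0 * bnd - inner
        if side_mode == "extrap":
            sl[axis] = slice(0, 2) if lo else slice(-2, None)
            two = f[tuple(sl)]
            i0, i1 = (0, 1) if lo else (1, 0)
            a = np.take(two, i0, axis=axis)
            b = np.take(two, i1, axis=axis)
            return np.expand_dims(2.0 * a - b, axis)
        if side_mode == "extrap2":
            # quadratic extrapolation: the centered difference at the
            # boundary node becomes the second-order one-sided stencil
            sl[axis] = slice(0, 3) if lo else slice(-3, None)
            three = f[tuple(sl)]
            i0, i1, i2 = (0, 1, 2) if lo else (2, 1, 0)
            a = np.take(three, i0, axis=axis)
            b = np.take(three, i1, axis=axis)
            c = np.take(three, i2, axis=axis)
            return np.expand_dims(3.0 * a - 3.0 * b + c, axis)
        raise ValueError(f"unknown ghost mode {side_mode!r}")

    return np.concatenate([ghost(mode_lo, True), f, ghost(mode_hi, False)],
                          axis=axis)


def _modes(grid: Grid, axis: int, bc) -> tuple:
    """Resolve a bc spec into (mode_lo, mode_hi) for one axis."""
    if grid.periodic[axis]:
        return "periodic", "periodic"
    if isinstance(bc, str):
        return bc, bc
    if isinstance(bc, (tuple, list)):
        return bc[axis] if isinstance(bc[axis], tuple) else (bc[axis], bc[axis])
    raise ValueError("bad bc spec")


def deriv(f: np.ndarray, grid: Grid, axis: int, bc="mirror") -> np.ndarray:
    """Second-order centered first derivative along ``axis``."""
    mode_lo, mode_hi = _modes(grid, axis, bc)
    g = pad_axis(f, axis, mode_lo, mode_hi)
    dx = grid.spacing[axis]
    sl_p = [slice(None)] * f.ndim
    sl_m = [slice(None)] * f.ndim
    sl_p[axis] = slice(2, None)
    sl_m[axis] = slice(0, -2)
    return (g[tuple(sl_p)] - g[tuple(sl_m)]) / (2.0 * dx)


def grad(f: np.ndarray, grid: Grid, bc="mirror") -> list:
    return [deriv(f, grid, a, bc) for a in range(grid.ndim)]


def div(vec: Sequence[np.ndarray], grid: Grid, bc="odd") -> np.ndarray:
    """Centered divergence of a vector field.

    Default ``odd`` ghosts are consistent with impermeable walls (normal
    component vanishing at the boundary node), which makes the trapezoid
    integral of the divergence of a wall-tangent flux vanish exactly.
    """
    out = np.zeros(vec[0].shape)
    for a in range(grid.ndim):
        out += deriv(vec[a], grid, a, bc)
    return out


def laplacian(f: np.ndarray, grid: Grid, bc="mirror") -> np.ndarray:
    out = np.zeros(f.shape)
    for a in range(grid.ndim):
        mode_lo, mode_hi = _modes(grid, a, bc)
        g = pad_axis(f, a, mode_lo, mode_hi)
        dx2 = grid.spacing[a] ** 2
        sl_p = [slice(None)] * f.ndim
        sl_m = [slice(None)] * f.ndim
        sl_c = [slice(None)] * f.ndim
        sl_p[a] = slice(2, None)
        sl_m[a] = slice(0, -2)
        sl_c[a] = slice(1, -1)
        out += (g[tuple(sl_p)] - 2.0 * g[tuple(sl_c)] + g[tuple(sl_m)]) / dx2
    return out


def trapezoid_weights(grid: Grid) -> np.ndarray:
    """Tensor-product trapezoid quadrature weights (x cell volume)."""
    w = np.ones(grid.shape)
    for a in range(grid.ndim):
        if grid.periodic[a]:
            continue
        sl = [slice(None)] * grid.ndim
        sl[a] = slice(0, 1)
        w[tuple(sl)] *= 0.5
        sl[a] = slice(-1, None)
        w[tuple(sl)] *= 0.5
    return w * grid.cell_volume


def integrate(f: np.ndarray, grid: Grid) -> float:
    return float(np.sum(f * trapezoid_weights(grid)))


@dataclass
class SimulationState:
    """The coupled fields that every solver step transforms.

    ``phi`` is the phase (1 = blood, 0 = thrombus), ``u`` a list of velocity
    components, ``p`` pressure.  Deformation is carried either by the rank-2
    tensor ``F`` (entry [i][j] an array) or, in 2D, by the two-component
    potential ``psi`` with F = curl(psi) derived on demand; exactly one of the
    two is primary.
    """

    grid: Grid
    phi: np.ndarray
    u: list
    p: np.ndarray
    F: list = None          # F[i][j]: ndarray, or None when psi is primary
    psi: list = None        # [psi1, psi2] in 2D, else None
    time: float = 0.0
    meta: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        shp = self.grid.shape
        if self.phi.shape != shp or self.p.shape != shp:
            raise ValueError("phi/p shape does not match grid")
        if len(self.u) != self.grid.ndim:
            raise ValueError("velocity component count != grid ndim")
        for comp in self.u:
            if comp.shape != shp:
                raise ValueError("velocity component shape mismatch")
        if (self.F is None) == (self.psi is None):
            raise ValueError("exactly one of F, psi must be primary")
        if self.psi is not None and self.grid.ndim != 2:
            raise ValueError("psi formulation is 2D only")

    @classmethod
    def uniform_blood(cls, grid: Grid, formulation: str = "F"):
        """Quiescent pure-blood state (phi = 1, u = 0, F = I)."""
        d = grid.ndim
        if formulation == "psi":
            if d != 2:
                raise ValueError("psi formulation is 2D only")
            x, y = grid.meshgrid()
            psi = [y.copy(), -x.copy()]
            return cls(grid, np.ones(grid.shape),
                       [grid.zeros() for _ in range(d)], grid.zeros(),
                       psi=psi)
        F = [[np.full(grid.shape, 1.0 if i == j else 0.0) for j in range(d)]
             for i in range(d)]
        return cls(grid, np.ones(grid.shape),
                   [grid.zeros() for _ in range(d)], grid.zeros(), F=F)

    def identity_F(self) -> list:
        d = self.grid.ndim
        return [[np.full(self.grid.shape, 1.0 if i == j else 0.0)
                 for j in range(d)] for i in range(d)]

    def deformation_gradient(self) -> list:
        """F, derived from psi if the 2D potential is primary.

        The derived tensor is the transpose of the row-curl of psi: with
        G = curl(psi) (divergence-free rows), F = G^T both satisfies the 3D
        evolution law dF/dt + u.grad F = (grad u) F for incompressible u and
        carries the same preserved constraint (divergence over the first
        index vanishing) as the transported 3D tensor.
        """
        if self.F is not None:
            return self.F
        from .energetics import curl_potential_to_F
        G = curl_potential_to_F(self.psi, self.grid)
        return [[G[j][i] for j in range(2)] for i in range(2)]

    def copy(self) -> "SimulationState":
        return SimulationState(
            self.grid, self.phi.copy(), [c.copy() for c in self.u],
            self.p.copy(),
            F=None if self.F is None else
            [[c.copy() for c in row] for row in self.F],
            psi=None if self.psi is None else [c.copy() for c in self.psi],
            time=self.time, meta=dict(self.meta))
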