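"""Constant-coefficient Helmholtz/Poisson solves on structured grids.

All implicit solves in the scheme are of the form (a I - b Lap) x = rhs with
constant a, b, so each operator is assembled once per run, LU-factorized
(SuperLU) and reused every step.  Boundary kinds per axis side:

``neumann``    zero normal gradient (mirror ghost folded into the stencil)
``dirichlet``  value imposed at boundary nodes (identity rows; the caller
               writes the boundary values into the right-hand side)
``periodic``   wrap-around (forced on periodic grid axes)

A pure-Neumann/periodic Poisson operator (a = 0) is singular; the solver then
removes the incompatible component of the right-hand side (projection onto
the left null vector, which is the trapezoid weight vector) and pins one node.
"""

from __future__ import annotations

import math

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .fields import Grid, trapezoid_weights

__all__ = ["FactorizedHelmholtz", "VariableCoeffPoisson", "normalize_bcs"]


def normalize_bcs(grid: Grid, bcs) -> tuple:
    """Resolve a bc spec into a canonical tuple ((lo, hi), ...) per axis."""
    out = []
    for a in range(grid.ndim):
        if grid.periodic[a]:
            out.append(("periodic", "periodic"))
            continue
        spec = bcs[a] if not isinstance(bcs, str) else bcs
        if isinstance(spec, str):
            spec = (spec, spec)
        lo, hi = spec
        for s in (lo, hi):
            if s not in ("neumann", "dirichlet"):
                raise ValueError(f"unknown bc kind {s!r}")
        out.append((lo, hi))
    return tuple(out)


def _d2_1d(n: int, dx: float, lo: str, hi: str) -> sp.csr_matrix:
    """1D second-difference operator; rows at dirichlet nodes left zero
    (they are replaced by identity rows after the Kronecker sum)."""
    inv = 1.0 / dx**2
    main = np.full(n, -2.0 * inv)
    off = np.full(n - 1, inv)
    D = sp.diags([off, main, off], [-1, 0, 1], format="lil")
    if lo == "periodic":
        D[0, -1] = inv
        D[-1, 0] = inv
    else:
        if lo == "neumann":
            D[0, 1] = 2.0 * inv
        else:  # dirichlet: zero the row
            D[0, :] = 0.0
        if hi == "neumann":
            D[-1, -2] = 2.0 * inv
        else:
            D[-1, :] = 0.0
    return D.tocsr()


def _laplacian_matrix(grid: Grid, bcs) -> tuple:
    """Assemble the ndim Laplacian by Kronecker sums; also return the boolean
    mask of dirichlet nodes."""
    mats = []
    dir_mask = np.zeros(grid.shape, dtype=bool)
    for a in range(grid.ndim):
        lo, hi = bcs[a]
        mats.append(_d2_1d(grid.shape[a], grid.spacing[a], lo, hi))
        sl = [slice(None)] * grid.ndim
        if lo == "dirichlet":
            sl[a] = 0
            dir_mask[tuple(sl)] = True
        if hi == "dirichlet":
            sl = [slice(None)] * grid.ndim
            sl[a] = -1
            dir_mask[tuple(sl)] = True
    eyes = [sp.identity(n, format="csr") for n in grid.shape]
    L = None
    for a in range(grid.ndim):
        term = None
        for b in range(grid.ndim):
            m = mats[b] if b == a else eyes[b]
            term = m if term is None else sp.kron(term, m, format="csr")
        L = term if L is None else L + term
    return L.tocsr(), dir_mask


class VariableCoeffPoisson:
    """LU-factorized finite-volume operator div(beta grad p).

    Used by the drag-consistent projection: beta = dt/(rho + dt*c) with c the
    Darcy drag coefficient, so the pressure correction inside a nearly
    impermeable clot is damped exactly like the velocity.  Face coefficients
    are harmonic means (continuity of flux across the permeability jump).
    Boundary kinds as in :class:`FactorizedHelmholtz`; with no dirichlet face
    the operator is singular and handled by rhs projection plus pinning.
    On 3D grids with a periodic z axis and z-invariant beta the solve runs
    mode-by-mode in z through small 2D factorizations.
    """

    @staticmethod
    def _assemble(grid: Grid, beta: np.ndarray, bcs):
        """(coo matrix without bc row replacement, face_beta list)."""
        shape = grid.shape
        n = int(np.prod(shape))
        idx = np.arange(n).reshape(shape)
        rows, cols, vals = [], [], []
        diag = np.zeros(shape)
        face_beta = []
        for a in range(grid.ndim):
            dx2 = grid.spacing[a] ** 2
            per = bcs[a][0] == "periodic"
            b_lo = beta
            b_hi = np.roll(beta, -1, axis=a)
            fb = 2.0 * b_lo * b_hi / (b_lo + b_hi + 1e-300)
            if not per:
                sl = [slice(None)] * grid.ndim
                sl[a] = -1
                fb = fb.copy()
                fb[tuple(sl)] = 0.0  # no wrap face on bounded axes
            face_beta.append(fb)
            face = fb / dx2
            i_lo = idx
            i_hi = np.roll(idx, -1, axis=a)
            rows += [i_lo.ravel(), i_hi.ravel()]
            cols += [i_hi.ravel(), i_lo.ravel()]
            vals += [face.ravel(), face.ravel()]
            diag -= face + np.roll(face, 1, axis=a)
        M = sp.coo_matrix(
            (np.concatenate(vals + [diag.ravel()]),
             (np.concatenate(rows + [idx.ravel()]),
              np.concatenate(cols + [idx.ravel()]))),
            shape=(n, n))
        return M, face_beta

    @staticmethod
    def _dirichlet_mask(grid: Grid, bcs) -> np.ndarray:
        mask = np.zeros(grid.shape, dtype=bool)
        for a in range(grid.ndim):
            lo, hi = bcs[a]
            if lo == "dirichlet":
                sl = [slice(None)] * grid.ndim
                sl[a] = 0
                mask[tuple(sl)] = True
            if hi == "dirichlet":
                sl = [slice(None)] * grid.ndim
                sl[a] = -1
                mask[tuple(sl)] = True
        return mask

    def __init__(self, grid: Grid, beta: np.ndarray, bcs) -> None:
        self.grid = grid
        self.bcs = normalize_bcs(grid, bcs)
        beta = np.asarray(beta, dtype=float)
        _, self.face_beta = self._assemble(grid, beta, self.bcs)
        self.fast_z = (grid.ndim == 3 and self.bcs[2][0] == "periodic"
                       and bool(np.all(np.ptp(beta, axis=2) <=
                                       1e-12 * float(np.max(np.abs(beta))))))
        if self.fast_z:
            g2 = Grid(grid.shape[:2], grid.lengths[:2], grid.periodic[:2])
            beta2 = beta[:, :, 0]
            M2, _ = self._assemble(g2, beta2, self.bcs[:2])
            dmask2 = self._dirichlet_mask(g2, self.bcs[:2])
            dir2 = np.flatnonzero(dmask2.ravel())
            free = np.ones(M2.shape[0])
            free[dir2] = 0.0
            lams = _z_eigenvalues(grid.shape[2], grid.spacing[2])
            self._lus = []
            self.singular = False
            self._null2 = None
            for m, lam in enumerate(lams):
                Mm = (M2.tocsr()
                      - sp.diags(lam * beta2.ravel() * free)).tolil()
                if dir2.size:
                    Mm[dir2, :] = 0.0
                    Mm[dir2, dir2] = 1.0
                if m == 0 and dir2.size == 0:
                    self.singular = True
                    w = np.ones(M2.shape[0])
                    self._null2 = w / np.linalg.norm(w)
                    Mm[0, :] = 0.0
                    Mm[0, 0] = 1.0
                self._lus.append(splu(Mm.tocsc()))
            self.dirichlet_mask = np.repeat(
                dmask2[:, :, None], grid.shape[2], axis=2)
            return
        M, _ = self._assemble(grid, beta, self.bcs)
        M = M.tolil()
        dmask = self._dirichlet_mask(grid, self.bcs)
        self.dirichlet_mask = dmask
        dir_idx = np.flatnonzero(dmask.ravel())
        if dir_idx.size:
            M[dir_idx, :] = 0.0
            M[dir_idx, dir_idx] = 1.0
        self.singular = dir_idx.size == 0
        if self.singular:
            w = np.ones(M.shape[0])
            self._null = w / np.linalg.norm(w)
            M[0, :] = 0.0
            M[0, 0] = 1.0
        self._lu = splu(M.tocsc())

    def solve(self, rhs: np.ndarray) -> np.ndarray:
        b = np.array(rhs, dtype=float)
        if self.dirichlet_mask.any():
            b[self.dirichlet_mask] = 0.0
        if self.fast_z:
            shape = self.grid.shape
            bh = np.fft.rfft(b, axis=2)
            out = np.empty_like(bh)
            for m, lu in enumerate(self._lus):
                r = bh[:, :, m].ravel()
                if m == 0 and self.singular:
                    rr = r.real - self._null2 * (self._null2 @ r.real)
                    rr[0] = 0.0
                    out[:, :, m] = lu.solve(rr).reshape(shape[:2])
                    continue
                sol = lu.solve(r.real) + 1j * lu.solve(r.imag)
                out[:, :, m] = sol.reshape(shape[:2])
            return np.fft.irfft(out, n=shape[2], axis=2)
        b = b.ravel()
        if self.singular:
            b = b - self._null * (self._null @ b)
            b[0] = 0.0
        return self._lu.solve(b).reshape(self.grid.shape)

    def corrections(self, p: np.ndarray) -> list:
        """Velocity corrections beta grad(p) per axis, built from the same
        harmonic-mean face mobilities as the operator (each node takes the
        average of its two face fluxes), so a free node adjacent to a
        near-impermeable one is corrected through the face value, never
        through a raw central gradient across the jump."""
        out = []
        for a in range(self.grid.ndim):
            dx = self.grid.spacing[a]
            F = self.face_beta[a] * (np.roll(p, -1, axis=a) - p) / dx
            out.append(0.5 * (F + np.roll(F, 1, axis=a)))
        return out


def _z_eigenvalues(n: int, dz: float) -> np.ndarray:
    """Symbol of the 1D periodic second-difference operator for rfft modes."""
    m = np.arange(n // 2 + 1)
    return 4.0 * np.sin(math.pi * m / n) ** 2 / dz**2


class FactorizedHelmholtz:
    """LU-factorized (a I - b Lap) with the boundary handling above.

    On a 3D grid whose last axis is periodic, the solve is done mode-by-mode
    in z (real FFT): each mode reduces to a small 2D operator
    (a + b lam_m) I - b Lap_2D, which is dramatically cheaper to factor and
    apply than the full 3D LU.  Dirichlet boundary node sets are z-invariant
    cylinders, so the identity rows commute with the transform.
    """

    def __init__(self, grid: Grid, a: float, b: float, bcs) -> None:
        self.grid = grid
        self.a = float(a)
        self.b = float(b)
        self.bcs = normalize_bcs(grid, bcs)
        self.fast_z = grid.ndim == 3 and self.bcs[2][0] == "periodic"
        if self.fast_z:
            g2 = Grid(grid.shape[:2], grid.lengths[:2], grid.periodic[:2])
            L2, dmask2 = _laplacian_matrix(g2, self.bcs[:2])
            n2 = int(np.prod(g2.shape))
            dir2 = np.flatnonzero(dmask2.ravel())
            free_diag = np.ones(n2)
            free_diag[dir2] = 0.0
            self._lus = []
            self.singular = False
            self._null2 = None
            lams = _z_eigenvalues(grid.shape[2], grid.spacing[2])
            for m, lam in enumerate(lams):
                M = (self.a * sp.identity(n2, format="csr") - self.b * L2
                     + sp.diags(self.b * lam * free_diag)).tolil()
                if dir2.size:
                    M[dir2, :] = 0.0
                    M[dir2, dir2] = 1.0
                if m == 0 and self.a == 0.0 and dir2.size == 0:
                    self.singular = True
                    w = trapezoid_weights(g2).ravel()
                    self._null2 = w / np.linalg.norm(w)
                    M[0, :] = 0.0
                    M[0, 0] = 1.0
                self._lus.append(splu(M.tocsc()))
            self.dirichlet_mask = np.repeat(
                dmask2[:, :, None], grid.shape[2], axis=2)
            return
        L, dir_mask = _laplacian_matrix(grid, self.bcs)
        n = int(np.prod(grid.shape))
        M = (self.a * sp.identity(n, format="csr") - self.b * L).tolil()
        self.dirichlet_mask = dir_mask
        dir_idx = np.flatnonzero(dir_mask.ravel())
        if dir_idx.size:
            M[dir_idx, :] = 0.0
            M[dir_idx, dir_idx] = 1.0
        self.singular = (self.a == 0.0) and dir_idx.size == 0
        if self.singular:
            w = trapezoid_weights(grid).ravel()
            self._null = w / np.linalg.norm(w)
            M[0, :] = 0.0
            M[0, 0] = 1.0
        self._lu = splu(M.tocsc())

    def _solve_fast_z(self, b: np.ndarray) -> np.ndarray:
        shape = self.grid.shape
        bh = np.fft.rfft(b, axis=2)
        out = np.empty_like(bh)
        n2 = shape[0] * shape[1]
        for m, lu in enumerate(self._lus):
            rhs = bh[:, :, m].ravel()
            if m == 0 and self.singular:
                r = rhs.real - self._null2 * (self._null2 @ rhs.real)
                r[0] = 0.0
                out[:, :, m] = lu.solve(r).reshape(shape[:2])
                continue
            sol = lu.solve(rhs.real) + 1j * lu.solve(rhs.imag)
            out[:, :, m] = sol.reshape(shape[:2])
        return np.fft.irfft(out, n=shape[2], axis=2)

    def solve(self, rhs: np.ndarray, dirichlet_values=None) -> np.ndarray:
        """Solve for a full-grid field.  ``dirichlet_values`` (full field or
        scalar) supplies boundary values at dirichlet nodes."""
        b = np.array(rhs, dtype=float)
        if dirichlet_values is not None:
            mask = self.dirichlet_mask
            vals = (np.asarray(dirichlet_values, dtype=float)
                    if np.ndim(dirichlet_values) else
                    np.full(b.shape, float(dirichlet_values)))
            b[mask] = vals[mask]
        elif self.dirichlet_mask.any():
            b[self.dirichlet_mask] = 0.0
        if self.fast_z:
            return self._solve_fast_z(b)
        b = b.ravel()
        if self.singular:
            b = b - self._null * (self._null @ b)
            b[0] = 0.0
        return self._lu.solve(b).reshape(self.grid.shape)
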