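"""Coarse-grained platelet transport and aggregation (force-coupling style).

Platelets are point particles with finite-width Gaussian envelopes.  They
progress irreversibly through three states: passive (physiological radius
r_p = 1.5 um, non-adhesive), triggered (contact with a deposition site or an
activated platelet started the activation clock), and activated
(pseudo-platelet: platelet plus associated fibrin, radius grown to
r_eff = 60 r_p, adhesive).  Activated pairs attract through a Morse
potential and repel through a short-range exponential; parameters are binned
by local shear rate.  The interaction constants shipped here are placeholder
defaults scaled to balance viscous drag at a wall shear rate of ~100 1/s —
they require recalibration against aggregation data before quantitative use.

The Lagrangian aggregate is converted to an Eulerian volume-fraction field
through the same Gaussian envelopes,

    Psi_fcm(x) = sum_n V_p^n Delta(x - Y^n),   int Delta = 1,

and the thrombus volume fraction handed to the phase-field solver is
VF = [Psi_f(c_Fbg) + Psi_p(c_plat)] Psi_fcm.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field as dc_field, replace

import numpy as np

from .fields import Grid, integrate, laplacian
from .materials import fibrin_volume_fraction

__all__ = ["Platelet", "PlateletEnsemble", "FCMConfig", "seed_platelets",
           "update_states", "pairwise_forces", "advect_platelets",
           "stationarity", "fcm_volume_fraction", "thrombus_VF",
           "handoff_to_phasefield"]

PASSIVE, TRIGGERED, ACTIVATED = 0, 1, 2


@dataclass(frozen=True)
class FCMConfig:
    """Parameters of the coarse-grained aggregation stage (lengths in the
    scenario's nondimensional units unless noted)."""

    r_p: float = 0.005           # passive platelet radius
    r_eff_factor: float = 60.0   # pseudo-platelet growth factor
    tau_act: float = 0.2         # activation delay, seconds (range 0.1-0.3)
    capture_margin: float = 0.01
    # Morse well depth/width/equilibrium per shear-rate bin (low, high);
    # placeholder defaults, see module docstring
    shear_bins: tuple = (100.0,)         # bin edges, 1/s
    morse_depth: tuple = (5e-4, 2e-4)
    morse_beta: tuple = (30.0, 30.0)
    morse_r0_factor: float = 2.1         # equilibrium distance / r_eff
    repulsion_amplitude: float = 1e-3
    repulsion_length: float = 0.02
    envelope_factor: float = 1.0 / math.sqrt(math.pi)  # sigma = r/sqrt(pi)
    mobility: float = 1.0
    coupling: str = "one_way"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.1 <= self.tau_act <= 0.3):
            raise ValueError("tau_act must lie in [0.1, 0.3] s")
        for name in ("r_p", "repulsion_length", "capture_margin"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.coupling not in ("one_way", "two_way"):
            raise ValueError("coupling must be one_way or two_way")

    @property
    def r_eff(self) -> float:
        return self.r_eff_factor * self.r_p

    def morse_params(self, shear_rate: float) -> tuple:
        """(depth, beta, r0) for the local shear-rate bin."""
        k = int(np.searchsorted(self.shear_bins, shear_rate))
        k = min(k, len(self.morse_depth) - 1)
        return (self.morse_depth[k], self.morse_beta[k],
                self.morse_r0_factor * self.r_eff)

    def with_(self, **kw) -> "FCMConfig":
        return replace(self, **kw)


@dataclass
class Platelet:
    """Single-particle view (the ensemble stores arrays internally)."""

    position: np.ndarray
    velocity: np.ndarray
    radius: float
    state: int = PASSIVE
    trigger_time: float = math.nan
    displacement_history: list = dc_field(default_factory=list)


@dataclass
class PlateletEnsemble:
    """Struct-of-arrays platelet population."""

    x: np.ndarray                 # (n, 3) positions
    v: np.ndarray                 # (n, 3) velocities
    radius: np.ndarray            # (n,)
    state: np.ndarray             # (n,) int
    trigger_time: np.ndarray      # (n,), nan while passive
    frozen: np.ndarray            # (n,) bool: adhered / stationary
    ids: np.ndarray = None        # (n,) persistent particle ids
    history: list = dc_field(default_factory=list)  # positions per cycle mark

    def __post_init__(self) -> None:
        n = self.x.shape[0]
        if self.ids is None:
            self.ids = np.arange(n)
        for arr, nd in ((self.v, 2), (self.radius, 1), (self.state, 1),
                        (self.trigger_time, 1), (self.frozen, 1),
                        (self.ids, 1)):
            if arr.shape[0] != n:
                raise ValueError("ensemble array length mismatch")
        bad = (self.state == PASSIVE) & ~np.isnan(self.trigger_time)
        if np.any(bad):
            raise ValueError("trigger_time set on a passive platelet")

    @property
    def n(self) -> int:
        return self.x.shape[0]

    def copy(self) -> "PlateletEnsemble":
        return PlateletEnsemble(self.x.copy(), self.v.copy(),
                                self.radius.copy(), self.state.copy(),
                                self.trigger_time.copy(), self.frozen.copy(),
                                self.ids.copy(),
                                [h.copy() for h in self.history])


# --------------------------------------------------------------------------
# seeding
# --------------------------------------------------------------------------

def near_wall_profile(s: np.ndarray) -> np.ndarray:
    """Default marginated density vs normalized radial position s in [0, 1]
    (0 = axis, 1 = wall): piecewise-linear, peaked near the wall to emulate
    the enrichment caused by collisions with red cells."""
    return np.where(s < 0.6, 0.4, 0.4 + 3.0 * (s - 0.6) / 0.4)


def seed_platelets(domain, n: int, profile=near_wall_profile,
                   seed: int = 0, lumen_radius=None) -> PlateletEnsemble:
    """Place ``n`` passive platelets inside a cylindrical lumen.

    ``domain`` is (length, cy, cz) extents of the bounding box; the lumen is
    a tube of radius ``lumen_radius(x)`` (callable or constant, default:
    0.45 * min cross extent) about the box axis.  Radial positions are drawn
    from ``profile`` by rejection sampling; axial and angular positions are
    uniform.  Deterministic given ``seed``.
    """
    if n < 1:
        raise ValueError("need n >= 1")
    rng = np.random.default_rng(seed)
    L, Wy, Wz = domain
    cy, cz = Wy / 2.0, Wz / 2.0
    if lumen_radius is None:
        R0 = 0.45 * min(Wy, Wz)
        lumen_radius = lambda x: np.full(np.shape(x), R0)  # noqa: E731
    elif not callable(lumen_radius):
        R0 = float(lumen_radius)
        lumen_radius = lambda x: np.full(np.shape(x), R0)  # noqa: E731
    xs, ys, zs = [], [], []
    got = 0
    pmax = float(np.max(profile(np.linspace(0, 1, 257))))
    tries = 0
    while got < n:
        tries += 1
        if tries > 10000:
            raise RuntimeError("domain too small to place the requested "
                               "number of platelets")
        m = max(2 * (n - got), 64)
        x = rng.uniform(0, L, m)
        s = rng.uniform(0, 1, m)
        keep = rng.uniform(0, pmax, m) < profile(s)
        theta = rng.uniform(0, 2 * math.pi, m)
        R = lumen_radius(x) * 0.98  # strictly inside
        r = s * R
        x, r, theta = x[keep], r[keep], theta[keep]
        xs.append(x)
        ys.append(cy + r * np.cos(theta))
        zs.append(cz + r * np.sin(theta))
        got += len(x)
    X = np.column_stack([np.concatenate(xs)[:n], np.concatenate(ys)[:n],
                         np.concatenate(zs)[:n]])
    cfg = FCMConfig()
    return PlateletEnsemble(
        x=X, v=np.zeros_like(X), radius=np.full(n, cfg.r_p),
        state=np.full(n, PASSIVE, dtype=int),
        trigger_time=np.full(n, math.nan),
        frozen=np.zeros(n, dtype=bool))


# --------------------------------------------------------------------------
# state machine
# --------------------------------------------------------------------------

def update_states(ens: PlateletEnsemble, sites, t: float,
                  config: FCMConfig, site_geometry=None) -> PlateletEnsemble:
    """Advance the passive -> triggered -> activated state machine.

    Passive platelets touching a deposition site or an activated platelet
    (center distance < sum of radii + capture margin) become triggered at
    time ``t``; triggered platelets activate (radius -> r_eff) once
    t >= trigger_time + tau_act.  Transitions are irreversible.

    ``site_geometry(site, x) -> bool array`` decides site contact; by default
    a site must expose ``contains(x, angle)`` and the ensemble's bounding
    geometry is a cylinder around the x-axis with the site's capture radius
    measured from the wall (see :mod:`clotflow.scenarios`).
    """
    ens = ens.copy()
    # triggered -> activated on clock expiry
    expire = ((ens.state == TRIGGERED)
              & (t >= ens.trigger_time + config.tau_act))
    ens.state[expire] = ACTIVATED
    ens.radius[expire] = config.r_eff

    passive = ens.state == PASSIVE
    if not np.any(passive):
        return ens
    touched = np.zeros(ens.n, dtype=bool)
    act_idx = np.flatnonzero(ens.state == ACTIVATED)
    if act_idx.size:
        pas_idx = np.flatnonzero(passive)
        d = np.linalg.norm(ens.x[pas_idx, None, :] - ens.x[None, act_idx, :],
                           axis=2)
        reach = (ens.radius[pas_idx, None] + ens.radius[None, act_idx]
                 + config.capture_margin)
        touched[pas_idx[np.any(d < reach, axis=1)]] = True
    if sites:
        for site in sites:
            if site_geometry is not None:
                touched |= passive & site_geometry(site, ens.x)
            else:
                hit = _default_site_contact(site, ens.x, ens.radius, config)
                touched |= passive & hit
    newly = passive & touched
    ens.state[newly] = TRIGGERED
    ens.trigger_time[newly] = t
    return ens


def _default_site_contact(site, x: np.ndarray, radius: np.ndarray,
                          config: FCMConfig) -> np.ndarray:
    """Contact test for wall-patch sites on a unit-box cylindrical lumen:
    requires the site to carry ``lumen`` metadata (cy, cz, radius_fn)."""
    meta = getattr(site, "lumen", None)
    if meta is None:
        raise ValueError("deposition site lacks lumen geometry; pass "
                         "site_geometry explicitly")
    cy, cz, radius_fn = meta
    dy = x[:, 1] - cy
    dz = x[:, 2] - cz
    r = np.hypot(dy, dz)
    ang = np.arctan2(dz, dy) % (2 * math.pi)
    R = radius_fn(x[:, 0])
    near_wall = (R - r) < (site.capture_radius + radius
                           + config.capture_margin)
    in_patch = np.array([site.contains(xi, ai)
                         for xi, ai in zip(x[:, 0], ang)])
    return near_wall & in_patch


# --------------------------------------------------------------------------
# interactions
# --------------------------------------------------------------------------

def morse_force_mag(r: np.ndarray, depth: float, beta: float,
                    r0: float) -> np.ndarray:
    """Radial derivative -dU/dr of the Morse potential
    U = depth [exp(-2 beta (r - r0)) - 2 exp(-beta (r - r0))]; positive is
    repulsive (pushes the pair apart)."""
    e = np.exp(-beta * (r - r0))
    return 2.0 * depth * beta * (e**2 - e)


def pairwise_forces(ens: PlateletEnsemble, config: FCMConfig,
                    local_shear_rate: float = 0.0) -> np.ndarray:
    """Morse + exponential-repulsion forces between ACTIVATED pairs.

    The cutoff is 5/beta beyond the Morse equilibrium distance; pairs
    farther apart contribute exactly zero.  Newton's third law holds to
    machine precision by construction.  Coincident centers get a capped
    repulsion along a deterministic axis with a warning.
    """
    F = np.zeros_like(ens.x)
    idx = np.flatnonzero(ens.state == ACTIVATED)
    if idx.size < 2:
        return F
    depth, beta, r0 = config.morse_params(local_shear_rate)
    cutoff = r0 + 5.0 / beta
    X = ens.x[idx]
    # cell-list neighbor search with deterministic ordering
    pairs = _neighbor_pairs(X, cutoff)
    if pairs.size == 0:
        return F
    i, j = pairs[:, 0], pairs[:, 1]
    dx = X[j] - X[i]
    r = np.linalg.norm(dx, axis=1)
    coincident = r < 1e-12
    if np.any(coincident):
        warnings.warn("coincident platelet centers: capped repulsion applied",
                      RuntimeWarning, stacklevel=2)
        dx[coincident] = np.array([1.0, 0.0, 0.0])
        r[coincident] = 1e-12
    rhat = dx / r[:, None]
    mag = morse_force_mag(r, depth, beta, r0)
    mag = mag + config.repulsion_amplitude * np.exp(
        -r / config.repulsion_length)
    cap = 100.0 * depth * beta
    mag = np.clip(mag, -cap, cap)
    mag[r > cutoff] = 0.0
    fij = -mag[:, None] * rhat  # force ON i FROM j (negative mag attracts)
    np.add.at(F, idx[i], fij)
    np.add.at(F, idx[j], -fij)
    return F


def _neighbor_pairs(X: np.ndarray, cutoff: float) -> np.ndarray:
    """Unique index pairs with |Xi - Xj| possibly < cutoff, via a uniform
    cell list with cell size = cutoff; deterministic ordering."""
    n = len(X)
    if n < 2:
        return np.empty((0, 2), dtype=int)
    cells = np.floor(X / cutoff).astype(int)
    from collections import defaultdict
    table = defaultdict(list)
    for k in range(n):
        table[tuple(cells[k])].append(k)
    out = []
    offsets = [(a, b, c) for a in (-1, 0, 1) for b in (-1, 0, 1)
               for c in (-1, 0, 1)]
    for key in sorted(table):
        members = table[key]
        for off in offsets:
            nk = (key[0] + off[0], key[1] + off[1], key[2] + off[2])
            if nk < key:
                continue
            other = table.get(nk)
            if other is None:
                continue
            if nk == key:
                out += [(i, j) for ii, i in enumerate(members)
                        for j in members[ii + 1:]]
            else:
                out += [(i, j) if i < j else (j, i)
                        for i in members for j in other]
    if not out:
        return np.empty((0, 2), dtype=int)
    return np.unique(np.array(out, dtype=int), axis=0)


# --------------------------------------------------------------------------
# transport
# --------------------------------------------------------------------------

def envelope_average_velocity(flow_field, grid: Grid, pos: np.ndarray,
                              sigma: float) -> np.ndarray:
    """Gaussian-envelope-weighted average of the fluid velocity at one
    particle position (quadrature over the grid)."""
    Xs = grid.meshgrid()
    r2 = sum((Xs[a] - pos[a]) ** 2 for a in range(grid.ndim))
    w = np.exp(-r2 / (2.0 * sigma**2))
    wsum = integrate(w, grid)
    return np.array([integrate(w * flow_field[a], grid) / wsum
                     for a in range(grid.ndim)])


def advect_platelets(ens: PlateletEnsemble, flow, dt: float,
                     config: FCMConfig, forces: np.ndarray = None,
                     domain=None) -> PlateletEnsemble:
    """Explicit Euler transport step.

    Particle velocity = envelope-averaged fluid velocity at the particle
    position plus mobility x interaction force; frozen (adhered) platelets
    do not move.  ``flow`` is either a callable pos -> velocity array or a
    (fields, grid) pair, in which case the Gaussian envelope average is
    evaluated by grid quadrature.  Platelets leaving ``domain`` (per-axis
    (lo, hi) bounds) are removed and counted in ``ens.meta``-style history.
    """
    ens = ens.copy()
    n = ens.n
    if callable(flow):
        uf = np.array([flow(ens.x[k]) for k in range(n)])
    elif flow is None:
        uf = np.zeros_like(ens.x)
    else:
        fields, grid = flow
        uf = np.zeros((n, 3))
        for k in range(n):
            sigma = config.envelope_factor * ens.radius[k]
            uf[k, :grid.ndim] = envelope_average_velocity(
                fields, grid, ens.x[k][:grid.ndim], sigma)
    v = uf
    if forces is not None:
        v = v + config.mobility * forces
    v[ens.frozen] = 0.0
    ens.v = v
    ens.x = ens.x + dt * v
    if domain is not None:
        keep = np.ones(n, dtype=bool)
        for a, (lo, hi) in enumerate(domain):
            keep &= (ens.x[:, a] >= lo) & (ens.x[:, a] <= hi)
        if not np.all(keep):
            ens = PlateletEnsemble(
                ens.x[keep], ens.v[keep], ens.radius[keep], ens.state[keep],
                ens.trigger_time[keep], ens.frozen[keep], ens.ids[keep],
                [h[keep] if len(h) == n else h for h in ens.history])
    return ens


def stationarity(displacement: float, diameter: float) -> bool:
    """Adhesion rule: a platelet is part of the thrombus once its net
    displacement over one full cardiac cycle is below diameter/100."""
    if diameter <= 0:
        raise ValueError("diameter must be > 0")
    return displacement < diameter / 100.0


def mark_stationary(ens: PlateletEnsemble, cycle_start) -> PlateletEnsemble:
    """Freeze activated platelets whose displacement over the last cycle
    satisfies the stationarity rule.

    ``cycle_start`` maps particle id -> position at the cycle start (robust
    to particles deleted at the outlet during the cycle); an (n, 3) array is
    also accepted when no particle was removed.
    """
    ens = ens.copy()
    if isinstance(cycle_start, dict):
        disp = np.full(ens.n, np.inf)
        for k, pid in enumerate(ens.ids):
            x0 = cycle_start.get(int(pid))
            if x0 is not None:
                disp[k] = np.linalg.norm(ens.x[k] - x0)
    else:
        disp = np.linalg.norm(ens.x - cycle_start, axis=1)
    stat = np.array([stationarity(d, 2.0 * r) if np.isfinite(d) else False
                     for d, r in zip(disp, ens.radius)])
    ens.frozen |= stat & (ens.state == ACTIVATED)
    return ens


# --------------------------------------------------------------------------
# Lagrangian -> Eulerian conversion
# --------------------------------------------------------------------------

def fcm_volume_fraction(ens: PlateletEnsemble, grid: Grid,
                        config: FCMConfig) -> np.ndarray:
    """Psi_fcm(x) = sum_n V_p^n Delta(x - Y^n) with normalized Gaussian
    envelopes Delta (int Delta = 1).  Requires >= 3 cells per envelope
    standard deviation."""
    sigma_min = config.envelope_factor * float(np.min(ens.radius))
    hmax = max(grid.spacing)
    if sigma_min < 3.0 * hmax:
        raise ValueError(
            f"under-resolved envelope: sigma = {sigma_min:.3g} needs grid "
            f"spacing <= {sigma_min / 3.0:.3g} (current max {hmax:.3g})")
    Xs = grid.meshgrid()
    out = np.zeros(grid.shape)
    d = grid.ndim
    for k in range(ens.n):
        sigma = config.envelope_factor * ens.radius[k]
        Vp = 4.0 / 3.0 * math.pi * ens.radius[k] ** 3
        r2 = sum((Xs[a] - ens.x[k, a]) ** 2 for a in range(d))
        out += (Vp * np.exp(-r2 / (2.0 * sigma**2))
                / (2.0 * math.pi * sigma**2) ** (d / 2.0))
    return out


def thrombus_VF(psi_fcm: np.ndarray, c_Fbg: float, c_plat: float,
                config: FCMConfig, rho_Fbg: float = 1400.0) -> np.ndarray:
    """VF = [Psi_f(c_Fbg) + Psi_p(c_plat)] Psi_fcm, clipped to [0, 1).

    Psi_p is evaluated directly from the single-platelet volume and the
    local platelet number density; the clipped fraction is reported via a
    warning when it exceeds 1% of nodes.
    """
    if c_Fbg < 0 or c_plat < 0:
        raise ValueError("concentrations must be >= 0")
    psi_f = fibrin_volume_fraction(c_Fbg, rho_Fbg) if c_Fbg > 0 else 0.0
    v_p = 4.0 / 3.0 * math.pi * config.r_p**3
    psi_p = c_plat * v_p
    vf = (psi_f + psi_p) * psi_fcm
    clipped = np.mean(vf >= 1.0)
    if clipped > 0.01:
        warnings.warn(f"thrombus VF clipped on {100 * clipped:.1f}% of nodes",
                      RuntimeWarning, stacklevel=2)
    return np.clip(vf, 0.0, 1.0 - 1e-9)


def handoff_to_phasefield(vf_field: np.ndarray, grid: Grid,
                          h: float) -> np.ndarray:
    """phi0 = 1 - VF followed by diffusion smoothing at length scale h.

    The smoother is explicit heat-equation sub-stepping with zero-flux
    boundaries: it conserves int(1 - phi0), obeys the maximum principle
    (phi0 stays in [0, 1]) and regularizes the handoff field on the scale of
    the phase interface thickness.
    """
    phi0 = 1.0 - np.clip(vf_field, 0.0, 1.0)
    hmin = min(grid.spacing)
    T = 0.5 * h**2  # Gaussian smoothing width = h
    dt_max = hmin**2 / (4.0 * grid.ndim)  # explicit stability
    nsub = max(1, int(math.ceil(T / dt_max)))
    dt = T / nsub
    for _ in range(nsub):
        phi0 = phi0 + dt * laplacian(phi0, grid, bc="mirror")
    return np.clip(phi0, 0.0, 1.0)


# --------------------------------------------------------------------------
# scaled-down aggregation driver
# --------------------------------------------------------------------------

def simulate_aggregation(sites, config: FCMConfig, domain,
                         lumen_radius_fn, n_platelets: int = 300,
                         cycles: int = 3, steps_per_cycle: int = 40,
                         period: float = 1.0, inlet_scale=None,
                         seed: int = 0) -> dict:
    """Desk-scale aggregation run with a prescribed (one-way) lumen flow.

    The flow is an axial quasi-Poiseuille profile
    u_x = s(t) (1 - (r/R(x))^2) scaled by the waveform ``inlet_scale(t)``
    (defaults to the generic pulsatile waveform); platelet-flow coupling is
    one-way, interactions act between activated pseudo-platelets, and the
    stationarity rule is applied at each cycle boundary.  Returns the final
    ensemble plus counts per state and the fraction of stationary platelets
    within two capture radii of a deposition site.
    """
    from .scenarios import pulsatile_waveform
    if inlet_scale is None:
        inlet_scale = lambda t: pulsatile_waveform(t, period=period)  # noqa: E731
    L, Wy, Wz = domain
    cy, cz = Wy / 2.0, Wz / 2.0
    ens = seed_platelets(domain, n_platelets, seed=seed,
                         lumen_radius=lumen_radius_fn)
    dt = period / steps_per_cycle
    t = 0.0
    removed = 0

    def flow(pos):
        r = math.hypot(pos[1] - cy, pos[2] - cz)
        R = float(lumen_radius_fn(pos[0]))
        s = max(0.0, 1.0 - (r / R) ** 2)
        return np.array([float(inlet_scale(t)) * s, 0.0, 0.0])

    for cyc in range(cycles):
        x_start = {int(pid): ens.x[k].copy()
                   for k, pid in enumerate(ens.ids)}
        for k in range(steps_per_cycle):
            ens = update_states(ens, sites, t, config)
            # bond formation: activated platelets touching a deposition site
            # or an already-adhered platelet stick to the forming aggregate
            act = ens.state == ACTIVATED
            if np.any(act):
                touch = np.zeros(ens.n, dtype=bool)
                for site in sites:
                    touch |= _default_site_contact(site, ens.x, ens.radius,
                                                   config)
                fro = np.flatnonzero(ens.frozen)
                if fro.size:
                    ai = np.flatnonzero(act & ~ens.frozen)
                    if ai.size:
                        dmat = np.linalg.norm(
                            ens.x[ai, None, :] - ens.x[None, fro, :], axis=2)
                        reach = (ens.radius[ai, None] + ens.radius[None, fro]
                                 + config.capture_margin)
                        touch[ai[np.any(dmat < reach, axis=1)]] = True
                ens.frozen |= act & touch
            F = pairwise_forces(ens, config)
            n_before = ens.n
            ens = advect_platelets(ens, flow, dt, config, forces=F,
                                   domain=((0.0, L), (0.0, Wy), (0.0, Wz)))
            removed += n_before - ens.n
            # confine to the lumen (impermeable wall)
            dy = ens.x[:, 1] - cy
            dz = ens.x[:, 2] - cz
            r = np.hypot(dy, dz)
            R = np.asarray(lumen_radius_fn(ens.x[:, 0]), dtype=float)
            out = r > 0.98 * R
            if np.any(out):
                scale = 0.98 * R[out] / r[out]
                ens.x[out, 1] = cy + dy[out] * scale
                ens.x[out, 2] = cz + dz[out] * scale
            t += dt
        ens = mark_stationary(ens, x_start)
    stats = {"n": ens.n, "removed": removed,
             "passive": int(np.sum(ens.state == PASSIVE)),
             "triggered": int(np.sum(ens.state == TRIGGERED)),
             "activated": int(np.sum(ens.state == ACTIVATED)),
             "stationary": int(np.sum(ens.frozen))}
    if stats["stationary"]:
        frozen_x = ens.x[ens.frozen]
        near = np.zeros(len(frozen_x), dtype=bool)
        for site in sites:
            x1, x2 = site.x_interval
            pad = 2.0 * site.capture_radius
            near |= ((frozen_x[:, 0] >= x1 - pad)
                     & (frozen_x[:, 0] <= x2 + pad))
        stats["stationary_near_sites"] = float(np.mean(near))
    return {"ensemble": ens, "stats": stats, "time": t}
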