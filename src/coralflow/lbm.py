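"""D3Q19 lattice-Boltzmann flow solver with BGK collision.

The solver reproduces the standard single-relaxation-time scheme on a
regular voxel grid:

* collision relaxes each of the 19 distributions ``f_i`` toward the
  low-Mach equilibrium with relaxation time ``tau``;
* streaming propagates distributions along the discrete velocities;
* solid voxels act through half-way bounce-back (no-slip walls placed
  half a cell outside the first fluid cell);
* the simulated ocean-current box uses the submerged-branch boundary set:
  velocity inlet with an open-channel profile, constant-pressure outlet,
  periodic transverse sides, free-slip top (sea surface) and no-slip
  bottom (seabed).

Lattice-to-physical conversion follows the characteristic lattice velocity
``C = dl/dt``; kinematic viscosity maps as ``nu = C^2 dt (tau - 1/2) / 3``
and pressure as ``p = C^2 rho / 3`` (kinematic pressure, m^2/s^2).

The per-step kernels are compiled with numba; the moment/equilibrium
helpers are plain numpy and serve as the reference definitions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .geometry import SOLID, VoxelGeometry

# --- D3Q19 stencil ----------------------------------------------------------
# index 0: rest; 1-6: axis directions; 7-18: face diagonals
E = np.array(
    [
        [0, 0, 0],
        [1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1],
        [1, 1, 0], [-1, -1, 0], [1, -1, 0], [-1, 1, 0],
        [1, 0, 1], [-1, 0, -1], [1, 0, -1], [-1, 0, 1],
        [0, 1, 1], [0, -1, -1], [0, 1, -1], [0, -1, 1],
    ],
    dtype=np.int64,
)
W = np.array([1 / 3] + [1 / 18] * 6 + [1 / 36] * 12, dtype=np.float64)

def _find(v):
    return int(np.where((E == v).all(axis=1))[0][0])

OPP = np.array([_find(-E[i]) for i in range(19)], dtype=np.int64)
ZFLIP = np.array([_find(E[i] * np.array([1, 1, -1])) for i in range(19)], dtype=np.int64)


class InstabilityError(RuntimeError):
    """Raised when the lattice state develops NaNs or non-positive density."""


def equilibrium(density, velocity, i=None, c: float = 1.0):
    """Low-Mach equilibrium distribution.

    ``f_i^eq = w_i rho (1 + 3 e_i.u/C^2 + 9 (e_i.u)^2/(2 C^4) - 3 u^2/(2 C^2))``
    with ``e_i`` the lattice velocity of magnitude ``C`` along direction
    ``i``.  ``density`` may be a scalar or an array of shape ``S``;
    ``velocity`` has shape ``S + (3,)``.  Returns shape ``S + (19,)`` or
    ``S`` when a single direction ``i`` is requested.
    """
    rho = np.asarray(density, dtype=np.float64)
    u = np.asarray(velocity, dtype=np.float64)
    dirs = E if i is None else E[i : i + 1] if np.isscalar(i) else E[i]
    w = W if i is None else W[i : i + 1] if np.isscalar(i) else W[i]
    eu = np.tensordot(u, dirs.T * c, axes=([-1], [0]))  # S + (ndir,)
    u2 = np.sum(u * u, axis=-1)[..., None]
    feq = w * rho[..., None] * (
        1.0 + 3.0 * eu / c**2 + 4.5 * eu**2 / c**4 - 1.5 * u2 / c**2
    )
    if np.isscalar(i):
        return feq[..., 0] if feq.ndim > 1 else float(feq[0])
    return feq


def moments(f, c: float = 1.0):
    """Density and velocity moments: ``rho = sum f_i``, ``u = sum f_i e_i / rho``."""
    f = np.asarray(f, dtype=np.float64)
    rho = f.sum(axis=-1)
    mom = np.tensordot(f, E.astype(np.float64) * c, axes=([-1], [0]))
    u = mom / rho[..., None]
    return rho, u


@dataclass
class FlowConfig:
    """Physical flow conditions and run control for the submerged-branch box.

    Parameters
    ----------
    u_inlet
        Maximum inlet velocity (m/s) of the ambient current.
    nu
        Kinematic viscosity of seawater (m^2/s).
    width
        Characteristic branch width W (m) used in the Reynolds number.
    inlet_profile
        ``"half_poiseuille"`` (zero at the bed, zero shear at the surface),
        ``"power_law"`` (1/7 profile) or ``"uniform"``.
    u_lattice
        Target lattice inlet speed; sets the time step (low-Mach contract
        requires < 0.1).
    tol
        Quasi-steady tolerance on the windowed relative change of
        domain-average kinetic energy.
    """

    u_inlet: float = 0.0009
    nu: float = 1.0e-6
    width: float = 0.012
    inlet_profile: str = "half_poiseuille"
    u_lattice: float = 0.04
    tau_bounds: tuple[float, float] = (0.55, 1.2)
    max_steps: int = 8000
    ramp_steps: int = 400
    check_every: int = 50
    tol: float = 2.0e-5
    steady_checks: int = 4
    monitor_points: list[tuple[int, int, int]] = field(default_factory=list)


def reynolds(u_inlet: float, width: float, nu: float) -> float:
    """Reynolds number ``Re = |u_inlet| W / nu`` of the ambient flow."""
    return abs(u_inlet) * width / nu


def resolve_lattice_units(dl: float, config: FlowConfig):
    """Choose the time step and relaxation time for a voxel spacing ``dl``.

    Sets ``dt`` from the target lattice inlet speed, derives
    ``tau = 3 nu dt / dl^2 + 1/2`` and, if it falls outside the accuracy
    window, re-adjusts ``dt`` to pin ``tau`` at the nearest bound.
    Returns ``(dt, tau, u_lat)``.
    """
    if config.u_inlet > 0:
        dt = config.u_lattice * dl / config.u_inlet
    else:
        dt = dl**2 / (6.0 * config.nu)  # tau = 1 for quiescent runs
    tau = 3.0 * config.nu * dt / dl**2 + 0.5
    lo, hi = config.tau_bounds
    if not lo <= tau <= hi:
        tau = min(max(tau, lo), hi)
        dt = (tau - 0.5) * dl**2 / (3.0 * config.nu)
    u_lat = config.u_inlet * dt / dl
    if u_lat > 0.1:
        warnings.warn(
            f"lattice inlet speed {u_lat:.3f} exceeds the low-Mach limit 0.1; "
            "refine the grid or lower u_inlet"
        )
    return dt, tau, u_lat


@dataclass
class LatticeState:
    """Distribution functions plus the lattice/physical conversion context."""

    f: np.ndarray           # (nx, ny, nz, 19)
    solid: np.ndarray       # (nx, ny, nz) bool
    dl: float               # voxel edge (m)
    dt: float               # time step (s)
    tau: float              # relaxation time (lattice)

    @property
    def C(self) -> float:
        """Characteristic lattice velocity ``dl/dt`` (m/s)."""
        return self.dl / self.dt

    @property
    def nu(self) -> float:
        """Kinematic viscosity implied by tau: ``C^2 dt (tau - 1/2)/3``."""
        return self.C**2 * self.dt * (self.tau - 0.5) / 3.0


@dataclass
class FlowField:
    """Macroscopic fields in physical units on the voxel grid."""

    velocity: np.ndarray    # (nx, ny, nz, 3), m/s, zero on solid
    density: np.ndarray     # lattice density (dimensionless, ~1)
    pressure: np.ndarray    # kinematic pressure C^2 rho / 3, m^2/s^2
    spacing: float          # m
    solid: np.ndarray       # bool mask
    time: float = 0.0       # physical time (s)

    @property
    def speed(self) -> np.ndarray:
        return np.sqrt((self.velocity**2).sum(axis=-1))


def macroscopics(state: LatticeState) -> FlowField:
    """Convert a lattice state to physical macroscopic fields."""
    rho, u_lat = moments(state.f)
    if np.any(~np.isfinite(rho)) or np.any(rho[~state.solid] <= 0):
        raise InstabilityError("non-positive or non-finite density encountered")
    u = u_lat * state.C
    u[state.solid] = 0.0
    p = state.C**2 * rho / 3.0
    return FlowField(velocity=u, density=rho, pressure=p, spacing=state.dl,
                     solid=state.solid.copy())


# --- numba kernels ----------------------------------------------------------

@njit(cache=True)
def _collide_kernel(f, fpost, solid, tau, gx, gy, gz, ex, ey, ez, w):
    nx, ny, nz, q = f.shape
    omega = 1.0 / tau
    guo = 1.0 - 0.5 * omega
    forced = gx != 0.0 or gy != 0.0 or gz != 0.0
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                if solid[x, y, z]:
                    for i in range(q):
                        fpost[x, y, z, i] = f[x, y, z, i]
                    continue
                rho = 0.0
                mx = 0.0
                my = 0.0
                mz = 0.0
                for i in range(q):
                    fi = f[x, y, z, i]
                    rho += fi
                    mx += fi * ex[i]
                    my += fi * ey[i]
                    mz += fi * ez[i]
                fx = rho * gx
                fy = rho * gy
                fz = rho * gz
                ux = (mx + 0.5 * fx) / rho
                uy = (my + 0.5 * fy) / rho
                uz = (mz + 0.5 * fz) / rho
                usq = ux * ux + uy * uy + uz * uz
                for i in range(q):
                    eu = ex[i] * ux + ey[i] * uy + ez[i] * uz
                    feq = w[i] * rho * (1.0 + 3.0 * eu + 4.5 * eu * eu - 1.5 * usq)
                    out = f[x, y, z, i] + omega * (feq - f[x, y, z, i])
                    if forced:
                        ef = ex[i] * fx + ey[i] * fy + ez[i] * fz
                        uf = ux * fx + uy * fy + uz * fz
                        out += guo * w[i] * (3.0 * (ef - uf) + 9.0 * eu * ef)
                    fpost[x, y, z, i] = out


@njit(cache=True)
def _stream_kernel(fpost, fnew, solid, ex, ey, ez, opp, zflip,
                   periodic_x, periodic_z):
    nx, ny, nz, q = fpost.shape
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                if solid[x, y, z]:
                    for i in range(q):
                        fnew[x, y, z, i] = fpost[x, y, z, i]
                    continue
                for i in range(q):
                    sx = x - ex[i]
                    sy = y - ey[i]
                    sz = z - ez[i]
                    j = i
                    if sy < 0:
                        sy += ny
                    elif sy >= ny:
                        sy -= ny
                    if periodic_x:
                        if sx < 0:
                            sx += nx
                        elif sx >= nx:
                            sx -= nx
                    else:
                        if sx < 0:
                            sx = 0        # zero-gradient; inlet layer re-imposed after
                        elif sx >= nx:
                            sx = nx - 1   # zero-gradient; outlet layer re-imposed after
                    if periodic_z:
                        if sz < 0:
                            sz += nz
                        elif sz >= nz:
                            sz -= nz
                    else:
                        if sz < 0:
                            # seabed: half-way no-slip bounce-back
                            fnew[x, y, z, i] = fpost[x, y, z, opp[i]]
                            continue
                        elif sz >= nz:
                            # sea surface: free-slip specular reflection
                            j = zflip[i]
                            sz = nz - 1
                    if solid[sx, sy, sz]:
                        fnew[x, y, z, i] = fpost[x, y, z, opp[i]]
                    else:
                        fnew[x, y, z, i] = fpost[sx, sy, sz, j]


class LBMSimulation:
    """Stepping engine: collision, streaming and the boundary set.

    ``periodic_x``/``periodic_z`` switch the inlet/outlet and bed/surface
    boundaries to fully periodic ones (used by the physics validation
    cases); ``body_force`` is a constant acceleration in lattice units
    applied with Guo forcing.
    """

    def __init__(self, solid: np.ndarray, tau: float,
                 periodic_x: bool = False, periodic_z: bool = False,
                 body_force: tuple[float, float, float] = (0.0, 0.0, 0.0),
                 inlet_velocity: np.ndarray | None = None,
                 outlet_density: float = 1.0,
                 ramp_steps: int = 0):
        self.solid = np.ascontiguousarray(solid.astype(np.bool_))
        self.shape = self.solid.shape
        self.tau = float(tau)
        if self.tau <= 0.5:
            raise ValueError("BGK stability requires tau > 0.5")
        self.periodic_x = bool(periodic_x)
        self.periodic_z = bool(periodic_z)
        self.body_force = tuple(float(g) for g in body_force)
        # inlet_velocity: (ny, nz, 3) lattice velocity profile at x = 0
        self.inlet_velocity = inlet_velocity
        self.outlet_density = float(outlet_density)
        self.ramp_steps = int(ramp_steps)
        self.step_count = 0
        nx, ny, nz = self.shape
        self.f = np.empty((nx, ny, nz, 19), dtype=np.float64)
        self.f[:] = W  # equilibrium cold start at rho = 1, u = 0
        self._fpost = np.empty_like(self.f)
        self._fnew = np.empty_like(self.f)
        self._ex = np.ascontiguousarray(E[:, 0].astype(np.float64))
        self._ey = np.ascontiguousarray(E[:, 1].astype(np.float64))
        self._ez = np.ascontiguousarray(E[:, 2].astype(np.float64))
        self._exi = np.ascontiguousarray(E[:, 0])
        self._eyi = np.ascontiguousarray(E[:, 1])
        self._ezi = np.ascontiguousarray(E[:, 2])

    def initialize(self, density=1.0, velocity=(0.0, 0.0, 0.0)):
        """Set ``f`` to the equilibrium of the given macroscopic fields."""
        nx, ny, nz = self.shape
        rho = np.broadcast_to(np.asarray(density, dtype=np.float64), (nx, ny, nz))
        u = np.broadcast_to(np.asarray(velocity, dtype=np.float64), (nx, ny, nz, 3))
        self.f[:] = equilibrium(rho, u)
        self.step_count = 0

    def _ramp(self) -> float:
        if self.ramp_steps <= 0:
            return 1.0
        return min(1.0, self.step_count / self.ramp_steps)

    def _apply_open_boundaries(self):
        if self.periodic_x:
            return
        nx = self.shape[0]
        if self.inlet_velocity is not None:
            u_in = self.inlet_velocity * self._ramp()
            self.f[0] = equilibrium(np.ones(u_in.shape[:-1]), u_in)
        # constant-pressure outlet: fixed density, zero-gradient velocity
        rho_n, u_n = moments(self.f[nx - 2])
        u_n[self.solid[nx - 2]] = 0.0
        self.f[nx - 1] = equilibrium(
            np.full(u_n.shape[:-1], self.outlet_density), u_n
        )

    def step(self, n: int = 1):
        gx, gy, gz = self.body_force
        for _ in range(n):
            _collide_kernel(self.f, self._fpost, self.solid, self.tau,
                            gx, gy, gz, self._ex, self._ey, self._ez, W)
            _stream_kernel(self._fpost, self._fnew, self.solid,
                           self._exi, self._eyi, self._ezi, OPP, ZFLIP,
                           self.periodic_x, self.periodic_z)
            self.f, self._fnew = self._fnew, self.f
            self.step_count += 1
            self._apply_open_boundaries()
        return self

    def total_mass(self) -> float:
        return float(self.f[~self.solid].sum())

    def macroscopic(self):
        """Lattice-unit density and velocity (zero on solid)."""
        rho, u = moments(self.f)
        u[self.solid] = 0.0
        return rho, u

    def kinetic_energy(self) -> float:
        """Domain-average kinetic energy per fluid cell, lattice units."""
        rho, u = self.macroscopic()
        fluid = ~self.solid
        return float(0.5 * (rho[fluid] * (u[fluid] ** 2).sum(axis=-1)).mean())


def _inlet_profile(ny: int, nz: int, u_max: float, kind: str) -> np.ndarray:
    """Lattice inlet velocity profile (ny, nz, 3), x-directed."""
    zeta = (np.arange(nz) + 0.5) / nz  # bed at zeta=0, surface at zeta=1
    if kind == "half_poiseuille":
        ux = u_max * (2.0 * zeta - zeta**2)
    elif kind == "power_law":
        ux = u_max * zeta ** (1.0 / 7.0)
    elif kind == "uniform":
        ux = np.full(nz, u_max)
    else:
        raise ValueError(f"unknown inlet profile {kind!r}")
    prof = np.zeros((ny, nz, 3))
    prof[:, :, 0] = ux[None, :]
    return prof


def run_to_quasi_steady(geometry: VoxelGeometry, config: FlowConfig):
    """Simulate the submerged branch until the kinetic energy plateaus.

    Iterates collide/stream/boundaries, monitoring the domain-average
    kinetic energy every ``config.check_every`` steps; the run is declared
    quasi-steady once the windowed relative change stays below
    ``config.tol`` for ``config.steady_checks`` consecutive checks (after
    the inlet ramp).  Returns ``(FlowField, trace)`` where ``trace`` holds
    the kinetic-energy series, probe-point series and convergence flag.
    """
    solid = geometry.labels == SOLID
    nx, ny, nz = solid.shape
    dl = geometry.spacing
    dt, tau, u_lat = resolve_lattice_units(dl, config)
    sim = LBMSimulation(
        solid, tau,
        inlet_velocity=_inlet_profile(ny, nz, u_lat, config.inlet_profile),
        ramp_steps=config.ramp_steps,
    )
    trace = {
        "step": [], "time": [], "kinetic_energy": [],
        "monitors": {pt: [] for pt in map(tuple, config.monitor_points)},
        "converged": False, "dt": dt, "dl": dl, "tau": tau, "u_lattice": u_lat,
    }
    ke_prev = None
    steady = 0
    while sim.step_count < config.max_steps:
        sim.step(config.check_every)
        ke = sim.kinetic_energy()
        if not np.isfinite(ke):
            raise InstabilityError(
                f"diverged at step {sim.step_count}: tau={tau:.3f}, "
                f"lattice inlet speed={u_lat:.3f}"
            )
        trace["step"].append(sim.step_count)
        trace["time"].append(sim.step_count * dt)
        trace["kinetic_energy"].append(ke)
        if trace["monitors"]:
            rho, u = sim.macroscopic()
            C = dl / dt
            for pt in trace["monitors"]:
                ux, uy, uz = u[pt] * C
                trace["monitors"][pt].append(
                    (ux, uy, uz, C**2 * rho[pt] / 3.0)
                )
        if ke_prev is not None and sim.step_count > config.ramp_steps:
            rel = abs(ke - ke_prev) / max(ke, 1e-300)
            steady = steady + 1 if rel < config.tol else 0
            if steady >= config.steady_checks:
                trace["converged"] = True
                break
        ke_prev = ke
    if not trace["converged"]:
        warnings.warn("flow did not reach the quasi-steady tolerance; "
                      "returning the final field flagged unconverged")
    state = LatticeState(f=sim.f, solid=solid, dl=dl, dt=dt, tau=tau)
    fld = macroscopics(state)
    fld.time = sim.step_count * dt
    return fld, trace
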