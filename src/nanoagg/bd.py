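"""Brownian/Langevin dynamics of spherical nanoparticle beads.

Each nanoparticle is a single bead with stoichiometric mass, interacting
through a tabulated pairwise potential in a cubic periodic box.  The
equation of motion is Langevin's — Newtonian forces plus Stokes friction
gamma = 6*pi*mu*R/m and a fluctuation-dissipation-balanced Gaussian
noise — integrated with the impulse scheme: a full force kick followed
by an exact Ornstein-Uhlenbeck velocity update,

    v' = v + (F/m) dt
    v  = exp(-gamma dt) v' + sqrt(kBT/m (1 - exp(-2 gamma dt))) xi,

which has the exact stationary velocity variance kBT/m for free
particles at any timestep.

Internal units: nm, ps, kJ/mol, u (1 u nm^2 ps^-2 = 1 kJ/mol).
Hydrodynamic interactions between particles are neglected; they enter
the kinetics theory only through the B(h) correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .constants import AMU_KG, KB_KJ_MOL_K
from .potentials import TabulatedPotential

__all__ = [
    "ParticleSpec",
    "SimulationState",
    "BDConfig",
    "Trajectory",
    "stokes_friction",
    "maxwell_velocities",
    "compute_forces",
    "bd_step",
    "run_simulation",
]


def stokes_friction(radius: float, mu: float, mass: float) -> float:
    """Stokes friction rate gamma (ps^-1) of a bead in a viscous fluid.

    gamma = 6*pi*mu*R / (m*u) converted from s^-1 to ps^-1, with R in nm,
    mu in Pa s, m in u and u = 1.66054e-27 kg the atomic mass unit.
    """
    if min(radius, mu, mass) <= 0:
        raise ValueError("radius, mu and mass must be positive")
    gamma_si = 6.0 * math.pi * mu * (radius * 1e-9) / (mass * AMU_KG)
    return gamma_si * 1e-12


@dataclass
class ParticleSpec:
    """One bead species: radius (nm), mass (u), friction gamma (ps^-1)."""

    radius: float
    mass: float
    gamma: float

    def __post_init__(self) -> None:
        if min(self.radius, self.mass, self.gamma) <= 0:
            raise ValueError("radius, mass and gamma must be positive")

    @classmethod
    def from_viscosity(cls, radius: float, mass: float, mu: float) -> "ParticleSpec":
        return cls(radius=radius, mass=mass, gamma=stokes_friction(radius, mu, mass))


@dataclass
class SimulationState:
    """Positions/velocities of all beads plus box, clock and RNG bookkeeping.

    positions are wrapped into [0, h_box); ``images`` counts box
    crossings per particle so unwrapped coordinates (for MSD) are
    positions + images * h_box.
    """

    positions: np.ndarray
    velocities: np.ndarray
    h_box: float
    time: float = 0.0
    seed: int = 0
    step_count: int = 0
    images: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.positions = np.ascontiguousarray(self.positions, dtype=np.float64)
        self.velocities = np.ascontiguousarray(self.velocities, dtype=np.float64)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must be (N, 3)")
        if self.positions.shape != self.velocities.shape:
            raise ValueError("positions and velocities shapes differ")
        if self.positions.shape[0] < 1:
            raise ValueError("need at least one particle")
        if self.h_box <= 0:
            raise ValueError("h_box must be positive")
        if not np.all(np.isfinite(self.velocities)):
            raise ValueError("velocities must be finite")
        self.positions = np.mod(self.positions, self.h_box)
        if self.images is None:
            self.images = np.zeros_like(self.positions, dtype=np.int64)

    @property
    def n_particles(self) -> int:
        return self.positions.shape[0]

    def unwrapped_positions(self) -> np.ndarray:
        return self.positions + self.images * self.h_box


@dataclass
class BDConfig:
    """Integration parameters for one BD run."""

    table: TabulatedPotential
    dt: float = 0.1  # ps
    T: float = 310.0  # K
    n_steps: int = 1000
    stride: int = 100  # snapshot interval in steps
    rebuild_interval: int = 100  # neighbor-list rebuild period
    skin: float = 1.0  # nm, neighbor-list margin beyond the table range
    noise: bool = True  # disable for deterministic integrator checks

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.T <= 0:
            raise ValueError("dt and T must be positive")
        if self.n_steps < 1 or self.stride < 1 or self.rebuild_interval < 1:
            raise ValueError("n_steps, stride and rebuild_interval must be >= 1")
        if self.skin < 0:
            raise ValueError("skin must be non-negative")


@dataclass
class Trajectory:
    """Snapshots of a BD run: frame times (ps) and wrapped positions."""

    times: np.ndarray  # (n_frames,)
    positions: np.ndarray  # (n_frames, N, 3) wrapped
    images: np.ndarray  # (n_frames, N, 3) box-crossing counts
    velocities: np.ndarray  # (n_frames, N, 3)
    h_box: float

    def __len__(self) -> int:
        return self.times.size

    def unwrapped(self) -> np.ndarray:
        return self.positions + self.images * self.h_box

    def frames(self):
        """Iterate (time_ps, positions) pairs, e.g. for cluster analysis."""
        for k in range(len(self)):
            yield float(self.times[k]), self.positions[k]


def maxwell_velocities(n: int, T: float, mass: float, seed: int = 0) -> np.ndarray:
    """Maxwell-Boltzmann velocities at temperature T: std sqrt(kBT/m)."""
    rng = np.random.default_rng(seed)
    return rng.normal(0.0, math.sqrt(KB_KJ_MOL_K * T / mass), size=(n, 3))


@njit(cache=True)
def _min_image(dx, h_box):  # pragma: no cover
    return dx - h_box * math.floor(dx / h_box + 0.5)


@njit(cache=True)
def _all_pairs(pos, h_box, cutoff):  # pragma: no cover
    n = pos.shape[0]
    cut2 = cutoff * cutoff
    count = 0
    for i in range(n - 1):
        for j in range(i + 1, n):
            dx = _min_image(pos[i, 0] - pos[j, 0], h_box)
            dy = _min_image(pos[i, 1] - pos[j, 1], h_box)
            dz = _min_image(pos[i, 2] - pos[j, 2], h_box)
            if dx * dx + dy * dy + dz * dz < cut2:
                count += 1
    pairs = np.empty((count, 2), np.int64)
    k = 0
    for i in range(n - 1):
        for j in range(i + 1, n):
            dx = _min_image(pos[i, 0] - pos[j, 0], h_box)
            dy = _min_image(pos[i, 1] - pos[j, 1], h_box)
            dz = _min_image(pos[i, 2] - pos[j, 2], h_box)
            if dx * dx + dy * dy + dz * dz < cut2:
                pairs[k, 0] = i
                pairs[k, 1] = j
                k += 1
    return pairs


@njit(cache=True)
def _cell_pairs(pos, h_box, cutoff):  # pragma: no cover
    """Candidate pairs within cutoff via a linked-cell list."""
    n = pos.shape[0]
    m = int(h_box / cutoff)
    # keep the cell count commensurate with N: an over-fine grid costs
    # more to scan than it saves (cell edge stays >= cutoff)
    m_opt = int(round(n ** (1.0 / 3.0))) * 2
    if m_opt >= 3 and m_opt < m:
        m = m_opt
    if m < 3 or n < 32:
        return _all_pairs(pos, h_box, cutoff)
    edge = h_box / m
    ncell = m * m * m
    head = np.full(ncell, -1, np.int64)
    nxt = np.full(n, -1, np.int64)
    cx = np.empty(n, np.int64)
    cy = np.empty(n, np.int64)
    cz = np.empty(n, np.int64)
    for i in range(n):
        ix = int(pos[i, 0] / edge) % m
        iy = int(pos[i, 1] / edge) % m
        iz = int(pos[i, 2] / edge) % m
        cx[i], cy[i], cz[i] = ix, iy, iz
        c = (ix * m + iy) * m + iz
        nxt[i] = head[c]
        head[c] = i
    # forward half-stencil: self cell (i<j) + 13 neighbor cells
    offs = np.empty((13, 3), np.int64)
    o = 0
    for ox in range(0, 2):
        for oy in range(-1, 2):
            for oz in range(-1, 2):
                if ox == 1 or (oy == 1) or (oy == 0 and oz == 1):
                    offs[o, 0] = ox
                    offs[o, 1] = oy
                    offs[o, 2] = oz
                    o += 1
    cut2 = cutoff * cutoff
    # two passes: count then fill
    total = 0
    for phase in range(2):
        k = 0
        if phase == 1:
            pairs = np.empty((total, 2), np.int64)
        else:
            pairs = np.empty((1, 2), np.int64)
        for ix in range(m):
            for iy in range(m):
                for iz in range(m):
                    c = (ix * m + iy) * m + iz
                    i = head[c]
                    while i >= 0:
                        # same cell, i < j by list order
                        j = nxt[i]
                        while j >= 0:
                            dx = _min_image(pos[i, 0] - pos[j, 0], h_box)
                            dy = _min_image(pos[i, 1] - pos[j, 1], h_box)
                            dz = _min_image(pos[i, 2] - pos[j, 2], h_box)
                            if dx * dx + dy * dy + dz * dz < cut2:
                                if phase == 1:
                                    pairs[k, 0] = i
                                    pairs[k, 1] = j
                                k += 1
                            j = nxt[j]
                        # neighbor cells
                        for o in range(13):
                            jx = (ix + offs[o, 0]) % m
                            jy = (iy + offs[o, 1]) % m
                            jz = (iz + offs[o, 2]) % m
                            c2 = (jx * m + jy) * m + jz
                            j = head[c2]
                            while j >= 0:
                                dx = _min_image(pos[i, 0] - pos[j, 0], h_box)
                                dy = _min_image(pos[i, 1] - pos[j, 1], h_box)
                                dz = _min_image(pos[i, 2] - pos[j, 2], h_box)
                                if dx * dx + dy * dy + dz * dz < cut2:
                                    if phase == 1:
                                        pairs[k, 0] = i
                                        pairs[k, 1] = j
                                    k += 1
                                j = nxt[j]
                        i = nxt[i]
        total = k
    return pairs


@njit(cache=True)
def _pair_forces(pos, h_box, pairs, f_table, d_min, step, d_max, forces):  # pragma: no cover
    """Accumulate tabulated pair forces. Returns -1, or the index of an
    overlapping pair (distance below the table range)."""
    forces[:] = 0.0
    nbins = f_table.size
    for p in range(pairs.shape[0]):
        i = pairs[p, 0]
        j = pairs[p, 1]
        dx = _min_image(pos[i, 0] - pos[j, 0], h_box)
        dy = _min_image(pos[i, 1] - pos[j, 1], h_box)
        dz = _min_image(pos[i, 2] - pos[j, 2], h_box)
        d = math.sqrt(dx * dx + dy * dy + dz * dz)
        if d >= d_max:
            continue
        if d < d_min:
            return p
        x = (d - d_min) / step
        k = int(x)
        if k >= nbins - 1:
            continue
        frac = x - k
        fmag = f_table[k] + frac * (f_table[k + 1] - f_table[k])
        fx = fmag * dx / d
        fy = fmag * dy / d
        fz = fmag * dz / d
        forces[i, 0] += fx
        forces[i, 1] += fy
        forces[i, 2] += fz
        forces[j, 0] -= fx
        forces[j, 1] -= fy
        forces[j, 2] -= fz
    return -1


@njit(cache=True)
def _run_kernel(
    pos, vel, img, h_box, mass, gamma, kbt, dt, n_steps, stride,
    f_table, t_dmin, t_step, t_dmax, skin, rebuild, seed, noise_on,
    out_t, out_pos, out_img, out_vel,
):  # pragma: no cover
    """Integrate n_steps of impulse Langevin dynamics, storing snapshots
    every ``stride`` steps.  Returns the failing step (negative: overlap
    at |code|; n_steps+1: success)."""
    np.random.seed(seed)
    n = pos.shape[0]
    decay = math.exp(-gamma * dt)
    sigma = math.sqrt(kbt / mass * (1.0 - decay * decay))
    forces = np.zeros((n, 3))
    cutoff = t_dmax + skin
    pairs = _cell_pairs(pos, h_box, cutoff)
    frame = 0
    for s in range(1, n_steps + 1):
        bad = _pair_forces(pos, h_box, pairs, f_table, t_dmin, t_step, t_dmax, forces)
        if bad >= 0:
            return -s
        for i in range(n):
            for c in range(3):
                v = vel[i, c] + forces[i, c] / mass * dt
                v *= decay
                if noise_on:
                    v += sigma * np.random.standard_normal()
                vel[i, c] = v
                x = pos[i, c] + v * dt
                shift = math.floor(x / h_box)
                pos[i, c] = x - shift * h_box
                img[i, c] += int(shift)
        if not math.isfinite(pos[0, 0]):
            return -s
        if s % rebuild == 0 and s < n_steps:
            pairs = _cell_pairs(pos, h_box, cutoff)
        if s % stride == 0:
            out_t[frame] = s * dt
            for i in range(n):
                for c in range(3):
                    out_pos[frame, i, c] = pos[i, c]
                    out_img[frame, i, c] = img[i, c]
                    out_vel[frame, i, c] = vel[i, c]
            frame += 1
    return n_steps + 1


def compute_forces(state: SimulationState, table: TabulatedPotential) -> np.ndarray:
    """Pairwise tabulated forces (kJ/mol/nm) on every particle.

    Forces are equal and opposite per pair; pairs beyond the table range
    contribute nothing.  Raises if any pair is closer than the table's
    lower edge (overlapping particles).
    """
    pos = state.positions
    pairs = _cell_pairs(pos, state.h_box, table.d_max)
    forces = np.zeros_like(pos)
    bad = _pair_forces(
        pos, state.h_box, pairs, table.force, table.d_min, table.step,
        table.d_max, forces,
    )
    if bad >= 0:
        i, j = pairs[bad]
        raise RuntimeError(
            f"overlapping particles {i} and {j}: pair distance below the "
            f"table range (d_min = {table.d_min} nm)"
        )
    return forces


def _derived_seed(seed: int, step_count: int) -> int:
    return int((seed * 2654435761 + step_count * 97531) % (2**31 - 1))


def bd_step(state: SimulationState, spec: ParticleSpec, cfg: BDConfig) -> SimulationState:
    """Advance the system by one Langevin impulse step.

    Functional: returns a new state; the input state is not modified.
    Reproducible via the state's seed and step counter.
    """
    traj, final = run_simulation(
        cfg.__class__(
            table=cfg.table, dt=cfg.dt, T=cfg.T, n_steps=1, stride=1,
            rebuild_interval=cfg.rebuild_interval, skin=cfg.skin, noise=cfg.noise,
        ),
        spec,
        state,
    )
    return final


def run_simulation(
    cfg: BDConfig, spec: ParticleSpec, initial: SimulationState
) -> tuple[Trajectory, SimulationState]:
    """Run a BD trajectory; returns (trajectory, final state).

    Fully reproducible given the initial state's seed.  Snapshots are
    stored every ``cfg.stride`` steps (the initial frame is not stored;
    prepend it from ``initial`` if needed).
    """
    table = cfg.table
    n_frames = cfg.n_steps // cfg.stride
    n = initial.n_particles
    pos = initial.positions.copy()
    vel = initial.velocities.copy()
    img = initial.images.copy()
    out_t = np.zeros(n_frames)
    out_pos = np.zeros((n_frames, n, 3))
    out_img = np.zeros((n_frames, n, 3), dtype=np.int64)
    out_vel = np.zeros((n_frames, n, 3))
    kbt = KB_KJ_MOL_K * cfg.T
    code = _run_kernel(
        pos, vel, img, initial.h_box, spec.mass, spec.gamma, kbt, cfg.dt,
        cfg.n_steps, cfg.stride, table.force, table.d_min, table.step,
        table.d_max, cfg.skin, cfg.rebuild_interval,
        _derived_seed(initial.seed, initial.step_count), cfg.noise,
        out_t, out_pos, out_img, out_vel,
    )
    if code <= 0:
        raise RuntimeError(
            f"BD step {-code}: overlapping particles or non-finite "
            "coordinates (timestep too large or table underflow)"
        )
    if not (np.all(np.isfinite(pos)) and np.all(np.isfinite(vel))):
        raise RuntimeError("non-finite coordinates after run")
    traj = Trajectory(
        times=initial.time + out_t,
        positions=out_pos,
        images=out_img,
        velocities=out_vel,
        h_box=initial.h_box,
    )
    final = SimulationState(
        positions=pos,
        velocities=vel,
        h_box=initial.h_box,
        time=initial.time + cfg.n_steps * cfg.dt,
        seed=initial.seed,
        step_count=initial.step_count + cfg.n_steps,
        images=img,
    )
    return traj, final
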