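"""Desk-scale Langevin dynamics in a periodic cubic box.

A minimal NVT integrator (BAOAB splitting) over the coarse-grained
potential, intended to generate small condensation/dissolution
trajectories that exercise the droplet-detection and kinetics analysis
end to end.  It is not meant for production sampling: bead masses are
uniform by default and the time step is set conservatively by the
stiffest term (the harmonic bond, omega = sqrt(k/m) ~ 3/ps at
k = 1000 kJ/mol/nm^2 and m ~ 110 Da, so dt defaults to 0.02 ps).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .forcefield import ForceFieldConfig, SystemTopology, total_forces
from .units import kT_kJ_per_mol

__all__ = [
    "SimulationState",
    "IntegratorConfig",
    "init_configuration",
    "minimize_energy",
    "run_langevin",
]


@dataclass
class SimulationState:
    """Coordinates of all beads plus the chain map at one time point."""

    coordinates: np.ndarray        # (n_beads, 3) nm
    box_length: float              # nm
    chain_of_bead: np.ndarray      # (n_beads,) chain index, contiguous
    time: float = 0.0              # ns

    def __post_init__(self):
        if self.box_length <= 0:
            raise ValueError("box_length must be positive")
        c = np.asarray(self.chain_of_bead)
        if len(c) and np.any(np.diff(c) < 0):
            raise ValueError("chain_of_bead must be contiguous and sorted")

    @property
    def n_chains(self) -> int:
        return int(self.chain_of_bead[-1]) + 1 if len(self.chain_of_bead) else 0


@dataclass
class IntegratorConfig:
    dt: float = 0.02               # ps
    friction: float = 1.0          # 1/ps
    temperature: float = 300.0     # K
    seed: int = 0
    n_steps: int = 1000
    save_every: int = 100
    bead_mass: float = 110.0       # Da (uniform; ~average residue mass)
    max_displacement: float = 0.1  # nm per half-step; tames overlap kicks

    def __post_init__(self):
        if self.dt <= 0 or self.temperature <= 0:
            raise ValueError("dt and temperature must be positive")


def _random_walk_chain(n_beads: int, bond_length: float, rng) -> np.ndarray:
    """Freely jointed chain: unit-random bond vectors of fixed length."""
    steps = rng.normal(size=(n_beads - 1, 3)) if n_beads > 1 else np.zeros((0, 3))
    if n_beads > 1:
        steps *= bond_length / np.linalg.norm(steps, axis=1)[:, None]
    return np.vstack([np.zeros(3), np.cumsum(steps, axis=0)])


def init_configuration(
    n_chains: int,
    chain_length: int,
    box_length: float,
    mode: str = "homogeneous",
    seed: int = 0,
    n_droplet: int | None = None,
    droplet_radius: float | None = None,
    bond_length: float = 0.38,
) -> SimulationState:
    """Place random-walk coils in a periodic cubic box.

    ``homogeneous`` scatters all chain centers uniformly; ``droplet``
    puts ``n_droplet`` chain centers inside a central sphere of radius
    ``droplet_radius`` (default L/6) and the rest in the remaining
    volume.  Same seed -> identical coordinates.
    """
    rng = np.random.default_rng(seed)
    contour = (chain_length - 1) * bond_length
    if contour > 10 * box_length:
        raise ValueError("chain contour length vastly exceeds the box")
    if mode == "droplet":
        n_in = n_chains if n_droplet is None else int(n_droplet)
        if n_in > n_chains:
            raise ValueError("n_droplet exceeds n_chains")
        radius = box_length / 6.0 if droplet_radius is None else float(droplet_radius)
        if radius > box_length / 2:
            raise ValueError("droplet radius exceeds the half-box")
    elif mode == "homogeneous":
        n_in, radius = 0, 0.0
    else:
        raise ValueError(f"unknown mode {mode!r}")

    center = np.full(3, box_length / 2.0)
    coords, chain_of_bead = [], []
    for c in range(n_chains):
        if c < n_in:
            # uniform point in the sphere
            while True:
                p = rng.uniform(-1.0, 1.0, size=3)
                if p @ p <= 1.0:
                    break
            com = center + p * radius
        else:
            while True:
                com = rng.uniform(0.0, box_length, size=3)
                if mode != "droplet" or np.linalg.norm(com - center) > radius:
                    break
        chain = _random_walk_chain(chain_length, bond_length, rng)
        chain += com - chain.mean(axis=0)
        coords.append(chain)
        chain_of_bead.extend([c] * chain_length)
    return SimulationState(
        coordinates=np.vstack(coords) % box_length,
        box_length=box_length,
        chain_of_bead=np.asarray(chain_of_bead, dtype=int),
    )


def minimize_energy(
    state: SimulationState,
    system_top,
    ff_config: ForceFieldConfig,
    max_steps: int = 500,
    max_move: float = 0.05,
    f_tol: float = 100.0,
) -> SimulationState:
    """Capped steepest descent to relax bead overlaps before dynamics.

    Moves each bead along its force, at most ``max_move`` nm per step,
    until the maximum force magnitude drops below ``f_tol`` kJ/mol/nm
    or ``max_steps`` is reached.  Random initial placements overlap
    freely (chains are grown without excluded volume), so a short
    minimization is required before Langevin integration with the
    r^-12 core.
    """
    x = state.coordinates.astype(float).copy()
    box = state.box_length
    for _ in range(max_steps):
        _, f = total_forces(x % box, box, system_top, ff_config)
        fmax = np.linalg.norm(f, axis=1).max()
        if fmax < f_tol:
            break
        scale = min(max_move / fmax, 1e-4)
        move = f * scale
        norms = np.linalg.norm(move, axis=1)
        over = norms > max_move
        if np.any(over):
            move[over] *= (max_move / norms[over])[:, None]
        x += move
    return SimulationState(x % box, box, state.chain_of_bead, state.time)


@dataclass
class Trajectory:
    """Sequence of saved frames (coordinates wrapped into the box)."""

    frames: list[SimulationState] = field(default_factory=list)

    def __len__(self):
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    def __getitem__(self, i):
        return self.frames[i]


def run_langevin(
    state: SimulationState,
    system_top: SystemTopology,
    ff_config: ForceFieldConfig,
    integ: IntegratorConfig,
) -> Trajectory:
    """BAOAB Langevin integration; frames every ``save_every`` steps.

    The initial state is always the first frame (so n_steps = 0 returns
    a single-frame trajectory).  Aborts with the frame index when
    forces become non-finite (overlapping beads).
    """
    rng = np.random.default_rng(integ.seed)
    kT = kT_kJ_per_mol(integ.temperature)
    m = integ.bead_mass
    dt, gamma = integ.dt, integ.friction
    c1 = np.exp(-gamma * dt)
    c2 = np.sqrt(kT / m * (1.0 - c1 * c1))

    x = state.coordinates.astype(float).copy()
    box = state.box_length
    v = rng.normal(scale=np.sqrt(kT / m), size=x.shape)
    _, f = total_forces(x, box, system_top, ff_config)

    cap = integ.max_displacement / (0.5 * dt)  # speed cap per half-step

    def _clip(vel):
        speed = np.linalg.norm(vel, axis=1)
        over = speed > cap
        if np.any(over):
            vel = vel.copy()
            vel[over] *= (cap / speed[over])[:, None]
        return vel

    traj = Trajectory([SimulationState(x.copy() % box, box, state.chain_of_bead, state.time)])
    for step in range(1, integ.n_steps + 1):
        v += 0.5 * dt * f / m
        x += 0.5 * dt * _clip(v)
        v = c1 * v + c2 * rng.normal(size=v.shape)
        x += 0.5 * dt * _clip(v)
        _, f = total_forces(x % box, box, system_top, ff_config)
        if not np.all(np.isfinite(f)):
            raise FloatingPointError(
                f"non-finite force at step {step} (frame {len(traj)}); "
                "likely overlapping beads -- reduce dt or soften the potential"
            )
        v += 0.5 * dt * f / m
        if step % integ.save_every == 0:
            t_ns = state.time + step * dt * 1e-3
            traj.frames.append(
                SimulationState(x.copy() % box, box, state.chain_of_bead, t_ns)
            )
    return traj
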