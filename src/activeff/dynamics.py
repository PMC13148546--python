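"""NVT Langevin molecular dynamics for sampling trajectories.

The integrator is the BAOAB splitting of Langevin dynamics: half-kick,
half-drift, an exact Ornstein–Uhlenbeck velocity update, half-drift,
half-kick.  At zero friction and zero temperature the OU step is the
identity and the scheme reduces *exactly* to velocity Verlet, which is the
testable contract this module guarantees.  Units: Å, fs, eV, eV/Å, K, amu.

Each trajectory owns an independent RNG stream derived from
(master seed, trajectory id), so adding trajectories to a run never
perturbs the noise sequence of existing ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import AtomicSystem, minimum_image_displacement
from .units import FORCE_TO_ACC, KB, KE_TO_EV, mass_of


class DynamicsError(RuntimeError):
    """Non-finite forces or positions encountered during propagation."""


def masses_of(system: AtomicSystem) -> np.ndarray:
    return np.array([mass_of(s) for s in system.species])


def init_velocities(system: AtomicSystem, T: float, seed: int) -> np.ndarray:
    """Maxwell–Boltzmann velocities (Å/fs) at temperature T, zero net momentum.

    Each component is drawn from N(0, k_B T / m); the center-of-mass drift is
    removed afterwards.  Deterministic per seed; T=0 gives zero velocities.
    """
    if T < 0:
        raise ValueError("temperature must be >= 0")
    m = masses_of(system)
    if T == 0:
        return np.zeros((system.n_atoms, 3))
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(KB * T / (m * KE_TO_EV))
    v = rng.standard_normal((system.n_atoms, 3)) * sigma[:, None]
    v -= (m[:, None] * v).sum(axis=0) / m.sum()
    return v


def kinetic_temperature(system: AtomicSystem) -> float:
    """Instantaneous kinetic temperature (K) from 2⟨KE⟩/(3N k_B)."""
    m = masses_of(system)
    ke = 0.5 * float(np.sum(m[:, None] * system.velocities**2)) * KE_TO_EV
    return 2 * ke / (3 * system.n_atoms * KB)


@dataclass
class StabilityParams:
    """Bonded pairs and the bond-length cutoff for the stability monitor."""

    bond_pairs: list[tuple[int, int]]
    max_bond_length: float = 2.0


def check_stability(system: AtomicSystem, params: StabilityParams) -> bool:
    """True iff no bonded pair distance strictly exceeds the cutoff.

    Distances use the minimum-image convention for periodic systems.
    """
    for i, j in params.bond_pairs:
        delta = minimum_image_displacement(
            system.positions[j] - system.positions[i], system.cell, system.pbc
        )
        if float(np.linalg.norm(delta)) > params.max_bond_length:
            return False
    return True


def chain_bonds(n_atoms: int) -> list[tuple[int, int]]:
    """Consecutive bonded pairs of an ordered chain."""
    return [(i, i + 1) for i in range(n_atoms - 1)]


@dataclass
class TrajectoryState:
    """One sampling trajectory: geometry, thermostat settings and RNG stream."""

    system: AtomicSystem
    temperature: float
    friction: float = 0.001   # fs⁻¹
    dt: float = 1.0           # fs
    rng_seed: int = 0
    trajectory_id: int = 0
    check_interval: int = 20  # MD steps between uncertainty checks
    step: int = 0
    status: str = "running"   # running | halted_for_label | stopped
    rng: np.random.Generator = field(default=None, repr=False)
    _forces: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.friction < 0:
            raise ValueError("dt must be > 0 and friction >= 0")
        if self.rng is None:
            self.rng = np.random.default_rng((self.rng_seed, self.trajectory_id))
        if self.system.velocities is None:
            self.system.velocities = init_velocities(
                self.system, self.temperature,
                (self.rng_seed, self.trajectory_id, 7),
            )


def langevin_step(trajectory: TrajectoryState, force_provider) -> TrajectoryState:
    """Advance one BAOAB step of dt; flags the trajectory on non-finite forces."""
    sys_ = trajectory.system
    m = masses_of(sys_)[:, None]
    dt = trajectory.dt
    if trajectory._forces is None:
        trajectory._forces = np.asarray(force_provider(sys_), dtype=float)
    f = trajectory._forces
    if not np.all(np.isfinite(f)):
        trajectory.status = "stopped"
        raise DynamicsError(
            f"non-finite forces in trajectory {trajectory.trajectory_id} "
            f"at step {trajectory.step}"
        )
    v = sys_.velocities + 0.5 * dt * f / m * FORCE_TO_ACC
    x = sys_.positions + 0.5 * dt * v
    if trajectory.friction > 0:
        c1 = np.exp(-trajectory.friction * dt)
        sigma = np.sqrt(KB * trajectory.temperature / (m * KE_TO_EV))
        v = c1 * v + np.sqrt(1 - c1**2) * sigma * trajectory.rng.standard_normal(v.shape)
    x = x + 0.5 * dt * v
    sys_.positions = x
    f_new = np.asarray(force_provider(sys_), dtype=float)
    if not np.all(np.isfinite(f_new)):
        trajectory.status = "stopped"
        raise DynamicsError(
            f"non-finite forces in trajectory {trajectory.trajectory_id} "
            f"at step {trajectory.step + 1}"
        )
    sys_.velocities = v + 0.5 * dt * f_new / m * FORCE_TO_ACC
    trajectory._forces = f_new
    trajectory.step += 1
    return trajectory


def propagate_until_check(
    trajectory: TrajectoryState, force_provider
) -> tuple[TrajectoryState, AtomicSystem]:
    """Advance exactly ``check_interval`` steps; return the snapshot for UQ."""
    if trajectory.status != "running":
        raise RuntimeError(f"trajectory status is {trajectory.status!r}, not running")
    for _ in range(trajectory.check_interval):
        langevin_step(trajectory, force_provider)
    return trajectory, trajectory.system.copy()
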