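"""Analytic potential-energy-surface oracles that stand in for ab initio labeling.

Each oracle maps an :class:`~activeff.data.AtomicSystem` to a total energy
(eV) and analytic forces (eV/Å, exact negative gradients).  A ``level`` tag
travels into sample provenance so that datasets relabeled by a
"higher-level" oracle remain distinguishable.  Wrappers add a smooth seeded
energy perturbation (a stand-in for a more accurate level of theory) and
seeded convergence failures (a stand-in for non-converged SCF cycles).

All oracles operate on raw Cartesian distances; periodic images are out of
scope for the built-in toy surfaces.
"""

from __future__ import annotations

import time

import numpy as np

from .data import AtomicSystem


class OracleFailure(RuntimeError):
    """A (simulated) reference-calculation convergence failure."""


class EvaluationError(ValueError):
    """The geometry is outside the oracle's domain (e.g. coincident atoms)."""


class OraclePES:
    """Base reference calculator: ``evaluate(system) -> (energy, forces)``.

    ``latency`` (seconds) injects a wall-clock delay per call and exists only
    so scheduler tests can emulate slow reference codes; it never affects
    numerics.
    """

    def __init__(self, level: str = "ref", latency: float = 0.0):
        self.level = level
        self.latency = float(latency)

    def evaluate(self, system: AtomicSystem) -> tuple[float, np.ndarray]:
        if self.latency > 0:
            time.sleep(self.latency)
        energy, forces = self._evaluate(system)
        return float(energy), np.asarray(forces, dtype=float)

    def _evaluate(self, system: AtomicSystem) -> tuple[float, np.ndarray]:
        raise NotImplementedError


class LennardJones(OraclePES):
    """All-pair 12-6 Lennard-Jones potential: 4ε[(σ/r)¹² − (σ/r)⁶]."""

    def __init__(self, epsilon: float = 0.1, sigma: float = 3.0, level: str = "lj",
                 latency: float = 0.0):
        super().__init__(level=level, latency=latency)
        self.epsilon = float(epsilon)
        self.sigma = float(sigma)

    def _evaluate(self, system: AtomicSystem):
        pos = system.positions
        n = system.n_atoms
        if n < 2:
            raise EvaluationError("need at least 2 atoms")
        energy = 0.0
        forces = np.zeros((n, 3))
        for i in range(n - 1):
            rij = pos[i + 1 :] - pos[i]
            r = np.linalg.norm(rij, axis=1)
            if np.any(r < 1e-8):
                raise EvaluationError("coincident atoms")
            sr6 = (self.sigma / r) ** 6
            energy += float(np.sum(4 * self.epsilon * (sr6**2 - sr6)))
            # dU/dr = 4ε(−12 σ¹²/r¹³ + 6 σ⁶/r⁷) = −24ε(2 sr6² − sr6)/r
            dudr = -24 * self.epsilon * (2 * sr6**2 - sr6) / r
            fpair = -(dudr / r)[:, None] * rij  # force on atom j = i+1+k
            forces[i + 1 :] += fpair
            forces[i] -= fpair.sum(axis=0)
        return energy, forces


class MorseChain(OraclePES):
    """Morse bonds D(1−exp(−a(r−r0)))² over a bonded neighbor list.

    By default atoms are bonded as an ordered chain (i, i+1).
    """

    def __init__(self, D: float = 4.0, a: float = 2.0, r0: float = 1.5,
                 bonds: list[tuple[int, int]] | None = None, level: str = "morse",
                 latency: float = 0.0):
        super().__init__(level=level, latency=latency)
        self.D, self.a, self.r0 = float(D), float(a), float(r0)
        self.bonds = bonds

    def _bond_list(self, n: int) -> list[tuple[int, int]]:
        return self.bonds if self.bonds is not None else [(i, i + 1) for i in range(n - 1)]

    def _evaluate(self, system: AtomicSystem):
        pos = system.positions
        forces = np.zeros_like(pos)
        energy = 0.0
        for i, j in self._bond_list(system.n_atoms):
            rij = pos[j] - pos[i]
            r = float(np.linalg.norm(rij))
            if r < 1e-8:
                raise EvaluationError("coincident bonded atoms")
            e = np.exp(-self.a * (r - self.r0))
            energy += self.D * (1 - e) ** 2
            dudr = 2 * self.D * (1 - e) * self.a * e
            f = -(dudr / r) * rij
            forces[j] += f
            forces[i] -= f
        return energy, forces


# -- internal force-field terms shared by the chain oracles -----------------


def _angle_and_grad(r1, r2, r3):
    """Angle at r2 between (r1−r2) and (r3−r2) and its gradient (3×3)."""
    u = r1 - r2
    v = r3 - r2
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    cos_t = float(np.dot(u, v) / (nu * nv))
    cos_t = max(-1.0, min(1.0, cos_t))
    theta = float(np.arccos(cos_t))
    sin_t = np.sqrt(max(1.0 - cos_t**2, 1e-14))
    # d cosθ / d r1 and r3; chain rule through dθ = −dcosθ/sinθ
    dcos_dr1 = v / (nu * nv) - cos_t * u / nu**2
    dcos_dr3 = u / (nu * nv) - cos_t * v / nv**2
    dth_dr1 = -dcos_dr1 / sin_t
    dth_dr3 = -dcos_dr3 / sin_t
    dth_dr2 = -(dth_dr1 + dth_dr3)
    return theta, np.array([dth_dr1, dth_dr2, dth_dr3])


def _dihedral_and_grad(r1, r2, r3, r4):
    """Dihedral over the bonded quadruplet and its gradient (4×3).

    Raises :class:`EvaluationError` when either bonded triple is collinear
    (the dihedral is then undefined).
    """
    b1 = r2 - r1
    b2 = r3 - r2
    b3 = r4 - r3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    n1sq = float(np.dot(n1, n1))
    n2sq = float(np.dot(n2, n2))
    nb2 = float(np.linalg.norm(b2))
    if n1sq < 1e-12 or n2sq < 1e-12:
        raise EvaluationError("collinear triple: dihedral undefined")
    # signed dihedral via atan2
    m1 = np.cross(n1, b2 / nb2)
    x = float(np.dot(n1, n2))
    y = float(np.dot(m1, n2))
    phi = float(np.arctan2(y, x))
    # Blondel–Karplus analytic gradient (signs match the atan2 convention above)
    dphi_dr1 = (nb2 / n1sq) * n1
    dphi_dr4 = -(nb2 / n2sq) * n2
    s12 = float(np.dot(b1, b2)) / nb2**2
    s32 = float(np.dot(b3, b2)) / nb2**2
    dphi_dr2 = -(1.0 + s12) * dphi_dr1 + s32 * dphi_dr4
    dphi_dr3 = -(1.0 + s32) * dphi_dr4 + s12 * dphi_dr1
    return phi, np.array([dphi_dr1, dphi_dr2, dphi_dr3, dphi_dr4])


class ChainForceField(OraclePES):
    """Harmonic bonds and angles on an ordered chain, plus optional torsions.

    The torsional term per consecutive quadruplet is either a symmetric
    double well in the dihedral angle φ,

        U(φ) = barrier · (cos φ − cos φ₀)² / (1 − cos φ₀)²,

    with minima at ±φ₀ and a barrier of exactly ``barrier`` at φ = 0, or
    (``single_well_k`` set) a stiff single well k·(1 − cos(φ − φ₀)).  The
    double-well flavor emulates a floppy, hard-to-learn molecule; the
    torsion-free or single-well flavors emulate rigid ones.
    """

    def __init__(
        self,
        bond_k: float = 20.0,
        bond_r0: float = 1.5,
        angle_k: float = 3.0,
        angle_theta0: float = 1.911,  # ≈109.5°
        barrier: float | None = None,
        phi0: float = 1.2,
        single_well_k: float | None = None,
        level: str = "chain",
        latency: float = 0.0,
    ):
        super().__init__(level=level, latency=latency)
        self.bond_k = float(bond_k)
        self.bond_r0 = float(bond_r0)
        self.angle_k = float(angle_k)
        self.angle_theta0 = float(angle_theta0)
        self.barrier = None if barrier is None else float(barrier)
        self.phi0 = float(phi0)
        self.single_well_k = None if single_well_k is None else float(single_well_k)

    def _evaluate(self, system: AtomicSystem):
        pos = system.positions
        n = system.n_atoms
        forces = np.zeros_like(pos)
        energy = 0.0
        for i in range(n - 1):
            rij = pos[i + 1] - pos[i]
            r = float(np.linalg.norm(rij))
            if r < 1e-8:
                raise EvaluationError("coincident bonded atoms")
            energy += 0.5 * self.bond_k * (r - self.bond_r0) ** 2
            f = -(self.bond_k * (r - self.bond_r0) / r) * rij
            forces[i + 1] += f
            forces[i] -= f
        for i in range(n - 2):
            theta, grad = _angle_and_grad(pos[i], pos[i + 1], pos[i + 2])
            energy += 0.5 * self.angle_k * (theta - self.angle_theta0) ** 2
            dudth = self.angle_k * (theta - self.angle_theta0)
            forces[i : i + 3] -= dudth * grad
        if (self.barrier is not None or self.single_well_k is not None) and n >= 4:
            for i in range(n - 3):
                phi, grad = _dihedral_and_grad(*pos[i : i + 4])
                if self.barrier is not None:
                    c0 = np.cos(self.phi0)
                    norm = (1.0 - c0) ** 2
                    cphi = np.cos(phi)
                    energy += self.barrier * (cphi - c0) ** 2 / norm
                    dudphi = -2 * self.barrier * (cphi - c0) * np.sin(phi) / norm
                else:
                    energy += self.single_well_k * (1 - np.cos(phi - self.phi0))
                    dudphi = self.single_well_k * np.sin(phi - self.phi0)
                forces[i : i + 4] -= dudphi * grad
        return energy, forces


def double_well_dihedral(
    barrier: float = 0.08,
    phi0: float = 1.2,
    bond_k: float = 20.0,
    bond_r0: float = 1.5,
    angle_k: float = 3.0,
    angle_theta0: float = 1.911,
    level: str = "double-well",
) -> ChainForceField:
    """A flexible chain PES: harmonic backbone plus double-well torsions."""
    return ChainForceField(
        bond_k=bond_k, bond_r0=bond_r0, angle_k=angle_k, angle_theta0=angle_theta0,
        barrier=barrier, phi0=phi0, level=level,
    )


class PerturbedOracle(OraclePES):
    """A 'higher level of theory': base energy plus a smooth seeded perturbation.

    The perturbation is ``amplitude``·(mean over atom pairs of a small random
    Fourier series in the pair distance); it is deterministic for a fixed
    seed, has analytic forces, and vanishes identically at amplitude 0.
    """

    N_TERMS = 4

    def __init__(self, base: OraclePES, amplitude: float, seed: int = 0,
                 level: str | None = None, latency: float = 0.0):
        if amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        super().__init__(level=level or base.level + "+hi", latency=latency)
        self.base = base
        self.amplitude = float(amplitude)
        rng = np.random.default_rng(seed)
        self.coeff = rng.standard_normal(self.N_TERMS)
        self.coeff /= np.sum(np.abs(self.coeff))
        self.omega = rng.uniform(0.5, 2.0, self.N_TERMS)
        self.phase = rng.uniform(0, 2 * np.pi, self.N_TERMS)

    def gradient_bound(self, n_atoms: int) -> float:
        """Upper bound on the perturbation's per-atom gradient norm."""
        per_pair = float(np.sum(np.abs(self.coeff * self.omega)))
        n_pairs = n_atoms * (n_atoms - 1) // 2
        return self.amplitude * per_pair * (n_atoms - 1) / max(n_pairs, 1)

    def _evaluate(self, system: AtomicSystem):
        energy, forces = self.base._evaluate(system)
        if self.amplitude == 0:
            return energy, forces
        pos = system.positions
        n = system.n_atoms
        n_pairs = n * (n - 1) // 2
        for i in range(n - 1):
            for j in range(i + 1, n):
                rij = pos[j] - pos[i]
                r = float(np.linalg.norm(rij))
                arg = self.omega * r + self.phase
                energy += self.amplitude * float(np.sum(self.coeff * np.sin(arg))) / n_pairs
                dudr = self.amplitude * float(
                    np.sum(self.coeff * self.omega * np.cos(arg))
                ) / n_pairs
                f = -(dudr / r) * rij
                forces[j] += f
                forces[i] -= f
        return energy, forces


class FailingOracle(OraclePES):
    """Wraps an oracle with seeded random convergence failures.

    A seeded fraction of calls raises :class:`OracleFailure`; successful
    calls are byte-identical to the base oracle.  The engine is expected to
    catch the failure, discard the candidate and resume sampling.
    """

    def __init__(self, base: OraclePES, failure_rate: float, seed: int = 0,
                 latency: float = 0.0):
        if not 0 <= failure_rate < 1:
            raise ValueError("failure_rate must be in [0, 1)")
        super().__init__(level=base.level, latency=latency)
        self.base = base
        self.failure_rate = float(failure_rate)
        self._rng = np.random.default_rng(seed)

    def _evaluate(self, system: AtomicSystem):
        if self._rng.random() < self.failure_rate:
            raise OracleFailure("simulated reference-calculation non-convergence")
        return self.base._evaluate(system)


def perturbed_level(base: OraclePES, amplitude: float, seed: int = 0) -> PerturbedOracle:
    """Construct the higher-level variant of ``base`` (distinct level tag)."""
    return PerturbedOracle(base, amplitude, seed)


def with_failures(base: OraclePES, failure_rate: float, seed: int = 0) -> FailingOracle:
    """Wrap ``base`` so a seeded fraction of calls fails."""
    return FailingOracle(base, failure_rate, seed)
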