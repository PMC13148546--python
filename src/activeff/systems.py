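"""Toy study systems: chain molecules of tunable floppiness.

These generators define the desk-scale analogs of the systems an active
learning force-field run samples: a *flexible* chain whose double-well
torsions make its potential energy surface hard to learn, and a *rigid*
chain with stiff single-well torsions that a surrogate captures almost
immediately.  A ``softened`` variant of any chain oracle plays the role of
an approximate general-purpose force field used purely as a geometry
generator during initial data set generation.
"""

from __future__ import annotations

import numpy as np

from .data import AtomicSystem
from .oracles import ChainForceField


def place_chain(
    n_atoms: int,
    bond_r0: float = 1.5,
    angle_theta0: float = 1.911,
    phi: float | list[float] = 1.2,
    element: str = "C",
    tag: str = "",
    alternate: bool = True,
) -> AtomicSystem:
    """Build an ordered chain with given bond length, angle and dihedral(s).

    ``phi`` is either one dihedral value — alternating ±phi along the chain
    when ``alternate`` is set, giving a compact helix-free geometry near a
    torsional minimum — or a sequence of ``n_atoms - 3`` explicit dihedrals
    selecting a particular conformer.
    """
    if np.ndim(phi) == 0:
        phis = [phi * (-1) ** i if alternate else phi for i in range(3, n_atoms)]
    else:
        phis = list(phi)
        if len(phis) != max(n_atoms - 3, 0):
            raise ValueError(f"need {n_atoms - 3} dihedrals, got {len(phis)}")
    pos = np.zeros((n_atoms, 3))
    if n_atoms > 1:
        pos[1] = [bond_r0, 0.0, 0.0]
    if n_atoms > 2:
        pos[2] = pos[1] + bond_r0 * np.array(
            [-np.cos(angle_theta0), np.sin(angle_theta0), 0.0]
        )
    for i in range(3, n_atoms):
        pos[i] = _nerf(
            pos[i - 3], pos[i - 2], pos[i - 1], bond_r0, angle_theta0, phis[i - 3]
        )
    return AtomicSystem(species=[element] * n_atoms, positions=pos, tag=tag)


def _nerf(a, b, c, r, theta, phi):
    """Natural-extension place of atom d from a-b-c internals (r, θ, φ)."""
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [-r * np.cos(theta), r * np.sin(theta) * np.cos(phi), r * np.sin(theta) * np.sin(phi)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def flexible_chain_oracle(
    barrier: float = 0.15,
    phi0: float = 1.2,
    bond_k: float = 20.0,
    angle_k: float = 3.0,
    level: str = "ref",
) -> ChainForceField:
    """The hard toy PES: harmonic backbone + double-well torsions.

    The default torsional barrier (0.15 eV ≈ 3.5 k_B T at 500 K) puts well
    crossings in the rare-but-present regime, so sampling keeps
    encountering genuinely new conformers — the flexible-molecule behavior
    this fixture emulates.
    """
    return ChainForceField(
        bond_k=bond_k, angle_k=angle_k, barrier=barrier, phi0=phi0, level=level
    )


def rigid_chain_oracle(
    bond_k: float = 20.0,
    angle_k: float = 3.0,
    torsion_k: float = 0.5,
    phi0: float = 1.2,
    level: str = "ref",
) -> ChainForceField:
    """The easy toy PES: harmonic chain with single-well torsions.

    Backbone stiffness matches the flexible chain so the force scales are
    comparable; what differs is conformational complexity — one torsional
    minimum instead of a double well, so there is nothing new to discover
    once the initial region is sampled.  The single-well curvature
    (k ≈ 0.5 eV) is close to the double well's curvature at its minima.
    """
    return ChainForceField(
        bond_k=bond_k, angle_k=angle_k, single_well_k=torsion_k, phi0=phi0, level=level
    )


def softened(oracle: ChainForceField, factor: float = 0.8) -> ChainForceField:
    """An approximate geometry-generator variant of a chain oracle.

    All stiffnesses are scaled by ``factor``: physically plausible but
    deliberately wrong, which is exactly the role a general-purpose
    foundation force field plays when it drives sampling while the
    reference oracle provides labels.
    """
    return ChainForceField(
        bond_k=oracle.bond_k * factor,
        bond_r0=oracle.bond_r0,
        angle_k=oracle.angle_k * factor,
        angle_theta0=oracle.angle_theta0,
        barrier=None if oracle.barrier is None else oracle.barrier * factor,
        phi0=oracle.phi0,
        single_well_k=(
            None if oracle.single_well_k is None else oracle.single_well_k * factor
        ),
        level=oracle.level + "-soft",
    )
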