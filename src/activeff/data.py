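"""Domain types, extended-XYZ persistence and dataset-manipulation procedures.

The in-memory containers are deliberately small: an :class:`AtomicSystem` is a
set of atoms with Cartesian coordinates (Å), a :class:`LabeledSample` attaches
a reference energy (eV) and forces (eV/Å) plus provenance, and a
:class:`DatasetStore` is an ordered collection of samples with a train/val
split and per-committee-member index subsets.

Persistence uses the extended-XYZ dialect: a per-frame atom count line, a
key/value comment line carrying ``energy=`` and (for periodic frames)
``Lattice="..."``, and per-atom columns ``species x y z [fx fy fz]``
declared through a ``Properties=`` key.
"""

from __future__ import annotations

import shlex
from dataclasses import dataclass, field

import numpy as np

STAGES = ("idg", "al", "probe", "recompute")


class ConfigurationError(ValueError):
    """A caller-supplied parameter violates an operation precondition."""


class ExtxyzParseError(ValueError):
    """Malformed extended-XYZ input; the message names the offending line."""


@dataclass
class AtomicSystem:
    """A molecular or periodic configuration.

    Parameters
    ----------
    species
        Element symbols, one per atom.
    positions
        N×3 Cartesian coordinates in Å.
    cell
        Optional 3×3 lattice vectors in Å (rows are lattice vectors).
        Present iff any periodic flag is set.
    pbc
        Three periodic-boundary flags.
    velocities
        Optional N×3 velocities in Å/fs.
    tag
        System identifier used for per-system bookkeeping in multi-system
        runs.
    """

    species: list[str]
    positions: np.ndarray
    cell: np.ndarray | None = None
    pbc: tuple[bool, bool, bool] = (False, False, False)
    velocities: np.ndarray | None = None
    tag: str = ""

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.shape != (len(self.species), 3):
            raise ValueError(
                f"positions shape {self.positions.shape} does not match "
                f"{len(self.species)} species"
            )
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("non-finite coordinates")
        if self.velocities is not None:
            self.velocities = np.asarray(self.velocities, dtype=float)
            if self.velocities.shape != self.positions.shape:
                raise ValueError("velocities shape does not match positions")
        self.pbc = tuple(bool(b) for b in self.pbc)
        if self.cell is not None:
            self.cell = np.asarray(self.cell, dtype=float).reshape(3, 3)
        if (self.cell is not None) != any(self.pbc):
            raise ValueError("cell must be present iff any pbc flag is true")

    @property
    def n_atoms(self) -> int:
        return len(self.species)

    def copy(self) -> "AtomicSystem":
        return AtomicSystem(
            species=list(self.species),
            positions=self.positions.copy(),
            cell=None if self.cell is None else self.cell.copy(),
            pbc=self.pbc,
            velocities=None if self.velocities is None else self.velocities.copy(),
            tag=self.tag,
        )


@dataclass
class LabeledSample:
    """An :class:`AtomicSystem` plus reference labels and provenance.

    ``energy``/``forces`` may both be absent (an unlabeled frame as read from
    a geometry-only extended-XYZ file); when present they must be finite and
    shape-consistent.  ``stage`` records which phase of the workflow produced
    the label.
    """

    system: AtomicSystem
    energy: float | None = None
    forces: np.ndarray | None = None
    level: str = "ref"
    stage: str = "idg"
    trajectory_id: int = 0
    step: int = 0

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"stage {self.stage!r} not in {STAGES}")
        if self.forces is not None:
            self.forces = np.asarray(self.forces, dtype=float)
            if self.forces.shape != (self.system.n_atoms, 3):
                raise ValueError("forces shape does not match atom count")
            if not np.all(np.isfinite(self.forces)):
                raise ValueError("non-finite forces")
        if self.energy is not None:
            self.energy = float(self.energy)
            if not np.isfinite(self.energy):
                raise ValueError("non-finite energy")

    @property
    def is_labeled(self) -> bool:
        return self.energy is not None and self.forces is not None


class DatasetStore:
    """Ordered labeled samples with a train/val split and member subsets.

    ``member_train[m]`` / ``member_val[m]`` hold the sample indices committee
    member ``m`` trains and validates on.  During initial data generation the
    member training subsets are disjoint; every active-learning addition is
    appended to all members.
    """

    def __init__(self) -> None:
        self.samples: list[LabeledSample] = []
        self.split: list[str] = []
        self.member_train: list[list[int]] = []
        self.member_val: list[list[int]] = []

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def n_members(self) -> int:
        return len(self.member_train)

    def add(self, sample: LabeledSample, split: str) -> int:
        if split not in ("train", "val"):
            raise ValueError(f"split must be 'train' or 'val', got {split!r}")
        self.samples.append(sample)
        self.split.append(split)
        return len(self.samples) - 1

    def train_indices(self) -> list[int]:
        return [i for i, s in enumerate(self.split) if s == "train"]

    def val_indices(self) -> list[int]:
        return [i for i, s in enumerate(self.split) if s == "val"]

    @property
    def n_train(self) -> int:
        return sum(1 for s in self.split if s == "train")

    @property
    def n_val(self) -> int:
        return sum(1 for s in self.split if s == "val")

    def add_to_all_members(self, index: int) -> None:
        """Append an index to every member's subset matching its split."""
        target = self.member_train if self.split[index] == "train" else self.member_val
        for subset in target:
            subset.append(index)


# ---------------------------------------------------------------------------
# extended-XYZ persistence
# ---------------------------------------------------------------------------


def _format_comment(sample: LabeledSample) -> str:
    sys_ = sample.system
    parts = []
    if sys_.cell is not None:
        flat = " ".join(f"{x:.10g}" for x in sys_.cell.reshape(-1))
        parts.append(f'Lattice="{flat}"')
    props = "species:S:1:pos:R:3"
    if sample.forces is not None:
        props += ":forces:R:3"
    parts.append(f"Properties={props}")
    if sample.energy is not None:
        parts.append(f"energy={sample.energy:.12g}")
    parts.append('pbc="' + " ".join("T" if b else "F" for b in sys_.pbc) + '"')
    if sys_.tag:
        parts.append(f"tag={sys_.tag}")
    parts.append(f"level={sample.level}")
    parts.append(f"stage={sample.stage}")
    parts.append(f"trajectory_id={sample.trajectory_id}")
    parts.append(f"step={sample.step}")
    return " ".join(parts)


def write_extxyz(samples: list[LabeledSample], path, allow_empty: bool = True) -> None:
    """Write samples as extended XYZ; round-trips through :func:`read_extxyz`."""
    if not samples and not allow_empty:
        raise ValueError("refusing to write an empty dataset")
    with open(path, "w") as fh:
        for sample in samples:
            sys_ = sample.system
            fh.write(f"{sys_.n_atoms}\n")
            fh.write(_format_comment(sample) + "\n")
            for i, symbol in enumerate(sys_.species):
                x, y, z = sys_.positions[i]
                line = f"{symbol} {x:.12g} {y:.12g} {z:.12g}"
                if sample.forces is not None:
                    fx, fy, fz = sample.forces[i]
                    line += f" {fx:.12g} {fy:.12g} {fz:.12g}"
                fh.write(line + "\n")


def _parse_comment(comment: str, lineno: int) -> dict:
    try:
        tokens = shlex.split(comment)
    except ValueError as exc:
        raise ExtxyzParseError(f"line {lineno}: malformed comment line ({exc})")
    out: dict = {}
    for token in tokens:
        if "=" in token:
            key, _, value = token.partition("=")
            out[key] = value
    return out


def read_extxyz(path) -> list[LabeledSample]:
    """Read an extended-XYZ file into labeled (or unlabeled) samples.

    Frames whose per-atom rows lack force columns yield samples with
    ``forces=None``.  Malformed atom counts, non-numeric coordinates or a
    force-column mismatch raise :class:`ExtxyzParseError` naming the line.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    samples: list[LabeledSample] = []
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            natoms = int(lines[i].strip())
        except ValueError:
            raise ExtxyzParseError(f"line {i + 1}: malformed atom count {lines[i]!r}")
        if natoms < 0 or i + 1 + natoms >= len(lines) + 1 and natoms > 0:
            raise ExtxyzParseError(f"line {i + 1}: atom count {natoms} exceeds file")
        if i + 1 >= len(lines):
            raise ExtxyzParseError(f"line {i + 1}: missing comment line")
        keys = _parse_comment(lines[i + 1], i + 2)
        has_forces = "forces" in keys.get("Properties", "")
        ncols = 7 if has_forces else 4
        if i + 2 + natoms > len(lines):
            raise ExtxyzParseError(
                f"line {i + 1}: frame declares {natoms} atoms but file ends early"
            )
        species: list[str] = []
        positions = np.empty((natoms, 3))
        forces = np.empty((natoms, 3)) if has_forces else None
        for a in range(natoms):
            lineno = i + 3 + a
            parts = lines[i + 2 + a].split()
            if len(parts) != ncols:
                raise ExtxyzParseError(
                    f"line {lineno}: expected {ncols} columns, got {len(parts)}"
                )
            species.append(parts[0])
            try:
                values = [float(p) for p in parts[1:]]
            except ValueError:
                raise ExtxyzParseError(f"line {lineno}: non-numeric atom data")
            positions[a] = values[:3]
            if forces is not None:
                forces[a] = values[3:6]
        # a stray extra atom row (declared count too small) is a contract violation
        if i + 2 + natoms < len(lines):
            nxt = lines[i + 2 + natoms].split()
            if len(nxt) == ncols and not _is_int(nxt[0]):
                raise ExtxyzParseError(
                    f"line {i + 1}: frame declares {natoms} atoms but more atom "
                    f"rows follow (line {i + 3 + natoms})"
                )
        cell = None
        pbc = (False, False, False)
        if "Lattice" in keys:
            cell = np.array([float(x) for x in keys["Lattice"].split()]).reshape(3, 3)
            pbc = (True, True, True)
        if "pbc" in keys:
            pbc = tuple(t == "T" for t in keys["pbc"].split())
            if not any(pbc):
                cell = None
        system = AtomicSystem(
            species=species, positions=positions, cell=cell, pbc=pbc,
            tag=keys.get("tag", ""),
        )
        energy = float(keys["energy"]) if "energy" in keys else None
        samples.append(
            LabeledSample(
                system=system,
                energy=energy,
                forces=forces,
                level=keys.get("level", "ref"),
                stage=keys.get("stage", "idg"),
                trajectory_id=int(keys.get("trajectory_id", 0)),
                step=int(keys.get("step", 0)),
            )
        )
        i += 2 + natoms
    return samples


def _is_int(token: str) -> bool:
    try:
        int(token)
        return True
    except ValueError:
        return False


# ---------------------------------------------------------------------------
# dataset manipulation
# ---------------------------------------------------------------------------


def split_member_subsets(dataset: DatasetStore, M: int, seed: int) -> DatasetStore:
    """Randomly partition train and val samples into M disjoint member subsets.

    Each member receives ``floor(n/M)`` samples; the remainder stays
    unassigned until a later addition.  Deterministic for a fixed seed.
    """
    if M < 2:
        raise ConfigurationError("need at least 2 committee members")
    train = dataset.train_indices()
    if len(train) < M:
        raise ConfigurationError(
            f"cannot split {len(train)} training samples into {M} member subsets"
        )
    rng = np.random.default_rng(seed)

    def _partition(indices: list[int]) -> list[list[int]]:
        perm = rng.permutation(len(indices))
        per = len(indices) // M
        return [
            sorted(indices[perm[m * per + j]] for j in range(per)) for m in range(M)
        ]

    dataset.member_train = _partition(train)
    val = dataset.val_indices()
    if len(val) >= M:
        dataset.member_val = _partition(val)
    else:
        # too few validation points to split: every member validates on all
        dataset.member_val = [list(val) for _ in range(M)]
    return dataset


def assign_train_val(counter: int, ratio_train: int, ratio_val: int) -> str:
    """Deterministic round-robin split assignment.

    Within each block of ``ratio_train + ratio_val`` consecutive labels the
    first ``ratio_train`` go to training, the rest to validation.
    """
    if counter < 0 or ratio_train < 1 or ratio_val < 1:
        raise ConfigurationError("counter must be >=0 and ratios positive integers")
    return "train" if counter % (ratio_train + ratio_val) < ratio_train else "val"


def subsample_stride(records, stride: int, prefix_limit: int | None = None) -> list[int]:
    """Select every ``stride``-th record (1-based) from a prefix of the input.

    Returns 0-based indices ``stride-1, 2*stride-1, ...`` within the first
    ``prefix_limit`` records; the count is ``floor(prefix_limit / stride)``.
    """
    if stride < 1:
        raise ConfigurationError("stride must be >= 1")
    n = len(records)
    if prefix_limit is not None:
        if prefix_limit > n:
            raise ConfigurationError("prefix_limit exceeds record count")
        n = prefix_limit
    return [i for i in range(n) if (i + 1) % stride == 0]


def draw_train_val(n: int, n_train: int, n_val: int, seed: int) -> tuple[list[int], list[int]]:
    """Randomly draw disjoint train and validation index sets from ``n`` records."""
    if n_train + n_val > n:
        raise ConfigurationError("cannot draw more points than available")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return sorted(int(i) for i in perm[:n_train]), sorted(
        int(i) for i in perm[n_train : n_train + n_val]
    )


def farthest_point_sampling(
    descriptors: np.ndarray, k: int, start_index: int = 0
) -> list[int]:
    """Greedy max-min (farthest point) selection under Euclidean distance.

    Starting from ``start_index``, repeatedly adds the point whose minimum
    distance to the selected set is largest; ties break to the lowest index.
    """
    descriptors = np.asarray(descriptors, dtype=float)
    if descriptors.ndim == 1:
        descriptors = descriptors[:, None]
    n = descriptors.shape[0]
    if not 1 <= k <= n:
        raise ConfigurationError(f"k={k} out of range for {n} points")
    if not 0 <= start_index < n:
        raise ConfigurationError("start_index out of range")
    selected = [start_index]
    mindist = np.linalg.norm(descriptors - descriptors[start_index], axis=1)
    while len(selected) < k:
        nxt = int(np.argmax(mindist))  # argmax returns the lowest tied index
        selected.append(nxt)
        mindist = np.minimum(
            mindist, np.linalg.norm(descriptors - descriptors[nxt], axis=1)
        )
    return selected


def minimum_image_displacement(
    delta: np.ndarray, cell: np.ndarray | None, pbc: tuple[bool, bool, bool]
) -> np.ndarray:
    """Apply the minimum-image convention to displacement vectors.

    Aperiodic directions are left untouched; for periodic ones the fractional
    coordinate is wrapped into [-0.5, 0.5).
    """
    if cell is None or not any(pbc):
        return delta
    frac = np.linalg.solve(cell.T, np.atleast_2d(delta).T).T
    for d, periodic in enumerate(pbc):
        if periodic:
            frac[..., d] -= np.round(frac[..., d])
    out = frac @ cell
    return out.reshape(np.shape(delta))
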