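"""Committee (ensemble) machinery: prediction and continual-learning schedules.

A committee is M surrogate members distinguished by their weight-
initialization seeds and (initially) disjoint data subsets.  During active
learning every member is incrementally updated for a small number of epochs
per new sample — continual learning from the current weights, never
reinitialized — and only after sampling stops is the selected member trained
to convergence with patience-based early stopping.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np

from .data import AtomicSystem, ConfigurationError, DatasetStore
from .surrogate import SurrogateMember, SurrogateSpec, UntrainedModelError, descriptor


@dataclass
class TrainingSchedule:
    """Incremental-training schedule shared by all members.

    ``intermediate_split`` optionally chunks the per-event epochs (e.g.
    ``[5, 5]``): chunk boundaries are yield points at which the engine may
    propagate other trajectories before finishing the event's training; the
    numerics are unchanged by the chunking.
    """

    al_epochs_per_event: int = 1
    idg_epochs_per_event: int = 5
    intermediate_split: list[int] | None = None
    convergence_patience: int = 50

    def __post_init__(self) -> None:
        if self.al_epochs_per_event < 0 or self.idg_epochs_per_event < 1:
            raise ConfigurationError("epoch counts must be positive")
        if self.intermediate_split is not None:
            if any(c < 1 for c in self.intermediate_split):
                raise ConfigurationError("intermediate chunks must be positive")

    def al_chunks(self) -> list[int]:
        if self.intermediate_split is not None:
            return list(self.intermediate_split)
        return [self.al_epochs_per_event] if self.al_epochs_per_event else []


@dataclass
class CommitteePrediction:
    """All member energies/forces and their arithmetic means."""

    per_member_energy: np.ndarray  # (M,)
    per_member_forces: np.ndarray  # (M, N, 3)
    mean_energy: float
    mean_forces: np.ndarray        # (N, 3)


class Committee:
    """M independently seeded surrogate members plus their training schedule."""

    def __init__(self, members: list[SurrogateMember], schedule: TrainingSchedule):
        self.members = members
        self.schedule = schedule

    @property
    def M(self) -> int:
        return len(self.members)

    @property
    def member_seeds(self) -> list[int]:
        return [m.seed for m in self.members]

    def predict(self, system: AtomicSystem) -> CommitteePrediction:
        """Evaluate every member on ``system``; pure (no state change)."""
        if any(not m.trained for m in self.members):
            raise UntrainedModelError("committee has untrained members")
        phi, jac = descriptor(self.members[0].spec, system)
        energies = np.empty(self.M)
        forces = np.empty((self.M, system.n_atoms, 3))
        for j, member in enumerate(self.members):
            energies[j], forces[j] = member.predict_from(phi, jac)
        return CommitteePrediction(
            per_member_energy=energies,
            per_member_forces=forces,
            mean_energy=float(energies.mean()),
            mean_forces=forces.mean(axis=0),
        )

    def mean_forces(self, system: AtomicSystem) -> np.ndarray:
        return self.predict(system).mean_forces

    # -- persistence --------------------------------------------------------

    def save(self, directory) -> None:
        os.makedirs(directory, exist_ok=True)
        manifest = {"M": self.M, "seeds": self.member_seeds}
        with open(os.path.join(directory, "manifest.json"), "w") as fh:
            json.dump(manifest, fh)
        for j, member in enumerate(self.members):
            state = member.state_dict()
            np.savez(
                os.path.join(directory, f"member_{j}.npz"),
                **{k: np.asarray(v) for k, v in state.items()},
            )

    def load(self, directory) -> None:
        for j, member in enumerate(self.members):
            with np.load(os.path.join(directory, f"member_{j}.npz")) as data:
                member.load_state_dict({k: data[k] for k in data.files})


def init_committee(
    M: int,
    seeds: list[int],
    surrogate_spec: SurrogateSpec | None = None,
    schedule: TrainingSchedule | None = None,
) -> Committee:
    """Build a committee of M members with pairwise-distinct seeds."""
    if M < 2:
        raise ConfigurationError("committee needs M >= 2 members")
    if len(seeds) != M or len(set(seeds)) != M:
        raise ConfigurationError("need exactly M pairwise-distinct member seeds")
    spec = surrogate_spec or SurrogateSpec()
    return Committee(
        members=[SurrogateMember(spec, s) for s in seeds],
        schedule=schedule or TrainingSchedule(),
    )


def train_increment(committee: Committee, dataset: DatasetStore, epochs: int) -> Committee:
    """Train every member for exactly ``epochs`` passes over its subset.

    Continues from the current weights and optimizer state (continual
    learning); deterministic given seeds and the members' lifetime epoch
    counters.  ``epochs=0`` leaves the committee unchanged.
    """
    if epochs == 0:
        return committee
    for j, member in enumerate(committee.members):
        indices = dataset.member_train[j]
        if not indices:
            raise ConfigurationError(f"member {j} has an empty training subset")
        member.train_epochs(dataset, indices, epochs)
    return committee


def validation_mae(member: SurrogateMember, dataset: DatasetStore, indices: list[int]) -> float:
    """Force MAE (eV/Å) over all components of the member's validation samples."""
    if not indices:
        raise ConfigurationError("empty validation subset")
    return member.force_mae(dataset, indices)


def train_to_convergence(
    member: SurrogateMember,
    dataset: DatasetStore,
    train_indices: list[int],
    val_indices: list[int],
    patience: int = 50,
    max_epochs: int = 5000,
) -> SurrogateMember:
    """Train until validation force MAE stalls for ``patience`` epochs.

    Returns the member restored to its best-validation state (the arg-min
    over the validation curve, not the last state).  ``max_epochs`` bounds
    pathological non-plateauing runs.
    """
    if not val_indices:
        raise ConfigurationError("empty validation subset")
    if not train_indices:
        raise ConfigurationError("empty training subset")
    best_mae = validation_mae(member, dataset, val_indices)
    best_state = member.state_dict()
    since_improvement = 0
    for _ in range(max_epochs):
        member.train_epochs(dataset, train_indices, 1)
        mae = validation_mae(member, dataset, val_indices)
        if mae < best_mae - 1e-12:
            best_mae = mae
            best_state = member.state_dict()
            since_improvement = 0
        else:
            since_improvement += 1
            if since_improvement > patience:
                break
    member.load_state_dict(best_state)
    return member


def select_best(committee: Committee, dataset: DatasetStore) -> int:
    """Index of the member with the lowest validation force MAE (ties → lowest)."""
    maes = [
        validation_mae(member, dataset, dataset.member_val[j])
        for j, member in enumerate(committee.members)
    ]
    return int(np.argmin(maes))
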