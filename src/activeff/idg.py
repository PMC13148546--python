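"""Initial data set generation (IDG): sampler-driven MD plus bounded pretraining.

Before active learning can start, the committee must be able to run stable
dynamics in some region of the potential energy surface.  A *sampler* PES —
either an approximate geometry generator (the role a general-purpose
foundation model plays) or the reference oracle itself — drives Langevin MD;
every ``decorrelation_stride``-th frame is labeled by the reference oracle.
The first round's labels are split into disjoint, equal-sized member
subsets; later rounds grow each member's subset disjointly.  After each
round the committee trains a small bounded number of epochs (continual
learning, weights never reinitialized) until a stopping criterion is met.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .committee import Committee, train_increment, validation_mae
from .data import (
    AtomicSystem,
    ConfigurationError,
    DatasetStore,
    LabeledSample,
    assign_train_val,
    split_member_subsets,
)
from .dynamics import DynamicsError, TrajectoryState, langevin_step
from .ledger import RunLedger
from .oracles import OracleFailure, OraclePES


@dataclass
class IDGConfig:
    """Settings of the initial data-generation phase.

    ``stop`` is one of ``max_epochs`` (total pretraining epochs),
    ``train_size`` (labeled training structures) or ``scaled_target_mae``
    (validation force MAE below ``scaled_target_mae_factor`` × the active
    learning target MAE).
    """

    sampler: OraclePES
    points_per_member_per_round: int = 8
    decorrelation_stride: int = 20
    epochs_per_round: int = 5
    stop: str = "max_epochs"
    max_epochs: int = 50
    train_size: int | None = None
    target_mae: float | None = None
    scaled_target_mae_factor: float = 2.0
    temperature: float = 500.0
    dt: float = 1.0
    friction: float = 0.001
    ratio_train: int = 1
    ratio_val: int = 1

    def __post_init__(self) -> None:
        if self.points_per_member_per_round < 1 or self.decorrelation_stride < 1:
            raise ConfigurationError("IDG counts and strides must be positive")
        if self.stop not in ("max_epochs", "train_size", "scaled_target_mae"):
            raise ConfigurationError(f"unknown IDG stop criterion {self.stop!r}")
        if self.stop == "train_size" and self.train_size is None:
            raise ConfigurationError("train_size stop requires a target size")
        if self.stop == "scaled_target_mae" and self.target_mae is None:
            raise ConfigurationError("scaled_target_mae stop requires target_mae")


@dataclass
class IDGState:
    """Progress counters the stopping criterion is evaluated against."""

    epochs: int = 0
    train_size: int = 0
    best_val_mae: float | None = None


def idg_stop_met(state: IDGState, config: IDGConfig) -> bool:
    """True iff the configured IDG stopping criterion holds."""
    if config.stop == "max_epochs":
        return state.epochs >= config.max_epochs
    if config.stop == "train_size":
        return state.train_size >= config.train_size
    if state.best_val_mae is None:
        return False
    return state.best_val_mae <= config.scaled_target_mae_factor * config.target_mae


def _best_val_mae(committee: Committee, dataset: DatasetStore) -> float | None:
    if any(not m.trained for m in committee.members):
        return None
    if not dataset.member_val or not all(dataset.member_val):
        return None
    return min(
        validation_mae(m, dataset, dataset.member_val[j])
        for j, m in enumerate(committee.members)
    )


def run_idg(
    config: IDGConfig,
    oracle: OraclePES,
    committee: Committee,
    initial_geometries: dict[str, AtomicSystem],
    seed: int = 0,
    ledger: RunLedger | None = None,
    dataset: DatasetStore | None = None,
) -> tuple[DatasetStore, Committee, RunLedger]:
    """Generate the initial labeled dataset and pretrain the committee.

    The sampler generates geometries only; every label comes from
    ``oracle``.  Oracle failures skip the frame and sampling continues;
    sampler instability aborts with a diagnostic.
    """
    ledger = ledger or RunLedger()
    dataset = dataset if dataset is not None else DatasetStore()
    if not hasattr(dataset, "label_counter"):
        dataset.label_counter = 0
    M = committee.M
    trajectories = {
        tag: TrajectoryState(
            system=geom.copy(),
            temperature=config.temperature,
            friction=config.friction,
            dt=config.dt,
            rng_seed=seed,
            trajectory_id=1000 + i,
            check_interval=config.decorrelation_stride,
        )
        for i, (tag, geom) in enumerate(initial_geometries.items())
    }
    state = IDGState(
        epochs=0, train_size=dataset.n_train, best_val_mae=_best_val_mae(committee, dataset)
    )
    first_round = dataset.n_members == 0
    round_index = 0
    while not idg_stop_met(state, config):
        new_train: list[int] = []
        new_val: list[int] = []
        quota = config.points_per_member_per_round * M
        for tag, traj in trajectories.items():
            collected = 0
            while collected < quota:
                try:
                    for _ in range(config.decorrelation_stride):
                        langevin_step(traj, lambda s: config.sampler.evaluate(s)[1])
                except DynamicsError as exc:
                    raise DynamicsError(f"IDG sampler unstable for {tag}: {exc}")
                ledger.record_md_steps(f"idg:{tag}", config.decorrelation_stride)
                try:
                    energy, forces = oracle.evaluate(traj.system)
                except OracleFailure:
                    ledger.record_failure()
                    continue
                split = assign_train_val(
                    dataset.label_counter, config.ratio_train, config.ratio_val
                )
                dataset.label_counter += 1
                sample = LabeledSample(
                    system=traj.system.copy(),
                    energy=energy,
                    forces=forces,
                    level=oracle.level,
                    stage="idg",
                    trajectory_id=traj.trajectory_id,
                    step=traj.step,
                )
                idx = dataset.add(sample, split)
                ledger.record_label("idg", tag)
                (new_train if split == "train" else new_val).append(idx)
                if split == "train":
                    collected += 1
        if first_round:
            split_member_subsets(dataset, M, seed)
            first_round = False
        else:
            _grow_member_subsets(dataset, new_train, new_val, M, (seed, round_index))
        epochs = config.epochs_per_round
        if config.stop == "max_epochs":
            epochs = min(epochs, config.max_epochs - state.epochs)
        if epochs > 0:
            train_increment(committee, dataset, epochs)
            state.epochs += epochs
        state.train_size = dataset.n_train
        state.best_val_mae = _best_val_mae(committee, dataset)
        round_index += 1
    ledger.log(f"idg finished: {dataset.n_train} train / {dataset.n_val} val")
    return dataset, committee, ledger


def _grow_member_subsets(
    dataset: DatasetStore, new_train: list[int], new_val: list[int], M: int, seed
) -> None:
    """Distribute a round's new indices disjointly across members."""
    rng = np.random.default_rng(seed)
    for indices, subsets in ((new_train, dataset.member_train), (new_val, dataset.member_val)):
        if not indices:
            continue
        perm = rng.permutation(len(indices))
        per = len(indices) // M
        for m in range(M):
            extra = [indices[perm[m * per + j]] for j in range(per)]
            subsets[m].extend(sorted(extra))
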