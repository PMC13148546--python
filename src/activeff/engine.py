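"""Orchestration of the active-learning workflow.

Serial and parallel multi-trajectory loops around the same contract:
propagate each sampling trajectory to its next uncertainty check point,
evaluate the committee disagreement, consult the *shared* adaptive
threshold, and — when a structure triggers — label it with the reference
oracle, append it to every member's dataset at the configured train/val
ratio, and run a small continual-learning training increment before the
triggering trajectory resumes from its halted configuration.

In parallel mode a triggering trajectory halts and submits its labeling
task to a worker pool while the other trajectories keep propagating;
training increments stay serialized.  Ground-truth probes fire every
``probe_interval`` MD steps per trajectory, independent of the trigger, and
never enter the training set or the threshold history.
"""

from __future__ import annotations

import itertools
from concurrent.futures import FIRST_COMPLETED, ThreadPoolExecutor, wait
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .committee import Committee, select_best, train_increment, train_to_convergence, validation_mae
from .data import (
    AtomicSystem,
    ConfigurationError,
    DatasetStore,
    LabeledSample,
    assign_train_val,
)
from .dynamics import DynamicsError, TrajectoryState, propagate_until_check
from .ledger import ProbeRecord, RunLedger
from .oracles import OracleFailure, OraclePES
from .uncertainty import BootstrapSignal, ThresholdState, qbc_force_variance


def derive_seed(*parts: int) -> int:
    """Fold integer parts into a reproducible 31-bit component seed."""
    return int(np.random.SeedSequence(list(parts)).generate_state(1)[0] % (2**31))


@dataclass
class TrajectorySpec:
    """One sampling trajectory's system and thermostat settings."""

    tag: str
    system: AtomicSystem
    temperature: float = 500.0
    dt: float = 1.0
    friction: float = 0.001
    check_interval: int = 20


@dataclass
class ALConfig:
    """Active-learning run settings.

    ``stop`` is one of ``train_size`` (training structures collected,
    evaluated once the current train/val ratio block is complete),
    ``target_mae`` (best member validation force MAE), ``max_epochs``
    (total AL training epochs) or ``max_md_steps`` (total MD steps summed
    over trajectories, also honored by the other criteria as a cap when
    set).
    """

    trajectories: list[TrajectorySpec]
    stop: str = "train_size"
    train_size: int = 500
    target_mae: float | None = None
    max_epochs: int | None = None
    max_md_steps: int | None = None
    ratio_train: int = 1
    ratio_val: int = 1
    threshold_window: int = 400
    threshold_c: float = 0.0
    freeze_at_train_size: int | None = None
    probe_interval: int | None = 100
    max_workers: int = 1
    mode: str = "serial"
    master_seed: int = 0

    def __post_init__(self) -> None:
        if not self.trajectories:
            raise ConfigurationError("need at least one trajectory")
        if self.stop not in ("train_size", "target_mae", "max_epochs", "max_md_steps"):
            raise ConfigurationError(f"unknown stop criterion {self.stop!r}")
        if self.stop == "target_mae" and self.target_mae is None:
            raise ConfigurationError("target_mae stop requires a value")
        if self.stop == "max_epochs" and self.max_epochs is None:
            raise ConfigurationError("max_epochs stop requires a value")
        if self.stop == "max_md_steps" and self.max_md_steps is None:
            raise ConfigurationError("max_md_steps stop requires a value")
        if self.max_workers < 1:
            raise ConfigurationError("max_workers must be >= 1")


class _RunState:
    """Mutable run context shared by the serial and parallel loops."""

    def __init__(self, config: ALConfig, oracle, committee, dataset, ledger):
        self.config = config
        self.oracle = oracle
        self.committee = committee
        self.dataset = dataset
        self.ledger = ledger
        if not hasattr(dataset, "label_counter"):
            dataset.label_counter = 0
        self.threshold = ThresholdState(
            window=config.threshold_window,
            c=config.threshold_c,
            freeze_at_train_size=config.freeze_at_train_size,
        )
        self.trajectories = [
            TrajectoryState(
                system=spec.system.copy(),
                temperature=spec.temperature,
                friction=spec.friction,
                dt=spec.dt,
                rng_seed=config.master_seed,
                trajectory_id=tid,
                check_interval=spec.check_interval,
            )
            for tid, spec in enumerate(config.trajectories)
        ]
        self.tags = [spec.tag for spec in config.trajectories]
        self.next_probe = [
            config.probe_interval if config.probe_interval else None
            for _ in config.trajectories
        ]
        self.al_epochs = 0
        self.stopped = False

    # -- pieces --------------------------------------------------------------

    def force_provider(self):
        committee = self.committee
        return lambda system: committee.mean_forces(system)

    def advance(self, tid: int) -> AtomicSystem | None:
        """Propagate one check interval; run due probes; return the snapshot."""
        traj = self.trajectories[tid]
        try:
            _, snapshot = propagate_until_check(traj, self.force_provider())
        except DynamicsError as exc:
            self.ledger.log(f"trajectory {tid} stopped: {exc}")
            return None
        self.ledger.record_md_steps(f"al:{self.tags[tid]}:{tid}", traj.check_interval)
        if self.next_probe[tid] is not None and traj.step >= self.next_probe[tid]:
            self.probe(tid, snapshot, traj.step)
            self.next_probe[tid] += self.config.probe_interval
        return snapshot

    def probe(self, tid: int, snapshot: AtomicSystem, step: int) -> None:
        record = probe_ground_truth(
            snapshot, self.committee, self.oracle, trajectory_id=tid, step=step
        )
        if record is None:
            self.ledger.record_failure()
        else:
            self.ledger.record_probe(record)

    def decide(self, tid: int, snapshot: AtomicSystem) -> tuple[bool, float]:
        delta = qbc_force_variance(self.committee.predict(snapshot))
        try:
            current = self.threshold.threshold_value()
        except BootstrapSignal:
            current = None
        labeled = self.threshold.observe_and_decide(delta, self.dataset.n_train)
        traj = self.trajectories[tid]
        self.ledger.record_threshold(traj.step, tid, delta, current, labeled)
        return labeled, delta

    def insert(self, tid: int, snapshot: AtomicSystem, energy, forces) -> int:
        config = self.config
        split = assign_train_val(
            self.dataset.label_counter, config.ratio_train, config.ratio_val
        )
        self.dataset.label_counter += 1
        sample = LabeledSample(
            system=snapshot,
            energy=energy,
            forces=forces,
            level=self.oracle.level,
            stage="al",
            trajectory_id=tid,
            step=self.trajectories[tid].step,
        )
        idx = self.dataset.add(sample, split)
        self.dataset.add_to_all_members(idx)
        self.ledger.record_label("al", self.tags[tid])
        return idx

    def best_val_mae(self) -> float | None:
        if not self.dataset.member_val or not all(self.dataset.member_val):
            return None
        return min(
            validation_mae(m, self.dataset, self.dataset.member_val[j])
            for j, m in enumerate(self.committee.members)
        )

    def total_md_steps(self) -> int:
        return sum(t.step for t in self.trajectories)

    def stop_met(self) -> bool:
        config = self.config
        if config.max_md_steps is not None and self.total_md_steps() >= config.max_md_steps:
            return True
        if config.stop == "train_size":
            block = config.ratio_train + config.ratio_val
            return (
                self.dataset.n_train >= config.train_size
                and self.dataset.label_counter % block == 0
            )
        if config.stop == "target_mae":
            mae = self.best_val_mae()
            return mae is not None and mae <= config.target_mae
        if config.stop == "max_epochs":
            return self.al_epochs >= config.max_epochs
        return False  # max_md_steps handled by the cap above


def probe_ground_truth(
    snapshot: AtomicSystem,
    committee: Committee,
    oracle: OraclePES,
    trajectory_id: int = 0,
    step: int = 0,
) -> ProbeRecord | None:
    """Evaluate uncertainty and true max-per-atom force error at a snapshot.

    The probe structure never enters training or the threshold history;
    returns None when the oracle call fails (the probe is skipped).
    """
    prediction = committee.predict(snapshot)
    delta = qbc_force_variance(prediction)
    try:
        _, ref_forces = oracle.evaluate(snapshot)
    except OracleFailure:
        return None
    err = np.linalg.norm(prediction.mean_forces - ref_forces, axis=1)
    return ProbeRecord(
        delta=delta,
        true_error=float(err.max()),
        trajectory_id=trajectory_id,
        step=step,
    )


def _train_event(state: _RunState, tid: int, queue: list) -> None:
    """Run one label event's training chunks with yield-point propagation.

    Between chunks the *other* running trajectories each advance one check
    interval; structures they trigger are queued FIFO and handled as their
    own label events afterwards.
    """
    chunks = state.committee.schedule.al_chunks()
    for chunk_index, chunk in enumerate(chunks):
        train_increment(state.committee, state.dataset, chunk)
        state.al_epochs += chunk
        if chunk_index < len(chunks) - 1:
            for other in range(len(state.trajectories)):
                if other == tid or state.trajectories[other].status != "running":
                    continue
                snapshot = state.advance(other)
                if snapshot is None:
                    continue
                labeled, _ = state.decide(other, snapshot)
                if labeled:
                    state.trajectories[other].status = "halted_for_label"
                    queue.append((other, snapshot))


def run_serial(
    config: ALConfig,
    oracle: OraclePES,
    committee: Committee,
    dataset: DatasetStore,
    ledger: RunLedger | None = None,
) -> tuple[Committee, DatasetStore, RunLedger]:
    """Fully synchronous active learning: the sampler waits for each label."""
    ledger = ledger or RunLedger()
    state = _RunState(config, oracle, committee, dataset, ledger)
    queue: list[tuple[int, AtomicSystem]] = []
    rotation = itertools.cycle(range(len(state.trajectories)))
    while not state.stop_met():
        if queue:
            tid, snapshot = queue.pop(0)
        else:
            if all(t.status != "running" for t in state.trajectories):
                ledger.log("all trajectories stopped before the criterion was met")
                break
            tid = next(rotation)
            traj = state.trajectories[tid]
            if traj.status != "running":
                continue
            snapshot = state.advance(tid)
            if snapshot is None:
                continue
            labeled, _ = state.decide(tid, snapshot)
            if not labeled:
                continue
            traj.status = "halted_for_label"
        # synchronous labeling of the halted trajectory's snapshot
        try:
            energy, forces = oracle.evaluate(snapshot)
        except OracleFailure:
            ledger.record_failure()
            state.trajectories[tid].status = "running"
            continue
        state.insert(tid, snapshot, energy, forces)
        _train_event(state, tid, queue)
        state.trajectories[tid].status = "running"
    ledger.log(
        f"al finished: {dataset.n_train} train / {dataset.n_val} val, "
        f"{state.total_md_steps()} MD steps"
    )
    return committee, dataset, ledger


def run_parallel(
    config: ALConfig,
    oracle: OraclePES,
    committee: Committee,
    dataset: DatasetStore,
    ledger: RunLedger | None = None,
) -> tuple[Committee, DatasetStore, RunLedger]:
    """Asynchronous labeling: triggering trajectories halt, the rest keep going.

    Up to ``max_workers`` labeling tasks run concurrently in a worker pool
    (scaled up and down on demand to the cap); completed labels are inserted
    FIFO by trigger time and each insertion is followed by a serialized
    training increment.  With one trajectory and one worker the label
    sequence coincides with :func:`run_serial`.  Labels in flight when the
    stop criterion fires are completed and inserted (logged overshoot).
    """
    ledger = ledger or RunLedger()
    state = _RunState(config, oracle, committee, dataset, ledger)
    pending: list[tuple] = []  # FIFO: (future, tid, snapshot)
    with ThreadPoolExecutor(max_workers=config.max_workers) as pool:
        while not state.stop_met():
            progressed = False
            for tid, traj in enumerate(state.trajectories):
                if traj.status != "running":
                    continue
                snapshot = state.advance(tid)
                if snapshot is None:
                    continue
                progressed = True
                labeled, _ = state.decide(tid, snapshot)
                if labeled:
                    traj.status = "halted_for_label"
                    future = pool.submit(oracle.evaluate, snapshot)
                    pending.append((future, tid, snapshot))
            if not progressed and not pending:
                ledger.log("all trajectories stopped before the criterion was met")
                break
            if not progressed and pending:
                wait([pending[0][0]], return_when=FIRST_COMPLETED)
            # insert completed labels FIFO by trigger time
            while pending and pending[0][0].done():
                future, tid, snapshot = pending.pop(0)
                try:
                    energy, forces = future.result()
                except OracleFailure:
                    ledger.record_failure()
                    state.trajectories[tid].status = "running"
                    continue
                state.insert(tid, snapshot, energy, forces)
                train_increment(
                    state.committee, state.dataset, state.committee.schedule.al_epochs_per_event
                )
                state.al_epochs += state.committee.schedule.al_epochs_per_event
                state.trajectories[tid].status = "running"
                if state.stop_met():
                    break
        # drain in-flight labels at stop (slight overshoot, logged)
        for future, tid, snapshot in pending:
            try:
                energy, forces = future.result()
            except OracleFailure:
                ledger.record_failure()
                continue
            state.insert(tid, snapshot, energy, forces)
            ledger.log(f"in-flight label from trajectory {tid} inserted after stop")
    ledger.log(
        f"al finished: {dataset.n_train} train / {dataset.n_val} val, "
        f"{state.total_md_steps()} MD steps"
    )
    return committee, dataset, ledger


def pearson(x, y) -> float:
    """Sample Pearson correlation coefficient in [−1, 1]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length inputs with at least 3 points")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    return float(stats.pearsonr(x, y).statistic)


def finalize(
    committee: Committee,
    dataset: DatasetStore,
    mode: str = "best",
    patience: int = 50,
) -> tuple[list[int], list[float]]:
    """Convergence-train the best member (or all members) on the full data.

    Returns the trained member indices and their final validation force MAE.
    Each member is trained on the entire training set with patience-based
    early stopping and restored to its best validation state.
    """
    if not dataset.val_indices():
        raise ConfigurationError("cannot finalize without validation data")
    train_idx = dataset.train_indices()
    val_idx = dataset.val_indices()
    if mode == "best":
        chosen = [select_best(committee, dataset)]
    elif mode == "all":
        chosen = list(range(committee.M))
    else:
        raise ConfigurationError(f"unknown finalize mode {mode!r}")
    maes = []
    for j in chosen:
        member = train_to_convergence(
            committee.members[j], dataset, train_idx, val_idx, patience=patience
        )
        maes.append(member.force_mae(dataset, val_idx))
    return chosen, maes


def recompute_at_level(
    dataset: DatasetStore,
    higher_oracle: OraclePES,
    ledger: RunLedger | None = None,
) -> tuple[DatasetStore, RunLedger]:
    """Relabel every collected structure once with a higher-level oracle.

    Geometries are untouched; provenance switches to the new level tag.
    Failed relabelings drop the structure (counted and logged); member
    subsets are remapped to the surviving indices.
    """
    ledger = ledger or RunLedger()
    out = DatasetStore()
    mapping: dict[int, int] = {}
    for idx, sample in enumerate(dataset.samples):
        try:
            energy, forces = higher_oracle.evaluate(sample.system)
        except OracleFailure:
            ledger.record_failure()
            ledger.log(f"recompute failed for sample {idx}; structure dropped")
            continue
        new_sample = LabeledSample(
            system=sample.system.copy(),
            energy=energy,
            forces=forces,
            level=higher_oracle.level,
            stage="recompute",
            trajectory_id=sample.trajectory_id,
            step=sample.step,
        )
        mapping[idx] = out.add(new_sample, dataset.split[idx])
        ledger.record_recompute()
    out.member_train = [
        [mapping[i] for i in subset if i in mapping] for subset in dataset.member_train
    ]
    out.member_val = [
        [mapping[i] for i in subset if i in mapping] for subset in dataset.member_val
    ]
    return out, ledger


def report(ledger: RunLedger) -> dict:
    """Summarize a run: per-system counts, stage totals, probe correlations.

    The probe stream is split into equal thirds per trajectory and the
    uncertainty–error Pearson coefficient is reported per segment.
    """
    if ledger.total_successful_calls == 0:
        raise ValueError("empty ledger")
    per_system = {
        tag: {
            "idg": counts.get("idg", 0),
            "al": counts.get("al", 0),
            "total": counts.get("idg", 0) + counts.get("al", 0),
        }
        for tag, counts in ledger.labels_by_system.items()
    }
    by_traj: dict[int, list[ProbeRecord]] = {}
    for rec in ledger.probe_records:
        by_traj.setdefault(rec.trajectory_id, []).append(rec)
    probe_correlation = {}
    for tid, records in sorted(by_traj.items()):
        segments = []
        n = len(records)
        for seg in range(3):
            chunk = records[seg * n // 3 : (seg + 1) * n // 3]
            if len(chunk) >= 3:
                try:
                    segments.append(
                        pearson([r.delta for r in chunk], [r.true_error for r in chunk])
                    )
                except ValueError:
                    segments.append(None)
            else:
                segments.append(None)
        probe_correlation[tid] = segments
    return {
        "labels_by_system": per_system,
        "oracle_calls": dict(ledger.oracle_calls),
        "total_successful_calls": ledger.total_successful_calls,
        "total_labels": sum(v["total"] for v in per_system.values()),
        "md_steps": dict(ledger.md_steps),
        "probe_count": len(ledger.probe_records),
        "probe_correlation_by_trajectory_thirds": probe_correlation,
        "threshold_trace_length": len(ledger.threshold_trace),
    }
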