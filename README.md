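# activeff

Parallel active learning for committee machine-learning force fields, at
desk scale.

Building a machine-learning force field (MLFF) traditionally means running
long *ab initio* MD and hand-curating the frames — tens of thousands of
expensive reference calculations, most of them redundant. Active learning
(AL) inverts the loop: an ensemble ("committee") of surrogate models
drives the sampling itself, and only configurations the committee
disagrees about are sent to the reference method for labeling. `activeff`
implements this workflow end to end for researchers who want to study,
prototype or teach it without a DFT code or a GPU: analytic
potential-energy-surface oracles stand in for the reference method, a
fast random-features committee stands in for neural-network potentials
behind a pluggable interface, and every stage — initial data generation,
multi-trajectory Langevin sampling, adaptive thresholding, continual
model updates, serial/parallel orchestration, diagnostics — is real,
tested code.

## The method

Uncertainty on a sampled configuration is the committee's maximum
per-atom force variance,

```
δ = max_i  (1/3M) Σ_{j=1..M} Σ_{k∈{x,y,z}} (F_ijk − F̄_ik)²
```

(M members j, atoms i, Cartesian components k). A configuration is labeled
when δ exceeds an adaptive threshold — a scaled moving average of the
uncertainties observed so far,

```
δ_t = (1 + c) · mean(last N observed δ),        N = 400, c = 0 by default
```

shared across all sampling trajectories. Each new label is appended to
every member's dataset (train or validation, deterministic round-robin)
and each member trains a single epoch from its current weights —
continual learning, never reinitialized — before the triggering
trajectory resumes. Unbiased ground-truth probes every 100 MD steps
record true error alongside δ, so the uncertainty–error correlation can
be monitored without biasing data collection. After sampling stops, the
best member by validation force MAE is trained to convergence, and the
collected structures can be relabeled once at a "higher level of theory".

See `docs/methods.md` for the full model descriptions, defaults, study
conditions and limitations.

## Worked example

```python
import activeff as a
from activeff.systems import flexible_chain_oracle, place_chain, softened

oracle = flexible_chain_oracle()                 # double-well chain reference PES
committee = a.init_committee(4, [0, 1, 2, 3])    # 4 members, distinct seeds

idg = a.IDGConfig(
    sampler=softened(oracle),                    # approximate geometry generator
    points_per_member_per_round=4,
    stop="max_epochs", max_epochs=20,
    temperature=300.0,
)
dataset, committee, ledger = a.run_idg(
    idg, oracle, committee, {"flex": place_chain(8, tag="flex")}, seed=7
)
print(f"IDG: {dataset.n_train} train / {dataset.n_val} val structures "
      f"({ledger.oracle_calls['idg']} oracle calls)")

config = a.ALConfig(
    trajectories=[a.TrajectorySpec(tag="flex", system=place_chain(8, tag="flex"))],
    stop="train_size", train_size=100,
    probe_interval=100,
    master_seed=11,
)
committee, dataset, ledger = a.run_serial(config, oracle, committee, dataset, ledger)
print(f"AL:  {dataset.n_train} train / {dataset.n_val} val structures "
      f"({ledger.oracle_calls['al']} labels, {ledger.total_md_steps} MD steps, "
      f"{len(ledger.probe_records)} probes)")

best, maes = a.finalize(committee, dataset, mode="best")
print(f"best member {best[0]}: validation force MAE {maes[0]:.4f} eV/A")
```

prints

```
IDG: 64 train / 63 val structures (127 oracle calls)
AL:  100 train / 100 val structures (73 labels, 19760 MD steps, 172 probes)
best member 3: validation force MAE 0.0766 eV/A
```

Reading: pretraining labeled 127 decorrelated sampler-MD frames; active
learning then propagated ~20k MD steps on the committee-mean forces but
paid for only 73 additional reference labels — the configurations the
committee disagreed on — to reach 100 training structures with a matched
1:1 validation set, after which convergence training of the best member
reached a 0.077 eV/Å validation force MAE. The 172 probes are diagnostic
ground-truth calls, never used for training.

The same workflow is scriptable from the shell (`activeff idg`, `learn`,
`finalize`, `recompute`, `report`) against a YAML config; outputs are
extended-XYZ datasets, model checkpoints, a JSON run ledger and CSV
threshold/probe traces.

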