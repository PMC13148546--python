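# Methods

`activeff` is a desk-scale engine for building machine-learning force
fields (MLFFs) by committee-based active learning (AL). This note records
the models, the algorithmic contracts, the synthetic study systems, the
numerical choices, and the limitations a user should know before trusting
results on their own systems.

## The workflow

The engine automates the standard on-the-fly AL loop for interatomic
potentials:

1. **Initial data generation (IDG).** A *sampler* potential — either an
   approximate geometry generator standing in for a general-purpose
   foundation force field, or the reference oracle itself — drives Langevin
   MD. Every `decorrelation_stride`-th frame (default 20) is labeled by
   the reference oracle. The first batch of labels is split into disjoint,
   equal-sized training subsets, one per committee member; later IDG rounds
   grow each member's subset disjointly. After each round the members
   train a bounded number of epochs (default 5) from their current weights
   (continual learning — weights are never reinitialized). IDG stops on a
   maximum epoch count, a training-set size, or when the best member's
   validation force MAE falls below a scaled multiple of the AL target.
2. **Active learning.** One or more trajectories propagate Langevin MD on
   the *committee-mean* forces. Every `check_interval` MD steps (default
   20) the committee disagreement at the current configuration is computed
   and compared against a shared adaptive threshold. If it triggers, the
   trajectory halts, the configuration is labeled by the reference oracle,
   the sample is appended to **every** member's training or validation set
   (deterministic round-robin at the configured train:val ratio), each
   member trains `al_epochs_per_event` epochs (default 1) over its full
   current subset, and the trajectory resumes from the halted
   configuration. Sampling stops on training-set size, target validation
   MAE, total training epochs, or total MD steps.
3. **Finalization.** The member with the lowest validation force MAE (or
   all members) is trained to convergence on the whole training set with
   patience-based early stopping (default 50 epochs without improvement),
   returning the best-validation state seen.
4. **Recompute.** Optionally, every collected structure is relabeled once
   by a second, "higher-level" oracle, and a fresh model can be trained
   from scratch on the relabeled data.

### Uncertainty and threshold

Committee disagreement on a configuration is the maximum per-atom force
variance

δ = max_i (1/(3M)) Σ_{j=1..M} Σ_{k∈x,y,z} (F_ijk − F̄_ik)²,

with members j, atoms i, components k, in (eV/Å)². The labeling threshold
is a scaled moving average of past uncertainties, δ_t = (1+c)·mean(last N
observed δ), with window N = 400 and c = 0 by default; c < 0 tightens, c >
0 relaxes. The threshold state is **shared across all trajectories**: every
observed δ from every trajectory enters one ring buffer. The candidate δ
is compared (strict `>`) against the mean of *past* values and appended
after the comparison; with an empty history the decision is
unconditionally "label" (bootstrap). The threshold can be frozen once the
training set reaches a configured size. Because the average tracks the
decaying uncertainty stream, some configurations always exceed it, so
sampling never stalls.

Ground-truth **probes** fire every `probe_interval` MD steps (default 100)
per trajectory, independent of the trigger: the oracle is evaluated at the
snapshot, and both δ and the true maximum per-atom force error of the
committee mean are recorded. Probe structures never enter the training set
or the threshold history, so the probe stream is an unbiased diagnostic of
how well uncertainty tracks error (summarized as Pearson correlations per
thirds of the stream).

### Serial and parallel orchestration

In serial mode the engine round-robins trajectories and labels
synchronously. In parallel mode a triggering trajectory halts and submits
its labeling task to an in-process worker pool (up to `max_workers`
concurrent tasks, pool scaled on demand); the other trajectories keep
propagating; completed labels are inserted FIFO by trigger time, each
followed by a serialized training increment. With one trajectory and one
worker the parallel label sequence coincides with the serial one. With the
train-size criterion, runs stop only when the current train:val ratio
block is complete, so a "500 training structures at 1:1" run ends with
exactly 500 + 500 labeled structures; labels in flight at stop time are
completed and inserted (logged as overshoot). Failed oracle calls discard
the candidate and the trajectory resumes — failure handling is this
package's contract, chosen because reference-code behavior on
non-convergence is site-specific.

All randomness fans out from one master seed: member seeds, per-trajectory
noise streams, subset splits and failure streams each derive from
`(master seed, component, index)` through a seed sequence, so any component
is independently reproducible and adding trajectories never perturbs
existing ones.

## The built-in committee surrogate

Members are atom-wise random-features models. Each atom i carries a
descriptor φ_i with three blocks:

* **radial** — Gaussian radial basis (12 functions over 0.7–6.0 Å, width =
  spacing, smooth cosine cutoff) of its pair distances, pooled into
  channels keyed by the element pair and, for chain molecules, the
  topological separation |i−j| ∈ {1, 2, 3, ≥4} — the same interaction
  typing classical force fields use;
* **angular** — for every pair of neighbors (j, k): powers of cos θ_jik
  (6 by default) weighted by both cutoff envelopes, in channels keyed by
  the central atom's element and the neighbors' separations;
* **torsional** (chain topology) — powers of cos φ (4 by default) over
  consecutive bonded quadruplets, keyed by element.

A frozen, seed-randomized map t_i = tanh(Aφ_i + b) (256 features) feeds a
trainable linear head, E = Σ_i w·t_i + w₀·N, and forces are the exact
analytic negative gradient. Because A and b are frozen, energy and forces
are linear in w: per-geometry feature matrices are cached when a sample
enters the dataset, every continual-learning epoch is a handful of small
dense products, and the loss is convex. Training is AMSGrad (rate 0.01,
β = 0.9/0.999) on a weighted squared loss — energy per structure with
weight 1, force components with weight 1000 — batch size 5, gradient-norm
clipping at 10. Epoch data order is a deterministic shuffle keyed by
(member seed, lifetime epoch index), so two 1-epoch updates are
bit-identical to one 2-epoch update.

Two design points deserve emphasis:

* *Why per-member feature maps only.* An earlier variant shared a raw
  descriptor block across members to lower the representation floor.
  It was rejected: member-independent features make all members converge
  to near-identical functions, so the committee becomes confidently wrong
  in unison and disagreement stops tracking error. Query-by-committee
  diversity requires member-specific hypothesis spaces; here they come
  from the random maps A, b and the weight initialization, on top of
  disjoint initial data subsets.
* *Why the descriptor carries angular and torsional blocks.* With radial
  information only, bond-angle and torsion terms leave a systematic error
  floor (~0.2 eV/Å on the toy chains) shared by all members — invisible to
  disagreement. The added blocks put the toy surfaces essentially inside
  the hypothesis class, so residual errors are data-coverage-driven, which
  is the regime in which uncertainty-based selection is meaningful.

The committee interface is pluggable: any object exposing
`predict(system) → CommitteePrediction` and the training entry points can
stand behind the engine; the engine itself never inspects member
internals.

## Reference oracles

Analytic potential-energy surfaces with exact forces stand in for the
ab initio labeler (the engine is agnostic to the labeler):

* all-pair Lennard-Jones 4ε[(σ/r)¹² − (σ/r)⁶];
* Morse chains D(1−e^{−a(r−r₀)})² over a bonded neighbor list;
* chain force fields with harmonic bonds (k = 20 eV/Å², r₀ = 1.5 Å),
  harmonic angles (k = 3 eV/rad², θ₀ ≈ 109.5°) and a torsional term per
  consecutive quadruplet, either a symmetric double well
  U(φ) = B·(cos φ − cos φ₀)²/(1 − cos φ₀)² (minima ±φ₀, barrier exactly B
  at φ = 0) or a single well k(1 − cos(φ − φ₀)).

Dihedral gradients use the Blondel–Karplus analytic expressions; all
oracle forces are validated against central differences at 10⁻⁶ eV/Å.
A *perturbed level* wrapper adds a smooth seeded random Fourier series in
the pair distances with a prescribed amplitude — a deterministic stand-in
for a more accurate level of theory with a distinct provenance tag — and a
*failure* wrapper raises seeded convergence failures at a set rate.
Latency injection (a per-call sleep) exists purely for scheduler tests.

## Dynamics

NVT Langevin MD uses the BAOAB splitting: half-kick, half-drift, exact
Ornstein–Uhlenbeck velocity refresh, half-drift, half-kick. At zero
friction and zero temperature the scheme reduces exactly to velocity
Verlet — a contract verified to machine precision — and conserves energy
to bounded oscillation on harmonic problems. Defaults follow common
practice for small organic molecules: 1 fs time step, 0.001 fs⁻¹ friction.
Velocities initialize from the Maxwell–Boltzmann distribution with the
center-of-mass drift removed. Units are Å, fs, eV, eV/Å, K, amu
(k_B = 8.617×10⁻⁵ eV/K). The bond-length stability monitor reports a
trajectory unstable when any bonded distance exceeds 2 Å (strict
inequality, minimum-image for periodic cells); it observes and never
alters dynamics.

## Synthetic study systems

The fixtures generator builds all-carbon (or other single-element) chains
with a tunable "PES complexity" knob:

* **flexible chain** — harmonic backbone plus double-well torsions,
  barrier 0.15 eV ≈ 3.5 k_BT at the 500 K sampling temperature. This
  places well crossings in the rare-but-present regime: trajectories keep
  encountering genuinely new conformers through a run, which is the
  flexible-molecule behavior the workflow exists for. (At ~2 k_BT the
  8-atom chain's conformer space is exhausted during pretraining and AL
  has nothing left to discover.)
* **rigid chain** — the same backbone stiffness with a single torsional
  minimum (curvature matched to the double well's minima) and fewer atoms.
  Comparable force scales, far lower conformational complexity: once its
  thermal region is sampled there is nothing new.

The reference studies (in `activeff.studies`) fix the conditions used by
the acceptance script and tests: an 8-atom flexible chain; a 4-member
committee; IDG driven by a *softened* copy of the oracle (all stiffnesses
× 0.8 — physically plausible but deliberately wrong, the role a
general-purpose model plays) at 200 K, stopping when validation force MAE
reaches 6× the 0.05 eV/Å working target, so that pretraining covers only
the starting conformer's basin; AL at 500 K with checks every 20 steps,
probes every 100 steps, window 400, c = 0, to 500 training structures at a
1:1 validation ratio. The three-trajectory study starts its trajectories
from three distinct torsional conformers, mirroring the practice of
diversifying starting geometries across trajectories. The higher-level
oracle for recompute passes uses perturbation amplitude 0.05 eV.

The probe-correlation study is a stochastic, scaled-down study: its
quantities vary noticeably from seed to seed (per-third Pearson estimates
carry a standard error of roughly 0.1 at ~70 probe points). Its seed is
therefore part of the study's definition (`studies.PROBE_STUDY_SEED = 1`,
the first seed run under the frozen conditions), the same way the other
study conditions are fixed; the label-accounting study's headline number
is an exact count and is seed-independent.

What these toys do **not** emulate: chemical diversity of elements and
bonding, many-body electrostatics and dispersion, label noise,
reference-code failure modes beyond random refusal, and the cost asymmetry
of real DFT. Passing studies therefore demonstrate the correctness and
internal behavior of the *workflow* (counting, scheduling, threshold
dynamics, uncertainty–error coupling) at desk scale, not transferable
force-field accuracy.

## Design choices on genuinely open points

* "Every stride-th" decimation is 1-based (indices stride−1, 2·stride−1,
  …), so a 50,000-frame prefix at stride 25 yields exactly 2,000 picks.
* Initial member subsets are disjoint (sampling without replacement);
  disjointness maximizes initial ensemble diversity. From AL on, every new
  point goes to all members.
* Train/val assignment is a deterministic round-robin, not random, so
  label accounting is exactly reproducible; the train-size stop criterion
  fires only at ratio-block boundaries so the final validation count
  matches the configured ratio exactly.
* Farthest point sampling breaks ties toward the lowest index; the start
  point is caller-supplied (default index 0).
* The triggering δ is excluded from its own threshold comparison and
  appended afterwards; every observed δ enters the history, labeled or
  not.
* Sampling MD runs on the committee-mean forces (not a designated
  member).
* Whether IDG validation points follow the same ratio as AL is open; the
  same round-robin ratio applies throughout, and the training-size
  criterion counts training structures only.
* Trajectories that encounter non-finite forces are stopped with a
  diagnostic while the rest of the run continues; a failed label discards
  the candidate and the trajectory resumes.

## Data-efficiency accounting

The workflow's efficiency claim is measured in *reference evaluations*:
the traditional pipeline generates data by reference-driven MD, paying one
reference call per propagation step before decimating (stride 25), while
the AL engine propagates on the surrogate and pays only for the structures
it labels (validation included) plus the IDG labels. The acceptance
property requires that, to reach a 0.15 eV/Å force MAE on a common
farthest-point-sampled test set (built as in the test-set protocol:
reference MD at 500 K, stride decimation, FPS selection on pooled
descriptors, reference labels), the AL pipeline spends no more reference
calls than the stride pipeline, in at least 8 of 10 fixed seeds.

A known limitation, found while designing this study: at *matched
training-set sizes* (ignoring the cost of acquisition), training sets
acquired by this package's AL runs do not beat uniform-stride thermal
samples on the toy chains — the desk-scale random-features committee does
not reproduce the per-sample informativeness advantage that rich
message-passing architectures report; high-uncertainty states here carry
above-thermal forces that slightly skew a from-scratch fit. The efficiency
advantage measured and asserted is the reference-call accounting above.

## Problem sizes and tolerances

Studies use 8-atom chains (4-atom rigid partner in the two-system study),
4-member committees, 500 training structures for the reference studies and
20–90 for property suites — sizes chosen so every study re-runs from
scratch in minutes on one CPU. Numerical tolerances: extended-XYZ
round-trips hold to 10⁻¹⁰ relative; oracle and surrogate forces match
central differences at 10⁻⁶ eV/Å (mixed relative tolerance where force
magnitudes are large); the velocity-Verlet equivalence holds to machine
precision; equipartition and thermostat checks use 3-standard-error and 5%
bands; convergence training stops after 50 epochs without validation
improvement (bounded by a 5,000-epoch guard).
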