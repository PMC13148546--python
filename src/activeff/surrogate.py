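"""Built-in committee member: an atom-wise random-features model.

Each atom i carries a descriptor φ_i with two blocks:

* radial — Gaussian radial-basis expansions of its pair distances, smoothly
  cut off and pooled into channels keyed by the element pair and (for chain
  molecules) the topological separation of the pair: bonds, 1-3, 1-4 and
  beyond get separate channels, the same interaction typing classical force
  fields use;
* angular — three-body terms: for every pair of neighbors (j, k) of atom i,
  powers of cos θ_jik weighted by the product of the two cutoff envelopes,
  bucketed by the neighbors' topological separations (the Behler-Parrinello
  style remedy for interactions that are not additive in pair distances,
  such as bond-angle terms);
* torsional (chain topology only) — powers of cos φ over consecutive
  bonded quadruplets, the interaction typing classical force fields use
  for dihedral terms.

A frozen, seed-randomized tanh feature map turns each φ_i into features
t_i = tanh(Aφ_i + b); the energy is an atom-wise sum through a trainable
linear head over the raw descriptor (which represents any interaction
additive in the descriptor channels exactly) plus the random features
(which capture cross-channel couplings),

    E = Σ_i (v·φ_i + w·t_i) + w₀·N,

and forces are the exact analytic negative gradient.  Because A and b are
frozen, energy and forces are both *linear in the trained weights*: the
per-geometry feature matrices (h, K) with E = h·w and F = (K·w) reshaped
are cached once per sample, making every continual-learning epoch a handful
of small dense matrix products, and the training loss convex.

Training uses AMSGrad on a weighted squared loss over energies (per
structure) and force components, with gradient-norm clipping.  Epoch data
order is a deterministic shuffle keyed by (member seed, lifetime epoch
index), so two successive 1-epoch updates are bit-identical to one 2-epoch
update on frozen data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import AtomicSystem, DatasetStore


class UntrainedModelError(RuntimeError):
    """Prediction requested from a member that has never been trained."""


@dataclass
class SurrogateSpec:
    """Hyperparameters of the built-in random-features surrogate.

    ``topology='chain'`` buckets radial pair channels by chain separation
    |i−j| ∈ {1, 2, 3, ≥4} (atom order is the chain order) and angular
    channels by the two neighbors' separations from the central atom
    capped at 2; ``topology='none'`` pools all pairs of an element pair
    together and uses a single angular channel.
    """

    elements: tuple[str, ...] = ("C",)
    topology: str = "chain"
    n_separation: int = 4
    r_cut: float = 6.0          # Å, descriptor cutoff
    r_min: float = 0.7          # Å, first radial center
    n_basis: int = 12           # radial Gaussians per channel
    n_angular: int = 6          # powers of cos θ per angular channel
    n_dihedral: int = 4         # powers of cos φ (chain topology only)
    n_features: int = 256       # random tanh features D
    linear_head: bool = False   # include the shared raw-descriptor block
    learning_rate: float = 0.01
    beta1: float = 0.9
    beta2: float = 0.999
    adam_eps: float = 1e-8
    energy_weight: float = 1.0
    force_weight: float = 1000.0
    batch_size: int = 5
    grad_clip: float = 10.0
    init_scale: float = 0.01

    def __post_init__(self) -> None:
        self.elements = tuple(self.elements)
        if self.topology not in ("chain", "none"):
            raise ValueError(f"unknown topology {self.topology!r}")
        pairs = []
        for a in range(len(self.elements)):
            for b in range(a, len(self.elements)):
                pairs.append((self.elements[a], self.elements[b]))
        self._pair_channels = {p: i for i, p in enumerate(pairs)}

    @property
    def n_sep_buckets(self) -> int:
        return self.n_separation if self.topology == "chain" else 1

    @property
    def n_radial_channels(self) -> int:
        return len(self._pair_channels) * self.n_sep_buckets

    @property
    def n_angular_channels(self) -> int:
        # element-resolved (by central atom) × neighbor-separation buckets
        # capped at 2, unordered: (1,1), (1,2), (2,2)
        per_element = 3 if self.topology == "chain" else 1
        return per_element * len(self.elements)

    @property
    def radial_dim(self) -> int:
        return self.n_radial_channels * self.n_basis

    @property
    def n_dihedral_terms(self) -> int:
        # element-resolved by the quadruplet's first atom
        if self.topology != "chain":
            return 0
        return self.n_dihedral * len(self.elements)

    @property
    def descriptor_dim(self) -> int:
        return (
            self.radial_dim
            + self.n_angular_channels * self.n_angular
            + self.n_dihedral_terms
        )

    def channel(self, el_a: str, el_b: str, separation: int) -> int:
        key = (el_a, el_b) if (el_a, el_b) in self._pair_channels else (el_b, el_a)
        try:
            pair = self._pair_channels[key]
        except KeyError:
            raise KeyError(f"element pair {el_a}-{el_b} not declared in spec") from None
        bucket = min(separation, self.n_sep_buckets) - 1 if self.topology == "chain" else 0
        return pair * self.n_sep_buckets + bucket

    def element_index(self, symbol: str) -> int:
        try:
            return self.elements.index(symbol)
        except ValueError:
            raise KeyError(f"element {symbol!r} not declared in spec") from None

    def angular_channel(self, center_element: str, sep_a: int, sep_b: int) -> int:
        e = self.element_index(center_element)
        if self.topology != "chain":
            return e
        s1, s2 = sorted((min(sep_a, 2), min(sep_b, 2)))
        bucket = {(1, 1): 0, (1, 2): 1, (2, 2): 2}[(s1, s2)]
        return e * 3 + bucket


def descriptor(spec: SurrogateSpec, system: AtomicSystem) -> tuple[np.ndarray, np.ndarray]:
    """Per-atom descriptors Φ (N, F) and their Jacobian J (N, F, N, 3)."""
    n = system.n_atoms
    pos = system.positions
    G = spec.n_basis
    Q = spec.n_angular
    centers = np.linspace(spec.r_min, spec.r_cut, G)
    width = (spec.r_cut - spec.r_min) / max(G - 1, 1)
    F = spec.descriptor_dim
    phi = np.zeros((n, F))
    jac_flat = np.zeros(n * F * n * 3)

    def scatter(center_atoms, cols, target_atoms, values):
        # accumulate values[(T, C, 3)] into jac[center, col, target, :]
        idx = ((center_atoms[:, None] * F + cols) * n + target_atoms[:, None])[
            ..., None
        ] * 3 + np.arange(3)
        np.add.at(jac_flat, idx.ravel(), values.ravel())

    # ---- radial block -----------------------------------------------------
    iu, ju = np.triu_indices(n, 1)
    rvec = pos[ju] - pos[iu]
    r = np.linalg.norm(rvec, axis=1)
    mask = (r < spec.r_cut) & (r > 1e-8)
    iu, ju, rvec, r = iu[mask], ju[mask], rvec[mask], r[mask]
    u = rvec / r[:, None]
    fc = 0.5 * (1 + np.cos(np.pi * r / spec.r_cut))
    dfc = -0.5 * np.pi / spec.r_cut * np.sin(np.pi * r / spec.r_cut)
    if len(r):
        chan = np.array(
            [
                spec.channel(system.species[a], system.species[b], abs(b - a))
                for a, b in zip(iu, ju)
            ]
        )
        gauss = np.exp(-((r[:, None] - centers) ** 2) / (2 * width**2))
        basis = gauss * fc[:, None]                                   # (P, G)
        dbasis = -(r[:, None] - centers) / width**2 * basis + gauss * dfc[:, None]
        cols = chan[:, None] * G + np.arange(G)                       # (P, G)
        np.add.at(phi, (np.repeat(iu, G), cols.ravel()), basis.ravel())
        np.add.at(phi, (np.repeat(ju, G), cols.ravel()), basis.ravel())
        values = dbasis[:, :, None] * u[:, None, :]                   # (P, G, 3)
        for center in (iu, ju):
            scatter(center, cols, ju, values)
            scatter(center, cols, iu, -values)

    # ---- angular block ----------------------------------------------------
    if Q > 0 and len(r):
        pair_index = -np.ones((n, n), dtype=int)
        pair_index[iu, ju] = pair_index[ju, iu] = np.arange(len(r))
        trips = [
            (c, a, b)
            for c in range(n)
            for ai, a in enumerate(np.where(pair_index[c] >= 0)[0])
            for b in np.where(pair_index[c] >= 0)[0][ai + 1 :]
        ]
        if trips:
            tc, ta, tb = np.array(trips).T
            pa, pb = pair_index[tc, ta], pair_index[tc, tb]
            sign_a = np.where(ta > tc, 1.0, -1.0)[:, None]
            sign_b = np.where(tb > tc, 1.0, -1.0)[:, None]
            ua = u[pa] * sign_a        # unit vectors from center to neighbor
            ub = u[pb] * sign_b
            ra, rb = r[pa], r[pb]
            ct = np.sum(ua * ub, axis=1)
            dct_da = (ub - ct[:, None] * ua) / ra[:, None]
            dct_db = (ua - ct[:, None] * ub) / rb[:, None]
            env = fc[pa] * fc[pb]
            denv_da = (dfc[pa] * fc[pb])[:, None] * ua
            denv_db = (fc[pa] * dfc[pb])[:, None] * ub
            achan = np.array(
                [
                    spec.angular_channel(system.species[c], abs(a - c), abs(b - c))
                    for c, a, b in zip(tc, ta, tb)
                ]
            )
            powers = np.arange(Q)
            ctq = ct[:, None] ** powers                               # (T, Q)
            dctq = np.zeros_like(ctq)
            dctq[:, 1:] = powers[1:] * ct[:, None] ** (powers[1:] - 1)
            cols = spec.radial_dim + achan[:, None] * Q + powers      # (T, Q)
            np.add.at(phi, (np.repeat(tc, Q), cols.ravel()), (ctq * env[:, None]).ravel())
            envq = env[:, None, None]
            val_a = dctq[:, :, None] * dct_da[:, None, :] * envq + ctq[:, :, None] * denv_da[:, None, :]
            val_b = dctq[:, :, None] * dct_db[:, None, :] * envq + ctq[:, :, None] * denv_db[:, None, :]
            scatter(tc, cols, ta, val_a)
            scatter(tc, cols, tb, val_b)
            scatter(tc, cols, tc, -(val_a + val_b))

    # ---- torsional block (chain quadruplets) ------------------------------
    Q2 = spec.n_dihedral_terms
    jac = jac_flat.reshape(n, F, n, 3)
    if Q2 > 0 and n >= 4:
        from .oracles import EvaluationError, _dihedral_and_grad

        region = F - Q2
        Qd = spec.n_dihedral
        for q0 in range(n - 3):
            try:
                dihedral, grad = _dihedral_and_grad(*pos[q0 : q0 + 4])
            except EvaluationError:
                continue  # undefined dihedral contributes nothing
            base = region + spec.element_index(system.species[q0]) * Qd
            cphi, sphi = np.cos(dihedral), np.sin(dihedral)
            for q in range(Qd):
                phi[q0, base + q] += cphi**q
                if q > 0:
                    dcol = -q * cphi ** (q - 1) * sphi * grad  # (4, 3)
                    jac[q0, base + q, q0 : q0 + 4, :] += dcol
    return phi, jac


class SurrogateMember:
    """One committee member: frozen random feature map + trainable linear head."""

    def __init__(self, spec: SurrogateSpec, seed: int):
        self.spec = spec
        self.seed = int(seed)
        rng = np.random.default_rng(seed)
        D, F = spec.n_features, spec.descriptor_dim
        self.A = rng.standard_normal((D, F)) / np.sqrt(F)
        self.b = rng.uniform(-0.5, 0.5, D)
        self.head_dim = (F if spec.linear_head else 0) + D + 1
        self.w = rng.standard_normal(self.head_dim) * spec.init_scale
        # AMSGrad state
        self.m = np.zeros(self.head_dim)
        self.v = np.zeros(self.head_dim)
        self.vhat = np.zeros(self.head_dim)
        self.epoch_count = 0
        self.trained = False
        self._cache: dict[int, tuple] = {}

    # -- feature construction ------------------------------------------------

    def features(self, phi: np.ndarray, jac: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Energy features h and force features K ((N·3) × head_dim).

        ``E = h·w`` and ``F.ravel() = K·w`` — both linear in ``w``.  The
        head concatenates the (optional) pooled raw descriptor, the pooled
        tanh features and an atom count (a per-atom energy baseline with
        no force contribution).
        """
        n, F = phi.shape
        lin = F if self.spec.linear_head else 0
        t = np.tanh(phi @ self.A.T + self.b)          # (N, D)
        blocks = ([phi.sum(axis=0)] if lin else []) + [t.sum(axis=0), [float(n)]]
        h = np.concatenate(blocks)
        K = np.empty((n * 3, self.head_dim))
        if lin:
            # shared linear block: d(Σ_i φ_i)/dx
            K[:, :lin] = -jac.sum(axis=0).transpose(1, 2, 0).reshape(n * 3, F)
        # tanh block: dE/dx = Σ_i (1−t_i²) ⊙ (A · J_i)
        aj = np.einsum("df,nfmk->ndmk", self.A, jac)  # (N, D, N, 3)
        K[:, lin:-1] = -np.einsum("nd,ndmk->mkd", 1 - t**2, aj).reshape(n * 3, -1)
        K[:, -1] = 0.0
        return h, K

    def cached_features(self, idx: int, sample) -> tuple[np.ndarray, np.ndarray, float, np.ndarray]:
        entry = self._cache.get(idx)
        if entry is not None and entry[0] is sample:
            return entry[1], entry[2], entry[3], entry[4]
        phi, jac = descriptor(self.spec, sample.system)
        h, K = self.features(phi, jac)
        entry = (sample, h, K, float(sample.energy), sample.forces.ravel().copy())
        self._cache[idx] = entry
        return entry[1], entry[2], entry[3], entry[4]

    # -- prediction ----------------------------------------------------------

    def predict_from(self, phi: np.ndarray, jac: np.ndarray) -> tuple[float, np.ndarray]:
        # direct contraction: ~100× cheaper than building the full K matrix
        n, F = phi.shape
        lin = F if self.spec.linear_head else 0
        t = np.tanh(phi @ self.A.T + self.b)
        energy = float(t.sum(axis=0) @ self.w[lin:-1] + n * self.w[-1])
        weight = (self.w[lin:-1] * (1 - t**2)) @ self.A                  # (N, F)
        if lin:
            energy += float(phi.sum(axis=0) @ self.w[:lin])
            weight = weight + self.w[None, :lin]
        forces = -np.einsum("nf,nfmk->mk", weight, jac)
        return energy, forces

    def predict(self, system: AtomicSystem) -> tuple[float, np.ndarray]:
        return self.predict_from(*descriptor(self.spec, system))

    # -- training ------------------------------------------------------------

    def _gradient(self, batch: list[tuple]) -> np.ndarray:
        spec = self.spec
        g = np.zeros_like(self.w)
        for h, K, e_ref, f_ref in batch:
            de = float(h @ self.w) - e_ref
            df = K @ self.w - f_ref
            g += 2 * spec.energy_weight * de * h
            g += (2 * spec.force_weight / len(f_ref)) * (K.T @ df)
        g /= len(batch)
        norm = float(np.linalg.norm(g))
        if norm > spec.grad_clip:
            g *= spec.grad_clip / norm
        return g

    def _adam_step(self, g: np.ndarray) -> None:
        spec = self.spec
        self.m = spec.beta1 * self.m + (1 - spec.beta1) * g
        self.v = spec.beta2 * self.v + (1 - spec.beta2) * g**2
        self.vhat = np.maximum(self.vhat, self.v)
        self.w = self.w - spec.learning_rate * self.m / (np.sqrt(self.vhat) + spec.adam_eps)

    def train_epochs(self, dataset: DatasetStore, indices: list[int], epochs: int) -> None:
        """Run ``epochs`` deterministic passes over ``indices`` (continual)."""
        if epochs < 0:
            raise ValueError("epochs must be >= 0")
        if epochs == 0:
            return
        if not indices:
            raise ValueError("refusing to train on an empty subset")
        bs = self.spec.batch_size
        for _ in range(epochs):
            order_rng = np.random.default_rng((self.seed, self.epoch_count))
            order = order_rng.permutation(len(indices))
            for start in range(0, len(order), bs):
                batch = [
                    self.cached_features(indices[k], dataset.samples[indices[k]])
                    for k in order[start : start + bs]
                ]
                self._adam_step(self._gradient(batch))
            self.epoch_count += 1
        self.trained = True

    def loss_on(self, dataset: DatasetStore, indices: list[int]) -> float:
        spec = self.spec
        total = 0.0
        for idx in indices:
            h, K, e_ref, f_ref = self.cached_features(idx, dataset.samples[idx])
            de = float(h @ self.w) - e_ref
            df = K @ self.w - f_ref
            total += spec.energy_weight * de**2 + spec.force_weight * float(
                np.mean(df**2)
            )
        return total / max(len(indices), 1)

    def force_mae(self, dataset: DatasetStore, indices: list[int]) -> float:
        """Mean absolute error over all force components of the given samples."""
        if not indices:
            raise ValueError("empty index set")
        errs = []
        for idx in indices:
            h, K, e_ref, f_ref = self.cached_features(idx, dataset.samples[idx])
            errs.append(np.abs(K @ self.w - f_ref))
        return float(np.mean(np.concatenate(errs)))

    def state_dict(self) -> dict:
        return {
            "seed": self.seed,
            "w": self.w.copy(),
            "m": self.m.copy(),
            "v": self.v.copy(),
            "vhat": self.vhat.copy(),
            "epoch_count": self.epoch_count,
            "trained": self.trained,
        }

    def load_state_dict(self, state: dict) -> None:
        self.w = np.asarray(state["w"], dtype=float).copy()
        self.m = np.asarray(state["m"], dtype=float).copy()
        self.v = np.asarray(state["v"], dtype=float).copy()
        self.vhat = np.asarray(state["vhat"], dtype=float).copy()
        self.epoch_count = int(state["epoch_count"])
        self.trained = bool(state["trained"])
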