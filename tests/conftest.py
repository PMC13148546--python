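"""Shared fixtures: toy chain systems, oracles and small pretrained committees."""

import numpy as np
import pytest

import activeff as a
from activeff.dynamics import TrajectoryState, langevin_step
from activeff.systems import flexible_chain_oracle, place_chain, softened


@pytest.fixture(scope="session")
def chain8():
    return place_chain(8, tag="flex")


@pytest.fixture(scope="session")
def flex_oracle():
    return flexible_chain_oracle()


def sample_chain_dataset(oracle, n=60, seed=7, n_atoms=8, temperature=500.0, stride=20):
    """Label decorrelated sampler-MD frames of a chain; alternate train/val."""
    sampler = softened(oracle)
    traj = TrajectoryState(
        system=place_chain(n_atoms, tag="flex"), temperature=temperature, rng_seed=seed
    )
    ds = a.DatasetStore()
    ds.label_counter = 0
    for i in range(n):
        for _ in range(stride):
            langevin_step(traj, lambda s: sampler.evaluate(s)[1])
        energy, forces = oracle.evaluate(traj.system)
        ds.add(
            a.LabeledSample(system=traj.system.copy(), energy=energy, forces=forces),
            "train" if i % 2 == 0 else "val",
        )
        ds.label_counter += 1
    return ds


@pytest.fixture(scope="session")
def chain_dataset(flex_oracle):
    return sample_chain_dataset(flex_oracle, n=60)


@pytest.fixture(scope="session")
def small_spec():
    # lighter feature map keeps unit tests quick
    return a.SurrogateSpec(n_basis=8, n_angular=4, n_features=48)


@pytest.fixture()
def committee4(small_spec):
    return a.init_committee(4, [10, 11, 12, 13], small_spec, a.TrainingSchedule())


@pytest.fixture(scope="session")
def pretrained_committee(chain_dataset, small_spec):
    """A committee trained a few epochs on disjoint subsets of the chain data."""
    committee = a.init_committee(4, [10, 11, 12, 13], small_spec, a.TrainingSchedule())
    ds = chain_dataset
    a.split_member_subsets(ds, 4, seed=3)
    a.train_increment(committee, ds, 10)
    return committee


def small_al_run(
    seed,
    train_size=40,
    n_traj=1,
    n_atoms=6,
    mode="serial",
    max_workers=1,
    probe_interval=None,
    oracle=None,
    extra_systems=(),
    max_md_steps=60000,
    idg_max_epochs=10,
    spec=None,
    sampler=None,
):
    """A compact IDG + AL run used by orchestration and property tests."""
    from activeff.systems import flexible_chain_oracle, place_chain, softened

    oracle = oracle or flexible_chain_oracle()
    spec = spec or a.SurrogateSpec(n_basis=8, n_angular=4, n_features=64)
    committee = a.init_committee(
        4, [a.derive_seed(seed, 1, j) for j in range(4)], spec, a.TrainingSchedule()
    )
    geoms = {"flex": place_chain(n_atoms, tag="flex")}
    for tag, system in extra_systems:
        geoms[tag] = system
    idg_cfg = a.IDGConfig(
        sampler=sampler or softened(oracle),
        points_per_member_per_round=2,
        stop="max_epochs",
        max_epochs=idg_max_epochs,
        temperature=300.0,
    )
    ds, committee, ledger = a.run_idg(
        idg_cfg, oracle, committee, geoms, seed=a.derive_seed(seed, 2)
    )
    trajectories = [
        a.TrajectorySpec(tag=tag, system=system.copy())
        for tag, system in geoms.items()
        for _ in range(max(n_traj // max(len(geoms), 1), 1))
    ]
    config = a.ALConfig(
        trajectories=trajectories,
        stop="train_size",
        train_size=train_size,
        probe_interval=probe_interval,
        max_md_steps=max_md_steps,
        max_workers=max_workers,
        mode=mode,
        master_seed=a.derive_seed(seed, 3),
    )
    runner = a.run_parallel if mode == "parallel" else a.run_serial
    committee, ds, ledger = runner(config, oracle, committee, ds, ledger)
    return committee, ds, ledger


def copy_dataset(ds):
    """Fresh DatasetStore sharing samples but with independent split state."""
    out = a.DatasetStore()
    out.samples = list(ds.samples)
    out.split = list(ds.split)
    out.member_train = [list(s) for s in ds.member_train]
    out.member_val = [list(s) for s in ds.member_val]
    out.label_counter = getattr(ds, "label_counter", len(ds.samples))
    return out


def random_prediction(m_members, n_atoms, seed=0):
    """A synthetic committee prediction with random member forces."""
    rng = np.random.default_rng(seed)
    forces = rng.normal(0, 1, (m_members, n_atoms, 3))
    energies = rng.normal(0, 1, m_members)
    return a.CommitteePrediction(
        per_member_energy=energies,
        per_member_forces=forces,
        mean_energy=float(energies.mean()),
        mean_forces=forces.mean(axis=0),
    )
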