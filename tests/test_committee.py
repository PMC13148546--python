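"""Committee construction, prediction, and continual-learning schedules."""

import numpy as np
import pytest

import activeff as a
from activeff.data import ConfigurationError
from conftest import copy_dataset
from activeff.surrogate import UntrainedModelError
from activeff.systems import place_chain


def wiggled_chain(seed, n=8, amp=0.08):
    system = place_chain(n)
    system.positions = system.positions + np.random.default_rng(seed).normal(
        0, amp, (n, 3)
    )
    return system


class TestInitCommittee:
    def test_members_differ_with_distinct_seeds(self, small_spec):
        committee = a.init_committee(4, [0, 1, 2, 3], small_spec)
        weights = [m.w for m in committee.members]
        for i in range(4):
            for j in range(i + 1, 4):
                assert not np.allclose(weights[i], weights[j])

    def test_duplicate_seeds_rejected(self, small_spec):
        with pytest.raises(ConfigurationError):
            a.init_committee(2, [7, 7], small_spec)

    def test_single_member_rejected(self, small_spec):
        with pytest.raises(ConfigurationError):
            a.init_committee(1, [7], small_spec)

    def test_same_seeds_give_identical_predictions(self, small_spec, chain8):
        first = a.init_committee(3, [5, 6, 7], small_spec)
        second = a.init_committee(3, [5, 6, 7], small_spec)
        for committee in (first, second):
            for member in committee.members:
                member.trained = True
        p1 = first.predict(chain8)
        p2 = second.predict(chain8)
        np.testing.assert_array_equal(p1.per_member_forces, p2.per_member_forces)


class TestPredict:
    def test_untrained_committee_refuses(self, committee4, chain8):
        with pytest.raises(UntrainedModelError):
            committee4.predict(chain8)

    def test_mean_is_arithmetic_average(self, pretrained_committee):
        system = wiggled_chain(1)
        pred = pretrained_committee.predict(system)
        np.testing.assert_allclose(
            pred.mean_forces, pred.per_member_forces.mean(axis=0), rtol=1e-12
        )
        assert pred.mean_energy == pytest.approx(pred.per_member_energy.mean())

    def test_member_permutation_leaves_mean_and_delta_unchanged(
        self, pretrained_committee
    ):
        system = wiggled_chain(2)
        pred = pretrained_committee.predict(system)
        delta = a.qbc_force_variance(pred)
        shuffled = a.Committee(
            members=pretrained_committee.members[::-1],
            schedule=pretrained_committee.schedule,
        )
        pred2 = shuffled.predict(system)
        np.testing.assert_allclose(pred2.mean_forces, pred.mean_forces, rtol=1e-12)
        assert a.qbc_force_variance(pred2) == pytest.approx(delta, rel=1e-12)

    def test_identical_members_have_zero_spread(self, small_spec, chain_dataset):
        committee = a.Committee(
            members=[a.SurrogateMember(small_spec, 3) for _ in range(3)],
            schedule=a.TrainingSchedule(),
        )
        for member in committee.members:
            member.trained = True
        pred = committee.predict(wiggled_chain(4))
        assert a.qbc_force_variance(pred) == pytest.approx(0.0, abs=1e-20)

    def test_forces_are_exact_energy_gradients(self, pretrained_committee):
        member = pretrained_committee.members[0]
        system = wiggled_chain(5)
        _, forces = member.predict(system)
        h = 1e-6
        for i in (0, 3, 7):
            for k in range(3):
                plus = system.positions.copy()
                plus[i, k] += h
                minus = system.positions.copy()
                minus[i, k] -= h
                ep, _ = member.predict(a.AtomicSystem(system.species, plus))
                em, _ = member.predict(a.AtomicSystem(system.species, minus))
                assert -(ep - em) / (2 * h) == pytest.approx(forces[i, k], abs=1e-7)


class TestTrainIncrement:
    def test_zero_epochs_is_identity(self, pretrained_committee, chain_dataset):
        before = [m.w.copy() for m in pretrained_committee.members]
        a.train_increment(pretrained_committee, chain_dataset, 0)
        for w_before, member in zip(before, pretrained_committee.members):
            np.testing.assert_array_equal(w_before, member.w)

    def test_one_plus_one_equals_two_epochs(self, small_spec, chain_dataset):
        ds = copy_dataset(chain_dataset)
        a.split_member_subsets(ds, 2, seed=4)

        split_twice = a.init_committee(2, [20, 21], small_spec)
        a.train_increment(split_twice, ds, 1)
        a.train_increment(split_twice, ds, 1)
        in_one = a.init_committee(2, [20, 21], small_spec)
        a.train_increment(in_one, ds, 2)
        for m1, m2 in zip(split_twice.members, in_one.members):
            np.testing.assert_array_equal(m1.w, m2.w)

    def test_training_reduces_force_mae(self, small_spec, chain_dataset):
        ds = copy_dataset(chain_dataset)
        committee = a.init_committee(2, [30, 31], small_spec)
        a.split_member_subsets(ds, 2, seed=4)
        before = [
            m.force_mae(ds, ds.member_train[j])
            for j, m in enumerate(committee.members)
        ]
        a.train_increment(committee, ds, 30)
        after = [
            m.force_mae(ds, ds.member_train[j])
            for j, m in enumerate(committee.members)
        ]
        assert all(b < a_ for b, a_ in zip(after, before))

    def test_empty_subset_refused(self, committee4):
        empty = a.DatasetStore()
        empty.member_train = [[] for _ in range(4)]
        with pytest.raises(ConfigurationError):
            a.train_increment(committee4, empty, 1)


class TestValidationMae:
    def test_perfect_predictions_give_zero(self, small_spec, chain_dataset):
        member = a.SurrogateMember(small_spec, 40)
        idx = chain_dataset.val_indices()[:3]
        # overwrite the labels with the member's own predictions
        clone = a.DatasetStore()
        for i in idx:
            system = chain_dataset.samples[i].system
            energy, forces = member.predict(system)
            clone.add(
                a.LabeledSample(system=system, energy=energy, forces=forces), "val"
            )
        assert a.validation_mae(member, clone, [0, 1, 2]) == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_single_atom_value(self):
        # prediction (1,0,0) vs label (0,0,0): MAE over 3 components = 1/3
        err = np.abs(np.array([1.0, 0.0, 0.0]) - np.zeros(3))
        assert err.mean() == pytest.approx(1 / 3)

    def test_sample_permutation_invariance(self, pretrained_committee, chain_dataset):
        member = pretrained_committee.members[0]
        idx = chain_dataset.val_indices()
        assert a.validation_mae(member, chain_dataset, idx) == pytest.approx(
            a.validation_mae(member, chain_dataset, idx[::-1])
        )


class TestTrainToConvergence:
    def test_returns_best_validation_state(self, small_spec, chain_dataset):
        member = a.SurrogateMember(small_spec, 50)
        tr = chain_dataset.train_indices()
        va = chain_dataset.val_indices()
        a.train_to_convergence(member, chain_dataset, tr, va, patience=10, max_epochs=200)
        final_mae = member.force_mae(chain_dataset, va)
        # retraining a copy and tracking the curve: returned state is its minimum
        member2 = a.SurrogateMember(small_spec, 50)
        curve = []
        for _ in range(member.epoch_count):
            member2.train_epochs(chain_dataset, tr, 1)
            curve.append(member2.force_mae(chain_dataset, va))
        assert final_mae == pytest.approx(min(m for m in curve), rel=1e-9)

    def test_patience_zero_stops_at_first_non_improvement(self, small_spec, chain_dataset):
        member = a.SurrogateMember(small_spec, 51)
        tr = chain_dataset.train_indices()
        va = chain_dataset.val_indices()
        a.train_to_convergence(member, chain_dataset, tr, va, patience=0, max_epochs=500)
        assert member.epoch_count < 500

    def test_empty_validation_refused(self, small_spec, chain_dataset):
        member = a.SurrogateMember(small_spec, 52)
        with pytest.raises(ConfigurationError):
            a.train_to_convergence(member, chain_dataset, [0], [], patience=5)


class TestSelectBest:
    def test_argmin_with_tie_break(self, pretrained_committee, chain_dataset, monkeypatch):
        maes = iter([0.3, 0.1, 0.2, 0.1])
        monkeypatch.setattr(
            "activeff.committee.validation_mae", lambda *args, **kw: next(maes)
        )
        assert a.select_best(pretrained_committee, chain_dataset) == 1

    def test_all_equal_gives_index_zero(self, pretrained_committee, chain_dataset, monkeypatch):
        monkeypatch.setattr(
            "activeff.committee.validation_mae", lambda *args, **kw: 0.5
        )
        assert a.select_best(pretrained_committee, chain_dataset) == 0

    def test_matches_exhaustive_scan(self, pretrained_committee, chain_dataset):
        maes = [
            a.validation_mae(m, chain_dataset, chain_dataset.member_val[j])
            for j, m in enumerate(pretrained_committee.members)
        ]
        assert a.select_best(pretrained_committee, chain_dataset) == int(np.argmin(maes))


class TestConvergenceInsideHypothesisClass:
    def test_validation_mae_vanishes_on_teacher_pes(self, small_spec):
        """A member can fit data generated by its own function class."""
        teacher = a.SurrogateMember(small_spec, 99)
        rng = np.random.default_rng(0)
        teacher.w = rng.standard_normal(teacher.head_dim) * 0.3
        ds = a.DatasetStore()
        for i in range(200):
            system = wiggled_chain(1000 + i, amp=0.06)
            energy, forces = teacher.predict(system)
            ds.add(
                a.LabeledSample(system=system, energy=energy, forces=forces),
                "train" if i % 2 == 0 else "val",
            )
        student = a.SurrogateMember(small_spec, 99)  # same feature map, new head
        student.w = rng.standard_normal(student.head_dim) * 0.01
        a.train_to_convergence(
            student, ds, ds.train_indices(), ds.val_indices(), patience=30,
            max_epochs=600,
        )
        scale = float(
            np.mean([np.abs(ds.samples[i].forces).mean() for i in ds.val_indices()])
        )
        mae = student.force_mae(ds, ds.val_indices())
        assert mae < 0.05 * max(scale, 1.0)


class TestMemberDiversity:
    def test_spread_positive_before_convergence(self, pretrained_committee):
        pred = pretrained_committee.predict(wiggled_chain(7))
        assert a.qbc_force_variance(pred) > 0


class TestCheckpointRoundTrip:
    def test_save_load_restores_predictions(self, pretrained_committee, tmp_path, chain8):
        pretrained_committee.save(tmp_path / "models")
        clone = a.init_committee(
            4, pretrained_committee.member_seeds, pretrained_committee.members[0].spec
        )
        clone.load(tmp_path / "models")
        p1 = pretrained_committee.predict(chain8)
        p2 = clone.predict(chain8)
        np.testing.assert_array_equal(p1.per_member_forces, p2.per_member_forces)
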