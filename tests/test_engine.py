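"""Orchestration: serial/parallel loops, probes, recompute, reporting."""

import time

import numpy as np
import pytest

import activeff as a
from activeff.data import ConfigurationError
from activeff.systems import flexible_chain_oracle, place_chain
from conftest import small_al_run


class TestPearson:
    def test_perfect_positive_line(self):
        x = np.arange(10.0)
        assert a.pearson(x, 2 * x + 1) == pytest.approx(1.0)

    def test_perfect_negative_line(self):
        x = np.arange(5.0)
        assert a.pearson(x, -x) == pytest.approx(-1.0)

    def test_hand_computed_half(self):
        assert a.pearson([1, 2, 3], [1, 3, 2]) == pytest.approx(0.5)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            a.pearson([1, 1, 1], [1, 2, 3])

    def test_short_input_rejected(self):
        with pytest.raises(ValueError):
            a.pearson([1, 2], [3, 4])


class TestRunSerial:
    def test_deterministic_given_seed(self):
        ledgers = []
        for _ in range(2):
            _, ds, ledger = small_al_run(seed=5, train_size=20)
            ledgers.append((ds.n_train, ds.n_val, ledger.to_dict()))
        assert ledgers[0] == ledgers[1]

    def test_train_size_stop_with_complete_ratio_block(self):
        _, ds, _ = small_al_run(seed=6, train_size=24)
        assert ds.n_train == 24
        assert ds.n_val == 24  # 1:1 ratio maintained at stop

    def test_every_member_gets_al_additions(self):
        _, ds, _ = small_al_run(seed=7, train_size=20)
        al_train = [
            i
            for i, s in enumerate(ds.samples)
            if s.stage == "al" and ds.split[i] == "train"
        ]
        assert al_train
        for subset in ds.member_train:
            assert set(al_train) <= set(subset)

    def test_ledger_conservation(self):
        _, ds, ledger = small_al_run(seed=8, train_size=20, probe_interval=100)
        assert ledger.total_successful_calls == len(ds) + len(ledger.probe_records)

    def test_constant_uncertainty_stream_stops_via_md_cap(self, small_spec, chain_dataset):
        """If the committee never exceeds the threshold after bootstrap, the
        run must terminate on the MD-step cap with only bootstrap labels."""
        committee = a.init_committee(
            4, [1, 2, 3, 4], small_spec,
            a.TrainingSchedule(al_epochs_per_event=0),  # freeze: spread stays zero
        )
        ds = a.DatasetStore()
        for i, s in enumerate(chain_dataset.samples):
            ds.add(s, chain_dataset.split[i])
        a.split_member_subsets(ds, 4, seed=0)
        a.train_increment(committee, ds, 2)
        # tie all members to member 0: zero spread forever
        for member in committee.members[1:]:
            member.A = committee.members[0].A
            member.b = committee.members[0].b
            member.w = committee.members[0].w
        config = a.ALConfig(
            trajectories=[a.TrajectorySpec(tag="flex", system=place_chain(8, tag="flex"))],
            stop="train_size",
            train_size=10_000,
            max_md_steps=400,
            master_seed=1,
        )
        _, ds, ledger = a.run_serial(config, flexible_chain_oracle(), committee, ds)
        assert ledger.oracle_calls["al"] == 1  # bootstrap label only


class TestProbes:
    def test_probe_calls_never_enter_training(self):
        _, ds_probed, ledger = small_al_run(seed=9, train_size=24, probe_interval=60)
        assert len(ledger.probe_records) > 0
        for sample in ds_probed.samples:
            assert sample.stage in ("idg", "al")
        assert ledger.oracle_calls["probe"] == len(ledger.probe_records)

    def test_self_consistent_committee_has_near_zero_probe_error(
        self, small_spec, chain8
    ):
        """Probing a committee against an oracle that IS one of its members
        yields (numerically) zero true error."""
        member = a.SurrogateMember(small_spec, 77)
        member.trained = True
        committee = a.Committee([member, member], a.TrainingSchedule())

        class MemberOracle(a.OraclePES):
            def _evaluate(self, system):
                return member.predict(system)

        record = a.probe_ground_truth(chain8, committee, MemberOracle())
        assert record.true_error == pytest.approx(0.0, abs=1e-12)
        assert record.delta == pytest.approx(0.0, abs=1e-20)


class TestParallel:
    def test_degenerate_case_matches_serial(self):
        _, ds_serial, ledger_serial = small_al_run(seed=11, train_size=16, mode="serial")
        _, ds_parallel, ledger_parallel = small_al_run(
            seed=11, train_size=16, mode="parallel", max_workers=1
        )
        assert ds_serial.n_train == ds_parallel.n_train
        assert [s.step for s in ds_serial.samples] == [
            s.step for s in ds_parallel.samples
        ]
        np.testing.assert_allclose(
            ds_serial.samples[-1].system.positions,
            ds_parallel.samples[-1].system.positions,
        )
        assert ledger_serial.oracle_calls == ledger_parallel.oracle_calls

    def test_label_total_independent_of_worker_count(self):
        totals = set()
        for workers in (1, 2, 4):
            _, ds, _ = small_al_run(
                seed=12, train_size=16, n_traj=2, mode="parallel", max_workers=workers
            )
            totals.add(ds.n_train)
        assert len(totals) == 1

    def test_concurrent_labeling_with_latency(self, small_spec, chain_dataset):
        """Two simultaneous triggers with 2 workers take ≈ one latency, not two."""
        tau = 0.5
        committee = a.init_committee(4, [1, 2, 3, 4], small_spec)
        ds = a.DatasetStore()
        for i, s in enumerate(chain_dataset.samples):
            ds.add(s, chain_dataset.split[i])
        ds.label_counter = len(ds.samples)
        a.split_member_subsets(ds, 4, seed=0)
        a.train_increment(committee, ds, 2)
        oracle = flexible_chain_oracle()
        oracle.latency = tau
        config = a.ALConfig(
            trajectories=[
                a.TrajectorySpec(tag="flex", system=place_chain(8, tag="flex")),
                a.TrajectorySpec(tag="flex", system=place_chain(8, tag="flex")),
            ],
            stop="train_size",
            train_size=ds.n_train + 1,  # met after one train + one val label
            threshold_c=-1.0,  # zero threshold: both trajectories trigger together
            max_md_steps=10_000,
            max_workers=2,
            mode="parallel",
            master_seed=2,
        )
        start = time.monotonic()
        a.run_parallel(config, oracle, committee, ds)
        elapsed = time.monotonic() - start
        assert elapsed < 1.5 * tau + 0.5  # both labels in ≈ tau, not 2·tau


class TestFinalize:
    def test_best_mode_returns_single_member(self):
        committee, ds, _ = small_al_run(seed=13, train_size=12)
        chosen, maes = a.finalize(committee, ds, mode="best", patience=5)
        assert len(chosen) == 1 and len(maes) == 1

    def test_final_mae_not_worse_than_pre_finalize(self):
        committee, ds, _ = small_al_run(seed=14, train_size=12)
        j = a.select_best(committee, ds)
        before = committee.members[j].force_mae(ds, ds.val_indices())
        _, maes = a.finalize(committee, ds, mode="best", patience=5)
        assert maes[0] <= before + 1e-12

    def test_empty_validation_refused(self, committee4):
        with pytest.raises(ConfigurationError):
            a.finalize(committee4, a.DatasetStore())


class TestRecompute:
    def test_every_structure_relabeled_once(self):
        _, ds, ledger = small_al_run(seed=15, train_size=12)
        higher = a.perturbed_level(flexible_chain_oracle(), 0.1, seed=3)
        new_ds, ledger = a.recompute_at_level(ds, higher, ledger)
        assert len(new_ds) == len(ds)
        assert ledger.oracle_calls["recompute"] == len(ds)
        assert all(s.level == higher.level for s in new_ds.samples)
        assert all(s.stage == "recompute" for s in new_ds.samples)

    def test_identity_perturbation_preserves_energies(self):
        _, ds, _ = small_al_run(seed=16, train_size=12)
        base = flexible_chain_oracle()
        higher = a.perturbed_level(base, 0.0, seed=1)
        new_ds, _ = a.recompute_at_level(ds, higher)
        for old, new in zip(ds.samples, new_ds.samples):
            assert new.energy == pytest.approx(old.energy, abs=1e-12)
            assert new.level != old.level

    def test_geometries_untouched_and_subsets_remapped(self):
        _, ds, _ = small_al_run(seed=17, train_size=12)
        higher = a.perturbed_level(flexible_chain_oracle(), 0.05, seed=2)
        new_ds, _ = a.recompute_at_level(ds, higher)
        np.testing.assert_array_equal(
            new_ds.samples[0].system.positions, ds.samples[0].system.positions
        )
        assert [len(s) for s in new_ds.member_train] == [
            len(s) for s in ds.member_train
        ]


class TestReport:
    def test_per_system_counts_sum_to_total(self):
        rigid = place_chain(6, tag="rigid")
        _, ds, ledger = small_al_run(
            seed=18, train_size=20, extra_systems=[("rigid", rigid)]
        )
        summary = a.report(ledger)
        assert set(summary["labels_by_system"]) == {"flex", "rigid"}
        assert summary["total_labels"] == len(ds)

    def test_probe_correlation_segments_present(self):
        _, _, ledger = small_al_run(seed=19, train_size=24, probe_interval=40)
        summary = a.report(ledger)
        segments = summary["probe_correlation_by_trajectory_thirds"]
        assert segments and all(len(v) == 3 for v in segments.values())

    def test_empty_ledger_rejected(self):
        with pytest.raises(ValueError):
            a.report(a.RunLedger())


class TestTrajectoryCountInsensitivity:
    def test_final_mae_overlaps_across_trajectory_counts(self):
        """At a fixed label budget the final accuracy should not depend on
        how many concurrent trajectories collected the data."""
        maes = {1: [], 4: []}
        for n_traj in maes:
            for seed in (0, 1, 2):
                committee, ds, _ = small_al_run(
                    seed=100 + seed, train_size=24, n_traj=n_traj
                )
                j = a.select_best(committee, ds)
                maes[n_traj].append(
                    committee.members[j].force_mae(ds, ds.val_indices())
                )
        lo = {k: np.mean(v) - np.std(v) for k, v in maes.items()}
        hi = {k: np.mean(v) + np.std(v) for k, v in maes.items()}
        assert lo[1] <= hi[4] and lo[4] <= hi[1]  # ±1 SD bands overlap
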