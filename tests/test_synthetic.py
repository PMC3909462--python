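"""Markov-chain trajectory generator: ground-truth fidelity and I/O."""

import math

import numpy as np
import pytest

from glycoconf.io import read_trajectory
from glycoconf.kinetics import poisson_ci
from glycoconf.pucker import (
    NEUAC_LABELS,
    assign_canonical_name,
    canonical_puckers,
    cremer_pople,
    cremer_pople_trajectory,
)
from glycoconf.synthetic import (
    MarkovState,
    SyntheticTrajectorySpec,
    build_ideal_ring,
    emit_ring_trajectory,
    emit_solvated_snapshot,
    simulate_markov_series,
    two_state_pucker_spec,
    write_system,
)


class TestSpecValidation:
    def test_populations_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            SyntheticTrajectorySpec(
                states=(MarkovState.make("a", (0.0,), (1.0,)),
                        MarkovState.make("b", (90.0,), (1.0,))),
                populations=(0.6, 0.6),
            )

    def test_unknown_rate_pair_rejected(self):
        with pytest.raises(ValueError, match="unknown state"):
            SyntheticTrajectorySpec(
                states=(MarkovState.make("a", (0.0,), (1.0,)),
                        MarkovState.make("b", (90.0,), (1.0,))),
                populations=(0.5, 0.5),
                pair_rates={frozenset({"a", "zz"}): 1.0},
            )

    def test_transition_matrix_invariants(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            p = rng.dirichlet(np.ones(3))
            labels = ("a", "b", "c")
            rates = {
                frozenset({"a", "b"}): float(rng.uniform(0, 30)),
                frozenset({"b", "c"}): float(rng.uniform(0, 30)),
                frozenset({"a", "c"}): float(rng.uniform(0, 30)),
            }
            spec = SyntheticTrajectorySpec(
                states=tuple(
                    MarkovState.make(l, (i * 60.0,), (5.0,))
                    for i, l in enumerate(labels)
                ),
                populations=tuple(p),
                pair_rates=rates,
                n_frames=10,
            )
            t = spec.transition_matrix()
            assert np.allclose(t.sum(axis=1), 1.0, atol=1e-12)
            assert np.max(np.abs(p @ t - p)) < 1e-9
            assert np.all(t >= 0.0)

    def test_ground_truth_record(self):
        spec = two_state_pucker_spec(p_major=0.95, rate_per_us=0.5,
                                     n_frames=100)
        gt = spec.ground_truth()
        assert gt["populations"] == pytest.approx([0.95, 0.05])
        kt = 1.9872041e-3 * 298.0
        assert gt["deltaG_kcal_per_mol"][1] == pytest.approx(
            kt * math.log(19.0)
        )
        assert gt["pair_rates_per_us"] == {"C(north)|C(south)": 0.5}


class TestSimulation:
    def test_single_state_emission_width(self):
        spec = SyntheticTrajectorySpec(
            states=(MarkovState.make("only", (100.0,), (8.0,)),),
            populations=(1.0,),
            n_frames=200_000,
            seed=1,
        )
        sim = simulate_markov_series(spec)
        assert np.all(sim.state_indices == 0)
        assert sim.angles[:, 0].std() == pytest.approx(8.0, rel=0.02)
        assert sim.angles[:, 0].mean() == pytest.approx(100.0, abs=0.1)

    def test_seed_reproducibility(self):
        spec = two_state_pucker_spec(n_frames=50_000, seed=9,
                                     rate_per_us=22.0)
        a = simulate_markov_series(spec)
        b = simulate_markov_series(spec)
        assert np.array_equal(a.state_indices, b.state_indices)
        assert np.array_equal(a.angles, b.angles)

    def test_two_state_occupancy_and_transition_band(self):
        """10 us at 10 ps with 0.95/0.05 populations and 0.5 events/us:
        occupancy within 3 SE and chain transitions inside the Poisson
        95% band of the expected count."""
        spec = two_state_pucker_spec(
            p_major=0.95, rate_per_us=0.5, n_frames=1_000_000, seed=2,
        )
        sim = simulate_markov_series(spec)
        occ_minor = np.mean(sim.state_indices == 1)
        # SE of a regenerative two-state occupancy estimate:
        # var ~= 2 p^2 q^2 / (events)
        expected_events = 0.5 * spec.total_time_us
        se = math.sqrt(2 * (0.95 * 0.05) ** 2 / expected_events)
        assert abs(occ_minor - 0.05) < 3 * se
        lo, hi = poisson_ci(round(expected_events))
        assert lo <= sim.n_chain_transitions() <= hi

    def test_occupancy_error_shrinks_with_length(self):
        """Stationarity: occupancy error decays roughly as 1/sqrt(n)."""
        errs = {}
        for n in (100_000, 1_000_000):
            devs = []
            for seed in range(5):
                spec = two_state_pucker_spec(
                    p_major=0.8, rate_per_us=22.0, n_frames=n, seed=seed,
                )
                sim = simulate_markov_series(spec)
                devs.append(abs(np.mean(sim.state_indices == 1) - 0.2))
            errs[n] = np.mean(devs)
        ratio = errs[100_000] / errs[1_000_000]
        assert 1.3 < ratio < 10.0


class TestIdealRings:
    def test_chair_poles(self):
        r = build_ideal_ring("4C1")
        assert cremer_pople(r).theta < 1.0
        r = build_ideal_ring("1C4")
        assert cremer_pople(r).theta > 179.0

    def test_all_38_names_round_trip(self):
        for labels in ((("O", "1", "2", "3", "4", "5")), NEUAC_LABELS):
            for canon in canonical_puckers(tuple(labels)):
                ring = build_ideal_ring(canon.name, labels=tuple(labels))
                got = assign_canonical_name(cremer_pople(ring), tuple(labels))
                assert got.name == canon.name

    def test_unknown_name_rejected(self):
        with pytest.raises(ValueError, match="unknown conformer"):
            build_ideal_ring("9C9")


class TestRingTrajectory:
    def test_chair_only_spec_classifies_4c1(self):
        spec = SyntheticTrajectorySpec(
            states=(MarkovState.make("chair", (5.0, 30.0), (5.0, 30.0)),),
            populations=(1.0,),
            n_frames=3000,
            seed=3,
        )
        coords, _ = emit_ring_trajectory(spec)
        _, theta, phi, _ = cremer_pople_trajectory(coords)
        names = [
            assign_canonical_name((t, p)).name for t, p in zip(theta, phi)
        ]
        assert np.mean([n == "4C1" for n in names]) >= 0.99

    def test_zero_noise_exact_recovery(self):
        spec = SyntheticTrajectorySpec(
            states=(MarkovState.make("skew", (90.0, 150.0), (0.0, 0.0)),),
            populations=(1.0,),
            n_frames=50,
            seed=4,
        )
        coords, _ = emit_ring_trajectory(spec)
        _, theta, phi, _ = cremer_pople_trajectory(coords)
        assert np.allclose(theta, 90.0, atol=1e-9)
        assert np.allclose(phi, 150.0, atol=1e-9)

    def test_chair_skew_exchange_rate_recovered(self):
        from glycoconf.kinetics import (
            IntervalCore,
            assign_states,
            count_transitions,
            exchange_rate,
        )

        spec = SyntheticTrajectorySpec(
            states=(MarkovState.make("chair", (10.0, 30.0), (6.0, 20.0)),
                    MarkovState.make("skew", (90.0, 150.0), (6.0, 20.0))),
            populations=(0.8, 0.2),
            pair_rates={frozenset({"chair", "skew"}): 20.0},
            n_frames=1_000_000,
            seed=5,
        )
        coords, sim = emit_ring_trajectory(spec)
        _, theta, _, _ = cremer_pople_trajectory(coords)
        st = assign_states(theta, (
            IntervalCore("chair", 0.0, 30.0),
            IntervalCore("skew", 60.0, 120.0),
        ), frame_interval_ps=10.0)
        est = exchange_rate(count_transitions(st), st.total_time_us)
        lo, hi = est.ci95_per_us
        assert lo <= 20.0 <= hi


class TestSolventAndIO:
    def test_uniform_profile_flat_rdf(self):
        from glycoconf.solvation import rdf

        box = np.array([15.0, 15.0, 15.0])
        frames = np.stack([
            emit_solvated_snapshot(3000, box, "uniform", seed=s)
            for s in range(60)
        ])
        ref = np.tile(box[None, None, :] / 2, (60, 1, 1))
        result = rdf(ref, frames, box, r_max=6.0)
        far = result.r > 2.0
        # smoke-level statistics only; the tight flatness check lives in
        # the solvation tests with a many-reference setup
        assert np.abs(result.g[far] - 1.0).mean() < 0.08

    def test_empty_solvent(self):
        out = emit_solvated_snapshot(0, (10.0, 10.0, 10.0))
        assert out.shape == (0, 3)

    def test_write_and_reload_round_trip(self, tmp_path, small_mock_glycan):
        mock = small_mock_glycan
        pdb = tmp_path / "system.pdb"
        dcd = tmp_path / "system.dcd"
        write_system(mock.universe, mock.frames, pdb, dcd)
        coords_pdb, _ = read_trajectory(pdb)
        coords_dcd, _ = read_trajectory(pdb, dcd)
        assert coords_pdb.shape == mock.frames.shape
        assert np.max(np.abs(coords_pdb - mock.frames)) < 1e-3
        assert np.max(np.abs(coords_dcd - mock.frames)) < 1e-3

    def test_zero_frames_rejected(self, small_mock_glycan, tmp_path):
        with pytest.raises(ValueError):
            write_system(small_mock_glycan.universe,
                         np.empty((0, 5, 3)), tmp_path / "x.pdb")

    def test_mock_topology_resolves(self, small_mock_glycan, tmp_path):
        from glycoconf.topology import load_topology

        pdb = tmp_path / "mock.pdb"
        write_system(small_mock_glycan.universe,
                     small_mock_glycan.frames[:1], pdb)
        topo = load_topology(pdb, small_mock_glycan.topology_config)
        assert len(topo.rings) == 4
        assert len(topo.linkages) == 3
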