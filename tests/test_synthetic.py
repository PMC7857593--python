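"""Generator contracts: determinism, conservation, ground-truth consistency."""

import numpy as np
import pytest
from scipy import stats as sps

from memlens.diffusion import collect_displacements, estimate_D
from memlens.synthetic import (
    Attraction, GeneratorConfig, Headgroups, TrapRing, preset_config,
    replicate_seeds, sample_displacements, simulate_membrane, site_positions,
)


def fast_config(**kw):
    base = dict(n_lipid_equivalents=2000, tag_molpercent=2.5, n_steps=2000,
                seed=5)
    base.update(kw)
    return GeneratorConfig(**base)


class TestDeterminism:
    def test_same_seed_bit_identical(self):
        cfg = fast_config(trap=TrapRing(enabled=True),
                          headgroups=Headgroups(enabled=True, n_per_leaflet=50))
        t1, g1 = simulate_membrane(cfg, seed=42)
        t2, g2 = simulate_membrane(cfg, seed=42)
        np.testing.assert_array_equal(t1.coords_array(), t2.coords_array())
        np.testing.assert_array_equal(g1.states, g2.states)
        assert [(e.start, e.end) for e in g1.events] == \
            [(e.start, e.end) for e in g2.events]

    def test_different_seeds_differ(self):
        cfg = fast_config(n_steps=200)
        t1, _ = simulate_membrane(cfg, seed=1)
        t2, _ = simulate_membrane(cfg, seed=2)
        assert not np.array_equal(t1.coords_array(), t2.coords_array())

    def test_replicate_seeds_deterministic(self):
        cfg = fast_config(n_replicates=5)
        assert replicate_seeds(cfg) == replicate_seeds(cfg)
        assert len(set(replicate_seeds(cfg))) == 5


class TestConservation:
    def test_positions_inside_box_and_count_constant(self):
        cfg = fast_config(trap=TrapRing(enabled=True), n_steps=500)
        traj, _ = simulate_membrane(cfg, seed=0)
        coords = traj.coords_array()
        box = traj.frames[0].box
        assert coords.shape[1] == traj.n_particles
        assert np.all(coords >= 0) and np.all(coords[:, :, :2] < box[:2])

    def test_bound_implies_within_capture_radius(self):
        cfg = fast_config(tag_molpercent=1.25, trap=TrapRing(enabled=True),
                          n_steps=3000)
        traj, truth = simulate_membrane(cfg, seed=3)
        sites = site_positions(cfg.trap)
        coords = traj.coords_array()[:, :cfg.n_tag, :2]
        box = np.asarray(cfg.box)
        for k in range(truth.states.shape[0]):
            bound = np.flatnonzero(truth.states[k] >= 0)
            if bound.size:
                d = coords[k, bound] - sites[truth.states[k, bound]]
                d -= box * np.round(d / box)
                assert np.all(np.linalg.norm(d, axis=1) <= cfg.trap.capture_radius
                              + 1e-9)

    def test_dt_too_large_rejected(self):
        with pytest.raises(ValueError, match="dt too large"):
            simulate_membrane(fast_config(dt=50.0, D_free=0.03))


class TestDiffusionGroundTruth:
    def test_free_diffusion_recovered_without_interactions(self):
        cfg = fast_config(attraction=Attraction(epsilon=0.0), n_steps=2000,
                          D_free=0.03)
        traj, truth = simulate_membrane(cfg, seed=9)
        ids = traj.topology.particles_in_group("TAG")
        est = estimate_D(collect_displacements(traj, ids, lag=1.0))
        se = est.D / np.sqrt(est.n)
        assert abs(est.D - cfg.D_free) < 3 * se

    def test_sample_displacements_msd_law(self):
        s = sample_displacements(D=0.5, lag=1.0, n=100_000, seed=11)
        assert np.mean(s.values ** 2) == pytest.approx(4 * 0.5 * 1.0, rel=0.01)

    def test_sample_displacements_seeded(self):
        s1 = sample_displacements(0.5, 1.0, 100, seed=7)
        s2 = sample_displacements(0.5, 1.0, 100, seed=7)
        np.testing.assert_array_equal(s1.values, s2.values)

    def test_sample_displacements_single_value(self):
        s = sample_displacements(0.5, 1.0, 1, seed=1)
        assert s.n == 1 and s.values[0] >= 0


class TestBindingGroundTruth:
    def test_dwell_times_exponential(self):
        """Aggregate KS test of uncensored dwells against Exp(1/k_off)."""
        dwells = []
        cfg = fast_config(tag_molpercent=1.25, n_steps=5000,
                          trap=TrapRing(enabled=True, lumen_epsilon=0.0),
                          attraction=Attraction(epsilon=0.0), k_off=0.1)
        for seed in range(10):
            _, truth = simulate_membrane(cfg, seed=100 + seed)
            dwells.extend(e.dwell for e in truth.events if not e.censored)
        assert len(dwells) > 300
        p = sps.kstest(dwells, "expon", args=(0, 1 / cfg.k_off)).pvalue
        assert p > 0.01

    def test_states_match_trajectory_bound_series(self):
        """Analysis-side bound detection agrees with the emitted truth."""
        from memlens.kinetics import bound_matrix
        cfg = fast_config(tag_molpercent=1.25, n_steps=3000,
                          trap=TrapRing(enabled=True), k_off=0.005)
        traj, truth = simulate_membrane(cfg, seed=4)
        times, tag_ids, site_ids, bound = bound_matrix(
            traj, cutoff_bind=cfg.trap.capture_radius, stride=1.0)
        detected = bound.any(axis=2)
        actual = truth.states >= 0
        agreement = np.mean(detected == actual)
        assert agreement >= 0.99

    def test_ground_truth_intervals_match_events(self):
        cfg = fast_config(tag_molpercent=1.25, n_steps=2000,
                          trap=TrapRing(enabled=True), k_off=0.01)
        _, truth = simulate_membrane(cfg, seed=8)
        intervals = truth.bound_intervals()
        n_spans = sum(len(v) for v in intervals.values())
        assert n_spans == len(truth.events)
        for pid, spans in intervals.items():
            for t0, t1 in spans:
                assert t1 > t0


class TestPresets:
    def test_no_trap_2_5(self):
        cfg = preset_config("no_trap_2_5")
        assert cfg.tag_molpercent == 2.5 and not cfg.trap.enabled

    def test_trap_1_25(self):
        cfg = preset_config("trap_1_25")
        assert cfg.tag_molpercent == 1.25
        assert cfg.trap.enabled and cfg.trap.n_sites == 11

    def test_replenished_4_85_total_concentration(self):
        cfg = preset_config("replenished_4_85")
        total_pct = 100 * cfg.n_tag / cfg.n_lipid_equivalents
        assert total_pct == pytest.approx(4.85, abs=0.01)

    def test_replenished_starts_with_in_ring_cluster(self):
        cfg = preset_config("replenished_4_85")
        cfg.n_lipid_equivalents = 2000
        cfg.n_steps = 10
        traj, _ = simulate_membrane(cfg, seed=0)
        pos0 = traj.frames[0].coords[:cfg.n_tag, :2]
        cluster = pos0[cfg.n_tag_free:]
        center = np.asarray(cfg.trap.center)
        assert np.all(np.linalg.norm(cluster - center, axis=1)
                      <= cfg.trap.ring_radius + 1.0)

    def test_unknown_preset(self):
        with pytest.raises(LookupError):
            preset_config("nonsense")

    def test_idle_gas_baseline_stays_unclustered(self):
        """No attraction, no trap, 1.25 mol%: essentially no clusters."""
        from memlens.clustering import clustered_fraction
        finals = []
        for seed in range(5):
            cfg = fast_config(tag_molpercent=1.25, n_steps=1000,
                              attraction=Attraction(epsilon=0.0))
            traj, _ = simulate_membrane(cfg, seed=seed)
            finals.append(clustered_fraction(traj.frames[-1], traj.topology))
        assert np.mean(finals) < 0.1

    def test_topology_layout_with_trap_and_headgroups(self):
        cfg = fast_config(trap=TrapRing(enabled=True),
                          headgroups=Headgroups(enabled=True, n_per_leaflet=30),
                          n_steps=10)
        traj, _ = simulate_membrane(cfg, seed=0)
        top = traj.topology
        assert (top.group == "TAG").sum() == cfg.n_tag
        assert (top.group == "SITE").sum() == 11
        assert (top.group == "RESIDUE").sum() == 22  # near + distal probes
        assert (top.group == "HEADGROUP").sum() == 60
        assert set(top.leaflet[top.group == "HEADGROUP"]) == {"UPPER", "LOWER"}
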