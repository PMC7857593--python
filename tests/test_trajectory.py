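"""Trajectory I/O round trips and periodic geometry."""

import numpy as np
import pytest

from memlens.trajectory import (
    ParseError, StructuralError,
    min_group_distance, min_image_distance, read_topology, read_trajectory,
    unwrap_coordinates, write_topology, write_trajectory,
    _min_group_distance_bruteforce,
)

from conftest import make_trajectory


def brute_min_image(a, b, box):
    """27-periodic-image brute-force minimum distance (oracle)."""
    best = np.inf
    for i in (-1, 0, 1):
        for j in (-1, 0, 1):
            for k in (-1, 0, 1):
                shift = np.array([i, j, k]) * box
                best = min(best, float(np.linalg.norm(b + shift - a)))
    return best


class TestFormats:
    @pytest.mark.parametrize("fmt,decimals", [("gro", 3), ("xyz", 6), ("csv", 6)])
    def test_round_trip_preserves_coordinates(self, tmp_path, rng, fmt, decimals):
        coords = [rng.uniform(0, 4, size=(3, 3)).round(3) for _ in range(2)]
        traj = make_trajectory(coords, box=(4.0, 4.0, 4.0))
        p = tmp_path / f"t.{fmt}"
        write_trajectory(traj, p, fmt)
        back = read_trajectory(p, fmt, topology=traj.topology)
        assert back.n_frames == 2 and back.n_particles == 3
        np.testing.assert_allclose(back.times, [0.0, 1.0], atol=1e-9)
        np.testing.assert_allclose(back.coords_array(), traj.coords_array(),
                                   atol=1.5 * 10 ** (-decimals))
        np.testing.assert_allclose(back.frames[0].box, traj.frames[0].box)

    def test_gro_box_line(self, tmp_path):
        text = ("fixture t= 0.0\n    2\n"
                "    1TAG    C1    1   0.100   0.200   0.300\n"
                "    2TAG    C1    2   1.100   1.200   1.300\n"
                "4.0 4.0 4.0\n")
        p = tmp_path / "one.gro"
        p.write_text(text)
        traj = read_trajectory(p, "gro")
        np.testing.assert_allclose(traj.frames[0].box, [4.0, 4.0, 4.0])
        np.testing.assert_allclose(traj.frames[0].coords[0], [0.1, 0.2, 0.3])

    def test_gro_time_comment_is_ps(self, tmp_path, rng):
        traj = make_trajectory([rng.uniform(0, 4, size=(2, 3))], times=[2.5])
        p = tmp_path / "t.gro"
        write_trajectory(traj, p, "gro")
        assert "t= 2500" in p.read_text()
        assert read_trajectory(p, "gro").times[0] == pytest.approx(2.5)

    def test_triclinic_gro_rejected(self, tmp_path):
        text = ("fixture t= 0.0\n    1\n"
                "    1TAG    C1    1   0.100   0.200   0.300\n"
                "4.0 4.0 4.0 0.0 0.0 1.0 0.0 0.0 0.0\n")
        p = tmp_path / "tri.gro"
        p.write_text(text)
        with pytest.raises(StructuralError, match="triclinic"):
            read_trajectory(p, "gro")

    def test_csv_dialect_header(self, tmp_path, rng):
        traj = make_trajectory([rng.uniform(0, 4, size=(2, 3))])
        p = tmp_path / "t.csv"
        write_trajectory(traj, p, "csv")
        lines = p.read_text().splitlines()
        assert lines[0].startswith("# box_nm=")
        assert lines[1] == "frame,time_ns,particle_id,x,y,z"

    def test_empty_trajectory_write_errors(self, tmp_path):
        traj = make_trajectory([np.zeros((2, 3))])
        traj.frames = []
        with pytest.raises(ValueError, match="no frames"):
            write_trajectory(traj, tmp_path / "e.xyz", "xyz")

    def test_malformed_record_names_line(self, tmp_path):
        p = tmp_path / "bad.xyz"
        p.write_text("2\ntime_ns=0 box_nm=4,4,4\nA 0 0 0\nB 0 0\n")
        with pytest.raises(ParseError, match="line 4"):
            read_trajectory(p, "xyz")

    def test_inconsistent_particle_count(self, tmp_path):
        p = tmp_path / "bad.xyz"
        p.write_text("2\ntime_ns=0 box_nm=4,4,4\nA 0 0 0\nB 1 1 1\n"
                     "1\ntime_ns=1 box_nm=4,4,4\nA 0 0 0\n")
        with pytest.raises(StructuralError, match="particle count"):
            read_trajectory(p, "xyz")

    def test_topology_sidecar_round_trip(self, tmp_path):
        traj = make_trajectory([np.zeros((3, 3))],
                               groups=["TAG", "RESIDUE", "SITE"],
                               molecule_ids=[0, -1, 0],
                               residue_numbers=[-1, 166, -1])
        p = tmp_path / "topology.csv"
        write_topology(traj.topology, p)
        back = read_topology(p)
        assert list(back.group) == ["TAG", "RESIDUE", "SITE"]
        assert back.residue_number[1] == 166

    def test_gro_readable_by_mdtraj(self, tmp_path, rng):
        """Independent cross-check: emitted GRO is valid GROMACS GRO."""
        mdtraj = pytest.importorskip("mdtraj")
        coords = [rng.uniform(0.5, 3.5, size=(4, 3)).round(3) for _ in range(3)]
        traj = make_trajectory(coords, box=(4.0, 4.0, 4.0))
        p = tmp_path / "x.gro"
        write_trajectory(traj, p, "gro")
        mt = mdtraj.load(str(p))
        assert mt.n_frames == 3 and mt.n_atoms == 4
        np.testing.assert_allclose(mt.xyz, np.array(coords, dtype=np.float32),
                                   atol=1e-3)


class TestPeriodicGeometry:
    def test_min_image_wraps_across_boundary(self):
        d = min_image_distance((0.1, 0, 0), (9.9, 0, 0), (10, 10, 10))
        assert d == pytest.approx(0.2)

    def test_identity(self):
        assert min_image_distance((3, 4, 5), (3, 4, 5), (10, 10, 10)) == 0.0

    def test_against_27_image_brute_force(self, rng):
        box = np.array([7.0, 9.0, 11.0])
        for _ in range(1000):
            a = rng.uniform(0, box)
            b = rng.uniform(0, box)
            assert min_image_distance(a, b, box) == pytest.approx(
                brute_min_image(a, b, box), abs=1e-12)

    def test_symmetry_and_half_diagonal_bound(self, rng):
        box = np.array([6.0, 6.0, 6.0])
        for _ in range(100):
            a, b = rng.uniform(0, box, size=(2, 3))
            dab = min_image_distance(a, b, box)
            assert dab == pytest.approx(min_image_distance(b, a, box))
            assert dab <= np.linalg.norm(box / 2) + 1e-12


class TestGroupDistance:
    def test_single_pair(self):
        traj = make_trajectory([[[0, 0, 0], [0.4, 0, 0]]],
                               groups=["RESIDUE", "TAG"],
                               residue_numbers=[166, -1],
                               molecule_ids=[-1, 0])
        d = min_group_distance(traj.frames[0], [0], [1])
        assert d == pytest.approx(0.4)

    def test_matches_quadratic_scan(self, random_fixture):
        frame = random_fixture.frames[0]
        a, b = np.arange(25), np.arange(25, 50)
        assert min_group_distance(frame, a, b) == pytest.approx(
            _min_group_distance_bruteforce(frame, a, b), abs=1e-12)

    def test_overlapping_groups_rejected(self, random_fixture):
        with pytest.raises(ValueError, match="disjoint"):
            min_group_distance(random_fixture.frames[0], [0, 1], [1, 2])

    def test_empty_group_rejected(self, random_fixture):
        with pytest.raises(ValueError, match="non-empty"):
            min_group_distance(random_fixture.frames[0], [], [1])


class TestUnwrap:
    def test_boundary_crossing(self):
        traj = make_trajectory([[[9.9, 5, 5]], [[0.1, 5, 5]]])
        paths, flagged = unwrap_coordinates(traj, [0])
        assert paths[1, 0, 0] == pytest.approx(10.1)
        assert flagged == []

    def test_stationary_particle_unchanged(self):
        traj = make_trajectory([[[2, 3, 0]]] * 5)
        paths, _ = unwrap_coordinates(traj, [0])
        assert np.all(paths[:, 0, 0] == 2) and np.all(paths[:, 0, 1] == 3)

    def test_wrap_then_unwrap_recovers_random_walk(self, rng):
        steps = rng.normal(0, 0.4, size=(200, 2))  # safely below L/2 per step
        true_path = np.concatenate([[np.zeros(2)], np.cumsum(steps, axis=0)])
        box = np.array([5.0, 5.0, 5.0])
        wrapped = np.zeros((201, 1, 3))
        wrapped[:, 0, :2] = np.mod(true_path, box[:2])
        traj = make_trajectory(list(wrapped), box=box)
        paths, flagged = unwrap_coordinates(traj, [0])
        assert flagged == []
        np.testing.assert_allclose(paths[:, 0, :] - paths[0, 0, :],
                                   true_path, atol=1e-9)
        # re-wrapping recovers the stored coordinates
        np.testing.assert_allclose(np.mod(paths[:, 0, :], box[:2]),
                                   wrapped[:, 0, :2], atol=1e-9)
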