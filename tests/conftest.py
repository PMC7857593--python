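"""Shared fixtures: small hand-built trajectories with known geometry."""

import numpy as np
import pytest

from memlens.trajectory import Frame, Topology, Trajectory


def make_topology(groups, molecule_ids=None, residue_numbers=None, leaflets=None):
    """Topology from a list of group names (one particle per entry)."""
    n = len(groups)
    return Topology(
        particle_id=np.arange(n),
        name=np.array([f"P{i}" for i in range(n)], dtype=object),
        group=np.array(groups, dtype=object),
        molecule_id=np.array(molecule_ids if molecule_ids is not None
                             else [i if g == "TAG" else -1
                                   for i, g in enumerate(groups)]),
        residue_number=np.array(residue_numbers if residue_numbers is not None
                                else [-1] * n),
        leaflet=np.array(leaflets if leaflets is not None
                         else ["UNASSIGNED"] * n, dtype=object),
    )


def make_trajectory(coords_per_frame, box=(10.0, 10.0, 10.0), groups=None,
                    times=None, **top_kwargs):
    """Trajectory from a list of (n, 3) coordinate arrays."""
    coords_per_frame = [np.asarray(c, dtype=float) for c in coords_per_frame]
    n = coords_per_frame[0].shape[0]
    if groups is None:
        groups = ["TAG"] * n
    top = make_topology(groups, **top_kwargs)
    if times is None:
        times = np.arange(len(coords_per_frame), dtype=float)
    frames = [Frame(time=float(t), box=np.asarray(box, dtype=float), coords=c)
              for t, c in zip(times, coords_per_frame)]
    return Trajectory(topology=top, frames=frames)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def random_fixture(rng):
    """20-frame, 50-particle random TAG trajectory in a periodic box."""
    box = (8.0, 8.0, 8.0)
    coords = [rng.uniform(0, 8, size=(50, 3)) for _ in range(20)]
    return make_trajectory(coords, box=box)
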