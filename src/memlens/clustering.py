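"""Per-TAG clustering statistic and cluster geometry.

Two TAG molecules are neighbors when the smallest minimum-image distance
over all cross particle pairs is at or below the cutoff (default 0.5 nm).
A TAG is *clustered* when it has at least two TAG neighbors, so monomers
and dimers contribute zero to the clustered fraction by construction.  The
per-TAG rule is the headline statistic; connected components of the same
neighbor graph are computed as auxiliary geometry (sizes, periodic
centroids, distance to a reference point such as the trap center).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components as _cc
from scipy.spatial import cKDTree

from .occupancy import sample_indices
from .trajectory import Frame, Topology, Trajectory, min_image_distance

DEFAULT_CUTOFF_NM = 0.5


@dataclass
class Components:
    """Connected components of the TAG neighbor graph in one frame."""

    molecule_ids: np.ndarray
    labels: np.ndarray
    sizes: np.ndarray            # per component label
    largest_size: int
    largest_centroid: np.ndarray  # (x, y) nm, periodic mean
    centroid_dist_to_reference: float | None = None


@dataclass
class ClusterSeries:
    """Per-frame clustering record of a trajectory."""

    sample_times: np.ndarray
    neighbor_counts: np.ndarray      # (n_samples, n_tags)
    clustered_fraction: np.ndarray   # (n_samples,)
    component_labels: np.ndarray     # (n_samples, n_tags)
    n_clusters: np.ndarray           # components of size >= 2
    largest_cluster_size: np.ndarray
    largest_cluster_centroid: np.ndarray  # (n_samples, 2)
    centroid_dist_to_reference: np.ndarray | None = None

    def to_table(self) -> pd.DataFrame:
        dist = (self.centroid_dist_to_reference
                if self.centroid_dist_to_reference is not None
                else np.full(len(self.sample_times), np.nan))
        return pd.DataFrame({
            "time_ns": self.sample_times,
            "clustered_fraction": self.clustered_fraction,
            "n_clusters": self.n_clusters,
            "largest_cluster_size": self.largest_cluster_size,
            "centroid_x": self.largest_cluster_centroid[:, 0],
            "centroid_y": self.largest_cluster_centroid[:, 1],
            "centroid_dist_to_trap": dist,
        })


def _molecule_pairs(frame: Frame, topology: Topology, cutoff: float
                    ) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """TAG molecule ids and the neighbor pairs (indices into that id list)."""
    mol_ids = topology.tag_molecule_ids()
    if mol_ids.size == 0:
        raise ValueError("topology has no TAG molecules")
    tag_mask = topology.group == "TAG"
    pids = topology.particle_id[tag_mask]
    mol_of_particle = topology.molecule_id[tag_mask]
    mol_index = {m: k for k, m in enumerate(mol_ids)}
    box = frame.box
    pts = np.mod(frame.coords[pids], box)
    pts = np.where(pts >= box, 0.0, pts)
    tree = cKDTree(pts, boxsize=box)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    seen = set()
    for a, b in pairs:
        ma, mb = mol_index[mol_of_particle[a]], mol_index[mol_of_particle[b]]
        if ma != mb:
            seen.add((min(ma, mb), max(ma, mb)))
    return mol_ids, sorted(seen)


def tag_neighbor_counts(frame: Frame, topology: Topology,
                        cutoff: float = DEFAULT_CUTOFF_NM) -> np.ndarray:
    """Number of other TAG molecules within the cutoff, per TAG molecule.

    Ordered by sorted molecule id; symmetric by construction.
    """
    mol_ids, pairs = _molecule_pairs(frame, topology, cutoff)
    counts = np.zeros(len(mol_ids), dtype=int)
    for a, b in pairs:
        counts[a] += 1
        counts[b] += 1
    return counts


def clustered_fraction(frame: Frame, topology: Topology,
                       cutoff: float = DEFAULT_CUTOFF_NM) -> float:
    """Fraction of TAGs with >= 2 TAG neighbors (monomers/dimers excluded)."""
    counts = tag_neighbor_counts(frame, topology, cutoff)
    return float(np.mean(counts >= 2))


def periodic_centroid(points: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Centroid of points under periodic boundaries via the circular mean.

    Each dimension is mapped to an angle, averaged on the circle, and mapped
    back, so clusters straddling the boundary get a sensible center.
    """
    points = np.asarray(points, dtype=float)
    box = np.asarray(box, dtype=float)[: points.shape[1]]
    theta = 2 * np.pi * points / box
    mean_angle = np.arctan2(np.sin(theta).mean(axis=0), np.cos(theta).mean(axis=0))
    return np.mod(mean_angle / (2 * np.pi), 1.0) * box


def connected_components(frame: Frame, topology: Topology,
                         cutoff: float = DEFAULT_CUTOFF_NM,
                         reference: np.ndarray | None = None) -> Components:
    """Connected components of the TAG neighbor graph.

    The largest component's centroid uses the periodic-mean convention; when
    ``reference`` (e.g. the trap center) is given, its minimum-image distance
    to the centroid is reported.
    """
    mol_ids, pairs = _molecule_pairs(frame, topology, cutoff)
    n = len(mol_ids)
    if pairs:
        rows, cols = zip(*pairs)
        adj = coo_matrix((np.ones(len(pairs)), (rows, cols)), shape=(n, n))
    else:
        adj = coo_matrix((n, n))
    n_comp, labels = _cc(adj, directed=False)
    sizes = np.bincount(labels, minlength=n_comp)
    largest = int(np.argmax(sizes))
    members = np.flatnonzero(labels == largest)
    tag_mask = topology.group == "TAG"
    # representative particle position per molecule: mean of its particles
    # min-imaged to the first one, then the periodic mean across molecules
    reps = []
    for m in mol_ids[members]:
        pids = topology.particle_id[tag_mask & (topology.molecule_id == m)]
        pts = frame.coords[pids][:, :2]
        ref0 = pts[0]
        d = pts - ref0
        d -= frame.box[:2] * np.round(d / frame.box[:2])
        reps.append(np.mod(ref0 + d.mean(axis=0), frame.box[:2]))
    centroid = periodic_centroid(np.array(reps), frame.box[:2])
    dist = None
    if reference is not None:
        dist = float(min_image_distance(
            np.append(centroid, 0.0),
            np.append(np.asarray(reference, dtype=float)[:2], 0.0),
            frame.box))
    return Components(molecule_ids=mol_ids, labels=labels, sizes=sizes,
                      largest_size=int(sizes[largest]),
                      largest_centroid=centroid,
                      centroid_dist_to_reference=dist)


def clustered_fraction_series(traj: Trajectory,
                              cutoff: float = DEFAULT_CUTOFF_NM,
                              stride: float = 1.0,
                              reference: np.ndarray | None = None) -> ClusterSeries:
    """Per-frame neighbor counts, clustered fraction and component geometry."""
    idx = sample_indices(traj.times, stride)
    n_tag = len(traj.topology.tag_molecule_ids())
    times = traj.times[idx]
    counts = np.zeros((len(idx), n_tag), dtype=int)
    labels = np.zeros((len(idx), n_tag), dtype=int)
    frac = np.zeros(len(idx))
    n_clusters = np.zeros(len(idx), dtype=int)
    largest = np.zeros(len(idx), dtype=int)
    centroids = np.zeros((len(idx), 2))
    dists = np.full(len(idx), np.nan)
    for k, i in enumerate(idx):
        frame = traj.frames[i]
        counts[k] = tag_neighbor_counts(frame, traj.topology, cutoff)
        frac[k] = np.mean(counts[k] >= 2)
        comp = connected_components(frame, traj.topology, cutoff, reference)
        labels[k] = comp.labels
        n_clusters[k] = int(np.sum(comp.sizes >= 2))
        largest[k] = comp.largest_size
        centroids[k] = comp.largest_centroid
        if comp.centroid_dist_to_reference is not None:
            dists[k] = comp.centroid_dist_to_reference
    return ClusterSeries(sample_times=times, neighbor_counts=counts,
                         clustered_fraction=frac, component_labels=labels,
                         n_clusters=n_clusters, largest_cluster_size=largest,
                         largest_cluster_centroid=centroids,
                         centroid_dist_to_reference=(
                             dists if reference is not None else None))
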