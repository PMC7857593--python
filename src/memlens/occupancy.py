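"""Per-residue TAG contact occupancy over time windows.

A residue is "in contact" in a sampled frame when the smallest minimum-image
distance between any of its particles and any TAG particle is at or below
the contact cutoff (default 0.5 nm; the boundary case counts as contact).
Occupancy over a half-open window [t0, t1) is the fraction of sampled frames
in contact; replicate aggregation reports mean +/- SEM (n-1 denominator).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trajectory import Trajectory, min_group_distance

logger = logging.getLogger(__name__)

DEFAULT_CUTOFF_NM = 0.5
DEFAULT_STRIDE_NS = 1.0


@dataclass
class ContactSeries:
    """Boolean contact record for one residue at the analysis stride."""

    residue_number: int
    sample_times: np.ndarray
    contacts: np.ndarray

    def __post_init__(self) -> None:
        self.sample_times = np.asarray(self.sample_times, dtype=float)
        self.contacts = np.asarray(self.contacts, dtype=bool)
        if self.sample_times.shape != self.contacts.shape:
            raise ValueError("one contact boolean per sampled frame required")


@dataclass
class OccupancyProfile:
    """Per-residue occupancy over a window, optionally with replicate stats."""

    residue_numbers: np.ndarray
    window: tuple[float, float]
    occupancy: np.ndarray
    occupancy_sem: np.ndarray | None = None
    n_replicates: int = 1

    def __post_init__(self) -> None:
        self.residue_numbers = np.asarray(self.residue_numbers, dtype=int)
        self.occupancy = np.asarray(self.occupancy, dtype=float)
        if np.any((self.occupancy < 0) | (self.occupancy > 1)):
            raise ValueError("occupancy must lie in [0, 1]")
        if self.occupancy_sem is not None:
            self.occupancy_sem = np.asarray(self.occupancy_sem, dtype=float)

    def to_table(self) -> pd.DataFrame:
        sem = (self.occupancy_sem if self.occupancy_sem is not None
               else np.full_like(self.occupancy, np.nan))
        return pd.DataFrame({
            "residue_number": self.residue_numbers,
            "window_t0_ns": self.window[0],
            "window_t1_ns": self.window[1],
            "occupancy_mean": self.occupancy,
            "occupancy_sem": sem,
            "n_replicates": self.n_replicates,
        })


def sample_indices(times: np.ndarray, stride: float) -> np.ndarray:
    """Frame indices realizing the analysis stride.

    Frames finer than the stride: nearest frame on the stride grid.  Frames
    coarser: every frame, with a logged warning.
    """
    times = np.asarray(times, dtype=float)
    if len(times) < 2:
        return np.arange(len(times))
    spacing = float(np.median(np.diff(times)))
    if spacing > stride * (1 + 1e-9):
        logger.warning("frame spacing %.3g ns coarser than stride %.3g ns; "
                       "using every frame", spacing, stride)
        return np.arange(len(times))
    grid = np.arange(times[0], times[-1] + stride / 2, stride)
    idx = np.searchsorted(times, grid)
    idx = np.clip(idx, 0, len(times) - 1)
    left = np.clip(idx - 1, 0, len(times) - 1)
    use_left = np.abs(times[left] - grid) <= np.abs(times[idx] - grid)
    idx = np.where(use_left, left, idx)
    return np.unique(idx)


def contact_series(traj: Trajectory, residue_number: int,
                   cutoff: float = DEFAULT_CUTOFF_NM,
                   stride: float = DEFAULT_STRIDE_NS) -> ContactSeries:
    """Contact record of one residue against all TAG particles."""
    res_ids = traj.topology.particles_of_residue(residue_number)
    if res_ids.size == 0:
        raise LookupError(f"residue {residue_number} not found in topology")
    tag_ids = traj.topology.particles_in_group("TAG")
    if tag_ids.size == 0:
        raise ValueError("topology has no TAG particles")
    idx = sample_indices(traj.times, stride)
    contacts = np.empty(len(idx), dtype=bool)
    for k, i in enumerate(idx):
        d = min_group_distance(traj.frames[i], res_ids, tag_ids)
        contacts[k] = d <= cutoff  # boundary case counts as contact
    return ContactSeries(residue_number=residue_number,
                         sample_times=traj.times[idx], contacts=contacts)


def occupancy_profile(series_set: list[ContactSeries],
                      window: tuple[float, float]) -> OccupancyProfile:
    """Windowed occupancy per residue from its contact series.

    The window is half-open [t0, t1) so consecutive windows partition the
    sampled times cleanly.
    """
    t0, t1 = window
    if not t0 < t1:
        raise ValueError("window must satisfy t0 < t1")
    residues = []
    occ = []
    for s in series_set:
        in_win = (s.sample_times >= t0) & (s.sample_times < t1)
        n = int(np.sum(in_win))
        if n == 0:
            raise ValueError(
                f"window [{t0}, {t1}) contains no samples for residue "
                f"{s.residue_number}")
        residues.append(s.residue_number)
        occ.append(np.sum(s.contacts[in_win]) / n)
    return OccupancyProfile(residue_numbers=np.array(residues),
                            window=(t0, t1), occupancy=np.array(occ))


def aggregate_replicates(profiles: list[OccupancyProfile]) -> OccupancyProfile:
    """Mean +/- SEM per residue across replicate profiles."""
    if not profiles:
        raise ValueError("need at least one replicate profile")
    ref = profiles[0]
    for p in profiles[1:]:
        if not np.array_equal(p.residue_numbers, ref.residue_numbers):
            raise ValueError("replicates must share identical residue sets")
        if p.window != ref.window:
            raise ValueError("replicates must share identical windows")
    values = np.stack([p.occupancy for p in profiles])
    n = values.shape[0]
    mean = values.mean(axis=0)
    if n > 1:
        sem = values.std(axis=0, ddof=1) / np.sqrt(n)
        sem[np.ptp(values, axis=0) == 0] = 0.0  # identical replicates: exactly 0
    else:
        sem = np.full_like(mean, np.nan)  # SEM undefined for a single replicate
    return OccupancyProfile(residue_numbers=ref.residue_numbers, window=ref.window,
                            occupancy=mean, occupancy_sem=sem, n_replicates=n)


def contact_matrix(traj: Trajectory, cutoff: float = DEFAULT_CUTOFF_NM,
                   stride: float = DEFAULT_STRIDE_NS
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Contact indicator for every residue at once.

    Returns ``(sample_times, residue_numbers, contacts)`` with contacts of
    shape ``(n_samples, n_residues)``; equivalent to stacking
    :func:`contact_series` over residues but vectorized per frame.
    """
    top = traj.topology
    residues = top.residue_numbers()
    if residues.size == 0:
        raise LookupError("topology has no RESIDUE particles")
    tag_ids = top.particles_in_group("TAG")
    if tag_ids.size == 0:
        raise ValueError("topology has no TAG particles")
    res_mask = top.group == "RESIDUE"
    rp = top.particle_id[res_mask]
    res_of = np.searchsorted(residues, top.residue_number[res_mask])
    idx = sample_indices(traj.times, stride)
    contacts = np.zeros((len(idx), len(residues)), dtype=bool)
    for k, i in enumerate(idx):
        fr = traj.frames[i]
        d = fr.coords[rp][:, None, :] - fr.coords[tag_ids][None, :, :]
        d -= fr.box * np.round(d / fr.box)
        r = np.sqrt(np.einsum("ijk,ijk->ij", d, d))
        dmin = np.full(len(residues), np.inf)
        np.minimum.at(dmin, res_of, r.min(axis=1))
        contacts[k] = dmin <= cutoff
    return traj.times[idx], residues, contacts


def occupancy_analysis(trajs: list[Trajectory], windows: list[tuple[float, float]],
                       cutoff: float = DEFAULT_CUTOFF_NM,
                       stride: float = DEFAULT_STRIDE_NS) -> pd.DataFrame:
    """Full occupancy workflow: all residues, all windows, replicate stats."""
    per_rep = []
    for traj in trajs:
        times, residues, contacts = contact_matrix(traj, cutoff=cutoff,
                                                   stride=stride)
        per_rep.append((times, residues, contacts))
    tables = []
    for window in windows:
        profiles = []
        for times, residues, contacts in per_rep:
            series = [ContactSeries(residue_number=int(r), sample_times=times,
                                    contacts=contacts[:, j])
                      for j, r in enumerate(residues)]
            profiles.append(occupancy_profile(series, window))
        tables.append(aggregate_replicates(profiles).to_table())
    return pd.concat(tables, ignore_index=True)
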