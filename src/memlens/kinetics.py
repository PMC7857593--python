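"""Binding-complex detection, dwell-time statistics and H-bond geometry.

A TAG molecule is bound to a site while their smallest minimum-image
distance stays at or below the binding cutoff.  Maximal runs of the bound
indicator (optionally merging short unbound gaps) become binding events;
events truncated by either trajectory end are flagged censored and excluded
from the mean lifetime (they would bias it downward) but kept in the
survival curve S(t) = fraction of events with dwell >= t.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .occupancy import sample_indices
from .trajectory import Frame, Trajectory, min_group_distance, min_image_displacement

logger = logging.getLogger(__name__)

DEFAULT_CUTOFF_BIND_NM = 0.5


@dataclass
class BindingEvent:
    tag_molecule_id: int
    site_id: int
    start: float  # ns
    end: float    # ns
    censored: bool = False

    @property
    def dwell(self) -> float:
        return self.end - self.start


@dataclass
class BoundSeries:
    """Boolean bound indicator for one (TAG, site) pair at the stride."""

    tag_molecule_id: int
    site_id: int
    times: np.ndarray
    bound: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.bound = np.asarray(self.bound, dtype=bool)


@dataclass
class DwellStatistics:
    events: list[BindingEvent]
    mean_lifetime: float           # ns, over uncensored events (nan if none)
    survival_t: np.ndarray         # ns grid
    survival: np.ndarray           # S(t), all events

    def events_table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "tag_id": [e.tag_molecule_id for e in self.events],
            "site_id": [e.site_id for e in self.events],
            "start_ns": [e.start for e in self.events],
            "end_ns": [e.end for e in self.events],
            "dwell_ns": [e.dwell for e in self.events],
            "censored": [e.censored for e in self.events],
        })

    def survival_table(self) -> pd.DataFrame:
        return pd.DataFrame({"t_ns": self.survival_t, "survival": self.survival})


@dataclass
class HBondCriterion:
    """Geometric hydrogen-bond rule: donor–acceptor distance and D–H–A angle."""

    d_max: float = 0.35       # nm
    angle_min: float = 150.0  # degrees

    def __post_init__(self) -> None:
        if self.d_max <= 0:
            raise ValueError("d_max must be positive")
        if not 0 < self.angle_min <= 180:
            raise ValueError("angle_min must lie in (0, 180]")


def bound_series(traj: Trajectory, tag_molecule_id: int, site_id: int,
                 cutoff_bind: float = DEFAULT_CUTOFF_BIND_NM,
                 stride: float = 1.0) -> BoundSeries:
    """Bound indicator: min TAG-site distance <= cutoff at each sample."""
    tag_ids = traj.topology.particles_of_tag(tag_molecule_id)
    if tag_ids.size == 0:
        raise LookupError(f"TAG molecule {tag_molecule_id} not in topology")
    site_ids = traj.topology.particles_of_site(site_id)
    if site_ids.size == 0:
        raise LookupError(f"site {site_id} not in topology")
    idx = sample_indices(traj.times, stride)
    bound = np.empty(len(idx), dtype=bool)
    for k, i in enumerate(idx):
        d = min_group_distance(traj.frames[i], tag_ids, site_ids)
        bound[k] = d <= cutoff_bind
    return BoundSeries(tag_molecule_id=tag_molecule_id, site_id=site_id,
                       times=traj.times[idx], bound=bound)


def _runs_with_gaps(bound: np.ndarray, gap_tolerance: int) -> list[tuple[int, int]]:
    """Maximal (start, stop) index runs of True, merging gaps <= tolerance."""
    idx = np.flatnonzero(bound)
    if idx.size == 0:
        return []
    runs = []
    start = prev = idx[0]
    for i in idx[1:]:
        if i - prev - 1 <= gap_tolerance:
            prev = i
        else:
            runs.append((start, prev))
            start = prev = i
    runs.append((start, prev))
    return runs


def extract_dwell_statistics(series: BoundSeries | np.ndarray,
                             gap_tolerance: int = 0,
                             times: np.ndarray | None = None,
                             tag_molecule_id: int = -1,
                             site_id: int = -1) -> DwellStatistics:
    """Binding events, mean lifetime and survival curve from a bound series.

    A run of k bound samples at frame spacing dt has dwell k*dt (the event
    spans [t_first, t_last + dt)).  Runs touching either series end are
    censored.
    """
    if isinstance(series, BoundSeries):
        bound = series.bound
        times = series.times
        tag_molecule_id = series.tag_molecule_id
        site_id = series.site_id
    else:
        bound = np.asarray(series, dtype=bool)
        if times is None:
            times = np.arange(len(bound), dtype=float)
    if len(bound) == 0:
        raise ValueError("bound series is empty")
    dt = float(np.median(np.diff(times))) if len(times) > 1 else 1.0
    events = []
    for start, stop in _runs_with_gaps(bound, gap_tolerance):
        censored = start == 0 or stop == len(bound) - 1
        events.append(BindingEvent(
            tag_molecule_id=tag_molecule_id, site_id=site_id,
            start=float(times[start]), end=float(times[stop]) + dt,
            censored=censored))
    return summarize_events(events)


def summarize_events(events: list[BindingEvent]) -> DwellStatistics:
    """Mean lifetime (uncensored) and survival curve (all events)."""
    uncensored = [e.dwell for e in events if not e.censored]
    if uncensored:
        mean = float(np.mean(uncensored))
    elif events:
        # every event touches a series end: fall back to the biased mean
        # over all events rather than reporting nothing
        logger.warning("all %d events censored; mean lifetime is a lower "
                       "bound", len(events))
        mean = float(np.mean([e.dwell for e in events]))
    else:
        mean = float("nan")
    dwells = np.array([e.dwell for e in events], dtype=float)
    if dwells.size:
        grid = np.unique(np.concatenate([[0.0], dwells]))
        surv = np.array([np.mean(dwells >= t) for t in grid])
    else:
        grid = np.array([0.0])
        surv = np.array([np.nan])
    return DwellStatistics(events=events, mean_lifetime=mean,
                           survival_t=grid, survival=surv)


def hbond_geometric(frame: Frame, donor: int, hydrogen: int, acceptor: int,
                    crit: HBondCriterion | None = None) -> bool:
    """Geometric hydrogen bond: D–A distance and D–H–A angle thresholds.

    Intended for atomistic-mode topologies where explicit hydrogens exist.
    """
    if crit is None:
        crit = HBondCriterion()
    if len({donor, hydrogen, acceptor}) != 3:
        raise ValueError("donor, hydrogen and acceptor must be distinct particles")
    box = frame.box
    d_pos = frame.coords[donor]
    h_pos = frame.coords[hydrogen]
    a_pos = frame.coords[acceptor]
    da = min_image_displacement(d_pos, a_pos, box)
    d_da = float(np.linalg.norm(da))
    hd = min_image_displacement(h_pos, d_pos, box)
    ha = min_image_displacement(h_pos, a_pos, box)
    n_hd, n_ha = np.linalg.norm(hd), np.linalg.norm(ha)
    if n_hd == 0 or n_ha == 0 or d_da == 0:
        raise ValueError("coincident particles in hydrogen-bond geometry")
    cosang = float(np.clip(np.dot(hd, ha) / (n_hd * n_ha), -1.0, 1.0))
    angle = float(np.degrees(np.arccos(cosang)))
    return d_da <= crit.d_max and angle >= crit.angle_min


def bound_matrix(traj: Trajectory, cutoff_bind: float = DEFAULT_CUTOFF_BIND_NM,
                 stride: float = 1.0
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Bound indicator for every (TAG molecule, site) pair at once.

    Returns ``(times, tag_ids, site_ids, bound)`` with bound of shape
    ``(n_samples, n_tags, n_sites)``.  Distances are molecule-to-site
    minima over all cross particle pairs, vectorized per frame.
    """
    top = traj.topology
    tag_ids = top.tag_molecule_ids()
    site_ids = np.unique(top.molecule_id[top.group == "SITE"])
    if tag_ids.size == 0 or site_ids.size == 0:
        raise LookupError("topology needs both TAG and SITE groups")
    tag_mask = top.group == "TAG"
    site_mask = top.group == "SITE"
    tp = top.particle_id[tag_mask]
    sp = top.particle_id[site_mask]
    tag_of = np.searchsorted(tag_ids, top.molecule_id[tag_mask])
    site_of = np.searchsorted(site_ids, top.molecule_id[site_mask])
    idx = sample_indices(traj.times, stride)
    bound = np.zeros((len(idx), len(tag_ids), len(site_ids)), dtype=bool)
    for k, i in enumerate(idx):
        fr = traj.frames[i]
        d = fr.coords[tp][:, None, :] - fr.coords[sp][None, :, :]
        d -= fr.box * np.round(d / fr.box)
        r = np.sqrt(np.einsum("ijk,ijk->ij", d, d))
        dmin = np.full((len(tag_ids), len(site_ids)), np.inf)
        np.minimum.at(dmin, (tag_of[:, None], site_of[None, :]), r)
        bound[k] = dmin <= cutoff_bind
    return traj.times[idx], tag_ids, site_ids, bound


def site_lifetimes(traj: Trajectory, cutoff_bind: float = DEFAULT_CUTOFF_BIND_NM,
                   stride: float = 1.0, gap_tolerance: int = 0) -> DwellStatistics:
    """Dwell statistics pooled over every (TAG molecule, site) pair."""
    times, tag_ids, site_ids, bound = bound_matrix(traj, cutoff_bind, stride)
    events: list[BindingEvent] = []
    for ti, tag in enumerate(tag_ids):
        for si, site in enumerate(site_ids):
            if bound[:, ti, si].any():
                series = BoundSeries(tag_molecule_id=int(tag), site_id=int(site),
                                     times=times, bound=bound[:, ti, si])
                events.extend(extract_dwell_statistics(
                    series, gap_tolerance=gap_tolerance).events)
    events.sort(key=lambda e: (e.start, e.tag_molecule_id, e.site_id))
    return summarize_events(events)
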