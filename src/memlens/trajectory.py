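"""Domain types and I/O for membrane particle trajectories.

Internal units are nm for lengths and ns for times.  Boxes are orthorhombic;
triclinic input is rejected.  Particle indexing is 0-based internally and
1-based only at format boundaries (GRO).

Supported dialects
------------------
* multi-frame GRO: fixed columns, coordinates in nm, a ``t=`` time comment on
  the title line (interpreted in ps, the GROMACS convention, and converted
  to ns);
* extended XYZ: the comment line carries ``time_ns=<t> box_nm=<Lx,Ly,Lz>``;
* long-format CSV with header ``frame,time_ns,particle_id,x,y,z`` and the
  (constant) box stored in a leading ``# box_nm=Lx,Ly,Lz`` comment line.

Group membership (TAG molecules, protein residues, head-group markers, trap
sites) lives in a sidecar topology CSV with header
``particle_id,name,group,molecule_id,residue_number,leaflet``.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)

GROUPS = ("TAG", "RESIDUE", "HEADGROUP", "SITE", "OTHER")
LEAFLETS = ("UPPER", "LOWER", "UNASSIGNED")

# GRO residue-name encoding of the particle groups (5-char field).
_GROUP_TO_RESNAME = {
    "TAG": "TAG",
    "RESIDUE": "RES",
    "HEADGROUP": "HG",
    "SITE": "SITE",
    "OTHER": "OTH",
}
_RESNAME_TO_GROUP = {v: k for k, v in _GROUP_TO_RESNAME.items()}


class TrajectoryError(Exception):
    """Base error for trajectory parsing/validation problems."""


class ParseError(TrajectoryError):
    """Malformed record in a trajectory file (carries a line number)."""


class StructuralError(TrajectoryError):
    """Inconsistent structure (particle counts, time ordering, ...)."""


@dataclass
class Topology:
    """Assignment of particles to named groups and molecules.

    ``molecule_id`` is -1 where not applicable, ``residue_number`` -1 where
    absent.  Every TAG particle must carry a molecule_id and every RESIDUE
    particle a residue_number.
    """

    particle_id: np.ndarray
    name: np.ndarray
    group: np.ndarray
    molecule_id: np.ndarray
    residue_number: np.ndarray
    leaflet: np.ndarray

    def __post_init__(self) -> None:
        self.particle_id = np.asarray(self.particle_id, dtype=int)
        self.name = np.asarray(self.name, dtype=object)
        self.group = np.asarray(self.group, dtype=object)
        self.molecule_id = np.asarray(self.molecule_id, dtype=int)
        self.residue_number = np.asarray(self.residue_number, dtype=int)
        self.leaflet = np.asarray(self.leaflet, dtype=object)
        self.validate()

    def validate(self) -> None:
        n = len(self.particle_id)
        if not np.array_equal(self.particle_id, np.arange(n)):
            raise StructuralError("particle_ids must be unique, contiguous and 0-based")
        for arr, label in ((self.name, "name"), (self.group, "group"),
                           (self.molecule_id, "molecule_id"),
                           (self.residue_number, "residue_number"),
                           (self.leaflet, "leaflet")):
            if len(arr) != n:
                raise StructuralError(f"topology field {label} has wrong length")
        bad = set(self.group) - set(GROUPS)
        if bad:
            raise StructuralError(f"unknown particle groups: {sorted(bad)}")
        bad = set(self.leaflet) - set(LEAFLETS)
        if bad:
            raise StructuralError(f"unknown leaflet labels: {sorted(bad)}")
        tag = self.group == "TAG"
        if np.any(self.molecule_id[tag] < 0):
            raise StructuralError("every TAG particle needs a molecule_id")
        res = self.group == "RESIDUE"
        if np.any(self.residue_number[res] < 0):
            raise StructuralError("every RESIDUE particle needs a residue_number")

    def __len__(self) -> int:
        return len(self.particle_id)

    # -- selections -----------------------------------------------------
    def particles_in_group(self, group: str) -> np.ndarray:
        return self.particle_id[self.group == group]

    def tag_molecule_ids(self) -> np.ndarray:
        """Sorted unique molecule ids of TAG molecules."""
        return np.unique(self.molecule_id[self.group == "TAG"])

    def particles_of_tag(self, molecule_id: int) -> np.ndarray:
        mask = (self.group == "TAG") & (self.molecule_id == molecule_id)
        return self.particle_id[mask]

    def particles_of_residue(self, residue_number: int) -> np.ndarray:
        mask = (self.group == "RESIDUE") & (self.residue_number == residue_number)
        return self.particle_id[mask]

    def particles_of_site(self, site_id: int) -> np.ndarray:
        mask = (self.group == "SITE") & (self.molecule_id == site_id)
        return self.particle_id[mask]

    def residue_numbers(self) -> np.ndarray:
        return np.unique(self.residue_number[self.group == "RESIDUE"])


@dataclass
class Frame:
    """One trajectory frame: time (ns), orthorhombic box (nm), wrapped coords (nm)."""

    time: float
    box: np.ndarray
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.box = np.asarray(self.box, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.box.shape != (3,):
            raise StructuralError("box must be (Lx, Ly, Lz); triclinic boxes unsupported")
        if np.any(self.box <= 0):
            raise StructuralError("box lengths must be positive")
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise StructuralError("coords must have shape (n_particles, 3)")


@dataclass
class Trajectory:
    """Time-ordered frames plus the particle topology."""

    topology: Topology
    frames: list[Frame] = field(default_factory=list)
    replicate_id: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        n = len(self.topology)
        for i, fr in enumerate(self.frames):
            if fr.coords.shape[0] != n:
                raise StructuralError(
                    f"frame {i} has {fr.coords.shape[0]} particles, topology has {n}")
        times = self.times
        if len(times) > 1 and np.any(np.diff(times) <= 0):
            raise StructuralError("frame times must be strictly increasing")

    @property
    def times(self) -> np.ndarray:
        return np.array([fr.time for fr in self.frames], dtype=float)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def n_particles(self) -> int:
        return len(self.topology)

    def coords_array(self) -> np.ndarray:
        """All coordinates as an (n_frames, n_particles, 3) array."""
        return np.stack([fr.coords for fr in self.frames])

    def frame_spacing(self) -> float:
        dts = np.diff(self.times)
        if len(dts) == 0:
            raise StructuralError("trajectory needs at least 2 frames for a spacing")
        return float(np.median(dts))


# ---------------------------------------------------------------------------
# periodic geometry
# ---------------------------------------------------------------------------

def min_image_displacement(a: np.ndarray, b: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Minimum-image displacement vector(s) b - a in an orthorhombic box."""
    box = np.asarray(box, dtype=float)
    d = np.asarray(b, dtype=float) - np.asarray(a, dtype=float)
    return d - box * np.round(d / box)


def min_image_distance(a, b, box) -> float | np.ndarray:
    """Minimum-image Euclidean distance between points (broadcastable)."""
    box = np.asarray(box, dtype=float)
    if np.any(box <= 0):
        raise ValueError("box lengths must be positive")
    d = min_image_displacement(a, b, box)
    return np.sqrt(np.sum(d * d, axis=-1))


def min_group_distance(frame: Frame, group_a: Sequence[int], group_b: Sequence[int],
                       box: np.ndarray | None = None) -> float:
    """Smallest minimum-image distance over all cross pairs of two particle groups.

    Accelerated with a periodic k-d tree; exact (identical to the quadratic
    all-pairs scan).
    """
    group_a = np.asarray(group_a, dtype=int)
    group_b = np.asarray(group_b, dtype=int)
    if group_a.size == 0 or group_b.size == 0:
        raise ValueError("both groups must be non-empty")
    if np.intersect1d(group_a, group_b).size:
        raise ValueError("groups must be disjoint")
    if box is None:
        box = frame.box
    box = np.asarray(box, dtype=float)
    pa = np.mod(frame.coords[group_a], box)
    pb = np.mod(frame.coords[group_b], box)
    # cKDTree with boxsize needs points strictly inside [0, L)
    pa = np.where(pa >= box, 0.0, pa)
    pb = np.where(pb >= box, 0.0, pb)
    tree = cKDTree(pb, boxsize=box)
    d, _ = tree.query(pa, k=1)
    return float(np.min(d))


def _min_group_distance_bruteforce(frame: Frame, group_a, group_b,
                                   box=None) -> float:
    """Quadratic all-pairs reference used as the oracle in tests."""
    if box is None:
        box = frame.box
    pa = frame.coords[np.asarray(group_a, dtype=int)]
    pb = frame.coords[np.asarray(group_b, dtype=int)]
    d = min_image_distance(pa[:, None, :], pb[None, :, :], box)
    return float(np.min(d))


def unwrap_coordinates(traj: Trajectory, particle_ids: Sequence[int]
                       ) -> tuple[np.ndarray, list[int]]:
    """Continuous in-plane (x, y) paths for the selected particles.

    Returns ``(paths, flagged_frames)`` where paths has shape
    ``(n_frames, n_particles, 2)``.  Each step is min-imaged; a step whose
    magnitude reaches half the box in either dimension is ambiguous
    (aliasing) and the destination frame index is flagged and a warning
    logged.  Re-wrapping the paths into the box recovers the input.
    """
    ids = np.asarray(particle_ids, dtype=int)
    coords = traj.coords_array()[:, ids, :2]
    boxes = np.array([fr.box[:2] for fr in traj.frames])
    paths = np.empty_like(coords)
    paths[0] = coords[0]
    flagged: list[int] = []
    for i in range(1, coords.shape[0]):
        box = boxes[i]
        d = coords[i] - coords[i - 1]
        d -= box * np.round(d / box)
        if np.any(np.abs(d) >= box / 2):
            flagged.append(i)
            logger.warning("unwrap: apparent jump >= L/2 into frame %d; flagged", i)
        paths[i] = paths[i - 1] + d
    return paths, flagged


# ---------------------------------------------------------------------------
# topology I/O
# ---------------------------------------------------------------------------

TOPOLOGY_HEADER = "particle_id,name,group,molecule_id,residue_number,leaflet"


def write_topology(top: Topology, path) -> None:
    df = pd.DataFrame({
        "particle_id": top.particle_id,
        "name": top.name,
        "group": top.group,
        "molecule_id": top.molecule_id,
        "residue_number": top.residue_number,
        "leaflet": top.leaflet,
    })
    df.to_csv(path, index=False)


def read_topology(path) -> Topology:
    df = pd.read_csv(path)
    expected = TOPOLOGY_HEADER.split(",")
    if list(df.columns) != expected:
        raise ParseError(f"topology CSV must have header {TOPOLOGY_HEADER!r}")
    return Topology(
        particle_id=df["particle_id"].to_numpy(),
        name=df["name"].astype(str).to_numpy(dtype=object),
        group=df["group"].astype(str).to_numpy(dtype=object),
        molecule_id=df["molecule_id"].to_numpy(),
        residue_number=df["residue_number"].to_numpy(),
        leaflet=df["leaflet"].astype(str).to_numpy(dtype=object),
    )


def _default_topology(n: int) -> Topology:
    return Topology(
        particle_id=np.arange(n),
        name=np.array([f"P{i}" for i in range(n)], dtype=object),
        group=np.array(["OTHER"] * n, dtype=object),
        molecule_id=np.full(n, -1),
        residue_number=np.full(n, -1),
        leaflet=np.array(["UNASSIGNED"] * n, dtype=object),
    )


# ---------------------------------------------------------------------------
# trajectory readers / writers
# ---------------------------------------------------------------------------

def read_trajectory(path, format: str, topology: Topology | None = None,
                    topology_path=None, box=None, replicate_id: int = 0) -> Trajectory:
    """Read a trajectory in one of the supported dialects.

    ``topology``/``topology_path`` attach a sidecar topology; without one, a
    minimal all-OTHER topology is built (GRO additionally recovers groups
    from its residue names).  ``box`` overrides/provides the box for the CSV
    dialect when the file carries no box comment.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if topology is None and topology_path is not None:
        topology = read_topology(topology_path)
    if format == "gro":
        traj = _read_gro(path, topology)
    elif format == "xyz":
        traj = _read_xyz(path, topology)
    elif format == "csv":
        traj = _read_csv(path, topology, box)
    else:
        raise ValueError(f"unknown trajectory format {format!r}")
    traj.replicate_id = replicate_id
    return traj


def write_trajectory(traj: Trajectory, path, format: str) -> None:
    if traj.n_frames == 0:
        raise ValueError("refusing to write a trajectory with no frames")
    if format == "gro":
        _write_gro(traj, path)
    elif format == "xyz":
        _write_xyz(traj, path)
    elif format == "csv":
        _write_csv(traj, path)
    else:
        raise ValueError(f"unknown trajectory format {format!r}")


# -- GRO --------------------------------------------------------------------

_GRO_TIME_RE = re.compile(r"t=\s*([-+0-9.eE]+)")


def _read_gro(path: Path, topology: Topology | None) -> Trajectory:
    frames: list[Frame] = []
    lines = path.read_text().splitlines()
    i = 0
    names: list[str] = []
    resids: list[int] = []
    resnames: list[str] = []
    first = True
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        title = lines[i]
        m = _GRO_TIME_RE.search(title)
        time_ns = float(m.group(1)) / 1000.0 if m else float(len(frames))
        try:
            n = int(lines[i + 1].strip())
        except (IndexError, ValueError) as exc:
            raise ParseError(f"line {i + 2}: expected particle count") from exc
        if i + 2 + n >= len(lines) + 1 and i + 2 + n > len(lines):
            raise ParseError(f"line {len(lines)}: truncated GRO frame")
        coords = np.empty((n, 3))
        for j in range(n):
            ln = lines[i + 2 + j]
            try:
                coords[j, 0] = float(ln[20:28])
                coords[j, 1] = float(ln[28:36])
                coords[j, 2] = float(ln[36:44])
            except (ValueError, IndexError) as exc:
                raise ParseError(f"line {i + 3 + j}: malformed GRO atom record") from exc
            if first:
                resids.append(int(ln[0:5]))
                resnames.append(ln[5:10].strip())
                names.append(ln[10:15].strip())
        box_fields = lines[i + 2 + n].split()
        if len(box_fields) not in (3, 9):
            raise ParseError(f"line {i + 3 + n}: malformed GRO box line")
        if len(box_fields) == 9 and any(float(v) != 0.0 for v in box_fields[3:]):
            raise StructuralError("triclinic boxes are not supported")
        box = np.array([float(v) for v in box_fields[:3]])
        frames.append(Frame(time=time_ns, box=box, coords=coords))
        if frames[0].coords.shape[0] != n:
            raise StructuralError("inconsistent particle count across GRO frames")
        first = False
        i += n + 3
    if not frames:
        raise ParseError("line 1: no frames found in GRO file")
    if topology is None:
        n = frames[0].coords.shape[0]
        top = _default_topology(n)
        top.name = np.array(names, dtype=object)
        top.group = np.array(
            [_RESNAME_TO_GROUP.get(rn, "OTHER") for rn in resnames], dtype=object)
        top.molecule_id = np.array(
            [rid - 1 if g in ("TAG", "SITE") else -1
             for rid, g in zip(resids, top.group)])
        top.residue_number = np.array(
            [rid if g == "RESIDUE" else -1 for rid, g in zip(resids, top.group)])
        top.validate()
        topology = top
    return Trajectory(topology=topology, frames=frames)


def _write_gro(traj: Trajectory, path) -> None:
    top = traj.topology
    out = []
    for fr in traj.frames:
        out.append(f"memlens trajectory, t= {fr.time * 1000.0:.5f}")
        out.append(f"{traj.n_particles:5d}")
        for pid in range(traj.n_particles):
            group = top.group[pid]
            resname = _GROUP_TO_RESNAME[group]
            if group in ("TAG", "SITE") and top.molecule_id[pid] >= 0:
                resid = int(top.molecule_id[pid]) + 1
            elif group == "RESIDUE":
                resid = int(top.residue_number[pid])
            else:
                resid = pid + 1
            resid = resid % 100000
            atomnum = (pid + 1) % 100000
            x, y, z = fr.coords[pid]
            out.append(f"{resid:5d}{resname:<5.5s}{top.name[pid]:>5.5s}"
                       f"{atomnum:5d}{x:8.3f}{y:8.3f}{z:8.3f}")
        out.append(f"{fr.box[0]:10.5f}{fr.box[1]:10.5f}{fr.box[2]:10.5f}")
    Path(path).write_text("\n".join(out) + "\n")


# -- extended XYZ -----------------------------------------------------------

def _read_xyz(path: Path, topology: Topology | None) -> Trajectory:
    frames: list[Frame] = []
    lines = path.read_text().splitlines()
    i = 0
    names: list[str] = []
    first = True
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError as exc:
            raise ParseError(f"line {i + 1}: expected particle count") from exc
        comment = lines[i + 1] if i + 1 < len(lines) else ""
        mt = re.search(r"time_ns=([-+0-9.eE]+)", comment)
        mb = re.search(r"box_nm=([-+0-9.eE]+),([-+0-9.eE]+),([-+0-9.eE]+)", comment)
        if mt is None or mb is None:
            raise ParseError(f"line {i + 2}: XYZ comment must carry time_ns= and box_nm=")
        time_ns = float(mt.group(1))
        box = np.array([float(mb.group(k)) for k in (1, 2, 3)])
        coords = np.empty((n, 3))
        for j in range(n):
            parts = lines[i + 2 + j].split()
            if len(parts) < 4:
                raise ParseError(f"line {i + 3 + j}: malformed XYZ atom record")
            coords[j] = [float(parts[1]), float(parts[2]), float(parts[3])]
            if first:
                names.append(parts[0])
        if frames and frames[0].coords.shape[0] != n:
            raise StructuralError("inconsistent particle count across XYZ frames")
        frames.append(Frame(time=time_ns, box=box, coords=coords))
        first = False
        i += n + 2
    if not frames:
        raise ParseError("line 1: no frames found in XYZ file")
    if topology is None:
        topology = _default_topology(frames[0].coords.shape[0])
        topology.name = np.array(names, dtype=object)
    return Trajectory(topology=topology, frames=frames)


def _write_xyz(traj: Trajectory, path) -> None:
    top = traj.topology
    out = []
    for fr in traj.frames:
        out.append(str(traj.n_particles))
        out.append(f"time_ns={fr.time:.6f} "
                   f"box_nm={fr.box[0]:.6f},{fr.box[1]:.6f},{fr.box[2]:.6f}")
        for pid in range(traj.n_particles):
            x, y, z = fr.coords[pid]
            out.append(f"{top.name[pid]} {x:.6f} {y:.6f} {z:.6f}")
    Path(path).write_text("\n".join(out) + "\n")


# -- CSV --------------------------------------------------------------------

CSV_HEADER = "frame,time_ns,particle_id,x,y,z"


def _read_csv(path: Path, topology: Topology | None, box) -> Trajectory:
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("# box_nm="):
        box = np.array([float(v) for v in first.strip()[len("# box_nm="):].split(",")])
    elif box is None:
        raise ParseError("line 1: CSV trajectory needs a '# box_nm=' comment "
                         "or an explicit box argument")
    box = np.asarray(box, dtype=float)
    df = pd.read_csv(path, comment="#")
    if list(df.columns) != CSV_HEADER.split(","):
        raise ParseError(f"line 1: CSV header must be {CSV_HEADER!r}")
    frames: list[Frame] = []
    n = None
    for fidx, sub in df.groupby("frame", sort=True):
        sub = sub.sort_values("particle_id")
        if n is None:
            n = len(sub)
        elif len(sub) != n:
            raise StructuralError("inconsistent particle count across CSV frames")
        coords = sub[["x", "y", "z"]].to_numpy(dtype=float)
        frames.append(Frame(time=float(sub["time_ns"].iloc[0]), box=box, coords=coords))
    if not frames:
        raise ParseError("line 2: no frames found in CSV file")
    if topology is None:
        topology = _default_topology(n)
    return Trajectory(topology=topology, frames=frames)


def _write_csv(traj: Trajectory, path) -> None:
    box = traj.frames[0].box
    rows = []
    for fidx, fr in enumerate(traj.frames):
        for pid in range(traj.n_particles):
            x, y, z = fr.coords[pid]
            rows.append(f"{fidx},{fr.time:.6f},{pid},{x:.6f},{y:.6f},{z:.6f}")
    header = f"# box_nm={box[0]:.6f},{box[1]:.6f},{box[2]:.6f}\n{CSV_HEADER}\n"
    Path(path).write_text(header + "\n".join(rows) + "\n")
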