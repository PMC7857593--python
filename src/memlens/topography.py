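"""Leaflet assignment, height fields and mean-curvature maps.

Head-group positions are binned onto a periodic (nx, ny) grid, averaged over
time and particles, Gaussian-smoothed, and referenced to the leaflet's mean
plane.  Mean curvature H is computed from the height surface h(x, y) by
periodic finite differences, either in the small-slope approximation

    H = -(1/2) (h_xx + h_yy)

or with the full divergence form  H = -div(grad h / sqrt(1 + |grad h|^2)) / 2.

Sign convention: H > 0 where the leaflet bulges toward the bilayer midplane.
Height fields store raw z relative to the leaflet mean plane; the curvature
of the UPPER leaflet is therefore sign-flipped (a dip in the upper leaflet
points toward the midplane).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .trajectory import Frame, Trajectory

SIGN_CONVENTION = "positive_toward_midplane"


class AmbiguousLeafletError(ValueError):
    """Head groups coplanar within tolerance: cannot split leaflets."""


class ResolutionError(ValueError):
    """Too many empty grid cells; a coarser grid is needed."""


@dataclass
class HeightField:
    leaflet: str
    h: np.ndarray                  # (nx, ny) nm, zero spatial mean
    spacing: tuple[float, float]   # nm per cell
    counts: np.ndarray             # head groups per cell before filling
    interpolated: np.ndarray       # bool mask of filled cells
    window: tuple[float, float]

    def __post_init__(self) -> None:
        if self.h.shape[0] < 4 or self.h.shape[1] < 4:
            raise ValueError("grid must be at least 4x4")


@dataclass
class CurvatureMap:
    H: np.ndarray                  # (nx, ny) nm^-1
    leaflet: str
    mode: str
    sign_convention: str = SIGN_CONVENTION


def assign_leaflets(frame: Frame, headgroup_ids, tolerance: float = 0.1
                    ) -> np.ndarray:
    """Label head groups UPPER/LOWER by z relative to their median plane."""
    ids = np.asarray(headgroup_ids, dtype=int)
    if ids.size < 2:
        raise ValueError("need at least two head-group particles")
    z = frame.coords[ids, 2]
    zmed = np.median(z)
    upper = z > zmed
    lower = ~upper
    if not upper.any() or not lower.any() or \
            (z.max() - z.min()) < tolerance:
        raise AmbiguousLeafletError(
            "head groups coplanar within tolerance; cannot assign leaflets")
    return np.where(upper, "UPPER", "LOWER").astype(object)


def _leaflet_headgroups(traj: Trajectory, leaflet: str) -> np.ndarray:
    top = traj.topology
    hg = top.group == "HEADGROUP"
    ids = top.particle_id[hg & (top.leaflet == leaflet)]
    if ids.size == 0:
        # fall back to geometric assignment on the first frame
        all_hg = top.particle_id[hg]
        if all_hg.size == 0:
            raise ValueError("topology has no HEADGROUP particles")
        labels = assign_leaflets(traj.frames[0], all_hg)
        ids = all_hg[labels == leaflet]
    if ids.size == 0:
        raise ValueError(f"no head groups in leaflet {leaflet}")
    return ids


def height_field(traj: Trajectory, leaflet: str, grid: tuple[int, int] = (64, 64),
                 smoothing_sigma: float = 1.0,
                 window: tuple[float, float] | None = None) -> HeightField:
    """Time-averaged leaflet height surface from head-group positions.

    Smoothing and empty-cell filling use a single periodic normalized
    convolution (Gaussian of the z-sums divided by Gaussian of the counts),
    so sparse sampling interpolates smoothly.  With ``smoothing_sigma=0``
    the raw per-cell averages are returned (all cells must then be hit).
    """
    nx, ny = grid
    ids = _leaflet_headgroups(traj, leaflet)
    times = traj.times
    if window is None:
        window = (float(times[0]), float(times[-1]) + 1e-9)
    in_win = (times >= window[0]) & (times < window[1])
    if not in_win.any():
        raise ValueError("window contains no frames")
    box = traj.frames[0].box
    dx, dy = box[0] / nx, box[1] / ny
    zsum = np.zeros((nx, ny))
    counts = np.zeros((nx, ny))
    for i in np.flatnonzero(in_win):
        fr = traj.frames[i]
        pts = fr.coords[ids]
        ix = np.mod(np.floor(pts[:, 0] / dx).astype(int), nx)
        iy = np.mod(np.floor(pts[:, 1] / dy).astype(int), ny)
        np.add.at(zsum, (ix, iy), pts[:, 2])
        np.add.at(counts, (ix, iy), 1.0)
    empty = counts == 0
    if np.mean(empty) > 0.5:
        raise ResolutionError(
            f"{np.mean(empty):.0%} of grid cells empty; use a coarser grid")
    if smoothing_sigma > 0:
        sig = (smoothing_sigma / dx, smoothing_sigma / dy)
        num = gaussian_filter(zsum, sig, mode="wrap")
        den = gaussian_filter(counts, sig, mode="wrap")
        h = num / np.where(den == 0, np.nan, den)
    else:
        with np.errstate(invalid="ignore"):
            h = zsum / np.where(empty, np.nan, counts)
        if empty.any():
            # minimal fill so downstream stencils stay finite
            num = gaussian_filter(np.where(empty, 0.0, zsum), 1.0, mode="wrap")
            den = gaussian_filter(np.where(empty, 0.0, counts), 1.0, mode="wrap")
            h = np.where(empty, num / den, h)
    h = h - np.nanmean(h)
    return HeightField(leaflet=leaflet, h=h, spacing=(dx, dy), counts=counts,
                       interpolated=empty, window=window)


def _is_planar(h: np.ndarray, dx: float, dy: float) -> bool:
    """True when h is exactly a plane a*x + b*y + c (within float tolerance).

    A uniform tilt carries no curvature, but it is also not representable on
    a periodic patch, so it is detected and short-circuited rather than
    pushed through the periodic stencils (which would see a seam jump).
    """
    nx, ny = h.shape
    x = (np.arange(nx) * dx)[:, None] * np.ones((1, ny))
    y = (np.arange(ny) * dy)[None, :] * np.ones((nx, 1))
    A = np.column_stack([x.ravel(), y.ravel(), np.ones(h.size)])
    coef, *_ = np.linalg.lstsq(A, h.ravel(), rcond=None)
    resid = h.ravel() - A @ coef
    scale = max(np.abs(h).max(), 1.0)
    return bool(np.abs(resid).max() < 1e-10 * scale)


def _ddx(f: np.ndarray, d: float, axis: int) -> np.ndarray:
    return (np.roll(f, -1, axis=axis) - np.roll(f, 1, axis=axis)) / (2 * d)


def _d2(f: np.ndarray, d: float, axis: int) -> np.ndarray:
    return (np.roll(f, -1, axis=axis) - 2 * f + np.roll(f, 1, axis=axis)) / d ** 2


def mean_curvature(field: HeightField, mode: str = "small_slope") -> CurvatureMap:
    """Mean curvature of the leaflet height surface.

    ``small_slope`` uses the negative half-Laplacian; ``full`` the exact
    divergence form.  Periodic central differences; an exactly planar field
    (uniform tilt, which carries no curvature but is incompatible with the
    periodic stencils) yields identically zero.
    """
    dx, dy = field.spacing
    h = field.h
    if mode not in ("small_slope", "full"):
        raise ValueError(f"unknown curvature mode {mode!r}")
    if _is_planar(h, dx, dy):
        return CurvatureMap(H=np.zeros_like(h), leaflet=field.leaflet, mode=mode)
    if mode == "small_slope":
        H = -0.5 * (_d2(h, dx, 0) + _d2(h, dy, 1))
    else:
        hx = _ddx(h, dx, 0)
        hy = _ddx(h, dy, 1)
        g = np.sqrt(1.0 + hx ** 2 + hy ** 2)
        H = -0.5 * (_ddx(hx / g, dx, 0) + _ddx(hy / g, dy, 1))
    if field.leaflet == "UPPER":
        H = -H  # bulge toward the midplane is a dip in raw z for the upper leaflet
    if not np.all(np.isfinite(H)):
        raise ValueError("curvature map contains non-finite values")
    return CurvatureMap(H=H, leaflet=field.leaflet, mode=mode)
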