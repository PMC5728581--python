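"""Trajectory-analysis coordinates for nucleosome sliding.

The repositioning of nucleosomal DNA is tracked with two angular
coordinates measured on each frame:

* the sliding coordinate ``zeta``: the angle, about the histone core,
  between the nucleosome symmetry axis and the vector from the core
  centroid to a tracked base pair (the one initially at the dyad).  A
  reference table built from the first frame converts ``zeta`` to a
  slid-base-pair count by linear interpolation.
* the rotation coordinate ``eta``: the rotational phase of the tracked
  base pair's strand-1 phosphate about the local DNA helical axis,
  measured from the direction pointing toward the histone core centroid
  and unwrapped over the trajectory.

The local DNA axis is extracted per base pair by following ten contour
splines along the strand-1 phosphates (index classes mod 10), finding
the nearest subdivision point of each contour and fitting a circle to
the resulting ten-point ring.

Signs: a principal normal of the wrapped DNA path is oriented so that
the base-pair index increases counter-clockwise; ``zeta`` is positive
for displacements in the direction of increasing base-pair index, and
``eta`` is a right-handed angle about the local DNA tangent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .errors import GeometryError, WindowError

#: Average base pairs per helical turn of nucleosomal DNA, used only to
#: label superhelical locations with base-pair offsets.
BP_PER_TWIST_TURN = 10.17


# ---------------------------------------------------------------------
# Primitive fits
# ---------------------------------------------------------------------

def fit_plane(points):
    """Least-squares plane: returns (centroid, unit normal)."""
    pts = np.asarray(points, dtype=float)
    c = pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts - c, full_matrices=False)
    return c, vt[-1]


def fit_circle_3d(points):
    """Fit a circle to >=3 roughly coplanar 3D points.

    Plane-fit, project, then algebraic (Kasa) circle fit; exact on
    noiseless circles.  Returns (center, radius, plane normal).
    """
    pts = np.asarray(points, dtype=float)
    if len(pts) < 3:
        raise GeometryError("need at least 3 points for a circle fit")
    c0, normal = fit_plane(pts)
    # in-plane basis
    seed = np.array([1.0, 0.0, 0.0])
    if abs(normal @ seed) > 0.9:
        seed = np.array([0.0, 1.0, 0.0])
    u = np.cross(normal, seed)
    u /= np.linalg.norm(u)
    v = np.cross(normal, u)
    rel = pts - c0
    x, y = rel @ u, rel @ v
    a = np.column_stack([2 * x, 2 * y, np.ones_like(x)])
    b = x**2 + y**2
    sol, *_ = np.linalg.lstsq(a, b, rcond=None)
    cx, cy, cc = sol
    radius = float(np.sqrt(cc + cx**2 + cy**2))
    center = c0 + cx * u + cy * v
    return center, radius, normal


def kabsch_rotation(mobile, reference):
    """Optimal least-squares rotation matrix aligning centered clouds."""
    h = mobile.T @ reference
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    return vt.T @ corr @ u.T


def signed_angle(a, b, axis):
    """Signed angle (deg) from ``a`` to ``b`` about unit vector ``axis``."""
    return float(np.degrees(np.arctan2(axis @ np.cross(a, b), a @ b)))


# ---------------------------------------------------------------------
# DNA axis
# ---------------------------------------------------------------------

@dataclass
class DnaAxis:
    """Per-base-pair DNA axis points and tangents.

    ``points``/``tangents`` are indexed by base-pair index; entries
    outside ``window = (lo, hi)`` (inclusive) are NaN.
    """

    points: np.ndarray
    tangents: np.ndarray
    window: tuple

    def point(self, bp):
        self._check(bp)
        return self.points[bp]

    def tangent(self, bp):
        self._check(bp)
        return self.tangents[bp]

    def _check(self, bp):
        lo, hi = self.window
        if not lo <= bp <= hi:
            raise WindowError(f"base pair {bp} outside axis window [{lo}, {hi}]")


def dna_axis(structure, positions=None, subdivisions: int = 10,
             edge_trim: int = 10, local_window_bp: float = 7.0) -> DnaAxis:
    """Extract the DNA helical axis from strand-1 phosphates.

    Ten contour splines connect phosphates whose index is congruent
    mod 10; each spline segment is subdivided into ``subdivisions``
    equal parameter steps, and for every phosphate the nearest
    subdivision point on each contour is collected.  The ten points are
    circle-fitted; the center is the axis point at that base pair.
    Tangents are normalized central differences of the axis points.

    The nearest-point search on each contour is restricted to
    candidates within ``local_window_bp`` base pairs of the phosphate's
    own position along the DNA: on a strongly bent wrap the globally
    closest point of an opposite-side contour can lie a turn away
    across the tube, which would corrupt the ring.  ``edge_trim`` base
    pairs at each end are excluded from the valid window (shortened end
    contours are unreliable there).
    """
    pos = structure.positions if positions is None else positions
    m1 = structure.strand1
    bps = sorted(b for b in m1 if "P" in m1[b])
    n = len(bps)
    if n < 31:
        raise WindowError("need at least 31 strand-1 phosphates for the axis")
    p = pos[[m1[b]["P"] for b in bps]]
    bp_arr = np.asarray(bps, dtype=float)

    cand_pts, cand_bps = [], []
    for j in range(10):
        pts = p[j::10]
        node_bp = bp_arr[j::10]
        if len(pts) < 3:
            raise WindowError("contour classes too short for spline fit")
        t = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(pts, axis=0),
                                                            axis=1))])
        spline = CubicSpline(t, pts, bc_type="natural", axis=0)
        frac = np.arange(subdivisions) / subdivisions
        ts, cb = [], []
        for k in range(len(t) - 1):
            ts.append(t[k] + (t[k + 1] - t[k]) * frac)
            cb.append(node_bp[k] + (node_bp[k + 1] - node_bp[k]) * frac)
        ts.append(t[-1:])
        cb.append(node_bp[-1:])
        cand_pts.append(spline(np.concatenate(ts)))
        cand_bps.append(np.concatenate(cb))

    n_bp = structure.n_bp
    points = np.full((n_bp, 3), np.nan)
    for k, b in enumerate(bps):
        ring = np.empty((10, 3))
        for j in range(10):
            sel = np.abs(cand_bps[j] - b) <= local_window_bp
            if not np.any(sel):
                sel = slice(None)
            pts = cand_pts[j][sel]
            d = np.linalg.norm(pts - p[k], axis=1)
            ring[j] = pts[np.argmin(d)]
        center, _, _ = fit_circle_3d(ring)
        points[b] = center

    tangents = np.full((n_bp, 3), np.nan)
    valid = [b for b in bps if np.isfinite(points[b]).all()]
    for i, b in enumerate(valid):
        lo = valid[max(i - 1, 0)]
        hi = valid[min(i + 1, len(valid) - 1)]
        d = points[hi] - points[lo]
        nrm = np.linalg.norm(d)
        if nrm > 0:
            tangents[b] = d / nrm
    window = (bps[edge_trim], bps[-(edge_trim + 1)])
    return DnaAxis(points=points, tangents=tangents, window=window)


# ---------------------------------------------------------------------
# Symmetry axis and per-frame reference geometry
# ---------------------------------------------------------------------

@dataclass
class SymmetryAxis:
    point: np.ndarray
    direction: np.ndarray


def symmetry_axis(structure, positions=None) -> SymmetryAxis:
    """Total-least-squares line through the symmetric-pair midpoints.

    The direction sign is fixed toward the dyad side: positive along
    the vector from the midpoint centroid to the central base pair.
    """
    pos = structure.positions if positions is None else positions
    pairs = structure.symmetric_pairs
    if len(pairs) < 2:
        raise GeometryError("need at least two symmetric pairs")
    mids = np.array([(pos[i] + pos[j]) / 2.0 for i, j in pairs])
    center = mids.mean(axis=0)
    rel = mids - center
    if np.linalg.norm(rel, axis=1).max() < 1e-9:
        raise GeometryError("symmetric-pair midpoints are coincident")
    _, _, vt = np.linalg.svd(rel, full_matrices=False)
    direction = vt[0] / np.linalg.norm(vt[0])
    if structure.n_bp:
        toward = structure.bp_center(structure.n_bp // 2, pos) - center
        if direction @ toward < 0:
            direction = -direction
    return SymmetryAxis(point=center, direction=direction)


def superhelix_normal(structure, positions=None,
                      window_bp: int = 147) -> np.ndarray:
    """Unit normal of the wrapped DNA path, oriented so the base-pair
    index increases counter-clockwise about it.

    Computed as the areal vector of the wrapped path (the sum of cross
    products of consecutive radius vectors, i.e. twice the enclosed
    area vector).  Unlike a least-squares plane fit, this is barely
    tilted by the superhelical pitch: the horizontal contributions of a
    near-closed wrap cancel turn by turn.  Only the central
    ``window_bp`` base pairs enter (straight linker arms would
    otherwise bias the estimate).
    """
    pos = structure.positions if positions is None else positions
    m1 = structure.strand1
    center = structure.n_bp // 2
    bps = sorted(b for b in m1
                 if "P" in m1[b] and abs(b - center) <= window_bp // 2)
    pts = pos[[m1[b]["P"] for b in bps]]
    v = pts - pts.mean(axis=0)
    areal = np.cross(v[:-1], v[1:]).sum(axis=0)
    nrm = np.linalg.norm(areal)
    if nrm < 1e-9:
        raise GeometryError("degenerate wrap geometry: no enclosed area")
    return areal / nrm


@dataclass
class FrameAxes:
    """Per-frame reference geometry for the sliding coordinates."""

    centroid: np.ndarray
    symmetry: SymmetryAxis
    normal: np.ndarray


def compute_frame_axes(structure, positions=None) -> FrameAxes:
    pos = structure.positions if positions is None else positions
    return FrameAxes(
        centroid=structure.core_centroid(pos),
        symmetry=symmetry_axis(structure, pos),
        normal=superhelix_normal(structure, pos),
    )


# ---------------------------------------------------------------------
# Sliding coordinate zeta and the zeta -> bp table
# ---------------------------------------------------------------------

def sliding_zeta(structure, tracked_bp, positions=None, axes: FrameAxes = None,
                 reference_direction=None) -> float:
    """Signed sliding angle (deg) of a tracked base pair.

    The magnitude is the angle between the reference direction (the
    symmetry axis by default) and the vector from the core centroid to
    the base-pair center; the sign follows the sense of rotation about
    the oriented superhelix normal.
    """
    pos = structure.positions if positions is None else positions
    if tracked_bp not in structure.strand1:
        raise KeyError(f"base pair {tracked_bp} not in structure")
    axes = axes or compute_frame_axes(structure, pos)
    a = axes.symmetry.direction if reference_direction is None \
        else np.asarray(reference_direction, dtype=float)
    b = structure.bp_center(tracked_bp, pos) - axes.centroid
    cosang = np.clip(a @ b / (np.linalg.norm(a) * np.linalg.norm(b)), -1.0, 1.0)
    ang = np.degrees(np.arccos(cosang))
    sign = np.sign(axes.normal @ np.cross(a, b))
    return float(ang if sign >= 0 else -ang)


@dataclass
class ZetaTable:
    """Monotone map between base-pair index and zeta (deg), built from
    the initial frame."""

    bps: np.ndarray    # integer bp indices, ascending
    zetas: np.ndarray  # strictly increasing zeta values

    def __post_init__(self):
        if len(self.bps) < 2:
            raise ValueError("zeta table needs at least two entries")
        if not np.all(np.diff(self.zetas) > 0):
            raise ValueError("zeta table must be strictly increasing")


def build_zeta_table(structure, positions=None, center_bp=None,
                     axes: FrameAxes = None, reference_direction=None,
                     half_width: int | None = None) -> ZetaTable:
    """Tabulate zeta for base pairs around ``center_bp`` (default: the
    central base pair), restricted to the maximal strictly monotone run
    containing the center."""
    pos = structure.positions if positions is None else positions
    axes = axes or compute_frame_axes(structure, pos)
    if center_bp is None:
        center_bp = structure.n_bp // 2
    bps = sorted(structure.strand1)
    if half_width is not None:
        bps = [b for b in bps if abs(b - center_bp) <= half_width]
    z = np.array([
        sliding_zeta(structure, b, pos, axes, reference_direction) for b in bps
    ])
    bps = np.asarray(bps)
    k = int(np.where(bps == center_bp)[0][0])
    lo = k
    while lo > 0 and z[lo - 1] < z[lo]:
        lo -= 1
    hi = k
    while hi < len(bps) - 1 and z[hi + 1] > z[hi]:
        hi += 1
    return ZetaTable(bps=bps[lo:hi + 1].astype(float), zetas=z[lo:hi + 1])


def zeta_to_bp(zeta, table: ZetaTable):
    """Convert zeta (deg) to a fractional base-pair index by linear
    interpolation in the reference table; values outside the table are
    linearly extrapolated from the terminal segment with a warning."""
    zeta = np.asarray(zeta, dtype=float)
    z, b = table.zetas, table.bps
    out = np.interp(zeta, z, b)
    below, above = zeta < z[0], zeta > z[-1]
    if np.any(below) or np.any(above):
        warnings.warn("zeta outside the reference table window; extrapolating",
                      stacklevel=2)
        s_lo = (b[1] - b[0]) / (z[1] - z[0])
        s_hi = (b[-1] - b[-2]) / (z[-1] - z[-2])
        out = np.where(below, b[0] + (zeta - z[0]) * s_lo, out)
        out = np.where(above, b[-1] + (zeta - z[-1]) * s_hi, out)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------
# Rotation coordinate eta
# ---------------------------------------------------------------------

def rotation_eta(structure, tracked_bp, positions=None, axis: DnaAxis = None,
                 centroid=None, wrap_normal=None) -> float:
    """Rotation angle (deg) of the tracked strand-1 phosphate about the
    local DNA axis, measured from the direction toward the histone core
    centroid; right-handed about the local tangent; not unwrapped.

    Both vectors are projected onto the plane normal to the local DNA
    tangent.  When ``wrap_normal`` (the oriented superhelix normal) is
    given, the centroid vector is additionally measured in the plane of
    the wrap — its component along the superhelix normal is discarded.
    Without this, the superhelical pitch makes the reference direction
    rotate slowly (~0.5 deg/bp) as the tracked base pair advances along
    the wrap, biasing the rotation-per-bp coupling.
    """
    pos = structure.positions if positions is None else positions
    axis = axis if axis is not None else dna_axis(structure, pos)
    centroid = structure.core_centroid(pos) if centroid is None else centroid
    bp_map = structure.strand1.get(tracked_bp, {})
    if "P" not in bp_map:
        raise WindowError(f"base pair {tracked_bp} has no strand-1 phosphate")
    o = axis.point(tracked_bp)
    t = axis.tangent(tracked_bp)
    a = pos[bp_map["P"]] - o
    b = centroid - o
    if wrap_normal is not None:
        n = np.asarray(wrap_normal, dtype=float)
        b = b - (b @ n) * n
    a = a - (a @ t) * t
    b = b - (b @ t) * t
    if np.linalg.norm(a) == 0 or np.linalg.norm(b) == 0:
        raise GeometryError("degenerate eta geometry (vector along the tangent)")
    return signed_angle(b, a, t)


def unwrap_degrees(series):
    """Remove ±360 deg jumps from an angle time series."""
    return np.degrees(np.unwrap(np.radians(np.asarray(series, dtype=float))))


# ---------------------------------------------------------------------
# RMSD
# ---------------------------------------------------------------------

def central_bp_dna_indices(structure, n_bp: int = 20, center_bp=None):
    """Bead indices of the DNA beads of the central ``n_bp`` base pairs."""
    center = structure.n_bp // 2 if center_bp is None else center_bp
    lo = center - n_bp // 2
    idx = []
    for b in range(lo, lo + n_bp):
        idx.extend(structure.strand1.get(b, {}).values())
        idx.extend(structure.strand2.get(b, {}).values())
    return sorted(idx)


def rmsd_central(structure, reference_positions, positions=None,
                 fit_indices=None, measure_indices=None) -> float:
    """RMSD (Angstrom) of the central DNA after superposing the histone core.

    The frame is optimally superposed onto the reference using the fit
    set (default: non-tail histone core beads); RMSD is then measured
    over the measure set (default: DNA beads of the central 20 base
    pairs around the dyad).
    """
    pos = structure.positions if positions is None else positions
    ref = np.asarray(reference_positions, dtype=float)
    fit = sorted(structure.histone_core) if fit_indices is None else list(fit_indices)
    if len(fit) < 3:
        raise GeometryError("need at least three beads to superpose")
    meas = central_bp_dna_indices(structure) if measure_indices is None \
        else list(measure_indices)
    if not meas:
        raise GeometryError("empty measure set")
    mob_c = pos[fit].mean(axis=0)
    ref_c = ref[fit].mean(axis=0)
    rot = kabsch_rotation(pos[fit] - mob_c, ref[fit] - ref_c)
    moved = (pos[meas] - mob_c) @ rot.T + ref_c
    diff = moved - ref[meas]
    return float(np.sqrt((diff**2).sum(axis=1).mean()))


# ---------------------------------------------------------------------
# Whole-trajectory analyses
# ---------------------------------------------------------------------

def moving_average(series, window: int = 10):
    """Trailing moving average over ``window`` time points."""
    return pd.Series(series).rolling(window, min_periods=1).mean().to_numpy()


def analyze_sliding(traj, dyad_bp=None, smooth: int | None = None) -> pd.DataFrame:
    """Track the base pair initially at the dyad across a trajectory.

    Returns a frame-indexed table of zeta (deg), unwrapped eta (deg)
    and the slid base pairs ``bp_shift`` obtained through the
    initial-frame zeta table.  ``smooth`` applies a trailing moving
    average over that many time points (off by default).
    """
    top = traj.topology
    dyad = top.n_bp // 2 if dyad_bp is None else int(dyad_bp)
    axes0 = compute_frame_axes(top, traj.coords[0])
    table = build_zeta_table(top, traj.coords[0], center_bp=dyad, axes=axes0)
    zetas, etas = [], []
    for xyz in traj.coords:
        axes = compute_frame_axes(top, xyz)
        zetas.append(sliding_zeta(top, dyad, xyz, axes))
        ax = dna_axis(top, xyz)
        etas.append(rotation_eta(top, dyad, xyz, ax, axes.centroid,
                                 wrap_normal=axes.normal))
    zetas = np.asarray(zetas)
    etas = unwrap_degrees(etas)
    bp = zeta_to_bp(zetas, table) - dyad
    if smooth:
        zetas = moving_average(zetas, smooth)
        etas = moving_average(etas, smooth)
        bp = moving_average(bp, smooth)
    return pd.DataFrame({
        "frame": np.arange(len(traj.coords)),
        "zeta_deg": zetas, "eta_deg": etas, "bp_shift": bp,
    })


def shl_bp_index(dyad_bp: int, shl: float, bp_per_turn: float = BP_PER_TWIST_TURN):
    """Base-pair index initially at a given superhelical location."""
    return int(dyad_bp + round(bp_per_turn * shl))


def shl_sliding(traj, shl_list, dyad_bp=None,
                bp_per_turn: float = BP_PER_TWIST_TURN) -> pd.DataFrame:
    """Per-SHL sliding series (bp shift of the bp initially at each SHL).

    The global signed zeta wraps within a ~1.7-turn wrap, so each SHL
    uses a local zeta zero: the initial direction of its own tracked
    base pair.  The shift of the dyad itself (SHL 0) is identical to the
    main sliding coordinate.
    """
    top = traj.topology
    dyad = top.n_bp // 2 if dyad_bp is None else int(dyad_bp)
    axes0 = compute_frame_axes(top, traj.coords[0])
    refs, tables, tracked = {}, {}, {}
    for shl in shl_list:
        b = shl_bp_index(dyad, shl, bp_per_turn)
        if b not in top.strand1:
            raise WindowError(f"SHL {shl} maps to bp {b}, outside the DNA")
        ref = top.bp_center(b, traj.coords[0]) - axes0.centroid
        refs[shl] = ref / np.linalg.norm(ref)
        tables[shl] = build_zeta_table(top, traj.coords[0], center_bp=b,
                                       axes=axes0, reference_direction=refs[shl],
                                       half_width=20)
        tracked[shl] = b
    out = {"frame": np.arange(len(traj.coords))}
    for shl in shl_list:
        series = []
        for xyz in traj.coords:
            axes = compute_frame_axes(top, xyz)
            z = sliding_zeta(top, tracked[shl], xyz, axes,
                             reference_direction=refs[shl])
            series.append(zeta_to_bp(z, tables[shl]) - tracked[shl])
        out[f"shl_{shl}"] = np.asarray(series)
    return pd.DataFrame(out)


def loop_delta_r(structure, reference_positions, positions=None, bp=None) -> float:
    """Loop-size coordinate: increase of the base-pair-to-core distance
    relative to the reference structure (Angstrom)."""
    pos = structure.positions if positions is None else positions
    ref = np.asarray(reference_positions, dtype=float)
    if bp is None:
        bp = structure.n_bp // 2
    if bp not in structure.strand1:
        raise KeyError(f"base pair {bp} not in structure")
    d_now = np.linalg.norm(structure.bp_center(bp, pos)
                           - structure.core_centroid(pos))
    d_ref = np.linalg.norm(structure.bp_center(bp, ref)
                           - structure.core_centroid(ref))
    return float(d_now - d_ref)
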