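"""Outer-wall contour tracing and basal-turn morphometry.

All measurements are made on the curve delineating the cochlear outer
(lateral) wall.  The contour runs from the round window (index 0) to the apex
and is resampled to 101 points at equal arc-length intervals.  Angular position
along the contour is the *turning angle*: the cumulative angle through which
the 3-D tangent has turned since the round window (summed over consecutive
tangent segments).  This deliberately avoids the modiolar polar-angle
convention, which would require locating the modiolus.

The three scalar measurements:

* ``reach`` — max distance from the round window to any point within the first
  270 degrees of turning (comparable with the clinical "A-value");
* ``duct_length`` — total arc length of the contour, round window to apex;
* ``non_planarity`` — mean absolute distance between the 270-degree window and
  the *basal plane*, the total-least-squares plane fitted to that window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError, TracingError

WINDOW_DEG_DEFAULT = 270.0


# ---------------------------------------------------------------------------
# polyline primitives
# ---------------------------------------------------------------------------

def polyline_arc_length(points: np.ndarray) -> np.ndarray:
    """Cumulative Euclidean arc length per point (mm), starting at 0."""
    pts = np.asarray(points, float)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def resample_polyline(points: np.ndarray, n: int = 101) -> np.ndarray:
    """Resample a polyline to ``n`` points at equal arc-length intervals."""
    pts = np.asarray(points, float)
    if pts.shape[0] < 2:
        raise ParameterError("need at least two points to resample")
    s = polyline_arc_length(pts)
    total = s[-1]
    if total <= 0:
        raise ParameterError("degenerate (zero-length) polyline")
    target = np.linspace(0.0, total, n)
    out = np.empty((n, 3))
    for dim in range(3):
        out[:, dim] = np.interp(target, s, pts[:, dim])
    return out


def cumulative_turning(points: np.ndarray) -> np.ndarray:
    """Cumulative turning angle (degrees) per point.

    The turn at interior vertex ``i`` is the angle between the incoming and
    outgoing tangent segments; point 0 carries zero turning and the final
    point inherits the last interior sum.
    """
    pts = np.asarray(points, float)
    seg = np.diff(pts, axis=0)
    norms = np.linalg.norm(seg, axis=1)
    if np.any(norms == 0):
        # merge duplicate samples rather than fail on zero-length tangents
        keep = np.concatenate([[True], norms > 0])
        return cumulative_turning(pts[keep]) if keep.sum() < len(pts) else _raise_dup()
    t = seg / norms[:, None]
    cosang = np.clip(np.einsum("ij,ij->i", t[:-1], t[1:]), -1.0, 1.0)
    turns = np.degrees(np.arccos(cosang))
    cum = np.concatenate([[0.0], np.cumsum(turns), [np.sum(turns)]])
    cum[-1] = cum[-2]
    return cum


def _raise_dup():
    raise ParameterError("polyline contains coincident consecutive points")


def window_indices(points: np.ndarray, window_deg: float = WINDOW_DEG_DEFAULT) -> range:
    """Contiguous index range whose cumulative turning is <= ``window_deg``."""
    cum = cumulative_turning(points)
    if window_deg <= 0:
        raise ParameterError("window must be positive")
    if cum[-1] < window_deg:
        raise TracingError(
            f"contour turns only {cum[-1]:.1f} deg, less than the "
            f"{window_deg:.0f} deg window")
    last = int(np.searchsorted(cum, window_deg, side="right")) - 1
    return range(0, last + 1)


# ---------------------------------------------------------------------------
# basal plane
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BasalPlane:
    normal: np.ndarray  # unit 3-vector
    offset: float       # plane is {x : normal . x = offset}
    rms_residual: float

    def signed_height(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, float) @ self.normal - self.offset


def fit_basal_plane(points: np.ndarray, toward: np.ndarray | None = None) -> BasalPlane:
    """Total-least-squares plane through ``points``.

    The normal is the smallest principal direction of the centered points.
    If ``toward`` is given (typically the apex), the normal is oriented so that
    point has non-negative height; otherwise the orientation tie-breaks toward
    the axis with the largest normal component.
    """
    pts = np.asarray(points, float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 3:
        raise ParameterError("plane fit needs at least three 3-D points")
    centroid = pts.mean(axis=0)
    c = pts - centroid
    sv = np.linalg.svd(c, compute_uv=False)
    if sv[1] <= 1e-12 * max(sv[0], 1.0):
        raise ParameterError("collinear points: plane is degenerate")
    _, _, Vt = np.linalg.svd(c, full_matrices=False)
    normal = Vt[-1]
    if toward is not None:
        h = float(np.dot(np.asarray(toward, float) - centroid, normal))
        if h < 0:
            normal = -normal
    else:
        k = int(np.argmax(np.abs(normal)))
        if normal[k] < 0:
            normal = -normal
    offset = float(normal @ centroid)
    rms = float(np.sqrt(np.mean((c @ normal) ** 2)))
    return BasalPlane(normal=normal, offset=offset, rms_residual=rms)


# ---------------------------------------------------------------------------
# contour container and measurements
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OuterWallContour:
    """101 ordered points along the lateral wall, round window -> apex."""

    points: np.ndarray
    cum_arc_length: np.ndarray
    cum_turning_angle: np.ndarray

    @staticmethod
    def from_polyline(points: np.ndarray, n: int = 101) -> "OuterWallContour":
        res = resample_polyline(points, n)
        # the points divide the traced contour into equal arc-length
        # intervals; cum_arc_length records that (exactly uniform) division
        total = polyline_arc_length(points)[-1]
        return OuterWallContour(
            points=res,
            cum_arc_length=np.linspace(0.0, total, n),
            cum_turning_angle=cumulative_turning(res),
        )

    @property
    def round_window(self) -> np.ndarray:
        return self.points[0]

    @property
    def apex(self) -> np.ndarray:
        return self.points[-1]


def turning_angle_window(contour: OuterWallContour,
                         window_deg: float = WINDOW_DEG_DEFAULT) -> range:
    return window_indices(contour.points, window_deg)


def basal_plane(contour_points: np.ndarray,
                window_deg: float = WINDOW_DEG_DEFAULT) -> BasalPlane:
    idx = window_indices(contour_points, window_deg)
    return fit_basal_plane(contour_points[list(idx)], toward=contour_points[-1])


def non_planarity(contour, window_deg: float = WINDOW_DEG_DEFAULT) -> float:
    """Mean absolute distance of the turning-angle window from the basal plane."""
    pts = _points_of(contour)
    idx = window_indices(pts, window_deg)
    plane = fit_basal_plane(pts[list(idx)], toward=pts[-1])
    return float(np.mean(np.abs(plane.signed_height(pts[list(idx)]))))


def reach(contour, window_deg: float = WINDOW_DEG_DEFAULT) -> float:
    """Max distance from the round window to any point within the window."""
    pts = _points_of(contour)
    idx = window_indices(pts, window_deg)
    return float(np.max(np.linalg.norm(pts[list(idx)] - pts[0], axis=1)))


def duct_length(contour) -> float:
    """Total outer-wall arc length, round window to apex."""
    pts = _points_of(contour)
    return float(polyline_arc_length(pts)[-1])


def vertical_trajectory(contour, plane: BasalPlane | None = None,
                        window_deg: float = WINDOW_DEG_DEFAULT) -> np.ndarray:
    """(N, 2) array of (cumulative turning angle deg, signed height mm)."""
    pts = _points_of(contour)
    if plane is None:
        plane = basal_plane(pts, window_deg)
    return np.column_stack([cumulative_turning(pts), plane.signed_height(pts)])


def _points_of(contour) -> np.ndarray:
    if isinstance(contour, OuterWallContour):
        return contour.points
    return np.asarray(contour, float)


@dataclass(frozen=True)
class MeasurementReport:
    non_planarity: float
    reach: float
    duct_length: float
    trajectory: np.ndarray  # (N, 2): turning angle deg, signed height mm

    def to_dict(self) -> dict:
        return {
            "non_planarity_mm": self.non_planarity,
            "reach_mm": self.reach,
            "duct_length_mm": self.duct_length,
            "trajectory": self.trajectory.tolist(),
        }

    @property
    def values(self) -> dict:
        return {"non_planarity": self.non_planarity, "reach": self.reach,
                "duct_length": self.duct_length}


def measure_polyline(points: np.ndarray,
                     window_deg: float = WINDOW_DEG_DEFAULT) -> MeasurementReport:
    """Apply all three measurements to an ordered outer-wall polyline.

    The polyline may be a 101-point contour or a dense analytic sampling; the
    definitions are identical either way.
    """
    pts = np.asarray(points, float)
    plane = basal_plane(pts, window_deg)
    return MeasurementReport(
        non_planarity=non_planarity(pts, window_deg),
        reach=reach(pts, window_deg),
        duct_length=duct_length(pts),
        trajectory=vertical_trajectory(pts, plane, window_deg),
    )


def measure_contour(contour: OuterWallContour,
                    window_deg: float = WINDOW_DEG_DEFAULT) -> MeasurementReport:
    return measure_polyline(contour.points, window_deg)


# ---------------------------------------------------------------------------
# outer-wall tracing on a fitted surface
# ---------------------------------------------------------------------------

def trace_outer_wall(mesh, apex: np.ndarray, round_window: np.ndarray,
                     coiling_axis: np.ndarray, *, rings: np.ndarray | None = None,
                     axis_point: np.ndarray | None = None,
                     n_points: int = 101) -> OuterWallContour:
    """Trace the lateral-wall contour on a (possibly deformed) capsule mesh.

    The contour passes through the laterally extremal points of the duct —
    where the surface normal is perpendicular to the coiling axis, on the
    outward side — then is resampled to ``n_points`` equal-arc-length samples
    indexed round window (0) to apex (last).

    When ``rings`` (an (n_rings, n_phi) array of vertex indices, one ring per
    duct cross-section, carried through any vertex-preserving deformation) is
    supplied, the extremum is located per ring with sub-vertex quadratic
    interpolation.  Otherwise a slower generic sweep intersects the mesh with
    half-planes through the coiling axis.
    """
    apex = np.asarray(apex, float)
    round_window = np.asarray(round_window, float)
    axis = np.asarray(coiling_axis, float)
    nrm = np.linalg.norm(axis)
    if nrm == 0:
        raise ParameterError("coiling axis must be non-zero")
    axis = axis / nrm
    verts = np.asarray(mesh.vertices, float)
    o = np.asarray(axis_point, float) if axis_point is not None else verts.mean(axis=0)

    for name, p in (("apex", apex), ("round_window", round_window)):
        d = np.min(np.linalg.norm(verts - p, axis=1))
        if d > 1.0:
            raise TracingError(f"{name} point is {d:.2f} mm from the surface")

    if rings is not None:
        poly = _ring_extrema(verts, np.asarray(rings, int), o, axis)
    else:
        poly = _section_sweep(mesh, apex, round_window, o, axis)

    if (np.linalg.norm(poly[0] - round_window)
            > np.linalg.norm(poly[-1] - round_window)):
        poly = poly[::-1]
    if np.linalg.norm(poly[-1] - apex) > 2.0:
        raise TracingError("traced contour does not terminate at the apex")
    return OuterWallContour.from_polyline(poly, n_points)


def _ring_extrema(verts: np.ndarray, rings: np.ndarray, o: np.ndarray,
                  axis: np.ndarray) -> np.ndarray:
    rel = verts - o
    radial = rel - np.outer(rel @ axis, axis)
    rdist = np.linalg.norm(radial, axis=1)
    out = np.empty((rings.shape[0], 3))
    for i, ring in enumerate(rings):
        r = rdist[ring]
        j = int(np.argmax(r))
        jm, jp = (j - 1) % len(ring), (j + 1) % len(ring)
        denom = r[jm] - 2.0 * r[j] + r[jp]
        delta = 0.0 if abs(denom) < 1e-12 else 0.5 * (r[jm] - r[jp]) / denom
        delta = float(np.clip(delta, -0.5, 0.5))
        # quadratic (Lagrange) interpolation of the three candidate positions
        wm = 0.5 * delta * (delta - 1.0)
        w0 = 1.0 - delta * delta
        wp = 0.5 * delta * (delta + 1.0)
        out[i] = (wm * verts[ring[jm]] + w0 * verts[ring[j]] + wp * verts[ring[jp]])
    return out


def _section_sweep(mesh, apex, round_window, o, axis, step_deg: float = 2.0,
                   max_turns: float = 4.0) -> np.ndarray:
    """Generic lateral-ridge tracer: walk half-planes around the coiling axis."""
    u = np.array([1.0, 0.0, 0.0])
    if abs(u @ axis) > 0.9:
        u = np.array([0.0, 1.0, 0.0])
    u = u - (u @ axis) * axis
    u /= np.linalg.norm(u)
    v = np.cross(axis, u)

    def candidates(phi):
        d = np.cos(phi) * u + np.sin(phi) * v
        n = -np.sin(phi) * u + np.cos(phi) * v
        sect = mesh.section(plane_origin=o, plane_normal=n)
        if sect is None:
            return []
        cands = []
        for poly in sect.discrete:
            pts = np.asarray(poly, float)
            side = (pts - o) @ d
            keep = side > 0
            if not np.any(keep):
                continue
            pts, side = pts[keep], side[keep]
            cands.append(pts[int(np.argmax(side))])
        return cands

    rel_rw = round_window - o
    phi0 = float(np.arctan2(rel_rw @ v, rel_rw @ u))
    start_c = candidates(phi0)
    if not start_c:
        raise TracingError("no section candidates at the round-window azimuth")
    cur = min(start_c, key=lambda p: np.linalg.norm(p - round_window))
    step = np.radians(step_deg)
    n_steps = int(360.0 / step_deg * max_turns)

    best = None
    for direction in (1.0, -1.0):
        pts = [cur]
        p = cur
        for k in range(1, n_steps + 1):
            cands = candidates(phi0 + direction * step * k)
            if not cands:
                continue
            nxt = min(cands, key=lambda q: np.linalg.norm(q - p))
            jump = np.linalg.norm(nxt - p)
            local_r = np.linalg.norm(p - o)
            if jump > max(1.0, 3.0 * local_r * step):
                continue
            p = nxt
            pts.append(p)
            if np.linalg.norm(p - apex) < 0.75:
                break
        if np.linalg.norm(pts[-1] - apex) < 1.5:
            if best is None or len(pts) > len(best):
                best = pts
    if best is None or len(best) < 10:
        raise TracingError("section sweep failed to reach the apex")
    return np.asarray(best)
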