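"""Standardised length axis and bilateral length-difference measurement.

After mirroring and registration, the longer ulna defines the measurement
axis: the bone is cut halfway between the olecranon tip and the dome tip, a
circle is fit to the cut contour, and the axis runs from the fitted circle
center to the dome tip (proximal to distal).  The signed left-right length
difference is the difference of the two dome-tip projections on this axis,
reported right-minus-left (positive = right longer).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .errors import (
    DegenerateFitError,
    DegenerateGeometryError,
    EmptySectionError,
)
from .mesh_io import SurfaceMesh
from .registration import (
    AlignmentCheck,
    ICPResult,
    ReflectionPlane,
    RigidTransform,
    check_alignment,
    default_mirror_plane,
    icp_register,
    mirror_mesh,
    mirror_point,
    principal_axes_init,
)
from .synthetic import LandmarkSet

__all__ = [
    "LengthAxis",
    "CrossSection",
    "CircleFit",
    "PairMeasurement",
    "detect_landmarks",
    "select_longer",
    "cut_halfway",
    "fit_circle",
    "build_axis",
    "project_on_axis",
    "measure_length_difference",
    "full_ulna_length",
    "measure_pair",
]


@dataclass(frozen=True)
class LengthAxis:
    """The standardised measurement line: arc center -> dome tip direction."""

    origin: np.ndarray  # fitted circle center at the halfway cut, mm
    direction: np.ndarray  # unit vector, proximal to distal

    def __post_init__(self) -> None:
        o = np.asarray(self.origin, dtype=np.float64).reshape(3)
        d = np.asarray(self.direction, dtype=np.float64).reshape(3)
        n = np.linalg.norm(d)
        if abs(n - 1.0) > 1e-9:
            raise DegenerateGeometryError("axis direction must be a unit vector")
        object.__setattr__(self, "origin", o)
        object.__setattr__(self, "direction", d)


@dataclass(frozen=True)
class CrossSection:
    """Ordered contour of a plane-mesh intersection."""

    points: np.ndarray  # (n, 3), on the plane
    plane: ReflectionPlane

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=np.float64)
        if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 8:
            raise EmptySectionError("cross-section needs at least 8 points")
        off = np.abs((pts - self.plane.point) @ self.plane.normal)
        if off.max() > 1e-6:
            raise EmptySectionError("cross-section points not on the cut plane")
        object.__setattr__(self, "points", pts)

    @property
    def perimeter(self) -> float:
        closed = np.vstack([self.points, self.points[:1]])
        return float(np.linalg.norm(np.diff(closed, axis=0), axis=1).sum())


@dataclass(frozen=True)
class CircleFit:
    center: np.ndarray  # 3D, mm
    radius: float  # mm
    rms_residual: float  # RMS radial misfit, mm


@dataclass(frozen=True)
class PairMeasurement:
    """Bilateral ulnar length difference for one patient (all mm / percent).

    ``signed_diff`` is right minus left: positive means the right ulna is
    longer.  ``relative_diff`` is ``100 * abs_diff / full_length_longer``.
    """

    signed_diff: float
    abs_diff: float
    relative_diff: float
    longer_side: str  # 'left' | 'right' | 'equal'
    full_length_longer: float
    alignment_ok: bool
    icp_rms: float = float("nan")
    alignment: AlignmentCheck | None = None

    def to_record(self, patient_id: str | None = None) -> dict:
        rec = {
            "signed_diff_mm": self.signed_diff,
            "abs_diff_mm": self.abs_diff,
            "relative_diff_pct": self.relative_diff,
            "longer_side": self.longer_side,
            "full_length_mm": self.full_length_longer,
            "alignment_ok": self.alignment_ok,
            "icp_rms_mm": self.icp_rms,
        }
        if patient_id is not None:
            rec = {"patient_id": patient_id, **rec}
        return rec


# ---------------------------------------------------------------------------
# landmarks


def detect_landmarks(mesh: SurfaceMesh, olecranon_end: int | None = None) -> LandmarkSet:
    """Locate the olecranon tip and dome tip of an elongated bone mesh.

    The two candidate tips are the extremal surface points along the first
    principal axis of the vertex cloud, each refined to the point farthest
    from the centroid within its end cap (outer 15% of the axial extent).
    The olecranon end is the one with the larger end-cap girth (maximal
    perpendicular distance from the principal axis); pass ``olecranon_end``
    (0 for the low-projection end, 1 for the high end) to override.

    Raises
    ------
    DegenerateGeometryError
        If the mesh is not elongated (longest principal extent < 3x the
        next one).
    """
    v = mesh.vertices
    c = v.mean(axis=0)
    centered = v - c
    # principal axes of the vertex cloud
    _, _, Vt = np.linalg.svd(centered, full_matrices=False)
    axes = Vt  # rows: principal directions
    proj = centered @ axes.T
    extents = proj.max(axis=0) - proj.min(axis=0)
    order = np.argsort(extents)[::-1]
    if extents[order[0]] < 3.0 * extents[order[1]]:
        raise DegenerateGeometryError(
            f"mesh not elongated: extents {extents[order[0]]:.1f} vs "
            f"{extents[order[1]]:.1f} mm (need 3x)"
        )
    u = axes[order[0]]
    t = centered @ u
    t_min, t_max = t.min(), t.max()
    span = t_max - t_min
    cap_depth = 0.15 * span

    tips = []
    girths = []
    for lo, hi in ((t_min, t_min + cap_depth), (t_max - cap_depth, t_max)):
        in_cap = (t >= lo) & (t <= hi)
        cap = centered[in_cap]
        r = np.linalg.norm(cap, axis=1)
        tips.append(v[np.flatnonzero(in_cap)[np.argmax(r)]])
        perp = cap - np.outer(cap @ u, u)
        girths.append(np.linalg.norm(perp, axis=1).max())

    if olecranon_end is None:
        olecranon_end = int(np.argmax(girths))
    dome_end = 1 - olecranon_end
    return LandmarkSet(olecranon_tip=tips[olecranon_end], dome_tip=tips[dome_end])


def select_longer(
    mesh_a: SurfaceMesh,
    lm_a: LandmarkSet,
    mesh_b: SurfaceMesh,
    lm_b: LandmarkSet,
) -> str:
    """'a' if the first bone's landmark chord is at least as long, else 'b'.

    Ties (within 1e-9 mm) resolve to 'a'.
    """
    return "a" if lm_a.chord_length >= lm_b.chord_length - 1e-9 else "b"


# ---------------------------------------------------------------------------
# halfway cut and circle fit


def cut_halfway(mesh: SurfaceMesh, lm: LandmarkSet) -> CrossSection:
    """Cut the bone halfway along the olecranon-to-dome chord.

    The cut plane passes through the chord midpoint with its normal along
    the chord.  If the plane produces several closed contours, the one with
    the largest perimeter (the shaft outline) is returned.
    """
    chord = lm.dome_tip - lm.olecranon_tip
    norm = np.linalg.norm(chord)
    if norm < 1e-12:
        raise DegenerateGeometryError("landmarks coincide")
    normal = chord / norm
    midpoint = 0.5 * (lm.olecranon_tip + lm.dome_tip)

    section = mesh.to_trimesh().section(plane_origin=midpoint, plane_normal=normal)
    if section is None or len(section.entities) == 0:
        raise EmptySectionError("cut plane does not intersect the mesh")
    contours = section.discrete  # list of (n, 3) polylines
    best = None
    best_per = -1.0
    for poly in contours:
        pts = np.asarray(poly, dtype=np.float64)
        if len(pts) > 1 and np.allclose(pts[0], pts[-1]):
            pts = pts[:-1]
        per = float(
            np.linalg.norm(np.diff(np.vstack([pts, pts[:1]]), axis=0), axis=1).sum()
        )
        if per > best_per:
            best, best_per = pts, per
    if best is None or len(best) < 8:
        raise EmptySectionError("cut produced no usable contour")
    # snap to the plane (intersection arithmetic is exact to ~1e-12 anyway)
    best = best - np.outer((best - midpoint) @ normal, normal)
    return CrossSection(points=best, plane=ReflectionPlane(midpoint, normal))


def _plane_basis(normal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n = normal / np.linalg.norm(normal)
    helper = np.zeros(3)
    helper[np.argmin(np.abs(n))] = 1.0
    e1 = np.cross(n, helper)
    e1 /= np.linalg.norm(e1)
    return e1, np.cross(n, e1)


def fit_circle(section: CrossSection) -> CircleFit:
    """Least-squares circle through the cut contour.

    Points are projected into the cut plane; an algebraic (Kasa) fit seeds a
    geometric refinement that minimises the RMS radial misfit.  Works for
    full contours and open arcs alike.

    Raises
    ------
    DegenerateFitError
        If the points are (near-)collinear.
    """
    pts = section.points
    e1, e2 = _plane_basis(section.plane.normal)
    rel = pts - section.plane.point
    xy = np.column_stack([rel @ e1, rel @ e2])

    A = np.column_stack([2.0 * xy, np.ones(len(xy))])
    b = (xy**2).sum(axis=1)
    sol, _, rank, sv = np.linalg.lstsq(A, b, rcond=None)
    if rank < 3 or sv[-1] < 1e-9 * sv[0]:
        raise DegenerateFitError("contour points are collinear")
    cx, cy = sol[0], sol[1]
    r0 = float(np.sqrt(sol[2] + cx**2 + cy**2))

    def residuals(p):
        return np.hypot(xy[:, 0] - p[0], xy[:, 1] - p[1]) - p[2]

    fit = least_squares(residuals, x0=[cx, cy, r0], method="lm")
    cx, cy, radius = fit.x
    rms = float(np.sqrt(np.mean(residuals(fit.x) ** 2)))
    center3d = section.plane.point + cx * e1 + cy * e2
    return CircleFit(center=center3d, radius=float(radius), rms_residual=rms)


# ---------------------------------------------------------------------------
# axis and projections


def build_axis(arc_center: np.ndarray, dome_tip: np.ndarray) -> LengthAxis:
    """Axis from the halfway-cut circle center towards the dome tip."""
    arc_center = np.asarray(arc_center, dtype=np.float64).reshape(3)
    dome_tip = np.asarray(dome_tip, dtype=np.float64).reshape(3)
    d = dome_tip - arc_center
    n = np.linalg.norm(d)
    if n < 1e-12:
        raise DegenerateGeometryError("arc center and dome tip coincide")
    return LengthAxis(origin=arc_center, direction=d / n)


def project_on_axis(point: np.ndarray, axis: LengthAxis) -> float:
    """Signed coordinate of ``point`` along the axis (mm from the origin)."""
    return float((np.asarray(point, dtype=np.float64) - axis.origin) @ axis.direction)


def measure_length_difference(
    dome_long: np.ndarray,
    dome_short: np.ndarray,
    axis: LengthAxis,
    long_is_right: bool,
) -> float:
    """Signed right-minus-left dome-height difference along the axis."""
    p_long = project_on_axis(dome_long, axis)
    p_short = project_on_axis(dome_short, axis)
    return p_long - p_short if long_is_right else p_short - p_long


def full_ulna_length(lm: LandmarkSet, axis: LengthAxis) -> float:
    """Olecranon-to-dome extent of one bone projected on the axis (mm)."""
    return project_on_axis(lm.dome_tip, axis) - project_on_axis(lm.olecranon_tip, axis)


# ---------------------------------------------------------------------------
# full pipeline


def measure_pair(
    left: SurfaceMesh,
    right: SurfaceMesh,
    left_landmarks: LandmarkSet | None = None,
    right_landmarks: LandmarkSet | None = None,
    icp_max_iter: int = 100,
    icp_tol: float = 1e-4,
    olecranon_tol: float = 2.0,
    dome_lateral_tol: float = 2.0,
    proximal_fraction: float = 0.5,
    trim_fraction: float = 0.0,
) -> PairMeasurement:
    """Measure the bilateral ulnar length difference of one left/right pair.

    Pipeline: mirror the left ulna -> landmark-guided initialization -> ICP
    refinement -> alignment gate -> longer bone selection -> halfway cut ->
    circle fit -> length axis -> projected dome-height difference.

    ICP correspondences are restricted to the proximal ``proximal_fraction``
    of the moving bone (measured along its own landmark chord): the bones
    are aligned proximal-to-distal so the olecranons overlap, leaving the
    distal dome separation — the measurand — unconstrained.  Landmarks may
    be supplied (ground truth or manual picks) to bypass detection.

    A failed alignment gate yields ``alignment_ok=False`` on the result
    rather than an exception; geometric failures raise with the stage named.
    """
    lm_left = left_landmarks if left_landmarks is not None else detect_landmarks(left)
    lm_right = (
        right_landmarks if right_landmarks is not None else detect_landmarks(right)
    )

    # mirror the left bone (and its landmarks) across a default plane
    plane = default_mirror_plane(left)
    moving = mirror_mesh(left, plane)
    lm_moving = LandmarkSet(
        mirror_point(lm_left.olecranon_tip, plane),
        mirror_point(lm_left.dome_tip, plane),
    )

    init = principal_axes_init(moving, right, lm_moving, lm_right)

    # proximal mask from the moving bone's own chord (rigid-invariant)
    chord = lm_moving.dome_tip - lm_moving.olecranon_tip
    u = chord / np.linalg.norm(chord)
    tpos = (moving.vertices - lm_moving.olecranon_tip) @ u
    mask = tpos <= proximal_fraction * np.linalg.norm(chord)

    icp = icp_register(
        moving,
        right,
        init=init,
        max_iter=icp_max_iter,
        tol=icp_tol,
        trim_fraction=trim_fraction,
        moving_mask=mask,
    )
    lm_left_common = lm_moving.transformed(icp.transform)

    which = select_longer(right, lm_right, moving, lm_left_common)
    long_is_right = which == "a"
    if long_is_right:
        longer_mesh, lm_longer = right, lm_right
        dome_short = lm_left_common.dome_tip
    else:
        longer_mesh = SurfaceMesh(icp.transform.apply(moving.vertices), moving.faces)
        lm_longer = lm_left_common
        dome_short = lm_right.dome_tip

    section = cut_halfway(longer_mesh, lm_longer)
    circle = fit_circle(section)
    axis = build_axis(circle.center, lm_longer.dome_tip)

    alignment = check_alignment(
        lm_left_common,
        lm_right,
        axis,
        olecranon_tol=olecranon_tol,
        dome_lateral_tol=dome_lateral_tol,
    )

    signed = measure_length_difference(
        lm_longer.dome_tip, dome_short, axis, long_is_right
    )
    abs_diff = abs(signed)
    full_len = full_ulna_length(lm_longer, axis)
    if abs_diff < 1e-9:
        longer_side = "equal"
    else:
        longer_side = "right" if signed > 0 else "left"
    return PairMeasurement(
        signed_diff=signed,
        abs_diff=abs_diff,
        relative_diff=100.0 * abs_diff / full_len,
        longer_side=longer_side,
        full_length_longer=full_len,
        alignment_ok=alignment.success,
        icp_rms=icp.rms,
        alignment=alignment,
    )
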