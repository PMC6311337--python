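"""Corridor analysis: virtual 3.5 mm screws inside the pubic body.

The measurement core of the package. Given a watertight hemipelvis
surface, its landmarks and the plate-derived insertion points, this
module finds

* the **tangential-obturator screw** from the outer site L — the most
  laterally inclined contained screw, tangent to the obturator-side
  inner cortex — and its length L0, medial inclination angle (MIA) and
  anterior/posterior inclination angle (APIA);
* the four **cross-section planes** that define the measuring frames;
* for the inner (M) and outer (L) screws the **maximum anterior and
  posterior inclination angles** (MAIA >= 0, MPIA <= 0) and the screw
  lengths at maximal anterior inclination (L1, L2), with the screw
  tangential to the corresponding cortex;
* the **safe-region pattern** (blunt V / sharp V / disjoint) of the
  projected anterior and posterior cortical boundaries seen along the
  tangential screw axis.

Containment of a screw is decided by sampling its lateral surface and
tip cap and requiring every sample to lie inside the bone within a
small protrusion tolerance; samples above the local entry tangent plane
(the countersunk screw head) are exempt. Maximal angles and lengths are
found by bisection between a contained and a violating bracket, located
by a coarse sweep.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .config import PipelineConfig
from .geometry import (MeshQuery, closest_point_on_polyline,
                       cylinder_surface_points, in_plane_angle,
                       project_to_plane, rotate_about, unit)
from .mesh_io import LandmarkSet, validate_mesh
from .plate import locate_insertion_points, offset_brim_curve

_MAX_TILT = 89.0


class NoCorridorError(RuntimeError):
    """No contained screw exists under the stated conditions."""


class BelowMinimumLengthError(RuntimeError):
    """No contained screw of at least the minimum implantable length."""


class CorridorGeometryError(RuntimeError):
    """Degenerate construction (parallel spans, missing silhouette...)."""


class StageError(RuntimeError):
    """Pipeline failure, tagged with the stage that raised it."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


# ---------------------------------------------------------------------------
# data types
# ---------------------------------------------------------------------------

@dataclass
class ScrewCylinder:
    """A virtual screw: entry point, unit axis (tip direction), mm sizes."""

    entry: np.ndarray
    axis: np.ndarray
    diameter: float = 3.5
    length: float = 14.0

    def __post_init__(self):
        self.entry = np.asarray(self.entry, dtype=np.float64)
        self.axis = unit(self.axis)
        if self.diameter <= 0 or self.length <= 0:
            raise ValueError("screw diameter and length must be positive")

    @property
    def radius(self) -> float:
        return self.diameter / 2.0


@dataclass
class ContainmentResult:
    contained: bool
    clearance_mm: float  # min signed surface distance over samples (+ inside)


@dataclass
class Plane:
    point: np.ndarray
    normal: np.ndarray

    def distance(self, p) -> float:
        return float((np.asarray(p, float) - self.point) @ self.normal)


@dataclass
class CrossSectionSet:
    """The four measuring planes and the two cortical reference lines.

    plane1: spanned by the L-to-brim perpendicular and the tangential
    screw axis; plane2 orthogonal to it, still containing the axis;
    plane3: the inner-screw insertion plane through M and O; plane4
    orthogonal to plane3 through O and M (where the plane MIA lives).
    """

    plane1: Plane
    plane2: Plane
    plane3: Plane
    plane4: Plane
    reference_line_M: np.ndarray
    reference_line_L: np.ndarray


@dataclass
class TiltResult:
    angle_deg: float  # signed: anterior >= 0, posterior <= 0
    screw: ScrewCylinder


@dataclass
class TangentialScrew:
    screw: ScrewCylinder
    length_L0_mm: float
    mia_deg: float
    apia_deg: float
    tangency_constrained: bool  # False when no obturator-side limit binds


@dataclass
class SafeRegion:
    anterior_boundary: np.ndarray   # (n, 2) projected polyline (u, v)
    posterior_boundary: np.ndarray
    pattern: str                    # blunt_V | sharp_V | disjoint
    apex_angle_deg: Optional[float]


@dataclass
class InnerScrewResult:
    maia_deg: float
    mpia_deg: float
    length_L1_mm: float
    plane_mia_deg: float


@dataclass
class OuterScrewResult:
    maia_deg: float
    mpia_deg: float
    length_L2_mm: float


@dataclass
class CorridorResult:
    """All measured safe-corridor parameters for one hemipelvis."""

    inner: InnerScrewResult
    outer: OuterScrewResult
    tangential: TangentialScrew
    region: SafeRegion
    cross_sections: CrossSectionSet
    screws: dict = field(default_factory=dict)

    def to_flat_dict(self) -> dict:
        return {
            "inner_L1_mm": round(self.inner.length_L1_mm, 2),
            "inner_MAIA_deg": round(self.inner.maia_deg, 2),
            "inner_MPIA_deg": round(self.inner.mpia_deg, 2),
            "inner_plane_MIA_deg": round(self.inner.plane_mia_deg, 2),
            "outer_L2_mm": round(self.outer.length_L2_mm, 2),
            "outer_MAIA_deg": round(self.outer.maia_deg, 2),
            "outer_MPIA_deg": round(self.outer.mpia_deg, 2),
            "tangential_L0_mm": round(self.tangential.length_L0_mm, 2),
            "tangential_MIA_deg": round(self.tangential.mia_deg, 2),
            "tangential_APIA_deg": round(self.tangential.apia_deg, 2),
            "region_pattern": self.region.pattern,
        }


# ---------------------------------------------------------------------------
# containment
# ---------------------------------------------------------------------------

def _as_query(mesh) -> MeshQuery:
    return mesh if isinstance(mesh, MeshQuery) else MeshQuery(mesh)


def _eff_radius(radius: float, n_circ: int) -> float:
    """Sampling radius circumscribing the nominal screw circle, so that
    the sampled polygon never under-covers the true cylinder."""
    return radius / math.cos(math.pi / n_circ)


#: countersink depth of the head-clip plane below the entry point (mm):
#: on a gently convex cortex the exact tangent plane would retain samples
#: protruding through neighbouring facets by the faceting sagitta
_HEAD_CLIP_DEPTH = 0.3


def _entry_clip(mq: MeshQuery, entry) -> Optional[tuple]:
    """Tangent-plane clip at the entry when the entry lies on the surface."""
    entry = np.asarray(entry, float)
    if float(mq.distance(entry[None, :])[0]) < 0.5:
        n = mq.surface_normal(entry)
        return (entry - _HEAD_CLIP_DEPTH * n, n)
    return None


def _n_axial(n_ax: int, length: float, spacing: float = 2.5) -> int:
    """Axial rings: at least the configured count, never sparser than
    ``spacing`` mm (grazing tangencies alias with sparse rings)."""
    return max(n_ax, int(math.ceil(length / spacing)) + 1)


def _feasible(mq, entry, axis, length, radius, clip, tol, n_ax, n_circ,
              spacing=2.5) -> bool:
    pts = cylinder_surface_points(entry, axis, _eff_radius(radius, n_circ),
                                  length,
                                  n_axial=_n_axial(n_ax, length, spacing),
                                  n_circ=n_circ, clip_plane=clip)
    if len(pts) == 0:
        return False  # whole cylinder above the entry cortex
    inside = mq.contains(pts)
    if inside.all():
        return True
    return bool(mq.distance(pts[~inside]).max() <= tol)


def _feasible_many(mq, entry, axes, length, radius, clip, tol, n_ax, n_circ,
                   spacing=2.5):
    """Vectorised feasibility of many candidate axes from one entry.

    ``length`` may be a scalar or a per-axis sequence.
    """
    lengths = (np.full(len(axes), length, dtype=float)
               if np.isscalar(length) else np.asarray(length, dtype=float))
    r_eff = _eff_radius(radius, n_circ)
    blocks = [cylinder_surface_points(entry, a, r_eff, ln,
                                      n_axial=_n_axial(n_ax, ln, spacing),
                                      n_circ=n_circ, clip_plane=clip)
              for a, ln in zip(axes, lengths)]
    sizes = np.array([len(b) for b in blocks])
    if sizes.sum() == 0:
        return np.zeros(len(axes), dtype=bool)
    pts = np.vstack([b for b in blocks if len(b)])
    ids = np.repeat(np.arange(len(axes)), sizes)
    inside = mq.contains(pts)
    ok = sizes > 0  # fully head-clipped candidates are not contained
    bad = ~inside
    if bad.any():
        d = mq.distance(pts[bad])
        viol = d > tol
        if viol.any():
            ok[ids[bad][viol]] = False
    return ok


def contains_cylinder(mesh, cyl: ScrewCylinder, tol: float = 0.02,
                      n_axial: int = 24, n_circ: int = 32,
                      clip: str | None = "auto") -> ContainmentResult:
    """Is the screw inside the bone, and by how much?

    Samples the lateral surface and tip cap; ``clearance_mm`` is the
    minimum signed surface distance over the samples (positive inside).
    With ``clip='auto'`` samples above the entry tangent plane (the
    protruding screw head) are exempt whenever the entry lies on the
    surface; pass ``clip=None`` to test the full cylinder.
    """
    mq = _as_query(mesh)
    if not mq.mesh.is_watertight:
        raise CorridorGeometryError("containment requires a watertight mesh")
    plane = _entry_clip(mq, cyl.entry) if clip == "auto" else clip
    pts = cylinder_surface_points(cyl.entry, cyl.axis,
                                  _eff_radius(cyl.radius, n_circ), cyl.length,
                                  n_axial=_n_axial(n_axial, cyl.length),
                                  n_circ=n_circ, clip_plane=plane)
    if len(pts) == 0:  # whole cylinder above the entry cortex
        return ContainmentResult(contained=False, clearance_mm=-math.inf)
    sd = mq.signed_distance(pts)
    clearance = float(sd.min())
    return ContainmentResult(contained=bool(clearance >= -tol),
                             clearance_mm=clearance)


# ---------------------------------------------------------------------------
# searches
# ---------------------------------------------------------------------------

def _spanning_length(mq: MeshQuery, entry, axis, cfg: PipelineConfig):
    """Test length for a screw required to span the corridor.

    Backs off from the centreline's far exit just enough for a full
    screw cross-section to clear the exit face: for an exit at
    incidence ``cos_inc = |axis . n|`` the centreline must stand
    ``r / cos_inc`` short of the face, so oblique and grazing exits are
    handled. Returns ``None`` when the axis cannot host a spanning screw
    of at least the minimum implantable length (e.g. the centreline
    crosses a void such as the obturator foramen).
    """
    entry = np.asarray(entry, float)
    axis = unit(axis)
    chord, n_exit = mq.ray_exit(entry, axis)
    if chord <= cfg.min_screw_length or n_exit is None:
        return None
    r_eff = _eff_radius(cfg.screw_radius, cfg.n_circ)
    cos_inc = abs(float(axis @ n_exit))
    back = min(cfg.crossing_margin_mm,
               r_eff / max(cos_inc, r_eff / cfg.crossing_margin_mm) + 0.5)
    return max(cfg.min_screw_length, chord - back)


def screw_length(mesh, entry, axis, config: PipelineConfig | None = None,
                 clip="auto", lo_start: float | None = None) -> float:
    """Maximal contained screw length along a fixed axis (bisection).

    ``lo_start`` seeds the search with a length already known to be
    contained (used by the anterior searches so the bisection cannot
    stop at a grazing mid-corridor contact the screw actually clears).
    Raises :class:`BelowMinimumLengthError` if not even the minimum
    implantable screw fits.
    """
    cfg = config or PipelineConfig()
    mq = _as_query(mesh)
    entry = np.asarray(entry, float)
    axis = unit(axis)
    plane = _entry_clip(mq, entry) if clip == "auto" else clip
    args = (cfg.screw_radius, plane, cfg.contain_tol, cfg.n_axial,
            cfg.n_circ, cfg.axial_spacing_mm)
    if lo_start is not None and lo_start >= cfg.min_screw_length \
            and _feasible(mq, entry, axis, lo_start, *args):
        lo = lo_start
    elif _feasible(mq, entry, axis, cfg.min_screw_length, *args):
        lo = cfg.min_screw_length
    else:
        raise BelowMinimumLengthError(
            f"no contained screw of >= {cfg.min_screw_length} mm along this axis")
    diag = float(np.linalg.norm(mq.mesh.bounds[1] - mq.mesh.bounds[0]))
    hi = lo
    while _feasible(mq, entry, axis, hi, *args):
        lo = hi
        hi = hi * 1.5 + 5.0
        if hi > diag * 1.2:
            hi = diag * 1.2
            if _feasible(mq, entry, axis, hi, *args):
                return hi
            break
    while hi - lo > cfg.length_tol_mm:
        mid = 0.5 * (lo + hi)
        if _feasible(mq, entry, axis, mid, *args):
            lo = mid
        else:
            hi = mid
    return lo


def max_inclination_angle(mesh, entry, plane_normal, reference_line,
                          sense: str, anterior_hint,
                          config: PipelineConfig | None = None,
                          length_policy: str | None = None,
                          clip="auto") -> TiltResult:
    """Maximal in-plane screw tilt before the cortex is breached.

    Rotates the screw axis within the measuring plane away from the
    reference line, in the anterior or posterior sense, and finds the
    supremum tilt (bisection to ``angle_tol_deg`` between a contained
    and a violating bracket located by a coarse sweep) at which the
    screw lies tangential to that cortex. Two length policies define
    what "still contained" means:

    * ``'fixed'`` (the posterior default): a screw of the minimum
      implantable length (14 mm) is contained. The returned screw has
      that fixed length — the short screw shown at maximal posterior
      inclination.
    * ``'max-tangent'`` (the anterior default): the maximal-tangent-
      length screw still spans the corridor, i.e. a screw reaching the
      far cortex (the axial exit chord minus ``crossing_margin_mm``) is
      contained. Beyond this tilt the near cortex cuts the screw short
      of the far cortex: the screw at the maximum is tangential to the
      near cortex while running its full length, which the returned
      screw carries (L1/L2 at maximal anterior inclination).

    Sign convention: anterior angles are >= 0, posterior <= 0.
    """
    cfg = config or PipelineConfig()
    if sense not in ("anterior", "posterior"):
        raise ValueError("sense must be 'anterior' or 'posterior'")
    if length_policy is None:
        length_policy = "max-tangent" if sense == "anterior" else "fixed"
    if length_policy not in ("fixed", "max-tangent"):
        raise ValueError("length_policy must be 'fixed' or 'max-tangent'")
    mq = _as_query(mesh)
    entry = np.asarray(entry, float)
    n = unit(plane_normal)
    ref = unit(project_to_plane(reference_line, n))
    a_ip = project_to_plane(anterior_hint, n)
    if np.linalg.norm(a_ip) < 1e-9:
        raise CorridorGeometryError(
            "anterior direction is perpendicular to the measuring plane")
    s_ant = 1.0 if (np.cross(ref, a_ip) @ n) > 0 else -1.0
    rot = s_ant if sense == "anterior" else -s_ant
    plane = _entry_clip(mq, entry) if clip == "auto" else clip
    args = (cfg.screw_radius, plane, cfg.contain_tol, cfg.n_axial,
            cfg.n_circ, cfg.axial_spacing_mm)

    def axis_at(theta):
        return rotate_about(ref, n, rot * theta)

    if length_policy == "fixed":
        def test_length(axis):
            return cfg.min_screw_length
    else:
        def test_length(axis):
            return _spanning_length(mq, entry, axis, cfg)

    def feasible_one(theta):
        axis = axis_at(theta)
        ln = test_length(axis)
        return ln is not None and _feasible(mq, entry, axis, ln, *args)

    if not feasible_one(0.0):
        raise NoCorridorError(
            f"{sense} search: screw not contained even at the reference line")
    lo, hi = 0.0, None
    theta = cfg.coarse_step_deg
    while theta <= _MAX_TILT:
        batch = [min(theta + k * cfg.coarse_step_deg, _MAX_TILT)
                 for k in range(6)]
        axes = [axis_at(t) for t in batch]
        lens = [test_length(a) for a in axes]
        ok = np.array([ln is not None for ln in lens])
        if ok.any():
            ok[ok] = _feasible_many(mq, entry,
                                    [a for a, ln in zip(axes, lens)
                                     if ln is not None],
                                    [ln for ln in lens if ln is not None],
                                    *args)
        if not ok.all():
            k = int(np.argmin(ok))
            hi = batch[k]
            lo = batch[k - 1] if k > 0 else theta - cfg.coarse_step_deg
            break
        lo = batch[-1]
        theta = batch[-1] + cfg.coarse_step_deg
        if batch[-1] >= _MAX_TILT:
            break
    if hi is None:
        hi = _MAX_TILT  # tilt capped; treat the ceiling as the bracket
        lo = min(lo, _MAX_TILT - cfg.angle_tol_deg)
    while hi - lo > cfg.angle_tol_deg:
        mid = 0.5 * (lo + hi)
        if feasible_one(mid):
            lo = mid
        else:
            hi = mid
    if length_policy == "max-tangent":
        # measure the length a hair inside the supremum: exactly at the
        # tangency the clearance is zero and the tangent length is
        # numerically bistable (stop at the contact vs run to the far
        # cortex); just inside, the screw clears the contact and the
        # measured length is the stable full corridor run
        back = max(4.0 * cfg.angle_tol_deg, 0.4)
        axis = axis_at(max(0.0, lo - back))
        length = screw_length(mq, entry, axis, cfg, clip=plane,
                              lo_start=test_length(axis))
    else:
        axis = axis_at(lo)
        length = cfg.min_screw_length
    screw = ScrewCylinder(entry=entry, axis=axis,
                          diameter=cfg.screw_diameter, length=length)
    signed = lo if sense == "anterior" else -lo
    return TiltResult(angle_deg=signed, screw=screw)


def medial_inclination_angle(M, O, reference_line, plane4_normal) -> float:
    """Angle between the OM line and the cortical reference line, both
    projected into the MIA measuring plane (degrees, in [0, 90))."""
    M = np.asarray(M, float)
    O = np.asarray(O, float)
    if np.linalg.norm(O - M) < 1.0:
        raise CorridorGeometryError("landmarks M and O nearly coincide "
                                    f"({np.linalg.norm(O - M):.2f} mm apart)")
    n = unit(plane4_normal)
    om = unit(project_to_plane(O - M, n))
    ref = unit(project_to_plane(reference_line, n))
    ang = abs(in_plane_angle(ref, om, n))
    return min(ang, 180.0 - ang)


def _axis_angles(mq, entry, axis, brim, anterior_hint):
    """(MIA, APIA, plane1, plane2) of a screw axis at an entry point.

    plane1 holds the L-to-brim perpendicular and the axis (the A/P
    measuring plane); plane2 is orthogonal, still containing the axis
    (the medial-inclination measuring plane). Reference lines are the
    in-plane directions perpendicular to the local cortical tangent.
    """
    entry = np.asarray(entry, float)
    foot, _ = closest_point_on_polyline(brim, entry)
    u = foot - entry
    if np.linalg.norm(u) < 1e-6:
        raise CorridorGeometryError("entry point lies on the brim curve")
    u = unit(u)
    if np.linalg.norm(np.cross(u, axis)) < 1e-8:
        raise CorridorGeometryError("screw axis is parallel to the "
                                    "brim-perpendicular: degenerate plane")
    n1 = unit(np.cross(u, axis))
    n2 = unit(np.cross(n1, axis))
    inward = -mq.surface_normal(entry)
    ref1 = unit(project_to_plane(inward, n1))
    ref2 = unit(project_to_plane(inward, n2))
    a1 = in_plane_angle(ref1, axis, n1)
    side = in_plane_angle(ref1, anterior_hint, n1)
    apia = abs(a1) * (1.0 if a1 * side >= 0 else -1.0)
    mia = abs(in_plane_angle(ref2, axis, n2))
    mia = min(mia, 180.0 - mia)
    return mia, apia, Plane(entry, n1), Plane(entry, n2)


def tangential_obturator_screw(mesh, L, O, brim, anterior_hint,
                               config: PipelineConfig | None = None,
                               obturator_loop=None) -> TangentialScrew:
    """The most laterally inclined contained screw from the outer site L.

    Screw directions are parametrised by medial inclination ``alpha``
    (away from the inward surface normal, toward the symphysis) and A/P
    tilt ``beta``. The search returns the minimal ``alpha`` at which any
    ``beta`` admits a contained corridor-spanning screw (one whose
    length runs to the far cortex): the screw tangent to the
    obturator-side inner cortex. If even ``alpha = 0`` is feasible no
    obturator-side limit binds and the result is flagged
    ``tangency_constrained=False``.

    L0 is the maximal contained length of the tangential screw; MIA and
    APIA are its axis angles in the cross-section planes at L.
    """
    cfg = config or PipelineConfig()
    mq = _as_query(mesh)
    L = np.asarray(L, float)
    O = np.asarray(O, float)
    w = unit(-mq.surface_normal(L))
    mhat = unit(project_to_plane(O - L, w))
    ahat = project_to_plane(anterior_hint, w)
    ahat = ahat - (ahat @ mhat) * mhat
    if np.linalg.norm(ahat) < 1e-9:
        raise CorridorGeometryError("anterior hint degenerate at L")
    ahat = unit(ahat)
    plane = _entry_clip(mq, L)
    args = (cfg.screw_radius, plane, cfg.contain_tol, cfg.n_axial,
            cfg.n_circ, cfg.axial_spacing_mm)
    betas = np.arange(-cfg.beta_range_deg, cfg.beta_range_deg + 1e-9,
                      cfg.beta_step_deg)

    def axis_at(alpha, beta):
        a, b = math.radians(alpha), math.radians(beta)
        core = w * math.cos(a) + mhat * math.sin(a)
        return unit(core * math.cos(b) + ahat * math.sin(b))

    def feasible_one(alpha, beta):
        axis = axis_at(alpha, beta)
        ln = _spanning_length(mq, L, axis, cfg)
        return ln is not None and _feasible(mq, L, axis, ln, *args)

    def feasible_betas(alpha):
        axes = [axis_at(alpha, b) for b in betas]
        lens = [_spanning_length(mq, L, a, cfg) for a in axes]
        ok = np.array([ln is not None for ln in lens])
        if ok.any():
            ok[ok] = _feasible_many(mq, L,
                                    [a for a, ln in zip(axes, lens)
                                     if ln is not None],
                                    [ln for ln in lens if ln is not None],
                                    *args)
        return betas[ok]

    b_seed = [0.0]

    def feasible_any(alpha):
        """Lazy scan of the A/P grid, starting near the last success."""
        order = sorted(betas, key=lambda b: abs(b - b_seed[0]))
        for b in order:
            if feasible_one(alpha, b):
                b_seed[0] = b
                return True
        return False

    if feasible_any(0.0):
        alpha_star, constrained = 0.0, False
    else:
        constrained = True
        step = 5.0
        alpha_hi = None
        a = step
        while a <= cfg.mia_max_deg + 1e-9:
            if feasible_any(a):
                alpha_hi = a
                break
            a += step
        if alpha_hi is None:
            raise NoCorridorError(
                "no contained screw direction from L up to "
                f"{cfg.mia_max_deg} deg medial inclination")
        lo, hi = alpha_hi - step, alpha_hi
        while hi - lo > cfg.angle_tol_deg:
            mid = 0.5 * (lo + hi)
            if feasible_any(mid):
                hi = mid
            else:
                lo = mid
        alpha_star = hi
    fb = feasible_betas(alpha_star)
    if len(fb) == 0:  # numerical edge: nudge back up into feasibility
        alpha_star += 2.0 * cfg.angle_tol_deg
        fb = feasible_betas(alpha_star)
        if len(fb) == 0:
            raise NoCorridorError("tangential feasibility lost on refinement")

    def refine_edge(b_ok, b_bad):
        while abs(b_bad - b_ok) > 0.05:
            mid = 0.5 * (b_ok + b_bad)
            if feasible_one(alpha_star, mid):
                b_ok = mid
            else:
                b_bad = mid
        return b_ok

    b_lo, b_hi = float(fb.min()), float(fb.max())
    if b_lo > betas[0]:
        b_lo = refine_edge(b_lo, b_lo - cfg.beta_step_deg)
    if b_hi < betas[-1]:
        b_hi = refine_edge(b_hi, b_hi + cfg.beta_step_deg)
    beta_star = 0.5 * (b_lo + b_hi)
    axis = axis_at(alpha_star, beta_star)
    L0 = screw_length(mq, L, axis, cfg, clip=plane,
                      lo_start=_spanning_length(mq, L, axis, cfg))
    mia, apia, _, _ = _axis_angles(mq, L, axis, brim, anterior_hint)
    screw = ScrewCylinder(entry=L, axis=axis, diameter=cfg.screw_diameter,
                          length=L0)
    return TangentialScrew(screw=screw, length_L0_mm=L0, mia_deg=mia,
                           apia_deg=apia, tangency_constrained=constrained)


# ---------------------------------------------------------------------------
# cross sections
# ---------------------------------------------------------------------------

def build_cross_sections(mesh, M, L, O, brim, tangential_axis) -> CrossSectionSet:
    """The four measuring planes of the screw-insertion frame.

    plane1/plane2 at L follow the tangential screw axis; plane3 is the
    inner-screw insertion plane through M and O (spanned by the
    M-to-brim perpendicular and the MO direction); plane4 is orthogonal
    to plane3 through O and M. Reference lines at M and L are the
    in-plane perpendiculars to the local cortical tangent.
    """
    mq = _as_query(mesh)
    M = np.asarray(M, float)
    L = np.asarray(L, float)
    O = np.asarray(O, float)
    axis = unit(tangential_axis)

    foot_L, _ = closest_point_on_polyline(brim, L)
    u_L = foot_L - L
    if np.linalg.norm(np.cross(u_L, axis)) < 1e-8:
        raise CorridorGeometryError("plane1 span degenerate (L-brim "
                                    "perpendicular parallel to screw axis)")
    n1 = unit(np.cross(unit(u_L), axis))
    n2 = unit(np.cross(n1, axis))

    foot_M, _ = closest_point_on_polyline(brim, M)
    u_M = foot_M - M
    v_MO = O - M
    if np.linalg.norm(np.cross(u_M, v_MO)) < 1e-8:
        raise CorridorGeometryError("plane3 span degenerate (M-brim "
                                    "perpendicular parallel to MO)")
    n3 = unit(np.cross(unit(u_M), unit(v_MO)))
    n4 = unit(np.cross(n3, unit(v_MO)))

    ref_M = unit(project_to_plane(-mq.surface_normal(M), n3))
    ref_L = unit(project_to_plane(-mq.surface_normal(L), n3))
    return CrossSectionSet(
        plane1=Plane(L, n1), plane2=Plane(L, n2),
        plane3=Plane(M, n3), plane4=Plane(M, n4),
        reference_line_M=ref_M, reference_line_L=ref_L,
    )


# ---------------------------------------------------------------------------
# safe region
# ---------------------------------------------------------------------------

def safe_region(mesh, tangential_axis, anterior_hint,
                config: PipelineConfig | None = None,
                n_bins: int = 24) -> SafeRegion:
    """Classify the projected anterior/posterior cortical boundaries.

    Viewed along the tangential screw axis, the anterior and posterior
    cortical walls (faces nearly parallel to the axis) project to two
    boundary curves; their inner envelopes bound the safe insertion
    region. The pattern is ``blunt_V`` or ``sharp_V`` when the fitted
    boundaries cross inside the silhouette (apex angle >= / < the
    configured threshold) and ``disjoint`` otherwise.
    """
    cfg = config or PipelineConfig()
    mq = _as_query(mesh)
    axis = unit(tangential_axis)
    a_p = project_to_plane(anterior_hint, axis)
    if np.linalg.norm(a_p) < 1e-9:
        raise CorridorGeometryError("anterior hint parallel to the view axis")
    a_p = unit(a_p)
    u_dir = unit(np.cross(a_p, axis))

    normals = mq.mesh.face_normals
    centroids = mq.mesh.triangles_center
    wallish = np.abs(normals @ axis) < 0.35
    # steeply converging walls still face mostly +-anterior in the
    # projection plane, but their normals may pitch far along u/z; the
    # sign of the anterior component is what separates the two cortices
    ant = wallish & (normals @ a_p > 0.2)
    post = wallish & (normals @ a_p < -0.2)
    if ant.sum() < 2 or post.sum() < 2:
        raise CorridorGeometryError(
            "projection yields fewer than 2 boundary segments per side")

    def boundary(sel, inner_is_max):
        verts = mq.mesh.vertices[np.unique(mq.mesh.faces[sel])]
        u = verts @ u_dir
        v = verts @ a_p
        edges = np.linspace(u.min(), u.max(), n_bins + 1)
        us, vs = [], []
        for i in range(n_bins):
            m = (u >= edges[i] - 1e-9) & (u <= edges[i + 1] + 1e-9)
            if m.any():
                us.append(0.5 * (edges[i] + edges[i + 1]))
                vs.append(v[m].max() if inner_is_max else v[m].min())
        return np.column_stack([us, vs])

    # the anterior cortex sits on the high-v (anterior) side, so its
    # endosteal (inner) envelope is the min-v edge, and vice versa
    b_ant = boundary(ant, inner_is_max=False)
    b_post = boundary(post, inner_is_max=True)
    if len(b_ant) < 2 or len(b_post) < 2:
        raise CorridorGeometryError("too few silhouette bins to fit boundaries")

    ma, ca = np.polyfit(b_ant[:, 0], b_ant[:, 1], 1)
    mp, cp = np.polyfit(b_post[:, 0], b_post[:, 1], 1)
    u_all = np.concatenate([b_ant[:, 0], b_post[:, 0]])
    u_min, u_max = u_all.min(), u_all.max()
    if abs(ma - mp) < 1e-6:
        return SafeRegion(b_ant, b_post, "disjoint", None)
    u_star = (cp - ca) / (ma - mp)
    da = np.array([1.0, ma]) / math.hypot(1.0, ma)
    dp = np.array([1.0, mp]) / math.hypot(1.0, mp)
    apex = math.degrees(math.acos(float(np.clip(da @ dp, -1.0, 1.0))))
    # a V pattern exists when the boundaries cross within the silhouette
    # or pinch to less than a screw's width at its edge (an apex the
    # faceted silhouette truncates just short of meeting)
    def gap(u):
        return abs((mp * u + cp) - (ma * u + ca))

    crosses = (u_min - 1e-6 <= u_star <= u_max + 1e-6
               or min(gap(u_min), gap(u_max)) < cfg.screw_diameter)
    if not crosses:
        return SafeRegion(b_ant, b_post, "disjoint", apex)
    pattern = "blunt_V" if apex >= cfg.apex_threshold_deg else "sharp_V"
    return SafeRegion(b_ant, b_post, pattern, apex)


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def _stage(name):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, StageError):
                raise StageError(name, str(exc)) from exc
            return False

    return _Ctx()


def _frame(mesh, landmarks: LandmarkSet, cfg: PipelineConfig, mq=None):
    """Shared preamble: validation, offset curve, S/M/L, anterior hint."""
    mq = mq or MeshQuery(mesh)
    with _stage("validate"):
        report = validate_mesh(mq.mesh)
        if not report.watertight or (mq.mesh.volume < 0):
            raise CorridorGeometryError(
                "mesh failed validation: " + "; ".join(report.failures))
    with _stage("plate_placement"):
        # the tubercle-edge curve crosses the superior surface, so its
        # centroid marks the side of the brim the offset curve must take
        hint = np.asarray(landmarks.tubercle_edge_m, float).mean(axis=0)
        offs = offset_brim_curve(mq.mesh, landmarks.brim, cfg.offset_mm,
                                 step=cfg.offset_step_mm, mq=mq,
                                 interior_hint=hint)
        pts = locate_insertion_points(mq.mesh, offs, landmarks.tubercle_edge_m,
                                      cfg.plate)
        anterior_hint = unit((offs - np.asarray(landmarks.brim)).mean(axis=0))
    return mq, offs, pts, anterior_hint


def analyze_hemipelvis(mesh, landmarks: LandmarkSet,
                       config: PipelineConfig | None = None) -> CorridorResult:
    """Run the full corridor pipeline on one hemipelvis.

    Orchestrates plate placement, the tangential-obturator screw, the
    cross-section planes, the inner- and outer-screw inclination/length
    searches and the safe-region classification. Deterministic for fixed
    inputs and config. Stage failures raise :class:`StageError` naming
    the stage.
    """
    cfg = config or PipelineConfig()
    mq, offs, pts, anterior_hint = _frame(mesh, landmarks, cfg)
    O = landmarks.symphysis_lowest_O

    with _stage("tangential_screw"):
        tang = tangential_obturator_screw(mq, pts.L, O, landmarks.brim,
                                          anterior_hint, cfg)
    with _stage("cross_sections"):
        cs = build_cross_sections(mq, pts.M, pts.L, O, landmarks.brim,
                                  tang.screw.axis)
    with _stage("inner_screw"):
        ant = max_inclination_angle(mq, pts.M, cs.plane3.normal,
                                    cs.reference_line_M, "anterior",
                                    anterior_hint, cfg)
        post = max_inclination_angle(mq, pts.M, cs.plane3.normal,
                                     cs.reference_line_M, "posterior",
                                     anterior_hint, cfg)
        ref4 = unit(project_to_plane(-mq.surface_normal(pts.M),
                                     cs.plane4.normal))
        plane_mia = medial_inclination_angle(pts.M, O, ref4, cs.plane4.normal)
        inner = InnerScrewResult(maia_deg=ant.angle_deg,
                                 mpia_deg=post.angle_deg,
                                 length_L1_mm=ant.screw.length,
                                 plane_mia_deg=plane_mia)
        inner_screws = {"inner_anterior": ant.screw, "inner_posterior": post.screw}
    with _stage("outer_screw"):
        o_ant = max_inclination_angle(mq, pts.L, cs.plane3.normal,
                                      cs.reference_line_L, "anterior",
                                      anterior_hint, cfg)
        o_post = max_inclination_angle(mq, pts.L, cs.plane3.normal,
                                       cs.reference_line_L, "posterior",
                                       anterior_hint, cfg)
        outer = OuterScrewResult(maia_deg=o_ant.angle_deg,
                                 mpia_deg=o_post.angle_deg,
                                 length_L2_mm=o_ant.screw.length)
    with _stage("safe_region"):
        region = safe_region(mq, tang.screw.axis, anterior_hint, cfg)

    screws = {"tangential": tang.screw, **inner_screws,
              "outer_anterior": o_ant.screw, "outer_posterior": o_post.screw}
    return CorridorResult(inner=inner, outer=outer, tangential=tang,
                          region=region, cross_sections=cs, screws=screws)


def measure_outer_screw(mesh, landmarks: LandmarkSet,
                        config: PipelineConfig | None = None,
                        include_posterior: bool = True) -> OuterScrewResult:
    """Outer-screw (site L) measurements only — the fast path used by
    cohort-scale simulation studies. ``include_posterior=False`` skips
    the posterior search (MPIA reported as nan)."""
    cfg = config or PipelineConfig()
    mq, offs, pts, anterior_hint = _frame(mesh, landmarks, cfg)
    O = landmarks.symphysis_lowest_O
    with _stage("cross_sections"):
        foot_M, _ = closest_point_on_polyline(landmarks.brim, pts.M)
        n3 = unit(np.cross(unit(foot_M - pts.M), unit(O - pts.M)))
        ref_L = unit(project_to_plane(-mq.surface_normal(pts.L), n3))
    with _stage("outer_screw"):
        ant = max_inclination_angle(mq, pts.L, n3, ref_L, "anterior",
                                    anterior_hint, cfg)
        mpia = math.nan
        if include_posterior:
            post = max_inclination_angle(mq, pts.L, n3, ref_L, "posterior",
                                         anterior_hint, cfg)
            mpia = post.angle_deg
    return OuterScrewResult(maia_deg=ant.angle_deg, mpia_deg=mpia,
                            length_L2_mm=ant.screw.length)
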