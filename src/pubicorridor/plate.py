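"""Plate placement: the offset brim curve and insertion points S, M, L.

A 3.5 mm reconstruction plate laid along the pelvic brim puts its screw
holes on a curve running parallel to the brim, about 5 mm onto the
superior pubic surface. The plate starts where that offset curve meets
the outer edge of the pubic tubercle (point S); the two innermost screw
holes sit 6.5 mm (M, inner screw) and 6.5 + 13 = 19.5 mm (L, outer
screw) further along the curve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import (MeshQuery, point_at_arc_length, polyline_lengths,
                       points_to_polyline_distance, project_to_plane, unit)


class PlateGeometryError(ValueError):
    """Offset/intersection construction failed on this surface."""


@dataclass
class PlateSpec:
    """Implant geometry (mm): defaults match a 3.5 mm low-profile
    reconstruction plate (10 mm wide, 13 mm hole pitch, first hole
    6.5 mm from the tip)."""

    width: float = 10.0
    hole_pitch: float = 13.0
    first_hole_offset: float = 6.5
    screw_diameter: float = 3.5

    def __post_init__(self):
        if min(self.width, self.hole_pitch, self.screw_diameter) <= 0:
            raise ValueError("plate dimensions must be positive")
        if self.first_hole_offset < 0:
            raise ValueError("first_hole_offset must be >= 0")


@dataclass
class InsertionPoints:
    """S (plate start), M (inner screw), L (outer screw) on the offset curve."""

    S: np.ndarray
    M: np.ndarray
    L: np.ndarray
    offset_curve: np.ndarray
    arc_S: float
    arc_M: float
    arc_L: float


def _march_normal(mq: MeshQuery, p, travel_dir, tangent_dir=None):
    """Surface normal near ``p`` for marching along ``travel_dir``.

    At a cortical edge (e.g. the brim, where the superior surface meets
    the posterior wall) a plain patch normal mixes both sheets; among
    the faces the point actually touches (exact face distance), keeping
    only those roughly parallel to the travel direction — and to the
    curve tangent, at end corners — selects the sheet being marched on.
    """
    from .geometry import point_to_triangles_distance

    mesh = mq.mesh
    t = unit(travel_dir)
    d_face = point_to_triangles_distance(p, mq.v0, mq.v1, mq.v2)
    for tol in (0.5, 2.0, 6.0):
        sel = d_face < tol
        if not sel.any():
            continue
        normals = mesh.face_normals[sel]
        areas = mesh.area_faces[sel]
        par = np.abs(normals @ t) < 0.6
        if tangent_dir is not None:
            par &= np.abs(normals @ unit(tangent_dir)) < 0.6
        if par.any():
            return unit((normals[par] * areas[par, None]).sum(axis=0))
    sel = d_face <= np.partition(d_face, 2)[2]
    normals = mesh.face_normals[sel]
    areas = mesh.area_faces[sel]
    return unit((normals * areas[:, None]).sum(axis=0))


def offset_brim_curve(mesh, brim, offset: float = 5.0, step: float = 0.5,
                      interior_hint=None, mq: MeshQuery | None = None) -> np.ndarray:
    """Offset the brim polyline across the superior surface by ``offset`` mm.

    Geodesic surface offset by tangent-plane stepping with re-projection:
    from each brim point, march perpendicular to the brim within the local
    tangent plane in sub-steps of ``step`` mm, projecting back onto the
    surface after each sub-step. On a planar face this reduces to the
    exact Euclidean offset. The march heads away from the brim edge into
    the surface (toward ``interior_hint``, default the mesh centroid).

    Raises :class:`PlateGeometryError` naming the failing station when the
    curve would fall off the bone.
    """
    brim = np.asarray(brim, dtype=np.float64)
    if offset < 0:
        raise PlateGeometryError("offset must be >= 0")
    if offset == 0:
        return brim.copy()
    if mq is None:
        mq = MeshQuery(mesh)
    if interior_hint is None:
        interior_hint = mesh.vertices.mean(axis=0)
    interior_hint = np.asarray(interior_hint, dtype=np.float64)

    n_sub = max(1, int(np.ceil(offset / step)))
    sub = offset / n_sub
    n = len(brim)
    tangents = np.empty_like(brim)
    tangents[1:-1] = brim[2:] - brim[:-2]
    tangents[0] = brim[1] - brim[0]
    tangents[-1] = brim[-1] - brim[-2]
    dirs = np.empty_like(brim)
    prev = None
    for i in range(n):
        tangent = unit(tangents[i])
        # seed the crossing direction from the interior hint at the first
        # (medial) station, then propagate it along the brim: the hint
        # only disambiguates which sheet of the cortical edge to march
        # on, and direction continuity keeps later stations on that sheet
        rough = interior_hint - brim[i] if prev is None else prev
        travel = rough - (rough @ tangent) * tangent
        if np.linalg.norm(travel) < 1e-9:
            raise PlateGeometryError(
                f"interior hint is tangent to the brim at station {i}")
        normal = _march_normal(mq, brim[i], travel, tangent)
        d = np.cross(normal, tangent)
        if d @ travel < 0:
            d = -d
        dirs[i] = unit(d)
        prev = dirs[i]
    pos = brim.copy()
    for _ in range(n_sub):
        cand = pos + sub * dirs
        _, foot = mq.closest_points(cand)
        moved = np.linalg.norm(foot - pos, axis=1)
        if (moved < 0.25 * sub).any():
            i = int(np.argmin(moved))
            raise PlateGeometryError(
                f"offset curve falls off the surface at brim station {i} "
                f"(offset {offset} mm exceeds the local surface extent)")
        for i in range(n):
            normal = _march_normal(mq, foot[i], dirs[i], tangents[i])
            dirs[i] = unit(project_to_plane(dirs[i], normal))
        pos = foot
    return pos


def locate_insertion_points(mesh, offset_curve, tubercle_edge_m,
                            plate: PlateSpec | None = None,
                            intersect_tol: float = 1.0) -> InsertionPoints:
    """Find S at the offset-curve / tubercle-edge crossing, then M and L.

    S is the most medial close approach (within ``intersect_tol`` mm) of
    the offset curve to the tubercle edge curve ``m``; M and L lie at the
    plate's first-hole and second-hole arc lengths lateral of S along the
    offset curve (chord-accumulated arc length). The curve is assumed
    ordered medial to lateral, as the brim is.
    """
    if plate is None:
        plate = PlateSpec()
    curve = np.asarray(offset_curve, dtype=np.float64)
    m = np.asarray(tubercle_edge_m, dtype=np.float64)
    d = points_to_polyline_distance(curve, m)
    if d.min() > intersect_tol:
        raise PlateGeometryError(
            f"offset curve and tubercle edge m never approach within "
            f"{intersect_tol} mm (closest {d.min():.2f} mm)")
    # most medial contiguous approach within tolerance, refined by fine
    # resampling (if the curves cross more than once this keeps the most
    # medial crossing: the plate starts at the tubercle's outer edge)
    near = np.flatnonzero(d <= max(intersect_tol, d.min() + 1e-12))
    grp_end = near[0]
    for idx in near:
        if idx - grp_end <= 1:
            grp_end = idx
        else:
            break
    cum = polyline_lengths(curve)
    lo = cum[max(near[0] - 1, 0)]
    hi = max(cum[min(grp_end + 1, len(curve) - 1)], lo + 1e-6)
    s_grid = np.arange(lo, hi + 0.01, 0.01)
    pts = np.array([point_at_arc_length(curve, s) for s in s_grid])
    dd = points_to_polyline_distance(pts, m)
    k = int(np.argmin(dd))
    arc_S = float(s_grid[k])
    S = pts[k]
    arc_M = arc_S + plate.first_hole_offset
    arc_L = arc_S + plate.first_hole_offset + plate.hole_pitch
    if arc_L > cum[-1] + 1e-9:
        raise PlateGeometryError(
            f"offset curve too short: needs {arc_L - arc_S:.1f} mm beyond S "
            f"but only {cum[-1] - arc_S:.1f} mm remain")
    M = point_at_arc_length(curve, arc_M)
    L = point_at_arc_length(curve, arc_L)
    return InsertionPoints(S=S, M=M, L=L, offset_curve=curve,
                           arc_S=arc_S, arc_M=float(arc_M), arc_L=float(arc_L))
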