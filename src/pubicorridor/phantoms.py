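"""Parametric bone phantoms with landmarks and analytic ground truth.

Real pubic-body corridor measurements require CT-derived hemipelvis
surfaces, which ship with no public study. This module provides three
substitutes, each first-class tested code:

* **strip phantom** — a rectangular slab with two parallel cortical
  walls a known distance apart. Maximal anterior/posterior screw tilts
  and tangent screw lengths have closed 2D solutions (and an
  independent dense-sweep reference), so the slab is the analytic
  acceptance surface for every angle/length search.
* **pubis phantom** — a watertight idealised hemipubis: a medial body
  with a flat symphyseal face (thick bone), a lateral superior ramus
  (thin bone), a through-hole bounded by the obturator loop, and a
  tubercle prominence on the superior surface. All landmarks are
  emitted exactly on the surface. The medial-thick / lateral-thin
  gradient of the real pubis is reproduced by construction.
* **wedge phantom** — two cortical walls converging at a prescribed
  apex angle, used to exercise the safe-region V-shape classifier.

A cohort sampler draws per-subject phantom parameters from per-sex
normal distributions (intertubercular distance, symphysis height,
ramus length, thickness scale), reproducibly from one integer seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import trimesh
from scipy.interpolate import PchipInterpolator

from .mesh_io import LandmarkSet

DEG = math.pi / 180.0


class PhantomParameterError(ValueError):
    """Phantom spec violates its invariants."""


# ---------------------------------------------------------------------------
# ground truth container
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """Closed-form corridor answers for a phantom, where they exist."""

    entry_point: Optional[np.ndarray] = None
    maia_deg: Optional[float] = None          # max anterior tilt, degrees (>= 0)
    mpia_deg: Optional[float] = None          # max posterior tilt, degrees (<= 0)
    max_length_mm: Optional[float] = None     # tangent screw length at tilt 0
    mia_deg: Optional[float] = None
    symphysis_height_mm: Optional[float] = None
    intertubercular_mm: Optional[float] = None
    params: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# strip phantom + 2D oracle
# ---------------------------------------------------------------------------

@dataclass
class StripPhantomSpec:
    """Rectangular slab: walls ``thickness_T`` apart, entry on the top face.

    ``entry_offset_da`` is the entry distance from the anterior wall,
    ``entry_offset_dl`` the distance from the medial end. ``m_position``
    places the tubercle-edge marker curve along the top face.
    """

    thickness_T: float = 20.0
    height_H: float = 60.0
    width_W: float = 40.0
    entry_offset_da: float = 10.0
    entry_offset_dl: float = 20.0
    m_position: float = 5.0

    def __post_init__(self):
        if self.thickness_T <= 3.5:
            raise PhantomParameterError("thickness_T must exceed the 3.5 mm screw")
        if not (0 < self.entry_offset_da < self.thickness_T):
            raise PhantomParameterError("entry_offset_da must lie strictly "
                                        "between the cortical walls")
        if self.height_H <= 0 or self.width_W <= 0:
            raise PhantomParameterError("height_H and width_W must be positive")


def _submerged_extremes(T, da, r, theta_deg, length):
    """Wall coordinates of the submerged part of a tilted 2D screw rectangle.

    Coordinates: y in [0, T] across the strip (anterior wall at 0),
    z <= 0 below the entry surface. Positive theta tilts anterior.
    Returns (points_y, points_z) of every corner at z <= 0 plus every
    surface (z = 0) crossing of the rectangle's edges.
    """
    th = theta_deg * DEG
    d = np.array([-math.sin(th), -math.cos(th)])
    p = np.array([-math.cos(th), math.sin(th)])
    e = np.array([da, 0.0])
    c = [e + r * p, e - r * p, e + r * p + length * d, e - r * p + length * d]
    edges = [(0, 1), (0, 2), (1, 3), (2, 3)]
    ys, zs = [], []
    for pt in c:
        if pt[1] <= 1e-12:
            ys.append(pt[0])
            zs.append(pt[1])
    for i, j in edges:
        zi, zj = c[i][1], c[j][1]
        if (zi > 0) != (zj > 0):
            t = zi / (zi - zj)
            ys.append(c[i][0] + t * (c[j][0] - c[i][0]))
            zs.append(0.0)
    return np.array(ys), np.array(zs)


def strip_rect_contained(T, da, r, theta_deg, length, H=None) -> bool:
    """Exact 2D test: does the submerged screw rectangle stay in the strip?"""
    ys, zs = _submerged_extremes(T, da, r, theta_deg, length)
    if len(ys) == 0:
        return True
    ok = (ys.min() >= -1e-9) and (ys.max() <= T + 1e-9)
    if H is not None:
        ok = ok and (zs.min() >= -H - 1e-9)
    return bool(ok)


def strip_max_tilt_sweep(T, da, r, length=14.0, sense="anterior",
                         H=None, step_deg=0.01) -> float:
    """Reference oracle: densest-grid sweep of the exact 2D containment test.

    Scans tilts from 0 upward in ``step_deg`` increments and returns the
    last feasible angle before the first violation (degrees, >= 0).
    """
    if 2 * r >= T:
        raise PhantomParameterError("no corridor: screw diameter >= strip thickness")
    da_eff = da if sense == "anterior" else T - da
    if not strip_rect_contained(T, da_eff, r, 0.0, length, H):
        raise PhantomParameterError("screw not contained even at zero tilt")
    theta = 0.0
    while theta < 90.0:
        nxt = theta + step_deg
        if not strip_rect_contained(T, da_eff, r, nxt, length, H):
            return theta
        theta = nxt
    return theta


def strip_max_tilt_closed(T, da, r, length=14.0, sense="anterior") -> float:
    """Closed-form maximal tilt toward one wall for a fixed-length screw.

    Two constraints bind as the screw tilts toward the near wall: the far
    bottom corner reaching the wall (l*sin(t) + r*cos(t) = d) and the
    screw edge's surface crossing reaching the wall (r/cos(t) = d),
    where d is the entry clearance to that wall. Deep strips only;
    the dense sweep is the reference when a bottom bound applies.
    """
    if 2 * r >= T:
        raise PhantomParameterError("no corridor: screw diameter >= strip thickness")
    d = da if sense == "anterior" else T - da
    if d < r:
        raise PhantomParameterError("entry is inside the wall clearance")
    hyp = math.hypot(length, r)
    t_tip = 90.0 if d >= hyp else (math.degrees(math.asin(d / hyp))
                                   - math.degrees(math.atan2(r, length)))
    t_surf = 0.0 if d <= r else math.degrees(math.acos(r / d))
    # the screw-edge/surface crossing only exists while the upper long
    # edge still dips below the surface (tilt < atan(l/r)); beyond that
    # the edge lifts clear and only the tip corner constrains
    if t_surf > math.degrees(math.atan2(length, r)):
        t_surf = 90.0
    return max(0.0, min(t_tip, t_surf))


def strip_max_length(T, da, r, theta_deg, H) -> float:
    """Closed-form maximal tangent screw length at a (feasible) tilt."""
    th = abs(theta_deg) * DEG
    d = da if theta_deg >= 0 else T - da
    bounds = [(H - r * math.sin(th)) / math.cos(th)]
    if math.sin(th) > 1e-12:
        bounds.append((d - r * math.cos(th)) / math.sin(th))
    return max(0.0, min(bounds))


def strip_phantom_oracle(T, da, r=1.75, length_policy="fixed-14",
                         length=14.0, H=None, method="sweep",
                         step_deg=0.01) -> GroundTruth:
    """Ground truth for the strip phantom's tangency searches.

    ``method='sweep'`` (the reference) uses the dense 0.01-degree sweep of
    the exact 2D rectangle-in-strip test; ``method='closed'`` uses the
    closed-form tangency solution (deep-strip assumption).
    """
    if 2 * r >= T:
        raise PhantomParameterError("no corridor: screw diameter >= strip thickness")
    if not (r <= da <= T - r):
        raise PhantomParameterError("entry must be at least one screw radius "
                                    "from each wall")
    ell = length if length_policy == "fixed-14" else 14.0
    if method == "sweep":
        maia = strip_max_tilt_sweep(T, da, r, ell, "anterior", H, step_deg)
        mpia = -strip_max_tilt_sweep(T, da, r, ell, "posterior", H, step_deg)
    else:
        maia = strip_max_tilt_closed(T, da, r, ell, "anterior")
        mpia = -strip_max_tilt_closed(T, da, r, ell, "posterior")
    return GroundTruth(
        maia_deg=maia, mpia_deg=mpia,
        max_length_mm=None if H is None else strip_max_length(T, da, r, 0.0, H),
        params=dict(T=T, da=da, r=r, length=ell, H=H, method=method),
    )


_BOX_FACES = np.array([
    [0, 2, 1], [0, 3, 2], [4, 5, 6], [4, 6, 7],
    [0, 1, 5], [0, 5, 4], [1, 2, 6], [1, 6, 5],
    [2, 3, 7], [2, 7, 6], [3, 0, 4], [3, 4, 7],
])


def generate_strip_phantom(spec: StripPhantomSpec):
    """Closed slab + landmarks + analytic ground truth.

    Axes: x medial->lateral (0..W), y anterior->posterior (0..T),
    z depth (top face at z = 0, bottom at -H). The brim runs along the
    posterior top edge, mirroring the plate-on-the-pelvic-boundary setup.
    """
    T, H, W = spec.thickness_T, spec.height_H, spec.width_W
    v = np.array([
        [0, 0, -H], [W, 0, -H], [W, T, -H], [0, T, -H],
        [0, 0, 0], [W, 0, 0], [W, T, 0], [0, T, 0],
    ], dtype=np.float64)
    mesh = trimesh.Trimesh(vertices=v, faces=_BOX_FACES.copy(), process=False)
    if mesh.volume < 0:
        mesh.invert()

    xs = np.linspace(0.0, W, 17)
    brim = np.column_stack([xs, np.full_like(xs, T), np.zeros_like(xs)])
    m_x = spec.m_position
    m_curve = np.column_stack([np.full(9, m_x), np.linspace(T, max(T - 10, 0), 9),
                               np.zeros(9)])
    loop = np.array([[W / 2 - 2, 0, -H / 2 - 2], [W / 2 + 2, 0, -H / 2 - 2],
                     [W / 2 + 2, 0, -H / 2 + 2], [W / 2 - 2, 0, -H / 2 + 2],
                     [W / 2 - 2, 0, -H / 2 - 2]], dtype=np.float64)
    ls = LandmarkSet(
        brim=brim,
        tubercle_edge_m=m_curve,
        symphysis_lowest_O=np.array([0.0, T / 2, -H]),
        symphysis_upper=np.array([0.0, T / 2, 0.0]),
        symphysis_lower=np.array([0.0, T / 2, -H]),
        obturator_loop=loop,
        tubercle_apex=np.array([max(m_x - 3, 0.5), T - 1.0, 0.0]),
    )
    gt = strip_phantom_oracle(T, spec.entry_offset_da, H=H)
    gt.entry_point = np.array([spec.entry_offset_dl, spec.entry_offset_da, 0.0])
    gt.max_length_mm = H
    gt.params.update(vars(spec))
    return mesh, ls, gt


# ---------------------------------------------------------------------------
# wedge phantom (safe-region classifier fixture)
# ---------------------------------------------------------------------------

def generate_wedge_phantom(apex_angle_deg: Optional[float], depth: float = 40.0,
                           top_halfwidth: float = 12.0, length: float = 60.0):
    """Prism whose anterior/posterior walls converge at ``apex_angle_deg``.

    ``apex_angle_deg=None`` builds parallel walls. Returns
    (mesh, axis, anterior_hint): the long axis (the direction a
    tangential screw would run) and the outward anterior direction.
    """
    if apex_angle_deg is None:
        bottom_half = top_halfwidth
    else:
        bottom_half = top_halfwidth - depth * math.tan(apex_angle_deg / 2 * DEG)
        if bottom_half < 0.5:
            depth = (top_halfwidth - 0.5) / math.tan(apex_angle_deg / 2 * DEG)
            bottom_half = 0.5
    w, b, D, L = top_halfwidth, bottom_half, depth, length
    v = np.array([
        [0, -w, 0], [0, w, 0], [0, b, -D], [0, -b, -D],
        [L, -w, 0], [L, w, 0], [L, b, -D], [L, -b, -D],
    ], dtype=np.float64)
    f = np.array([
        [0, 1, 2], [0, 2, 3], [4, 6, 5], [4, 7, 6],
        [0, 4, 5], [0, 5, 1], [1, 5, 6], [1, 6, 2],
        [2, 6, 7], [2, 7, 3], [3, 7, 4], [3, 4, 0],
    ])
    mesh = trimesh.Trimesh(vertices=v, faces=f, process=False)
    trimesh.repair.fix_normals(mesh)
    if mesh.volume < 0:
        mesh.invert()
    axis = np.array([1.0, 0.0, 0.0])
    anterior_hint = np.array([0.0, -1.0, 0.0])
    return mesh, axis, anterior_hint


# ---------------------------------------------------------------------------
# pubis phantom
# ---------------------------------------------------------------------------

@dataclass
class PubisPhantomSpec:
    """Idealised hemipubis: medial body + superior ramus + obturator hole.

    The symphyseal face lies in the x = 0 plane (the body midline), so the
    tubercle apex sits at x = intertubercular / 2. The anterior/posterior
    cortical walls are ``body_thickness * thickness_scale`` apart across
    the entry zone, thinning laterally to ``lateral_thickness`` — the
    medial-thick / lateral-thin gradient of the pubis. The corridor depth
    below the entry surface scales as ``depth_ratio * ramus_length`` so
    that overall bone size (and with it the attainable screw length)
    follows the ramus-length distribution.
    """

    intertubercular: float = 58.40
    symphysis_height: float = 41.82
    ramus_length: float = 55.0
    thickness_scale: float = 1.0
    body_thickness: float = 13.5
    lateral_thickness: float = 9.0
    obturator_radius: float = 9.0
    hole_top_depth: float = 17.0      # superior hole margin below the top surface
    tubercle_height: float = 4.0
    tubercle_sigma: float = 4.0
    anterior_slope: float = 0.04      # wall lean per mm of depth
    posterior_slope: float = 0.04
    anterior_waist: float = 3.0       # anterior cortex narrowing at waist_depth
    waist_depth: float = 12.0         # depth of the thinnest anterior clearance
    flare_start: float = 15.0         # depth where the body starts thickening
    anterior_flare: float = 0.5       # deep anterior bulge of the pubic body
    posterior_flare: float = 0.25
    bow: float = 2.0                  # posterior bowing of the ramus (mm)
    depth_ratio: float = 1.0          # corridor chord as a fraction of
                                      # ramus_length (inferior extent is
                                      # defined along the oblique corridor)
    resolution: float = 1.0           # >1 refines the mesh, <1 coarsens it
    seed: int = 0                     # recorded in manifests; generation is
                                      # deterministic given the spec alone

    def __post_init__(self):
        if min(self.intertubercular, self.symphysis_height, self.ramus_length,
               self.body_thickness, self.lateral_thickness) <= 0:
            raise PhantomParameterError("all phantom lengths must be positive")
        if self.body_thickness * self.thickness_scale < 4.0:
            raise PhantomParameterError("body thickness at the symphysis end "
                                        "must be at least 4 mm")
        if self.obturator_radius < 0:
            raise PhantomParameterError("obturator_radius must be >= 0")

    # derived stations -----------------------------------------------------
    @property
    def tubercle_x(self) -> float:
        return self.intertubercular / 2.0

    @property
    def m_x(self) -> float:
        """Outer (lateral) edge of the tubercle prominence."""
        return self.tubercle_x + self.tubercle_sigma + 1.0

    @property
    def lateral_extent(self) -> float:
        return self.tubercle_x + float(np.clip(0.8 * self.ramus_length, 42.0, 70.0))

    @property
    def corridor_obliquity_rad(self) -> float:
        """Predicted medial obliquity of the screw corridor: the OM line
        runs from the inner screw site (~intertubercular/2 + 11.5 mm
        lateral of the midline) down to the inferior symphysis point."""
        return math.atan2(self.intertubercular / 2.0 + 11.5,
                          self.symphysis_height)

    @property
    def hole_center(self):
        r = self.obturator_radius if self.obturator_radius > 0 else 9.0
        xc = self.m_x + 11.5 + r
        zc = self._z_top(xc) - self.hole_top_depth - r
        return xc, zc

    def _z_top(self, x):
        # gentle lateral taper of the superior surface
        return self.symphysis_height - 3.0 * np.asarray(x) / self.lateral_extent

    def _thickness(self, x):
        xc, _ = self.hole_center
        u = np.clip((np.asarray(x, float) - (xc - 2.0)) /
                    max(self.lateral_extent - (xc - 2.0), 1.0), 0.0, 1.0)
        s = u * u * (3 - 2 * u)
        return self.thickness_scale * (self.body_thickness
                                       + (self.lateral_thickness
                                          - self.body_thickness) * s)


def _outline(spec: PubisPhantomSpec):
    """Closed boundary polyline of the bone silhouette in the x-z plane.

    Returns (points(N,2), markers) with markers holding the index ranges
    of the top edge and the indices of key stations.
    """
    xmax = spec.lateral_extent
    xc, zc = spec.hole_center
    rs = spec.obturator_radius if spec.obturator_radius > 0 else 9.0
    hole_left, hole_right = xc - rs, xc + rs
    z_lat = zc - rs - 6.0
    z_top_entry = float(spec._z_top(spec.m_x + 13.0))
    # inferior extent of the pubic body, measured along the oblique
    # corridor (the inferior-ramus direction): the vertical dip is the
    # corridor chord times the cosine of the predicted obliquity
    depth = float(np.clip(spec.depth_ratio * spec.ramus_length
                          * math.cos(spec.corridor_obliquity_rad), 20.0, 60.0))
    z_deep = z_top_entry - depth

    step = 2.2 / spec.resolution
    xs_top = np.linspace(0.0, xmax, max(int(xmax / step), 12) + 1)
    xs_top = np.unique(np.concatenate(
        [xs_top, [spec.tubercle_x, spec.m_x]]))
    top = np.column_stack([xs_top, spec._z_top(xs_top)])

    # shape-preserving inferior boundary: symphysis bottom -> deep body
    # dip -> thin strip below the obturator -> lateral end
    cx = np.array([0.0, 10.0, hole_left - 6.0, hole_left, xc, hole_right, xmax])
    cz = np.array([0.0, z_deep, z_deep, z_lat, z_lat, z_lat, z_lat + 2.0])
    if not np.all(np.diff(cx) > 0):
        raise PhantomParameterError("phantom stations overlap; parameters "
                                    "produce a self-intersecting outline")
    z_bot = PchipInterpolator(cx, cz)
    xs_bot = np.linspace(xmax, 0.0, max(int(xmax / (3.5 / spec.resolution)), 10) + 1)

    right = np.column_stack([np.full(4, xmax),
                             np.linspace(spec._z_top(xmax), z_lat + 2.0, 6)[1:-1]])
    bottom = np.column_stack([xs_bot, z_bot(xs_bot)])
    left = np.column_stack([np.zeros(5),
                            np.linspace(0.0, spec.symphysis_height, 7)[1:-1]])
    pts = np.vstack([top, right, bottom, left])
    markers = {
        "top": np.arange(len(top)),
        "i_tubercle": int(np.argmin(np.abs(xs_top - spec.tubercle_x))),
        "i_m": int(np.argmin(np.abs(xs_top - spec.m_x))),
        "i_bottom_left": len(top) + len(right) + len(bottom) - 1,
        "i_top_left": 0,
        "z_bot": z_bot,
        "z_deep": z_deep,
    }
    return pts, markers


def generate_pubis_phantom(spec: PubisPhantomSpec, n_y: int = 2):
    """Build the watertight hemipubis mesh and its on-surface landmarks.

    Deterministic for a fixed spec: two calls return bitwise-identical
    vertex arrays. Raises :class:`PhantomParameterError` for parameter
    combinations that would self-intersect.
    """
    outline, mk = _outline(spec)
    xc, zc = spec.hole_center
    rs = spec.obturator_radius
    has_hole = rs > 0
    if has_hole:
        # hole must stay strictly inside the outline with margin
        top_at = float(spec._z_top(xc))
        if zc + rs > top_at - 4.0 or xc + rs > spec.lateral_extent - 4.0:
            raise PhantomParameterError("obturator hole would breach the cortex")

    N = len(outline)
    # angular pairing of outline and inner ring (outline is star-shaped
    # with respect to the hole centre by construction); radial layers
    # cluster near the outline so the wall profile (waist/flare) is
    # resolved in the entry zone below the superior surface
    phi = np.unwrap(np.arctan2(outline[:, 1] - zc, outline[:, 0] - xc))
    r0 = rs if has_hole else 0.9
    ring0 = np.column_stack([xc + r0 * np.cos(phi), zc + r0 * np.sin(phi)])
    frac = np.array([0.0, 0.35, 0.62, 0.80, 0.91, 1.0])
    layers = [ring0 + f * (outline - ring0) for f in frac]

    zt = spec._z_top  # noqa: E731  (used closure-style below)

    def embed(pts2d, f):
        """2D station + wall fraction f in [0,1] (0=anterior) -> 3D point.

        The anterior cortex narrows to a waist ~waist_depth below the
        superior surface (the thin supra-obturator shell) and flares
        anteriorly below flare_start (the thick inferomedial body), so
        the maximally anteverted screw is tangent at the waist and then
        runs the full corridor depth — the medial-thick / lateral-thin,
        deep-thick gradient of the pubis.
        """
        x = pts2d[:, 0]
        z = pts2d[:, 1]
        t = spec._thickness(x)
        depth = np.maximum(np.asarray(zt(x)) - z, 0.0)
        # the whole wall profile is expressed in corridor-distance units
        # (vertical depth divided by the predicted corridor obliquity's
        # cosine, referenced to 45 deg): waist, flare onset and slopes
        # then act at fixed distances ALONG the screw path, so the
        # tangency angle of a maximally anteverted screw depends on the
        # waist amplitude and entry clearance, not on pelvis obliquity
        d_eff = depth * (math.cos(math.pi / 4.0)
                         / math.cos(spec.corridor_obliquity_rad))
        waist = spec.anterior_waist * (d_eff / spec.waist_depth) * np.exp(
            1.0 - d_eff / spec.waist_depth)
        dw = d_eff - spec.flare_start
        uf = np.clip(dw / 10.0, 0.0, 1.0)
        ramp = np.maximum(dw, 0.0) * uf * uf * (3 - 2 * uf)
        y_ant = -t / 2.0 - (spec.anterior_slope * d_eff
                            + spec.anterior_flare * ramp - waist)
        y_post = t / 2.0 + (spec.posterior_slope * d_eff
                            + spec.posterior_flare * ramp)
        y = y_ant + f * (y_post - y_ant) + spec.bow * np.sin(
            math.pi * x / spec.lateral_extent)
        # tubercle bump: raises the top 8 mm of the surface near tubercle_x
        u = np.clip((z - (np.asarray(zt(x)) - 8.0)) / 8.0, 0.0, 1.0)
        bump = spec.tubercle_height * np.exp(
            -0.5 * ((x - spec.tubercle_x) / spec.tubercle_sigma) ** 2)
        return np.column_stack([x, y, z + bump * u * u * (3 - 2 * u)])

    fs = np.linspace(0.0, 1.0, n_y + 1)
    n_lay = len(layers)
    verts: list = []
    faces: list = []

    def quad(a, b, c, d):
        faces.append([a, b, c])
        faces.append([a, c, d])

    # ring0 and the outline carry every y-layer (they become walls);
    # intermediate rings only exist on the two faces (f = 0 and f = 1)
    idx_inner = np.empty((N, n_y + 1), dtype=int)
    idx_outer = np.empty((N, n_y + 1), dtype=int)
    for j, f in enumerate(fs):
        idx_inner[:, j] = len(verts) + np.arange(N)
        verts.extend(embed(layers[0], f))
        idx_outer[:, j] = len(verts) + np.arange(N)
        verts.extend(embed(layers[-1], f))
    face_rings = {}
    for side, f in (("a", 0.0), ("p", 1.0)):
        rings = [idx_inner[:, 0] if side == "a" else idx_inner[:, n_y]]
        for lay in layers[1:-1]:
            rings.append(len(verts) + np.arange(N))
            verts.extend(embed(lay, f))
        rings.append(idx_outer[:, 0] if side == "a" else idx_outer[:, n_y])
        face_rings[side] = rings

    nxt = np.roll(np.arange(N), -1)
    for i in range(N):
        k = nxt[i]
        for l in range(n_lay - 1):
            ra, rb = face_rings["a"][l], face_rings["a"][l + 1]
            quad(ra[i], ra[k], rb[k], rb[i])
            ra, rb = face_rings["p"][l], face_rings["p"][l + 1]
            quad(rb[i], rb[k], ra[k], ra[i])
        for j in range(n_y):
            quad(idx_outer[i, j], idx_outer[k, j],
                 idx_outer[k, j + 1], idx_outer[i, j + 1])
            if has_hole:
                quad(idx_inner[k, j], idx_inner[i, j],
                     idx_inner[i, j + 1], idx_inner[k, j + 1])
    if not has_hole:
        # cap the tiny inner ring with a fan on both faces
        for side, col, flip in (("a", 0, False), ("p", n_y, True)):
            c = len(verts)
            verts.extend(embed(np.array([[xc, zc]]), 0.0 if side == "a" else 1.0))
            ring = idx_inner[:, col]
            for i in range(N):
                k = nxt[i]
                tri = [c, ring[i], ring[k]]
                faces.append(tri[::-1] if flip else tri)

    mesh = trimesh.Trimesh(vertices=np.array(verts), faces=np.array(faces),
                           process=False)
    trimesh.repair.fix_normals(mesh)
    if mesh.is_watertight and mesh.volume < 0:
        mesh.invert()
    V = mesh.vertices.view(np.ndarray)

    mid_j = n_y // 2
    top_idx = mk["top"]
    brim = V[idx_outer[top_idx, n_y]]              # posterior top edge, medial->lateral
    m_wall = V[idx_outer[mk["i_m"], :]]            # across the top surface at m_x
    apex = V[idx_outer[mk["i_tubercle"], mid_j]]
    sym_up = V[idx_outer[mk["i_top_left"], mid_j]]

    # lowest symphysis point, vertically below the upper landmark: pick
    # the wall fraction whose embedded y matches (the deep anterior
    # flare skews the naive mid-wall point anteriorly); the point lies
    # on a wall-quad edge, hence exactly on the surface
    def _wall_point_at_y(station_2d, y_target):
        ya = float(embed(station_2d, 0.0)[0, 1])
        yp = float(embed(station_2d, 1.0)[0, 1])
        f = min(max((y_target - ya) / (yp - ya), 0.0), 1.0)
        return embed(station_2d, f)[0]

    i_bl = mk["i_bottom_left"]
    bl_station = outline[i_bl:i_bl + 1]
    sym_lo = _wall_point_at_y(bl_station, float(sym_up[1]))
    if has_hole:
        loop = V[idx_inner[:, 0]]
        loop = np.vstack([loop, loop[:1]])
    else:
        c = np.array([xc, zc])
        ring = np.column_stack([c[0] + 3 * np.cos(np.linspace(0, 2 * math.pi, 13)),
                                c[1] + 3 * np.sin(np.linspace(0, 2 * math.pi, 13))])
        loop = embed(ring, 0.0)
    ls = LandmarkSet(
        brim=brim,
        tubercle_edge_m=m_wall,
        symphysis_lowest_O=sym_lo.copy(),
        symphysis_upper=sym_up.copy(),
        symphysis_lower=sym_lo.copy(),
        obturator_loop=loop,
        tubercle_apex=apex.copy(),
        contralateral_tubercle_apex=apex * np.array([-1.0, 1.0, 1.0]),
    )
    return mesh, ls


# ---------------------------------------------------------------------------
# cohort sampling
# ---------------------------------------------------------------------------

#: per-sex (mean, sd) of the sampled morphometric parameters (mm / unitless)
DEFAULT_DISTRIBUTIONS = {
    "male": {
        "intertubercular": (58.40, 6.03),
        "symphysis_height": (41.82, 4.65),
        "ramus_length": (55.0, 6.36),
        "thickness_scale": (1.0, 0.10),
        "wall_slope": (0.04, 0.05),
        "anterior_waist": (2.8, 2.0),
        "waist_depth": (12.0, 2.5),
    },
    "female": {
        "intertubercular": (61.98, 9.04),
        "symphysis_height": (39.85, 3.26),
        "ramus_length": (48.0, 8.65),
        "thickness_scale": (1.0, 0.10),
        "wall_slope": (0.04, 0.05),
        "anterior_waist": (2.8, 2.0),
        "waist_depth": (12.0, 2.5),
    },
}

#: hard safety clips keeping sampled phantoms constructible in the tails
_CLIPS = {
    "intertubercular": (44.0, 88.0),
    "symphysis_height": (30.0, 54.0),
    "ramus_length": (22.0, 86.0),
    "thickness_scale": (0.85, 1.25),
    "wall_slope": (-0.04, 0.15),
    "anterior_waist": (0.2, 5.5),
    "waist_depth": (7.0, 18.0),
}


@dataclass
class CohortSpec:
    """A virtual study population: per-sex counts + parameter normals."""

    n_male: int = 40
    n_female: int = 40
    seed: int = 0
    distributions: dict = field(
        default_factory=lambda: {s: dict(d) for s, d in
                                 DEFAULT_DISTRIBUTIONS.items()})
    resolution: float = 1.0

    def __post_init__(self):
        if self.n_male < 1 or self.n_female < 1:
            raise PhantomParameterError("need at least one subject per sex")
        for sex, table in self.distributions.items():
            for key, (_, sd) in table.items():
                if sd <= 0:
                    raise PhantomParameterError(
                        f"sd for {sex}/{key} must be positive")


@dataclass
class CohortSubject:
    subject_id: str
    sex: str
    spec: PubisPhantomSpec


def draw_subject_spec(rng, table: dict, resolution: float = 1.0,
                      seed: int = 0) -> PubisPhantomSpec:
    """One subject's phantom spec from a parameter table and a generator.

    Draws each parameter in a fixed order (so two generators with the
    same state produce common-random-number pairs across tables), clips
    to construction-safe ranges, and enforces the joint-tail validity
    constraint: the anterior waist may not consume the whole entry
    clearance (thin walls + inward slope + deep waist would leave no
    corridor even at the reference direction, violating the phantom's
    own invariant).
    """
    draw = {}
    for key in ("intertubercular", "symphysis_height", "ramus_length",
                "thickness_scale", "wall_slope", "anterior_waist",
                "waist_depth"):
        mean, sd = table[key]
        lo, hi = _CLIPS[key]
        draw[key] = float(np.clip(rng.normal(mean, sd), lo, hi))
    slope2 = float(np.clip(rng.normal(*table["wall_slope"]),
                           *_CLIPS["wall_slope"]))
    clearance = (13.5 * draw["thickness_scale"] - 5.0) - 1.79 \
        + 12.0 * draw["wall_slope"] - 0.8
    draw["anterior_waist"] = min(draw["anterior_waist"], clearance)
    return PubisPhantomSpec(
        intertubercular=draw["intertubercular"],
        symphysis_height=draw["symphysis_height"],
        ramus_length=draw["ramus_length"],
        thickness_scale=draw["thickness_scale"],
        anterior_slope=draw["wall_slope"],
        posterior_slope=slope2,
        anterior_waist=draw["anterior_waist"],
        waist_depth=draw["waist_depth"],
        resolution=resolution,
        seed=seed,
    )


def sample_cohort(spec: CohortSpec) -> list[CohortSubject]:
    """Draw per-subject phantom parameters from the per-sex normals.

    Reproducible: subject ``i`` uses the substream ``seed + i``, so the
    same spec and seed always yield the same manifest. Sampled values are
    clipped to construction-safe ranges (see module docs).
    """
    subjects = []
    i = 0
    for sex, n in (("male", spec.n_male), ("female", spec.n_female)):
        table = spec.distributions[sex]
        for k in range(n):
            ps = draw_subject_spec(np.random.default_rng(spec.seed + i),
                                   table, spec.resolution, spec.seed + i)
            subjects.append(CohortSubject(f"{sex[0].upper()}{k + 1:03d}", sex, ps))
            i += 1
    return subjects


def cohort_manifest(subjects: list[CohortSubject]):
    """Cohort parameters as a pandas DataFrame (one row per subject)."""
    import pandas as pd

    rows = []
    for s in subjects:
        row = {"subject_id": s.subject_id, "sex": s.sex}
        row.update(vars(s.spec))
        rows.append(row)
    return pd.DataFrame(rows)
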