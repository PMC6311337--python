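"""Low-level geometric kernels for corridor analysis.

Everything in this module is coordinate-free numerics on raw arrays:
point-in-mesh queries via the generalized winding number, exact
point-to-triangle distances, cylinder surface sampling, polyline
arc-length bookkeeping and small plane/rotation helpers.

The winding-number inside test is robust for watertight meshes (no
ray/edge degeneracies) and is the workhorse of every containment
search, so it is JIT-compiled with numba when available; a vectorised
numpy fallback keeps the package functional without it.
"""

from __future__ import annotations

import math

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore
        def wrap(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return wrap


_FOUR_PI = 4.0 * math.pi


# ---------------------------------------------------------------------------
# winding number / inside test
# ---------------------------------------------------------------------------

@njit(cache=False, fastmath=True)
def _winding_kernel(points, v0, v1, v2):  # pragma: no cover - numba path
    n = points.shape[0]
    m = v0.shape[0]
    out = np.empty(n, dtype=np.float64)
    for i in range(n):
        px = points[i, 0]
        py = points[i, 1]
        pz = points[i, 2]
        acc = 0.0
        for j in range(m):
            ax = v0[j, 0] - px
            ay = v0[j, 1] - py
            az = v0[j, 2] - pz
            bx = v1[j, 0] - px
            by = v1[j, 1] - py
            bz = v1[j, 2] - pz
            cx = v2[j, 0] - px
            cy = v2[j, 1] - py
            cz = v2[j, 2] - pz
            la = math.sqrt(ax * ax + ay * ay + az * az)
            lb = math.sqrt(bx * bx + by * by + bz * bz)
            lc = math.sqrt(cx * cx + cy * cy + cz * cz)
            # triple product a . (b x c)
            num = (ax * (by * cz - bz * cy)
                   + ay * (bz * cx - bx * cz)
                   + az * (bx * cy - by * cx))
            den = (la * lb * lc
                   + (ax * bx + ay * by + az * bz) * lc
                   + (bx * cx + by * cy + bz * cz) * la
                   + (ax * cx + ay * cy + az * cz) * lb)
            acc += 2.0 * math.atan2(num, den)
        out[i] = acc / _FOUR_PI
    return out


def _winding_numpy(points: np.ndarray, v0, v1, v2) -> np.ndarray:
    out = np.empty(len(points), dtype=np.float64)
    # chunk over points to bound the (chunk, faces) intermediates
    chunk = max(1, int(4e6 // max(len(v0), 1)))
    for s in range(0, len(points), chunk):
        p = points[s:s + chunk, None, :]
        a = v0[None, :, :] - p
        b = v1[None, :, :] - p
        c = v2[None, :, :] - p
        la = np.linalg.norm(a, axis=2)
        lb = np.linalg.norm(b, axis=2)
        lc = np.linalg.norm(c, axis=2)
        num = np.einsum("ijk,ijk->ij", a, np.cross(b, c))
        den = (la * lb * lc
               + np.einsum("ijk,ijk->ij", a, b) * lc
               + np.einsum("ijk,ijk->ij", b, c) * la
               + np.einsum("ijk,ijk->ij", a, c) * lb)
        out[s:s + chunk] = np.arctan2(num, den).sum(axis=1) * 2.0 / _FOUR_PI
    return out


# ---------------------------------------------------------------------------
# point-to-triangle distance (Ericson's closest-point construction)
# ---------------------------------------------------------------------------

@njit(cache=False, fastmath=True)
def _dist_kernel(points, v0, v1, v2):  # pragma: no cover - numba path
    n = points.shape[0]
    m = v0.shape[0]
    out = np.empty(n, dtype=np.float64)
    for i in range(n):
        px = points[i, 0]
        py = points[i, 1]
        pz = points[i, 2]
        best = 1e300
        for j in range(m):
            ax = v0[j, 0]
            ay = v0[j, 1]
            az = v0[j, 2]
            abx = v1[j, 0] - ax
            aby = v1[j, 1] - ay
            abz = v1[j, 2] - az
            acx = v2[j, 0] - ax
            acy = v2[j, 1] - ay
            acz = v2[j, 2] - az
            apx = px - ax
            apy = py - ay
            apz = pz - az
            d1 = abx * apx + aby * apy + abz * apz
            d2 = acx * apx + acy * apy + acz * apz
            if d1 <= 0.0 and d2 <= 0.0:
                qx, qy, qz = ax, ay, az
            else:
                bpx = px - v1[j, 0]
                bpy = py - v1[j, 1]
                bpz = pz - v1[j, 2]
                d3 = abx * bpx + aby * bpy + abz * bpz
                d4 = acx * bpx + acy * bpy + acz * bpz
                if d3 >= 0.0 and d4 <= d3:
                    qx, qy, qz = v1[j, 0], v1[j, 1], v1[j, 2]
                else:
                    vc = d1 * d4 - d3 * d2
                    if vc <= 0.0 and d1 >= 0.0 and d3 <= 0.0:
                        t = d1 / (d1 - d3)
                        qx = ax + t * abx
                        qy = ay + t * aby
                        qz = az + t * abz
                    else:
                        cpx = px - v2[j, 0]
                        cpy = py - v2[j, 1]
                        cpz = pz - v2[j, 2]
                        d5 = abx * cpx + aby * cpy + abz * cpz
                        d6 = acx * cpx + acy * cpy + acz * cpz
                        if d6 >= 0.0 and d5 <= d6:
                            qx, qy, qz = v2[j, 0], v2[j, 1], v2[j, 2]
                        else:
                            vb = d5 * d2 - d1 * d6
                            if vb <= 0.0 and d2 >= 0.0 and d6 <= 0.0:
                                t = d2 / (d2 - d6)
                                qx = ax + t * acx
                                qy = ay + t * acy
                                qz = az + t * acz
                            else:
                                va = d3 * d6 - d5 * d4
                                if va <= 0.0 and (d4 - d3) >= 0.0 and (d5 - d6) >= 0.0:
                                    t = (d4 - d3) / ((d4 - d3) + (d5 - d6))
                                    qx = v1[j, 0] + t * (v2[j, 0] - v1[j, 0])
                                    qy = v1[j, 1] + t * (v2[j, 1] - v1[j, 1])
                                    qz = v1[j, 2] + t * (v2[j, 2] - v1[j, 2])
                                else:
                                    denom = 1.0 / (va + vb + vc)
                                    v = vb * denom
                                    w = vc * denom
                                    qx = ax + abx * v + acx * w
                                    qy = ay + aby * v + acy * w
                                    qz = az + abz * v + acz * w
            dx = px - qx
            dy = py - qy
            dz = pz - qz
            d = dx * dx + dy * dy + dz * dz
            if d < best:
                best = d
        out[i] = math.sqrt(best)
    return out


def _closest_on_triangles(points: np.ndarray, v0, v1, v2):
    """Vectorised closest point on each triangle for every query point.

    Returns (distances, closest_points) with shapes (n,), (n, 3).
    numpy-only; used for the (rarer) queries that need the foot point.
    """
    n = len(points)
    m = len(v0)
    best_d = np.full(n, np.inf)
    best_q = np.zeros((n, 3))
    chunk = max(1, int(2e6 // max(m, 1)))
    ab = v1 - v0
    ac = v2 - v0
    for s in range(0, n, chunk):
        p = points[s:s + chunk]
        ap = p[:, None, :] - v0[None, :, :]
        d1 = np.einsum("jk,ijk->ij", ab, ap)
        d2 = np.einsum("jk,ijk->ij", ac, ap)
        bp = p[:, None, :] - v1[None, :, :]
        d3 = np.einsum("jk,ijk->ij", ab, bp)
        d4 = np.einsum("jk,ijk->ij", ac, bp)
        cp = p[:, None, :] - v2[None, :, :]
        d5 = np.einsum("jk,ijk->ij", ab, cp)
        d6 = np.einsum("jk,ijk->ij", ac, cp)
        vc = d1 * d4 - d3 * d2
        vb = d5 * d2 - d1 * d6
        va = d3 * d6 - d5 * d4
        with np.errstate(divide="ignore", invalid="ignore"):
            t_ab = np.clip(d1 / (d1 - d3), 0, 1)
            t_ac = np.clip(d2 / (d2 - d6), 0, 1)
            t_bc = np.clip((d4 - d3) / ((d4 - d3) + (d5 - d6)), 0, 1)
            denom = va + vb + vc
            v = vb / denom
            w = vc / denom
        q = v0[None, :, :] + v[..., None] * ab[None, :, :] + w[..., None] * ac[None, :, :]
        # region overrides, applied in priority order (interior last)
        on_bc = (va <= 0) & ((d4 - d3) >= 0) & ((d5 - d6) >= 0)
        q_bc = v1[None, :, :] + t_bc[..., None] * (v2 - v1)[None, :, :]
        q = np.where(on_bc[..., None], q_bc, q)
        on_ac = (vb <= 0) & (d2 >= 0) & (d6 <= 0)
        q_ac = v0[None, :, :] + t_ac[..., None] * ac[None, :, :]
        q = np.where(on_ac[..., None], q_ac, q)
        on_ab = (vc <= 0) & (d1 >= 0) & (d3 <= 0)
        q_ab = v0[None, :, :] + t_ab[..., None] * ab[None, :, :]
        q = np.where(on_ab[..., None], q_ab, q)
        at_c = (d6 >= 0) & (d5 <= d6)
        q = np.where(at_c[..., None], v2[None, :, :], q)
        at_b = (d3 >= 0) & (d4 <= d3)
        q = np.where(at_b[..., None], v1[None, :, :], q)
        at_a = (d1 <= 0) & (d2 <= 0)
        q = np.where(at_a[..., None], v0[None, :, :], q)
        d = np.linalg.norm(p[:, None, :] - q, axis=2)
        j = np.argmin(d, axis=1)
        idx = np.arange(len(p))
        best_d[s:s + chunk] = d[idx, j]
        best_q[s:s + chunk] = q[idx, j]
    return best_d, best_q


def point_to_triangles_distance(p, v0, v1, v2) -> np.ndarray:
    """Exact distance from one point to every triangle (m,)."""
    p = np.asarray(p, dtype=np.float64)
    d, _ = _closest_on_triangles_full(p[None, :], v0, v1, v2)
    return d[0]


def _closest_on_triangles_full(points, v0, v1, v2):
    """(n, m) distances and closest points from points to all triangles."""
    ab = v1 - v0
    ac = v2 - v0
    ap = points[:, None, :] - v0[None, :, :]
    d1 = np.einsum("jk,ijk->ij", ab, ap)
    d2 = np.einsum("jk,ijk->ij", ac, ap)
    bp = points[:, None, :] - v1[None, :, :]
    d3 = np.einsum("jk,ijk->ij", ab, bp)
    d4 = np.einsum("jk,ijk->ij", ac, bp)
    cp = points[:, None, :] - v2[None, :, :]
    d5 = np.einsum("jk,ijk->ij", ab, cp)
    d6 = np.einsum("jk,ijk->ij", ac, cp)
    vc = d1 * d4 - d3 * d2
    vb = d5 * d2 - d1 * d6
    va = d3 * d6 - d5 * d4
    with np.errstate(divide="ignore", invalid="ignore"):
        t_ab = np.clip(d1 / (d1 - d3), 0, 1)
        t_ac = np.clip(d2 / (d2 - d6), 0, 1)
        t_bc = np.clip((d4 - d3) / ((d4 - d3) + (d5 - d6)), 0, 1)
        denom = va + vb + vc
        v = vb / denom
        w = vc / denom
    q = v0[None, :, :] + v[..., None] * ab[None, :, :] + w[..., None] * ac[None, :, :]
    on_bc = (va <= 0) & ((d4 - d3) >= 0) & ((d5 - d6) >= 0)
    q = np.where(on_bc[..., None],
                 v1[None, :, :] + t_bc[..., None] * (v2 - v1)[None, :, :], q)
    on_ac = (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    q = np.where(on_ac[..., None],
                 v0[None, :, :] + t_ac[..., None] * ac[None, :, :], q)
    on_ab = (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    q = np.where(on_ab[..., None],
                 v0[None, :, :] + t_ab[..., None] * ab[None, :, :], q)
    q = np.where(((d6 >= 0) & (d5 <= d6))[..., None], v2[None, :, :], q)
    q = np.where(((d3 >= 0) & (d4 <= d3))[..., None], v1[None, :, :], q)
    q = np.where(((d1 <= 0) & (d2 <= 0))[..., None], v0[None, :, :], q)
    d = np.linalg.norm(points[:, None, :] - q, axis=2)
    return d, q


class MeshQuery:
    """Fast repeated geometric queries against one triangulated surface.

    Caches the triangle vertex arrays of a watertight mesh so that
    thousands of containment / distance calls during an angle search
    do not touch trimesh internals.
    """

    def __init__(self, mesh):
        tri = np.asarray(mesh.triangles, dtype=np.float64)
        self.v0 = np.ascontiguousarray(tri[:, 0])
        self.v1 = np.ascontiguousarray(tri[:, 1])
        self.v2 = np.ascontiguousarray(tri[:, 2])
        self.mesh = mesh

    def winding(self, points: np.ndarray) -> np.ndarray:
        points = np.ascontiguousarray(np.atleast_2d(points), dtype=np.float64)
        if _HAVE_NUMBA:
            return _winding_kernel(points, self.v0, self.v1, self.v2)
        return _winding_numpy(points, self.v0, self.v1, self.v2)

    def contains(self, points: np.ndarray) -> np.ndarray:
        return self.winding(points) > 0.5

    def distance(self, points: np.ndarray) -> np.ndarray:
        """Unsigned distance to the surface."""
        points = np.ascontiguousarray(np.atleast_2d(points), dtype=np.float64)
        if _HAVE_NUMBA:
            return _dist_kernel(points, self.v0, self.v1, self.v2)
        return _closest_on_triangles(points, self.v0, self.v1, self.v2)[0]

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        """Positive inside, negative outside (mm)."""
        points = np.atleast_2d(points)
        d = self.distance(points)
        sign = np.where(self.contains(points), 1.0, -1.0)
        return d * sign

    def closest_points(self, points: np.ndarray):
        """(distances, foot points) of the closest surface points."""
        points = np.ascontiguousarray(np.atleast_2d(points), dtype=np.float64)
        return _closest_on_triangles(points, self.v0, self.v1, self.v2)

    def ray_exit(self, origin, direction):
        """Farthest mesh intersection along ``direction`` from ``origin``.

        Returns (distance, unit normal of the hit face); (0.0, None) if
        the ray hits nothing. Moller-Trumbore over all faces.
        """
        o = np.asarray(origin, dtype=np.float64)
        d = unit(direction)
        e1 = self.v1 - self.v0
        e2 = self.v2 - self.v0
        p = np.cross(d[None, :], e2)
        det = np.einsum("ij,ij->i", e1, p)
        ok = np.abs(det) > 1e-12
        inv = np.where(ok, 1.0 / np.where(ok, det, 1.0), 0.0)
        s = o[None, :] - self.v0
        u = np.einsum("ij,ij->i", s, p) * inv
        q = np.cross(s, e1)
        v = np.einsum("j,ij->i", d, q) * inv
        t = np.einsum("ij,ij->i", e2, q) * inv
        hit = ok & (u >= -1e-9) & (v >= -1e-9) & (u + v <= 1 + 1e-9) & (t > 1e-6)
        if not hit.any():
            return 0.0, None
        i = int(np.flatnonzero(hit)[np.argmax(t[hit])])
        n = np.cross(e1[i], e2[i])
        return float(t[hit].max()), n / np.linalg.norm(n)

    def ray_exit_length(self, origin, direction) -> float:
        return self.ray_exit(origin, direction)[0]

    def surface_normal(self, point: np.ndarray, patch_radius: float = 2.0) -> np.ndarray:
        """Outward unit normal near ``point``, area-averaged over faces whose
        centroid lies within ``patch_radius`` mm (stabilises faceted meshes)."""
        centroids = (self.v0 + self.v1 + self.v2) / 3.0
        d = np.linalg.norm(centroids - np.asarray(point, float), axis=1)
        sel = d < patch_radius
        if not sel.any():
            sel = d <= d.min() + 1e-9
        n = np.cross(self.v1[sel] - self.v0[sel], self.v2[sel] - self.v0[sel])
        total = n.sum(axis=0)
        norm = np.linalg.norm(total)
        if norm < 1e-12:
            raise ValueError("degenerate surface patch: zero mean normal")
        return total / norm


# ---------------------------------------------------------------------------
# cylinder sampling
# ---------------------------------------------------------------------------

def cylinder_surface_points(entry, axis, radius, length,
                            n_axial: int = 24, n_circ: int = 32,
                            n_cap: int = 16,
                            clip_plane=None) -> np.ndarray:
    """Sample the lateral surface + tip-cap of a cylinder.

    ``clip_plane`` is an optional (point, outward_normal) pair; samples on
    the strictly positive side of the plane (above the entry cortex, i.e.
    the protruding screw head) are dropped — the countersunk-head
    convention used by every containment test in this package.
    """
    entry = np.asarray(entry, float)
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    u, v = plane_basis(axis)
    t = np.linspace(0.0, length, n_axial)
    ang = np.arange(n_circ) * (2.0 * math.pi / n_circ)
    ring = radius * (np.outer(np.cos(ang), u) + np.outer(np.sin(ang), v))
    pts = (entry[None, None, :]
           + t[:, None, None] * axis[None, None, :]
           + ring[None, :, :]).reshape(-1, 3)
    if n_cap:
        rr = radius * np.sqrt(np.linspace(0.15, 0.85, max(1, n_cap // 8)))
        cang = np.arange(8) * (2.0 * math.pi / 8)
        cap = (entry[None, :] + length * axis[None, :]
               + (np.outer(np.cos(cang), u)[None, :, :]
                  * rr[:, None, None]).reshape(-1, 3)
               + (np.outer(np.sin(cang), v)[None, :, :]
                  * rr[:, None, None]).reshape(-1, 3))
        tip = entry + length * axis
        pts = np.vstack([pts, cap, tip[None, :]])
    if clip_plane is not None:
        p0, n0 = clip_plane
        keep = (pts - np.asarray(p0, float)) @ np.asarray(n0, float) <= 1e-9
        pts = pts[keep]
    return pts


# ---------------------------------------------------------------------------
# planes, angles, rotations
# ---------------------------------------------------------------------------

def unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=np.float64)
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ValueError("cannot normalise a zero vector")
    return v / n


def plane_basis(normal):
    """Two orthonormal vectors spanning the plane with the given normal."""
    n = unit(normal)
    a = np.array([1.0, 0.0, 0.0])
    if abs(n @ a) > 0.9:
        a = np.array([0.0, 1.0, 0.0])
    u = unit(np.cross(n, a))
    v = np.cross(n, u)
    return u, v


def project_to_plane(v, normal) -> np.ndarray:
    n = unit(normal)
    v = np.asarray(v, dtype=np.float64)
    return v - (v @ n) * n


def in_plane_angle(a, b, normal) -> float:
    """Signed angle (degrees) from a to b measured within the plane,
    positive counter-clockwise about ``normal``."""
    n = unit(normal)
    ap = unit(project_to_plane(a, n))
    bp = unit(project_to_plane(b, n))
    s = np.cross(ap, bp) @ n
    c = float(np.clip(ap @ bp, -1.0, 1.0))
    return math.degrees(math.atan2(float(s), c))


def rotate_about(v, axis, angle_deg) -> np.ndarray:
    """Rodrigues rotation of v about a unit axis by angle (degrees)."""
    k = unit(axis)
    v = np.asarray(v, dtype=np.float64)
    th = math.radians(angle_deg)
    return (v * math.cos(th)
            + np.cross(k, v) * math.sin(th)
            + k * (k @ v) * (1.0 - math.cos(th)))


# ---------------------------------------------------------------------------
# polylines
# ---------------------------------------------------------------------------

def polyline_lengths(points: np.ndarray) -> np.ndarray:
    """Cumulative chord length along a polyline, starting at 0."""
    points = np.asarray(points, dtype=np.float64)
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def point_at_arc_length(points: np.ndarray, s: float) -> np.ndarray:
    """Point at chord-accumulated arc length ``s`` along a polyline."""
    points = np.asarray(points, dtype=np.float64)
    cum = polyline_lengths(points)
    if s < -1e-9 or s > cum[-1] + 1e-9:
        raise ValueError(
            f"arc length {s:.3f} outside polyline range [0, {cum[-1]:.3f}]")
    s = min(max(s, 0.0), cum[-1])
    i = int(np.searchsorted(cum, s, side="right") - 1)
    i = min(i, len(points) - 2)
    seg = cum[i + 1] - cum[i]
    t = 0.0 if seg < 1e-15 else (s - cum[i]) / seg
    return points[i] * (1 - t) + points[i + 1] * t


def resample_polyline(points: np.ndarray, step: float) -> np.ndarray:
    """Resample at (approximately) uniform chord spacing ``step``."""
    cum = polyline_lengths(points)
    total = cum[-1]
    n = max(2, int(round(total / step)) + 1)
    s_new = np.linspace(0.0, total, n)
    return np.array([point_at_arc_length(points, s) for s in s_new])


def points_to_polyline_distance(queries: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Distance from each query point to a polyline (vectorised)."""
    pts = np.asarray(points, dtype=np.float64)
    q = np.atleast_2d(np.asarray(queries, dtype=np.float64))
    a = pts[:-1]
    ab = pts[1:] - a
    denom = np.einsum("ij,ij->i", ab, ab)
    denom[denom < 1e-30] = 1e-30
    ap = q[:, None, :] - a[None, :, :]
    t = np.clip(np.einsum("qij,ij->qi", ap, ab) / denom, 0.0, 1.0)
    proj = a[None, :, :] + t[..., None] * ab[None, :, :]
    d = np.linalg.norm(proj - q[:, None, :], axis=2)
    return d.min(axis=1)


def closest_point_on_polyline(points: np.ndarray, query) -> tuple[np.ndarray, float]:
    """Closest point on the polyline to ``query`` and its arc position."""
    pts = np.asarray(points, dtype=np.float64)
    q = np.asarray(query, dtype=np.float64)
    a = pts[:-1]
    b = pts[1:]
    ab = b - a
    denom = np.einsum("ij,ij->i", ab, ab)
    denom[denom < 1e-30] = 1e-30
    t = np.clip(np.einsum("ij,ij->i", q[None, :] - a, ab) / denom, 0.0, 1.0)
    proj = a + t[:, None] * ab
    d = np.linalg.norm(proj - q, axis=1)
    i = int(np.argmin(d))
    cum = polyline_lengths(pts)
    return proj[i], float(cum[i] + t[i] * np.linalg.norm(ab[i]))
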