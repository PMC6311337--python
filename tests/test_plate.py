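"""Offset brim curve and insertion points S, M, L."""

import numpy as np
import pytest
import trimesh

from pubicorridor import (PlateGeometryError, PlateSpec, locate_insertion_points,
                          offset_brim_curve)
from pubicorridor.geometry import (points_to_polyline_distance,
                                   polyline_lengths, resample_polyline)


def test_offset_on_planar_face_is_exact_translation(strip_default):
    mesh, ls, _ = strip_default
    offs = offset_brim_curve(mesh, ls.brim, offset=5.0,
                             interior_hint=[20.0, 10.0, 0.0])
    expect = ls.brim + np.array([0.0, -5.0, 0.0])
    assert np.allclose(offs, expect, atol=1e-6)


def test_offset_zero_is_identity(strip_default):
    mesh, ls, _ = strip_default
    assert np.allclose(offset_brim_curve(mesh, ls.brim, 0.0), ls.brim)


def test_offset_too_large_falls_off_the_bone(strip_default):
    mesh, ls, _ = strip_default
    with pytest.raises(PlateGeometryError, match="station"):
        offset_brim_curve(mesh, ls.brim, offset=35.0,
                          interior_hint=[20.0, 10.0, 0.0])


def test_offset_distance_held_on_curved_phantom(pubis_default):
    """Each offset point sits ~5 mm (surface distance) from the brim."""
    mesh, lm = pubis_default
    hint = lm.tubercle_edge_m.mean(axis=0)
    offs = offset_brim_curve(mesh, lm.brim, 5.0, interior_hint=hint)
    d = points_to_polyline_distance(offs, lm.brim)
    # chordal distance slightly under-measures the geodesic on the bump
    assert d.min() > 4.6 and d.max() < 5.2


def test_insertion_points_on_strip(strip_default):
    mesh, ls, _ = strip_default
    offs = offset_brim_curve(mesh, ls.brim, 5.0,
                             interior_hint=[20.0, 10.0, 0.0])
    pts = locate_insertion_points(mesh, offs, ls.tubercle_edge_m, PlateSpec())
    # m crosses the offset curve at x = 5 -> S there, M/L 6.5 and 19.5 on
    assert np.allclose(pts.S, [5.0, 15.0, 0.0], atol=0.02)
    assert np.allclose(pts.M, [11.5, 15.0, 0.0], atol=0.02)
    assert np.allclose(pts.L, [24.5, 15.0, 0.0], atol=0.02)
    assert pts.arc_M - pts.arc_S == pytest.approx(6.5)
    assert pts.arc_L - pts.arc_S == pytest.approx(19.5)


def test_zero_first_hole_offset_puts_M_at_S(strip_default):
    mesh, ls, _ = strip_default
    offs = offset_brim_curve(mesh, ls.brim, 5.0,
                             interior_hint=[20.0, 10.0, 0.0])
    pts = locate_insertion_points(mesh, offs, ls.tubercle_edge_m,
                                  PlateSpec(first_hole_offset=1e-9))
    assert np.allclose(pts.M, pts.S, atol=1e-6)


def test_insertion_arc_lengths_via_fine_resampling(pubis_default):
    """Independent oracle: re-measure S->M and S->L arcs on a 0.01 mm
    resampled copy of the offset curve."""
    mesh, lm = pubis_default
    hint = lm.tubercle_edge_m.mean(axis=0)
    offs = offset_brim_curve(mesh, lm.brim, 5.0, interior_hint=hint)
    pts = locate_insertion_points(mesh, offs, lm.tubercle_edge_m, PlateSpec())
    fine = resample_polyline(offs, 0.01)
    cum = polyline_lengths(fine)
    dS = np.linalg.norm(fine - pts.S, axis=1)
    dM = np.linalg.norm(fine - pts.M, axis=1)
    dL = np.linalg.norm(fine - pts.L, axis=1)
    arc_SM = abs(cum[np.argmin(dM)] - cum[np.argmin(dS)])
    arc_SL = abs(cum[np.argmin(dL)] - cum[np.argmin(dS)])
    assert arc_SM == pytest.approx(6.5, abs=0.1)
    assert arc_SL == pytest.approx(19.5, abs=0.1)


def test_no_intersection_error(strip_default):
    mesh, ls, _ = strip_default
    offs = offset_brim_curve(mesh, ls.brim, 5.0,
                             interior_hint=[20.0, 10.0, 0.0])
    far_m = ls.tubercle_edge_m + np.array([0.0, 0.0, 50.0])
    with pytest.raises(PlateGeometryError, match="approach"):
        locate_insertion_points(mesh, offs, far_m, PlateSpec())


def test_curve_too_short_error(strip_default):
    mesh, ls, _ = strip_default
    offs = offset_brim_curve(mesh, ls.brim, 5.0,
                             interior_hint=[20.0, 10.0, 0.0])
    with pytest.raises(PlateGeometryError, match="short"):
        locate_insertion_points(mesh, offs[:4], ls.tubercle_edge_m,
                                PlateSpec(hole_pitch=40.0))


def test_rigid_motion_equivariance_of_insertion_points(pubis_default):
    mesh, lm = pubis_default
    hint = lm.tubercle_edge_m.mean(axis=0)
    offs = offset_brim_curve(mesh, lm.brim, 5.0, interior_hint=hint)
    pts = locate_insertion_points(mesh, offs, lm.tubercle_edge_m, PlateSpec())

    T = trimesh.transformations.rotation_matrix(0.9, [0.2, 0.9, 0.4],
                                                point=[5, 5, 5])
    T[:3, 3] += [11.0, -3.0, 7.0]
    mesh2 = mesh.copy()
    mesh2.apply_transform(T)
    lm2 = lm.transformed(T)
    hint2 = lm2.tubercle_edge_m.mean(axis=0)
    offs2 = offset_brim_curve(mesh2, lm2.brim, 5.0, interior_hint=hint2)
    pts2 = locate_insertion_points(mesh2, offs2, lm2.tubercle_edge_m,
                                   PlateSpec())
    R, t = T[:3, :3], T[:3, 3]
    for a, b in ((pts.S, pts2.S), (pts.M, pts2.M), (pts.L, pts2.L)):
        assert np.allclose(a @ R.T + t, b, atol=1e-5)
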