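"""Containment, inclination searches, cross sections, safe region."""

import math

import numpy as np
import pytest
import trimesh

from pubicorridor import (BelowMinimumLengthError, CorridorGeometryError,
                          NoCorridorError, PipelineConfig, PubisPhantomSpec,
                          ScrewCylinder, StripPhantomSpec,
                          analyze_hemipelvis, build_cross_sections,
                          contains_cylinder, generate_pubis_phantom,
                          generate_strip_phantom, generate_wedge_phantom,
                          max_inclination_angle, medial_inclination_angle,
                          safe_region, screw_length, strip_max_length,
                          strip_max_tilt_sweep, tangential_obturator_screw)
from pubicorridor.corridor import _frame
from pubicorridor.geometry import MeshQuery, project_to_plane, unit

CFG = PipelineConfig()

# strip measuring frame: tilts live in the y-z plane, anterior is -y
PLANE_N = np.array([1.0, 0, 0])
REF = np.array([0.0, 0, -1.0])
ANT = np.array([0.0, -1.0, 0])


# ---------------------------------------------------------------------------
# containment
# ---------------------------------------------------------------------------

def test_coaxial_cylinder_in_tube_clearance():
    tube = trimesh.creation.cylinder(radius=5.0, height=40.0, sections=128)
    cyl = ScrewCylinder(entry=[0, 0, -10.0], axis=[0, 0, 1.0], diameter=2.0,
                        length=20.0)
    res = contains_cylinder(tube, cyl)
    assert res.contained
    assert res.clearance_mm == pytest.approx(4.0, abs=0.05)
    fat = ScrewCylinder(entry=[0, 0, -10.0], axis=[0, 0, 1.0], diameter=12.0,
                        length=20.0)
    res2 = contains_cylinder(tube, fat)
    assert not res2.contained and res2.clearance_mm < -0.5


def test_containment_refuses_open_mesh():
    cube = trimesh.creation.box(extents=[20, 20, 20])
    holed = trimesh.Trimesh(cube.vertices.copy(), cube.faces[:-1].copy(),
                            process=False)
    with pytest.raises(CorridorGeometryError, match="watertight"):
        contains_cylinder(holed, ScrewCylinder(entry=[0, 0, 0],
                                               axis=[0, 0, 1.0]))


def test_containment_brackets_the_oracle_angle(strip_default):
    """One degree inside the strip oracle's max tilt is contained, one
    degree outside is not."""
    mesh, _, gt = strip_default
    mq = MeshQuery(mesh)
    for sgn, sense in ((+1, "anterior"), (-1, "posterior")):
        for delta, expect in ((-1.0, True), (+1.0, False)):
            th = math.radians(gt.maia_deg + delta)
            axis = unit([0.0, -sgn * math.sin(th), -math.cos(th)])
            cyl = ScrewCylinder(entry=gt.entry_point, axis=axis, length=14.0)
            assert contains_cylinder(mq, cyl, tol=CFG.contain_tol).contained \
                is expect, (sense, delta)


# ---------------------------------------------------------------------------
# inclination searches and lengths
# ---------------------------------------------------------------------------

def test_fixed_policy_search_matches_oracle(strip_default):
    mesh, _, gt = strip_default
    mq = MeshQuery(mesh)
    a = max_inclination_angle(mq, gt.entry_point, PLANE_N, REF, "anterior",
                              ANT, CFG, length_policy="fixed")
    p = max_inclination_angle(mq, gt.entry_point, PLANE_N, REF, "posterior",
                              ANT, CFG, length_policy="fixed")
    assert a.angle_deg == pytest.approx(gt.maia_deg, abs=0.1)
    assert p.angle_deg == pytest.approx(gt.mpia_deg, abs=0.1)
    assert a.angle_deg >= 0 >= p.angle_deg
    assert p.screw.length == CFG.min_screw_length


def test_search_requires_containment_at_reference():
    mesh, _, gt = generate_strip_phantom(
        StripPhantomSpec(entry_offset_da=1.76))
    mq = MeshQuery(mesh)
    # flush entry: anterior tilt is (almost) impossible
    res = max_inclination_angle(mq, gt.entry_point, PLANE_N, REF, "anterior",
                                ANT, CFG, length_policy="fixed")
    assert res.angle_deg < 0.8


def test_screw_length_straight_and_tilted(strip_default):
    mesh, _, gt = strip_default
    mq = MeshQuery(mesh)
    down = screw_length(mq, gt.entry_point, [0, 0, -1.0], CFG)
    assert down == pytest.approx(60.0, abs=0.1)
    th = 20.0
    axis = unit([0.0, -math.sin(math.radians(th)), -math.cos(math.radians(th))])
    tilted = screw_length(mq, gt.entry_point, axis, CFG)
    assert tilted == pytest.approx(strip_max_length(20, 10, 1.75, th, 60.0),
                                   abs=0.1)


def test_screw_length_below_minimum_errors(strip_default):
    mesh, _, gt = strip_default
    mq = MeshQuery(mesh)
    with pytest.raises(BelowMinimumLengthError):
        screw_length(mq, gt.entry_point, [0, 0, 1.0], CFG)  # straight out


# ---------------------------------------------------------------------------
# cross sections & MIA
# ---------------------------------------------------------------------------

def test_cross_sections_closed_form_on_strip(strip_default):
    mesh, ls, gt = strip_default
    M = np.array([11.5, 15.0, 0.0])
    L = np.array([24.5, 15.0, 0.0])
    O = ls.symphysis_lowest_O
    axis = np.array([0.0, 0.0, -1.0])  # a vertical tangential screw
    cs = build_cross_sections(mesh, M, L, O, ls.brim, axis)
    # plane1 spans +y (to brim) and -z -> normal +-x; plane2 orthogonal
    assert abs(cs.plane1.normal @ [1, 0, 0]) == pytest.approx(1.0, abs=1e-9)
    assert abs(cs.plane1.normal @ cs.plane2.normal) < 1e-9
    assert abs(cs.plane3.normal @ cs.plane4.normal) < 1e-9
    # plane3 contains M and O
    assert abs(cs.plane3.distance(M)) < 1e-6
    assert abs(cs.plane3.distance(O)) < 1e-6
    # plane2 contains the screw axis
    assert abs(cs.plane2.normal @ axis) < 1e-9
    # reference lines are unit vectors within their planes
    assert np.linalg.norm(cs.reference_line_M) == pytest.approx(1.0)
    assert abs(cs.reference_line_M @ cs.plane3.normal) < 1e-9


def test_cross_sections_degenerate_span_error(strip_default):
    mesh, ls, _ = strip_default
    M = np.array([11.5, 15.0, 0.0])
    L = np.array([24.5, 15.0, 0.0])
    O = ls.symphysis_lowest_O
    to_brim = np.array([0.0, 1.0, 0.0])  # axis parallel to L->brim line
    with pytest.raises(CorridorGeometryError, match="plane1"):
        build_cross_sections(mesh, M, L, O, ls.brim, to_brim)


def test_medial_inclination_angle_constructed_cases():
    M = np.array([0.0, 0, 0])
    n4 = np.array([0.0, 1, 0])
    ref = np.array([0.0, 0, -1])
    # O straight along the reference line
    assert medial_inclination_angle(M, [0, 0, -40.0], ref, n4) == \
        pytest.approx(0.0, abs=1e-9)
    # O at 45 degrees within the plane
    O45 = np.array([-40.0, 0, -40.0]) / math.sqrt(2)
    assert medial_inclination_angle(M, O45, ref, n4) == pytest.approx(45.0)
    with pytest.raises(CorridorGeometryError):
        medial_inclination_angle(M, [0.3, 0, 0], ref, n4)


def test_plane_mia_agrees_with_independent_trigonometry(pubis_default,
                                                        pubis_analysis):
    """Recompute the plane MIA from raw dot products."""
    mesh, lm = pubis_default
    cs = pubis_analysis.cross_sections
    mq = MeshQuery(mesh)
    M = cs.plane3.point
    O = lm.symphysis_lowest_O
    n4 = cs.plane4.normal
    ref = unit(project_to_plane(-mq.surface_normal(M), n4))
    om = unit(project_to_plane(O - M, n4))
    expect = math.degrees(math.acos(np.clip(abs(ref @ om), -1, 1)))
    assert pubis_analysis.inner.plane_mia_deg == pytest.approx(expect,
                                                               abs=1e-6)


# ---------------------------------------------------------------------------
# tangential screw
# ---------------------------------------------------------------------------

def test_tangential_screw_hugs_the_obturator(pubis_default, pubis_analysis):
    mesh, lm = pubis_default
    tang = pubis_analysis.tangential
    assert tang.tangency_constrained
    assert tang.length_L0_mm >= 14.0
    # post hoc: the returned screw is contained and its clearance to the
    # obturator ring is tangentially small
    res = contains_cylinder(MeshQuery(mesh), tang.screw, tol=CFG.contain_tol)
    assert res.contained
    from pubicorridor.geometry import cylinder_surface_points

    pts = cylinder_surface_points(tang.screw.entry, tang.screw.axis,
                                  tang.screw.radius, tang.screw.length,
                                  n_axial=64, n_circ=32, n_cap=0)
    # tangency certificate: the screw surface grazes the foramen wall
    # (a cylinder of the obturator radius around the hole centre)
    xc, zc = PubisPhantomSpec().hole_center
    gap = np.hypot(pts[:, 0] - xc, pts[:, 2] - zc) - \
        PubisPhantomSpec().obturator_radius
    assert -CFG.contain_tol - 0.02 < gap.min() < 0.35


def test_tangential_without_foramen_is_unconstrained(pubis_nohole,
                                                     fast_config):
    mesh, lm = pubis_nohole
    mq, offs, pts, hint = _frame(mesh, lm, fast_config)
    res = tangential_obturator_screw(mq, pts.L, lm.symphysis_lowest_O,
                                     lm.brim, hint, fast_config)
    assert not res.tangency_constrained
    assert res.mia_deg < 5.0


def test_tangential_mia_larger_with_foramen(pubis_analysis, pubis_nohole,
                                            fast_config):
    mesh, lm = pubis_nohole
    mq, offs, pts, hint = _frame(mesh, lm, fast_config)
    nohole = tangential_obturator_screw(mq, pts.L, lm.symphysis_lowest_O,
                                        lm.brim, hint, fast_config)
    assert pubis_analysis.tangential.mia_deg > nohole.mia_deg + 5.0


def test_mid_corridor_direction_is_contained(pubis_default, pubis_analysis):
    """Sanity: a screw along the found tangential axis but only 14 mm
    long is trivially contained."""
    mesh, _ = pubis_default
    s = pubis_analysis.tangential.screw
    short = ScrewCylinder(entry=s.entry, axis=s.axis, length=14.0)
    assert contains_cylinder(MeshQuery(mesh), short,
                             tol=CFG.contain_tol).contained


# ---------------------------------------------------------------------------
# safe region
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("apex,expected", [(120.0, "blunt_V"),
                                           (40.0, "sharp_V"),
                                           (None, "disjoint")])
def test_safe_region_classification_on_wedges(apex, expected):
    mesh, axis, hint = generate_wedge_phantom(apex)
    region = safe_region(mesh, axis, hint, CFG)
    assert region.pattern == expected
    if apex is not None:
        assert region.apex_angle_deg == pytest.approx(apex, abs=3.0)


def test_safe_region_needs_wall_silhouette():
    # a tetrahedron viewed along one face normal leaves only one face on
    # the anterior side: no boundary pair to fit
    v = np.array([[0, 0, 0], [30, 0, 0], [15, 26, 0], [15, 9, 25.0]])
    f = np.array([[0, 1, 2], [0, 3, 1], [1, 3, 2], [0, 2, 3]])
    tetra = trimesh.Trimesh(v, f, process=False)
    trimesh.repair.fix_normals(tetra)
    if tetra.volume < 0:
        tetra.invert()
    axis = np.array([0.0, 0.0, 1.0])
    with pytest.raises(CorridorGeometryError):
        safe_region(tetra, axis, [0, 1.0, 0], CFG)


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def test_analysis_invariants_hold(pubis_analysis):
    r = pubis_analysis
    assert r.inner.maia_deg >= 0 >= r.inner.mpia_deg
    assert r.outer.maia_deg >= 0 >= r.outer.mpia_deg
    assert r.inner.maia_deg > r.inner.mpia_deg
    assert min(r.inner.length_L1_mm, r.outer.length_L2_mm,
               r.tangential.length_L0_mm) >= 14.0
    assert 0 <= r.inner.plane_mia_deg < 90
    assert 0 <= r.tangential.mia_deg < 90
    assert r.region.pattern in ("blunt_V", "sharp_V", "disjoint")


def test_outer_screw_never_more_lateral_than_tangential(pubis_analysis):
    """The outer screw's most lateral direction cannot pass outside the
    obturator-tangential screw, or it would breach the foramen."""
    tang = pubis_analysis.tangential
    for name in ("outer_anterior", "outer_posterior"):
        screw = pubis_analysis.screws[name]
        # medial inclination of each outer screw axis must be at least
        # the tangential screw's (angles vs the downward entry normal)
        assert _medial_angle(screw) >= _medial_angle(tang.screw) - 0.5


def _medial_angle(screw):
    down = np.array([0.0, 0.0, -1.0])
    ax = screw.axis
    lateral = math.degrees(math.atan2(-ax[0], -ax[2]))
    return lateral


def test_analysis_rejects_open_mesh(pubis_default):
    mesh, lm = pubis_default
    holed = trimesh.Trimesh(mesh.vertices.copy(), mesh.faces[:-1].copy(),
                            process=False)
    from pubicorridor import StageError

    with pytest.raises(StageError, match="validate"):
        analyze_hemipelvis(holed, lm, PipelineConfig.fast())


def test_analysis_deterministic(pubis_default, fast_config):
    mesh, lm = pubis_default
    a = analyze_hemipelvis(mesh, lm, fast_config).to_flat_dict()
    b = analyze_hemipelvis(mesh, lm, fast_config).to_flat_dict()
    assert a == b
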