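"""Phantom generators and the 2D strip tangency oracle."""

import numpy as np
import pytest

from pubicorridor import (CohortSpec, PhantomParameterError, PubisPhantomSpec,
                          StripPhantomSpec, cohort_manifest,
                          generate_pubis_phantom, generate_strip_phantom,
                          generate_wedge_phantom, sample_cohort,
                          strip_max_length, strip_max_tilt_closed,
                          strip_max_tilt_sweep, strip_phantom_oracle,
                          validate_mesh)

R = 1.75  # 3.5 mm screw radius


# ---------------------------------------------------------------------------
# strip phantom + oracle
# ---------------------------------------------------------------------------

def test_strip_phantom_is_a_closed_box_of_right_volume():
    spec = StripPhantomSpec(thickness_T=20, height_H=60, width_W=40)
    mesh, ls, gt = generate_strip_phantom(spec)
    rep = validate_mesh(mesh)
    assert rep.ok
    assert mesh.volume == pytest.approx(20 * 60 * 40, rel=1e-3)
    assert np.allclose(gt.entry_point, [20, 10, 0])


def test_strip_spec_invariants():
    with pytest.raises(PhantomParameterError):
        StripPhantomSpec(thickness_T=3.0)
    with pytest.raises(PhantomParameterError):
        StripPhantomSpec(entry_offset_da=25.0)


@pytest.mark.parametrize("T", [8.0, 12.0, 20.0, 30.0])
def test_oracle_closed_form_matches_dense_sweep(T):
    """Closed-form tangency angles vs the 0.01-degree reference sweep."""
    for da in np.linspace(R, T - R, 5):
        for sense in ("anterior", "posterior"):
            sweep = strip_max_tilt_sweep(T, da, R, 14.0, sense)
            closed = strip_max_tilt_closed(T, da, R, 14.0, sense)
            assert closed == pytest.approx(sweep, abs=0.02), (T, da, sense)


def test_oracle_symmetry_and_zero_clearance_limits():
    gt = strip_phantom_oracle(20.0, 10.0, R)
    assert gt.maia_deg == pytest.approx(-gt.mpia_deg, abs=1e-6)
    # entry flush against a wall leaves no tilt toward it
    assert strip_max_tilt_sweep(20.0, R, R, 14.0, "anterior") == pytest.approx(0.0, abs=0.011)
    assert strip_max_tilt_sweep(20.0, 20.0 - R, R, 14.0, "posterior") == \
        pytest.approx(0.0, abs=0.011)
    # mirror: anterior max at da equals posterior max at T - da
    for da in (4.0, 7.0, 13.0):
        assert strip_max_tilt_sweep(20.0, da, R, 14.0, "anterior") == \
            pytest.approx(strip_max_tilt_sweep(20.0, 20.0 - da, R, 14.0,
                                               "posterior"), abs=1e-9)


def test_oracle_monotone_in_entry_clearance():
    tilts = [strip_max_tilt_sweep(20.0, da, R, 14.0, "anterior")
             for da in np.linspace(R, 20 - R, 8)]
    assert all(b >= a - 1e-9 for a, b in zip(tilts, tilts[1:]))


def test_oracle_rejects_no_corridor():
    with pytest.raises(PhantomParameterError):
        strip_phantom_oracle(3.0, 1.5, R)
    with pytest.raises(PhantomParameterError):
        strip_phantom_oracle(20.0, 0.5, R)


def test_strip_max_length_formula():
    # straight down a 60 mm strip the tangent length is the full height
    assert strip_max_length(20, 10, R, 0.0, 60.0) == pytest.approx(60.0)
    # tilted, the near-wall cut dominates once shallow enough
    ln = strip_max_length(20, 10, R, 30.0, 60.0)
    assert ln == pytest.approx((10 - R * np.cos(np.radians(30)))
                               / np.sin(np.radians(30)), abs=1e-9)


# ---------------------------------------------------------------------------
# pubis phantom
# ---------------------------------------------------------------------------

def test_pubis_phantom_watertight_and_deterministic():
    spec = PubisPhantomSpec()
    m1, l1 = generate_pubis_phantom(spec)
    m2, l2 = generate_pubis_phantom(spec)
    assert validate_mesh(m1).ok
    assert np.array_equal(m1.vertices, m2.vertices)
    assert np.array_equal(m1.faces, m2.faces)
    assert np.array_equal(l1.brim, l2.brim)


def test_pubis_phantom_morphometric_ground_truth(pubis_default):
    _, lm = pubis_default
    spec = PubisPhantomSpec()
    sym = np.linalg.norm(lm.symphysis_upper - lm.symphysis_lower)
    assert sym == pytest.approx(spec.symphysis_height, abs=0.1)
    it = np.linalg.norm(lm.tubercle_apex - lm.contralateral_tubercle_apex)
    assert it == pytest.approx(spec.intertubercular, abs=1e-6)


def test_pubis_phantom_thick_medial_thin_lateral(pubis_default):
    """The anterior-posterior wall separation shrinks toward the ramus."""
    mesh, lm = pubis_default
    spec = PubisPhantomSpec()
    v = mesh.vertices
    z0 = spec.symphysis_height - 4.0  # just below the superior surface

    def width_at(x0):
        sel = (np.abs(v[:, 0] - x0) < 4.0) & (np.abs(v[:, 2] - z0) < 3.0)
        assert sel.any()
        return v[sel, 1].max() - v[sel, 1].min()

    assert width_at(6.0) > width_at(spec.lateral_extent - 6.0) + 2.0


def test_pubis_phantom_invalid_spec():
    with pytest.raises(PhantomParameterError):
        PubisPhantomSpec(body_thickness=3.0)
    with pytest.raises(PhantomParameterError):
        PubisPhantomSpec(ramus_length=-5.0)


def test_no_hole_variant_is_closed(pubis_nohole):
    mesh, lm = pubis_nohole
    assert validate_mesh(mesh).ok


def test_wedge_phantoms_are_closed():
    for apex in (120.0, 40.0, None):
        mesh, axis, hint = generate_wedge_phantom(apex)
        assert validate_mesh(mesh).ok


# ---------------------------------------------------------------------------
# cohort sampling
# ---------------------------------------------------------------------------

def test_cohort_sampling_reproducible_and_sized():
    spec = CohortSpec(n_male=6, n_female=4, seed=42)
    a = cohort_manifest(sample_cohort(spec))
    b = cohort_manifest(sample_cohort(spec))
    assert len(a) == 10
    assert (a["sex"] == "male").sum() == 6
    assert a.equals(b)
    c = cohort_manifest(sample_cohort(CohortSpec(n_male=6, n_female=4, seed=43)))
    assert not a["ramus_length"].equals(c["ramus_length"])


def test_cohort_recovers_configured_intertubercular_means():
    subs = sample_cohort(CohortSpec(n_male=40, n_female=40, seed=5))
    it = {"male": [], "female": []}
    for s in subs:
        it[s.sex].append(s.spec.intertubercular)
    for sex, mean, sd in (("male", 58.40, 6.03), ("female", 61.98, 9.04)):
        tol = 3 * sd / np.sqrt(40)
        assert abs(np.mean(it[sex]) - mean) < tol


def test_cohort_rejects_empty_stratum():
    with pytest.raises(PhantomParameterError):
        CohortSpec(n_male=0, n_female=10)
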