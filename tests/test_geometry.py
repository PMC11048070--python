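"""Geometric metric computations: fixtures, sign conventions, invariances."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from spondyref import (
    DegenerateGeometryError,
    Level,
    METRIC_COLUMNS,
    Subject,
    VertebraLandmarks,
    bisectrix,
    composite_metrics,
    endplate_width,
    level_metrics,
    method1_metrics,
    method2_metrics,
    metrics_table,
    vertebral_midplane,
)
from spondyref.synth import metrics_to_landmarks

from conftest import mirror_level, random_level, transform_level


def test_rectangle_fixture_all_metrics_exact(rectangle_level):
    m = level_metrics(rectangle_level)
    assert m.adh == pytest.approx(30, abs=1e-12)
    assert m.pdh == pytest.approx(30, abs=1e-12)
    assert m.vdh == pytest.approx(30, abs=1e-12)
    assert m.ddh == pytest.approx(30, abs=1e-12)
    assert m.avg_dh == pytest.approx(30, abs=1e-12)
    assert m.da == pytest.approx(0, abs=1e-12)
    assert m.mpa == pytest.approx(0, abs=1e-12)
    assert m.aspo == pytest.approx(0, abs=1e-12)
    assert m.pspo == pytest.approx(0, abs=1e-12)
    assert m.cspo == pytest.approx(0, abs=1e-12)
    assert m.disc_area == pytest.approx(0.30, abs=1e-12)
    assert m.epwr == pytest.approx(1.0, abs=1e-12)
    assert m.hw_ratio == pytest.approx(0.6, abs=1e-12)
    assert not m.self_intersecting


def test_anterior_translation_sign_convention(rectangle_level):
    """Moving the superior vertebra anteriorly: ASPO positive, PSPO negative
    (its posterior corner moves anteriorly), CSPO positive, heights unchanged."""
    lv = Level("L3L4", rectangle_level.sup.transformed(translation=(2, 0)),
               rectangle_level.inf)
    m = level_metrics(lv)
    assert m.aspo == pytest.approx(10, abs=1e-9)
    assert m.pspo == pytest.approx(-10, abs=1e-9)
    assert m.cspo == pytest.approx(10, abs=1e-9)
    assert m.adh == pytest.approx(30, abs=1e-9)
    assert m.pdh == pytest.approx(30, abs=1e-9)
    assert m.vdh == pytest.approx(30, abs=1e-9)


def test_rotation_sign_convention_and_bisectrix_tilt(rectangle_level):
    """Rotating the superior vertebra +5° about its centroid opens the disc
    anteriorly: DA = MPA = +5° and ADH > PDH.  The bisectrix tilts by half
    the midplane angle, so the vertical centroid separation acquires an
    along-bisectrix component |c_sup − c_inf|·sin(mpa/2)."""
    sup = rectangle_level.sup
    c = sup.centroid
    rot = sup.transformed(rotation_deg=5)
    rot = rot.transformed(translation=c - rot.centroid)
    m = level_metrics(Level("L3L4", rot, rectangle_level.inf))
    assert m.da == pytest.approx(5, abs=1e-9)
    assert m.mpa == pytest.approx(5, abs=1e-9)
    assert m.adh > m.pdh
    sep = np.linalg.norm(c - rectangle_level.inf.centroid)
    expected_cspo = sep * np.sin(np.radians(2.5)) / 20 * 100
    assert m.cspo == pytest.approx(expected_cspo, abs=1e-9)


def test_negative_angle_when_anterior_height_smaller():
    m = level_metrics(metrics_to_landmarks(
        dict(adh=20, pdh=40, aspo=0, pspo=0, epwr=1, hw_ratio=0.6), width=20))
    assert m.da < 0 and m.mpa < 0
    assert m.adh < m.pdh and m.vdh < m.ddh


def test_endplate_width_cases():
    v = VertebraLandmarks("L3", (10, 13), (-10, 12), (10, 0), (-10, 0))
    assert endplate_width(v, "inferior") == pytest.approx(20)
    assert endplate_width(v, "superior") == pytest.approx(np.sqrt(401))
    degen = VertebraLandmarks("L3", (0, 12), (0, 12), (10, 0), (-10, 0))
    with pytest.raises(DegenerateGeometryError):
        endplate_width(degen, "superior")
    with pytest.raises(ValueError):
        endplate_width(v, "sideways")


def test_midplane_through_wall_midpoints():
    rect = VertebraLandmarks("L3", (10, 18), (-10, 18), (10, 6), (-10, 6))
    p, d = vertebral_midplane(rect)
    assert p[1] == pytest.approx(12)
    assert abs(d[1]) < 1e-12 and d[0] > 0  # horizontal, pointing anterior
    sheared = VertebraLandmarks("L3", (13, 18), (-7, 18), (10, 6), (-10, 6))
    p2, d2 = vertebral_midplane(sheared)
    # same line as the bounding rectangle's midline construction: through
    # both wall midpoints
    assert p2[1] + (1.5 - p2[0]) / d2[0] * d2[1] == pytest.approx(12)


@pytest.mark.parametrize("m_sup, m_inf, probe, want_y", [
    # parallel horizontal midplanes y=12 and y=-6 -> midway line y=3
    ((np.array([0.0, 12.0]), np.array([1.0, 0.0])),
     (np.array([0.0, -6.0]), np.array([1.0, 0.0])), 5.0, 3.0),
])
def test_bisectrix_parallel_case(m_sup, m_inf, probe, want_y):
    p, d = bisectrix(m_sup, m_inf)
    y_at_probe = p[1] + (probe - p[0]) / d[0] * d[1]
    assert y_at_probe == pytest.approx(want_y, abs=1e-12)


def test_bisectrix_angle_cases():
    th = np.radians(10)
    up = (np.array([0.0, 0.0]), np.array([np.cos(th), np.sin(th)]))
    dn = (np.array([0.0, 0.0]), np.array([np.cos(th), -np.sin(th)]))
    p, d = bisectrix(up, dn)
    assert abs(d[1]) < 1e-12          # symmetric pair bisects to the x-axis
    diag = (np.array([0.0, 0.0]), np.array([1.0, 1.0]) / np.sqrt(2))
    flat = (np.array([0.0, 0.0]), np.array([1.0, 0.0]))
    _, d2 = bisectrix(diag, flat)
    assert np.degrees(np.arctan2(d2[1], d2[0])) == pytest.approx(22.5, abs=1e-9)


@settings(max_examples=60, derandomize=True, deadline=None)
@given(seed=st.integers(0, 10_000), angle=st.floats(-180, 180),
       tx=st.floats(-200, 200), ty=st.floats(-200, 200),
       scale=st.floats(0.05, 20))
def test_similarity_invariance(seed, angle, tx, ty, scale):
    """Rigid motion + uniform scaling changes no metric (all ratios/angles)."""
    rng = np.random.default_rng(seed)
    lv = random_level(rng)
    m0 = level_metrics(lv).as_dict()
    m1 = level_metrics(transform_level(lv, angle, (tx, ty), scale)).as_dict()
    for k in METRIC_COLUMNS:
        assert m1[k] == pytest.approx(m0[k], abs=1e-9), k


@settings(max_examples=40, derandomize=True, deadline=None)
@given(seed=st.integers(0, 10_000))
def test_mirror_swaps_corner_metrics_and_negates_angles(seed):
    """Reflecting about a vertical axis while swapping anterior/posterior
    corner roles reverses the anatomy's AP sense: the corner-wise metrics
    swap (aspo↔pspo, adh↔pdh, vdh↔ddh), the signed angles and centroid
    offset negate, and the symmetric composites are preserved."""
    rng = np.random.default_rng(seed)
    lv = random_level(rng)
    m0 = level_metrics(lv).as_dict()
    m1 = level_metrics(mirror_level(lv)).as_dict()
    for a, b in (("aspo", "pspo"), ("adh", "pdh"), ("vdh", "ddh")):
        assert m1[a] == pytest.approx(m0[b], abs=1e-9), (a, b)
        assert m1[b] == pytest.approx(m0[a], abs=1e-9), (b, a)
    for k in ("cspo", "da", "mpa"):
        assert m1[k] == pytest.approx(-m0[k], abs=1e-9), k
    for k in ("avg_dh", "disc_area", "epwr", "hw_ratio"):
        assert m1[k] == pytest.approx(m0[k], abs=1e-9), k


def test_parallel_endplate_stacks_have_equal_method1_method2_heights():
    """For rectangles stacked with parallel endplates adh==vdh, pdh==ddh."""
    m = level_metrics(metrics_to_landmarks(
        dict(adh=35, pdh=35, aspo=0, pspo=0, epwr=1, hw_ratio=0.55), width=40))
    assert m.adh == pytest.approx(m.vdh, abs=1e-9)
    assert m.pdh == pytest.approx(m.ddh, abs=1e-9)


def test_cspo_projection_equals_bruteforce_foot_distance():
    """CSPO equals the distance between the perpendicular feet of the two
    centroids on the bisectrix, found by brute-force minimization."""
    rng = np.random.default_rng(7)
    for _ in range(25):
        lv = random_level(rng)
        m = level_metrics(lv)
        p, d = bisectrix(vertebral_midplane(lv.sup), vertebral_midplane(lv.inf))
        # grid centered between the centroid projections (the bisectrix
        # anchor point can be arbitrarily far for near-parallel midplanes)
        mid = (lv.sup.centroid + lv.inf.centroid) / 2
        t_mid = np.dot(mid - p, d)
        ts = t_mid + np.linspace(-120, 120, 4_000_001)

        def foot(c):
            i = np.argmin((p[0] + ts * d[0] - c[0])**2 + (p[1] + ts * d[1] - c[1])**2)
            return ts[i]

        w = endplate_width(lv.inf, "superior")
        brute = (foot(lv.sup.centroid) - foot(lv.inf.centroid)) / w * 100
        assert m.cspo == pytest.approx(brute, abs=1e-3)


def test_metrics_table_counts_and_skips(rectangle_level):
    good = Subject("a", levels=[rectangle_level])
    # zero-width inferior endplate on the superior vertebra
    degen_sup = VertebraLandmarks("L3", (10, 18), (-10, 18), (0, 6), (0, 6))
    bad = Subject("b", levels=[Level("L3L4", degen_sup, rectangle_level.inf)])
    table, skips = metrics_table([good, bad])
    assert len(table) == 1 and len(skips) == 1
    assert skips.iloc[0]["subject_id"] == "b"
    empty, empty_skips = metrics_table([])
    assert len(empty) == 0 and len(empty_skips) == 0
    assert list(empty.columns[:2]) == ["subject_id", "level_name"]


def test_self_intersecting_disc_is_flagged_with_absolute_area():
    lv = metrics_to_landmarks(
        dict(adh=10, pdh=-8, aspo=0, pspo=0, epwr=1, hw_ratio=0.6), width=20)
    m = level_metrics(lv)
    assert m.self_intersecting
    assert m.disc_area >= 0


def test_operation_subsets_agree_with_full_metrics(rectangle_level):
    full = level_metrics(rectangle_level).as_dict()
    assert method1_metrics(rectangle_level) == {
        k: full[k] for k in ("adh", "pdh", "da", "aspo", "pspo")}
    assert method2_metrics(rectangle_level) == {
        k: full[k] for k in ("vdh", "ddh", "mpa", "cspo")}
    comp = composite_metrics(rectangle_level)
    for k in ("avg_dh", "disc_area", "epwr", "hw_ratio"):
        assert comp[k] == full[k]
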