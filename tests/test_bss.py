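"""Constraint-envelope (BSS) test: geometry, statistic, resampling null."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from endemicity import (
    BoundaryConfig,
    BoundaryTest,
    EnvelopePoints,
    boundary_distance,
    bss_statistic,
    bss_test,
    simulate_envelope,
    standardize,
    triangle_vertices,
)

SQ2 = np.sqrt(2.0) / 2.0


def unit_points():
    return EnvelopePoints(np.array([0.0, 0.5, 1.0]), np.array([0.0, 0.5, 1.0]))


# ---------------------------------------------------------------------------
# standardisation and triangle geometry
# ---------------------------------------------------------------------------

def test_standardize_affine_map_and_idempotence():
    pts = EnvelopePoints(np.array([0.0, 5.0, 10.0]), np.array([3.0, 4.0, 5.0]))
    s = standardize(pts)
    assert s.x.tolist() == [0.0, 0.5, 1.0]
    assert s.y.tolist() == [0.0, 0.5, 1.0]
    assert s.x_map == (0.0, 10.0) and s.y_map == (3.0, 2.0)
    s2 = standardize(s)
    assert np.array_equal(s2.x, s.x) and np.array_equal(s2.y, s.y)


def test_standardize_rejects_zero_range():
    with pytest.raises(ValueError, match="zero range"):
        EnvelopePoints(np.array([1.0, 1.0, 1.0]), np.array([0.0, 1.0, 2.0]))


def test_triangle_vertices_both_orientations():
    tri = triangle_vertices(unit_points(), "lower_right")
    assert {tuple(v) for v in tri.vertices} == {(0, 0), (1, 1), (1, 0)}
    assert tri.hypotenuse == ((0, 0), (1, 1))
    tri = triangle_vertices(unit_points(), "lower_left")
    assert {tuple(v) for v in tri.vertices} == {(0, 0), (1, 0), (0, 1)}
    assert tri.hypotenuse == ((0, 1), (1, 0))
    # vertices lie on the bounding rectangle
    for v in tri.vertices:
        assert v[0] in (0, 1) or v[1] in (0, 1)


def test_boundary_distance_inside_on_and_outside():
    tri = triangle_vertices(unit_points(), "lower_right")
    assert boundary_distance((0.5, 0.25), tri) == 0.0
    assert boundary_distance((0.5, 0.5), tri) == 0.0  # on the hypotenuse
    assert boundary_distance((0.0, 1.0), tri) == pytest.approx(SQ2, abs=1e-12)
    # dense sampling of the segment confirms the perpendicular distance
    t = np.linspace(0, 1, 20001)
    dense = np.min(np.hypot(0.0 - t, 1.0 - t))
    assert boundary_distance((0.0, 1.0), tri) == pytest.approx(dense, abs=1e-4)


def test_bss_statistic_examples():
    cfg = BoundaryConfig(standardize=False)
    inside = EnvelopePoints(np.array([0.2, 0.6, 1.0, 0.0]),
                            np.array([0.1, 0.2, 1.0, 0.0]))
    assert bss_statistic(inside, cfg) == (0.0, 0)
    one_out = EnvelopePoints(np.array([0.0, 1.0, 0.0]),
                             np.array([0.0, 1.0, 1.0]))
    stat, n_out = bss_statistic(one_out, cfg)
    assert n_out == 1 and stat == pytest.approx(SQ2, abs=1e-12)
    stat2, _ = bss_statistic(one_out, BoundaryConfig(standardize=False,
                                                     distance_power=2))
    assert stat2 == pytest.approx(0.5, abs=1e-12)


# ---------------------------------------------------------------------------
# the test itself
# ---------------------------------------------------------------------------

def test_bss_rejects_constant_y():
    with pytest.raises(ValueError, match="zero range"):
        bss_test(EnvelopePoints(np.array([0.0, 1.0, 2.0]),
                                np.array([1.0, 1.0, 1.0])))


def test_bss_deterministic_given_seed():
    pts = simulate_envelope(40, constrained=False, seed=3)
    cfg = BoundaryConfig(n_randomizations=200, seed=11)
    assert bss_test(pts, cfg).p_value == bss_test(pts, cfg).p_value


def test_bss_p_on_grid_and_never_zero():
    for seed in range(5):
        pts = simulate_envelope(30, noise_sd=0.0, seed=seed)
        res = bss_test(pts, BoundaryConfig(n_randomizations=99, seed=seed))
        k = res.p_value * 100
        assert k == pytest.approx(round(k)) and 1 <= round(k) <= 100


def test_bss_affine_invariance_of_decision():
    """With standardisation on, positive affine maps of either axis leave
    the test essentially unchanged."""
    pts = simulate_envelope(50, noise_sd=0.1, seed=21)
    cfg = BoundaryConfig(n_randomizations=500, seed=5)
    p0 = bss_test(pts, cfg).p_value
    pts2 = EnvelopePoints(3.5 * pts.x - 7.0, 0.2 * pts.y + 100.0)
    p1 = bss_test(pts2, cfg).p_value
    assert abs(p0 - p1) <= 2.0 / 501.0
    assert (p0 <= 0.05) == (p1 <= 0.05)


def test_bss_warns_below_five_points():
    pts = EnvelopePoints(np.array([0.0, 0.5, 1.0]), np.array([0.2, 0.9, 0.4]))
    with pytest.warns(UserWarning, match="fewer than 5"):
        bss_test(pts, BoundaryConfig(n_randomizations=20, seed=0))


def test_bss_power_increases_as_envelope_sharpens():
    """Mean p over replicates falls as envelope noise shrinks."""
    mean_p = {}
    for sd in (0.05, 0.4):
        ps = []
        for i in range(30):
            pts = simulate_envelope(60, noise_sd=sd, seed=[7, i])
            ps.append(bss_test(pts, BoundaryConfig(n_randomizations=200,
                                                   seed=[8, i])).p_value)
        mean_p[sd] = np.mean(ps)
    assert mean_p[0.05] < mean_p[0.4]


def test_bss_null_p_distribution_near_uniform():
    """Permutation p-values on data from the permutation null are uniform
    to within KS distance 0.1 at 500 replicates."""
    ps = []
    for i in range(500):
        pts = simulate_envelope(30, constrained=False, seed=[3, i])
        ps.append(bss_test(pts, BoundaryConfig(n_randomizations=199,
                                               seed=[4, i])).p_value)
    ps = np.sort(ps)
    grid = np.arange(1, 501) / 500.0
    ks = max(np.max(np.abs(ps - grid)), np.max(np.abs(ps - grid + 1 / 500.0)))
    assert ks < 0.1


def test_boundary_test_model_facade():
    pts = simulate_envelope(60, noise_sd=0.05, seed=2)
    res = BoundaryTest(pts.x, pts.y, orientation="lower_right").fit(
        n_randomizations=500, seed=9)
    assert res.p_value < 0.05
    assert "p (one-sided)" in res.summary()


def test_lower_left_orientation_detects_falling_ceiling():
    """Mirrored data (ceiling falls with x, as for altitude) is significant
    with the lower-left triangle, not the lower-right one."""
    pts = simulate_envelope(60, noise_sd=0.02, seed=13)
    mirrored = EnvelopePoints(1.0 - pts.x, pts.y)
    p_ll = bss_test(mirrored, BoundaryConfig(orientation="lower_left",
                                             n_randomizations=500, seed=1)).p_value
    p_lr = bss_test(mirrored, BoundaryConfig(orientation="lower_right",
                                             n_randomizations=500, seed=1)).p_value
    assert p_ll < 0.05 < p_lr


@given(seed=st.integers(0, 10**6))
@settings(max_examples=20, deadline=None, derandomize=True)
def test_uniform_rectangle_null_also_valid(seed):
    pts = simulate_envelope(40, constrained=False, seed=seed)
    res = bss_test(pts, BoundaryConfig(null_model="uniform_rectangle",
                                       n_randomizations=99, seed=seed))
    assert 0.0 < res.p_value <= 1.0
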