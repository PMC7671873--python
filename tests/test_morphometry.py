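import math

import numpy as np
import pytest
from scipy import optimize

from onhmorph.errors import CoverageError, DegenerateFitError
from onhmorph.morphometry import (
    PolarThicknessMap,
    alcs_depth,
    bmo_height,
    circle_eccentricity_um,
    circular_means,
    fit_bmo_ellipse,
    global_mrw,
    minimum_rim_width,
    session_morphometry,
    trt_annuli,
    trt_map,
)
from onhmorph.scan_model import (
    CircularScan,
    LayerPolyline,
    RadialBScan,
    SegmentedRadialSet,
)
from onhmorph.synthetic import PhantomSpec, make_phantom


def _bscan(ilm_pts, bm_pts, bmo_left, bmo_right, alcs_pts=None, index=0, angle=0.0):
    return RadialBScan(
        index=index,
        angle_deg=angle,
        ilm=LayerPolyline("ILM", ilm_pts),
        bm=LayerPolyline("BM", bm_pts),
        alcs=None if alcs_pts is None else LayerPolyline("ALCS", alcs_pts),
        bmo_left=bmo_left,
        bmo_right=bmo_right,
    )


def _flat_bm(z=0.0, span=2500.0):
    return [[-span, z], [span, z]]


# ---------------------------------------------------------------------------
# Ellipse fit
# ---------------------------------------------------------------------------

def _circle_points_3d(r, n=48, z=0.0):
    t = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    return np.column_stack([r * np.cos(t), r * np.sin(t), np.full(n, z)])


def test_ellipse_fit_printed_mean_area():
    # circle with area 2.04 mm^2 -> equivalent diameter rounds to 1600 um
    r = math.sqrt(2.04 / math.pi) * 1000.0
    e = fit_bmo_ellipse(_circle_points_3d(r))
    assert e.area_mm2 == pytest.approx(2.04, abs=1e-9)
    assert round(e.equivalent_diameter_um / 100.0) * 100 == 1600


def test_ellipse_fit_exact_ellipse_area():
    t = np.linspace(0.0, 2.0 * np.pi, 48, endpoint=False)
    pts = np.column_stack([1000.0 * np.cos(t), 500.0 * np.sin(t), np.zeros(48)])
    e = fit_bmo_ellipse(pts)
    assert e.area_mm2 == pytest.approx(math.pi * 0.5, rel=1e-9)
    assert e.a == pytest.approx(1000.0, rel=1e-6)
    assert e.b == pytest.approx(500.0, rel=1e-6)


def test_ellipse_fit_recovers_tilted_ellipse():
    # planar ellipse tilted out of the x-y plane; non-uniform parameter spacing
    rng = np.random.default_rng(3)
    t = np.sort(rng.uniform(0.0, 2.0 * np.pi, 48))
    a, b = 900.0, 700.0
    u = np.array([math.cos(0.4), 0.0, math.sin(0.4)])
    v = np.array([0.0, 1.0, 0.0])
    c = np.array([50.0, -30.0, 10.0])
    pts = c + a * np.cos(t)[:, None] * u + b * np.sin(t)[:, None] * v
    e = fit_bmo_ellipse(pts)
    assert e.a == pytest.approx(a, rel=1e-6)
    assert e.b == pytest.approx(b, rel=1e-6)
    assert e.area_mm2 == pytest.approx(math.pi * a * b / 1e6, rel=1e-6)
    assert np.allclose(e.center, c, atol=1e-6)


def test_ellipse_fit_noisy_circle_vs_nls_oracle():
    rng = np.random.default_rng(11)
    t = np.linspace(0.0, 2.0 * np.pi, 48, endpoint=False)
    r0 = 800.0
    x = r0 * np.cos(t) + rng.normal(0, 5.0, 48)
    y = r0 * np.sin(t) + rng.normal(0, 5.0, 48)
    pts = np.column_stack([x, y, np.zeros(48)])
    e = fit_bmo_ellipse(pts)
    assert abs(e.a - r0) / r0 < 0.02
    assert abs(e.b - r0) / r0 < 0.02

    # oracle: nonlinear least squares on radial residuals in the ellipse frame
    def resid(p):
        cx, cy, a, b, phi = p
        dx, dy = x - cx, y - cy
        ang = np.arctan2(dy, dx) - phi
        r_ell = a * b / np.sqrt((b * np.cos(ang)) ** 2 + (a * np.sin(ang)) ** 2)
        return np.hypot(dx, dy) - r_ell

    sol = optimize.least_squares(resid, x0=[0.0, 0.0, 820.0, 780.0, 0.0]).x
    a_or, b_or = max(sol[2], sol[3]), min(sol[2], sol[3])
    assert e.a == pytest.approx(a_or, rel=5e-3)
    assert e.b == pytest.approx(b_or, rel=5e-3)


def test_ellipse_fit_too_few_points():
    with pytest.raises(DegenerateFitError, match=">= 6"):
        fit_bmo_ellipse(_circle_points_3d(800.0, n=5))


def test_ellipse_fit_collinear_points():
    s = np.linspace(-800.0, 800.0, 48)
    pts = np.column_stack([s, 2.0 * s, np.zeros(48)])
    with pytest.raises(DegenerateFitError, match="collinear"):
        fit_bmo_ellipse(pts)


# ---------------------------------------------------------------------------
# Minimum rim width
# ---------------------------------------------------------------------------

def test_mrw_flat_ilm_directly_above():
    b = _bscan(
        ilm_pts=[[-900.0, 350.0], [900.0, 350.0]],
        bm_pts=_flat_bm(),
        bmo_left=(-800.0, 0.0),
        bmo_right=(800.0, 0.0),
    )
    assert minimum_rim_width(b, "right") == pytest.approx(350.0, abs=1e-12)
    assert minimum_rim_width(b, "left") == pytest.approx(350.0, abs=1e-12)


def test_mrw_point_to_vertex():
    # vertex at (700, 300) closer than its neighbours
    b = _bscan(
        ilm_pts=[[-900.0, 1200.0], [0.0, 1200.0], [700.0, 300.0], [900.0, 1200.0]],
        bm_pts=_flat_bm(),
        bmo_left=(-800.0, 0.0),
        bmo_right=(800.0, 0.0),
    )
    assert minimum_rim_width(b, "right") == pytest.approx(
        math.hypot(100.0, 300.0), abs=1e-9
    )


def test_mrw_search_restricted_to_bmo_region():
    # a spuriously close ILM point outside the BMO interval must be ignored
    b = _bscan(
        ilm_pts=[[-900.0, 5.0], [-850.0, 400.0], [850.0, 400.0], [900.0, 5.0]],
        bm_pts=_flat_bm(),
        bmo_left=(-800.0, 0.0),
        bmo_right=(800.0, 0.0),
    )
    assert minimum_rim_width(b, "left") > 300.0


def test_mrw_coverage_error():
    b = _bscan(
        ilm_pts=[[-100.0, 350.0], [100.0, 350.0]],
        bm_pts=_flat_bm(),
        bmo_left=(-800.0, 0.0),
        bmo_right=(800.0, 0.0),
    )
    with pytest.raises(CoverageError):
        minimum_rim_width(b, "left")


def _dense_mrw_oracle(bscan, side, step=0.1):
    """Brute-force minimum over the ILM resampled at ``step`` um."""
    p = np.asarray(bscan.bmo_left if side == "left" else bscan.bmo_right)
    s = np.arange(bscan.bmo_left[0], bscan.bmo_right[0] + step / 2, step)
    z = np.interp(s, bscan.ilm.s, bscan.ilm.z)
    return float(np.min(np.hypot(s - p[0], z - p[1])))


def test_mrw_matches_dense_resampling_oracle(rng):
    for _ in range(10):
        # randomized smooth ILM across the BMO interval
        r = rng.uniform(700.0, 900.0)
        sk = np.linspace(-r, r, 41)
        zk = (
            rng.uniform(250.0, 450.0)
            - rng.uniform(200.0, 400.0) * (1 - (sk / r) ** 2)
            + 30.0 * np.sin(sk / r * rng.uniform(1.0, 6.0))
        )
        ilm = np.column_stack(
            [np.concatenate([[-r - 50], sk, [r + 50]]),
             np.concatenate([[zk[0]], zk, [zk[-1]]])]
        )
        b = _bscan(ilm, _flat_bm(), (-r, 0.0), (r, 0.0))
        for side in ("left", "right"):
            assert minimum_rim_width(b, side) == pytest.approx(
                _dense_mrw_oracle(b, side), abs=0.5
            )


def test_global_mrw_mean_of_halves():
    # left shelf at 300, right shelf at 400 -> per-scan (300, 400), global 350
    bscans = []
    for k in range(24):
        bscans.append(_bscan(
            ilm_pts=[[-900.0, 300.0], [-1e-6, 300.0], [1e-6, 400.0], [900.0, 400.0]],
            bm_pts=_flat_bm(),
            bmo_left=(-800.0, 0.0),
            bmo_right=(800.0, 0.0),
            index=k,
            angle=k * 7.5,
        ))
    rset = SegmentedRadialSet(bscans=tuple(bscans))
    g, per = global_mrw(rset)
    assert g == pytest.approx(350.0, abs=1e-9)
    assert per.shape == (48,)
    assert per[0] == pytest.approx(300.0) and per[1] == pytest.approx(400.0)


def test_mrw_not_larger_than_axial_distance(default_phantom):
    rset, _, _ = default_phantom
    _, per = global_mrw(rset)
    i = 0
    for b in rset.bscans:
        for pt in (b.bmo_left, b.bmo_right):
            axial = abs(float(b.ilm.z_at(pt[0])) - pt[1])
            assert per[i] <= axial + 1e-9
            i += 1


# ---------------------------------------------------------------------------
# BMO height
# ---------------------------------------------------------------------------

def test_bmo_height_flat_zero():
    b = _bscan([[-900.0, 350.0], [900.0, 350.0]], _flat_bm(),
               (-800.0, 0.0), (800.0, 0.0))
    assert bmo_height(b) == pytest.approx((0.0, 0.0), abs=1e-12)


def test_bmo_height_posterior_sign_convention():
    b = _bscan([[-900.0, 350.0], [900.0, 350.0]], _flat_bm(),
               (-800.0, -102.0), (800.0, -102.0))
    left, right = bmo_height(b)
    assert left == pytest.approx(-102.0, abs=1e-12)
    assert right == pytest.approx(-102.0, abs=1e-12)


def test_bmo_height_tilted_reference_closed_form():
    # BM along z = 0.1 s; point (0, -100) is -100/sqrt(1.01) from the chord
    bm = [[-2500.0, -250.0], [2500.0, 250.0]]
    b = _bscan([[-900.0, 350.0], [900.0, 350.0]], bm, (0.0 - 1e-9, -100.0), (800.0, 80.0))
    left, _ = bmo_height(b)
    assert left == pytest.approx(-100.0 / math.sqrt(1.01), abs=1e-6)


def test_bmo_height_coverage_error():
    b = _bscan([[-900.0, 350.0], [900.0, 350.0]], _flat_bm(span=1500.0),
               (-800.0, 0.0), (800.0, 0.0))
    with pytest.raises(CoverageError, match="BM span"):
        bmo_height(b)


# ---------------------------------------------------------------------------
# ALCS depth
# ---------------------------------------------------------------------------

def test_alcsd_flat_lamina():
    alcs = [[s, -440.0] for s in np.arange(-600.0, 601.0, 50.0)]
    b = _bscan([[-900.0, 350.0], [900.0, 350.0]], _flat_bm(),
               (-800.0, 0.0), (800.0, 0.0), alcs_pts=alcs)
    assert alcs_depth(b) == pytest.approx(-440.0, abs=1e-12)


def test_alcsd_mean_of_samples():
    alcs = [[-300.0, -400.0], [0.0, -440.0], [300.0, -480.0]]
    b = _bscan([[-900.0, 350.0], [900.0, 350.0]], _flat_bm(),
               (-800.0, 0.0), (800.0, 0.0), alcs_pts=alcs)
    assert alcs_depth(b) == pytest.approx(-440.0, abs=1e-12)


def test_alcsd_missing_when_too_few_in_window():
    # only samples near one edge, outside the central 50 % window
    alcs = [[-790.0, -440.0], [-700.0, -440.0], [-650.0, -440.0]]
    b = _bscan([[-900.0, 350.0], [900.0, 350.0]], _flat_bm(),
               (-800.0, 0.0), (800.0, 0.0), alcs_pts=alcs)
    assert alcs_depth(b) is None
    b2 = _bscan([[-900.0, 350.0], [900.0, 350.0]], _flat_bm(),
                (-800.0, 0.0), (800.0, 0.0))
    assert alcs_depth(b2) is None


def test_alcsd_slanted_chord_vs_dense_oracle(rng):
    for _ in range(5):
        zl, zr = rng.uniform(-80.0, 80.0, 2)
        s = np.arange(-600.0, 600.0, 5.0)
        z = -440.0 + 40.0 * np.sin(s / 200.0) + rng.uniform(-20, 20)
        b = _bscan([[-900.0, 350.0], [900.0, 350.0]], _flat_bm(),
                   (-800.0, zl), (800.0, zr),
                   alcs_pts=np.column_stack([s, z]))
        got = alcs_depth(b)

        # dense numeric-integration oracle over the clipped window
        p0 = np.array([-800.0, zl]); p1 = np.array([800.0, zr])
        u = (p1 - p0) / np.linalg.norm(p1 - p0)
        n = np.array([-u[1], u[0]])
        if n[1] < 0:
            n = -n
        sd = np.arange(-600.0, 600.0, 0.1)
        zd = np.interp(sd, s, -440.0 + 40.0 * np.sin(s / 200.0)) + (z[0] + 440.0 - 40.0 * np.sin(s[0] / 200.0))
        q = np.column_stack([sd, zd]) - p0
        foot = q @ u
        L = np.linalg.norm(p1 - p0)
        keep = (foot >= 0.25 * L) & (foot <= 0.75 * L)
        oracle = float((q[keep] @ n).mean())
        assert got == pytest.approx(oracle, abs=0.5)


# ---------------------------------------------------------------------------
# TRT map and annuli
# ---------------------------------------------------------------------------

def _uniform_rset(thickness_fn):
    """Radial set whose TRT along each half-line is thickness_fn(r, angle)."""
    bscans = []
    for k in range(24):
        ang = k * 7.5
        s = np.arange(-2460.0, 2461.0, 10.0)
        r = np.abs(s)
        a = np.where(s >= 0, ang, ang + 180.0)
        t = thickness_fn(r, np.radians(a))
        bscans.append(_bscan(
            np.column_stack([s, t]), np.column_stack([s, np.zeros_like(s)]),
            (-800.0, 0.0), (800.0, 0.0), index=k, angle=ang,
        ))
    return SegmentedRadialSet(bscans=tuple(bscans))


def test_trt_map_constant():
    rset = _uniform_rset(lambda r, a: np.full_like(r, 300.0))
    m = trt_map(rset)
    assert np.allclose(m.values, 300.0)


def test_trt_map_linear_in_radius_exact():
    rset = _uniform_rset(lambda r, a: 200.0 + 0.05 * r)
    m = trt_map(rset)
    # linear interpolation reproduces linear functions exactly, also between nodes
    r_q = np.array([123.4, 777.7, 2001.5])
    got = m.sample(np.full(3, 33.0), r_q)
    assert np.allclose(got, 200.0 + 0.05 * r_q, atol=1e-9)


def test_trt_map_smooth_angular_variation_vs_analytic():
    fn = lambda r, a: 300.0 + 20.0 * np.cos(a) + 0.01 * r  # noqa: E731
    rset = _uniform_rset(fn)
    m = trt_map(rset)
    th = np.arange(0.0, 360.0, 1.0)
    r = np.full_like(th, 1500.0)
    got = m.sample(th, r)
    assert np.max(np.abs(got - fn(r, np.radians(th)))) < 1.0


def test_trt_annuli_constant_any_ellipse():
    rset = _uniform_rset(lambda r, a: np.full_like(r, 300.0))
    m = trt_map(rset)
    t = np.linspace(0, 2 * np.pi, 48, endpoint=False)
    pts = np.column_stack([900.0 * np.cos(t), 500.0 * np.sin(t), np.zeros(48)])
    ann = trt_annuli(m, fit_bmo_ellipse(pts))
    for name in ("trt250", "trt500", "trt1000", "trt1500"):
        assert ann.values[name] == pytest.approx(300.0, abs=1e-9)


def test_trt_annuli_piecewise_constant():
    # 400 inside 500 um of eccentricity from a circular BMO (r=800), 300 outside
    radii = np.arange(0.0, 2451.0, 1.0)
    angles = np.arange(0.0, 360.0, 7.5)
    vals = np.where(radii <= 1300.0, 400.0, 300.0)
    m = PolarThicknessMap(angles, radii, np.tile(vals, (48, 1)))
    ann = trt_annuli(m, fit_bmo_ellipse(_circle_points_3d(800.0)))
    assert ann.values["trt250"] == pytest.approx(400.0, abs=0.15)
    assert ann.values["trt500"] == pytest.approx(400.0, abs=0.15)
    assert ann.values["trt1000"] == pytest.approx(300.0, abs=0.15)
    assert ann.values["trt1500"] == pytest.approx(300.0, abs=0.15)


def test_trt_annuli_partial_coverage_masking():
    rset = _uniform_rset(lambda r, a: np.full_like(r, 300.0))
    m = trt_map(rset, r_max_um=1500.0)  # 1500-um annulus extends past the map
    ann = trt_annuli(m, fit_bmo_ellipse(_circle_points_3d(800.0)))
    assert math.isnan(ann.values["trt1500"])
    assert ann.masked_fraction["trt1500"] > 0.25
    assert ann.values["trt250"] == pytest.approx(300.0, abs=1e-9)


def test_trt_annuli_vs_quadrature_oracle(default_phantom):
    # elliptical BMO with radial thickness gradient vs fine 2-D integration
    rset, _, gt = default_phantom
    ellipse = fit_bmo_ellipse(rset.bmo_points_3d())
    ann = trt_annuli(trt_map(rset), ellipse)
    for name in ("trt250", "trt500", "trt1000", "trt1500"):
        assert ann.values[name] == pytest.approx(getattr(gt, name), abs=1.0)


# ---------------------------------------------------------------------------
# Circular means
# ---------------------------------------------------------------------------

def _circle(theta, rnflt, trt, chor, valid=None):
    ilm = np.full_like(theta, 0.0)
    return CircularScan(
        diameter_mm=3.5,
        theta=theta,
        ilm_z=ilm,
        rnfl_post_z=ilm - rnflt,
        bm_z=ilm - trt,
        choroid_sclera_z=ilm - trt - chor,
        valid=np.ones_like(theta, dtype=bool) if valid is None else valid,
    )


def test_circular_means_constant():
    th = np.arange(0.0, 360.0, 1.0)
    scan = _circle(th, np.full_like(th, 119.0), np.full_like(th, 320.0),
                   np.full_like(th, 210.0))
    r, t, c = circular_means(scan)
    assert r == pytest.approx(119.0, abs=1e-12)
    assert t == pytest.approx(320.0, abs=1e-12)
    assert c == pytest.approx(210.0, abs=1e-12)


def test_circular_means_sinusoid():
    th = np.arange(0.0, 360.0, 1.0)
    rnflt = 100.0 + 20.0 * np.sin(np.radians(th))
    scan = _circle(th, rnflt, np.full_like(th, 300.0), np.full_like(th, 200.0))
    r, _, _ = circular_means(scan)
    assert r == pytest.approx(100.0, abs=0.01)


def test_circular_means_masked_sector_vs_trapezoid_oracle():
    th = np.arange(0.0, 360.0, 1.0)
    rnflt = 100.0 + 20.0 * np.sin(np.radians(th))
    valid = np.ones_like(th, dtype=bool)
    valid[40:76] = False  # 10 % contiguous masked sector
    scan = _circle(th, rnflt, np.full_like(th, 300.0), np.full_like(th, 200.0),
                   valid=valid)
    got, _, _ = circular_means(scan)

    # independent trapezoidal oracle over each contiguous valid arc
    thx = np.concatenate([th, [360.0]])
    fx = np.concatenate([rnflt, [rnflt[0]]])
    vx = np.concatenate([valid, [valid[0]]])
    total = wsum = 0.0
    i = 0
    while i < len(thx) - 1:
        if vx[i]:
            j = i
            while j + 1 < len(thx) and vx[j + 1]:
                j += 1
            if j > i:
                total += np.trapezoid(fx[i:j + 1], thx[i:j + 1])
                wsum += thx[j] - thx[i]
            i = j + 1
        else:
            i += 1
    assert got == pytest.approx(total / wsum, abs=0.1)


# ---------------------------------------------------------------------------
# Invariance properties
# ---------------------------------------------------------------------------

def _scaled_rset(rset, k):
    bscans = []
    for b in rset.bscans:
        bscans.append(RadialBScan(
            index=b.index, angle_deg=b.angle_deg,
            ilm=LayerPolyline("ILM", b.ilm.samples * k),
            bm=LayerPolyline("BM", b.bm.samples * k),
            alcs=None if b.alcs is None else LayerPolyline("ALCS", b.alcs.samples * k),
            bmo_left=(b.bmo_left[0] * k, b.bmo_left[1] * k),
            bmo_right=(b.bmo_right[0] * k, b.bmo_right[1] * k),
        ))
    return SegmentedRadialSet(bscans=tuple(bscans), eye=rset.eye)


def test_scale_equivariance(default_phantom):
    rset, _, _ = default_phantom
    k = 1.7
    scaled = _scaled_rset(rset, k)
    g0, per0 = global_mrw(rset)
    g1, per1 = global_mrw(scaled)
    assert np.allclose(per1, k * per0, rtol=1e-12)
    # the 4-mm reference chord must scale with the geometry for equivariance
    b0 = bmo_height(rset.bscans[4])
    b1 = bmo_height(scaled.bscans[4], half_span_um=2000.0 * k)
    assert b1 == pytest.approx(tuple(k * v for v in b0), rel=1e-12)
    a0 = alcs_depth(rset.bscans[4])
    a1 = alcs_depth(scaled.bscans[4])
    assert a1 == pytest.approx(k * a0, rel=1e-9)
    e0 = fit_bmo_ellipse(rset.bmo_points_3d())
    e1 = fit_bmo_ellipse(scaled.bmo_points_3d())
    assert e1.area_mm2 == pytest.approx(k * k * e0.area_mm2, rel=1e-9)


def test_rotation_invariance_one_step(default_phantom):
    rset, _, _ = default_phantom
    rotated = SegmentedRadialSet(bscans=tuple(
        RadialBScan(
            index=b.index, angle_deg=(b.angle_deg + 7.5) % 360.0,
            ilm=b.ilm, bm=b.bm, alcs=b.alcs,
            bmo_left=b.bmo_left, bmo_right=b.bmo_right,
        )
        for b in rset.bscans
    ))
    g0, _ = global_mrw(rset)
    g1, _ = global_mrw(rotated)
    assert g1 == pytest.approx(g0, rel=1e-12)
    e0 = fit_bmo_ellipse(rset.bmo_points_3d())
    e1 = fit_bmo_ellipse(rotated.bmo_points_3d())
    assert e1.area_mm2 == pytest.approx(e0.area_mm2, rel=1e-6)
    a0 = trt_annuli(trt_map(rset), e0)
    a1 = trt_annuli(trt_map(rotated), e1)
    for name in ("trt250", "trt500", "trt1000", "trt1500"):
        assert a1.values[name] == pytest.approx(a0.values[name], rel=1e-6)


# ---------------------------------------------------------------------------
# Session aggregation
# ---------------------------------------------------------------------------

def test_session_morphometry_full(default_phantom):
    rset, circles, _ = default_phantom
    res = session_morphometry(rset, circles)
    assert all(
        v == "ok" or v.startswith("missing")
        for v in res.completeness.values()
    )
    assert res.mrw_per_point.shape == (48,)
    assert res.alcsd_global is not None
    d = res.to_dict()
    assert d["mrw_global_um"] == pytest.approx(res.mrw_global)


def test_session_morphometry_without_alcs():
    rset, circles, _ = make_phantom(PhantomSpec(include_alcs=False))
    res = session_morphometry(rset, circles)
    assert res.alcsd_global is None
    assert "missing" in res.completeness["alcsd"]
    assert math.isfinite(res.mrw_global)


def test_circle_eccentricity_helper():
    assert circle_eccentricity_um(4.9, 1600.0) == 1650.0
    assert circle_eccentricity_um(2.7, 1600.0) == 550.0
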