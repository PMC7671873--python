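"""ONH and peripapillary structural parameters from segmented scans.

All distance metrics are computed per B-scan plane in physical micrometres:

* ``minimum_rim_width``  — BMO point to nearest interpolated ILM point,
  searched only on the ILM arc between the two BMO marks of the B-scan.
* ``bmo_height``         — signed perpendicular distance of each BMO point to
  the 4-mm BM chord (BM interpolated at s = -2000 and +2000 um); anterior
  displacement is positive.
* ``alcs_depth``         — mean signed perpendicular distance of lamina
  samples to the BMO chord, restricted to the central 50 % of that chord.
* ``fit_bmo_ellipse``    — least-squares plane + direct conic fit constrained
  to an ellipse; area is pi*a*b in the fitted plane.
* ``trt_map``/``trt_annuli`` — polar total-retinal-thickness map (ILM-BM) and
  area-weighted annular means at eccentricities measured outward from the
  BMO ellipse boundary along rays from the ellipse centre.
* ``circular_means``     — angular-gap weighted circumpapillary means.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import (
    CoverageError,
    DegenerateFitError,
    FitError,
    GeometryError,
)
from .scan_model import CircularScan, RadialBScan, SegmentedRadialSet

TRT_ANNULUS_BOUNDS_UM = (0.0, 250.0, 500.0, 1000.0, 1500.0)
ANNULUS_NAMES = ("trt250", "trt500", "trt1000", "trt1500")
BM_REFERENCE_HALF_SPAN_UM = 2000.0  # 4-mm reference chord
ALCS_CENTRAL_FRACTION = (0.25, 0.75)  # central 50 % of the BMO chord


# ---------------------------------------------------------------------------
# Ellipse fitting
# ---------------------------------------------------------------------------

@dataclass
class BMOEllipse:
    """Best-fit ellipse to the 48 BMO points.

    The ellipse lives in the least-squares plane of the points; ``a``/``b``
    are in-plane semi-axes (um) and ``area_mm2 = pi*a*b / 1e6``.  The lateral
    (x-y) projection, itself an ellipse, is kept for eccentricity geometry.
    """

    center: np.ndarray          # (3,) um
    normal: np.ndarray          # (3,) unit, oriented anterior (z >= 0)
    a: float                    # semi-major, um
    b: float                    # semi-minor, um
    orientation_rad: float      # major-axis angle within the plane basis
    area_mm2: float
    lateral_center: np.ndarray = field(default=None)  # (2,)
    _lateral_gram_inv: np.ndarray = field(default=None, repr=False)  # (2,2)

    def boundary_radius(self, theta_rad: np.ndarray | float) -> np.ndarray:
        """Distance from the lateral centre to the projected ellipse boundary
        along the lateral direction(s) ``theta_rad``."""
        th = np.asarray(theta_rad, dtype=float)
        d = np.stack([np.cos(th), np.sin(th)], axis=-1)
        q = np.einsum("...i,ij,...j->...", d, self._lateral_gram_inv, d)
        return 1.0 / np.sqrt(q)

    @property
    def equivalent_diameter_um(self) -> float:
        """Diameter of the circle with the same area, in micrometres."""
        return 2.0 * math.sqrt(self.area_mm2 / math.pi) * 1000.0


def _direct_ellipse_fit(xy: np.ndarray) -> np.ndarray:
    """Numerically stable direct least-squares conic fit constrained to an
    ellipse (Halir & Flusser variant of the Fitzgibbon method).

    Returns conic coefficients (A, B, C, D, E, F) for
    ``A x^2 + B x y + C y^2 + D x + E y + F = 0`` with ``B^2 - 4AC < 0``.
    """
    x, y = xy[:, 0], xy[:, 1]
    d1 = np.column_stack([x * x, x * y, y * y])
    d2 = np.column_stack([x, y, np.ones_like(x)])
    s1 = d1.T @ d1
    s2 = d1.T @ d2
    s3 = d2.T @ d2
    try:
        t = -np.linalg.solve(s3, s2.T)
    except np.linalg.LinAlgError as exc:
        raise DegenerateFitError("singular scatter matrix in ellipse fit") from exc
    m = s1 + s2 @ t
    c1inv = np.array([[0.0, 0.0, 0.5], [0.0, -1.0, 0.0], [0.5, 0.0, 0.0]])
    evals, evecs = np.linalg.eig(c1inv @ m)
    # the ellipse solution is the eigenvector with 4AC - B^2 > 0
    cond = 4.0 * evecs[0] * evecs[2] - evecs[1] ** 2
    ok = np.where(np.isreal(evals) & (cond > 0))[0]
    if ok.size == 0:
        raise FitError("conic fit did not yield an ellipse")
    a1 = np.real(evecs[:, ok[0]])
    return np.concatenate([a1, t @ a1])


def _conic_to_geometric(coeffs: np.ndarray) -> tuple[np.ndarray, float, float, float]:
    """Conic coefficients -> (center, semi-major, semi-minor, angle)."""
    A, B, C, D, E, F = coeffs
    den = B * B - 4.0 * A * C
    if den >= 0:
        raise FitError("conic is not an ellipse")
    cx = (2.0 * C * D - B * E) / den
    cy = (2.0 * A * E - B * D) / den
    # value of the quadratic form at the centre
    f0 = A * cx * cx + B * cx * cy + C * cy * cy + D * cx + E * cy + F
    m = np.array([[A, B / 2.0], [B / 2.0, C]])
    evals, evecs = np.linalg.eigh(m)
    axes2 = -f0 / evals
    if np.any(axes2 <= 0):
        raise FitError("conic is not an ellipse (non-positive axis)")
    axes = np.sqrt(axes2)
    order = np.argsort(axes)[::-1]  # semi-major first
    a, b = axes[order]
    major = evecs[:, order[0]]
    return np.array([cx, cy]), float(a), float(b), float(math.atan2(major[1], major[0]))


def fit_bmo_ellipse(points: np.ndarray) -> BMOEllipse:
    """Fit the BMO ellipse to >= 6 non-collinear 3-D points (um).

    Steps: least-squares plane (SVD), projection into the plane, direct
    least-squares ellipse fit, back-substitution of the centre into 3-D.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise GeometryError("BMO points must be an (n, 3) array")
    if pts.shape[0] < 6:
        raise DegenerateFitError(f"need >= 6 BMO points, got {pts.shape[0]}")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    _, sv, vt = np.linalg.svd(centered, full_matrices=False)
    if sv[1] <= 1e-9 * max(sv[0], 1.0):
        raise DegenerateFitError("BMO points are collinear")
    normal = vt[2]
    if normal[2] < 0:
        normal = -normal
    u, v = vt[0], vt[1]
    uv = np.column_stack([centered @ u, centered @ v])
    # normalise for conditioning, then rescale the conic solution
    scale = float(np.abs(uv).max())
    coeffs = _direct_ellipse_fit(uv / scale)
    center2, a_s, b_s, phi = _conic_to_geometric(coeffs)
    center2, a, b = center2 * scale, a_s * scale, b_s * scale
    center3 = centroid + center2[0] * u + center2[1] * v
    area_mm2 = math.pi * a * b / 1e6

    # lateral projection: P(t) = c + a cos(t) A + b sin(t) B; drop z.
    amaj = a * (math.cos(phi) * u + math.sin(phi) * v)
    bmin = b * (-math.sin(phi) * u + math.cos(phi) * v)
    mlat = np.column_stack([amaj[:2], bmin[:2]])
    gram = mlat @ mlat.T
    if np.linalg.det(gram) <= 0:
        raise FitError("degenerate lateral projection of the BMO ellipse")
    return BMOEllipse(
        center=center3,
        normal=normal,
        a=a,
        b=b,
        orientation_rad=phi,
        area_mm2=area_mm2,
        lateral_center=center3[:2].copy(),
        _lateral_gram_inv=np.linalg.inv(gram),
    )


# ---------------------------------------------------------------------------
# Per-B-scan rim metrics
# ---------------------------------------------------------------------------

def _clip_polyline(samples: np.ndarray, s_lo: float, s_hi: float) -> np.ndarray:
    """Restrict a polyline to lateral interval [s_lo, s_hi], interpolating
    the boundary vertices."""
    s, z = samples[:, 0], samples[:, 1]
    if s[0] > s_lo or s[-1] < s_hi:
        raise CoverageError(
            f"polyline spans [{s[0]:.1f}, {s[-1]:.1f}] um but "
            f"[{s_lo:.1f}, {s_hi:.1f}] um is required"
        )
    inside = (s > s_lo) & (s < s_hi)
    pts = [np.array([s_lo, np.interp(s_lo, s, z)])]
    pts.extend(samples[inside])
    pts.append(np.array([s_hi, np.interp(s_hi, s, z)]))
    return np.vstack(pts)


def _min_distance_to_polyline(p: np.ndarray, poly: np.ndarray) -> tuple[float, np.ndarray]:
    """Minimum Euclidean distance from point ``p`` to a 2-D polyline.

    Ties (within 1e-9 relative) are broken toward the candidate point with
    the smaller |s| so output is deterministic.
    """
    a, b = poly[:-1], poly[1:]
    ab = b - a
    denom = np.einsum("ij,ij->i", ab, ab)
    denom[denom == 0] = 1.0
    t = np.clip(np.einsum("ij,ij->i", p - a, ab) / denom, 0.0, 1.0)
    proj = a + t[:, None] * ab
    d = np.hypot(*(p - proj).T)
    dmin = d.min()
    cand = np.where(d <= dmin + 1e-9 * (1.0 + dmin))[0]
    best = cand[np.argmin(np.abs(proj[cand, 0]))]
    return float(d[best]), proj[best]


def minimum_rim_width(bscan: RadialBScan, side: str) -> float:
    """BMO-MRW for one BMO point: distance to the nearest point of the ILM
    arc lying laterally between the two BMO marks of this B-scan."""
    if side not in ("left", "right"):
        raise ValueError("side must be 'left' or 'right'")
    p = np.asarray(bscan.bmo_left if side == "left" else bscan.bmo_right)
    arc = _clip_polyline(bscan.ilm.samples, bscan.bmo_left[0], bscan.bmo_right[0])
    dist, _ = _min_distance_to_polyline(p, arc)
    return dist


def global_mrw(rset: SegmentedRadialSet) -> tuple[float, np.ndarray]:
    """Arithmetic mean (and the 48 per-point values, ordered
    bscan0-left, bscan0-right, bscan1-left, ...) of BMO-MRW."""
    values = []
    for b in rset.bscans:
        for side in ("left", "right"):
            try:
                values.append(minimum_rim_width(b, side))
            except CoverageError as exc:
                raise CoverageError(f"bscan {b.index} ({side}): {exc}") from exc
    per_point = np.asarray(values)
    return float(per_point.mean()), per_point


def bmo_height(
    bscan: RadialBScan,
    half_span_um: float = BM_REFERENCE_HALF_SPAN_UM,
) -> tuple[float, float]:
    """Signed perpendicular distances (left, right) of the BMO points to the
    4-mm BM reference chord (BM interpolated at s = +/- ``half_span_um``);
    anterior (toward the vitreous) is positive."""
    bm = bscan.bm
    if not bm.covers(-half_span_um, half_span_um):
        raise CoverageError(
            f"bscan {bscan.index}: BM span does not cover +/- "
            f"{half_span_um:.0f} um"
        )
    q0 = np.array([-half_span_um, float(bm.z_at(-half_span_um))])
    q1 = np.array([half_span_um, float(bm.z_at(half_span_um))])
    t = q1 - q0
    n = np.array([-t[1], t[0]])  # t[0] > 0, so n points anterior (z+)
    n = n / np.linalg.norm(n)
    out = []
    for pt in (bscan.bmo_left, bscan.bmo_right):
        out.append(float(n @ (np.asarray(pt) - q0)))
    return out[0], out[1]


def global_bmo_height(rset: SegmentedRadialSet) -> tuple[float, np.ndarray]:
    values = []
    for b in rset.bscans:
        values.extend(bmo_height(b))
    per_point = np.asarray(values)
    return float(per_point.mean()), per_point


def alcs_depth(bscan: RadialBScan) -> Optional[float]:
    """Mean signed perpendicular distance of lamina samples to the BMO chord,
    using only samples whose perpendicular foot falls within the central 50 %
    of the chord.  Posterior is negative.  Returns None when the lamina is
    absent or fewer than 3 samples fall in the window (missing value, not an
    error)."""
    if bscan.alcs is None:
        return None
    p0 = np.asarray(bscan.bmo_left, dtype=float)
    p1 = np.asarray(bscan.bmo_right, dtype=float)
    chord = p1 - p0
    length = float(np.linalg.norm(chord))
    if length == 0:
        raise GeometryError(f"bscan {bscan.index}: zero-length BMO chord")
    u = chord / length
    n = np.array([-u[1], u[0]])
    if n[1] < 0:  # orient anterior-positive
        n = -n
    q = bscan.alcs.samples - p0
    foot = q @ u
    lo, hi = ALCS_CENTRAL_FRACTION[0] * length, ALCS_CENTRAL_FRACTION[1] * length
    in_win = (foot >= lo) & (foot <= hi)
    if int(in_win.sum()) < 3:
        return None
    return float((q[in_win] @ n).mean())


def global_alcs_depth(rset: SegmentedRadialSet) -> Optional[float]:
    vals = [v for v in (alcs_depth(b) for b in rset.bscans) if v is not None]
    if not vals:
        return None
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# Total retinal thickness map and annuli
# ---------------------------------------------------------------------------

@dataclass
class PolarThicknessMap:
    """TRT sampled on a polar grid centred on the radial-scan rotation centre.

    The angular grid is the native set of half-line angles (uniform step);
    sampling between grid nodes is bilinear (periodic in angle).  Masked
    cells are NaN.
    """

    angles_deg: np.ndarray  # (na,) uniform, [0, 360)
    radii_um: np.ndarray    # (nr,) uniform from 0
    values: np.ndarray      # (na, nr) um, NaN = masked

    def sample(self, theta_deg: np.ndarray, r_um: np.ndarray) -> np.ndarray:
        """Bilinear interpolation at arbitrary polar points (NaN outside the
        radial range or where a supporting cell is masked)."""
        th = np.mod(np.asarray(theta_deg, dtype=float), 360.0)
        r = np.asarray(r_um, dtype=float)
        na = self.angles_deg.size
        dth = 360.0 / na
        fa = (th - self.angles_deg[0]) / dth
        ia = np.floor(fa).astype(int)
        wa = fa - ia
        ia0 = np.mod(ia, na)
        ia1 = np.mod(ia + 1, na)

        r0, dr = self.radii_um[0], self.radii_um[1] - self.radii_um[0]
        fr = (r - r0) / dr
        ir = np.floor(fr).astype(int)
        wr = fr - ir
        out_of_range = (ir < 0) | (ir + 1 >= self.radii_um.size)
        ir = np.clip(ir, 0, self.radii_um.size - 2)

        v00 = self.values[ia0, ir]
        v01 = self.values[ia0, ir + 1]
        v10 = self.values[ia1, ir]
        v11 = self.values[ia1, ir + 1]
        vals = ((1 - wa) * ((1 - wr) * v00 + wr * v01)
                + wa * ((1 - wr) * v10 + wr * v11))
        vals = np.where(out_of_range, np.nan, vals)
        return vals

    def to_table(self) -> np.ndarray:
        """(angle_deg, radius_um, trt_um) rows for TSV dumps."""
        aa, rr = np.meshgrid(self.angles_deg, self.radii_um, indexing="ij")
        return np.column_stack([aa.ravel(), rr.ravel(), self.values.ravel()])


def trt_map(
    rset: SegmentedRadialSet,
    d_radius_um: float = 10.0,
    r_max_um: float = 2450.0,
) -> PolarThicknessMap:
    """Total retinal thickness (ILM - BM, axial) on a polar grid.

    Thickness is linearly interpolated in radius along each of the 48
    half-lines; the angular grid is the half-line angles themselves so that
    circumferential interpolation (done at sampling time) is linear between
    adjacent half-lines with period 360 degrees.
    """
    radii = np.arange(0.0, r_max_um + 0.5 * d_radius_um, d_radius_um)
    entries = []  # (angle, trt-per-radius)
    for b in rset.bscans:
        ilm_s, ilm_z = b.ilm.samples[:, 0], b.ilm.samples[:, 1]
        bm_s, bm_z = b.bm.samples[:, 0], b.bm.samples[:, 1]
        for half, ang in ((1.0, b.angle_deg), (-1.0, b.angle_deg + 180.0)):
            s = half * radii
            covered = (s >= max(ilm_s[0], bm_s[0])) & (s <= min(ilm_s[-1], bm_s[-1]))
            t = np.where(
                covered,
                np.interp(s, ilm_s, ilm_z) - np.interp(s, bm_s, bm_z),
                np.nan,
            )
            entries.append((np.mod(ang, 360.0), t))
    entries.sort(key=lambda e: e[0])
    angles = np.array([e[0] for e in entries])
    values = np.vstack([e[1] for e in entries])
    steps = np.diff(np.concatenate([angles, [angles[0] + 360.0]]))
    if not np.allclose(steps, steps[0], atol=1e-6):
        raise GeometryError("radial set angles are not uniformly spaced")
    return PolarThicknessMap(angles_deg=angles, radii_um=radii, values=values)


@dataclass
class AnnulusResult:
    values: dict[str, float]          # NaN when invalid
    masked_fraction: dict[str, float]


def trt_annuli(
    tmap: PolarThicknessMap,
    ellipse: BMOEllipse,
    d_phi_deg: float = 0.5,
    d_e_um: float = 2.0,
    bounds_um: Sequence[float] = TRT_ANNULUS_BOUNDS_UM,
    max_masked_fraction: float = 0.25,
) -> AnnulusResult:
    """Area-weighted annular TRT means at eccentricities measured from the
    BMO ellipse boundary along rays from the ellipse centre.

    The quadrature is midpoint in (ray angle, eccentricity) with area weight
    rho = boundary_radius + eccentricity (distance from the ellipse centre).
    An annulus with more than ``max_masked_fraction`` of its area masked is
    reported as NaN.
    """
    phi = np.arange(0.0, 360.0, d_phi_deg) + 0.5 * d_phi_deg
    phir = np.radians(phi)
    rb = ellipse.boundary_radius(phir)  # (nphi,)
    cx, cy = ellipse.lateral_center
    values: dict[str, float] = {}
    masked: dict[str, float] = {}
    for name, e0, e1 in zip(ANNULUS_NAMES, bounds_um[:-1], bounds_um[1:]):
        e = np.arange(e0, e1, d_e_um) + 0.5 * d_e_um
        rho = rb[:, None] + e[None, :]
        x = cx + rho * np.cos(phir)[:, None]
        y = cy + rho * np.sin(phir)[:, None]
        theta_s = np.degrees(np.arctan2(y, x))
        r_s = np.hypot(x, y)
        t = tmap.sample(theta_s, r_s)
        w = rho
        bad = np.isnan(t)
        wtot = float(w.sum())
        wbad = float(w[bad].sum())
        frac = wbad / wtot if wtot > 0 else 1.0
        masked[name] = frac
        if frac > max_masked_fraction:
            values[name] = float("nan")
        else:
            values[name] = float((w[~bad] * t[~bad]).sum() / w[~bad].sum())
    return AnnulusResult(values=values, masked_fraction=masked)


# ---------------------------------------------------------------------------
# Circular scans
# ---------------------------------------------------------------------------

def circle_eccentricity_um(scan_diameter_mm: float, bmo_diameter_um: float) -> float:
    """Mean eccentricity of a circumpapillary circle from the BMO margin:
    (scan diameter - BMO equivalent diameter) / 2, in micrometres."""
    return (scan_diameter_mm * 1000.0 - bmo_diameter_um) / 2.0


def circular_means(scan: CircularScan) -> tuple[float, float, float]:
    """(RNFLT, TRT, choroid thickness) means over one circular scan.

    Thicknesses are axial (z) differences; the mean is the trapezoidal
    integral over contiguous valid arcs (including the wrap-around segment)
    divided by the total valid arc length, i.e. angular-gap weighting.
    """
    rnfl = scan.ilm_z - scan.rnfl_post_z
    trt = scan.ilm_z - scan.bm_z
    chor = scan.bm_z - scan.choroid_sclera_z
    th = scan.theta
    valid = scan.valid

    gaps = np.diff(th)
    wrap_gap = th[0] + 360.0 - th[-1]
    pair_ok = valid[:-1] & valid[1:]
    wrap_ok = bool(valid[-1] and valid[0]) and wrap_gap > 0

    def wmean(t: np.ndarray) -> float:
        total = float(((t[:-1] + t[1:]) / 2.0 * gaps)[pair_ok].sum())
        wsum = float(gaps[pair_ok].sum())
        if wrap_ok:
            total += (t[-1] + t[0]) / 2.0 * wrap_gap
            wsum += wrap_gap
        if wsum == 0:
            raise GeometryError("no contiguous valid arc on circular scan")
        return total / wsum

    return wmean(rnfl), wmean(trt), wmean(chor)


# ---------------------------------------------------------------------------
# Session aggregation
# ---------------------------------------------------------------------------

@dataclass
class MorphometryResult:
    """All global structural parameters of one imaging session."""

    mrw_global: float = float("nan")
    mrw_per_point: Optional[np.ndarray] = None  # (48,)
    bmo_height_global: float = float("nan")
    alcsd_global: Optional[float] = None
    bmo_area_mm2: float = float("nan")
    trt250: float = float("nan")
    trt500: float = float("nan")
    trt1000: float = float("nan")
    trt1500: float = float("nan")
    rnflt: dict[float, float] = field(default_factory=dict)      # by diameter_mm
    trt_circ: dict[float, float] = field(default_factory=dict)
    choroidt: dict[float, float] = field(default_factory=dict)
    completeness: dict[str, str] = field(default_factory=dict)

    def to_dict(self) -> dict:
        def _clean(v):
            return None if v is None or (isinstance(v, float) and math.isnan(v)) else v

        return {
            "mrw_global_um": _clean(self.mrw_global),
            "mrw_per_point_um": (
                None if self.mrw_per_point is None else [float(v) for v in self.mrw_per_point]
            ),
            "bmo_height_global_um": _clean(self.bmo_height_global),
            "alcsd_global_um": _clean(self.alcsd_global),
            "bmo_area_mm2": _clean(self.bmo_area_mm2),
            "trt_annuli_um": {k: _clean(getattr(self, k)) for k in ANNULUS_NAMES},
            "rnflt_um": {str(k): _clean(v) for k, v in sorted(self.rnflt.items())},
            "trt_circ_um": {str(k): _clean(v) for k, v in sorted(self.trt_circ.items())},
            "choroidt_um": {str(k): _clean(v) for k, v in sorted(self.choroidt.items())},
            "completeness": dict(sorted(self.completeness.items())),
        }


def session_morphometry(
    rset: SegmentedRadialSet,
    circles: Sequence[CircularScan] = (),
) -> MorphometryResult:
    """Compute every structural parameter for one session.

    Per-field failures are recorded in ``result.completeness`` rather than
    aborting the whole session.
    """
    res = MorphometryResult()

    def _stage(name: str, fn) -> None:
        try:
            fn()
            res.completeness.setdefault(name, "ok")
        except Exception as exc:  # noqa: BLE001 - recorded, not swallowed silently
            res.completeness[name] = f"{type(exc).__name__}: {exc}"

    def _mrw():
        res.mrw_global, res.mrw_per_point = global_mrw(rset)

    def _height():
        res.bmo_height_global, _ = global_bmo_height(rset)

    def _alcsd():
        res.alcsd_global = global_alcs_depth(rset)
        if res.alcsd_global is None:
            res.completeness["alcsd"] = "missing: no usable ALCS samples"

    def _ellipse_and_annuli():
        ellipse = fit_bmo_ellipse(rset.bmo_points_3d())
        res.bmo_area_mm2 = ellipse.area_mm2
        res.completeness["bmo_area"] = "ok"
        tmap = trt_map(rset)
        ann = trt_annuli(tmap, ellipse)
        for name in ANNULUS_NAMES:
            v = ann.values[name]
            setattr(res, name, v)
            res.completeness[name] = (
                "ok" if not math.isnan(v)
                else f"invalid: {ann.masked_fraction[name]:.0%} masked"
            )

    _stage("mrw", _mrw)
    _stage("bmo_height", _height)
    _stage("alcsd", _alcsd)
    _stage("trt_annuli", _ellipse_and_annuli)

    for scan in circles:
        def _circ(scan=scan):
            r, t, c = circular_means(scan)
            res.rnflt[scan.diameter_mm] = r
            res.trt_circ[scan.diameter_mm] = t
            res.choroidt[scan.diameter_mm] = c

        _stage(f"circle_{scan.diameter_mm}", _circ)
    return res
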