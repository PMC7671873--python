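"""Synthetic data: analytic ONH phantoms and simulated diurnal cohorts.

Phantoms
--------
A phantom is a small family of closed-form surfaces (all in um, anterior
positive z, lateral polar coordinates ``r``, ``theta`` about the scan
centre):

* BMO boundary: lateral ellipse ``(a cos t, b sin t)`` lying in the plane
  ``z = tan(tilt) * x - depth`` (so the 48 marks are exactly coplanar and
  exactly on an ellipse).
* BM: ``z = tan(tilt) * x - depth * g(e)`` with ``e = r - R(theta)`` the
  lateral eccentricity from the BMO margin; ``g`` is 1 inside the opening
  and decays smoothly outward, which produces a negative BMO height against
  the 4-mm BM chord.
* outer ILM: ``BM + T(e)`` where the thickness profile
  ``T(e) = h + (base - h)(1 - exp(-e/knee)) + slope * e`` starts at the rim
  height ``h`` (continuity at the margin) and relaxes toward the
  peripapillary baseline.
* inner ILM: a flat rim shelf of height ``h`` above the BMO point for the
  first ``rim_shelf_um`` of inward distance, then a polynomial cup.  With
  ``rim_shelf_um >= h`` the nearest ILM point to each BMO mark is the one
  directly above it, so ground-truth MRW is exactly ``h``.
* lamina: ``z = tan(tilt) * x - depth - d_L + bow * (r/1000)^2``.

``make_phantom`` samples these surfaces as a ``SegmentedRadialSet`` and four
``CircularScan`` objects, and separately computes ground truth by dense
numeric evaluation (0.1 um resampling / fine quadrature) of the analytic
surfaces — never via the measurement pipeline, so it can serve as an
independent oracle.

Cohorts
-------
``simulate_cohort`` draws per-subject baselines, piecewise-linear diurnal
trajectories (decline to the 3 p.m. session, then plateau, with
subject-level random total change and a sex effect), head-down-tilt step
responses, and independent per-session measurement noise.  Every default is
a config field; all generators are fully determined by the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .errors import GeometryError
from .morphometry import MorphometryResult
from .pressures import mopp as _mopp
from .scan_model import (
    ANGLE_STEP_DEG,
    CIRCLE_DIAMETERS_MM,
    N_BSCANS,
    TIME_LABELS,
    HDT_ENDPOINT_LABEL,
    CircularScan,
    LayerPolyline,
    RadialBScan,
    SegmentedRadialSet,
)

# ---------------------------------------------------------------------------
# Phantom specification and surfaces
# ---------------------------------------------------------------------------

_BM_DECAY_UM = 700.0  # lateral decay scale of the BM depression beyond the margin


@dataclass(frozen=True)
class PhantomSpec:
    """Parametric ONH phantom with derivable ground-truth morphometry."""

    bmo_a_um: float = 850.0           # lateral semi-major axis
    bmo_b_um: float = 764.0           # lateral semi-minor axis
    bmo_tilt_deg: float = 2.0         # BMO plane tilt about the y axis
    bmo_depth_um: float = 105.0       # depth of the BMO plane below peripheral BM
    rim_height_um: float = 355.0      # ILM shelf height above the BMO points
    rim_shelf_um: float = 400.0       # inward extent of the flat rim shelf
    cup_depth_um: float = 380.0
    cup_exponent: float = 2.0
    trt_base_um: float = 385.0        # peripapillary thickness plateau
    trt_knee_um: float = 220.0
    trt_slope_per_um: float = -0.05
    choroid_base_um: float = 180.0    # at r = 1350 um
    choroid_slope_per_um: float = 0.056
    rnfl_base_um: float = 142.8       # at r = 1350 um
    rnfl_slope_per_um: float = -0.048
    rnfl_cos2_amp_um: float = 8.0
    lamina_depth_um: float = 440.0    # below the BMO plane
    lamina_bow_um: float = 0.0
    alcs_cover_fraction: float = 0.85
    include_alcs: bool = True
    noise_sd_um: float = 0.0          # axial segmentation noise
    seed: int = 0

    def validate(self) -> "PhantomSpec":
        if not (self.bmo_a_um >= self.bmo_b_um > 0):
            raise GeometryError("phantom: need bmo_a >= bmo_b > 0")
        if self.rim_height_um <= 0:
            raise GeometryError("phantom: rim height must be positive")
        if self.cup_depth_um < 0 or self.cup_depth_um > self.rim_height_um + self.lamina_depth_um:
            raise GeometryError("phantom: cup reaches below the lamina")
        e = np.linspace(0.0, 1800.0, 512)
        if np.any(self._trt(e) <= 0):
            raise GeometryError("phantom: TRT profile non-positive (ILM below BM)")
        if not (0 < self.alcs_cover_fraction <= 1):
            raise GeometryError("phantom: alcs_cover_fraction must be in (0, 1]")
        if self.noise_sd_um < 0:
            raise GeometryError("phantom: noise SD must be >= 0")
        return self

    # -- analytic surfaces (vectorised over numpy arrays) -------------------

    @property
    def _k(self) -> float:
        return math.tan(math.radians(self.bmo_tilt_deg))

    def boundary_radius(self, theta_rad):
        a, b = self.bmo_a_um, self.bmo_b_um
        return a * b / np.sqrt(
            (b * np.cos(theta_rad)) ** 2 + (a * np.sin(theta_rad)) ** 2
        )

    def _trt(self, e):
        h, base = self.rim_height_um, self.trt_base_um
        return (
            h
            + (base - h) * (1.0 - np.exp(-np.maximum(e, 0.0) / self.trt_knee_um))
            + self.trt_slope_per_um * np.maximum(e, 0.0)
        )

    def bm_z(self, x, y):
        r = np.hypot(x, y)
        theta = np.arctan2(y, x)
        e = r - self.boundary_radius(theta)
        g = np.where(e <= 0, 1.0, np.exp(-((np.maximum(e, 0.0) / _BM_DECAY_UM) ** 2)))
        return self._k * x - self.bmo_depth_um * g

    def ilm_z(self, x, y):
        r = np.hypot(x, y)
        theta = np.arctan2(y, x)
        rb = self.boundary_radius(theta)
        e = r - rb
        outer = self.bm_z(x, y) + self._trt(e)
        # inner: flat shelf then polynomial cup, hung from the BMO point z
        z_margin = self._k * rb * np.cos(theta) - self.bmo_depth_um
        d = rb - r
        denom = np.maximum(rb - self.rim_shelf_um, 1.0)
        q = np.clip((d - self.rim_shelf_um) / denom, 0.0, 1.0)
        inner = z_margin + self.rim_height_um - self.cup_depth_um * q ** self.cup_exponent
        return np.where(e > 0, outer, inner)

    def alcs_z(self, x, y):
        r = np.hypot(x, y)
        return (
            self._k * x
            - self.bmo_depth_um
            - self.lamina_depth_um
            + self.lamina_bow_um * (r / 1000.0) ** 2
        )

    def rnfl_thickness(self, r, theta_rad):
        return (
            self.rnfl_base_um
            + self.rnfl_slope_per_um * (r - 1350.0)
            + self.rnfl_cos2_amp_um * np.cos(2.0 * theta_rad)
        )

    def choroid_thickness(self, r, theta_rad):
        return np.broadcast_to(
            self.choroid_base_um + self.choroid_slope_per_um * (np.asarray(r, dtype=float) - 1350.0),
            np.broadcast_shapes(np.shape(r), np.shape(theta_rad)),
        ).copy()


def random_phantom_spec(rng: np.random.Generator, noise_sd_um: float = 0.0) -> PhantomSpec:
    """A randomized valid phantom, bounded to plausible adult ONH geometry."""
    a = rng.uniform(720.0, 940.0)
    b = rng.uniform(0.75 * a, a)
    h = rng.uniform(300.0, 420.0)
    d_l = rng.uniform(380.0, 500.0)
    return PhantomSpec(
        bmo_a_um=a,
        bmo_b_um=b,
        bmo_tilt_deg=rng.uniform(0.0, 3.0),
        bmo_depth_um=rng.uniform(60.0, 150.0),
        rim_height_um=h,
        rim_shelf_um=rng.uniform(340.0, 460.0),
        cup_depth_um=rng.uniform(250.0, min(500.0, h + d_l - 50.0)),
        trt_base_um=rng.uniform(360.0, 420.0),
        trt_knee_um=rng.uniform(150.0, 300.0),
        trt_slope_per_um=rng.uniform(-0.06, -0.03),
        choroid_base_um=rng.uniform(150.0, 220.0),
        choroid_slope_per_um=rng.uniform(0.03, 0.07),
        rnfl_base_um=rng.uniform(120.0, 160.0),
        rnfl_slope_per_um=rng.uniform(-0.055, -0.04),
        rnfl_cos2_amp_um=rng.uniform(0.0, 15.0),
        lamina_depth_um=d_l,
        lamina_bow_um=rng.uniform(0.0, 25.0),
        alcs_cover_fraction=rng.uniform(0.7, 0.9),
        noise_sd_um=noise_sd_um,
        seed=int(rng.integers(0, 2**31 - 1)),
    ).validate()


# ---------------------------------------------------------------------------
# Phantom sampling
# ---------------------------------------------------------------------------

_RADIAL_SPAN_UM = 2460.0
_RADIAL_STEP_UM = 10.0
_ALCS_STEP_UM = 5.0
_CIRCLE_STEP_DEG = 1.0


def _bscan_grid(spec: PhantomSpec, r_bmo: float) -> np.ndarray:
    base = np.arange(-_RADIAL_SPAN_UM, _RADIAL_SPAN_UM + 0.5 * _RADIAL_STEP_UM,
                     _RADIAL_STEP_UM)
    extra = np.array([-2000.0, 2000.0, -r_bmo, r_bmo])
    return np.unique(np.concatenate([base, extra]))


def make_phantom(
    spec: PhantomSpec,
) -> tuple[SegmentedRadialSet, list[CircularScan], MorphometryResult]:
    """Sample a phantom as scan containers and return dense-evaluation ground
    truth computed on the noise-free analytic surfaces."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    truth = phantom_ground_truth(spec)

    bscans = []
    for k in range(N_BSCANS):
        ang = k * ANGLE_STEP_DEG
        th = math.radians(ang)
        r_b = float(spec.boundary_radius(th))  # same on both half-lines
        s = _bscan_grid(spec, r_b)
        x, y = s * math.cos(th), s * math.sin(th)
        ilm = spec.ilm_z(x, y) + rng.normal(0.0, spec.noise_sd_um, s.size)
        bm = spec.bm_z(x, y) + rng.normal(0.0, spec.noise_sd_um, s.size)
        z_left = float(spec.bm_z(-r_b * math.cos(th), -r_b * math.sin(th)))
        z_right = float(spec.bm_z(r_b * math.cos(th), r_b * math.sin(th)))
        z_left += float(rng.normal(0.0, spec.noise_sd_um))
        z_right += float(rng.normal(0.0, spec.noise_sd_um))
        alcs = None
        if spec.include_alcs:
            half = spec.alcs_cover_fraction * r_b
            s_a = np.arange(-half, half + 0.5 * _ALCS_STEP_UM, _ALCS_STEP_UM)
            za = spec.alcs_z(s_a * math.cos(th), s_a * math.sin(th))
            za = za + rng.normal(0.0, spec.noise_sd_um, s_a.size)
            alcs = LayerPolyline("ALCS", np.column_stack([s_a, za]))
        bscans.append(RadialBScan(
            index=k,
            angle_deg=ang,
            ilm=LayerPolyline("ILM", np.column_stack([s, ilm])),
            bm=LayerPolyline("BM", np.column_stack([s, bm])),
            alcs=alcs,
            bmo_left=(-r_b, z_left),
            bmo_right=(r_b, z_right),
        ))
    rset = SegmentedRadialSet(bscans=tuple(bscans))

    circles = []
    for diam in CIRCLE_DIAMETERS_MM:
        r_c = diam * 1000.0 / 2.0
        theta = np.arange(0.0, 360.0, _CIRCLE_STEP_DEG)
        tr = np.radians(theta)
        x, y = r_c * np.cos(tr), r_c * np.sin(tr)
        bm = spec.bm_z(x, y)
        ilm = spec.ilm_z(x, y)
        rnfl_post = ilm - spec.rnfl_thickness(r_c, tr)
        chs = bm - spec.choroid_thickness(r_c, tr)
        noise = lambda: rng.normal(0.0, spec.noise_sd_um, theta.size)  # noqa: E731
        circles.append(CircularScan(
            diameter_mm=diam,
            theta=theta,
            ilm_z=ilm + noise(),
            rnfl_post_z=rnfl_post + noise(),
            bm_z=bm + noise(),
            choroid_sclera_z=chs + noise(),
            valid=np.ones(theta.size, dtype=bool),
        ))
    return rset, circles, truth


# ---------------------------------------------------------------------------
# Dense-evaluation ground truth (the oracle; independent of the pipeline)
# ---------------------------------------------------------------------------

_DENSE_STEP_UM = 0.1
_QUAD_PHI_STEP_DEG = 0.25
_QUAD_E_STEP_UM = 0.5
_CIRC_QUAD_STEP_DEG = 0.02


def _truth_mrw(spec: PhantomSpec) -> np.ndarray:
    """48 per-point rim widths by brute-force dense search of the inner ILM."""
    out = []
    for k in range(N_BSCANS):
        th = math.radians(k * ANGLE_STEP_DEG)
        r_b = float(spec.boundary_radius(th))
        s = np.arange(-r_b, r_b + 0.5 * _DENSE_STEP_UM, _DENSE_STEP_UM)
        z = spec.ilm_z(s * math.cos(th), s * math.sin(th))
        for sign in (-1.0, 1.0):
            p_s = sign * r_b
            p_z = float(spec.bm_z(p_s * math.cos(th), p_s * math.sin(th)))
            out.append(float(np.min(np.hypot(s - p_s, z - p_z))))
    # reorder: dense loop appended (left, right) per b-scan already
    return np.asarray(out)


def _truth_bmo_height(spec: PhantomSpec) -> np.ndarray:
    out = []
    for k in range(N_BSCANS):
        th = math.radians(k * ANGLE_STEP_DEG)
        c, sn = math.cos(th), math.sin(th)
        q0 = np.array([-2000.0, float(spec.bm_z(-2000.0 * c, -2000.0 * sn))])
        q1 = np.array([2000.0, float(spec.bm_z(2000.0 * c, 2000.0 * sn))])
        t = q1 - q0
        nvec = np.array([-t[1], t[0]])
        nvec = nvec / np.linalg.norm(nvec)
        r_b = float(spec.boundary_radius(th))
        for sign in (-1.0, 1.0):
            p = np.array([sign * r_b, float(spec.bm_z(sign * r_b * c, sign * r_b * sn))])
            out.append(float(nvec @ (p - q0)))
    return np.asarray(out)


def _truth_alcsd(spec: PhantomSpec) -> Optional[float]:
    if not spec.include_alcs:
        return None
    vals = []
    for k in range(N_BSCANS):
        th = math.radians(k * ANGLE_STEP_DEG)
        c, sn = math.cos(th), math.sin(th)
        r_b = float(spec.boundary_radius(th))
        p0 = np.array([-r_b, float(spec.bm_z(-r_b * c, -r_b * sn))])
        p1 = np.array([r_b, float(spec.bm_z(r_b * c, r_b * sn))])
        chord = p1 - p0
        length = float(np.linalg.norm(chord))
        u = chord / length
        nvec = np.array([-u[1], u[0]])
        if nvec[1] < 0:
            nvec = -nvec
        half = spec.alcs_cover_fraction * r_b
        s = np.arange(-half, half + 0.5 * _DENSE_STEP_UM, _DENSE_STEP_UM)
        z = spec.alcs_z(s * c, s * sn)
        q = np.column_stack([s, z]) - p0
        foot = q @ u
        keep = (foot >= 0.25 * length) & (foot <= 0.75 * length)
        if keep.sum() >= 3:
            vals.append(float((q[keep] @ nvec).mean()))
    return float(np.mean(vals)) if vals else None


def _truth_area_mm2(spec: PhantomSpec) -> float:
    # planar ellipse tilted about y: in-plane axes stretch the x extent
    k = spec._k
    return math.pi * spec.bmo_a_um * spec.bmo_b_um * math.sqrt(1.0 + k * k) / 1e6


def _truth_annuli(spec: PhantomSpec) -> dict[str, float]:
    """Fine (phi, eccentricity) quadrature with area weight rho = R(phi) + e.

    The phantom thickness depends only on eccentricity, so the phi integral
    reduces to the mean boundary radius; both factors are still evaluated
    densely rather than in closed form.
    """
    phi = np.radians(np.arange(0.0, 360.0, _QUAD_PHI_STEP_DEG) + 0.5 * _QUAD_PHI_STEP_DEG)
    mean_r = float(spec.boundary_radius(phi).mean())
    bounds = (0.0, 250.0, 500.0, 1000.0, 1500.0)
    names = ("trt250", "trt500", "trt1000", "trt1500")
    out = {}
    for name, e0, e1 in zip(names, bounds[:-1], bounds[1:]):
        e = np.arange(e0, e1, _QUAD_E_STEP_UM) + 0.5 * _QUAD_E_STEP_UM
        w = mean_r + e
        out[name] = float((spec._trt(e) * w).sum() / w.sum())
    return out


def _truth_circles(spec: PhantomSpec) -> dict[str, dict[float, float]]:
    out = {"rnflt": {}, "trt": {}, "choroidt": {}}
    tr = np.radians(np.arange(0.0, 360.0, _CIRC_QUAD_STEP_DEG))
    for diam in CIRCLE_DIAMETERS_MM:
        r_c = diam * 1000.0 / 2.0
        e = r_c - spec.boundary_radius(tr)
        out["rnflt"][diam] = float(spec.rnfl_thickness(r_c, tr).mean())
        out["trt"][diam] = float(spec._trt(e).mean())
        out["choroidt"][diam] = float(spec.choroid_thickness(r_c, tr).mean())
    return out


def phantom_ground_truth(spec: PhantomSpec) -> MorphometryResult:
    """Ground-truth morphometry of the noise-free phantom surfaces."""
    spec.validate()
    mrw = _truth_mrw(spec)
    heights = _truth_bmo_height(spec)
    annuli = _truth_annuli(spec)
    circ = _truth_circles(spec)
    res = MorphometryResult(
        mrw_global=float(mrw.mean()),
        mrw_per_point=mrw,
        bmo_height_global=float(heights.mean()),
        alcsd_global=_truth_alcsd(spec),
        bmo_area_mm2=_truth_area_mm2(spec),
        rnflt=circ["rnflt"],
        trt_circ=circ["trt"],
        choroidt=circ["choroidt"],
    )
    for name, v in annuli.items():
        setattr(res, name, v)
    res.completeness = {"source": "dense ground truth"}
    return res


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

# session-profile shapes (one coefficient per time label, 7 a.m. first)
PROFILE_FLAT = (0.0,) * 7
PROFILE_DECLINE_PLATEAU = (0.0, 0.25, 0.5, 0.75, 1.0, 1.0, 1.0)
PROFILE_MIDDAY_DIP = (0.0, 0.5, 1.0, 1.0, 0.6, 0.3, 0.1)
PROFILE_LATE_RISE = (0.0, 0.0, 0.0, 0.0, 1 / 3, 2 / 3, 1.0)
PROFILE_STEP = (1.0,) * 7
PROFILE_HDT_IOP = (1.0, 0.7, 0.55, 0.45, 0.4, 0.35, 0.45)
PROFILE_HDT_BMOH = (-0.2, 0.8, 1.0, 0.9, 1.0, 0.95, 0.9)
PROFILE_HDT_MAP = (1.0, 1.0, 0.7, 0.4, 0.1, -0.1, -0.3)


@dataclass(frozen=True)
class ParamSim:
    """Simulation settings for one cohort parameter."""

    baseline_mean: float
    baseline_sd: float
    noise_sw: float                      # per-session measurement noise SD
    change_female: float = 0.0           # 12-h total change, seated arm
    change_male: float = 0.0
    change_sd: float = 0.0               # between-subject SD of total change
    profile: tuple = PROFILE_DECLINE_PLATEAU
    hdt_step: float = 0.0                # step response on HDT sessions
    hdt_step_sd: float = 0.0
    hdt_profile: tuple = PROFILE_STEP


def default_cohort_params() -> dict[str, ParamSim]:
    """Default parameter set for a healthy diurnal cohort.

    Baseline means/SDs, seated 12-hour changes (including the sex split for
    the rim and inner annuli), HDT step responses, and measurement noise
    (within-subject SD = coefficient of repeatability / 2.77) are all
    configurable fields; IOP/ONSD/MAP noise defaults are assumptions, the
    rest mirror measured repeatability of the same parameters.
    """
    sw = {  # noise defaults: repeatability / 2.77
        "mrw": 4.40 / 2.77, "bmo_height": 8.03 / 2.77, "alcsd": 25.01 / 2.77,
        "bmo_area": 0.06 / 2.77,
        "trt250": 4.85 / 2.77, "trt500": 3.07 / 2.77,
        "trt1000": 2.13 / 2.77, "trt1500": 2.80 / 2.77,
        "rnflt_27": 3.82 / 2.77, "rnflt_35": 2.60 / 2.77,
        "rnflt_42": 2.41 / 2.77, "rnflt_49": 2.24 / 2.77,
        "choroidt_27": 20.28 / 2.77, "choroidt_35": 13.85 / 2.77,
        "choroidt_42": 13.71 / 2.77, "choroidt_49": 14.76 / 2.77,
    }
    p = {
        "iop": ParamSim(13.50, 3.14, 0.8, hdt_step=4.37, hdt_step_sd=1.92,
                        hdt_profile=PROFILE_HDT_IOP),
        "onsd": ParamSim(5.07, 0.49, 0.15, hdt_step=0.43, hdt_step_sd=0.48),
        "map": ParamSim(87.51, 9.46, 4.0,
                        change_female=4.0, change_male=4.0, change_sd=3.0,
                        profile=PROFILE_LATE_RISE,
                        hdt_step=-6.80, hdt_step_sd=5.49,
                        hdt_profile=PROFILE_HDT_MAP),
        "mrw": ParamSim(355.31, 61.76, sw["mrw"],
                        change_female=-13.56, change_male=-5.55, change_sd=7.05),
        "bmo_height": ParamSim(-102.01, 45.59, sw["bmo_height"],
                               change_female=-3.7, change_male=-3.7, change_sd=3.0,
                               profile=PROFILE_MIDDAY_DIP,
                               hdt_step=11.0, hdt_step_sd=5.0,
                               hdt_profile=PROFILE_HDT_BMOH),
        "alcsd": ParamSim(-440.14, 90.69, sw["alcsd"]),
        "bmo_area": ParamSim(2.04, 0.44, sw["bmo_area"], profile=PROFILE_FLAT),
        "trt250": ParamSim(394.77, 36.66, sw["trt250"],
                           change_female=-9.6, change_male=-4.6, change_sd=6.0),
        "trt500": ParamSim(375.02, 20.64, sw["trt500"],
                           change_female=-4.9, change_male=-2.1, change_sd=3.5),
        "trt1000": ParamSim(343.08, 13.27, sw["trt1000"]),
        "trt1500": ParamSim(317.12, 11.22, sw["trt1500"]),
        "rnflt_27": ParamSim(142.85, 14.51, sw["rnflt_27"],
                             change_female=-1.24, change_male=-1.24, change_sd=2.35),
        "rnflt_35": ParamSim(118.96, 10.79, sw["rnflt_35"],
                             change_female=-0.91, change_male=-0.91, change_sd=1.91),
        "rnflt_42": ParamSim(102.93, 9.10, sw["rnflt_42"],
                             change_female=-1.0, change_male=-1.0, change_sd=2.0),
        "rnflt_49": ParamSim(90.10, 7.91, sw["rnflt_49"]),
        "choroidt_27": ParamSim(179.84, 41.48, sw["choroidt_27"],
                                change_female=-8.0, change_male=-8.0, change_sd=6.0,
                                profile=PROFILE_MIDDAY_DIP),
        "choroidt_35": ParamSim(211.25, 50.72, sw["choroidt_35"],
                                change_female=-8.0, change_male=-8.0, change_sd=6.0,
                                profile=PROFILE_MIDDAY_DIP),
        "choroidt_42": ParamSim(228.83, 53.85, sw["choroidt_42"],
                                change_female=-9.0, change_male=-9.0, change_sd=6.0,
                                profile=PROFILE_MIDDAY_DIP),
        "choroidt_49": ParamSim(241.26, 55.44, sw["choroidt_49"],
                                change_female=-9.0, change_male=-9.0, change_sd=6.0,
                                profile=PROFILE_MIDDAY_DIP),
    }
    return p


@dataclass(frozen=True)
class CohortSimSpec:
    """Simulation settings for a diurnal cohort."""

    n_subjects: int = 30
    n_female: int = 15
    seed: int = 0
    params: dict = field(default_factory=default_cohort_params)
    cuff_seated_cm: float = 38.4       # eye above cuff when seated
    cuff_hdt_cm: float = -10.0         # eye below cuff in head-down tilt
    include_baseline_duplicates: bool = True
    p_missing_bp: float = 0.0

    def validate(self) -> "CohortSimSpec":
        if self.n_subjects < 1 or not (0 <= self.n_female <= self.n_subjects):
            raise GeometryError("cohort: invalid subject counts")
        for name, ps in self.params.items():
            for f in ("baseline_sd", "noise_sw", "change_sd", "hdt_step_sd"):
                if getattr(ps, f) < 0:
                    raise GeometryError(f"cohort: {name}.{f} must be >= 0")
            if len(ps.profile) != 7 or len(ps.hdt_profile) != 7:
                raise GeometryError(f"cohort: {name}: profiles must have 7 entries")
        return self


def _finish_rows(rows: list[dict], spec: CohortSimSpec, rng: np.random.Generator) -> None:
    """Fill derived pressure columns on simulated rows in place."""
    for row in rows:
        cuff = spec.cuff_seated_cm if row["posture"] == "SEATED" else spec.cuff_hdt_cm
        row["cuff_eye_cm"] = cuff
        row["mopp"] = _mopp(row["map"], cuff, row["iop"])
        row["dbp"] = row["map"] - 40.0 / 3.0
        row["sbp"] = row["dbp"] + 40.0
        delta = abs(rng.normal(0.0, 0.4))
        row["iop1"], row["iop2"], row["iop3"] = (
            row["iop"] + delta, row["iop"], row["iop"] - delta,
        )


def simulate_cohort(spec: CohortSimSpec, arm: str = "seated") -> pd.DataFrame:
    """Simulate a long-format cohort table.

    ``arm``: ``"seated"`` (12-h seated experiment), ``"hdt"`` (12-h
    head-down-tilt day, with a 7 a.m. seated baseline and a seated
    endpoint), or ``"both"`` (the same subjects on both days).
    Deterministic for a fixed spec and seed.
    """
    if arm not in ("seated", "hdt", "both"):
        raise ValueError(f"arm must be seated|hdt|both, got {arm!r}")
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    names = list(spec.params)
    rows: list[dict] = []

    for i in range(spec.n_subjects):
        sid = f"S{i + 1:03d}"
        sex = "F" if i < spec.n_female else "M"
        base = {
            n: rng.normal(ps.baseline_mean, ps.baseline_sd)
            for n, ps in spec.params.items()
        }
        change = {
            n: rng.normal(
                ps.change_female if sex == "F" else ps.change_male, ps.change_sd
            )
            for n, ps in spec.params.items()
        }
        hdt_step = {
            n: rng.normal(ps.hdt_step, ps.hdt_step_sd)
            for n, ps in spec.params.items()
        }

        def _noise(n):
            return rng.normal(0.0, spec.params[n].noise_sw)

        if arm in ("seated", "both"):
            for j, tl in enumerate(TIME_LABELS):
                row = {"subject_id": sid, "sex": sex, "arm": "seated",
                       "time_label": tl, "posture": "SEATED", "replicate": 1}
                for n, ps in spec.params.items():
                    row[n] = base[n] + ps.profile[j] * change[n] + _noise(n)
                rows.append(row)
            if spec.include_baseline_duplicates:
                row = {"subject_id": sid, "sex": sex, "arm": "seated",
                       "time_label": "7a", "posture": "SEATED", "replicate": 2}
                for n, ps in spec.params.items():
                    row[n] = base[n] + ps.profile[0] * change[n] + _noise(n)
                rows.append(row)

        if arm in ("hdt", "both"):
            row = {"subject_id": sid, "sex": sex, "arm": "hdt",
                   "time_label": "7a", "posture": "SEATED", "replicate": 1}
            for n in names:
                row[n] = base[n] + _noise(n)
            rows.append(row)
            for j, tl in enumerate(TIME_LABELS):
                row = {"subject_id": sid, "sex": sex, "arm": "hdt",
                       "time_label": tl, "posture": "HDT", "replicate": 1}
                for n, ps in spec.params.items():
                    row[n] = base[n] + ps.hdt_profile[j] * hdt_step[n] + _noise(n)
                rows.append(row)
            row = {"subject_id": sid, "sex": sex, "arm": "hdt",
                   "time_label": HDT_ENDPOINT_LABEL, "posture": "SEATED",
                   "replicate": 1}
            for n in names:
                row[n] = base[n] + _noise(n)
            rows.append(row)

    _finish_rows(rows, spec, rng)
    df = pd.DataFrame(rows)

    if spec.p_missing_bp > 0:
        miss = (
            (rng.random(len(df)) < spec.p_missing_bp)
            & (df["time_label"] != "7a").to_numpy()
        )
        df.loc[miss, ["map", "mopp", "sbp", "dbp"]] = np.nan
    return df


def simulate_repeatability(
    n: int,
    sigma_w: float,
    seed: int,
    mean: float = 355.31,
    between_sd: float = 61.76,
) -> pd.DataFrame:
    """Duplicate-measurement table: per-subject true value plus two noisy
    replicates with within-subject SD ``sigma_w``."""
    if n < 2:
        raise ValueError("need n >= 2 subjects")
    if sigma_w < 0:
        raise ValueError("sigma_w must be >= 0")
    rng = np.random.default_rng(seed)
    true = rng.normal(mean, between_sd, n)
    reps = true[:, None] + rng.normal(0.0, sigma_w, (n, 2))
    return pd.DataFrame({
        "subject_id": np.repeat([f"S{i + 1:03d}" for i in range(n)], 2),
        "replicate": np.tile([1, 2], n),
        "value": reps.ravel(),
    })
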