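"""Pressure covariates and optic nerve sheath diameter.

MAP and MOPP follow the standard estimates

    MAP  = (2 * DBP + SBP) / 3
    MOPP = [MAP - 0.77 mmHg/cm * (vertical cuff-to-eye distance)] - IOP

with the cuff-to-eye distance signed positive when the eye is vertically
above the cuff (seated); in head-down tilt the distance is negative, which
raises MOPP even when MAP falls.

ONSD is measured at the point 3 mm along the nerve axis (arc length) from
the posterior globe: the sheath width is the distance between the
intersections of the line through that point, perpendicular to the local
axis tangent, with the upper and lower sheath boundary traces.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from shapely.geometry import LineString

from .errors import AnalysisError, GeometryError, MeasurementError, SchemaError

HYDROSTATIC_MMHG_PER_CM = 0.77
ONSD_STATION_MM = 3.0


def mean_iop(readings: Sequence[float], strict: bool = True) -> float:
    """Mean of (normally three) rebound-tonometry readings, mmHg."""
    vals = np.asarray(list(readings), dtype=float)
    if vals.size == 0:
        raise AnalysisError("mean_iop: no readings")
    if not np.all(np.isfinite(vals)):
        raise AnalysisError("mean_iop: non-finite reading")
    if vals.size != 3:
        if strict:
            raise AnalysisError(f"mean_iop: expected 3 readings, got {vals.size}")
        warnings.warn(f"mean_iop: averaging {vals.size} readings instead of 3")
    # sort before summing so the mean is exactly permutation-invariant
    return float(np.sort(vals).mean())


def mean_arterial_pressure(sbp: float, dbp: float) -> float:
    """MAP = (2*DBP + SBP)/3; requires 0 < DBP < SBP."""
    if not (0 < dbp < sbp):
        raise AnalysisError(f"mean_arterial_pressure: need 0 < dbp < sbp, got {dbp}, {sbp}")
    return (2.0 * dbp + sbp) / 3.0


def mopp(map_mmhg: float, cuff_eye_cm: float, iop_mmhg: float) -> float:
    """Mean ocular perfusion pressure with hydrostatic cuff-height correction."""
    for name, v in (("map", map_mmhg), ("cuff_eye_cm", cuff_eye_cm), ("iop", iop_mmhg)):
        if not math.isfinite(v):
            raise AnalysisError(f"mopp: non-finite {name}")
    return map_mmhg - HYDROSTATIC_MMHG_PER_CM * cuff_eye_cm - iop_mmhg


@dataclass(frozen=True)
class PressureRecord:
    """IOP / MAP / MOPP for one session."""

    iop_readings: tuple[float, float, float]
    iop_mean: float
    sbp: float
    dbp: float
    map: float
    cuff_eye_cm: float
    mopp: float
    posture: str


def make_pressure_record(
    iop_readings: Sequence[float],
    sbp: float,
    dbp: float,
    cuff_eye_cm: float,
    posture: str,
) -> PressureRecord:
    """Compute all derived pressures and return a validated record."""
    iop = mean_iop(iop_readings)
    m = mean_arterial_pressure(sbp, dbp)
    return PressureRecord(
        iop_readings=tuple(float(v) for v in iop_readings),
        iop_mean=iop,
        sbp=float(sbp),
        dbp=float(dbp),
        map=m,
        cuff_eye_cm=float(cuff_eye_cm),
        mopp=mopp(m, cuff_eye_cm, iop),
        posture=posture,
    )


def pressure_record_from_row(row: Mapping) -> PressureRecord:
    """Build a record from one session-table row (iop1..iop3, sbp, dbp,
    cuff_eye_cm, posture)."""
    return make_pressure_record(
        [row["iop1"], row["iop2"], row["iop3"]],
        row["sbp"], row["dbp"], row["cuff_eye_cm"], row["posture"],
    )


# ---------------------------------------------------------------------------
# ONSD
# ---------------------------------------------------------------------------

def _as_polyline_mm(data, where: str) -> np.ndarray:
    arr = np.asarray(data, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise SchemaError(f"{where}: expected an (n>=2, 2) array of [x, z] in mm")
    if not np.all(np.isfinite(arr)):
        raise GeometryError(f"{where}: non-finite coordinate")
    return arr


@dataclass
class OnsdTrace:
    """Nerve axis and sheath boundary traces from one ultrasound frame (mm)."""

    globe_posterior: tuple[float, float]
    axis: np.ndarray           # (n, 2), starts at globe_posterior
    sheath_upper: np.ndarray
    sheath_lower: np.ndarray

    def __post_init__(self) -> None:
        self.axis = _as_polyline_mm(self.axis, "axis")
        self.sheath_upper = _as_polyline_mm(self.sheath_upper, "sheath_upper")
        self.sheath_lower = _as_polyline_mm(self.sheath_lower, "sheath_lower")
        gp = np.asarray(self.globe_posterior, dtype=float)
        if gp.shape != (2,) or not np.all(np.isfinite(gp)):
            raise SchemaError("globe_posterior: expected a finite [x, z] point")
        self.globe_posterior = (float(gp[0]), float(gp[1]))
        if np.linalg.norm(self.axis[0] - gp) > 1e-6:
            raise GeometryError("axis must start at globe_posterior")


def read_onsd_trace(path) -> OnsdTrace:
    with open(path) as fh:
        try:
            data = json.load(fh)
        except json.JSONDecodeError as exc:
            raise SchemaError(f"{path}: not valid JSON ({exc})") from exc
    for key in ("globe_posterior", "axis", "sheath_upper", "sheath_lower"):
        if key not in data:
            raise SchemaError(f"onsd trace: missing required field {key!r}")
    return OnsdTrace(
        globe_posterior=tuple(data["globe_posterior"]),
        axis=data["axis"],
        sheath_upper=data["sheath_upper"],
        sheath_lower=data["sheath_lower"],
    )


def _point_at_arclength(axis: np.ndarray, station: float) -> tuple[np.ndarray, np.ndarray]:
    """Point and unit tangent at a given arc length along a polyline."""
    seg = np.diff(axis, axis=0)
    seglen = np.hypot(seg[:, 0], seg[:, 1])
    cum = np.concatenate([[0.0], np.cumsum(seglen)])
    if cum[-1] < station:
        raise MeasurementError(
            f"nerve axis arc length {cum[-1]:.2f} mm is shorter than the "
            f"{station:.1f} mm measurement station"
        )
    i = int(np.searchsorted(cum, station, side="right") - 1)
    i = min(i, len(seglen) - 1)
    t = (station - cum[i]) / seglen[i] if seglen[i] > 0 else 0.0
    point = axis[i] + t * seg[i]
    tangent = seg[i] / seglen[i]
    return point, tangent


def measure_onsd(trace: OnsdTrace, station_mm: float = ONSD_STATION_MM) -> float:
    """ONSD (mm) at ``station_mm`` of arc length behind the globe."""
    p, tangent = _point_at_arclength(trace.axis, station_mm)
    normal = np.array([-tangent[1], tangent[0]])
    # a caliper line long enough to cross both sheath traces
    reach = 10.0 * (station_mm + max(
        np.abs(trace.sheath_upper).max(), np.abs(trace.sheath_lower).max(), 1.0
    ))
    caliper = LineString([p - reach * normal, p + reach * normal])

    hits = []
    for name, sheath in (("sheath_upper", trace.sheath_upper),
                         ("sheath_lower", trace.sheath_lower)):
        inter = caliper.intersection(LineString(sheath))
        if inter.is_empty:
            raise MeasurementError(f"caliper does not intersect {name}")
        pts = []
        geoms = getattr(inter, "geoms", [inter])
        for g in geoms:
            pts.extend(np.asarray(g.coords))
        pts = np.asarray(pts)
        # nearest crossing to the axis point
        hits.append(pts[np.argmin(np.hypot(*(pts - p).T))])
    return float(np.linalg.norm(hits[0] - hits[1]))
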