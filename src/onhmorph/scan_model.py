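"""Containers and validated I/O for segmented OCT scan geometry.

Coordinate conventions
----------------------
* All radial/circular scan coordinates are physical micrometres.
* ``s`` is the lateral position along a radial B-scan line; ``s = 0`` is the
  common rotation centre of the radial set, negative ``s`` is the half-line
  opposite the scan's nominal angle.
* ``z`` is axial position and increases toward the vitreous (anterior
  positive), so posterior displacements are negative.
* A radial set holds 24 diameters spaced 7.5 degrees apart; together the 48
  half-lines cover the full circle.

The JSON interchange formats written/read here round-trip bit-for-bit on all
numeric fields (Python's ``json`` emits shortest-repr doubles).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .errors import (
    CompletenessError,
    GeometryError,
    QualityError,
    SchemaError,
)

N_BSCANS = 24
ANGLE_STEP_DEG = 360.0 / (2 * N_BSCANS)  # 7.5 deg between half-lines
CIRCLE_DIAMETERS_MM = (2.7, 3.5, 4.2, 4.9)
LAYER_IDS = ("ILM", "BM", "RNFL_POST", "CHOROID_SCLERA", "ALCS")
TIME_LABELS = ("7a", "9a", "11a", "1p", "3p", "5p", "7p")
HDT_ENDPOINT_LABEL = "7p_end"
POSTURES = ("SEATED", "HDT", "LLD")
MIN_QUALITY_DB = 30.0


def _as_points(samples, where: str) -> np.ndarray:
    arr = np.asarray(samples, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise SchemaError(f"{where}: expected an (n>=2, 2) array of [s, z] samples")
    if not np.all(np.isfinite(arr)):
        raise GeometryError(f"{where}: non-finite coordinate")
    return arr


@dataclass
class LayerPolyline:
    """An ordered segmentation polyline ``[(s, z), ...]`` for one layer."""

    layer_id: str
    samples: np.ndarray  # (n, 2) float64, columns [s_um, z_um]

    def __post_init__(self) -> None:
        if self.layer_id not in LAYER_IDS:
            raise SchemaError(f"layer_id: unknown layer {self.layer_id!r}")
        self.samples = _as_points(self.samples, f"{self.layer_id}.samples")
        s = self.samples[:, 0]
        if np.any(np.diff(s) <= 0):
            raise GeometryError(f"{self.layer_id}: s not strictly increasing")

    @property
    def s(self) -> np.ndarray:
        return self.samples[:, 0]

    @property
    def z(self) -> np.ndarray:
        return self.samples[:, 1]

    def z_at(self, s: np.ndarray | float) -> np.ndarray:
        """Linear interpolation of z at lateral position(s) ``s`` (in-span)."""
        return np.interp(s, self.samples[:, 0], self.samples[:, 1])

    def covers(self, s_lo: float, s_hi: float) -> bool:
        return self.samples[0, 0] <= s_lo and self.samples[-1, 0] >= s_hi

    def __eq__(self, other) -> bool:  # value semantics for round-trip tests
        return (
            isinstance(other, LayerPolyline)
            and self.layer_id == other.layer_id
            and np.array_equal(self.samples, other.samples)
        )


@dataclass
class RadialBScan:
    """One radial B-scan (full diameter) with its two marked BMO points."""

    index: int
    angle_deg: float
    ilm: LayerPolyline
    bm: LayerPolyline
    bmo_left: tuple[float, float]  # (s, z), s < bmo_right s
    bmo_right: tuple[float, float]
    alcs: Optional[LayerPolyline] = None

    def __post_init__(self) -> None:
        if not (0 <= int(self.index) < N_BSCANS):
            raise SchemaError(f"index: must be 0..{N_BSCANS - 1}, got {self.index}")
        self.index = int(self.index)
        self.angle_deg = float(self.angle_deg)
        self.bmo_left = (float(self.bmo_left[0]), float(self.bmo_left[1]))
        self.bmo_right = (float(self.bmo_right[0]), float(self.bmo_right[1]))
        for name, pt in (("bmo_left", self.bmo_left), ("bmo_right", self.bmo_right)):
            if not all(math.isfinite(v) for v in pt):
                raise GeometryError(f"{name}: non-finite coordinate")
        if not self.bmo_left[0] < self.bmo_right[0]:
            raise GeometryError(
                f"bscan {self.index}: bmo_left.s ({self.bmo_left[0]}) must be "
                f"< bmo_right.s ({self.bmo_right[0]})"
            )
        if self.ilm.layer_id != "ILM" or self.bm.layer_id != "BM":
            raise SchemaError(f"bscan {self.index}: ilm/bm polylines mislabelled")
        if self.alcs is not None and self.alcs.layer_id != "ALCS":
            raise SchemaError(f"bscan {self.index}: alcs polyline mislabelled")
        span_lo, span_hi = self.bm.s[0], self.bm.s[-1]
        for name, pt in (("bmo_left", self.bmo_left), ("bmo_right", self.bmo_right)):
            if not (span_lo <= pt[0] <= span_hi):
                raise GeometryError(
                    f"bscan {self.index}: {name}.s outside BM lateral span"
                )

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, RadialBScan)
            and self.index == other.index
            and self.angle_deg == other.angle_deg
            and self.ilm == other.ilm
            and self.bm == other.bm
            and self.alcs == other.alcs
            and self.bmo_left == other.bmo_left
            and self.bmo_right == other.bmo_right
        )


@dataclass
class SegmentedRadialSet:
    """The 24 radial B-scans of one composite ONH scan."""

    bscans: tuple[RadialBScan, ...]
    eye: str = "OD"
    axial_sign: int = 1  # +1: z increases toward the vitreous

    def __post_init__(self) -> None:
        if self.eye not in ("OD", "OS"):
            raise SchemaError(f"eye: must be OD or OS, got {self.eye!r}")
        if int(self.axial_sign) not in (1, -1):
            raise SchemaError(f"axial_sign: must be +1 or -1, got {self.axial_sign}")
        self.axial_sign = int(self.axial_sign)
        self.bscans = tuple(sorted(self.bscans, key=lambda b: b.index))
        indices = [b.index for b in self.bscans]
        if indices != list(range(N_BSCANS)):
            missing = sorted(set(range(N_BSCANS)) - set(indices))
            dupes = sorted({i for i in indices if indices.count(i) > 1})
            raise CompletenessError(
                f"radial set must contain indices 0..23 exactly once "
                f"(missing={missing}, duplicated={dupes})"
            )

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, SegmentedRadialSet)
            and self.eye == other.eye
            and self.axial_sign == other.axial_sign
            and self.bscans == other.bscans
        )

    def bmo_points_3d(self) -> np.ndarray:
        """All 48 BMO marks as (x, y, z) in micrometres, ordered
        (bscan0 left, bscan0 right, bscan1 left, ...)."""
        pts = []
        for b in self.bscans:
            th = math.radians(b.angle_deg)
            c, s = math.cos(th), math.sin(th)
            for (ss, zz) in (b.bmo_left, b.bmo_right):
                pts.append((ss * c, ss * s, zz))
        return np.asarray(pts, dtype=float)


@dataclass
class CircularScan:
    """One circumpapillary circular B-scan, angularly sampled."""

    diameter_mm: float
    theta: np.ndarray  # degrees, strictly increasing, span >= 359
    ilm_z: np.ndarray
    rnfl_post_z: np.ndarray
    bm_z: np.ndarray
    choroid_sclera_z: np.ndarray
    valid: np.ndarray  # bool per sample

    def __post_init__(self) -> None:
        if float(self.diameter_mm) not in CIRCLE_DIAMETERS_MM:
            raise SchemaError(
                f"diameter_mm: must be one of {CIRCLE_DIAMETERS_MM}, "
                f"got {self.diameter_mm}"
            )
        self.diameter_mm = float(self.diameter_mm)
        self.theta = np.asarray(self.theta, dtype=float)
        n = self.theta.size
        for name in ("ilm_z", "rnfl_post_z", "bm_z", "choroid_sclera_z"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n,):
                raise SchemaError(f"{name}: length must match theta ({n})")
            setattr(self, name, arr)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.valid.shape != (n,):
            raise SchemaError(f"valid: length must match theta ({n})")
        if n < 8 or np.any(np.diff(self.theta) <= 0):
            raise GeometryError("theta: must be strictly increasing")
        if self.theta[-1] - self.theta[0] < 359.0:
            raise GeometryError("theta: angular span must be >= 359 degrees")
        layers = np.stack([self.ilm_z, self.rnfl_post_z, self.bm_z, self.choroid_sclera_z])
        if not np.all(np.isfinite(layers[:, self.valid])):
            raise GeometryError("non-finite z at a sample flagged valid")
        masked_frac = 1.0 - float(self.valid.mean())
        if masked_frac > 0.25:
            raise QualityError(
                f"circular scan rejected: {masked_frac:.0%} of samples masked (> 25%)"
            )

    @property
    def radius_um(self) -> float:
        return self.diameter_mm * 1000.0 / 2.0

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, CircularScan)
            and self.diameter_mm == other.diameter_mm
            and all(
                np.array_equal(getattr(self, k), getattr(other, k))
                for k in ("theta", "ilm_z", "rnfl_post_z", "bm_z", "choroid_sclera_z", "valid")
            )
        )


@dataclass(frozen=True)
class SessionMeta:
    """Identity of one subject x time-point x posture scan session."""

    subject_id: str
    time_label: str
    posture: str
    scan_quality_db: float = 35.0

    def __post_init__(self) -> None:
        if self.time_label not in TIME_LABELS + (HDT_ENDPOINT_LABEL,):
            raise SchemaError(f"time_label: unknown label {self.time_label!r}")
        if self.posture not in POSTURES:
            raise SchemaError(f"posture: must be one of {POSTURES}")

    @property
    def acceptable(self) -> bool:
        """Scan acceptance rule: signal quality of at least 30 dB."""
        return self.scan_quality_db >= MIN_QUALITY_DB

    def validate_accepted(self) -> "SessionMeta":
        if not self.acceptable:
            raise QualityError(
                f"session {self.subject_id}/{self.time_label}: quality "
                f"{self.scan_quality_db} dB below {MIN_QUALITY_DB} dB"
            )
        return self


# ---------------------------------------------------------------------------
# JSON interchange
# ---------------------------------------------------------------------------

def _require(obj: Mapping, key: str, where: str):
    if key not in obj:
        raise SchemaError(f"{where}: missing required field {key!r}")
    return obj[key]


def _polyline_from_json(data, layer_id: str, where: str) -> LayerPolyline:
    if not isinstance(data, list):
        raise SchemaError(f"{where}: expected a list of [s, z] pairs")
    return LayerPolyline(layer_id=layer_id, samples=data)


def radial_set_to_dict(rset: SegmentedRadialSet) -> dict:
    out = {"eye": rset.eye, "axial_sign": rset.axial_sign, "bscans": []}
    for b in rset.bscans:
        entry = {
            "index": b.index,
            "angle_deg": b.angle_deg,
            "ilm": b.ilm.samples.tolist(),
            "bm": b.bm.samples.tolist(),
            "bmo_left": list(b.bmo_left),
            "bmo_right": list(b.bmo_right),
        }
        if b.alcs is not None:
            entry["alcs"] = b.alcs.samples.tolist()
        out["bscans"].append(entry)
    return out


def radial_set_from_dict(data: Mapping) -> SegmentedRadialSet:
    if not isinstance(data, Mapping):
        raise SchemaError("top level: expected a JSON object")
    eye = _require(data, "eye", "top level")
    axial_sign = _require(data, "axial_sign", "top level")
    bscans_json = _require(data, "bscans", "top level")
    if not isinstance(bscans_json, list):
        raise SchemaError("bscans: expected a list")
    bscans = []
    for i, entry in enumerate(bscans_json):
        where = f"bscans[{i}]"
        if not isinstance(entry, Mapping):
            raise SchemaError(f"{where}: expected an object")
        alcs_json = entry.get("alcs")
        bscans.append(
            RadialBScan(
                index=_require(entry, "index", where),
                angle_deg=_require(entry, "angle_deg", where),
                ilm=_polyline_from_json(_require(entry, "ilm", where), "ILM", f"{where}.ilm"),
                bm=_polyline_from_json(_require(entry, "bm", where), "BM", f"{where}.bm"),
                alcs=(
                    _polyline_from_json(alcs_json, "ALCS", f"{where}.alcs")
                    if alcs_json is not None
                    else None
                ),
                bmo_left=tuple(_require(entry, "bmo_left", where)),
                bmo_right=tuple(_require(entry, "bmo_right", where)),
            )
        )
    return SegmentedRadialSet(bscans=tuple(bscans), eye=eye, axial_sign=axial_sign)


def read_radial_set(path) -> SegmentedRadialSet:
    """Read and validate a radial-set JSON file (see ``schemas/``)."""
    with open(path) as fh:
        try:
            data = json.load(fh)
        except json.JSONDecodeError as exc:
            raise SchemaError(f"{path}: not valid JSON ({exc})") from exc
    return radial_set_from_dict(data)


def write_radial_set(rset: SegmentedRadialSet, path) -> None:
    """Write a radial set; ``read_radial_set`` round-trips it exactly."""
    with open(path, "w") as fh:
        json.dump(radial_set_to_dict(rset), fh, indent=1)
        fh.write("\n")


def circular_scan_to_dict(scan: CircularScan) -> dict:
    return {
        "diameter_mm": scan.diameter_mm,
        "theta": scan.theta.tolist(),
        "ilm_z": scan.ilm_z.tolist(),
        "rnfl_post_z": scan.rnfl_post_z.tolist(),
        "bm_z": scan.bm_z.tolist(),
        "choroid_sclera_z": scan.choroid_sclera_z.tolist(),
        "valid": [bool(v) for v in scan.valid],
    }


def circular_scan_from_dict(data: Mapping) -> CircularScan:
    if not isinstance(data, Mapping):
        raise SchemaError("top level: expected a JSON object")
    kwargs = {}
    for key in ("diameter_mm", "theta", "ilm_z", "rnfl_post_z", "bm_z",
                "choroid_sclera_z", "valid"):
        kwargs[key] = _require(data, key, "top level")
    return CircularScan(**kwargs)


def read_circular_scan(path) -> CircularScan:
    with open(path) as fh:
        try:
            data = json.load(fh)
        except json.JSONDecodeError as exc:
            raise SchemaError(f"{path}: not valid JSON ({exc})") from exc
    return circular_scan_from_dict(data)


def write_circular_scan(scan: CircularScan, path) -> None:
    with open(path, "w") as fh:
        json.dump(circular_scan_to_dict(scan), fh, indent=1)
        fh.write("\n")


# ---------------------------------------------------------------------------
# 3-D embedding
# ---------------------------------------------------------------------------

def to_3d(rset: SegmentedRadialSet) -> dict[str, np.ndarray]:
    """Embed a radial set in 3-D scan space.

    Each sample ``(s, z)`` on the B-scan at angle ``theta`` maps to
    ``(s*cos(theta), s*sin(theta), z)``.  Returns a dict with one (N, 3)
    point-cloud per layer plus the 48 BMO points under key ``"BMO"``.
    """
    clouds: dict[str, list[np.ndarray]] = {"ILM": [], "BM": [], "ALCS": []}
    for b in rset.bscans:
        th = math.radians(b.angle_deg)
        c, s = math.cos(th), math.sin(th)
        for key, poly in (("ILM", b.ilm), ("BM", b.bm), ("ALCS", b.alcs)):
            if poly is None:
                continue
            sv, zv = poly.samples[:, 0], poly.samples[:, 1]
            clouds[key].append(np.column_stack([sv * c, sv * s, zv]))
    out = {k: np.concatenate(v) for k, v in clouds.items() if v}
    out["BMO"] = rset.bmo_points_3d()
    return out


# ---------------------------------------------------------------------------
# Session table CSV
# ---------------------------------------------------------------------------

SESSION_CSV_COLUMNS = (
    "subject_id", "time_label", "posture",
    "iop1", "iop2", "iop3", "sbp", "dbp", "cuff_eye_cm",
)


def read_session_table(path) -> pd.DataFrame:
    """Read a per-session physiology CSV and validate its required columns."""
    df = pd.read_csv(path)
    missing = [c for c in SESSION_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"session table: missing columns {missing}")
    bad = ~df["posture"].isin(POSTURES)
    if bad.any():
        raise SchemaError(
            f"session table: unknown posture values {sorted(df.loc[bad, 'posture'].unique())}"
        )
    bad = ~df["time_label"].isin(TIME_LABELS + (HDT_ENDPOINT_LABEL,))
    if bad.any():
        raise SchemaError(
            f"session table: unknown time labels {sorted(df.loc[bad, 'time_label'].unique())}"
        )
    return df
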