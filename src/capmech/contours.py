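"""Segmented cross-section contours and morphological risk factors.

A coronary cross-section (an IVUS+OCT "IO slice") is represented by closed
2-D polylines in millimetres: the lumen border, the vessel outer boundary,
and zero or more lipid and calcification pools.  From these we compute the
morphological vulnerability predictors: lumen area (LA), plaque area (PA),
plaque burden PB = PA/(PA+LA), and the minimum / mean fibrous-cap thickness
(MinCapT / MeanCapT) over the cap arc.

Cap quantities are sampled with the four-quarter even-spacing scheme:
100 points at equal arc length around the lumen, grouped into four
consecutive 25-point quarters.  A point belongs to the cap when the ray
from the lumen centroid through the point crosses a lipid pool; its cap
thickness is the distance from the point to the nearest lipid border.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from shapely.geometry import LineString, Point, Polygon

__all__ = [
    "SliceContours",
    "MorphologyRecord",
    "CapSamples",
    "read_slice",
    "write_slice",
    "polygon_area",
    "polygon_centroid",
    "morphology",
    "resample_even",
    "cap_thickness_profile",
    "make_cap_samples",
]

N_SAMPLES = 100  # four-quarter even-spacing point count
N_QUARTERS = 4


class ContourValidationError(ValueError):
    """A polyline or contour set violates a geometric invariant."""


def _as_closed_array(poly: Sequence) -> np.ndarray:
    """Return an (n,2) float array with no duplicate closing vertex."""
    arr = np.asarray(poly, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ContourValidationError("polyline must be an (n, 2) array")
    if len(arr) > 1 and np.allclose(arr[0], arr[-1]):
        arr = arr[:-1]
    if not np.all(np.isfinite(arr)):
        raise ContourValidationError("polyline has non-finite coordinates")
    return arr


def _signed_area(poly: np.ndarray) -> float:
    x, y = poly[:, 0], poly[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def polygon_area(poly: Sequence) -> float:
    """Shoelace area of a simple closed polyline, positive for either orientation."""
    arr = _as_closed_array(poly)
    if len(arr) < 3:
        raise ContourValidationError("polygon needs at least 3 vertices")
    return abs(_signed_area(arr))


def polygon_centroid(poly: Sequence) -> np.ndarray:
    """Area centroid of a simple closed polyline."""
    arr = _as_closed_array(poly)
    a = _signed_area(arr)
    if abs(a) < 1e-14:
        raise ContourValidationError("degenerate polygon")
    xn, yn = np.roll(arr[:, 0], -1), np.roll(arr[:, 1], -1)
    cross = arr[:, 0] * yn - xn * arr[:, 1]
    cx = np.sum((arr[:, 0] + xn) * cross) / (6.0 * a)
    cy = np.sum((arr[:, 1] + yn) * cross) / (6.0 * a)
    return np.array([cx, cy])


def _ensure_ccw(poly: np.ndarray) -> np.ndarray:
    return poly if _signed_area(poly) > 0 else poly[::-1].copy()


def _validate_ring(poly: np.ndarray, name: str, min_vertices: int = 8) -> None:
    if len(poly) < min_vertices:
        raise ContourValidationError(
            f"{name}: needs >= {min_vertices} vertices, got {len(poly)}"
        )
    ring = Polygon(poly)
    if not ring.is_valid or not ring.is_simple:
        raise ContourValidationError(f"{name}: self-intersecting polyline")


@dataclass
class SliceContours:
    """One cross-section's segmented geometry.

    Polylines are stored counter-clockwise without a duplicate closing
    vertex, coordinates in millimetres in the image frame.
    """

    slice_id: str
    patient_id: str
    timepoint: str  # "baseline" | "followup"
    lumen: np.ndarray
    outer: np.ndarray
    lipids: list[np.ndarray] = field(default_factory=list)
    calcifications: list[np.ndarray] = field(default_factory=list)
    pressure_mmHg: dict | None = None  # {"dia": float, "sys": float}

    def __post_init__(self) -> None:
        if self.timepoint not in ("baseline", "followup"):
            raise ContourValidationError(
                f"timepoint must be baseline/followup, got {self.timepoint!r}"
            )
        self.lumen = _ensure_ccw(_as_closed_array(self.lumen))
        self.outer = _ensure_ccw(_as_closed_array(self.outer))
        _validate_ring(self.lumen, "lumen")
        _validate_ring(self.outer, "outer")
        self.lipids = [_ensure_ccw(_as_closed_array(p)) for p in self.lipids]
        self.calcifications = [
            _ensure_ccw(_as_closed_array(p)) for p in self.calcifications
        ]
        for i, p in enumerate(self.lipids):
            _validate_ring(p, f"lipid[{i}]", min_vertices=8)
        for i, p in enumerate(self.calcifications):
            _validate_ring(p, f"ca[{i}]", min_vertices=8)
        if not Polygon(self.outer).contains(Polygon(self.lumen)):
            raise ContourValidationError("lumen not strictly inside outer boundary")

    # -- convenience -------------------------------------------------------
    @property
    def has_lipid(self) -> bool:
        return len(self.lipids) > 0

    def with_contours(self, **kw) -> "SliceContours":
        return replace(self, **kw)

    def translated(self, dx: float, dy: float) -> "SliceContours":
        d = np.array([dx, dy])
        return replace(
            self,
            lumen=self.lumen + d,
            outer=self.outer + d,
            lipids=[p + d for p in self.lipids],
            calcifications=[p + d for p in self.calcifications],
        )

    def rotated(self, angle: float) -> "SliceContours":
        c, s = math.cos(angle), math.sin(angle)
        R = np.array([[c, -s], [s, c]])
        rot = lambda p: p @ R.T
        return replace(
            self,
            lumen=rot(self.lumen),
            outer=rot(self.outer),
            lipids=[rot(p) for p in self.lipids],
            calcifications=[rot(p) for p in self.calcifications],
        )


@dataclass(frozen=True)
class MorphologyRecord:
    """Morphological risk factors of one slice (areas mm^2, thicknesses mm)."""

    slice_id: str
    LA: float
    PA: float
    PB: float
    MinCapT: float | None = None
    MeanCapT: float | None = None


@dataclass
class CapSamples:
    """Even-spaced lumen sample points with quarter labels and cap scalars."""

    points: np.ndarray  # (n, 2) mm
    quarter: np.ndarray  # (n,) int 1..4
    in_cap: np.ndarray  # (n,) bool
    cap_thickness: np.ndarray  # (n,) mm, nan outside the cap
    stress: np.ndarray | None = None  # kPa, filled by the FE stage
    strain: np.ndarray | None = None  # dimensionless

    @property
    def n(self) -> int:
        return len(self.points)

    def cap_stats(self) -> tuple[float | None, float | None]:
        """(MinCapT, MeanCapT) over in-cap points, or (None, None)."""
        if not np.any(self.in_cap):
            return None, None
        t = self.cap_thickness[self.in_cap]
        return float(np.min(t)), float(np.mean(t))


# ---------------------------------------------------------------------------
# file I/O (contour JSON dialect)
# ---------------------------------------------------------------------------

def read_slice(path: str | Path) -> SliceContours:
    """Read one slice from the contour JSON dialect and validate it.

    The file holds ``{slice_id, patient_id, timepoint, pressure_mmHg:
    {dia, sys}, contours: {lumen, outer, lipid: [...], ca: [...]}}`` with
    polylines as ``[[x, y], ...]`` in mm (closure implicit).
    """
    path = Path(path)
    with open(path) as fh:
        try:
            raw = json.load(fh)
        except json.JSONDecodeError as e:
            raise ContourValidationError(f"{path}: malformed JSON: {e}") from e
    for key in ("slice_id", "patient_id", "timepoint", "contours"):
        if key not in raw:
            raise ContourValidationError(f"{path}: missing field {key!r}")
    con = raw["contours"]
    for key in ("lumen", "outer"):
        if key not in con:
            raise ContourValidationError(f"{path}: missing contour {key!r}")
    return SliceContours(
        slice_id=str(raw["slice_id"]),
        patient_id=str(raw["patient_id"]),
        timepoint=str(raw["timepoint"]),
        lumen=con["lumen"],
        outer=con["outer"],
        lipids=list(con.get("lipid", [])),
        calcifications=list(con.get("ca", [])),
        pressure_mmHg=raw.get("pressure_mmHg"),
    )


def write_slice(slc: SliceContours, path: str | Path) -> None:
    """Write a slice in the contour JSON dialect."""
    doc = {
        "slice_id": slc.slice_id,
        "patient_id": slc.patient_id,
        "timepoint": slc.timepoint,
        "pressure_mmHg": slc.pressure_mmHg,
        "contours": {
            "lumen": slc.lumen.tolist(),
            "outer": slc.outer.tolist(),
            "lipid": [p.tolist() for p in slc.lipids],
            "ca": [p.tolist() for p in slc.calcifications],
        },
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


# ---------------------------------------------------------------------------
# morphology
# ---------------------------------------------------------------------------

def morphology(slc: SliceContours, samples: CapSamples | None = None) -> MorphologyRecord:
    """Compute LA, PA, PB and (when a lipid pool exists) cap statistics.

    PB = PA / (PA + LA), the fraction of the vessel cross-section occupied
    by plaque.  Cap statistics pool every in-cap sample point over all lipid
    pools; slices without lipid have no fibrous cap and the cap fields stay
    absent.
    """
    LA = polygon_area(slc.lumen)
    outer_area = polygon_area(slc.outer)
    if outer_area <= LA:
        raise ContourValidationError("outer area <= lumen area")
    PA = outer_area - LA
    PB = PA / (PA + LA)
    min_t = mean_t = None
    if slc.has_lipid:
        if samples is None:
            samples = cap_thickness_profile(slc, make_cap_samples(slc))
        min_t, mean_t = samples.cap_stats()
    return MorphologyRecord(slc.slice_id, LA, PA, PB, min_t, mean_t)


# ---------------------------------------------------------------------------
# even-spacing resampling
# ---------------------------------------------------------------------------

def resample_even(poly: Sequence, n: int) -> np.ndarray:
    """Resample a closed polyline at ``n`` equal arc-length positions.

    The traversal is counter-clockwise starting from the vertex farthest in
    +x from the contour centroid (ties broken toward smaller y), so quarter
    labels are reproducible across re-digitizations of the same contour.
    """
    if n < 4:
        raise ValueError("need n >= 4 sample points")
    arr = _ensure_ccw(_as_closed_array(poly))
    cx, cy = polygon_centroid(arr)
    rel_x = arr[:, 0] - cx
    # start vertex: max +x offset, tie -> smaller y
    order = np.lexsort((arr[:, 1], -rel_x))
    start = order[0]
    arr = np.roll(arr, -start, axis=0)
    closed = np.vstack([arr, arr[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    perim = float(seg.sum())
    if perim <= 0:
        raise ValueError("zero-perimeter polyline")
    s = np.concatenate([[0.0], np.cumsum(seg)])
    targets = np.arange(n) * perim / n
    idx = np.searchsorted(s, targets, side="right") - 1
    idx = np.clip(idx, 0, len(seg) - 1)
    frac = (targets - s[idx]) / np.where(seg[idx] > 0, seg[idx], 1.0)
    return closed[idx] + frac[:, None] * (closed[idx + 1] - closed[idx])


def make_cap_samples(slc: SliceContours, n: int = N_SAMPLES) -> CapSamples:
    """Build the four-quarter even-spacing sample set on the lumen."""
    pts = resample_even(slc.lumen, n)
    per_quarter = n // N_QUARTERS
    quarter = 1 + np.minimum(np.arange(n) // per_quarter, N_QUARTERS - 1)
    return CapSamples(
        points=pts,
        quarter=quarter.astype(int),
        in_cap=np.zeros(n, dtype=bool),
        cap_thickness=np.full(n, np.nan),
    )


def cap_thickness_profile(slc: SliceContours, samples: CapSamples) -> CapSamples:
    """Mark cap membership and measure cap thickness at each sample point.

    A point is in the cap when the outward ray from the lumen centroid
    through the point crosses a lipid pool; its thickness is the minimum
    distance to the nearest lipid border.  Calcification does not interrupt
    membership.
    """
    if not slc.has_lipid:
        raise ValueError("slice has no lipid pool")
    centroid = polygon_centroid(slc.lumen)
    # ray length safely beyond the outer contour
    reach = 4.0 * np.max(np.linalg.norm(slc.outer - centroid, axis=1))
    lipid_polys = [Polygon(p) for p in slc.lipids]
    lipid_rings = [LineString(np.vstack([p, p[:1]])) for p in slc.lipids]
    in_cap = np.zeros(samples.n, dtype=bool)
    thick = np.full(samples.n, np.nan)
    for i, pt in enumerate(samples.points):
        d = pt - centroid
        nd = np.linalg.norm(d)
        if nd < 1e-12:
            continue
        ray = LineString([centroid, centroid + d / nd * reach])
        if any(ray.intersects(poly) for poly in lipid_polys):
            in_cap[i] = True
            p = Point(pt)
            thick[i] = min(ring.distance(p) for ring in lipid_rings)
    if not np.any(in_cap):
        warnings.warn(
            f"slice {slc.slice_id}: lipid present but no sample point subtends it; "
            "cap statistics absent",
            stacklevel=2,
        )
    return CapSamples(
        points=samples.points,
        quarter=samples.quarter,
        in_cap=in_cap,
        cap_thickness=thick,
        stress=samples.stress,
        strain=samples.strain,
    )
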