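"""Zone partitioning and the quantitative biomarkers: smoothness index and area.

The scan is split laterally into three zones around the fovea — the foveal
zone holds the central 20% of columns, flanked by nasal/temporal (horizontal
scans) or superior/inferior (vertical scans).  Within each zone two families
of biomarkers are computed from the segmented boundaries:

* the smoothness index SI = LL / CL, the ratio of the straight-line distance
  between the zone endpoints of a boundary (LL) to its polyline arc length
  (CL); SI = 1 for a perfectly smooth (straight) boundary and decreases as
  the boundary becomes irregular;
* the inter-layer areas S, trapezoidal integrals of the vertical gap between
  consecutive boundaries: INL between IPL and the upper OPL border, OPL
  between the two OPL borders, ONL between the lower OPL border and the EZ.

SI is reported for the IPL, the upper OPL border and the EZ.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .segment import BoundaryCurve, LayerSet

__all__ = [
    "ZonePartition",
    "BiomarkerRecord",
    "FoveaResult",
    "UndefinedZoneError",
    "locate_fovea",
    "partition_zones",
    "smoothness_index",
    "band_area",
    "compute_record",
    "zone_labels",
    "record_key",
]

#: biomarker variables reported per zone (SI for OPL lower border is not used)
SI_VARS = (("SI_IPL", "IPL"), ("SI_OPL_up", "OPL_upper"), ("SI_EZ", "EZ"))
AREA_VARS = (("S_INL", "IPL", "OPL_upper"),
             ("S_OPL", "OPL_upper", "OPL_lower"),
             ("S_ONL", "OPL_lower", "EZ"))


class UndefinedZoneError(ValueError):
    """Raised when a zone has fewer than two valid columns for a biomarker."""


class FoveaResult(NamedTuple):
    column: int
    fallback: bool  # True when the IPL was too flat and the midpoint was used


def zone_labels(orientation: str) -> tuple[str, str, str]:
    """Canonical zone names for output tables (the column order of nasal vs
    temporal depends on the optic-disc side, so no spatial order is implied)."""
    if orientation == "horizontal":
        return ("Nasal", "fovea", "Temporal")
    return ("SUP", "fovea", "INF")


def record_key(var: str, orientation: str, zone: str) -> str:
    """Flat variable name for output tables, e.g. ``SI_IPL.H.Nasal`` or ``S_INL.V.fovea``."""
    return f"{var}.{'H' if orientation == 'horizontal' else 'V'}.{zone}"


@dataclass
class ZonePartition:
    """Three contiguous, disjoint half-open column intervals covering a domain."""

    intervals: dict[str, tuple[int, int]]
    fovea_column: int
    orientation: str
    shifted: bool = False  # True when the foveal interval was clipped inward

    def __post_init__(self) -> None:
        spans = sorted(self.intervals.values())
        for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
            if a1 != b0:
                raise ValueError(f"zones not contiguous: {spans}")
        if any(a >= b for a, b in spans):
            raise ValueError(f"empty zone interval in {spans}")

    @property
    def domain(self) -> tuple[int, int]:
        spans = sorted(self.intervals.values())
        return spans[0][0], spans[-1][1]

    def __getitem__(self, label: str) -> tuple[int, int]:
        return self.intervals[label]

    def labels(self) -> tuple[str, ...]:
        return tuple(self.intervals)


def locate_fovea(
    layers: LayerSet,
    orientation: str = "horizontal",
    smooth_px: int = 65,
    search_fraction: float = 0.60,
) -> FoveaResult:
    """Fovea center = deepest point of the smoothed IPL trace.

    The IPL depth profile is smoothed with a ``smooth_px`` moving average
    (the default window is matched to the scale of pathological boundary
    undulation, so waves cancel), and the pit is taken as the maximum of the
    center-surround response ``y(x) - (y(x-D) + y(x+D)) / 2`` with
    ``D = smooth_px``, searched within the central ``search_fraction`` of
    the domain.  The surround subtraction cancels any linear depth trend
    (tilted scans, asymmetric retinal thickening), which a plain argmax of
    depth would follow instead of the pit.  If no depression stands out
    (response < 1 px everywhere), the domain midpoint is returned with
    ``fallback`` set — pitless scans carry no anchor.
    """
    d = layers.ipl.depth
    n = d.size
    k = np.ones(smooth_px) / smooth_px
    sm = np.convolve(np.pad(d, smooth_px // 2, mode="edge"), k, mode="valid")
    delta = smooth_px
    padded = np.pad(sm, delta, mode="edge")
    center = padded[delta:delta + n]
    response = center - 0.5 * (padded[:n] + padded[2 * delta:2 * delta + n])
    margin = int(round((1 - search_fraction) / 2 * n))
    region = response[margin: n - margin]
    if region.max() < 1.0:
        return FoveaResult(layers.start + n // 2, True)
    return FoveaResult(layers.start + margin + int(np.argmax(region)), False)


def partition_zones(
    domain: tuple[int, int],
    fovea_col: int,
    orientation: str = "horizontal",
    laterality: str = "unknown",
    disc_side: str = "none",
    zone_fraction: float = 0.20,
) -> ZonePartition:
    """Split the domain into the three analysis zones.

    The foveal zone spans ``round(zone_fraction * width)`` columns centered on
    ``fovea_col`` (an odd count puts the extra column on the high-column
    side); if it would spill over the domain it is shifted inward and flagged.
    For horizontal scans the interval on the optic-disc side is nasal and the
    other temporal; for vertical scans lower column indices are superior.
    """
    start, end = domain
    width = end - start
    if not (start <= fovea_col < end):
        raise ValueError(f"fovea column {fovea_col} outside domain {domain}")
    fw = int(round(zone_fraction * width))
    fw = max(fw, 1)
    left = fw // 2
    f0 = fovea_col - left
    f1 = f0 + fw
    shifted = False
    if f0 < start + 1:
        f0, f1, shifted = start + 1, start + 1 + fw, True
    if f1 > end - 1:
        f0, f1, shifted = end - 1 - fw, end - 1, True
    if orientation == "horizontal":
        if disc_side not in ("left", "right"):
            raise ValueError("horizontal partition requires disc_side left|right")
        if disc_side == "right":
            names = ("Temporal", "fovea", "Nasal")
        else:
            names = ("Nasal", "fovea", "Temporal")
    else:
        names = ("SUP", "fovea", "INF")
    intervals = {names[0]: (start, f0), names[1]: (f0, f1), names[2]: (f1, end)}
    return ZonePartition(intervals=intervals, fovea_column=fovea_col,
                         orientation=orientation, shifted=shifted)


def _zone_points(curve: BoundaryCurve, interval: tuple[int, int]):
    lo, hi = interval
    i0, i1 = max(lo - curve.start, 0), min(hi - curve.start, curve.depth.size)
    if i0 >= i1:
        raise UndefinedZoneError(f"interval {interval} outside curve domain")
    idx = np.arange(i0, i1)[curve.valid[i0:i1]]
    return idx + curve.start, curve.depth[idx]


def smoothness_index(curve: BoundaryCurve, interval: tuple[int, int]) -> float:
    """SI = LL / CL over a zone.

    LL is the Euclidean distance between the first and last valid points in
    the zone; CL sums segment lengths between consecutive valid columns, the
    column gap of excluded columns entering the segment as its true lateral
    span (bridging by skipping).  SI is in (0, 1], equal to 1 iff the
    polyline is straight.
    """
    x, y = _zone_points(curve, interval)
    if x.size < 2:
        raise UndefinedZoneError(f"fewer than 2 valid columns in {interval}")
    ll = float(np.hypot(x[-1] - x[0], y[-1] - y[0]))
    cl = float(np.sum(np.hypot(np.diff(x), np.diff(y))))
    if cl <= 0:
        raise UndefinedZoneError("degenerate zero-length curve")
    si = ll / cl
    # collinear polylines give CL == LL up to floating-point rounding only
    return 1.0 if si > 1 - 1e-12 else si


def band_area(
    upper: BoundaryCurve,
    lower: BoundaryCurve,
    interval: tuple[int, int],
    pixel_area: float = 1.0,
) -> float:
    """Trapezoidal area between two boundaries over a zone, in pixel^2.

    Integration runs over unit-spaced pairs of columns where both curves are
    valid; excluded columns are omitted from the integral (no bridging).
    ``pixel_area`` rescales to physical units when a micron-per-pixel pair is
    known (pass dx_um * dz_um).
    """
    lo, hi = interval
    if (upper.start, upper.end) != (lower.start, lower.end):
        raise ValueError("curves must share a domain")
    i0, i1 = max(lo - upper.start, 0), min(hi - upper.start, upper.depth.size)
    if i1 - i0 < 2:
        raise UndefinedZoneError(f"fewer than 2 columns in {interval}")
    v = upper.valid[i0:i1] & lower.valid[i0:i1]
    gap = lower.depth[i0:i1] - upper.depth[i0:i1]
    if np.any(gap[v] < 0):
        raise ValueError("crossing curves: lower above upper inside the zone")
    if v.sum() < 2:
        raise UndefinedZoneError(f"fewer than 2 valid columns in {interval}")
    pair = v[:-1] & v[1:]
    area = float(np.sum(0.5 * (gap[:-1] + gap[1:]) * pair))
    return area * pixel_area


@dataclass
class BiomarkerRecord:
    """One analysis row: per-zone SI and S values of one scan, plus covariates."""

    patient_id: str
    eye: str
    group: str
    age: float
    sex: str
    orientation: str
    values: dict[str, float] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def to_row(self) -> dict:
        row = {
            "patient_id": self.patient_id,
            "eye": self.eye,
            "group": self.group,
            "age": self.age,
            "sex": self.sex,
        }
        row.update(self.values)
        return row


def compute_record(
    layers: LayerSet,
    partition: ZonePartition,
    patient_id: str = "",
    eye: str = "",
    group: str = "",
    age: float = float("nan"),
    sex: str = "",
    pixel_area: float = 1.0,
) -> BiomarkerRecord:
    """Compute all 18 per-zone biomarkers (3 SI + 3 S in each of 3 zones).

    A zone-level failure (too few valid columns) is recorded as NaN with a
    warning, never raised: one bad zone must not void a scan.
    """
    rec = BiomarkerRecord(patient_id=patient_id, eye=eye, group=group,
                          age=age, sex=sex, orientation=partition.orientation)
    o = partition.orientation
    for zone in partition.labels():
        iv = partition[zone]
        for var, role in SI_VARS:
            key = record_key(var, o, zone)
            try:
                rec.values[key] = smoothness_index(layers[role], iv)
            except UndefinedZoneError as exc:
                rec.values[key] = float("nan")
                rec.warnings.append(f"{key}: {exc}")
        for var, up, lowr in AREA_VARS:
            key = record_key(var, o, zone)
            try:
                rec.values[key] = band_area(layers[up], layers[lowr], iv,
                                            pixel_area=pixel_area)
            except UndefinedZoneError as exc:
                rec.values[key] = float("nan")
                rec.warnings.append(f"{key}: {exc}")
    return rec
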