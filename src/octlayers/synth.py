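"""Synthetic OCT B-scan cohorts with known ground truth.

No public OCT dataset with per-eye retinopathy grades and raw B-scans backs
this analysis, so every downstream stage is exercised against a generator
that emulates the relevant anatomy of a macular cross-section:

* a bright thin IPL line, a bright OPL band with an upper and lower border,
  and a bright thin EZ line, stacked with configurable inter-layer spacing
  over darker nuclear layers (INL, ONL);
* a Gaussian foveal pit depressing the inner boundaries, fading with depth
  (the EZ stays flat);
* controllable per-zone boundary irregularity: a single-frequency sinusoid,
  shared in phase across boundaries, whose per-zone amplitude is calibrated
  by root finding so each boundary's zone smoothness index matches a drawn
  target to +/-0.002;
* multiplicative gamma speckle.

Cohort defaults reproduce the group structure of the clinical study the
pipeline targets: three groups (normal / NPDR / PDR) of 33 / 36 / 15 eyes,
~47% of patients contributing both eyes, group-specific age and sex mixes,
and per-zone biomarker means and SDs for horizontal and vertical scans.

Area targets are expressed in the source tables' arbitrary area unit; those
values are too large to be pixel^2 on a 256-row canvas, so rendering maps
drawn areas onto the canvas through a fixed axial scale factor
(``depth_scale``).  Stored ground truth always reports what was actually
rendered, so segmentation fidelity is judged against the true rendered
geometry; cohort statistics use the drawn (unit-preserving) values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.optimize import brentq
from scipy.special import ndtr

from .biomarkers import ZonePartition, partition_zones, record_key
from .preprocess import BScanImage
from .segment import ROLES, BoundaryCurve, LayerSet

__all__ = [
    "LayerProfileParams",
    "NoiseParams",
    "CohortParams",
    "GroundTruth",
    "SyntheticScan",
    "DEFAULT_BIOMARKERS",
    "DEFAULT_N_EYES",
    "generate_boundary",
    "calibrate_irregularity",
    "render_bscan",
    "generate_cohort",
    "write_cohort",
]

GROUPS = ("normal", "NPDR", "PDR")

#: per-group, per-variable (mean, SD) biomarker targets for both scan
#: orientations; areas in the source tables' area unit, SI dimensionless.
DEFAULT_BIOMARKERS: dict[str, dict[str, tuple[float, float]]] = {
    "normal": {
        # horizontal, foveal zone
        "S_INL.H.fovea": (3357.44, 866.07),
        "S_ONL.H.fovea": (24879.87, 3237.89),
        "S_OPL.H.fovea": (2307.19, 724.41),
        "SI_IPL.H.fovea": (0.91, 0.02),
        "SI_OPL_up.H.fovea": (0.93, 0.02),
        "SI_EZ.H.fovea": (0.95, 0.01),
        # horizontal, temporal zone
        "S_INL.H.Temporal": (20271.5, 3098.11),
        "S_ONL.H.Temporal": (54562.81, 6418.32),
        "S_OPL.H.Temporal": (12490.53, 1566.0),
        "SI_IPL.H.Temporal": (0.93, 0.01),
        "SI_OPL_up.H.Temporal": (0.93, 0.01),
        "SI_EZ.H.Temporal": (0.94, 0.02),
        # horizontal, nasal zone
        "S_INL.H.Nasal": (22617.88, 3607.72),
        "S_ONL.H.Nasal": (58425.69, 7715.16),
        "S_OPL.H.Nasal": (13122.72, 2189.31),
        "SI_IPL.H.Nasal": (0.93, 0.01),
        "SI_OPL_up.H.Nasal": (0.93, 0.01),
        "SI_EZ.H.Nasal": (0.94, 0.01),
        # vertical, foveal zone
        "S_INL.V.fovea": (6733.0, 1753.0),
        "S_ONL.V.fovea": (29166.0, 3910.0),
        "S_OPL.V.fovea": (4453.0, 1009.0),
        "SI_IPL.V.fovea": (0.918, 0.026),
        "SI_OPL_up.V.fovea": (0.942, 0.016),
        "SI_EZ.V.fovea": (0.946, 0.011),
        # vertical, inferior zone
        "S_INL.V.INF": (22476.0, 3243.0),
        "S_ONL.V.INF": (50752.0, 6300.0),
        "S_OPL.V.INF": (13038.0, 2148.0),
        "SI_IPL.V.INF": (0.927, 0.015),
        "SI_OPL_up.V.INF": (0.932, 0.013),
        "SI_EZ.V.INF": (0.942, 0.018),
        # vertical, superior zone
        "S_INL.V.SUP": (22792.0, 3087.0),
        "S_ONL.V.SUP": (52050.0, 6720.0),
        "S_OPL.V.SUP": (14599.0, 2191.0),
        "SI_IPL.V.SUP": (0.936, 0.015),
        "SI_OPL_up.V.SUP": (0.934, 0.015),
        "SI_EZ.V.SUP": (0.946, 0.013),
    },
    "NPDR": {
        "S_INL.H.fovea": (5179.56, 1169.94),
        "S_ONL.H.fovea": (29462.08, 5319.02),
        "S_OPL.H.fovea": (2604.81, 906.79),
        "SI_IPL.H.fovea": (0.91, 0.02),
        "SI_OPL_up.H.fovea": (0.94, 0.02),
        "SI_EZ.H.fovea": (0.95, 0.01),
        "S_INL.H.Temporal": (21607.47, 3732.75),
        "S_ONL.H.Temporal": (53070.61, 8910.94),
        "S_OPL.H.Temporal": (11237.22, 1747.79),
        "SI_IPL.H.Temporal": (0.93, 0.01),
        "SI_OPL_up.H.Temporal": (0.93, 0.01),
        "SI_EZ.H.Temporal": (0.94, 0.01),
        "S_INL.H.Nasal": (23088.25, 3417.13),
        "S_ONL.H.Nasal": (60214.31, 12619.52),
        "S_OPL.H.Nasal": (12177.72, 2775.48),
        "SI_IPL.H.Nasal": (0.93, 0.01),
        "SI_OPL_up.H.Nasal": (0.93, 0.01),
        "SI_EZ.H.Nasal": (0.94, 0.01),
        "S_INL.V.fovea": (5856.0, 1402.0),
        "S_ONL.V.fovea": (27450.0, 4772.0),
        "S_OPL.V.fovea": (4193.0, 1228.0),
        "SI_IPL.V.fovea": (0.912, 0.024),
        "SI_OPL_up.V.fovea": (0.936, 0.015),
        "SI_EZ.V.fovea": (0.949, 0.013),
        "S_INL.V.INF": (23461.0, 3611.0),
        "S_ONL.V.INF": (47902.0, 10501.0),
        "S_OPL.V.INF": (14512.0, 2950.0),
        "SI_IPL.V.INF": (0.928, 0.013),
        "SI_OPL_up.V.INF": (0.93, 0.015),
        "SI_EZ.V.INF": (0.938, 0.015),
        "S_INL.V.SUP": (22941.0, 4454.0),
        "S_ONL.V.SUP": (51708.0, 8842.0),
        "S_OPL.V.SUP": (15487.0, 3507.0),
        "SI_IPL.V.SUP": (0.931, 0.015),
        "SI_OPL_up.V.SUP": (0.928, 0.029),
        "SI_EZ.V.SUP": (0.946, 0.014),
    },
    "PDR": {
        "S_INL.H.fovea": (5316.13, 1598.35),
        "S_ONL.H.fovea": (29361.67, 2845.06),
        "S_OPL.H.fovea": (2599.07, 1132.69),
        "SI_IPL.H.fovea": (0.91, 0.02),
        "SI_OPL_up.H.fovea": (0.93, 0.01),
        "SI_EZ.H.fovea": (0.94, 0.03),
        "S_INL.H.Temporal": (21666.21, 3334.99),
        "S_ONL.H.Temporal": (57912.64, 8575.12),
        "S_OPL.H.Temporal": (11354.5, 3125.23),
        "SI_IPL.H.Temporal": (0.90, 0.02),
        "SI_OPL_up.H.Temporal": (0.91, 0.02),
        "SI_EZ.H.Temporal": (0.93, 0.02),
        "S_INL.H.Nasal": (23575.07, 3849.62),
        "S_ONL.H.Nasal": (60470.47, 7431.86),
        "S_OPL.H.Nasal": (12287.4, 2189.84),
        "SI_IPL.H.Nasal": (0.89, 0.03),
        "SI_OPL_up.H.Nasal": (0.90, 0.03),
        "SI_EZ.H.Nasal": (0.94, 0.02),
        "S_INL.V.fovea": (7022.0, 2247.0),
        "S_ONL.V.fovea": (26275.0, 3956.0),
        "S_OPL.V.fovea": (5711.0, 1575.0),
        "SI_IPL.V.fovea": (0.914, 0.031),
        "SI_OPL_up.V.fovea": (0.924, 0.034),
        "SI_EZ.V.fovea": (0.937, 0.034),
        "S_INL.V.INF": (24563.0, 4926.0),
        "S_ONL.V.INF": (53080.0, 11555.0),
        "S_OPL.V.INF": (16054.0, 2926.0),
        "SI_IPL.V.INF": (0.932, 0.013),
        "SI_OPL_up.V.INF": (0.926, 0.017),
        "SI_EZ.V.INF": (0.942, 0.014),
        "S_INL.V.SUP": (23060.0, 3145.0),
        "S_ONL.V.SUP": (54366.0, 10127.0),
        "S_OPL.V.SUP": (16400.0, 3161.0),
        "SI_IPL.V.SUP": (0.929, 0.02),
        "SI_OPL_up.V.SUP": (0.929, 0.02),
        "SI_EZ.V.SUP": (0.942, 0.021),
    },
}

DEFAULT_N_EYES = {"normal": 33, "NPDR": 36, "PDR": 15}
DEFAULT_AGE = {"normal": (45.0, 11.3), "NPDR": (56.0, 13.1), "PDR": (57.0, 9.6)}
DEFAULT_MALE_FRACTION = {"normal": 0.515, "NPDR": 0.388, "PDR": 0.333}

#: foveal-pit depth multiplier per boundary; the pit fades with depth and the
#: EZ stays flat, so the ONL thickens under the fovea as on real scans.
PIT_SCALE = {"IPL": 1.0, "OPL_upper": 0.96, "OPL_lower": 0.92, "EZ": 0.0}


# ---------------------------------------------------------------------------
# Elementary boundary model
# ---------------------------------------------------------------------------

@dataclass
class LayerProfileParams:
    """Parameters of a single synthetic boundary profile."""

    width_px: int = 728
    base_depth_px: float = 100.0
    pit_depth_px: float = 0.0
    pit_sigma_px: float = 40.0
    pit_center_px: float | None = None  # defaults to width/2
    irregularity_amplitude_px: float = 0.0
    irregularity_wavelength_px: float = 64.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width_px < 16:
            raise ValueError("width_px must be >= 16")
        if self.pit_depth_px < 0 or self.irregularity_amplitude_px < 0:
            raise ValueError("pit depth and irregularity amplitude must be >= 0")
        if self.irregularity_wavelength_px <= 0 or self.pit_sigma_px <= 0:
            raise ValueError("wavelength and pit sigma must be > 0")


def _si_polyline(y: np.ndarray) -> float:
    """Smoothness index of a unit-column-spaced depth trace."""
    n = y.size
    ll = float(np.hypot(n - 1, y[-1] - y[0]))
    cl = float(np.sum(np.hypot(1.0, np.diff(y))))
    return ll / cl


def generate_boundary(params: LayerProfileParams, role: str = "IPL") -> BoundaryCurve:
    """One boundary: Gaussian foveal pit plus a band-limited sinusoid.

    The pit is scaled by the boundary role (deep layers are less depressed,
    the EZ flat).  The sinusoid phase is drawn deterministically from the
    seed, so a fixed seed reproduces the curve bit for bit.  Parameters that
    would push the curve above row 0 are rejected.
    """
    if role not in ROLES:
        raise ValueError(f"unknown role {role!r}")
    x = np.arange(params.width_px, dtype=float)
    center = params.pit_center_px if params.pit_center_px is not None else params.width_px / 2
    pit = params.pit_depth_px * PIT_SCALE[role] * np.exp(
        -0.5 * ((x - center) / params.pit_sigma_px) ** 2
    )
    if params.irregularity_amplitude_px > 0:
        phase = np.random.default_rng(params.seed).uniform(0, 2 * np.pi)
        wave = params.irregularity_amplitude_px * np.sin(
            2 * np.pi * x / params.irregularity_wavelength_px + phase
        )
    else:
        wave = 0.0
    depth = params.base_depth_px + pit + wave
    if np.min(depth) < 0:
        raise ValueError("boundary leaves the image (row < 0); reduce amplitude or raise base")
    return BoundaryCurve(depth=depth, start=0, role=role)


def calibrate_irregularity(
    target_si: float,
    wavelength_px: float = 64.0,
    zone_width_px: int = 124,
    phase: float = 0.0,
) -> float:
    """Amplitude of a sinusoid whose zone smoothness index equals ``target_si``.

    Inverts the monotone amplitude -> SI map of
    ``y = A sin(2 pi x / wavelength + phase)`` sampled on the zone's integer
    columns, by Brent root finding; the returned amplitude reproduces the
    target within +/-0.002.  ``target_si`` must be in (0, 1]; 1 maps to 0.
    """
    if not 0 < target_si <= 1:
        raise ValueError(f"target SI must be in (0, 1], got {target_si}")
    if target_si == 1.0:
        return 0.0
    x = np.arange(zone_width_px, dtype=float)
    k = 2 * np.pi / wavelength_px

    def si_of(a: float) -> float:
        return _si_polyline(a * np.sin(k * x + phase))

    a_hi = wavelength_px / 4
    while si_of(a_hi) > target_si:
        a_hi *= 2
        if a_hi > 100 * wavelength_px:
            raise ValueError(f"target SI {target_si} unreachable")
    return float(brentq(lambda a: si_of(a) - target_si, 0.0, a_hi, xtol=1e-4))


# ---------------------------------------------------------------------------
# Ground truth for a full scan
# ---------------------------------------------------------------------------

@dataclass
class NoiseParams:
    """Speckle model: multiplicative gamma noise with unit mean.

    ``speckle_shape`` is the gamma shape parameter k (coefficient of
    variation 1/sqrt(k)); ``None`` renders a noise-free scan.
    """

    speckle_shape: float | None = 16.0


@dataclass
class GroundTruth:
    """True geometry of one synthetic scan."""

    curves: dict[str, np.ndarray]
    fovea_col: int
    width: int
    height: int
    orientation: str
    domain: tuple[int, int]
    partition: ZonePartition
    targets: dict[str, float]          # drawn biomarkers, source-table units
    achieved: dict[str, float]         # recomputed from the curves; areas px^2
    depth_scale: float
    params: dict = field(default_factory=dict)

    def boundary(self, role: str) -> BoundaryCurve:
        return BoundaryCurve(depth=self.curves[role], start=0, role=role)

    def layer_set(self) -> LayerSet:
        return LayerSet(*(self.boundary(r) for r in ROLES))

    def validate(self) -> None:
        ipl, u, l, ez = (self.curves[r] for r in ROLES)
        if not (np.all(ipl < u) and np.all(u <= l) and np.all(l < ez)):
            raise ValueError("layer ordering violated in ground truth")
        allc = np.concatenate([self.curves[r] for r in ROLES])
        if allc.min() < 0 or allc.max() >= self.height:
            raise ValueError("ground-truth curve outside image rows")


@dataclass
class SyntheticScan:
    image: BScanImage | None
    truth: GroundTruth
    covariates: dict


@dataclass
class CohortParams:
    """Cohort-level generator settings; defaults reproduce the study layout."""

    n_eyes: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_N_EYES))
    biomarkers: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=lambda: DEFAULT_BIOMARKERS
    )
    two_eye_fraction: float = (84 - 57) / 57
    age: dict[str, tuple[float, float]] = field(default_factory=lambda: dict(DEFAULT_AGE))
    male_fraction: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_MALE_FRACTION))
    orientations: tuple[str, ...] = ("horizontal",)
    seed: int = 0
    width: int = 728
    height: int = 256
    depth_scale: float = 0.33
    trim_fraction: float = 0.15
    zone_fraction: float = 0.20
    pit_depth_px: float = 16.0
    pit_sigma_px: float = 52.0
    tent_split: float = 0.35
    wavelength_px: float = 64.0
    base_row: float = 22.0
    noise: NoiseParams = field(default_factory=NoiseParams)
    max_retries: int = 10
    min_gap_px: float = 3.5

    def __post_init__(self) -> None:
        for g, table in self.biomarkers.items():
            for key, (mean, sd) in table.items():
                if sd <= 0 and sd != 0.0:
                    raise ValueError(f"{g}/{key}: SD must be >= 0")
                if key.startswith("SI") and not 0 < mean <= 1:
                    raise ValueError(f"{g}/{key}: SI target must be in (0, 1]")
        if not 0 <= self.two_eye_fraction <= 1:
            raise ValueError("two_eye_fraction must be in [0, 1]")


class _InfeasibleDraw(Exception):
    pass


def _smooth_zone_profile(partition: ZonePartition, values: dict[str, float],
                         width: int, sigma: float = 8.0) -> np.ndarray:
    """Per-zone profile over the full width: linear interpolation between zone
    centers with lightly rounded knots.

    Piecewise-linear transitions keep the base boundaries nearly
    chord-aligned inside each zone (a sigmoid blend would cost smoothness
    index before any irregularity is added)."""
    xs, ys = [], []
    for zone, (lo, hi) in sorted(partition.intervals.items(), key=lambda kv: kv[1]):
        xs.append(0.5 * (lo + hi))
        ys.append(values[zone])
    prof = np.interp(np.arange(width, dtype=float), xs, ys)
    return gaussian_filter1d(prof, sigma, mode="nearest")


def _taper_zone_profile(partition: ZonePartition, values: dict[str, float],
                        width: int, sigma: float = 5.0) -> np.ndarray:
    """Piecewise-constant per-zone profile with short tapers at zone edges.

    Used for irregularity amplitudes: each zone keeps its own level except
    within ~2 sigma of a boundary, so calibrating one zone barely perturbs
    its neighbours."""
    prof = np.empty(width, dtype=float)
    lo0, hi0 = partition.domain
    for zone, (lo, hi) in partition.intervals.items():
        prof[lo:hi] = values[zone]
    prof[:lo0] = prof[lo0]
    prof[hi0:] = prof[hi0 - 1]
    return gaussian_filter1d(prof, sigma, mode="nearest")


def _zone_si(y: np.ndarray, interval: tuple[int, int]) -> float:
    lo, hi = interval
    return _si_polyline(y[lo:hi])


def _build_truth(
    cp: CohortParams,
    orientation: str,
    disc_side: str,
    targets: dict[str, float],
    rng: np.random.Generator,
) -> GroundTruth:
    """Assemble the four true boundaries realizing drawn per-zone targets."""
    width, height = cp.width, cp.height
    o = "H" if orientation == "horizontal" else "V"

    if orientation == "horizontal":
        n_trim = int(round(cp.trim_fraction * width))
        domain = (0, width - n_trim) if disc_side == "right" else (n_trim, width)
    else:
        domain = (0, width)
    fovea_col = width // 2 + int(rng.integers(-8, 9))
    partition = partition_zones(domain, fovea_col, orientation,
                                disc_side=disc_side, zone_fraction=cp.zone_fraction)
    zwidth = {z: hi - lo for z, (lo, hi) in partition.intervals.items()}

    # Inter-layer spacing profiles (px), from drawn areas via the axial scale.
    gaps = {}
    for gap_name in ("INL", "OPL", "ONL"):
        vals = {z: targets[record_key(f"S_{gap_name}", orientation, z)]
                / zwidth[z] * cp.depth_scale for z in partition.labels()}
        gaps[gap_name] = _smooth_zone_profile(partition, vals, width)

    x = np.arange(width, dtype=float)
    pit_shape = np.exp(-0.5 * ((x - fovea_col) / cp.pit_sigma_px) ** 2)
    pit = {r: cp.pit_depth_px * PIT_SCALE[r] * pit_shape for r in ROLES}
    # The lateral trend of the total retinal thickness is split between the
    # EZ (fraction tent_split) and the inner boundaries: hanging the whole
    # trend on a single boundary would curve it more than its SI target.
    total = gaps["INL"] + gaps["OPL"] + gaps["ONL"]
    lo0, hi0 = domain
    ref = float(np.median(total[lo0:hi0]))
    ez_base = cp.tent_split * (total - ref)
    base = {
        "EZ": ez_base,
        "OPL_lower": ez_base - gaps["ONL"] + pit["OPL_lower"],
        "OPL_upper": ez_base - gaps["ONL"] - gaps["OPL"] + pit["OPL_upper"],
        "IPL": ez_base - total + pit["IPL"],
    }
    # Shift everything so the shallowest IPL point sits at the top margin.
    shift = cp.base_row - float(np.min(base["IPL"][lo0:hi0]))
    base = {r: b + shift for r, b in base.items()}

    phase = rng.uniform(0, 2 * np.pi)
    wave = np.sin(2 * np.pi * x / cp.wavelength_px + phase)

    # Per-zone irregularity amplitudes, calibrated so each boundary's zone SI
    # hits its drawn target on the assembled curve (pit and spacing blends
    # included).  OPL_lower reuses the OPL_upper amplitudes: the band moves
    # as a whole, which both matches the band reading of the anatomy and
    # keeps the borders from crossing.
    amp_profiles: dict[str, np.ndarray] = {}
    for var, role in (("SI_IPL", "IPL"), ("SI_OPL_up", "OPL_upper"), ("SI_EZ", "EZ")):
        amps = {}
        for z in partition.labels():
            t = targets[record_key(var, orientation, z)]
            amps[z] = calibrate_irregularity(min(t, 0.9995), cp.wavelength_px, zwidth[z])
        for _ in range(4):
            done = True
            for z in partition.labels():
                t = min(targets[record_key(var, orientation, z)], 0.9995)
                iv = partition[z]
                lo_a, hi_a = 0.0, amps[z] * 3 + 8.0

                def f(a, _z=z, _iv=iv, _t=t):
                    trial = dict(amps); trial[_z] = a
                    p2 = _taper_zone_profile(partition, trial, width)
                    return _zone_si(base[role] + p2 * wave, _iv) - _t

                if f(0.0) < 0:
                    raise _InfeasibleDraw(
                        f"{var}.{o}.{z}: base curvature already below SI target {t}"
                    )
                new = brentq(f, lo_a, hi_a, xtol=5e-4)
                if abs(new - amps[z]) > 1e-3:
                    done = False
                amps[z] = float(new)
            if done:
                break
        amp_profiles[role] = _taper_zone_profile(partition, amps, width)
    amp_profiles["OPL_lower"] = amp_profiles["OPL_upper"]

    curves = {r: base[r] + amp_profiles[r] * wave for r in ROLES}

    # Feasibility of the realized geometry on the canvas.
    for up, lowr, name in (("IPL", "OPL_upper", "INL"),
                           ("OPL_upper", "OPL_lower", "OPL"),
                           ("OPL_lower", "EZ", "ONL")):
        min_gap = np.min(curves[lowr][lo0:hi0] - curves[up][lo0:hi0])
        if name != "OPL" and min_gap < cp.min_gap_px:
            raise _InfeasibleDraw(f"{name} gap {min_gap:.2f} px < {cp.min_gap_px}")
        if name == "OPL" and min_gap < cp.min_gap_px:
            raise _InfeasibleDraw(f"band width {min_gap:.2f} px < {cp.min_gap_px}")
    allc = np.concatenate(list(curves.values()))
    if allc.min() < 6 or allc.max() > height - 10:
        raise _InfeasibleDraw("geometry leaves the canvas margins")

    truth = GroundTruth(
        curves=curves, fovea_col=fovea_col, width=width, height=height,
        orientation=orientation, domain=domain, partition=partition,
        targets={k: v for k, v in targets.items() if f".{o}." in k},
        achieved={}, depth_scale=cp.depth_scale,
        params={"wavelength_px": cp.wavelength_px, "pit_depth_px": cp.pit_depth_px,
                "pit_sigma_px": cp.pit_sigma_px, "base_row": cp.base_row},
    )
    truth.validate()

    # Recompute per-zone biomarkers from the stored curves.
    from .biomarkers import band_area, smoothness_index  # local import, no cycle

    ls = truth.layer_set()
    for z in partition.labels():
        iv = partition[z]
        truth.achieved[record_key("SI_IPL", orientation, z)] = smoothness_index(ls.ipl, iv)
        truth.achieved[record_key("SI_OPL_up", orientation, z)] = smoothness_index(ls.opl_upper, iv)
        truth.achieved[record_key("SI_EZ", orientation, z)] = smoothness_index(ls.ez, iv)
        truth.achieved[record_key("S_INL", orientation, z)] = band_area(ls.ipl, ls.opl_upper, iv)
        truth.achieved[record_key("S_OPL", orientation, z)] = band_area(ls.opl_upper, ls.opl_lower, iv)
        truth.achieved[record_key("S_ONL", orientation, z)] = band_area(ls.opl_lower, ls.ez, iv)
    return truth


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def render_bscan(
    truth: GroundTruth,
    height_px: int | None = None,
    noise: NoiseParams | None = None,
    seed: int = 0,
    **meta,
) -> BScanImage:
    """Render a B-scan from ground-truth geometry.

    Bright Gaussian ridges at the IPL and EZ rows, a bright soft-edged band
    between the OPL borders, a dim tissue fill between IPL and EZ over a dark
    background, then multiplicative gamma speckle.  Deterministic for a fixed
    seed; intensities clipped to [0, 1].
    """
    if height_px is None:
        height_px = truth.height
    if noise is None:
        noise = NoiseParams()
    allc = np.concatenate(list(truth.curves.values()))
    if allc.min() < 0 or allc.max() >= height_px:
        raise ValueError("truth curves do not fit within height_px")
    r = np.arange(height_px, dtype=float)[:, None]
    ipl = truth.curves["IPL"][None, :]
    up = truth.curves["OPL_upper"][None, :]
    low = truth.curves["OPL_lower"][None, :]
    ez = truth.curves["EZ"][None, :]

    img = np.full((height_px, truth.width), 0.06)
    img += 0.10 * (ndtr((r - ipl) / 1.5) - ndtr((r - ez) / 1.5))       # tissue fill
    img += 0.50 * np.exp(-0.5 * ((r - ipl) / 1.6) ** 2)                # IPL ridge
    img += 0.65 * np.exp(-0.5 * ((r - ez) / 1.6) ** 2)                 # EZ ridge
    img += 0.45 * (ndtr((r - up) / 1.2) - ndtr((r - low) / 1.2))       # OPL band
    if noise.speckle_shape is not None:
        rng = np.random.default_rng(seed)
        img = img * rng.gamma(noise.speckle_shape, 1.0 / noise.speckle_shape, img.shape)
    img = np.clip(img, 0.0, 1.0)
    return BScanImage(pixels=img, orientation=truth.orientation, **meta)


# ---------------------------------------------------------------------------
# Cohort assembly
# ---------------------------------------------------------------------------

def _draw_targets(table: dict[str, tuple[float, float]],
                  rng: np.random.Generator) -> dict[str, float]:
    """Per-eye biomarker draws, truncated to their valid ranges."""
    out = {}
    for key in sorted(table):
        mean, sd = table[key]
        is_si = key.startswith("SI")
        for _ in range(200):
            v = rng.normal(mean, sd)
            if is_si and 0 < v <= 1:
                break
            if not is_si and v > 0:
                break
        else:
            raise ValueError(f"could not draw a valid value for {key}")
        out[key] = float(v)
    return out


def _patient_layout(n_eyes: int, two_eye_fraction: float,
                    rng: np.random.Generator) -> list[list[str]]:
    """Assign eyes to patients: a fraction of patients contributes both eyes."""
    if n_eyes == 0:
        return []
    n_pat = max(1, int(round(n_eyes / (1 + two_eye_fraction))))
    n_two = n_eyes - n_pat
    if n_two < 0:
        n_pat, n_two = n_eyes, 0
    if n_two > n_pat:
        raise ValueError("two-eye fraction incompatible with eye count")
    out = []
    for i in range(n_pat):
        if i < n_two:
            out.append(["OD", "OS"])
        else:
            out.append([str(rng.choice(["OD", "OS"]))])
    return out


def generate_cohort(params: CohortParams | None = None, render: bool = True) -> list[SyntheticScan]:
    """Generate the labelled cohort.

    One :class:`SyntheticScan` per eye and orientation.  With ``render=False``
    only ground-truth biomarker draws and covariates are produced (no
    geometry, no image): this is the statistics path, whose biomarker
    distributions follow the configured group targets exactly (no
    renderability resampling).  With ``render=True`` each eye's draws are
    realized as an actual scan; draws whose geometry cannot be laid out on
    the canvas are re-sampled up to ``max_retries`` times, then rejected with
    an error.
    """
    if params is None:
        params = CohortParams()
    rng = np.random.default_rng(params.seed)
    scans: list[SyntheticScan] = []
    scan_no = 0
    for group in GROUPS:
        n = params.n_eyes.get(group, 0)
        layout = _patient_layout(n, params.two_eye_fraction, rng)
        for p_idx, eyes in enumerate(layout):
            patient_id = f"{group}-{p_idx:03d}"
            a_mean, a_sd = params.age[group]
            age = float(np.clip(rng.normal(a_mean, a_sd), 18, 90))
            sex = "M" if rng.random() < params.male_fraction[group] else "F"
            for eye in eyes:
                disc_side = "right" if eye == "OD" else "left"
                for orientation in params.orientations:
                    ok = False
                    for _ in range(params.max_retries):
                        targets = _draw_targets(params.biomarkers[group], rng)
                        if not render:
                            ok = True
                            truth = GroundTruth(
                                curves={}, fovea_col=params.width // 2,
                                width=params.width, height=params.height,
                                orientation=orientation, domain=(0, params.width),
                                partition=partition_zones(
                                    (0, params.width), params.width // 2,
                                    orientation, disc_side=disc_side,
                                    zone_fraction=params.zone_fraction),
                                targets=targets, achieved={},
                                depth_scale=params.depth_scale)
                            image = None
                            break
                        try:
                            truth = _build_truth(params, orientation, disc_side,
                                                 targets, rng)
                            ok = True
                        except _InfeasibleDraw:
                            continue
                        image = render_bscan(
                            truth, params.height, params.noise,
                            seed=int(rng.integers(2 ** 31)),
                            laterality=eye, disc_side=disc_side if orientation == "horizontal" else "none",
                            quality_ssi=float(np.round(rng.uniform(55, 90), 1)),
                        )
                        break
                    if render and not ok:
                        raise ValueError(
                            f"{patient_id}/{eye}/{orientation}: no feasible draw in "
                            f"{params.max_retries} attempts")
                    covariates = {
                        "scan_id": f"scan{scan_no:04d}",
                        "patient_id": patient_id,
                        "eye": eye,
                        "orientation": orientation,
                        "laterality": eye,
                        "disc_side": disc_side if orientation == "horizontal" else "none",
                        "group": group,
                        "age": round(age, 1),
                        "sex": sex,
                        "quality_ssi": image.quality_ssi if image is not None else 75.0,
                    }
                    scans.append(SyntheticScan(image=image, truth=truth,
                                               covariates=covariates))
                    scan_no += 1
    return scans


def write_cohort(scans: list[SyntheticScan], outdir: str | Path,
                 image_format: str = "png"):
    """Write images, per-scan ground-truth JSON sidecars, and the manifest CSV.

    PNG is written 8-bit, TIFF 16-bit.  Returns the manifest DataFrame.
    """
    import imageio.v3 as iio
    import pandas as pd

    outdir = Path(outdir)
    (outdir / "scans").mkdir(parents=True, exist_ok=True)
    rows = []
    for scan in scans:
        sid = scan.covariates["scan_id"]
        rel = f"scans/{sid}.{image_format}"
        if scan.image is not None:
            px = scan.image.pixels
            if image_format == "png":
                iio.imwrite(outdir / rel, np.round(px * 255).astype(np.uint8))
            elif image_format in ("tif", "tiff"):
                iio.imwrite(outdir / rel, np.round(px * 65535).astype(np.uint16))
            else:
                raise ValueError(f"unsupported image format {image_format!r}")
        truth = scan.truth
        sidecar = {
            "curves": {r: np.round(c, 4).tolist() for r, c in truth.curves.items()},
            "fovea_col": truth.fovea_col,
            "domain": list(truth.domain),
            "orientation": truth.orientation,
            "partition": {z: list(iv) for z, iv in truth.partition.intervals.items()},
            "targets": truth.targets,
            "achieved": truth.achieved,
            "depth_scale": truth.depth_scale,
            "params": truth.params,
            **{k: v for k, v in scan.covariates.items()},
        }
        with open(outdir / "scans" / f"{sid}.truth.json", "w") as fh:
            json.dump(sidecar, fh)
        rows.append({"scan_path": rel, **scan.covariates})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(outdir / "manifest.csv", index=False)
    return manifest
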