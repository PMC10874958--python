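"""Boundary segmentation of the hyperreflective retinal layers.

Three bright structures are extracted from a preprocessed B-scan: the IPL and
EZ, which appear as thin lines, and the OPL, which appears as a thick band
with an upper and a lower border.  Per column, candidate boundary points are
localized sub-pixel by small parametric profile fits (Gaussian ridge for the
lines, an erf-pair for the band edges); a support vector regression with a
translation-invariant wavelet kernel then turns the noisy candidate cloud of
each role into a smooth curve, re-fitting once after gross mislabels are
dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import find_peaks
from scipy.special import ndtr
from sklearn.svm import SVR

from .preprocess import BScanImage, GaborBankParams, enhance_retina

__all__ = [
    "ROLES",
    "BoundaryCurve",
    "LayerSet",
    "CandidateSet",
    "SegmentParams",
    "UnsegmentableScanError",
    "InsufficientCandidatesError",
    "wavelet_kernel",
    "wavelet_gram",
    "extract_candidates",
    "fit_boundary",
    "replace_mislabels",
    "segment_layers",
]

ROLES = ("IPL", "OPL_upper", "OPL_lower", "EZ")


class UnsegmentableScanError(ValueError):
    """Raised when too few columns yield any boundary candidate."""


class InsufficientCandidatesError(ValueError):
    """Raised when a single boundary role has too few candidates to fit."""

    def __init__(self, role: str, n: int, needed: int = 10):
        self.role = role
        super().__init__(f"role {role}: {n} candidate columns (< {needed} required)")


@dataclass
class BoundaryCurve:
    """Per-column sub-pixel depth trace of one layer boundary.

    ``depth[i]`` is the row of the boundary at column ``start + i``.  ``valid``
    marks columns retained for biomarker computation (ordering repair may
    exclude columns).
    """

    depth: np.ndarray
    start: int
    role: str
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=float)
        if self.depth.ndim != 1 or self.depth.size == 0:
            raise ValueError("depth must be a non-empty 1-D array")
        if not np.all(np.isfinite(self.depth)):
            raise ValueError("depth must be finite on its domain")
        if self.valid is None:
            self.valid = np.ones(self.depth.size, dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
            if self.valid.shape != self.depth.shape:
                raise ValueError("valid mask must match depth shape")

    @property
    def end(self) -> int:
        return self.start + self.depth.size

    @property
    def columns(self) -> np.ndarray:
        return np.arange(self.start, self.end)


@dataclass
class LayerSet:
    """The four segmented boundaries on a common domain.

    Invariant: at every *valid* column, IPL < OPL_upper <= OPL_lower < EZ
    (rows increase with depth).
    """

    ipl: BoundaryCurve
    opl_upper: BoundaryCurve
    opl_lower: BoundaryCurve
    ez: BoundaryCurve

    def __post_init__(self) -> None:
        doms = {(c.start, c.end) for c in self.curves()}
        if len(doms) != 1:
            raise ValueError(f"curves must share one domain, got {doms}")
        v = self.valid
        ipl, u, l, ez = (c.depth for c in self.curves())
        ok = (ipl[v] < u[v]) & (u[v] <= l[v]) & (l[v] < ez[v])
        if not ok.all():
            raise ValueError(f"layer ordering violated at {np.sum(~ok)} valid columns")

    def curves(self) -> tuple[BoundaryCurve, ...]:
        return (self.ipl, self.opl_upper, self.opl_lower, self.ez)

    def __getitem__(self, role: str) -> BoundaryCurve:
        return dict(zip(ROLES, self.curves()))[role]

    @property
    def valid(self) -> np.ndarray:
        v = np.ones(self.ipl.depth.size, dtype=bool)
        for c in self.curves():
            v &= c.valid
        return v

    @property
    def start(self) -> int:
        return self.ipl.start

    @property
    def end(self) -> int:
        return self.ipl.end

    def to_frame(self, column_offset: int = 0):
        """Serialize as a table (column in original image coordinates)."""
        import pandas as pd

        return pd.DataFrame(
            {
                "column": self.ipl.columns + column_offset,
                "ipl": self.ipl.depth,
                "opl_upper": self.opl_upper.depth,
                "opl_lower": self.opl_lower.depth,
                "ez": self.ez.depth,
                "valid": self.valid.astype(int),
            }
        )

    @classmethod
    def from_frame(cls, df, column_offset: int = 0) -> "LayerSet":
        cols = np.asarray(df["column"], dtype=int) - column_offset
        start = int(cols[0])
        valid = np.asarray(df["valid"], dtype=bool)
        def mk(name, role):
            return BoundaryCurve(np.asarray(df[name], float), start, role, valid.copy())
        return cls(mk("ipl", "IPL"), mk("opl_upper", "OPL_upper"),
                   mk("opl_lower", "OPL_lower"), mk("ez", "EZ"))


@dataclass
class CandidateSet:
    """Per-role candidate boundary points: (columns, rows, ridge strengths)."""

    points: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]
    width: int

    def __getitem__(self, role):
        return self.points[role]

    def n_columns(self, role: str) -> int:
        return self.points[role][0].size


@dataclass
class SegmentParams:
    """Tunable knobs of the segmentation stage.

    dilation is the wavelet-kernel scale in normalized column units (columns
    are mapped to [0, 1] before regression); 0.016 corresponds to ~10 px on a
    620-column domain, wide enough to average candidate jitter but narrow
    enough to follow boundary undulations of a few tens of pixels wavelength.
    epsilon is the SVR insensitivity tube in pixels; C the box constraint.
    """

    dilation: float = 0.016
    svr_c: float = 100.0
    epsilon_px: float = 0.25
    mislabel_threshold_px: float = 8.0
    min_prominence: float = 0.15
    min_candidate_fraction: float = 0.25
    gabor: GaborBankParams = field(default_factory=GaborBankParams)


def wavelet_kernel(u, v, a: float) -> float:
    """Translation-invariant wavelet kernel with mother wavelet
    h(x) = cos(1.75 x) exp(-x^2 / 2).

    K(u, v) = prod_i cos(1.75 (u_i - v_i) / a) * exp(-(u_i - v_i)^2 / (2 a^2))

    ``a`` > 0 is the dilation.  K(u, u) = 1 for any u.
    """
    if a <= 0:
        raise ValueError(f"dilation a must be > 0, got {a}")
    u = np.atleast_1d(np.asarray(u, dtype=float))
    v = np.atleast_1d(np.asarray(v, dtype=float))
    if u.shape != v.shape:
        raise ValueError("u and v must have equal length")
    d = (u - v) / a
    return float(np.prod(np.cos(1.75 * d) * np.exp(-0.5 * d * d)))


def wavelet_gram(x: np.ndarray, y: np.ndarray, a: float) -> np.ndarray:
    """Gram matrix of the 1-D wavelet kernel between point sets x and y."""
    if a <= 0:
        raise ValueError(f"dilation a must be > 0, got {a}")
    d = (np.asarray(x, float)[:, None] - np.asarray(y, float)[None, :]) / a
    return np.cos(1.75 * d) * np.exp(-0.5 * d * d)


# ---------------------------------------------------------------------------
# Per-column candidate detection
# ---------------------------------------------------------------------------

_SQRT2PI_EARLY = float(np.sqrt(2 * np.pi))


def _gauss_line(r, b0, amp, c0, s, d):
    """Bright ridge on a tissue step: Gaussian plus an erf step sharing the
    ridge center and width (the reflectivity of the tissue differs above and
    below a hyperreflective line; a flat or linear baseline misplaces the
    center by a fraction of a pixel)."""
    z = (r - c0) / s
    return b0 + amp * np.exp(-0.5 * z * z) + d * ndtr(z)


def _gauss_line_jac(r, b0, amp, c0, s, d):
    z = (r - c0) / s
    e = np.exp(-0.5 * z * z)
    phi = e / _SQRT2PI_EARLY
    return np.stack([
        np.ones_like(r),
        e,
        amp * e * z / s - d * phi / s,
        amp * e * z * z / s - d * phi * z / s,
        ndtr(z),
    ], axis=1)


def _erf_band(r, b, amp, m, h, s):
    return b + amp * (ndtr((r - (m - h)) / s) - ndtr((r - (m + h)) / s))


_SQRT2PI = float(np.sqrt(2 * np.pi))


def _erf_band_jac(r, b, amp, m, h, s):
    z1 = (r - (m - h)) / s
    z2 = (r - (m + h)) / s
    phi1 = np.exp(-0.5 * z1 * z1) / _SQRT2PI
    phi2 = np.exp(-0.5 * z2 * z2) / _SQRT2PI
    return np.stack([
        np.ones_like(r),
        ndtr(z1) - ndtr(z2),
        -amp / s * (phi1 - phi2),
        amp / s * (phi1 + phi2),
        -amp / s * (phi1 * z1 - phi2 * z2),
    ], axis=1)


def _fit_line_peak(p: np.ndarray, pk: int, lo: int, hi: int,
                   step_sign: float = 0.0) -> tuple[float, float, float] | None:
    """Sub-pixel ridge center by a Gaussian-plus-step fit.

    ``step_sign`` seeds the direction of the tissue step under the ridge
    (positive: brighter below, as at the IPL; negative: brighter above, as
    at the EZ); the step magnitude is free.  Returns (row, strength, sigma)
    or None.
    """
    w0, w1 = max(lo, pk - 7), min(hi, pk + 8)
    r = np.arange(w0, w1, dtype=float)
    y = p[w0:w1]
    if r.size < 6:
        return None
    base = float(y.min())
    p0 = (base, float(p[pk] - base), float(pk), 2.4, 0.05 * step_sign)
    try:
        popt, _ = curve_fit(_gauss_line, r, y, p0=p0, method="lm",
                            jac=_gauss_line_jac, maxfev=300)
    except RuntimeError:
        return None
    _, amp, c0, s, d = popt
    if not (abs(c0 - pk) <= 3.5 and 0.5 <= abs(s) <= 8 and amp > 0.02
            and abs(d) < 1.0):
        return None
    return float(c0), float(amp), float(abs(s))


def _half_max_crossings(p: np.ndarray, pk: int, lo: int, hi: int) -> tuple[float, float]:
    """Linear-interpolated half-maximum crossings around a band peak."""
    base = float(np.percentile(p[lo:hi], 10))
    half = base + 0.5 * (p[pk] - base)
    left = float(lo)
    for i in range(pk, lo, -1):
        if p[i - 1] <= half <= p[i]:
            left = (i - 1) + (half - p[i - 1]) / max(p[i] - p[i - 1], 1e-12)
            break
    right = float(hi - 1)
    for i in range(pk, hi - 1):
        if p[i + 1] <= half <= p[i]:
            right = i + (p[i] - half) / max(p[i] - p[i + 1], 1e-12)
            break
    return left, right


def _fit_band(p: np.ndarray, pk: int, lo: int, hi: int
              ) -> tuple[float, float, float, float] | None:
    """Sub-pixel band borders by an erf-pair fit with free transition scale.

    A blurred constant-intensity band is exactly an erf-pair, so fitting the
    transition scale ``s`` jointly with center/half-width removes the
    half-maximum bias that appears once the band is only a few pixels thick.
    Returns (upper_row, lower_row, strength, s) or None.  For bands thinner
    than the blur the four shape parameters degenerate and the fit fails;
    those columns are retried with :func:`_fit_band_frozen`.
    """
    l0, r0 = _half_max_crossings(p, pk, lo, hi)
    m0, h0 = 0.5 * (l0 + r0), max(0.5 * (r0 - l0), 1.0)
    w0 = max(lo, int(np.floor(l0 - 9)))
    w1 = min(hi, int(np.ceil(r0 + 9)) + 1)
    r = np.arange(w0, w1, dtype=float)
    y = p[w0:w1]
    if r.size < 8:
        return None
    base = float(np.percentile(y, 10))
    p0 = (base, float(p[pk] - base), m0, h0, 2.2)
    try:
        popt, _ = curve_fit(_erf_band, r, y, p0=p0, method="lm",
                            jac=_erf_band_jac, maxfev=200)
    except RuntimeError:
        return None
    _, amp, m, h, s = popt
    h, s = abs(h), abs(s)
    if not (w0 <= m <= w1 and 0.6 <= h <= 45 and 0.5 <= s <= 6 and amp > 0.02):
        return None
    return float(m - h), float(m + h), float(amp), float(s)


def _integral_halfwidth(resid: np.ndarray, w0: int, m: float, h0: float,
                        s: float, amp: float) -> float:
    """Band half-width from the integral of the background-subtracted profile.

    Blur redistributes but preserves the integral of the band, and the
    integral is linear in the data, so this estimator is immune both to a
    misspecified transition scale and to the nonlinear noise bias of the
    least-squares width.  ``resid`` is the profile minus everything but the
    band (baseline, and ridge/step terms where fitted), on rows starting at
    ``w0``.  The model-tail fraction outside the integration window is
    corrected iteratively from the erf-pair shape.
    """
    if amp <= 0.05:
        return h0
    rows = np.arange(w0, w0 + resid.size, dtype=float)
    dist = np.abs(rows - m)
    half_win = h0 + 3.0 * s
    win = dist <= half_win
    if win.sum() < 4:
        return h0
    # Local re-baselining: after model subtraction the flanking strips
    # should average zero; any smooth residual there is a baseline error
    # that would otherwise leak into the integral.
    flank = (dist > half_win) & (dist <= half_win + 4.0)
    offset = float(np.median(resid[flank])) if flank.sum() >= 4 else 0.0
    integral = float((resid[win] - offset).sum())
    h = max(h0, 0.3)
    for _ in range(3):
        model = _erf_band(rows[win], 0.0, amp, m, h, s)
        frac = float(model.sum()) / (2.0 * h * amp)
        if frac < 0.5:
            return h0
        h_new = integral / (2.0 * amp * frac)
        if not 0.3 <= h_new <= 45.0:
            return h0
        if abs(h_new - h) < 1e-3:
            h = h_new
            break
        h = h_new
    if abs(h - h0) > 2.0:
        return h0
    return h


def _fit_band_frozen(p: np.ndarray, pk: int, lo: int, hi: int,
                     amp: float, s: float) -> tuple[float, float] | None:
    """Erf-pair band fit with brightness and blur frozen at scan-level values.

    With ``amp`` and ``s`` fixed, (baseline, center, half-width) remain
    identifiable even for bands much thinner than the blur, where the free
    fit degenerates (brightness and width only enter through their product).
    """
    l0, r0 = _half_max_crossings(p, pk, lo, hi)
    m0, h0 = 0.5 * (l0 + r0), max(0.5 * (r0 - l0), 1.0)
    w0 = max(lo, int(np.floor(l0 - 9)))
    w1 = min(hi, int(np.ceil(r0 + 9)) + 1)
    r = np.arange(w0, w1, dtype=float)
    y = p[w0:w1]
    if r.size < 6:
        return None

    def model(r_, b, m, h):
        return _erf_band(r_, b, amp, m, h, s)

    def jac(r_, b, m, h):
        return _erf_band_jac(r_, b, amp, m, h, s)[:, [0, 2, 3]]

    base = float(np.percentile(y, 10))
    try:
        popt, _ = curve_fit(model, r, y, p0=(base, m0, h0), method="lm",
                            jac=jac, maxfev=200)
    except RuntimeError:
        return None
    b, m, h = popt
    h = abs(h)
    if not (w0 <= m <= w1 and 0.3 <= h <= 45):
        return None
    h = _integral_halfwidth(y - b, w0, float(m), float(h), s, amp)
    return float(m - h), float(m + h)


def _fit_merged(p: np.ndarray, lo: int, hi: int,
                c0_init: float, up_init: float, low_init: float,
                ridge_amp: float, ridge_s: float,
                band_amp: float, band_s: float,
                ) -> tuple[float, float, float] | None:
    """Joint Gaussian-ridge + erf-pair fit for a pinched IPL/OPL complex.

    Near the fovea the inner nuclear layer can thin until the IPL ridge and
    the OPL band upper border no longer produce separate intensity peaks.
    The two structures remain jointly identifiable: with the scan-level
    ridge width, band brightness and band blur frozen, (baseline, ridge
    strength, ridge row, band center, band half-width) are fit together,
    initialized by continuation from neighbouring resolved columns.
    Returns (ipl_row, upper_row, lower_row) or None.
    """
    w0 = max(lo, int(np.floor(c0_init - 8)))
    w1 = min(hi, int(np.ceil(low_init + 9)) + 1)
    r = np.arange(w0, w1, dtype=float)
    y = p[w0:w1]
    if r.size < 10:
        return None
    m0 = 0.5 * (up_init + low_init)
    h0 = max(0.5 * (low_init - up_init), 0.5)

    def model(r_, b, a_r, c0, m, h, d):
        z = (r_ - c0) / ridge_s
        return (b + a_r * np.exp(-0.5 * z * z) + d * ndtr(z)
                + band_amp * (ndtr((r_ - (m - h)) / band_s)
                              - ndtr((r_ - (m + h)) / band_s)))

    def jac(r_, b, a_r, c0, m, h, d):
        z = (r_ - c0) / ridge_s
        e = np.exp(-0.5 * z * z)
        phi = e / _SQRT2PI
        bj = _erf_band_jac(r_, 0.0, band_amp, m, h, band_s)
        return np.stack([np.ones_like(r_), e,
                         a_r * e * z / ridge_s - d * phi / ridge_s,
                         bj[:, 2], bj[:, 3], ndtr(z)], axis=1)

    base = float(np.percentile(y, 10))
    p0 = (base, ridge_amp, c0_init, m0, h0, 0.05)
    try:
        popt, _ = curve_fit(model, r, y, p0=p0, method="lm", jac=jac, maxfev=300)
    except RuntimeError:
        return None
    b, a_r, c0, m, h, d = popt
    h = abs(h)
    if not (abs(c0 - c0_init) <= 5 and abs((m - h) - up_init) <= 5
            and 0.3 <= h <= 45 and a_r > 0.02 and c0 < m - h + 1.0):
        return None
    z = (r - c0) / ridge_s
    resid = y - b - a_r * np.exp(-0.5 * z * z) - d * ndtr(z)
    h = _integral_halfwidth(resid, w0, float(m), float(h), band_s, band_amp)
    if not c0 < m - h + 1.0:
        return None
    return float(c0), float(m - h), float(m + h)


def _sheared_profile(px: np.ndarray, c: int, slope: float, curv: float = 0.0,
                     halfspan: int = 5, sigma: float = 2.5) -> np.ndarray:
    """Locally flattened lateral average of axial profiles around column c.

    Each neighbouring column's profile is shifted by the local quadratic
    trend of the boundary (``-slope * dc - curv * dc^2 / 2``, linear
    interpolation) before Gaussian-weighted averaging, so the average tracks
    a tilted or gently curved boundary without blurring it axially or
    rounding off undulation crests.  Averaging ahead of the nonlinear
    profile fits suppresses the speckle-induced estimator bias, which
    scales with the local noise variance.
    """
    h, width = px.shape
    rows = np.arange(h, dtype=float)
    acc = np.zeros(h)
    wsum = 0.0
    for dc in range(-halfspan, halfspan + 1):
        cc = c + dc
        if not 0 <= cc < width:
            continue
        w = float(np.exp(-0.5 * (dc / sigma) ** 2))
        shifted = np.interp(rows + slope * dc + 0.5 * curv * dc * dc,
                            rows, px[:, cc])
        acc += w * shifted
        wsum += w
    return acc / wsum


def _local_trend(up: dict[int, tuple[float, float]],
                 low: dict[int, tuple[float, float]], c: int,
                 halfspan: int = 10) -> tuple[float, float]:
    """Local (slope, curvature) of the band center near column c."""
    rows = [(k, 0.5 * (up[k][0] + low[k][0])) for k in up if k in low
            and abs(k - c) <= halfspan]
    if len(rows) < 6:
        return 0.0, 0.0
    arr = np.array(rows, dtype=float)
    x = arr[:, 0] - c
    coef = np.polyfit(x, arr[:, 1], 2)
    return float(coef[1]), float(2 * coef[0])


def _interp_cand(pts: dict[int, tuple[float, float]], c: int) -> float | None:
    """Linear interpolation of candidate rows onto column c."""
    if len(pts) < 2:
        return None
    cols = np.fromiter(pts.keys(), dtype=float)
    vals = np.array([pts[int(k)][0] for k in cols])
    order = np.argsort(cols)
    return float(np.interp(c, cols[order], vals[order]))


def extract_candidates(
    image: np.ndarray | BScanImage,
    mask: np.ndarray,
    min_prominence: float = 0.15,
    min_candidate_fraction: float = 0.25,
    merge_gap_px: float = 16.0,
    lateral_sigma: float = 11 / 6,
) -> CandidateSet:
    """Detect per-column boundary candidates inside the retina mask.

    Per column the axial intensity profile restricted to the mask is scanned
    for local maxima; the topmost ridge is assigned to the IPL, the
    bottommost to the EZ, and the strongest interior peak is read as the OPL
    band whose borders are localized sub-pixel by an erf-pair fit.  Columns
    where the IPL ridge and the band lie within ``merge_gap_px`` (including
    full pinches where the separate peaks are lost) are resolved by the
    joint ridge + band fit seeded from neighbouring columns, which removes
    the mutual-shoulder bias that grows as 1/gap.  Columns may miss any or all roles;
    the scan is rejected only when fewer than ``min_candidate_fraction`` of
    columns yield any candidate.
    """
    px = image.pixels if isinstance(image, BScanImage) else np.asarray(image, float)
    if mask.shape != px.shape:
        raise ValueError("mask shape must match image shape")
    if not mask.any():
        raise UnsegmentableScanError("empty retina mask")
    width = px.shape[1]
    # per-role, per-column: (row, strength)
    pts: dict[str, dict[int, tuple[float, float]]] = {role: {} for role in ROLES}
    band_amp_s: list[tuple[float, float]] = []
    ridge_stats: list[tuple[float, float]] = []
    band_pass2: list[tuple[int, int, int, int]] = []
    merged_cols: list[tuple[int, int, int]] = []

    for c in range(width):
        rows = np.nonzero(mask[:, c])[0]
        if rows.size < 12:
            continue
        lo, hi = int(rows.min()), int(rows.max()) + 1
        p = px[:, c]
        seg = p[lo:hi]
        rng = float(seg.max() - seg.min())
        if rng < 1e-6:
            continue
        peaks, props = find_peaks(seg, prominence=min_prominence * rng, distance=3)
        peaks = peaks + lo
        if peaks.size == 2:
            # IPL merged into the band upper border; last peak is the EZ.
            first, last = int(peaks[0]), int(peaks[-1])
            res = _fit_line_peak(p, last, max((first + last) // 2, last - 7), hi,
                                 step_sign=-1.0)
            if res is not None:
                pts["EZ"][c] = (res[0], res[1])
            merged_cols.append((c, first, last))
            continue
        if peaks.size < 2:
            continue
        ipl_pk, ez_pk = int(peaks[0]), int(peaks[-1])
        interior = peaks[1:-1]
        prom = props["prominences"][1:-1]
        opl_pk = int(interior[int(np.argmax(prom))])

        mid_ipl_opl = (ipl_pk + opl_pk) // 2
        mid_opl_ez = (opl_pk + ez_pk) // 2
        res = _fit_line_peak(p, ipl_pk, lo, min(mid_ipl_opl, ipl_pk + 8),
                             step_sign=1.0)
        if res is not None:
            pts["IPL"][c] = (res[0], res[1])
            ridge_stats.append((res[1], res[2]))
        res = _fit_line_peak(p, ez_pk, max(mid_opl_ez, ez_pk - 7), hi,
                             step_sign=-1.0)
        if res is not None:
            pts["EZ"][c] = (res[0], res[1])
        res = _fit_band(p, opl_pk, mid_ipl_opl, mid_opl_ez + 1)
        if res is not None and res[0] < res[1]:
            band_amp_s.append((res[2], res[3]))
            pts["OPL_upper"][c] = (res[0], res[2])
            pts["OPL_lower"][c] = (res[1], res[2])
        band_pass2.append((c, opl_pk, mid_ipl_opl, mid_opl_ez + 1))

    # Second pass over the band.  The free 5-parameter fit is weakly
    # identified once the band is not much wider than the blur (brightness
    # and width then enter mostly through their product) and acquires an
    # inward bias under speckle; so the free fits only calibrate scan-level
    # brightness and blur, and every column is refit with those two frozen.
    if len(band_amp_s) >= 20:
        band_amp = float(np.median([a for a, _ in band_amp_s]))
        # Scan-level edge blur of a flat band: low quantile of the free-fit
        # estimates (tilted columns only widen it); the tilt term from the
        # lateral denoise kernel is added back per column in quadrature.
        band_s0 = float(np.quantile([s for _, s in band_amp_s], 0.25))
        for c, opl_pk, blo, bhi in band_pass2:
            sl, cv = _local_trend(pts["OPL_upper"], pts["OPL_lower"], c)
            prof = _sheared_profile(px, c, sl, cv)
            refit = _fit_band_frozen(prof, opl_pk, blo, bhi, band_amp,
                                     float(np.hypot(band_s0, sl * lateral_sigma)))
            if refit is not None and refit[0] < refit[1]:
                pts["OPL_upper"][c] = (refit[0], band_amp)
                pts["OPL_lower"][c] = (refit[1], band_amp)
    else:
        band_amp = band_s0 = None

    # Third pass: pinched IPL/band columns, by the joint ridge + band fit
    # seeded from the resolved neighbourhood.
    if band_amp is not None and len(ridge_stats) >= 20:
        ridge_amp = float(np.median([a for a, _ in ridge_stats]))
        ridge_s = float(np.quantile([s for _, s in ridge_stats], 0.25))
        near_merged = [
            (c, int(round(pts["IPL"][c][0])), 0)
            for c in list(pts["IPL"])
            if c in pts["OPL_upper"]
            and pts["OPL_upper"][c][0] - pts["IPL"][c][0] < merge_gap_px
        ]
        for c, first, _last in merged_cols + near_merged:
            rows = np.nonzero(mask[:, c])[0]
            lo, hi = int(rows.min()), int(rows.max()) + 1
            ipl_i = _interp_cand(pts["IPL"], c)
            up_i = _interp_cand(pts["OPL_upper"], c)
            low_i = _interp_cand(pts["OPL_lower"], c)
            if ipl_i is None or up_i is None or low_i is None:
                continue
            sl, cv = _local_trend(pts["OPL_upper"], pts["OPL_lower"], c)
            prof = _sheared_profile(px, c, sl, cv)
            res = _fit_merged(prof, lo, hi, ipl_i, up_i, low_i,
                              ridge_amp,
                              float(np.hypot(ridge_s, sl * lateral_sigma)),
                              band_amp,
                              float(np.hypot(band_s0, sl * lateral_sigma)))
            if res is None:
                # unresolvable pinch: drop any contaminated single fits
                for role in ("IPL", "OPL_upper", "OPL_lower"):
                    pts[role].pop(c, None)
                continue
            pts["IPL"][c] = (res[0], ridge_amp)
            pts["OPL_upper"][c] = (res[1], band_amp)
            pts["OPL_lower"][c] = (res[2], band_amp)

    hit_cols = set().union(*(pts[role].keys() for role in ROLES))
    if len(hit_cols) < min_candidate_fraction * width:
        raise UnsegmentableScanError(
            f"only {len(hit_cols)}/{width} columns produced candidates"
        )
    out = {}
    for role, d in pts.items():
        cols = np.array(sorted(d), dtype=int)
        out[role] = (cols,
                     np.array([d[c][0] for c in cols]),
                     np.array([d[c][1] for c in cols]))
    return CandidateSet(points=out, width=width)


# ---------------------------------------------------------------------------
# SVR curve regression
# ---------------------------------------------------------------------------

def fit_boundary(
    cols: np.ndarray,
    rows: np.ndarray,
    domain: tuple[int, int],
    role: str = "",
    dilation: float = 0.016,
    svr_c: float = 100.0,
    epsilon_px: float = 0.25,
) -> BoundaryCurve:
    """epsilon-insensitive SVR of boundary row on column with the wavelet kernel.

    Columns are normalized to [0, 1] over the domain.  The curve is evaluated
    on every domain column, so candidate gaps are filled by model prediction.
    """
    cols = np.asarray(cols, dtype=float)
    rows = np.asarray(rows, dtype=float)
    n_unique = np.unique(cols).size
    if n_unique < 10:
        raise InsufficientCandidatesError(role or "?", n_unique)
    start, end = domain
    width = float(end - start)
    x = (cols - start) / width
    model = SVR(kernel="precomputed", C=svr_c, epsilon=epsilon_px, tol=1e-4, cache_size=64)
    model.fit(wavelet_gram(x, x, dilation), rows)
    xq = (np.arange(start, end) - start) / width
    pred = model.predict(wavelet_gram(xq, x, dilation))
    return BoundaryCurve(depth=pred, start=start, role=role)


def replace_mislabels(
    curve: BoundaryCurve,
    cols: np.ndarray,
    rows: np.ndarray,
    threshold_px: float = 8.0,
    **fit_kwargs,
) -> BoundaryCurve:
    """Drop candidates deviating > threshold from the fitted curve and refit once.

    No-op (the input curve is returned) when nothing exceeds the threshold.
    """
    cols = np.asarray(cols, dtype=int)
    rows = np.asarray(rows, dtype=float)
    resid = np.abs(rows - curve.depth[cols - curve.start])
    keep = resid <= threshold_px
    if keep.all():
        return curve
    return fit_boundary(cols[keep], rows[keep], (curve.start, curve.end),
                        role=curve.role, **fit_kwargs)


def segment_layers(
    img: BScanImage,
    params: SegmentParams | None = None,
    mask: np.ndarray | None = None,
) -> LayerSet:
    """Full segmentation of a preprocessed (denoised, disc-trimmed) B-scan.

    Pipeline: Gabor retina mask -> per-column candidates -> per-role SVR fit
    -> mislabel replacement -> ordering repair.  Columns where the fitted
    curves still violate IPL < OPL_upper <= OPL_lower < EZ are marked invalid
    and excluded from downstream biomarkers.
    """
    if params is None:
        params = SegmentParams()
    if mask is None:
        _, mask = enhance_retina(img, params.gabor)
    cand = extract_candidates(
        img, mask,
        min_prominence=params.min_prominence,
        min_candidate_fraction=params.min_candidate_fraction,
    )
    domain = (0, img.width)
    fit_kw = dict(dilation=params.dilation, svr_c=params.svr_c, epsilon_px=params.epsilon_px)
    fitted: dict[str, BoundaryCurve] = {}
    for role in ROLES:
        cols, rows, _ = cand[role]
        try:
            curve = fit_boundary(cols, rows, domain, role=role, **fit_kw)
            curve = replace_mislabels(curve, cols, rows,
                                      threshold_px=params.mislabel_threshold_px, **fit_kw)
        except InsufficientCandidatesError as exc:
            raise UnsegmentableScanError(f"stage fit_boundary: {exc}") from exc
        fitted[role] = curve

    ipl, u, l, ez = (fitted[r].depth for r in ROLES)
    ok = (ipl < u) & (u <= l) & (l < ez)
    for role in ROLES:
        fitted[role].valid = ok.copy()
    if not ok.any():
        raise UnsegmentableScanError("ordering repair excluded every column")
    return LayerSet(fitted["IPL"], fitted["OPL_upper"], fitted["OPL_lower"], fitted["EZ"])
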