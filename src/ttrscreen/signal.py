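"""Spectrum container and raw-signal processing for linear MALDI-TOF data.

The processing chain mirrors what vendor software does behind the scenes for
intact-protein spectra, made explicit and testable:

* baseline by morphological opening (rolling minimum then rolling maximum
  over a window wide relative to any peak) followed by light smoothing;
* noise by the scaled median absolute deviation of the baseline-subtracted
  signal in non-overlapping mass windows;
* peak detection as SNR-thresholded local maxima with intensity-weighted
  centroids over the half-maximum support, splitting near-lying maxima into
  distinct peaks only when the valley between them is deep enough;
* external calibration as an affine (slope/offset) least-squares fit of
  reference masses on observed centroids.

Centroids rather than apex positions are reported throughout: with a ~0.5-Da
grid and peaks several Da wide, sub-grid positioning is what makes measured
mass shifts comparable to theory at the ~1-Da level.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any, Mapping, Sequence

import numpy as np
from scipy import ndimage

from .errors import CalibrationError

__all__ = [
    "Spectrum",
    "Peak",
    "CalibrationModel",
    "estimate_baseline",
    "estimate_noise",
    "detect_peaks",
    "fit_calibration",
    "apply_calibration",
]

_FWHM_PER_SIGMA = 2.3548200450309493  # 2*sqrt(2*ln 2)


@dataclass
class Spectrum:
    """An intensity trace on a strictly ascending m/z grid.

    Negative intensities (possible after noise or baseline subtraction at
    acquisition time) are clipped to zero on construction.
    """

    mz: np.ndarray
    intensity: np.ndarray
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.clip(np.asarray(self.intensity, dtype=float), 0.0, None)
        if self.mz.ndim != 1 or self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity must be 1-D arrays of equal length")
        if len(self.mz) < 16:
            raise ValueError(f"spectrum too short ({len(self.mz)} points; need >= 16)")
        if not np.all(np.diff(self.mz) > 0):
            raise ValueError("mz values must be strictly ascending")

    def __len__(self) -> int:
        return len(self.mz)

    @property
    def grid_step(self) -> float:
        """Median grid spacing (Da)."""
        return float(np.median(np.diff(self.mz)))


@dataclass(frozen=True)
class Peak:
    """A detected spectral feature."""

    centroid_mz: float
    apex_intensity: float
    fwhm: float
    snr: float
    area: float

    def __post_init__(self) -> None:
        if self.fwhm <= 0:
            raise ValueError("fwhm must be positive")
        if self.snr <= 0:
            raise ValueError("snr must be positive")


@dataclass(frozen=True)
class CalibrationModel:
    """Affine map from observed to calibrated m/z: true = slope * observed + offset."""

    slope: float
    offset: float
    rms_residual: float
    n_points: int

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise ValueError("calibration needs at least 2 reference points")
        if not 0.9 < self.slope < 1.1:
            raise ValueError(f"implausible calibration slope {self.slope}")

    def __call__(self, mz):
        return self.slope * np.asarray(mz, dtype=float) + self.offset

    @classmethod
    def identity(cls) -> "CalibrationModel":
        return cls(slope=1.0, offset=0.0, rms_residual=0.0, n_points=2)


def _odd(n: int) -> int:
    return n if n % 2 == 1 else n + 1


def estimate_baseline(spec: Spectrum, window: float = 200.0) -> np.ndarray:
    """Slowly varying chemical background under the peaks.

    Morphological opening (rolling minimum then rolling maximum, ``window``
    Da wide) flattens any feature narrower than the window while following
    the broad matrix background, and a ``window/2`` moving average removes
    the staircase the opening leaves behind.
    """
    step = spec.grid_step
    if window < 10 * step:
        raise ValueError(
            f"baseline window {window} Da too small for grid step {step} Da "
            f"(need >= {10 * step})"
        )
    w = _odd(max(3, int(round(window / step))))
    opened = ndimage.grey_dilation(
        ndimage.grey_erosion(spec.intensity, size=w), size=w
    )
    smooth_w = max(1, w // 2)
    return ndimage.uniform_filter1d(opened, size=smooth_w, mode="nearest")


def estimate_noise(
    spec: Spectrum, baseline: np.ndarray, window: float = 100.0
) -> np.ndarray:
    """Per-point noise standard deviation.

    Robustly estimated as 1.4826 x median-absolute-deviation of the
    baseline-subtracted signal in non-overlapping ``window``-Da bins and
    interpolated back onto the grid; a small positive floor keeps SNR
    well-defined on noiseless synthetic data.
    """
    if len(baseline) != len(spec):
        raise ValueError("baseline must align with the spectrum")
    resid = spec.intensity - baseline
    edges = np.arange(spec.mz[0], spec.mz[-1] + window, window)
    centers, sds = [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = (spec.mz >= lo) & (spec.mz < hi)
        if sel.sum() < 4:
            continue
        r = resid[sel]
        mad = np.median(np.abs(r - np.median(r)))
        centers.append(0.5 * (lo + hi))
        sds.append(1.4826 * mad)
    if not centers:  # single short window: global fallback
        mad = np.median(np.abs(resid - np.median(resid)))
        centers, sds = [spec.mz[len(spec) // 2]], [1.4826 * mad]
    noise = np.interp(spec.mz, centers, sds)
    floor = max(1e-12, 1e-9 * float(np.max(np.abs(resid), initial=0.0)))
    return np.maximum(noise, floor)


def _half_max_support(
    y: np.ndarray, apex: int, left_limit: int, right_limit: int
) -> tuple[int, int]:
    """Contiguous index range around ``apex`` staying above half the apex,
    clipped at the valley indices toward neighbouring peaks."""
    half = y[apex] / 2.0
    lo = apex
    while lo > left_limit and y[lo - 1] >= half:
        lo -= 1
    hi = apex
    while hi < right_limit and y[hi + 1] >= half:
        hi += 1
    return lo, hi


def _interp_fwhm(x: np.ndarray, y: np.ndarray, apex: int, lo: int, hi: int) -> float:
    """FWHM via linear interpolation of the half-max crossings; support edges
    stand in where a side never drops below half (overlapped peaks)."""
    half = y[apex] / 2.0
    if lo > 0 and y[lo - 1] < half < y[lo]:
        f = (y[lo] - half) / (y[lo] - y[lo - 1])
        left = x[lo] - f * (x[lo] - x[lo - 1])
    else:
        left = x[lo]
    if hi < len(x) - 1 and y[hi + 1] < half < y[hi]:
        f = (y[hi] - half) / (y[hi] - y[hi + 1])
        right = x[hi] + f * (x[hi + 1] - x[hi])
    else:
        right = x[hi]
    return right - left


def detect_peaks(
    spec: Spectrum,
    baseline: np.ndarray | None = None,
    noise: np.ndarray | None = None,
    snr_min: float = 5.0,
    min_fwhm_points: int = 3,
    valley_frac: float = 0.75,
) -> list[Peak]:
    """Detect peaks as SNR-thresholded local maxima of the corrected signal.

    Adjacent maxima are reported as distinct peaks only if the valley between
    them drops below ``valley_frac`` of the lower apex; otherwise the smaller
    maximum is absorbed into the larger (this is what keeps noise ripple on a
    broad peak from splitting it, and is the formal criterion for when a
    variant doublet counts as resolved).  Each surviving peak is centroided
    over its half-maximum support, clipped at the valley toward a neighbour.
    """
    if baseline is None:
        baseline = estimate_baseline(spec)
    if noise is None:
        noise = estimate_noise(spec, baseline)
    y = spec.intensity - baseline
    x = spec.mz
    n = len(y)

    apexes = [
        i
        for i in range(1, n - 1)
        if y[i] > 0 and y[i] >= y[i - 1] and y[i] > y[i + 1] and y[i] / noise[i] >= snr_min
    ]

    # valley-based merging of near-lying maxima
    changed = True
    while changed and len(apexes) > 1:
        changed = False
        for k in range(len(apexes) - 1):
            i, j = apexes[k], apexes[k + 1]
            valley = y[i : j + 1].min()
            if valley > valley_frac * min(y[i], y[j]):
                drop = k if y[i] < y[j] else k + 1
                del apexes[drop]
                changed = True
                break

    peaks: list[Peak] = []
    for k, apex in enumerate(apexes):
        left_limit = 0
        if k > 0:
            prev = apexes[k - 1]
            left_limit = prev + int(np.argmin(y[prev : apex + 1]))
        right_limit = n - 1
        if k < len(apexes) - 1:
            nxt = apexes[k + 1]
            right_limit = apex + int(np.argmin(y[apex : nxt + 1]))
        lo, hi = _half_max_support(y, apex, left_limit, right_limit)
        if hi - lo + 1 < min_fwhm_points:
            continue
        seg_x, seg_y = x[lo : hi + 1], np.clip(y[lo : hi + 1], 0.0, None)
        total = seg_y.sum()
        if total <= 0:
            continue
        centroid = float((seg_x * seg_y).sum() / total)
        fwhm = float(_interp_fwhm(x, y, apex, lo, hi))
        if fwhm <= 0:
            continue
        peaks.append(
            Peak(
                centroid_mz=centroid,
                apex_intensity=float(y[apex]),
                fwhm=fwhm,
                snr=float(y[apex] / noise[apex]),
                area=float(np.trapezoid(seg_y, seg_x)),
            )
        )
    peaks.sort(key=lambda p: p.centroid_mz)
    return peaks


def fit_calibration(
    peaks: Sequence[Peak],
    references: Sequence[float],
    match_tol_frac: float = 0.003,
) -> CalibrationModel:
    """Affine external calibration from calibrant peaks.

    For each reference mass the nearest detected centroid within
    ``match_tol_frac * reference`` is taken (ties go to the more intense
    peak), and reference is regressed on observed by ordinary least squares.
    Within each tolerance window only peaks reaching 10% of the window's
    most intense peak are eligible, so low-level noise features next to a
    reference cannot outcompete the actual calibrant peak.
    """
    matched: list[tuple[float, float]] = []
    unmatched: list[float] = []
    for ref in references:
        tol = match_tol_frac * ref
        cands = [p for p in peaks if abs(p.centroid_mz - ref) <= tol]
        if cands:
            apex_floor = 0.1 * max(p.apex_intensity for p in cands)
            cands = [p for p in cands if p.apex_intensity >= apex_floor]
        if not cands:
            unmatched.append(ref)
            continue
        best_dist = min(abs(p.centroid_mz - ref) for p in cands)
        tied = [p for p in cands if abs(abs(p.centroid_mz - ref) - best_dist) < 1e-12]
        best = max(tied, key=lambda p: p.apex_intensity)
        matched.append((best.centroid_mz, ref))
    if len(matched) < 2:
        raise CalibrationError(
            f"only {len(matched)} of {len(references)} calibrants matched "
            f"(matched at {[round(m[1], 2) for m in matched]}, "
            f"unmatched {[round(u, 2) for u in unmatched]})"
        )
    obs = np.array([m[0] for m in matched])
    ref = np.array([m[1] for m in matched])
    slope, offset = np.polyfit(obs, ref, 1)
    resid = ref - (slope * obs + offset)
    return CalibrationModel(
        slope=float(slope),
        offset=float(offset),
        rms_residual=float(np.sqrt(np.mean(resid**2))),
        n_points=len(matched),
    )


def apply_calibration(obj, model: CalibrationModel):
    """Map a Spectrum, a Peak, or a sequence of Peaks through the calibration."""
    if isinstance(obj, Spectrum):
        return Spectrum(
            mz=model(obj.mz), intensity=obj.intensity.copy(), metadata=dict(obj.metadata)
        )
    if isinstance(obj, Peak):
        return replace(
            obj, centroid_mz=float(model(obj.centroid_mz)), fwhm=obj.fwhm * model.slope
        )
    return [apply_calibration(p, model) for p in obj]
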