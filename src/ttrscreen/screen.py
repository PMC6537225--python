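"""Variant calling from a calibrated peak list.

The screen formalises how a reader of an intact-protein serum spectrum
calls a TTR variant: find the wild-type monomer peak near its theoretical
mass, look for a companion peak within the window that plausible single
substitutions can reach, measure the centroid-to-centroid mass shift, and
match it against the catalogue of theoretical shifts.  The method
identifies *mass shifts*, not sequence positions, so isobaric variants
(e.g. Val28Met vs Val30Met, both +32.06 Da) are reported together, ranked
by deviation.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Sequence

from .errors import CalibrationError, InputDomainError
from .masses import (
    PointMutation,
    RESOLVABILITY_THRESHOLD_DA,
    VariantCatalogEntry,
    WT_TTR_MONOMER_MASS,
    parse_mutation,
    residue_delta,
)
from .signal import (
    CalibrationModel,
    Peak,
    Spectrum,
    apply_calibration,
    detect_peaks,
    estimate_baseline,
    estimate_noise,
    fit_calibration,
)
from .simulate import CALIBRANT_MASSES, PROTON_MASS

__all__ = [
    "ScreenParams",
    "ScreenStatus",
    "VariantCall",
    "ScreenResult",
    "locate_wt_peak",
    "candidate_variant_peaks",
    "match_catalog",
    "screen_spectrum",
]


@dataclass(frozen=True)
class ScreenParams:
    """Thresholds of the variant screen (all in Da unless noted).

    The wild-type window is half the resolvability threshold so that WT
    assignment can never swallow a resolvable variant peak; the variant
    window covers the shift range single substitutions can produce
    (roughly -76 to +99 Da for TTR) with margin; the match tolerance covers
    the worst measured-vs-theoretical deviation seen in practice (~3.3 Da
    for barely resolved doublets, whose centroids are pulled together).
    """

    wt_mass: float = WT_TTR_MONOMER_MASS
    wt_window: float = 6.0
    variant_window: float = 120.0
    match_tol: float = 3.5
    resolvability_threshold: float = RESOLVABILITY_THRESHOLD_DA
    #: candidate peaks must reach this fraction of the WT apex intensity
    min_variant_rel_intensity: float = 0.2

    def __post_init__(self) -> None:
        if not 0 < self.wt_window < self.resolvability_threshold <= self.variant_window:
            raise ValueError(
                "require 0 < wt_window < resolvability_threshold <= variant_window"
            )
        if self.match_tol <= 0:
            raise ValueError("match_tol must be positive")


class ScreenStatus(str, enum.Enum):
    DETECTED = "detected"
    NOT_DETECTED = "not_detected"
    UNRESOLVABLE_CANDIDATE = "unresolvable_candidate"
    NO_WT_PEAK = "no_wt_peak"


@dataclass(frozen=True)
class VariantCall:
    """Catalogue entries compatible with a measured shift, best first."""

    matches: tuple[tuple[VariantCatalogEntry, float], ...]

    def __bool__(self) -> bool:
        return bool(self.matches)

    @property
    def best(self) -> VariantCatalogEntry | None:
        return self.matches[0][0] if self.matches else None

    @property
    def labels(self) -> list[str]:
        return [e.label for e, _ in self.matches]


@dataclass(frozen=True)
class ScreenResult:
    """Per-spectrum outcome of the screen."""

    status: ScreenStatus
    wt_peak: Peak | None = None
    variant_peak: Peak | None = None
    measured_shift: float | None = None
    call: VariantCall | None = None
    calibration: CalibrationModel | None = None
    peaks: tuple[Peak, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.status is ScreenStatus.DETECTED:
            if self.variant_peak is None or self.measured_shift is None or not self.call:
                raise ValueError(
                    "detected result requires variant peak, shift and a non-empty call"
                )


def locate_wt_peak(peaks: Sequence[Peak], params: ScreenParams) -> Peak | None:
    """The most intense peak within ``wt_window`` of the theoretical WT mass."""
    cands = [p for p in peaks if abs(p.centroid_mz - params.wt_mass) <= params.wt_window]
    if not cands:
        return None
    return max(cands, key=lambda p: p.apex_intensity)


def candidate_variant_peaks(
    peaks: Sequence[Peak], wt_peak: Peak, params: ScreenParams
) -> list[Peak]:
    """Peaks that could be a variant monomer.

    Within ``variant_window`` of the theoretical WT mass, excluding the WT
    peak itself, anything within ``wt_window`` of it, anything below the
    relative-intensity floor, and the doubly-charged companion region.
    """
    dication_mz = (params.wt_mass + 2 * PROTON_MASS) / 2.0
    out = []
    for p in peaks:
        if p is wt_peak:
            continue
        if abs(p.centroid_mz - params.wt_mass) > params.variant_window:
            continue
        if abs(p.centroid_mz - wt_peak.centroid_mz) <= params.wt_window:
            continue
        if p.apex_intensity < params.min_variant_rel_intensity * wt_peak.apex_intensity:
            continue
        if abs(p.centroid_mz - dication_mz) <= params.variant_window / 2.0:
            continue
        out.append(p)
    return sorted(out, key=lambda p: p.centroid_mz)


def match_catalog(
    measured_shift: float,
    catalog: Sequence[VariantCatalogEntry],
    params: ScreenParams,
) -> VariantCall:
    """All catalogue entries within ``match_tol`` of the measured shift, ascending by deviation."""
    scored = [
        (entry, abs(measured_shift - entry.delta_mass))
        for entry in catalog
        if abs(measured_shift - entry.delta_mass) <= params.match_tol
    ]
    scored.sort(key=lambda t: (t[1], t[0].label))
    return VariantCall(matches=tuple(scored))


def screen_spectrum(
    spec: Spectrum,
    catalog: Sequence[VariantCatalogEntry],
    params: ScreenParams | None = None,
    expected: str | PointMutation | None = None,
    snr_min: float = 5.0,
    baseline_window: float = 200.0,
    calibration_references: Sequence[float] = CALIBRANT_MASSES,
) -> ScreenResult:
    """Run the full per-spectrum pipeline: process, calibrate, locate, call.

    ``expected`` (optional, e.g. from genetic testing) only affects the
    status of negative outcomes: a carrier of a sub-threshold variant is
    reported as an ``unresolvable_candidate`` instead of ``not_detected``.
    Without it the screen is blind and sub-threshold variants are simply
    not detected.
    """
    params = params or ScreenParams()
    if spec.mz[0] > params.wt_mass - params.variant_window or spec.mz[-1] < (
        params.wt_mass + params.variant_window
    ):
        raise InputDomainError(
            f"spectrum [{spec.mz[0]:.0f}, {spec.mz[-1]:.0f}] does not cover the "
            f"variant window [{params.wt_mass - params.variant_window:.0f}, "
            f"{params.wt_mass + params.variant_window:.0f}]"
        )

    baseline = estimate_baseline(spec, window=baseline_window)
    noise = estimate_noise(spec, baseline)
    raw_peaks = detect_peaks(spec, baseline, noise, snr_min=snr_min)

    model: CalibrationModel | None = None
    if calibration_references is not None and len(calibration_references) >= 2:
        try:
            model = fit_calibration(raw_peaks, calibration_references)
        except CalibrationError:
            model = None
    peaks = apply_calibration(raw_peaks, model) if model is not None else list(raw_peaks)

    def negative(status: ScreenStatus, wt: Peak | None) -> ScreenResult:
        return ScreenResult(
            status=status,
            wt_peak=wt,
            call=VariantCall(matches=()),
            calibration=model,
            peaks=tuple(peaks),
        )

    wt = locate_wt_peak(peaks, params)
    if wt is None:
        return negative(ScreenStatus.NO_WT_PEAK, None)

    best: tuple[Peak, float, VariantCall] | None = None
    for cand in candidate_variant_peaks(peaks, wt, params):
        shift = cand.centroid_mz - wt.centroid_mz
        call = match_catalog(shift, catalog, params)
        if call and (best is None or cand.apex_intensity > best[0].apex_intensity):
            best = (cand, shift, call)

    if best is not None:
        cand, shift, call = best
        return ScreenResult(
            status=ScreenStatus.DETECTED,
            wt_peak=wt,
            variant_peak=cand,
            measured_shift=shift,
            call=call,
            calibration=model,
            peaks=tuple(peaks),
        )

    if expected is not None:
        mut = expected if isinstance(expected, PointMutation) else parse_mutation(expected)
        if abs(residue_delta(mut)) < params.resolvability_threshold:
            return negative(ScreenStatus.UNRESOLVABLE_CANDIDATE, wt)
    return negative(ScreenStatus.NOT_DETECTED, wt)
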