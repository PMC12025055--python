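"""Segment cleaning, band-pass filtering, scaling and class balancing.

The pipeline order is fixed: screen → impute/drop → bandpass → min–max scale
→ (label encoding) → balance. Filtering uses a 4th-order Butterworth band
0.53–40 Hz applied forward–backward (zero phase), which keeps spike
morphology intact for the wavelet features.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .errors import DegenerateInputError, ParameterError
from .io_formats import EEGSegment, SegmentSet

__all__ = [
    "ValidityReport",
    "Rejection",
    "bandpass",
    "screen_validity",
    "impute_or_drop",
    "minmax_scale",
    "balance_classes",
    "preprocess_segment",
    "preprocess_set",
    "DEFAULT_BAND",
]

log = logging.getLogger(__name__)

#: Default pass band (Hz) for scalp EEG.
DEFAULT_BAND = (0.53, 40.0)


@dataclass
class ValidityReport:
    """Outcome of screening a segment for NaNs, zeros and flat stretches."""

    has_nan: bool
    has_all_zero: bool
    constant: bool
    flat_windows: list[tuple[int, int]] = field(default_factory=list)
    nan_fraction: float = 0.0

    @property
    def usable(self) -> bool:
        return not self.constant and not self.has_all_zero and not self.has_nan


@dataclass
class Rejection:
    """Typed outcome for a segment dropped during cleaning."""

    segment_id: str
    reason: str


def bandpass(
    segment: EEGSegment,
    low: float = DEFAULT_BAND[0],
    high: float = DEFAULT_BAND[1],
    order: int = 4,
) -> EEGSegment:
    """Zero-phase Butterworth band-pass copy of a segment.

    Length is unchanged; DC and out-of-band rhythms are attenuated.
    """
    nyq = segment.fs / 2.0
    if not 0 < low < high:
        raise ParameterError(f"need 0 < low < high, got ({low}, {high})")
    if high >= nyq:
        raise ParameterError(
            f"high cutoff {high} Hz must lie below Nyquist {nyq:.3f} Hz"
        )
    sos = signal.butter(order, [low, high], btype="bandpass", fs=segment.fs, output="sos")
    return segment.copy_with(signal.sosfiltfilt(sos, segment.samples))


def screen_validity(
    segment: EEGSegment,
    flat_window_s: float = 1.0,
    flat_tol: float | None = None,
) -> ValidityReport:
    """Report NaNs, all-zero/constant content and flat (no-fluctuation) windows.

    ``flat_tol`` is an absolute variance threshold; by default it adapts to
    the segment (``1e-10 * (var + eps)``) so gain does not matter.
    """
    x = segment.samples
    w = int(round(flat_window_s * segment.fs))
    if w < 2:
        raise ParameterError("flat_window_s * fs must be >= 2 samples")

    has_nan = bool(np.any(np.isnan(x)))
    nan_fraction = float(np.mean(np.isnan(x)))
    finite = x[np.isfinite(x)]
    has_all_zero = finite.size > 0 and bool(np.all(finite == 0.0))
    constant = finite.size > 0 and bool(np.nanmax(finite) == np.nanmin(finite))

    if flat_tol is None:
        flat_tol = 1e-10 * (float(np.var(finite)) + 1e-30) if finite.size else 1e-10

    flat_windows: list[tuple[int, int]] = []
    if x.size >= w and not has_nan:
        # rolling variance via cumulative sums; mark flat starts, merge maximal runs
        c1 = np.concatenate([[0.0], np.cumsum(x)])
        c2 = np.concatenate([[0.0], np.cumsum(x * x)])
        s1 = c1[w:] - c1[:-w]
        s2 = c2[w:] - c2[:-w]
        var = s2 / w - (s1 / w) ** 2
        flat_start = np.flatnonzero(var < flat_tol)
        if flat_start.size:
            run_start = flat_start[0]
            prev = flat_start[0]
            for s in flat_start[1:]:
                if s > prev + w:  # gap: windows no longer overlap into one run
                    flat_windows.append((int(run_start), int(prev + w)))
                    run_start = s
                prev = s
            flat_windows.append((int(run_start), int(prev + w)))

    return ValidityReport(
        has_nan=has_nan,
        has_all_zero=has_all_zero,
        constant=constant,
        flat_windows=flat_windows,
        nan_fraction=nan_fraction,
    )


def impute_or_drop(
    segment: EEGSegment,
    report: ValidityReport,
    max_nan_fraction: float = 0.01,
) -> EEGSegment | Rejection:
    """Linearly interpolate isolated NaNs; reject unusable segments.

    Segments with more than ``max_nan_fraction`` missing samples, or that are
    constant/all-zero, are rejected with a reason rather than raising.
    """
    if report.constant or report.has_all_zero:
        return Rejection(segment.segment_id, "constant or all-zero signal")
    if not report.has_nan:
        return segment
    if report.nan_fraction > max_nan_fraction:
        return Rejection(segment.segment_id, "excessive missingness")
    x = segment.samples.copy()
    bad = np.isnan(x)
    good_idx = np.flatnonzero(~bad)
    if good_idx.size < 2:
        return Rejection(segment.segment_id, "too few valid samples to interpolate")
    x[bad] = np.interp(np.flatnonzero(bad), good_idx, x[good_idx])
    return segment.copy_with(x)


def minmax_scale(x: np.ndarray) -> np.ndarray:
    """Rescale a sequence to [0, 1]: x' = (x − min) / (max − min)."""
    x = np.asarray(x, dtype=float)
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi == lo:
        raise DegenerateInputError(
            "constant input: min == max, min-max scaling undefined"
        )
    return (x - lo) / (hi - lo)


def balance_classes(segset: SegmentSet, seed: int = 0) -> SegmentSet:
    """Randomly undersample the majority class to the minority count.

    Membership (not order) of the minority class is untouched; the selection
    is deterministic given the seed. An already balanced set passes through
    with identical membership.
    """
    labels = segset.labels
    counts = segset.class_counts
    if set(counts) != {0, 1}:
        raise ParameterError(f"need both classes present, got counts {counts}")
    n0, n1 = counts[0], counts[1]
    if n0 == n1:
        return segset
    minority = 0 if n0 < n1 else 1
    target = min(n0, n1)
    rng = np.random.default_rng(seed)
    majority_idx = np.flatnonzero(labels != minority)
    keep_majority = set(rng.choice(majority_idx, size=target, replace=False).tolist())
    kept = [
        s
        for i, s in enumerate(segset)
        if s.label == minority or i in keep_majority
    ]
    return SegmentSet(kept)


def preprocess_segment(
    segment: EEGSegment,
    low: float = DEFAULT_BAND[0],
    high: float = DEFAULT_BAND[1],
    order: int = 4,
    scale: bool = True,
) -> EEGSegment | Rejection:
    """Screen → impute/drop → bandpass → per-segment min–max scale."""
    report = screen_validity(segment)
    cleaned = impute_or_drop(segment, report)
    if isinstance(cleaned, Rejection):
        return cleaned
    filtered = bandpass(cleaned, low=low, high=high, order=order)
    if not scale:
        return filtered
    try:
        return filtered.copy_with(minmax_scale(filtered.samples))
    except DegenerateInputError:
        return Rejection(segment.segment_id, "constant after filtering")


def preprocess_set(
    segset: SegmentSet,
    low: float = DEFAULT_BAND[0],
    high: float = DEFAULT_BAND[1],
    order: int = 4,
    scale: bool = True,
    balance: bool = False,
    seed: int = 0,
) -> tuple[SegmentSet, list[Rejection]]:
    """Apply the fixed cleaning pipeline to every segment; log the audit trail."""
    kept: list[EEGSegment] = []
    rejected: list[Rejection] = []
    for seg in segset:
        out = preprocess_segment(seg, low=low, high=high, order=order, scale=scale)
        (rejected if isinstance(out, Rejection) else kept).append(out)  # type: ignore[arg-type]
    result = SegmentSet(kept)
    log.info(
        "preprocess: %d in, %d kept, %d rejected", len(segset), len(result), len(rejected)
    )
    if balance:
        result = balance_classes(result, seed=seed)
        log.info("balance: %d after undersampling", len(result))
    return result, rejected
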