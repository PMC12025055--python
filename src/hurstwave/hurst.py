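"""Rescaled-range (R/S) Hurst analysis.

The R/S statistic of a window x_1..x_n is the range of the cumulative
deviations from the window mean, rescaled by the window standard deviation:

    R(n) = max_t S_t − min_t S_t,   S_t = Σ_{i≤t} (x_i − x̄)
    R/S  = R(n) / σ(x)              (population σ)

For a self-affine series E[R(n)/S(n)] ≈ C·n^H, so regressing log(R/S̄) on
log(n) over a dyadic grid of window sizes yields the Hurst exponent H
(slope) and the Hurst constant C (exp of the intercept, natural log). H>0.5
marks persistent long-range dependence, H<0.5 anti-persistence.

Two scalar features are exported per segment: ``hurstex`` (= H) and
``hurstc`` (= C). A sliding-window H profile is available as a diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import EstimationError, ParameterError, ZeroDispersionError
from .io_formats import EEGSegment

__all__ = ["HurstFit", "rescaled_range", "estimate_hurst", "hurst_features", "hurst_profile"]


@dataclass
class HurstFit:
    """Result of a log–log R/S fit.

    ``H`` is the fitted slope, ``C = exp(intercept)`` with natural logs.
    ``out_of_range`` flags estimates outside (0, 1), which strong trends can
    produce; they are reported, never clipped.
    """

    H: float
    C: float
    window_sizes: np.ndarray
    rs_values: np.ndarray
    r_squared: float
    n_windows_skipped: int = 0
    log_base: str = "e"

    @property
    def out_of_range(self) -> bool:
        return not 0.0 < self.H < 1.0


def rescaled_range(x: np.ndarray, sd_mode: str = "population") -> float:
    """R/S statistic of one window.

    Raises :class:`ZeroDispersionError` for constant windows (S = 0), which
    callers treat as a skip signal rather than an error.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ParameterError("window must have at least 2 samples")
    ddof = 0 if sd_mode == "population" else 1
    s = float(np.std(x, ddof=ddof))
    if s == 0.0:
        raise ZeroDispersionError("window has zero dispersion; R/S undefined")
    dev = np.cumsum(x - np.mean(x))
    r = float(np.max(dev) - np.min(dev))
    return r / s


def _rs_blocks(x: np.ndarray, n: int, ddof: int) -> tuple[float, int]:
    """Mean R/S over the ⌊len(x)/n⌋ disjoint blocks of size n.

    Vectorised across blocks; returns (mean R/S over usable blocks, number of
    blocks skipped for zero dispersion).
    """
    m = x.size // n
    blocks = x[: m * n].reshape(m, n)
    sd = np.std(blocks, axis=1, ddof=ddof)
    usable = sd > 0
    skipped = int(m - usable.sum())
    if not np.any(usable):
        return np.nan, skipped
    b = blocks[usable]
    dev = np.cumsum(b - b.mean(axis=1, keepdims=True), axis=1)
    r = dev.max(axis=1) - dev.min(axis=1)
    return float(np.mean(r / sd[usable])), skipped


def estimate_hurst(
    x: np.ndarray,
    min_window: int = 16,
    max_window: int | None = None,
    grid: str = "dyadic",
    sd_mode: str = "population",
) -> HurstFit:
    """Estimate H and C by rescaled-range analysis over a window-size grid.

    The series is partitioned, for each window size n in a dyadic grid
    ``min_window, 2·min_window, …, max_window``, into disjoint blocks whose
    R/S values are averaged; ``log(mean R/S)`` is then regressed on
    ``log n``. ``max_window`` defaults to half the series length.

    For band-limited signals, cap ``max_window`` at the longest period the
    filter retains (samples per cycle of the low cutoff): beyond that scale
    R/S measures the filter's roll-off, not the signal's persistence.
    """
    x = np.asarray(x, dtype=float)
    if min_window < 8:
        raise ParameterError("min_window must be >= 8")
    if x.size < 4 * min_window:
        raise ParameterError(
            f"series length {x.size} too short; need >= {4 * min_window}"
        )
    top = x.size // 2 if max_window is None else min(int(max_window), x.size // 2)
    if top < 4 * min_window:
        raise ParameterError("max_window leaves fewer than 3 dyadic sizes")
    if grid == "dyadic":
        sizes = []
        n = min_window
        while n <= top:
            sizes.append(n)
            n *= 2
    elif grid == "log-spaced":
        sizes = np.unique(
            np.round(
                np.exp(np.linspace(np.log(min_window), np.log(top), 12))
            ).astype(int)
        ).tolist()
    else:
        raise ParameterError(f"unknown grid {grid!r}")

    ddof = 0 if sd_mode == "population" else 1
    used_sizes, rs_means = [], []
    skipped = 0
    for n in sizes:
        mean_rs, n_skip = _rs_blocks(x, n, ddof)
        skipped += n_skip
        if np.isfinite(mean_rs) and mean_rs > 0:
            used_sizes.append(n)
            rs_means.append(mean_rs)
    if len(used_sizes) < 3:
        raise EstimationError(
            f"only {len(used_sizes)} usable window sizes (need >= 3); "
            "series may be constant or too short"
        )
    log_n = np.log(used_sizes)
    log_rs = np.log(rs_means)
    slope, intercept = np.polyfit(log_n, log_rs, 1)
    fitted = slope * log_n + intercept
    ss_res = float(np.sum((log_rs - fitted) ** 2))
    ss_tot = float(np.sum((log_rs - log_rs.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return HurstFit(
        H=float(slope),
        C=float(np.exp(intercept)),
        window_sizes=np.array(used_sizes),
        rs_values=np.array(rs_means),
        r_squared=r2,
        n_windows_skipped=skipped,
    )


def hurst_features(
    segment: EEGSegment,
    min_window: int = 16,
    low_cut_hz: float | None = 0.53,
) -> tuple[float, float]:
    """The two scalar Hurst features of a segment: (hurstex, hurstc).

    Segments arriving here have passed the cleaning pipeline, whose band-pass
    removes fluctuations slower than ``low_cut_hz``; the R/S fit is therefore
    restricted to window lengths within the pass-band (``fs / low_cut_hz``
    samples), where the scaling reflects the signal rather than the filter.
    Pass ``low_cut_hz=None`` for unfiltered series.
    """
    max_window = None
    if low_cut_hz is not None and low_cut_hz > 0:
        max_window = max(int(segment.fs / low_cut_hz), 4 * min_window)
    fit = estimate_hurst(segment.samples, min_window=min_window, max_window=max_window)
    return fit.H, fit.C


def hurst_profile(
    segment: EEGSegment, window_s: float = 6.0, hop_s: float = 1.0, min_window: int = 16
) -> tuple[np.ndarray, np.ndarray]:
    """Diagnostic sliding-window H profile (times, H estimates).

    Not part of the feature vector; useful for inspecting time-dependent
    persistence within a recording.
    """
    w = int(round(window_s * segment.fs))
    hop = int(round(hop_s * segment.fs))
    if w < 4 * min_window:
        raise ParameterError("profile window too short for estimation")
    times, hs = [], []
    for start in range(0, segment.n_samples - w + 1, hop):
        chunk = segment.samples[start : start + w]
        try:
            fit = estimate_hurst(chunk, min_window=min_window)
        except (EstimationError, ZeroDispersionError):
            continue
        times.append((start + w / 2) / segment.fs)
        hs.append(fit.H)
    return np.array(times), np.array(hs)
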