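"""Daubechies-4 discrete wavelet decomposition and sub-band statistics.

A level-4 db4 pyramid splits a 173.61 Hz signal into five coefficient sets
with approximate bands

    cA4  0–5.4 Hz    cD4  5.4–10.9 Hz   cD3  10.9–21.7 Hz
    cD2  21.7–43.4 Hz   cD1  43.4–86.8 Hz

and nine statistics are computed per set: the 5th/25th/75th/95th
percentiles (n5, n25, n75, n95 — the spread of the coefficient
distribution, whose upper tail responds to epileptic spikes), the median,
mean, standard deviation, variance (population convention) and RMS. With
the approximation band included this yields 5 × 9 = 45 named features.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt

from .errors import ParameterError
from .io_formats import EEGSegment

__all__ = [
    "WaveletCoefficients",
    "dwt_decompose",
    "wavelet_stats",
    "dwt_features",
    "wavelet_feature_names",
    "STAT_NAMES",
    "SET_NAMES",
]

#: Statistic order within each coefficient set (fixed; part of the layout).
STAT_NAMES = ("n5", "n25", "n75", "n95", "median", "mean", "std", "var", "rms")

#: Coefficient-set order (approximation first, then details coarse→fine).
SET_NAMES = ("cA4", "cD4", "cD3", "cD2", "cD1")

_DEFAULT_WAVELET = "db4"
_DEFAULT_LEVEL = 4


@dataclass
class WaveletCoefficients:
    """Ordered coefficient sets [cA4, cD4, cD3, cD2, cD1] of a level-4 DWT."""

    sets: list[np.ndarray]
    wavelet: str = _DEFAULT_WAVELET
    level: int = _DEFAULT_LEVEL
    boundary_mode: str = "symmetric"

    def __post_init__(self) -> None:
        if len(self.sets) != self.level + 1:
            raise ParameterError(
                f"expected {self.level + 1} coefficient sets, got {len(self.sets)}"
            )
        if any(s.size == 0 for s in self.sets):
            raise ParameterError("empty coefficient set")

    @property
    def names(self) -> tuple[str, ...]:
        return (f"cA{self.level}",) + tuple(
            f"cD{j}" for j in range(self.level, 0, -1)
        )

    def energy(self) -> float:
        return float(sum(np.sum(s * s) for s in self.sets))


def dwt_decompose(
    x: np.ndarray,
    wavelet: str = _DEFAULT_WAVELET,
    level: int = _DEFAULT_LEVEL,
    mode: str = "symmetric",
) -> WaveletCoefficients:
    """Level-``level`` analysis filter bank applied to the approximation branch.

    ``mode`` is the boundary extension; ``"periodization"`` makes the
    transform orthonormal (exact energy conservation), ``"symmetric"`` is the
    usual EEG default.
    """
    x = np.asarray(x, dtype=float)
    filt_len = pywt.Wavelet(wavelet).dec_len
    min_len = 2**level * filt_len
    if x.size < min_len:
        raise ParameterError(
            f"input length {x.size} too short for {wavelet} level {level}; "
            f"need >= {min_len} samples"
        )
    coeffs = pywt.wavedec(x, wavelet, level=level, mode=mode)
    return WaveletCoefficients(
        sets=[np.asarray(c) for c in coeffs],
        wavelet=wavelet,
        level=level,
        boundary_mode=mode,
    )


def inverse_dwt(coeffs: WaveletCoefficients) -> np.ndarray:
    """Reconstruct the signal from its pyramid (perfect up to float error)."""
    return pywt.waverec(list(coeffs.sets), coeffs.wavelet, mode=coeffs.boundary_mode)


def wavelet_stats(c: np.ndarray) -> dict[str, float]:
    """The nine per-set statistics, in :data:`STAT_NAMES` order.

    Percentiles use linear interpolation between order statistics; std/var
    use the population convention; rms = sqrt(mean of squares).
    """
    c = np.asarray(c, dtype=float)
    if c.size == 0:
        raise ParameterError("empty coefficient sequence")
    n5, n25, n75, n95 = np.percentile(c, [5, 25, 75, 95])
    var = float(np.var(c))
    return {
        "n5": float(n5),
        "n25": float(n25),
        "n75": float(n75),
        "n95": float(n95),
        "median": float(np.median(c)),
        "mean": float(np.mean(c)),
        "std": float(np.sqrt(var)),
        "var": var,
        "rms": float(np.sqrt(np.mean(c * c))),
    }


def wavelet_feature_names(
    level: int = _DEFAULT_LEVEL, include_approx: bool = True
) -> list[str]:
    """Fixed feature-name order, ``cA4_n5 … cD1_rms``."""
    sets = ([f"cA{level}"] if include_approx else []) + [
        f"cD{j}" for j in range(level, 0, -1)
    ]
    return [f"{s}_{stat}" for s in sets for stat in STAT_NAMES]


def dwt_features(
    segment: EEGSegment,
    wavelet: str = _DEFAULT_WAVELET,
    level: int = _DEFAULT_LEVEL,
    mode: str = "symmetric",
    include_approx: bool = True,
) -> dict[str, float]:
    """Named wavelet features of a segment (45 with the approximation band)."""
    coeffs = dwt_decompose(segment.samples, wavelet=wavelet, level=level, mode=mode)
    out: dict[str, float] = {}
    for name, c in zip(coeffs.names, coeffs.sets):
        if not include_approx and name.startswith("cA"):
            continue
        for stat, value in wavelet_stats(c).items():
            out[f"{name}_{stat}"] = value
    return out
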