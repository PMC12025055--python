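"""Synthetic single-channel EEG with controllable long-memory and ictal bursts.

Two-class segments in the regime of the Bonn epilepsy corpus (23.6 s at
173.61 Hz, one channel):

* class 0 (non-seizure): fractional Gaussian noise background with a chosen
  Hurst exponent, a 10 Hz alpha rhythm and additive white measurement noise;
* class 1 (seizure): the same background plus a ~3 Hz spike-and-wave burst
  train — sharp positive spikes followed by slower negative waves — at an
  amplitude several times the background SD, covering a configurable fraction
  of the segment.

The fGn generator is exact: it embeds the analytic fGn autocovariance

    gamma(k) = (sd^2 / 2) * (|k+1|^{2H} - 2|k|^{2H} + |k-1|^{2H})

in a circulant matrix (Davies–Harte) so samples have the prescribed
covariance up to floating point, which makes Hurst-recovery tests sound.
A dense Cholesky factorisation is used for very short series where the
circulant spectrum can go (numerically) negative.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import ParameterError
from .io_formats import EEGSegment, SegmentSet

__all__ = ["SyntheticSpec", "fgn_autocovariance", "gen_fgn", "gen_segment", "gen_dataset"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Generator parameters for EEG-like two-class segments.

    Attributes
    ----------
    fs : float
        Sampling rate in Hz.
    duration_s : float
        Segment duration in seconds; sample count is ``round(fs * duration_s)``.
    hurst_bg : float
        Hurst exponent of the fGn background, in (0, 1). Above 0.5 the
        background is persistent, matching resting EEG.
    alpha_amp : float
        Amplitude of the 10 Hz alpha rhythm, in units of the background SD.
    sw_rate : float
        Spike-and-wave fundamental frequency (Hz); ~3 Hz is the classical
        generalized ictal discharge rate.
    sw_amp : float
        Burst amplitude as a multiple of the background SD (> 1 for a
        recognisable seizure class).
    burst_fraction : float
        Fraction of the segment covered by ictal bursts, in [0, 1].
    noise_sd : float
        SD of additive white measurement noise, same units as the background.
    seed : int
        Master seed; identical spec + seed gives bit-identical output.
    """

    fs: float = 173.61
    duration_s: float = 23.6
    hurst_bg: float = 0.7
    alpha_amp: float = 0.5
    sw_rate: float = 3.0
    sw_amp: float = 4.0
    burst_fraction: float = 0.5
    noise_sd: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.hurst_bg < 1.0:
            raise ParameterError(f"hurst_bg must be in (0,1), got {self.hurst_bg}")
        if not self.fs > 2 * self.sw_rate:
            raise ParameterError("fs must exceed twice the spike-and-wave rate")
        if not 0.0 <= self.burst_fraction <= 1.0:
            raise ParameterError("burst_fraction must lie in [0,1]")
        if self.duration_s <= 0 or self.noise_sd < 0 or self.alpha_amp < 0:
            raise ParameterError("duration must be positive; amplitudes non-negative")

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.duration_s))


def fgn_autocovariance(h: float, lags: np.ndarray, sd: float = 1.0) -> np.ndarray:
    """Analytic autocovariance of fractional Gaussian noise at integer lags."""
    k = np.abs(np.asarray(lags, dtype=float))
    two_h = 2.0 * h
    return 0.5 * sd * sd * (
        np.abs(k + 1) ** two_h - 2 * k ** two_h + np.abs(k - 1) ** two_h
    )


def _gen_fgn_rng(h: float, n: int, sd: float, rng: np.random.Generator) -> np.ndarray:
    gamma = fgn_autocovariance(h, np.arange(n + 1), sd)
    # circulant embedding of size 2n: [g0 .. g_{n-1}, g_n, g_{n-1} .. g1]
    row = np.concatenate([gamma, gamma[-2:0:-1]])
    eig = np.fft.rfft(row).real
    if np.min(eig) < -1e-8 * np.max(eig) or n < 16:
        # embedding not nonnegative-definite at this size: exact dense fallback
        cov = fgn_autocovariance(h, np.subtract.outer(np.arange(n), np.arange(n)), sd)
        cov[np.diag_indices(n)] += 1e-12 * sd * sd
        chol = np.linalg.cholesky(cov)
        return chol @ rng.standard_normal(n)
    eig = np.clip(eig, 0.0, None)
    m = 2 * n
    # complex Gaussian spectrum with Hermitian symmetry via two real draws
    z = rng.standard_normal(m // 2 + 1) + 1j * rng.standard_normal(m // 2 + 1)
    z[0] = z[0].real * np.sqrt(2.0)
    z[-1] = z[-1].real * np.sqrt(2.0)
    spectrum = z * np.sqrt(eig * m / 2.0)
    sample = np.fft.irfft(spectrum, n=m)
    return sample[:n]


def gen_fgn(h: float, n: int, sd: float = 1.0, seed: int = 0) -> np.ndarray:
    """Generate stationary fractional Gaussian noise.

    Parameters
    ----------
    h : Hurst parameter in (0, 1).
    n : number of samples (>= 2).
    sd : marginal standard deviation (> 0).
    seed : RNG seed; output is deterministic given (h, n, sd, seed).
    """
    if not 0.0 < h < 1.0:
        raise ParameterError(f"h must be in (0,1), got {h}")
    if n < 2:
        raise ParameterError(f"n must be >= 2, got {n}")
    if not sd > 0:
        raise ParameterError(f"sd must be positive, got {sd}")
    rng = np.random.default_rng(seed)
    return _gen_fgn_rng(h, int(n), float(sd), rng)


def _spike_wave_train(
    n: int, fs: float, rate: float, burst_fraction: float, rng: np.random.Generator
) -> np.ndarray:
    """Unit-amplitude spike-and-wave burst train covering ``burst_fraction``.

    Each cycle is an asymmetric biphasic transient: a sharp positive spike
    (~60 ms Gaussian) followed by a slower negative half-sine wave. Bursts
    are contiguous runs starting at a randomised onset.
    """
    out = np.zeros(n)
    if burst_fraction <= 0:
        return out
    covered = int(round(burst_fraction * n))
    onset = int(rng.integers(0, max(1, n - covered + 1)))
    t = np.arange(n) / fs

    period = 1.0 / rate
    spike_width = 0.03  # seconds (SD of the Gaussian spike)
    wave_len = 0.55 * period

    in_burst = slice(onset, onset + covered)
    tt = t[in_burst] - t[onset]
    phase = np.mod(tt, period)
    spike = np.exp(-0.5 * ((phase - 0.1 * period) / spike_width) ** 2)
    wave_mask = (phase >= 0.25 * period) & (phase < 0.25 * period + wave_len)
    wave = np.where(
        wave_mask, -0.6 * np.sin(np.pi * (phase - 0.25 * period) / wave_len), 0.0
    )
    out[in_burst] = spike + wave
    return out


def gen_segment(spec: SyntheticSpec, label: int) -> EEGSegment:
    """Generate one labelled segment under ``spec``.

    Class 0 is background (fGn + alpha + white noise); class 1 adds the
    spike-and-wave burst train. With ``burst_fraction == 0`` the two classes
    coincide sample-for-sample under the same seed.
    """
    if label not in (0, 1):
        raise ParameterError(f"label must be 0 or 1, got {label!r}")
    n = spec.n_samples
    # independent child streams so the background does not depend on whether
    # the burst stream is consumed
    ss = np.random.SeedSequence(spec.seed)
    bg_rng, alpha_rng, noise_rng, burst_rng = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )

    background = _gen_fgn_rng(spec.hurst_bg, n, 1.0, bg_rng)
    bg_sd = float(np.std(background))
    t = np.arange(n) / spec.fs
    alpha = spec.alpha_amp * bg_sd * np.sin(
        2 * np.pi * 10.0 * t + alpha_rng.uniform(0, 2 * np.pi)
    )
    noise = spec.noise_sd * noise_rng.standard_normal(n)
    x = background + alpha + noise
    if label == 1:
        train = _spike_wave_train(n, spec.fs, spec.sw_rate, spec.burst_fraction, burst_rng)
        x = x + spec.sw_amp * bg_sd * train
    return EEGSegment(
        samples=x,
        fs=spec.fs,
        label=label,
        segment_id=f"syn_{spec.seed}_{label}",
        channel="SYN",
    )


def _segment_seed(master_seed: int, index: int, label: int) -> int:
    """Deterministic per-segment seed derived from (master seed, index, label)."""
    return int(
        np.random.SeedSequence([master_seed, index, label]).generate_state(1)[0]
        % (2**31 - 1)
    )


def gen_dataset(n_per_class: int, spec: SyntheticSpec | None = None) -> SegmentSet:
    """Generate a balanced labelled set of ``2 * n_per_class`` segments.

    Per-segment seeds are derived deterministically from ``spec.seed`` so the
    whole set is reproducible while segments stay mutually independent.
    """
    if n_per_class < 1:
        raise ParameterError(f"n_per_class must be >= 1, got {n_per_class}")
    spec = spec or SyntheticSpec()
    segments = []
    for label in (0, 1):
        for i in range(n_per_class):
            sub = replace(spec, seed=_segment_seed(spec.seed, i, label))
            seg = gen_segment(sub, label)
            seg.segment_id = f"syn{spec.seed}_c{label}_{i:04d}"
            segments.append(seg)
    return SegmentSet(segments)
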