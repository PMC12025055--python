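"""Cleaning-pipeline contracts: filter response, screening, scaling, balancing."""

import numpy as np
import pytest
from scipy import signal as sps

from hurstwave.errors import DegenerateInputError, ParameterError
from hurstwave.io_formats import EEGSegment, SegmentSet
from hurstwave.preprocess import (
    Rejection,
    balance_classes,
    bandpass,
    impute_or_drop,
    minmax_scale,
    preprocess_segment,
    screen_validity,
)

FS = 173.61


def _sine(freq, n=4097, fs=FS):
    t = np.arange(n) / fs
    return EEGSegment(np.sin(2 * np.pi * freq * t), fs=fs)


def _designed_gain(freq, fs=FS, low=0.53, high=40.0, order=4):
    """Oracle: squared magnitude response of the designed filter (filtfilt
    applies it twice)."""
    sos = sps.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    _, h = sps.sosfreqz(sos, worN=[freq], fs=fs)
    return np.abs(h[0]) ** 2


class TestBandpass:
    def test_passband_tone_preserved(self):
        seg = _sine(10.0)
        out = bandpass(seg)
        rms_ratio = np.sqrt(np.mean(out.samples**2) / np.mean(seg.samples**2))
        assert rms_ratio == pytest.approx(_designed_gain(10.0), abs=0.12)
        assert abs(rms_ratio - 1.0) < 0.12

    def test_stopband_tone_suppressed(self):
        seg = _sine(60.0)
        out = bandpass(seg)
        rms_ratio = np.sqrt(np.mean(out.samples**2) / np.mean(seg.samples**2))
        assert rms_ratio < 0.10
        # away from the edge transients the steady-state gain matches the
        # designed response
        mid = slice(1000, 3000)
        mid_ratio = np.sqrt(np.mean(out.samples[mid] ** 2) / np.mean(seg.samples[mid] ** 2))
        assert mid_ratio == pytest.approx(_designed_gain(60.0), abs=0.01)

    def test_dc_removed(self):
        seg = EEGSegment(np.full(4097, 5.0), fs=FS)
        out = bandpass(seg)
        assert abs(np.mean(out.samples)) < 1e-6 * 5.0

    def test_length_unchanged(self):
        seg = _sine(7.0, n=1234)
        assert bandpass(seg).n_samples == 1234

    def test_high_cut_above_nyquist_rejected(self):
        with pytest.raises(ParameterError):
            bandpass(_sine(10.0), high=90.0)

    def test_linearity(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(2048)
        seg = EEGSegment(x, fs=FS)
        seg5 = EEGSegment(5.0 * x, fs=FS)
        a = 5.0 * bandpass(seg).samples
        b = bandpass(seg5).samples
        assert np.max(np.abs(a - b)) <= 1e-9 * np.max(np.abs(b))


class TestScreenValidity:
    def test_nan_flagged(self):
        x = np.arange(400.0)
        x[10] = np.nan
        rep = screen_validity(EEGSegment(x, fs=FS))
        assert rep.has_nan and not rep.usable

    def test_all_zero(self):
        rep = screen_validity(EEGSegment(np.zeros(400), fs=FS))
        assert rep.has_all_zero and rep.constant and not rep.usable

    def test_white_noise_clean(self):
        x = np.random.default_rng(1).standard_normal(4097)
        rep = screen_validity(EEGSegment(x, fs=FS))
        assert rep.usable and not rep.flat_windows

    def test_flat_run_located(self):
        x = np.random.default_rng(2).standard_normal(2000)
        x[500:900] = 3.14  # 400 samples (> 1 s) of no fluctuation
        rep = screen_validity(EEGSegment(x, fs=FS), flat_tol=1e-12)
        assert rep.flat_windows
        start, end = rep.flat_windows[0]
        assert start >= 490 and end <= 910


class TestImputeOrDrop:
    def test_isolated_nans_interpolated(self):
        x = np.sin(np.arange(4097) / 50)
        x[[100, 2000, 3000]] = np.nan
        seg = EEGSegment(x, fs=FS)
        out = impute_or_drop(seg, screen_validity(seg))
        assert isinstance(out, EEGSegment)
        assert np.all(np.isfinite(out.samples))

    def test_excessive_missingness_rejected(self):
        x = np.sin(np.arange(1000) / 50)
        x[::2] = np.nan
        seg = EEGSegment(x, fs=FS)
        out = impute_or_drop(seg, screen_validity(seg))
        assert isinstance(out, Rejection) and "missing" in out.reason

    def test_clean_segment_passes_through_unchanged(self):
        seg = EEGSegment(np.sin(np.arange(500) / 10), fs=FS)
        out = impute_or_drop(seg, screen_validity(seg))
        assert out is seg


class TestMinmaxScale:
    @pytest.mark.parametrize(
        "x,expected",
        [([2, 4, 6], [0, 0.5, 1]), ([-1, 0, 3], [0, 0.25, 1])],
    )
    def test_worked_examples(self, x, expected):
        np.testing.assert_allclose(minmax_scale(np.array(x, float)), expected)

    def test_constant_input_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            minmax_scale(np.array([5.0, 5.0, 5.0]))

    def test_bounds_exact(self):
        x = np.random.default_rng(3).standard_normal(1000)
        y = minmax_scale(x)
        assert y.min() == 0.0 and y.max() == 1.0

    def test_idempotent(self):
        x = np.random.default_rng(4).standard_normal(1000)
        y = minmax_scale(x)
        assert np.max(np.abs(minmax_scale(y) - y)) <= 1e-12


class TestBalanceClasses:
    def _set(self, n0, n1, seed=0):
        rng = np.random.default_rng(seed)
        segs = [
            EEGSegment(rng.standard_normal(64), fs=FS, label=lab, segment_id=f"s{lab}_{i}")
            for lab, n in ((0, n0), (1, n1))
            for i in range(n)
        ]
        return SegmentSet(segs)

    def test_undersamples_majority(self):
        out = balance_classes(self._set(80, 20), seed=1)
        assert out.class_counts == {0: 20, 1: 20}

    def test_already_balanced_untouched(self):
        s = self._set(10, 10)
        out = balance_classes(s, seed=1)
        assert [x.segment_id for x in out] == [x.segment_id for x in s]

    def test_deterministic(self):
        a = balance_classes(self._set(30, 10), seed=42)
        b = balance_classes(self._set(30, 10), seed=42)
        assert [x.segment_id for x in a] == [x.segment_id for x in b]

    def test_single_class_rejected(self):
        with pytest.raises(ParameterError):
            balance_classes(self._set(10, 0))


class TestPipelineOrder:
    def test_scaled_output_in_unit_interval(self):
        seg = _sine(10.0)
        out = preprocess_segment(seg)
        assert isinstance(out, EEGSegment)
        assert out.samples.min() == 0.0 and out.samples.max() == 1.0

    def test_constant_segment_rejected_not_raised(self):
        seg = EEGSegment(np.full(4097, 2.0), fs=FS)
        out = preprocess_segment(seg)
        assert isinstance(out, Rejection)
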