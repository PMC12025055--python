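"""Assembly of the per-segment feature vector.

The canonical layout is 47 features per segment: two rescaled-range features
(``hurstex``, ``hurstc``) followed by the 45 wavelet sub-band statistics in
``cA4_n5 … cD1_rms`` order. The layout is versioned; reordering or renaming
is a breaking change guarded by a golden test.
"""

from __future__ import annotations

import numpy as np

from .hurst import hurst_features
from .io_formats import EEGSegment, FeatureTable, SegmentSet
from .wavelet import dwt_features, wavelet_feature_names

__all__ = ["FEATURE_LAYOUT_VERSION", "feature_names", "extract_features", "extract_feature_table"]

FEATURE_LAYOUT_VERSION = 1

HURST_FEATURE_NAMES = ("hurstex", "hurstc")


def feature_names(include_approx: bool = True) -> list[str]:
    """The full ordered feature layout (47 names with cA4 included)."""
    return list(HURST_FEATURE_NAMES) + wavelet_feature_names(include_approx=include_approx)


def extract_features(
    segment: EEGSegment,
    low_cut_hz: float | None = 0.53,
    dwt_mode: str = "symmetric",
    include_approx: bool = True,
) -> dict[str, float]:
    """Feature dict for one preprocessed segment, in canonical order."""
    h, c = hurst_features(segment, low_cut_hz=low_cut_hz)
    out = {"hurstex": h, "hurstc": c}
    out.update(dwt_features(segment, mode=dwt_mode, include_approx=include_approx))
    return out


def extract_feature_table(
    segset: SegmentSet,
    low_cut_hz: float | None = 0.53,
    dwt_mode: str = "symmetric",
    include_approx: bool = True,
) -> FeatureTable:
    """Feature table for a set of preprocessed, labelled segments."""
    names = feature_names(include_approx=include_approx)
    rows = []
    for seg in segset:
        feats = extract_features(
            seg, low_cut_hz=low_cut_hz, dwt_mode=dwt_mode, include_approx=include_approx
        )
        rows.append([feats[n] for n in names])
    labels = [0 if s.label is None else s.label for s in segset]
    return FeatureTable(
        feature_names=names,
        matrix=np.array(rows, dtype=float).reshape(len(segset), len(names)),
        labels=labels,
        row_ids=[s.segment_id for s in segset],
    )
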