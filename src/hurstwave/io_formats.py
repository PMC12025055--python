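"""Readers and writers for single-channel EEG segments and feature tables.

Supported on-disk formats:

* Bonn-style ASCII — one sample value per line, one segment per file, class
  encoded by the parent folder initial (``Z/O/N/F`` non-seizure, ``S/E``
  seizure, the usual subset naming of the Bonn epilepsy corpus).
* EDF (European Data Format) — a named channel is extracted from a standard
  polygraphic recording (CHB-MIT style); reading goes through :mod:`mne`.
  A minimal EDF writer is included so synthetic segments can be exported and
  round-tripped.
* CSV feature tables — rows are segments, columns are named features, with
  ``segment_id`` first and the binary ``label`` last.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ChannelLookupError, FormatError, ParameterError

__all__ = [
    "EEGSegment",
    "SegmentSet",
    "FeatureTable",
    "read_bonn_segment",
    "read_bonn_dir",
    "write_bonn_segment",
    "read_edf_channel",
    "write_edf",
    "read_feature_table",
    "write_feature_table",
    "BONN_DEFAULT_FS",
]

#: Sampling rate of the Bonn epilepsy corpus (Hz).
BONN_DEFAULT_FS = 173.61

# Bonn folder initial -> binary label (subset E, folder "S", is ictal).
_BONN_FOLDER_LABELS = {"z": 0, "o": 0, "n": 0, "f": 0, "s": 1, "e": 1}


@dataclass
class EEGSegment:
    """One labelled single-channel EEG segment.

    Parameters
    ----------
    samples
        Amplitude values (µV-like units before normalisation).
    fs
        Sampling rate in Hz.
    label
        0 (non-seizure), 1 (seizure) or ``None`` when unknown.
    segment_id
        Stable identifier, unique within a :class:`SegmentSet`.
    channel
        Channel label, empty when not applicable.
    """

    samples: np.ndarray
    fs: float
    label: int | None = None
    segment_id: str = ""
    channel: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 2:
            raise ParameterError("segment needs a 1-D sample array of length >= 2")
        if not self.fs > 0:
            raise ParameterError(f"sampling rate must be positive, got {self.fs}")
        if self.label is not None and self.label not in (0, 1):
            raise ParameterError(f"label must be 0, 1 or None, got {self.label!r}")

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def copy_with(self, samples: np.ndarray) -> "EEGSegment":
        """Return a copy carrying new sample values but the same metadata."""
        return EEGSegment(
            samples=np.asarray(samples, dtype=float),
            fs=self.fs,
            label=self.label,
            segment_id=self.segment_id,
            channel=self.channel,
        )


@dataclass
class SegmentSet:
    """An ordered collection of segments with unique ids."""

    segments: list[EEGSegment] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [s.segment_id for s in self.segments]
        dupes = [i for i, c in Counter(ids).items() if c > 1]
        if dupes:
            raise ParameterError(f"duplicate segment ids: {dupes}")

    def __len__(self) -> int:
        return len(self.segments)

    def __iter__(self):
        return iter(self.segments)

    def __getitem__(self, i: int) -> EEGSegment:
        return self.segments[i]

    @property
    def class_counts(self) -> dict[int | None, int]:
        return dict(Counter(s.label for s in self.segments))

    @property
    def labels(self) -> np.ndarray:
        return np.array([s.label for s in self.segments])


class FeatureTable:
    """A segments × features matrix with binary labels.

    The canonical serialisation is a CSV with ``segment_id`` as the first
    column, one column per feature, and ``label`` (0/1) last.
    """

    def __init__(
        self,
        feature_names: Sequence[str],
        matrix: np.ndarray,
        labels: Sequence[int],
        row_ids: Sequence[str],
    ):
        self.feature_names = list(feature_names)
        self.matrix = np.asarray(matrix, dtype=float).reshape(
            len(row_ids), len(self.feature_names)
        )
        self.labels = np.asarray(labels, dtype=int)
        self.row_ids = list(row_ids)
        self._validate()

    def _validate(self) -> None:
        if len(set(self.feature_names)) != len(self.feature_names):
            raise FormatError("duplicate feature names")
        if self.matrix.shape != (len(self.row_ids), len(self.feature_names)):
            raise ParameterError(
                f"matrix shape {self.matrix.shape} inconsistent with "
                f"{len(self.row_ids)} rows x {len(self.feature_names)} features"
            )
        if self.labels.shape != (len(self.row_ids),):
            raise ParameterError("one label per row required")
        if self.matrix.size and not np.all(np.isfinite(self.matrix)):
            raise ParameterError("feature matrix contains non-finite entries")
        if self.labels.size and not np.all(np.isin(self.labels, [0, 1])):
            raise FormatError("labels must be binary 0/1")

    @property
    def n_rows(self) -> int:
        return len(self.row_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def select(self, names: Sequence[str]) -> "FeatureTable":
        """Return a column-subset table, preserving the requested order."""
        missing = [n for n in names if n not in self.feature_names]
        if missing:
            raise ParameterError(f"unknown feature names: {missing}")
        idx = [self.feature_names.index(n) for n in names]
        return FeatureTable(list(names), self.matrix[:, idx], self.labels, self.row_ids)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.matrix, columns=self.feature_names)
        df.insert(0, "segment_id", self.row_ids)
        df["label"] = self.labels
        return df

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "FeatureTable":
        cols = list(df.columns)
        if "segment_id" not in cols or "label" not in cols:
            raise FormatError("feature table requires 'segment_id' and 'label' columns")
        names = [c for c in cols if c not in ("segment_id", "label")]
        labels = df["label"].to_numpy()
        if labels.size and not np.all(np.isin(labels, [0, 1])):
            raise FormatError("labels must be binary 0/1")
        return cls(
            feature_names=names,
            matrix=df[names].to_numpy(dtype=float).reshape(len(df), len(names)),
            labels=labels.astype(int),
            row_ids=[str(s) for s in df["segment_id"]],
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FeatureTable):
            return NotImplemented
        return (
            self.feature_names == other.feature_names
            and self.row_ids == other.row_ids
            and np.array_equal(self.labels, other.labels)
            and np.array_equal(self.matrix, other.matrix)
        )


# ---------------------------------------------------------------------------
# Bonn-style ASCII
# ---------------------------------------------------------------------------

def _bonn_label_from_path(path: Path) -> int | None:
    folder = path.parent.name
    if folder:
        return _BONN_FOLDER_LABELS.get(folder[0].lower())
    return None


def read_bonn_segment(path: str | Path, fs: float = BONN_DEFAULT_FS) -> EEGSegment:
    """Read a one-value-per-line ASCII segment.

    The class label is inferred from the parent folder name when it follows
    the Bonn convention (``S``/``E`` → seizure, ``Z``/``O``/``N``/``F`` →
    non-seizure); otherwise the label is left unknown.
    """
    path = Path(path)
    values: list[float] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.strip()
            if not text:
                continue
            try:
                values.append(float(text))
            except ValueError:
                raise FormatError(
                    f"{path}: line {lineno}: cannot parse {text!r} as a number"
                ) from None
    if len(values) < 2:
        raise FormatError(f"{path}: fewer than 2 samples")
    return EEGSegment(
        samples=np.array(values),
        fs=fs,
        label=_bonn_label_from_path(path),
        segment_id=path.stem,
    )


def read_bonn_dir(root: str | Path, fs: float = BONN_DEFAULT_FS) -> SegmentSet:
    """Read every ``*.txt``/``*.TXT`` file below ``root`` as a segment."""
    root = Path(root)
    paths = sorted(p for p in root.rglob("*") if p.suffix.lower() == ".txt")
    if not paths:
        raise FormatError(f"no ASCII segment files found under {root}")
    segments = []
    for p in paths:
        seg = read_bonn_segment(p, fs=fs)
        # disambiguate stems repeated across subset folders
        seg.segment_id = f"{p.parent.name}_{p.stem}"
        segments.append(seg)
    return SegmentSet(segments)


def write_bonn_segment(segment: EEGSegment, path: str | Path) -> None:
    """Write a segment as one-value-per-line ASCII."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        for v in segment.samples:
            fh.write(repr(float(v)) + "\n")


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

def _normalise_channel(name: str) -> str:
    return "".join(ch for ch in name.lower() if ch not in " -_")


def read_edf_channel(path: str | Path, channel: str) -> EEGSegment:
    """Extract one channel from an EDF recording.

    Channel matching is case-insensitive and tolerant of hyphens/spaces, so
    ``"cz-pz"`` matches a stored ``"CZ-PZ"``. Amplitudes are returned in µV.
    """
    import mne

    path = Path(path)
    try:
        raw = mne.io.read_raw_edf(path, preload=False, verbose="error")
    except Exception as exc:  # mne raises a zoo of types for bad headers
        raise FormatError(f"{path}: not a readable EDF file ({exc})") from exc

    wanted = _normalise_channel(channel)
    matches = [nm for nm in raw.ch_names if _normalise_channel(nm) == wanted]
    if not matches:
        raise ChannelLookupError(channel, raw.ch_names)
    name = matches[0]
    idx = raw.ch_names.index(name)
    try:
        data = raw.get_data(picks=[idx], units="uV")
    except ValueError:
        data = raw.get_data(picks=[idx])
    return EEGSegment(
        samples=data[0],
        fs=float(raw.info["sfreq"]),
        label=None,
        segment_id=path.stem,
        channel=name,
    )


def _edf_ascii(value, width: int) -> bytes:
    """Format a header field as fixed-width space-padded ASCII."""
    text = str(value)
    if len(text) > width:
        raise FormatError(f"EDF header field {text!r} exceeds {width} bytes")
    return text.ljust(width).encode("ascii")


def _edf_float(value: float, width: int = 8) -> str:
    """Render a float into at most ``width`` ASCII chars, losing precision
    gracefully."""
    for prec in range(10, -1, -1):
        text = f"{value:.{prec}g}"
        if len(text) <= width:
            return text
    raise FormatError(f"cannot encode {value} in {width} chars")


def write_edf(segment: EEGSegment, path: str | Path, channel: str | None = None) -> None:
    """Write a single-channel segment as a minimal standard-conforming EDF.

    All samples go into one data record whose duration is
    ``n_samples / fs`` seconds; amplitudes are quantised to the EDF 16-bit
    digital range over the segment's physical min/max, so the round-trip
    error is at most half a quantisation step.
    """
    path = Path(path)
    x = segment.samples
    n = x.size
    ch = channel or segment.channel or "EEG"

    pmin, pmax = float(np.min(x)), float(np.max(x))
    if pmax == pmin:  # constant signal still needs a non-degenerate range
        pmax = pmin + 1.0
    # Use the values as they will be parsed back, so quantisation is exact.
    pmin_s, pmax_s = _edf_float(pmin), _edf_float(pmax)
    pmin_r, pmax_r = float(pmin_s), float(pmax_s)
    if pmax_r <= pmin_r:
        pmax_r = pmin_r + 1.0
        pmax_s = _edf_float(pmax_r)
    dmin, dmax = -32768, 32767
    scale = (pmax_r - pmin_r) / (dmax - dmin)
    digital = np.clip(np.round((x - pmin_r) / scale) + dmin, dmin, dmax).astype("<i2")

    record_dur = _edf_float(n / segment.fs)

    header = b"".join(
        [
            _edf_ascii("0", 8),
            _edf_ascii("X X X X", 80),
            _edf_ascii("Startdate 01-JAN-2000 X X X", 80),
            _edf_ascii("01.01.00", 8),
            _edf_ascii("00.00.00", 8),
            _edf_ascii(256 + 256, 8),
            _edf_ascii("", 44),
            _edf_ascii(1, 8),
            _edf_ascii(record_dur, 8),
            _edf_ascii(1, 4),
            # per-signal fields (one signal)
            _edf_ascii(ch, 16),
            _edf_ascii("", 80),
            _edf_ascii("uV", 8),
            _edf_ascii(pmin_s, 8),
            _edf_ascii(pmax_s, 8),
            _edf_ascii(dmin, 8),
            _edf_ascii(dmax, 8),
            _edf_ascii("", 80),
            _edf_ascii(n, 8),
            _edf_ascii("", 32),
        ]
    )
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(digital.tobytes())


def edf_quantisation_step(x: np.ndarray) -> float:
    """Worst-case EDF 16-bit quantisation step for a signal's dynamic range."""
    pmin, pmax = float(np.min(x)), float(np.max(x))
    if pmax == pmin:
        pmax = pmin + 1.0
    return (pmax - pmin) / (32767 - (-32768))


# ---------------------------------------------------------------------------
# Feature-table CSV
# ---------------------------------------------------------------------------

def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    """Serialise a feature table to CSV (segment_id first, label last)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_dataframe().to_csv(path, index=False)


def read_feature_table(path: str | Path) -> FeatureTable:
    """Read a CSV feature table, validating header structure and labels."""
    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split(",")
    if len(set(header)) != len(header):
        raise FormatError(f"{path}: duplicate column names in header")
    if "label" not in header:
        raise FormatError(f"{path}: missing 'label' column")
    if "segment_id" not in header:
        raise FormatError(f"{path}: missing 'segment_id' column")
    df = pd.read_csv(path, dtype={"segment_id": str})
    if len(df) == 0:
        return FeatureTable(
            feature_names=[c for c in header if c not in ("segment_id", "label")],
            matrix=np.empty((0, len(header) - 2)),
            labels=np.empty(0, dtype=int),
            row_ids=[],
        )
    return FeatureTable.from_dataframe(df)
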