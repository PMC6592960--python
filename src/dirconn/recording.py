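"""Multichannel recordings and segment sets, with delimited-text / EDF I/O.

A :class:`MultichannelRecording` holds a sampled multichannel time series
(samples as rows) together with its sampling rate, channel labels and
experiment metadata (condition W/A, modality). A :class:`SegmentSet` is a
contiguous non-overlapping partition of such a recording into equal-length
analysis segments.

The delimited dialect is deliberately strict: comma separated, one header
row of channel labels, one sample per row, ``.`` decimal point. That makes
write → read a bit-exact round trip, which the tests rely on.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .errors import FormatError, InvalidParameterError, ParseError

__all__ = [
    "MultichannelRecording",
    "SegmentSet",
    "read_timeseries",
    "write_timeseries",
]


@dataclass
class MultichannelRecording:
    """Sampled multichannel time series.

    Parameters
    ----------
    data : ndarray, shape (n_samples, n_channels)
        Signal in µV-equivalent units, one sample per row.
    fs : float
        Sampling rate in Hz.
    channel_labels : list of str
        One label per channel, order matching the columns of ``data``.
    condition : str or None
        ``"W"`` (wakefulness) or ``"A"`` (anaesthesia).
    modality : str or None
        ``"ECOG"``, ``"RS"`` (reconstructed source) or ``"SYNTH"``.
    """

    data: np.ndarray
    fs: float
    channel_labels: list[str] = field(default_factory=list)
    condition: str | None = None
    modality: str | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise InvalidParameterError("data must be 2-D (samples x channels)")
        if self.data.shape[0] < 1:
            raise InvalidParameterError("recording needs at least one sample")
        if self.fs <= 0:
            raise InvalidParameterError(f"sampling rate must be positive, got {self.fs}")
        if not self.channel_labels:
            self.channel_labels = [f"ch{i}" for i in range(self.data.shape[1])]
        if len(self.channel_labels) != self.data.shape[1]:
            raise InvalidParameterError(
                f"{len(self.channel_labels)} labels for {self.data.shape[1]} channels"
            )

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def with_data(self, data: np.ndarray) -> "MultichannelRecording":
        """Copy of the recording with ``data`` replaced, metadata kept."""
        return replace(self, data=np.asarray(data, dtype=float))


@dataclass
class SegmentSet:
    """Equal-length, non-overlapping, contiguous analysis segments."""

    segments: list[np.ndarray]
    fs: float
    seg_duration_s: float
    condition: str | None = None
    modality: str | None = None
    channel_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        shapes = {s.shape for s in self.segments}
        if len(shapes) > 1:
            raise InvalidParameterError(f"segments differ in shape: {shapes}")

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    @property
    def n_channels(self) -> int:
        return self.segments[0].shape[1]

    @property
    def seg_len(self) -> int:
        return self.segments[0].shape[0]

    def concatenate(self) -> np.ndarray:
        return np.concatenate(self.segments, axis=0)


def read_timeseries(
    path: str | Path,
    fs: float,
    format: str = "delimited",
    condition: str | None = None,
    modality: str | None = None,
) -> MultichannelRecording:
    """Read a recording from disk.

    ``delimited`` expects one header row of channel labels followed by
    numeric sample rows. ``edf`` reads a European Data Format file through
    :mod:`mne` (optional dependency) and ignores ``fs`` in favour of the
    rate stored in the file header.
    """
    path = Path(path)
    if format == "edf":
        return _read_edf(path, condition=condition, modality=modality)
    if format != "delimited":
        raise InvalidParameterError(f"unknown format {format!r}")

    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            labels = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty file") from None
        labels = [lab.strip() for lab in labels]
        n_cols = len(labels)
        rows: list[list[float]] = []
        for r, row in enumerate(reader, start=2):  # 1-based, header is row 1
            if len(row) != n_cols:
                raise FormatError(
                    f"{path}: row {r} has {len(row)} fields, expected {n_cols}"
                )
            vals = []
            for c, cell in enumerate(row, start=1):
                try:
                    vals.append(float(cell))
                except ValueError:
                    raise ParseError(
                        f"{path}: non-numeric value {cell!r} at row {r}, column {c}"
                    ) from None
            rows.append(vals)
    if not rows:
        raise FormatError(f"{path}: no sample rows")
    return MultichannelRecording(
        data=np.array(rows, dtype=float),
        fs=fs,
        channel_labels=labels,
        condition=condition,
        modality=modality,
    )


def write_timeseries(rec: MultichannelRecording, path: str | Path) -> None:
    """Write a recording in the strict delimited dialect (round-trip exact)."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(rec.channel_labels)
        for row in rec.data:
            writer.writerow([repr(float(v)) for v in row])


def _read_edf(path: Path, condition=None, modality=None) -> MultichannelRecording:
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("EDF support requires the optional 'mne' dependency") from exc
    raw = mne.io.read_raw_edf(path, preload=True, verbose="ERROR")
    return MultichannelRecording(
        data=raw.get_data().T,
        fs=float(raw.info["sfreq"]),
        channel_labels=list(raw.ch_names),
        condition=condition,
        modality=modality,
    )
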