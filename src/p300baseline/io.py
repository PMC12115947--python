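"""Continuous EEG and event I/O, plus photosensor onset recovery.

Continuous recordings travel either as EDF (the clinical interchange format)
or as plain delimited text; events as a small TSV with a ``# target=`` header.
Amplitudes are microvolts throughout; sample indices are 0-based and time 0 is
the stimulus-onset sample.
"""

from __future__ import annotations

import logging
import pathlib
import struct
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, FormatError, ParameterError

log = logging.getLogger(__name__)

#: Channel label under which the photosensor trace is stored in files.
PHOTOSENSOR_LABEL = "PHOTO"


@dataclass
class EEGRecording:
    """A continuous multichannel scalp-EEG recording.

    Parameters
    ----------
    channel_labels
        One label per EEG channel (e.g. ``["Cz", "Pz"]``).
    sampling_rate
        Sampling rate in Hz; the nominal acquisition rate is 1 kHz.
    data
        Array of shape ``(n_channels, n_samples)``, amplitudes in µV.
    photosensor
        Optional auxiliary trace of the display photosensor, same length as
        the EEG channels.  Units are whatever the sensor produces; onset
        detection only thresholds it.
    meta
        Free-form provenance text.
    """

    channel_labels: list[str]
    sampling_rate: float
    data: np.ndarray
    photosensor: np.ndarray | None = None
    meta: str = ""

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        self.channel_labels = [str(c) for c in self.channel_labels]
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} labels for {self.data.shape[0]} channels"
            )
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("amplitudes must be finite")
        if self.photosensor is not None:
            self.photosensor = np.asarray(self.photosensor, dtype=float)
            if self.photosensor.shape != (self.data.shape[1],):
                raise ValueError("photosensor length differs from EEG channels")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate

    def channel(self, label: str | None = None) -> np.ndarray:
        """Return one channel by label (default: the first channel)."""
        if label is None:
            return self.data[0]
        try:
            return self.data[self.channel_labels.index(label)]
        except ValueError:
            raise KeyError(
                f"no channel {label!r}; available: {self.channel_labels}"
            ) from None


@dataclass
class EventList:
    """Ordered stimulus onsets with labels and the attended target label.

    ``onsets`` are sample indices into the recording, strictly increasing.
    ``labels`` are integer stimulus ids (1..N in the 9-digit oddball design).
    """

    onsets: np.ndarray
    labels: np.ndarray
    target_label: int
    n_stimulus_types: int = 9

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=np.int64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.onsets.shape != self.labels.shape or self.onsets.ndim != 1:
            raise ValueError("onsets and labels must be 1-d and equally long")
        if len(self.onsets) and np.any(np.diff(self.onsets) <= 0):
            raise FormatError("events not sorted: onsets must be strictly increasing")
        if len(self.labels) > 1 and np.any(self.labels[1:] == self.labels[:-1]):
            warnings.warn(
                "repeated stimulus label in consecutive events", stacklevel=2
            )
        if len(self.labels) and self.target_label not in self.labels:
            raise ValueError(
                f"target_label {self.target_label} not among presented labels"
            )

    def __len__(self) -> int:
        return len(self.onsets)

    @property
    def events(self) -> list[tuple[int, int]]:
        """(onset_sample, stimulus_label) pairs in presentation order."""
        return list(zip(self.onsets.tolist(), self.labels.tolist()))

    @property
    def present_labels(self) -> np.ndarray:
        return np.unique(self.labels)


# ---------------------------------------------------------------------------
# Delimited recordings


def _sniff_delimiter(header_line: str) -> str:
    return "\t" if "\t" in header_line else ","


def write_recording(
    rec: EEGRecording, path: str | pathlib.Path, format: str | None = None
) -> pathlib.Path:
    """Write a recording as EDF or delimited text (chosen by ``format`` or suffix)."""
    path = pathlib.Path(path)
    fmt = format or ("edf" if path.suffix.lower() == ".edf" else "delimited")
    if fmt == "edf":
        _write_edf(rec, path)
    elif fmt == "delimited":
        labels = list(rec.channel_labels)
        cols = [rec.data[i] for i in range(rec.data.shape[0])]
        if rec.photosensor is not None:
            labels.append(PHOTOSENSOR_LABEL)
            cols.append(rec.photosensor)
        frame = pd.DataFrame(dict(zip(labels, cols)))
        with open(path, "w") as fh:
            fh.write(f"# sampling_rate_hz={rec.sampling_rate:g}\n")
            frame.to_csv(fh, index=False, float_format="%.10g")
    else:
        raise ParameterError(f"unknown recording format {fmt!r}")
    return path


def read_recording(
    path: str | pathlib.Path,
    format: str | None = None,
    sampling_rate: float | None = None,
    photosensor_label: str = PHOTOSENSOR_LABEL,
) -> EEGRecording:
    """Read a continuous recording from EDF or delimited text.

    Delimited files carry one header row of channel labels, optionally
    preceded by a ``# sampling_rate_hz=...`` comment; otherwise
    ``sampling_rate`` must be given.  A column named ``PHOTO`` (configurable)
    is split off as the photosensor trace.
    """
    path = pathlib.Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    fmt = format or ("edf" if path.suffix.lower() == ".edf" else "delimited")
    if fmt == "edf":
        labels, fs, data = _read_edf(path)
    elif fmt == "delimited":
        labels, fs, data = _read_delimited(path, sampling_rate)
    else:
        raise ParameterError(f"unknown recording format {fmt!r}")

    photosensor = None
    if photosensor_label in labels:
        k = labels.index(photosensor_label)
        photosensor = data[k]
        data = np.delete(data, k, axis=0)
        labels = [c for i, c in enumerate(labels) if i != k]
    return EEGRecording(labels, fs, data, photosensor=photosensor, meta=f"read from {path}")


def _read_delimited(
    path: pathlib.Path, sampling_rate: float | None
) -> tuple[list[str], float, np.ndarray]:
    with open(path) as fh:
        first = fh.readline()
        skip = 0
        if first.startswith("#"):
            skip = 1
            for token in first.lstrip("#").split():
                if token.startswith("sampling_rate_hz="):
                    sampling_rate = float(token.split("=", 1)[1])
            header = fh.readline()
        else:
            header = first
    if sampling_rate is None:
        raise ConfigurationError(
            f"{path}: no sampling rate in the file header and none configured"
        )
    delim = _sniff_delimiter(header)
    try:
        frame = pd.read_csv(path, sep=delim, skiprows=skip)
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: {exc}") from exc
    if frame.isna().any().any():
        bad = int(frame.index[frame.isna().any(axis=1)][0]) + 1  # 1-based data row
        raise FormatError(f"{path}: malformed row {bad} (wrong field count)")
    labels = [str(c) for c in frame.columns]
    return labels, float(sampling_rate), frame.to_numpy(dtype=float).T


# ---------------------------------------------------------------------------
# EDF

_EDF_DIG_MIN, _EDF_DIG_MAX = -32768, 32767


def _ascii(value: str, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def _fmt_phys(v: float) -> float:
    """Round a physical bound to what fits in EDF's 8-char ASCII field."""
    return float(f"{v:.6g}"[:8])


def _write_edf(rec: EEGRecording, path: pathlib.Path) -> None:
    """Minimal EDF writer: one data record holding the whole recording,
    16-bit samples scaled to each channel's physical range."""
    labels = list(rec.channel_labels)
    signals = [rec.data[i] for i in range(rec.data.shape[0])]
    if rec.photosensor is not None:
        labels.append(PHOTOSENSOR_LABEL)
        signals.append(rec.photosensor)
    ns = len(signals)
    n = rec.n_samples
    duration = n / rec.sampling_rate

    header = b"".join(
        [
            _ascii("0", 8),
            _ascii("X X X X", 80),
            _ascii("Startdate 01-JAN-2000 synthetic", 80),
            _ascii("01.01.00", 8),
            _ascii("00.00.00", 8),
            _ascii(str(256 * (ns + 1)), 8),
            _ascii("", 44),
            _ascii("1", 8),
            _ascii(f"{duration:.6g}"[:8], 8),
            _ascii(str(ns), 4),
        ]
    )
    pmins, pmaxs = [], []
    for x in signals:
        lo, hi = _fmt_phys(float(np.min(x))), _fmt_phys(float(np.max(x)))
        if hi <= lo:
            hi = lo + 1.0
        pmins.append(lo)
        pmaxs.append(hi)
    sig_header = b"".join(
        [
            b"".join(_ascii(c, 16) for c in labels),
            b"".join(_ascii("", 80) for _ in labels),
            b"".join(_ascii("uV", 8) for _ in labels),
            b"".join(_ascii(f"{p:.6g}"[:8], 8) for p in pmins),
            b"".join(_ascii(f"{p:.6g}"[:8], 8) for p in pmaxs),
            b"".join(_ascii(str(_EDF_DIG_MIN), 8) for _ in labels),
            b"".join(_ascii(str(_EDF_DIG_MAX), 8) for _ in labels),
            b"".join(_ascii("", 80) for _ in labels),
            b"".join(_ascii(str(n), 8) for _ in labels),
            b"".join(_ascii("", 32) for _ in labels),
        ]
    )
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig_header)
        span = _EDF_DIG_MAX - _EDF_DIG_MIN
        for x, lo, hi in zip(signals, pmins, pmaxs):
            dig = np.round((x - lo) / (hi - lo) * span + _EDF_DIG_MIN)
            dig = np.clip(dig, _EDF_DIG_MIN, _EDF_DIG_MAX).astype("<i2")
            fh.write(dig.tobytes())


def _read_edf(path: pathlib.Path) -> tuple[list[str], float, np.ndarray]:
    import mne  # deferred: mne import is slow

    try:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as exc:  # pragma: no cover - mne error text varies
        raise IOError(f"unreadable EDF file {path}: {exc}") from exc
    data = raw.get_data(units="uV")
    return list(raw.ch_names), float(raw.info["sfreq"]), np.asarray(data, dtype=float)


# ---------------------------------------------------------------------------
# Event files


def write_events(events: EventList, path: str | pathlib.Path) -> pathlib.Path:
    """Write an event list as TSV with ``# target=`` / ``# n_stimulus_types=`` headers."""
    path = pathlib.Path(path)
    with open(path, "w") as fh:
        fh.write(f"# target={events.target_label}\n")
        fh.write(f"# n_stimulus_types={events.n_stimulus_types}\n")
        fh.write("onset_sample\tstimulus_label\n")
        for onset, label in events.events:
            fh.write(f"{onset}\t{label}\n")
    return path


def read_events(path: str | pathlib.Path) -> EventList:
    """Read an event TSV/CSV.

    Out-of-order onsets raise :class:`FormatError`; consecutive duplicate
    labels only warn (the stimulation program forbids them, but ingest is
    lenient).  Onsets beyond the recording length are accepted here and fail
    at epoching time.
    """
    path = pathlib.Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    target: int | None = None
    n_types = 9
    rows: list[tuple[int, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                for token in line.lstrip("#").replace(",", " ").split():
                    if token.startswith("target="):
                        target = int(token.split("=", 1)[1])
                    elif token.startswith("n_stimulus_types="):
                        n_types = int(token.split("=", 1)[1])
                continue
            fields = line.replace(",", "\t").split("\t")
            if fields[0].lstrip("-").isdigit():
                if len(fields) < 2:
                    raise FormatError(f"{path}: malformed row at line {lineno}")
                rows.append((int(fields[0]), int(fields[1])))
            # non-numeric first field: the column-name header row
    if target is None:
        raise FormatError(f"{path}: missing '# target=<label>' header")
    if not rows:
        raise FormatError(f"{path}: no event rows")
    onsets = np.array([r[0] for r in rows])
    labels = np.array([r[1] for r in rows])
    return EventList(onsets, labels, target_label=target, n_stimulus_types=n_types)


# ---------------------------------------------------------------------------
# Photosensor onsets


def detect_onsets_from_photosensor(
    rec: EEGRecording,
    threshold: float,
    min_separation_ms: float = 300.0,
) -> np.ndarray:
    """Recover stimulus onsets from upward threshold crossings of the photosensor.

    A crossing is a sample where the previous value is below ``threshold`` and
    the current value is at or above it.  Crossings closer than
    ``min_separation_ms`` (default 300 ms, safely below the 400 ms ISI) to the
    previously accepted onset are discarded as flash-edge glitches.
    """
    if rec.photosensor is None:
        raise ConfigurationError("recording has no photosensor channel")
    if min_separation_ms < 0:
        raise ParameterError("min_separation_ms must be >= 0")
    x = rec.photosensor
    crossings = np.flatnonzero((x[:-1] < threshold) & (x[1:] >= threshold)) + 1
    if len(crossings) == 0:
        warnings.warn("photosensor never crosses the threshold; no onsets detected")
        return np.array([], dtype=np.int64)
    min_sep = int(round(min_separation_ms * rec.sampling_rate / 1000.0))
    accepted = [int(crossings[0])]
    for c in crossings[1:]:
        if c - accepted[-1] >= min_sep:
            accepted.append(int(c))
    return np.array(accepted, dtype=np.int64)
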