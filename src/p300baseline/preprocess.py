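"""Software high-pass filtering, peri-stimulus epoching and artifact rejection.

The pipeline order mirrors common ERP practice: filter the continuous
recording (0.05 Hz second-order Butterworth, zero-phase), cut fixed-extent
epochs around each stimulus onset (−1000 … +500 ms by default, both endpoint
samples included), then reject any epoch whose amplitude leaves ±100 µV.
"""

from __future__ import annotations

import json
import logging
import pathlib
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .exceptions import ParameterError
from .io import EEGRecording, EventList

log = logging.getLogger(__name__)


def ms_to_samples(t_ms: float, sampling_rate: float, what: str = "time") -> int:
    """Convert a time in ms to a whole sample count, warning when rounding occurs."""
    exact = t_ms * sampling_rate / 1000.0
    k = int(round(exact))
    if abs(exact - k) > 1e-9:
        warnings.warn(
            f"{what} {t_ms} ms is not an integer number of samples at "
            f"{sampling_rate} Hz; rounded to {k} samples",
            stacklevel=2,
        )
    return k


@dataclass(frozen=True)
class EpochWindow:
    """Fixed epoch extent: ``pre_ms`` before to ``post_ms`` after stimulus onset."""

    pre_ms: float = 1000.0
    post_ms: float = 500.0

    def __post_init__(self) -> None:
        if self.pre_ms < 0 or self.post_ms < 0 or self.pre_ms + self.post_ms <= 0:
            raise ParameterError("epoch window must have positive total extent")

    def pre_samples(self, fs: float) -> int:
        return ms_to_samples(self.pre_ms, fs, "pre_ms")

    def post_samples(self, fs: float) -> int:
        return ms_to_samples(self.post_ms, fs, "post_ms")

    def n_samples(self, fs: float) -> int:
        # both endpoints included: 1501 samples for (1000, 500) at 1 kHz
        return self.pre_samples(fs) + self.post_samples(fs) + 1

    def times_ms(self, fs: float) -> np.ndarray:
        pre, post = self.pre_samples(fs), self.post_samples(fs)
        return np.arange(-pre, post + 1) * 1000.0 / fs


@dataclass
class Epoch:
    """One peri-stimulus segment; ``signal`` spans [−pre_ms, +post_ms] in µV."""

    stimulus_label: int
    onset_sample: int
    signal: np.ndarray
    sampling_rate: float
    window: EpochWindow
    rejected: bool = False
    reject_reason: str = ""

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        n = self.window.n_samples(self.sampling_rate)
        if self.signal.shape != (n,):
            raise ValueError(f"epoch signal must have {n} samples, got {self.signal.shape}")
        if self.rejected and not self.reject_reason:
            raise ValueError("rejected epochs must carry a reject_reason")

    def index_of(self, t_ms: float) -> int:
        """Local sample index of time ``t_ms`` (0 ms = stimulus onset)."""
        pre = self.window.pre_samples(self.sampling_rate)
        idx = pre + ms_to_samples(t_ms, self.sampling_rate, "baseline time")
        if not 0 <= idx < len(self.signal):
            raise ParameterError(
                f"time {t_ms} ms outside the epoch extent "
                f"[-{self.window.pre_ms}, {self.window.post_ms}] ms"
            )
        return idx

    def times_ms(self) -> np.ndarray:
        return self.window.times_ms(self.sampling_rate)

    def with_signal(self, signal: np.ndarray) -> "Epoch":
        return replace(self, signal=np.asarray(signal, dtype=float))


@dataclass
class EpochSet:
    """Epochs grouped by stimulus label, sharing one window and sampling rate."""

    epochs: list[Epoch]
    sampling_rate: float
    window: EpochWindow
    target_label: int | None = None
    n_stimulus_types: int = 9

    def __post_init__(self) -> None:
        for ep in self.epochs:
            if ep.sampling_rate != self.sampling_rate or ep.window != self.window:
                raise ValueError("all epochs must share the set's window and rate")

    @property
    def labels(self) -> list[int]:
        return sorted({ep.stimulus_label for ep in self.epochs})

    def of_label(self, label: int) -> list[Epoch]:
        return [ep for ep in self.epochs if ep.stimulus_label == label]

    def retained(self, label: int | None = None) -> list[Epoch]:
        eps = self.epochs if label is None else self.of_label(label)
        return [ep for ep in eps if not ep.rejected]

    def stacked(self, label: int, n: int | None = None) -> np.ndarray:
        """Matrix of the first ``n`` retained epochs (presentation order) for a label."""
        kept = self.retained(label)
        if n is not None:
            kept = kept[:n]
        return np.stack([ep.signal for ep in kept]) if kept else np.empty((0, 0))

    def counts(self) -> dict[int, tuple[int, int]]:
        """Per label: (retained, rejected) epoch counts."""
        out = {}
        for label in self.labels:
            eps = self.of_label(label)
            nrej = sum(ep.rejected for ep in eps)
            out[label] = (len(eps) - nrej, nrej)
        return out


def highpass_filter(
    rec: EEGRecording, cutoff_hz: float = 0.05, order: int = 2
) -> EEGRecording:
    """Zero-phase Butterworth high-pass of the EEG channels.

    The filter runs forward and backward (``sosfiltfilt``) so the net phase
    shift is zero — a causal filter would move the P300 latency and corrupt
    the 300–370 ms window logic.  The photosensor passes through unfiltered.
    """
    nyquist = rec.sampling_rate / 2.0
    if not 0 < cutoff_hz < nyquist:
        raise ParameterError(f"cutoff {cutoff_hz} Hz not in (0, {nyquist}) Hz")
    if order < 1:
        raise ParameterError("filter order must be >= 1")
    sos = sps.butter(order, cutoff_hz, btype="highpass", fs=rec.sampling_rate, output="sos")
    filtered = sps.sosfiltfilt(sos, rec.data, axis=1)
    photo = None if rec.photosensor is None else rec.photosensor.copy()
    return EEGRecording(
        list(rec.channel_labels),
        rec.sampling_rate,
        filtered,
        photosensor=photo,
        meta=rec.meta + f" | highpass {cutoff_hz} Hz order {order} zero-phase",
    )


def extract_epochs(
    rec: EEGRecording,
    events: EventList,
    window: EpochWindow = EpochWindow(),
    channel: str | None = None,
) -> EpochSet:
    """Cut one epoch per event from a single channel.

    Events whose window does not fit inside the recording are dropped with a
    warning (padding would fabricate baseline data).  The epoch sample at
    local index ``pre_samples`` equals the recording sample at the onset.
    """
    x = rec.channel(channel)
    fs = rec.sampling_rate
    pre, post = window.pre_samples(fs), window.post_samples(fs)
    epochs: list[Epoch] = []
    dropped = 0
    for onset, label in events.events:
        if onset - pre < 0 or onset + post >= len(x):
            dropped += 1
            continue
    if dropped:
        warnings.warn(
            f"{dropped} event(s) dropped: epoch window ({window.pre_ms}, "
            f"{window.post_ms}) ms does not fit inside the {len(x)}-sample recording"
        )
    for onset, label in events.events:
        if onset - pre < 0 or onset + post >= len(x):
            continue
        epochs.append(
            Epoch(
                stimulus_label=int(label),
                onset_sample=int(onset),
                signal=x[onset - pre : onset + post + 1].copy(),
                sampling_rate=fs,
                window=window,
            )
        )
    if not epochs:
        raise ParameterError(
            f"no events admit a ({window.pre_ms}, {window.post_ms}) ms window "
            f"inside a {len(x)}-sample recording"
        )
    return EpochSet(
        epochs,
        sampling_rate=fs,
        window=window,
        target_label=events.target_label,
        n_stimulus_types=events.n_stimulus_types,
    )


def reject_artifacts(es: EpochSet, limit_uv: float = 100.0) -> EpochSet:
    """Mark every epoch whose amplitude leaves ±``limit_uv`` µV as rejected.

    The full epoch extent is examined, pre-stimulus included: baseline
    integrity is the whole point of the analysis.  Already-rejected epochs
    keep their flags; the operation is idempotent and monotone in the limit.
    """
    if not limit_uv > 0:
        raise ParameterError("limit_uv must be positive")
    out: list[Epoch] = []
    for ep in es.epochs:
        if not ep.rejected and np.any(np.abs(ep.signal) > limit_uv):
            out.append(replace(ep, rejected=True, reject_reason="amplitude"))
        else:
            out.append(replace(ep))
    new = EpochSet(
        out,
        sampling_rate=es.sampling_rate,
        window=es.window,
        target_label=es.target_label,
        n_stimulus_types=es.n_stimulus_types,
    )
    for label, (kept, rej) in new.counts().items():
        log.info("label %s: %d retained, %d rejected (±%g µV)", label, kept, rej, limit_uv)
    return new


# ---------------------------------------------------------------------------
# EpochSet serialization: per-label delimited matrices + a JSON sidecar


def save_epochs(es: EpochSet, directory: str | pathlib.Path) -> pathlib.Path:
    directory = pathlib.Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    sidecar = {
        "sampling_rate": es.sampling_rate,
        "window": {"pre_ms": es.window.pre_ms, "post_ms": es.window.post_ms},
        "target_label": es.target_label,
        "n_stimulus_types": es.n_stimulus_types,
        "labels": {},
    }
    for label in es.labels:
        eps = es.of_label(label)
        np.savetxt(
            directory / f"label_{label}.tsv",
            np.stack([ep.signal for ep in eps]),
            delimiter="\t",
            fmt="%.10g",
        )
        sidecar["labels"][str(label)] = [
            {
                "onset_sample": ep.onset_sample,
                "rejected": ep.rejected,
                "reject_reason": ep.reject_reason,
            }
            for ep in eps
        ]
    (directory / "epochs.json").write_text(json.dumps(sidecar, indent=1))
    return directory


def load_epochs(directory: str | pathlib.Path) -> EpochSet:
    directory = pathlib.Path(directory)
    sidecar = json.loads((directory / "epochs.json").read_text())
    window = EpochWindow(**sidecar["window"])
    fs = sidecar["sampling_rate"]
    epochs: list[Epoch] = []
    for label_s, metas in sidecar["labels"].items():
        label = int(label_s)
        mat = np.atleast_2d(np.loadtxt(directory / f"label_{label}.tsv", delimiter="\t"))
        for row, m in zip(mat, metas):
            epochs.append(
                Epoch(
                    stimulus_label=label,
                    onset_sample=int(m["onset_sample"]),
                    signal=row,
                    sampling_rate=fs,
                    window=window,
                    rejected=bool(m["rejected"]),
                    reject_reason=m["reject_reason"],
                )
            )
    epochs.sort(key=lambda ep: ep.onset_sample)
    return EpochSet(
        epochs,
        sampling_rate=fs,
        window=window,
        target_label=sidecar["target_label"],
        n_stimulus_types=sidecar["n_stimulus_types"],
    )
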