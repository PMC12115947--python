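"""Ensemble averaging, windowed peak scoring and target classification.

The decision rule is the classic oddball argmax: after baseline correction,
the averaged waveform of each stimulus label is scored by its maximum (most
positive) amplitude inside the post-stimulus detection window — 300–370 ms by
default, where the target's P300 peak concentrates — and the label with the
largest peak wins.  The multi-point method repeats that decision once per
reference instant on a 1 ms grid over [−200, 0) ms and takes the majority
vote across the 200 provisional winners.

Because both baseline corrections subtract a per-epoch constant, correcting
every epoch and then averaging equals averaging first and correcting the
average; the classifiers use the second (cheaper) form, and the equivalence
is asserted in the test suite.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .baseline import BaselineSpec, baseline_grid
from .exceptions import AveragingError, ParameterError
from .preprocess import EpochSet, EpochWindow, ms_to_samples

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class DetectionWindow:
    """Post-stimulus window scored for the P300 peak, inclusive of both ends."""

    start_ms: float = 300.0
    end_ms: float = 370.0

    def __post_init__(self) -> None:
        if not 0 <= self.start_ms < self.end_ms:
            raise ParameterError("detection window needs 0 <= start < end")


@dataclass
class AveragedERP:
    """Per-label averaged waveforms over the epoch extent (µV)."""

    labels: list[int]
    waveforms: dict[int, np.ndarray]
    n_epochs_used: dict[int, int]
    sampling_rate: float
    window: EpochWindow
    target_label: int | None = None
    baseline: BaselineSpec | str = "none"

    def matrix(self) -> np.ndarray:
        """Waveforms stacked in sorted-label order, shape (n_labels, n_samples)."""
        return np.stack([self.waveforms[l] for l in self.labels])

    def times_ms(self) -> np.ndarray:
        return self.window.times_ms(self.sampling_rate)


@dataclass
class PeakScore:
    label: int
    max_amplitude: float
    argmax_time_ms: float


@dataclass
class DetectionResult:
    """Provisional winners per reference instant, vote counts, and the verdict."""

    provisional_winners: dict[float, int]
    vote_counts: dict[int, int]
    final_label: int
    tie: bool
    true_target: int | None = None
    correct: bool | None = None

    def to_dict(self) -> dict:
        return {
            "final_label": self.final_label,
            "tie": self.tie,
            "true_target": self.true_target,
            "correct": self.correct,
            "vote_counts": {str(k): v for k, v in self.vote_counts.items()},
            "provisional_winners": {str(t): int(w) for t, w in self.provisional_winners.items()},
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def average_epochs(es: EpochSet, n_per_label: int | str = "all") -> AveragedERP:
    """Arithmetic mean of the first ``n_per_label`` retained epochs per label.

    "First n in presentation order" matches sequential-experiment semantics:
    the average after n presentations of each stimulus.  A label with zero
    retained epochs, or fewer than requested, raises :class:`AveragingError`.
    """
    labels = es.labels
    waveforms: dict[int, np.ndarray] = {}
    used: dict[int, int] = {}
    for label in labels:
        kept = es.retained(label)
        if not kept:
            raise AveragingError(f"label {label} has no retained epochs to average")
        if n_per_label != "all":
            n = int(n_per_label)
            if len(kept) < n:
                raise AveragingError(
                    f"label {label}: {len(kept)} retained epochs < requested {n}"
                )
            kept = kept[:n]
        waveforms[label] = np.mean([ep.signal for ep in kept], axis=0)
        used[label] = len(kept)
    return AveragedERP(
        labels=labels,
        waveforms=waveforms,
        n_epochs_used=used,
        sampling_rate=es.sampling_rate,
        window=es.window,
        target_label=es.target_label,
    )


# ---------------------------------------------------------------------------
# internal index helpers shared with the sweep machinery


def window_slice(win: DetectionWindow, epoch_window: EpochWindow, fs: float) -> slice:
    """Inclusive sample slice of the detection window inside the epoch extent."""
    pre = epoch_window.pre_samples(fs)
    i0 = pre + ms_to_samples(win.start_ms, fs, "window start")
    i1 = pre + ms_to_samples(win.end_ms, fs, "window end")
    n = epoch_window.n_samples(fs)
    if not 0 <= i0 < i1 < n:
        raise ParameterError(
            f"detection window [{win.start_ms}, {win.end_ms}] ms outside the epoch extent"
        )
    return slice(i0, i1 + 1)


def grid_indices(grid_ms: np.ndarray, epoch_window: EpochWindow, fs: float) -> np.ndarray:
    pre = epoch_window.pre_samples(fs)
    idx = np.array([pre + ms_to_samples(t, fs, "baseline time") for t in grid_ms])
    if np.any(idx < 0) or np.any(idx >= epoch_window.n_samples(fs)):
        raise ParameterError("baseline grid leaves the epoch extent")
    return idx


def _winner(labels: np.ndarray, scores: np.ndarray, what: str) -> int:
    """Argmax with deterministic ties: the smallest label id wins, with a log flag."""
    k = int(np.argmax(scores))  # first maximum == smallest label (labels sorted)
    if np.sum(scores == scores[k]) > 1:
        log.warning("%s tie between labels %s; smallest id %s returned",
                    what, labels[scores == scores[k]].tolist(), labels[k])
    return int(labels[k])


def score_peak(erp: AveragedERP, label: int, win: DetectionWindow = DetectionWindow()) -> PeakScore:
    """Maximum amplitude and its time over the inclusive window [start, end].

    The score is the literal (signed) maximum — the P300 is a positive
    deflection — and amplitude ties resolve to the earliest time.
    """
    if label not in erp.waveforms:
        raise ParameterError(f"label {label} not present in the averaged ERP")
    sl = window_slice(win, erp.window, erp.sampling_rate)
    w = erp.waveforms[label][sl]
    k = int(np.argmax(w))  # first occurrence == earliest time
    pre = erp.window.pre_samples(erp.sampling_rate)
    t_ms = (sl.start + k - pre) * 1000.0 / erp.sampling_rate
    return PeakScore(label=int(label), max_amplitude=float(w[k]), argmax_time_ms=t_ms)


def _peaks(erp: AveragedERP, win: DetectionWindow) -> tuple[np.ndarray, np.ndarray]:
    """(labels, uncorrected window maxima) in sorted-label order."""
    sl = window_slice(win, erp.window, erp.sampling_rate)
    W = erp.matrix()
    return np.asarray(erp.labels), W[:, sl].max(axis=1)


def classify_single_baseline(
    es: EpochSet,
    t_baseline_ms: float,
    win: DetectionWindow = DetectionWindow(),
    n_per_label: int | str = "all",
) -> int:
    """Winning label under single-point correction at ``t_baseline_ms``.

    Every epoch is corrected by its amplitude at the reference instant and the
    per-label averages are scored in the detection window; by linearity this
    equals correcting the per-label average, which is what runs.
    """
    erp = average_epochs(es, n_per_label)
    labels, peaks = _peaks(erp, win)
    idx = grid_indices(np.array([t_baseline_ms]), erp.window, erp.sampling_rate)[0]
    base = erp.matrix()[:, idx]
    return _winner(labels, peaks - base, "amplitude")


def classify_range_average(
    es: EpochSet,
    range_ms: tuple[float, float] = (-200.0, 0.0),
    win: DetectionWindow = DetectionWindow(),
    n_per_label: int | str = "all",
) -> int:
    """Winning label under time-range-averaged correction over [start, end) ms."""
    start, end = range_ms
    if not start < end:
        raise ParameterError("range_ms must satisfy start < end")
    erp = average_epochs(es, n_per_label)
    labels, peaks = _peaks(erp, win)
    fs, ewin = erp.sampling_rate, erp.window
    pre = ewin.pre_samples(fs)
    i0 = pre + ms_to_samples(start, fs, "range start")
    i1 = pre + ms_to_samples(end, fs, "range end")
    if not 0 <= i0 < i1 <= ewin.n_samples(fs):
        raise ParameterError(f"baseline range [{start}, {end}) ms outside the epoch extent")
    base = erp.matrix()[:, i0:i1].mean(axis=1)
    return _winner(labels, peaks - base, "amplitude")


def classify_multi_point(
    es: EpochSet,
    spec: BaselineSpec | None = None,
    win: DetectionWindow = DetectionWindow(),
    n_per_label: int | str = "all",
    true_target: int | None = None,
) -> DetectionResult:
    """Majority vote over single-point classifications on the reference grid.

    Every instant of the grid (default [−200, 0) ms at 1 ms → 200 points)
    produces a provisional winner; the per-label vote counts partition the
    grid and the label with the most votes is the final call.  Count ties
    resolve to the smallest label id and are flagged.
    """
    spec = spec or BaselineSpec.multi_point()
    grid = baseline_grid(spec)
    erp = average_epochs(es, n_per_label)
    labels, peaks = _peaks(erp, win)
    idx = grid_indices(grid, erp.window, erp.sampling_rate)
    base = erp.matrix()[:, idx]                      # (n_labels, n_grid)
    scores = peaks[:, None] - base                   # corrected window maxima
    winner_rows = np.argmax(scores, axis=0)          # first max == smallest label
    winners = np.asarray(labels)[winner_rows]
    vote_counts = {int(l): int(np.sum(winners == l)) for l in labels}
    best = max(vote_counts.values())
    leaders = [l for l, c in vote_counts.items() if c == best]
    tie = len(leaders) > 1
    if tie:
        log.warning("vote tie between labels %s; smallest id %s returned",
                    leaders, min(leaders))
    final = int(min(leaders))
    if true_target is None:
        true_target = es.target_label
    return DetectionResult(
        provisional_winners={float(t): int(w) for t, w in zip(grid, winners)},
        vote_counts=vote_counts,
        final_label=final,
        tie=tie,
        true_target=true_target,
        correct=None if true_target is None else final == true_target,
    )


def score_correctness(
    results: list[tuple[int, int]]
) -> tuple[float, list[bool]]:
    """Accuracy over (final_label, true_target) pairs, plus per-trial booleans."""
    if not results:
        raise ParameterError("score_correctness needs at least one result")
    flags = [final == target for final, target in results]
    return float(np.mean(flags)), flags
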