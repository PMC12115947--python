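"""The three baseline-correction strategies.

All three treat a pre-stimulus quantity as the zero-voltage EEG reference and
subtract it from the whole epoch:

* ``single_point`` — the amplitude at one instant (e.g. −100 ms);
* ``range_average`` — the mean amplitude over a half-open pre-stimulus
  interval (e.g. [−200, 0) ms);
* ``multi_point`` — every instant on a grid over [−200, 0) ms serves as a
  reference in turn; each yields a provisional target call and the majority
  vote decides (see :mod:`p300baseline.detect`).

Both corrections change an epoch only by an additive constant, so correcting
each epoch and averaging equals averaging and then correcting the average.
All ranges are half-open ``[start, end)``; the default 1 ms grid over
[−200, 0) therefore has exactly 200 points, and the stimulus-onset sample
itself (already stimulus-contaminated by definition) is excluded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ParameterError
from .preprocess import Epoch

METHODS = ("single_point", "range_average", "multi_point")


@dataclass(frozen=True)
class BaselineSpec:
    """Which correction to apply and its time parameters (all in signed ms)."""

    method: str
    t_baseline_ms: float | None = None
    range_ms: tuple[float, float] | None = None
    multi_window_ms: tuple[float, float] = (-200.0, 0.0)
    step_ms: float = 1.0

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ParameterError(f"method must be one of {METHODS}, got {self.method!r}")
        if self.method == "single_point" and self.t_baseline_ms is None:
            raise ParameterError("single_point needs t_baseline_ms")
        if self.method == "range_average":
            if self.range_ms is None or not self.range_ms[0] < self.range_ms[1]:
                raise ParameterError("range_average needs range_ms with start < end")
        if self.method == "multi_point":
            if not self.step_ms > 0:
                raise ParameterError("step_ms must be positive")
            if not self.multi_window_ms[0] < self.multi_window_ms[1]:
                raise ParameterError("multi_point window needs start < end")

    # convenience constructors -------------------------------------------------
    @classmethod
    def single_point(cls, t_baseline_ms: float = -100.0) -> "BaselineSpec":
        return cls("single_point", t_baseline_ms=t_baseline_ms)

    @classmethod
    def range_average(cls, range_ms: tuple[float, float] = (-200.0, 0.0)) -> "BaselineSpec":
        return cls("range_average", range_ms=tuple(range_ms))

    @classmethod
    def multi_point(
        cls, window_ms: tuple[float, float] = (-200.0, 0.0), step_ms: float = 1.0
    ) -> "BaselineSpec":
        return cls("multi_point", multi_window_ms=tuple(window_ms), step_ms=step_ms)


def baseline_grid(spec: BaselineSpec) -> np.ndarray:
    """Ordered reference instants of the multi-point method, half-open [start, end).

    The default (−200, 0) window at 1 ms step yields exactly 200 values,
    −200 … −1 ms.
    """
    if spec.method != "multi_point":
        raise ParameterError("baseline_grid applies to multi_point specs")
    start, end = spec.multi_window_ms
    return np.arange(start, end, spec.step_ms)


def correct_single_point(epoch: Epoch, t_baseline_ms: float) -> Epoch:
    """Subtract the amplitude at one pre-stimulus instant from the whole epoch.

    The corrected amplitude at ``t_baseline_ms`` is exactly zero.
    """
    idx = epoch.index_of(t_baseline_ms)
    return epoch.with_signal(epoch.signal - epoch.signal[idx])


def correct_range_average(epoch: Epoch, range_ms: tuple[float, float]) -> Epoch:
    """Subtract the mean amplitude over the half-open sample range [start, end)."""
    start, end = range_ms
    if not start < end:
        raise ParameterError("range_ms must satisfy start < end")
    i0 = epoch.index_of(start)
    pre = epoch.window.pre_samples(epoch.sampling_rate)
    from .preprocess import ms_to_samples

    i1 = pre + ms_to_samples(end, epoch.sampling_rate, "range end")
    if not 0 < i1 <= len(epoch.signal):
        raise ParameterError(f"range end {end} ms outside the epoch extent")
    if i1 <= i0:
        raise ParameterError("empty baseline range: no samples in [start, end)")
    return epoch.with_signal(epoch.signal - epoch.signal[i0:i1].mean())


def apply_baseline(epoch: Epoch, spec: BaselineSpec) -> Epoch:
    """Apply a single-point or range-average spec to one epoch."""
    if spec.method == "single_point":
        return correct_single_point(epoch, spec.t_baseline_ms)
    if spec.method == "range_average":
        return correct_range_average(epoch, spec.range_ms)
    raise ParameterError(
        "multi_point is a voting scheme over classifications; apply it with "
        "p300baseline.detect.classify_multi_point"
    )
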