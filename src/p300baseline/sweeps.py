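"""Characterisation sweeps and the three-way statistical comparison.

These analyses map how the choice of baseline parameter affects detection:

* :func:`sweep_single_point` — single-point correction at every instant of a
  pre-stimulus grid (default 1 ms steps over [−1000, 0) ms → 1000 points);
* :func:`sweep_range_end` — range-averaged correction over [−k, 0) for every
  end point k on the grid;
* :func:`sweep_range_start` — a fixed-width (200 ms) range slid backwards in
  10 ms steps, quantifying how much the target peak amplitude moves when the
  baseline window shifts (large movement reveals components with periods
  longer than the window);
* :func:`sweep_window_width` — detection windows 300 ± 10…100 ms, for peak
  amplitude/latency statistics of target vs non-target waveforms;
* :func:`ratio_summary` — the non-target/target peak-amplitude ratio (target
  = 100 %); a point classifies correctly exactly when its ratio is < 100 %;
* :func:`compare_methods` — paired Wilcoxon signed-rank tests across methods
  with Holm adjustment and effect size r = |Z|/√n.

All sweep axes are reported as signed (negative) milliseconds.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .detect import AveragedERP, DetectionWindow, average_epochs, grid_indices, \
    window_slice
from .baseline import BaselineSpec
from .exceptions import ParameterError
from .preprocess import EpochSet, ms_to_samples

log = logging.getLogger(__name__)

DEFAULT_N_LIST = (10, 20, 30, 40, 50, 60, 70, 80, 90, 100)


@dataclass
class SweepResult:
    """Per-axis-point per-label corrected window maxima and correctness."""

    kind: str
    axis_ms: np.ndarray          # ordered parameter values (signed ms)
    labels: np.ndarray           # sorted stimulus ids
    amplitudes: np.ndarray       # (n_axis, n_labels) corrected window maxima, µV
    correct: np.ndarray          # (n_axis,) bool
    accuracy: float
    n_average: int | str
    target_label: int

    def target_amplitudes(self) -> np.ndarray:
        return self.amplitudes[:, self.labels == self.target_label].ravel()

    def best_nontarget_amplitudes(self) -> np.ndarray:
        return self.amplitudes[:, self.labels != self.target_label].max(axis=1)

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            self.amplitudes, columns=[f"label_{l}" for l in self.labels]
        )
        frame.insert(0, "axis_ms", self.axis_ms)
        frame["correct"] = self.correct
        return frame


def _sweep_from_bases(
    kind: str,
    erp: AveragedERP,
    axis_ms: np.ndarray,
    bases: np.ndarray,
    win: DetectionWindow,
    n_average: int | str,
) -> SweepResult:
    """Assemble a SweepResult from per-axis per-label baseline values."""
    labels = np.asarray(erp.labels)
    sl = window_slice(win, erp.window, erp.sampling_rate)
    peaks = erp.matrix()[:, sl].max(axis=1)          # (L,)
    amplitudes = peaks[None, :] - bases              # (A, L)
    winner_cols = np.argmax(amplitudes, axis=1)      # first max == smallest label
    correct = labels[winner_cols] == erp.target_label
    return SweepResult(
        kind=kind,
        axis_ms=np.asarray(axis_ms, dtype=float),
        labels=labels,
        amplitudes=amplitudes,
        correct=correct,
        accuracy=float(np.mean(correct)),
        n_average=n_average,
        target_label=erp.target_label,
    )


def sweep_single_point(
    es: EpochSet,
    t_range_ms: tuple[float, float] = (-1000.0, 0.0),
    step_ms: float = 1.0,
    win: DetectionWindow = DetectionWindow(),
    n_list: tuple = DEFAULT_N_LIST,
) -> dict[int | str, SweepResult]:
    """Single-point correction swept over the pre-stimulus grid, per averaging count."""
    grid = np.arange(t_range_ms[0], t_range_ms[1], step_ms)
    if len(grid) == 0:
        raise ParameterError("empty baseline grid")
    out: dict[int | str, SweepResult] = {}
    for n in n_list:
        erp = average_epochs(es, n)
        idx = grid_indices(grid, erp.window, erp.sampling_rate)
        bases = erp.matrix()[:, idx].T               # (A, L)
        out[n] = _sweep_from_bases("single_point", erp, grid, bases, win, n)
    return out


def sweep_range_end(
    es: EpochSet,
    end_range_ms: tuple[float, float] = (-1000.0, 0.0),
    step_ms: float = 1.0,
    win: DetectionWindow = DetectionWindow(),
    n_list: tuple = DEFAULT_N_LIST,
) -> dict[int | str, SweepResult]:
    """Range-averaged correction over [−k, 0) for every end point −k on the grid.

    Axis value −k means the baseline was the mean over the last k ms before
    onset; −1 is a one-sample range, identical to single-point at −1 ms.
    """
    grid = np.arange(end_range_ms[0], end_range_ms[1], step_ms)
    if len(grid) == 0 or np.any(grid >= 0):
        raise ParameterError("range-end grid must consist of negative times")
    out: dict[int | str, SweepResult] = {}
    for n in n_list:
        erp = average_epochs(es, n)
        fs = erp.sampling_rate
        pre = erp.window.pre_samples(fs)
        W = erp.matrix()
        # cumulative means of the pre-stimulus samples, taken from onset backwards
        rev_csum = np.cumsum(W[:, :pre][:, ::-1], axis=1)     # (L, pre)
        ks = np.array([-ms_to_samples(t, fs, "range end") for t in grid])
        if np.any(ks < 1) or np.any(ks > pre):
            raise ParameterError("range-end grid leaves the pre-stimulus extent")
        bases = (rev_csum[:, ks - 1] / ks).T                  # (A, L)
        out[n] = _sweep_from_bases("range_end", erp, grid, bases, win, n)
    return out


@dataclass
class StartShiftResult:
    """Fixed-width baseline range slid backwards: the baseline-stability probe."""

    sweep: SweepResult
    start_grid_ms: np.ndarray
    target_peak_uv: np.ndarray     # target corrected peak per start
    variation_uv: float            # max - min across starts

    def to_frame(self) -> pd.DataFrame:
        frame = self.sweep.to_frame()
        frame.insert(1, "target_peak_uv", self.target_peak_uv)
        return frame


def sweep_range_start(
    es: EpochSet,
    width_ms: float = 200.0,
    start_grid_ms: np.ndarray | None = None,
    win: DetectionWindow = DetectionWindow(),
    n_per_label: int | str = "all",
) -> StartShiftResult:
    """Slide a fixed-width baseline range backwards from the stimulus.

    For each start s the baseline is the mean over [s − width, s); the default
    grid runs 0, −10, …, −300 ms (31 starts).  The spread (max − min) of the
    target's corrected peak across starts measures baseline stability: small
    when only rhythms with periods inside the window are present, large when
    longer-period components remain.
    """
    if start_grid_ms is None:
        start_grid_ms = np.arange(0.0, -301.0, -10.0)
    start_grid_ms = np.asarray(start_grid_ms, dtype=float)
    erp = average_epochs(es, n_per_label)
    fs = erp.sampling_rate
    pre = erp.window.pre_samples(fs)
    W = erp.matrix()
    wsamp = ms_to_samples(width_ms, fs, "range width")
    bases = np.empty((len(start_grid_ms), W.shape[0]))
    for a, s in enumerate(start_grid_ms):
        i1 = pre + ms_to_samples(s, fs, "range start")
        i0 = i1 - wsamp
        if i0 < 0:
            raise ParameterError(
                f"start {s} ms with width {width_ms} ms leaves the epoch extent"
            )
        bases[a] = W[:, i0:i1].mean(axis=1)
    sweep = _sweep_from_bases("range_start", erp, start_grid_ms, bases, win, n_per_label)
    target_peak = sweep.target_amplitudes()
    return StartShiftResult(
        sweep=sweep,
        start_grid_ms=start_grid_ms,
        target_peak_uv=target_peak,
        variation_uv=float(target_peak.max() - target_peak.min()),
    )


@dataclass
class WindowWidthResult:
    """Peak amplitude and latency per detection-window width, target vs non-target."""

    half_widths_ms: np.ndarray
    center_ms: float
    labels: np.ndarray
    max_amplitude: np.ndarray     # (n_widths, n_labels)
    argmax_time_ms: np.ndarray    # (n_widths, n_labels)
    target_label: int

    def _split(self, arr: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        t = self.labels == self.target_label
        return arr[:, t].ravel(), arr[:, ~t]

    def target_max(self) -> np.ndarray:
        return self._split(self.max_amplitude)[0]

    def nontarget_max(self) -> np.ndarray:
        return self._split(self.max_amplitude)[1]

    def target_argmax_ms(self) -> np.ndarray:
        return self._split(self.argmax_time_ms)[0]

    def nontarget_argmax_ms(self) -> np.ndarray:
        return self._split(self.argmax_time_ms)[1]

    def summary(self) -> pd.DataFrame:
        """Median and quartiles of the pooled non-target distributions per width."""
        rows = []
        for i, hw in enumerate(self.half_widths_ms):
            non = self.max_amplitude[i, self.labels != self.target_label]
            non_t = self.argmax_time_ms[i, self.labels != self.target_label]
            rows.append(
                {
                    "half_width_ms": hw,
                    "target_max_uv": self.target_max()[i],
                    "target_argmax_ms": self.target_argmax_ms()[i],
                    "nontarget_max_median_uv": float(np.median(non)),
                    "nontarget_max_q1_uv": float(np.percentile(non, 25)),
                    "nontarget_max_q3_uv": float(np.percentile(non, 75)),
                    "nontarget_argmax_median_ms": float(np.median(non_t)),
                }
            )
        return pd.DataFrame(rows)


def sweep_window_width(
    es: EpochSet,
    center_ms: float = 300.0,
    half_widths_ms: tuple = (10, 20, 30, 40, 50, 60, 70, 80, 90, 100),
    baseline: BaselineSpec | None = None,
    n_per_label: int | str = "all",
) -> WindowWidthResult:
    """Score nested detection windows ``center ± half_width`` for every label.

    Windows are nested, so the maximum amplitude is non-decreasing in the
    width for every waveform.  ``baseline`` (single-point or range-average)
    is applied to the averaged waveforms before scoring; None scores raw
    averages.
    """
    erp = average_epochs(es, n_per_label)
    fs = erp.sampling_rate
    pre = erp.window.pre_samples(fs)
    W = erp.matrix()
    if baseline is not None:
        if baseline.method == "single_point":
            idx = grid_indices(np.array([baseline.t_baseline_ms]), erp.window, fs)[0]
            W = W - W[:, idx : idx + 1]
        elif baseline.method == "range_average":
            i0 = pre + ms_to_samples(baseline.range_ms[0], fs, "range start")
            i1 = pre + ms_to_samples(baseline.range_ms[1], fs, "range end")
            W = W - W[:, i0:i1].mean(axis=1, keepdims=True)
        else:
            raise ParameterError("window-width sweep takes a single-point or range baseline")
    half_widths = np.asarray(half_widths_ms, dtype=float)
    L = W.shape[0]
    max_amp = np.empty((len(half_widths), L))
    argmax_ms = np.empty((len(half_widths), L))
    for i, hw in enumerate(half_widths):
        win = DetectionWindow(center_ms - hw, center_ms + hw)
        sl = window_slice(win, erp.window, fs)
        seg = W[:, sl]
        k = np.argmax(seg, axis=1)
        max_amp[i] = seg[np.arange(L), k]
        argmax_ms[i] = (sl.start + k - pre) * 1000.0 / fs
    return WindowWidthResult(
        half_widths_ms=half_widths,
        center_ms=center_ms,
        labels=np.asarray(erp.labels),
        max_amplitude=max_amp,
        argmax_time_ms=argmax_ms,
        target_label=erp.target_label,
    )


# ---------------------------------------------------------------------------
# amplitude-ratio summaries


@dataclass
class RatioSummary:
    """Best-non-target / target peak ratio per axis point, target = 100 %."""

    axis_ms: np.ndarray
    ratios_pct: np.ndarray        # (n_subjects, n_axis); NaN where target peak == 0
    mean_pct: np.ndarray
    sd_pct: np.ndarray
    min_pct: np.ndarray
    max_pct: np.ndarray


def ratio_summary(sweeps: SweepResult | list[SweepResult]) -> RatioSummary:
    """Cohort envelope of the non-target/target peak-amplitude ratio.

    For each sweep (one subject-run) and axis point, the ratio is
    100 × (best non-target corrected peak) / (target corrected peak).  Where
    the target peak is positive, ratio < 100 % is exactly the condition for a
    correct classification at that point.
    """
    if isinstance(sweeps, SweepResult):
        sweeps = [sweeps]
    axis = sweeps[0].axis_ms
    for sw in sweeps[1:]:
        if not np.array_equal(sw.axis_ms, axis):
            raise ParameterError("all sweeps must share the same axis")
    ratios = np.full((len(sweeps), len(axis)), np.nan)
    for s, sw in enumerate(sweeps):
        target = sw.target_amplitudes()
        best_non = sw.best_nontarget_amplitudes()
        ok = target != 0
        ratios[s, ok] = 100.0 * best_non[ok] / target[ok]
    return RatioSummary(
        axis_ms=axis,
        ratios_pct=ratios,
        mean_pct=np.nanmean(ratios, axis=0),
        sd_pct=np.nanstd(ratios, axis=0),
        min_pct=np.nanmin(ratios, axis=0),
        max_pct=np.nanmax(ratios, axis=0),
    )


# ---------------------------------------------------------------------------
# three-way statistical comparison


@dataclass
class PairTest:
    method_a: str
    method_b: str
    n_nonzero: int
    w: float
    p: float
    p_holm: float
    z: float
    r: float
    undefined: bool = False


@dataclass
class MethodComparison:
    pairs: list[PairTest]

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "pair": f"{p.method_a} vs {p.method_b}",
                    "n_nonzero": p.n_nonzero,
                    "W": p.w,
                    "p_raw": p.p,
                    "p_holm": p.p_holm,
                    "effect_size_r": p.r,
                    "undefined": p.undefined,
                }
                for p in self.pairs
            ]
        )

    def summary(self) -> str:
        return self.table().to_string(index=False, float_format=lambda v: f"{v:.4g}")


def _signed_rank_z(d: np.ndarray) -> tuple[float, float]:
    """(W = min rank sum, Z with tie correction and continuity correction)."""
    ranks = stats.rankdata(np.abs(d))
    wpos = float(ranks[d > 0].sum())
    wneg = float(ranks[d < 0].sum())
    n = len(d)
    mu = n * (n + 1) / 4.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - np.sum(tie_counts**3 - tie_counts) / 48.0
    if var <= 0:
        return min(wpos, wneg), 0.0
    dev = wpos - mu
    cc = 0.5 * np.sign(dev)
    z = (dev - cc) / np.sqrt(var) if dev != 0 else 0.0
    return min(wpos, wneg), float(z)


def compare_methods(
    per_subject_accuracy: dict[str, list[float] | np.ndarray]
) -> MethodComparison:
    """Pairwise two-sided Wilcoxon signed-rank tests with Holm adjustment.

    Zero differences are dropped (Wilcoxon's original rule) and tied absolute
    differences take mid-ranks.  The p-value comes from the exact signed-rank
    distribution for n ≤ 25, otherwise from the normal approximation with
    continuity correction; the effect size is
    r = |Z|/√n_nonzero.  All-zero difference vectors leave the statistic
    undefined and are reported as such (excluded from the Holm family).
    """
    methods = list(per_subject_accuracy)
    if len(methods) < 2:
        raise ParameterError("compare_methods needs at least two methods")
    arrays = {m: np.asarray(per_subject_accuracy[m], dtype=float) for m in methods}
    lengths = {len(a) for a in arrays.values()}
    if len(lengths) != 1:
        raise ParameterError("paired samples must have equal length")

    pairs: list[PairTest] = []
    for a, b in itertools.combinations(methods, 2):
        d = arrays[a] - arrays[b]
        d = d[d != 0]
        n = len(d)
        if n == 0:
            pairs.append(PairTest(a, b, 0, np.nan, np.nan, np.nan, np.nan, np.nan, True))
            continue
        mode = "exact" if n <= 25 else "approx"
        res = stats.wilcoxon(
            d, zero_method="wilcox", alternative="two-sided",
            method=mode, correction=(mode == "approx"),
        )
        w, z = _signed_rank_z(d)  # w agrees with scipy's min(R+, R-) statistic
        pairs.append(PairTest(a, b, n, w, float(res.pvalue), np.nan, z, abs(z) / np.sqrt(n)))
    defined = [p for p in pairs if not p.undefined]
    if defined:
        from statsmodels.stats.multitest import multipletests

        adj = multipletests([p.p for p in defined], method="holm")[1]
        for p, ph in zip(defined, adj):
            p.p_holm = float(ph)
    return MethodComparison(pairs)
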