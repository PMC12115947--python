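"""Small matplotlib helpers for the sweep outputs."""

from __future__ import annotations

import numpy as np

from .detect import AveragedERP
from .sweeps import RatioSummary, SweepResult


def _axes(ax):
    if ax is None:
        import matplotlib.pyplot as plt

        _, ax = plt.subplots()
    return ax


def plot_erp(erp: AveragedERP, ax=None):
    """Averaged waveform per label; the target label is drawn heavier."""
    ax = _axes(ax)
    t = erp.times_ms()
    for label in erp.labels:
        is_target = label == erp.target_label
        ax.plot(t, erp.waveforms[label], lw=2.0 if is_target else 0.8,
                label=f"{label}{' (target)' if is_target else ''}")
    ax.axvline(0, color="k", lw=0.5)
    ax.set_xlabel("time from stimulus onset (ms)")
    ax.set_ylabel("amplitude (µV)")
    ax.legend(fontsize="x-small", ncol=3)
    return ax


def plot_sweep(sweep: SweepResult, ax=None):
    """Per-label corrected window maxima along the sweep axis."""
    ax = _axes(ax)
    for j, label in enumerate(sweep.labels):
        is_target = label == sweep.target_label
        ax.plot(sweep.axis_ms, sweep.amplitudes[:, j],
                lw=2.0 if is_target else 0.8,
                label=f"{label}{' (target)' if is_target else ''}")
    ax.set_xlabel(f"{sweep.kind} axis (ms before stimulus)")
    ax.set_ylabel("window max amplitude (µV)")
    ax.set_title(f"accuracy {sweep.accuracy:.2f} at n={sweep.n_average}")
    ax.legend(fontsize="x-small", ncol=3)
    return ax


def plot_ratio_summary(ratio: RatioSummary, ax=None):
    """Cohort mean ± sd and min–max envelope of the non-target/target ratio."""
    ax = _axes(ax)
    x = ratio.axis_ms
    ax.fill_between(x, ratio.min_pct, ratio.max_pct, alpha=0.2, label="min–max")
    ax.fill_between(x, ratio.mean_pct - ratio.sd_pct, ratio.mean_pct + ratio.sd_pct,
                    alpha=0.4, label="mean ± sd")
    ax.plot(x, ratio.mean_pct, lw=1.5, label="mean")
    ax.axhline(100.0, color="r", ls="--", lw=0.8, label="target = 100 %")
    ax.set_xlabel("baseline point (ms before stimulus)")
    ax.set_ylabel("best non-target / target peak (%)")
    ax.legend(fontsize="x-small")
    return ax
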