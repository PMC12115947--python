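"""End-to-end detection runs: filter → epoch → reject → classify.

Convenience layer used by the CLI, the sweep analyses and the cohort
evaluation; every step is the corresponding library function with the
pipeline defaults (0.05 Hz zero-phase high-pass, −1000…+500 ms epochs,
±100 µV rejection).
"""

from __future__ import annotations

import pandas as pd

from .baseline import BaselineSpec
from .detect import DetectionResult, DetectionWindow, classify_multi_point, \
    classify_range_average, classify_single_baseline
from .io import EEGRecording, EventList
from .preprocess import EpochSet, EpochWindow, extract_epochs, highpass_filter, \
    reject_artifacts


def prepare_epochs(
    rec: EEGRecording,
    events: EventList,
    *,
    channel: str | None = None,
    epoch_window: EpochWindow = EpochWindow(),
    highpass_hz: float | None = 0.05,
    filter_order: int = 2,
    reject_uv: float | None = 100.0,
) -> EpochSet:
    """Filter the recording, cut epochs and apply amplitude rejection."""
    if highpass_hz is not None:
        rec = highpass_filter(rec, highpass_hz, filter_order)
    es = extract_epochs(rec, events, epoch_window, channel)
    if reject_uv is not None:
        es = reject_artifacts(es, reject_uv)
    return es


def classify(
    es: EpochSet,
    spec: BaselineSpec,
    win: DetectionWindow = DetectionWindow(),
    n_per_label: int | str = "all",
) -> DetectionResult:
    """Run whichever baseline method ``spec`` names, as a DetectionResult.

    Single-point and range-average produce one provisional winner; their
    result is a degenerate vote (one grid point) so all three methods share
    a return type.
    """
    if spec.method == "multi_point":
        return classify_multi_point(es, spec, win, n_per_label)
    if spec.method == "single_point":
        winner = classify_single_baseline(es, spec.t_baseline_ms, win, n_per_label)
        key = float(spec.t_baseline_ms)
    else:
        winner = classify_range_average(es, spec.range_ms, win, n_per_label)
        key = float(spec.range_ms[0])
    target = es.target_label
    return DetectionResult(
        provisional_winners={key: winner},
        vote_counts={winner: 1},
        final_label=winner,
        tie=False,
        true_target=target,
        correct=None if target is None else winner == target,
    )


def run_pipeline(
    rec: EEGRecording,
    events: EventList,
    spec: BaselineSpec,
    *,
    channel: str | None = None,
    win: DetectionWindow = DetectionWindow(),
    n_per_label: int | str = "all",
    **prepare_kwargs,
) -> DetectionResult:
    """Full detection run on one recording."""
    es = prepare_epochs(rec, events, channel=channel, **prepare_kwargs)
    return classify(es, spec, win, n_per_label)


def evaluate_cohort(
    cohort,
    methods: dict[str, BaselineSpec],
    n_per_label: int | str = 40,
    win: DetectionWindow = DetectionWindow(),
    **prepare_kwargs,
) -> pd.DataFrame:
    """Classify every run of every subject under each method.

    Returns one row per (subject, run, method) with the final label, the
    injected target and correctness; epochs are prepared once per run and
    shared across methods.
    """
    rows = []
    for subject in cohort:
        for run in subject.runs:
            es = prepare_epochs(run.recording, run.events, **prepare_kwargs)
            for name, spec in methods.items():
                res = classify(es, spec, win, n_per_label)
                rows.append(
                    {
                        "subject": subject.subject_id,
                        "run": run.run_index,
                        "method": name,
                        "final_label": res.final_label,
                        "target_label": run.target_label,
                        "correct": bool(res.final_label == run.target_label),
                    }
                )
    return pd.DataFrame(rows)


def cohort_accuracy(table: pd.DataFrame) -> dict[str, float]:
    """Fraction of correct runs per method."""
    return table.groupby("method")["correct"].mean().to_dict()


def per_subject_accuracy(table: pd.DataFrame) -> dict[str, list[float]]:
    """Per-method list of per-subject accuracies (runs averaged within subject)."""
    out: dict[str, list[float]] = {}
    for method, sub in table.groupby("method"):
        out[method] = sub.groupby("subject")["correct"].mean().tolist()
    return out
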