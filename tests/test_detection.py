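"""Averaging, peak scoring and the argmax/vote classifiers."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from p300baseline import (
    BaselineSpec,
    DetectionWindow,
    NoiseModel,
    SessionSpec,
    average_epochs,
    classify_multi_point,
    classify_range_average,
    classify_single_baseline,
    cohort_accuracy,
    evaluate_cohort,
    generate_cohort,
    score_correctness,
    score_peak,
)
from p300baseline.exceptions import AveragingError, ParameterError
from tests.conftest import make_epochset

WIN = DetectionWindow(5.0, 15.0)  # toy window inside the 41-sample epochs


def _gauss_bump(center_ms, amp=5.0, n=41, pre=20):
    k = np.arange(n) - pre
    return amp * np.exp(-0.5 * ((k - center_ms) / 3.0) ** 2)


class TestAveraging:
    def test_arithmetic_mean(self):
        es = make_epochset({1: np.array([[0.0, 2.0, 4.0] + [0.0] * 38,
                                         [2.0, 2.0, 2.0] + [0.0] * 38])}, target_label=1)
        erp = average_epochs(es)
        np.testing.assert_array_equal(erp.waveforms[1][:3], [1.0, 2.0, 3.0])
        assert erp.n_epochs_used[1] == 2

    def test_requested_count_is_honoured(self):
        rng = np.random.default_rng(0)
        mats = rng.normal(size=(100, 41))
        es = make_epochset({1: mats}, target_label=1)
        erp = average_epochs(es, 40)
        assert erp.n_epochs_used[1] == 40
        np.testing.assert_allclose(erp.waveforms[1], mats[:40].mean(axis=0))

    def test_insufficient_epochs_raise_with_counts(self):
        es = make_epochset({1: np.zeros((3, 41))}, target_label=1)
        with pytest.raises(AveragingError, match="3 retained"):
            average_epochs(es, 10)

    def test_noise_rms_attenuates_as_inverse_sqrt_n(self):
        """Averaging N i.i.d. unit-variance epochs leaves RMS ~ 1/sqrt(N)."""
        rng = np.random.default_rng(123)
        n_epochs, n_samples, reps = 100, 50, 1000
        rms = np.empty(reps)
        for r in range(reps):
            avg = rng.standard_normal((n_epochs, n_samples)).mean(axis=0)
            rms[r] = np.sqrt(np.mean(avg**2))
        expected = 1.0 / np.sqrt(n_epochs)
        # sampling sd of the mean RMS over `reps` replicates
        tol = 3.0 * rms.std() / np.sqrt(reps)
        assert abs(rms.mean() - expected) < tol + 0.01 * expected


class TestScorePeak:
    def test_gaussian_bump_scored_at_its_peak(self):
        es = make_epochset({1: _gauss_bump(10.0)[None, :]}, target_label=1)
        s = score_peak(average_epochs(es), 1, WIN)
        assert s.argmax_time_ms == 10.0
        assert s.max_amplitude == pytest.approx(5.0)

    def test_monotone_waveform_peaks_at_window_start(self):
        sig = -np.arange(41.0)
        es = make_epochset({1: sig[None, :]}, target_label=1)
        s = score_peak(average_epochs(es), 1, WIN)
        assert s.argmax_time_ms == WIN.start_ms

    def test_ties_resolve_to_earliest_time(self):
        sig = np.zeros(41)
        sig[[27, 31]] = 2.0  # equal maxima at +7 and +11 ms
        es = make_epochset({1: sig[None, :]}, target_label=1)
        assert score_peak(average_epochs(es), 1, WIN).argmax_time_ms == 7.0

    @given(seed=st.integers(0, 2**16))
    @settings(max_examples=30, deadline=None)
    def test_matches_linear_scan_oracle(self, seed):
        sig = np.random.default_rng(seed).normal(size=41)
        es = make_epochset({1: sig[None, :]}, target_label=1)
        s = score_peak(average_epochs(es), 1, WIN)
        best_amp, best_t = -np.inf, None
        for k in range(25, 36):  # +5 .. +15 ms inclusive
            if sig[k] > best_amp:
                best_amp, best_t = sig[k], k - 20
        assert s.max_amplitude == best_amp and s.argmax_time_ms == best_t

    def test_window_outside_extent_rejected(self):
        es = make_epochset({1: np.zeros((1, 41))}, target_label=1)
        with pytest.raises(ParameterError):
            score_peak(average_epochs(es), 1, DetectionWindow(5.0, 50.0))


def _toy_classify_oracle(es, t_baseline_ms, win):
    """Straight-line recomputation from raw epochs: correct each epoch at the
    reference instant, average per label, scan the window, argmax over labels."""
    best_label, best_amp = None, -np.inf
    pre = es.window.pre_samples(es.sampling_rate)
    b = pre + int(round(t_baseline_ms * es.sampling_rate / 1000.0))
    i0 = pre + int(round(win.start_ms * es.sampling_rate / 1000.0))
    i1 = pre + int(round(win.end_ms * es.sampling_rate / 1000.0))
    for label in es.labels:
        corrected = [ep.signal - ep.signal[b] for ep in es.retained(label)]
        avg = np.mean(corrected, axis=0)
        amp = max(avg[i0 : i1 + 1])
        if amp > best_amp:
            best_label, best_amp = label, amp
    return best_label


class TestClassifiers:
    def _bump_set(self, target=3, n_labels=5, n_epochs=4, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        arrays = {}
        for label in range(1, n_labels + 1):
            base = rng.normal(0, noise, size=(n_epochs, 41))
            if label == target:
                base = base + _gauss_bump(10.0)
            arrays[label] = base
        return make_epochset(arrays, target_label=target)

    def test_label_with_bump_wins(self):
        es = self._bump_set()
        assert classify_single_baseline(es, -10.0, WIN) == 3
        assert classify_range_average(es, (-15.0, 0.0), WIN) == 3

    def test_identical_waveforms_tie_to_smallest_label(self, caplog):
        es = make_epochset({l: np.ones((2, 41)) for l in (2, 5, 7)}, target_label=5)
        with caplog.at_level("WARNING", logger="p300baseline.detect"):
            assert classify_single_baseline(es, -10.0, WIN) == 2
        assert any("tie" in r.message for r in caplog.records)

    @given(seed=st.integers(0, 2**16), t=st.integers(-18, 0))
    @settings(max_examples=30, deadline=None)
    def test_winner_matches_exhaustive_oracle(self, seed, t):
        es = self._bump_set(noise=3.0, seed=seed)
        got = classify_single_baseline(es, float(t), WIN)
        assert got == _toy_classify_oracle(es, float(t), WIN)

    def test_multi_point_votes_partition_the_grid(self):
        es = self._bump_set(noise=2.0, seed=5)
        spec = BaselineSpec.multi_point((-18.0, 0.0), 1.0)
        res = classify_multi_point(es, spec, WIN)
        assert sum(res.vote_counts.values()) == 18
        assert len(res.provisional_winners) == 18
        assert res.final_label == max(res.vote_counts, key=res.vote_counts.get)

    def test_single_point_grid_degenerates_to_single_classification(self):
        es = self._bump_set(noise=2.0, seed=8)
        spec = BaselineSpec.multi_point((-7.0, -6.0), 1.0)
        res = classify_multi_point(es, spec, WIN)
        assert res.final_label == classify_single_baseline(es, -7.0, WIN)
        assert res.vote_counts[res.final_label] == 1

    @given(offset=st.floats(-50.0, 50.0, allow_nan=False))
    @settings(max_examples=20, deadline=None)
    def test_constant_offset_never_changes_any_classification(self, offset):
        es = self._bump_set(noise=2.0, seed=2)
        shifted = make_epochset(
            {l: np.stack([ep.signal + offset for ep in es.of_label(l)]) for l in es.labels},
            target_label=es.target_label,
        )
        assert classify_single_baseline(es, -5.0, WIN) == \
            classify_single_baseline(shifted, -5.0, WIN)
        assert classify_range_average(es, (-15.0, 0.0), WIN) == \
            classify_range_average(shifted, (-15.0, 0.0), WIN)
        a = classify_multi_point(es, BaselineSpec.multi_point((-18.0, 0.0)), WIN)
        b = classify_multi_point(shifted, BaselineSpec.multi_point((-18.0, 0.0)), WIN)
        assert a.final_label == b.final_label

    def test_high_snr_synthetic_target_recovered(self, clean_epochs):
        res = classify_multi_point(clean_epochs, n_per_label="all")
        assert res.final_label == clean_epochs.target_label == 4
        assert classify_range_average(clean_epochs) == 4


class TestScoreCorrectness:
    def test_examples(self):
        acc, flags = score_correctness([(3, 3), (5, 5)])
        assert acc == 1.0 and flags == [True, True]
        acc, flags = score_correctness([(3, 5)])
        assert acc == 0.0 and flags == [False]

    def test_matches_hand_count(self):
        rng = np.random.default_rng(0)
        finals = rng.integers(1, 10, size=22)
        targets = rng.integers(1, 10, size=22)
        acc, flags = score_correctness(list(zip(finals, targets)))
        assert acc == sum(f == t for f, t in zip(finals, targets)) / 22
        assert acc == np.mean(flags)


class TestMonotoneSnrRecovery:
    def test_accuracy_does_not_degrade_with_more_averages(self):
        """On the packaged fixture cohort, n=100 accuracy >= n=10 accuracy
        for all three baseline methods."""
        cohort = generate_cohort(n_subjects=4, seed=0)
        methods = {
            "single": BaselineSpec.single_point(-100.0),
            "range": BaselineSpec.range_average((-200.0, 0.0)),
            "multi": BaselineSpec.multi_point(),
        }
        acc10 = cohort_accuracy(evaluate_cohort(cohort, methods, n_per_label=10))
        acc100 = cohort_accuracy(evaluate_cohort(cohort, methods, n_per_label=100))
        for m in methods:
            assert acc100[m] >= acc10[m]
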