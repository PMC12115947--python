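"""Baseline/window sweeps, ratio summaries and the Wilcoxon comparison."""

from __future__ import annotations

import itertools
from dataclasses import replace

import numpy as np
import pytest

from p300baseline import (
    BaselineSpec,
    DetectionWindow,
    NoiseModel,
    SessionSpec,
    classify_range_average,
    classify_single_baseline,
    compare_methods,
    generate_session,
    prepare_epochs,
    ratio_summary,
    sweep_range_end,
    sweep_range_start,
    sweep_single_point,
    sweep_window_width,
)
from p300baseline.exceptions import ParameterError
from tests.conftest import make_epochset

WIN = DetectionWindow(5.0, 15.0)


@pytest.fixture(scope="module")
def drift_pair():
    """Paired sessions, identical seed: 10 Hz rhythm only vs added slow drift.

    The drift's ~500 ms period exceeds the 200 ms baseline window — the
    regime in which fixed-width baseline ranges become unstable.
    """
    spec = SessionSpec()
    calm = NoiseModel()
    drifty = replace(calm, drift_amp_uv=15.0)
    rec_a, ev_a, _ = generate_session(spec, calm, seed=0)
    rec_b, ev_b, _ = generate_session(spec, drifty, seed=0)
    return prepare_epochs(rec_a, ev_a), prepare_epochs(rec_b, ev_b)


class TestSinglePointSweep:
    def test_default_grid_has_1000_points(self, clean_epochs):
        out = sweep_single_point(clean_epochs, n_list=("all",))
        sw = out["all"]
        assert len(sw.axis_ms) == 1000
        assert sw.axis_ms[0] == -1000.0 and sw.axis_ms[-1] == -1.0
        assert sw.amplitudes.shape == (1000, 9)

    def test_high_snr_accuracy_is_one_everywhere(self, clean_epochs):
        sw = sweep_single_point(clean_epochs, n_list=("all",))["all"]
        assert sw.accuracy == 1.0
        assert sw.correct.all()

    def test_single_point_grid_reduces_to_classifier(self, clean_epochs):
        sw = sweep_single_point(
            clean_epochs, t_range_ms=(-50.0, -49.0), n_list=(20,)
        )[20]
        assert len(sw.axis_ms) == 1
        winner = classify_single_baseline(clean_epochs, -50.0, n_per_label=20)
        assert sw.correct[0] == (winner == clean_epochs.target_label)


class TestRangeEndSweep:
    def test_k200_equals_range_average_classifier(self, clean_epochs):
        sw = sweep_range_end(clean_epochs, n_list=(20,))[20]
        k200 = np.flatnonzero(sw.axis_ms == -200.0)[0]
        winner = classify_range_average(clean_epochs, (-200.0, 0.0), n_per_label=20)
        assert sw.correct[k200] == (winner == clean_epochs.target_label)

    def test_one_ms_range_equals_single_point_at_minus_one(self, clean_epochs):
        end = sweep_range_end(clean_epochs, n_list=(20,))[20]
        point = sweep_single_point(clean_epochs, n_list=(20,))[20]
        k1 = np.flatnonzero(end.axis_ms == -1.0)[0]
        p1 = np.flatnonzero(point.axis_ms == -1.0)[0]
        np.testing.assert_allclose(end.amplitudes[k1], point.amplitudes[p1], atol=1e-12)

    def test_wide_ranges_erode_target_margin_on_drift_fixture(self, drift_pair):
        """With a >200 ms-period component present, widening the baseline
        range past 200 ms erodes the target's lead over the best competitor."""
        _, drifty = drift_pair
        sw = sweep_range_end(drifty, n_list=(40,))[40]
        margin = sw.target_amplitudes() - sw.best_nontarget_amplitudes()
        at = lambda k: margin[sw.axis_ms == -float(k)][0]
        assert at(200) > at(800)


class TestRangeStartSweep:
    def test_default_grid_has_31_starts(self, clean_epochs):
        res = sweep_range_start(clean_epochs, n_per_label="all")
        assert len(res.start_grid_ms) == 31
        assert res.start_grid_ms[0] == 0.0 and res.start_grid_ms[-1] == -300.0

    def test_constant_baseline_gives_zero_variation(self):
        sig = np.zeros(1501)
        sig[1320] = 4.0  # single spike at +320 ms
        mats = {l: np.tile(sig if l == 1 else np.zeros(1501), (2, 1)) for l in (1, 2)}
        es = make_epochset(mats, pre_ms=1000.0, post_ms=500.0, target_label=1)
        res = sweep_range_start(es)
        assert res.variation_uv == 0.0

    def test_drift_increases_peak_variation(self, drift_pair):
        """Sliding the 200 ms baseline window moves the measured target peak
        far more when a longer-period component is present."""
        calm, drifty = drift_pair
        v_calm = sweep_range_start(calm, n_per_label=100).variation_uv
        v_drift = sweep_range_start(drifty, n_per_label=100).variation_uv
        assert v_drift > v_calm


class TestWindowWidthSweep:
    def _bumpy_epochs(self):
        k = np.arange(1501) - 1000
        sig = 5.0 * np.exp(-0.5 * ((k - 330) / 20.0) ** 2)
        return make_epochset(
            {1: sig[None, :], 2: np.zeros((1, 1501))},
            pre_ms=1000.0, post_ms=500.0, target_label=1,
        )

    def test_narrow_window_misses_late_bump_wide_window_catches_it(self):
        res = sweep_window_width(self._bumpy_epochs())
        tmax = res.target_max()
        narrow = tmax[res.half_widths_ms == 10][0]   # 290-310 ms
        wide = tmax[res.half_widths_ms == 70][0]     # 230-370 ms
        assert narrow < 0.8 * 5.0
        assert wide == pytest.approx(5.0, rel=1e-6)

    def test_nested_windows_make_max_non_decreasing(self, clean_epochs):
        res = sweep_window_width(clean_epochs, baseline=BaselineSpec.range_average())
        assert (np.diff(res.max_amplitude, axis=0) >= -1e-12).all()

    def test_target_argmax_clusters_after_300ms(self, default_epochs):
        """Injected 330 ms bumps put the target's window maximum after 300 ms."""
        res = sweep_window_width(default_epochs, baseline=BaselineSpec.range_average())
        wide = res.half_widths_ms >= 50
        assert (res.target_argmax_ms()[wide] > 300.0).all()


def _two_label_sweep_source():
    a = np.zeros(41); a[30] = 4.0   # target peak 4 µV
    b = np.zeros(41); b[30] = 2.0   # best non-target 2 µV
    return make_epochset({1: a[None, :], 2: b[None, :]}, target_label=1)


class TestRatioSummary:
    def test_fifty_percent_example(self):
        sw = sweep_single_point(
            _two_label_sweep_source(), t_range_ms=(-10.0, -9.0), win=WIN,
            n_list=("all",),
        )["all"]
        rs = ratio_summary(sw)
        assert rs.ratios_pct.shape == (1, 1)
        assert rs.mean_pct[0] == pytest.approx(50.0)

    def test_ratio_below_100_iff_correct(self, clean_epochs):
        sw = sweep_single_point(clean_epochs, n_list=(20,))[20]
        rs = ratio_summary(sw)
        ratios = rs.ratios_pct[0]
        target = sw.target_amplitudes()
        ok = target > 0
        assert ok.any()
        np.testing.assert_array_equal(ratios[ok] < 100.0, sw.correct[ok])

    def test_cohort_envelope_orders_min_mean_max(self, clean_epochs):
        sw = sweep_single_point(clean_epochs, n_list=(10, 20))
        rs = ratio_summary([sw[10], sw[20]])
        assert rs.ratios_pct.shape[0] == 2
        assert (rs.min_pct <= rs.mean_pct + 1e-12).all()
        assert (rs.mean_pct <= rs.max_pct + 1e-12).all()


class TestCompareMethods:
    def test_identical_samples_reported_undefined(self):
        cmp = compare_methods({"a": [0.5, 0.6, 0.7], "b": [0.5, 0.6, 0.7]})
        (pair,) = cmp.pairs
        assert pair.undefined and np.isnan(pair.p)

    def test_unit_shift_pairs_give_w_zero_matching_enumeration(self):
        cmp = compare_methods({"a": [1, 2, 3, 4, 5], "b": [2, 3, 4, 5, 6]})
        (pair,) = cmp.pairs
        assert pair.w == 0.0
        # all |d| tied at mid-rank 3, so W+ takes values 3k; over the 2^5
        # equiprobable sign patterns P(W+ <= 0) = 1/32, two-sided p = 2/32
        assert pair.p == pytest.approx(2 / 32)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_p_matches_exact_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))
        x = rng.normal(size=n)
        y = rng.normal(size=n)
        cmp = compare_methods({"a": x, "b": y})
        (pair,) = cmp.pairs
        d = x - y
        from scipy.stats import rankdata

        ranks = rankdata(np.abs(d))
        wobs = ranks[d > 0].sum()
        dist = np.array(
            [
                sum(r for r, s in zip(ranks, signs) if s)
                for signs in itertools.product([False, True], repeat=n)
            ]
        )
        p_exact = min(1.0, 2 * min((dist <= wobs).mean(), (dist >= wobs).mean()))
        assert pair.p == pytest.approx(p_exact)
        assert 0.0 <= pair.r <= 1.0

    def test_holm_adjustment_is_monotone_over_three_pairs(self):
        rng = np.random.default_rng(5)
        data = {m: rng.uniform(0.3, 1.0, size=10) for m in ("single", "range", "multi")}
        cmp = compare_methods(data)
        assert len(cmp.pairs) == 3
        raw = [p.p for p in cmp.pairs]
        adj = [p.p_holm for p in cmp.pairs]
        order = np.argsort(raw)
        assert (np.diff(np.array(adj)[order]) >= -1e-12).all()
        assert all(a >= r for a, r in zip(adj, raw))

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ParameterError):
            compare_methods({"a": [1, 2], "b": [1, 2, 3]})
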