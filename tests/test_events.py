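"""Event detection, the thresholded average-magnitude statistic, summaries."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from nmspont.events import (
    AnalysisConfig,
    average_magnitude,
    compare_groups,
    detect_events,
    summarize,
)
from nmspont.model import EventParams
from nmspont.synthetic import render_trace, sample_event_train


class TestAverageMagnitude:
    def test_worked_example(self):
        dff = np.array([0, 0, 0.2, 0.3, 0, 0, 0, 0, 0, 0])
        assert average_magnitude(dff, 0.10) == pytest.approx(0.05)

    def test_all_subthreshold_is_zero(self):
        assert average_magnitude(np.full(50, 0.05), 0.10) == 0.0

    def test_boundary_is_strict(self):
        assert average_magnitude(np.full(10, 0.10), 0.10) == 0.0

    def test_empty_trace_rejected(self):
        with pytest.raises(ValueError):
            average_magnitude(np.array([]), 0.10)

    @given(
        st.lists(st.floats(0, 1), min_size=1, max_size=50),
        st.lists(st.floats(0, 0.5), min_size=50, max_size=50),
    )
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_pointwise_increase(self, values, bumps):
        dff = np.array(values)
        bumped = dff + np.array(bumps[: len(dff)])
        assert average_magnitude(bumped) >= average_magnitude(dff)


def brute_force_peaks(x, height, prominence):
    """Oracle: all strict local maxima, then height and prominence filters."""
    out = []
    for p in range(1, len(x) - 1):
        if not (x[p - 1] < x[p] > x[p + 1]):
            continue
        if x[p] < height:
            continue
        # left base: minimum back to the previous sample higher than x[p]
        lmin = x[p]
        i = p - 1
        while i >= 0 and x[i] <= x[p]:
            lmin = min(lmin, x[i])
            i -= 1
        rmin = x[p]
        i = p + 1
        while i < len(x) and x[i] <= x[p]:
            rmin = min(rmin, x[i])
            i += 1
        if x[p] - max(lmin, rmin) >= prominence:
            out.append(p)
    return out


class TestDetectEvents:
    def test_flat_trace_empty_table(self):
        ev = detect_events(np.zeros(100), AnalysisConfig(), 3.0)
        assert len(ev) == 0

    def test_matches_brute_force_oracle(self, rng):
        cfg = AnalysisConfig(min_peak_distance_s=0.5)  # 1 frame at dt=0.5
        for _ in range(1000):
            n = int(rng.integers(20, 80))
            x = np.convolve(rng.normal(0, 0.15, n), np.ones(3) / 3, "same")
            x = np.abs(x) + rng.normal(0, 1e-6, n)
            ev = detect_events(x, cfg, 0.5)
            expected = brute_force_peaks(x, cfg.threshold_dff,
                                         cfg.min_prominence_dff)
            assert list(ev.peak_frame) == expected
            np.testing.assert_allclose(
                np.asarray(ev.peak_magnitude_dff, float), x[expected]
            )

    def test_single_transient_recovers_magnitude_and_duration(self):
        p = EventParams(0.001, 0.8, 14.22, noise_sd_dff=0.0)
        tr = render_trace(np.array([100.0]), p, 0.5, 400.0,
                          np.random.default_rng(0))
        dff = (tr.F - p.baseline_f) / p.baseline_f
        ev = detect_events(dff, AnalysisConfig(), 0.5)
        assert len(ev) == 1
        assert ev.peak_magnitude_dff[0] == pytest.approx(0.8, abs=0.05)
        assert ev.duration_s[0] == pytest.approx(14.22, abs=0.5)

    def test_two_separated_transients_in_order(self):
        p = EventParams(0.001, 0.8, 14.22, noise_sd_dff=0.0)
        tr = render_trace(np.array([60.0, 200.0]), p, 1.0, 400.0,
                          np.random.default_rng(0))
        dff = (tr.F - p.baseline_f) / p.baseline_f
        ev = detect_events(dff, AnalysisConfig(), 1.0)
        assert len(ev) == 2
        assert ev.peak_time_s.is_monotonic_increasing

    def test_merged_events_split_at_trough(self):
        dff = np.array([0.0, 0.5, 0.3, 0.6, 0.0])
        cfg = AnalysisConfig(min_peak_distance_s=1.0)
        ev = detect_events(dff, cfg, 1.0)
        assert list(ev.peak_frame) == [1, 3]
        # shared above-threshold segment [1, 4) split at the trough (2)
        assert list(ev.start_frame) == [1, 2]
        assert list(ev.end_frame) == [2, 4]
        assert ev.duration_s.sum() == pytest.approx(3.0)

    def test_event_parameter_recovery(self):
        """Detector recovery of the generative rate, amplitude, duration.

        100 independent cells at 0.5 s sampling, ΔF/F0 against the true
        baseline: frequency within 10% of λ, mean peak within 5% of A,
        mean duration within one frame interval of D.
        """
        p = EventParams(0.012, 0.8, 14.22, noise_sd_dff=0.01)
        rng = np.random.default_rng(7)
        freqs, peaks, durs = [], [], []
        for _ in range(100):
            events = sample_event_train(p.rate_per_s, 900.0, rng)
            tr = render_trace(events, p, 0.5, 900.0, rng)
            dff = (tr.F - p.baseline_f) / p.baseline_f
            ev = detect_events(dff, AnalysisConfig(), 0.5)
            freqs.append(len(ev) / 900.0)
            if len(ev):
                peaks.append(ev.peak_magnitude_dff.mean())
                durs.append(ev.duration_s.mean())
        assert np.mean(freqs) == pytest.approx(0.012, rel=0.10)
        assert np.mean(peaks) == pytest.approx(0.8, rel=0.05)
        assert np.mean(durs) == pytest.approx(14.22, abs=0.5)


class TestSummarize:
    def _events(self, rows):
        from nmspont.events import EVENT_COLUMNS

        return pd.DataFrame(rows, columns=EVENT_COLUMNS)

    def test_frequency_arithmetic(self):
        rows = [
            ("nm1", "c1", "soma", i, i * 3.0, 0.5, 12.0, i, i + 4)
            for i in range(9)
        ]
        dffs = {("nm1", "c1", "soma"): np.zeros(300)}
        per_roi, per_nm = summarize(self._events(rows), dffs, 900.0)
        assert per_roi.frequency_per_s[0] == pytest.approx(0.01)

    def test_neuromast_mean_of_roi_values(self):
        dffs = {
            ("nm1", "c1", "soma"): np.array([0.0, 0.2, 0.0, 0.2, 0.0]),
            ("nm1", "c2", "soma"): np.array([0.0, 0.4, 0.4, 0.0, 0.0]),
        }
        per_roi, per_nm = summarize(self._events([]), dffs, 15.0)
        assert per_roi.average_magnitude.tolist() == pytest.approx([0.08, 0.16])
        assert per_nm.average_magnitude[0] == pytest.approx(0.12)

    def test_zero_event_roi_counts_in_frequency_not_duration(self):
        rows = [("nm1", "c1", "soma", 5, 15.0, 0.5, 12.0, 3, 8)]
        dffs = {
            ("nm1", "c1", "soma"): np.zeros(300),
            ("nm1", "c2", "soma"): np.zeros(300),
        }
        per_roi, per_nm = summarize(self._events(rows), dffs, 900.0)
        silent = per_roi[per_roi.cell_id == "c2"].iloc[0]
        assert silent.frequency_per_s == 0.0
        assert np.isnan(silent.mean_duration_s)
        # neuromast duration averages only the active ROI
        assert per_nm.mean_duration_s[0] == pytest.approx(12.0)
        assert per_nm.frequency_per_s[0] == pytest.approx(0.5 / 900.0)

    def test_invalid_recording_rejected(self):
        with pytest.raises(ValueError):
            summarize(self._events([]), {}, 0.0)


class TestCompareGroups:
    def test_identical_groups_null(self):
        g = [1.0, 2.0, 3.0, 4.0]
        res = compare_groups(g, g)
        assert res.statistic == 0.0 and res.pvalue == 1.0

    def test_large_shift_is_significant(self, rng):
        a = rng.normal(0, 1, 10)
        res = compare_groups(a, a + 50.0)
        assert res.pvalue < 0.001
        assert "t-test" in res.test

    def test_degenerate_variance_takes_rank_path(self):
        with pytest.warns(UserWarning, match="zero-variance"):
            res = compare_groups([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert "t-test" not in res.test

    def test_insufficient_n_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([1.0, 2.0], [1.0, 2.0, 3.0])

    def test_paired_needs_equal_lengths(self):
        with pytest.raises(ValueError):
            compare_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0, 4.0], paired=True)
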