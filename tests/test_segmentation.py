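"""Pulse, IPI, histogram and bout segmentation of VeDBA series."""
import numpy as np
import pytest

from conftest import ipi_bin_oracle, segmentation_oracle
from nestescape.body_acceleration import DbaSeries
from nestescape.errors import DataError
from nestescape.segmentation import (
    IPI_BIN_LABELS,
    PulseSeries,
    bin_ipis,
    detect_bouts,
    detect_pulses,
    inter_pulse_intervals,
    summarize_segments,
    threshold_sensitivity,
)


def vedba_series(values, t=None, period=1.0):
    """A DbaSeries whose VeDBA equals ``values`` (z carries the signal)."""
    values = np.asarray(values, float)
    t = np.arange(values.size) * period if t is None else np.asarray(t, float)
    zeros = np.zeros_like(values)
    d = DbaSeries(timestamps=t, sa_x=zeros, sa_y=zeros, sa_z=zeros,
                  dba_x=zeros, dba_y=zeros, dba_z=values,
                  window_s=3.0, sample_period=period)
    d.vedba = values
    return d


def pulses_at(times, period=1.0, seg=None):
    times = np.asarray(times, float)
    return PulseSeries(
        animal_id="t", times=times,
        segment_ids=np.zeros(times.size, int) if seg is None else np.asarray(seg),
        noise_threshold=0.035, analysis_start=float(times.min(initial=0.0)),
        analysis_end=float(times.max(initial=0.0) + period),
        sample_period=period, n_window_samples=times.size,
    )


class TestDetectPulses:
    def test_hand_enumeration(self):
        d = vedba_series([0.01, 0.05, 0.04, 0.01, 0.06])
        p = detect_pulses(d, 0.035)
        assert p.times.tolist() == [1, 2, 4]

    def test_all_subthreshold_is_flagged_not_error(self):
        p = detect_pulses(vedba_series([0.01, 0.02, 0.03]), 0.035)
        assert p.is_empty

    def test_threshold_zero_keeps_everything(self):
        p = detect_pulses(vedba_series([0.01, 0.02, 0.03]), 0.0)
        assert p.n_pulses == 3

    def test_boundary_value_is_inactive(self):
        p = detect_pulses(vedba_series([0.035, 0.0351]), 0.035)
        assert p.times.tolist() == [1]  # strictly above only

    def test_window_restriction_and_empty_window(self):
        d = vedba_series(np.full(10, 0.1))
        p = detect_pulses(d, 0.035, analysis_start=3, analysis_end=7)
        assert p.times.tolist() == [3, 4, 5, 6]
        with pytest.raises(DataError):
            detect_pulses(d, 0.035, analysis_start=100, analysis_end=200)


class TestIpis:
    def test_single_gap(self):
        ipis = inter_pulse_intervals(pulses_at([1, 2, 4]))
        assert len(ipis) == 1
        r = ipis[0]
        assert (r.start, r.end, r.duration) == (2, 4, 2)

    def test_consecutive_pulses_no_ipi(self):
        assert inter_pulse_intervals(pulses_at([0, 1, 2, 3])) == []

    def test_hour_long_gap(self):
        ipis = inter_pulse_intervals(pulses_at([0, 3600]))
        assert ipis[0].duration == 3600

    def test_no_ipi_across_recording_gap(self):
        ipis = inter_pulse_intervals(pulses_at([0, 1, 50, 51], seg=[0, 0, 1, 1]))
        assert ipis == []

    def test_fewer_than_two_pulses(self):
        assert inter_pulse_intervals(pulses_at([5.0])) == []


class TestBinning:
    def test_single_short_ipi(self):
        h = bin_ipis(inter_pulse_intervals(pulses_at([0, 45])))
        assert h.counts[0] == 1
        assert h.proportions[0] == 1.0

    @pytest.mark.parametrize(
        "duration,bin_idx",
        [(2, 0), (60, 0), (61, 1), (600, 1), (601, 2), (1800, 2), (3600, 3),
         (5400, 4), (7200, 5), (9000, 6), (10800, 7), (10801, 8), (86400, 8)],
    )
    def test_right_closed_edges(self, duration, bin_idx):
        h = bin_ipis(inter_pulse_intervals(pulses_at([0, duration])))
        assert h.counts[bin_idx] == 1
        assert ipi_bin_oracle(duration) == bin_idx

    def test_mixed_durations_time_shares(self):
        h = bin_ipis(inter_pulse_intervals(pulses_at([0, 30, 30 + 7200])))
        assert h.counts.tolist() == [1, 0, 0, 0, 0, 1, 0, 0, 0]
        assert h.proportions[0] == pytest.approx(30 / 7230)
        assert h.proportions[5] == pytest.approx(7200 / 7230)
        assert h.proportions.sum() == pytest.approx(1.0, abs=1e-9)

    def test_normalise_by_analysis_time(self):
        h = bin_ipis(inter_pulse_intervals(pulses_at([0, 30])), total_time_s=300)
        assert h.proportions[0] == pytest.approx(0.1)

    def test_empty_histogram(self):
        h = bin_ipis([])
        assert h.n_ipis == 0
        assert h.proportions.sum() == 0


class TestBouts:
    def test_merge_within_one_minute(self):
        p = pulses_at(np.r_[np.arange(0, 6), np.arange(35, 41)])
        bouts = detect_bouts(p, 60)
        assert len(bouts) == 1
        assert bouts[0].duration == 41
        assert bouts[0].n_pulses == 12

    def test_small_threshold_splits(self):
        p = pulses_at(np.r_[np.arange(0, 6), np.arange(35, 41)])
        bouts = detect_bouts(p, 10)
        assert [b.duration for b in bouts] == [6, 6]

    def test_single_pulse_has_one_sample_duration(self):
        bouts = detect_bouts(pulses_at([7.0]), 60)
        assert bouts[0].duration == 1.0
        assert bouts[0].n_pulses == 1

    def test_gap_exactly_at_threshold_merges(self):
        bouts = detect_bouts(pulses_at([0, 60]), 60)
        assert len(bouts) == 1

    def test_bouts_never_span_recording_gap(self):
        p = pulses_at([0, 1, 5, 6], seg=[0, 0, 1, 1])
        assert len(detect_bouts(p, 600)) == 2


class TestSummaries:
    def test_median_and_max(self):
        p = pulses_at([0, 100, 101, 102, 103, 300])
        bouts = {60.0: detect_bouts(pulses_at([0, 5, 10, 200, 205, 600]), 60.0)}
        df = summarize_segments(inter_pulse_intervals(p), bouts, "a")
        ipi_row = df[df["quantity"] == "ipi"].iloc[0]
        assert ipi_row["median_s"] == pytest.approx((100 + 197) / 2)  # midpoint rule
        assert ipi_row["max_s"] == 197

    def test_even_count_midpoint(self):
        p = pulses_at([0, 4, 12])  # gaps 4 and 8
        df = summarize_segments(inter_pulse_intervals(p), {}, "a")
        assert df.iloc[0]["median_s"] == 6


class TestSensitivity:
    def test_pulse_count_monotone_in_threshold(self, rng):
        d = vedba_series(rng.exponential(0.03, 400))
        res = threshold_sensitivity(d, (0.02, 0.04, 0.06))
        assert res.monotone
        counts = [res.pulse_counts[t] for t in sorted(res.pulse_counts)]
        assert counts == sorted(counts, reverse=True)

    def test_threshold_above_max_gives_zero(self):
        d = vedba_series([0.01, 0.02])
        res = threshold_sensitivity(d, (5.0,))
        assert res.pulse_counts[5.0] == 0


class TestOracleEquivalence:
    def test_random_series_match_loop_oracle(self, rng):
        """Vectorised segmentation equals the explicit single-pass loop."""
        for _ in range(100):
            n = int(rng.integers(50, 400))
            v = rng.exponential(0.03, n)
            t = np.arange(n, dtype=float)
            if rng.random() < 0.5:  # inject a recording gap
                t[n // 2:] += rng.integers(2, 50)
            d = vedba_series(v, t=t)
            for thr in (0.025, 0.035, 0.055):
                for merge in (10.0, 60.0):
                    p = detect_pulses(d, thr)
                    ipis = inter_pulse_intervals(p)
                    bouts = detect_bouts(p, merge)
                    ot, oi, ob = segmentation_oracle(t, v, thr, merge, 1.0)
                    assert p.times.tolist() == ot
                    assert [(r.start, r.end, r.duration) for r in ipis] == oi
                    assert [
                        (b.start, b.end, b.duration, b.n_pulses) for b in bouts
                    ] == ob

    def test_bout_pulse_conservation_and_merge_monotonicity(self, rng):
        for _ in range(30):
            v = rng.exponential(0.03, 500)
            p = detect_pulses(vedba_series(v), 0.035)
            if p.is_empty:
                continue
            prev_nb, prev_max = None, None
            for merge in (10.0, 60.0, 300.0, 600.0):
                bouts = detect_bouts(p, merge)
                assert sum(b.n_pulses for b in bouts) == p.n_pulses
                nb = len(bouts)
                mx = max(b.duration for b in bouts)
                if prev_nb is not None:
                    assert nb <= prev_nb
                    assert mx >= prev_max
                prev_nb, prev_max = nb, mx


def test_ipi_duration_convention_flag():
    """Optional gap-minus-one-sample IPI duration convention."""
    p = pulses_at([0, 10])
    raw = inter_pulse_intervals(p)[0].duration
    strict = inter_pulse_intervals(p, subtract_sample_period=True)[0].duration
    assert raw == 10 and strict == 9
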