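"""Synthetic-trace generator: determinism, calibration and recoverability."""
import numpy as np
import pytest

from nestescape.body_acceleration import compute_dba, mean_axis_dba
from nestescape.orientation import (
    ALL_LABELS,
    classify_codes,
    detect_headup_onset,
    orientation_budget,
)
from nestescape.segmentation import detect_pulses, inter_pulse_intervals
from nestescape.simulate import (
    IPI_MIXTURE_LAW,
    SimulationConfig,
    build_schedule,
    ipi_law_median,
    pulse_match_scores,
    simulate_buried_noise,
    simulate_crawl_trace,
    simulate_emergence_trace,
    simulate_rotation_trace,
    true_orientation_proportions,
)


class TestDeterminism:
    def test_identical_config_identical_output(self):
        cfg = SimulationConfig(seed=7, duration_h=4.0)
        t1, g1 = simulate_emergence_trace(cfg)
        t2, g2 = simulate_emergence_trace(SimulationConfig(seed=7, duration_h=4.0))
        assert np.array_equal(t1.x, t2.x)
        assert np.array_equal(t1.z, t2.z)
        assert np.array_equal(g1.pulse_times, g2.pulse_times)
        assert g1.headup_onset_s == g2.headup_onset_s

    def test_seed_changes_output(self):
        t1, _ = simulate_emergence_trace(SimulationConfig(seed=1, duration_h=2.0))
        t2, _ = simulate_emergence_trace(SimulationConfig(seed=2, duration_h=2.0))
        assert not np.array_equal(t1.z, t2.z)


class TestNoiseFloor:
    def test_calibrated_sd_stays_below_noise_bound(self):
        d = compute_dba(simulate_buried_noise(1.0, seed=3))
        assert np.percentile(d.vedba, 99) < 0.02

    def test_zero_sd_gives_zero_vedba(self):
        d = compute_dba(simulate_buried_noise(0.1, noise_sd=0.0, seed=0))
        assert np.allclose(d.vedba, 0.0, atol=1e-12)

    def test_mean_vedba_scales_linearly_with_sd(self):
        d1 = compute_dba(simulate_buried_noise(1.0, noise_sd=0.004, seed=5))
        d2 = compute_dba(simulate_buried_noise(1.0, noise_sd=0.008, seed=5))
        assert d2.vedba.mean() / d1.vedba.mean() == pytest.approx(2.0, rel=0.05)


class TestRotationTrace:
    def test_visits_all_six_poles(self):
        tr = simulate_rotation_trace()
        codes = classify_codes(tr.x, tr.y, tr.z)
        seen = {ALL_LABELS[c] for c in codes}
        assert set(ALL_LABELS[:6]) <= seen

    def test_plateaus_are_static(self):
        tr = simulate_rotation_trace(noise_sd=0.0)
        d = compute_dba(tr)
        # movement only during the 10-s transitions between poles
        active = np.mean(d.vedba > 0.035)
        assert active < 9 * 10 / d.n + 0.01

    def test_unit_gravity_norm(self):
        tr = simulate_rotation_trace(noise_sd=0.0)
        norm = np.sqrt(tr.x**2 + tr.y**2 + tr.z**2)
        assert np.all(norm < 1 + 1e-6)
        assert np.median(norm) == pytest.approx(1.0, abs=1e-6)


class TestCrawlTrace:
    def test_carapace_up_budget(self):
        tr = simulate_crawl_trace(seed=2)
        assert orientation_budget(tr).proportions["carapace_up"] == 1.0

    def test_pitch_roll_balance_distinct_from_digging(self):
        def active_axis_means(trace):
            d = compute_dba(trace)
            sel = d.vedba > 0.035  # compare movement, not the noise floor
            out = {}
            for ax in ("x", "y", "z"):
                out[ax] = float(np.abs(getattr(d, f"dba_{ax}")[sel]).mean())
            return out

        crawl = active_axis_means(simulate_crawl_trace(seed=2))
        assert 0.8 < crawl["x"] / crawl["y"] < 1.25
        dig_tr, _ = simulate_emergence_trace(SimulationConfig(seed=4, duration_h=6.0))
        dig = active_axis_means(dig_tr)
        assert dig["z"] > dig["y"] > dig["x"]  # heave-dominant digging
        # the crawl signature has far more relative x (pitch) content
        assert crawl["x"] / crawl["y"] > 2 * dig["x"] / dig["y"]


@pytest.fixture(scope="module")
def sim():
    cfg = SimulationConfig(seed=11, duration_h=12.0)
    return cfg, *simulate_emergence_trace(cfg)


class TestEmergenceTrace:
    def test_schedule_fractions_recovered(self, sim):
        cfg, trace, truth = sim
        est = orientation_budget(trace).proportions
        want = true_orientation_proportions(truth)
        for lab in ALL_LABELS:
            assert est[lab] == pytest.approx(want[lab], abs=0.02)

    def test_onset_recovered_within_five_seconds(self, sim):
        cfg, trace, truth = sim
        detected = detect_headup_onset(trace)
        assert abs(detected - truth.headup_onset_s) <= 5.0

    def test_pulse_set_recovered(self, sim):
        cfg, trace, truth = sim
        d = compute_dba(trace)
        p = detect_pulses(d, 0.035, truth.headup_onset_s, cfg.emergence_time)
        sens, prec = pulse_match_scores(truth.pulse_times, p.times)
        assert sens >= 0.95 and prec >= 0.95

    def test_truth_pulses_consistent_with_bouts(self, sim):
        cfg, trace, truth = sim
        assert truth.pulse_times.size == sum(n for _, _, n in truth.bouts)
        assert len(truth.ipis) == len(truth.bouts) - 1

    def test_no_activity_when_bout_law_disabled(self):
        cfg = SimulationConfig(seed=1, duration_h=2.0, bout_law=None)
        trace, truth = simulate_emergence_trace(cfg)
        assert truth.pulse_times.size == 0
        d = compute_dba(trace)
        onset = truth.headup_onset_s
        quiet = d.vedba[d.timestamps >= onset]
        assert np.mean(quiet > 0.035) < 0.001

    def test_night_gain_elevates_final_night_blocks(self):
        from nestescape.diel import block_means

        cfg = SimulationConfig(seed=9, duration_h=60.0, diel_night_gain=3.0,
                               orientation_schedule=(("head_up", 60 * 3600.0),))
        trace, truth = simulate_emergence_trace(cfg)
        d = compute_dba(trace)
        last = d.timestamps >= cfg.emergence_time - 86400
        cells = block_means(
            d.timestamps[last], d.vedba[last], cfg.clock_offset_s
        ).set_index("block")["mean_vedba"]
        night_blocks, day_blocks = ["20-24", "00-04"], ["04-08", "08-12", "12-16", "16-20"]
        assert cells[night_blocks].min() > cells[day_blocks].max()


class TestIpiLaw:
    def test_lognormal_median_closed_form(self):
        assert ipi_law_median({"kind": "lognormal", "median_s": 420.0, "sigma": 1.3}) == 420.0

    def test_mixture_median_matches_sampling(self):
        law = IPI_MIXTURE_LAW
        med = ipi_law_median(law)
        rng = np.random.default_rng(0)
        short = rng.lognormal(np.log(law["median_short_s"]), law["sigma_short"], 200000)
        long = rng.lognormal(np.log(law["median_long_s"]), law["sigma_long"], 200000)
        pick = rng.random(200000) < law["w_short"]
        sample = np.where(pick, short, long)
        assert med == pytest.approx(np.median(sample), rel=0.05)

    def test_default_law_is_skewed_with_long_tails(self):
        cfg = SimulationConfig()
        law = cfg.ipi_law
        assert ipi_law_median(law) == 420.0
        rng = np.random.default_rng(1)
        draws = rng.lognormal(np.log(law["median_s"]), law["sigma"], 100000)
        assert np.mean(draws > 3 * 3600) < 0.02  # rare multi-hour rests
        assert np.mean(draws < 60) > 0.03        # short intervals present


class TestSchedule:
    def test_default_fractions_sum_and_order(self):
        sched = build_schedule(72 * 3600.0)
        assert sum(d for _, d in sched) == 72 * 3600.0
        assert sched[0][0] == "carapace_up"
        assert sched[-1][0] == "head_up"
        assert sched[-1][1] == pytest.approx(0.67 * 72 * 3600.0, rel=0.01)
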