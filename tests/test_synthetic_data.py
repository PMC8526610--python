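"""Generator correctness: schedules, thinning, suppression, audio truth."""

import math

import numpy as np
import pytest
from scipy import stats

from railbat.event_processing import build_gaps
from railbat.interval_analysis import make_intervals
from railbat.synthetic_data import (SiteConfig, SuppressionConfig,
                                    TrainScheduleConfig, _merge_windows,
                                    generate_bat_events,
                                    generate_calibration_audio,
                                    generate_train_schedule,
                                    suppression_windows)


def _window_occupancy(ev, sch, tau, horizon):
    """(events inside windows, merged window time) for one night."""
    win = suppression_windows(sch, tau)
    if win.size == 0:
        return 0, 0.0
    win = _merge_windows(win)
    mask = np.zeros(ev.size, dtype=bool)
    dur = 0.0
    for a, b in win:
        b = min(b, horizon)
        mask |= (ev >= a) & (ev < b)
        dur += max(b - a, 0.0)
    return int(mask.sum()), dur


class TestTrainSchedule:
    def test_zero_rate_is_empty(self):
        cfg = SiteConfig(trains_per_hour=0.0)
        assert generate_train_schedule(cfg, seed=0) == []

    def test_mean_count_matches_rate(self):
        """Poisson arrivals: mean count over many seeds within 3 SE of rate."""
        cfg = SiteConfig(trains_per_hour=6.0, recording_duration=3600.0)
        counts = [len(generate_train_schedule(cfg, seed=s)) for s in range(1000)]
        se = np.std(counts) / math.sqrt(len(counts))
        assert abs(np.mean(counts) - 6.0) < 3 * se + 0.05

    def test_pass_physics_consistent(self):
        cfg = SiteConfig(trains_per_hour=10.0)
        for p in generate_train_schedule(cfg, seed=3):
            assert p.length_m == pytest.approx(p.n_cars * 21.0)
            assert p.end_s - p.start_s == pytest.approx(p.length_m / (p.speed_kmh / 3.6))

    def test_twelve_cars_is_252_m(self):
        tcfg = TrainScheduleConfig(car_count_range=(12, 12))
        cfg = SiteConfig(trains_per_hour=10.0)
        sch = generate_train_schedule(cfg, tcfg, seed=1)
        assert all(p.length_m == pytest.approx(252.0) for p in sch)

    def test_sorted_nonoverlapping_output(self):
        cfg = SiteConfig(trains_per_hour=19.3)
        sch = generate_train_schedule(cfg, seed=11)
        starts = [p.start_s for p in sch]
        assert starts == sorted(starts)
        for a, b in zip(sch, sch[1:]):
            if not (a.overlap or b.overlap):
                assert b.start_s >= a.end_s

    def test_impossible_rate_rejected(self):
        cfg = SiteConfig(trains_per_hour=2000.0)
        with pytest.raises(ValueError, match="occupancy"):
            generate_train_schedule(cfg, seed=0)

    def test_same_seed_bit_identical(self):
        cfg = SiteConfig(trains_per_hour=8.0)
        a = generate_train_schedule(cfg, seed=9)
        b = generate_train_schedule(cfg, seed=9)
        assert [(p.start_s, p.end_s, p.track, p.n_cars) for p in a] == \
               [(p.start_s, p.end_s, p.track, p.n_cars) for p in b]


class TestBatEvents:
    def test_zero_baseline_no_events(self, quiet_sup):
        cfg = SiteConfig(baseline_rate=0.0)
        assert generate_bat_events([], cfg, quiet_sup, seed=0).size == 0

    def test_same_seed_bit_identical(self, site_cfg):
        sch = generate_train_schedule(site_cfg, seed=5)
        a = generate_bat_events(sch, site_cfg, seed=6)
        b = generate_bat_events(sch, site_cfg, seed=6)
        assert np.array_equal(a, b)

    def test_interevent_times_exponential_without_suppression(self):
        """Thinning correctness: constant rate, Poisson stream -> Exp gaps."""
        cfg = SiteConfig(baseline_rate=120.0, time_trend=0.0, site_effect_sd=0.0,
                         recording_duration=36000.0)
        sup = SuppressionConfig(factor_s=1.0, dispersion_theta=float("inf"))
        gaps = []
        for seed in range(5):
            ev = generate_bat_events([], cfg, sup, seed=seed, site_effect=0.0)
            gaps.append(np.diff(ev))
        gaps = np.concatenate(gaps)
        stat = stats.kstest(gaps, "expon", args=(0, 3600.0 / 120.0))
        assert stat.pvalue > 0.01

    def test_no_suppression_rates_equal(self, site_cfg):
        """factor_s = 1: post-train windows show the baseline rate."""
        sup = SuppressionConfig(factor_s=1.0, duration_tau=120.0,
                                dispersion_theta=float("inf"))
        cfg = SiteConfig(baseline_rate=200.0, time_trend=0.0, site_effect_sd=0.0)
        inside = outside = t_in = t_out = 0.0
        for seed in range(40):
            sch = generate_train_schedule(cfg, seed=seed)
            ev = generate_bat_events(sch, cfg, sup, seed=1000 + seed, site_effect=0.0)
            n_in, dur = _window_occupancy(ev, sch, sup.duration_tau,
                                          cfg.recording_duration)
            inside += n_in; t_in += dur
            outside += ev.size - n_in; t_out += cfg.recording_duration - dur
        ratio = (inside / t_in) / (outside / t_out)
        assert ratio == pytest.approx(1.0, abs=0.05)

    def test_suppression_halves_post_train_rate(self):
        """factor 0.5 for 120 s: post-train rate is half the ambient rate."""
        cfg = SiteConfig(baseline_rate=60.0, time_trend=0.0, site_effect_sd=0.0,
                         trains_per_hour=6.0)
        sup = SuppressionConfig(factor_s=0.5, duration_tau=120.0,
                                dispersion_theta=float("inf"))
        inside = outside = t_in = t_out = 0.0
        for seed in range(500):
            sch = generate_train_schedule(cfg, seed=seed)
            ev = generate_bat_events(sch, cfg, sup, seed=7000 + seed, site_effect=0.0)
            n_in, dur = _window_occupancy(ev, sch, sup.duration_tau,
                                          cfg.recording_duration)
            inside += n_in; t_in += dur
            outside += ev.size - n_in; t_out += cfg.recording_duration - dur
        ratio = (inside / t_in) / (outside / t_out)
        assert ratio == pytest.approx(0.5, abs=0.05)

    @pytest.mark.parametrize("s,tau", [(0.3, 30.0), (0.5, 120.0), (0.8, 480.0)])
    def test_suppression_round_trip_irr(self, s, tau):
        """Downstream after-vs-between rate ratio recovers the factor.

        Only gaps long enough that the between interval clears the
        suppression window (gap >= 2 tau + d) identify the factor cleanly;
        the train rate is adapted so such gaps are common.
        """
        d = 30.0
        rate = 6.0 if tau <= 120 else 1.7
        cfg = SiteConfig(baseline_rate=120.0, time_trend=0.0, site_effect_sd=0.0,
                         trains_per_hour=rate)
        sup = SuppressionConfig(factor_s=s, duration_tau=tau,
                                dispersion_theta=float("inf"))
        n_after = n_between = 0
        for seed in range(120):
            sch = generate_train_schedule(cfg, seed=seed)
            ev = generate_bat_events(sch, cfg, sup, seed=5000 + seed, site_effect=0.0)
            for gap in build_gaps(sch, (0, cfg.recording_duration)):
                if gap.duration_s < 2 * tau + d:
                    continue
                for iv in make_intervals(gap, d):
                    c = int(np.sum((ev >= iv.start_s) & (ev < iv.end_s)))
                    if iv.category == "after":
                        n_after += c
                    elif iv.category == "between":
                        n_between += c
        assert n_between > 200, "simulation too small to resolve the ratio"
        ratio = n_after / n_between
        se = ratio * math.sqrt(1 / n_after + 1 / n_between)
        assert abs(ratio - s) < 3 * se + 0.02


class TestCalibrationAudio:
    def test_no_passes_tone_then_silence(self):
        wav, truth = generate_calibration_audio(passes=[], sample_rate=8000.0,
                                                tone_duration_s=2.0)
        assert truth.empty
        n_tone = int(2.0 * 8000)
        assert np.max(np.abs(wav[:n_tone])) > 0
        assert np.allclose(wav[n_tone + 100:], 0.0)

    def test_low_sample_rate_rejected(self):
        with pytest.raises(ValueError, match="sample_rate"):
            generate_calibration_audio(tone_freq=1000.0, sample_rate=3000.0)

    def test_clipping_is_an_error(self):
        from railbat.event_processing import TrainPass
        with pytest.raises(ValueError, match="clip"):
            generate_calibration_audio(
                passes=[TrainPass(start_s=15, end_s=20)], peak_spl=150.0,
                sample_rate=8000.0, gain=0.05)

    def test_ground_truth_rows_match_passes(self):
        from railbat.event_processing import TrainPass
        passes = [TrainPass(start_s=15, end_s=20), TrainPass(start_s=40, end_s=44)]
        wav, truth = generate_calibration_audio(passes=passes, peak_spl=[100.0, 95.0],
                                                sample_rate=8000.0)
        assert list(truth["true_peak_spl_db"]) == [100.0, 95.0]
        assert len(wav) >= int(50 * 8000)
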