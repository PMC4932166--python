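"""sEMG calibration, episode extraction and channel-pattern classification."""

import numpy as np
import pytest

from eogsemg import (GenConfig, EventSpec, make_schedule, synthesize,
                     calibrate_thresholds, extract_episodes, classify_episode,
                     EmgEpisode, PreprocessConfig, UserCalibration)
from eogsemg.emg_patterns import emg_envelope, _peak_in
from eogsemg.errors import CalibrationError, InvalidEpisodeError
from conftest import make_calibration


class TestClassifyEpisode:
    @pytest.mark.parametrize("ch5,ch6,label", [
        (True, False, "right_blink"),
        (False, True, "left_blink"),
        (True, True, "bite"),
    ])
    def test_channel_pattern_rule(self, ch5, ch6, label):
        ep = EmgEpisode(1.0, 1.3, ch5, ch6, 1.0, 1.0)
        assert classify_episode(ep) == label

    def test_inactive_episode_rejected(self):
        with pytest.raises(InvalidEpisodeError):
            EmgEpisode(1.0, 1.3, False, False, 0.0, 0.0)


class TestCalibration:
    def test_thresholds_sit_between_normal_and_voluntary_peaks(self):
        """With rest noise ~0.1, voluntary envelope peaks ~5 and normal-blink
        peaks ~2, both thresholds land inside (2, 5)."""
        cfg = GenConfig(seed=11, white_noise_sigma=0.1, emg_burst_amp=6.27,
                        normal_blink_amp_fraction=0.4)
        cal, rec, truth = make_calibration(cfg)
        pp = PreprocessConfig()
        fs = cfg.sampling_rate
        for thr, ch, classes in (
                (cal.emg_threshold_ch5, rec.ch5_emg, ("right_blink", "bite")),
                (cal.emg_threshold_ch6, rec.ch6_emg, ("left_blink", "bite"))):
            env = emg_envelope(ch, pp, fs)
            vol = min(_peak_in(env, fs, e.onset, e.onset + e.duration + 0.1)
                      for e in truth if e.label in classes)
            nb = max(_peak_in(env, fs, e.onset, e.onset + e.duration + 0.1)
                     for e in truth if e.label == "normal_blink")
            assert nb < thr < vol
            assert 2.0 < thr < 5.0

    def test_identical_recordings_give_identical_calibration(self):
        a, _, _ = make_calibration(GenConfig(seed=12))
        b, _, _ = make_calibration(GenConfig(seed=12))
        assert a == b

    def test_normal_blink_stronger_than_voluntary_is_infeasible(self):
        cfg = GenConfig(seed=13)
        schedule = [EventSpec("right", 3.0, 0.8),
                    EventSpec("left", 6.0, 0.8),
                    EventSpec("right_blink", 9.0, 0.3, amplitude_scale=0.2),
                    EventSpec("left_blink", 12.0, 0.3, amplitude_scale=0.2),
                    EventSpec("bite", 15.0, 0.3, amplitude_scale=0.2),
                    EventSpec("normal_blink", 18.0, 0.2, amplitude_scale=3.0)]
        rec, truth = synthesize(schedule, cfg)
        with pytest.raises(CalibrationError):
            calibrate_thresholds(rec, truth)

    def test_generated_normal_blink_stays_below_calibrated_threshold(self):
        """The default involuntary-blink amplitude must be rejected by the
        thresholds the default calibration produces."""
        cal, _, _ = make_calibration(GenConfig(seed=14))
        cfg = GenConfig(seed=15)
        rec, truth = synthesize(
            make_schedule(["normal_blink"], repeats=5, interval=3.0), cfg)
        pp = PreprocessConfig()
        for ev in truth:
            p5 = _peak_in(emg_envelope(rec.ch5_emg, pp, cfg.sampling_rate),
                          cfg.sampling_rate, ev.onset, ev.onset + ev.duration)
            p6 = _peak_in(emg_envelope(rec.ch6_emg, pp, cfg.sampling_rate),
                          cfg.sampling_rate, ev.onset, ev.onset + ev.duration)
            assert p5 < cal.emg_threshold_ch5
            assert p6 < cal.emg_threshold_ch6


class TestExtractEpisodes:
    def test_right_blink_yields_single_ch5_only_episode(self, default_calibration):
        cfg = GenConfig(seed=20)
        rec, truth = synthesize([EventSpec("right_blink", 3.0, 0.3)], cfg)
        eps = extract_episodes(rec.ch5_emg, rec.ch6_emg, default_calibration,
                               PreprocessConfig(), cfg.sampling_rate)
        assert len(eps) == 1
        assert eps[0].ch5_active and not eps[0].ch6_active
        assert abs(eps[0].start - 3.0) < 0.15

    def test_normal_blink_yields_no_episode(self, default_calibration):
        cfg = GenConfig(seed=21)
        rec, _ = synthesize([EventSpec("normal_blink", 3.0, 0.2)], cfg)
        eps = extract_episodes(rec.ch5_emg, rec.ch6_emg, default_calibration,
                               PreprocessConfig(), cfg.sampling_rate)
        assert eps == []

    def test_two_separated_blinks_give_two_episodes(self, default_calibration):
        cfg = GenConfig(seed=22)
        rec, _ = synthesize([EventSpec("left_blink", 3.0, 0.3),
                             EventSpec("left_blink", 4.3, 0.3)], cfg)
        eps = extract_episodes(rec.ch5_emg, rec.ch6_emg, default_calibration,
                               PreprocessConfig(), cfg.sampling_rate)
        assert len(eps) == 2
        assert all(e.ch6_active and not e.ch5_active for e in eps)

    def test_bite_merges_channels_into_one_episode(self, default_calibration):
        cfg = GenConfig(seed=23)
        rec, _ = synthesize([EventSpec("bite", 3.0, 0.3)], cfg)
        eps = extract_episodes(rec.ch5_emg, rec.ch6_emg, default_calibration,
                               PreprocessConfig(), cfg.sampling_rate)
        assert len(eps) == 1
        assert eps[0].ch5_active and eps[0].ch6_active

    def test_subthreshold_recording_never_yields_episodes(self, default_calibration):
        rng = np.random.default_rng(24)
        quiet = rng.normal(0, 0.01, 5000)
        eps = extract_episodes(quiet, quiet.copy(), default_calibration,
                               PreprocessConfig(), 1000.0)
        assert eps == []

    def test_episode_count_invariant_to_small_noise(self, default_calibration):
        """Adding white noise of sigma <= threshold/10 never changes the
        episode count (20 seeds)."""
        cfg = GenConfig(seed=25, white_noise_sigma=0.0, drift_rate=0.0,
                        drift_walk_sigma=0.0, line_noise_amp=0.0)
        rec, _ = synthesize([EventSpec("right_blink", 3.0, 0.3),
                             EventSpec("bite", 6.0, 0.3)], cfg)
        sigma = default_calibration.emg_threshold_ch5 / 10.0
        pp = PreprocessConfig()
        for seed in range(20):
            rng = np.random.default_rng(seed)
            eps = extract_episodes(
                rec.ch5_emg + rng.normal(0, sigma, rec.n_samples),
                rec.ch6_emg + rng.normal(0, sigma, rec.n_samples),
                default_calibration, pp, cfg.sampling_rate)
            assert len(eps) == 2


def test_user_calibration_json_round_trip(tmp_path, default_calibration):
    p = tmp_path / "cal.json"
    default_calibration.to_json(p)
    assert UserCalibration.from_json(p) == default_calibration
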