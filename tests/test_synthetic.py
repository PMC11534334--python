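"""Synthetic generators: reproducibility, spectral shape, injection fidelity,
and the behavior simulator's trial structure."""

import numpy as np
import pytest

import tmreeg as tm
from tmreeg.behavior import score_session


class TestBackground:
    def test_zero_amplitude_is_silent(self):
        rec = tm.generate_background(5.0, 500.0, 3, amplitude_scale=0.0, seed=1)
        assert not rec.data.any()

    def test_seed_reproducibility_bitwise(self):
        a = tm.generate_background(5.0, 500.0, 2, seed=42)
        b = tm.generate_background(5.0, 500.0, 2, seed=42)
        np.testing.assert_array_equal(a.data, b.data)

    def test_spectral_slope_matches_exponent(self):
        # periodogram-fit oracle: log-log slope of a 1/f process is -beta
        from scipy.signal import welch

        rec = tm.generate_background(60.0, 500.0, 1, spectral_exponent=1.0, seed=5)
        f, p = welch(rec.data[0], fs=500.0, nperseg=4096)
        sel = (f > 1.0) & (f < 100.0)
        slope = np.polyfit(np.log(f[sel]), np.log(p[sel]), 1)[0]
        assert slope == pytest.approx(-1.0, abs=0.2)

    def test_nonpositive_duration_rejected(self):
        with pytest.raises(ValueError):
            tm.generate_background(0.0, 500.0, 1)


class TestCueEvents:
    def test_isi_bounds(self):
        ev = tm.generate_cue_events(100, seed=2)
        isis = np.diff(ev.onsets)
        assert len(ev) == 100 and len(isis) == 99
        assert isis.min() >= 6.0 and isis.max() <= 10.0

    def test_single_cue(self):
        assert len(tm.generate_cue_events(1, seed=0)) == 1

    def test_jitter_must_be_below_mean(self):
        with pytest.raises(ValueError):
            tm.generate_cue_events(5, isi_mean=8.0, isi_jitter=8.0)

    def test_seed_determinism(self):
        a = tm.generate_cue_events(20, seed=9)
        b = tm.generate_cue_events(20, seed=9)
        np.testing.assert_array_equal(a.onsets, b.onsets)


class TestSlowWaveInjection:
    def test_zero_amplitude_leaves_recording_unchanged(self, zero_recording):
        out, _ = tm.inject_slow_waves(zero_recording, [10.0], [0.0])
        assert not out.data.any()

    def test_waveform_trough_to_peak_closed_form(self, zero_recording):
        # closed-form oracle: one -A/2*sin cycle has trough-to-posterior-peak A
        out, _ = tm.inject_slow_waves(zero_recording, [10.0], [160.0])
        trace = out.data[0]
        trough = np.argmin(trace)
        post_peak = trough + np.argmax(trace[trough:])
        assert trace[post_peak] - trace[trough] == pytest.approx(160.0, abs=1.0)
        assert trough / 500.0 == pytest.approx(10.0, abs=0.002)

    def test_detector_recovers_noiseless_injection(self, zero_recording):
        out, _ = tm.inject_slow_waves(zero_recording, [10.0], [160.0])
        events = tm.detect_slow_waves(out, channel=out.channel_labels[0])
        assert len(events) == 1
        assert events[0].trough_time == pytest.approx(10.0, abs=0.02)
        assert events[0].amplitude == pytest.approx(160.0, abs=2.0)

    def test_injection_is_additive(self, noise_recording):
        silent = tm.generate_background(60.0, 500.0, 1, amplitude_scale=0.0, seed=0)
        onto_zero, _ = tm.inject_slow_waves(silent, [20.0, 30.0], [100.0, 120.0])
        onto_noise, _ = tm.inject_slow_waves(noise_recording, [20.0, 30.0], [100.0, 120.0])
        np.testing.assert_allclose(onto_zero.data + noise_recording.data,
                                   onto_noise.data, atol=1e-9)

    def test_out_of_bounds_injection_rejected(self, zero_recording):
        with pytest.raises(ValueError):
            tm.inject_slow_waves(zero_recording, [0.1], [100.0])

    def test_overlapping_injections_warn_and_sum(self, zero_recording):
        with pytest.warns(UserWarning, match="overlap"):
            out, _ = tm.inject_slow_waves(zero_recording, [10.0, 10.4], [50.0, 50.0])
        assert out.data.any()


class TestSpindleInjection:
    def test_zero_amplitude_leaves_recording_unchanged(self, zero_recording):
        out, _ = tm.inject_spindles(zero_recording, onsets=[5.0], amplitudes=0.0)
        assert not out.data.any()

    def test_envelope_peak_at_center(self, zero_recording):
        out, gt = tm.inject_spindles(zero_recording, onsets=[8.0], durations=1.0,
                                     amplitudes=20.0)
        from scipy.signal import hilbert

        env = np.abs(hilbert(out.data[0]))
        assert np.argmax(env) / 500.0 == pytest.approx(8.5, abs=0.05)
        assert gt.spindle_center_times == [8.5]

    def test_coupled_placement_and_classification(self, zero_recording):
        rec, _ = tm.inject_slow_waves(zero_recording, [8.0], [150.0])
        rec, _ = tm.inject_spindles(rec, coupled_to=[8.0], lags=0.5,
                                    durations=1.0, amplitudes=25.0)
        sws = tm.detect_slow_waves(rec, channel=rec.channel_labels[0])
        # classify against the injected ground truth peak
        spindle = tm.SpindleEvent(8.0, 9.0, 8.5, 25.0)
        labelled = tm.classify_coupling([spindle], sws)
        assert labelled[0].coupled
        assert labelled[0].lag == pytest.approx(0.5, abs=0.05)

    def test_out_of_band_center_frequency_warns(self, zero_recording):
        with pytest.warns(UserWarning, match="12-16"):
            tm.inject_spindles(zero_recording, onsets=[5.0], center_freqs=10.0,
                               amplitudes=5.0)

    def test_detector_recall_on_injected_bursts(self):
        from tmreeg.validation import spindle_recovery

        res = spindle_recovery(seed=1)
        assert res["recall"] >= 0.9
        assert res["fdr"] <= 0.1


class TestBehaviorGenerator:
    def test_encoding_has_480_trials(self):
        tables = tm.generate_behavior(tm.BehaviorSimParams(seed=0))
        assert len(tables["encoding"]) == 480

    def test_memory_sessions_have_160_trials(self):
        tables = tm.generate_behavior(tm.BehaviorSimParams(seed=0))
        assert len(tables["pre_sleep"]) == 160
        assert len(tables["post_sleep"]) == 160

    def test_word_structure(self):
        tables = tm.generate_behavior(tm.BehaviorSimParams(seed=1))
        enc = tables["encoding"]
        words = enc.drop_duplicates("word_id")
        assert len(words) == 160
        assert (words.groupby("condition").size() == 80).all()
        assert (words.groupby(["condition", "reward_category"]).size() == 40).all()
        # every word shown exactly 3 times, presentation = occurrence order
        assert (enc.groupby("word_id").size() == 3).all()
        assert sorted(enc["presentation"].unique()) == [1, 2, 3]

    def test_seed_determinism(self):
        a = tm.generate_behavior(tm.BehaviorSimParams(seed=5))
        b = tm.generate_behavior(tm.BehaviorSimParams(seed=5))
        for key in a:
            assert a[key].equals(b[key])

    def test_easy_condition_learns_faster_by_presentation_three(self):
        # by construction: easy accuracy > difficult accuracy at presentation 3
        diffs = []
        for seed in range(100):
            tables = tm.generate_behavior(tm.BehaviorSimParams(seed=seed))
            scores = score_session(tables["encoding"], by=("condition", "presentation"))
            third = scores[scores["presentation"] == 3].set_index("condition")["dprime"]
            diffs.append(third["high_pp"] - third["low_pp"])
        assert np.mean(diffs) > 0
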