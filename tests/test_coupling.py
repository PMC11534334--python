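"""SW-spindle coupling classification and SW-locked spectral power."""

import numpy as np
import pytest

import tmreeg as tm
from tmreeg.coupling import classify_coupling, coupled_amplitude_contrast, sw_locked_tfr, upstate_band_power
from tmreeg.spindles import SpindleEvent
from tmreeg.sw import SWEvent


def _sw(trough):
    return SWEvent(trough, trough - 0.4, trough + 0.4, 100.0)


def _spindle(peak, amp=10.0):
    return SpindleEvent(peak - 0.5, peak + 0.5, peak, amp)


def brute_force_coupling(spindles, sws, window=(0.3, 0.8)):
    """Oracle: full double loop over every (spindle, SW) pair."""
    mid = 0.5 * (window[0] + window[1])
    out = []
    for sp in spindles:
        best, best_score = None, None
        for sw in sws:
            lag = sp.peak_time - sw.trough_time
            if window[0] <= lag <= window[1]:
                score = abs(lag - mid)
                if best is None or score < best_score:
                    best, best_score = sw, score
        out.append(best)
    return out


class TestClassification:
    @pytest.mark.parametrize("lag,expected", [
        (0.50, True), (0.25, False), (0.30, True), (0.80, True),
        (0.85, False), (-0.2, False),
    ])
    def test_window_rule_with_closed_boundaries(self, lag, expected):
        res = classify_coupling([_spindle(10.0 + lag)], [_sw(10.0)])
        assert res[0].coupled is expected
        if expected:
            assert res[0].lag == pytest.approx(lag)

    def test_partition(self):
        rng = np.random.default_rng(0)
        spindles = [_spindle(p) for p in np.sort(rng.uniform(5, 500, 200))]
        sws = [_sw(t) for t in np.sort(rng.uniform(5, 500, 100))]
        res = classify_coupling(spindles, sws)
        n_c = sum(r.coupled for r in res)
        n_u = sum(not r.coupled for r in res)
        assert n_c + n_u == len(spindles)

    def test_multiple_candidates_pick_nearest_to_midpoint(self):
        # troughs at 9.5 and 9.9; spindle peak at 10.2 -> lags 0.7 and 0.3;
        # |0.7-0.55| > |0.3-0.55| is false: 0.15 vs 0.25 -> lag 0.7 wins? no:
        # |0.7-0.55|=0.15, |0.3-0.55|=0.25 -> the 9.5 trough is nearer
        res = classify_coupling([_spindle(10.2)], [_sw(9.5), _sw(9.9)])
        assert res[0].coupled
        assert res[0].sw.trough_time == pytest.approx(9.5)

    @pytest.mark.parametrize("n_spindles,n_sws,seed", [
        (50, 30, 0), (300, 200, 1), (1000, 1000, 2),
    ])
    def test_matches_brute_force_oracle(self, n_spindles, n_sws, seed):
        rng = np.random.default_rng(seed)
        spindles = [_spindle(p) for p in np.sort(rng.uniform(5, 2000, n_spindles))]
        sws = [_sw(t) for t in np.sort(rng.uniform(5, 2000, n_sws))]
        ours = classify_coupling(spindles, sws)
        oracle = brute_force_coupling(spindles, sws)
        for got, want in zip(ours, oracle):
            assert got.coupled == (want is not None)
            if want is not None:
                assert got.sw.trough_time == pytest.approx(want.trough_time)


class TestSwLockedTfr:
    def _session(self, amp, seed=5):
        rec = tm.generate_background(120.0, 500.0, 2, amplitude_scale=15.0, seed=seed)
        troughs = list(10.0 + 10.0 * np.arange(11))
        rec, _ = tm.inject_slow_waves(rec, troughs, 150.0)
        if amp > 0:
            rec, _ = tm.inject_spindles(rec, coupled_to=troughs, lags=0.5,
                                        durations=1.0, amplitudes=amp)
        return rec, troughs

    def test_coupled_power_peaks_in_upstate_window(self):
        rec, troughs = self._session(amp=30.0)
        tfr = sw_locked_tfr(rec, troughs, freqs=np.arange(10.0, 17.0, 1.0))
        band = (tfr.freqs >= 12) & (tfr.freqs <= 16)
        upstate = (tfr.times >= 0.3) & (tfr.times <= 0.8)
        pre = (tfr.times >= -1.2) & (tfr.times <= -0.7)
        p_up = tfr.power[:, band][:, :, upstate].mean()
        p_pre = tfr.power[:, band][:, :, pre].mean()
        assert p_up > p_pre

    def test_null_session_near_zero_upstate_power(self):
        rec, troughs = self._session(amp=0.0)
        tfr = sw_locked_tfr(rec, troughs, freqs=np.arange(10.0, 17.0, 1.0))
        with_spindles, _ = self._session(amp=30.0)
        tfr_sp = sw_locked_tfr(with_spindles, troughs, freqs=np.arange(10.0, 17.0, 1.0))
        null_power = upstate_band_power(tfr, channels=tfr.channel_labels)
        spindle_power = upstate_band_power(tfr_sp, channels=tfr.channel_labels)
        assert abs(null_power) < 0.2 * spindle_power

    def test_deterministic(self):
        rec, troughs = self._session(amp=20.0)
        t1 = sw_locked_tfr(rec, troughs, freqs=np.arange(11.0, 15.0, 1.0))
        t2 = sw_locked_tfr(rec, troughs, freqs=np.arange(11.0, 15.0, 1.0))
        np.testing.assert_array_equal(t1.power, t2.power)

    def test_edge_troughs_dropped_and_all_dropped_errors(self):
        rec = tm.generate_background(20.0, 500.0, 1, amplitude_scale=10.0, seed=0)
        with pytest.raises(ValueError, match="troughs"):
            sw_locked_tfr(rec, [1.0], freqs=np.array([12.0]))

    def test_monotone_in_coupled_amplitude(self):
        powers = []
        for amp in (10.0, 20.0, 40.0):
            rec, troughs = self._session(amp=amp, seed=6)
            tfr = sw_locked_tfr(rec, troughs, freqs=np.arange(11.0, 15.0, 1.0))
            powers.append(upstate_band_power(tfr, channels=tfr.channel_labels))
        assert powers[0] < powers[1] < powers[2]


class TestUpstatePower:
    def test_constant_tfr_value(self):
        freqs = np.arange(10.0, 16.0, 1.0)
        times = np.arange(-1.0, 1.5, 0.05)
        power = np.full((2, len(freqs), len(times)), 4.2)
        tfr = tm.TFR(power, freqs, times, ["Pz", "P3"])
        assert upstate_band_power(tfr, channels=("Pz", "P3")) == pytest.approx(4.2)

    def test_empty_channel_selection_rejected(self):
        freqs = np.arange(10.0, 16.0, 1.0)
        times = np.arange(-1.0, 1.5, 0.05)
        tfr = tm.TFR(np.ones((1, len(freqs), len(times))), freqs, times, ["Pz"])
        with pytest.raises(ValueError):
            upstate_band_power(tfr, channels=())


class TestAmplitudeContrast:
    def test_equal_amplitudes_equal_means(self):
        labelled = classify_coupling(
            [_spindle(10.5, amp=7.0), _spindle(50.0, amp=7.0)], [_sw(10.0)])
        means = coupled_amplitude_contrast(labelled)
        assert means["coupled"] == pytest.approx(7.0)
        assert means["uncoupled"] == pytest.approx(7.0)

    def test_coupled_class_larger_by_construction(self):
        labelled = classify_coupling(
            [_spindle(10.5, amp=20.0), _spindle(50.0, amp=10.0)], [_sw(10.0)])
        means = coupled_amplitude_contrast(labelled)
        assert means["coupled"] > means["uncoupled"]

    def test_reordering_invariance(self):
        rng = np.random.default_rng(4)
        spindles = [_spindle(p, amp=a) for p, a in
                    zip(np.sort(rng.uniform(5, 200, 40)), rng.uniform(5, 20, 40))]
        sws = [_sw(t) for t in np.sort(rng.uniform(5, 200, 20))]
        fwd = coupled_amplitude_contrast(classify_coupling(spindles, sws))
        rev = coupled_amplitude_contrast(classify_coupling(spindles[::-1], sws))
        assert fwd.sort_index().equals(rev.sort_index())

    def test_missing_class_absent(self):
        labelled = classify_coupling([_spindle(10.5)], [_sw(10.0)])
        means = coupled_amplitude_contrast(labelled)
        assert "uncoupled" not in means.index
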