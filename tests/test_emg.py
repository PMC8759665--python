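"""EMG pipeline: file dialect, preprocessing, noise floor, burst
detection and per-muscle statistics."""

import warnings

import numpy as np
import pandas as pd
import pytest

from pawshake.emg import (EMGRecording, EMGFormatError, read_s1_recording,
                          write_s1_recording, preprocess_emg,
                          find_quiet_interval, estimate_noise_floor,
                          detect_emg_bursts, emg_cycle_metrics,
                          muscle_group_stats, analyze_episode)


class TestFileDialect:
    def test_two_column_file(self, tmp_path):
        f = tmp_path / "S1_Data_3-1-0_ab_1A.txt"
        body = "\n".join("0.01 -0.02" for _ in range(6000))
        f.write_text("MG SO\n" + body + "\n")
        rec = read_s1_recording(f)
        assert set(rec.channels) == {"MG", "SO"}
        assert rec.n_samples == 6000
        assert rec.duration == pytest.approx(2.0)
        assert (rec.session, rec.animal, rec.episode) == ("3-1-0", "ab", "1A")

    def test_header_only_errors(self, tmp_path):
        f = tmp_path / "empty.txt"
        f.write_text("MG SO\n")
        with pytest.raises(EMGFormatError):
            read_s1_recording(f)

    def test_unknown_muscle_warns_but_passes(self, tmp_path):
        f = tmp_path / "x.txt"
        f.write_text("MG XX\n" + "\n".join("0.0 0.1" for _ in range(700)))
        with pytest.warns(UserWarning, match="XX"):
            rec = read_s1_recording(f)
        assert "XX" in rec.channels

    def test_ragged_columns_error(self, tmp_path):
        f = tmp_path / "ragged.txt"
        f.write_text("MG SO\n0.1 0.2\n0.1\n0.3 0.4\n")
        with pytest.raises(EMGFormatError):
            read_s1_recording(f)

    def test_roundtrip(self, tmp_path):
        rng = np.random.default_rng(1)
        rec = EMGRecording({"MG": rng.normal(size=900),
                            "IP": rng.normal(size=900)})
        f = tmp_path / "S1_Data_s_a_e.txt"
        write_s1_recording(rec, f)
        back = read_s1_recording(f)
        assert back.n_samples == rec.n_samples
        np.testing.assert_allclose(back.channels["MG"],
                                   rec.channels["MG"], atol=1e-5)

    def test_unequal_channel_lengths_rejected(self):
        with pytest.raises(EMGFormatError):
            EMGRecording({"MG": np.zeros(10), "SO": np.zeros(11)})


class TestPreprocess:
    def test_constant_signal(self):
        out = preprocess_emg(np.full(1000, -0.3))
        np.testing.assert_allclose(out, 0.3)

    def test_nyquist_alternation_rectifies_to_one(self):
        x = np.tile([1.0, -1.0], 500)
        out = preprocess_emg(x)
        np.testing.assert_allclose(out, 1.0)

    def test_zero_lag_window_is_odd_and_centered(self):
        # an isolated unit impulse spreads symmetrically around itself
        x = np.zeros(601)
        x[300] = 1.0
        out = preprocess_emg(x, 3000, window=0.008)
        n = int(round(0.008 * 3000)) | 1
        nz = np.nonzero(out)[0]
        assert len(nz) == n
        assert nz[0] == 300 - n // 2 and nz[-1] == 300 + n // 2

    def test_envelope_peaks_at_burst_centers(self):
        fs = 3000.0
        t = np.arange(0, 1.0, 1 / fs)
        x = np.zeros_like(t)
        centers = (0.2, 0.5, 0.8)
        for c in centers:
            m = np.abs(t - c) < 0.02
            x[m] = np.sin(2 * np.pi * 300 * t[m])
        env = preprocess_emg(x, fs)
        from scipy.signal import find_peaks
        pk, _ = find_peaks(env, height=0.3, distance=int(0.1 * fs))
        assert len(pk) >= 3
        for c in centers:
            assert np.min(np.abs(pk / fs - c)) < 0.025


class TestNoiseFloor:
    def test_zero_signal(self):
        m, sd = estimate_noise_floor(np.zeros(3000), 3000, (0.0, 1.0))
        assert m == 0.0 and sd == 0.0

    def test_known_sigma_recovered(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0, 0.02, 3000)
        _, sd = estimate_noise_floor(x, 3000, (0.0, 1.0))
        assert sd == pytest.approx(0.02, rel=0.10)

    def test_short_interval_rejected(self):
        with pytest.raises(ValueError):
            estimate_noise_floor(np.zeros(3000), 3000, (0.0, 0.15))

    def test_quiet_window_avoids_bursts(self):
        fs = 3000.0
        x = np.random.default_rng(0).normal(0, 0.01, int(fs))
        x[1500:2100] += 1.0  # active stretch
        t0, t1 = find_quiet_interval(np.abs(x), fs)
        assert t1 - t0 == pytest.approx(0.2, abs=1e-3)
        assert t1 <= 0.5 or t0 >= 0.7


class TestBurstDetection:
    def _pulse_train(self, fs=3000.0, sd=0.001):
        """Rectangular pulses 30 ms wide, 100 ms apart, amplitude 10 sd."""
        n = int(fs)
        x = np.zeros(n)
        t = np.arange(n) / fs
        for k in range(8):
            x[(t >= 0.1 + 0.1 * k) & (t < 0.13 + 0.1 * k)] = 10 * sd
        return x, t

    def test_rectangular_pulses_measured_exactly(self):
        fs = 3000.0
        x, t = self._pulse_train(fs)
        bursts = detect_emg_bursts(x, fs, noise_sd=0.001,
                                   min_burst=0.0, min_gap=0.0)
        cm = emg_cycle_metrics(bursts)
        tol = 1.01 / fs  # one sample
        assert np.allclose(cm["BD"], 0.030, atol=tol)
        assert np.allclose(cm["CP"], 0.100, atol=tol)
        assert np.allclose(cm["DC"], 30.0, atol=1.0)

    def test_all_noise_below_threshold(self):
        rng = np.random.default_rng(2)
        x = np.abs(rng.normal(0, 0.001, 3000))
        b = detect_emg_bursts(x, 3000, threshold=0.5)
        assert len(b) == 0
        assert emg_cycle_metrics(b) is None

    def test_threshold_monotonicity(self):
        """Raising the threshold never increases total detected BD; on a
        clean (noise-free) signal the burst count is non-increasing too.
        (With raw noise a connected run can split as the threshold rises,
        so the count guarantee holds for the time above threshold.)"""
        clean, _ = self._pulse_train()
        noisy = np.abs(clean + np.random.default_rng(3)
                       .normal(0, 0.001, len(clean)))
        prev_bd = np.inf
        for thr in (0.002, 0.004, 0.006, 0.008):
            b = detect_emg_bursts(noisy, 3000, threshold=thr,
                                  min_burst=0.0, min_gap=0.0)
            total_bd = float((b["offset"] - b["onset"]).sum())
            assert total_bd <= prev_bd + 1e-9
            prev_bd = total_bd
        prev_n = np.inf
        for thr in (0.002, 0.005, 0.009, 0.011):
            b = detect_emg_bursts(clean, 3000, threshold=thr,
                                  min_burst=0.0, min_gap=0.0)
            assert len(b) <= prev_n
            prev_n = len(b)

    def test_degenerate_threshold_rejected(self):
        with pytest.raises(ValueError):
            detect_emg_bursts(np.zeros(100), 3000, noise_sd=0.0)

    def test_short_gap_merging(self):
        fs = 1000.0
        x = np.zeros(200)
        x[50:60] = 1.0
        x[62:72] = 1.0  # 2 ms gap -> merged
        b = detect_emg_bursts(x, fs, threshold=0.5, min_burst=0.0,
                              min_gap=0.005)
        assert len(b) == 1


class TestMuscleStats:
    def _linear_tables(self, slope, n_episodes=8, n_cycles=7):
        tables = []
        for k in range(n_episodes):
            onset = np.arange(n_cycles) * 0.1
            bd = 0.03 + slope * onset
            cp = np.full(n_cycles, 0.1)
            tables.append(pd.DataFrame(
                {"onset": onset, "CP": cp, "BD": bd, "IBI": cp - bd,
                 "DC": 100 * bd / cp}))
        return tables

    def test_exactly_linear_episodes_have_unit_pearson_r(self):
        stats_df = muscle_group_stats({"IP": self._linear_tables(0.02)})
        row = stats_df[(stats_df.muscle == "IP")
                       & (stats_df.metric == "BD")].iloc[0]
        assert row["median_r"] == pytest.approx(1.0)
        assert row["median_slope"] == pytest.approx(0.02, rel=1e-9)
        assert row["wilcoxon_p"] < 0.01

    def test_small_sample_warns(self):
        with pytest.warns(UserWarning, match="weakly powered"):
            muscle_group_stats({"TA": self._linear_tables(0.01,
                                                          n_episodes=3)})

    def test_flexor_extensor_pattern_on_synthetic_cohort(
            self, emg_cohort_stats):
        """Flexor-like channels carry BD growth, extensor-like channels
        IBI growth; duty cycles move oppositely."""
        s = emg_cohort_stats.set_index(["muscle", "metric"])
        for ext in ("MG", "SO"):
            assert s.loc[(ext, "IBI"), "median_slope"] > 0
            assert s.loc[(ext, "IBI"), "wilcoxon_p"] < 0.05
            assert s.loc[(ext, "DC"), "median_slope"] < 0
        for flex in ("IP", "TA"):
            assert s.loc[(flex, "BD"), "median_slope"] > 0
            assert s.loc[(flex, "BD"), "wilcoxon_p"] < 0.05
            assert s.loc[(flex, "IBI"), "wilcoxon_p"] > 0.05


def test_pipeline_identity_on_detected_bursts():
    rng = np.random.default_rng(8)
    fs = 3000.0
    x = np.abs(rng.normal(0, 0.002, int(2 * fs)))
    for k in range(10):
        a = int((0.2 + 0.15 * k) * fs)
        x[a:a + int(0.05 * fs)] += 0.05
    b = detect_emg_bursts(x, fs, noise_sd=0.002)
    cm = emg_cycle_metrics(b)
    np.testing.assert_allclose(cm["CP"].to_numpy(),
                               (cm["BD"] + cm["IBI"]).to_numpy(),
                               rtol=0, atol=1e-12)
    assert ((cm["DC"] > 0) & (cm["DC"] <= 100)).all()
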