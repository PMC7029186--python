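"""Generators: determinism, spectral ground truth, event statistics."""

import numpy as np
import pytest
from scipy.signal import periodogram

import tailbeat as tb
from tailbeat.synth import SyntheticTraceSpec


def band_power(x, rate, lo, hi):
    f, p = periodogram(x, fs=rate)
    return p[(f >= lo) & (f <= hi)].sum()


class TestFictiveTrace:
    def test_seed_determinism(self):
        spec = SyntheticTraceSpec(mode="bg_ctrl", seed=7)
        t1, g1 = tb.generate_fictive_trace(spec)
        t2, g2 = tb.generate_fictive_trace(spec)
        assert np.array_equal(t1.samples, t2.samples)
        assert g1.episode_intervals == g2.episode_intervals

    def test_band_power_concentrated_in_episodes(self, bg_ctrl_trace):
        trace, truth = bg_ctrl_trace
        inside = np.concatenate([
            trace.samples[int(s * trace.rate_hz):int(e * trace.rate_hz)]
            for s, e in truth.episode_intervals])
        mask = np.ones(trace.n_samples, bool)
        for s, e in truth.episode_intervals:
            mask[int(s * trace.rate_hz):int(e * trace.rate_hz)] = False
        outside = trace.samples[mask]
        n = min(inside.size, outside.size)
        p_in = band_power(inside[:n], trace.rate_hz, 20, 40)
        p_out = band_power(outside[:n], trace.rate_hz, 20, 40)
        assert p_in > 10 * p_out

    def test_strychnine_mode_suppresses_tailbeat_band(self):
        kw = dict(tailbeat_hz=30.0, snr=5.0, seed=3)
        ctrl, gt_c = tb.generate_fictive_trace(SyntheticTraceSpec(mode="bg_ctrl", **kw))
        stry, gt_s = tb.generate_fictive_trace(SyntheticTraceSpec(mode="bg_str", **kw))

        def band_fraction(trace, truth):
            segs = [trace.samples[int(s * trace.rate_hz):int(e * trace.rate_hz)]
                    for s, e in truth.episode_intervals]
            x = np.concatenate(segs)
            return band_power(x, trace.rate_hz, 20, 40) / band_power(
                x, trace.rate_hz, 0, trace.rate_hz / 2)

        assert band_fraction(stry, gt_s) < band_fraction(ctrl, gt_c)

    def test_episode_intervals_sorted_disjoint_and_long_enough(self, bg_ctrl_trace):
        _, truth = bg_ctrl_trace
        iv = truth.episode_intervals
        assert all(e - s > 0.2 for s, e in iv)
        assert all(iv[i + 1][0] >= iv[i][1] for i in range(len(iv) - 1))

    def test_episode_dominant_frequency_matches_ground_truth(self, bg_ctrl_trace):
        trace, truth = bg_ctrl_trace
        for (s, e), f_true in zip(truth.episode_intervals[:5], truth.tailbeat_hz):
            seg = trace.samples[int(s * trace.rate_hz):int(e * trace.rate_hz)]
            f, p = periodogram(seg - seg.mean(), fs=trace.rate_hz)
            df = f[1] - f[0]
            assert abs(f[np.argmax(p)] - f_true) <= df

    def test_too_short_duration_raises(self):
        spec = SyntheticTraceSpec(mode="burst_ctrl", duration_s=0.4)
        with pytest.raises(ValueError, match="too short"):
            tb.generate_fictive_trace(spec)

    @pytest.mark.parametrize("bad", [
        dict(tailbeat_hz=45.0), dict(tailbeat_hz=10.0),
        dict(episode_dur_s=0.1), dict(mode="nope"), dict(snr=-1.0),
    ])
    def test_invalid_spec_rejected(self, bad):
        with pytest.raises(ValueError):
            SyntheticTraceSpec(**bad).resolved()


class TestIpscTrace:
    def test_zero_jitter_periodic_intervals(self):
        _, truth = tb.generate_ipsc_trace(25.0, rhythmic=True, jitter_sd_ms=0.0,
                                          duration_s=5.0, seed=1)
        iv = np.diff(truth.event_times_s)
        assert np.allclose(iv, 0.040, atol=1e-9)

    def test_poisson_interval_cv_near_one(self):
        _, truth = tb.generate_ipsc_trace(25.0, rhythmic=False,
                                          duration_s=100.0, seed=2)
        iv = np.diff(truth.event_times_s)
        cv = iv.std() / iv.mean()
        assert 0.9 < cv < 1.1

    def test_jittered_interval_sd(self):
        # SD of the difference of two independent 2-ms jitters: sqrt(2)*2 ms
        _, truth = tb.generate_ipsc_trace(25.0, rhythmic=True, jitter_sd_ms=2.0,
                                          duration_s=60.0, seed=3)
        iv_ms = np.diff(truth.event_times_s) * 1e3
        assert iv_ms.size >= 1000
        assert 1.5 < iv_ms.std() < 3.5

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            tb.generate_ipsc_trace(0.0, rhythmic=False)
        with pytest.raises(ValueError):
            tb.generate_ipsc_trace(25.0, rhythmic=True, jitter_sd_ms=-1.0)

    def test_seed_determinism(self):
        a, _ = tb.generate_ipsc_trace(25.0, rhythmic=False, duration_s=3.0, seed=9)
        b, _ = tb.generate_ipsc_trace(25.0, rhythmic=False, duration_s=3.0, seed=9)
        assert np.array_equal(a.samples, b.samples)


class TestSwimVideo:
    def test_rest_posture_when_amplitude_zero(self):
        frames, _, angles, _ = tb.generate_swim_video(30.0, 10, 500.0,
                                                      amp_px=0.0)
        assert all(np.array_equal(frames[0], f) for f in frames)
        assert np.allclose(angles, 0.0)

    def test_ground_truth_caudal_segment_fft_peak(self, swim_video):
        _, _, angles, _ = swim_video
        spec = tb.per_segment_fft(angles, fps=500.0)
        caudal = spec.magnitude[-1]
        assert spec.freqs_hz[np.argmax(caudal)] == pytest.approx(30.0, abs=2.0)

    def test_caudal_amplitude_exceeds_rostral(self, swim_video):
        _, _, angles, _ = swim_video
        amp = np.abs(angles).max(axis=1)
        assert amp[-1] > amp[0]

    def test_precondition_errors(self):
        with pytest.raises(ValueError, match="fps"):
            tb.generate_swim_video(300.0, 5, fps=500.0)
        with pytest.raises(ValueError, match="thickness"):
            tb.generate_swim_video(30.0, 5, tail_halfwidth_px=1.0)

    def test_determinism(self):
        a, *_ = tb.generate_swim_video(30.0, 3, 500.0)
        b, *_ = tb.generate_swim_video(30.0, 3, 500.0)
        assert np.array_equal(a, b)

    def test_frame_io_roundtrip(self, tmp_path):
        frames, *_ = tb.generate_swim_video(30.0, 4, 500.0,
                                            img_shape=(60, 120))
        tif = tmp_path / "swim.tif"
        tb.synth.save_frames(frames, tif)
        assert np.array_equal(tb.synth.load_frames(tif), frames)
        png_dir = tmp_path / "frames"
        tb.synth.save_frames(frames, png_dir)
        assert np.array_equal(tb.synth.load_frames(png_dir), frames)
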