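import numpy as np
import pytest
from scipy import signal as sps

from revaci.signals import (NoiseSpec, Waveform, apply_ramps, generate_noise,
                            mix_at_snr, pure_tone, rove_level, set_level)


def welch_loglog_slope(w, f_lo, f_hi):
    """Least-squares slope (dB/decade) of the Welch PSD over [f_lo, f_hi]."""
    f, p = sps.welch(w.samples, fs=w.rate, nperseg=2048)
    keep = (f >= f_lo) & (f <= f_hi)
    return np.polyfit(np.log10(f[keep]), 10 * np.log10(p[keep]), 1)[0]


class TestGenerateNoise:
    def test_seeded_determinism_and_length(self):
        spec = NoiseSpec("white", 0.5, 10_000, seed=7)
        w1, w2 = generate_noise(spec), generate_noise(spec)
        assert len(w1) == 5000
        assert np.array_equal(w1.samples, w2.samples)

    @pytest.mark.parametrize("kind", ["white", "pink", "bump", "mps"])
    def test_zero_mean_unit_rms(self, kind):
        w = generate_noise(NoiseSpec(kind, 0.5, 8000, seed=1))
        assert abs(w.samples.mean()) < 1e-12
        assert abs(w.rms - 1.0) < 1e-9

    def test_pink_spectral_slope(self):
        # power ~ 1/f means -10 dB/decade on a log-log periodogram
        w = generate_noise(NoiseSpec("pink", 2.0, 16_000, seed=5))
        slope = welch_loglog_slope(w, 100, 4000)
        assert abs(slope - (-10.0)) < 1.5

    def test_white_spectrum_flat(self):
        w = generate_noise(NoiseSpec("white", 2.0, 16_000, seed=5))
        slope = welch_loglog_slope(w, 100, 4000)
        assert abs(slope) < 1.0
        # per-band power within 3 sigma of the uniform expectation
        f, p = sps.welch(w.samples, fs=w.rate, nperseg=1024)
        bands = np.array_split(p[(f > 100) & (f < 7000)], 8)
        means = np.array([b.mean() for b in bands])
        rel = means / means.mean()
        assert np.all(np.abs(rel - 1) < 3 * 1.0 / np.sqrt(bands[0].size * 3.5))

    def test_bump_noise_has_larger_envelope_fluctuations(self):
        # flat long-term spectrum like white noise, but a more variable
        # temporal envelope (the point of bump maskers)
        def env_cv(w):
            env = np.abs(sps.hilbert(w.samples))
            env = sps.savgol_filter(env, 201, 2)
            return env.std() / env.mean()

        white = generate_noise(NoiseSpec("white", 1.0, 8000, seed=3))
        bump = generate_noise(NoiseSpec("bump", 1.0, 8000, seed=3))
        assert env_cv(bump) > env_cv(white)
        assert abs(welch_loglog_slope(bump, 200, 3000)) < 3.0

    def test_mps_noise_envelope_fluctuations(self):
        white = generate_noise(NoiseSpec("white", 1.0, 8000, seed=4))
        mps = generate_noise(NoiseSpec("mps", 1.0, 8000, seed=4))

        def env_cv(w):
            env = np.abs(sps.hilbert(w.samples))
            env = sps.savgol_filter(env, 201, 2)
            return env.std() / env.mean()

        assert env_cv(mps) > env_cv(white)

    def test_unknown_kind_names_supported(self):
        with pytest.raises(ValueError, match="white"):
            NoiseSpec("brownian", 1.0, 8000, seed=0)


class TestSetLevel:
    def test_reference_level_gives_unit_rms(self):
        w = generate_noise(NoiseSpec("white", 0.1, 8000, seed=0))
        assert abs(set_level(w, 100, 100).rms - 1.0) < 1e-12

    def test_closed_form_rms(self):
        w = generate_noise(NoiseSpec("white", 0.1, 8000, seed=0))
        out = set_level(w, 65, 100)
        assert abs(out.rms - 10 ** (-35 / 20)) < 1e-12

    def test_scale_invariance_and_idempotence(self):
        w = generate_noise(NoiseSpec("white", 0.1, 8000, seed=0))
        doubled = Waveform(2 * w.samples, w.rate, w.dbfs_ref)
        a = set_level(w, 70, 100).samples
        b = set_level(doubled, 70, 100).samples
        c = set_level(set_level(w, 55, 100), 70, 100).samples
        assert np.allclose(a, b) and np.allclose(a, c)

    def test_silent_input_raises(self):
        silent = Waveform(np.zeros(100), 8000)
        with pytest.raises(ValueError, match="silent"):
            set_level(silent, 65, 100)


class TestMixAtSnr:
    def setup_method(self):
        self.noise = generate_noise(NoiseSpec("white", 0.5, 10_000, seed=2))
        self.tone = pure_tone(500, 0.1, 10_000)

    def test_zero_snr_matches_rms_over_overlap(self):
        out = mix_at_snr(self.tone, self.noise, 0.0, mode="broadband_rms")
        start = (len(self.noise) - len(self.tone)) // 2
        seg_noise = self.noise.samples[start:start + len(self.tone)]
        added = out.samples[start:start + len(self.tone)] - seg_noise
        assert abs(np.sqrt(np.mean(added**2)) / np.sqrt(np.mean(seg_noise**2)) - 1) < 1e-9

    def test_es_over_n0_recovered_from_components(self):
        # classic tone-in-noise calibration: 100-ms 500-Hz tone in 500-ms
        # white noise at 10 log10(Es/N0) = 11.8 dB
        out = mix_at_snr(self.tone, self.noise, 11.8, mode="es_over_n0")
        start = (len(self.noise) - len(self.tone)) // 2
        added = out.samples - self.noise.samples
        es = np.sum(added**2) / 10_000
        n0 = np.mean(self.noise.samples**2) / (10_000 / 2)
        assert abs(10 * np.log10(es / n0) - 11.8) < 1e-9
        # tone is centered: energy confined to the middle window
        assert np.allclose(added[:start], 0) and np.allclose(added[start + 1000:], 0)

    def test_zero_amplitude_target_returns_noise(self):
        silent = Waveform(np.zeros(1000), 10_000)
        out = mix_at_snr(silent, self.noise, 5.0)
        assert np.array_equal(out.samples, self.noise.samples)

    def test_monotone_in_snr(self):
        def added_rms(snr):
            out = mix_at_snr(self.tone, self.noise, snr)
            return np.sqrt(np.mean((out.samples - self.noise.samples) ** 2))

        rms = [added_rms(s) for s in (-10, 0, 10, 20)]
        assert np.all(np.diff(rms) > 0)

    def test_rate_mismatch_and_too_long_target(self):
        other = pure_tone(500, 0.1, 8000)
        with pytest.raises(ValueError, match="rate"):
            mix_at_snr(other, self.noise, 0)
        long_tone = pure_tone(500, 1.0, 10_000)
        with pytest.raises(ValueError, match="longer"):
            mix_at_snr(long_tone, self.noise, 0)


class TestRoveLevel:
    def test_zero_range_is_identity(self):
        w = pure_tone(500, 0.1, 8000)
        out, off = rove_level(w, 0.0, np.random.default_rng(0))
        assert off == 0.0 and np.array_equal(out.samples, w.samples)

    def test_offsets_within_range(self):
        w = pure_tone(500, 0.05, 8000)
        rng = np.random.default_rng(1)
        offs = [rove_level(w, 2.5, rng)[1] for _ in range(500)]
        assert np.all(np.abs(offs) <= 2.5)

    def test_mean_offset_near_zero(self):
        w = pure_tone(500, 0.01, 8000)
        rng = np.random.default_rng(2)
        offs = np.array([rove_level(w, 2.5, rng)[1] for _ in range(10_000)])
        se = 2.5 / np.sqrt(3) / np.sqrt(offs.size)
        assert abs(offs.mean()) < 3 * se


def test_ramps_shape_edges():
    w = pure_tone(500, 0.2, 8000)
    out = apply_ramps(w, 0.01)
    assert out.samples[0] == 0.0
    mid = slice(len(w) // 2 - 100, len(w) // 2 + 100)
    assert np.allclose(out.samples[mid], w.samples[mid])
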