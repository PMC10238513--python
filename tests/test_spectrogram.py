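"""Spectral front-end contracts: framing geometry, mel filterbank support,
band-pass attenuation, per-band normalization and SpecAugment masking."""

import numpy as np
import pytest

from auscult.audio_io import AudioClip
from auscult.spectrogram import (
    SpectrogramConfig,
    bandpass_filter,
    compute_logmel,
    crop_or_pad,
    fit_band_stats,
    mel_filterbank,
    n_frames,
    spec_augment,
)

CFG = SpectrogramConfig()


def tone(freq, seconds=1.0, rate=4000, amp=0.5):
    t = np.arange(int(seconds * rate)) / rate
    return AudioClip((amp * np.sin(2 * np.pi * freq * t)).astype(np.float32), rate)


class TestCropOrPad:
    def test_short_clip_zero_padded(self, rng):
        clip = AudioClip(np.ones(8000, dtype=np.float32), 4000)
        out = crop_or_pad(clip, 5.0, rng)
        assert out.samples.size == 20_000
        assert np.all(out.samples[8000:] == 0.0)
        assert np.all(out.samples[:8000] == 1.0)

    def test_exact_length_identity(self, rng):
        clip = AudioClip(np.arange(20_000, dtype=np.float32), 4000)
        out = crop_or_pad(clip, 5.0, rng)
        np.testing.assert_array_equal(out.samples, clip.samples)

    def test_long_clip_window_bounds_and_determinism(self):
        clip = AudioClip(np.arange(120_000, dtype=np.float32), 4000)
        starts = set()
        for seed in range(200):
            out = crop_or_pad(clip, 5.0, np.random.default_rng(seed))
            again = crop_or_pad(clip, 5.0, np.random.default_rng(seed))
            np.testing.assert_array_equal(out.samples, again.samples)
            start = int(out.samples[0])
            starts.add(start)
            assert 0 <= start <= 100_000
            np.testing.assert_array_equal(
                out.samples, np.arange(start, start + 20_000, dtype=np.float32)
            )
        assert len(starts) > 50  # the start offset is actually random


class TestLogmelGeometry:
    def test_5s_clip_is_32x313(self, rng):
        clip = AudioClip(rng.normal(size=20_000).astype(np.float32), 4000)
        spec = compute_logmel(clip, CFG)
        assert spec.values.shape == (32, 313)

    def test_frame_rate_62_5(self, rng):
        clip = AudioClip(rng.normal(size=4000).astype(np.float32), 4000)
        spec = compute_logmel(clip, CFG)
        assert spec.frame_rate == pytest.approx(62.5)
        assert spec.values.shape == (32, 63)

    def test_window_and_hop_durations(self):
        assert CFG.window_len / 4000 == pytest.approx(0.064)  # 64 ms
        assert CFG.hop_len / 4000 == pytest.approx(0.016)  # 16 ms

    def test_frame_count_non_decreasing(self):
        counts = [n_frames(n) for n in range(1, 3000, 37)]
        assert all(b >= a for a, b in zip(counts, counts[1:]))

    def test_zero_signal_constant_log_floor(self):
        clip = AudioClip(np.zeros(4000, dtype=np.float32), 4000)
        spec = compute_logmel(clip, CFG)
        np.testing.assert_allclose(spec.values, np.log(CFG.log_floor), rtol=1e-6)

    def test_deterministic(self, rng):
        clip = AudioClip(rng.normal(size=9000).astype(np.float32), 4000)
        a = compute_logmel(clip, CFG).values
        b = compute_logmel(clip, CFG).values
        np.testing.assert_array_equal(a, b)

    def test_sub_window_clip_single_frame(self):
        clip = AudioClip(np.ones(50, dtype=np.float32), 4000)
        spec = compute_logmel(clip, CFG)
        assert spec.values.shape == (32, 1)


class TestMelFilterbank:
    def test_rows_nonneg_contiguous_support_in_band(self):
        fb = mel_filterbank(32, 256, 4000, 250.0, 750.0)
        freqs = np.linspace(0, 2000, 129)
        assert (fb >= 0).all()
        for row in fb:
            support = np.flatnonzero(row > 0)
            assert support.size > 0
            assert np.array_equal(support, np.arange(support[0], support[-1] + 1))
            assert freqs[support[0]] > 250.0 - 2000 / 128
            assert freqs[support[-1]] < 750.0 + 2000 / 128

    def test_out_of_band_tone_invisible(self):
        in_band = compute_logmel(tone(500.0), CFG).values.max()
        out_band = compute_logmel(tone(1500.0), CFG).values.max()
        assert in_band > out_band + 3.0


class TestConfigFile:
    def test_yaml_round_trip(self, tmp_path):
        path = tmp_path / "spec.yaml"
        path.write_text("window_len: 128\nhop_len: 32\nn_mels: 16\nf_high: 900.0\n")
        cfg = SpectrogramConfig.from_yaml(path)
        assert (cfg.window_len, cfg.hop_len, cfg.n_mels) == (128, 32, 16)
        assert cfg.f_low == 250.0  # untouched default

    def test_unknown_key_rejected(self, tmp_path):
        path = tmp_path / "bad.yaml"
        path.write_text("fft_size: 512\n")
        with pytest.raises(ValueError, match="unknown config keys"):
            SpectrogramConfig.from_yaml(path)


class TestBandpass:
    def test_passband_tone_preserved(self):
        clip = tone(500.0, seconds=2.0)
        out = bandpass_filter(clip, 250.0, 750.0)
        ratio = np.sqrt(np.mean(out.samples**2) / np.mean(clip.samples**2))
        assert abs(20 * np.log10(ratio)) < 1.0

    @pytest.mark.parametrize("freq", [50.0, 1900.0])
    def test_stopband_attenuated_40db(self, freq):
        clip = tone(freq, seconds=2.0)
        out = bandpass_filter(clip, 250.0, 750.0)
        ratio = np.sqrt(np.mean(out.samples**2) / np.mean(clip.samples**2))
        assert 20 * np.log10(ratio) < -40.0

    def test_zero_in_zero_out(self):
        clip = AudioClip(np.zeros(4000, dtype=np.float32), 4000)
        out = bandpass_filter(clip, 250.0, 750.0)
        np.testing.assert_allclose(out.samples, 0.0, atol=1e-12)

    def test_invalid_band_rejected(self):
        with pytest.raises(ValueError):
            bandpass_filter(tone(100.0), 750.0, 250.0)


class TestBandNorm:
    def test_batch_standardized_per_band(self, rng):
        specs = [
            compute_logmel(AudioClip(rng.normal(size=20_000).astype(np.float32), 4000))
            for _ in range(8)
        ]
        batch = np.stack([s.values for s in specs])
        stats = fit_band_stats(specs)
        normed = stats.update(batch)  # training mode on the same batch
        assert np.abs(normed.mean(axis=(0, 2))).max() < 1e-4
        np.testing.assert_allclose(normed.var(axis=(0, 2)), 1.0, atol=1e-3)

    def test_bands_centred_independently(self, rng):
        base = rng.normal(size=(4, 2, 50)).astype(np.float32)
        base[:, 0] += 10.0  # band 0 offset differs from band 1
        before = base.mean(axis=(0, 2))
        assert abs(before[0] - before[1]) > 5.0
        from auscult.spectrogram import BandStats

        stats = BandStats(2)
        normed = stats.update(base)
        after = normed.mean(axis=(0, 2))
        assert abs(after[0] - after[1]) < 1e-4

    def test_constant_band_maps_to_zero(self):
        from auscult.spectrogram import BandStats

        batch = np.full((3, 2, 10), 7.0, dtype=np.float32)
        stats = BandStats(2)
        normed = stats.update(batch)
        np.testing.assert_allclose(normed, 0.0, atol=1e-2)

    def test_empty_batch_rejected(self):
        with pytest.raises(ValueError):
            fit_band_stats([])


class TestSpecAugment:
    def _spec(self, rng):
        return compute_logmel(
            AudioClip(rng.normal(size=20_000).astype(np.float32), 4000), CFG
        )

    def test_zero_masks_identity(self, rng):
        spec = self._spec(rng)
        out = spec_augment(spec, 0, 0, rng=np.random.default_rng(0))
        np.testing.assert_array_equal(out.values, spec.values)

    def test_time_mask_width_counts(self, rng):
        spec = self._spec(rng)
        for seed in range(20):
            out = spec_augment(
                spec, n_freq_masks=0, n_time_masks=1, max_time_width=10,
                rng=np.random.default_rng(seed), fill=np.nan,
            )
            changed = np.flatnonzero(np.isnan(out.values).any(axis=0))
            assert changed.size <= 10
            if changed.size:  # masked columns are contiguous
                assert np.array_equal(
                    changed, np.arange(changed[0], changed[-1] + 1)
                )

    def test_deterministic_given_seed(self, rng):
        spec = self._spec(rng)
        a = spec_augment(spec, rng=np.random.default_rng(7)).values
        b = spec_augment(spec, rng=np.random.default_rng(7)).values
        np.testing.assert_array_equal(a, b)

    def test_unmasked_cells_unchanged(self, rng):
        spec = self._spec(rng)
        out = spec_augment(spec, rng=np.random.default_rng(3), fill=np.nan)
        mask = np.isnan(out.values)
        np.testing.assert_array_equal(out.values[~mask], spec.values[~mask])
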