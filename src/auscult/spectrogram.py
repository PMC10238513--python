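"""Band-limited log-mel spectrogram front end.

Audio is framed with a 256-sample Hann window and 64-sample hop (64 ms and
16 ms at 4 kHz, i.e. 62.5 frames per second), magnitude spectra are projected
onto 32 mel bands spanning 250-750 Hz, and converted to log magnitudes.  The
narrow band suppresses heart sounds and ambient noise below 250 Hz and leaves
the tonal range of wheezes and the broadband signature of crackles intact.
A 5-second clip maps to a 32 x 313 matrix.

Also provides training-time utilities: random 5-second crop / zero-pad,
optional zero-phase band-pass filtering, per-band normalization statistics,
and SpecAugment-style time/frequency masking.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path

import numpy as np
import yaml
from scipy.signal import butter, sosfiltfilt
from scipy.signal.windows import hann

from .audio_io import AudioClip
from ._nn import BatchNorm

__all__ = [
    "SpectrogramConfig",
    "Spectrogram",
    "BandStats",
    "crop_or_pad",
    "bandpass_filter",
    "mel_filterbank",
    "compute_logmel",
    "logmel_batch",
    "n_frames",
    "fit_band_stats",
    "apply_band_norm",
    "spec_augment",
]


@dataclass(frozen=True)
class SpectrogramConfig:
    """STFT and mel-projection parameters (defaults follow the 4 kHz pipeline)."""

    window_len: int = 256  # samples (64 ms at 4 kHz)
    hop_len: int = 64  # samples (16 ms at 4 kHz)
    n_mels: int = 32
    f_low: float = 250.0  # Hz
    f_high: float = 750.0  # Hz
    log_floor: float = 1e-10

    def __post_init__(self) -> None:
        if self.hop_len > self.window_len:
            raise ValueError("hop_len must not exceed window_len")
        if not (0 <= self.f_low < self.f_high):
            raise ValueError("need 0 <= f_low < f_high")
        if self.n_mels < 1:
            raise ValueError("n_mels must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SpectrogramConfig":
        """Load a config from a YAML mapping whose keys mirror the fields."""
        doc = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        return cls(**doc)


@dataclass
class Spectrogram:
    """A log-mel matrix (n_mels x T) with its frame-time geometry."""

    values: np.ndarray
    frame_rate: float  # frames / second = rate / hop_len
    frame_times: np.ndarray  # centre time of each frame (s)

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]


def n_frames(n_samples: int, cfg: SpectrogramConfig | None = None) -> int:
    """Frame count of a centred STFT: floor(n / hop) + 1."""
    cfg = cfg or SpectrogramConfig()
    return n_samples // cfg.hop_len + 1


def crop_or_pad(
    clip: AudioClip, duration: float, rng: np.random.Generator
) -> AudioClip:
    """Extract a fixed-duration window for batch training.

    Shorter clips are right-padded with zeros; longer clips yield a contiguous
    window whose start offset is drawn uniformly from the valid range.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    n_target = int(round(duration * clip.rate))
    x = clip.samples
    if x.size < n_target:
        out = np.zeros(n_target, dtype=np.float32)
        out[: x.size] = x
    elif x.size == n_target:
        out = x
    else:
        start = int(rng.integers(0, x.size - n_target + 1))
        out = x[start : start + n_target]
    return AudioClip(
        out, clip.rate, patient_id=clip.patient_id, site=clip.site, centre=clip.centre
    )


def bandpass_filter(clip: AudioClip, f_low: float, f_high: float, order: int = 5) -> AudioClip:
    """Zero-phase Butterworth band-pass (>= 40 dB one octave outside the band)."""
    nyq = clip.rate / 2.0
    if not (0 < f_low < f_high < nyq):
        raise ValueError(f"invalid band ({f_low}, {f_high}) for rate {clip.rate}")
    sos = butter(order, [f_low, f_high], btype="bandpass", fs=clip.rate, output="sos")
    filtered = sosfiltfilt(sos, clip.samples.astype(np.float64)).astype(np.float32)
    return AudioClip(
        filtered, clip.rate, patient_id=clip.patient_id, site=clip.site, centre=clip.centre
    )


def _hz_to_mel(f: np.ndarray | float) -> np.ndarray:
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=np.float64) / 700.0)


def _mel_to_hz(m: np.ndarray | float) -> np.ndarray:
    return 700.0 * (10.0 ** (np.asarray(m, dtype=np.float64) / 2595.0) - 1.0)


def mel_filterbank(
    n_mels: int, n_fft: int, rate: int, f_low: float, f_high: float
) -> np.ndarray:
    """Triangular mel filterbank (HTK mel scale), shape (n_mels, n_fft//2 + 1).

    Filter endpoints sit exactly at ``f_low`` and ``f_high``; rows are
    non-negative with contiguous support.
    """
    n_bins = n_fft // 2 + 1
    fft_freqs = np.linspace(0.0, rate / 2.0, n_bins)
    mel_pts = np.linspace(_hz_to_mel(f_low), _hz_to_mel(f_high), n_mels + 2)
    hz_pts = _mel_to_hz(mel_pts)
    fb = np.zeros((n_mels, n_bins), dtype=np.float64)
    for i in range(n_mels):
        lo, ctr, hi = hz_pts[i], hz_pts[i + 1], hz_pts[i + 2]
        up = (fft_freqs - lo) / max(ctr - lo, 1e-12)
        down = (hi - fft_freqs) / max(hi - ctr, 1e-12)
        fb[i] = np.maximum(0.0, np.minimum(up, down))
    return fb.astype(np.float32)


def _frame_signal(x: np.ndarray, cfg: SpectrogramConfig) -> np.ndarray:
    """Centred framing with reflect padding: frame f is centred at f * hop."""
    w, h = cfg.window_len, cfg.hop_len
    half = w // 2
    n = x.shape[-1]
    if n > half:
        pad = np.pad(x, [(0, 0)] * (x.ndim - 1) + [(half, half)], mode="reflect")
    else:  # too short to reflect; fall back to zero padding
        pad = np.pad(x, [(0, 0)] * (x.ndim - 1) + [(half, half)])
    t = n // h + 1
    idx = np.arange(w)[None, :] + h * np.arange(t)[:, None]
    return pad[..., idx]  # (..., T, window)


def _logmel_values(x: np.ndarray, rate: int, cfg: SpectrogramConfig) -> np.ndarray:
    """Log-mel matrices for one (n,) or a batch (B, n) of waveforms."""
    frames = _frame_signal(np.asarray(x, dtype=np.float32), cfg)
    window = hann(cfg.window_len, sym=False).astype(np.float32)
    spec = np.abs(np.fft.rfft(frames * window, axis=-1))  # (..., T, bins)
    fb = mel_filterbank(cfg.n_mels, cfg.window_len, rate, cfg.f_low, cfg.f_high)
    mel = spec @ fb.T  # (..., T, n_mels)
    out = np.log(mel + cfg.log_floor).astype(np.float32)
    return np.swapaxes(out, -1, -2)  # (..., n_mels, T)


def compute_logmel(clip: AudioClip, cfg: SpectrogramConfig | None = None) -> Spectrogram:
    """Log-mel spectrogram of a clip; deterministic for identical input."""
    cfg = cfg or SpectrogramConfig()
    values = _logmel_values(clip.samples, clip.rate, cfg)
    t = values.shape[1]
    return Spectrogram(
        values=values,
        frame_rate=clip.rate / cfg.hop_len,
        frame_times=np.arange(t) * cfg.hop_len / clip.rate,
    )


def logmel_batch(waveforms: np.ndarray, rate: int, cfg: SpectrogramConfig | None = None) -> np.ndarray:
    """Batched log-mel transform: (B, n_samples) -> (B, n_mels, T)."""
    cfg = cfg or SpectrogramConfig()
    return _logmel_values(waveforms, rate, cfg)


class BandStats:
    """Per-mel-band normalization statistics with learned scale/shift.

    Thin wrapper over batch normalization applied with the mel bands as
    channels, so every frequency band is standardized independently.
    """

    def __init__(self, n_mels: int):
        self._bn = BatchNorm(n_mels)

    @property
    def mean(self) -> np.ndarray:
        return self._bn.running_mean

    @property
    def var(self) -> np.ndarray:
        return self._bn.running_var

    def update(self, batch: np.ndarray) -> np.ndarray:
        """Normalize a (B, n_mels, T) batch with batch statistics and update
        the running statistics (training mode)."""
        return self._bn.forward(batch, training=True)

    def normalize(self, batch: np.ndarray) -> np.ndarray:
        """Normalize with the running statistics (inference mode)."""
        return self._bn.forward(batch, training=False)


def fit_band_stats(specs: list[Spectrogram]) -> BandStats:
    """Fit per-band statistics on a non-empty batch of equal-length spectrograms."""
    if not specs:
        raise ValueError("cannot fit band statistics on an empty batch")
    batch = np.stack([s.values for s in specs])
    stats = BandStats(batch.shape[1])
    stats.update(batch)
    return stats


def apply_band_norm(spec: Spectrogram, stats: BandStats, training: bool = False) -> Spectrogram:
    """Normalize one spectrogram band-wise with fitted statistics."""
    batch = spec.values[None]
    values = stats.update(batch)[0] if training else stats.normalize(batch)[0]
    return Spectrogram(values=values, frame_rate=spec.frame_rate, frame_times=spec.frame_times)


def spec_augment(
    spec: Spectrogram,
    n_freq_masks: int = 2,
    n_time_masks: int = 2,
    max_freq_width: int = 8,
    max_time_width: int = 32,
    rng: np.random.Generator | None = None,
    fill: float | None = None,
) -> Spectrogram:
    """Mask random frequency bands and time ranges.

    Masked cells are set to ``fill``; by default the per-band mean of the
    input, which is the band-normalized zero value once per-band
    normalization is applied.  Deterministic given ``rng``.
    """
    rng = rng or np.random.default_rng()
    values = spec.values.copy()
    f, t = values.shape
    if max_freq_width > f or max_time_width > t:
        raise ValueError("mask width exceeds spectrogram dimension")
    band_fill = values.mean(axis=1) if fill is None else np.full(f, fill, dtype=values.dtype)
    for _ in range(n_freq_masks):
        width = int(rng.integers(0, max_freq_width + 1))
        if width:
            start = int(rng.integers(0, f - width + 1))
            values[start : start + width, :] = band_fill[start : start + width, None]
    for _ in range(n_time_masks):
        width = int(rng.integers(0, max_time_width + 1))
        if width:
            start = int(rng.integers(0, t - width + 1))
            values[:, start : start + width] = band_fill[:, None]
    return Spectrogram(values=values, frame_rate=spec.frame_rate, frame_times=spec.frame_times)
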