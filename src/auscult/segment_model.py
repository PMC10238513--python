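"""CNN audio classifier with temporal attention pooling.

The trunk is a stack of convolutional blocks (two 3x3 convolutions with batch
normalization and ReLU each), with 2x2 average pooling after every block but
the last (capped at four poolings, matching the standard five-block
configuration).  After the last block the frequency axis is averaged away,
feature maps are smoothed over time (summed size-3 average and max pooling),
and a per-time-step fully connected layer yields a sequence of feature
vectors x = {x_1..x_T}, one per *segment* of the recording.

An attention block computes, per segment, a prediction p(x_i) (sigmoid head)
and an attention logit v(x_i) (tanh head).  Attention values are normalized
over segments,

    g(x_i) = exp(v(x_i)) / sum_j exp(v(x_j)),

and the clip-level prediction is the attention-weighted mean

    p(x) = sum_i g(x_i) p(x_i),

a convex combination of the segment predictions.  At inference the model
consumes recordings of any duration; fixed 5-second crops are only a
training-time batching device.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from . import _nn
from .audio_io import AudioClip
from .spectrogram import SpectrogramConfig, compute_logmel, logmel_batch

__all__ = [
    "ModelConfig",
    "SegmentGeometry",
    "SegmentOutputs",
    "BreathCNN",
    "attention_pool",
    "segment_time_span",
    "analytic_receptive_field",
    "empirical_receptive_field",
    "predict_clip",
]


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    The default is the full five-block network with channels doubling up to a
    final feature width of 1024.  ``rf_frames`` fixes the receptive-field
    width (in STFT frames) used to map segments to time spans; when ``None``
    the analytic receptive field of the architecture is used.  The standard
    configuration pins it to the conventional 78-frame / 1296 ms geometry.
    """

    n_blocks: int = 5
    channels: tuple[int, ...] = (64, 128, 256, 512, 1024)
    dropout: float = 0.2
    n_mels: int = 32
    rf_frames: int | None = 78

    def __post_init__(self) -> None:
        if len(self.channels) != self.n_blocks:
            raise ValueError("need one channel count per block")

    @property
    def n_pools(self) -> int:
        return min(max(self.n_blocks - 1, 0), 4)

    @property
    def stride_frames(self) -> int:
        """Input frames consumed per output segment."""
        return 2**self.n_pools

    @staticmethod
    def reduced(channels: tuple[int, ...] = (8, 16), dropout: float = 0.2) -> "ModelConfig":
        """A small two-block configuration for desk-scale experiments."""
        return ModelConfig(
            n_blocks=len(channels), channels=channels, dropout=dropout, rf_frames=None
        )


@dataclass(frozen=True)
class SegmentGeometry:
    """Mapping from segment index to a time span of the input clip."""

    rf_frames: int  # receptive-field width in STFT frames
    stride_frames: int  # frames between consecutive segment centres
    window_len: int = 256  # STFT window (samples)
    hop_len: int = 64  # STFT hop (samples)
    rate: int = 4000  # Hz

    @property
    def span_seconds(self) -> float:
        """Width of one segment's span: ((rf - 1) * hop + window) / rate."""
        return ((self.rf_frames - 1) * self.hop_len + self.window_len) / self.rate

    @property
    def stride_seconds(self) -> float:
        return self.stride_frames * self.hop_len / self.rate


def segment_time_span(
    i: int, geometry: SegmentGeometry, n_segments: int | None = None,
    clip_duration: float | None = None,
) -> tuple[float, float]:
    """Time span (seconds) covered by segment ``i``, clipped to clip bounds."""
    if i < 0 or (n_segments is not None and i >= n_segments):
        raise IndexError(f"segment index {i} out of range")
    centre_frame = i * geometry.stride_frames
    half_window = geometry.window_len / 2
    start = (centre_frame - (geometry.rf_frames - 1) / 2) * geometry.hop_len - half_window
    end = (centre_frame + (geometry.rf_frames - 1) / 2) * geometry.hop_len + half_window
    start_s = max(start / geometry.rate, 0.0)
    end_s = end / geometry.rate
    if clip_duration is not None:
        end_s = min(end_s, clip_duration)
        start_s = min(start_s, end_s)
    return (start_s, end_s)


def analytic_receptive_field(cfg: ModelConfig) -> int:
    """Receptive-field width (input frames) of one output segment, from the
    layer-by-layer composition of 3x3 convolutions, 2x2 poolings and the
    size-3 time smoothing."""
    rf, stride = 1, 1
    for b in range(cfg.n_blocks):
        rf += 2 * 2 * stride  # two 3x3 convolutions
        if b < cfg.n_pools:
            rf += stride  # 2x2 average pooling window
            stride *= 2
    rf += 2 * stride  # size-3 time smoothing
    return rf


@dataclass
class SegmentOutputs:
    """Per-segment predictions/attention plus the clip-level score."""

    p: np.ndarray  # segment predictions p(x_i), in [0, 1]
    v: np.ndarray  # attention logits v(x_i), in (-1, 1) (tanh head)
    g: np.ndarray  # normalized attention, sums to 1
    clip_p: float  # clip-level prediction p(x)
    spans: list[tuple[float, float]] = field(default_factory=list)


def attention_pool(p: np.ndarray, v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Normalize attention logits and pool segment predictions.

    Accepts (T,) or (N, T) arrays; returns (g, clip_p).
    """
    g = _nn.softmax(np.asarray(v, dtype=np.float64), axis=-1)
    clip_p = (g * np.asarray(p, dtype=np.float64)).sum(axis=-1)
    return g, clip_p


class BreathCNN:
    """The attention-pooled audio classifier (NumPy, manual gradients)."""

    def __init__(
        self,
        cfg: ModelConfig | None = None,
        spec_cfg: SpectrogramConfig | None = None,
        seed: int = 0,
    ):
        self.cfg = cfg or ModelConfig()
        self.spec_cfg = spec_cfg or SpectrogramConfig(n_mels=self.cfg.n_mels)
        if self.spec_cfg.n_mels != self.cfg.n_mels:
            raise ValueError(
                f"model expects {self.cfg.n_mels} mel bands but the spectrogram "
                f"config produces {self.spec_cfg.n_mels}"
            )
        self.rng = np.random.default_rng(seed)
        rng = self.rng
        c = self.cfg

        self.input_bn = _nn.BatchNorm(c.n_mels)  # per-band normalization
        layers2d: list[_nn.Layer] = []
        prev = 1
        for b, ch in enumerate(c.channels):
            layers2d += [
                _nn.Conv2d(prev, ch, rng),
                _nn.BatchNorm(ch),
                _nn.ReLU(),
                _nn.Conv2d(ch, ch, rng),
                _nn.BatchNorm(ch),
                _nn.ReLU(),
            ]
            if b < c.n_pools:
                layers2d += [_nn.AvgPool2x2(), _nn.Dropout(c.dropout, rng)]
            prev = ch
        self.stack2d = _nn.Sequential(*layers2d)
        width = c.channels[-1]
        self.time_stack = _nn.Sequential(
            _nn.FreqMean(),
            _nn.TimeSmooth(),
            _nn.Dropout(c.dropout, rng),
            _nn.PointwiseLinear(width, width, rng),
            _nn.ReLU(),
            _nn.Dropout(c.dropout, rng),
        )
        # zero-initialized heads: untrained model outputs p = 0.5 with uniform
        # attention, so the initial BCE loss is ln 2 per clip
        self.p_head = _nn.PointwiseLinear(width, 1, rng, zero_init=True)
        self.v_head = _nn.PointwiseLinear(width, 1, rng, zero_init=True)
        self._fwd: dict | None = None

    # ---------------------------------------------------------------- params
    def params(self) -> list[_nn.Param]:
        return (
            self.input_bn.params()
            + self.stack2d.params()
            + self.time_stack.params()
            + self.p_head.params()
            + self.v_head.params()
        )

    def state_dict(self) -> dict:
        state = {"params": [p.data.copy() for p in self.params()], "bn": []}
        for layer in self._bn_layers():
            state["bn"].append((layer.running_mean.copy(), layer.running_var.copy()))
        return state

    def load_state_dict(self, state: dict) -> None:
        for p, data in zip(self.params(), state["params"]):
            p.data[...] = data
        for layer, (rm, rv) in zip(self._bn_layers(), state["bn"]):
            layer.running_mean[...] = rm
            layer.running_var[...] = rv

    def _bn_layers(self) -> list[_nn.BatchNorm]:
        bns = [self.input_bn]
        for layer in self.stack2d.layers + self.time_stack.layers:
            if isinstance(layer, _nn.BatchNorm):
                bns.append(layer)
        return bns

    # --------------------------------------------------------------- forward
    def forward_features(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """Spectrogram batch (N, n_mels, T) -> feature sequence (N, C, T')."""
        h = self.input_bn.forward(x.astype(np.float32), training)
        h = self.stack2d.forward(h[:, None, :, :], training)
        return self.time_stack.forward(h, training)

    def forward(self, x: np.ndarray, training: bool = False) -> dict[str, np.ndarray]:
        """Full forward pass on a spectrogram batch (N, n_mels, T).

        Returns segment predictions ``p`` (N, T'), attention logits ``v``,
        normalized attention ``g`` and clip-level ``clip_p`` (N,).
        """
        feats = self.forward_features(x, training)
        s = self.p_head.forward(feats, training)[:, 0, :]  # (N, T')
        w = self.v_head.forward(feats, training)[:, 0, :]
        p = _nn.sigmoid(s)
        v = np.tanh(w)
        g, clip_p = attention_pool(p, v)
        self._fwd = {"p": p, "v": v, "g": g, "clip_p": clip_p} if training else None
        return {"p": p, "v": v, "g": g.astype(np.float32), "clip_p": clip_p}

    def backward(self, dclip: np.ndarray) -> np.ndarray:
        """Backpropagate d(loss)/d(clip_p) through attention, heads and trunk."""
        assert self._fwd is not None, "backward requires forward(training=True)"
        p, v, g, clip_p = (self._fwd[k] for k in ("p", "v", "g", "clip_p"))
        dclip = np.asarray(dclip, dtype=np.float64)[:, None]  # (N, 1)
        dp = dclip * g
        dv = dclip * g * (p - clip_p[:, None])
        ds = (dp * p * (1.0 - p)).astype(np.float32)  # sigmoid head logit
        dw = (dv * (1.0 - v**2)).astype(np.float32)  # tanh head pre-activation
        dfeat = self.p_head.backward(ds[:, None, :]) + self.v_head.backward(dw[:, None, :])
        return self.features_backward(dfeat)

    def features_backward(self, dfeat: np.ndarray) -> np.ndarray:
        """Backpropagate a feature-sequence gradient to the input spectrogram."""
        dh = self.time_stack.backward(dfeat)
        dh = self.stack2d.backward(dh)
        return self.input_bn.backward(dh[:, 0, :, :])

    # -------------------------------------------------------------- geometry
    def geometry(self) -> SegmentGeometry:
        rf = self.cfg.rf_frames or analytic_receptive_field(self.cfg)
        return SegmentGeometry(
            rf_frames=rf,
            stride_frames=self.cfg.stride_frames,
            window_len=self.spec_cfg.window_len,
            hop_len=self.spec_cfg.hop_len,
        )

    def copy(self) -> "BreathCNN":
        clone = BreathCNN(self.cfg, self.spec_cfg)
        clone.load_state_dict(copy.deepcopy(self.state_dict()))
        return clone


def save_model(path, model: BreathCNN) -> None:
    """Serialize a model (architecture + weights + BN statistics) as NPZ."""
    import json

    cfg, spec = model.cfg, model.spec_cfg
    meta = {
        "n_blocks": cfg.n_blocks, "channels": list(cfg.channels),
        "dropout": cfg.dropout, "n_mels": cfg.n_mels, "rf_frames": cfg.rf_frames,
        "window_len": spec.window_len, "hop_len": spec.hop_len,
        "f_low": spec.f_low, "f_high": spec.f_high, "log_floor": spec.log_floor,
    }
    state = model.state_dict()
    arrays = {f"param_{i}": a for i, a in enumerate(state["params"])}
    for i, (rm, rv) in enumerate(state["bn"]):
        arrays[f"bn_mean_{i}"] = rm
        arrays[f"bn_var_{i}"] = rv
    np.savez(path, meta=json.dumps(meta), **arrays)


def load_model(path) -> BreathCNN:
    import json

    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        cfg = ModelConfig(
            n_blocks=meta["n_blocks"], channels=tuple(meta["channels"]),
            dropout=meta["dropout"], n_mels=meta["n_mels"], rf_frames=meta["rf_frames"],
        )
        spec_cfg = SpectrogramConfig(
            window_len=meta["window_len"], hop_len=meta["hop_len"],
            n_mels=meta["n_mels"], f_low=meta["f_low"], f_high=meta["f_high"],
            log_floor=meta["log_floor"],
        )
        model = BreathCNN(cfg, spec_cfg)
        n_params = len(model.params())
        state = {
            "params": [data[f"param_{i}"] for i in range(n_params)],
            "bn": [
                (data[f"bn_mean_{i}"], data[f"bn_var_{i}"])
                for i in range(len(model._bn_layers()))
            ],
        }
        model.load_state_dict(state)
    return model


def empirical_receptive_field(model: BreathCNN, n_frames: int = 512, seed: int = 0) -> int:
    """Measure the receptive-field width of one interior segment in input
    frames, as the support of the gradient of that segment's summed feature
    activations with respect to the input spectrogram."""
    rng = np.random.default_rng(seed)
    x = rng.normal(size=(1, model.cfg.n_mels, n_frames)).astype(np.float32)
    feats = model.forward_features(x, training=False)
    t_out = feats.shape[2]
    dfeat = np.zeros_like(feats)
    dfeat[0, :, t_out // 2] = 1.0
    dx = model.features_backward(dfeat)
    support = np.flatnonzero(np.abs(dx[0]).sum(axis=0) > 1e-12)
    return int(support[-1] - support[0] + 1) if support.size else 0


def predict_clip(
    clip: AudioClip,
    model: BreathCNN,
    spec_cfg: SpectrogramConfig | None = None,
) -> SegmentOutputs:
    """Full-length inference on one recording of arbitrary duration."""
    spec_cfg = spec_cfg or model.spec_cfg
    samples = clip.samples
    # pad so that at least one full segment's worth of frames is present
    min_samples = (model.cfg.stride_frames - 1) * spec_cfg.hop_len + 1
    if samples.size < min_samples:
        samples = np.pad(samples, (0, min_samples - samples.size))
    padded = AudioClip(samples, clip.rate, patient_id=clip.patient_id,
                       site=clip.site, centre=clip.centre)
    spec = compute_logmel(padded, spec_cfg)
    out = model.forward(spec.values[None], training=False)
    geom = model.geometry()
    t_out = out["p"].shape[1]
    spans = [
        segment_time_span(i, geom, t_out, clip_duration=clip.duration)
        for i in range(t_out)
    ]
    return SegmentOutputs(
        p=out["p"][0], v=out["v"][0], g=out["g"][0],
        clip_p=float(out["clip_p"][0]), spans=spans,
    )


def predict_waveforms(
    waveforms: np.ndarray, model: BreathCNN, rate: int = 4000, batch_size: int = 16,
) -> np.ndarray:
    """Clip-level scores for a stack of equal-length waveforms (B, n)."""
    scores = []
    for start in range(0, waveforms.shape[0], batch_size):
        batch = waveforms[start : start + batch_size]
        specs = logmel_batch(batch, rate, model.spec_cfg)
        scores.append(model.forward(specs, training=False)["clip_p"])
    return np.concatenate(scores)
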