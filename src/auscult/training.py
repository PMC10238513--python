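"""Training of one binary classifier per diagnostic class.

Each model is trained with binary cross-entropy on clip-level predictions
(the patient's diagnosis broadcast to all of its recordings), an AdamW
optimizer with a 1cycle learning-rate schedule, and a balanced sampling
strategy that equalizes the target class against the three other classes
and balances recording centres within each class.  From a configurable
epoch onward the tune fold is scored each epoch with the mean positional
AUROC (one AUROC per thoracic site, averaged), and the best checkpoint is
kept.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score

from ._nn import AdamW, one_cycle_lr
from .audio_io import DIAGNOSES, SITES, AudioClip, PatientRecord
from .segment_model import BreathCNN, ModelConfig
from .spectrogram import SpectrogramConfig, crop_or_pad, logmel_batch, spec_augment, Spectrogram

logger = logging.getLogger(__name__)

__all__ = [
    "TrainConfig",
    "Recording",
    "recordings_from_patients",
    "balanced_batches",
    "one_cycle_lr",
    "mean_positional_auroc",
    "train_binary_model",
]


@dataclass(frozen=True)
class TrainConfig:
    """Optimization hyperparameters (defaults follow the standard recipe)."""

    batch_size: int = 64
    epochs: int = 100
    selection_start_epoch: int = 60
    max_lr: float = 1e-3
    weight_decay: float = 5e-3
    crop_duration: float = 5.0  # seconds
    seed: int = 0
    augment: bool = True

    def __post_init__(self) -> None:
        if self.selection_start_epoch >= self.epochs:
            raise ValueError("selection_start_epoch must be < epochs")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


@dataclass
class Recording:
    """One recording with the labels used for sampling and training."""

    clip: AudioClip
    patient_id: str
    site: str
    centre: str
    diagnosis: str


def recordings_from_patients(patients: list[PatientRecord]) -> list[Recording]:
    """Flatten patients into their available recordings (all clips are used
    for CNN training, regardless of per-patient completeness)."""
    recs = []
    for patient in patients:
        for site, clip in patient.clips.items():
            recs.append(
                Recording(
                    clip=clip,
                    patient_id=patient.patient_id,
                    site=site,
                    centre=patient.centre,
                    diagnosis=patient.diagnosis,
                )
            )
    return recs


def _sampling_probabilities(
    recordings: list[Recording], target_class: str
) -> np.ndarray:
    """Per-recording sampling probabilities balancing the binary target and
    centres: positives and negatives equiprobable, negatives split equally
    across the present other classes, centres equiprobable within a class."""
    if target_class not in DIAGNOSES:
        raise ValueError(f"unknown target class {target_class!r}")
    if not any(r.diagnosis == target_class for r in recordings):
        raise ValueError(f"target class {target_class!r} absent from dataset")
    by_class: dict[str, dict[str, list[int]]] = {}
    for i, rec in enumerate(recordings):
        by_class.setdefault(rec.diagnosis, {}).setdefault(rec.centre, []).append(i)
    neg_classes = [d for d in DIAGNOSES if d != target_class and d in by_class]
    probs = np.zeros(len(recordings))
    for diagnosis, centres in by_class.items():
        if diagnosis == target_class:
            class_mass = 0.5
        else:
            class_mass = 0.5 / len(neg_classes)
        centre_mass = class_mass / len(centres)
        for idxs in centres.values():
            probs[list(idxs)] = centre_mass / len(idxs)
    return probs / probs.sum()


def balanced_batches(
    recordings: list[Recording],
    target_class: str,
    cfg: TrainConfig,
    rng: np.random.Generator,
    n_draws: int | None = None,
):
    """Yield index batches for one epoch: exactly N draws (N = number of
    recordings) with replacement, in ceil(N / batch_size) batches."""
    if not recordings:
        raise ValueError("empty dataset")
    probs = _sampling_probabilities(recordings, target_class)
    n = n_draws if n_draws is not None else len(recordings)
    draws = rng.choice(len(recordings), size=n, replace=True, p=probs)
    for start in range(0, n, cfg.batch_size):
        yield draws[start : start + cfg.batch_size]


def mean_positional_auroc(
    scores: np.ndarray, sites: list[str], labels: np.ndarray
) -> float:
    """Mean over thoracic sites of the per-site AUROC of recording scores.

    Sites whose labels are single-class are excluded with a warning.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    site_arr = np.asarray(sites)
    aurocs = []
    for site in SITES:
        mask = site_arr == site
        if not mask.any():
            continue
        if len(np.unique(labels[mask])) < 2:
            warnings.warn(f"site {site}: single-class labels, excluded from mean AUROC")
            continue
        aurocs.append(roc_auc_score(labels[mask], scores[mask]))
    if not aurocs:
        raise ValueError("no site had both classes present")
    return float(np.mean(aurocs))


@dataclass
class TrainHistory:
    loss: list[float] = field(default_factory=list)  # mean BCE per epoch
    lr: list[float] = field(default_factory=list)  # last LR per epoch
    tune_auroc: dict[int, float] = field(default_factory=dict)  # epoch -> metric
    best_epoch: int | None = None
    best_auroc: float | None = None


def _bce_and_grad(clip_p: np.ndarray, labels: np.ndarray, eps: float = 1e-7):
    c = np.clip(clip_p, eps, 1.0 - eps)
    loss = -(labels * np.log(c) + (1.0 - labels) * np.log(1.0 - c)).mean()
    dclip = (c - labels) / (c * (1.0 - c)) / len(labels)
    return float(loss), dclip


def _score_recordings(model: BreathCNN, specs: list[np.ndarray], batch: int = 16) -> np.ndarray:
    """Clip scores for precomputed spectrogram matrices (grouped by length)."""
    scores = np.empty(len(specs))
    by_len: dict[int, list[int]] = {}
    for i, s in enumerate(specs):
        by_len.setdefault(s.shape[1], []).append(i)
    for idxs in by_len.values():
        for start in range(0, len(idxs), batch):
            chunk = idxs[start : start + batch]
            x = np.stack([specs[i] for i in chunk])
            scores[chunk] = model.forward(x, training=False)["clip_p"]
    return scores


def train_binary_model(
    train_recordings: list[Recording],
    tune_recordings: list[Recording],
    target_class: str,
    model_cfg: ModelConfig | None = None,
    train_cfg: TrainConfig | None = None,
    spec_cfg: SpectrogramConfig | None = None,
) -> tuple[BreathCNN, TrainHistory]:
    """Train one binary CNN (``target_class`` vs the rest).

    The loss is BCE between the clip-level attention-pooled prediction and
    the patient label broadcast to each recording.  Tune-fold evaluation
    (mean positional AUROC on full-length recordings) starts at
    ``selection_start_epoch`` and the best checkpoint is restored at the end.
    """
    train_cfg = train_cfg or TrainConfig()
    spec_cfg = spec_cfg or SpectrogramConfig()
    if not train_recordings or not tune_recordings:
        raise ValueError("train and tune folds must be non-empty")
    tune_labels = np.array(
        [int(r.diagnosis == target_class) for r in tune_recordings]
    )
    if len(np.unique(tune_labels)) < 2:
        raise ValueError("tune fold must contain positive and negative patients")

    rng = np.random.default_rng(train_cfg.seed)
    model = BreathCNN(model_cfg, spec_cfg, seed=train_cfg.seed)
    opt = AdamW(model.params(), lr=train_cfg.max_lr, weight_decay=train_cfg.weight_decay)

    n = len(train_recordings)
    steps_per_epoch = -(-n // train_cfg.batch_size)
    total_steps = train_cfg.epochs * steps_per_epoch
    rate = train_recordings[0].clip.rate
    n_crop = int(round(train_cfg.crop_duration * rate))
    labels_all = np.array(
        [int(r.diagnosis == target_class) for r in train_recordings]
    )
    tune_specs = [
        logmel_batch(r.clip.samples[None], rate, spec_cfg)[0] for r in tune_recordings
    ]
    tune_sites = [r.site for r in tune_recordings]

    history = TrainHistory()
    best_state = None
    step = 0
    for epoch in range(1, train_cfg.epochs + 1):
        epoch_losses = []
        lr = train_cfg.max_lr
        for batch_idx in balanced_batches(train_recordings, target_class, train_cfg, rng):
            waves = np.zeros((len(batch_idx), n_crop), dtype=np.float32)
            for row, i in enumerate(batch_idx):
                cropped = crop_or_pad(train_recordings[i].clip, train_cfg.crop_duration, rng)
                waves[row] = cropped.samples
            x = logmel_batch(waves, rate, spec_cfg)
            if train_cfg.augment:
                for row in range(x.shape[0]):
                    aug = spec_augment(
                        Spectrogram(x[row], rate / spec_cfg.hop_len,
                                    np.arange(x.shape[2]) * spec_cfg.hop_len / rate),
                        rng=rng,
                    )
                    x[row] = aug.values
            out = model.forward(x, training=True)
            loss, dclip = _bce_and_grad(out["clip_p"], labels_all[batch_idx])
            opt.zero_grad()
            model.backward(dclip)
            lr = one_cycle_lr(step, total_steps, train_cfg.max_lr)
            opt.step(lr=lr)
            step += 1
            epoch_losses.append(loss)
        history.loss.append(float(np.mean(epoch_losses)))
        history.lr.append(lr)

        if epoch > train_cfg.selection_start_epoch:
            scores = _score_recordings(model, tune_specs)
            metric = mean_positional_auroc(scores, tune_sites, tune_labels)
            history.tune_auroc[epoch] = metric
            if history.best_auroc is None or metric > history.best_auroc:
                history.best_auroc = metric
                history.best_epoch = epoch
                best_state = model.state_dict()
            logger.info(
                "epoch %d loss %.4f lr %.2e tune mAUROC %.3f",
                epoch, history.loss[-1], lr, metric,
            )
        else:
            logger.info("epoch %d loss %.4f lr %.2e", epoch, history.loss[-1], lr)

    if best_state is not None:
        model.load_state_dict(best_state)
    return model, history
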