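"""Patient-level aggregation of per-site clip scores.

For each binary model, the eight clip-level probabilities of a patient (one
per thoracic site, canonical order) form a length-8 feature vector scored by
a logistic regression fitted on the train+tune folds.  For multi-class
diagnosis, the four binary models' site vectors are stacked into a 4x8
array whose columns (sites) are L1-normalized, flattened class-major to a
length-32 vector, and classified with a multinomial logistic regression.
Patients missing any of the eight recordings are excluded from aggregation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.linear_model import LogisticRegression

from .audio_io import DIAGNOSES, SITES

__all__ = [
    "IncompletePatientError",
    "SiteVector",
    "MulticlassFeatures",
    "build_site_vector",
    "fit_binary_aggregator",
    "predict_patient",
    "build_multiclass_features",
    "fit_multiclass",
    "predict_diagnosis",
    "save_aggregator",
    "load_aggregator",
]

# deterministic convex solver settings shared by both aggregators (L2, C=1)
_SOLVER = dict(C=1.0, solver="lbfgs", tol=1e-6, max_iter=10_000)


class IncompletePatientError(ValueError):
    """Raised when a patient is missing one of the eight site recordings."""


@dataclass
class SiteVector:
    """Length-8 vector of clip probabilities in canonical site order."""

    scores: np.ndarray
    patient_id: str

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(SITES),):
            raise ValueError(f"expected {len(SITES)} site scores, got {self.scores.shape}")
        if ((self.scores < 0) | (self.scores > 1)).any():
            raise ValueError("site scores must lie in [0, 1]")


@dataclass
class MulticlassFeatures:
    """4 (classes) x 8 (sites) score array and its normalized flattening."""

    array: np.ndarray  # raw 4x8 clip probabilities
    flat: np.ndarray  # length-32, column-L1-normalized, class-major
    patient_id: str


def build_site_vector(predictions: dict[str, float], patient_id: str = "") -> SiteVector:
    """Order per-site clip probabilities canonically; all 8 sites required."""
    missing = [site for site in SITES if site not in predictions]
    if missing:
        raise IncompletePatientError(
            f"patient {patient_id or '<unknown>'} missing sites {missing}"
        )
    return SiteVector(
        scores=np.array([predictions[site] for site in SITES]), patient_id=patient_id
    )


def fit_binary_aggregator(
    vectors: list[SiteVector], labels: np.ndarray
) -> LogisticRegression:
    """Fit the site-score logistic regression on train+tune patients."""
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("aggregator fit requires both classes in the labels")
    x = np.stack([v.scores for v in vectors])
    return LogisticRegression(**_SOLVER).fit(x, y)


def predict_patient(vector: SiteVector, aggregator: LogisticRegression) -> float:
    """Calibrated patient-level probability from one site vector."""
    return float(aggregator.predict_proba(vector.scores[None])[0, 1])


def build_multiclass_features(
    site_vectors: dict[str, SiteVector], patient_id: str = ""
) -> MulticlassFeatures:
    """Stack the four binary models' site vectors and column-L1-normalize.

    ``site_vectors`` maps each diagnosis to that binary model's SiteVector.
    A column summing to zero is left as zeros rather than inventing uniform
    evidence.
    """
    missing = [d for d in DIAGNOSES if d not in site_vectors]
    if missing:
        raise ValueError(f"missing binary-model outputs for {missing}")
    array = np.stack([site_vectors[d].scores for d in DIAGNOSES])  # 4 x 8
    sums = array.sum(axis=0, keepdims=True)
    normalized = np.divide(array, sums, out=np.zeros_like(array), where=sums > 0)
    return MulticlassFeatures(
        array=array, flat=normalized.reshape(-1), patient_id=patient_id
    )


def fit_multiclass(
    features: list[MulticlassFeatures], diagnoses: list[str]
) -> LogisticRegression:
    """Fit the multinomial logistic regression on train+tune patients."""
    present = set(diagnoses)
    if present != set(DIAGNOSES):
        raise ValueError(
            f"multiclass fit requires all four diagnoses, got {sorted(present)}"
        )
    x = np.stack([f.flat for f in features])
    y = np.array([DIAGNOSES.index(d) for d in diagnoses])
    return LogisticRegression(**_SOLVER).fit(x, y)


def predict_diagnosis(
    features: MulticlassFeatures, aggregator: LogisticRegression
) -> dict[str, float]:
    """Per-diagnosis probabilities (summing to 1) for one patient."""
    proba = aggregator.predict_proba(features.flat[None])[0]
    return {DIAGNOSES[int(c)]: float(p) for c, p in zip(aggregator.classes_, proba)}


def save_aggregator(path: str | Path, aggregator: LogisticRegression) -> None:
    """Serialize an aggregator as a small JSON document."""
    doc = {
        "coef": aggregator.coef_.tolist(),
        "intercept": aggregator.intercept_.tolist(),
        "classes": aggregator.classes_.tolist(),
        "n_features": int(aggregator.coef_.shape[1]),
        "site_order": list(SITES),
        "class_order": list(DIAGNOSES),
    }
    Path(path).write_text(json.dumps(doc, indent=2))


def load_aggregator(path: str | Path) -> LogisticRegression:
    doc = json.loads(Path(path).read_text())
    agg = LogisticRegression(**_SOLVER)
    agg.coef_ = np.array(doc["coef"])
    agg.intercept_ = np.array(doc["intercept"])
    agg.classes_ = np.array(doc["classes"])
    agg.n_features_in_ = doc["n_features"]
    return agg
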