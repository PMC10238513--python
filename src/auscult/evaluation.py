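"""Nested cross-validation, metrics with confidence intervals, the clinical
baseline, and the inference duration/position sweep.

Internal evaluation uses nested 5-fold stratified cross-validation on
patients: every ordered (test fold, tune fold) pair defines one split, so
k folds give k*(k-1) splits (20 for k = 5).  Sensitivity and specificity
carry exact Clopper-Pearson intervals; AUROC carries DeLong intervals.
External-style evaluation averages predictions of the per-split models into
an ensemble.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import beta, norm
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler

from .aggregation import IncompletePatientError
from .audio_io import DIAGNOSES, SITES, PatientRecord
from .segment_model import BreathCNN, predict_waveforms

__all__ = [
    "FoldPlan",
    "Metrics",
    "make_nested_folds",
    "evaluate_binary",
    "clopper_pearson",
    "delong_auroc",
    "confidence_intervals",
    "ensemble_predict",
    "confusion_matrix",
    "fit_baseline",
    "score_patients",
    "sweep_inference",
]


@dataclass
class FoldPlan:
    """k patient folds and the k*(k-1) (train, tune, test) split triples."""

    k: int
    folds: list[list[str]]  # patient_ids per fold
    splits: list[tuple[tuple[int, ...], int, int]]  # (train fold ids, tune, test)

    def to_json(self, path) -> None:
        """Serialize the plan so a run can be reproduced split-for-split."""
        import json
        from pathlib import Path

        doc = {
            "k": self.k,
            "folds": self.folds,
            "splits": [[list(tr), tu, te] for tr, tu, te in self.splits],
        }
        Path(path).write_text(json.dumps(doc, indent=2))

    @classmethod
    def from_json(cls, path) -> "FoldPlan":
        import json
        from pathlib import Path

        doc = json.loads(Path(path).read_text())
        return cls(
            k=doc["k"],
            folds=[list(f) for f in doc["folds"]],
            splits=[(tuple(tr), tu, te) for tr, tu, te in doc["splits"]],
        )

    def split_patients(
        self, patients: list[PatientRecord], split_idx: int
    ) -> tuple[list[PatientRecord], list[PatientRecord], list[PatientRecord]]:
        train_ids, tune_id, test_id = self.splits[split_idx]
        by_fold = {pid: f for f, fold in enumerate(self.folds) for pid in fold}
        train = [p for p in patients if by_fold[p.patient_id] in train_ids]
        tune = [p for p in patients if by_fold[p.patient_id] == tune_id]
        test = [p for p in patients if by_fold[p.patient_id] == test_id]
        return train, tune, test


def make_nested_folds(
    patients: list[PatientRecord],
    k: int = 5,
    rng: np.random.Generator | int | None = None,
) -> FoldPlan:
    """Stratified (by diagnosis) patient-level fold plan with nested splits.

    All recordings of a patient stay in one fold, so no patient leaks across
    train/tune/test of any split.
    """
    if k < 3:
        raise ValueError("nested CV requires k >= 3")
    labels = [p.diagnosis for p in patients]
    for d in set(labels):
        if labels.count(d) < k:
            raise ValueError(f"class {d!r} has fewer than {k} patients")
    seed = (
        rng if isinstance(rng, (int, np.integer)) else
        int(np.random.default_rng(rng).integers(2**31))
    )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=int(seed) % 2**31)
    ids = np.array([p.patient_id for p in patients])
    folds = [list(ids[test_idx]) for _, test_idx in skf.split(ids, labels)]
    splits = []
    for test in range(k):
        for tune in range(k):
            if tune == test:
                continue
            train = tuple(f for f in range(k) if f not in (test, tune))
            splits.append((train, tune, test))
    return FoldPlan(k=k, folds=folds, splits=splits)


@dataclass
class Metrics:
    """Point estimates with confidence bounds for one binary evaluation."""

    sensitivity: float
    specificity: float
    auroc: float
    n_pos: int
    n_neg: int
    threshold: float = 0.5
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)


def evaluate_binary(
    scores: np.ndarray, labels: np.ndarray, threshold: float = 0.5
) -> Metrics:
    """Sensitivity/specificity at ``threshold`` plus rank-based AUROC."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos, neg = labels == 1, labels == 0
    if not pos.any() or not neg.any():
        raise ValueError("both classes must be present to compute metrics")
    sens = float((scores[pos] >= threshold).mean())
    spec = float((scores[neg] < threshold).mean())
    auroc = float(roc_auc_score(labels, scores))
    return Metrics(
        sensitivity=sens, specificity=spec, auroc=auroc,
        n_pos=int(pos.sum()), n_neg=int(neg.sum()), threshold=threshold,
    )


def clopper_pearson(successes: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact binomial (Clopper-Pearson) confidence interval for a proportion."""
    if n <= 0:
        raise ValueError("n must be positive")
    alpha = 1.0 - level
    lower = 0.0 if successes == 0 else float(beta.ppf(alpha / 2, successes, n - successes + 1))
    upper = 1.0 if successes == n else float(beta.ppf(1 - alpha / 2, successes + 1, n - successes))
    return lower, upper


def _midrank(x: np.ndarray) -> np.ndarray:
    order = np.argsort(x, kind="mergesort")
    xs = x[order]
    n = len(x)
    ranks = np.empty(n, dtype=float)
    i = 0
    while i < n:
        j = i
        while j < n and xs[j] == xs[i]:
            j += 1
        ranks[i:j] = 0.5 * (i + j - 1) + 1.0
        i = j
    out = np.empty(n, dtype=float)
    out[order] = ranks
    return out


def delong_auroc(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """DeLong AUROC point estimate and variance from placement values.

    The point estimate equals the rank/concordance AUROC (ties half-credit).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos_scores = scores[labels == 1]
    neg_scores = scores[labels == 0]
    m, n = len(pos_scores), len(neg_scores)
    if m == 0 or n == 0:
        raise ValueError("both classes must be present")
    all_ranks = _midrank(np.concatenate([pos_scores, neg_scores]))
    pos_ranks = _midrank(pos_scores)
    neg_ranks = _midrank(neg_scores)
    auc = (all_ranks[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v_pos = (all_ranks[:m] - pos_ranks) / n  # placement of each positive
    v_neg = 1.0 - (all_ranks[m:] - neg_ranks) / m  # placement of each negative
    var = (np.var(v_pos, ddof=1) / m if m > 1 else 0.0) + (
        np.var(v_neg, ddof=1) / n if n > 1 else 0.0
    )
    return float(auc), float(var)


def confidence_intervals(
    scores: np.ndarray, labels: np.ndarray, threshold: float = 0.5, level: float = 0.95
) -> Metrics:
    """Metrics with Clopper-Pearson (sens/spec) and DeLong (AUROC) intervals."""
    metrics = evaluate_binary(scores, labels, threshold)
    tp = round(metrics.sensitivity * metrics.n_pos)
    tn = round(metrics.specificity * metrics.n_neg)
    metrics.ci["sensitivity"] = clopper_pearson(int(tp), metrics.n_pos, level)
    metrics.ci["specificity"] = clopper_pearson(int(tn), metrics.n_neg, level)
    auc, var = delong_auroc(scores, labels)
    if var == 0.0:
        warnings.warn("degenerate DeLong interval: zero variance (perfect separation)")
        metrics.ci["auroc"] = (auc, auc)
    else:
        z = norm.ppf(0.5 + level / 2)
        half = z * np.sqrt(var)
        metrics.ci["auroc"] = (max(auc - half, 0.0), min(auc + half, 1.0))
    return metrics


def mean_roc_curve(
    per_split: list[tuple[np.ndarray, np.ndarray]], grid_size: int = 101
) -> tuple[np.ndarray, np.ndarray]:
    """Vertically averaged ROC curve across CV splits (for plotting only).

    ``per_split`` holds (scores, labels) per split; TPR is interpolated on a
    common FPR grid and averaged.  Returns (fpr_grid, mean_tpr).
    """
    from sklearn.metrics import roc_curve

    grid = np.linspace(0.0, 1.0, grid_size)
    tprs = []
    for scores, labels in per_split:
        fpr, tpr, _ = roc_curve(labels, scores)
        tprs.append(np.interp(grid, fpr, tpr))
    mean_tpr = np.mean(tprs, axis=0)
    mean_tpr[0], mean_tpr[-1] = 0.0, 1.0
    return grid, mean_tpr


def ensemble_predict(per_model_scores: list[float]) -> float:
    """Unweighted mean of one patient's probabilities across the CV models."""
    if not per_model_scores:
        raise ValueError("ensemble requires at least one model prediction")
    return float(np.mean(per_model_scores))


def confusion_matrix(predicted: list[str], truth: list[str]) -> np.ndarray:
    """Row-normalized 4x4 confusion matrix in canonical diagnosis order."""
    mat = np.zeros((len(DIAGNOSES), len(DIAGNOSES)))
    for p, t in zip(predicted, truth):
        mat[DIAGNOSES.index(t), DIAGNOSES.index(p)] += 1
    sums = mat.sum(axis=1, keepdims=True)
    return np.divide(mat, sums, out=np.zeros_like(mat), where=sums > 0)


# --------------------------------------------------------------------------
# clinical baseline: logistic regression on age and respiratory rate
# --------------------------------------------------------------------------

BASELINE_GRID = {
    "C": (0.01, 0.1, 1.0, 10.0, 100.0),
    "penalty": ("l1", "l2"),
}


def fit_baseline(
    train_features: np.ndarray,
    train_labels: np.ndarray,
    tune_features: np.ndarray,
    tune_labels: np.ndarray,
):
    """Grid-search the baseline (age, RR) logistic regression.

    Hyperparameters are scored by tune-fold AUROC; the winning setting is
    refitted on train+tune.  Features are standardized, so the model is
    invariant to affine shifts of age or RR.  Returns a fitted
    (scaler, model) pipeline tuple.
    """
    if train_features.shape[1] != 2:
        raise ValueError("baseline consumes exactly (age, respiratory_rate)")
    best = None
    for c in BASELINE_GRID["C"]:
        for penalty in BASELINE_GRID["penalty"]:
            l1_ratio = 1.0 if penalty == "l1" else 0.0
            scaler = StandardScaler().fit(train_features)
            model = LogisticRegression(
                C=c, l1_ratio=l1_ratio, solver="liblinear", max_iter=10_000
            ).fit(scaler.transform(train_features), train_labels)
            auc = roc_auc_score(
                tune_labels, model.predict_proba(scaler.transform(tune_features))[:, 1]
            )
            if best is None or auc > best[0]:
                best = (auc, c, penalty)
    _, c, penalty = best
    both_x = np.vstack([train_features, tune_features])
    both_y = np.concatenate([train_labels, tune_labels])
    scaler = StandardScaler().fit(both_x)
    model = LogisticRegression(
        C=c, l1_ratio=(1.0 if penalty == "l1" else 0.0),
        solver="liblinear", max_iter=10_000,
    ).fit(scaler.transform(both_x), both_y)
    return scaler, model


def baseline_predict(pipeline, features: np.ndarray) -> np.ndarray:
    scaler, model = pipeline
    return model.predict_proba(scaler.transform(features))[:, 1]


def fit_baseline_cv(
    patients: list[PatientRecord], plan: FoldPlan, target_class: str
) -> list[tuple]:
    """One baseline (age, RR) model per nested-CV split — 20 for k = 5.

    Patients without a recorded respiratory rate are excluded (the baseline
    is computed on that subset).  Returns one (scaler, model) pipeline per
    split, fitted with the same split plan the audio models use.
    """
    eligible = [p for p in patients if p.respiratory_rate is not None]

    def xy(group):
        x = np.array([[p.age, p.respiratory_rate] for p in group])
        y = np.array([int(p.diagnosis == target_class) for p in group])
        return x, y

    pipelines = []
    for s in range(len(plan.splits)):
        train, tune, _ = plan.split_patients(eligible, s)
        x_tr, y_tr = xy(train)
        x_tu, y_tu = xy(tune)
        pipelines.append(fit_baseline(x_tr, y_tr, x_tu, y_tu))
    return pipelines


# --------------------------------------------------------------------------
# pipeline scoring and the duration x position inference sweep
# --------------------------------------------------------------------------

#: Position subsets explored by the inference sweep, anchored on the
#: anterior superior sites (least heart/stomach interference).
POSITION_SETS: dict[int, tuple[str, ...]] = {
    8: SITES,
    4: (
        "anterior_right_superior",
        "anterior_left_superior",
        "posterior_right_superior",
        "posterior_left_superior",
    ),
    2: ("anterior_right_superior", "anterior_left_superior"),
    1: ("anterior_right_superior",),
}

SWEEP_DURATIONS: tuple[float, ...] = tuple(2.5 * k for k in range(1, 13))  # 2.5..30 s


def _site_scores(
    model: BreathCNN,
    patients: list[PatientRecord],
    sites: tuple[str, ...],
    duration: float | None = None,
) -> dict[str, dict[str, float]]:
    """CNN clip scores per patient and site, optionally cropped from the
    recording start to ``duration`` seconds."""
    clips: list[np.ndarray] = []
    keys: list[tuple[str, str]] = []
    lengths = []
    for patient in patients:
        for site in sites:
            clip = patient.clips[site]
            x = clip.samples
            if duration is not None:
                n = int(round(duration * clip.rate))
                x = x[:n] if x.size >= n else np.pad(x, (0, n - x.size))
            clips.append(x)
            keys.append((patient.patient_id, site))
            lengths.append(x.size)
    if len(set(lengths)) != 1:
        raise ValueError("recordings must share a duration for batched scoring")
    scores = predict_waveforms(np.stack(clips), model)
    out: dict[str, dict[str, float]] = {}
    for (pid, site), score in zip(keys, scores):
        out.setdefault(pid, {})[site] = float(score)
    return out


def score_patients(
    model: BreathCNN,
    fit_patients: list[PatientRecord],
    eval_patients: list[PatientRecord],
    target_class: str,
    sites: tuple[str, ...] = SITES,
    duration: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Patient-level probabilities for ``eval_patients``.

    Site-score vectors over ``sites`` are computed with the CNN, a logistic
    aggregator of matching dimensionality is fitted on ``fit_patients``
    (train+tune), and evaluation patients are scored.  Returns
    (scores, binary labels).  Patients missing any requested site are
    excluded (the completeness rule).
    """
    fit_patients = [p for p in fit_patients if all(s in p.clips for s in sites)]
    eval_patients = [p for p in eval_patients if all(s in p.clips for s in sites)]
    if not eval_patients:
        raise IncompletePatientError("no eligible patients with the requested sites")

    def vectors(patients):
        raw = _site_scores(model, patients, sites, duration)
        x = np.stack([[raw[p.patient_id][s] for s in sites] for p in patients])
        y = np.array([int(p.diagnosis == target_class) for p in patients])
        return x, y

    x_fit, y_fit = vectors(fit_patients)
    x_eval, y_eval = vectors(eval_patients)
    agg = LogisticRegression(C=1.0, solver="lbfgs", tol=1e-6,
                             max_iter=10_000).fit(x_fit, y_fit)
    return agg.predict_proba(x_eval)[:, 1], y_eval


def sweep_inference(
    model: BreathCNN,
    fit_patients: list[PatientRecord],
    test_patients: list[PatientRecord],
    target_class: str,
    position_sets: dict[int, tuple[str, ...]] | None = None,
    durations: tuple[float, ...] = SWEEP_DURATIONS,
    min_duration: float = 30.0,
) -> dict[int, dict[float, float]]:
    """AUROC grid over position subsets and crop durations.

    Only patients with all 8 sites and at least ``min_duration`` seconds at
    every site are eligible.  Crops are anchored at the recording start and
    the aggregator is refitted per cell on the reduced feature vectors.
    """
    position_sets = position_sets or POSITION_SETS

    def eligible(patients):
        return [
            p for p in patients
            if p.complete and all(c.duration >= min_duration for c in p.clips.values())
        ]

    fit_ok, test_ok = eligible(fit_patients), eligible(test_patients)
    if not test_ok:
        raise ValueError("no eligible patients (need 8 sites and >= 30 s everywhere)")
    grid: dict[int, dict[float, float]] = {}
    for n_pos, sites in sorted(position_sets.items(), reverse=True):
        grid[n_pos] = {}
        for duration in durations:
            scores, labels = score_patients(
                model, fit_ok, test_ok, target_class, sites=sites, duration=duration
            )
            grid[n_pos][duration] = float(roc_auc_score(labels, scores))
    return grid
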