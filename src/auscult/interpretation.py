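"""Attention curves and the Mean-Attention Difference (MAD).

A trained classifier emits one attention value g(x_i) per segment of a
recording.  Comparing the attention with clinician-annotated respiration
phases quantifies whether the model listens to inspiration or expiration:
with alpha_in and alpha_out the mean attention over segments assigned to
inspiration and expiration respectively,

    MAD = (alpha_out - alpha_in) / max(alpha_out, alpha_in)

lies in [-1, 1]; positive values mean the model attends more to expiration
(where most adventitious sounds occur), negative values more to inspiration.
MAD is invariant to uniform rescaling of the attention values and is exactly
negated when the phase labels are swapped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import skew

from .audio_io import PhaseAnnotation
from .segment_model import SegmentOutputs
from .spectrogram import Spectrogram

__all__ = [
    "AttentionCurve",
    "MADResult",
    "UndefinedMADError",
    "assign_segments_to_phases",
    "compute_mad",
    "mad_cohort_summary",
    "export_overlay",
]


class UndefinedMADError(ValueError):
    """Raised when a phase has no assigned segments (MAD undefined)."""


@dataclass
class AttentionCurve:
    """Per-segment attention/prediction values with their time spans."""

    g: np.ndarray
    p: np.ndarray
    spans: list[tuple[float, float]]

    @classmethod
    def from_outputs(cls, outputs: SegmentOutputs) -> "AttentionCurve":
        return cls(g=outputs.g, p=outputs.p, spans=outputs.spans)


@dataclass
class MADResult:
    alpha_in: float  # mean attention over inspiration segments
    alpha_out: float  # mean attention over expiration segments
    mad: float
    n_in: int
    n_out: int


def _overlap(span: tuple[float, float], intervals: list[tuple[float, float]]) -> float:
    start, end = span
    total = 0.0
    for s, e in intervals:
        total += max(0.0, min(end, e) - max(start, s))
    return total


def assign_segments_to_phases(
    curve: AttentionCurve, ann: PhaseAnnotation
) -> tuple[list[int], list[int]]:
    """Assign each segment to the phase covering the majority of its span.

    Returns (inspiration indices, expiration indices); segments overlapping
    no annotated interval are left unassigned.
    """
    if len(ann) == 0:
        raise UndefinedMADError("empty annotation: no phases to assign")
    insp = ann.intervals("inspiration")
    exp = ann.intervals("expiration")
    in_idx, out_idx = [], []
    for i, span in enumerate(curve.spans):
        o_in = _overlap(span, insp)
        o_out = _overlap(span, exp)
        if o_in == 0.0 and o_out == 0.0:
            continue
        (out_idx if o_out > o_in else in_idx).append(i)
    return in_idx, out_idx


def compute_mad(curve: AttentionCurve, ann: PhaseAnnotation) -> MADResult:
    """Mean-Attention Difference of one recording against its annotations."""
    in_idx, out_idx = assign_segments_to_phases(curve, ann)
    if not in_idx or not out_idx:
        raise UndefinedMADError(
            f"need segments in both phases (T_in={len(in_idx)}, T_out={len(out_idx)})"
        )
    alpha_in = float(np.mean(curve.g[in_idx]))
    alpha_out = float(np.mean(curve.g[out_idx]))
    mad = (alpha_out - alpha_in) / max(alpha_out, alpha_in)
    return MADResult(
        alpha_in=alpha_in, alpha_out=alpha_out, mad=float(mad),
        n_in=len(in_idx), n_out=len(out_idx),
    )


def mad_cohort_summary(
    mads_by_diagnosis: dict[str, list[float]]
) -> pd.DataFrame:
    """Per-diagnosis summary of MAD distributions.

    Returns a table with count, median and adjusted Fisher-Pearson sample
    skewness (undefined for groups of fewer than 3 values, reported as NaN);
    empty groups are skipped with a warning.
    """
    rows = []
    for diagnosis, values in mads_by_diagnosis.items():
        if not values:
            warnings.warn(f"diagnosis group {diagnosis!r} has no MAD values; skipped")
            continue
        arr = np.asarray(values, dtype=float)
        skewness = float(skew(arr, bias=False)) if arr.size >= 3 else np.nan
        rows.append(
            {
                "diagnosis": diagnosis,
                "n": arr.size,
                "median_mad": float(np.median(arr)),
                "mean_mad": float(arr.mean()),
                "skewness": skewness,
            }
        )
    return pd.DataFrame(rows)


def export_overlay(
    curve: AttentionCurve,
    spec: Spectrogram,
    ann: PhaseAnnotation,
    mad: MADResult,
    path: str | Path,
) -> pd.DataFrame:
    """Write an attention-over-spectrogram overlay plot plus its data table.

    The phase intervals shown follow the MAD sign: inspiration when MAD < 0,
    expiration otherwise.  Writes ``path`` (image) and a CSV next to it;
    returns the table of (time, attention, prediction, phase).
    """
    clip_dur = float(spec.frame_times[-1])
    span_end = max(e for _, e in curve.spans)
    if abs(span_end - clip_dur) > max(2.0, 0.1 * clip_dur):
        raise ValueError(
            f"attention curve ({span_end:.2f} s) and spectrogram ({clip_dur:.2f} s) "
            "do not describe the same clip"
        )
    centres = np.array([(s + e) / 2 for s, e in curve.spans])
    phase_shown = "inspiration" if mad.mad < 0 else "expiration"
    intervals = ann.intervals(phase_shown)

    def phase_at(t: float) -> str:
        for s, e, p in ann.segments:
            if s <= t < e:
                return p
        return ""

    table = pd.DataFrame(
        {
            "time": centres,
            "attention": curve.g,
            "prediction": curve.p,
            "phase": [phase_at(t) for t in centres],
        }
    )
    path = Path(path)
    table.to_csv(path.with_suffix(".csv"), index=False)

    from matplotlib.figure import Figure

    fig = Figure(figsize=(10, 4))
    ax = fig.add_subplot(111)
    ax.imshow(
        spec.values, origin="lower", aspect="auto",
        extent=(0.0, clip_dur, 0, spec.values.shape[0]), cmap="magma",
    )
    ax2 = ax.twinx()
    ax2.plot(centres, curve.g, color="cyan", lw=2, label="attention g(x_i)")
    for s, e in intervals:
        ax2.axvspan(s, min(e, clip_dur), color="white", alpha=0.2)
    ax.set_xlim(0.0, clip_dur)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("mel band")
    ax2.set_ylabel("attention")
    ax2.legend(loc="upper right")
    ax.set_title(f"MAD = {mad.mad:+.2f} ({phase_shown} phases shown)")
    fig.savefig(path, dpi=100)
    return table
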