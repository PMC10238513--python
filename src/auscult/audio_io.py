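"""Audio and annotation I/O for digital lung auscultation (DLA) datasets.

The acquisition contract mirrors a Littmann-class electronic stethoscope:
mono WAV at 4,000 Hz / 16-bit, one recording per thoracic quadrant
(4 anterior + 4 posterior sites).  Respiration-phase annotations are CSV
tables of timestamped inspiration/expiration segments, and patient metadata
is a CSV table with diagnosis, centre, age and respiratory rate.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile
from scipy.signal import resample_poly

logger = logging.getLogger(__name__)

#: Canonical ordering of the eight thoracic auscultation sites.  The order is
#: fixed so that per-patient site-score vectors are reproducible.
SITES: tuple[str, ...] = (
    "anterior_right_superior",
    "anterior_left_superior",
    "anterior_right_inferior",
    "anterior_left_inferior",
    "posterior_right_superior",
    "posterior_left_superior",
    "posterior_right_inferior",
    "posterior_left_inferior",
)

#: The four diagnostic categories, in fixed reporting order.
DIAGNOSES: tuple[str, ...] = (
    "control",
    "pneumonia",
    "wheezing_disorder",
    "bronchiolitis",
)

PHASES: tuple[str, str] = ("inspiration", "expiration")

#: Nominal stethoscope sampling rate (Hz); the whole pipeline runs at 4 kHz.
NOMINAL_RATE = 4000


class AudioFormatError(ValueError):
    """Raised for unreadable or empty audio containers."""


class AnnotationError(ValueError):
    """Raised for malformed respiration-phase annotation tables."""


@dataclass
class AudioClip:
    """A mono auscultation recording with patient/site linkage.

    ``samples`` are dimensionless amplitudes in nominal range [-1, 1];
    ``rate`` is the sampling rate in Hz.
    """

    samples: np.ndarray
    rate: int
    patient_id: str | None = None
    site: str | None = None
    centre: str | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float32)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise AudioFormatError("clip must contain a non-empty 1-D sample array")
        if self.rate <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.rate}")
        if self.site is not None and self.site not in SITES:
            raise ValueError(f"unknown site {self.site!r}; expected one of {SITES}")

    @property
    def duration(self) -> float:
        """Clip duration in seconds."""
        return self.samples.size / self.rate


@dataclass
class PhaseAnnotation:
    """Timestamped inspiration/expiration segments for one recording.

    ``segments`` is an ordered list of ``(start, end, phase)`` with times in
    seconds.  Segments of the same phase must not overlap.
    """

    segments: list[tuple[float, float, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for start, end, phase in self.segments:
            if not (0.0 <= start < end):
                raise AnnotationError(f"invalid segment bounds ({start}, {end})")
            if phase not in PHASES:
                raise AnnotationError(f"unknown phase label {phase!r}")
        self.segments = sorted(self.segments, key=lambda s: (s[0], s[1]))
        for phase in PHASES:
            intervals = [(s, e) for s, e, p in self.segments if p == phase]
            for (s1, e1), (s2, e2) in zip(intervals, intervals[1:]):
                if s2 < e1:
                    raise AnnotationError(
                        f"overlapping {phase} segments ({s1}, {e1}) and ({s2}, {e2})"
                    )

    def __len__(self) -> int:
        return len(self.segments)

    def intervals(self, phase: str) -> list[tuple[float, float]]:
        """All (start, end) intervals annotated with ``phase``."""
        return [(s, e) for s, e, p in self.segments if p == phase]


@dataclass
class PatientRecord:
    """One patient: diagnosis, covariates, and up to 8 site recordings."""

    patient_id: str
    diagnosis: str
    centre: str
    age: float
    respiratory_rate: float | None = None
    clips: dict[str, AudioClip] = field(default_factory=dict)
    annotations: dict[str, PhaseAnnotation] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.diagnosis not in DIAGNOSES:
            raise ValueError(
                f"unknown diagnosis {self.diagnosis!r}; expected one of {DIAGNOSES}"
            )
        for site in self.clips:
            if site not in SITES:
                raise ValueError(f"unknown site {site!r}")

    @property
    def complete(self) -> bool:
        """True when all eight canonical sites have a recording."""
        return all(site in self.clips for site in SITES)


def _pcm_to_float(data: np.ndarray) -> np.ndarray:
    if data.dtype == np.int16:
        return data.astype(np.float32) / 32768.0
    if data.dtype == np.int32:
        return data.astype(np.float32) / 2147483648.0
    if data.dtype == np.uint8:
        return (data.astype(np.float32) - 128.0) / 128.0
    if data.dtype in (np.float32, np.float64):
        return data.astype(np.float32)
    raise AudioFormatError(f"unsupported WAV sample format {data.dtype}")


def read_wav(
    path: str | Path,
    *,
    patient_id: str | None = None,
    site: str | None = None,
    centre: str | None = None,
    target_rate: int | None = NOMINAL_RATE,
) -> AudioClip:
    """Read a WAV file as a mono :class:`AudioClip`.

    Multi-channel audio is averaged to mono and integer PCM is rescaled to
    [-1, 1].  Audio whose rate differs from ``target_rate`` is resampled on
    load with a warning (pass ``target_rate=None`` to keep the native rate).
    """
    try:
        rate, data = wavfile.read(str(path))
    except (ValueError, OSError) as exc:
        raise AudioFormatError(f"cannot read WAV file {path}: {exc}") from exc
    if data.size == 0:
        raise AudioFormatError(f"WAV file {path} contains no audio")
    samples = _pcm_to_float(data)
    if samples.ndim == 2:
        samples = samples.mean(axis=1)
    clip = AudioClip(samples, int(rate), patient_id=patient_id, site=site, centre=centre)
    if target_rate is not None and clip.rate != target_rate:
        warnings.warn(
            f"{path}: resampling {clip.rate} Hz -> {target_rate} Hz to match the "
            "4 kHz acquisition contract",
            stacklevel=2,
        )
        clip = resample(clip, target_rate)
    return clip


def write_wav(path: str | Path, clip: AudioClip) -> None:
    """Write a clip as 16-bit PCM mono WAV (lossless round trip for 16-bit input)."""
    scaled = np.round(np.asarray(clip.samples, dtype=np.float64) * 32768.0)
    pcm = np.clip(scaled, -32768, 32767).astype(np.int16)
    wavfile.write(str(path), clip.rate, pcm)


def resample(clip: AudioClip, target_rate: int) -> AudioClip:
    """Band-limited (polyphase) resampling to ``target_rate`` Hz."""
    if target_rate <= 0:
        raise ValueError("target_rate must be positive")
    if target_rate == clip.rate:
        return clip
    frac = Fraction(target_rate, clip.rate)
    samples = resample_poly(clip.samples.astype(np.float64), frac.numerator, frac.denominator)
    return AudioClip(
        samples.astype(np.float32),
        target_rate,
        patient_id=clip.patient_id,
        site=clip.site,
        centre=clip.centre,
    )


def read_annotations(path: str | Path) -> PhaseAnnotation:
    """Read a phase-annotation CSV with header ``start,end,phase`` (seconds)."""
    table = pd.read_csv(path)
    missing = {"start", "end", "phase"} - set(table.columns)
    if missing:
        raise AnnotationError(f"{path}: missing annotation columns {sorted(missing)}")
    segments = [
        (float(row.start), float(row.end), str(row.phase)) for row in table.itertuples()
    ]
    return PhaseAnnotation(segments)


def write_annotations(path: str | Path, ann: PhaseAnnotation) -> None:
    pd.DataFrame(ann.segments, columns=["start", "end", "phase"]).to_csv(path, index=False)


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read the patient metadata CSV (patient_id,diagnosis,centre,age,respiratory_rate)."""
    table = pd.read_csv(
        path, dtype={"patient_id": str, "diagnosis": str, "centre": str}
    )
    required = {"patient_id", "diagnosis", "centre", "age"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"{path}: missing metadata columns {sorted(missing)}")
    if "respiratory_rate" not in table.columns:
        table["respiratory_rate"] = np.nan
    return table


def load_cohort(directory: str | Path) -> list[PatientRecord]:
    """Load a cohort from the on-disk layout written by the simulator.

    Expects ``metadata.csv`` plus per-recording files ``{patient_id}_s{k}.wav``
    (k = 1..8 following the canonical site ordering) and optional
    ``{patient_id}_s{k}_phases.csv`` annotation tables.
    """
    directory = Path(directory)
    meta = read_metadata(directory / "metadata.csv")
    patients = []
    for row in meta.itertuples():
        rr = None if pd.isna(row.respiratory_rate) else float(row.respiratory_rate)
        record = PatientRecord(
            patient_id=str(row.patient_id),
            diagnosis=str(row.diagnosis),
            centre=str(row.centre),
            age=float(row.age),
            respiratory_rate=rr,
        )
        for k, site in enumerate(SITES, start=1):
            wav_path = directory / f"{row.patient_id}_s{k}.wav"
            if not wav_path.exists():
                continue
            record.clips[site] = read_wav(
                wav_path, patient_id=record.patient_id, site=site, centre=record.centre
            )
            ann_path = directory / f"{row.patient_id}_s{k}_phases.csv"
            if ann_path.exists():
                record.annotations[site] = read_annotations(ann_path)
        patients.append(record)
    return patients
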