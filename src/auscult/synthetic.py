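"""Synthetic pediatric auscultation cohorts with known ground truth.

Clinical auscultation audio is rarely shareable, so every stage of the
pipeline is exercised on simulated patients instead.  The generative model
is deliberately minimal but carries the statistical structure the pipeline
assumes:

* breath sounds are band-limited (250-600 Hz) Gaussian noise, amplitude-
  modulated by the respiratory cycle (inspiration slightly louder), with the
  cycle timing recorded as phase annotations;
* a wheezing disorder adds a tonal, frequency-modulated sinusoid
  (350-650 Hz, +-20 Hz vibrato) locked to expiration on all sites;
* pneumonia adds brief damped-noise crackle transients confined to a random
  contiguous subset of 2-3 sites (a lobar pattern), during inspiration;
* bronchiolitis adds a mild biphasic wheeze plus diffuse crackles on all
  sites (the infant airway picture);
* each centre contributes its own colored background-noise floor, and age /
  respiratory rate are drawn class-conditionally (bronchiolitis patients are
  infants; all disease classes have elevated RR).

Every planted event is logged so that tests can verify the audio, the
annotations and the event log agree.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.signal import butter, sosfilt

from .audio_io import (
    DIAGNOSES,
    SITES,
    AudioClip,
    PatientRecord,
    PhaseAnnotation,
    write_annotations,
    write_wav,
)

__all__ = [
    "SimulationConfig",
    "SyntheticPatient",
    "simulate_patient",
    "simulate_cohort",
    "planted_signal_check",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Generative parameters of the synthetic cohort.

    Defaults produce the standard desk-scale cohort: 120 patients
    (15 per diagnosis per centre, 2 centres), 30-second clips at 4 kHz.
    """

    n_per_class_centre: int = 15
    centres: tuple[str, ...] = ("centre_a", "centre_b")
    clip_seconds: float = 30.0
    rate: int = 4000
    seed: int = 1234

    # respiratory cycle (seconds)
    insp_range: tuple[float, float] = (0.5, 1.0)
    exp_range: tuple[float, float] = (0.8, 1.5)
    pause_range: tuple[float, float] = (0.05, 0.35)

    # breath noise
    breath_band: tuple[float, float] = (250.0, 600.0)
    insp_gain: float = 1.0
    exp_gain: float = 0.92

    # adventitious sounds (amplitudes relative to unit-RMS breath noise)
    wheeze_freq_range: tuple[float, float] = (350.0, 650.0)
    wheeze_gain: float = 1.6
    wheeze_vibrato_hz: float = 20.0
    wheeze_vibrato_rate: float = 5.0
    mild_wheeze_gain: float = 0.35
    crackle_gain: float = 3.0
    crackle_len_ms: tuple[float, float] = (5.0, 20.0)
    crackles_per_cycle: tuple[int, int] = (2, 5)
    lobar_sites: tuple[int, int] = (2, 3)  # contiguous site-count range

    # centre noise floors (amplitude of the coloured noise)
    centre_noise_gain: float = 0.25

    # covariates: diagnosis -> (age mean, age sd, rr mean, rr sd)
    covariates: dict = field(
        default_factory=lambda: {
            "control": (6.0, 3.0, 22.0, 4.0),
            "pneumonia": (4.0, 2.5, 38.0, 8.0),
            "wheezing_disorder": (5.0, 3.0, 34.0, 7.0),
            "bronchiolitis": (0.8, 0.4, 45.0, 10.0),
        }
    )
    rr_missing_prob: float = 0.06

    def __post_init__(self) -> None:
        nyq = self.rate / 2
        for f in (*self.breath_band, *self.wheeze_freq_range):
            if not 0 < f < nyq:
                raise ValueError(f"frequency {f} outside (0, {nyq})")
        for lo, hi in (self.insp_range, self.exp_range):
            if not 0 < lo <= hi:
                raise ValueError("cycle durations must be positive")


@dataclass
class SyntheticPatient:
    """A generated PatientRecord plus its ground-truth event log."""

    record: PatientRecord
    events: list[dict] = field(default_factory=list)


def _breath_cycles(cfg: SimulationConfig, rng: np.random.Generator):
    """Yield (start, end, phase) covering the clip, with short pauses."""
    t = float(rng.uniform(0.0, 0.3))
    segments = []
    while t < cfg.clip_seconds:
        insp = float(rng.uniform(*cfg.insp_range))
        exp = float(rng.uniform(*cfg.exp_range))
        pause = float(rng.uniform(*cfg.pause_range))
        if t + insp >= cfg.clip_seconds:
            break
        segments.append((t, t + insp, "inspiration"))
        t += insp
        end_exp = min(t + exp, cfg.clip_seconds)
        if end_exp - t > 0.1:
            segments.append((t, end_exp, "expiration"))
        t = end_exp + pause
    return segments


def _phase_envelope(n: int, rate: int, segments, cfg: SimulationConfig) -> np.ndarray:
    env = np.zeros(n, dtype=np.float64)
    for start, end, phase in segments:
        i0, i1 = int(start * rate), min(int(end * rate), n)
        if i1 <= i0:
            continue
        gain = cfg.insp_gain if phase == "inspiration" else cfg.exp_gain
        shape = np.sin(np.pi * np.linspace(0.0, 1.0, i1 - i0)) ** 0.6
        env[i0:i1] = gain * shape
    return env


def _centre_noise(n: int, centre_idx: int, cfg: SimulationConfig,
                  rng: np.random.Generator) -> np.ndarray:
    """Centre-specific coloured noise floor (distinct spectral tilt)."""
    white = rng.normal(size=n)
    if centre_idx % 2 == 0:  # low-pass rumble
        sos = butter(2, 300.0, btype="lowpass", fs=cfg.rate, output="sos")
    else:  # high-passed hiss
        sos = butter(2, 700.0, btype="highpass", fs=cfg.rate, output="sos")
    coloured = sosfilt(sos, white)
    coloured /= np.sqrt(np.mean(coloured**2)) + 1e-12
    return cfg.centre_noise_gain * coloured


def _wheeze(times: np.ndarray, segments, phases: tuple[str, ...], gain: float,
            cfg: SimulationConfig, rng: np.random.Generator, events: list,
            site: str) -> np.ndarray:
    f0 = float(rng.uniform(*cfg.wheeze_freq_range))
    vib_phase = float(rng.uniform(0, 2 * np.pi))
    inst_freq = f0 + cfg.wheeze_vibrato_hz * np.sin(
        2 * np.pi * cfg.wheeze_vibrato_rate * times + vib_phase
    )
    phase_acc = 2 * np.pi * np.cumsum(inst_freq) / cfg.rate
    tone = np.sin(phase_acc)
    out = np.zeros_like(times)
    rate = cfg.rate
    for start, end, phase in segments:
        if phase not in phases:
            continue
        i0, i1 = int(start * rate), min(int(end * rate), times.size)
        if i1 <= i0:
            continue
        shape = np.sin(np.pi * np.linspace(0.0, 1.0, i1 - i0)) ** 0.6
        out[i0:i1] = gain * shape * tone[i0:i1]
        events.append(
            {"site": site, "kind": "wheeze", "start": start, "end": min(end, times[-1]),
             "phase": phase, "freq_hz": f0}
        )
    return out


def _crackles(n: int, segments, phase: str, cfg: SimulationConfig,
              rng: np.random.Generator, events: list, site: str) -> np.ndarray:
    out = np.zeros(n, dtype=np.float64)
    rate = cfg.rate
    lo, hi = cfg.crackles_per_cycle
    for start, end, seg_phase in segments:
        if seg_phase != phase:
            continue
        count = int(rng.integers(lo, hi + 1))
        for _ in range(count):
            length_s = float(rng.uniform(*cfg.crackle_len_ms)) / 1000.0
            t0 = float(rng.uniform(start, max(end - length_s, start)))
            i0 = int(t0 * rate)
            m = max(int(length_s * rate), 4)
            if i0 + m > n:
                continue
            burst_t = np.arange(m) / rate
            burst = rng.normal(size=m) * np.exp(-burst_t / (length_s / 5.0))
            out[i0 : i0 + m] += cfg.crackle_gain * burst
            events.append(
                {"site": site, "kind": "crackle", "start": t0, "end": t0 + length_s,
                 "phase": phase}
            )
    return out


def simulate_patient(
    diagnosis: str,
    centre: str,
    cfg: SimulationConfig,
    rng: np.random.Generator,
    patient_id: str = "p0",
) -> SyntheticPatient:
    """Generate one patient: 8 annotated clips plus the planted-event log."""
    if diagnosis not in DIAGNOSES:
        raise ValueError(f"unknown diagnosis {diagnosis!r}")
    rate = cfg.rate
    n = int(cfg.clip_seconds * rate)
    times = np.arange(n) / rate
    centre_idx = cfg.centres.index(centre) if centre in cfg.centres else 0
    sos_breath = butter(4, cfg.breath_band, btype="bandpass", fs=rate, output="sos")

    age_mu, age_sd, rr_mu, rr_sd = cfg.covariates[diagnosis]
    age = float(np.clip(rng.normal(age_mu, age_sd), 0.05, 16.0))
    rr = float(np.clip(rng.normal(rr_mu, rr_sd), 10.0, 90.0))
    if rng.random() < cfg.rr_missing_prob:
        rr = None

    if diagnosis == "pneumonia":
        span = int(rng.integers(cfg.lobar_sites[0], cfg.lobar_sites[1] + 1))
        first = int(rng.integers(0, len(SITES) - span + 1))
        crackle_sites = set(SITES[first : first + span])
    else:
        crackle_sites = set(SITES) if diagnosis == "bronchiolitis" else set()

    record = PatientRecord(
        patient_id=patient_id, diagnosis=diagnosis, centre=centre,
        age=age, respiratory_rate=rr,
    )
    events: list[dict] = []
    for site in SITES:
        segments = _breath_cycles(cfg, rng)
        breath = sosfilt(sos_breath, rng.normal(size=n))
        breath /= np.sqrt(np.mean(breath**2)) + 1e-12  # unit RMS before envelope
        env = _phase_envelope(n, rate, segments, cfg)
        signal = breath * env

        site_events: list[dict] = []
        if diagnosis == "wheezing_disorder":
            signal += _wheeze(times, segments, ("expiration",), cfg.wheeze_gain,
                              cfg, rng, site_events, site)
        elif diagnosis == "bronchiolitis":
            signal += _wheeze(times, segments, ("inspiration", "expiration"),
                              cfg.mild_wheeze_gain, cfg, rng, site_events, site)
        if site in crackle_sites:
            signal += _crackles(n, segments, "inspiration", cfg, rng, site_events, site)

        signal += _centre_noise(n, centre_idx, cfg, rng)
        # fixed headroom scaling: keeps amplitudes comparable across clips
        signal *= 0.05
        np.clip(signal, -1.0, 1.0, out=signal)

        record.clips[site] = AudioClip(
            signal.astype(np.float32), rate,
            patient_id=patient_id, site=site, centre=centre,
        )
        record.annotations[site] = PhaseAnnotation(list(segments))
        events.extend(site_events)
    return SyntheticPatient(record=record, events=events)


def simulate_cohort(
    cfg: SimulationConfig | None = None,
    out_dir: str | Path | None = None,
) -> list[SyntheticPatient]:
    """Generate a cohort (fully reproducible from ``cfg.seed``).

    When ``out_dir`` is given, writes the on-disk layout read by
    :func:`auscult.audio_io.load_cohort`: ``metadata.csv``,
    ``{pid}_s{k}.wav``, ``{pid}_s{k}_phases.csv`` and ``events.jsonl``.
    """
    cfg = cfg or SimulationConfig()
    root = np.random.SeedSequence(cfg.seed)
    patients: list[SyntheticPatient] = []
    jobs = [
        (diagnosis, centre)
        for diagnosis in DIAGNOSES
        for centre in cfg.centres
        for _ in range(cfg.n_per_class_centre)
    ]
    for i, ((diagnosis, centre), child) in enumerate(zip(jobs, root.spawn(len(jobs)))):
        rng = np.random.default_rng(child)
        patients.append(
            simulate_patient(diagnosis, centre, cfg, rng, patient_id=f"p{i:04d}")
        )

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        rows = []
        with open(out / "events.jsonl", "w") as fh:
            for sp in patients:
                rec = sp.record
                rows.append(
                    {
                        "patient_id": rec.patient_id,
                        "diagnosis": rec.diagnosis,
                        "centre": rec.centre,
                        "age": round(rec.age, 3),
                        "respiratory_rate": (
                            "" if rec.respiratory_rate is None
                            else round(rec.respiratory_rate, 1)
                        ),
                    }
                )
                for k, site in enumerate(SITES, start=1):
                    write_wav(out / f"{rec.patient_id}_s{k}.wav", rec.clips[site])
                    write_annotations(
                        out / f"{rec.patient_id}_s{k}_phases.csv", rec.annotations[site]
                    )
                for event in sp.events:
                    fh.write(json.dumps({"patient_id": rec.patient_id, **event}) + "\n")
        import pandas as pd

        pd.DataFrame(rows).to_csv(out / "metadata.csv", index=False)
    return patients


def planted_signal_check(patients: list[SyntheticPatient]) -> dict:
    """Verify that every planted event lies inside an annotated interval of
    its declared phase on its declared site.  Returns a report with the
    number of events checked and a list of violations."""
    violations = []
    n_events = 0
    for sp in patients:
        for event in sp.events:
            n_events += 1
            ann = sp.record.annotations.get(event["site"])
            mid = 0.5 * (event["start"] + event["end"])
            ok = ann is not None and any(
                s <= mid <= e for s, e in ann.intervals(event["phase"])
            )
            if not ok:
                violations.append({"patient_id": sp.record.patient_id, **event})
    return {"n_events": n_events, "n_violations": len(violations), "violations": violations}
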