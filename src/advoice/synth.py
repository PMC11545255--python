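"""Synthetic two-group voice cohort with a controlled spectral-envelope contrast.

Real case-control conversational recordings cannot be redistributed, so this
module builds a fully ground-truthed stand-in: each subject is a
harmonic-plus-noise source — a glottal-style pulse train with cycle-level
jitter (an Ornstein-Uhlenbeck perturbation of the period) and shimmer
(amplitude modulation), spectrally shaped by a piecewise log-linear envelope —
alternating with pauses, over a ventilation-like 1/f background at a set SNR.

The class contrast is carried by the envelope: the patient profile rolls off
gently at a single slope across the band, while the healthy profile falls
slowly up to a ~6 kHz knee and steeply beyond it. Integrating either envelope
analytically predicts the spectral moments the extractor should measure, so
the generator doubles as its own oracle. Recordings are emitted in the same
WAV + annotation TSV + manifest CSV formats the preparation stage consumes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.fft import irfft, rfft, rfftfreq

from . import io as avio
from .prep import Interval, Recording

log = logging.getLogger(__name__)

F_REF = 100.0  # Hz; envelope is flat (0 dB) below this reference


@dataclass
class ClassProfile:
    """Class-conditional generator parameters.

    Envelope: amplitude gain in dB is ``slope_low_db_oct * log2(f/F_REF)``
    up to ``knee_hz`` and continues at ``slope_high_db_oct`` beyond it.
    F0 means/SDs are between-subject distributions by sex (Hz); jitter is the
    relative SD of the cycle-period perturbation, shimmer the relative SD of
    per-cycle amplitude. ``*_sd`` fields are between-subject scatter; setting
    them to zero makes every subject identical to the profile mean.
    """

    slope_low_db_oct: float = -6.0
    knee_hz: float = 6000.0
    slope_high_db_oct: float = -6.0
    f0_mean_male: float = 110.0
    f0_mean_female: float = 175.0
    f0_sd: float = 4.0
    slope_sd: float = 0.25      # dB/octave between-subject scatter
    knee_sd_hz: float = 200.0
    jitter: float = 0.01
    shimmer: float = 0.03
    speech_seg_mean_s: float = 3.0
    pause_mean_s: float = 0.8
    snr_db: float = 30.0
    speech_rms: float = 0.05

    def __post_init__(self):
        if self.slope_low_db_oct > 0 or self.slope_high_db_oct > 0:
            raise ValueError("envelope slopes must be <= 0 dB/octave")
        if not np.isfinite(self.snr_db):
            raise ValueError("snr_db must be finite")


def patient_profile(**overrides) -> ClassProfile:
    """Gentle single-slope roll-off across the whole band."""
    return replace(ClassProfile(slope_low_db_oct=-6.0, knee_hz=6000.0,
                                slope_high_db_oct=-6.0), **overrides)


def healthy_profile(**overrides) -> ClassProfile:
    """Slow roll-off up to a 6 kHz knee, then a rapid downward slope."""
    return replace(ClassProfile(slope_low_db_oct=-3.0, knee_hz=6000.0,
                                slope_high_db_oct=-24.0), **overrides)


@dataclass
class SubjectParams:
    """One subject's realized generator parameters."""

    subject_id: str
    group: str
    sex: str
    f0_hz: float
    slope_low_db_oct: float
    knee_hz: float
    slope_high_db_oct: float
    jitter: float
    shimmer: float
    speech_seg_mean_s: float
    pause_mean_s: float
    snr_db: float
    speech_rms: float


@dataclass
class CohortSpec:
    """Cohort-level design: group sizes, sex ratios, class profiles, seed."""

    n_patient: int = 83
    n_healthy: int = 75
    female_fraction_patient: float = 50 / 83
    female_fraction_healthy: float = 47 / 75
    patient: ClassProfile = field(default_factory=patient_profile)
    healthy: ClassProfile = field(default_factory=healthy_profile)
    duration_s: float = 120.0
    sample_rate: int = 44100
    seed: int = 0

    def __post_init__(self):
        if self.n_patient < 1 or self.n_healthy < 1:
            raise ValueError("need at least one subject per group")
        if self.duration_s < 10.0:
            raise ValueError("recordings must cover at least one block length")


def null_cohort_spec(n_per_group: int = 10, duration_s: float = 120.0,
                     seed: int = 0) -> CohortSpec:
    """Calibration cohort: both groups share one zero-scatter profile.

    Every subject is parameter-identical (single sex, no between-subject
    scatter), so group labels are pure noise and any downstream signal is a
    calibration failure. Used for type-I-rate and null-AUC checks.
    """
    base = ClassProfile(slope_low_db_oct=-4.0, knee_hz=6000.0,
                        slope_high_db_oct=-12.0, f0_sd=0.0, slope_sd=0.0,
                        knee_sd_hz=0.0)
    return CohortSpec(n_patient=n_per_group, n_healthy=n_per_group,
                      female_fraction_patient=0.0, female_fraction_healthy=0.0,
                      patient=base, healthy=replace(base),
                      duration_s=duration_s, seed=seed)


def envelope_amplitude(freqs, slope_low_db_oct: float, knee_hz: float,
                       slope_high_db_oct: float) -> np.ndarray:
    """Amplitude envelope |H(f)|: flat below F_REF, piecewise log-linear above."""
    f = np.asarray(freqs, dtype=np.float64)
    db = np.zeros_like(f)
    above_ref = f > F_REF
    low = np.minimum(f, knee_hz)
    db[above_ref] = slope_low_db_oct * np.log2(low[above_ref] / F_REF)
    past_knee = f > knee_hz
    db[past_knee] += slope_high_db_oct * np.log2(f[past_knee] / knee_hz)
    h = 10.0 ** (db / 20.0)
    h[f == 0] = 0.0
    return h


def envelope_power_moments(params, f0: float | None = None,
                           f_hi: float = 22050.0,
                           n_grid: int = 16384) -> dict[str, float]:
    """Predicted spectral moments from the subject's power envelope alone.

    With ``f0`` given (the generator's periodic-source case) the power mass
    sits on the harmonic comb k*f0, so the moments are computed over
    |H(k*f0)|^2 — the analytic prediction for what the extractor should
    measure on this subject's speech. Without ``f0`` a continuous integral of
    |H(f)|^2 over [F_REF, f_hi] is returned (broadband-source limit).
    """
    if f0 is not None:
        f = f0 * np.arange(1, int(f_hi / f0) + 1, dtype=np.float64)
        w = envelope_amplitude(f, params.slope_low_db_oct, params.knee_hz,
                               params.slope_high_db_oct) ** 2
        w = w / w.sum()
        c = float(f @ w)
        d = f - c
        m2, m3, m4 = (float(d**k @ w) for k in (2, 3, 4))
    else:
        f = np.linspace(F_REF, f_hi, n_grid)
        h2 = envelope_amplitude(f, params.slope_low_db_oct, params.knee_hz,
                                params.slope_high_db_oct) ** 2
        w = h2 / np.trapezoid(h2, f)
        c = float(np.trapezoid(f * w, f))
        m2 = float(np.trapezoid((f - c) ** 2 * w, f))
        m3 = float(np.trapezoid((f - c) ** 3 * w, f))
        m4 = float(np.trapezoid((f - c) ** 4 * w, f))
    sd = np.sqrt(m2)
    return {"centroid": c, "sd": float(sd),
            "skewness": float(m3 / sd**3), "kurtosis": float(m4 / m2**2)}


def sample_subject(profile: ClassProfile, sex: str, rng: np.random.Generator,
                   subject_id: str = "", group: str = "patient") -> SubjectParams:
    """Draw one subject's parameters from the class profile.

    With all scatter fields zero the draw equals the profile means exactly.
    """
    f0_mean = profile.f0_mean_female if sex == "female" else profile.f0_mean_male
    f0 = f0_mean + profile.f0_sd * rng.standard_normal()
    slope_low = min(0.0, profile.slope_low_db_oct + profile.slope_sd * rng.standard_normal())
    slope_high = min(0.0, profile.slope_high_db_oct + profile.slope_sd * rng.standard_normal())
    knee = max(1000.0, profile.knee_hz + profile.knee_sd_hz * rng.standard_normal())
    return SubjectParams(
        subject_id=subject_id, group=group, sex=sex, f0_hz=float(f0),
        slope_low_db_oct=float(slope_low), knee_hz=float(knee),
        slope_high_db_oct=float(slope_high), jitter=profile.jitter,
        shimmer=profile.shimmer, speech_seg_mean_s=profile.speech_seg_mean_s,
        pause_mean_s=profile.pause_mean_s, snr_db=profile.snr_db,
        speech_rms=profile.speech_rms,
    )


def _schedule(duration_s: float, speech_mean: float, pause_mean: float,
              rng: np.random.Generator) -> list[Interval]:
    """Alternating speech / noise_only intervals tiling [0, duration]."""
    ivs: list[Interval] = []
    t = 0.0
    speaking = True
    while t < duration_s - 1e-9:
        mean = speech_mean if speaking else pause_mean
        d = max(0.3, rng.normal(mean, mean / 3.0))
        end = min(t + d, duration_s)
        if end - t > 1e-6:
            ivs.append(Interval("speech" if speaking else "noise_only", t, end))
        t = end
        speaking = not speaking
    return ivs


def _pulse_train(n: int, sample_rate: int, segments, params: SubjectParams,
                 rng: np.random.Generator) -> np.ndarray:
    """Jittered, shimmered glottal pulse train inside the speech segments."""
    src = np.zeros(n)
    p0 = sample_rate / params.f0_hz  # nominal period in samples
    rho = np.exp(-(p0 / sample_rate) / 0.5)  # OU correlation time 0.5 s
    for (s, e) in segments:
        t = float(s)
        phi = 0.0
        while t < e - p0:
            phi = rho * phi + np.sqrt(1.0 - rho**2) * rng.standard_normal()
            period = p0 * (1.0 + params.jitter * phi)
            amp = max(0.2, 1.0 + params.shimmer * rng.standard_normal())
            i = int(t)
            frac = t - i
            if i + 1 < n:
                src[i] += amp * (1.0 - frac)
                src[i + 1] += amp * frac
            t += period
    return src


def synth_recording(params: SubjectParams, duration_s: float, sample_rate: int,
                    rng: np.random.Generator) -> tuple[np.ndarray, list[Interval]]:
    """Synthesize one recording and its speech / noise_only annotations.

    Voiced segments are the envelope-filtered pulse train; pauses carry only
    low-level envelope-shaped noise; a 1/f background at the subject's SNR is
    added over the whole file. Speech RMS is normalized to ``speech_rms``.
    """
    n = int(round(duration_s * sample_rate))
    ivs = _schedule(duration_s, params.speech_seg_mean_s, params.pause_mean_s, rng)
    speech_segs = [(iv.start_s * sample_rate, iv.end_s * sample_rate)
                   for iv in ivs if iv.label == "speech"]
    pause_segs = [(iv.start_s * sample_rate, iv.end_s * sample_rate)
                  for iv in ivs if iv.label == "noise_only"]

    src = _pulse_train(n, sample_rate, speech_segs, params, rng)
    # low-level aspiration-like noise in pauses, shaped by the same envelope
    for (s, e) in pause_segs:
        i0, i1 = int(s), min(int(e), n)
        src[i0:i1] += 0.02 * rng.standard_normal(i1 - i0)

    freqs = rfftfreq(n, 1.0 / sample_rate)
    h = envelope_amplitude(freqs, params.slope_low_db_oct, params.knee_hz,
                           params.slope_high_db_oct)
    y = irfft(rfft(src) * h, n)

    speech_mask = np.zeros(n, dtype=bool)
    for (s, e) in speech_segs:
        speech_mask[int(s):min(int(e), n)] = True
    rms = np.sqrt(np.mean(y[speech_mask] ** 2)) if speech_mask.any() else 0.0
    if rms > 0:
        y *= params.speech_rms / rms

    # ventilation-like 1/f background at the subject's SNR
    white = rng.standard_normal(n)
    shape = np.zeros_like(freqs)
    shape[1:] = 1.0 / np.sqrt(freqs[1:])
    noise = irfft(rfft(white) * shape, n)
    n_rms = np.sqrt(np.mean(noise ** 2))
    if n_rms > 0:
        noise *= params.speech_rms * 10.0 ** (-params.snr_db / 20.0) / n_rms
    y = y + noise

    peak = np.abs(y).max()
    if peak > 0.99:
        y *= 0.99 / peak
    return y, ivs


def simulate_subjects(spec: CohortSpec):
    """Yield (Recording, SubjectParams) for every subject of the cohort.

    Per-subject RNGs are spawned from (master seed, subject index) so any
    subject is reproducible in isolation and the cohort is bit-stable.
    """
    plan = []
    for gi, (group, n, ffrac, profile) in enumerate([
            ("patient", spec.n_patient, spec.female_fraction_patient, spec.patient),
            ("healthy", spec.n_healthy, spec.female_fraction_healthy, spec.healthy)]):
        n_f = int(round(n * ffrac))
        prefix = "P" if group == "patient" else "H"
        for j in range(n):
            sex = "female" if j < n_f else "male"
            plan.append((f"{prefix}{j + 1:03d}", group, sex, profile))
    for idx, (sid, group, sex, profile) in enumerate(plan):
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, idx]))
        params = sample_subject(profile, sex, rng, subject_id=sid, group=group)
        samples, ivs = synth_recording(params, spec.duration_s,
                                       spec.sample_rate, rng)
        rec = Recording(subject_id=sid, group=group,
                        sample_rate=spec.sample_rate, samples=samples,
                        annotations=ivs)
        yield rec, params


def generate_cohort(spec: CohortSpec, out_dir) -> Path:
    """Write the cohort to disk (WAVs, annotation TSVs, manifest CSV).

    Returns the manifest path. Re-running with the same spec produces
    byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec, params in simulate_subjects(spec):
        wav_path = out_dir / f"{rec.subject_id}.wav"
        tsv_path = out_dir / f"{rec.subject_id}.tsv"
        avio.write_wav(rec.samples, rec.sample_rate, wav_path)
        ann = pd.DataFrame({
            "subject_id": rec.subject_id,
            "label": [iv.label for iv in rec.annotations],
            "start_s": [iv.start_s for iv in rec.annotations],
            "end_s": [iv.end_s for iv in rec.annotations],
        })
        avio.write_annotations(ann, tsv_path)
        rows.append({"subject_id": rec.subject_id, "group": rec.group,
                     "wav_path": str(wav_path), "annotation_path": str(tsv_path),
                     "sex": params.sex, "f0_true_hz": params.f0_hz})
    manifest = pd.DataFrame(rows)
    manifest_path = out_dir / "manifest.csv"
    avio.write_manifest(manifest, manifest_path)
    log.info("cohort written: %d recordings under %s", len(rows), out_dir)
    return manifest_path
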