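"""Audio preparation: speech-segment extraction, noise pooling/remixing, blocking.

The preprocessing chain mirrors a conversational recording protocol where each
subject's file was manually segmented into ``speech`` and ``noise_only``
intervals: subject speech segments are concatenated into one signal, the
noise-only material of the whole cohort is chunked, shuffled and re-mixed into
every subject's speech (so the residual background is shared across subjects
rather than site-specific), and the result is cut into overlapping fixed-length
analysis blocks (default 10 s advanced by 5 s).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

LABELS = ("speech", "noise_only", "other")


class EmptySpeechError(ValueError):
    """Recording has no speech-labeled intervals."""


class EmptyNoiseError(ValueError):
    """No recording contributes a noise_only interval."""


@dataclass
class Interval:
    """Half-open labeled interval [start_s, end_s) within a recording."""

    label: str
    start_s: float
    end_s: float

    def __post_init__(self):
        if self.label not in LABELS:
            raise ValueError(f"unknown interval label {self.label!r}")
        if not (self.start_s < self.end_s):
            raise ValueError(f"interval must have start_s < end_s, got "
                             f"[{self.start_s}, {self.end_s})")


@dataclass
class Recording:
    """One subject's audio with segment annotations and a case/control label."""

    subject_id: str
    group: str  # "patient" | "healthy"
    sample_rate: int
    samples: np.ndarray
    annotations: list[Interval] = field(default_factory=list)

    def __post_init__(self):
        if self.group not in ("patient", "healthy"):
            raise ValueError(f"group must be patient|healthy, got {self.group!r}")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if not np.all(np.isfinite(self.samples)):
            raise ValueError(f"{self.subject_id}: non-finite amplitudes")
        dur = self.duration_s
        for iv in self.annotations:
            if iv.start_s < 0 or iv.end_s > dur + 1e-9:
                raise ValueError(f"{self.subject_id}: interval [{iv.start_s}, "
                                 f"{iv.end_s}) outside [0, {dur:.3f}]")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.sample_rate

    @classmethod
    def from_annotation_frame(cls, subject_id, group, sample_rate, samples,
                              annotations: pd.DataFrame) -> "Recording":
        ivs = [Interval(r.label, float(r.start_s), float(r.end_s))
               for r in annotations.itertuples()]
        return cls(subject_id, group, sample_rate, samples, ivs)


@dataclass
class SpeechBlock:
    """A fixed-length window of a subject's concatenated speech signal."""

    subject_id: str
    block_index: int
    start_s: float
    end_s: float
    sample_rate: int
    samples: np.ndarray


@dataclass
class NoisePool:
    """Shuffled concatenation of the cohort's noise-only audio."""

    samples: np.ndarray
    source_ids: list[str]


def merge_intervals(intervals) -> list[tuple[float, float]]:
    """Union of possibly-overlapping [start, end) intervals, sorted by start."""
    spans = sorted((iv.start_s, iv.end_s) for iv in intervals)
    merged: list[list[float]] = []
    for s, e in spans:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def extract_speech(recording: Recording) -> np.ndarray:
    """Concatenate the speech-labeled intervals of a recording in time order.

    Overlapping or touching speech intervals are merged (interval union)
    before slicing, so the output duration equals the merged-span total.
    """
    speech_ivs = [iv for iv in recording.annotations if iv.label == "speech"]
    if not speech_ivs:
        raise EmptySpeechError(f"{recording.subject_id}: no speech intervals")
    sr = recording.sample_rate
    pieces = []
    for s, e in merge_intervals(speech_ivs):
        i0 = int(round(s * sr))
        i1 = min(int(round(e * sr)), len(recording.samples))
        pieces.append(recording.samples[i0:i1])
    return np.concatenate(pieces) if pieces else np.empty(0)


def build_noise_pool(recordings, chunk_s: float = 1.0,
                     rng: np.random.Generator | int | None = None) -> NoisePool:
    """Cut all noise_only intervals into chunks, shuffle, and concatenate.

    Each interval is split into ``chunk_s``-second chunks; a shorter trailing
    remainder is kept as its own chunk so total duration is conserved. The
    chunk order is shuffled with ``rng`` (seed or Generator) so the pool is
    reproducible under a fixed seed.
    """
    rng = np.random.default_rng(rng)
    chunks: list[np.ndarray] = []
    source_ids: list[str] = []
    for rec in recordings:
        sr = rec.sample_rate
        step = max(1, int(round(chunk_s * sr)))
        contributed = False
        for iv in rec.annotations:
            if iv.label != "noise_only":
                continue
            i0 = int(round(iv.start_s * sr))
            i1 = min(int(round(iv.end_s * sr)), len(rec.samples))
            for j in range(i0, i1, step):
                chunks.append(rec.samples[j:min(j + step, i1)])
            contributed = True
        if contributed:
            source_ids.append(rec.subject_id)
    if not chunks:
        raise EmptyNoiseError("no noise_only intervals in any recording")
    order = rng.permutation(len(chunks))
    return NoisePool(np.concatenate([chunks[i] for i in order]), source_ids)


def remix_noise(speech: np.ndarray, pool: NoisePool | np.ndarray,
                gain: float = 1.0) -> np.ndarray:
    """Add the (tiled) noise pool to a speech signal: out[i] = speech[i] + gain*pool[i % len]."""
    if gain < 0:
        raise ValueError("gain must be >= 0")
    speech = np.asarray(speech, dtype=np.float64)
    noise = pool.samples if isinstance(pool, NoisePool) else np.asarray(pool, float)
    if noise.size == 0:
        raise ValueError("noise pool is empty")
    if gain == 0.0:
        return speech.copy()
    reps = int(np.ceil(len(speech) / len(noise)))
    tiled = np.tile(noise, reps)[: len(speech)]
    return speech + gain * tiled


def make_blocks(samples: np.ndarray, sample_rate: int,
                block_length_s: float = 10.0, hop_s: float = 5.0,
                subject_id: str = "") -> list[SpeechBlock]:
    """Cut a signal into full-length overlapping blocks.

    Blocks start at 0, hop, 2*hop, ...; trailing partial windows are dropped,
    so a signal of duration T yields floor((T - block) / hop) + 1 blocks when
    T >= block and none otherwise.
    """
    if block_length_s <= 0:
        raise ValueError("block_length_s must be > 0")
    if not (0 < hop_s <= block_length_s):
        raise ValueError("hop_s must satisfy 0 < hop_s <= block_length_s")
    samples = np.asarray(samples, dtype=np.float64)
    n_block = int(round(block_length_s * sample_rate))
    n_hop = int(round(hop_s * sample_rate))
    blocks: list[SpeechBlock] = []
    start = 0
    idx = 0
    while start + n_block <= len(samples):
        blocks.append(SpeechBlock(
            subject_id=subject_id,
            block_index=idx,
            start_s=start / sample_rate,
            end_s=(start + n_block) / sample_rate,
            sample_rate=sample_rate,
            samples=samples[start:start + n_block],
        ))
        start += n_hop
        idx += 1
    return blocks
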