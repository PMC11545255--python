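"""File formats: 16-bit PCM RIFF WAV, annotation TSV sidecars, cohort manifests.

Audio is exchanged as RIFF WAV (the recording format of the study protocol this
package supports: 44.1 kHz conversational recordings). Segment annotations are
plain TSV files with half-open ``[start_s, end_s)`` intervals labeled ``speech``,
``noise_only`` or ``other``; the cohort manifest is a CSV with one row per
subject.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

log = logging.getLogger(__name__)

ANNOTATION_COLUMNS = ["subject_id", "label", "start_s", "end_s"]
ANNOTATION_LABELS = frozenset({"speech", "noise_only", "other"})
MANIFEST_REQUIRED = ["subject_id", "group", "wav_path"]
GROUPS = frozenset({"patient", "healthy"})

#: nominal sampling rate of the supported recording protocol (Hz)
NOMINAL_RATE = 44100


class WavFormatError(ValueError):
    """Raised when a file cannot be parsed as PCM RIFF WAV."""


def load_wav(path) -> tuple[np.ndarray, int]:
    """Read a RIFF WAV file as float amplitudes in [-1, 1].

    Stereo files are averaged to mono. Integer PCM is rescaled by the full
    scale of its bit depth; float WAV is passed through. Sample rates other
    than 44.1 kHz are accepted but logged (no resampling is performed; all
    downstream analysis is rate-aware).

    Returns
    -------
    (samples, sample_rate) : float64 array, int
    """
    path = Path(path)
    try:
        sample_rate, data = wavfile.read(path)
    except (ValueError, EOFError, OSError) as exc:
        raise WavFormatError(f"cannot read {path} as RIFF WAV: {exc}") from exc

    if data.dtype == np.int16:
        x = data.astype(np.float64) / 2**15
    elif data.dtype == np.int32:
        x = data.astype(np.float64) / 2**31
    elif data.dtype == np.uint8:
        x = (data.astype(np.float64) - 128.0) / 128.0
    elif data.dtype in (np.float32, np.float64):
        x = data.astype(np.float64)
    else:
        raise WavFormatError(f"{path}: unsupported WAV sample format chunk dtype={data.dtype}")

    if x.ndim == 2:  # average channels to mono
        x = x.mean(axis=1)
    if int(sample_rate) != NOMINAL_RATE:
        log.info("%s: sample rate %d Hz (nominal %d Hz); no resampling applied",
                 path.name, sample_rate, NOMINAL_RATE)
    return x, int(sample_rate)


def write_wav(samples, sample_rate: int, path) -> None:
    """Write float amplitudes as 16-bit PCM RIFF WAV.

    Values outside [-1, 1] are clipped with a warning. Round-trips through
    :func:`load_wav` within 16-bit quantization (|error| <= 2**-15).
    """
    x = np.asarray(samples, dtype=np.float64)
    if not np.all(np.isfinite(x)):
        raise ValueError("write_wav: amplitudes must be finite")
    n_clip = int(np.count_nonzero(np.abs(x) > 1.0))
    if n_clip:
        warnings.warn(f"write_wav: clipping {n_clip} samples outside [-1, 1]",
                      stacklevel=2)
        log.warning("write_wav(%s): clipped %d samples", path, n_clip)
        x = np.clip(x, -1.0, 1.0)
    # full-scale 32768 with clip at the int16 max keeps round-trip
    # error within half an LSB (<= 2**-15 even at +1.0)
    pcm = np.clip(np.round(x * 32768.0), -32768, 32767).astype(np.int16)
    wavfile.write(Path(path), int(sample_rate), pcm)


def read_annotations(path) -> pd.DataFrame:
    """Read a TSV annotation sidecar (columns subject_id, label, start_s, end_s)."""
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str, "label": str})
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: annotation TSV missing columns {missing}")
    bad = set(df["label"]) - ANNOTATION_LABELS
    if bad:
        raise ValueError(f"{path}: unknown annotation labels {sorted(bad)}")
    df["start_s"] = df["start_s"].astype(float)
    df["end_s"] = df["end_s"].astype(float)
    if (df["start_s"] >= df["end_s"]).any():
        raise ValueError(f"{path}: intervals must satisfy start_s < end_s")
    return df[ANNOTATION_COLUMNS]


def write_annotations(annotations: pd.DataFrame, path) -> None:
    annotations[ANNOTATION_COLUMNS].to_csv(path, sep="\t", index=False,
                                           float_format="%.6f")


def read_manifest(path) -> pd.DataFrame:
    """Read a cohort manifest CSV (subject_id, group, wav_path + metadata)."""
    df = pd.read_csv(path, dtype={"subject_id": str, "group": str})
    missing = [c for c in MANIFEST_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: manifest missing columns {missing}")
    bad = set(df["group"]) - GROUPS
    if bad:
        raise ValueError(f"{path}: unknown group labels {sorted(bad)}; "
                         f"expected one of {sorted(GROUPS)}")
    if df["subject_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate subject_id rows")
    return df


def write_manifest(manifest: pd.DataFrame, path) -> None:
    manifest.to_csv(path, index=False)


def annotation_path_for(manifest_row) -> Path:
    """Sidecar TSV path for a manifest row (explicit column or wav stem + .tsv)."""
    if "annotation_path" in manifest_row and isinstance(manifest_row["annotation_path"], str):
        return Path(manifest_row["annotation_path"])
    return Path(manifest_row["wav_path"]).with_suffix(".tsv")
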