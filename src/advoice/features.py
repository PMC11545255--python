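"""Per-block acoustic features: spectral moments, intensity, F0, and their deltas.

Each 10-s speech block yields one 43-dimensional feature vector:

* 7 spectrum features — per-frame moments of the short-time power spectrum
  treated as a probability mass over frequency (center of gravity, standard
  deviation, skewness, Pearson kurtosis), aggregated across frames as mean and
  SD of centroid/skewness/kurtosis plus the mean spectral SD;
* 9 intensity features — the 9-statistic summary (mean, median, min, max,
  15th/85th percentile, SD, skewness, excess kurtosis) of the per-frame RMS
  amplitude series;
* 9 intensity-delta features — the same summary of the frame-to-frame first
  differences ("minute temporal variation");
* 9 F0 features — the summary of the voiced-frame fundamental-frequency
  series from a normalized-autocorrelation pitch tracker;
* 9 F0-delta features — the summary of F0 first differences taken over
  consecutive voiced frames only.

Conventions: population moments (divisor n), Fisher excess kurtosis for the
9-statistic summary, linear-interpolation percentiles. Spectral kurtosis uses
the Pearson (non-excess) convention, the established definition for spectral
shape moments; the two conventions are deliberately distinct and documented.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy.fft import rfft, rfftfreq
from scipy.signal import get_window

from .prep import SpeechBlock, make_blocks

log = logging.getLogger(__name__)

STAT9_NAMES = ["mean", "median", "minimum", "maximum", "p15", "p85",
               "sd", "skewness", "kurtosis"]

SPECTRUM_FEATURES = [
    "spectrum.cog_mean", "spectrum.cog_sd",
    "spectrum.skewness_mean", "spectrum.skewness_sd",
    "spectrum.kurtosis_mean", "spectrum.kurtosis_sd",
    "spectrum.sd_mean",
]

FEATURE_NAMES = (
    SPECTRUM_FEATURES
    + [f"intensity.{s}" for s in STAT9_NAMES]
    + [f"intensity_delta.{s}" for s in STAT9_NAMES]
    + [f"f0.{s}" for s in STAT9_NAMES]
    + [f"f0_delta.{s}" for s in STAT9_NAMES]
)

ID_COLUMNS = ["subject_id", "group", "block_index"]


@dataclass
class FrameGrid:
    """Short-time analysis grid shared by all per-frame measures."""

    frame_length: int = 2048
    hop: int = 512
    window: str = "hann"
    sample_rate: int = 44100

    def __post_init__(self):
        if not (0 < self.hop <= self.frame_length):
            raise ValueError("FrameGrid requires 0 < hop <= frame_length")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")


@dataclass
class SpectralMoments:
    """Moments of one power spectrum viewed as a frequency distribution."""

    centroid: float   # Hz ("center of gravity")
    sd: float         # Hz
    skewness: float   # dimensionless; NaN when sd == 0
    kurtosis: float   # Pearson (non-excess); NaN when sd == 0


@dataclass
class FrameSeries:
    """Per-frame values over one block plus their first-difference series."""

    values: np.ndarray
    voiced_mask: np.ndarray | None = None

    @property
    def delta(self) -> np.ndarray:
        return delta(self.values)


def _frames(samples: np.ndarray, frame_length: int, hop: int) -> np.ndarray:
    x = np.asarray(samples, dtype=np.float64)
    if len(x) < frame_length:
        raise ValueError(f"block of {len(x)} samples shorter than one "
                         f"frame ({frame_length})")
    return sliding_window_view(x, frame_length)[::hop]


def stft_power(samples, grid: FrameGrid) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame power spectra |X_k|^2 on the frame grid.

    Returns (power, frequencies): power has shape (n_frames, n_bins) with
    bin k at frequency k * sample_rate / frame_length (DC bin retained here;
    excluded by the moment aggregation downstream).
    """
    frames = _frames(samples, grid.frame_length, grid.hop)
    if grid.window in (None, "rectangular", "boxcar"):
        w = np.ones(grid.frame_length)
    else:
        w = get_window(grid.window, grid.frame_length, fftbins=True)
    spec = np.abs(rfft(frames * w, axis=1)) ** 2
    freqs = rfftfreq(grid.frame_length, 1.0 / grid.sample_rate)
    return spec, freqs


def _moments_2d(power: np.ndarray, freqs: np.ndarray):
    """Vectorized spectral moments for a (n_frames, n_bins) power array.

    Frames with zero total power get NaN in all four moments; frames with
    zero spread (point mass) get NaN skewness/kurtosis only.
    """
    power = np.asarray(power, dtype=np.float64)
    freqs = np.asarray(freqs, dtype=np.float64)
    tot = power.sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = power / tot[..., None]
        c = p @ freqs
        d = freqs[None, :] - c[..., None]
        m2 = np.einsum("ij,ij->i", p, d ** 2)
        m3 = np.einsum("ij,ij->i", p, d ** 3)
        m4 = np.einsum("ij,ij->i", p, d ** 4)
        m2 = np.maximum(m2, 0.0)
        sd = np.sqrt(m2)
        skew = np.where(sd > 0, m3 / np.where(sd > 0, sd, 1) ** 3, np.nan)
        kurt = np.where(m2 > 0, m4 / np.where(m2 > 0, m2, 1) ** 2, np.nan)
    bad = ~(tot > 0)
    for arr in (c, sd, skew, kurt):
        arr[bad] = np.nan
    return c, sd, skew, kurt


def spectral_moments(power_spectrum, frequencies) -> SpectralMoments:
    """Moments of a single power spectrum as a frequency distribution.

    Normalized power is treated as a probability mass p_k over the given
    bins: centroid = sum f_k p_k, sd = sqrt(sum (f_k-c)^2 p_k), skewness and
    Pearson kurtosis are the standardized third and fourth moments. A zero
    total power yields all-NaN moments; zero spread yields NaN shape moments.
    """
    p = np.atleast_2d(np.asarray(power_spectrum, dtype=np.float64))
    f = np.asarray(frequencies, dtype=np.float64)
    if p.shape[-1] != f.shape[0]:
        raise ValueError("power and frequency arrays must align")
    c, sd, sk, ku = _moments_2d(p, f)
    return SpectralMoments(float(c[0]), float(sd[0]), float(sk[0]), float(ku[0]))


def block_spectrum_features(samples, grid: FrameGrid, *, exclude_dc: bool = True,
                            weighting: str = "power") -> dict[str, float]:
    """The 7 spectrum features of one block (3 moments x mean/SD + mean SD).

    Per-frame moments are computed on the power spectrum (or magnitude if
    ``weighting='magnitude'``) with the DC bin excluded, then aggregated
    across frames: mean and population SD of centroid/skewness/kurtosis, and
    the mean of the per-frame spectral SD. Frames with undefined moments are
    excluded statistic-by-statistic; a statistic with fewer than two usable
    frames is missing.
    """
    power, freqs = stft_power(samples, grid)
    if weighting == "magnitude":
        power = np.sqrt(power)
    elif weighting != "power":
        raise ValueError("weighting must be 'power' or 'magnitude'")
    if exclude_dc:
        power, freqs = power[:, 1:], freqs[1:]
    c, sd, sk, ku = _moments_2d(power, freqs)

    def mean_sd(x):
        x = x[np.isfinite(x)]
        if x.size < 2:
            return math.nan, math.nan
        return float(x.mean()), float(x.std())

    cog_mean, cog_sd = mean_sd(c)
    sk_mean, sk_sd = mean_sd(sk)
    ku_mean, ku_sd = mean_sd(ku)
    sd_valid = sd[np.isfinite(sd)]
    sd_mean = float(sd_valid.mean()) if sd_valid.size >= 2 else math.nan
    return {
        "spectrum.cog_mean": cog_mean, "spectrum.cog_sd": cog_sd,
        "spectrum.skewness_mean": sk_mean, "spectrum.skewness_sd": sk_sd,
        "spectrum.kurtosis_mean": ku_mean, "spectrum.kurtosis_sd": ku_sd,
        "spectrum.sd_mean": sd_mean,
    }


def intensity_series(samples, grid: FrameGrid) -> FrameSeries:
    """Per-frame RMS amplitude (linear scale, rectangular window)."""
    frames = _frames(samples, grid.frame_length, grid.hop)
    rms = np.sqrt(np.mean(frames ** 2, axis=1))
    return FrameSeries(values=rms)


def f0_series(samples, grid: FrameGrid, fmin: float = 50.0, fmax: float = 400.0,
              voicing_threshold: float = 0.45, silence_rms: float = 1e-4,
              octave_cost: float = 0.05) -> FrameSeries:
    """Per-frame fundamental frequency by normalized autocorrelation.

    For each frame the mean-removed normalized autocorrelation
    r(tau) = sum x[n] x[n+tau] / sqrt(E_head(tau) E_tail(tau)) is searched
    for local maxima over lags in [sr/fmax, sr/fmin]. Candidates are scored
    with an octave cost (``octave_cost`` per octave of lag, penalizing longer
    lags) so the true period wins over its near-tied integer multiples in
    noisy frames; the winning lag is refined by parabolic interpolation.
    A frame is unvoiced when no candidate reaches ``voicing_threshold`` or its
    RMS is below ``silence_rms``; unvoiced frames carry NaN.
    """
    sr = grid.sample_rate
    if not (fmin < fmax < sr / 4):
        raise ValueError("need fmin < fmax < Nyquist/2")
    frames = _frames(samples, grid.frame_length, grid.hop)
    n = grid.frame_length
    rms = np.sqrt(np.mean(frames ** 2, axis=1))
    xc = frames - frames.mean(axis=1, keepdims=True)

    nfft = 1 << int(np.ceil(np.log2(2 * n)))
    spec = np.abs(rfft(xc, nfft, axis=1)) ** 2
    acf = np.fft.irfft(spec, nfft, axis=1)[:, :n]

    sq = np.cumsum(xc ** 2, axis=1)
    total = sq[:, -1:]
    lags = np.arange(n)
    # E_head(tau) = sum_{i<n-tau} x^2, E_tail(tau) = sum_{i>=tau} x^2
    e_head = sq[:, n - 1 - lags]
    e_tail = total - np.concatenate([np.zeros((len(xc), 1)), sq[:, :-1]], axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = acf / np.sqrt(np.maximum(e_head * e_tail, 1e-300))

    lmin = max(2, int(np.floor(sr / fmax)))
    lmax = min(n - 2, int(np.ceil(sr / fmin)))
    rr = r[:, lmin:lmax + 1]
    inner = rr[:, 1:-1]
    is_peak = (inner >= rr[:, :-2]) & (inner >= rr[:, 2:]) & (inner >= voicing_threshold)
    rel_lag = np.arange(1, rr.shape[1] - 1)
    score = np.where(is_peak,
                     inner - octave_cost * np.log2((lmin + rel_lag) / lmin),
                     -np.inf)
    best = np.argmax(score, axis=1)
    has_peak = np.isfinite(score[np.arange(len(score)), best])
    voiced = has_peak & (rms >= silence_rms)

    tau = lmin + 1 + best  # absolute lag of the winning candidate
    f0 = np.full(len(frames), np.nan)
    if voiced.any():
        idx = np.flatnonzero(voiced)
        t = tau[idx]
        y0, y1, y2 = (r[idx, t - 1], r[idx, t], r[idx, t + 1])
        denom = y0 - 2 * y1 + y2
        with np.errstate(invalid="ignore", divide="ignore"):
            shift = np.where(np.abs(denom) > 1e-12, 0.5 * (y0 - y2) / denom, 0.0)
        shift = np.clip(shift, -0.5, 0.5)
        f0[idx] = sr / (t + shift)

    # temporal-continuity pass: an isolated frame deviating >30% from the
    # local (5-frame) running median is a gross tracking error (typically a
    # period-doubling slip at a segment seam) and is re-marked unvoiced
    if voiced.any():
        med = pd.Series(f0).rolling(5, center=True, min_periods=1).median().to_numpy()
        with np.errstate(invalid="ignore"):
            bad = voiced & (np.abs(f0 - med) > 0.3 * med)
        f0[bad] = np.nan
        voiced = voiced & ~bad
    return FrameSeries(values=f0, voiced_mask=voiced)


def delta(series) -> np.ndarray:
    """Consecutive first differences v[i+1] - v[i] (length n-1)."""
    v = np.asarray(series, dtype=np.float64)
    if v.size < 2:
        return np.empty(0)
    return np.diff(v)


def summarize9(sequence) -> dict[str, float]:
    """The 9-statistic summary of a sequence of finite values.

    mean, median, minimum, maximum, 15th/85th percentile (linear
    interpolation), population SD (divisor n), moment skewness g1 and excess
    kurtosis g2. Shape statistics are missing when the SD is zero; an empty
    sequence yields all-missing.
    """
    x = np.asarray(sequence, dtype=np.float64).ravel()
    x = x[np.isfinite(x)]
    if x.size == 0:
        return {s: math.nan for s in STAT9_NAMES}
    m = float(x.mean())
    sd = float(x.std())
    out = {
        "mean": m,
        "median": float(np.median(x)),
        "minimum": float(x.min()),
        "maximum": float(x.max()),
        "p15": float(np.percentile(x, 15)),
        "p85": float(np.percentile(x, 85)),
        "sd": sd,
    }
    if sd > 0:
        z = (x - m) / sd
        out["skewness"] = float(np.mean(z ** 3))
        out["kurtosis"] = float(np.mean(z ** 4) - 3.0)
    else:
        out["skewness"] = math.nan
        out["kurtosis"] = math.nan
    return out


def block_feature_vector(block: SpeechBlock | np.ndarray, grid: FrameGrid,
                         fmin: float = 50.0, fmax: float = 400.0,
                         voicing_threshold: float = 0.45,
                         silence_rms: float = 1e-4,
                         min_voiced_frames: int = 10) -> dict[str, float]:
    """All 43 features of one block (missing values as NaN, never fatal).

    The F0 and F0-delta groups are missing when fewer than
    ``min_voiced_frames`` frames are voiced; F0 deltas are taken between
    consecutive voiced frames only, so silences never produce spurious jumps.
    """
    samples = block.samples if isinstance(block, SpeechBlock) else np.asarray(block)
    out: dict[str, float] = {}
    out.update(block_spectrum_features(samples, grid))

    inten = intensity_series(samples, grid).values
    for s, v in summarize9(inten).items():
        out[f"intensity.{s}"] = v
    for s, v in summarize9(delta(inten)).items():
        out[f"intensity_delta.{s}"] = v

    f0 = f0_series(samples, grid, fmin=fmin, fmax=fmax,
                   voicing_threshold=voicing_threshold, silence_rms=silence_rms)
    voiced_vals = f0.values[np.isfinite(f0.values)]
    if voiced_vals.size < min_voiced_frames:
        for s in STAT9_NAMES:
            out[f"f0.{s}"] = math.nan
            out[f"f0_delta.{s}"] = math.nan
    else:
        for s, v in summarize9(voiced_vals).items():
            out[f"f0.{s}"] = v
        d = np.diff(f0.values)  # NaN wherever either neighbor is unvoiced
        d = d[np.isfinite(d)]
        for s, v in summarize9(d).items():
            out[f"f0_delta.{s}"] = v
    assert len(out) == 43
    return out


def subject_feature_rows(speech: np.ndarray, sample_rate: int, subject_id: str,
                         group: str, grid: FrameGrid | None = None,
                         block_length_s: float = 10.0, block_hop_s: float = 5.0,
                         **f0_kwargs) -> list[dict]:
    """Feature rows (one per block) for one subject's concatenated speech."""
    grid = grid or FrameGrid(sample_rate=sample_rate)
    rows = []
    for blk in make_blocks(speech, sample_rate, block_length_s, block_hop_s,
                           subject_id=subject_id):
        row = {"subject_id": subject_id, "group": group,
               "block_index": blk.block_index}
        row.update(block_feature_vector(blk, grid, **f0_kwargs))
        rows.append(row)
    return rows


def cohort_feature_table(speech_by_subject, sample_rate: int,
                         grid: FrameGrid | None = None,
                         block_length_s: float = 10.0, block_hop_s: float = 5.0,
                         **f0_kwargs) -> pd.DataFrame:
    """Feature table for a whole cohort: one row per block.

    ``speech_by_subject`` yields ``(subject_id, group, speech_samples)``
    triples. Subjects whose speech is shorter than one block are logged and
    skipped. Columns: subject_id, group, block_index + the 43 features.
    """
    all_rows: list[dict] = []
    for subject_id, group, speech in speech_by_subject:
        rows = subject_feature_rows(speech, sample_rate, subject_id, group,
                                    grid, block_length_s, block_hop_s,
                                    **f0_kwargs)
        if not rows:
            log.warning("subject %s: no full-length blocks (speech %.2f s); skipped",
                        subject_id, len(speech) / sample_rate)
            continue
        all_rows.extend(rows)
    if not all_rows:
        raise ValueError("no subject produced any block")
    return pd.DataFrame(all_rows, columns=ID_COLUMNS + FEATURE_NAMES)


def write_feature_table(table: pd.DataFrame, path) -> None:
    """CSV with dotted feature-name header; missing values as empty cells."""
    table.to_csv(path, index=False, float_format="%.12g")


def read_feature_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"subject_id": str, "group": str})
    missing = [c for c in ID_COLUMNS + FEATURE_NAMES if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: feature table missing columns {missing[:5]}...")
    return df
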