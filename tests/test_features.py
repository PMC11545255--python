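"""Feature extraction: spectral moments, 9-statistic summaries, intensity,
pitch tracking, deltas, and the 43-slot block feature vector."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from advoice.features import (FEATURE_NAMES, FrameGrid, block_feature_vector,
                              block_spectrum_features, cohort_feature_table,
                              delta, f0_series, intensity_series,
                              read_feature_table, spectral_moments,
                              stft_power, summarize9, write_feature_table)
from tests.conftest import SR, sawtooth


# --- independent brute-force oracles -----------------------------------------

def moments_oracle(power, freqs):
    """Plain-loop spectral moments over bins, independent of the implementation."""
    tot = sum(power)
    p = [w / tot for w in power]
    c = sum(f * w for f, w in zip(freqs, p))
    m2 = sum((f - c) ** 2 * w for f, w in zip(freqs, p))
    m3 = sum((f - c) ** 3 * w for f, w in zip(freqs, p))
    m4 = sum((f - c) ** 4 * w for f, w in zip(freqs, p))
    sd = math.sqrt(m2)
    if sd == 0:
        return c, sd, math.nan, math.nan
    return c, sd, m3 / sd**3, m4 / m2**2


def summarize9_oracle(x):
    """Order-statistic + moment summary by explicit formulas."""
    xs = sorted(x)
    n = len(xs)
    m = sum(xs) / n

    def pct(q):
        pos = q / 100 * (n - 1)
        lo = int(math.floor(pos))
        hi = min(lo + 1, n - 1)
        return xs[lo] + (pos - lo) * (xs[hi] - xs[lo])

    var = sum((v - m) ** 2 for v in xs) / n
    sd = math.sqrt(var)
    med = pct(50)
    if sd == 0:
        skew = kurt = math.nan
    else:
        skew = sum(((v - m) / sd) ** 3 for v in xs) / n
        kurt = sum(((v - m) / sd) ** 4 for v in xs) / n - 3
    return dict(mean=m, median=med, minimum=xs[0], maximum=xs[-1],
                p15=pct(15), p85=pct(85), sd=sd, skewness=skew, kurtosis=kurt)


# --- STFT ---------------------------------------------------------------------

class TestStftPower:
    def test_pure_tone_peaks_at_its_bin(self, grid):
        t = np.arange(SR) / SR
        x = np.sin(2 * np.pi * 1000.0 * t)
        power, freqs = stft_power(x, grid)
        peak_freqs = freqs[np.argmax(power, axis=1)]
        assert np.all(np.abs(peak_freqs - 1000.0) <= SR / grid.frame_length)

    def test_zeros_give_zero_spectra(self, grid):
        power, _ = stft_power(np.zeros(3 * 2048), grid)
        assert np.all(power == 0)

    def test_parseval_with_window_correction(self, grid):
        rng = np.random.default_rng(5)
        x = rng.standard_normal(SR)
        power, _ = stft_power(x, grid)
        # independent oracle: windowed time-domain energy per frame
        from numpy.lib.stride_tricks import sliding_window_view
        from scipy.signal import get_window
        w = get_window("hann", grid.frame_length, fftbins=True)
        frames = sliding_window_view(x, grid.frame_length)[::grid.hop] * w
        time_energy = np.sum(frames ** 2, axis=1)
        # full-FFT power from the rfft half-spectrum
        spec_energy = (power[:, 0] + power[:, -1] +
                       2 * power[:, 1:-1].sum(axis=1)) / grid.frame_length
        assert np.allclose(spec_energy, time_energy, rtol=0.01)

    def test_short_block_rejected(self, grid):
        with pytest.raises(ValueError, match="shorter"):
            stft_power(np.zeros(100), grid)


# --- spectral moments ---------------------------------------------------------

class TestSpectralMoments:
    def test_point_mass(self):
        m = spectral_moments([0.0, 5.0, 0.0], [0.0, 100.0, 200.0])
        assert m.centroid == 100.0 and m.sd == 0.0
        assert math.isnan(m.skewness) and math.isnan(m.kurtosis)

    def test_flat_four_bins(self):
        m = spectral_moments([1, 1, 1, 1], [0.0, 100.0, 200.0, 300.0])
        assert m.centroid == pytest.approx(150.0)
        assert m.sd == pytest.approx(111.8033988749895)
        assert m.skewness == pytest.approx(0.0, abs=1e-12)
        assert m.kurtosis == pytest.approx(1.64)

    def test_zero_power_all_missing(self):
        m = spectral_moments([0.0, 0.0], [100.0, 200.0])
        assert all(math.isnan(v) for v in
                   (m.centroid, m.sd, m.skewness, m.kurtosis))

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(st.lists(st.floats(1e-6, 1e3), min_size=2, max_size=64))
    def test_matches_brute_force_oracle(self, power):
        freqs = [21.5 * (k + 1) for k in range(len(power))]
        m = spectral_moments(power, freqs)
        c, sd, sk, ku = moments_oracle(power, freqs)
        assert m.centroid == pytest.approx(c, rel=1e-9)
        assert m.sd == pytest.approx(sd, rel=1e-9, abs=1e-9)
        if not math.isnan(sk):
            assert m.skewness == pytest.approx(sk, rel=1e-9, abs=1e-9)
            assert m.kurtosis == pytest.approx(ku, rel=1e-9)


class TestBlockSpectrumFeatures:
    def test_stationary_signal_has_zero_frame_spread(self):
        # period (512 samples) divides the hop, so every frame is identical
        f = 12 * SR / 512
        t = np.arange(5 * 2048) / SR
        x = np.sin(2 * np.pi * f * t)
        grid = FrameGrid(sample_rate=SR)
        feats = block_spectrum_features(x, grid)
        assert feats["spectrum.cog_sd"] == pytest.approx(0.0, abs=1e-6)
        assert feats["spectrum.skewness_sd"] == pytest.approx(0.0, abs=1e-9)
        assert feats["spectrum.kurtosis_sd"] == pytest.approx(0.0, abs=1e-6)

    def test_two_alternating_spectra_give_two_point_stats(self):
        # frames alternate pure tones at exact bins -> near point masses
        grid = FrameGrid(frame_length=2048, hop=2048, window="rectangular",
                         sample_rate=SR)
        f1, f2 = 10 * SR / 2048, 20 * SR / 2048
        n = np.arange(2048)
        fa = np.sin(2 * np.pi * f1 * n / SR)
        fb = np.sin(2 * np.pi * f2 * n / SR)
        x = np.concatenate([fa, fb] * 3)
        feats = block_spectrum_features(x, grid)
        # two-point oracle: mean (c1+c2)/2, population SD |c1-c2|/2
        assert feats["spectrum.cog_mean"] == pytest.approx((f1 + f2) / 2, rel=1e-6)
        assert feats["spectrum.cog_sd"] == pytest.approx((f2 - f1) / 2, rel=1e-6)

    def test_emits_exactly_seven_values(self, sawtooth_block, grid):
        feats = block_spectrum_features(sawtooth_block, grid)
        assert len(feats) == 7
        assert all(k.startswith("spectrum.") for k in feats)


# --- intensity, F0, delta -----------------------------------------------------

class TestIntensity:
    def test_constant_amplitude_exact(self, grid):
        vals = intensity_series(np.full(5 * 2048, 0.25), grid).values
        assert np.allclose(vals, 0.25, rtol=0, atol=1e-12)

    def test_zeros(self, grid):
        assert np.all(intensity_series(np.zeros(4096), grid).values == 0)

    def test_sine_rms_is_peak_over_sqrt2(self, grid):
        t = np.arange(SR) / SR
        vals = intensity_series(np.sin(2 * np.pi * 220 * t), grid).values
        assert np.mean(vals) == pytest.approx(1 / np.sqrt(2), rel=0.01)


class TestF0Series:
    def test_sawtooth_recovered(self, grid):
        fs = f0_series(sawtooth(120.0, 10.0), grid)
        voiced = fs.values[np.isfinite(fs.values)]
        assert len(voiced) / len(fs.values) >= 0.90
        assert np.median(voiced) == pytest.approx(120.0, rel=0.02)

    def test_white_noise_mostly_unvoiced(self, grid):
        x = np.random.default_rng(2).standard_normal(5 * SR) * 0.1
        fs = f0_series(x, grid)
        assert np.mean(~np.isfinite(fs.values)) >= 0.90

    def test_silence_fully_unvoiced(self, grid):
        fs = f0_series(np.zeros(5 * SR), grid)
        assert np.all(~np.isfinite(fs.values))
        assert not fs.voiced_mask.any()


class TestDelta:
    def test_simple_example(self):
        assert np.array_equal(delta([1, 3, 2]), [2, -1])

    def test_constant_series_all_zero(self):
        assert np.all(delta(np.full(10, 3.3)) == 0)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.lists(st.floats(-1e6, 1e6), min_size=2, max_size=100))
    def test_telescoping_sum(self, xs):
        assert np.sum(delta(xs)) == pytest.approx(xs[-1] - xs[0], abs=1e-6)


class TestSummarize9:
    def test_one_to_five_oracle(self):
        s = summarize9([1, 2, 3, 4, 5])
        assert s["mean"] == 3 and s["median"] == 3
        assert s["minimum"] == 1 and s["maximum"] == 5
        assert s["p15"] == pytest.approx(1.6)
        assert s["p85"] == pytest.approx(4.4)
        assert s["sd"] == pytest.approx(math.sqrt(2))
        assert s["skewness"] == pytest.approx(0.0, abs=1e-12)
        assert s["kurtosis"] == pytest.approx(-1.3)

    def test_degenerate_constant(self):
        s = summarize9([4.2, 4.2, 4.2])
        assert s["mean"] == s["median"] == s["minimum"] == s["maximum"] == 4.2
        assert s["sd"] == 0
        assert math.isnan(s["skewness"]) and math.isnan(s["kurtosis"])

    def test_empty_all_missing(self):
        assert all(math.isnan(v) for v in summarize9([]).values())

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(st.lists(st.floats(-1e3, 1e3), min_size=1, max_size=200))
    def test_matches_brute_force_oracle(self, xs):
        s = summarize9(xs)
        o = summarize9_oracle(xs)
        for k in s:
            if math.isnan(o[k]):
                assert math.isnan(s[k])
            else:
                assert s[k] == pytest.approx(o[k], rel=1e-9, abs=1e-9)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.lists(st.floats(-1e3, 1e3), min_size=1, max_size=100))
    def test_order_statistics_monotone(self, xs):
        s = summarize9(xs)
        assert (s["minimum"] <= s["p15"] + 1e-12 and
                s["p15"] <= s["median"] + 1e-12 and
                s["median"] <= s["p85"] + 1e-12 and
                s["p85"] <= s["maximum"] + 1e-12)


# --- block feature vector -----------------------------------------------------

class TestBlockFeatureVector:
    def test_exactly_43_named_slots(self, sawtooth_block, grid):
        fv = block_feature_vector(sawtooth_block, grid)
        assert list(fv) == FEATURE_NAMES
        assert len(fv) == 43

    def test_group_decomposition_7_18_18(self):
        groups = [n.split(".")[0] for n in FEATURE_NAMES]
        assert groups.count("spectrum") == 7
        assert groups.count("intensity") + groups.count("f0") == 18
        assert groups.count("intensity_delta") + groups.count("f0_delta") == 18

    def test_unvoiced_block_missing_f0_groups(self, grid):
        x = np.random.default_rng(9).standard_normal(10 * SR) * 0.1
        fv = block_feature_vector(x, grid)
        f0_slots = [k for k in fv if k.startswith(("f0.", "f0_delta."))]
        assert len(f0_slots) == 18
        assert all(math.isnan(fv[k]) for k in f0_slots)
        present = [k for k in fv if not k.startswith(("f0.", "f0_delta."))]
        assert len(present) == 25
        assert all(math.isfinite(fv[k]) for k in present)

    def test_amplitude_scaling_behavior(self, grid):
        rng = np.random.default_rng(4)
        x = sawtooth(120.0, 10.0) * 0.1 + rng.standard_normal(10 * SR) * 1e-3
        a, alpha = block_feature_vector(x, grid), 2.5
        b = block_feature_vector(alpha * x, grid)
        for stat in ("mean", "median", "minimum", "maximum", "p15", "p85", "sd"):
            assert b[f"intensity.{stat}"] == pytest.approx(
                alpha * a[f"intensity.{stat}"], rel=1e-6)
        for k in a:
            if k.startswith(("spectrum.", "f0.", "f0_delta.")) or \
                    k in ("intensity.skewness", "intensity.kurtosis"):
                assert b[k] == pytest.approx(a[k], rel=1e-6, abs=1e-9)

    def test_time_shift_robustness(self, grid):
        # stationary voiced signal with real vibrato and tremolo whose
        # periods divide the block, so a circular shift is an exact
        # re-framing and every delta series carries genuine structure
        t = np.arange(10 * SR) / SR
        phase = 126.0 * t - 5.0 / (2 * np.pi) * np.cos(2 * np.pi * t)
        x = (2.0 * (phase % 1.0) - 1.0) * (1.0 + 0.2 * np.sin(4 * np.pi * t))
        a = block_feature_vector(x, grid)
        b = block_feature_vector(np.roll(x, grid.hop), grid)
        for k in a:
            if math.isnan(a[k]):
                assert math.isnan(b[k])
            else:
                # abs floor = 1% of the O(1) natural scale of the
                # dimensionless statistics, for values structurally ~0
                assert b[k] == pytest.approx(a[k], rel=0.01, abs=0.01)


class TestCohortFeatureTable:
    def _speech(self, seconds, seed):
        rng = np.random.default_rng(seed)
        return sawtooth(118.0, seconds) * 0.1 + rng.standard_normal(
            int(seconds * SR)) * 1e-3

    def test_row_and_column_counts(self, grid):
        table = cohort_feature_table(
            [("a", "patient", self._speech(20, 0)),
             ("b", "healthy", self._speech(20, 1))], SR, grid)
        assert len(table) == 2 * 3  # 20 s -> 3 blocks each
        assert table.shape[1] == 43 + 3

    def test_round_trip_12_significant_digits(self, grid, tmp_path):
        table = cohort_feature_table(
            [("a", "patient", self._speech(10, 0))], SR, grid)
        p = tmp_path / "f.csv"
        write_feature_table(table, p)
        back = read_feature_table(p)
        for c in FEATURE_NAMES:
            np.testing.assert_allclose(back[c], table[c], rtol=1e-11)

    def test_short_subject_skipped(self, grid, caplog):
        table = cohort_feature_table(
            [("ok", "patient", self._speech(10, 0)),
             ("short", "healthy", self._speech(5, 1)),
             ("ok2", "healthy", self._speech(10, 2))], SR, grid)
        assert set(table["subject_id"]) == {"ok", "ok2"}
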