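"""Windowing, the feature registry against direct-formula oracles, and FM
normalization."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ssmseg.features import (
    DEFAULT_FEATURES,
    FEATURE_REGISTRY,
    WindowingConfig,
    extract_features,
    normalize_fm,
    sliding_windows,
)
from ssmseg.synth import TimeSeriesRecord


class TestWindowing:
    @pytest.mark.parametrize(
        "n,w,overlap,expected_starts",
        [
            (10, 4, 0.5, [0, 2, 4, 6]),
            (10, 4, 0.0, [0, 4]),  # disjoint tiling, trailing partial dropped
            (4, 4, 0.5, [0]),  # n == w: single window
            (12, 4, 0.0, [0, 4, 8]),
        ],
    )
    def test_start_indices(self, n, w, overlap, expected_starts):
        starts = sliding_windows(n, WindowingConfig(w, overlap))
        assert starts.tolist() == expected_starts

    def test_signal_shorter_than_window(self):
        with pytest.raises(ValueError, match="shorter than window"):
            sliding_windows(3, WindowingConfig(4))

    @pytest.mark.parametrize("w,overlap,hop", [(250, 0.95, 12), (50, 0.95, 2), (10, 0.95, 1)])
    def test_hop_half_even_rounding_robust_to_float_noise(self, w, overlap, hop):
        assert WindowingConfig(w, overlap).hop == hop

    @given(
        n=st.integers(20, 300),
        w=st.integers(2, 20),
        overlap=st.floats(0.0, 0.95),
    )
    def test_every_window_inside_signal(self, n, w, overlap):
        config = WindowingConfig(w, overlap)
        starts = sliding_windows(n, config)
        assert starts[0] == 0
        assert starts[-1] + w <= n
        assert np.all(np.diff(starts) == config.hop)


def _oracle(name: str, x: np.ndarray, fs: float) -> float:
    """Independent direct-formula evaluation of each registry feature."""
    n = len(x)
    mu = sum(x) / n
    var = sum((v - mu) ** 2 for v in x) / n
    sd = math.sqrt(var)
    xs = np.sort(x)
    if name == "mean":
        return mu
    if name == "std":
        return sd
    if name == "variance":
        return var
    if name == "median":
        return float(np.percentile(x, 50))
    if name == "min":
        return min(x)
    if name == "max":
        return max(x)
    if name == "peak_to_peak":
        return max(x) - min(x)
    if name in ("skewness", "kurtosis"):
        lo, hi = mu - 3 * sd, mu + 3 * sd
        w = np.array([min(max(v, lo), hi) for v in x])
        wm = w.mean()
        m2 = ((w - wm) ** 2).mean()
        m3 = ((w - wm) ** 3).mean()
        m4 = ((w - wm) ** 4).mean()
        return m3 / m2**1.5 if name == "skewness" else m4 / m2**2 - 3.0
    if name == "iqr":
        return float(np.percentile(x, 75) - np.percentile(x, 25))
    if name == "rms":
        return math.sqrt(sum(v * v for v in x) / n)
    if name == "abs_energy":
        return sum(v * v for v in x)
    if name == "mean_abs_diff":
        return sum(abs(x[i + 1] - x[i]) for i in range(n - 1)) / (n - 1)
    if name == "slope":
        t = np.arange(n)
        tm = t.mean()
        return float(np.sum((t - tm) * (x - mu)) / np.sum((t - tm) ** 2))
    if name == "autocorr_lag1":
        c = x - mu
        return float(sum(c[:-1] * c[1:]) / sum(c * c))
    if name == "entropy":
        z = np.sort((x - mu) / sd)
        m = max(1, round(math.sqrt(n)))
        total = 0.0
        for i in range(n):
            lo, hi = max(i - m, 0), min(i + m, n - 1)
            total += math.log(n * max(z[hi] - z[lo], 1e-12) / (hi - lo))
        return total / n
    # spectral family: shared periodogram of the mean-removed window
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    X = np.fft.rfft(x - mu)
    pxx = (np.abs(X) ** 2) / (fs * n)
    pxx[1:] *= 2
    if n % 2 == 0:
        pxx[-1] /= 2
    total = pxx.sum()
    if name == "spectral_centroid":
        return float(np.sum(freqs * pxx) / total)
    if name == "spectral_spread":
        c = np.sum(freqs * pxx) / total
        return float(math.sqrt(np.sum((freqs - c) ** 2 * pxx) / total))
    if name == "median_frequency":
        return float(freqs[int(np.searchsorted(np.cumsum(pxx), 0.5 * total))])
    if name == "max_power_frequency":
        return float(freqs[int(np.argmax(pxx))])
    if name == "spectral_entropy":
        p = pxx[pxx > 0] / total
        return float(-np.sum(p * np.log2(p)))
    raise KeyError(name)


class TestRegistryOracle:
    def test_all_features_match_direct_formulas_on_random_windows(self, rng):
        """Registry values agree with independent formulas to 1e-9."""
        fs = 100.0
        for _ in range(100):
            n = int(rng.integers(16, 120))
            x = rng.normal(scale=rng.uniform(0.5, 3.0), size=n) + rng.uniform(-2, 2)
            for name in DEFAULT_FEATURES:
                if name == "zero_crossings":
                    continue  # sign-convention oracle below
                got = FEATURE_REGISTRY[name](x, fs)
                want = _oracle(name, x, fs)
                assert got == pytest.approx(want, abs=1e-9, rel=1e-9), name

    def test_zero_crossings_counts_sign_changes(self, rng):
        x = rng.normal(size=200)
        want = int(np.sum(np.signbit(x[:-1]) != np.signbit(x[1:])))
        assert FEATURE_REGISTRY["zero_crossings"](x, 100.0) == want

    def test_sine_full_cycle_has_two_crossings(self):
        # one full 1 Hz cycle at fs=100, started off-phase so no sample is 0
        t = np.arange(10, 110) / 100.0
        x = np.sin(2 * np.pi * t)
        assert FEATURE_REGISTRY["zero_crossings"](x, 100.0) == 2


class TestExtraction:
    def test_constant_signal_rows(self):
        rec = TimeSeriesRecord(np.full((40, 1), 3.5), fs=10.0)
        fm = extract_features(rec, WindowingConfig(10, 0.5), ["mean", "std"])
        assert np.allclose(fm.values[0], 3.5)
        assert np.allclose(fm.values[1], 0.0)

    def test_row_order_channel_major_then_registry_order(self, rng):
        rec = TimeSeriesRecord(rng.normal(size=(60, 3)), fs=10.0)
        fm = extract_features(rec, WindowingConfig(20, 0.0), ["mean", "max"])
        assert fm.values.shape[0] == 6
        assert fm.feature_names == [
            "ch0:mean", "ch0:max", "ch1:mean", "ch1:max", "ch2:mean", "ch2:max",
        ]
        # row content matches the per-channel windows
        assert fm.values[2, 0] == pytest.approx(rec.samples[0:20, 1].mean())

    def test_unknown_feature_rejected(self, rng):
        rec = TimeSeriesRecord(rng.normal(size=(30, 1)), fs=10.0)
        with pytest.raises(ValueError, match="unknown feature"):
            extract_features(rec, WindowingConfig(10), ["mean", "wavelets"])

    def test_extraction_deterministic(self, rng):
        rec = TimeSeriesRecord(rng.normal(size=(100, 2)), fs=10.0)
        a = extract_features(rec, WindowingConfig(20, 0.5))
        b = extract_features(rec, WindowingConfig(20, 0.5))
        assert np.array_equal(a.values, b.values)

    def test_frame_to_sample_mapping_is_window_centre(self, rng):
        rec = TimeSeriesRecord(rng.normal(size=(100, 1)), fs=10.0)
        fm = extract_features(rec, WindowingConfig(20, 0.5), ["mean"])
        samples = fm.sample_of(np.arange(fm.m))
        assert samples.tolist() == (fm.window_starts + 10).tolist()
        assert np.all(np.diff(samples) > 0)


class TestNormalization:
    def test_row_zscore_values(self):
        rec = TimeSeriesRecord(np.arange(30, dtype=float)[:, None], fs=10.0)
        fm = extract_features(rec, WindowingConfig(10, 0.0), ["mean"])
        z = normalize_fm(fm)
        # single-feature FM: after z-score each column is scaled to unit
        # norm, i.e. sign of the z-score
        raw = fm.values[0]
        expect = (raw - raw.mean()) / raw.std()
        assert np.allclose(z.values[0], np.sign(expect))

    def test_zscore_arithmetic_example(self):
        row = np.array([1.0, 2.0, 3.0])
        z = (row - row.mean()) / row.std()
        assert np.allclose(z, [-1.22474487, 0.0, 1.22474487])

    def test_zero_variance_row_becomes_zero(self, rng):
        rec = TimeSeriesRecord(
            np.column_stack([np.ones(40), rng.normal(size=40)]), fs=10.0
        )
        fm = extract_features(rec, WindowingConfig(10, 0.5), ["mean", "std"])
        z = normalize_fm(fm)
        assert np.allclose(z.values[0], 0.0)  # constant channel's mean row
        assert np.allclose(z.values[1], 0.0)  # and its std row

    def test_nonzero_columns_have_unit_norm(self, rng):
        rec = TimeSeriesRecord(rng.normal(size=(200, 2)), fs=50.0)
        z = normalize_fm(extract_features(rec, WindowingConfig(25, 0.5)))
        norms = np.linalg.norm(z.values, axis=0)
        nonzero = norms > 0
        assert np.allclose(norms[nonzero], 1.0, atol=1e-12)

    def test_double_normalization_rejected(self, rng):
        rec = TimeSeriesRecord(rng.normal(size=(50, 1)), fs=10.0)
        z = normalize_fm(extract_features(rec, WindowingConfig(10, 0.5)))
        with pytest.raises(ValueError, match="already normalized"):
            normalize_fm(z)
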