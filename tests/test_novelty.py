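"""Checkerboard kernel algebra, the novelty correlation against a
nested-loop oracle, and peak selection rules."""

import numpy as np
import pytest

from ssmseg.features import WindowingConfig
from ssmseg.novelty import (
    NoveltyCurve,
    build_kernel,
    novelty_function,
    pick_peaks,
)
from ssmseg.ssm import SelfSimilarityMatrix


class TestKernel:
    def test_sign_grid_for_unit_half_size(self):
        k = build_kernel(1, sigma=0.5, normalize=False)
        assert np.array_equal(np.sign(k.values), [[1, 0, -1], [0, 0, 0], [-1, 0, 1]])

    @pytest.mark.parametrize("L", range(1, 11))
    @pytest.mark.parametrize("sigma", [0.1, 0.5, 1.0])
    def test_zero_sum_symmetry_and_zero_centre(self, L, sigma):
        k = build_kernel(L, sigma, normalize=False)
        assert abs(k.values.sum()) <= 1e-12
        assert np.allclose(k.values[L, :], 0.0)
        assert np.allclose(k.values[:, L], 0.0)
        assert np.array_equal(k.values, k.values.T)
        assert k.D == 2 * L + 1

    def test_matches_elementwise_taper_oracle(self):
        L, sigma = 8, 0.5
        k = build_kernel(L, sigma, normalize=False)
        for i, a in enumerate(range(-L, L + 1)):
            for j, b in enumerate(range(-L, L + 1)):
                want = np.exp(-(a * a + b * b) / (2 * L * L * sigma * sigma)) * np.sign(a) * np.sign(b)
                assert k.values[i, j] == pytest.approx(want, abs=1e-12)

    def test_normalization_divides_by_abs_sum(self):
        raw = build_kernel(5, 0.5, normalize=False).values
        norm = build_kernel(5, 0.5, normalize=True).values
        assert np.allclose(norm, raw / np.abs(raw).sum())

    @pytest.mark.parametrize("L,sigma", [(0, 0.5), (3, 0.0), (3, -1.0)])
    def test_invalid_parameters(self, L, sigma):
        with pytest.raises(ValueError):
            build_kernel(L, sigma)


def _ssm_from(values, w=8, overlap=0.5):
    config = WindowingConfig(w, overlap)
    starts = np.arange(values.shape[0]) * config.hop
    return SelfSimilarityMatrix(values, starts, config, fs=100.0)


class TestNoveltyFunction:
    def test_constant_field_gives_zero_curve(self):
        ssm = _ssm_from(np.ones((50, 50)))
        curve = novelty_function(ssm, build_kernel(5, 0.5))
        # the zero-sum kernel nulls the constant field wherever it sits
        # fully inside the matrix; at the borders the zero padding leaks in
        L = 5
        assert np.allclose(curve.raw[L:-L], 0.0, atol=1e-12)
        assert np.allclose(curve.values, 0.0)

    def test_two_block_field_peaks_at_boundary(self):
        v = np.zeros((50, 50))
        v[:25, :25] = 1.0
        v[25:, 25:] = 1.0
        curve = novelty_function(_ssm_from(v), build_kernel(5, 0.5), smooth=0)
        top = int(np.argmax(curve.raw))
        assert top in (24, 25)
        # first-index tie-breaking: argmax returns the earlier frame on ties
        assert int(np.argmax(curve.raw)) == top

    def test_matches_four_nested_loop_oracle(self, random_ssm):
        kernel = build_kernel(4, 0.5)
        curve = novelty_function(random_ssm, kernel)
        S, m, L = random_ssm.values, random_ssm.m, kernel.L
        for c in range(m):
            total = 0.0
            for ai, a in enumerate(range(-L, L + 1)):
                for bi, b in enumerate(range(-L, L + 1)):
                    if 0 <= c + a < m and 0 <= c + b < m:
                        total += kernel.values[ai, bi] * S[c + a, c + b]
            assert curve.raw[c] == pytest.approx(total, abs=1e-10)

    def test_scale_invariance_of_normalized_curve(self, random_ssm):
        kernel = build_kernel(4, 0.5)
        a = novelty_function(random_ssm, kernel)
        scaled = SelfSimilarityMatrix(
            random_ssm.values * 0.5,
            random_ssm.window_starts,
            random_ssm.config,
            random_ssm.fs,
        )
        b = novelty_function(scaled, kernel)
        assert np.allclose(a.values, b.values, atol=1e-9)

    def test_kernel_larger_than_matrix_rejected(self):
        ssm = _ssm_from(np.eye(5))
        with pytest.raises(ValueError, match="exceeds"):
            novelty_function(ssm, build_kernel(3, 0.5))

    def test_border_values_cannot_be_peaks(self):
        # all-high similarity except a fake "transition" at the very start
        v = np.ones((60, 60)) * 0.9
        curve = novelty_function(_ssm_from(v), build_kernel(10, 0.5))
        interior = curve.values[10:-10]
        assert np.all(curve.values[:10] <= interior.max() + 1e-12)


def _curve(values, w=8, hop=4):
    values = np.asarray(values, dtype=float)
    return NoveltyCurve(values, values.copy(), np.arange(values.size) * hop, w)


class TestPickPeaks:
    def test_threshold_keeps_single_peak(self):
        ev = pick_peaks(_curve([0, 1, 0, 0.5, 0]), strategy="threshold", theta=0.6)
        assert ev.frame_indices.tolist() == [1]

    def test_top_n_rank_selection(self):
        ev = pick_peaks(_curve([0, 1, 0, 0.5, 0]), strategy="top_n", top_n=2)
        assert ev.frame_indices.tolist() == [1, 3]

    def test_shoulder_below_maximum_is_not_a_candidate(self):
        ev = pick_peaks(
            _curve([0, 0.9, 1.0, 0, 0]), strategy="threshold", theta=0.5, min_separation=2
        )
        assert ev.frame_indices.tolist() == [2]

    def test_suppression_keeps_higher_peak(self):
        ev = pick_peaks(
            _curve([0, 0.8, 0, 1.0, 0, 0.9, 0]),
            strategy="threshold",
            theta=0.5,
            min_separation=3,
        )
        assert ev.frame_indices.tolist() == [3]

    def test_suppression_tie_resolves_to_earlier_frame(self):
        ev = pick_peaks(
            _curve([0, 0.8, 0, 0.8, 0]), strategy="threshold", theta=0.5, min_separation=3
        )
        assert ev.frame_indices.tolist() == [1]

    def test_peak_fraction_keeps_top_share(self):
        values = [0, 0.2, 0, 0.4, 0, 0.6, 0, 0.8, 0]
        ev = pick_peaks(_curve(values), strategy="peak_fraction", peak_fraction=0.5)
        assert ev.frame_indices.tolist() == [5, 7]

    def test_sample_indices_follow_frame_mapping(self):
        ev = pick_peaks(_curve([0, 1, 0, 0.5, 0], w=8, hop=4), strategy="top_n", top_n=2)
        assert ev.sample_indices.tolist() == [1 * 4 + 4, 3 * 4 + 4]

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"strategy": "threshold", "theta": 1.5},
            {"strategy": "top_n", "top_n": None},
            {"strategy": "peak_fraction", "peak_fraction": 0.0},
            {"strategy": "bogus"},
        ],
    )
    def test_invalid_strategy_parameters(self, kwargs):
        with pytest.raises(ValueError):
            pick_peaks(_curve([0, 1, 0]), **kwargs)
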