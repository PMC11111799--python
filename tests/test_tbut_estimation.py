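"""Smoothing oracle, threshold crossing, fallback rule, aggregation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tbut.dataset import FrameRecord
from tbut.tbut_estimation import (
    RULE_CROSSED,
    RULE_FALLBACK,
    PredictionSeries,
    TBUTEstimate,
    average_tbut,
    estimate_tbut,
    gaussian_smooth,
    predict_subtest,
    predict_video,
)


def brute_force_gaussian(x, sigma):
    """Independent O(n*k) convolution: truncated normalized kernel, reflect pad."""
    radius = int(4.0 * sigma + 0.5)
    offsets = np.arange(-radius, radius + 1)
    kernel = np.exp(-0.5 * (offsets / sigma) ** 2)
    kernel /= kernel.sum()
    n = len(x)
    out = np.zeros(n)
    for i in range(n):
        acc = 0.0
        for o, w in zip(offsets, kernel):
            j = i + o
            # reflect boundary: ...2 1 0 | 0 1 2... (scipy 'reflect')
            while j < 0 or j >= n:
                if j < 0:
                    j = -j - 1
                if j >= n:
                    j = 2 * n - j - 1
            acc += w * x[j]
        out[i] = acc
    return out


class TestGaussianSmooth:
    def test_constant_series_unchanged(self):
        series = PredictionSeries(probs=np.full(50, 0.7), fps=60.0)
        out = gaussian_smooth(series, sigma=5.0)
        np.testing.assert_allclose(out.smoothed, 0.7, atol=1e-12)

    def test_impulse_peak_is_kernel_center_weight(self):
        x = np.zeros(101)
        x[50] = 1.0
        out = gaussian_smooth(PredictionSeries(probs=x, fps=60.0), sigma=5.0)
        offsets = np.arange(-20, 21)
        kernel = np.exp(-0.5 * (offsets / 5.0) ** 2)
        assert out.smoothed[50] == pytest.approx(kernel[20] / kernel.sum(), abs=1e-10)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(10):
            n = int(rng.integers(5, 200))
            sigma = float(rng.uniform(0.5, 8.0))
            x = rng.uniform(size=n)
            out = gaussian_smooth(PredictionSeries(probs=x, fps=60.0), sigma=sigma)
            np.testing.assert_allclose(out.smoothed, brute_force_gaussian(x, sigma), atol=1e-10)

    def test_total_variation_shrinks(self, rng):
        for _ in range(100):
            x = rng.uniform(size=int(rng.integers(10, 100)))
            out = gaussian_smooth(PredictionSeries(probs=x, fps=60.0), sigma=3.0)
            tv = lambda a: np.abs(np.diff(a)).sum()
            assert tv(out.smoothed) <= tv(x) + 1e-12

    def test_invalid_sigma(self):
        with pytest.raises(ValueError, match="sigma"):
            gaussian_smooth(PredictionSeries(probs=np.array([0.5]), fps=60.0), sigma=0.0)

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            PredictionSeries(probs=np.array([]), fps=60.0)


def _smoothed(values, fps=60.0):
    values = np.asarray(values, dtype=float)
    return PredictionSeries(probs=values, fps=fps, smoothed=values)


class TestEstimateTBUT:
    def test_immediate_breakup(self):
        est = estimate_tbut(_smoothed(np.ones(100)))
        assert est.tbut_s == 0.0 and est.crossing_index == 0 and est.rule == RULE_CROSSED

    def test_fallback_on_all_zero(self):
        est = estimate_tbut(_smoothed(np.zeros(120)))
        assert est.rule == RULE_FALLBACK
        assert est.crossing_index is None
        assert est.tbut_s == pytest.approx(119 / 60, abs=1e-12)

    def test_step_at_frame_60_gives_one_second(self):
        raw = np.zeros(120)
        raw[60:] = 1.0
        series = gaussian_smooth(PredictionSeries(probs=raw, fps=60.0), sigma=5.0)
        est = estimate_tbut(series, threshold=0.5)
        assert est.crossing_index == 60
        assert est.tbut_s == pytest.approx(1.0, abs=1e-12)

    def test_exact_threshold_counts_as_crossing(self):
        x = np.full(10, 0.2)
        x[4] = 0.5
        est = estimate_tbut(_smoothed(x))
        assert est.crossing_index == 4

    def test_threshold_monotonicity(self, rng):
        for _ in range(50):
            series = _smoothed(rng.uniform(size=80))
            prev = -1.0
            for thr in np.linspace(0.05, 0.95, 19):
                t = estimate_tbut(series, threshold=thr).tbut_s
                assert t >= prev
                prev = t

    def test_linear_scan_matches_binary_search_on_monotone_series(self, rng):
        for _ in range(50):
            x = np.sort(rng.uniform(size=60))
            series = _smoothed(x)
            est = estimate_tbut(series, threshold=0.5)
            bs = int(np.searchsorted(x, 0.5, side="left"))
            if bs == len(x):
                assert est.rule == RULE_FALLBACK
            else:
                assert est.crossing_index == bs

    def test_fps_scaling_on_step_inputs(self):
        raw = np.zeros(240)
        raw[100:] = 1.0
        full = estimate_tbut(_smoothed(raw, fps=60.0))
        for m in (2, 4, 12):
            dec = estimate_tbut(_smoothed(raw[::m], fps=60.0 / m))
            assert abs(dec.tbut_s - full.tbut_s) <= m / 60.0

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        probs=st.lists(st.floats(0.0, 1.0), min_size=1, max_size=120),
        sigma=st.floats(0.5, 10.0),
        threshold=st.floats(0.05, 0.95),
    )
    def test_estimate_always_within_series_duration(self, probs, sigma, threshold):
        """Smoothing keeps values in [0,1] and any estimate lies inside the
        subtest's time span with a consistent rule/index pairing."""
        series = gaussian_smooth(
            PredictionSeries(probs=np.array(probs), fps=60.0), sigma=sigma
        )
        assert series.smoothed.min() >= 0.0 and series.smoothed.max() <= 1.0
        est = estimate_tbut(series, threshold=threshold)
        assert 0.0 <= est.tbut_s <= (len(probs) - 1) / 60.0
        if est.rule == RULE_CROSSED:
            assert series.smoothed[est.crossing_index] >= threshold
            assert np.all(series.smoothed[: est.crossing_index] < threshold)
        else:
            assert np.all(series.smoothed < threshold)

    def test_invalid_threshold(self):
        with pytest.raises(ValueError, match="threshold"):
            estimate_tbut(_smoothed(np.zeros(5)), threshold=1.5)

    def test_unsmoothed_series_rejected(self):
        with pytest.raises(ValueError, match="smoothed"):
            estimate_tbut(PredictionSeries(probs=np.zeros(5), fps=60.0))


class TestAverageTBUT:
    def test_mean_of_three_subtests(self):
        ests = [TBUTEstimate(t, RULE_CROSSED, 0) for t in (2.0, 3.0, 4.0)]
        assert average_tbut(ests) == 3.0

    def test_singleton(self):
        assert average_tbut([TBUTEstimate(5.0, RULE_CROSSED, 0)]) == 5.0

    def test_mean_within_range(self, rng):
        ts = rng.uniform(0, 10, size=5)
        ests = [TBUTEstimate(float(t), RULE_CROSSED, 0) for t in ts]
        assert ts.min() <= average_tbut(ests) <= ts.max()

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            average_tbut([])


class _StubModel:
    """Deterministic classifier stub: breakup probability = 1 - mean intensity."""

    def __init__(self, resolution=32):
        from tbut.model import ModelConfig

        self.config = ModelConfig(input_resolution=resolution)

    def forward_single(self, x):
        return 1.0 - np.asarray(x).mean(axis=(1, 2, 3))


def _frames(images):
    return [
        FrameRecord("v0", "R", "s0", i, "non-breakup", img) for i, img in enumerate(images)
    ]


class TestPredictVideo:
    def test_bright_frames_trigger_fallback(self):
        frames = _frames([np.full((32, 32), 0.9, dtype=np.float32)] * 80)
        est, series = predict_subtest([_StubModel()], frames, fps=60.0)
        assert est.rule == RULE_FALLBACK
        assert np.all(series.smoothed < 0.5)

    def test_dark_transition_recovers_onset(self):
        images = [np.full((32, 32), 0.9, dtype=np.float32)] * 60 + [
            np.full((32, 32), 0.05, dtype=np.float32)
        ] * 60
        est, _ = predict_subtest([_StubModel()], _frames(images), fps=60.0)
        assert est.rule == RULE_CROSSED
        assert abs(est.tbut_s - 1.0) < 0.1

    def test_deterministic_and_writes_outputs(self, tmp_path):
        images = [np.full((32, 32), v, dtype=np.float32) for v in np.linspace(0.9, 0.1, 50)]
        subtests = [_frames(images)]
        a = predict_video([_StubModel()], subtests, fps=60.0, out_dir=tmp_path / "p1")
        b = predict_video([_StubModel()], subtests, fps=60.0, out_dir=tmp_path / "p2")
        assert a.estimates == b.estimates
        assert (tmp_path / "p1" / "scores_s0.csv").exists()
        assert (
            (tmp_path / "p1" / "estimates.json").read_text()
            == (tmp_path / "p2" / "estimates.json").read_text()
        )

    def test_empty_subtest_rejected(self):
        with pytest.raises(ValueError, match="no open-eye frames"):
            predict_subtest([_StubModel()], [], fps=60.0)
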