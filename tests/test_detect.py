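import numpy as np
import pytest

import dermoborder as db
from dermoborder import detect as dt

from conftest import brute_force_maxima


class TestSmoothing:
    def test_kernel_is_normalized_and_symmetric(self):
        k = dt.SmoothingConfig(size=15, sigma=2.5).kernel()
        assert len(k) == 15
        assert abs(k.sum() - 1.0) < 1e-12
        assert np.allclose(k, k[::-1])
        assert k.argmax() == 7

    def test_constant_signal_is_unchanged(self):
        cfg = dt.SmoothingConfig()
        out = dt.smooth_values(np.full(100, 3.7), cfg)
        assert np.allclose(out, 3.7, atol=1e-12)

    def test_impulse_response_is_the_kernel(self):
        cfg = dt.SmoothingConfig(size=9, sigma=1.5)
        sig = np.zeros(41)
        sig[20] = 1.0
        out = dt.smooth_values(sig, cfg)
        assert np.allclose(out[16:25], cfg.kernel(), atol=1e-12)

    def test_matches_direct_convolution(self, rng):
        cfg = dt.SmoothingConfig()
        kernel = cfg.kernel()
        half = cfg.size // 2
        for _ in range(20):
            sig = rng.normal(size=200)
            padded = np.concatenate([np.full(half, sig[0]), sig, np.full(half, sig[-1])])
            direct = np.array(
                [padded[i : i + cfg.size] @ kernel[::-1] for i in range(len(sig))]
            )
            assert np.allclose(dt.smooth_values(sig, cfg), direct, atol=1e-10)

    def test_sine_attenuation_follows_kernel_spectrum(self):
        cfg = dt.SmoothingConfig(size=15, sigma=2.5)
        n, period = 1000, 200
        x = np.arange(n)
        sig = np.sin(2 * np.pi * x / period)
        out = dt.smooth_values(sig, cfg)
        k = cfg.kernel()
        offsets = np.arange(cfg.size) - cfg.size // 2
        gain = np.abs((k * np.exp(-2j * np.pi * offsets / period)).sum())
        measured = out[300:700].max()  # away from the replicated edges
        assert measured == pytest.approx(gain, rel=1e-3)

    def test_never_exceeds_signal_bounds(self, rng):
        cfg = dt.SmoothingConfig()
        sig = rng.normal(size=300)
        out = dt.smooth_values(sig, cfg)
        assert out.max() <= sig.max() + 1e-12
        assert out.min() >= sig.min() - 1e-12

    def test_signal_shorter_than_kernel_raises(self):
        with pytest.raises(ValueError):
            dt.smooth_values(np.zeros(10), dt.SmoothingConfig(size=15))


class TestTurningPoints:
    def test_monotone_signal_has_no_calls(self):
        idx, _ = dt.turning_points(np.arange(50.0))
        assert idx == []

    def test_triangle_has_one_call_at_the_apex(self):
        sig = np.concatenate([np.arange(10.0), np.arange(10.0)[::-1]])
        idx, proms = dt.turning_points(sig)
        assert idx == [9]
        assert proms[0] == 9.0

    def test_plateau_yields_one_call_at_floor_midpoint(self):
        idx, _ = dt.turning_points(np.array([0.0, 1.0, 1.0, 1.0, 0.0]))
        assert idx == [2]
        idx, _ = dt.turning_points(np.array([0.0, 1.0, 1.0, 1.0, 1.0, 0.0]))
        assert idx == [2]

    def test_seven_period_sine_has_seven_calls(self):
        n = 700
        sig = np.sin(2 * np.pi * 7 * np.arange(n) / n)
        idx, _ = dt.turning_points(sig)
        assert len(idx) == 7
        assert idx == brute_force_maxima(sig)

    def test_agrees_with_brute_force_on_random_signals(self, rng):
        for _ in range(50):
            sig = rng.normal(size=300)
            if rng.random() < 0.5:
                sig = np.round(sig * 3)  # plateau-rich integer signal
            idx, _ = dt.turning_points(sig)
            assert idx == brute_force_maxima(sig)

    def test_prominence_floor_drops_shallow_ripples(self):
        sig = np.array([0, 5, 4.9, 4.95, 0.0])  # main peak + 0.05-deep ripple
        idx, _ = dt.turning_points(sig, min_prominence=0.5)
        assert idx == [1]
        idx_all, _ = dt.turning_points(sig, min_prominence=0.0)
        assert len(idx_all) == 2

    def test_call_count_non_increasing_with_sigma(self):
        spec = db.tier_spec("standard", seed=7, k=12)
        _, truth = db.render_phantom(spec)
        sig = db.borderline_from_mask(truth.mask)
        counts = []
        for sigma in (1.0, 2.0, 2.5, 4.0, 6.0):
            sm = dt.gaussian_smooth(sig, dt.SmoothingConfig(size=31, sigma=sigma))
            counts.append(len(dt.turning_points(sm.values, 0.5)[0]))
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestScores:
    def test_border_score_counts_occupied_octants(self):
        spec = db.tier_spec("clean", seed=3, k=8)
        _, truth = db.render_phantom(spec)
        sig = db.gaussian_smooth(db.borderline_from_mask(truth.mask))
        assert dt.border_score([], sig) == 0
        n = len(sig)
        mk = lambda i: dt.IrregularityCall(index=i, coord=(0, 0), prominence=1, segment="top")
        centers = [int((o + 0.5) * n / 8) for o in range(8)]
        assert dt.border_score([mk(i) for i in centers], sig) == 8
        one_octant = [mk(5 + j) for j in range(5)]  # five calls, one octant
        assert dt.border_score(one_octant, sig) == 1

    @pytest.mark.parametrize(
        "scores, tds, label",
        [
            ((0, 0, 1, 1), 1.0, "benign"),
            ((2, 8, 6, 5), 8.9, "highly_suspicious"),
            ((1, 8, 4, 3), 5.6, "highly_suspicious"),
            ((1, 5, 3, 2), 4.3, "benign"),
            ((1, 0, 4, 3), 4.8, "suspicious"),
        ],
    )
    def test_tds_weighted_sum_and_classification(self, scores, tds, label):
        s = dt.AbcdScores(*scores)
        assert s.tds == pytest.approx(tds)
        assert dt.classify_tds(s) == label

    def test_lower_suspicious_edge(self):
        # the integer score grid steps in 0.1, so 4.8 is the lowest
        # reachable suspicious value
        s = dt.AbcdScores(1, 5, 3, 3)
        assert s.tds == pytest.approx(4.8)
        assert dt.classify_tds(s) == "suspicious"

    def test_component_range_validation(self):
        for bad in [(3, 0, 1, 1), (0, 9, 1, 1), (0, 0, 0, 1), (0, 0, 1, 6)]:
            with pytest.raises(ValueError):
                dt.AbcdScores(*bad)

    def test_tds_monotone_in_every_component(self):
        base = dt.AbcdScores(1, 4, 3, 2)
        for field, hi in (("A", 2), ("B", 5), ("C", 4), ("D", 3)):
            kwargs = {"A": 1, "B": 4, "C": 3, "D": 2}
            kwargs[field] = hi
            assert dt.AbcdScores(**kwargs).tds >= base.tds
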