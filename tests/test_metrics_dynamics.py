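import numpy as np
import pytest

from strokewc import (AvalancheSet, criticality_k, detect_avalanches,
                      kuramoto_series, sample_powerlaw_sizes,
                      synchrony_metastability)
from strokewc.metrics_dynamics import truncated_powerlaw_cdf


def _brute_force_avalanches(x, thr=2.3):
    """Independent loop-based reference for the avalanche rule."""
    x = np.asarray(x, dtype=float)
    N, T = x.shape
    z = np.empty_like(x)
    for i in range(N):
        z[i] = (x[i] - x[i].mean()) / x[i].std()
    events = np.zeros((N, T), dtype=bool)
    for i in range(N):
        in_pos = in_neg = False
        for t in range(T):
            pos, neg = z[i, t] > thr, z[i, t] < -thr
            if pos and not in_pos:
                events[i, t] = True
            if neg and not in_neg:
                events[i, t] = True
            in_pos, in_neg = pos, neg
    sizes, durs = [], []
    t = 0
    while t < T:
        if events[:, t].any():
            start = t
            while t < T and events[:, t].any():
                t += 1
            sizes.append(int(events[:, start:t].sum()))
            durs.append(t - start)
        else:
            t += 1
    return sizes, durs


class TestKuramoto:
    def test_identical_signals_fully_synchronized(self):
        t = np.arange(500) * 0.05
        x = np.tile(np.sin(2 * np.pi * 0.3 * t), (6, 1))
        R = kuramoto_series(x)
        np.testing.assert_allclose(R, 1.0, atol=1e-9)

    def test_roots_of_unity_phases_cancel(self):
        t = np.arange(2000) * 0.05
        N = 8
        x = np.array([np.sin(2 * np.pi * 0.3 * t + 2 * np.pi * n / N)
                      for n in range(N)])
        R = kuramoto_series(x, trim=50)
        assert R.max() < 0.02

    def test_independent_phases_match_sqrt_n_scaling(self):
        # E[R] ~ 0.886/sqrt(N) for uniform independent phases
        rng = np.random.default_rng(0)
        N = 64
        t = np.arange(6000) * 0.05
        freqs = rng.uniform(0.25, 0.45, N)
        phases = rng.uniform(0, 2 * np.pi, N)
        x = np.array([np.sin(2 * np.pi * f * t + p)
                      for f, p in zip(freqs, phases)])
        R = kuramoto_series(x, trim=200)
        expected = np.sqrt(np.pi) / 2 / np.sqrt(N)
        assert R.mean() == pytest.approx(expected, rel=0.25)

    def test_bounds_and_degenerate_input(self):
        rng = np.random.default_rng(1)
        R = kuramoto_series(rng.standard_normal((5, 300)))
        assert (R >= 0).all() and (R <= 1).all()
        with pytest.raises(ValueError, match="constant"):
            kuramoto_series(np.ones((3, 100)))


class TestSynchronyMetastability:
    def test_constant_series(self):
        sync, meta = synchrony_metastability(np.full(100, 0.7))
        assert sync == pytest.approx(0.7)
        assert meta == pytest.approx(0.0, abs=1e-12)

    def test_square_wave(self):
        R = np.tile([0.0, 1.0], 50)
        sync, meta = synchrony_metastability(R)
        assert sync == pytest.approx(0.5) and meta == pytest.approx(0.5)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            synchrony_metastability(np.array([]))


class TestDetectAvalanches:
    def test_no_excursions_gives_empty_set(self):
        rng = np.random.default_rng(2)
        x = np.sin(np.arange(300) * 0.3)[None, :] * 0.5 + 1.0
        x = np.vstack([x, x])  # sinusoid never passes 2.3 SD
        av = detect_avalanches(x)
        assert av.n == 0

    def test_single_crossing_single_event(self):
        x = np.zeros((1, 200)) + np.random.default_rng(3).normal(
            0, 0.01, (1, 200))
        x[0, 100] = 5.0
        av = detect_avalanches(x)
        assert av.n == 1
        assert av.sizes.tolist() == [1] and av.durations.tolist() == [1]

    def test_manual_three_node_raster(self):
        """Events at bins (5), (5,6), (9) -> avalanches of sizes 3 and 1."""
        rng = np.random.default_rng(4)
        x = rng.normal(0, 0.01, (3, 40))
        x[0, 5] = 9.0
        x[1, 5] = 9.0
        x[1, 6] = -9.0  # flip to the other side: a new crossing at bin 6
        x[2, 9] = 9.0
        av = detect_avalanches(x)
        # event bins: n0@5, n1@5, n1@6, n2@9 -> runs {5,6} and {9}
        assert av.sizes.tolist() == [3, 1]
        assert av.durations.tolist() == [2, 1]

    def test_consecutive_active_bins_merge(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0, 0.01, (3, 40))
        x[0, 5] = 9.0
        x[1, 5] = 9.0
        x[1, 6] = 0.0
        x[2, 6] = 9.0
        av = detect_avalanches(x)
        assert av.sizes.tolist() == [3]
        assert av.durations.tolist() == [2]

    @pytest.mark.parametrize("seed", range(50))
    def test_matches_brute_force_reference(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal((5, 80))
        av = detect_avalanches(x)
        sizes, durs = _brute_force_avalanches(x)
        assert av.sizes.tolist() == sizes
        assert av.durations.tolist() == durs

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            detect_avalanches(np.ones((2, 50)))


class TestCriticalityK:
    def test_exact_powerlaw_sample_scores_near_one(self):
        sizes = sample_powerlaw_sizes(10_000, smax=78, rng=0)
        k = criticality_k(sizes, m=10, smax=78)
        assert k == pytest.approx(1.0, abs=0.05)

    def test_all_small_avalanches_subcritical(self):
        k = criticality_k(np.ones(500, dtype=int), m=10, smax=78)
        # direct evaluation: F_NA = 1 at beta = 1, F_PL(1) = p(1)
        p1 = truncated_powerlaw_cdf(78)[0]
        assert k == pytest.approx(1.0 + (p1 - 1.0))
        assert k < 1

    def test_excess_large_avalanches_supercritical(self):
        rng = np.random.default_rng(6)
        sizes = rng.integers(39, 79, size=2000)
        assert criticality_k(sizes, m=10, smax=78) > 1

    def test_invariant_to_duplicating_the_set(self):
        sizes = sample_powerlaw_sizes(500, smax=78, rng=7)
        a = criticality_k(sizes, m=10, smax=78)
        b = criticality_k(np.tile(sizes, 3), m=10, smax=78)
        assert a == pytest.approx(b, abs=1e-12)

    def test_avalanche_set_supplies_truncation(self):
        av = AvalancheSet(sizes=sample_powerlaw_sizes(2000, smax=16, rng=8),
                          durations=np.ones(2000, dtype=int), n_nodes=16)
        assert criticality_k(av) == pytest.approx(1.0, abs=0.1)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            criticality_k(np.array([], dtype=int), smax=78)
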