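import numpy as np
import pytest
from scipy.optimize import fsolve

from strokewc import (Connectome, ModelConfig, NetworkState, RegionSet,
                      build_delay_steps, sigmoid, simulate, step)

pytestmark = pytest.mark.filterwarnings("ignore::RuntimeWarning")


def _conn(W, L=None):
    n = W.shape[0]
    hemi = np.array(["L"] * (n // 2) + ["R"] * (n - n // 2))
    regions = RegionSet([f"r{i}" for i in range(n)], hemi,
                        np.arange(3 * n, dtype=float).reshape(n, 3))
    if L is None:
        L = np.where(W > 0, 10.0, 0.0)
    return Connectome(W, L, regions)


def _isolated():
    return _conn(np.zeros((1, 1)), np.zeros((1, 1)))


class TestSigmoid:
    def test_midpoint_saturation_and_closed_form(self):
        assert sigmoid(1.0, mu=1.0, sigma=0.25) == pytest.approx(0.5)
        assert sigmoid(1e3) == pytest.approx(1.0)
        assert sigmoid(-1e3) == pytest.approx(0.0)
        # x = mu + sigma gives 1/(1 + e^-1)
        assert sigmoid(1.25, 1.0, 0.25) == pytest.approx(1 / (1 + np.e ** -1),
                                                         rel=1e-6)

    def test_strictly_increasing(self):
        x = np.linspace(-3, 3, 101)
        assert (np.diff(sigmoid(x)) > 0).all()


class TestDelaySteps:
    def test_zero_mean_delay_gives_zero_matrix(self):
        W = np.array([[0.0, 1.0], [1.0, 0.0]])
        assert not build_delay_steps(_conn(W), 0.0, 0.2).any()

    def test_uniform_lengths_give_uniform_delay(self):
        W = np.ones((3, 3)) - np.eye(3)
        steps = build_delay_steps(_conn(W, np.full((3, 3), 12.0) - 12 * np.eye(3)),
                                  4.0, 0.2)
        off = steps[~np.eye(3, dtype=bool)]
        assert (off == round(4.0 / 0.2)).all()

    def test_mean_preserving_scaling(self):
        # lengths 10/20/30 mm with 4 ms mean -> raw delays 2/4/6 ms
        W = np.zeros((4, 4))
        L = np.zeros((4, 4))
        for (i, j), l in zip([(0, 1), (1, 2), (2, 3)], [10.0, 20.0, 30.0]):
            W[i, j] = W[j, i] = 1.0
            L[i, j] = L[j, i] = l
        steps = build_delay_steps(_conn(W, L), 4.0, 0.2)
        assert steps[0, 1] == 10 and steps[1, 2] == 20 and steps[2, 3] == 30

    def test_connected_pairs_have_at_least_one_step(self):
        W = np.array([[0.0, 1.0], [1.0, 0.0]])
        L = np.array([[0.0, 0.01], [0.01, 0.0]])
        steps = build_delay_steps(_conn(W, L), 4.0, 0.2)
        assert steps[0, 1] >= 1


class TestIntegration:
    def test_kernel_matches_numpy_step_oracle(self):
        rng = np.random.default_rng(0)
        W = rng.random((4, 4))
        W = np.triu(W, 1)
        W = W + W.T
        conn = _conn(W, np.where(W > 0, 20.0, 0.0))
        cfg = ModelConfig(noise_var=0.0, mean_delay=2.0, record_dt=0.2,
                          C=1.0, seed=1)
        n_steps = 200
        rec, _ = simulate(cfg, conn, n_steps * cfg.dt / 1000.0,
                          plasticity_on=True, discard_s=0.0)
        delay_steps = build_delay_steps(conn, cfg.mean_delay, cfg.dt)
        D = delay_steps.max() + 1
        st = NetworkState.initial(4)
        st.buffer = np.tile(st.rE, (D, 1))
        traj = []
        for _ in range(n_steps):
            st = step(st, cfg, conn, delay_steps, plasticity_on=True)
            traj.append(st.rE.copy())
        np.testing.assert_allclose(rec.rE.T, np.array(traj), rtol=1e-9)

    def test_seeded_runs_are_bit_identical(self, tiny_conn):
        cfg = ModelConfig(seed=5)
        a, _ = simulate(cfg, tiny_conn, 2.0, discard_s=0.0)
        b, _ = simulate(cfg, tiny_conn, 2.0, discard_s=0.0)
        assert (a.rE == b.rE).all()
        c, _ = simulate(cfg, tiny_conn, 2.0, discard_s=0.0, seed=6)
        assert (a.rE != c.rE).any()

    def test_rates_stay_in_unit_interval(self, tiny_conn):
        cfg = ModelConfig(seed=2)
        rec, state = simulate(cfg, tiny_conn, 5.0, plasticity_on=True,
                              discard_s=0.0)
        for arr in (rec.rE, state.rE, state.rI):
            assert (arr > 0).all() and (arr < 1).all()

    def test_identical_nodes_symmetric_coupling_stay_identical(self):
        W = np.array([[0.0, 1.0], [1.0, 0.0]])
        conn = _conn(W)
        cfg = ModelConfig(noise_var=0.0, C=0.5, mean_delay=1.0, seed=0)
        rec, _ = simulate(cfg, conn, 1.0, discard_s=0.0)
        np.testing.assert_allclose(rec.rE[0], rec.rE[1], rtol=1e-12)


class TestFixedPointsAndBifurcation:
    def _wc_roots(self, cEI, P, cfg):
        def eqs(v):
            rE, rI = v
            fE = 1 / (1 + np.exp(-(cfg.c_EE * rE - cEI * rI + P - cfg.mu)
                                 / cfg.sigma))
            fI = 1 / (1 + np.exp(-(cfg.c_IE * rE - cfg.mu) / cfg.sigma))
            return [fE - rE, fI - rI]
        return fsolve(eqs, [0.1, 0.1], full_output=False, xtol=1e-13)

    def test_isolated_node_converges_to_solver_fixed_point(self):
        cfg = ModelConfig(C=0.0, P=0.2, noise_var=0.0, mean_delay=0.0, seed=0)
        state = NetworkState.initial(1, cei=1.5)
        rec, final = simulate(cfg, _isolated(), 2.0, state=state,
                              discard_s=0.0)
        rE_star, rI_star = self._wc_roots(1.5, 0.2, cfg)
        assert abs(final.rE[0] - rE_star) < 1e-8
        assert abs(final.rI[0] - rI_star) < 1e-8

    def test_supercritical_transition_to_oscillation_with_input(self):
        """Low activity below the bifurcation, limit cycle above it."""
        amps = {}
        for P in (0.31, 0.40):
            cfg = ModelConfig(C=0.0, P=P, noise_var=0.0, mean_delay=0.0,
                              seed=0)
            state = NetworkState.initial(1, cei=2.5)
            rec, _ = simulate(cfg, _isolated(), 6.0, state=state,
                              discard_s=3.0)
            amps[P] = np.ptp(rec.rE[0])
        assert amps[0.31] < 1e-4
        assert amps[0.40] > 0.2

    def test_limit_cycle_frequency_converges_first_order_in_dt(self):
        """Euler biases the cycle frequency ~ O(dt); halving dt must halve
        the successive differences (peak stays inside the gamma band)."""
        peaks = {}
        for dt in (0.2, 0.1, 0.05):
            cfg = ModelConfig(C=0.0, P=0.40, noise_var=0.0, mean_delay=0.0,
                              dt=dt, seed=0)
            state = NetworkState.initial(1, cei=2.5)
            rec, _ = simulate(cfg, _isolated(), 10.0, state=state,
                              discard_s=2.0)
            x = rec.rE[0] - rec.rE[0].mean()
            f = np.fft.rfftfreq(x.size, rec.record_dt / 1000.0)
            peaks[dt] = f[np.abs(np.fft.rfft(x)).argmax()]
        assert abs(peaks[0.05] - peaks[0.1]) < abs(peaks[0.1] - peaks[0.2])
        assert all(35.0 < p < 45.0 for p in peaks.values())

    def test_noise_free_trajectory_converges_under_dt_halving(self):
        """Euler check: halving dt changes the relaxing trajectory < 1% RMS."""
        W = np.ones((3, 3)) - np.eye(3)
        conn = _conn(W)
        out = {}
        for dt in (0.2, 0.1):
            cfg = ModelConfig(C=0.2, P=0.2, noise_var=0.0, mean_delay=1.0,
                              dt=dt, seed=0)
            state = NetworkState.initial(3, cei=1.5)
            rec, _ = simulate(cfg, conn, 10.0, state=state, discard_s=0.0)
            out[dt] = rec.rE
        rms = np.sqrt(np.mean((out[0.2] - out[0.1]) ** 2))
        assert rms < 0.01 * np.sqrt(np.mean(out[0.2] ** 2))
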