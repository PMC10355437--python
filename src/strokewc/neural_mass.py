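"""Delayed, noisy Wilson-Cowan network on a connectome.

Each region holds an excitatory/inhibitory population pair with rates in
(0, 1). The excitatory population of region i receives recurrent drive
``c_EE r^E_i``, local inhibition ``-c_EI,i r^I_i``, delayed long-range
excitation ``C sum_j W_ij r^E_j(t - tau_ij)`` (connections exist only
between excitatory populations), Gaussian input noise, and an intrinsic
excitability offset ``P``, all passed through a sigmoid with threshold
``mu`` and sensitivity ``sigma``. The inhibitory population is driven by
``c_IE r^E_i`` plus noise. Integration is explicit Euler at ``dt`` = 0.2 ms
(5 kHz); noise is drawn independently per node, per population, per step,
with SD sqrt(noise_var), injected inside the sigmoid argument and *not*
scaled by sqrt(dt) (a discrete-time input-fluctuation convention).

Optionally, inhibitory synaptic scaling adjusts ``c_EI,i`` each step to pull
the excitatory rate toward the target ``rho`` (see :mod:`strokewc.homeostasis`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy.sparse import csr_matrix

from .connectome import Connectome

__all__ = [
    "ModelConfig",
    "NetworkState",
    "SimulationRecord",
    "sigmoid",
    "build_delay_steps",
    "step",
    "simulate",
]


@dataclass
class ModelConfig:
    """Every fixed and free parameter of the network model.

    Time constants and delays in ms. Defaults are the reference parameter
    set with the fitted working point (C = 4.07, rho = 0.2, mean delay 4 ms).
    """

    tau_E: float = 2.5
    tau_I: float = 5.0
    c_EE: float = 3.5
    c_IE: float = 3.75
    P: float = 0.31
    mu: float = 1.0
    sigma: float = 0.25
    C: float = 4.07
    mean_delay: float = 4.0
    rho: float = 0.2
    tau_homeo: float = 2500.0
    noise_var: float = 0.01
    dt: float = 0.2
    seed: int = 0
    record_dt: float = 1.0       # rate-series decimation, ms
    cei_sample_s: float = 10.0   # c_EI sampling period, s
    cei_floor: float = 0.0

    def __post_init__(self):
        for name in ("tau_E", "tau_I", "tau_homeo", "sigma", "dt", "record_dt"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.noise_var < 0:
            raise ValueError("noise_var must be non-negative")
        if self.mean_delay < 0:
            raise ValueError("mean_delay must be non-negative")

    @property
    def noise_sd(self) -> float:
        return float(np.sqrt(self.noise_var))


@dataclass
class NetworkState:
    """Instantaneous network state plus the delay ring buffer."""

    rE: np.ndarray
    rI: np.ndarray
    cEI: np.ndarray
    buffer: np.ndarray = None   # (depth, N) past rE, ring
    ptr: int = 0

    @classmethod
    def initial(cls, n: int, cei: float | np.ndarray = 1.0,
                rate: float = 0.1) -> "NetworkState":
        cei_arr = np.full(n, float(cei)) if np.isscalar(cei) else np.asarray(
            cei, dtype=float).copy()
        return cls(rE=np.full(n, rate), rI=np.full(n, rate), cEI=cei_arr)

    def copy(self) -> "NetworkState":
        return NetworkState(
            self.rE.copy(), self.rI.copy(), self.cEI.copy(),
            None if self.buffer is None else self.buffer.copy(), self.ptr,
        )


@dataclass
class SimulationRecord:
    """Decimated rate series plus the sampled c_EI trajectory.

    ``rE`` (and optional ``rI``) are (regions, samples) at ``record_dt`` ms;
    ``cei`` is (regions, samples) at ``cei_dt_s`` seconds.
    """

    rE: np.ndarray
    cei: np.ndarray
    record_dt: float
    cei_dt_s: float
    duration_s: float
    dt: float
    rI: np.ndarray | None = None

    @property
    def n_regions(self) -> int:
        return self.rE.shape[0]

    @property
    def times_s(self) -> np.ndarray:
        return (1 + np.arange(self.rE.shape[1])) * self.record_dt / 1000.0


def sigmoid(x, mu: float = 1.0, sigma: float = 0.25):
    """Population activation function F(x) = 1 / (1 + exp(-(x - mu)/sigma))."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    return 1.0 / (1.0 + np.exp(-(np.asarray(x, dtype=float) - mu) / sigma))


def build_delay_steps(conn: Connectome, mean_delay: float, dt: float) -> np.ndarray:
    """Integer-step conduction delays from tract lengths.

    The conduction speed v is chosen so that the mean of tau_ij = L_ij / v
    over connected pairs equals ``mean_delay``; each tau_ij is rounded to
    the nearest integer multiple of ``dt`` with a minimum of one step for
    connected pairs (zero-delay coupling only when mean_delay = 0).
    """
    n = conn.n_regions
    steps = np.zeros((n, n), dtype=np.int64)
    if mean_delay == 0:
        return steps
    mask = conn.W > 0
    if not mask.any():
        raise ValueError("no connected pairs to carry delays")
    mean_len = conn.L[mask].mean()
    v = mean_len / mean_delay  # mm per ms
    raw = conn.L / v
    steps[mask] = np.maximum(1, np.rint(raw[mask] / dt).astype(np.int64))
    return steps


@njit(cache=True, fastmath=True)
def _integrate(indptr, indices, wdata, ddata, buf, ptr, rE, rI, cEI,
               n_steps, dt, tauE, tauI, cEE, cIE, C, P, mu, sig, noise_sd,
               plast, rho, tau_h, floor, rec_every, cei_every, rec_rI, seed):
    np.random.seed(seed)
    N = rE.shape[0]
    D = buf.shape[0]
    n_rec = n_steps // rec_every
    n_cei = n_steps // cei_every
    rE_out = np.empty((n_rec, N))
    rI_out = np.empty((n_rec if rec_rI else 0, N))
    cei_out = np.empty((n_cei, N))
    coup = np.empty(N)
    aE = dt / tauE
    aI = dt / tauI
    ah = dt / tau_h
    k = 0
    kc = 0
    for t in range(n_steps):
        for i in range(N):
            acc = 0.0
            for p in range(indptr[i], indptr[i + 1]):
                idx = ptr - ddata[p]
                if idx < 0:
                    idx += D
                acc += wdata[p] * buf[idx, indices[p]]
            coup[i] = C * acc
        for i in range(N):
            xE = cEE * rE[i] - cEI[i] * rI[i] + coup[i] + P
            xI = cIE * rE[i]
            if noise_sd > 0.0:
                xE += np.random.normal() * noise_sd
                xI += np.random.normal() * noise_sd
            fE = 1.0 / (1.0 + np.exp(-(xE - mu) / sig))
            fI = 1.0 / (1.0 + np.exp(-(xI - mu) / sig))
            if plast:
                cEI[i] += ah * rI[i] * (rE[i] - rho)
                if cEI[i] < floor:
                    cEI[i] = floor
            rE[i] = rE[i] + aE * (fE - rE[i])
            rI[i] = rI[i] + aI * (fI - rI[i])
        ptr += 1
        if ptr == D:
            ptr = 0
        for j in range(N):
            buf[ptr, j] = rE[j]
        if (t + 1) % rec_every == 0:
            for j in range(N):
                rE_out[k, j] = rE[j]
            if rec_rI:
                for j in range(N):
                    rI_out[k, j] = rI[j]
            k += 1
        if (t + 1) % cei_every == 0:
            for j in range(N):
                cei_out[kc, j] = cEI[j]
            kc += 1
    return rE_out, rI_out, cei_out, ptr


def step(state: NetworkState, cfg: ModelConfig, conn: Connectome,
         delay_steps: np.ndarray | None = None,
         noise_E: np.ndarray | None = None,
         noise_I: np.ndarray | None = None,
         plasticity_on: bool = False) -> NetworkState:
    """One Euler step (numpy reference implementation).

    Used as the readable specification of the update rule and as the oracle
    the compiled integrator is checked against. Noise vectors may be passed
    explicitly (defaults to zero). Returns a new state; the input state's
    ring buffer must have been initialized (see :func:`simulate`), or, when
    ``delay_steps`` is None or all zero, instantaneous coupling is used.
    """
    n = conn.n_regions
    new = state.copy()
    if delay_steps is None or not delay_steps.any():
        delayed = state.rE[np.newaxis, :].repeat(n, axis=0)
    else:
        if state.buffer is None:
            raise ValueError("state has no delay buffer")
        D = state.buffer.shape[0]
        rows = (state.ptr - delay_steps) % D
        delayed = state.buffer[rows, np.arange(n)[np.newaxis, :]]
    coup = cfg.C * (conn.W * delayed).sum(axis=1)
    zE = np.zeros(n) if noise_E is None else noise_E
    zI = np.zeros(n) if noise_I is None else noise_I
    xE = cfg.c_EE * state.rE - state.cEI * state.rI + coup + zE + cfg.P
    xI = cfg.c_IE * state.rE + zI
    if plasticity_on:
        new.cEI = np.maximum(
            state.cEI + cfg.dt * state.rI * (state.rE - cfg.rho) / cfg.tau_homeo,
            cfg.cei_floor,
        )
    new.rE = state.rE + cfg.dt / cfg.tau_E * (sigmoid(xE, cfg.mu, cfg.sigma) - state.rE)
    new.rI = state.rI + cfg.dt / cfg.tau_I * (sigmoid(xI, cfg.mu, cfg.sigma) - state.rI)
    if not (np.isfinite(new.rE).all() and np.isfinite(new.rI).all()):
        raise FloatingPointError("non-finite network state")
    if new.buffer is not None:
        new.ptr = (state.ptr + 1) % new.buffer.shape[0]
        new.buffer[new.ptr] = new.rE
    return new


def simulate(
    cfg: ModelConfig,
    conn: Connectome,
    duration_s: float,
    plasticity_on: bool = False,
    state: NetworkState | None = None,
    discard_s: float = 10.0,
    record_rI: bool = False,
    seed: int | None = None,
) -> tuple[SimulationRecord, NetworkState]:
    """Integrate the full network and record decimated series.

    The first ``discard_s`` seconds of the rate recording are dropped (the
    simulation still runs through them); the delay buffer is filled with the
    initial rates so no spurious zero-input transient occurs. A given seed
    makes runs bit-identical. Returns the record and the final state, which
    can be passed back in to continue the run.
    """
    n = conn.n_regions
    if duration_s <= discard_s:
        raise ValueError("duration must exceed the discard window")
    if state is None:
        state = NetworkState.initial(n)
    else:
        state = state.copy()
    delay_steps = build_delay_steps(conn, cfg.mean_delay, cfg.dt)
    D = int(delay_steps.max()) + 1
    if state.buffer is None or state.buffer.shape[0] != D:
        state.buffer = np.tile(state.rE, (D, 1))
        state.ptr = 0
    S = csr_matrix(conn.W)
    ddata = np.empty(S.data.size, dtype=np.int64)
    for i in range(n):
        for p in range(S.indptr[i], S.indptr[i + 1]):
            ddata[p] = delay_steps[i, S.indices[p]]

    rec_every = max(1, int(round(cfg.record_dt / cfg.dt)))
    cei_every = max(1, int(round(cfg.cei_sample_s * 1000.0 / cfg.dt)))
    n_steps = int(round(duration_s * 1000.0 / cfg.dt))
    use_seed = cfg.seed if seed is None else seed
    rE_out, rI_out, cei_out, ptr = _integrate(
        S.indptr.astype(np.int64), S.indices.astype(np.int64),
        S.data.astype(np.float64), ddata,
        state.buffer, state.ptr, state.rE, state.rI, state.cEI,
        n_steps, cfg.dt, cfg.tau_E, cfg.tau_I, cfg.c_EE, cfg.c_IE, cfg.C,
        cfg.P, cfg.mu, cfg.sigma, cfg.noise_sd,
        plasticity_on, cfg.rho, cfg.tau_homeo, cfg.cei_floor,
        rec_every, cei_every, record_rI, int(use_seed) % (2 ** 31),
    )
    state.ptr = ptr
    if not np.isfinite(state.rE).all():
        raise FloatingPointError("simulation diverged to a non-finite state")
    n_drop = int(round(discard_s * 1000.0 / cfg.record_dt))
    record = SimulationRecord(
        rE=rE_out[n_drop:].T.copy(),
        rI=rI_out[n_drop:].T.copy() if record_rI else None,
        cei=cei_out.T.copy(),
        record_dt=cfg.record_dt,
        cei_dt_s=cfg.cei_sample_s,
        duration_s=duration_s - discard_s,
        dt=cfg.dt,
    )
    return record, state
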