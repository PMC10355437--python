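"""Balloon-Windkessel transform from excitatory rate to BOLD.

The forward model couples the excitatory population rate r(t) to a
vasodilatory signal s, inflow f, venous volume v, and deoxyhemoglobin
content q:

    ds/dt      = r - kappa s - gamma (f - 1)
    df/dt      = s
    tau dv/dt  = f - v^(1/alpha)
    tau dq/dt  = f (1 - (1 - rho)^(1/f)) / rho - v^(1/alpha) q / v
    y          = V0 (7 rho (1 - q) + 2 (1 - q/v) + (2 rho - 0.2)(1 - v))

with resting state s=0, f=v=q=1 giving y=0 exactly. Constants default to
the standard set (kappa=0.65 s^-1, gamma=0.41 s^-1, tau=0.98 s, alpha=0.32,
rho=0.34, V0=0.02). The ODEs are integrated with Euler at the rate-series
decimation step and the output is downsampled to the fMRI TR (0.72 s).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy.signal import butter, sosfiltfilt

from .neural_mass import SimulationRecord

__all__ = ["HemoConfig", "BoldRecord", "bold_transform", "bandpass"]


@dataclass
class HemoConfig:
    kappa: float = 0.65      # signal decay, 1/s
    gamma_f: float = 0.41    # flow-dependent elimination, 1/s
    tau_h: float = 0.98      # hemodynamic transit time, s
    alpha: float = 0.32      # Grubb vessel-stiffness exponent
    rho_h: float = 0.34      # resting oxygen extraction fraction
    V0: float = 0.02         # resting venous volume fraction
    tr_out: float = 0.72     # output sampling period, s
    band: tuple = (0.01, 0.1)  # band-pass cutoffs, Hz
    drive_scale: float = 1.0
    drop_samples: int = 10   # leading BOLD samples discarded (transient)

    def __post_init__(self):
        for name in ("kappa", "gamma_f", "tau_h", "rho_h", "V0", "tr_out"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


@dataclass
class BoldRecord:
    """Per-region BOLD series, (regions, samples) at sampling period ``tr``."""

    series: np.ndarray
    tr: float
    filtered: bool = False

    @property
    def n_regions(self) -> int:
        return self.series.shape[0]

    @property
    def n_samples(self) -> int:
        return self.series.shape[1]


@njit(cache=True)
def _balloon(rates, dt_s, kappa, gamma, tau, alpha, rho, V0):
    N, T = rates.shape
    y = np.empty((N, T))
    inv_alpha = 1.0 / alpha
    k1 = 7.0 * rho
    k2 = 2.0
    k3 = 2.0 * rho - 0.2
    for i in range(N):
        s = 0.0
        f = 1.0
        v = 1.0
        q = 1.0
        for t in range(T):
            r = rates[i, t]
            va = v ** inv_alpha
            ds = r - kappa * s - gamma * (f - 1.0)
            df = s
            dv = (f - va) / tau
            dq = (f * (1.0 - (1.0 - rho) ** (1.0 / f)) / rho - va * q / v) / tau
            s += dt_s * ds
            f += dt_s * df
            v += dt_s * dv
            q += dt_s * dq
            if f < 1e-6:
                f = 1e-6
            if v < 1e-6:
                v = 1e-6
            y[i, t] = V0 * (k1 * (1.0 - q) + k2 * (1.0 - q / v) + k3 * (1.0 - v))
    return y


def bold_transform(record: SimulationRecord | np.ndarray,
                   cfg: HemoConfig | None = None,
                   record_dt_ms: float | None = None) -> BoldRecord:
    """Transform an excitatory rate series into an (unfiltered) BOLD record.

    Accepts a :class:`SimulationRecord` or a raw (regions, samples) array
    with ``record_dt_ms`` giving its sampling step. The hemodynamic states
    start at rest; the first ``cfg.drop_samples`` output samples are
    discarded to remove the onset transient.
    """
    cfg = cfg or HemoConfig()
    if isinstance(record, SimulationRecord):
        rates = record.rE
        dt_ms = record.record_dt
    else:
        if record_dt_ms is None:
            raise ValueError("record_dt_ms required for a raw array")
        rates = np.atleast_2d(np.asarray(record, dtype=float))
        dt_ms = record_dt_ms
    dt_s = dt_ms / 1000.0
    y = _balloon(np.ascontiguousarray(rates * cfg.drive_scale), dt_s,
                 cfg.kappa, cfg.gamma_f, cfg.tau_h, cfg.alpha, cfg.rho_h,
                 cfg.V0)
    if not np.isfinite(y).all():
        raise FloatingPointError("hemodynamic integration became unstable")
    stride = int(round(cfg.tr_out / dt_s))
    if stride < 1:
        raise ValueError("output TR finer than the rate-series step")
    series = y[:, stride - 1::stride]
    series = series[:, cfg.drop_samples:]
    return BoldRecord(series=series.copy(), tr=cfg.tr_out, filtered=False)


def bandpass(bold: BoldRecord, cfg: HemoConfig | None = None,
             order: int = 2) -> BoldRecord:
    """Zero-phase band-pass in the resting-state band; mean removed."""
    cfg = cfg or HemoConfig()
    lo, hi = cfg.band
    nyq = 0.5 / bold.tr
    if hi >= nyq:
        raise ValueError(f"high cutoff {hi} Hz at or above Nyquist {nyq:.3f} Hz")
    sos = butter(order, [lo / nyq, hi / nyq], btype="bandpass", output="sos")
    x = bold.series - bold.series.mean(axis=1, keepdims=True)
    filt = sosfiltfilt(sos, x, axis=1)
    return BoldRecord(series=filt, tr=bold.tr, filtered=True)
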