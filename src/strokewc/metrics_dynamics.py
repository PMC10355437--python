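"""Phase synchrony, metastability, avalanches and the criticality statistic.

The Kuramoto order parameter R(t) = |mean_n exp(i theta_n(t))| measures
instantaneous phase synchrony across regions (theta_n from the analytic
signal); its time mean is the network's synchrony and its time SD the
metastability.

Neuronal avalanches are detected on Z-scored rate series: an *event* is the
first bin of each excursion beyond +/-2.3 SD of a node's signal (p < 0.01
against Gaussian noise); an *avalanche* is a maximal run of consecutive
bins containing at least one event anywhere in the network, its size the
total number of events in the run. Closeness to criticality is scored by

    k = 1 + (1/m) sum_n [F_PL(beta_n) - F_NA(beta_n)],

comparing the empirical avalanche-size CDF F_NA with the CDF F_PL of a
power law with exponent -1.5 truncated at the network size, at m
log-spaced points beta_n between the smallest and largest observed sizes.
k is ~1 at criticality; an excess of small avalanches (subcritical) puts
F_NA above F_PL and drives k below 1, an excess of large ones above 1.
(The sign convention follows that reading; see the methods note.)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert

__all__ = [
    "AvalancheSet",
    "kuramoto_series",
    "synchrony_metastability",
    "detect_avalanches",
    "criticality_k",
    "truncated_powerlaw_cdf",
    "sample_powerlaw_sizes",
]


@dataclass
class AvalancheSet:
    sizes: np.ndarray
    durations: np.ndarray
    n_nodes: int

    def __post_init__(self):
        self.sizes = np.asarray(self.sizes, dtype=int)
        self.durations = np.asarray(self.durations, dtype=int)
        if (self.sizes < 1).any() or (self.durations < 1).any():
            raise ValueError("avalanche sizes and durations must be >= 1")

    @property
    def n(self) -> int:
        return self.sizes.size


def kuramoto_series(signals, trim: int = 10) -> np.ndarray:
    """Kuramoto order parameter R(t) from narrowband signals.

    ``signals`` is (regions, samples), already band-limited (e.g. filtered
    BOLD); phases come from the analytic signal, and ``trim`` samples are
    dropped at each end where the Hilbert transform is unreliable.
    """
    x = np.atleast_2d(np.asarray(signals, dtype=float))
    if x.shape[0] < 2:
        raise ValueError("need at least 2 regions for a phase-order parameter")
    if (x.std(axis=1) == 0).any():
        raise ValueError("constant signal: instantaneous phase undefined")
    phases = np.angle(hilbert(x - x.mean(axis=1, keepdims=True), axis=1))
    R = np.abs(np.exp(1j * phases).mean(axis=0))
    if trim > 0 and R.size > 2 * trim:
        R = R[trim:-trim]
    return R


def synchrony_metastability(R: np.ndarray) -> tuple[float, float]:
    """Time mean and SD of the Kuramoto order parameter."""
    R = np.asarray(R, dtype=float)
    if R.size == 0:
        raise ValueError("empty order-parameter series")
    return float(R.mean()), float(R.std())


def detect_avalanches(rate_series, z_threshold: float = 2.3) -> AvalancheSet:
    """Threshold-crossing avalanches on Z-scored per-node series.

    Z-scoring uses each node's full series mean/SD. Events are the first
    bin of each excursion beyond +threshold or below -threshold per node
    (tracked separately per sign: a direct flip from one side to the other
    is a new crossing, hence a new event); avalanches are maximal runs of
    consecutive bins with >= 1 event network-wide.
    """
    x = np.atleast_2d(np.asarray(rate_series, dtype=float))
    sd = x.std(axis=1)
    if (sd == 0).any():
        raise ValueError("constant node series cannot be Z-scored")
    z = (x - x.mean(axis=1, keepdims=True)) / sd[:, None]
    events = np.zeros(z.shape, dtype=bool)
    for beyond in (z > z_threshold, z < -z_threshold):
        events |= beyond & ~np.pad(beyond[:, :-1], ((0, 0), (1, 0)))
    counts = events.sum(axis=0)
    active = counts > 0
    sizes, durations = [], []
    t = 0
    T = active.size
    while t < T:
        if active[t]:
            start = t
            while t < T and active[t]:
                t += 1
            sizes.append(int(counts[start:t].sum()))
            durations.append(t - start)
        else:
            t += 1
    return AvalancheSet(sizes=np.array(sizes, dtype=int),
                        durations=np.array(durations, dtype=int),
                        n_nodes=x.shape[0])


def truncated_powerlaw_cdf(smax: int, exponent: float = -1.5) -> np.ndarray:
    """CDF of the discrete power law p(s) ~ s^exponent on s = 1..smax."""
    s = np.arange(1, smax + 1, dtype=float)
    p = s ** exponent
    p /= p.sum()
    return np.cumsum(p)


def sample_powerlaw_sizes(n: int, smax: int = 78, exponent: float = -1.5,
                          rng=None) -> np.ndarray:
    """Draw avalanche sizes exactly from the truncated discrete power law."""
    rng = np.random.default_rng(rng)
    cdf = truncated_powerlaw_cdf(smax, exponent)
    p = np.diff(np.concatenate([[0.0], cdf]))
    return rng.choice(np.arange(1, smax + 1), size=n, p=p)


def criticality_k(av: AvalancheSet | np.ndarray, m: int = 10,
                  smax: int | None = None, exponent: float = -1.5) -> float:
    """Criticality statistic k from an avalanche-size distribution.

    ``smax`` is the truncation of the reference power law (defaults to the
    avalanche set's network size). Evaluation points are m log-spaced
    values between the minimum and maximum observed sizes, endpoints
    included; both CDFs are evaluated right-continuously (P[S <= beta]).
    Depends only on the size distribution, not on the number of avalanches.
    """
    if isinstance(av, AvalancheSet):
        sizes = av.sizes
        smax = smax if smax is not None else av.n_nodes
    else:
        sizes = np.asarray(av, dtype=int)
        if smax is None:
            raise ValueError("smax required when passing raw sizes")
    if sizes.size == 0:
        raise ValueError("empty avalanche set")
    ref_cdf = truncated_powerlaw_cdf(smax, exponent)

    def F_pl(beta):
        idx = np.clip(np.floor(beta).astype(int), 0, smax)
        return np.where(idx < 1, 0.0, ref_cdf[np.minimum(idx, smax) - 1])

    sorted_sizes = np.sort(sizes)

    def F_na(beta):
        return np.searchsorted(sorted_sizes, beta, side="right") / sizes.size

    lo, hi = sizes.min(), sizes.max()
    betas = np.logspace(np.log10(lo), np.log10(hi), m)
    return float(1.0 + np.mean(F_pl(betas) - F_na(betas)))
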