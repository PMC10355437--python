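"""Static FC, FC dynamics, fit metrics, FC distance and SC-FC coupling.

Static functional connectivity (FC) is the matrix of pairwise Pearson
correlations between regional BOLD series. FC dynamics (FCD) correlates the
upper triangles of FC matrices computed in sliding windows of 80 samples
with 80% overlap (step 16); the distribution of its off-diagonal values
characterizes the variability of connectivity over time. Model-vs-reference
fit is scored by the Pearson correlation and mean squared error over FC
upper triangles and the Kolmogorov-Smirnov distance between FCD value
distributions. FC distance between two conditions is the Frobenius norm of
the matrix difference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .connectome import Connectome
from .hemodynamics import BoldRecord

__all__ = [
    "FCMatrix",
    "FCDMatrix",
    "FitMetrics",
    "static_fc",
    "fcd",
    "fit_metrics",
    "fc_distance",
    "fc_sc_correlation",
]


@dataclass
class FCMatrix:
    values: np.ndarray
    source: str = ""

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def triu(self) -> np.ndarray:
        iu = np.triu_indices(self.n, 1)
        return self.values[iu]

    def without_node(self, node: int) -> "FCMatrix":
        keep = np.delete(np.arange(self.n), node)
        return FCMatrix(self.values[np.ix_(keep, keep)], self.source)


@dataclass
class FCDMatrix:
    values: np.ndarray
    window: int = 80
    step: int = 16

    @property
    def n_windows(self) -> int:
        return self.values.shape[0]

    def offdiag(self) -> np.ndarray:
        iu = np.triu_indices(self.n_windows, 1)
        return self.values[iu]


@dataclass
class FitMetrics:
    corr: float
    mse: float
    ks: float


def _series(b) -> np.ndarray:
    return b.series if isinstance(b, BoldRecord) else np.atleast_2d(np.asarray(b))


def static_fc(bold) -> FCMatrix:
    """Pairwise Pearson correlation matrix of a (regions, samples) record."""
    x = _series(bold)
    if x.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    sd = x.std(axis=1)
    if (sd == 0).any():
        warnings.warn(
            f"{int((sd == 0).sum())} zero-variance region(s); correlations "
            "undefined there (NaN)", stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        fc = np.corrcoef(x)
    return FCMatrix(values=fc)


def fcd(bold, window: int = 80, step: int = 16) -> FCDMatrix:
    """Correlation between windowed FC upper-triangle patterns.

    With the conventional 80-sample window and 80% overlap the step is 16
    samples, giving floor((T - window)/step) + 1 windows.
    """
    x = _series(bold)
    T = x.shape[1]
    if T < window:
        raise ValueError(f"series length {T} shorter than window {window}")
    starts = range(0, T - window + 1, step)
    iu = np.triu_indices(x.shape[0], 1)
    pats = np.array([np.corrcoef(x[:, s:s + window])[iu] for s in starts])
    vals = np.corrcoef(pats) if len(pats) > 1 else np.ones((1, 1))
    return FCDMatrix(values=np.atleast_2d(vals), window=window, step=step)


def fit_metrics(model_fc: FCMatrix, ref_fc: FCMatrix,
                model_fcd: FCDMatrix | None = None,
                ref_fcd: FCDMatrix | None = None) -> FitMetrics:
    """Pearson r and MSE over FC upper triangles; KS distance over FCD values."""
    if model_fc.n != ref_fc.n:
        raise ValueError("FC matrices have different parcellation sizes")
    a, b = model_fc.triu(), ref_fc.triu()
    corr = float(stats.pearsonr(a, b)[0])
    mse = float(np.mean((a - b) ** 2))
    ks = float("nan")
    if model_fcd is not None and ref_fcd is not None:
        x, y = model_fcd.offdiag(), ref_fcd.offdiag()
        if x.size and y.size:
            ks = float(stats.ks_2samp(x, y).statistic)
        else:
            ks = 0.0 if x.size == y.size else float("nan")
    return FitMetrics(corr=corr, mse=mse, ks=ks)


def fc_distance(a: FCMatrix, b: FCMatrix, exclude: int | None = None) -> float:
    """Frobenius norm of the difference between two FC matrices.

    ``exclude`` removes one region's row and column from both matrices
    before the difference (used to compare lesioned conditions over a
    consistent node set).
    """
    if a.n != b.n:
        raise ValueError("FC matrices have different sizes")
    if exclude is not None:
        a, b = a.without_node(exclude), b.without_node(exclude)
    return float(np.linalg.norm(a.values - b.values, "fro"))


def fc_sc_correlation(fc: FCMatrix, conn: Connectome | np.ndarray,
                      exclude: int | None = None) -> float:
    """Pearson correlation between upper triangles of FC and SC."""
    W = conn.W if isinstance(conn, Connectome) else np.asarray(conn)
    if fc.n != W.shape[0]:
        raise ValueError("FC and SC have different parcellation sizes")
    if exclude is not None:
        keep = np.delete(np.arange(fc.n), exclude)
        W = W[np.ix_(keep, keep)]
        fc = fc.without_node(exclude)
    iu = np.triu_indices(W.shape[0], 1)
    w = W[iu]
    if np.ptp(w) == 0:
        raise ValueError("SC upper triangle is constant; correlation undefined")
    return float(stats.pearsonr(fc.triu(), w)[0])
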