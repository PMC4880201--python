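"""Two probeset-level normalization routes from one probe-level dataset.

``rma`` runs normexp background correction per array, probe-level quantile
normalization, log2, and median-polish summarization.  ``mas5_like`` runs
trimmed-mean global scaling per array, log2, and one-step Tukey-biweight
summarization.  Vendor-exact MAS5 (ideal-mismatch correction, scaled Ct)
is deliberately not replicated: the point of the dual route is two
*different* normalizations feeding the same downstream consensus.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .synthdata import ProbeLevelDataset

__all__ = [
    "ExpressionMatrix",
    "quantile_normalize",
    "normexp_background",
    "median_polish_summarize",
    "tukey_biweight_summarize",
    "scale_trimmed_mean",
    "rma",
    "mas5_like",
]

LOG2_FLOOR = 2.0 ** -10


@dataclass
class ExpressionMatrix:
    """Probeset x sample log2 expression values from one normalization."""

    values: np.ndarray  # [probeset, sample], log2 scale
    probeset_ids: list[str]
    sample_ids: list[str]
    normalization_tag: str  # "MAS5like" or "RMA"

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.probeset_ids), len(self.sample_ids)):
            raise ValueError("values shape does not match id lists")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite")
        if len(set(self.probeset_ids)) != len(self.probeset_ids):
            raise ValueError("duplicate probeset ids")


def quantile_normalize(matrix: np.ndarray) -> np.ndarray:
    """Force identical column distributions (mean-of-sorted-columns target).

    Within-column rank order is preserved; ties receive the mean of the
    target values spanned by the tied ranks, so the map is idempotent.
    """
    x = np.asarray(matrix, dtype=float)
    if x.size == 0:
        raise ValueError("empty matrix")
    if x.ndim != 2:
        raise ValueError("expected a 2-D matrix")
    target = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        col = x[:, j]
        order = np.argsort(col, kind="stable")
        vals = target.copy()
        sorted_col = col[order]
        # average the target over each run of tied input values
        boundaries = np.flatnonzero(np.diff(sorted_col) != 0) + 1
        starts = np.concatenate(([0], boundaries))
        ends = np.concatenate((boundaries, [len(col)]))
        sums = np.add.reduceat(vals, starts)
        means = sums / (ends - starts)
        vals = np.repeat(means, ends - starts)
        out[order, j] = vals
    return out


def _density_mode(x: np.ndarray) -> float:
    kde = stats.gaussian_kde(x, bw_method="silverman")
    grid = np.linspace(x.min(), x.max(), 512)
    return float(grid[np.argmax(kde(grid))])


def _background_mode(x: np.ndarray) -> float:
    """Two-pass mode estimate: the first KDE mode of the skewed full data
    is right-biased, so the mode is re-estimated from the sub-mode values
    where the background dominates."""
    mode = _density_mode(x)
    below = x[x < mode]
    if below.size >= 50 and np.ptp(below) > 0:
        mode = _density_mode(below)
    return mode


def normexp_background(array_intensities: np.ndarray) -> np.ndarray:
    """Normal+exponential background correction of one array.

    Parameters are estimated by method of moments around the density mode
    (Silverman-bandwidth Gaussian KDE): background mean = mode, background
    sd from the values below the mode, signal (exponential) mean from the
    mean excess above the mode.  Returns E[signal | observed], which is
    strictly positive and monotone in the input.
    """
    x = np.asarray(array_intensities, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected one array (1-D)")
    if np.ptp(x) == 0:
        # degenerate input: shift to a small positive constant
        return x - (x.min() - 1e-6)
    mode = _background_mode(x)
    below = x[x < mode]
    if below.size == 0:
        sigma = float(np.std(x)) / 10.0
    else:
        sigma = float(np.sqrt(np.mean((below - mode) ** 2)))
    sigma = max(sigma, 1e-8)
    above = x[x >= mode]
    alpha = max(float(np.mean(above - mode)), 1e-8)

    mu_sf = x - mode - sigma ** 2 / alpha
    z = mu_sf / sigma
    # sigma * phi(z)/Phi(z) evaluated in log space for stability at z << 0
    mills = np.exp(stats.norm.logpdf(z) - stats.norm.logcdf(z))
    return mu_sf + sigma * mills


def _median_polish_batch(x: np.ndarray, tol: float, max_iter: int) -> np.ndarray:
    """Median polish over a [probeset, probe, sample] stack; returns
    grand + column effects per probeset, shape [probeset, sample]."""
    resid = x.copy()
    t = np.zeros(x.shape[0])
    row = np.zeros(x.shape[:2])
    col = np.zeros((x.shape[0], x.shape[2]))
    for _ in range(max_iter):
        rmed = np.median(resid, axis=2)
        row += rmed
        resid -= rmed[:, :, None]
        delta = np.abs(rmed).max()
        cm = np.median(col, axis=1)
        t += cm
        col -= cm[:, None]
        cmed = np.median(resid, axis=1)
        col += cmed
        resid -= cmed[:, None, :]
        delta = max(delta, np.abs(cmed).max())
        rm = np.median(row, axis=1)
        t += rm
        row -= rm[:, None]
        if delta < tol:
            break
    return t[:, None] + col


def median_polish_summarize(
    log2_probe_matrix: np.ndarray, tol: float = 1e-6, max_iter: int = 20
) -> np.ndarray:
    """Additive median-polish fit of one [probe, sample] block.

    Alternating row/column median sweeps until the largest sweep change
    drops below ``tol`` (or ``max_iter`` sweeps); the per-sample summary is
    the grand effect plus the column effects.  A single probe is returned
    unchanged.
    """
    x = np.asarray(log2_probe_matrix, dtype=float)
    if x.ndim != 2 or x.size == 0:
        raise ValueError("expected non-empty [probe, sample] matrix")
    if x.shape[0] == 1:
        return x[0].copy()
    return _median_polish_batch(x[None, :, :], tol, max_iter)[0]


def _tukey_biweight_batch(x: np.ndarray, c: float, eps: float) -> np.ndarray:
    """One-step Tukey biweight along axis 0."""
    med = np.median(x, axis=0)
    mad = np.median(np.abs(x - med), axis=0)
    u = (x - med) / (c * mad + eps)
    w = np.where(np.abs(u) < 1.0, (1.0 - u ** 2) ** 2, 0.0)
    wsum = w.sum(axis=0)
    out = np.where(wsum > 0, (w * x).sum(axis=0) / np.where(wsum > 0, wsum, 1.0), med)
    return out


def tukey_biweight_summarize(
    values: np.ndarray, c: float = 5.0, eps: float = 1e-4
) -> float:
    """One-step Tukey biweight location estimate of a 1-D sample."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("empty input")
    return float(_tukey_biweight_batch(x[:, None], c, eps)[0])


def scale_trimmed_mean(
    matrix: np.ndarray, target: float = 500.0, trim: float = 0.02
) -> np.ndarray:
    """Scale each column so its ``trim``-trimmed mean equals ``target``."""
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2 or x.size == 0:
        raise ValueError("expected non-empty [row, sample] matrix")
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        tm = stats.trim_mean(x[:, j], trim)
        if tm == 0:
            raise ValueError(f"column {j} has zero trimmed mean")
        out[:, j] = x[:, j] * (target / tm)
    return out


def _log2_floor(x: np.ndarray) -> np.ndarray:
    return np.log2(np.maximum(x, LOG2_FLOOR))


def rma(dataset: ProbeLevelDataset) -> ExpressionMatrix:
    """RMA route: normexp -> probe-level quantile normalization -> log2 ->
    median polish per probeset."""
    P, J, N = dataset.intensities.shape
    flat = dataset.intensities.reshape(P * J, N)
    corrected = np.column_stack([normexp_background(flat[:, j]) for j in range(N)])
    normalized = quantile_normalize(corrected)
    logged = _log2_floor(normalized).reshape(P, J, N)
    values = _median_polish_batch(logged, tol=1e-6, max_iter=20)
    return ExpressionMatrix(values, list(dataset.probeset_ids), list(dataset.sample_ids), "RMA")


def mas5_like(dataset: ProbeLevelDataset) -> ExpressionMatrix:
    """MAS5-like route: trimmed-mean array scaling -> log2 -> Tukey biweight
    per probeset and sample."""
    P, J, N = dataset.intensities.shape
    flat = dataset.intensities.reshape(P * J, N)
    scaled = scale_trimmed_mean(flat)
    logged = _log2_floor(scaled).reshape(P, J, N)
    values = _tukey_biweight_batch(np.moveaxis(logged, 1, 0), c=5.0, eps=1e-4)
    return ExpressionMatrix(values, list(dataset.probeset_ids), list(dataset.sample_ids), "MAS5like")
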