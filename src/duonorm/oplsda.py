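"""Pareto-scaled two-class OPLS-DA with correlation loadings, VIP and
jack-knifed VIP confidence intervals.

The model is fitted NIPALS-style for a single predictive component after
removal of ``n_orth`` Y-orthogonal components.  Correlation loadings
(``pcorr``) are Pearson correlations between the predictive score vector
and the columns of the *undeflated* scaled matrix, bounded in [-1, 1].
VIP is defined on the predictive component only, which gives the
mean-square-one identity ``mean(vip^2) = 1`` used as a model invariant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "ScaledMatrix",
    "OplsModel",
    "CvSpec",
    "pareto_scale",
    "fit_oplsda",
    "pcorr",
    "vip",
    "jackknife_vip_ci",
]


@dataclass
class ScaledMatrix:
    """Column-centered, pareto-scaled data matrix [sample x variable]."""

    X: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    dropped: list[int] = field(default_factory=list)  # zero-variance columns removed


@dataclass
class OplsModel:
    """One fitted pareto-scaled OPLS-DA model (single predictive component)."""

    w: np.ndarray  # predictive weights, unit norm
    t_p: np.ndarray  # predictive scores
    p_p: np.ndarray  # predictive loadings
    w_o: np.ndarray  # [n_orth, p] orthogonal weights
    t_o: np.ndarray  # [n_orth, n] orthogonal scores
    p_o: np.ndarray  # [n_orth, p] orthogonal loadings
    pcorr: np.ndarray  # Cor(t_p, x_j) on undeflated scaled data
    vip: np.ndarray
    y: np.ndarray  # centered +/-1 class code used in the fit
    n_orth: int
    vip_lower: np.ndarray | None = None
    vip_upper: np.ndarray | None = None


@dataclass(frozen=True)
class CvSpec:
    """Stratified fold assignment for jack-knife refits."""

    n_folds: int = 7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("need >= 2 folds")


def pareto_scale(matrix: np.ndarray) -> ScaledMatrix:
    """Center each column and divide by the square root of its sd."""
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("expected [sample x variable] matrix with >= 2 samples")
    means = x.mean(axis=0)
    sds = x.std(axis=0, ddof=1)
    keep = sds > 0
    if not keep.any():
        raise ValueError("all columns are constant")
    dropped = list(np.flatnonzero(~keep))
    x = x[:, keep]
    scaled = (x - means[keep]) / np.sqrt(sds[keep])
    return ScaledMatrix(X=scaled, means=means[keep], sds=sds[keep], dropped=dropped)


def _encode_y(y_labels, positive_level) -> np.ndarray:
    labels = np.asarray(y_labels)
    levels = sorted(set(labels.tolist()))
    if len(levels) != 2:
        raise ValueError(f"need exactly two class levels, got {levels}")
    if positive_level is None:
        positive_level = levels[0]
    if positive_level not in levels:
        raise ValueError(f"positive level {positive_level!r} not among {levels}")
    y = np.where(labels == positive_level, 1.0, -1.0)
    return y - y.mean()


def fit_oplsda(
    scaled: ScaledMatrix,
    y_labels,
    n_orth: int = 1,
    positive_level=None,
) -> OplsModel:
    """Fit a two-class OPLS-DA model on a pareto-scaled matrix.

    ``positive_level`` names the experimental class; the sign of the
    predictive component is oriented so that its mean score is positive,
    which removes the NIPALS sign indeterminacy and makes correlation
    loadings comparable across normalizations.
    """
    X = scaled.X.copy()
    n, p = X.shape
    y = _encode_y(y_labels, positive_level)
    if n_orth < 0:
        raise ValueError("n_orth must be >= 0")

    w_o_list, t_o_list, p_o_list = [], [], []
    for a in range(n_orth):
        w = X.T @ y
        nw = np.linalg.norm(w)
        if nw < 1e-12:
            raise ValueError(f"deflation exhausted rank at orthogonal component {a + 1}")
        w /= nw
        t = X @ w
        pl = X.T @ t / (t @ t)
        w_orth = pl - (w @ pl) * w
        n_wo = np.linalg.norm(w_orth)
        if n_wo < 1e-10:
            raise ValueError(
                f"no Y-orthogonal variation left for component {a + 1} (rank exhausted)"
            )
        w_orth /= n_wo
        t_orth = X @ w_orth
        p_orth = X.T @ t_orth / (t_orth @ t_orth)
        X = X - np.outer(t_orth, p_orth)
        w_o_list.append(w_orth)
        t_o_list.append(t_orth)
        p_o_list.append(p_orth)

    w = X.T @ y
    nw = np.linalg.norm(w)
    if nw < 1e-12:
        raise ValueError("predictive weight vector is null (no class-correlated variation)")
    w /= nw
    t_p = X @ w
    if t_p[np.asarray(y_labels) == _positive_of(y_labels, positive_level)].mean() < 0:
        w, t_p = -w, -t_p
    p_p = X.T @ t_p / (t_p @ t_p)

    model = OplsModel(
        w=w,
        t_p=t_p,
        p_p=p_p,
        w_o=np.array(w_o_list).reshape(n_orth, p) if n_orth else np.empty((0, p)),
        t_o=np.array(t_o_list).reshape(n_orth, n) if n_orth else np.empty((0, n)),
        p_o=np.array(p_o_list).reshape(n_orth, p) if n_orth else np.empty((0, p)),
        pcorr=np.empty(0),
        vip=np.empty(0),
        y=y,
        n_orth=n_orth,
    )
    model.pcorr = pcorr(model, scaled)
    model.vip = vip(model)
    return model


def _positive_of(y_labels, positive_level):
    if positive_level is not None:
        return positive_level
    return sorted(set(np.asarray(y_labels).tolist()))[0]


def pcorr(model: OplsModel, scaled: ScaledMatrix) -> np.ndarray:
    """Correlation loadings Cor(t_p, x_j) on the undeflated scaled data."""
    t = model.t_p - model.t_p.mean()
    tn = np.linalg.norm(t)
    Xc = scaled.X - scaled.X.mean(axis=0)
    norms = np.linalg.norm(Xc, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Xc.T @ t) / (norms * tn)
    r = np.where(norms > 0, r, 0.0)
    return np.clip(r, -1.0, 1.0)


def vip(model: OplsModel) -> np.ndarray:
    """Predictive-component VIP: sqrt(p) * |w_j| / ||w||."""
    w = model.w
    p = w.size
    return np.sqrt(p) * np.abs(w) / np.linalg.norm(w)


def _stratified_folds(y_labels, spec: CvSpec) -> list[np.ndarray]:
    """Assign samples to folds, keeping both classes in every fold.

    The requested fold count is clamped to the minority class size so the
    invariant (each fold holds >= 1 sample of each group) is satisfiable.
    Assignment is re-drawn (seeded) if a fold misses a class.
    """
    labels = np.asarray(y_labels)
    levels = sorted(set(labels.tolist()))
    min_class = min(int((labels == lv).sum()) for lv in levels)
    k = min(spec.n_folds, min_class)
    if k < 2:
        raise ValueError("minority class too small for cross-validation")
    rng = np.random.default_rng(spec.seed)
    for _ in range(100):
        fold = np.empty(labels.size, dtype=int)
        for lv in levels:
            idx = np.flatnonzero(labels == lv)
            rng.shuffle(idx)
            fold[idx] = np.arange(idx.size) % k
        ok = all(
            all(np.any((fold == f) & (labels == lv)) for lv in levels) for f in range(k)
        )
        if ok:
            return [np.flatnonzero(fold == f) for f in range(k)]
    raise ValueError("could not build stratified folds with both classes in each fold")


def jackknife_vip_ci(
    matrix: np.ndarray,
    y_labels,
    cv: CvSpec = CvSpec(),
    n_orth: int = 1,
    alpha: float = 0.05,
    positive_level=None,
) -> tuple[np.ndarray, np.ndarray, OplsModel]:
    """Jack-knife VIP confidence intervals from leave-one-fold-out refits.

    Each fold's refit weight vector is sign-aligned to the full model
    before the VIP spread is accumulated; the interval is
    ``vip_full +/- t_{1-alpha/2, k-1} * SE`` with the jack-knife standard
    error ``SE_j = sqrt(((k-1)/k) * sum_folds (vip_fold_j - vip_full_j)^2)``.
    Returns (lower, upper, full_model).
    """
    x = np.asarray(matrix, dtype=float)
    labels = np.asarray(y_labels)
    scaled_full = pareto_scale(x)
    full = fit_oplsda(scaled_full, labels, n_orth=n_orth, positive_level=positive_level)
    vip_full = full.vip

    folds = _stratified_folds(labels, cv)
    k = len(folds)
    sq = np.zeros_like(vip_full)
    for hold in folds:
        train = np.setdiff1d(np.arange(labels.size), hold)
        sub_scaled = pareto_scale(x[train][:, _kept_columns(scaled_full, x.shape[1])])
        if sub_scaled.dropped:
            # a column constant within the training split: refit on the
            # surviving columns and treat the dropped ones as VIP 0
            vip_fold = np.zeros_like(vip_full)
            kept = np.setdiff1d(np.arange(vip_full.size), np.array(sub_scaled.dropped))
            m = fit_oplsda(sub_scaled, labels[train], n_orth=n_orth, positive_level=positive_level)
            wf = m.w if (m.w @ full.w[kept]) >= 0 else -m.w
            vip_fold[kept] = np.sqrt(vip_full.size) * np.abs(wf)
        else:
            m = fit_oplsda(sub_scaled, labels[train], n_orth=n_orth, positive_level=positive_level)
            wf = m.w if (m.w @ full.w) >= 0 else -m.w
            vip_fold = np.sqrt(wf.size) * np.abs(wf)
        sq += (vip_fold - vip_full) ** 2
    se = np.sqrt((k - 1) / k * sq)
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, k - 1)
    lower = vip_full - tcrit * se
    upper = vip_full + tcrit * se
    full.vip_lower = lower
    full.vip_upper = upper
    return lower, upper, full


def _kept_columns(scaled: ScaledMatrix, p_original: int) -> np.ndarray:
    kept = np.setdiff1d(np.arange(p_original), np.array(scaled.dropped, dtype=int))
    return kept
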