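"""Empirical-Bayes moderated two-group t-statistics per normalization.

Gene-wise pooled variances are shrunk toward a common prior variance
``s0^2`` with prior degrees of freedom ``d0``; both hyperparameters are
estimated by matching the first two moments of ``log s^2`` through the
digamma/trigamma equations, with the trigamma equation inverted by Newton
iteration.  p-values come from the t distribution with ``d_g + d0``
degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import special, stats

from .normalize import ExpressionMatrix

__all__ = [
    "GroupDesign",
    "ModeratedTestResult",
    "fit_moderated_t",
    "count_significant",
]


@dataclass(frozen=True)
class GroupDesign:
    """Sample-to-group assignment plus the oriented contrast.

    ``contrast = (experimental, reference)``: positive log2fc means higher
    expression in the experimental group.
    """

    assignment: dict[str, str] = field(hash=False)
    contrast: tuple[str, str] = ("EXP", "REF")

    def __post_init__(self) -> None:
        exp, ref = self.contrast
        levels = set(self.assignment.values())
        if exp not in levels or ref not in levels:
            raise ValueError("both contrast levels must appear in the assignment")
        if levels - {exp, ref}:
            raise ValueError(f"unexpected group labels: {levels - {exp, ref}}")

    def masks(self, sample_ids: list[str]) -> tuple[np.ndarray, np.ndarray]:
        unassigned = [s for s in sample_ids if s not in self.assignment]
        if unassigned:
            raise ValueError(f"samples without group assignment: {unassigned}")
        labels = np.array([self.assignment[s] for s in sample_ids])
        return labels == self.contrast[0], labels == self.contrast[1]


@dataclass
class ModeratedTestResult:
    """Per-probeset moderated-t output for one two-group contrast."""

    probeset_ids: list[str]
    log2fc: np.ndarray  # experimental - reference
    s2: np.ndarray  # ordinary pooled variance
    s2_post: np.ndarray  # moderated variance
    t: np.ndarray
    p: np.ndarray  # two-sided
    df_residual: float
    d0: float  # estimated prior df (may be inf)
    s0_2: float  # estimated prior variance

    @property
    def df_total(self) -> float:
        return self.df_residual + self.d0


def trigamma_inverse(x: float, max_iter: int = 50) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x <= 0:
        return np.inf
    # asymptotic start: trigamma(y) ~ 1/y for large y
    y = 0.5 + 1.0 / x
    for _ in range(max_iter):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def _estimate_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match d0 and s0^2 from the log pooled variances."""
    s2 = np.maximum(s2, 1e-300)
    e = np.log(s2) - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2.0))
    if evar <= 0:
        return np.inf, float(np.exp(emean))
    d0 = 2.0 * trigamma_inverse(evar)
    s0_2 = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_2


def fit_moderated_t(
    matrix: ExpressionMatrix,
    design: GroupDesign,
    d0_override: float | None = None,
    s0_2_override: float | None = None,
) -> ModeratedTestResult:
    """Moderated two-sample t-test for every probeset in ``matrix``.

    ``d0_override`` / ``s0_2_override`` bypass the empirical-Bayes
    hyperparameter estimation (d0 = 0 gives the ordinary pooled t-test,
    d0 = inf fixes every variance at s0^2).
    """
    m1, m2 = design.masks(matrix.sample_ids)
    n1, n2 = int(m1.sum()), int(m2.sum())
    if n1 < 2 or n2 < 2:
        raise ValueError("need >= 2 samples in each group")
    x1 = matrix.values[:, m1]
    x2 = matrix.values[:, m2]
    mean1 = x1.mean(axis=1)
    mean2 = x2.mean(axis=1)
    log2fc = mean1 - mean2
    df = float(n1 + n2 - 2)
    if df <= 0:
        raise ValueError("zero residual degrees of freedom")
    ss = ((x1 - mean1[:, None]) ** 2).sum(axis=1) + ((x2 - mean2[:, None]) ** 2).sum(axis=1)
    s2 = ss / df

    if d0_override is not None:
        d0 = float(d0_override)
        s0_2 = float(s0_2_override) if s0_2_override is not None else float(np.median(s2))
    else:
        d0, s0_2 = _estimate_prior(s2, df)

    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_2)
    else:
        s2_post = (d0 * s0_2 + df * s2) / (d0 + df)

    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, log2fc / se, 0.0)
    if np.isinf(d0):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df + d0)
    p = np.clip(p, np.finfo(float).tiny, 1.0)

    return ModeratedTestResult(
        probeset_ids=list(matrix.probeset_ids),
        log2fc=log2fc,
        s2=s2,
        s2_post=s2_post,
        t=t,
        p=p,
        df_residual=df,
        d0=d0,
        s0_2=s0_2,
    )


def count_significant(
    result: ModeratedTestResult, thresholds: tuple[float, ...] = (0.05, 0.01)
) -> dict[float, int]:
    """Number of probesets with unadjusted p below each threshold."""
    if len(result.p) == 0:
        raise ValueError("empty result")
    return {thr: int(np.sum(result.p < thr)) for thr in thresholds}
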