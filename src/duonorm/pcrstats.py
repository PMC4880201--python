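"""qPCR and ChIP-qPCR validation statistics.

Relative expression uses the 2^-ddCt method against the mean of the
housekeeping reference Cts, with many-to-one Dunnett comparisons versus
the control group.  ChIP enrichment is expressed as percent of the
diluted chromatin input and likewise Dunnett-compared against the IgG
control.  The Dunnett adjustment is evaluated by seeded Monte Carlo from
the equicorrelated multivariate-t maximum distribution (no closed form
exists for arbitrary group sizes); the Monte Carlo standard error is
reported alongside each adjusted p.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .synthdata import CtTable

__all__ = [
    "DdctResult",
    "DunnettResult",
    "ddct_fold_change",
    "dunnett_test",
    "percent_input",
]


@dataclass
class DdctResult:
    target: str
    control_group: str
    dct: pd.DataFrame  # per animal: group, dct
    ddct_mean: dict[str, float]  # per group, vs control
    fold_change: dict[str, float]  # 2^-mean(ddct)
    dunnett: "DunnettResult | None" = None


@dataclass
class DunnettResult:
    groups: list[str]
    t: dict[str, float]
    p_adjusted: dict[str, float]
    p_unadjusted: dict[str, float]
    mc_se: dict[str, float]
    df: float


def _mean_ct(table: CtTable, gene: str) -> pd.Series:
    """Replicate-averaged Ct per animal for one gene."""
    df = table.records
    sub = df[df["gene"] == gene]
    if sub.empty:
        raise ValueError(f"gene {gene!r} not in Ct table")
    counts = sub.groupby("animal_id")["ct"].size()
    incomplete = counts[counts != 2]
    if not incomplete.empty:
        raise ValueError(f"missing replicate for animal(s): {list(incomplete.index)}")
    return sub.groupby("animal_id")["ct"].mean()


def ddct_fold_change(
    table: CtTable,
    target: str,
    reference_genes: list[str] | None = None,
    control_group: str | None = None,
    run_dunnett: bool = True,
    seed: int = 0,
    n_mc: int = 200_000,
) -> DdctResult:
    """Relative expression of ``target`` by the 2^-ddCt method.

    Technical replicates are averaged; the reference Ct per animal is the
    arithmetic mean over the housekeeping genes (equivalent to the
    geometric mean of their expressions); dCt = Ct_target - Ct_ref;
    ddCt subtracts the control-group mean dCt; the group fold change is
    2^-mean(ddCt).
    """
    if reference_genes is None:
        reference_genes = table.reference_genes
    if control_group is None:
        control_group = table.control_group

    ct_target = _mean_ct(table, target)
    ref = pd.concat([_mean_ct(table, g) for g in reference_genes], axis=1).mean(axis=1)
    dct = ct_target - ref

    groups = table.records[["animal_id", "group"]].drop_duplicates().set_index("animal_id")["group"]
    dct_df = pd.DataFrame({"group": groups.loc[dct.index], "dct": dct})
    if control_group not in set(dct_df["group"]):
        raise ValueError(f"control group {control_group!r} absent")

    control_mean = dct_df.loc[dct_df["group"] == control_group, "dct"].mean()
    dct_df["ddct"] = dct_df["dct"] - control_mean

    ddct_mean, fold = {}, {}
    for grp, sub in dct_df.groupby("group"):
        ddct_mean[grp] = float(sub["ddct"].mean())
        fold[grp] = float(2.0 ** (-ddct_mean[grp]))

    dunnett = None
    if run_dunnett:
        others = [g for g in sorted(set(dct_df["group"])) if g != control_group]
        samples = {g: dct_df.loc[dct_df["group"] == g, "dct"].to_numpy() for g in others}
        control = dct_df.loc[dct_df["group"] == control_group, "dct"].to_numpy()
        dunnett = dunnett_test(samples, control, seed=seed, n_mc=n_mc)

    return DdctResult(
        target=target,
        control_group=control_group,
        dct=dct_df,
        ddct_mean=ddct_mean,
        fold_change=fold,
        dunnett=dunnett,
    )


def dunnett_test(
    groups: dict[str, np.ndarray],
    control: np.ndarray,
    seed: int = 0,
    n_mc: int = 200_000,
) -> DunnettResult:
    """Two-sided many-to-one comparisons against a shared control.

    Pooled variance across all groups; the familywise-adjusted p for each
    comparison is P(max_j |T_j| >= |t_obs|) under the null multivariate t
    with Dunnett correlation rho_ij = lambda_i * lambda_j,
    lambda_i = sqrt((1/n0) / (1/n_i + 1/n0)), estimated from ``n_mc``
    seeded Monte Carlo draws.  With one comparison this reduces to the
    pooled two-sample t-test (within Monte Carlo error).
    """
    names = sorted(groups)
    xs = [np.asarray(groups[g], dtype=float) for g in names]
    x0 = np.asarray(control, dtype=float)
    if x0.size < 2 or any(x.size < 2 for x in xs):
        raise ValueError("need >= 2 samples per group")
    ns = np.array([x.size for x in xs])
    n0 = x0.size
    df = float(ns.sum() + n0 - (len(xs) + 1))
    ss = sum(((x - x.mean()) ** 2).sum() for x in xs) + ((x0 - x0.mean()) ** 2).sum()
    s2 = ss / df
    if s2 <= 0:
        raise ValueError("zero pooled variance")

    t_obs = np.array([(x.mean() - x0.mean()) / np.sqrt(s2 * (1 / x.size + 1 / n0)) for x in xs])
    lam = np.sqrt((1.0 / n0) / (1.0 / ns + 1.0 / n0))

    rng = np.random.default_rng(seed)
    z0 = rng.standard_normal(n_mc)
    z = rng.standard_normal((n_mc, len(xs)))
    # equicorrelated normal: Z_i = lam_i * z0 + sqrt(1 - lam_i^2) * z_i
    zz = lam[None, :] * z0[:, None] + np.sqrt(1.0 - lam ** 2)[None, :] * z
    w = np.sqrt(rng.chisquare(df, n_mc) / df)
    max_abs_t = np.abs(zz / w[:, None]).max(axis=1)

    p_adj, mc_se, p_raw = {}, {}, {}
    for g, t in zip(names, t_obs):
        exceed = float(np.mean(max_abs_t >= abs(t)))
        p_adj[g] = max(exceed, 1.0 / n_mc)
        mc_se[g] = float(np.sqrt(exceed * (1 - exceed) / n_mc))
        p_raw[g] = float(2.0 * stats.t.sf(abs(t), df))

    return DunnettResult(
        groups=names,
        t={g: float(t) for g, t in zip(names, t_obs)},
        p_adjusted=p_adj,
        p_unadjusted=p_raw,
        mc_se=mc_se,
        df=df,
    )


def percent_input(
    ct_chip: np.ndarray | float,
    ct_input: np.ndarray | float,
    input_fraction: float = 0.0025,
) -> np.ndarray | float:
    """ChIP signal as percent of the (diluted) chromatin input.

    The input Ct is shifted down by log2(1/input_fraction) to undo the
    dilution; percent = 100 * 2^(adjusted_input - ct_chip).
    """
    if input_fraction <= 0 or input_fraction > 1:
        raise ValueError("input_fraction must be in (0, 1]")
    adjusted = np.asarray(ct_input, dtype=float) - np.log2(1.0 / input_fraction)
    out = 100.0 * 2.0 ** (adjusted - np.asarray(ct_chip, dtype=float))
    return float(out) if np.isscalar(ct_chip) or np.ndim(out) == 0 else out
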