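"""Fusion of the two per-normalization analyses into candidate sets.

A probeset becomes a candidate when its correlation loadings agree in sign
between the two normalizations, sit within a fixed radius of the shared
diagonal corner of the [-1, 1]^2 loading square, and carry VIP > 1 with a
non-negative jack-knifed lower confidence bound in *both* models.
Candidates are ranked by the sum of the two moderated-t p-values and split
into direction-specific top-N expression subsets; the cross-experiment
union keeps only probesets whose fold-change direction is
normalization-independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PerProbeStats",
    "CandidateSet",
    "ExpressionSubset",
    "make_probe_table",
    "select_candidates",
    "rank_and_split",
    "build_cre",
]

#: columns expected in a per-normalization probe table
_STAT_COLS = ("log2fc", "p", "pcorr", "vip", "viplow")


@dataclass
class PerProbeStats:
    """Per-probeset statistics from one normalization route."""

    table: pd.DataFrame  # index: probeset_id; columns: _STAT_COLS

    def __post_init__(self) -> None:
        missing = set(_STAT_COLS) - set(self.table.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        if self.table.index.has_duplicates:
            raise ValueError("duplicate probeset ids")


def make_probe_table(probeset_ids, log2fc, p, pcorr, vip, viplow) -> PerProbeStats:
    return PerProbeStats(
        pd.DataFrame(
            {"log2fc": log2fc, "p": p, "pcorr": pcorr, "vip": vip, "viplow": viplow},
            index=pd.Index(probeset_ids, name="probeset_id"),
        )
    )


@dataclass
class CandidateSet:
    """Fused candidate records for one experiment."""

    experiment: str  # e.g. CONSOL, REC, EXTNOR
    records: pd.DataFrame
    r: float
    vip_min: float
    ci_rule: str = ">=0"

    @property
    def selected(self) -> pd.DataFrame:
        return self.records[self.records["selected"]]

    @property
    def n_selected(self) -> int:
        return int(self.records["selected"].sum())


@dataclass
class ExpressionSubset:
    """Ordered direction-specific top-N probe list (ascending sum-of-p)."""

    tag: str
    probesets: list[str]
    direction: str  # "up" or "down"
    sump: list[float] = field(default_factory=list)


def select_candidates(
    mas: PerProbeStats,
    rma: PerProbeStats,
    r: float = 0.75,
    vip_min: float = 1.0,
    experiment: str = "EXP",
    ci_strict: bool = False,
) -> CandidateSet:
    """Apply the four consensus selection rules to every probeset.

    selected iff (a) sign(pcorr_mas) == sign(pcorr_rma) == s != 0;
    (b) distance from (pcorr_mas, pcorr_rma) to the corner (s, s) <= r;
    (c) vip > vip_min in both models; (d) lower VIP CI >= 0 in both
    (``ci_strict`` switches the bound to > 0).
    """
    ids_m = set(mas.table.index)
    ids_r = set(rma.table.index)
    if ids_m != ids_r:
        diff = sorted(ids_m.symmetric_difference(ids_r))
        raise ValueError(f"probeset id mismatch between normalizations: {diff[:10]}")

    m = mas.table
    q = rma.table.loc[m.index]

    sign_m = np.sign(m["pcorr"].to_numpy())
    sign_r = np.sign(q["pcorr"].to_numpy())
    concordant = (sign_m == sign_r) & (sign_m != 0)
    s = sign_m
    dist = np.hypot(m["pcorr"].to_numpy() - s, q["pcorr"].to_numpy() - s)
    within = dist <= r
    vip_ok = (m["vip"].to_numpy() > vip_min) & (q["vip"].to_numpy() > vip_min)
    if ci_strict:
        ci_ok = (m["viplow"].to_numpy() > 0) & (q["viplow"].to_numpy() > 0)
    else:
        ci_ok = (m["viplow"].to_numpy() >= 0) & (q["viplow"].to_numpy() >= 0)
    selected = concordant & within & vip_ok & ci_ok

    direction = np.where(s > 0, "up", np.where(s < 0, "down", ""))
    records = pd.DataFrame(
        {
            "log2fc_mas": m["log2fc"],
            "log2fc_rma": q["log2fc"],
            "p_mas": m["p"],
            "p_rma": q["p"],
            "pcorr_mas": m["pcorr"],
            "pcorr_rma": q["pcorr"],
            "vip_mas": m["vip"],
            "vip_rma": q["vip"],
            "viplow_mas": m["viplow"],
            "viplow_rma": q["viplow"],
            "sump": m["p"].to_numpy() + q["p"].to_numpy(),
            "selected": selected,
            "direction": direction,
        },
        index=m.index,
    )
    return CandidateSet(
        experiment=experiment,
        records=records,
        r=r,
        vip_min=vip_min,
        ci_rule=">0" if ci_strict else ">=0",
    )


def rank_and_split(
    cand: CandidateSet, n: int = 200, tags: tuple[str, str] | None = None
) -> tuple[ExpressionSubset, ExpressionSubset]:
    """Split selected records by direction and rank by ascending sum-of-p.

    Selected records whose MAS and RMA log2 fold changes disagree in sign
    are excluded (their regulation is not normalization-independent).
    Ties are broken by probeset id.
    """
    sel = cand.selected
    fc_sign_m = np.sign(sel["log2fc_mas"].to_numpy())
    fc_sign_r = np.sign(sel["log2fc_rma"].to_numpy())
    concordant = fc_sign_m == fc_sign_r
    if not concordant.all():
        import warnings

        warnings.warn(
            f"{int((~concordant).sum())} selected records have discordant "
            "MAS/RMA fold-change signs and were excluded from ranking",
            stacklevel=2,
        )
    sel = sel[concordant]
    if tags is None:
        tags = (f"{cand.experiment}_up", f"{cand.experiment}_down")

    out = []
    for direction, tag in zip(("up", "down"), tags):
        part = sel[sel["direction"] == direction]
        # id sort first, then stable sort by sump => ties broken lexicographically
        part = part.sort_index(kind="mergesort").sort_values("sump", kind="mergesort")
        part = part.head(n)
        out.append(
            ExpressionSubset(
                tag=tag,
                probesets=list(part.index),
                direction=direction,
                sump=list(part["sump"]),
            )
        )
    return out[0], out[1]


def build_cre(
    subsets: list[ExpressionSubset],
    log2fc_pairs: dict[str, pd.DataFrame],
    subset_experiment: dict[str, str],
) -> set[str]:
    """Union of subset members with normalization-independent direction.

    ``log2fc_pairs[experiment]`` holds columns ``log2fc_mas``/``log2fc_rma``
    indexed by probeset id; a member is kept only if the two log2
    fold-change signs agree within its own experiment (every experiment it
    appears in).
    """
    if not subsets:
        raise ValueError("need at least one subset")
    kept: set[str] = set()
    for sub in subsets:
        exp = subset_experiment[sub.tag]
        fc = log2fc_pairs[exp]
        for ps in sub.probesets:
            row = fc.loc[ps]
            if np.sign(row["log2fc_mas"]) == np.sign(row["log2fc_rma"]):
                kept.add(ps)
    return kept


def average_log2fc(table: pd.DataFrame) -> pd.Series:
    """Arithmetic mean of the per-normalization log2 fold changes."""
    return (table["log2fc_mas"] + table["log2fc_rma"]) / 2.0
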