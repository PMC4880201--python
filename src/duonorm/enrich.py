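"""Overrepresentation analysis with EASE scores and kappa term clustering.

The EASE score is a conservative one-sided Fisher exact test computed
after removing one gene from the overlap, so single-gene overlaps can
never reach significance.  Enriched terms are grouped by Cohen's kappa
agreement of their gene memberships using an agglomeration heuristic
(seed groups from kappa neighbourhoods, iterative merging on >50% member
sharing); the exact agglomeration rules of annotation web services are
undocumented, so this documented approximation is used instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import cluster as scicluster
from scipy import stats
from scipy.spatial.distance import pdist

from .synthdata import AnnotationSet

__all__ = [
    "EnrichmentResult",
    "TermCluster",
    "ease_score",
    "enrich_all",
    "cohen_kappa",
    "cluster_terms",
    "heatmap_order",
]


@dataclass
class EnrichmentResult:
    term_id: str
    k: int  # list hits
    n: int  # list size
    K: int  # term size
    N: int  # universe size
    ease_p: float
    fisher_p: float
    genes: set[str] = field(default_factory=set)


@dataclass
class TermCluster:
    terms: list[str]
    genes: set[str]
    score: float  # -mean log10(ease_p) over member terms

    def __len__(self) -> int:
        return len(self.terms)


def ease_score(k: int, n: int, K: int, N: int) -> tuple[float, float]:
    """(EASE p, Fisher p) for a k-gene overlap of an n-list with a K-term.

    EASE is the hypergeometric upper tail P(X >= k - 1); k = 0 or 1 gives
    p = 1 by construction.
    """
    if k < 0 or k > min(n, K) or n > N or K > N:
        raise ValueError(f"inconsistent counts k={k}, n={n}, K={K}, N={N}")
    fisher = float(stats.hypergeom.sf(k - 1, N, K, n))  # P(X >= k)
    if k == 0:
        return 1.0, fisher
    ease = float(stats.hypergeom.sf(k - 2, N, K, n))  # P(X >= k - 1)
    return min(ease, 1.0), min(fisher, 1.0)


def enrich_all(
    gene_list,
    annotation: AnnotationSet,
    ease_cutoff: float = 0.01,
    min_genes: int = 5,
) -> list[EnrichmentResult]:
    """EASE enrichment of every annotation term with >= ``min_genes`` hits.

    Genes outside the annotation universe are dropped with a warning.
    Returns all evaluated terms; callers filter on ``ease_p < ease_cutoff``
    (the ``significant`` helper below does exactly that).
    """
    genes = set(gene_list)
    outside = genes - annotation.universe
    if outside:
        warnings.warn(
            f"{len(outside)} list genes outside the annotation universe were dropped",
            stacklevel=2,
        )
        genes -= outside
    if not genes:
        return []
    N = len(annotation.universe)
    n = len(genes)
    results = []
    for term_id in sorted(annotation.terms):
        members = annotation.terms[term_id]
        hits = genes & members
        if len(hits) < min_genes:
            continue
        ease, fisher = ease_score(len(hits), n, len(members), N)
        results.append(
            EnrichmentResult(
                term_id=term_id,
                k=len(hits),
                n=n,
                K=len(members),
                N=N,
                ease_p=ease,
                fisher_p=fisher,
                genes=hits,
            )
        )
    return results


def significant(results: list[EnrichmentResult], ease_cutoff: float = 0.01):
    return [r for r in results if r.ease_p < ease_cutoff]


def cohen_kappa(member_a: np.ndarray, member_b: np.ndarray) -> float:
    """Chance-corrected agreement of two binary membership vectors."""
    a = np.asarray(member_a, dtype=bool)
    b = np.asarray(member_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("membership vectors differ in length")
    n = a.size
    if n == 0:
        raise ValueError("empty membership vectors")
    both = np.sum(a & b)
    neither = np.sum(~a & ~b)
    p_o = (both + neither) / n
    p_e = (a.sum() * b.sum() + (n - a.sum()) * (n - b.sum())) / n ** 2
    if p_e == 1.0:
        warnings.warn("degenerate memberships (chance agreement 1); kappa set to 0",
                      stacklevel=2)
        return 0.0
    return float((p_o - p_e) / (1.0 - p_e))


def _kappa_matrix(results: list[EnrichmentResult], gene_list: list[str]) -> np.ndarray:
    genes = sorted(gene_list)
    vecs = np.array([[g in r.genes for g in genes] for r in results], dtype=bool)
    t = len(results)
    kap = np.eye(t)
    for i in range(t):
        for j in range(i + 1, t):
            kap[i, j] = kap[j, i] = cohen_kappa(vecs[i], vecs[j])
    return kap


def cluster_terms(
    results: list[EnrichmentResult],
    gene_list,
    kappa_threshold: float = 0.7,
    min_terms: int = 3,
    ease_cutoff: float = 0.01,
) -> list[TermCluster]:
    """Group significant terms into kappa-linked annotation clusters.

    Seed groups are each term plus its kappa neighbours, kept when at
    least half of the within-group pairs exceed the threshold; groups
    sharing more than half of their members (relative to the smaller
    group) are merged until a fixed point; clusters below ``min_terms``
    are discarded.
    """
    sig = significant(results, ease_cutoff)
    if not sig:
        return []
    gene_list = sorted(set(gene_list))
    kap = _kappa_matrix(sig, gene_list)
    t = len(sig)
    linked = kap >= kappa_threshold

    groups: list[frozenset[int]] = []
    for i in range(t):
        nb = set(np.flatnonzero(linked[i]).tolist())  # includes i
        if len(nb) < 2:
            continue
        idx = sorted(nb)
        pairs = [(a, b) for ai, a in enumerate(idx) for b in idx[ai + 1:]]
        good = sum(linked[a, b] for a, b in pairs)
        if pairs and good / len(pairs) >= 0.5:
            groups.append(frozenset(nb))
    groups = list(dict.fromkeys(groups))

    changed = True
    while changed:
        changed = False
        merged: list[frozenset[int]] = []
        used = [False] * len(groups)
        for i in range(len(groups)):
            if used[i]:
                continue
            cur = set(groups[i])
            for j in range(i + 1, len(groups)):
                if used[j]:
                    continue
                other = groups[j]
                overlap = len(cur & other)
                if overlap > 0.5 * min(len(cur), len(other)):
                    cur |= other
                    used[j] = True
                    changed = True
            merged.append(frozenset(cur))
        groups = list(dict.fromkeys(merged))

    clusters = []
    for g in groups:
        if len(g) < min_terms:
            continue
        terms = sorted(sig[i].term_id for i in g)
        genes: set[str] = set()
        for i in g:
            genes |= sig[i].genes
        score = float(-np.mean([np.log10(max(sig[i].ease_p, 1e-300)) for i in g]))
        clusters.append(TermCluster(terms=terms, genes=genes, score=score))
    clusters.sort(key=lambda c: (-c.score, c.terms))
    return clusters


def heatmap_order(counts: "object", method: str = "complete"):
    """Order a term x subset gene-count matrix by hierarchical clustering.

    ``counts`` is a pandas DataFrame (rows: terms, columns: subsets).
    Rows and columns are each ordered by complete-linkage clustering on
    Euclidean distance; the input is pre-sorted by id so dendrogram leaf
    order is deterministic under ties.  Returns the reordered DataFrame.
    """
    import pandas as pd

    df = counts.sort_index().sort_index(axis=1)
    if df.shape[0] < 2:
        raise ValueError("need >= 2 terms")

    def _order(mat: np.ndarray) -> np.ndarray:
        if mat.shape[0] < 2:
            return np.arange(mat.shape[0])
        link = scicluster.hierarchy.linkage(pdist(mat), method=method)
        return np.asarray(scicluster.hierarchy.leaves_list(link))

    row_order = _order(df.to_numpy(dtype=float))
    col_order = _order(df.to_numpy(dtype=float).T)
    return df.iloc[row_order, col_order]
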