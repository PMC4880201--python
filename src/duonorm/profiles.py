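"""k-means clustering of cross-experiment fold-change profiles.

The combined candidate set is clustered separately per normalization on
its (CONSOL, REC, EXTNOR) log2 fold-change triples, then clusters are
matched one-to-one across normalizations by maximizing total Jaccard
overlap.  Matched pairs are kept when their per-experiment centroid sign
patterns (up / down / unchanged) agree and the overlap is large enough.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

__all__ = ["ProfileClustering", "MatchedProfile", "kmeans_profiles", "match_profiles"]


@dataclass
class ProfileClustering:
    normalization_tag: str
    probesets: list[str]
    labels: np.ndarray  # cluster index 0..k-1 per probe
    centroids: np.ndarray  # [k, n_experiments]
    inertia: float
    k: int
    n_restarts: int
    seed: int

    def members(self, cluster: int) -> set[str]:
        return {p for p, l in zip(self.probesets, self.labels) if l == cluster}


@dataclass
class MatchedProfile:
    cluster_mas: int
    cluster_rma: int
    members: set[str]  # intersection
    sign_pattern: tuple[str, ...]  # per experiment: up/down/unchanged
    jaccard: float


def _lloyd(x: np.ndarray, k: int, rng: np.random.Generator, max_iter: int = 100):
    n = x.shape[0]
    centroids = x[rng.choice(n, size=k, replace=False)].copy()
    labels = np.zeros(n, dtype=int)
    for _ in range(max_iter):
        d2 = ((x[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        new_labels = d2.argmin(axis=1)
        for c in range(k):
            mask = new_labels == c
            if mask.any():
                centroids[c] = x[mask].mean(axis=0)
            else:
                # empty cluster: re-seed at the point farthest from its centroid
                far = d2[np.arange(n), new_labels].argmax()
                centroids[c] = x[far]
                new_labels[far] = c
        if np.array_equal(new_labels, labels):
            labels = new_labels
            break
        labels = new_labels
    inertia = float(((x - centroids[labels]) ** 2).sum())
    return labels, centroids, inertia


def kmeans_profiles(
    profiles: np.ndarray,
    probesets: list[str],
    k: int = 6,
    restarts: int = 1000,
    seed: int = 0,
    normalization_tag: str = "",
) -> ProfileClustering:
    """Best-of-``restarts`` Lloyd's k-means on a [probe x experiment]
    log2 fold-change matrix, initial centroids drawn uniformly from the
    data points."""
    x = np.asarray(profiles, dtype=float)
    if x.ndim != 2:
        raise ValueError("profiles must be 2-D [probe, experiment]")
    if k > x.shape[0]:
        raise ValueError(f"k={k} exceeds number of probes {x.shape[0]}")
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(restarts):
        labels, centroids, inertia = _lloyd(x, k, rng)
        if best is None or inertia < best[2]:
            best = (labels, centroids, inertia)
    labels, centroids, inertia = best
    return ProfileClustering(
        normalization_tag=normalization_tag,
        probesets=list(probesets),
        labels=labels,
        centroids=centroids,
        inertia=inertia,
        k=k,
        n_restarts=restarts,
        seed=seed,
    )


def _sign_pattern(c_a: np.ndarray, c_b: np.ndarray, eps: float) -> tuple[str, ...]:
    out = []
    for a, b in zip(c_a, c_b):
        if abs(a) < eps and abs(b) < eps:
            out.append("unchanged")
        elif a > 0 and b > 0:
            out.append("up")
        elif a < 0 and b < 0:
            out.append("down")
        else:
            out.append("discordant")
    return tuple(out)


def match_profiles(
    mas: ProfileClustering,
    rma: ProfileClustering,
    unchanged_eps: float = 0.10,
    jaccard_min: float = 0.5,
) -> list[MatchedProfile]:
    """Optimal one-to-one cluster matching by total Jaccard overlap.

    The assignment is solved exactly by permutation enumeration (k <= 8).
    A pair is retained when its Jaccard overlap reaches ``jaccard_min``
    and the per-experiment sign patterns of the two centroids agree;
    experiments where *both* centroids are within ``unchanged_eps`` of
    zero are classed "unchanged".
    """
    if set(mas.probesets) != set(rma.probesets):
        raise ValueError("clusterings cover different probe universes")
    if mas.k != rma.k:
        raise ValueError("clusterings must use the same k")
    k = mas.k
    if k > 8:
        raise ValueError("exact assignment enumeration supports k <= 8")

    mem_m = [mas.members(c) for c in range(k)]
    mem_r = [rma.members(c) for c in range(k)]
    jac = np.zeros((k, k))
    for i in range(k):
        for j in range(k):
            union = mem_m[i] | mem_r[j]
            jac[i, j] = len(mem_m[i] & mem_r[j]) / len(union) if union else 0.0

    best_perm, best_total = None, -1.0
    for perm in itertools.permutations(range(k)):
        total = sum(jac[i, perm[i]] for i in range(k))
        if total > best_total:
            best_total, best_perm = total, perm

    matches: list[MatchedProfile] = []
    for i in range(k):
        j = best_perm[i]
        if jac[i, j] < jaccard_min:
            continue
        pattern = _sign_pattern(mas.centroids[i], rma.centroids[j], unchanged_eps)
        if "discordant" in pattern:
            continue
        matches.append(
            MatchedProfile(
                cluster_mas=i,
                cluster_rma=j,
                members=mem_m[i] & mem_r[j],
                sign_pattern=pattern,
                jaccard=float(jac[i, j]),
            )
        )
    return matches
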