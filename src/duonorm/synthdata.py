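"""Seeded generators for every input the pipeline consumes.

Each generator plants a known ground truth (differential probesets,
enriched annotation modules, conserved promoter motifs, qPCR fold
changes) so downstream stages can be tested for parameter recovery.

All randomness flows from a single integer seed.  Sub-streams are derived
with :class:`numpy.random.SeedSequence` spawn keys, one fixed key per
generator, so the same seed always yields bit-identical outputs and the
generators are independent of each other.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "SyntheticConfig",
    "ProbeLevelDataset",
    "AnnotationSet",
    "PromoterSet",
    "CtTable",
    "gen_probe_data",
    "gen_annotations",
    "gen_promoters",
    "gen_ct_table",
]

# fixed spawn keys: one independent stream per generator
_KEY_PROBES = 0
_KEY_ANNOT = 1
_KEY_PROMOTERS = 2
_KEY_CT = 3

ALPHABET = "ACGT"
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _rng(seed: int, key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed).spawn(key + 1)[key])


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic probe-level experiment.

    ``n_per_group`` mirrors the study designs (6/6 or 8/8).  ``effect_log2``
    is the absolute planted log2 fold change; the sign is drawn per
    probeset so both up- and down-regulated candidates occur.
    """

    n_probesets: int = 2000
    probes_per_set: int = 8
    n_per_group: tuple[int, int] = (6, 6)
    de_fraction: float = 0.05
    effect_log2: float = 1.0
    array_scale_sd: float = 0.15
    background_mean: float = 30.0
    noise_sd: float = 0.05
    probe_noise_sd: float = 0.10
    latent_sd: float = 0.20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_probesets < 1 or self.probes_per_set < 1:
            raise ValueError("counts must be >= 1")
        if min(self.n_per_group) < 1:
            raise ValueError("need >= 1 sample per group")
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ValueError("de_fraction must be in [0, 1]")
        if self.effect_log2 < 0:
            raise ValueError("effect_log2 must be non-negative")
        for name in ("array_scale_sd", "background_mean", "noise_sd", "probe_noise_sd", "latent_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def n_de(self) -> int:
        return int(round(self.de_fraction * self.n_probesets))

    def with_seed(self, seed: int) -> "SyntheticConfig":
        return replace(self, seed=seed)


@dataclass
class ProbeLevelDataset:
    """Raw probe x sample intensities grouped into probesets.

    ``truth`` maps planted differential probeset ids to their signed log2
    effect (positive = higher in the experimental group).
    """

    intensities: np.ndarray  # [probeset, probe, sample], linear scale
    probeset_ids: list[str]
    sample_ids: list[str]
    group_labels: np.ndarray  # str per sample, two levels
    groups: tuple[str, str]  # (experimental, reference)
    truth: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.intensities.ndim != 3:
            raise ValueError("intensities must be [probeset, probe, sample]")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities contain non-finite values")
        levels = set(self.group_labels.tolist())
        if levels != set(self.groups):
            raise ValueError("group_labels must use exactly the two declared levels")
        missing = set(self.truth) - set(self.probeset_ids)
        if missing:
            raise ValueError(f"truth ids not in probeset_ids: {sorted(missing)[:5]}")

    @property
    def n_probesets(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[2]


@dataclass
class AnnotationSet:
    """term id -> gene id set annotation, with planted enriched modules.

    ``planted_modules`` maps a module name to the *term ids* planted for
    it; the member terms share a common truth-gene core, so a working
    enrichment + kappa-clustering stage should recover each module as one
    term cluster.
    """

    terms: dict[str, set[str]]
    universe: set[str]
    planted_modules: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for term, genes in self.terms.items():
            if not genes:
                raise ValueError(f"term {term} is empty")
            if not genes <= self.universe:
                raise ValueError(f"term {term} annotates genes outside the universe")
        for module, term_ids in self.planted_modules.items():
            missing = term_ids - set(self.terms)
            if missing:
                raise ValueError(f"module {module} references unknown terms {missing}")


@dataclass
class PromoterSet:
    """Upstream promoter sequences with one ortholog per gene.

    Coordinates are TSS-relative (0-based, sequence index i maps to
    position ``i - length``, i.e. [-L, 0)).
    """

    length: int
    rat: dict[str, str]
    ortholog: dict[str, str]
    planted_positions: dict[str, list[int]] = field(default_factory=dict)
    candidate_genes: set[str] = field(default_factory=set)

    def genes(self) -> list[str]:
        return sorted(self.rat)


@dataclass
class CtTable:
    """Long-format qPCR cycle-threshold records with technical duplicates."""

    records: "object"  # pandas.DataFrame: animal_id, group, gene, replicate, ct
    reference_genes: list[str]
    control_group: str = "NoRecall"

    def __post_init__(self) -> None:
        df = self.records
        counts = df.groupby(["animal_id", "gene"])["ct"].size()
        if not (counts == 2).all():
            bad = counts[counts != 2].index.tolist()[:3]
            raise ValueError(f"each (animal, gene) needs exactly 2 replicates; bad: {bad}")
        if not ((df["ct"] > 0) & (df["ct"] <= 45)).all():
            raise ValueError("Ct values must lie in (0, 45]")


def gen_probe_data(config: SyntheticConfig) -> ProbeLevelDataset:
    """Generate a two-group probe-level dataset with planted effects.

    The generative model on the log2 scale is

        signal = mu_probeset + probe_offset + group_effect + latent + bio + meas

    where ``latent = loading_probeset * factor_sample`` is a shared
    structured-noise direction orthogonal (in expectation) to the group
    contrast — the kind of within-group variation the orthogonal OPLS
    component is meant to absorb — ``bio ~ N(0, noise_sd)`` is shared
    across the probes of one probeset within a sample, and
    ``meas ~ N(0, probe_noise_sd)`` is probe-level measurement noise.
    Observed intensity is

        2**signal * array_scale + background

    with ``array_scale ~ lognormal(0, array_scale_sd)`` per array and
    ``background ~ Exponential(background_mean)`` per probe cell, which
    makes normexp background correction identifiable.
    """
    rng = _rng(config.seed, _KEY_PROBES)
    P, J = config.n_probesets, config.probes_per_set
    n1, n2 = config.n_per_group
    N = n1 + n2

    probeset_ids = [f"ps{i:05d}_at" for i in range(P)]
    sample_ids = [f"EXP{i + 1}" for i in range(n1)] + [f"REF{i + 1}" for i in range(n2)]
    group_labels = np.array(["EXP"] * n1 + ["REF"] * n2)
    is_exp = (group_labels == "EXP").astype(float)

    mu = rng.uniform(5.0, 11.0, size=P)
    probe_offsets = rng.normal(0.0, 1.0, size=(P, J))

    n_de = config.n_de
    de_idx = rng.choice(P, size=n_de, replace=False) if n_de else np.array([], dtype=int)
    signs = rng.choice([-1.0, 1.0], size=n_de)
    beta = np.zeros(P)
    beta[de_idx] = signs * config.effect_log2
    truth = {probeset_ids[i]: float(beta[i]) for i in np.sort(de_idx)}

    factor = rng.standard_normal(N)
    loading = rng.normal(0.0, config.latent_sd, size=P)
    bio = rng.normal(0.0, config.noise_sd, size=(P, N))
    meas = rng.normal(0.0, config.probe_noise_sd, size=(P, J, N))
    log2_signal = (
        mu[:, None, None]
        + probe_offsets[:, :, None]
        + (beta[:, None] * is_exp[None, :])[:, None, :]
        + (loading[:, None] * factor[None, :])[:, None, :]
        + bio[:, None, :]
        + meas
    )

    scale = rng.lognormal(0.0, config.array_scale_sd, size=N)
    background = rng.exponential(config.background_mean, size=(P, J, N))
    intensities = np.exp2(log2_signal) * scale[None, None, :] + background

    return ProbeLevelDataset(
        intensities=intensities,
        probeset_ids=probeset_ids,
        sample_ids=sample_ids,
        group_labels=group_labels,
        groups=("EXP", "REF"),
        truth=truth,
    )


def gen_annotations(
    config: SyntheticConfig,
    truth_genes: set[str],
    *,
    universe: set[str] | None = None,
    n_terms: int = 100,
    term_size: tuple[int, int] = (10, 40),
    n_planted: int = 3,
    terms_per_module: int = 3,
    planted_size: int = 12,
    planted_fraction: float = 0.9,
) -> AnnotationSet:
    """Random annotation terms plus modules enriched among ``truth_genes``.

    Each planted module consists of ``terms_per_module`` terms built
    around a shared core: every member term draws ``planted_fraction`` of
    its genes from the module's truth-gene core and the remainder
    uniformly from the universe, so the member terms agree strongly on
    gene content (high pairwise kappa).  All other terms draw uniformly
    from the universe.
    """
    rng = _rng(config.seed, _KEY_ANNOT)
    if universe is None:
        universe = {f"ps{i:05d}_at" for i in range(config.n_probesets)}
    if not universe:
        raise ValueError("universe is empty")
    if not truth_genes <= universe:
        raise ValueError("truth_genes must be a subset of the universe")

    pool = np.array(sorted(universe))
    truth_pool = np.array(sorted(truth_genes))

    terms: dict[str, set[str]] = {}
    planted: dict[str, set[str]] = {}
    for m in range(n_planted):
        core_size = min(int(round(planted_fraction * planted_size)), len(truth_pool))
        core = (
            set(rng.choice(truth_pool, size=core_size, replace=False)) if core_size else set()
        )
        module_terms: set[str] = set()
        for t in range(terms_per_module):
            members = set(core)
            n_fill = planted_size - len(members)
            if n_fill > 0:
                members |= set(rng.choice(pool, size=n_fill, replace=False))
            tid = f"MODULE{m:03d}_T{t}"
            terms[tid] = members
            module_terms.add(tid)
        planted[f"MODULE{m:03d}"] = module_terms

    for t in range(n_terms):
        size = int(rng.integers(term_size[0], term_size[1] + 1))
        terms[f"TERM{t:04d}"] = set(rng.choice(pool, size=min(size, len(pool)), replace=False))

    return AnnotationSet(terms=terms, universe=set(universe), planted_modules=planted)


def gen_promoters(
    config: SyntheticConfig,
    candidate_genes: list[str],
    background_genes: list[str],
    motif_consensus: str,
    *,
    length: int = 2000,
    p_plant: float = 0.8,
    p_background: float = 0.05,
    substitution_rate: float = 0.05,
) -> PromoterSet:
    """Promoter pairs (rat + one ortholog) with a planted conserved motif.

    Candidate promoters carry the motif consensus at the same TSS-relative
    position in both species with probability ``p_plant``; background
    promoters at rate ``p_background``.  The ortholog is the rat sequence
    with per-base substitutions at ``substitution_rate`` outside the
    planted site, so local identity around planted motifs stays high.
    """
    rng = _rng(config.seed, _KEY_PROMOTERS)
    motif = motif_consensus.upper()
    if not set(motif) <= set(ALPHABET):
        raise ValueError("motif consensus must be ACGT")
    L = len(motif)
    if length < L:
        raise ValueError(f"promoter length {length} shorter than motif length {L}")

    rat: dict[str, str] = {}
    ortho: dict[str, str] = {}
    planted: dict[str, list[int]] = {}

    for gene, p in [(g, p_plant) for g in candidate_genes] + [
        (g, p_background) for g in background_genes
    ]:
        seq = rng.choice(list(ALPHABET), size=length)
        protected = np.zeros(length, dtype=bool)
        positions: list[int] = []
        if rng.random() < p:
            start = int(rng.integers(0, length - L + 1))
            seq[start : start + L] = list(motif)
            protected[start : start + L] = True
            positions.append(start - length)  # TSS-relative
        sub = (rng.random(length) < substitution_rate) & ~protected
        oseq = seq.copy()
        if sub.any():
            # substitute to a uniformly drawn *different* base
            shifts = rng.integers(1, 4, size=int(sub.sum()))
            idx = np.flatnonzero(sub)
            base_idx = np.searchsorted(list(ALPHABET), seq[idx])
            oseq[idx] = np.array(list(ALPHABET))[(base_idx + shifts) % 4]
        rat[gene] = "".join(seq)
        ortho[gene] = "".join(oseq)
        planted[gene] = positions

    return PromoterSet(
        length=length,
        rat=rat,
        ortholog=ortho,
        planted_positions=planted,
        candidate_genes=set(candidate_genes),
    )


def gen_ct_table(
    config: SyntheticConfig,
    fold_changes: dict[tuple[str, str], float],
    *,
    genes: list[str] | None = None,
    reference_genes: tuple[str, ...] = ("Gapdh", "Ywhaz"),
    groups: tuple[str, ...] = ("NoRecall", "2min", "10min"),
    n_per_group: int = 6,
    ct_noise_sd: float | None = None,
) -> CtTable:
    """qPCR Ct table with planted group fold changes and duplicates.

    ``fold_changes[(gene, group)]`` is expression relative to the control
    (first) group; missing entries default to 1.  Ct = base - log2(fc) +
    animal effect + replicate noise.  Reference genes always have fold 1.
    """
    import pandas as pd

    rng = _rng(config.seed, _KEY_CT)
    if ct_noise_sd is None:
        ct_noise_sd = config.noise_sd
    for (g, grp), fc in fold_changes.items():
        if fc <= 0:
            raise ValueError(f"non-positive fold change for ({g}, {grp})")
    if genes is None:
        genes = sorted({g for g, _ in fold_changes})
    all_genes = list(genes) + [g for g in reference_genes if g not in genes]

    base_ct = {g: float(rng.uniform(18.0, 28.0)) for g in all_genes}
    rows = []
    for gi, group in enumerate(groups):
        for a in range(n_per_group):
            animal = f"{group}_a{a + 1}"
            shift = float(rng.normal(0.0, 0.2))  # animal-wide pipetting shift
            for gene in all_genes:
                fc = 1.0 if gene in reference_genes else fold_changes.get((gene, group), 1.0)
                if gi == 0:
                    fc = 1.0
                true_ct = base_ct[gene] - np.log2(fc) + shift
                for rep in (1, 2):
                    ct = true_ct + float(rng.normal(0.0, ct_noise_sd))
                    rows.append((animal, group, gene, rep, float(np.clip(ct, 1e-3, 45.0))))
    df = pd.DataFrame(rows, columns=["animal_id", "group", "gene", "replicate", "ct"])
    return CtTable(records=df, reference_genes=list(reference_genes), control_group=groups[0])
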