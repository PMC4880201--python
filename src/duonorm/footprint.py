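"""Simplified phylogenetic footprinting of candidate-gene promoters.

PWM hits are scored against a uniform background in 2000-base upstream
windows, paired across an orthologous promoter through a global affine-gap
alignment, and retained when the ortholog carries a hit for the same PWM
within a small aligned-column offset inside a locally well-conserved
region.  Enrichment of conserved hits in candidate versus background
promoters is a one-sided Fisher exact test with the study's p < 0.0005
significance rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import Align
from scipy import stats

__all__ = [
    "Pwm",
    "PwmHit",
    "ConservedHit",
    "extract_promoter",
    "align_pair",
    "scan_pwm",
    "conserved_hits",
    "tfbs_enrichment",
    "rank_pwms",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_BASE_INDEX = {b: i for i, b in enumerate("ACGT")}
TFBS_ALPHA = 0.0005


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class Pwm:
    """4 x L position probability matrix (rows A, C, G, T)."""

    matrix: np.ndarray
    id: str = ""
    pseudocount: float = 0.01

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape[0] != 4:
            raise ValueError("PWM must have 4 rows (A, C, G, T)")
        m = m + self.pseudocount
        m = m / m.sum(axis=0, keepdims=True)
        self.matrix = m
        if not np.allclose(self.matrix.sum(axis=0), 1.0, atol=1e-9):
            raise ValueError("PWM columns must sum to 1")

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    @property
    def log_odds(self) -> np.ndarray:
        return np.log2(self.matrix / 0.25)

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=0).sum())

    @classmethod
    def from_counts(cls, counts: np.ndarray, id: str = "", pseudocount: float = 0.01) -> "Pwm":
        c = np.asarray(counts, dtype=float)
        return cls(matrix=c / c.sum(axis=0, keepdims=True), id=id, pseudocount=pseudocount)

    @classmethod
    def from_consensus(cls, consensus: str, id: str = "", p_major: float = 0.91) -> "Pwm":
        m = np.full((4, len(consensus)), (1.0 - p_major) / 3.0)
        for j, b in enumerate(consensus.upper()):
            m[_BASE_INDEX[b], j] = p_major
        return cls(matrix=m, id=id or consensus, pseudocount=0.0)


@dataclass
class PwmHit:
    position: int  # TSS-relative start (negative upstream)
    strand: str  # "+" or "-"
    score: float


@dataclass
class ConservedHit:
    gene: str
    pwm_id: str
    position: int  # rat TSS-relative
    strand: str
    ortholog_position: int
    identity: float


def extract_promoter(
    genome: str, tss: int, strand: str = "+", length: int = 2000
) -> tuple[str, bool]:
    """The ``length`` bases upstream of a TSS on the coding strand.

    Returns (sequence, truncated).  Minus-strand genes take the window
    downstream of the TSS and reverse-complement it.  Coordinates in the
    returned sequence map index ``i`` to TSS-relative position
    ``i - len(sequence)``.
    """
    if not 0 <= tss <= len(genome):
        raise ValueError("TSS outside sequence bounds")
    if strand == "+":
        start = max(0, tss - length)
        seq = genome[start:tss]
    elif strand == "-":
        seq = revcomp(genome[tss : tss + length])
    else:
        raise ValueError("strand must be '+' or '-'")
    return seq, len(seq) < length


def _check_acgt(seq: str) -> None:
    bad = set(seq) - set("ACGT")
    if bad:
        raise ValueError(f"non-ACGT symbols: {sorted(bad)}")


def align_pair(
    seq_a: str,
    seq_b: str,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = -5.0,
    gap_extend: float = -1.0,
):
    """Optimal global affine-gap alignment of two ACGT sequences.

    Gap cost convention: a gap of length g costs ``gap_open +
    (g - 1) * gap_extend`` (the first gapped base pays the open penalty
    only).  Returns a Bio.Align.Alignment.
    """
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    _check_acgt(seq_a)
    _check_acgt(seq_b)
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner.align(seq_a, seq_b)[0]


def alignment_columns(alignment) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(col_of_a, col_of_b, identity_per_column) from an alignment.

    ``col_of_a[i]`` is the alignment column of position i of sequence A.
    ``identity_per_column`` is 1 where both sequences are present and
    equal, 0 otherwise.
    """
    indices = alignment.indices  # 2 x n_cols, -1 at gaps
    n_cols = indices.shape[1]
    a_str, b_str = str(alignment[0]), str(alignment[1])
    len_a = int((indices[0] >= 0).sum())
    len_b = int((indices[1] >= 0).sum())
    col_of_a = np.full(len_a, -1, dtype=int)
    col_of_b = np.full(len_b, -1, dtype=int)
    ident = np.zeros(n_cols)
    for c in range(n_cols):
        ia, ib = indices[0, c], indices[1, c]
        if ia >= 0:
            col_of_a[ia] = c
        if ib >= 0:
            col_of_b[ib] = c
        if ia >= 0 and ib >= 0 and a_str[c] == b_str[c]:
            ident[c] = 1.0
    return col_of_a, col_of_b, ident


def scan_pwm(sequence: str, pwm: Pwm, threshold_frac: float = 0.8) -> list[PwmHit]:
    """Log-odds scan of both strands; hit iff score >= frac * max score.

    Hit positions are TSS-relative starts on the forward coordinates of
    ``sequence`` (index 0 maps to position -len(sequence)).
    """
    _check_acgt(sequence)
    L = pwm.length
    n = len(sequence)
    if n < L:
        raise ValueError("sequence shorter than PWM")
    lo = pwm.log_odds
    threshold = threshold_frac * pwm.max_score
    idx = np.fromiter((_BASE_INDEX[b] for b in sequence), dtype=int, count=n)
    hits: list[PwmHit] = []
    for strand in ("+", "-"):
        scan_idx = idx if strand == "+" else 3 - idx[::-1]
        # score at every offset
        scores = np.zeros(n - L + 1)
        for j in range(L):
            scores += lo[scan_idx[j : n - L + 1 + j], j]
        for off in np.flatnonzero(scores >= threshold):
            start = int(off) if strand == "+" else n - L - int(off)
            hits.append(PwmHit(position=start - n, strand=strand, score=float(scores[off])))
    hits.sort(key=lambda h: (h.position, h.strand))
    return hits


def conserved_hits(
    gene: str,
    seq_rat: str,
    seq_ortholog: str,
    pwm: Pwm,
    threshold_frac: float = 0.8,
    offset_tol: int = 10,
    id_window: int = 24,
    id_min: float = 0.8,
    alignment=None,
) -> list[ConservedHit]:
    """Rat PWM hits conserved in the orthologous promoter.

    A rat hit is retained when an ortholog hit for the same PWM and strand
    maps within ``offset_tol`` aligned columns and the alignment identity
    over the ``id_window`` columns centred on the site is >= ``id_min``.
    """
    if alignment is None:
        alignment = align_pair(seq_rat, seq_ortholog)
    col_a, col_b, ident = alignment_columns(alignment)
    rat_hits = scan_pwm(seq_rat, pwm, threshold_frac)
    ortho_hits = scan_pwm(seq_ortholog, pwm, threshold_frac)
    n_a, n_b = len(seq_rat), len(seq_ortholog)
    n_cols = ident.size

    out: list[ConservedHit] = []
    for hit in rat_hits:
        a_start = hit.position + n_a
        ca = col_a[a_start]
        best = None
        for oh in ortho_hits:
            if oh.strand != hit.strand:
                continue
            cb = col_b[oh.position + n_b]
            if abs(int(ca) - int(cb)) <= offset_tol:
                if best is None or abs(int(cb) - int(ca)) < abs(
                    int(col_b[best.position + n_b]) - int(ca)
                ):
                    best = oh
        if best is None:
            continue
        half = id_window // 2
        lo_c = max(0, int(ca) - half)
        hi_c = min(n_cols, int(ca) + half)
        local_id = float(ident[lo_c:hi_c].mean()) if hi_c > lo_c else 0.0
        if local_id >= id_min:
            out.append(
                ConservedHit(
                    gene=gene,
                    pwm_id=pwm.id,
                    position=hit.position,
                    strand=hit.strand,
                    ortholog_position=best.position,
                    identity=local_id,
                )
            )
    return out


def _genes_with_conserved_hit(promoters: dict[str, tuple[str, str]], pwm: Pwm, **kw) -> set[str]:
    hit_genes = set()
    for gene, (rat, ortho) in promoters.items():
        if conserved_hits(gene, rat, ortho, pwm, **kw):
            hit_genes.add(gene)
    return hit_genes


def tfbs_enrichment(
    candidate_promoters: dict[str, tuple[str, str]],
    background_promoters: dict[str, tuple[str, str]],
    pwm: Pwm,
    alpha: float = TFBS_ALPHA,
    **scan_kw,
) -> tuple[float, bool, dict]:
    """One-sided Fisher exact enrichment of conserved hits in candidates.

    Returns (p, significant, counts).  Promoter dicts map gene ->
    (rat sequence, ortholog sequence); the two sets must be disjoint.
    """
    if not candidate_promoters or not background_promoters:
        raise ValueError("both promoter sets must be non-empty")
    overlap = set(candidate_promoters) & set(background_promoters)
    if overlap:
        raise ValueError(f"candidate and background sets overlap: {sorted(overlap)[:5]}")
    cand_hits = _genes_with_conserved_hit(candidate_promoters, pwm, **scan_kw)
    bg_hits = _genes_with_conserved_hit(background_promoters, pwm, **scan_kw)
    a = len(cand_hits)
    b = len(candidate_promoters) - a
    c = len(bg_hits)
    d = len(background_promoters) - c
    p = float(stats.fisher_exact([[a, b], [c, d]], alternative="greater")[1])
    counts = {"candidate_hit": a, "candidate_miss": b, "background_hit": c, "background_miss": d}
    return p, p < alpha, counts


def rank_pwms(
    candidate_promoters: dict[str, tuple[str, str]],
    background_promoters: dict[str, tuple[str, str]],
    pwms: list[Pwm],
    top: int = 5,
    **scan_kw,
) -> list[tuple[str, float, float]]:
    """Rank PWMs by ascending enrichment p, fold-enrichment tie-break.

    Returns up to ``top`` tuples (pwm id, p, fold enrichment).
    """
    rows = []
    for pwm in pwms:
        p, _, counts = tfbs_enrichment(candidate_promoters, background_promoters, pwm, **scan_kw)
        rate_c = counts["candidate_hit"] / max(1, len(candidate_promoters))
        rate_b = counts["background_hit"] / max(1, len(background_promoters))
        fold = rate_c / rate_b if rate_b > 0 else np.inf
        rows.append((pwm.id, p, fold))
    rows.sort(key=lambda r: (r[1], -r[2], r[0]))
    return rows[:top]
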