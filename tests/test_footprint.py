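import itertools

import numpy as np
import pytest
from scipy import stats

from duonorm import synthdata
from duonorm.footprint import (
    Pwm,
    align_pair,
    alignment_columns,
    conserved_hits,
    extract_promoter,
    revcomp,
    scan_pwm,
    tfbs_enrichment,
)

MOTIF = "TTGACGTCAA"


@pytest.fixture(scope="module")
def pwm():
    return Pwm.from_consensus(MOTIF, id="TESTTF")


def _random_seq(n, seed=0):
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list("ACGT"), n))


class TestPwm:
    def test_columns_sum_to_one(self, pwm):
        np.testing.assert_allclose(pwm.matrix.sum(axis=0), 1.0, atol=1e-9)

    def test_bad_shape_raises(self):
        with pytest.raises(ValueError):
            Pwm(matrix=np.ones((3, 5)))

    def test_max_score_positive(self, pwm):
        assert pwm.max_score > 0


class TestExtractPromoter:
    def test_plus_strand_window(self):
        genome = _random_seq(6000, seed=1)
        seq, truncated = extract_promoter(genome, tss=5000, strand="+", length=2000)
        assert seq == genome[3000:5000]
        assert not truncated

    def test_minus_strand_revcomp(self):
        genome = _random_seq(3000, seed=2)
        seq, _ = extract_promoter(genome, tss=500, strand="-", length=1000)
        assert seq == revcomp(genome[500:1500])

    def test_truncation_flag(self):
        genome = _random_seq(1000, seed=3)
        seq, truncated = extract_promoter(genome, tss=100, strand="+", length=2000)
        assert len(seq) == 100 and truncated

    def test_tss_out_of_bounds(self):
        with pytest.raises(ValueError):
            extract_promoter("ACGT", tss=10)


class TestAlignPair:
    def test_identical_sequences(self):
        seq = _random_seq(50, seed=4)
        aln = align_pair(seq, seq)
        assert aln.score == pytest.approx(len(seq))
        _, _, ident = alignment_columns(aln)
        assert ident.mean() == 1.0

    def test_single_deletion_scoring(self):
        # "ACGT" vs "AGT": 3 matches + one length-1 gap (open only)
        aln = align_pair("ACGT", "AGT")
        assert aln.score == pytest.approx(3 * 1 + (-5))

    def test_non_acgt_raises(self):
        with pytest.raises(ValueError):
            align_pair("ACGN", "ACGT")

    def test_matches_exhaustive_oracle_short(self):
        # brute-force optimal global alignment score over all gap placements
        def brute(a, b):
            # enumerate alignments via recursion with memo on (i, j, state)
            from functools import lru_cache

            @lru_cache(maxsize=None)
            def go(i, j, state):  # state: 0 diag, 1 gap-in-b, 2 gap-in-a
                if i == len(a) and j == len(b):
                    return 0.0
                best = -np.inf
                if i < len(a) and j < len(b):
                    s = 1.0 if a[i] == b[j] else -1.0
                    best = max(best, s + go(i + 1, j + 1, 0))
                if i < len(a):
                    cost = -1.0 if state == 1 else -5.0
                    best = max(best, cost + go(i + 1, j, 1))
                if j < len(b):
                    cost = -1.0 if state == 2 else -5.0
                    best = max(best, cost + go(i, j + 1, 2))
                return best

            return go(0, 0, 0)

        rng = np.random.default_rng(5)
        for _ in range(10):
            a = "".join(rng.choice(list("ACGT"), rng.integers(3, 8)))
            b = "".join(rng.choice(list("ACGT"), rng.integers(3, 8)))
            assert align_pair(a, b).score == pytest.approx(brute(a, b))


class TestScanPwm:
    def test_consensus_hit_at_planted_position(self, pwm):
        seq = list(_random_seq(500, seed=6))
        seq[350 : 350 + len(MOTIF)] = list(MOTIF)
        hits = scan_pwm("".join(seq), pwm)
        positions = {h.position for h in hits if h.strand == "+"}
        assert 350 - 500 in positions
        top = max(hits, key=lambda h: h.score)
        assert top.score == pytest.approx(pwm.max_score)

    def test_revcomp_hit_on_minus_strand(self, pwm):
        seq = list(_random_seq(400, seed=7))
        seq[100 : 100 + len(MOTIF)] = list(revcomp(MOTIF))
        hits = scan_pwm("".join(seq), pwm)
        assert any(h.strand == "-" and h.position == 100 - 400 for h in hits)

    def test_matches_bruteforce_rescan(self, pwm):
        seq = _random_seq(500, seed=8)
        hits = scan_pwm(seq, pwm, threshold_frac=0.6)
        lo = pwm.log_odds
        L = pwm.length
        threshold = 0.6 * pwm.max_score
        expected = 0
        for strand_seq, strand in ((seq, "+"), (revcomp(seq), "-")):
            for off in range(len(seq) - L + 1):
                window = strand_seq[off : off + L]
                score = sum(lo["ACGT".index(b), j] for j, b in enumerate(window))
                if score >= threshold:
                    expected += 1
        assert len(hits) == expected

    def test_lower_threshold_monotone(self, pwm):
        seq = _random_seq(600, seed=9)
        strict = scan_pwm(seq, pwm, threshold_frac=0.9)
        loose = scan_pwm(seq, pwm, threshold_frac=0.5)
        assert len(loose) >= len(strict)

    def test_short_sequence_raises(self, pwm):
        with pytest.raises(ValueError):
            scan_pwm("ACG", pwm)


class TestConservedHits:
    def test_identical_promoters_conserved(self, pwm):
        seq = list(_random_seq(300, seed=10))
        seq[120 : 120 + len(MOTIF)] = list(MOTIF)
        seq = "".join(seq)
        hits = conserved_hits("g", seq, seq, pwm)
        assert any(h.position == 120 - 300 and h.identity == 1.0 for h in hits)

    def test_ablated_ortholog_dropped(self, pwm):
        seq = list(_random_seq(300, seed=11))
        seq[120 : 120 + len(MOTIF)] = list(MOTIF)
        rat = "".join(seq)
        ortho = list(rat)
        ortho[120 : 120 + len(MOTIF)] = list("GGGGGGGGGG")
        hits = conserved_hits("g", rat, "".join(ortho), pwm, threshold_frac=0.85)
        assert not any(abs(h.position - (120 - 300)) < 5 for h in hits)

    def test_matches_bruteforce_pairing(self, pwm):
        cfg = synthdata.SyntheticConfig(seed=12)
        ps = synthdata.gen_promoters(
            cfg, [f"g{i}" for i in range(20)], [], MOTIF,
            length=300, p_plant=0.7, substitution_rate=0.03,
        )
        for gene in ps.genes():
            rat, ortho = ps.rat[gene], ps.ortholog[gene]
            aln = align_pair(rat, ortho)
            hits = conserved_hits(gene, rat, ortho, pwm, alignment=aln)
            # brute-force oracle: re-pair rat and ortholog hits directly
            col_a, col_b, ident = alignment_columns(aln)
            rat_hits = scan_pwm(rat, pwm)
            ortho_hits = scan_pwm(ortho, pwm)
            expected = []
            for rh in rat_hits:
                ca = col_a[rh.position + len(rat)]
                ok = False
                for oh in ortho_hits:
                    if oh.strand != rh.strand:
                        continue
                    if abs(int(col_b[oh.position + len(ortho)]) - int(ca)) <= 10:
                        ok = True
                if ok:
                    lo_c = max(0, ca - 12)
                    hi_c = min(len(ident), ca + 12)
                    if ident[lo_c:hi_c].mean() >= 0.8:
                        expected.append(rh.position)
            assert sorted(h.position for h in hits) == sorted(expected)


class TestEnrichment:
    def _promoter_sets(self, p_cand, p_bg, n_cand=40, n_bg=200, seed=13, length=300):
        cfg = synthdata.SyntheticConfig(seed=seed)
        cand_genes = [f"c{i}" for i in range(n_cand)]
        bg_genes = [f"b{i}" for i in range(n_bg)]
        ps = synthdata.gen_promoters(
            cfg, cand_genes, bg_genes, MOTIF, length=length,
            p_plant=p_cand, p_background=p_bg, substitution_rate=0.02,
        )
        cand = {g: (ps.rat[g], ps.ortholog[g]) for g in cand_genes}
        bg = {g: (ps.rat[g], ps.ortholog[g]) for g in bg_genes}
        return cand, bg

    def test_planted_enrichment_significant(self, pwm):
        cand, bg = self._promoter_sets(0.8, 0.05)
        p, sig, counts = tfbs_enrichment(cand, bg, pwm)
        assert sig and p < 0.0005
        assert counts["candidate_hit"] >= 20

    def test_equal_rates_not_significant(self, pwm):
        cand, bg = self._promoter_sets(0.1, 0.1, n_cand=30, n_bg=60, seed=14)
        p, sig, _ = tfbs_enrichment(cand, bg, pwm)
        assert not sig

    def test_p_matches_hypergeom_oracle(self, pwm):
        cand, bg = self._promoter_sets(0.8, 0.05, n_cand=20, n_bg=50, seed=15)
        p, _, c = tfbs_enrichment(cand, bg, pwm)
        a, b_, cc, d = (
            c["candidate_hit"], c["candidate_miss"], c["background_hit"], c["background_miss"],
        )
        oracle = stats.hypergeom.sf(a - 1, a + b_ + cc + d, a + cc, a + b_)
        assert p == pytest.approx(oracle, rel=1e-9)

    def test_overlap_raises(self, pwm):
        cand, bg = self._promoter_sets(0.5, 0.1, n_cand=5, n_bg=10, seed=16)
        bg.update({list(cand)[0]: list(cand.values())[0]})
        with pytest.raises(ValueError):
            tfbs_enrichment(cand, bg, pwm)

    def test_input_order_invariant(self, pwm):
        cand, bg = self._promoter_sets(0.6, 0.05, n_cand=10, n_bg=30, seed=17)
        p1, _, _ = tfbs_enrichment(dict(sorted(cand.items())), bg, pwm)
        p2, _, _ = tfbs_enrichment(dict(sorted(cand.items(), reverse=True)), bg, pwm)
        assert p1 == p2
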