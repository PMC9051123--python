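"""PSSM scanning: log-odds, exact p-value DP, calling and gain/loss logic."""

import itertools

import numpy as np
import pytest

from isnp.annotation import RegionAnnotation, reverse_complement
from isnp.background import BackgroundModel, estimate_background
from isnp.io import MotifMatrix
from isnp.sites import GAIN, LOSS, NEUTRAL
from isnp.tfbs import (ScoredMotif, call_tfbs_change, fdr_scan, pssm_logodds,
                       scan_window)


def motif_from_rows(rows, motif_id="M"):
    return MotifMatrix(motif_id, ["TF"], np.array(rows, dtype=float))


def consensus_motif(consensus, weight=100.0, motif_id="M"):
    counts = np.zeros((len(consensus), 4))
    for i, b in enumerate(consensus):
        counts[i, "ACGT".index(b)] = weight
    return MotifMatrix(motif_id, ["TF"], counts)


def brute_force_tails(sm: ScoredMotif):
    """Exhaustive enumeration oracle over all L-mers with the same quantized
    weights; returns {score: P(score >= s)}."""
    L, bg = sm.L, sm.bg
    probs = {}
    for seq in itertools.product(range(4), repeat=L):
        p = bg.stationary[seq[0]]
        for a, b in zip(seq, seq[1:]):
            p *= bg.transition[a, b]
        q = int(sm.qm[range(L), seq].sum() - sm.qb0[seq[0]]
                - sum(sm.qbt[a, b] for a, b in zip(seq, seq[1:])))
        probs[q] = probs.get(q, 0.0) + p
    tail, out = 0.0, {}
    for s in sorted(probs, reverse=True):
        tail += probs[s]
        out[s] = tail
    return out


class TestLogOdds:
    def test_degenerate_column_no_pseudocount(self, uniform_bg):
        m = motif_from_rows([[1, 0, 0, 0]])
        w = pssm_logodds(m, uniform_bg, flat_pseudocount=0)
        assert w[0, 0] == pytest.approx(2.0)  # log2(1 / 0.25)
        assert np.all(np.isneginf(w[0, 1:]))

    def test_pseudocount_makes_finite(self, uniform_bg):
        m = motif_from_rows([[1, 0, 0, 0]])
        w = pssm_logodds(m, uniform_bg, flat_pseudocount=0.25)
        assert np.all(np.isfinite(w))

    def test_motif_equal_to_background_is_zero(self, uniform_bg):
        m = motif_from_rows([[1, 1, 1, 1], [2, 2, 2, 2]])
        w = pssm_logodds(m, uniform_bg, flat_pseudocount=0)
        np.testing.assert_allclose(w, 0.0, atol=1e-12)

    def test_hand_computed_value(self, uniform_bg):
        m = motif_from_rows([[2, 2, 0, 0]])
        w = pssm_logodds(m, uniform_bg, flat_pseudocount=1.0)
        assert w[0, 0] == pytest.approx(np.log2((3 / 8) / 0.25))


class TestExactPvalue:
    def test_single_base_tail(self, uniform_bg):
        m = motif_from_rows([[1, 0, 0, 0]])
        sm = ScoredMotif(m, uniform_bg)
        w_a = sm.qm[0, 0] - sm.qb0[0]
        assert sm.pvalue(w_a) == pytest.approx(0.25)

    @pytest.mark.parametrize("order", [0, 1])
    @pytest.mark.parametrize("L", [2, 3, 4])
    def test_dp_matches_enumeration(self, rng, order, L):
        bg = estimate_background("ACGGGTTACCGTAGGCATGCAAT" * 3, order=order)
        counts = rng.integers(0, 30, size=(L, 4)).astype(float)
        sm = ScoredMotif(MotifMatrix("M", [], counts + 1), bg)
        oracle = brute_force_tails(sm)
        for s, tail in oracle.items():
            assert sm.pvalue(s) == pytest.approx(tail, rel=1e-12)

    def test_min_score_has_pvalue_one(self, uniform_bg):
        sm = ScoredMotif(consensus_motif("ACGT"), uniform_bg)
        assert sm.pvalue(sm._smin) == pytest.approx(1.0)

    def test_monotone_non_increasing(self, uniform_bg):
        sm = ScoredMotif(consensus_motif("ACGTAC"), uniform_bg)
        assert np.all(np.diff(sm._tail) <= 1e-15)


class TestScan:
    def test_planted_consensus_single_hit(self, uniform_bg, rng):
        cons = "ACGTACGGTT"
        m = consensus_motif(cons)
        window = "TTGACCAGTC" * 4 + cons + "GGATCAATCC" * 4
        hits = scan_window(window, [m], uniform_bg, threshold_p=1e-5)
        assert len(hits) == 1
        (h,) = hits
        assert (h.start, h.strand) == (window.find(cons), "+")
        assert h.pvalue <= 1e-5

    def test_reverse_complement_mirror(self, uniform_bg):
        cons = "ACGTACGGTT"
        m = consensus_motif(cons)
        window = "TTGACCAGTC" * 3 + cons + "GGATCAATCC" * 3
        rc = reverse_complement(window)
        fwd = scan_window(window, [m], uniform_bg, threshold_p=1.0)
        rev = scan_window(rc, [m], uniform_bg, threshold_p=1.0)
        W = len(window)
        flip = {"+": "-", "-": "+"}
        mirrored = sorted((W - h.end, flip[h.strand], round(h.score, 9))
                          for h in rev)
        assert mirrored == sorted((h.start, h.strand, round(h.score, 9))
                                  for h in fwd)

    def test_window_shorter_than_motif(self, uniform_bg):
        assert scan_window("ACG", [consensus_motif("ACGTACGGTT")],
                           uniform_bg) == []

    def test_n_scores_as_background(self, uniform_bg):
        m = consensus_motif("ACGT")
        sm = ScoredMotif(m, uniform_bg)
        from isnp.tfbs import encode
        q_full = sm.quantized_scores(encode("ACGT"))[0]
        q_n = sm.quantized_scores(encode("ANGT"))[0]
        # the N position contributes zero log-odds
        per_pos = sm.qm[1, 1] - sm.qbt[0, 1]
        assert q_full - q_n == per_pos


class TestFDRScan:
    def test_single_test_q_equals_p(self, uniform_bg):
        cons = "ACGTACGGTT"
        hits = fdr_scan({"w": cons}, [consensus_motif(cons)], uniform_bg,
                        fdr=0.5)
        # only 2 positions scanned (both strands); best hit q = min(p * 2, ...)
        best = min(hits, key=lambda h: h.pvalue)
        assert best.qvalue <= 2 * best.pvalue + 1e-12

    def test_bh_hand_computed(self):
        from statsmodels.stats.multitest import multipletests
        _, q, _, _ = multipletests([0.01, 0.02, 0.03], method="fdr_bh")
        np.testing.assert_allclose(q, [0.03, 0.03, 0.03])

    def test_all_p_one_no_hits(self, uniform_bg):
        m = motif_from_rows([[1, 1, 1, 1]] * 4)  # uninformative motif
        hits = fdr_scan({"w": "ACGTACGTAC"}, [m], uniform_bg, fdr=0.1)
        assert hits == []


def ann_promoter(rsid="rs1", genes=("G1",)):
    return RegionAnnotation(rsid, "promoter", frozenset(genes))


class TestCallChange:
    def setup_method(self):
        self.cons = "ACGTACGGTT"
        self.m = consensus_motif(self.cons)
        self.bg = BackgroundModel.uniform()
        flank = "TTGACCAGTC" * 2
        # SNP at offset 25, inside the motif planted at 20
        self.anc = flank + self.cons + "GGATCAATCC" * 2
        snp_off = 25
        broken = [b for b in "ACGT" if b != self.anc[snp_off]][0]
        self.var = self.anc[:snp_off] + broken + self.anc[snp_off + 1:]
        self.snp_off = snp_off

    def hits(self, seq, tag):
        return scan_window(seq, [self.m], self.bg, threshold_p=1e-5, tag=tag)

    def test_planted_ablation_is_loss(self):
        sc = call_tfbs_change("M", self.hits(self.anc, "ancestral"),
                              self.hits(self.var, "variant"), self.snp_off,
                              ann_promoter())
        assert sc.change == LOSS and sc.propagates
        assert sc.site_type == "tfbs_promoter"
        assert sc.target_genes == frozenset({"G1"})

    def test_allele_swap_is_gain(self):
        sc = call_tfbs_change("M", self.hits(self.var, "ancestral"),
                              self.hits(self.anc, "variant"), self.snp_off,
                              ann_promoter())
        assert sc.change == GAIN

    def test_site_on_both_alleles_is_neutral_non_propagating(self):
        sc = call_tfbs_change("M", self.hits(self.anc, "ancestral"),
                              self.hits(self.anc, "variant"), self.snp_off,
                              ann_promoter())
        assert sc.change == NEUTRAL and not sc.propagates

    def test_hit_not_overlapping_snp_ignored(self):
        # SNP offset outside the planted site: no call either way
        sc = call_tfbs_change("M", self.hits(self.anc, "ancestral"),
                              self.hits(self.var, "variant"), 2,
                              ann_promoter())
        # the variant allele also carries the (distant) intact site, so both
        # alleles have no overlapping hit -> no record
        assert sc is None

    def test_non_regulatory_context_returns_none(self):
        a = RegionAnnotation("rs1", "exon", frozenset({"G1"}))
        assert call_tfbs_change("M", [], [], 25, a) is None


def test_antisymmetry_on_random_snps(uniform_bg, rng):
    """Swapping the two alleles maps gain <-> loss and fixes neutral."""
    from isnp.fixtures import random_snp_windows
    from isnp.sites import classify_change
    m = consensus_motif("ACGTACGGTT")
    sm = ScoredMotif(m, uniform_bg)
    flipped = {GAIN: LOSS, LOSS: GAIN, NEUTRAL: NEUTRAL, None: None}
    for anc, var, off in random_snp_windows(60, rng):
        ha = scan_window(anc, [sm], uniform_bg)
        hv = scan_window(var, [sm], uniform_bg)
        fwd = classify_change(any(h.overlaps(off) for h in ha),
                              any(h.overlaps(off) for h in hv))
        rev = classify_change(any(h.overlaps(off) for h in hv),
                              any(h.overlaps(off) for h in ha))
        assert rev == flipped[fwd]
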