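"""miRNA target-site calling: alignment, duplex energy, thresholds, context."""

import numpy as np
import pytest

from isnp.annotation import RegionAnnotation, reverse_complement
from isnp.mirna import (DUPLEX_INIT, STACK_TABLE, MiRNADuplex, align_mirna,
                        call_mirna_ts, duplex_energy, is_target_site,
                        stack_energy)
from isnp.sites import GAIN, LOSS


MIRNA = "UGAGGUAGUAGGUUGUAUAGUU"  # let-7-like, 22 nt


def complement_site(mirna: str) -> str:
    """DNA window site perfectly complementary to the miRNA."""
    return reverse_complement(mirna.replace("U", "T"))


def embed(site, left="ACGTACGTAC" * 3, right="GGATCAATCC" * 3):
    return left + site + right


class TestAlign:
    def test_perfect_complement_full_duplex(self):
        site = complement_site(MIRNA)
        win = embed(site)
        ds = align_mirna("m", MIRNA, win)
        d = ds[0]
        assert d.site_start == win.find(site)
        assert d.site_end == d.site_start + len(site)
        assert d.seed_matched
        assert d.alignment_score == max(x.alignment_score for x in ds)
        # 7 seed columns at 5*4 plus 15 plain matches at 5
        assert d.alignment_score == pytest.approx(7 * 20 + 15 * 5)

    def test_seed_only_site_lower_score(self):
        # complementary only at miRNA positions 2-8
        seed_site = complement_site(MIRNA)[-9:-1]  # pairs positions 1-8
        win = embed(seed_site)
        ds = align_mirna("m", MIRNA, win, floor=20)
        best = ds[0]
        assert best.seed_matched
        assert best.alignment_score < 7 * 20 + 15 * 5

    def test_length_and_alphabet_validation(self):
        with pytest.raises(ValueError, match="18-26"):
            align_mirna("m", "ACGU" * 3, "ACGT" * 20)
        with pytest.raises(ValueError):
            align_mirna("m", MIRNA[:-1] + "X", "ACGT" * 20)
        with pytest.raises(ValueError):
            align_mirna("m", MIRNA, "ACGT" * 10 + "J")

    def test_random_null_specificity(self, rng):
        """Random miRNA vs random windows: passing both thresholds is rare."""
        n_pass = 0
        n_trials = 150
        for _ in range(n_trials):
            win = "".join("ACGT"[b] for b in rng.integers(0, 4, 101))
            for d in align_mirna("m", MIRNA, win):
                n_pass += is_target_site(d)
        assert n_pass / n_trials < 0.05


class TestEnergy:
    def test_two_bp_duplex_hand_sum(self):
        pairs = [("C", "G"), ("A", "U")]
        d = MiRNADuplex("m", 0, 2, "UG", "CA", 10.0, pairs=pairs)
        expected = DUPLEX_INIT + STACK_TABLE[(("C", "G"), ("A", "U"))]
        assert duplex_energy(d) == pytest.approx(expected)
        assert STACK_TABLE[(("C", "G"), ("A", "U"))] == -2.11

    def test_reverse_orientation_mirror_identical(self, rng):
        bases = {"A": "U", "U": "A", "C": "G", "G": "C"}
        for _ in range(20):
            top = "".join(rng.choice(list("ACGU")) for _ in range(6))
            pairs = [(t, bases[t]) for t in top]
            mirror = [(b, t) for t, b in reversed(pairs)]
            assert stack_energy(pairs) == pytest.approx(stack_energy(mirror))

    def test_longer_duplex_never_higher_energy(self):
        site = complement_site(MIRNA)
        full = align_mirna("m", MIRNA, embed(site))[0]
        sub = align_mirna("m", MIRNA, embed(site[6:]))[0]
        assert full.energy <= sub.energy

    def test_needs_two_consecutive_pairs(self):
        d = MiRNADuplex("m", 0, 1, "U", "A", 5.0, pairs=[("A", "U")])
        with pytest.raises(ValueError):
            duplex_energy(d)

    def test_interruption_penalised(self):
        pairs = [("C", "G"), ("A", "U"), None, ("G", "C"), ("C", "G")]
        d = MiRNADuplex("m", 0, 5, "?", "?", 0.0, pairs=pairs)
        contiguous = MiRNADuplex("m", 0, 4, "?", "?", 0.0,
                                 pairs=[p for p in pairs if p])
        assert duplex_energy(d) > duplex_energy(contiguous)


def intron_annotation(rsid="rs1", strand="+"):
    return RegionAnnotation(rsid, "first_intron", frozenset({"G1"}), strand)


class TestCallTS:
    def setup_method(self):
        self.site = complement_site(MIRNA)
        win = embed(self.site)
        # SNP inside the seed-pairing region (pairs miRNA position 4)
        self.off = win.find(self.site) + len(self.site) - 4
        self.anc = win
        broken = next(b for b in "ACGT"
                      if b != win[self.off] and b not in ("G", "T"))
        self.var = win[:self.off] + broken + win[self.off + 1:]
        self.mirnas = {"m": MIRNA}

    def test_planted_ablation_is_loss(self):
        (sc,) = call_mirna_ts(self.mirnas, self.anc, self.var, self.off,
                              intron_annotation())
        assert sc.change == LOSS and sc.site_type == "mirna_ts"

    def test_allele_swap_is_gain(self):
        (sc,) = call_mirna_ts(self.mirnas, self.var, self.anc, self.off,
                              intron_annotation())
        assert sc.change == GAIN

    def test_enhancer_context_emits_nothing(self):
        a = RegionAnnotation("rs1", "enhancer", frozenset({"G1"}))
        assert call_mirna_ts(self.mirnas, self.anc, self.var, self.off, a) == []

    def test_minus_strand_site_found(self):
        """A site on the - strand gene is scanned on the reverse complement."""
        W = len(self.anc)
        anc_rc = reverse_complement(self.anc)
        var_rc = reverse_complement(self.var)
        off_rc = W - 1 - self.off
        (sc,) = call_mirna_ts(self.mirnas, anc_rc, var_rc, off_rc,
                              intron_annotation(strand="-"))
        assert sc.change == LOSS

    def test_score_threshold_above_max_never_calls(self):
        assert call_mirna_ts(self.mirnas, self.anc, self.var, self.off,
                             intron_annotation(), score_threshold=1e9) == []

    def test_snp_outside_site_not_called(self):
        off = 2  # far from the planted site
        anc = self.anc
        var = anc[:off] + ("C" if anc[off] != "C" else "G") + anc[off + 2 - 1:]
        assert call_mirna_ts(self.mirnas, anc, var, off,
                             intron_annotation()) == []


def test_bulged_seed_not_accepted(rng):
    """A mismatch at a seed position cannot be rescued by bulging the target
    base out of the helix: the seed must pair contiguously."""
    for _ in range(10):
        mirna = "".join("ACGU"[b] for b in rng.integers(0, 4, 22))
        gc = (mirna.count("G") + mirna.count("C")) / 22
        if not 0.4 <= gc <= 0.7:
            continue
        site = complement_site(mirna)
        win = embed(site)
        j = win.find(site) + len(site) - 4  # pairs miRNA position 4
        broken = next(b for b in "ACGT" if b != win[j] and b not in "GT")
        var = win[:j] + broken + win[j + 1:]
        for d in align_mirna("m", mirna, var):
            if d.site_start <= j < d.site_end:
                assert not d.seed_matched


def test_energy_monotone_adding_wc_pair():
    """Extending a helix by a Watson-Crick pair never raises the energy."""
    pairs = [("G", "C"), ("C", "G"), ("A", "U")]
    for extra in [("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")]:
        d0 = MiRNADuplex("m", 0, 3, "?", "?", 0.0, pairs=list(pairs))
        d1 = MiRNADuplex("m", 0, 4, "?", "?", 0.0, pairs=pairs + [extra])
        assert duplex_energy(d1) <= duplex_energy(d0)
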