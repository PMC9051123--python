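"""miRNA target-site calling on allele-specific windows.

A candidate site is found by Smith-Waterman-style local alignment of the
reversed miRNA (3'->5', so it runs antiparallel to the target read 5'->3')
against the window transcribed to RNA, scoring complementarity rather than
identity: Watson-Crick pair +5, G:U wobble +2, mismatch -3, gap open -9,
gap extend -4, with substitution scores in the seed region (miRNA positions
2-8) multiplied by 4.  A site is called a target site when the seed is fully
Watson-Crick paired, the alignment score is >= 90 and the hybridisation free
energy is <= -16 kcal/mol.

The free energy is a nearest-neighbour sum over consecutive base-pair steps
using a self-contained RNA/RNA stacking table (Watson-Crick step values from
the standard Turner/Xia parameter set, one generic value for wobble-
containing steps), a duplex initiation penalty, and a flat penalty for each
helix interruption.  The table ships with the package; no folding package is
called and no equivalence with any external tool is claimed.

Gain/loss/neutral classification against the SNP is identical to the TFBS
caller; miRNA calls are only made for SNPs in exons, UTRs or first introns,
scanned on the host gene's strand (miRNAs act on the mRNA).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .annotation import MIRNA_CONTEXTS, RegionAnnotation, reverse_complement
from .sites import SiteChange, classify_change

MATCH = 5.0
WOBBLE = 2.0
MISMATCH = -3.0
GAP_OPEN = -9.0
GAP_EXTEND = -4.0
SEED_MULTIPLIER = 4.0
SEED_POSITIONS = range(2, 9)  # miRNA positions 2-8, 1-based from the 5' end

SCORE_THRESHOLD = 90.0
ENERGY_THRESHOLD = -16.0  # kcal/mol
ALIGNMENT_FLOOR = 40.0  # weakest local optimum worth reporting

WC = {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C")}
GU = {("G", "U"), ("U", "G")}

DUPLEX_INIT = 4.09  # kcal/mol, duplex initiation
LOOP_PENALTY = 3.0  # kcal/mol per helix interruption (gap or mismatch run)
WOBBLE_STACK = -1.0  # kcal/mol for any step containing a G:U pair

# Watson-Crick nearest-neighbour stack free energies (kcal/mol), keyed by the
# two consecutive pairs (target_base, mirna_base) read 5'->3' on the target.
_WC_STACKS = {
    (("A", "U"), ("A", "U")): -0.93,  # 5'AA3'/3'UU5'
    (("A", "U"), ("U", "A")): -1.10,  # 5'AU3'/3'UA5'
    (("U", "A"), ("A", "U")): -1.33,  # 5'UA3'/3'AU5'
    (("C", "G"), ("U", "A")): -2.08,  # 5'CU3'/3'GA5'
    (("C", "G"), ("A", "U")): -2.11,  # 5'CA3'/3'GU5'
    (("G", "C"), ("U", "A")): -2.24,  # 5'GU3'/3'CA5'
    (("G", "C"), ("A", "U")): -2.35,  # 5'GA3'/3'CU5'
    (("C", "G"), ("G", "C")): -2.36,  # 5'CG3'/3'GC5'
    (("G", "C"), ("G", "C")): -3.26,  # 5'GG3'/3'CC5'
    (("G", "C"), ("C", "G")): -3.42,  # 5'GC3'/3'CG5'
}


def _flip(pair):
    return (pair[1], pair[0])


def _build_stack_table():
    table = dict(_WC_STACKS)
    # a duplex read in the reverse orientation is the same physical molecule
    for (p1, p2), e in _WC_STACKS.items():
        table.setdefault((_flip(p2), _flip(p1)), e)
    return table


STACK_TABLE = _build_stack_table()


def to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def _is_pair(a: str, b: str, allow_gu: bool = True) -> bool:
    return (a, b) in WC or (allow_gu and (a, b) in GU)


@dataclass
class MiRNADuplex:
    """One aligned miRNA:target candidate site."""

    mirna_id: str
    site_start: int  # window coordinates, 0-based half-open
    site_end: int
    aligned_mirna: str  # 3'->5' left to right (antiparallel to the site)
    aligned_site: str  # 5'->3'
    alignment_score: float
    energy: float = 0.0  # kcal/mol
    seed_matched: bool = False
    pairs: list = field(default_factory=list)  # [(site_base, mirna_base) | None]


def stack_energy(pairs: list[tuple[str, str]]) -> float:
    """Nearest-neighbour energy of an uninterrupted helix (list of pairs 5'->3')."""
    e = 0.0
    for p1, p2 in zip(pairs, pairs[1:]):
        if p1 in GU or p2 in GU:
            e += WOBBLE_STACK
        else:
            e += STACK_TABLE[(p1, p2)]
    return e


def duplex_energy(duplex: MiRNADuplex) -> float:
    """Free energy: initiation + stacks over maximal paired runs + loop penalties."""
    runs: list[list[tuple[str, str]]] = [[]]
    for p in duplex.pairs:
        if p is None:
            if runs[-1]:
                runs.append([])
        else:
            runs[-1].append(p)
    runs = [r for r in runs if len(r) >= 1]
    if not runs or max(len(r) for r in runs) < 2:
        raise ValueError("duplex needs at least 2 consecutive base pairs")
    e = DUPLEX_INIT
    for r in runs:
        e += stack_energy(r)
    e += LOOP_PENALTY * (len(runs) - 1)
    return e


def _substitution(q_base: str, t_base: str, q_index: int, mirna_len: int,
                  allow_gu: bool) -> float:
    """Complementarity score for reversed-miRNA row q_index vs a target base."""
    if (t_base, q_base) in WC:
        s = MATCH
    elif allow_gu and (t_base, q_base) in GU:
        s = WOBBLE
    else:
        s = MISMATCH
    mirna_pos = mirna_len - q_index  # 1-based position from the miRNA 5' end
    if mirna_pos in SEED_POSITIONS:
        s *= SEED_MULTIPLIER
    return s


def _smith_waterman(q: str, t: str, allow_gu: bool):
    """Affine-gap local alignment; returns (score, aligned_q, aligned_t, t0, t1)."""
    n, m = len(q), len(t)
    NEG = -1e9
    M = np.zeros((n + 1, m + 1))
    Ix = np.full((n + 1, m + 1), NEG)  # gap in target (q advances)
    Iy = np.full((n + 1, m + 1), NEG)  # gap in query (t advances)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = _substitution(q[i - 1], t[j - 1], i - 1, n, allow_gu)
            M[i, j] = max(0.0, s + max(M[i - 1, j - 1], Ix[i - 1, j - 1],
                                       Iy[i - 1, j - 1]))
            Ix[i, j] = max(M[i - 1, j] + GAP_OPEN, Ix[i - 1, j] + GAP_EXTEND)
            Iy[i, j] = max(M[i, j - 1] + GAP_OPEN, Iy[i, j - 1] + GAP_EXTEND)
    i, j = np.unravel_index(int(np.argmax(M)), M.shape)
    best = float(M[i, j])
    if best <= 0:
        return 0.0, "", "", 0, 0
    aq, at = [], []
    state = "M"
    t1 = j
    while i > 0 and j > 0:
        if state == "M":
            if M[i, j] <= 0:
                break
            s = _substitution(q[i - 1], t[j - 1], i - 1, n, allow_gu)
            aq.append(q[i - 1])
            at.append(t[j - 1])
            prev = M[i, j] - s
            if abs(prev - M[i - 1, j - 1]) < 1e-9 or prev <= 1e-9:
                state = "M"
            elif abs(prev - Ix[i - 1, j - 1]) < 1e-9:
                state = "Ix"
            else:
                state = "Iy"
            i, j = i - 1, j - 1
            if prev <= 1e-9:
                break
        elif state == "Ix":
            aq.append(q[i - 1])
            at.append("-")
            state = ("M" if abs(Ix[i, j] - (M[i - 1, j] + GAP_OPEN)) < 1e-9
                     else "Ix")
            i -= 1
        else:
            aq.append("-")
            at.append(t[j - 1])
            state = ("M" if abs(Iy[i, j] - (M[i, j - 1] + GAP_OPEN)) < 1e-9
                     else "Iy")
            j -= 1
    return best, "".join(reversed(aq)), "".join(reversed(at)), j, t1


def _duplex_from_alignment(mirna_id: str, mirna_len: int, score: float,
                           aq: str, at: str, t0: int, t1: int,
                           q_end_index: int, allow_gu_seed: bool) -> MiRNADuplex:
    """Assemble a duplex record; q columns map back to miRNA positions."""
    pairs: list = []
    seed_status: dict[int, bool] = {}
    seed_cols: dict[int, int] = {}
    qi = q_end_index  # reversed-miRNA index of the last aligned q base + 1
    # walk the alignment right to left to track q indices
    cols = list(zip(aq, at))
    q_idx = []
    k = qi
    for qc, _ in reversed(cols):
        if qc != "-":
            k -= 1
            q_idx.append(k)
        else:
            q_idx.append(None)
    q_idx.reverse()
    for col, ((qc, tc), k) in enumerate(zip(cols, q_idx)):
        if qc == "-" or tc == "-":
            pairs.append(None)
            continue
        paired = _is_pair(tc, qc, allow_gu=True)
        pairs.append((tc, qc) if paired else None)
        if k is not None:
            mirna_pos = mirna_len - k
            if mirna_pos in SEED_POSITIONS:
                ok = (tc, qc) in WC or (allow_gu_seed and (tc, qc) in GU)
                seed_status[mirna_pos] = ok
                seed_cols[mirna_pos] = col
    seed_matched = all(seed_status.get(p, False) for p in SEED_POSITIONS)
    if seed_matched:
        # the seed must form a contiguous helix: a target bulge between two
        # seed positions (extra alignment column) disqualifies the site
        span = max(seed_cols.values()) - min(seed_cols.values())
        seed_matched = span == len(SEED_POSITIONS) - 1
    d = MiRNADuplex(mirna_id=mirna_id, site_start=t0, site_end=t1,
                    aligned_mirna=aq, aligned_site=at,
                    alignment_score=score, seed_matched=seed_matched, pairs=pairs)
    runs = [p for p in pairs if p is not None]
    if len(runs) >= 2:
        try:
            d.energy = duplex_energy(d)
        except ValueError:
            d.energy = 0.0
    return d


def align_mirna(mirna_id: str, mirna: str, window: str,
                allow_gu_seed: bool = False,
                floor: float = ALIGNMENT_FLOOR) -> list[MiRNADuplex]:
    """Local optima of the reversed miRNA aligned against a window.

    The window is treated as its RNA transcript (T -> U).  Non-overlapping
    local optima with alignment score >= ``floor`` are returned, best first.
    """
    mirna = to_rna(mirna)
    if not 18 <= len(mirna) <= 26:
        raise ValueError(f"{mirna_id}: miRNA length {len(mirna)} outside 18-26")
    if set(mirna) - set("ACGU"):
        raise ValueError(f"{mirna_id}: non-RNA characters")
    target = to_rna(window)
    if set(target) - set("ACGUN"):
        raise ValueError("window has non-nucleotide characters")
    q = mirna[::-1]  # 3'->5', antiparallel to the target read 5'->3'
    out: list[MiRNADuplex] = []

    def recurse(t_sub: str, offset: int):
        if len(t_sub) < 8:
            return
        score, aq, at, t0, t1 = _smith_waterman(q, t_sub, allow_gu=True)
        if score < floor or not aq:
            return
        n_q = sum(1 for c in aq if c != "-")
        # q index one past the last aligned base: recover from traceback end
        # (_smith_waterman aligns a suffix-free local block; recompute end)
        q_end = _q_end_index(q, aq)
        d = _duplex_from_alignment(mirna_id, len(mirna), score, aq, at,
                                   offset + t0, offset + t1, q_end,
                                   allow_gu_seed)
        out.append(d)
        recurse(t_sub[:t0], offset)
        recurse(t_sub[t1:], offset + t1)

    recurse(target, 0)
    out.sort(key=lambda d: -d.alignment_score)
    return out


def _q_end_index(q: str, aligned_q: str) -> int:
    """Index one past the last q base used in the alignment."""
    core = aligned_q.replace("-", "")
    # the aligned block is a contiguous run of q; locate it
    idx = q.find(core)
    if idx < 0:  # should not happen: alignments use contiguous q
        raise RuntimeError("aligned query is not contiguous in the miRNA")
    return idx + len(core)


def is_target_site(d: MiRNADuplex, score_threshold: float = SCORE_THRESHOLD,
                   energy_threshold: float = ENERGY_THRESHOLD) -> bool:
    return (d.seed_matched and d.alignment_score >= score_threshold
            and d.energy <= energy_threshold)


def call_mirna_ts(mirnas: dict[str, str], ancestral_seq: str, variant_seq: str,
                  snp_offset: int, annotation: RegionAnnotation,
                  score_threshold: float = SCORE_THRESHOLD,
                  energy_threshold: float = ENERGY_THRESHOLD,
                  allow_gu_seed: bool = False) -> list[SiteChange]:
    """Gain/loss/neutral miRNA target-site calls for one annotated SNP.

    Calls are only emitted for exon / UTR / first-intron context, on the host
    gene's strand; the SNP base must fall inside the called site.
    """
    if annotation.region_class not in MIRNA_CONTEXTS:
        return []
    if annotation.strand == "-":
        W = len(ancestral_seq)
        ancestral_seq = reverse_complement(ancestral_seq)
        variant_seq = reverse_complement(variant_seq)
        snp_offset = W - 1 - snp_offset
    out: list[SiteChange] = []
    for mid in sorted(mirnas):
        seq = mirnas[mid]

        def sites(window):
            return [d for d in align_mirna(mid, seq, window,
                                           allow_gu_seed=allow_gu_seed)
                    if is_target_site(d, score_threshold, energy_threshold)
                    and d.site_start <= snp_offset < d.site_end]

        anc, var = sites(ancestral_seq), sites(variant_seq)
        change = classify_change(bool(anc), bool(var))
        if change is None:
            continue
        out.append(SiteChange(rsid=annotation.rsid, regulator_id=mid,
                              target_genes=annotation.target_genes,
                              change=change, site_type="mirna_ts",
                              evidence=anc + var))
    return out
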