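"""PSSM scanning with exact score p-values under a Markov background.

The scanner mirrors how matrix-scan-style tools call binding sites: each
window position (both strands) is scored with the log-odds of the motif
against the background, and the p-value of the score — the probability that
a random L-mer generated by the background model scores at least as high —
is computed exactly by dynamic programming over (position, previous base,
discretized score).  Scores are discretized once, on a fixed grid, and the
same quantized weights are used for scanning and for the DP, so the p-value
attached to a hit is exact for the reported (quantized) score.

Two calling modes are provided: a hard p-value threshold (default 1e-5) and
an FDR mode that pools every scanned position's p-value per motif and
applies Benjamini-Hochberg (default q <= 0.1).  The pipeline unions the two
callers' site sets, recording per-hit provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from statsmodels.stats.multitest import multipletests

from .annotation import RegionAnnotation, reverse_complement
from .background import BackgroundModel
from .io import MotifMatrix
from .sites import SiteChange, classify_change

DEFAULT_BIN_WIDTH = 0.01  # score grid, bits
MIN_WEIGHT = -100.0  # floor for log2(0) weights, bits
DEFAULT_PVALUE = 1e-5
DEFAULT_FDR = 0.1

_ENC = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


@dataclass(frozen=True)
class MotifHit:
    motif_id: str
    sequence_tag: str  # ancestral | variant (or free-form)
    strand: str  # + | -
    start: int  # 0-based half-open, + strand window coordinates
    end: int
    score: float  # bits
    pvalue: float
    qvalue: float | None = None
    caller: str = "pvalue"  # pvalue | fdr

    def overlaps(self, offset: int) -> bool:
        return self.start <= offset < self.end


def encode(seq: str) -> np.ndarray:
    try:
        return np.fromiter((_ENC[c] for c in seq.upper()), dtype=np.int64,
                           count=len(seq))
    except KeyError as exc:
        raise ValueError(f"non-ACGTN character {exc.args[0]!r} in sequence")


def pssm_logodds(motif: MotifMatrix, bg: BackgroundModel,
                 pseudocount_fraction: float = 0.01,
                 flat_pseudocount: float | None = None) -> np.ndarray:
    """L x 4 log-odds weights in bits: log2(p_motif / p_bg_stationary).

    The motif pseudocount defaults to 1% of each row's count total,
    distributed by the background composition; ``flat_pseudocount`` instead
    adds an absolute value to every cell.  With a zero pseudocount,
    impossible bases give -inf (floored to ``MIN_WEIGHT`` at scan time).
    """
    if flat_pseudocount is not None:
        probs = motif.counts + flat_pseudocount
        probs = probs / probs.sum(axis=1, keepdims=True)
    else:
        probs = motif.probabilities(bg.stationary, pseudocount_fraction)
    with np.errstate(divide="ignore"):
        return np.log2(probs) - np.log2(bg.stationary)[None, :]


class ScoredMotif:
    """A motif prepared for scanning: quantized weights and exact p-values.

    The quantized score of a site x_0..x_{L-1} is

        sum_i QM[i, x_i] - QB0[x_0] - sum_{i>=1} QBT[x_{i-1}, x_i]

    with QM the quantized log2 motif probabilities and QB0/QBT the quantized
    log2 stationary/transition background probabilities.  N bases contribute
    zero to both motif and background terms.
    """

    def __init__(self, motif: MotifMatrix, bg: BackgroundModel,
                 bin_width: float = DEFAULT_BIN_WIDTH,
                 pseudocount_fraction: float = 0.01,
                 flat_pseudocount: float | None = None,
                 min_weight: float = MIN_WEIGHT):
        self.motif = motif
        self.bg = bg
        self.bin_width = float(bin_width)
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        if flat_pseudocount is not None:
            probs = motif.counts + flat_pseudocount
            probs = probs / probs.sum(axis=1, keepdims=True)
        else:
            probs = motif.probabilities(bg.stationary, pseudocount_fraction)
        with np.errstate(divide="ignore"):
            logm = np.maximum(np.log2(probs), min_weight)
        self.L = motif.counts.shape[0]

        def q(x):
            return np.rint(np.asarray(x) / self.bin_width).astype(np.int64)

        self.qm = q(logm)  # (L, 4)
        with np.errstate(divide="ignore"):
            self.qb0 = q(np.log2(bg.stationary))  # (4,)
            self.qbt = q(np.maximum(np.log2(bg.transition), min_weight))  # (4, 4)
        # 5-state versions (index 4 = N): N scores as background, i.e. zero
        # log-odds: both motif and background terms vanish.  A transition out
        # of an N restarts from the stationary distribution.
        self.qm5 = np.pad(self.qm, ((0, 0), (0, 1)))
        self.qb0_5 = np.pad(self.qb0, (0, 1))
        self.qbt5 = np.zeros((5, 5), dtype=np.int64)
        self.qbt5[:4, :4] = self.qbt
        self.qbt5[4, :4] = self.qb0
        self._tail, self._smin = self._score_distribution()

    # -- exact score distribution under the background ---------------------
    def _score_distribution(self):
        """Tail probabilities P(score >= s) of a random background L-mer."""
        inc0 = self.qm[0] - self.qb0  # (4,)
        runmin, runmax = int(inc0.min()), int(inc0.max())
        prob = np.zeros((4, runmax - runmin + 1))
        for b in range(4):
            prob[b, inc0[b] - runmin] += self.bg.stationary[b]
        for i in range(1, self.L):
            inc = self.qm[i][None, :] - self.qbt  # (4 prev, 4 cur)
            newmin = runmin + int(inc.min())
            newmax = runmax + int(inc.max())
            new = np.zeros((4, newmax - newmin + 1))
            width = runmax - runmin + 1
            for a in range(4):
                for b in range(4):
                    off = runmin + inc[a, b] - newmin
                    new[b, off:off + width] += prob[a] * self.bg.transition[a, b]
            prob, runmin, runmax = new, newmin, newmax
        dist = prob.sum(axis=0)
        tail = dist[::-1].cumsum()[::-1]
        return np.minimum(tail, 1.0), runmin

    def pvalue(self, qscore) -> np.ndarray:
        """Exact P(score >= qscore) for quantized integer scores."""
        qscore = np.asarray(qscore, dtype=np.int64)
        idx = np.clip(qscore - self._smin, 0, len(self._tail) - 1)
        p = self._tail[idx]
        return np.where(qscore > self._smin + len(self._tail) - 1,
                        np.nextafter(0.0, 1.0), p)

    # -- scanning ----------------------------------------------------------
    def quantized_scores(self, encoded: np.ndarray) -> np.ndarray:
        """Quantized site scores at every start position of an encoded sequence."""
        n = len(encoded) - self.L + 1
        if n <= 0:
            return np.empty(0, dtype=np.int64)
        win = sliding_window_view(encoded, self.L)
        motif_part = self.qm5[np.arange(self.L)[None, :], win].sum(axis=1)
        bg_part = self.qb0_5[win[:, 0]]
        if self.L > 1:
            bg_part = bg_part + self.qbt5[win[:, :-1], win[:, 1:]].sum(axis=1)
        return motif_part - bg_part

    def scan(self, seq: str, tag: str = "", threshold_p: float | None = DEFAULT_PVALUE,
             both_strands: bool = True) -> list[MotifHit]:
        """Score every position (both strands) and keep hits with p <= threshold.

        Minus-strand hits are reported in + strand window coordinates.  With
        ``threshold_p=None`` every position is returned (used by the FDR mode).
        """
        hits: list[MotifHit] = []
        strands = [("+", seq)]
        if both_strands:
            strands.append(("-", reverse_complement(seq)))
        W = len(seq)
        for strand, s in strands:
            qs = self.quantized_scores(encode(s))
            ps = self.pvalue(qs)
            keep = (np.arange(len(qs)) if threshold_p is None
                    else np.nonzero(ps <= threshold_p)[0])
            for i in keep:
                start = int(i) if strand == "+" else W - int(i) - self.L
                hits.append(MotifHit(
                    motif_id=self.motif.motif_id, sequence_tag=tag, strand=strand,
                    start=start, end=start + self.L,
                    score=float(qs[i]) * self.bin_width, pvalue=float(ps[i])))
        hits.sort(key=lambda h: (h.start, h.strand))
        return hits


def prepare_motifs(motifs: list[MotifMatrix], bg: BackgroundModel,
                   bin_width: float = DEFAULT_BIN_WIDTH,
                   **kwargs) -> list["ScoredMotif"]:
    """Precompute quantized weights and score distributions once per motif."""
    return [ScoredMotif(m, bg, bin_width=bin_width, **kwargs) for m in motifs]


def scan_window(seq: str, motifs, bg: BackgroundModel,
                threshold_p: float = DEFAULT_PVALUE, tag: str = "",
                bin_width: float = DEFAULT_BIN_WIDTH, **kwargs) -> list[MotifHit]:
    """Scan one window with several motifs at a hard p-value threshold.

    ``motifs`` may hold raw ``MotifMatrix`` objects or prepared ``ScoredMotif``.
    """
    hits: list[MotifHit] = []
    for m in motifs:
        sm = m if isinstance(m, ScoredMotif) else ScoredMotif(
            m, bg, bin_width=bin_width, **kwargs)
        hits.extend(sm.scan(seq, tag=tag, threshold_p=threshold_p))
    return hits


def fdr_scan(windows: dict[str, str], motifs: list[MotifMatrix],
             bg: BackgroundModel, fdr: float = DEFAULT_FDR,
             bin_width: float = DEFAULT_BIN_WIDTH, **kwargs) -> list[MotifHit]:
    """FIMO-style calling: pool all positions per motif, BH-correct, keep q <= fdr."""
    out: list[MotifHit] = []
    for m in motifs:
        sm = m if isinstance(m, ScoredMotif) else ScoredMotif(
            m, bg, bin_width=bin_width, **kwargs)
        all_hits: list[MotifHit] = []
        for tag, seq in windows.items():
            all_hits.extend(sm.scan(seq, tag=tag, threshold_p=None))
        if not all_hits:
            continue
        pvals = np.array([h.pvalue for h in all_hits])
        _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
        for h, q in zip(all_hits, qvals):
            if q <= fdr:
                out.append(replace(h, qvalue=float(q), caller="fdr"))
    return out


def call_tfbs_change(motif_id: str, ancestral_hits: list[MotifHit],
                     variant_hits: list[MotifHit], snp_offset: int,
                     annotation: RegionAnnotation) -> SiteChange | None:
    """Gain/loss/neutral call for one (SNP, motif) pair in one regulatory context.

    Only hits whose interval covers the SNP base count.  TFBS changes are
    only meaningful in promoter or enhancer context.
    """
    if annotation.region_class not in ("promoter", "enhancer"):
        return None
    anc = [h for h in ancestral_hits if h.motif_id == motif_id
           and h.overlaps(snp_offset)]
    var = [h for h in variant_hits if h.motif_id == motif_id
           and h.overlaps(snp_offset)]
    change = classify_change(bool(anc), bool(var))
    if change is None:
        return None
    return SiteChange(
        rsid=annotation.rsid, regulator_id=motif_id,
        target_genes=annotation.target_genes, change=change,
        site_type=f"tfbs_{annotation.region_class}", evidence=anc + var)
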