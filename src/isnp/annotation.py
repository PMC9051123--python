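"""Allele-specific sequence windows for SNPs and regulatory-region assignment.

Each SNP yields two 101-nt windows (50 nt of flank either side, truncated at
contig edges) carrying the ancestral and the variant allele respectively.
Windows are extracted on the + strand; downstream scanners search both
strands.  Regulatory context decides which site classes may be called:
TF binding-site changes are kept for promoter and enhancer SNPs, miRNA
target-site changes for SNPs in exons, UTRs or the first intron of a gene.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .io import GenomicInterval

log = logging.getLogger(__name__)

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# region classes eligible for each site type
TFBS_CONTEXTS = frozenset({"promoter", "enhancer"})
MIRNA_CONTEXTS = frozenset({"exon", "utr", "first_intron"})

PROMOTER_UPSTREAM = 5000  # nt upstream of the TSS included in the promoter


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


@dataclass
class SNPWindow:
    """A SNP with its two allele-specific sequence windows (+ strand)."""

    rsid: str
    chrom: str
    pos: int  # 0-based position of the SNP base
    ancestral_allele: str
    variant_allele: str
    ancestral_seq: str
    variant_seq: str
    snp_offset: int

    def __post_init__(self):
        if len(self.ancestral_seq) != len(self.variant_seq):
            raise ValueError(f"{self.rsid}: window length mismatch")
        diffs = [i for i, (a, b) in
                 enumerate(zip(self.ancestral_seq, self.variant_seq)) if a != b]
        if diffs != [self.snp_offset]:
            raise ValueError(f"{self.rsid}: windows must differ exactly at snp_offset")
        for s in (self.ancestral_seq, self.variant_seq):
            if set(s) - set("ACGTN"):
                raise ValueError(f"{self.rsid}: non-ACGTN characters in window")

    def swapped(self) -> "SNPWindow":
        """The same SNP with the allele roles exchanged."""
        return SNPWindow(self.rsid, self.chrom, self.pos,
                         self.variant_allele, self.ancestral_allele,
                         self.variant_seq, self.ancestral_seq, self.snp_offset)


@dataclass
class GeneModel:
    """A gene with the exon structure of its canonical transcript."""

    gene_id: str
    chrom: str
    strand: str  # + or -
    exons: list[GenomicInterval]  # in transcription order
    utrs: list[GenomicInterval] = field(default_factory=list)

    @property
    def tss(self) -> int:
        first = self.exons[0]
        return first.start if self.strand == "+" else first.end - 1

    def promoter(self) -> GenomicInterval:
        """5 kb upstream of the TSS through the end of the first exon."""
        first = self.exons[0]
        if self.strand == "+":
            return GenomicInterval(self.chrom, max(0, first.start - PROMOTER_UPSTREAM),
                                   first.end, "+", self.gene_id)
        return GenomicInterval(self.chrom, first.start,
                               first.end + PROMOTER_UPSTREAM, "-", self.gene_id)

    def first_intron(self) -> GenomicInterval | None:
        if len(self.exons) < 2:
            return None
        e1, e2 = self.exons[0], self.exons[1]
        if self.strand == "+":
            start, end = e1.end, e2.start
        else:
            start, end = e2.end, e1.start
        if start >= end:
            return None
        return GenomicInterval(self.chrom, start, end, self.strand, self.gene_id)


@dataclass(frozen=True)
class RegionAnnotation:
    """One regulatory-context assignment for a SNP."""

    rsid: str
    region_class: str  # promoter | enhancer | first_intron | utr | exon | intergenic
    target_genes: frozenset[str]
    strand: str = "+"

    def __post_init__(self):
        if self.region_class != "intergenic" and not self.target_genes:
            raise ValueError(f"{self.rsid}: {self.region_class} needs target genes")


def extract_window(rsid: str, chrom: str, pos: int, ancestral: str, variant: str,
                   genome: dict[str, str], flank: int = 50) -> SNPWindow:
    """Build the allele-specific windows around one SNV.

    ``pos`` is 0-based; the reference base at ``pos`` must equal one of the
    declared alleles.  Near contig edges the window is truncated and
    ``snp_offset`` adjusted.  Indels are rejected.
    """
    ancestral, variant = ancestral.upper(), variant.upper()
    if len(ancestral) != 1 or len(variant) != 1:
        raise ValueError(f"{rsid}: only single-nucleotide variants are supported")
    if ancestral == variant:
        raise ValueError(f"{rsid}: alleles are identical")
    contig = genome[chrom]
    if not (0 <= pos < len(contig)):
        raise ValueError(f"{rsid}: position {pos} outside contig {chrom}")
    ref = contig[pos].upper()
    if ref not in (ancestral, variant):
        raise ValueError(
            f"{rsid}: reference base {ref!r} matches neither allele "
            f"({ancestral}/{variant})")
    start = max(0, pos - flank)
    end = min(len(contig), pos + flank + 1)
    if end - start < 2 * flank + 1:
        log.warning("%s: window truncated to %d nt at contig edge",
                    rsid, end - start)
    offset = pos - start
    left, right = contig[start:pos].upper(), contig[pos + 1:end].upper()
    return SNPWindow(rsid=rsid, chrom=chrom, pos=pos,
                     ancestral_allele=ancestral, variant_allele=variant,
                     ancestral_seq=left + ancestral + right,
                     variant_seq=left + variant + right,
                     snp_offset=offset)


def read_gene_models(path) -> list[GeneModel]:
    """Gene models from a GFF-like TSV: gene_id, feature, chrom, start, end, strand.

    Features are ``exon`` and ``utr``; exons are put in transcription order
    (by start for + genes, reversed for - genes).
    """
    rows: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.rstrip("\n").split("\t")
            if not parts or parts[0].startswith("#") or parts[0] == "gene_id":
                continue
            if len(parts) < 6:
                raise ValueError(f"{path}:{lineno}: need 6 columns")
            gene, feature, chrom, start, end, strand = parts[:6]
            iv = GenomicInterval(chrom, int(start), int(end), strand, gene)
            rec = rows.setdefault(gene, {"chrom": chrom, "strand": strand,
                                         "exons": [], "utrs": []})
            if feature == "exon":
                rec["exons"].append(iv)
            elif feature == "utr":
                rec["utrs"].append(iv)
            else:
                raise ValueError(f"{path}:{lineno}: unknown feature {feature!r}")
    models = []
    for gene in sorted(rows):
        rec = rows[gene]
        exons = sorted(rec["exons"], key=lambda iv: iv.start,
                       reverse=rec["strand"] == "-")
        if not exons:
            log.warning("gene model %s has no exons; skipped", gene)
            continue
        models.append(GeneModel(gene_id=gene, chrom=rec["chrom"],
                                strand=rec["strand"], exons=exons,
                                utrs=rec["utrs"]))
    return models


def write_gene_models(models: list[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tfeature\tchrom\tstart\tend\tstrand\n")
        for gm in sorted(models, key=lambda g: g.gene_id):
            for iv in gm.exons:
                fh.write(f"{gm.gene_id}\texon\t{gm.chrom}\t{iv.start}\t{iv.end}"
                         f"\t{gm.strand}\n")
            for iv in gm.utrs:
                fh.write(f"{gm.gene_id}\tutr\t{gm.chrom}\t{iv.start}\t{iv.end}"
                         f"\t{gm.strand}\n")


def annotate_regions(snp: SNPWindow, gene_models: list[GeneModel],
                     enhancers: list[GenomicInterval],
                     enhancer_genes: dict[str, set[str]]) -> list[RegionAnnotation]:
    """All regulatory contexts overlapping a SNP.

    A SNP may be the promoter SNP of one gene and an enhancer SNP of others;
    every overlapping annotation is returned.  Enhancer annotations are only
    emitted when the enhancer has at least one mapped target gene.  A SNP
    hitting nothing is reported once as intergenic.
    """
    out: list[RegionAnnotation] = []
    for gm in gene_models:
        if gm.chrom != snp.chrom:
            continue
        if not gm.exons:
            log.warning("gene model %s has no exons; skipped", gm.gene_id)
            continue
        genes = frozenset({gm.gene_id})
        if gm.promoter().contains(snp.pos):
            out.append(RegionAnnotation(snp.rsid, "promoter", genes, gm.strand))
        intron1 = gm.first_intron()
        if intron1 is not None and intron1.contains(snp.pos):
            out.append(RegionAnnotation(snp.rsid, "first_intron", genes, gm.strand))
        if any(e.contains(snp.pos) for e in gm.exons):
            out.append(RegionAnnotation(snp.rsid, "exon", genes, gm.strand))
        if any(u.contains(snp.pos) for u in gm.utrs):
            out.append(RegionAnnotation(snp.rsid, "utr", genes, gm.strand))
    for enh in enhancers:
        if enh.chrom == snp.chrom and enh.contains(snp.pos):
            targets = enhancer_genes.get(enh.label, set())
            if targets:  # enhancers without a mapped target gene are dropped
                out.append(RegionAnnotation(snp.rsid, "enhancer",
                                            frozenset(targets), enh.strand))
    if not out:
        out.append(RegionAnnotation(snp.rsid, "intergenic", frozenset()))
    return out
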