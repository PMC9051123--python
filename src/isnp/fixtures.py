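"""Synthetic input generator with planted, recoverable structure.

The generator emits the complete file suite the pipeline consumes — genome
FASTA, SNP VCF with per-patient genotypes, JASPAR motifs, mature-miRNA
FASTA, gene models, enhancers with a target-gene map, interaction network,
gene-ID map, gene-set GMT, a negative-binomially distributed count matrix
and a control-sample list — together with a JSON manifest of every planted
truth.  Generation is a pure function of the configuration: the same seed
produces byte-identical directories.

What is planted, per patient cluster: one SNP that ablates (or, for gain
plantings, creates) a high-information TF motif instance inside an enhancer,
and one SNP that ablates/creates a perfectly complementary miRNA site in
the first intron of a host gene.  Planted motifs put ~2 bits on every
position so a single substitution moves a site across the p <= 1e-5 calling
threshold; planted miRNA sites are full-length complements, so the seed,
score and energy thresholds are all comfortably cleared and a seed-region
substitution destroys the call.  Each regulatory SNP targets its own hub
protein wired to a distinct neighbour set, so patient footprints separate
the clusters; decoy SNPs carry no planted site and their enhancer target
genes are absent from the network.  Count data couple expression to
genotype: the neighbour genes of a cluster's hubs carry the planted log2
fold change in that cluster's patients.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .annotation import GeneModel, reverse_complement, write_gene_models
from .io import ALPHABET, GenomicInterval, MotifMatrix, write_fasta, write_gene_sets, \
    write_motifs, write_regions

DNA_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass
class ExpressionConfig:
    n_genes: int = 1000
    nb_dispersion: float = 0.1
    planted_log2fc: float = 2.0  # cluster-specific effect on a hub's neighbourhood
    global_log2fc: float = 0.75  # shared disease signal on all network genes
    n_controls: int = 20


@dataclass
class FixtureConfig:
    seed: int = 1
    n_patients: int = 200
    n_clusters: int = 4
    n_snps: int = 12  # 2 per cluster (1 TFBS + 1 miRNA) + decoys
    n_motifs: int = 6
    motif_length: int = 10
    n_mirnas: int = 6
    mirna_length: int = 22
    hub_degree: int = 12
    within_carrier_p: float = 0.95
    cross_carrier_p: float = 0.05
    decoy_carrier_p: float = 0.3
    locus_size: int = 6000
    expression: ExpressionConfig = field(default_factory=ExpressionConfig)

    def __post_init__(self):
        if isinstance(self.expression, dict):
            self.expression = ExpressionConfig(**self.expression)
        for p in (self.within_carrier_p, self.cross_carrier_p,
                  self.decoy_carrier_p):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"carrier probability {p} outside [0, 1]")
        for name in ("n_patients", "n_clusters", "n_snps", "n_motifs",
                     "motif_length", "n_mirnas", "hub_degree"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        self.n_regulatory = 2 * self.n_clusters
        if self.n_snps < self.n_regulatory:
            raise ValueError(
                f"n_snps={self.n_snps} < 2 * n_clusters={self.n_regulatory}")
        if self.n_motifs < self.n_clusters or self.n_mirnas < self.n_clusters:
            raise ValueError("need at least one motif and one miRNA per cluster")
        if not 18 <= self.mirna_length <= 26:
            raise ValueError("mirna_length outside 18-26")
        if self.locus_size < 2 * self.mirna_length + 300:
            raise ValueError("locus_size too small for planted sites")


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(ALPHABET[b] for b in rng.integers(0, 4, size=length))


def _random_mirna(rng: np.random.Generator, length: int) -> str:
    """Random mature miRNA with realistic GC content (45-65%)."""
    while True:
        seq = "".join("ACGU"[b] for b in rng.integers(0, 4, size=length))
        gc = (seq.count("G") + seq.count("C")) / length
        if 0.45 <= gc <= 0.65:
            return seq


def _nonpairing_base(mirna_base: str, exclude: str = "") -> str:
    """A DNA base that pairs with the given miRNA base neither WC nor wobble."""
    forbidden = {DNA_COMPLEMENT[mirna_base.replace("U", "T")]}
    if mirna_base == "U":
        forbidden.add("G")  # G:U wobble
    if mirna_base == "G":
        forbidden.add("T")  # U:G wobble
    forbidden.update(exclude)
    return next(b for b in "ACGT" if b not in forbidden)


def generate_fixture(config: FixtureConfig, out_dir) -> dict:
    """Write the full synthetic input suite; returns the truth manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    L = config.motif_length
    half = L // 2

    # --- regulators ---------------------------------------------------------
    # Planted motifs concentrate their information in the SNP-overlapping
    # column (counts 100/0): a substitution there drops the score into a
    # dense part of the null tail (many double mismatches elsewhere score
    # higher), so the degraded site sits far above the 1e-5 threshold while
    # the intact consensus sits far below it, for any estimated background.
    motifs = []
    for m in range(config.n_motifs):
        consensus = _random_seq(rng, L)
        counts = np.full((L, 4), 5.0)
        counts[half] = 0.0
        for i, b in enumerate(consensus):
            counts[i, ALPHABET.index(b)] = 100.0
        motifs.append(MotifMatrix(motif_id=f"MOTIF{m + 1}",
                                  tf_names=[f"TF{m + 1}"], counts=counts))
    mirnas = {f"miR-{i + 1}": _random_mirna(rng, config.mirna_length)
              for i in range(config.n_mirnas)}

    # --- genome and planted SNPs -------------------------------------------
    genome = list(_random_seq(rng, config.n_snps * config.locus_size))
    snps: list[dict] = []
    gene_models: list[GeneModel] = []
    enhancers: list[GenomicInterval] = []
    enhancer_map: dict[str, set[str]] = {}
    id_map: dict[str, str] = {}

    for k in range(config.n_snps):
        pos = k * config.locus_size + config.locus_size // 2
        rsid = f"rs{1000 + k}"
        if k < config.n_regulatory:
            cluster = k // 2
            kind = "tfbs" if k % 2 == 0 else "mirna"
            change = "loss" if cluster % 2 == 0 else "gain"
        else:
            cluster, kind, change = None, "decoy", None
        gene = f"G{k}"
        protein = f"PG{k}" if kind != "decoy" else f"PDECOY{k}"
        id_map[gene] = protein

        if kind == "tfbs":
            motif = motifs[cluster]
            consensus = motif.consensus()
            start = pos - half
            genome[start:start + L] = list(consensus)
            cons_base = consensus[half]
            other = next(b for b in "ACGT" if b != cons_base)
            if change == "loss":
                ancestral, variant = cons_base, other
            else:  # ancestral carries the broken site; variant restores it
                ancestral, variant = other, cons_base
            genome[pos] = ancestral
            enh = GenomicInterval("chr1", pos - 50, pos + 51, ".", f"ENH{k}")
            enhancers.append(enh)
            enhancer_map[f"ENH{k}"] = {gene}
            regulator = motif.motif_id
        elif kind == "mirna":
            mid = f"miR-{cluster + 1}"
            mseq = mirnas[mid]
            site = reverse_complement(mseq.replace("U", "T"))
            site_start = pos - (len(mseq) - 4)  # SNP pairs miRNA position 4
            genome[site_start:site_start + len(site)] = list(site)
            pairing = site[pos - site_start]
            broken = _nonpairing_base(mseq[3], exclude=pairing)
            if change == "loss":
                ancestral, variant = pairing, broken
            else:
                ancestral, variant = broken, pairing
            genome[pos] = ancestral
            gene_models.append(GeneModel(
                gene_id=gene, chrom="chr1", strand="+",
                exons=[GenomicInterval("chr1", pos - 130, pos - 80, "+", gene),
                       GenomicInterval("chr1", pos + 80, pos + 130, "+", gene)]))
            regulator = mid
        else:  # decoy: eligible enhancer context but no planted site
            ancestral = genome[pos]
            variant = next(b for b in "ACGT" if b != ancestral)
            enh = GenomicInterval("chr1", pos - 50, pos + 51, ".", f"ENH{k}")
            enhancers.append(enh)
            enhancer_map[f"ENH{k}"] = {gene}
            regulator = None
        snps.append({"rsid": rsid, "pos": pos, "ancestral": ancestral,
                     "variant": variant, "kind": kind, "change": change,
                     "cluster": cluster, "regulator": regulator,
                     "target_gene": gene, "protein": protein})

    genome_str = "".join(genome)
    write_fasta({"chr1": genome_str}, out / "genome.fa")

    # --- patients and genotypes --------------------------------------------
    patients = [f"P{i + 1:04d}" for i in range(config.n_patients)]
    labels = {p: i * config.n_clusters // config.n_patients
              for i, p in enumerate(patients)}
    carriers = np.zeros((config.n_snps, config.n_patients), dtype=bool)
    for j, p in enumerate(patients):
        for s in snps:
            k = int(s["rsid"][2:]) - 1000
            if s["kind"] == "decoy":
                prob = config.decoy_carrier_p
            elif s["cluster"] == labels[p]:
                prob = config.within_carrier_p
            else:
                prob = config.cross_carrier_p
            carriers[k, j] = rng.random() < prob
    hom = rng.random((config.n_snps, config.n_patients)) < 0.3

    with open(out / "snps.vcf", "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID=chr1,length={len(genome_str)}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(patients) + "\n")
        for s in snps:
            k = int(s["rsid"][2:]) - 1000
            gts = ["1/1" if carriers[k, j] and hom[k, j]
                   else "0/1" if carriers[k, j] else "0/0"
                   for j in range(config.n_patients)]
            fh.write(f"chr1\t{s['pos'] + 1}\t{s['rsid']}\t{s['ancestral']}\t"
                     f"{s['variant']}\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n")

    # --- motifs, miRNAs, gene models, enhancers ----------------------------
    write_motifs(motifs, out / "motifs.jaspar", format="jaspar")
    write_fasta(mirnas, out / "mirnas.fa")
    write_gene_models(gene_models, out / "gene_models.tsv")
    write_regions(enhancers, out / "enhancers.bed")
    with open(out / "enhancer_map.tsv", "w") as fh:
        for label in sorted(enhancer_map):
            for g in sorted(enhancer_map[label]):
                fh.write(f"{label}\t{g}\n")

    # --- interaction network and ID map ------------------------------------
    edges: list[tuple[str, str]] = []
    hubs = [s["protein"] for s in snps if s["kind"] != "decoy"]
    neighbour_sets: dict[str, list[str]] = {}
    for hub in hubs:
        neigh = [f"{hub}_N{j + 1}" for j in range(config.hub_degree)]
        neighbour_sets[hub] = neigh
        edges.extend((hub, n) for n in neigh)
    for a, b in zip(hubs, hubs[1:]):  # keep the union network connected
        edges.append((neighbour_sets[a][0], b))
    with open(out / "network.sif", "w") as fh:
        for a, b in edges:
            fh.write(f"{a}\tpp\t{b}\n")
    for hub, neigh in neighbour_sets.items():
        for n in neigh:
            id_map[n] = n
    with open(out / "id_map.tsv", "w") as fh:
        for g in sorted(id_map):
            fh.write(f"{g}\t{id_map[g]}\n")

    # --- gene sets aligned with hub neighbourhoods --------------------------
    universe = sorted({p for e in edges for p in e})
    gene_sets = {f"TERM_HUB{i}": {hub, *neighbour_sets[hub]}
                 for i, hub in enumerate(hubs)}
    for j in range(6):
        gene_sets[f"TERM_RND{j}"] = set(
            rng.choice(universe, size=10, replace=False))
    write_gene_sets(gene_sets, out / "gene_sets.gmt")

    # --- background training sequences (promoters + enhancers) -------------
    bg_seqs = {}
    for gm in gene_models:
        prom = gm.promoter()
        bg_seqs[f"prom_{gm.gene_id}"] = genome_str[prom.start:prom.end]
    for enh in enhancers:
        bg_seqs[f"enh_{enh.label}"] = genome_str[enh.start:enh.end]
    write_fasta(bg_seqs, out / "background.fa")

    # --- expression counts coupled to the genotype clusters ----------------
    exp = config.expression
    network_genes = universe
    n_bg = max(0, exp.n_genes - len(network_genes))
    genes = network_genes + [f"BGGENE{j}" for j in range(n_bg)]
    controls = [f"CTRL{i + 1:02d}" for i in range(exp.n_controls)]
    samples = controls + patients
    base_mean = 2.0 ** rng.uniform(4, 9, size=len(genes))
    disp = exp.nb_dispersion * np.exp(rng.normal(0, 0.3, size=len(genes)))
    cluster_effect_genes = {
        c: sorted(set().union(*[{s["protein"], *neighbour_sets[s["protein"]]}
                                for s in snps if s["cluster"] == c]))
        for c in range(config.n_clusters)}
    gene_idx = {g: i for i, g in enumerate(genes)}
    mean = np.tile(base_mean[:, None], (1, len(samples)))
    # shared disease component: half the hubs form a "disease core" whose
    # neighbourhoods shift in every case (common processes), on top of the
    # cluster-specific effects (patient-specific processes)
    core_hubs = hubs[::2]
    core_genes = sorted(set().union(*[{h, *neighbour_sets[h]}
                                      for h in core_hubs]))
    core_rows = [gene_idx[g] for g in core_genes]
    for j, p in enumerate(patients):
        col = len(controls) + j
        mean[core_rows, col] *= 2.0 ** exp.global_log2fc
        for g in cluster_effect_genes[labels[p]]:
            mean[gene_idx[g], col] *= 2.0 ** exp.planted_log2fc
    r = 1.0 / disp[:, None]
    counts = rng.negative_binomial(r, r / (r + mean))
    with open(out / "counts.tsv", "w") as fh:
        fh.write("gene\t" + "\t".join(samples) + "\n")
        for i, g in enumerate(genes):
            fh.write(g + "\t" + "\t".join(map(str, counts[i])) + "\n")
    with open(out / "controls.txt", "w") as fh:
        fh.write("\n".join(controls) + "\n")

    # --- manifest -----------------------------------------------------------
    manifest = {
        "config": asdict(config),
        "snps": snps,
        "patient_labels": labels,
        "cluster_effect_genes": cluster_effect_genes,
        "disease_core_genes": core_genes,
        "hub_neighbours": neighbour_sets,
        "controls": controls,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return manifest


def random_snp_windows(n: int, rng: np.random.Generator,
                       length: int = 101) -> list[tuple[str, str, int]]:
    """Random (ancestral_seq, variant_seq, snp_offset) triples for property tests."""
    out = []
    offset = length // 2
    for _ in range(n):
        seq = _random_seq(rng, length)
        anc = seq[offset]
        var = "ACGT"[(ALPHABET.index(anc) + int(rng.integers(1, 4))) % 4]
        out.append((seq, seq[:offset] + var + seq[offset + 1:], offset))
    return out
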