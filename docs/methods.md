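# Methods

## Sequence windows and regulatory context

Each SNV contributes two windows of 50 nt flank + SNP base + 50 nt flank
(101 nt; truncated at contig edges with the SNP offset adjusted), one per
allele, extracted on the + strand. The reference base must equal one of the
declared alleles; indels are rejected. Windows are scanned on both strands,
so the choice of extraction strand is immaterial for TFBS calling; miRNA
scanning transforms the window to the host gene's strand first, because
miRNAs act on the mRNA.

Regulatory context is assigned from gene models and enhancer intervals:

- **promoter** — 5 kb upstream of the TSS through the end of the first exon,
  on the gene's strand;
- **first intron** — between exons 1 and 2 of the canonical transcript
  supplied in the input (no isoform selection logic);
- **exon / UTR** — direct interval overlap;
- **enhancer** — overlap with an enhancer interval *that has at least one
  mapped target gene*; enhancers without a target-gene mapping are dropped.

All overlapping annotations are kept (a SNP can be the promoter SNP of one
gene and an enhancer SNP of several others). TFBS changes are called only in
promoter/enhancer context, miRNA target-site changes only in exon, UTR or
first-intron context.

## Background model

Order-0 or order-1 Markov chains over A/C/G/T, estimated from mono- and
dinucleotide counts of the supplied promoter + enhancer sequence universe
with a +0.01 pseudocount per count cell. For order 1 the stationary
distribution is recomputed as the left unit eigenvector of the transition
matrix, so the model is internally consistent regardless of training-set
length. Runs of N break dinucleotide counting. The default for scanning is
order 1.

## PSSM scanning and exact p-values

Motif count matrices (columns fixed as A, C, G, T) are converted to
probabilities with a pseudocount of 1% of each row total, distributed by the
background composition (an absolute per-cell pseudocount is available).
A site x_1..x_L starting a window position scores

    S = Σ_i log2 p_motif(x_i | i) − log2 P_bg(x_1..x_L),

with the background term using the stationary probability for the first
base and transition probabilities afterwards. All log terms are quantized
on a fixed grid (bin width 0.01 bits; log(0) floored at −100 bits), and the
same quantized components are used both to score windows and to build the
exact null distribution, a dynamic programme over (motif position × previous
base × discretized score). The p-value of a hit is therefore *exactly* the
tail probability of its reported (quantized) score under the background —
there is no sampling and no approximation beyond the score grid itself.
N bases contribute zero log-odds (they score "as background"). Minus-strand
hits are scored on the reverse-complemented window and reported in + strand
window coordinates.

Two calling modes:

- **p-value mode** (primary): hits with p ≤ 1e−5.
- **FDR mode** (complementary): all scanned positions of all windows are
  pooled per motif, BH-corrected, and hits with q ≤ 0.1 kept.

Gain/loss/neutral classification uses the p-value mode's hit sets; the FDR
mode's would-be classification is recorded alongside every site change as
provenance (`fdr_mode_call` column) but does not enter the decision. The
design reason: at q ≤ 0.1 the BH caller remains significant for a site
degraded by a single substitution whenever an intact site exists anywhere in
the pooled scan, so folding it into the decision would turn essentially
every single-nucleotide ablation into "neutral" and no SNP could ever gain
or lose a site. The permissive union of both callers is therefore not a
usable classification rule; keeping the FDR evidence as annotation preserves
the information without destroying the contrast the method exists to detect.

## miRNA target sites

The reversed miRNA (3'→5', antiparallel to the target read 5'→3') is
aligned to the window transcript (T→U) by affine-gap local alignment with
complementarity scoring: Watson–Crick +5, G:U wobble +2, mismatch −3, gap
open −9, gap extend −4, and substitution scores multiplied by 4 at miRNA
positions 2–8 (the seed). Non-overlapping local optima above a floor of 40
are reported, best first.

A reported site is a **target site** when all three hold:

1. *seed match*: miRNA positions 2–8 are Watson–Crick paired (G:U optional
   via a flag, off by default) **and form a contiguous helix** — a bulged-out
   target base inside the seed disqualifies the site. The contiguity rule is
   the canonical seed definition; it also prevents the aligner from rescuing
   a seed mismatch with a 1-nt target bulge, which the ×4 seed scaling would
   otherwise make profitable (gap −9 vs recovered seed match +20).
2. *alignment score* ≥ 90;
3. *duplex free energy* ≤ −16 kcal/mol.

The energy model is a self-contained nearest-neighbour table: the ten
standard Watson–Crick RNA/RNA stack free energies (applied to all sixteen
pair steps via strand symmetry), a generic −1.0 kcal/mol for any step
containing a G:U pair, +4.09 kcal/mol duplex initiation, and +3.0 kcal/mol
per helix interruption. Terminal-AU and symmetry corrections are omitted.
The table ships in `isnp/mirna.py`; equivalence with any external folding
package is not claimed — the thresholded contract (planted complements pass
comfortably, seed-broken sites fail) is what the pipeline relies on, and it
is what the tests pin down.

## Site-change classification

Per (SNP, regulator, context): only sites whose interval covers the SNP base
count. Ancestral-only → loss; variant-only → gain; both → neutral. Neutral
records are retained in the output tables but never propagate to footprints
("overlap with the SNP" is enforced programmatically rather than by manual
review). The classification is antisymmetric under allele swap by
construction, and the test suite verifies this exhaustively on random SNPs.

## Footprints, stratification, modules, enrichment

A patient's **direct** set is the union over carried SNPs (carrier = at
least one alternate allele; missing genotypes count as non-carrier, logged)
of the gain/loss target genes mapped to proteins present in the network;
**neighbours** are all adjacent nodes. Gains and losses contribute equally
(the profile is presence/absence). The patients × proteins binary matrix is
clustered with normalized Hamming distance and UPGMA (average) linkage;
`k` defaults to 4 and a silhouette-vs-k table (k = 2..8) is written for
inspection. Partitions are compared with the adjusted Rand index
(scikit-learn implementation, pinned against a brute-force pair-counting
oracle in the tests). Cluster-driving proteins are direct proteins ranked
both by network degree and by the (uncorrected) chi-square association of
their carrier pattern with the cluster labels; both rankings are reported
descriptively.

The union network is the subgraph induced by the union of all footprints;
analysis uses its giant component (ties broken toward the component with
the lexicographically smallest node). Modules come from Girvan–Newman
clustering: repeatedly delete the highest-betweenness edge (lexicographically
smallest on ties) and return the partition of maximum Newman modularity along
the removal sequence. Gene-set enrichment is the one-sided hypergeometric
tail with BH correction, background = giant-component nodes, terms taken as
flat sets from the GMT (no ontology-graph propagation).

## Expression validation

Genes with total count < 10 are removed (a per-sample variant exists behind
a flag); normalization is log2(CPM + 0.5). Per-patient log2 fold change is
the difference to the mean of the control samples; |log2FC| > 1 (strict)
flags a gene DE in that patient. This plain log-CPM route replaces a
precision-weighted (voom-style) fit: the per-patient binarization that
drives the validation depends on fold changes, not on regression weights.
The cohort-level DE set uses a moderated two-sample t-test: per-gene pooled
variances s_g² with d_g residual df are shrunk to (d0·s0² + d_g·s_g²)/(d0 +
d_g), with the prior (d0, s0²) estimated by method of moments on log s_g²
(digamma/trigamma matching, trigamma inverted by Newton iteration); p-values
use d0 + d_g degrees of freedom and BH correction; the DE set is |log2FC| >
1 and q < 0.05. Setting d0 = 0 reproduces the ordinary t-test exactly (a
tested limiting case). Validation summary 1 averages per-gene percentages
over genes with the population SD (÷n); summaries 2 and 3 are described in
the README.

## Synthetic data: what it emulates, and what it does not

The generator emits every input the pipeline consumes, as a pure function of
its configuration (same seed → byte-identical files). Defaults: 200
patients in 4 equal blocks; 12 SNPs — per cluster one enhancer-TFBS SNP and
one first-intron miRNA SNP (alternating loss/gain plantings), plus 4 decoys
with no planted site whose enhancer target genes are absent from the
network; within-block carrier probability 0.95, cross-block 0.05, decoys
0.30; motif length 10; miRNAs 22 nt with 45–65% GC; one hub protein per
regulatory SNP with 12 private neighbours, hubs chained through one
neighbour to keep the union network connected; counts for 1000 genes,
negative binomial with gene-wise dispersions around 0.1, 20 controls.
Expression couples to genotype through a +2 log2 effect on a cluster's hub
neighbourhoods in that cluster's patients, plus a +0.75 log2 shared disease
component on half the hubs' neighbourhoods ("disease core") in every case —
sub-threshold per patient, but detectable and term-structured at the cohort
level, which is what gives validation 3 a non-degenerate target.

Planted TFBS instances put counts 100 vs 0 at the SNP-overlapping column and
100 vs 5 elsewhere: the intact consensus then sits around p ≈ 1e−6 while a
single substitution at the SNP column lands in a dense part of the null tail
(p ≈ 3e−4), so recovery is robust to the skew of whatever background the
pipeline estimates, in both directions, without tuning.

Not emulated: linkage disequilibrium and realistic allele frequencies,
overlapping regulatory elements, isoform structure, sequencing batch
effects, library-composition artefacts beyond what CPM normalization sees,
and the long-tailed degree distribution of real interactomes. Passing tests
on these fixtures therefore demonstrates correctness of the algorithms and
end-to-end recoverability of planted signal — not performance on real
cohorts.

## Numerical choices and problem sizes

Score grid 0.01 bits; log(0) floored at −100 bits; UPGMA ties resolved by
scipy's ordering (the order-invariance test uses block-structured data,
since with heavily tied distances the merge order is inherently ambiguous);
hypergeometric p floored at the smallest positive double; the trigamma
inverse iterates Newton to 1e−10 relative tolerance; an infinite estimated
d0 (observed variance spread at or below sampling noise) degenerates to a
z-test with the pooled variance. The shipped checks use: exhaustive p-value
enumeration up to motif length 6; 1e5 scanned positions for calibration;
1000 random SNPs for antisymmetry; the default 200-patient fixture for
recovery; 2000 genes × (10+10) samples for moderated-t calibration — sizes
chosen so the whole suite re-runs in well under a coffee break on one core.

## Known limitations

- The scanner is this package's own documented implementation; no
  equivalence with any specific release of external scanning tools is
  claimed (their defaults are version-dependent).
- The FDR caller's evidence is annotation-only (see above); users who want
  FIMO-style calling as the decision rule can scan with `fdr_scan` directly.
- The miRNA energy table is deliberately minimal; absolute energies are
  approximate, thresholded decisions are the supported use.
- Enrichment treats GMT terms as flat sets; parent-child structure of an
  ontology is ignored.
- Chi-square driver rankings are descriptive; no p-values are attached.
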