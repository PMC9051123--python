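# isnp

Functional annotation of **non-coding SNPs** by allele-specific gain/loss of
transcription-factor binding sites (TFBS) and miRNA target sites, expansion of
the affected genes into **patient-specific protein-interaction network
footprints**, unsupervised **patient stratification**, and validation of the
predictions against an independent expression cohort.

The package is aimed at systems-genomics analyses of complex diseases (the
motivating use case is ulcerative colitis), where most risk variants are
regulatory rather than protein-coding: a variant that weakens one enhancer or
one miRNA site has a small effect on its own, but patient-specific
*combinations* of such variants perturb different parts of the signalling
network and can stratify a cohort into mechanistically distinct groups.

## Method

**Allele-specific site calling.** For each SNV, two 101-nt windows are built
(50 nt of flank either side) carrying the ancestral and the variant allele.
Each window is scanned on both strands with position-specific scoring
matrices; a site at position *i* scores

```
S = Σ_j log2 p_motif(x_j | j)  −  log2 P_bg(x_i .. x_{i+L−1})
```

under a first-order Markov background estimated from the promoter/enhancer
sequence universe. The p-value of a score — the probability that a random
background-generated L-mer scores at least as high — is computed **exactly**
by dynamic programming over (position × previous base × discretized score);
hits require p ≤ 1e−5. A complementary FDR mode pools every scanned
position per motif and applies Benjamini–Hochberg (q ≤ 0.1); its calls are
reported as per-hit provenance. miRNA target sites are called by local
alignment of the reversed miRNA against the window's transcript (match +5,
G:U +2, mismatch −3, gaps −9/−4, seed positions 2–8 scaled ×4) and require a
contiguous Watson–Crick seed, alignment score ≥ 90, and nearest-neighbour
duplex free energy ≤ −16 kcal/mol. A site change is a **loss** if the site
covering the SNP exists only with the ancestral allele, a **gain** if only
with the variant, **neutral** if with both; only gains and losses propagate.
TFBS calls are kept for promoter/enhancer context, miRNA calls for
exon/UTR/first-intron context.

**Network footprints and stratification.** For each patient, the proteins of
gain/loss-affected genes of carried SNPs plus their first neighbours in the
interaction network form the patient's footprint. The binary patients ×
proteins matrix is clustered with normalized Hamming distance and average
linkage (UPGMA); partitions are compared by the adjusted Rand index, modules
of the union network's giant component by Girvan–Newman edge-betweenness
clustering at maximum modularity, and gene sets by one-sided hypergeometric
tests (BH-corrected) against the giant component as background.

**Expression validation.** Counts are filtered (gene total ≥ 10), normalized
to log2 CPM, and turned into per-patient log2 fold changes against the
control mean; |log2FC| > 1 flags a gene DE in a patient. Three summaries:
(1) % of patients in which each predicted SNP-affected gene is DE;
(2) re-clustering patients from the DE flags of cluster-driving proteins and
their neighbours, compared with the genotype clustering by ARI;
(3) overlap of gene sets enriched in the cohort-level DE set (moderated
t-test with empirical-Bayes variance shrinkage, |log2FC| > 1, q < 0.05)
versus in each driver's first-neighbour set.

## Worked example

All inputs can be generated synthetically with planted, recoverable
structure (the generator is part of the package and fully seeded):

```python
from isnp.fixtures import FixtureConfig, generate_fixture
from isnp.pipeline import PipelineConfig, run_pipeline

generate_fixture(FixtureConfig(seed=1), "fx")        # 12 SNPs, 200 patients
summary = run_pipeline(PipelineConfig.for_fixture_dir("fx"), "out")
```

which prints (via the summary dict / `out/summary.json`):

```
site changes: 8 | gain/loss: 8
union network: 104 nodes, 103 edges, 8 modules (modularity 0.807)
patient clusters: 4
validation 1: mean 36.62% of patients DE per SNP-affected gene (SD 8.24%)
validation 2: expression-vs-genotype cluster ARI = 0.960
validation 3: mean enriched-term overlap = 0.133
```

The 8 gain/loss calls are exactly the 8 planted regulatory SNPs (2 per
cluster: one enhancer-TFBS and one first-intron miRNA site each); the 4
decoy SNPs yield no calls. The 104-node union network is the 8 hub proteins
with their neighbour sets, and cutting the Hamming/average-linkage dendrogram
at k = 4 recovers the planted patient blocks with ARI 0.96. Validation 1
reflects that each cluster-specific effect gene is differentially expressed
in roughly the quarter of patients carrying the corresponding SNP.

Equivalent shell interface: `isnp fixtures --out fx --seed 1`,
`isnp run --config config.yaml --out out`, plus per-stage subcommands
(`isnp tfbs`, `isnp mirna`, `isnp enrich`, `isnp validate`).

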