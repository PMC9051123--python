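"""Expression-based validation of predicted SNP effects.

Counts are filtered (total reads >= 10 per gene by default), normalized to
log2 counts-per-million with a 0.5 offset, and converted to per-patient
log2 fold changes against the mean of the control samples.  A gene is
flagged differentially expressed (DE) in a patient when |log2FC| > 1
(strict).  Three validation summaries are built on top:

1. per-gene percentage of patients in which a predicted SNP-affected gene
   is DE (mean and SD across genes);
2. re-clustering patients from the binary DE matrix restricted to the
   cluster-driving proteins and their first neighbours, compared with the
   genotype-derived clustering by adjusted Rand index;
3. overlap of gene sets over-represented in the cohort-level DE gene set
   versus in each driver's first-neighbour set.

The cohort-level DE set uses a moderated two-sample t-test: per-gene
variances are shrunk toward a pooled prior with an empirical-Bayes weight,
the prior (d0, s0^2) estimated by method of moments on the log sample
variances; p-values use a t distribution with d0 + dg degrees of freedom
and are BH-corrected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .enrich import enriched_terms, hypergeometric_enrich, term_set_overlap
from .stratify import adjusted_rand_index, hamming_matrix, hierarchical_cluster

log = logging.getLogger(__name__)


@dataclass
class DEMatrix:
    flags: pd.DataFrame  # genes x patients, 0/1
    fold_changes: pd.DataFrame  # genes x patients, log2
    control_ids: list[str]


def filter_and_normalize(counts: pd.DataFrame, min_total: int = 10,
                         per_sample: bool = False) -> pd.DataFrame:
    """Drop weakly expressed genes and return log2(CPM + 0.5).

    ``min_total`` applies to the gene's total count across samples; with
    ``per_sample`` a gene must instead reach the threshold in every sample.
    """
    if (counts.values < 0).any():
        raise ValueError("negative counts")
    lib = counts.sum(axis=0)
    if (lib == 0).any():
        bad = list(lib.index[lib == 0])
        raise ValueError(f"samples with zero total counts: {bad}")
    keep = ((counts >= min_total).all(axis=1) if per_sample
            else counts.sum(axis=1) >= min_total)
    kept = counts.loc[keep]
    log.info("kept %d of %d genes at min_total=%d", keep.sum(), len(counts),
             min_total)
    cpm = kept / lib * 1e6
    return np.log2(cpm + 0.5)


def per_patient_fc(normed: pd.DataFrame, control_ids: list[str]) -> pd.DataFrame:
    """log2 fold change of every sample against the control-sample mean."""
    missing = [c for c in control_ids if c not in normed.columns]
    if missing or not control_ids:
        raise ValueError(f"controls absent from the matrix: {missing}")
    ctrl_mean = normed[control_ids].mean(axis=1)
    cases = [c for c in normed.columns if c not in set(control_ids)]
    return normed[cases].sub(ctrl_mean, axis=0)


def binarize_de(fc: pd.DataFrame, cutoff: float = 1.0,
                control_ids: list[str] | None = None) -> DEMatrix:
    """Flag |log2FC| > cutoff (strict inequality)."""
    flags = (fc.abs() > cutoff).astype(int)
    return DEMatrix(flags=flags, fold_changes=fc,
                    control_ids=list(control_ids or []))


# -- moderated t --------------------------------------------------------------

@dataclass
class ModeratedTestResult:
    gene: str
    log2fc: float
    t: float
    df: float
    pvalue: float
    qvalue: float


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y by Newton iteration (y > 0)."""
    if y <= 0:
        return np.inf
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of (d0, s0^2) on log sample variances.

    Under the hierarchical model, e_g = log(s_g^2) - digamma(df/2) + log(df/2)
    has mean log(s0^2) + digamma(d0/2) - log(d0/2) and excess variance
    trigamma(d0/2); solving the trigamma equation gives d0.  Returns
    (inf, exp(mean)) when the observed spread is at or below the sampling
    noise (complete shrinkage).
    """
    s2 = np.asarray(s2, float)
    ok = s2 > 0
    if ok.sum() < 2:
        raise ValueError("need >= 2 positive variances to fit the prior")
    e = np.log(s2[ok]) - special.digamma(df / 2) + np.log(df / 2)
    emean = float(e.mean())
    evar = float(e.var(ddof=1)) - float(special.polygamma(1, df / 2))
    if evar <= 0:
        return np.inf, float(np.exp(emean))
    d0 = 2 * _trigamma_inverse(evar)
    s0_2 = float(np.exp(emean - special.digamma(d0 / 2) + np.log(d0 / 2)))
    return d0, s0_2


def moderated_t(normed: pd.DataFrame, case_ids: list[str], control_ids: list[str],
                prior_df: float | None = None) -> list[ModeratedTestResult]:
    """Per-gene moderated two-sample t-test (cases vs controls).

    ``prior_df`` overrides the estimated d0 (0 gives the ordinary t-test).
    """
    for name, ids in (("case", case_ids), ("control", control_ids)):
        if len(ids) < 2:
            raise ValueError(f"need >= 2 {name} samples")
    x = normed[case_ids].values
    y = normed[control_ids].values
    n1, n2 = x.shape[1], y.shape[1]
    dg = n1 + n2 - 2
    if dg <= 0:
        raise ValueError("zero residual degrees of freedom")
    m1, m2 = x.mean(axis=1), y.mean(axis=1)
    ss = ((x - m1[:, None]) ** 2).sum(axis=1) + ((y - m2[:, None]) ** 2).sum(axis=1)
    s2 = ss / dg
    if prior_df is None:
        d0, s0_2 = fit_variance_prior(s2, dg)
    elif prior_df == 0:
        d0, s0_2 = 0.0, 1.0
    else:
        d0 = float(prior_df)
        _, s0_2 = fit_variance_prior(s2, dg)
    if np.isinf(d0):
        post = np.full_like(s2, s0_2)
        df_total = np.inf
    else:
        post = (d0 * s0_2 + dg * s2) / (d0 + dg)
        df_total = d0 + dg
    se = np.sqrt(post * (1 / n1 + 1 / n2))
    fc = m1 - m2
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = fc / se
    if np.isinf(df_total):
        pvals = 2 * stats.norm.sf(np.abs(tstat))
    else:
        pvals = 2 * stats.t.sf(np.abs(tstat), df=df_total)
    pvals = np.nan_to_num(pvals, nan=1.0)
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    return [ModeratedTestResult(gene=g, log2fc=float(fc[i]), t=float(tstat[i]),
                                df=float(df_total), pvalue=float(pvals[i]),
                                qvalue=float(qvals[i]))
            for i, g in enumerate(normed.index)]


def de_gene_set(results: list[ModeratedTestResult], fc_cutoff: float = 1.0,
                q_threshold: float = 0.05) -> set[str]:
    """Cohort-level DE genes: |log2FC| > cutoff and BH q < threshold."""
    return {r.gene for r in results
            if abs(r.log2fc) > fc_cutoff and r.qvalue < q_threshold}


# -- validation approaches ----------------------------------------------------

def validation_1(de: DEMatrix, snp_genes: list[str]) -> dict:
    """Per predicted SNP-affected gene: % of patients in which it is DE.

    Returns per-gene percentages plus their unweighted mean and population
    SD across genes; genes absent from the matrix are listed, not scored.
    """
    present = [g for g in snp_genes if g in de.flags.index]
    missing = [g for g in snp_genes if g not in de.flags.index]
    if not present:
        raise ValueError("none of the SNP-affected genes are in the DE matrix")
    pct = de.flags.loc[present].mean(axis=1) * 100.0
    return {
        "per_gene_percent": pct,
        "mean_percent": float(pct.mean()),
        "sd_percent": float(pct.std(ddof=0)),
        "missing_genes": missing,
    }


def validation_2(de: DEMatrix, driver_gene_sets: dict[str, set[str]],
                 genotype_labels: pd.Series, k: int | None = None,
                 linkage: str = "average") -> dict:
    """Cluster patients from DE flags of driver + first-neighbour genes.

    Compares the expression-derived partition with the genotype-derived one
    (ARI over shared patients) and reports the per-cluster DE fraction per
    driver group.
    """
    genes: set[str] = set()
    for s in driver_gene_sets.values():
        genes |= s
    sub = de.flags.loc[sorted(genes & set(de.flags.index))]
    if sub.empty:
        raise ValueError("no driver genes present in the DE matrix")
    profiles = sub.T  # patients x genes
    if profiles.values.sum() == 0:
        return {"ari": float("nan"), "labels": None,
                "note": "all-zero DE matrix; single trivial cluster"}
    k = k or genotype_labels.nunique()
    clustering = hierarchical_cluster(hamming_matrix(profiles), linkage=linkage)
    labels = clustering.cut(k)
    shared = [p for p in labels.index if p in genotype_labels.index]
    ari = (adjusted_rand_index(labels.loc[shared], genotype_labels.loc[shared])
           if shared else float("nan"))
    per_cluster = {}
    for cl in sorted(labels.unique()):
        pats = labels.index[labels == cl]
        per_cluster[int(cl)] = {
            d: float(de.flags.loc[sorted(g & set(de.flags.index)), pats]
                     .values.mean())
            for d, g in driver_gene_sets.items()}
    return {"ari": ari, "labels": labels, "per_cluster_de_fraction": per_cluster}


def validation_3(de_genes: set[str], neighbour_sets: dict[str, set[str]],
                 collection: dict[str, set[str]], background: set[str],
                 q_threshold: float = 0.05) -> dict:
    """Per driver, overlap of terms enriched in the DE set vs its neighbours."""
    de_terms = enriched_terms(hypergeometric_enrich(
        de_genes & background, collection, background, q_threshold))
    per_driver = {}
    fractions = []
    for driver in sorted(neighbour_sets):
        terms = enriched_terms(hypergeometric_enrich(
            neighbour_sets[driver] & background, collection, background,
            q_threshold))
        if not terms or not de_terms:
            per_driver[driver] = {"overlap": float("nan"), "n_terms": len(terms)}
            continue
        ov = term_set_overlap(de_terms, terms)
        per_driver[driver] = {"overlap": ov["fraction_a_in_b"],
                              "jaccard": ov["jaccard"], "n_terms": len(terms)}
        fractions.append(ov["fraction_a_in_b"])
    mean_overlap = float(np.mean(fractions)) if fractions else float("nan")
    return {"de_terms": de_terms, "per_driver": per_driver,
            "mean_overlap": mean_overlap}
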