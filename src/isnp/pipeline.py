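"""End-to-end orchestration: annotation -> site calling -> footprints ->
stratification -> enrichment -> expression validation.

Stages run in order, each writing TSV/JSON outputs plus a provenance record
(a hash over the stage's configuration, its input files and the upstream
stage hashes).  A rerun skips any stage whose provenance hash is unchanged
and whose outputs are still present, reloading the outputs from disk; a
changed threshold re-executes only the stages downstream of it.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import annotation as ann
from . import io as iio
from .background import estimate_background
from .enrich import hypergeometric_enrich
from .expression import (binarize_de, de_gene_set, filter_and_normalize,
                         moderated_t, per_patient_fc, validation_1,
                         validation_2, validation_3)
from .mirna import call_mirna_ts
from .network import (NetworkFootprint, build_footprint, first_neighbours,
                      footprints_to_frame, giant_component,
                      girvan_newman_modules, union_network)
from .sites import SiteChange, classify_change
from .stratify import (hamming_matrix, hierarchical_cluster,
                       identify_cluster_drivers, profile_matrix,
                       protein_prevalence, silhouette_by_k)
from .tfbs import call_tfbs_change, fdr_scan, prepare_motifs, scan_window

log = logging.getLogger(__name__)

STAGES = ("sites", "network", "cluster", "enrich", "validate")


@dataclass
class Thresholds:
    tf_pvalue: float = 1e-5
    fimo_fdr: float = 0.1
    mirna_score: float = 90.0
    mirna_energy: float = -16.0
    fc_cutoff: float = 1.0
    enrich_q: float = 0.05
    k_clusters: int = 4
    min_total_counts: int = 10

    def __post_init__(self):
        if not 0 < self.tf_pvalue <= 1 or not 0 < self.fimo_fdr <= 1:
            raise ValueError("p-value / FDR thresholds must be in (0, 1]")
        if self.mirna_energy > 0:
            raise ValueError("energy threshold must be <= 0 kcal/mol")
        if self.k_clusters < 1 or self.min_total_counts < 0:
            raise ValueError("bad clustering / filtering parameters")


@dataclass
class PipelineConfig:
    inputs: dict[str, str]
    thresholds: Thresholds = field(default_factory=Thresholds)
    seed: int = 1
    stages: tuple[str, ...] = STAGES
    linkage: str = "average"

    def __post_init__(self):
        if isinstance(self.thresholds, dict):
            self.thresholds = Thresholds(**self.thresholds)
        bad = [s for s in self.stages if s not in STAGES]
        if bad:
            raise ValueError(f"unknown stages {bad}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        base = Path(path).parent
        inputs = {k: str((base / v)) for k, v in raw.get("inputs", {}).items()}
        return cls(inputs=inputs,
                   thresholds=Thresholds(**raw.get("thresholds", {})),
                   seed=int(raw.get("seed", 1)),
                   stages=tuple(raw.get("stages", STAGES)),
                   linkage=raw.get("linkage", "average"))

    @classmethod
    def for_fixture_dir(cls, fixture_dir, **kwargs) -> "PipelineConfig":
        d = Path(fixture_dir)
        names = {"genome": "genome.fa", "snps_vcf": "snps.vcf",
                 "motifs": "motifs.jaspar", "mirnas": "mirnas.fa",
                 "gene_models": "gene_models.tsv", "enhancers": "enhancers.bed",
                 "enhancer_map": "enhancer_map.tsv", "network": "network.sif",
                 "id_map": "id_map.tsv", "gene_sets": "gene_sets.gmt",
                 "counts": "counts.tsv", "controls": "controls.txt",
                 "background": "background.fa"}
        return cls(inputs={k: str(d / v) for k, v in names.items()}, **kwargs)


def _hash(*parts) -> str:
    h = hashlib.sha256()
    for p in parts:
        h.update(repr(p).encode())
    return h.hexdigest()[:16]


def _file_hash(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


class _Stage:
    """Provenance-hashed cache around one pipeline stage."""

    def __init__(self, name: str, out_dir: Path, stage_hash: str,
                 outputs: list[str]):
        self.name = name
        self.out_dir = out_dir
        self.hash = stage_hash
        self.outputs = [out_dir / o for o in outputs]
        self.prov = out_dir / f"{name}.provenance.json"

    def is_cached(self) -> bool:
        if not self.prov.exists() or not all(o.exists() for o in self.outputs):
            return False
        try:
            return json.loads(self.prov.read_text())["hash"] == self.hash
        except (KeyError, json.JSONDecodeError):
            return False

    def write_provenance(self, config: PipelineConfig) -> None:
        rec = {"stage": self.name, "hash": self.hash, "seed": config.seed,
               "thresholds": vars(config.thresholds)}
        self.prov.write_text(json.dumps(rec, indent=1, sort_keys=True) + "\n")


# --------------------------------------------------------------------------
# site calling

def call_sites_for_snp(window: ann.SNPWindow, annotations, scored_motifs,
                       bg, mirnas: dict[str, str],
                       th: Thresholds) -> list[SiteChange]:
    """All gain/loss/neutral calls for one SNP across its regulatory contexts."""
    anc_hits = scan_window(window.ancestral_seq, scored_motifs, bg,
                           threshold_p=th.tf_pvalue, tag="ancestral")
    var_hits = scan_window(window.variant_seq, scored_motifs, bg,
                           threshold_p=th.tf_pvalue, tag="variant")
    out: list[SiteChange] = []
    seen: set[tuple] = set()
    for a in annotations:
        if a.region_class in ann.TFBS_CONTEXTS:
            for sm in scored_motifs:
                sc = call_tfbs_change(sm.motif.motif_id, anc_hits, var_hits,
                                      window.snp_offset, a)
                if sc is not None:
                    key = (sc.rsid, sc.regulator_id, sc.site_type,
                           sc.target_genes, sc.change)
                    if key not in seen:
                        seen.add(key)
                        out.append(sc)
        if a.region_class in ann.MIRNA_CONTEXTS:
            for sc in call_mirna_ts(mirnas, window.ancestral_seq,
                                    window.variant_seq, window.snp_offset, a,
                                    score_threshold=th.mirna_score,
                                    energy_threshold=th.mirna_energy):
                key = (sc.rsid, sc.regulator_id, sc.site_type,
                       sc.target_genes, sc.change)
                if key not in seen:
                    seen.add(key)
                    out.append(sc)
    return out


def _fdr_support(windows: dict[str, tuple[ann.SNPWindow, int]], scored_motifs,
                 bg, th: Thresholds) -> dict[tuple[str, str], str]:
    """Complementary FDR-mode caller: (rsid, motif) -> would-be classification.

    Reported as provenance next to the primary p-value calls; it does not
    enter the gain/loss decision.
    """
    pool = {}
    for rsid, (w, _) in windows.items():
        pool[f"{rsid}|ancestral"] = w.ancestral_seq
        pool[f"{rsid}|variant"] = w.variant_seq
    hits = fdr_scan(pool, scored_motifs, bg, fdr=th.fimo_fdr)
    presence: dict[tuple[str, str, str], bool] = {}
    offsets = {rsid: w.snp_offset for rsid, (w, _) in windows.items()}
    for h in hits:
        rsid, allele = h.sequence_tag.split("|")
        if h.overlaps(offsets[rsid]):
            presence[(rsid, h.motif_id, allele)] = True
    out = {}
    for rsid in windows:
        for sm in scored_motifs:
            mid = sm.motif.motif_id
            c = classify_change(presence.get((rsid, mid, "ancestral"), False),
                                presence.get((rsid, mid, "variant"), False))
            if c is not None:
                out[(rsid, mid)] = c
    return out


def _site_changes_to_frame(changes: list[SiteChange],
                           fdr_calls: dict[tuple[str, str], str]) -> pd.DataFrame:
    rows = []
    for sc in changes:
        rows.append({
            "rsid": sc.rsid, "regulator": sc.regulator_id, "change": sc.change,
            "site_type": sc.site_type,
            "target_genes": ",".join(sorted(sc.target_genes)),
            "n_evidence": len(sc.evidence),
            "fdr_mode_call": fdr_calls.get((sc.rsid, sc.regulator_id), "none"),
        })
    df = pd.DataFrame(rows, columns=["rsid", "regulator", "change", "site_type",
                                     "target_genes", "n_evidence",
                                     "fdr_mode_call"])
    return df.sort_values(["rsid", "regulator", "site_type"]).reset_index(drop=True)


def _frame_to_site_changes(df: pd.DataFrame) -> list[SiteChange]:
    return [SiteChange(rsid=r.rsid, regulator_id=r.regulator, change=r.change,
                       site_type=r.site_type,
                       target_genes=frozenset(str(r.target_genes).split(","))
                       if pd.notna(r.target_genes) and r.target_genes else
                       frozenset())
            for r in df.itertuples()]


# --------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    inp = config.inputs
    th = config.thresholds
    summary: dict = {"stages_executed": [], "stages_cached": []}

    input_hashes = {k: _file_hash(v) for k, v in sorted(inp.items())
                    if Path(v).exists()}

    # ---- stage: sites ------------------------------------------------------
    sites_stage = _Stage("sites", out, _hash(
        "sites", {k: input_hashes.get(k) for k in
                  ("genome", "snps_vcf", "motifs", "mirnas", "gene_models",
                   "enhancers", "enhancer_map", "background")},
        th.tf_pvalue, th.fimo_fdr, th.mirna_score, th.mirna_energy),
        ["site_changes.tsv"])
    if "sites" not in config.stages:
        site_changes, genotypes = [], None
    elif sites_stage.is_cached():
        summary["stages_cached"].append("sites")
        site_changes = _frame_to_site_changes(
            pd.read_csv(sites_stage.outputs[0], sep="\t"))
    else:
        genome = iio.read_fasta(inp["genome"])
        motif_fmt = "transfac" if inp["motifs"].endswith(
            (".transfac", ".tf")) else "jaspar"
        motifs = iio.read_motifs(inp["motifs"], format=motif_fmt)
        mirnas = iio.read_fasta(inp["mirnas"])
        gene_models = ann.read_gene_models(inp["gene_models"])
        enhancers = iio.read_regions(inp["enhancers"])
        enh_map = iio.read_enhancer_map(inp["enhancer_map"])
        if inp.get("background"):
            bg = estimate_background(iio.read_fasta(inp["background"]).values(),
                                     order=1)
        else:
            bg_seqs = [genome[gm.chrom][gm.promoter().start:gm.promoter().end]
                       for gm in gene_models]
            bg_seqs += [genome[e.chrom][e.start:e.end] for e in enhancers]
            bg = estimate_background(bg_seqs, order=1)
        scored = prepare_motifs(motifs, bg)

        windows: dict[str, tuple[ann.SNPWindow, list]] = {}
        import pysam
        with pysam.VariantFile(inp["snps_vcf"]) as vf:
            for rec in vf:
                if rec.alts is None or len(rec.ref) != 1 or len(rec.alts[0]) != 1:
                    log.warning("skipping non-SNV record %s", rec.id)
                    continue
                w = ann.extract_window(rec.id or f"{rec.chrom}:{rec.pos}",
                                       rec.chrom, rec.pos - 1, rec.ref,
                                       rec.alts[0], genome)
                annots = ann.annotate_regions(w, gene_models, enhancers, enh_map)
                windows[w.rsid] = (w, annots)

        site_changes = []
        for rsid in sorted(windows):
            w, annots = windows[rsid]
            site_changes.extend(
                call_sites_for_snp(w, annots, scored, bg, mirnas, th))
        fdr_calls = _fdr_support(windows, scored, bg, th)
        _site_changes_to_frame(site_changes, fdr_calls).to_csv(
            sites_stage.outputs[0], sep="\t", index=False)
        sites_stage.write_provenance(config)
        summary["stages_executed"].append("sites")
    summary["n_site_changes"] = len(site_changes)
    summary["n_gain_loss"] = sum(1 for s in site_changes if s.propagates)

    # ---- stage: network ----------------------------------------------------
    net_stage = _Stage("network", out, _hash(
        "network", sites_stage.hash,
        input_hashes.get("network"), input_hashes.get("id_map"),
        input_hashes.get("snps_vcf")),
        ["footprints.tsv", "union_network.sif", "modules.tsv"])
    graph = iio.read_network(inp["network"], dialect="sif").graph
    id_map = iio.read_id_map(inp["id_map"])
    genotypes = iio.read_genotypes(inp["snps_vcf"])
    if "network" not in config.stages:
        footprints, giant, modules = [], None, None
    elif net_stage.is_cached():
        summary["stages_cached"].append("network")
        fp_df = pd.read_csv(net_stage.outputs[0], sep="\t")
        by_patient: dict[str, NetworkFootprint] = {}
        for pid in genotypes.index:
            by_patient[pid] = NetworkFootprint(pid, set(), set())
        for r in fp_df.itertuples():
            fp = by_patient[r.patient]
            (fp.direct_proteins if r.role == "direct"
             else fp.neighbour_proteins).add(r.protein)
        footprints = [by_patient[p] for p in genotypes.index]
        union = iio.read_network(net_stage.outputs[1], dialect="sif").graph
        giant = giant_component(union)
        mod_df = pd.read_csv(net_stage.outputs[2], sep="\t")
        modules = None  # partition reloaded lazily if needed
    else:
        footprints = [build_footprint(pid, genotypes.loc[pid], site_changes,
                                      id_map, graph)
                      for pid in genotypes.index]
        union = union_network(footprints, graph)
        giant = giant_component(union)
        modules = girvan_newman_modules(giant)
        footprints_to_frame(footprints).to_csv(net_stage.outputs[0], sep="\t",
                                               index=False)
        iio.write_network(iio.InteractionNetwork(graph=union), net_stage.outputs[1])
        pd.DataFrame(sorted(modules.labels.items()),
                     columns=["protein", "module"]).to_csv(
            net_stage.outputs[2], sep="\t", index=False)
        net_stage.write_provenance(config)
        summary["stages_executed"].append("network")
    if giant is not None:
        summary["union_nodes"] = int(giant.number_of_nodes())
        summary["union_edges"] = int(giant.number_of_edges())
    if modules is not None:
        summary["n_modules"] = modules.n_modules
        summary["modularity"] = modules.modularity

    # ---- stage: cluster ----------------------------------------------------
    cl_stage = _Stage("cluster", out, _hash(
        "cluster", net_stage.hash, th.k_clusters, config.linkage),
        ["profile_matrix.tsv", "cluster_labels.tsv", "dendrogram.nwk",
         "prevalence.tsv", "drivers.tsv"])
    labels = None
    if "cluster" not in config.stages or not footprints:
        profiles = None
    elif cl_stage.is_cached():
        summary["stages_cached"].append("cluster")
        profiles = pd.read_csv(cl_stage.outputs[0], sep="\t", index_col=0)
        labels = pd.read_csv(cl_stage.outputs[1], sep="\t",
                             index_col=0)["cluster"]
    else:
        profiles = profile_matrix(footprints)
        if profiles.shape[1] == 0:
            log.warning("no affected proteins; skipping clustering")
        else:
            dist = hamming_matrix(profiles)
            clustering = hierarchical_cluster(dist, linkage=config.linkage)
            labels = clustering.cut(th.k_clusters)
            prevalence = protein_prevalence(profiles)
            direct = set().union(*[fp.direct_proteins for fp in footprints])
            drivers = identify_cluster_drivers(profiles, labels, graph, direct)
            sil = silhouette_by_k(dist, clustering)
            profiles.to_csv(cl_stage.outputs[0], sep="\t")
            labels.to_frame().to_csv(cl_stage.outputs[1], sep="\t")
            Path(cl_stage.outputs[2]).write_text(clustering.to_newick() + "\n")
            prevalence.rename("n_patients").to_csv(cl_stage.outputs[3], sep="\t")
            drivers.to_csv(cl_stage.outputs[4], sep="\t", index=False)
            (out / "silhouette.tsv").write_text(
                "k\tsilhouette\n" + "".join(f"{k}\t{v:.4f}\n"
                                            for k, v in sil.items()))
            cl_stage.write_provenance(config)
            summary["stages_executed"].append("cluster")
    if labels is not None:
        summary["n_patient_clusters"] = int(labels.nunique())

    # ---- driver gene sets (shared by enrich + validate) -------------------
    driver_sets: dict[str, set[str]] = {}
    if labels is not None and cl_stage.outputs[4].exists():
        drv = pd.read_csv(cl_stage.outputs[4], sep="\t")
        top = drv.sort_values("rank_chi2").head(th.k_clusters + 1)
        for p in top["protein"]:
            if giant is not None and p in giant:
                driver_sets[p] = {p} | first_neighbours(giant, {p})

    # ---- stage: enrich -----------------------------------------------------
    en_stage = _Stage("enrich", out, _hash(
        "enrich", cl_stage.hash, input_hashes.get("gene_sets"), th.enrich_q),
        ["enrichment.tsv"])
    if "enrich" not in config.stages or giant is None or not driver_sets:
        pass
    elif en_stage.is_cached():
        summary["stages_cached"].append("enrich")
    else:
        collection = iio.read_gene_sets(inp["gene_sets"])
        background = set(giant.nodes)
        rows = []
        for driver in sorted(driver_sets):
            for r in hypergeometric_enrich(driver_sets[driver] & background,
                                           collection, background, th.enrich_q):
                rows.append({"driver": driver, "term": r.term_id,
                             "overlap": r.overlap, "term_size": r.term_size,
                             "pvalue": r.pvalue, "qvalue": r.qvalue,
                             "enriched": r.enriched})
        pd.DataFrame(rows).to_csv(en_stage.outputs[0], sep="\t", index=False)
        en_stage.write_provenance(config)
        summary["stages_executed"].append("enrich")

    # ---- stage: validate ---------------------------------------------------
    va_stage = _Stage("validate", out, _hash(
        "validate", cl_stage.hash, input_hashes.get("counts"),
        input_hashes.get("controls"), th.fc_cutoff, th.min_total_counts,
        th.enrich_q),
        ["validation.json"])
    if "validate" not in config.stages or labels is None:
        pass
    elif va_stage.is_cached():
        summary["stages_cached"].append("validate")
        summary["validation"] = json.loads(va_stage.outputs[0].read_text())
    else:
        counts = iio.read_counts(inp["counts"])
        controls = Path(inp["controls"]).read_text().split()
        normed = filter_and_normalize(counts, min_total=th.min_total_counts)
        fc = per_patient_fc(normed, controls)
        de = binarize_de(fc, cutoff=th.fc_cutoff, control_ids=controls)
        snp_genes = sorted({id_map.get(g, g) for sc in site_changes
                            if sc.propagates for g in sc.target_genes})
        v1 = validation_1(de, [g for g in snp_genes if g in de.flags.index]
                          or snp_genes)
        v2 = validation_2(de, driver_sets, labels, k=th.k_clusters,
                          linkage=config.linkage) if driver_sets else {
                              "ari": float("nan")}
        cases = [c for c in normed.columns if c not in set(controls)]
        mt = moderated_t(normed, cases, controls)
        de_set = de_gene_set(mt, fc_cutoff=th.fc_cutoff, q_threshold=0.05)
        collection = iio.read_gene_sets(inp["gene_sets"])
        background = set(giant.nodes) if giant is not None else set(normed.index)
        v3 = validation_3(de_set, driver_sets, collection, background,
                          q_threshold=th.enrich_q) if driver_sets else {
                              "mean_overlap": float("nan")}
        report = {
            "validation_1": {"mean_percent": v1["mean_percent"],
                             "sd_percent": v1["sd_percent"],
                             "per_gene_percent": {
                                 g: float(v) for g, v in
                                 v1["per_gene_percent"].items()},
                             "missing_genes": v1["missing_genes"]},
            "validation_2": {"ari": (None if pd.isna(v2["ari"])
                                     else float(v2["ari"]))},
            "validation_3": {"mean_overlap": (
                None if pd.isna(v3["mean_overlap"])
                else float(v3["mean_overlap"])),
                "n_de_genes": len(de_set)},
        }
        va_stage.outputs[0].write_text(
            json.dumps(report, indent=1, sort_keys=True) + "\n")
        va_stage.write_provenance(config)
        summary["stages_executed"].append("validate")
        summary["validation"] = report

    (out / "summary.json").write_text(
        json.dumps(summary, indent=1, sort_keys=True, default=str) + "\n")
    return summary
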