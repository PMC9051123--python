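"""Patient network footprints and disease-network module detection.

A patient's footprint is the set of proteins encoded by the genes whose
regulation is changed by a SNP the patient carries (gains and losses only;
neutral changes do not propagate), expanded with the proteins' first
neighbours in the interaction network.  The union of all footprints induces
the disease-associated network; analysis is restricted to its giant
component, which is decomposed into modules by Girvan-Newman edge-betweenness
clustering with the partition of maximum Newman modularity retained.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .sites import SiteChange

log = logging.getLogger(__name__)


@dataclass
class NetworkFootprint:
    patient_id: str
    direct_proteins: set[str]
    neighbour_proteins: set[str]

    @property
    def affected(self) -> set[str]:
        return self.direct_proteins | self.neighbour_proteins


@dataclass
class ModulePartition:
    labels: dict[str, int]  # node -> module label
    modularity: float
    n_modules: int = field(init=False)

    def __post_init__(self):
        self.n_modules = len(set(self.labels.values()))

    def modules(self) -> list[set[str]]:
        out: dict[int, set[str]] = {}
        for node, lab in self.labels.items():
            out.setdefault(lab, set()).add(node)
        return [out[k] for k in sorted(out)]


def snp_affected_proteins(carrier_row: pd.Series, site_changes: list[SiteChange],
                          id_map: dict[str, str], network_nodes: set[str],
                          dropped: set[str] | None = None) -> set[str]:
    """Proteins directly affected for one patient.

    ``carrier_row`` maps rsid -> carrier status (missing treated as
    non-carrier).  Target genes of gain/loss changes of carried SNPs are
    mapped to proteins; genes whose protein is absent from the network are
    dropped (collected into ``dropped`` when given).
    """
    out: set[str] = set()
    for sc in site_changes:
        if not sc.propagates:
            continue
        carried = carrier_row.get(sc.rsid)
        if carried is None or pd.isna(carried) or not bool(carried):
            continue  # non-carrier, or missing genotype treated conservatively
        for gene in sc.target_genes:
            prot = id_map.get(gene, gene)
            if prot in network_nodes:
                out.add(prot)
            elif dropped is not None:
                dropped.add(gene)
    return out


def first_neighbours(graph: nx.Graph, proteins: set[str]) -> set[str]:
    """All nodes adjacent to the seed set, excluding the seeds themselves."""
    present = proteins & set(graph.nodes)
    if len(present) < len(proteins):
        log.warning("%d seed proteins absent from the network",
                    len(proteins) - len(present))
    out: set[str] = set()
    for p in present:
        out.update(graph.neighbors(p))
    return out - proteins


def build_footprint(patient_id: str, carrier_row: pd.Series,
                    site_changes: list[SiteChange], id_map: dict[str, str],
                    graph: nx.Graph) -> NetworkFootprint:
    direct = snp_affected_proteins(carrier_row, site_changes, id_map,
                                   set(graph.nodes))
    return NetworkFootprint(patient_id=patient_id, direct_proteins=direct,
                            neighbour_proteins=first_neighbours(graph, direct))


def union_network(footprints: list[NetworkFootprint],
                  graph: nx.Graph) -> nx.Graph:
    """Subgraph induced by the union of all patients' affected sets."""
    if not footprints:
        raise ValueError("need at least one footprint")
    nodes: set[str] = set()
    for fp in footprints:
        nodes |= fp.affected
    if not nodes:
        log.warning("union of footprints is empty")
    return graph.subgraph(nodes & set(graph.nodes)).copy()


def giant_component(graph: nx.Graph) -> nx.Graph:
    """Largest connected component; ties broken by smallest member node ID."""
    if graph.number_of_nodes() == 0:
        return graph.copy()
    comps = sorted(nx.connected_components(graph),
                   key=lambda c: (-len(c), min(c)))
    return graph.subgraph(comps[0]).copy()


def _highest_betweenness_edge(graph: nx.Graph) -> tuple[str, str]:
    eb = nx.edge_betweenness_centrality(graph)
    best = max(eb.items(),
               key=lambda kv: (kv[1], tuple(sorted(kv[0], reverse=True))))
    # among maximal-betweenness edges pick the lexicographically smallest
    top = max(eb.values())
    cands = [tuple(sorted(e)) for e, v in eb.items() if abs(v - top) < 1e-12]
    return min(cands)


def girvan_newman_modules(graph: nx.Graph, stop: str = "max_modularity",
                          target_k: int | None = None) -> ModulePartition:
    """Girvan-Newman community detection with deterministic tie-breaks.

    Edges of highest betweenness are removed one at a time (lexicographically
    smallest edge on ties); connected components along the removal sequence
    form candidate partitions.  With ``stop='max_modularity'`` the partition
    maximizing Newman modularity on the original graph is returned; with
    ``stop='target_k'`` the first partition with >= target_k components.
    """
    if graph.number_of_nodes() < 3:
        labels = {n: 0 for n in graph.nodes}
        mod = (nx.community.modularity(graph, [set(graph.nodes)])
               if graph.number_of_edges() else 0.0)
        return ModulePartition(labels=labels, modularity=mod)

    def partition_labels(g) -> list[set[str]]:
        return sorted(nx.connected_components(g), key=min)

    work = graph.copy()
    best_parts = partition_labels(work)
    best_mod = nx.community.modularity(graph, best_parts)
    while work.number_of_edges() > 0:
        u, v = _highest_betweenness_edge(work)
        work.remove_edge(u, v)
        parts = partition_labels(work)
        if stop == "target_k" and target_k is not None:
            if len(parts) >= target_k:
                best_parts = parts
                best_mod = nx.community.modularity(graph, parts)
                break
            continue
        mod = nx.community.modularity(graph, parts)
        if mod > best_mod + 1e-12:
            best_mod, best_parts = mod, parts
    labels = {}
    for i, part in enumerate(sorted(best_parts, key=min)):
        for n in part:
            labels[n] = i
    return ModulePartition(labels=labels, modularity=best_mod)


def footprints_to_frame(footprints: list[NetworkFootprint]) -> pd.DataFrame:
    """Long-format table: patient, protein, role (direct|neighbour)."""
    rows = []
    for fp in footprints:
        for p in sorted(fp.direct_proteins):
            rows.append((fp.patient_id, p, "direct"))
        for p in sorted(fp.neighbour_proteins):
            rows.append((fp.patient_id, p, "neighbour"))
    return pd.DataFrame(rows, columns=["patient", "protein", "role"])
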