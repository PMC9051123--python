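"""Patient stratification from binary network-footprint profiles.

Patients are described by a binary patients x proteins matrix (1 = the
protein is directly or indirectly affected in that patient), compared with
the normalized Hamming distance and clustered by average-linkage (UPGMA)
agglomeration.  Partitions are compared with the adjusted Rand index.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.stats import chi2_contingency
from sklearn.metrics import adjusted_rand_score, silhouette_score

from .network import NetworkFootprint


def profile_matrix(footprints: list[NetworkFootprint],
                   proteins: list[str] | None = None) -> pd.DataFrame:
    """Binary patients x proteins matrix from footprints.

    By default the protein universe is the union of all affected sets
    (columns with at least one 1), sorted; pass ``proteins`` to fix it.
    """
    if proteins is None:
        universe: set[str] = set()
        for fp in footprints:
            universe |= fp.affected
        proteins = sorted(universe)
    data = np.zeros((len(footprints), len(proteins)), dtype=int)
    col = {p: j for j, p in enumerate(proteins)}
    for i, fp in enumerate(footprints):
        for p in fp.affected:
            if p in col:
                data[i, col[p]] = 1
    return pd.DataFrame(data, index=[fp.patient_id for fp in footprints],
                        columns=proteins)


def hamming_matrix(profiles: pd.DataFrame) -> pd.DataFrame:
    """Pairwise normalized Hamming distances between patients."""
    if len(profiles) < 2:
        raise ValueError("need at least two patients")
    x = profiles.values.astype(bool)
    d = (x[:, None, :] != x[None, :, :]).mean(axis=2)
    return pd.DataFrame(d, index=profiles.index, columns=profiles.index)


class PatientClustering:
    """Average-linkage tree over patients; cut at any k."""

    def __init__(self, distances: pd.DataFrame, linkage: str = "average"):
        self.patients = list(distances.index)
        condensed = squareform(distances.values, checks=False)
        self.linkage_matrix = hierarchy.linkage(condensed, method=linkage)

    def cut(self, k: int) -> pd.Series:
        if not 1 <= k <= len(self.patients):
            raise ValueError(f"k={k} outside 1..{len(self.patients)}")
        labels = hierarchy.fcluster(self.linkage_matrix, t=k, criterion="maxclust")
        return pd.Series(labels, index=self.patients, name="cluster")

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage_matrix)

        def walk(node):
            if node.is_leaf():
                return self.patients[node.id]
            return (f"({walk(node.left)}:{node.dist - node.left.dist:.6g},"
                    f"{walk(node.right)}:{node.dist - node.right.dist:.6g})")

        return walk(tree) + ";"


def hierarchical_cluster(distances: pd.DataFrame,
                         linkage: str = "average") -> PatientClustering:
    return PatientClustering(distances, linkage=linkage)


def adjusted_rand_index(labels_a, labels_b) -> float:
    a, b = np.asarray(labels_a), np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValueError("label vectors differ in length")
    return float(adjusted_rand_score(a, b))


def silhouette_by_k(distances: pd.DataFrame, clustering: PatientClustering,
                    ks=range(2, 9)) -> dict[int, float]:
    """Silhouette width of the dendrogram cut at each k (precomputed distances)."""
    out = {}
    for k in ks:
        labels = clustering.cut(k).values
        if len(set(labels)) < 2 or len(set(labels)) >= len(labels):
            out[k] = float("nan")
            continue
        out[k] = float(silhouette_score(distances.values, labels,
                                        metric="precomputed"))
    return out


def protein_prevalence(profiles: pd.DataFrame) -> pd.Series:
    """Number of patients in which each protein is affected."""
    return profiles.sum(axis=0).sort_values(ascending=False)


def threshold_sets(prevalence: pd.Series, high: int,
                   low: int) -> tuple[set[str], set[str]]:
    """(commonly affected, rarely affected) protein sets: count > high / <= low."""
    common = set(prevalence.index[prevalence > high])
    rare = set(prevalence.index[prevalence <= low])
    return common, rare


def identify_cluster_drivers(profiles: pd.DataFrame, labels: pd.Series,
                             graph, direct_proteins: set[str]) -> pd.DataFrame:
    """Rank directly SNP-affected proteins as candidate cluster drivers.

    Two descriptive rankings are reported: interaction-network degree, and
    the chi-square statistic (no continuity correction) of the protein's
    presence/absence pattern against the cluster labels.
    """
    rows = []
    lab = labels.reindex(profiles.index).values
    for p in sorted(direct_proteins):
        if p not in profiles.columns:
            continue
        col = profiles[p].values
        degree = graph.degree(p) if p in graph else 0
        tab = pd.crosstab(col, lab)
        if tab.shape[0] < 2:  # constant column: no association
            chi2 = 0.0
        else:
            chi2 = float(chi2_contingency(tab.values, correction=False)[0])
        rows.append((p, degree, chi2, int(col.sum())))
    df = pd.DataFrame(rows, columns=["protein", "degree", "chi2", "n_patients"])
    df["rank_degree"] = df["degree"].rank(ascending=False, method="min").astype(int)
    df["rank_chi2"] = df["chi2"].rank(ascending=False, method="min").astype(int)
    return df.sort_values(["rank_chi2", "rank_degree", "protein"]).reset_index(drop=True)
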