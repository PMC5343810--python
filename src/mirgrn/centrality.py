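"""Degree-centrality analysis: hub binning and the miRNA-protein coupling.

The workflow mirrors the hub-regulation question: do miRNAs with many
targets preferentially regulate proteins that are themselves hubs?
Proteins are ranked by degree in the (large) gene-gene network and cut
into consecutive clusters of fixed size (50 proteins per cluster by
default; cluster 1 holds the top-degree proteins).  Each cluster is then
summarized by its mean protein degree and by the mean degree of the
miRNAs regulating its proteins in the enriched network, and the Pearson
correlation across clusters quantifies the coupling.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .errors import MirgrnError, ParameterError
from .netcore import GeneNetwork, MirnaGRN, Network

__all__ = ["CentralityProfile", "CentralityCorrelation", "degree_centrality",
           "bin_by_centrality", "centrality_correlation", "top_mirna_table"]


def degree_centrality(net: Network) -> dict[str, int]:
    """Degree of every node, counting both edge classes.

    A miRNA's degree is its number of distinct target genes; a gene's
    degree counts gene-gene neighbours plus regulating miRNAs.
    """
    return dict(net.graph.degree())


@dataclass
class CentralityProfile:
    """Node degrees plus fixed-size descending-centrality cluster labels.

    Nodes are sorted by decreasing degree (ties by node id) and cut into
    consecutive blocks of ``cluster_size``; cluster 1 contains the
    maximum-degree node and the last block may be smaller.
    """

    degrees: dict[str, int]
    clusters: dict[str, int]
    cluster_size: int

    @property
    def n_clusters(self) -> int:
        return max(self.clusters.values(), default=0)

    def members(self, cluster: int) -> set[str]:
        return {n for n, c in self.clusters.items() if c == cluster}


def bin_by_centrality(degrees: Mapping[str, int],
                      cluster_size: int = 50) -> CentralityProfile:
    """Cut nodes into descending-degree clusters of ``cluster_size``."""
    if cluster_size < 1:
        raise ParameterError("cluster_size must be >= 1")
    order = sorted(degrees, key=lambda n: (-degrees[n], n))
    clusters = {n: i // cluster_size + 1 for i, n in enumerate(order)}
    return CentralityProfile(degrees=dict(degrees), clusters=clusters,
                             cluster_size=cluster_size)


@dataclass
class CentralityCorrelation:
    """Cluster-level coupling between protein and regulator-miRNA centrality.

    ``r`` is the Pearson correlation between a cluster's mean protein
    degree and the mean degree of the miRNAs regulating its proteins,
    over clusters containing at least one regulated protein.
    ``per_cluster`` carries the underlying table.
    """

    r: float
    per_cluster: pd.DataFrame


def centrality_correlation(grn: MirnaGRN,
                           gene_net: Optional[GeneNetwork] = None,
                           cluster_size: int = 50) -> CentralityCorrelation:
    """Correlate protein hubness with regulator-miRNA hubness.

    Proteins are binned on their degree in the gene-gene network
    (``gene_net`` when given — typically the full association network the
    enrichment started from — else the gene-gene layer of ``grn``);
    miRNA degrees are distinct-target counts in the enriched ``grn``.
    Per cluster, each regulated protein contributes the mean degree of
    its regulators, and those contributions are averaged.
    """
    if not grn.mirna_edges:
        raise MirgrnError("network has no miRNA edges; nothing to correlate")
    base = gene_net if gene_net is not None else grn.gene_subnetwork()
    profile = bin_by_centrality(base.degrees(), cluster_size=cluster_size)
    mirna_deg = {m: len(grn.targets_of(m)) for m in grn.mirna_nodes}

    rows = []
    for cid in range(1, profile.n_clusters + 1):
        members = profile.members(cid)
        reg_means = []
        for gene in members:
            if gene in grn.gene_nodes:
                regs = grn.regulators_of(gene)
                if regs:
                    reg_means.append(float(np.mean([mirna_deg[m] for m in regs])))
        rows.append({
            "cluster": cid,
            "mean_protein_degree": float(np.mean([profile.degrees[n]
                                                  for n in members])),
            "mean_regulator_degree": (float(np.mean(reg_means))
                                      if reg_means else np.nan),
            "n_regulated": len(reg_means),
        })
    table = pd.DataFrame(rows, columns=["cluster", "mean_protein_degree",
                                        "mean_regulator_degree", "n_regulated"])
    usable = table[table["n_regulated"] >= 1]
    if len(usable) < 2:
        raise MirgrnError("fewer than 2 clusters contain regulated proteins; "
                          "correlation undefined")
    x = usable["mean_protein_degree"].to_numpy()
    y = usable["mean_regulator_degree"].to_numpy()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise MirgrnError("zero variance across clusters; correlation undefined")
    r = float(stats.pearsonr(x, y).statistic)
    return CentralityCorrelation(r=r, per_cluster=table)


def top_mirna_table(grn: MirnaGRN,
                    gene_net: Optional[GeneNetwork] = None,
                    cluster_size: int = 50,
                    top_m: int = 10) -> pd.DataFrame:
    """Top-m miRNAs by degree with their targets in the top protein cluster.

    One row per top miRNA: its degree and the subset of its targets that
    fall in cluster 1 (the highest-centrality proteins), each with that
    protein's degree — the hub-regulator summary table.  Proteins are
    ranked on ``gene_net`` degrees when given; otherwise on their
    combined degree in ``grn`` (gene-gene neighbours plus regulators).
    """
    if top_m < 1:
        raise ParameterError("top_m must be >= 1")
    if gene_net is not None:
        gene_degrees = gene_net.degrees()
    else:
        gene_degrees = {g: grn.degree(g) for g in grn.gene_nodes}
    profile = bin_by_centrality(gene_degrees, cluster_size=cluster_size)
    cluster1 = profile.members(1)
    mirna_deg = {m: len(grn.targets_of(m)) for m in grn.mirna_nodes}
    top = sorted(mirna_deg, key=lambda m: (-mirna_deg[m], m))[:top_m]
    rows = []
    for m in top:
        hub_targets = sorted(grn.targets_of(m) & cluster1,
                             key=lambda g: (-profile.degrees[g], g))
        rows.append({
            "mirna": m,
            "mirna_degree": mirna_deg[m],
            "hub_targets": ";".join(hub_targets),
            "hub_target_degrees": ";".join(str(profile.degrees[g])
                                           for g in hub_targets),
        })
    return pd.DataFrame(rows, columns=["mirna", "mirna_degree",
                                       "hub_targets", "hub_target_degrees"])
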