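"""Biomarker-driven interaction selection on a miRNA-GRN.

Given a set of biomarkers of interest (BIs — genes, miRNAs, or both),
four selections are offered: direct edges touching any BI, direct edges
between BIs only, the distance-<=2 neighbourhood around the BIs (as an
induced subgraph), and a degree filter keeping BIs with more direct
neighbours than a cut-off.  BIs absent from the network are ignored with
a warning, since BI lists typically come from external literature.
"""
from __future__ import annotations

import logging
from typing import Iterable

import networkx as nx

from .errors import ParameterError
from .netcore import MIRNA_GENE, MirnaGRN

__all__ = ["select_direct_any", "select_direct_only",
           "select_direct_indirect", "filter_by_degree"]

logger = logging.getLogger(__name__)


def _present(grn: MirnaGRN, bis: Iterable[str]) -> set[str]:
    bis = set(bis)
    if not bis:
        raise ParameterError("biomarker set must be non-empty")
    present = bis & grn.nodes
    if not present:
        logger.warning("no biomarker of interest occurs in the network")
    elif len(present) < len(bis):
        logger.warning("%d biomarker(s) absent from the network ignored",
                       len(bis) - len(present))
    return present


def _from_edges(grn: MirnaGRN, edges: list[tuple[str, str]]) -> MirnaGRN:
    """Build a MirnaGRN from a subset of grn's edges (nodes = endpoints)."""
    gene_edges = []
    mirna_edges = []
    prov = {}
    for u, v in edges:
        if grn.graph.edges[u, v].get("edge_class") == MIRNA_GENE:
            m, t = (u, v) if u in grn.mirna_nodes else (v, u)
            mirna_edges.append((m, t))
            prov[(m, t)] = grn.sources_of(m, t)
        else:
            gene_edges.append((u, v, grn.gene_weight(u, v)))
    return MirnaGRN(gene_edges=gene_edges, mirna_edges=mirna_edges,
                    provenance=prov, organism=grn.organism)


def select_direct_any(grn: MirnaGRN, bis: set[str]) -> MirnaGRN:
    """Edges (either class) with at least one endpoint among the BIs."""
    present = _present(grn, bis)
    edges = [(u, v) for u, v in grn.graph.edges()
             if u in present or v in present]
    return _from_edges(grn, edges)


def select_direct_only(grn: MirnaGRN, bis: set[str]) -> MirnaGRN:
    """Edges with both endpoints among the BIs."""
    present = _present(grn, bis)
    edges = [(u, v) for u, v in grn.graph.edges()
             if u in present and v in present]
    return _from_edges(grn, edges)


def select_direct_indirect(grn: MirnaGRN, bis: set[str],
                           max_dist: int = 2) -> MirnaGRN:
    """Induced subgraph on all nodes within distance ``max_dist`` of a BI.

    Distances are undirected over the union of both edge classes;
    "indirect" defaults to two hops.
    """
    if max_dist < 0:
        raise ParameterError("max_dist must be >= 0")
    present = _present(grn, bis)
    reachable: set[str] = set()
    for bi in present:
        lengths = nx.single_source_shortest_path_length(grn.graph, bi,
                                                        cutoff=max_dist)
        reachable.update(lengths)
    if not reachable:
        return MirnaGRN()
    return grn.induced(reachable)


def filter_by_degree(grn: MirnaGRN, bis: set[str], cutoff: int) -> set[str]:
    """BIs whose number of direct neighbours is strictly above ``cutoff``."""
    if cutoff < 0:
        raise ParameterError("cutoff must be >= 0")
    present = _present(grn, bis)
    return {b for b in present if grn.degree(b) > cutoff}
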