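"""Network containers: plain gene networks and heterogeneous miRNA-GRNs.

A ``GeneNetwork`` is an undirected simple graph over gene/protein symbols.
A ``MirnaGRN`` overlays directed miRNA->gene targeting edges onto such a
graph; the two node namespaces must stay disjoint, and every miRNA must
keep at least one target edge.  Degree is defined uniformly across both
edge classes: a miRNA's degree is its number of distinct target genes and
a gene's degree counts gene-gene neighbours plus regulating miRNAs, so
the centrality analyses get one number per node.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence, Union

import networkx as nx
import pandas as pd

from .errors import ConsistencyError, MembershipError

logger = logging.getLogger(__name__)

GENE_GENE = "gene_gene"
MIRNA_GENE = "mirna_gene"

EdgeLike = Union[tuple[str, str], tuple[str, str, Optional[float]]]


def _canon(a: str, b: str) -> tuple[str, str]:
    """Canonical unordered-pair representation of a gene-gene edge."""
    return (a, b) if a <= b else (b, a)


class GeneNetwork:
    """Undirected simple graph of gene/protein association edges."""

    def __init__(self, graph: Optional[nx.Graph] = None,
                 network_type: str = "physical",
                 organism: str = "homo_sapiens"):
        g = nx.Graph() if graph is None else graph
        if any(u == v for u, v in g.edges()):
            raise ConsistencyError("gene network contains a self-loop")
        self._g = g
        self.network_type = network_type
        self.organism = organism

    @classmethod
    def from_edges(cls, edges: Iterable[EdgeLike],
                   nodes: Iterable[str] = (),
                   network_type: str = "physical",
                   organism: str = "homo_sapiens") -> "GeneNetwork":
        g = nx.Graph()
        g.add_nodes_from(nodes)
        for edge in edges:
            a, b = edge[0], edge[1]
            w = edge[2] if len(edge) > 2 else None
            if a == b:
                raise ConsistencyError(f"self-loop on {a!r}")
            if w is None:
                g.add_edge(a, b)
            else:
                g.add_edge(a, b, weight=float(w))
        return cls(g, network_type=network_type, organism=organism)

    @property
    def graph(self) -> nx.Graph:
        return self._g

    @property
    def nodes(self) -> set[str]:
        return set(self._g.nodes())

    @property
    def edges(self) -> set[tuple[str, str]]:
        return {_canon(u, v) for u, v in self._g.edges()}

    def weight(self, a: str, b: str) -> Optional[float]:
        return self._g.edges[a, b].get("weight")

    def degree(self, node: str) -> int:
        return self._g.degree(node)

    def degrees(self) -> dict[str, int]:
        return dict(self._g.degree())

    @property
    def n_nodes(self) -> int:
        return self._g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (f"GeneNetwork({self.n_nodes} nodes, {self.n_edges} edges, "
                f"type={self.network_type})")


class MirnaGRN:
    """Heterogeneous miRNA-gene regulatory network.

    Internally one undirected simple ``networkx`` graph; node attribute
    ``node_class`` distinguishes genes from miRNAs and edge attribute
    ``edge_class`` distinguishes gene-gene association edges from
    miRNA->gene targeting edges (whose direction is implied by the node
    classes).  Per-edge ``sources`` tuples carry targeting provenance.
    """

    def __init__(self,
                 gene_edges: Iterable[EdgeLike] = (),
                 mirna_edges: Iterable[tuple[str, str]] = (),
                 gene_nodes: Iterable[str] = (),
                 provenance: Optional[Mapping[tuple[str, str], Iterable[str]]] = None,
                 organism: str = "homo_sapiens"):
        g = nx.Graph()
        provenance = provenance or {}
        gene_set: set[str] = set(gene_nodes)
        gedges: list[tuple[str, str, Optional[float]]] = []
        for edge in gene_edges:
            a, b = edge[0], edge[1]
            w = edge[2] if len(edge) > 2 else None
            if a == b:
                raise ConsistencyError(f"self-loop on gene {a!r}")
            gene_set.update((a, b))
            gedges.append((a, b, w))
        medges = [(m, t) for m, t in mirna_edges]
        mirna_set = {m for m, _ in medges}
        gene_set.update(t for _, t in medges)  # auto-register target genes

        collision = mirna_set & gene_set
        if collision:
            raise ConsistencyError(
                f"identifiers used as both gene and miRNA: {sorted(collision)[:5]}")

        g.add_nodes_from(gene_set, node_class="gene")
        g.add_nodes_from(mirna_set, node_class="mirna")
        for a, b, w in gedges:
            if w is None:
                g.add_edge(a, b, edge_class=GENE_GENE)
            else:
                g.add_edge(a, b, edge_class=GENE_GENE, weight=float(w))
        for m, t in medges:
            sources = tuple(sorted(provenance.get((m, t), ())))
            g.add_edge(m, t, edge_class=MIRNA_GENE, sources=sources)

        self._g = g
        self.organism = organism
        self._check()

    def _check(self) -> None:
        for n in self.mirna_nodes:
            if self._g.degree(n) == 0:
                raise ConsistencyError(f"isolated miRNA node {n!r}")

    # -- accessors ---------------------------------------------------------

    @property
    def graph(self) -> nx.Graph:
        return self._g

    @property
    def gene_nodes(self) -> set[str]:
        return {n for n, c in self._g.nodes(data="node_class") if c == "gene"}

    @property
    def mirna_nodes(self) -> set[str]:
        return {n for n, c in self._g.nodes(data="node_class") if c == "mirna"}

    @property
    def nodes(self) -> set[str]:
        return set(self._g.nodes())

    @property
    def gene_edges(self) -> set[tuple[str, str]]:
        return {_canon(u, v) for u, v, c in self._g.edges(data="edge_class")
                if c == GENE_GENE}

    @property
    def mirna_edges(self) -> set[tuple[str, str]]:
        out = set()
        for u, v, c in self._g.edges(data="edge_class"):
            if c == MIRNA_GENE:
                m, t = (u, v) if self._g.nodes[u]["node_class"] == "mirna" else (v, u)
                out.add((m, t))
        return out

    def sources_of(self, mirna: str, gene: str) -> tuple[str, ...]:
        return self._g.edges[mirna, gene].get("sources", ())

    @property
    def provenance(self) -> dict[tuple[str, str], tuple[str, ...]]:
        return {(m, t): self.sources_of(m, t) for m, t in self.mirna_edges}

    def gene_weight(self, a: str, b: str) -> Optional[float]:
        return self._g.edges[a, b].get("weight")

    def degree(self, node: str) -> int:
        return self._g.degree(node)

    def degrees(self) -> dict[str, int]:
        return dict(self._g.degree())

    def targets_of(self, mirna: str) -> set[str]:
        return {v for v in self._g.neighbors(mirna)}

    def regulators_of(self, gene: str) -> set[str]:
        return {v for v in self._g.neighbors(gene)
                if self._g.nodes[v]["node_class"] == "mirna"}

    @property
    def n_nodes(self) -> int:
        return self._g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    # -- derived networks --------------------------------------------------

    def gene_subnetwork(self) -> GeneNetwork:
        """The gene-gene layer as a plain GeneNetwork (all gene nodes kept)."""
        g = nx.Graph()
        g.add_nodes_from(self.gene_nodes)
        for a, b in self.gene_edges:
            data = {k: v for k, v in self._g.edges[a, b].items() if k == "weight"}
            g.add_edge(a, b, **data)
        return GeneNetwork(g, organism=self.organism)

    def induced(self, members: Iterable[str]) -> "MirnaGRN":
        """Induced subgraph on ``members``.

        Gene members are kept even when isolated; miRNA members that lose
        all their target edges are dropped (with a log line) to preserve
        the no-isolated-miRNA invariant.
        """
        members = set(members)
        missing = members - self.nodes
        if missing:
            raise MembershipError(f"nodes not in network: {sorted(missing)[:5]}")
        gene_m = members & self.gene_nodes
        gene_e = [(a, b, self.gene_weight(a, b)) for a, b in self.gene_edges
                  if a in members and b in members]
        mirna_e = [(m, t) for m, t in self.mirna_edges
                   if m in members and t in members]
        kept_mirnas = {m for m, _ in mirna_e}
        dropped = (members & self.mirna_nodes) - kept_mirnas
        if dropped:
            logger.info("induced subgraph dropped %d isolated miRNA(s)", len(dropped))
        prov = {(m, t): self.sources_of(m, t) for m, t in mirna_e}
        return MirnaGRN(gene_edges=gene_e, mirna_edges=mirna_e,
                        gene_nodes=gene_m, provenance=prov,
                        organism=self.organism)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (f"MirnaGRN({len(self.mirna_nodes)} miRNAs, "
                f"{len(self.gene_nodes)} genes, {self.n_edges} edges)")


Network = Union[GeneNetwork, MirnaGRN]


@dataclass(frozen=True)
class NetworkSummary:
    """Node/edge/miRNA tallies reported for every network."""

    n_nodes: int
    n_edges: int
    n_mirnas: int
    n_genes: int

    def __post_init__(self) -> None:
        if self.n_nodes != self.n_mirnas + self.n_genes:
            raise ConsistencyError("n_nodes must equal n_mirnas + n_genes")
        if min(self.n_nodes, self.n_edges, self.n_mirnas, self.n_genes) < 0:
            raise ConsistencyError("negative count in network summary")


def summarize(net: Network) -> NetworkSummary:
    """Count nodes, edges, miRNAs and genes of a network."""
    if isinstance(net, MirnaGRN):
        n_mirnas = len(net.mirna_nodes)
        n_genes = len(net.gene_nodes)
    else:
        n_mirnas = 0
        n_genes = net.n_nodes
    return NetworkSummary(n_nodes=net.n_nodes, n_edges=net.n_edges,
                          n_mirnas=n_mirnas, n_genes=n_genes)


def degree_distribution(net: Network) -> dict[int, int]:
    """Map each observed degree to the number of nodes having it.

    Degree counts all incident edges regardless of class; miRNA->gene
    direction is ignored.
    """
    dist: dict[int, int] = {}
    for _, d in net.graph.degree():
        dist[d] = dist.get(d, 0) + 1
    return dist


def cumulative_degree_distribution(net: Network) -> list[tuple[int, int]]:
    """(degree, number of nodes with degree <= that value), ascending.

    The count sequence is monotone non-decreasing and ends at n_nodes.
    """
    dist = degree_distribution(net)
    out: list[tuple[int, int]] = []
    running = 0
    for d in sorted(dist):
        running += dist[d]
        out.append((d, running))
    return out


def community_adjacency(net: Network, members: Sequence[str]) -> pd.DataFrame:
    """0/1 adjacency matrix over ``members`` (sorted), any edge class.

    miRNA->gene edges are symmetrized for display; the diagonal is zero.
    """
    members = sorted(set(members))
    missing = set(members) - set(net.graph.nodes())
    if missing:
        raise MembershipError(f"members not in network: {sorted(missing)[:5]}")
    mat = pd.DataFrame(0, index=members, columns=members, dtype=int)
    for i, u in enumerate(members):
        for v in members[i + 1:]:
            if net.graph.has_edge(u, v):
                mat.loc[u, v] = 1
                mat.loc[v, u] = 1
    return mat
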