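"""Community detection and characterization on miRNA-GRNs.

Both edge classes are treated as one undirected, unweighted graph for
clustering.  Two modularity-maximizing methods are offered: the
Clauset-Newman-Moore greedy agglomeration (``fast_greedy``, the default)
and Louvain.  Detected partitions always carry the Newman-Girvan
modularity of the assignment, recomputed in-package:

    Q = sum_c [ L_c / m  -  (d_c / 2m)^2 ]

with m the total edge count, L_c the intra-community edge count and d_c
the community degree sum.  Community ids are consecutive integers from 1,
ordered by decreasing size (ties by smallest member id), so the largest
community is always id 1.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import networkx as nx
import pandas as pd

from .errors import ConsistencyError, ParameterError
from .netcore import MirnaGRN, Network

__all__ = ["CommunityPartition", "modularity_score", "detect_communities",
           "community_sizes", "community_of", "extract_community",
           "largest_community_id", "ABSENT"]

#: Marker returned by community_of for biomarkers absent from the network.
ABSENT = "absent"

METHODS = ("fast_greedy", "louvain")


@dataclass
class CommunityPartition:
    """A disjoint node -> community assignment with its modularity.

    ``assignment`` maps every network node to a community id; ids are the
    consecutive integers 1..k; ``modularity`` is the Newman-Girvan score
    of the assignment on the clustered (unweighted, undirected) graph.
    """

    assignment: dict[str, int]
    modularity: float
    method: str
    seed: int

    @property
    def n_communities(self) -> int:
        return max(self.assignment.values(), default=0)

    def members(self, community_id: int) -> set[str]:
        return {n for n, c in self.assignment.items() if c == community_id}

    def communities(self) -> list[set[str]]:
        out: list[set[str]] = [set() for _ in range(self.n_communities)]
        for n, c in self.assignment.items():
            out[c - 1].add(n)
        return out


def modularity_score(graph: nx.Graph, communities: Sequence[Iterable[str]]) -> float:
    """Newman-Girvan modularity of a partition on an unweighted graph.

    Returns 0.0 for an edgeless graph, where modularity is otherwise
    undefined.
    """
    m = graph.number_of_edges()
    if m == 0:
        return 0.0
    degree = dict(graph.degree())
    q = 0.0
    for community in communities:
        cset = set(community)
        intra = sum(1 for u, v in graph.edges(cset) if u in cset and v in cset)
        dsum = sum(degree[n] for n in cset)
        q += intra / m - (dsum / (2 * m)) ** 2
    return q


def _order_communities(communities: Iterable[Iterable[str]]) -> list[set[str]]:
    return sorted((set(c) for c in communities),
                  key=lambda c: (-len(c), min(c)))


def detect_communities(net: Network, method: str = "fast_greedy",
                       seed: int = 0) -> CommunityPartition:
    """Detect communities by modularity maximization.

    The graph is clustered as undirected and unweighted (miRNA->gene
    direction and edge weights ignored).  Deterministic for a fixed
    (method, seed, input); ``seed`` only matters for Louvain.
    Disconnected components are allowed; isolated nodes become singleton
    communities.
    """
    if method not in METHODS:
        raise ParameterError(f"unknown method {method!r}; choose from {METHODS}")
    g = nx.Graph()
    g.add_nodes_from(net.graph.nodes())
    g.add_edges_from(net.graph.edges())
    if g.number_of_nodes() == 0:
        raise ParameterError("cannot detect communities on an empty network")
    if g.number_of_edges() == 0:
        communities: list[set[str]] = [{n} for n in sorted(g.nodes())]
    elif method == "fast_greedy":
        communities = [set(c) for c in
                       nx.community.greedy_modularity_communities(g)]
    else:
        communities = [set(c) for c in
                       nx.community.louvain_communities(g, seed=seed)]
    ordered = _order_communities(communities)
    assignment = {n: i for i, c in enumerate(ordered, start=1) for n in c}
    if set(assignment) != set(g.nodes()):
        raise ConsistencyError("partition does not cover all nodes")
    return CommunityPartition(assignment=assignment,
                              modularity=modularity_score(g, ordered),
                              method=method, seed=seed)


def community_sizes(partition: CommunityPartition, net: Network) -> pd.DataFrame:
    """Per-community tallies: (community, n_nodes, n_mirnas, n_genes)."""
    if set(partition.assignment) != set(net.graph.nodes()):
        raise ConsistencyError("partition does not match the network's node set")
    mirnas = net.mirna_nodes if isinstance(net, MirnaGRN) else set()
    rows = []
    for cid, members in enumerate(partition.communities(), start=1):
        n_mir = sum(1 for n in members if n in mirnas)
        rows.append({"community": cid, "n_nodes": len(members),
                     "n_mirnas": n_mir, "n_genes": len(members) - n_mir})
    return pd.DataFrame(rows, columns=["community", "n_nodes",
                                       "n_mirnas", "n_genes"])


def community_of(partition: CommunityPartition,
                 bis: Iterable[str]) -> dict[str, object]:
    """Map each biomarker to its community id, or to ABSENT if unassigned."""
    return {b: partition.assignment.get(b, ABSENT) for b in bis}


def largest_community_id(partition: CommunityPartition) -> int:
    """Id of the largest community (ties broken by smallest id)."""
    if not partition.assignment:
        raise ParameterError("empty partition")
    sizes: dict[int, int] = {}
    for c in partition.assignment.values():
        sizes[c] = sizes.get(c, 0) + 1
    return min(sizes, key=lambda c: (-sizes[c], c))


def extract_community(grn: MirnaGRN, partition: CommunityPartition,
                      community_id: int) -> MirnaGRN:
    """Induced subnetwork of one community (isolated miRNAs dropped, logged)."""
    members = partition.members(community_id)
    if not members:
        raise ParameterError(f"unknown community id {community_id}")
    return grn.induced(members)
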