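"""Shared fixtures: small hand-built networks and random-instance helpers."""
import itertools

import numpy as np
import pytest

from mirgrn import MirnaGRN


def random_grn(rng: np.random.Generator, n_genes: int = 12, n_mirnas: int = 4,
               p_edge: float = 0.3, p_target: float = 0.3) -> MirnaGRN:
    """A random heterogeneous network; miRNAs without targets are omitted."""
    genes = [f"g{i}" for i in range(n_genes)]
    gene_edges = [(a, b) for a, b in itertools.combinations(genes, 2)
                  if rng.random() < p_edge]
    mirna_edges = []
    for j in range(n_mirnas):
        targets = [g for g in genes if rng.random() < p_target]
        mirna_edges.extend((f"miR-{j + 1}", g) for g in targets)
    return MirnaGRN(gene_edges=gene_edges, mirna_edges=mirna_edges,
                    gene_nodes=genes)


@pytest.fixture
def two_clique_grn() -> MirnaGRN:
    """Two 4-cliques joined by a single bridge edge (gene-gene only)."""
    edges = list(itertools.combinations(["a1", "a2", "a3", "a4"], 2))
    edges += list(itertools.combinations(["b1", "b2", "b3", "b4"], 2))
    edges.append(("a1", "b1"))
    return MirnaGRN(gene_edges=edges)


@pytest.fixture
def small_grn() -> MirnaGRN:
    """3 gene-gene edges, 2 miRNAs with 3 targeting edges."""
    return MirnaGRN(
        gene_edges=[("g1", "g2"), ("g2", "g3"), ("g3", "g4")],
        mirna_edges=[("miR-1", "g1"), ("miR-1", "g3"), ("miR-2", "g4")],
        provenance={("miR-1", "g1"): ("dbA",), ("miR-1", "g3"): ("dbA", "dbB"),
                    ("miR-2", "g4"): ("dbB",)},
    )
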