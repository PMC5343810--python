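"""Synthetic input generation for offline testing and benchmarking.

Everything the pipeline normally pulls from interaction and target
databases can be generated here: random gene networks (scale-free,
planted-partition, Erdos-Renyi), multi-source predicted-target tables
with controlled between-source overlap, hub-coupled miRNA targeting, and
a small curated fixture of validated miRNA->hub-protein interactions.
All generators are pure functions of their configuration — the seed is
part of the config, and identical configs give bit-identical outputs.

The multi-source table generator draws a ground-truth pair set and lets
each source report each true pair independently with probability
``overlap_p``; the >=2-source consensus rule then has the closed-form
expected retention P(Binomial(n_sources, overlap_p) >= 2), which the
tests exploit.

The hub-coupled generator embodies the hypothesis that highly connected
miRNAs preferentially regulate highly connected proteins: each miRNA
draws a target count k from a log-uniform distribution, and picks its
targets with probability proportional to gene degree raised to
``alpha * k / k_max`` — at ``alpha = 0`` targeting is uniform for every
miRNA, while for larger ``alpha`` the better-connected miRNAs
concentrate increasingly on network hubs.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import networkx as nx
import numpy as np

from .errors import ParameterError
from .netcore import GeneNetwork
from .records import MirnaTargetTable, TargetRecord

__all__ = ["GeneratorConfig", "gen_gene_network", "planted_labels",
           "gen_target_tables", "gen_hub_coupled_targets",
           "hub_target_fixture"]

MODELS = ("scale_free", "planted_partition", "erdos_renyi")


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters for all synthetic generators (seed included)."""

    seed: int = 0
    n_genes: int = 500
    n_mirnas: int = 50
    model: str = "scale_free"
    attach_m: int = 2          # scale_free: edges added per new node
    p: float = 0.01            # erdos_renyi: edge probability
    n_blocks: int = 4          # planted_partition: number of blocks
    block_size: int = 25       # planted_partition: nodes per block
    p_in: float = 0.3          # planted_partition: within-block edge prob
    p_out: float = 0.01        # planted_partition: between-block edge prob
    n_pairs: int = 200         # target tables: ground-truth pair count
    overlap_p: float = 0.6     # target tables: per-source report probability
    alpha: float = 1.0         # hub coupling exponent
    k_max: int = 30            # hub coupling: max targets per miRNA

    def __post_init__(self) -> None:
        for name in ("p", "p_in", "p_out", "overlap_p"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} must be in [0, 1], got {v}")
        if self.alpha < 0:
            raise ParameterError("alpha must be >= 0")
        if min(self.n_genes, self.n_mirnas, self.n_pairs) < 0:
            raise ParameterError("counts must be >= 0")


def _gene_name(i: int) -> str:
    return f"G{i:04d}"


def _mirna_name(i: int) -> str:
    return f"miR-{i + 1}"


def gen_gene_network(cfg: GeneratorConfig) -> GeneNetwork:
    """Random simple undirected gene network per ``cfg.model``.

    Nodes are named G0000, G0001, ...; for the planted-partition model
    the block label of each node is stored as node attribute ``block``
    (see :func:`planted_labels`).
    """
    if cfg.model == "scale_free":
        g = nx.barabasi_albert_graph(cfg.n_genes, cfg.attach_m, seed=cfg.seed)
    elif cfg.model == "erdos_renyi":
        g = nx.gnp_random_graph(cfg.n_genes, cfg.p, seed=cfg.seed)
    elif cfg.model == "planted_partition":
        g = nx.planted_partition_graph(cfg.n_blocks, cfg.block_size,
                                       cfg.p_in, cfg.p_out, seed=cfg.seed)
    else:
        raise ParameterError(f"unknown model {cfg.model!r}; choose from {MODELS}")
    g = nx.relabel_nodes(g, {n: _gene_name(n) for n in g.nodes()})
    return GeneNetwork(g, network_type="predicted", organism="synthetic")


def planted_labels(net: GeneNetwork) -> dict[str, int]:
    """Planted block label per node of a planted-partition network."""
    labels = {n: d.get("block") for n, d in net.graph.nodes(data=True)}
    if any(v is None for v in labels.values()):
        raise ParameterError("network carries no planted block labels")
    return labels


def gen_target_tables(cfg: GeneratorConfig, n_sources: int,
                      ) -> tuple[list[MirnaTargetTable], set[tuple[str, str]]]:
    """Noisy multi-source predicted-target tables plus their ground truth.

    A ground-truth set of ``cfg.n_pairs`` distinct (miRNA, gene) pairs is
    drawn; each of the ``n_sources`` databases then reports each true
    pair independently with probability ``cfg.overlap_p``.  Every source
    table is a subset of the ground truth.
    """
    if n_sources < 1:
        raise ParameterError("n_sources must be >= 1")
    if cfg.n_pairs > cfg.n_genes * cfg.n_mirnas:
        raise ParameterError("n_pairs exceeds the number of possible pairs")
    rng = np.random.default_rng(cfg.seed)
    flat = rng.choice(cfg.n_genes * cfg.n_mirnas, size=cfg.n_pairs,
                      replace=False)
    truth = {(_mirna_name(int(x) // cfg.n_genes), _gene_name(int(x) % cfg.n_genes))
             for x in flat}
    ordered = sorted(truth)
    tables = []
    for j in range(n_sources):
        source = f"source_{j + 1}"
        mask = rng.random(len(ordered)) < cfg.overlap_p
        tables.append(MirnaTargetTable(
            TargetRecord(m, g, source, "predicted")
            for (m, g), keep in zip(ordered, mask) if keep))
    return tables, truth


def gen_hub_coupled_targets(net: GeneNetwork,
                            cfg: GeneratorConfig) -> MirnaTargetTable:
    """miRNA targeting coupled to gene hubness with strength ``cfg.alpha``.

    Each of ``cfg.n_mirnas`` miRNAs draws a target count k log-uniformly
    in [1, k_max], then samples k distinct genes with probability
    proportional to degree**(alpha * k / k_max).  Records are tagged
    evidence=validated, source="hub_coupled_sim".
    """
    genes = sorted(net.nodes)
    if not genes:
        raise ParameterError("gene network has no nodes")
    deg = np.array([net.degree(g) for g in genes], dtype=float)
    if cfg.alpha > 0 and deg.max() == 0:
        raise ParameterError("degenerate weights: alpha > 0 on an edgeless network")
    rng = np.random.default_rng(cfg.seed)
    records = []
    for i in range(cfg.n_mirnas):
        k_max = min(cfg.k_max, len(genes))
        k = int(round(np.exp(rng.uniform(0.0, np.log(k_max)))))
        k = max(1, min(k, k_max))
        exponent = cfg.alpha * k / k_max
        if exponent == 0:
            weights = np.ones(len(genes))
        else:
            weights = deg ** exponent
        positive = int((weights > 0).sum())
        k = min(k, positive)
        p = weights / weights.sum()
        picks = rng.choice(len(genes), size=k, replace=False, p=p)
        for idx in sorted(picks):
            records.append(TargetRecord(_mirna_name(i), genes[int(idx)],
                                        "hub_coupled_sim", "validated"))
    return MirnaTargetTable(records)


def hub_target_fixture() -> MirnaTargetTable:
    """Curated validated interactions between hub miRNAs and hub proteins.

    Twelve experimentally supported miRNA->protein pairs among
    high-degree-centrality hubs of the human physical-interaction
    network (seven miRNAs, eight proteins; e.g. miR-17-5p -> MYC and
    miR-125b -> TP53), shipped as a small worked-example input.
    """
    pairs = [
        ("miR-17-5p", "APP"),
        ("miR-17-5p", "HSP90AA1"),
        ("miR-17-5p", "MYC"),
        ("miR-125b", "TP53"),
        ("miR-146a", "TRAF6"),
        ("miR-146a", "BRCA1"),
        ("miR-30a-3p", "EP300"),
        ("miR-30a-3p", "YWHAE"),
        ("let-7a", "MYC"),
        ("miR-429", "MYC"),
        ("miR-429", "EP300"),
        ("miR-145", "MYC"),
    ]
    return MirnaTargetTable(TargetRecord(m, g, "curated_hubs", "validated")
                            for m, g in pairs)
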