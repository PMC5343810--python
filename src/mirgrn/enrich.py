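"""Target-table aggregation and network enrichment.

Two consensus rules govern how multi-database target tables merge:
validated sources are unioned (an interaction supported by any validated
database is kept), while predicted sources require consensus — a
(miRNA, gene) pair must be reported by at least two distinct predicted
databases to survive.  The surviving table can then be overlaid onto a
gene network as directed miRNA->gene edges, and a DEG list can cut the
result down to the differentially-expressed core.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .errors import EvidenceClassError, ParameterError
from .harmonize import normalize_mirna_id
from .netcore import GeneNetwork, MirnaGRN
from .records import (ANNOTATION_KINDS, AnnotationRecord, MirnaTargetTable,
                      TargetRecord)

__all__ = [
    "MirnaTargetTable", "TargetRecord", "combine_validated",
    "combine_predicted", "enrich_network", "deg_subnetwork",
    "join_annotations", "filter_extracellular", "AnnotatedTarget",
]

logger = logging.getLogger(__name__)


def _check_evidence(tables: Sequence[MirnaTargetTable], expected: str) -> None:
    for table in tables:
        bad = table.evidence_classes - {expected}
        if bad:
            raise EvidenceClassError(
                f"expected evidence {expected!r}, found {sorted(bad)}")


def combine_validated(tables: Sequence[MirnaTargetTable]) -> MirnaTargetTable:
    """Union of (miRNA, gene) pairs across validated databases.

    Provenance is retained: the combined table keeps one record per
    (mirna, gene, source) triple, so every contributing database remains
    queryable via :meth:`MirnaTargetTable.sources_of`.
    """
    _check_evidence(tables, "validated")
    records: list[TargetRecord] = []
    for table in tables:
        records.extend(table)
    return MirnaTargetTable(records)


def combine_predicted(tables: Sequence[MirnaTargetTable]) -> MirnaTargetTable:
    """Consensus of predicted databases: keep pairs seen in >= 2 sources.

    A (miRNA, gene) pair survives iff reported by at least two *distinct*
    source databases (record multiplicity within one source does not
    count).  All supporting records are retained for provenance.
    """
    if len(tables) < 2:
        raise ParameterError("combine_predicted requires at least 2 tables")
    _check_evidence(tables, "predicted")
    support: dict[tuple[str, str], set[str]] = {}
    all_records: list[TargetRecord] = []
    for table in tables:
        for rec in table:
            support.setdefault(rec.pair, set()).add(rec.source)
            all_records.append(rec)
    kept = {pair for pair, sources in support.items() if len(sources) >= 2}
    return MirnaTargetTable(r for r in all_records if r.pair in kept)


def enrich_network(net: GeneNetwork,
                   targets: MirnaTargetTable,
                   include_gene_edges: bool = True) -> MirnaGRN:
    """Overlay miRNA->gene target edges onto a gene network.

    Only targets whose gene is a node of ``net`` become edges.  With
    ``include_gene_edges=True`` (the "complete network" mode) the full
    gene layer is retained; with ``False`` (the "miRNA network" mode)
    only targeted genes survive and gene-gene edges are restricted to
    pairs of targeted genes.
    """
    net_nodes = net.nodes
    pair_sources: dict[tuple[str, str], set[str]] = {}
    for rec in targets:
        if rec.gene in net_nodes:
            pair_sources.setdefault(rec.pair, set()).add(rec.source)
    if not pair_sources:
        logger.warning("no target gene occurs in the network; "
                       "enrichment yields no miRNA edges")
    mirna_edges = sorted(pair_sources)
    targeted = {g for _, g in mirna_edges}
    if include_gene_edges:
        gene_edges = [(a, b, net.weight(a, b)) for a, b in net.edges]
        gene_nodes = net_nodes
    else:
        gene_edges = [(a, b, net.weight(a, b)) for a, b in net.edges
                      if a in targeted and b in targeted]
        gene_nodes = targeted
    return MirnaGRN(gene_edges=gene_edges, mirna_edges=mirna_edges,
                    gene_nodes=gene_nodes,
                    provenance={p: tuple(sorted(s))
                                for p, s in pair_sources.items()},
                    organism=net.organism)


def deg_subnetwork(grn: MirnaGRN, degs: set[str]) -> MirnaGRN:
    """Restrict a miRNA-GRN to directly-interacting DEGs.

    Surviving genes are DEGs with at least one gene-gene edge to another
    DEG; gene edges need both endpoints differentially expressed; miRNA
    edges are re-attached only to surviving genes, and miRNAs left
    without targets are dropped.  Idempotent for a fixed DEG set.
    """
    if not degs:
        logger.warning("empty DEG set; DEG subnetwork is empty")
        return MirnaGRN()
    gene_edges = [(a, b, grn.gene_weight(a, b)) for a, b in grn.gene_edges
                  if a in degs and b in degs]
    surviving = {n for edge in gene_edges for n in edge[:2]}
    mirna_edges = [(m, t) for m, t in grn.mirna_edges if t in surviving]
    prov = {(m, t): grn.sources_of(m, t) for m, t in mirna_edges}
    return MirnaGRN(gene_edges=gene_edges, mirna_edges=mirna_edges,
                    gene_nodes=surviving, provenance=prov,
                    organism=grn.organism)


@dataclass(frozen=True)
class AnnotatedTarget:
    """A target record together with its (possibly empty) annotations."""

    record: TargetRecord
    annotations: tuple[AnnotationRecord, ...]


def join_annotations(targets: MirnaTargetTable,
                     ann: Iterable[AnnotationRecord],
                     kind: str) -> list[AnnotatedTarget]:
    """Left-join annotations of one kind onto a target table.

    The join key is the normalized miRNA id on both sides; target records
    without a matching annotation are kept with an empty annotation list.
    """
    if kind not in ANNOTATION_KINDS:
        raise ParameterError(f"unknown annotation kind {kind!r}")

    def _norm(mirna: str) -> str:
        try:
            return normalize_mirna_id(mirna)
        except Exception:
            return mirna

    by_mirna: dict[str, list[AnnotationRecord]] = {}
    for a in ann:
        if a.kind == kind:
            by_mirna.setdefault(_norm(a.mirna), []).append(a)
    return [AnnotatedTarget(rec, tuple(by_mirna.get(_norm(rec.mirna), ())))
            for rec in targets]


def filter_extracellular(targets: MirnaTargetTable,
                         circ: set[str]) -> MirnaTargetTable:
    """Keep only records whose miRNA is in the circulating/extracellular set.

    Also the general literature-list filter: ``circ`` may be any set of
    normalized miRNA ids (e.g. miRNAs reported as deregulated in a
    disease), and sources are preserved.
    """
    return MirnaTargetTable(r for r in targets if r.mirna in circ)
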