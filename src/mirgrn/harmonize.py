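"""Identifier harmonization: one namespace for genes and miRNAs.

Interaction tables may mix Ensembl gene IDs with symbols, and miRNA
databases disagree on species prefixes and capitalisation.  Everything
downstream assumes bare gene symbols and miRNA ids of the form
``miR-17-5p`` / ``let-7a``, produced here.
"""
from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

from .errors import NormalizationError
from .netcore import GeneNetwork
from .records import ENSEMBL_GENE_RE, IdMap, InteractionRecord

__all__ = ["IdMap", "normalize_mirna_id", "map_ensembl_to_symbol",
           "build_gene_network", "MappingReport"]

logger = logging.getLogger(__name__)

_FAMILY = {"mir": "miR", "let": "let"}
_PREFIX_RE = re.compile(r"^[A-Za-z]{3}$")


def normalize_mirna_id(raw: str) -> str:
    """Normalize a miRNA identifier.

    A three-letter species prefix (``hsa-``, ``mmu-``, ...) is stripped,
    the family token is canonicalized to ``miR`` or ``let``, and the
    numeric/arm suffix tokens (``-3p``, ``-5p``, letter variants) are kept
    verbatim.  The function is idempotent.

    >>> normalize_mirna_id("hsa-miR-17-5p")
    'miR-17-5p'
    >>> normalize_mirna_id("hsa-let-7a")
    'let-7a'
    """
    if not raw or not raw.strip():
        raise NormalizationError("empty miRNA identifier")
    parts = raw.strip().split("-")
    fam_idx = None
    for i in (0, 1):
        if i < len(parts) and parts[i].lower() in _FAMILY:
            fam_idx = i
            break
    if fam_idx is None:
        raise NormalizationError(f"no miR/let family token in {raw!r}")
    if fam_idx == 1 and not _PREFIX_RE.match(parts[0]):
        raise NormalizationError(f"unrecognized species prefix in {raw!r}")
    fam = _FAMILY[parts[fam_idx].lower()]
    rest = parts[fam_idx + 1:]
    if not rest or not rest[0]:
        raise NormalizationError(f"miRNA id {raw!r} has no family member token")
    return "-".join([fam] + rest)


@dataclass
class MappingReport:
    """Bookkeeping from map_ensembl_to_symbol: what could not be mapped."""

    n_input: int = 0
    n_mapped: int = 0
    n_dropped: int = 0
    unmapped_ids: set[str] = field(default_factory=set)


def map_ensembl_to_symbol(records: list[InteractionRecord],
                          idmap: IdMap) -> tuple[list[InteractionRecord], MappingReport]:
    """Replace Ensembl gene IDs by symbols; drop edges with unmapped IDs.

    Nodes that do not look like Ensembl gene IDs pass through unchanged
    (they are assumed to already be symbols).  Records with at least one
    Ensembl-pattern node absent from ``idmap`` are dropped and reported.
    """
    report = MappingReport(n_input=len(records))
    out: list[InteractionRecord] = []
    for rec in records:
        nodes = []
        ok = True
        for node in (rec.node_a, rec.node_b):
            if ENSEMBL_GENE_RE.match(node):
                symbol = idmap.get(node)
                if symbol is None:
                    ok = False
                    report.unmapped_ids.add(node)
                    break
                nodes.append(symbol)
            else:
                nodes.append(node)
        if ok:
            out.append(InteractionRecord(nodes[0], nodes[1], rec.weight,
                                         rec.network_type, rec.organism))
        else:
            report.n_dropped += 1
    report.n_mapped = len(out)
    if report.n_dropped:
        logger.info("dropped %d record(s) with unmapped Ensembl IDs",
                    report.n_dropped)
    return out, report


def build_gene_network(records: list[InteractionRecord]) -> GeneNetwork:
    """Collapse an edge list into an undirected simple GeneNetwork.

    Self-loops are removed; parallel edges (including those created by a
    many-to-one ID mapping) are collapsed keeping the maximum weight; an
    edge whose duplicates are all unweighted stays unweighted.
    """
    if not records:
        logger.warning("building gene network from an empty record list")
        return GeneNetwork()
    best: dict[tuple[str, str], float | None] = {}
    for rec in records:
        if rec.node_a == rec.node_b:
            continue
        key = (rec.node_a, rec.node_b) if rec.node_a <= rec.node_b \
            else (rec.node_b, rec.node_a)
        if key not in best:
            best[key] = rec.weight
        elif rec.weight is not None:
            prev = best[key]
            best[key] = rec.weight if prev is None else max(prev, rec.weight)
    edges = [(a, b, w) for (a, b), w in best.items()]
    return GeneNetwork.from_edges(edges,
                                  network_type=records[0].network_type,
                                  organism=records[0].organism)
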