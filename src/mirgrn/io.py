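"""Readers and writers for every on-disk artifact.

All text I/O is UTF-8 TSV (or one-symbol-per-line lists); networks export
to GraphML via networkx.  Two interaction-table dialects are supported:

``genemania3col``
    Header line, three tab-separated columns ``Gene_A  Gene_B  Weight``.
``simple2col``
    Headerless, two tab-separated columns, no weights.

Malformed rows (missing node fields) are skipped with a log line and
counted in the returned :class:`ParseResult`; ``strict=True`` upgrades
skips to :class:`~mirgrn.errors.ParseError`.  Non-numeric weights are
always an error naming the line.
"""
from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional, Union

import networkx as nx

from .errors import ParameterError, ParseError
from .netcore import GENE_GENE, MIRNA_GENE, GeneNetwork, MirnaGRN, Network
from .records import (ANNOTATION_KINDS, ENSEMBL_GENE_RE, AnnotationRecord,
                      IdMap, InteractionRecord, MirnaTargetTable, TargetRecord)

__all__ = [
    "ParseResult", "read_interactions", "write_interactions",
    "read_mirna_targets", "read_idmap", "read_deg_list", "read_annotations",
    "write_graphml", "read_graphml", "write_edgelist",
]

logger = logging.getLogger(__name__)

DIALECTS = ("genemania3col", "simple2col")


@dataclass
class ParseResult:
    """Records parsed from a file plus skip bookkeeping.

    Behaves like a list of records; ``n_skipped`` counts data rows dropped
    for missing node fields, so ``len(result) + result.n_skipped`` equals
    the number of data rows in the file.
    """

    records: list[InteractionRecord] = field(default_factory=list)
    n_skipped: int = 0

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[InteractionRecord]:
        return iter(self.records)

    def __getitem__(self, i):
        return self.records[i]


def _rows(path: Union[str, Path]) -> Iterator[tuple[int, list[str]]]:
    with open(path, encoding="utf-8", newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            yield lineno, row


def read_interactions(path: Union[str, Path],
                      dialect: str = "genemania3col",
                      strict: bool = False,
                      network_type: str = "physical",
                      organism: str = "homo_sapiens") -> ParseResult:
    """Read a gene-gene interaction table in one of the two dialects."""
    if dialect not in DIALECTS:
        raise ParameterError(f"unknown dialect {dialect!r}; choose from {DIALECTS}")
    result = ParseResult()
    has_header = dialect == "genemania3col"
    for lineno, row in _rows(path):
        if has_header and lineno == 1:
            continue
        if not row or (len(row) == 1 and not row[0].strip()):
            continue
        a = row[0].strip() if len(row) > 0 else ""
        b = row[1].strip() if len(row) > 1 else ""
        if not a or not b:
            if strict:
                raise ParseError(f"{path}:{lineno}: missing node field")
            logger.info("%s:%d: skipping row with missing node field", path, lineno)
            result.n_skipped += 1
            continue
        weight: Optional[float] = None
        if dialect == "genemania3col" and len(row) > 2 and row[2].strip():
            try:
                weight = float(row[2])
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-numeric weight {row[2]!r}")
        result.records.append(InteractionRecord(a, b, weight,
                                                network_type, organism))
    return result


def write_interactions(records: list[InteractionRecord],
                       path: Union[str, Path],
                       dialect: str = "genemania3col") -> None:
    """Write interaction records back in one of the two dialects."""
    if dialect not in DIALECTS:
        raise ParameterError(f"unknown dialect {dialect!r}; choose from {DIALECTS}")
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        if dialect == "genemania3col":
            writer.writerow(["Gene_A", "Gene_B", "Weight"])
            for rec in records:
                w = "" if rec.weight is None else repr(rec.weight)
                writer.writerow([rec.node_a, rec.node_b, w])
        else:
            for rec in records:
                writer.writerow([rec.node_a, rec.node_b])


def read_mirna_targets(path: Union[str, Path],
                       source: str,
                       evidence: str) -> MirnaTargetTable:
    """Read a headerless miRNA-target TSV (miRNA, gene, extras ignored).

    Every row is tagged with the given source database name and evidence
    class; miRNA ids pass through verbatim (normalization is the
    harmonization layer's job).  Duplicate rows are preserved only up to
    the table's (mirna, gene, source) deduplication.
    """
    records: list[TargetRecord] = []
    for lineno, row in _rows(path):
        if not row or (len(row) == 1 and not row[0].strip()):
            continue
        if len(row) < 2 or not row[0].strip() or not row[1].strip():
            raise ParseError(f"{path}:{lineno}: expected at least 2 columns "
                             "(miRNA, gene)")
        records.append(TargetRecord(row[0].strip(), row[1].strip(),
                                    source, evidence))
    if not records:
        logger.warning("%s: empty miRNA-target table", path)
    return MirnaTargetTable(records)


def read_idmap(path: Union[str, Path]) -> IdMap:
    """Read a 2-column TSV (ensembl_id, symbol); a header line is tolerated."""
    entries: dict[str, str] = {}
    for lineno, row in _rows(path):
        if not row or (len(row) == 1 and not row[0].strip()):
            continue
        if len(row) < 2:
            raise ParseError(f"{path}:{lineno}: expected 2 columns")
        key, value = row[0].strip(), row[1].strip()
        if not ENSEMBL_GENE_RE.match(key):
            if lineno == 1:
                continue  # header
            raise ParseError(f"{path}:{lineno}: {key!r} is not an Ensembl gene ID")
        entries[key] = value
    return IdMap(entries)


def read_deg_list(path: Union[str, Path]) -> set[str]:
    """Read a plain symbol list (first whitespace-separated token per line)."""
    symbols: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            tokens = line.split()
            if tokens:
                symbols.add(tokens[0])
    if not symbols:
        logger.warning("%s: empty symbol list", path)
    return symbols


def read_annotations(path: Union[str, Path], kind: str) -> list[AnnotationRecord]:
    """Read a miRNA annotation TSV: (miRNA, value[, gene])."""
    if kind not in ANNOTATION_KINDS:
        raise ParameterError(f"unknown annotation kind {kind!r}")
    out: list[AnnotationRecord] = []
    for lineno, row in _rows(path):
        if not row or (len(row) == 1 and not row[0].strip()):
            continue
        if len(row) < 2 or not row[0].strip() or not row[1].strip():
            raise ParseError(f"{path}:{lineno}: expected at least 2 columns "
                             "(miRNA, value)")
        gene = row[2].strip() if len(row) > 2 and row[2].strip() else None
        out.append(AnnotationRecord(row[0].strip(), kind, row[1].strip(), gene))
    return out


# -- network export/import -------------------------------------------------

def write_graphml(net: Network, path: Union[str, Path]) -> None:
    """Export a network to GraphML.

    Nodes carry ``node_class`` in {gene, mirna}; edges carry
    ``edge_class`` in {gene_gene, mirna_gene} and ``weight`` when present.
    The file re-imports losslessly through :func:`read_graphml`.
    """
    g = nx.Graph()
    g.graph["kind"] = "mirna_grn" if isinstance(net, MirnaGRN) else "gene_network"
    g.graph["organism"] = net.organism
    if isinstance(net, GeneNetwork):
        g.graph["network_type"] = net.network_type
    for n in net.graph.nodes():
        cls = net.graph.nodes[n].get("node_class", "gene")
        g.add_node(n, node_class=cls)
    for u, v, data in net.graph.edges(data=True):
        attrs = {"edge_class": data.get("edge_class", GENE_GENE)}
        if data.get("weight") is not None:
            attrs["weight"] = float(data["weight"])
        if data.get("sources"):
            attrs["sources"] = ";".join(data["sources"])
        g.add_edge(u, v, **attrs)
    nx.write_graphml(g, str(path))


def read_graphml(path: Union[str, Path]) -> Network:
    """Re-import a GraphML file written by :func:`write_graphml`."""
    g = nx.read_graphml(str(path))
    kind = g.graph.get("kind", "mirna_grn")
    organism = g.graph.get("organism", "homo_sapiens")
    if kind == "gene_network":
        out = nx.Graph()
        out.add_nodes_from(g.nodes())
        for u, v, data in g.edges(data=True):
            attrs = {}
            if data.get("weight") is not None:
                attrs["weight"] = float(data["weight"])
            out.add_edge(u, v, **attrs)
        return GeneNetwork(out, network_type=g.graph.get("network_type", "physical"),
                           organism=organism)
    gene_edges = []
    mirna_edges = []
    prov = {}
    gene_nodes = [n for n, d in g.nodes(data=True)
                  if d.get("node_class", "gene") == "gene"]
    for u, v, data in g.edges(data=True):
        if data.get("edge_class", GENE_GENE) == MIRNA_GENE:
            m, t = (u, v) if g.nodes[u].get("node_class") == "mirna" else (v, u)
            mirna_edges.append((m, t))
            if data.get("sources"):
                prov[(m, t)] = tuple(data["sources"].split(";"))
        else:
            gene_edges.append((u, v, data.get("weight")))
    return MirnaGRN(gene_edges=gene_edges, mirna_edges=mirna_edges,
                    gene_nodes=gene_nodes, provenance=prov, organism=organism)


def write_edgelist(net: Network, path: Union[str, Path]) -> None:
    """Export any network as a 4-column TSV: node_a, node_b, edge_class, weight."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["node_a", "node_b", "edge_class", "weight"])
        for u, v in sorted((min(u, v), max(u, v))
                           for u, v, c in net.graph.edges(data="edge_class")
                           if c in (None, GENE_GENE)):
            w = net.graph.edges[u, v].get("weight")
            writer.writerow([u, v, GENE_GENE, "" if w is None else repr(w)])
        if isinstance(net, MirnaGRN):
            for m, t in sorted(net.mirna_edges):
                writer.writerow([m, t, MIRNA_GENE, ""])
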