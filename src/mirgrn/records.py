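"""Plain-data record types shared by the I/O, harmonization and enrichment layers.

Interaction tables, miRNA-target tables and annotation tables are all
row-oriented; each row maps onto one frozen dataclass instance so that
records can live in sets and be compared structurally.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Optional

from .errors import ConsistencyError, EvidenceClassError

#: The seven association-network classes a gene-gene edge can belong to.
NETWORK_TYPES = frozenset(
    {
        "coexpression",
        "physical",
        "genetic",
        "colocalization",
        "pathway",
        "shared_protein_domain",
        "predicted",
    }
)

#: Evidence classes a miRNA-target record can carry.
EVIDENCE_CLASSES = frozenset({"validated", "predicted", "extracellular"})

#: Annotation kinds joinable onto target tables.
ANNOTATION_KINDS = frozenset({"disease", "drug", "extracellular_location"})

ENSEMBL_GENE_RE = re.compile(r"^ENSG\d+$")


@dataclass(frozen=True)
class InteractionRecord:
    """One weighted gene-gene / protein-protein edge from an interaction table."""

    node_a: str
    node_b: str
    weight: Optional[float] = None
    network_type: str = "physical"
    organism: str = "homo_sapiens"

    def __post_init__(self) -> None:
        if not self.node_a or not self.node_b:
            raise ConsistencyError("interaction record with empty node field")
        if self.weight is not None and self.weight < 0:
            raise ConsistencyError(f"negative weight {self.weight!r} on edge "
                                   f"({self.node_a}, {self.node_b})")
        if self.network_type not in NETWORK_TYPES:
            raise ConsistencyError(f"unknown network_type {self.network_type!r}")


@dataclass(frozen=True)
class TargetRecord:
    """One miRNA -> gene targeting assertion from a single source database."""

    mirna: str
    gene: str
    source: str
    evidence: str

    def __post_init__(self) -> None:
        if not (self.mirna and self.gene and self.source):
            raise ConsistencyError("target record with empty field")
        if self.evidence not in EVIDENCE_CLASSES:
            raise EvidenceClassError(f"unknown evidence class {self.evidence!r}")

    @property
    def pair(self) -> tuple[str, str]:
        return (self.mirna, self.gene)


@dataclass(frozen=True)
class AnnotationRecord:
    """miRNA-level annotation: disease, drug or extracellular localization."""

    mirna: str
    kind: str
    value: str
    gene: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.mirna or not self.value:
            raise ConsistencyError("annotation record with empty mirna/value")
        if self.kind not in ANNOTATION_KINDS:
            raise ConsistencyError(f"unknown annotation kind {self.kind!r}")


class IdMap:
    """Ensembl gene ID -> gene symbol mapping (many-to-one permitted)."""

    def __init__(self, entries: Mapping[str, str]):
        for key, value in entries.items():
            if not ENSEMBL_GENE_RE.match(key):
                raise ConsistencyError(f"identifier {key!r} is not an Ensembl gene ID")
            if not value:
                raise ConsistencyError(f"empty symbol mapped from {key!r}")
        self._entries = dict(entries)

    def __contains__(self, key: str) -> bool:
        return key in self._entries

    def __getitem__(self, key: str) -> str:
        return self._entries[key]

    def __len__(self) -> int:
        return len(self._entries)

    def get(self, key: str, default: Optional[str] = None) -> Optional[str]:
        return self._entries.get(key, default)

    def items(self):
        return self._entries.items()

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"IdMap({len(self._entries)} entries)"


class MirnaTargetTable:
    """A source-tagged collection of miRNA-target records.

    Records are deduplicated on (mirna, gene, source); the same pair
    reported by two sources keeps both rows, which is what the consensus
    rules downstream count.
    """

    def __init__(self, records: Iterable[TargetRecord]):
        seen: dict[tuple[str, str, str], TargetRecord] = {}
        for rec in records:
            seen.setdefault((rec.mirna, rec.gene, rec.source), rec)
        self._records: tuple[TargetRecord, ...] = tuple(seen.values())

    @property
    def records(self) -> tuple[TargetRecord, ...]:
        return self._records

    @property
    def sources(self) -> frozenset[str]:
        return frozenset(r.source for r in self._records)

    @property
    def evidence_classes(self) -> frozenset[str]:
        return frozenset(r.evidence for r in self._records)

    def pairs(self) -> set[tuple[str, str]]:
        """Distinct (mirna, gene) pairs, collapsing sources."""
        return {r.pair for r in self._records}

    def sources_of(self, mirna: str, gene: str) -> frozenset[str]:
        return frozenset(r.source for r in self._records
                         if r.mirna == mirna and r.gene == gene)

    def mirnas(self) -> set[str]:
        return {r.mirna for r in self._records}

    def genes(self) -> set[str]:
        return {r.gene for r in self._records}

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[TargetRecord]:
        return iter(self._records)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MirnaTargetTable):
            return NotImplemented
        return set(self._records) == set(other._records)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (f"MirnaTargetTable({len(self._records)} records, "
                f"{len(self.sources)} sources)")
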