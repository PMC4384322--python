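"""Identifier unification and merging of the reference interaction databases.

Reference databases export interactions under different identifier systems
(UniProt accessions, Entrez gene ids, Ensembl peptide ids, or database-native
ids).  A :class:`Translator` holds direct cross-references between these
namespaces and rewrites every interactor to one canonical identifier —
the highest-priority namespace (uniprot > entrez > ensembl) reachable in a
single hop.  Transitive closure is deliberately not taken: chaining noisy
cross-references merges proteins that are not the same.

After canonicalization, the per-database record lists are merged into one
standardized set.  Records whose interactors cannot be expressed in any of
the three chosen namespaces are dropped (each interactor must carry at least
one chosen identifier).  Exact duplicates — same canonical pair, species,
method, publication and source database — collapse to one record; the same
interaction reported by two source databases stays as two records, because
cross-database evidence is aggregated later, in the confidence computation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .records import CHOSEN_NAMESPACES, IdentifierRef, SourceInteractionRecord

log = logging.getLogger(__name__)

#: namespace priority used when an identifier maps into several systems
PRIORITY = ("uniprot", "entrez", "ensembl")


@dataclass(frozen=True)
class MappingEntry:
    source: IdentifierRef
    target: IdentifierRef

    def __post_init__(self) -> None:
        if self.source == self.target:
            raise ValueError("mapping entry with identical source and target")


@dataclass
class Translator:
    """Symmetric one-hop lookup over identifier cross-references."""

    edges: dict[IdentifierRef, set[IdentifierRef]] = field(default_factory=dict)
    ambiguous: set[IdentifierRef] = field(default_factory=set)
    priority: tuple[str, ...] = PRIORITY

    def add(self, a: IdentifierRef, b: IdentifierRef) -> None:
        if a == b:
            raise ValueError("self-mapping")
        # flag ambiguity: same source already maps to a different target in
        # the same namespace; both targets are retained
        for prior in self.edges.get(a, ()):
            if prior.namespace == b.namespace and prior.accession != b.accession:
                self.ambiguous.add(a)
        for prior in self.edges.get(b, ()):
            if prior.namespace == a.namespace and prior.accession != a.accession:
                self.ambiguous.add(b)
        self.edges.setdefault(a, set()).add(b)
        self.edges.setdefault(b, set()).add(a)

    def neighbors(self, idref: IdentifierRef) -> frozenset[IdentifierRef]:
        return frozenset(self.edges.get(idref, frozenset()))

    def __len__(self) -> int:
        return sum(len(v) for v in self.edges.values()) // 2


def build_translator(
    mapping_tables: Iterable[Sequence[tuple[IdentifierRef, IdentifierRef] | MappingEntry]],
) -> Translator:
    """Load mapping tables into a symmetric translator (no transitive closure)."""
    tr = Translator()
    n = 0
    for table in mapping_tables:
        for entry in table:
            if isinstance(entry, MappingEntry):
                a, b = entry.source, entry.target
            else:
                a, b = entry
            tr.add(a, b)
            n += 1
    log.info("translator: %d entries loaded, %d ambiguous ids", n, len(tr.ambiguous))
    return tr


def canonical_id(idref: IdentifierRef, translator: Translator) -> IdentifierRef:
    """Rewrite an identifier into the best chosen namespace reachable in one hop.

    Candidates are the identifier itself plus its direct mappings, restricted
    to the chosen namespaces; the highest-priority namespace wins, and within
    it the lexicographically smallest accession (a deterministic tie-break
    for ambiguous multi-mappings).  An identifier reaching no chosen
    namespace is returned unchanged — callers treat a non-chosen namespace in
    the result as the "unmappable" flag.
    """
    candidates = [idref, *translator.neighbors(idref)]
    for ns in translator.priority:
        in_ns = sorted(c.accession for c in candidates if c.namespace == ns)
        if in_ns:
            return IdentifierRef(ns, in_ns[0])
    return idref


def is_canonical(idref: IdentifierRef) -> bool:
    return idref.namespace in CHOSEN_NAMESPACES


@dataclass
class MergeResult:
    records: list[SourceInteractionRecord]
    n_input: int
    n_dropped: int
    n_collapsed: int


def merge_interactomes(
    record_sets: Iterable[Sequence[SourceInteractionRecord]],
    translator: Translator,
) -> MergeResult:
    """Canonicalize and merge per-database record lists into one set.

    The dedup key is (canonical unordered pair, species, method, publication,
    source_db); records differing only in source database are both kept.
    Output order is deterministic (sorted by the dedup key), which makes the
    merge idempotent and independent of input-set order.
    """
    seen: set[tuple] = set()
    kept: list[tuple[tuple, SourceInteractionRecord]] = []
    n_input = n_dropped = n_collapsed = 0
    for records in record_sets:
        for rec in records:
            n_input += 1
            a = canonical_id(rec.interactor_a, translator)
            b = canonical_id(rec.interactor_b, translator)
            if not (is_canonical(a) and is_canonical(b)):
                n_dropped += 1
                continue
            if (b.namespace, b.accession) < (a.namespace, a.accession):
                a, b = b, a
            key = (str(a), str(b), rec.species, rec.method, rec.publication, rec.source_db)
            if key in seen:
                n_collapsed += 1
                continue
            seen.add(key)
            kept.append((key, SourceInteractionRecord(a, b, rec.species, rec.method,
                                                      rec.publication, rec.source_db)))
    kept.sort(key=lambda kv: kv[0])
    log.info("merge: %d in, %d kept, %d dropped (untranslatable), %d duplicates collapsed",
             n_input, len(kept), n_dropped, n_collapsed)
    return MergeResult([r for _, r in kept], n_input, n_dropped, n_collapsed)
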