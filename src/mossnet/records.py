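"""Core domain records shared across the pipeline stages.

The pipeline moves interaction evidence through three shapes:

* :class:`SourceInteractionRecord` — one row of a reference-organism
  interaction database (two interactors, species, experimental method,
  publication, source database).
* :class:`EvidenceRecord` — the provenance attached to a single transferred
  (interolog) prediction: which reference species/method/publication/source
  database supports the moss pair, and which reference pair it came from.
* :class:`UniqueInteraction` — one canonical unordered moss pair together
  with its full evidence list and the multiplicative confidence summary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

CHOSEN_NAMESPACES = ("uniprot", "entrez", "ensembl")
NAMESPACES = CHOSEN_NAMESPACES + ("native",)

SOURCE_DBS = ("BIND", "DIP", "BioGrid", "IntAct", "other")


@dataclass(frozen=True, order=True)
class IdentifierRef:
    """A protein identifier qualified by its namespace.

    ``namespace`` is one of ``uniprot``, ``entrez``, ``ensembl`` or
    ``native`` (anything outside the three cross-referenced systems).
    """

    namespace: str
    accession: str

    def __post_init__(self) -> None:
        if self.namespace not in NAMESPACES:
            raise ValueError(f"unknown namespace: {self.namespace!r}")
        if not self.accession:
            raise ValueError("empty accession")
        if "\t" in self.accession or "\n" in self.accession:
            raise ValueError("accession contains tab/newline")

    def __str__(self) -> str:
        return f"{self.namespace}:{self.accession}"

    @classmethod
    def parse(cls, token: str, default_namespace: str = "native") -> "IdentifierRef":
        """Parse ``namespace:accession``; bare tokens fall into *default_namespace*.

        The MITAB spelling ``uniprotkb:`` is accepted as ``uniprot``.
        """
        token = token.strip()
        if ":" in token:
            ns, acc = token.split(":", 1)
            ns = ns.strip().lower()
            if ns == "uniprotkb":
                ns = "uniprot"
            if ns in NAMESPACES:
                return cls(ns, acc.strip())
            # unknown prefix: keep whole token as a native accession
            return cls("native", token)
        return cls(default_namespace, token)


@dataclass(frozen=True)
class SourceInteractionRecord:
    """One interaction row from a reference database export."""

    interactor_a: IdentifierRef
    interactor_b: IdentifierRef
    species: str
    method: str
    publication: str
    source_db: str

    def __post_init__(self) -> None:
        for f in ("species", "method", "publication", "source_db"):
            if not getattr(self, f):
                raise ValueError(f"empty field: {f}")


@dataclass(frozen=True)
class EvidenceRecord:
    """Provenance of one raw interolog prediction."""

    species: str
    method: str
    publication: str
    source_db: str
    source_pair: tuple[str, str]


@dataclass(frozen=True)
class EvidenceSummary:
    """Multiplicative confidence summary over an evidence list.

    ``R`` distinct publications, ``E`` distinct experimental method codes,
    ``S`` distinct reference species; ``cv = R * E * S``.
    """

    R: int
    E: int
    S: int
    cv: int
    confidence_class: str


@dataclass
class RawPrediction:
    """A transferred moss pair before deduplication.

    ``collapsed`` marks predictions whose two reference partners mapped to
    the same moss protein (a heterodimer collapsing onto a self-loop).
    """

    pair: tuple[str, str]
    evidence: EvidenceRecord
    collapsed: bool = False


@dataclass
class UniqueInteraction:
    """A canonical unordered moss pair with its pooled evidence."""

    pair: tuple[str, str]
    evidence: list[EvidenceRecord]
    summary: EvidenceSummary
    collapsed: bool = False

    @property
    def is_self_loop(self) -> bool:
        return self.pair[0] == self.pair[1]


@dataclass
class OrthologCluster:
    """An InParanoid-style cluster: members of two species with inparalog scores.

    ``species_pair`` is oriented (target species, reference species); each
    side of ``members`` holds ``(protein_id, score)`` with scores in [0, 1]
    and at least one seed ortholog of score 1.0 per side.
    """

    cluster_id: str
    species_pair: tuple[str, str]
    members: dict[str, list[tuple[str, float]]]

    def side(self, species: str) -> list[tuple[str, float]]:
        return self.members[species]


@dataclass
class OrthologMap:
    """Strict one-to-one ortholog pairing per reference species.

    ``pairs[ref_species][ref_protein] = (target_protein, cluster_id)``;
    within each species both columns are duplicate-free (a bijection on the
    mapped subset).  Non-selected cluster members (inparalogs) never enter
    the map.
    """

    target_species: str
    pairs: dict[str, dict[str, tuple[str, str]]] = field(default_factory=dict)
    conflicts: list[str] = field(default_factory=list)

    def lookup(self, ref_species: str, ref_protein: str) -> Optional[str]:
        entry = self.pairs.get(ref_species, {}).get(ref_protein)
        return entry[0] if entry else None

    @property
    def reference_species(self) -> list[str]:
        return sorted(self.pairs)

    def target_proteins(self) -> set[str]:
        """Target proteins mapped to at least one reference species."""
        out: set[str] = set()
        for mapping in self.pairs.values():
            out.update(t for t, _ in mapping.values())
        return out
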