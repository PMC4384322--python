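"""Interolog transfer and the multiplicative confidence value.

A reference interaction in species *s* transfers to the target species iff
BOTH interactors have a one-to-one ortholog in *s*'s mapping; the transferred
pair keeps the full provenance of the source record.  After canonicalizing
and grouping the raw predictions into unique unordered pairs, each unique
interaction is scored with the confidence value

    CV = R × E × S

where R is the number of distinct publications, E the number of distinct
experimental-method codes, and S the number of distinct reference species in
its evidence list.  Four publications over two methods in three species give
CV = 4 × 2 × 3 = 24; four publications with one method in one species give
CV = 4.  The score rewards methodological diversity and evolutionary
conservation of the interaction.

Confidence classes: CV = 1 low, 2 ≤ CV ≤ 10 medium, CV > 10 high ("between
2 and 10" read inclusively so the three classes partition all CV ≥ 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

from .records import (
    EvidenceRecord,
    EvidenceSummary,
    OrthologMap,
    RawPrediction,
    SourceInteractionRecord,
    UniqueInteraction,
)

log = logging.getLogger(__name__)

#: class boundaries: CV <= LOW_MAX → low; CV <= MEDIUM_MAX → medium; else high
LOW_MAX = 1
MEDIUM_MAX = 10


def canonicalize_pair(a: str, b: str) -> tuple[str, str]:
    """Unordered canonical form: lexicographically smaller id first."""
    if not a or not b:
        raise ValueError("empty protein id")
    return (a, b) if a <= b else (b, a)


@dataclass
class PredictionResult:
    predictions: list[RawPrediction]
    n_reference_records: int
    n_unmapped: int


def predict_interologs(
    refs: Iterable[SourceInteractionRecord],
    omap: OrthologMap,
) -> PredictionResult:
    """Transfer reference interactions through the ortholog map.

    A record in species *s* yields a prediction only when both interactors
    have an ortholog in *s*; misses are counted, not errors.  Predictions
    whose reference partners collapse onto the same target protein become
    flagged self-loops.
    """
    predictions: list[RawPrediction] = []
    n_refs = n_unmapped = 0
    for rec in refs:
        n_refs += 1
        ta = omap.lookup(rec.species, rec.interactor_a.accession)
        tb = omap.lookup(rec.species, rec.interactor_b.accession)
        if ta is None or tb is None:
            n_unmapped += 1
            continue
        collapsed = (ta == tb) and (rec.interactor_a.accession != rec.interactor_b.accession)
        ev = EvidenceRecord(
            species=rec.species,
            method=rec.method,
            publication=rec.publication,
            source_db=rec.source_db,
            source_pair=(rec.interactor_a.accession, rec.interactor_b.accession),
        )
        predictions.append(RawPrediction(canonicalize_pair(ta, tb), ev, collapsed))
    log.info("predict: %d reference records -> %d raw predictions (%d without both orthologs)",
             n_refs, len(predictions), n_unmapped)
    return PredictionResult(predictions, n_refs, n_unmapped)


def compute_cv(evidence: Sequence[EvidenceRecord]) -> EvidenceSummary:
    """Summarize an evidence list into (R, E, S, CV, class)."""
    if not evidence:
        raise ValueError("empty evidence list")
    r = len({e.publication for e in evidence})
    e_ = len({e.method for e in evidence})
    s = len({e.species for e in evidence})
    cv = r * e_ * s
    return EvidenceSummary(R=r, E=e_, S=s, cv=cv, confidence_class=classify_confidence(cv))


def classify_confidence(cv: int, low_max: int = LOW_MAX, medium_max: int = MEDIUM_MAX) -> str:
    """Map a confidence value to its class (low / medium / high)."""
    if cv < 1:
        raise ValueError(f"confidence value must be >= 1, got {cv}")
    if cv <= low_max:
        return "low"
    if cv <= medium_max:
        return "medium"
    return "high"


def deduplicate(raw: Iterable[RawPrediction]) -> list[UniqueInteraction]:
    """Group raw predictions by canonical pair into unique interactions.

    Evidence lists partition the raw list: the sum of evidence-list lengths
    equals the raw prediction count.  Output is sorted by pair.
    """
    grouped: dict[tuple[str, str], list[RawPrediction]] = {}
    for p in raw:
        grouped.setdefault(p.pair, []).append(p)
    out: list[UniqueInteraction] = []
    for pair in sorted(grouped):
        preds = grouped[pair]
        evidence = [p.evidence for p in preds]
        out.append(UniqueInteraction(
            pair=pair,
            evidence=evidence,
            summary=compute_cv(evidence),
            collapsed=any(p.collapsed for p in preds),
        ))
    return out


def class_counts(interactions: Iterable[UniqueInteraction]) -> dict[str, int]:
    """Number of unique interactions per confidence class."""
    counts = {"low": 0, "medium": 0, "high": 0}
    for ia in interactions:
        counts[ia.summary.confidence_class] += 1
    return counts


def write_unique_interactions(interactions: Iterable[UniqueInteraction], path) -> None:
    """Unique-interaction table: pair, evidence count, R, E, S, CV, class."""
    import csv
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["protein_a", "protein_b", "n_evidence", "R", "E", "S", "CV", "class", "collapsed"])
        for ia in interactions:
            s = ia.summary
            w.writerow([ia.pair[0], ia.pair[1], len(ia.evidence), s.R, s.E, s.S,
                        s.cv, s.confidence_class, int(ia.collapsed)])
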