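"""Tab-delimited readers and writers for every external table the pipeline touches.

All dialects are tab-delimited with a single header line.  Column orders:

``generic-tsv``
    interactor_a, interactor_b, species, method, publication, source_db.
    Interactor ids are ``namespace:accession`` (bare tokens → native).
``biogrid-tab``
    interactor_a, interactor_b, experimental_system, pubmed_id, organism.
    Ids are Entrez gene ids; source database is BioGrid.
``mitab``
    id_a, id_b, detection_method, publication, taxon.  Ids carry the
    ``uniprotkb:`` prefix; source database is IntAct.
``bind-flat``
    id_a, id_b, species, method, publication.  Bare native ids; source
    database is BIND.

Other tables: InParanoid-style cluster TSV (cluster_id, species, score,
protein_id); two-column mapping tables (``namespace:accession`` ↔
``namespace:accession``); SIF + node-attribute export; two-column GO
annotation TSV with optional term→slim projection.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional

import networkx as nx

from .records import (
    EvidenceRecord,
    IdentifierRef,
    OrthologCluster,
    RawPrediction,
    SourceInteractionRecord,
)

log = logging.getLogger(__name__)

DIALECTS = ("generic-tsv", "biogrid-tab", "mitab", "bind-flat")

#: canonical experimental-method codes (the Fig-4-style abbreviation set)
METHOD_CODES = (
    "NR", "AC", "NG", "Y2H", "PE", "SL", "SGD", "DR", "PS", "PG", "RC",
    "Co-P", "SR", "BA", "PCA", "Co-F", "Co-CS", "Co-L", "DL", "FW", "SH",
    "DGD", "Prot", "FRET",
)


@dataclass
class MethodDictionary:
    """Table-driven normalization of raw experimental-system strings.

    Unknown strings fall back to ``NR`` (not reported), so the mapping is
    total on any vocabulary.
    """

    mapping: dict[str, str]
    fallback: str = "NR"

    def normalize(self, raw: str) -> str:
        raw = raw.strip()
        if raw in self.mapping:
            return self.mapping[raw]
        if raw in METHOD_CODES:
            return raw
        return self.fallback

    @classmethod
    def default(cls) -> "MethodDictionary":
        """Load the method-code table shipped with the package."""
        text = resources.files("mossnet.data").joinpath("method_codes.tsv").read_text()
        mapping: dict[str, str] = {}
        for line in text.splitlines()[1:]:
            if not line.strip():
                continue
            raw, code = line.split("\t")
            mapping[raw.strip()] = code.strip()
        return cls(mapping)


@dataclass
class ParsedInteractions:
    """Result of parsing one interaction table: records plus the skip count."""

    records: list[SourceInteractionRecord]
    skipped: int = 0


def _data_rows(path: Path | str) -> Iterable[list[str]]:
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None:
            return
        for row in reader:
            if row:
                yield row


def read_reference_interactions(
    path: Path | str,
    dialect: str,
    method_dict: Optional[MethodDictionary] = None,
) -> ParsedInteractions:
    """Parse one reference-interaction table in the given dialect.

    Malformed rows (wrong column count) are skipped and counted; an
    unreadable file raises.  Method strings are normalized through
    *method_dict* (default dictionary when omitted).
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect: {dialect!r} (expected one of {DIALECTS})")
    md = method_dict or MethodDictionary.default()
    records: list[SourceInteractionRecord] = []
    skipped = 0
    for row in _data_rows(path):
        try:
            rec = _parse_row(row, dialect, md)
        except (ValueError, IndexError):
            skipped += 1
            continue
        records.append(rec)
    log.info("%s [%s]: %d records, %d rows skipped", path, dialect, len(records), skipped)
    return ParsedInteractions(records, skipped)


def _parse_row(row: list[str], dialect: str, md: MethodDictionary) -> SourceInteractionRecord:
    if dialect == "generic-tsv":
        if len(row) != 6:
            raise ValueError("column count")
        a, b, species, method, pub, src = (c.strip() for c in row)
        return SourceInteractionRecord(
            IdentifierRef.parse(a), IdentifierRef.parse(b),
            species, md.normalize(method), pub or "NR", src or "other",
        )
    if dialect == "biogrid-tab":
        if len(row) != 5:
            raise ValueError("column count")
        a, b, system, pub, organism = (c.strip() for c in row)
        return SourceInteractionRecord(
            IdentifierRef("entrez", a), IdentifierRef("entrez", b),
            organism, md.normalize(system), pub or "NR", "BioGrid",
        )
    if dialect == "mitab":
        if len(row) != 5:
            raise ValueError("column count")
        a, b, method, pub, taxon = (c.strip() for c in row)
        return SourceInteractionRecord(
            IdentifierRef.parse(a, default_namespace="uniprot"),
            IdentifierRef.parse(b, default_namespace="uniprot"),
            taxon, md.normalize(method), pub or "NR", "IntAct",
        )
    # bind-flat
    if len(row) != 5:
        raise ValueError("column count")
    a, b, species, method, pub = (c.strip() for c in row)
    return SourceInteractionRecord(
        IdentifierRef("native", a), IdentifierRef("native", b),
        species, md.normalize(method), pub or "NR", "BIND",
    )


def write_reference_interactions(records: Iterable[SourceInteractionRecord], path: Path | str) -> None:
    """Write records in the generic-tsv dialect (the round-trip format)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["interactor_a", "interactor_b", "species", "method", "publication", "source_db"])
        for r in records:
            w.writerow([str(r.interactor_a), str(r.interactor_b), r.species, r.method, r.publication, r.source_db])


# ---------------------------------------------------------------------------
# InParanoid-style cluster tables


def read_inparanoid_clusters(
    path: Path | str,
    target_species: str,
) -> list[OrthologCluster]:
    """Parse a (cluster_id, species, score, protein_id) table into clusters.

    Rows are grouped by cluster_id; each cluster must contain the target
    species plus exactly one reference species.  Clusters with members from
    only one species are dropped with a warning.
    """
    grouped: dict[str, dict[str, list[tuple[str, float]]]] = {}
    order: list[str] = []
    for row in _data_rows(path):
        if len(row) != 4:
            raise ValueError(f"cluster row needs 4 columns, got {len(row)}: {row}")
        cid, species, score, pid = (c.strip() for c in row)
        if cid not in grouped:
            grouped[cid] = {}
            order.append(cid)
        grouped[cid].setdefault(species, []).append((pid, float(score)))
    clusters: list[OrthologCluster] = []
    for cid in order:
        members = grouped[cid]
        species = set(members)
        if len(species) != 2 or target_species not in species:
            log.warning("cluster %s dropped: species %s (need target %s plus one reference)",
                        cid, sorted(species), target_species)
            continue
        ref = next(s for s in species if s != target_species)
        clusters.append(OrthologCluster(cid, (target_species, ref), members))
    return clusters


def write_ortholog_map(omap, path: Path | str) -> None:
    """Export an OrthologMap as (ref_species, ref_protein, target_protein, cluster_id)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["ref_species", "ref_protein", "target_protein", "cluster_id"])
        for sp in omap.reference_species:
            for ref_protein in sorted(omap.pairs[sp]):
                target, cid = omap.pairs[sp][ref_protein]
                w.writerow([sp, ref_protein, target, cid])


# ---------------------------------------------------------------------------
# Evidence (Table-S1-style) tables

#: default column names of an evidence spreadsheet; override via column_map
EVIDENCE_COLUMNS = {
    "moss_a": "moss_a",
    "moss_b": "moss_b",
    "species": "ref_species",
    "method": "method",
    "publication": "publication",
    "source_db": "source_db",
    "ref_a": "ref_a",
    "ref_b": "ref_b",
}


@dataclass
class ParsedEvidence:
    predictions: list[RawPrediction]
    skipped: int = 0


def read_evidence_table(
    path: Path | str,
    column_map: Optional[dict[str, str]] = None,
    method_dict: Optional[MethodDictionary] = None,
) -> ParsedEvidence:
    """Read a raw-prediction evidence spreadsheet (one row per evidence item).

    The layout is configurable through *column_map* (role → column name; see
    ``EVIDENCE_COLUMNS`` for roles and defaults) because supplementary
    spreadsheets vary.  ``source_db``, ``ref_a`` and ``ref_b`` are optional
    columns.  Rows missing either moss id are skipped and counted.  No
    deduplication happens here: duplicated rows become duplicated records.
    """
    cols = dict(EVIDENCE_COLUMNS)
    if column_map:
        cols.update(column_map)
    md = method_dict or MethodDictionary.default()
    predictions: list[RawPrediction] = []
    skipped = 0
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            a = (row.get(cols["moss_a"]) or "").strip()
            b = (row.get(cols["moss_b"]) or "").strip()
            if not a or not b:
                skipped += 1
                continue
            ev = EvidenceRecord(
                species=(row.get(cols["species"]) or "NR").strip(),
                method=md.normalize((row.get(cols["method"]) or "NR")),
                publication=(row.get(cols["publication"]) or "NR").strip(),
                source_db=(row.get(cols["source_db"]) or "other").strip(),
                source_pair=(
                    (row.get(cols["ref_a"]) or "").strip(),
                    (row.get(cols["ref_b"]) or "").strip(),
                ),
            )
            pair = (a, b) if a <= b else (b, a)
            predictions.append(RawPrediction(pair, ev))
    log.info("%s: %d evidence rows, %d skipped", path, len(predictions), skipped)
    return ParsedEvidence(predictions, skipped)


def write_evidence_table(predictions: Iterable[RawPrediction], path: Path | str) -> None:
    """Write raw predictions in the default evidence layout (round-trips)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["moss_a", "moss_b", "ref_species", "method", "publication", "source_db", "ref_a", "ref_b"])
        for p in predictions:
            e = p.evidence
            w.writerow([p.pair[0], p.pair[1], e.species, e.method, e.publication,
                        e.source_db, e.source_pair[0], e.source_pair[1]])


# ---------------------------------------------------------------------------
# Network export (SIF + node attributes)


def write_network_export(
    network: nx.Graph,
    node_attributes: Optional[dict[str, dict]] = None,
    path_prefix: Path | str = "network",
) -> tuple[Path, Path]:
    """Write a SIF edge file and a node-attribute table.

    SIF lines are ``nodeA <tab> pp <tab> nodeB``, one per unique canonical
    edge (self-loops produce ``A pp A``).  The attribute table always carries
    id and degree; extra per-node columns come from *node_attributes*.
    """
    if network.number_of_nodes() == 0:
        raise ValueError("refusing to export an empty network")
    prefix = Path(path_prefix)
    sif_path = prefix.with_suffix(".sif")
    attr_path = prefix.parent / (prefix.name + "_nodes.tsv")
    edges = sorted(tuple(sorted((u, v))) for u, v in network.edges())
    with open(sif_path, "w", newline="") as fh:
        for u, v in edges:
            fh.write(f"{u}\tpp\t{v}\n")
    extra_cols: list[str] = []
    if node_attributes:
        seen = set()
        for attrs in node_attributes.values():
            for k in attrs:
                if k not in seen:
                    seen.add(k)
                    extra_cols.append(k)
    with open(attr_path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["id", "degree"] + extra_cols)
        for node in sorted(network.nodes()):
            attrs = (node_attributes or {}).get(node, {})
            w.writerow([node, network.degree(node)] + [attrs.get(c, "") for c in extra_cols])
    return sif_path, attr_path


def read_sif(path: Path | str) -> nx.Graph:
    """Re-import a SIF edge file written by :func:`write_network_export`."""
    g = nx.Graph()
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 3:
                continue
            a, _, b = parts
            g.add_edge(a, b)
    return g


# ---------------------------------------------------------------------------
# GO annotations

AnnotationMap = dict[str, set[str]]


def read_slim_map(path: Path | str) -> dict[str, str]:
    """Two-column term → slim-term projection table."""
    out: dict[str, str] = {}
    for row in _data_rows(path):
        if len(row) != 2:
            raise ValueError(f"slim map row needs 2 columns: {row}")
        out[row[0].strip()] = row[1].strip()
    return out


def read_go_annotations(
    path: Path | str,
    slim_map: Optional[dict[str, str]] = None,
) -> AnnotationMap:
    """Read a two-column gene → GO-term table into a gene → term-set map.

    With *slim_map*, terms are projected onto their slim terms (terms absent
    from the map are dropped) and duplicates collapse; genes whose terms all
    vanish are retained with an empty set.
    """
    annotations: AnnotationMap = {}
    for row in _data_rows(path):
        if len(row) != 2:
            raise ValueError(f"annotation row needs 2 columns: {row}")
        gene, term = row[0].strip(), row[1].strip()
        terms = annotations.setdefault(gene, set())
        if slim_map is not None:
            if term in slim_map:
                terms.add(slim_map[term])
        else:
            terms.add(term)
    return annotations


def write_go_annotations(annotations: AnnotationMap, path: Path | str) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["gene", "term"])
        for gene in sorted(annotations):
            for term in sorted(annotations[gene]):
                w.writerow([gene, term])


# ---------------------------------------------------------------------------
# Identifier mapping tables


def read_mapping_table(path: Path | str) -> list[tuple[IdentifierRef, IdentifierRef]]:
    """Two-column namespaced mapping table (``ns:acc <tab> ns:acc``)."""
    entries: list[tuple[IdentifierRef, IdentifierRef]] = []
    for row in _data_rows(path):
        if len(row) != 2:
            raise ValueError(f"mapping row needs 2 columns: {row}")
        entries.append((IdentifierRef.parse(row[0]), IdentifierRef.parse(row[1])))
    return entries
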