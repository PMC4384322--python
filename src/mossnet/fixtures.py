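"""Deterministic synthetic worlds with planted ground truth.

A *world* is a miniature version of the study system: a toy target proteome,
per-reference-species one-to-one ortholog clusters (with inparalogs that
must be left out), reference interaction tables split across four source
databases in their respective dialects, identifier mapping tables, and a GO
annotation table with one planted enriched term.  A manifest records, for
every planted unique interaction, its true evidence count and (R, E, S, CV),
so the whole pipeline can be verified end to end with no external data.

Every artifact type draws from its own named pseudo-random stream derived
from the single world seed, so adding an artifact never perturbs existing
ones, and regeneration with the same seed is byte-identical on any platform.

Default world dimensions emulate the study conditions at desk scale: a few
hundred target proteins, four reference species with ortholog fractions
falling from ~0.5 (a close, well-annotated reference) to ~0.15 (a distant
prokaryote), evidence dominated by single-reference low-confidence
interactions with a planted tail of multi-species high-confidence ones —
mirroring the heavily low-CV-skewed confidence distribution such predicted
interactomes show.
"""

from __future__ import annotations

import csv
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

#: raw method vocabulary (as found in database exports) and canonical codes
DEFAULT_METHODS = ("Two-hybrid", "Affinity Capture-MS", "Reconstituted Complex",
                   "Co-purification", "Negative Genetic", "Far Western")

SOURCE_DIALECTS = {
    "BioGrid": "biogrid-tab",
    "IntAct": "mitab",
    "DIP": "generic-tsv",
    "BIND": "bind-flat",
}


@dataclass(frozen=True)
class SpeciesSpec:
    """One reference species of the synthetic world."""

    name: str
    id_prefix: str
    ortholog_fraction: float
    n_decoy_interactions: int = 10

    def __post_init__(self) -> None:
        if not (0.0 <= self.ortholog_fraction <= 1.0):
            raise ValueError("ortholog_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class PlantedEvidence:
    """Desired evidence structure of one planted unique interaction."""

    r: int = 1
    e: int = 1
    s: int = 1

    @property
    def cv(self) -> int:
        return self.r * self.e * self.s


@dataclass
class WorldSpec:
    seed: int = 0
    n_target_proteins: int = 200
    species: tuple[SpeciesSpec, ...] = (
        SpeciesSpec("human", "HS", 0.50, 12),
        SpeciesSpec("yeast", "SC", 0.35, 12),
        SpeciesSpec("fruitfly", "DM", 0.30, 8),
        SpeciesSpec("ecoli", "EC", 0.15, 6),
    )
    n_publications: int = 60
    methods: tuple[str, ...] = DEFAULT_METHODS
    n_planted_interactions: int = 60
    #: explicitly structured high-evidence interactions, prepended to the
    #: random singletons; defaults exercise the two canonical CV examples
    planted_high_cv: tuple[PlantedEvidence, ...] = (
        PlantedEvidence(4, 2, 3),
        PlantedEvidence(4, 1, 1),
        PlantedEvidence(3, 3, 2),
        PlantedEvidence(2, 2, 1),
        PlantedEvidence(2, 1, 1),
    )
    inparalog_rate: float = 0.25
    same_db_duplicate_rate: float = 0.08
    n_go_terms: int = 20
    go_background_rate: float = 0.15
    enriched_term: str = "GO:0000001"
    enrichment_fold: float = 5.0
    n_study_genes: int = 30

    def validate(self) -> None:
        n = self.n_target_proteins
        if self.n_planted_interactions + len(self.planted_high_cv) > n * (n - 1) // 2:
            raise ValueError("more planted interactions than available protein pairs")
        for p in self.planted_high_cv:
            if min(p.r, p.e, p.s) < 1:
                raise ValueError("planted R, E, S must all be >= 1")
            if p.s > len(self.species):
                raise ValueError("planted S exceeds the number of reference species")
            if p.r > self.n_publications or p.e > len(self.methods):
                raise ValueError("planted R/E exceed the publication/method vocabulary")


@dataclass
class WorldManifest:
    """Ground truth of a generated world."""

    interactions: list[dict] = field(default_factory=list)  # pair truth rows
    n_raw_predictions: int = 0
    n_unique_interactions: int = 0
    n_proteins: int = 0
    ortholog_counts: dict[str, int] = field(default_factory=dict)
    study_genes: list[str] = field(default_factory=list)
    enriched_term: str = ""


def _stream(seed: int, name: str) -> np.random.Generator:
    """Independent deterministic stream per artifact type."""
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(name.encode())])


def generate_world(spec: WorldSpec, out_dir: Path | str) -> WorldManifest:
    """Write a complete synthetic world to *out_dir* and return its truth."""
    spec.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    proteins = [f"Pp{i:04d}" for i in range(1, spec.n_target_proteins + 1)]
    species_names = [s.name for s in spec.species]
    pubs = [f"pm{i:05d}" for i in range(1, spec.n_publications + 1)]

    # ---- plant unique interactions and their evidence structure ----
    rng = _stream(spec.seed, "interactions")
    plans: list[PlantedEvidence] = list(spec.planted_high_cv)
    plans += [PlantedEvidence(1, 1, 1)] * spec.n_planted_interactions
    pair_set: set[tuple[str, str]] = set()
    planted: list[tuple[tuple[str, str], PlantedEvidence]] = []
    while len(planted) < len(plans):
        a, b = rng.choice(len(proteins), size=2, replace=False)
        pair = tuple(sorted((proteins[a], proteins[b])))
        if pair in pair_set:
            continue
        pair_set.add(pair)
        planted.append((pair, plans[len(planted)]))

    # per-species ortholog assignment: forced by planted evidence first
    orthologs: dict[str, dict[str, str]] = {s.name: {} for s in spec.species}
    ref_counter: dict[str, int] = {s.name: 0 for s in spec.species}

    def ref_id(sp: SpeciesSpec, moss: str) -> str:
        table = orthologs[sp.name]
        if moss not in table:
            ref_counter[sp.name] += 1
            table[moss] = f"{sp.id_prefix}{ref_counter[sp.name]:05d}"
        return table[moss]

    sp_by_name = {s.name: s for s in spec.species}
    evidence_rows: list[tuple[tuple[str, str], str, str, str, str]] = []  # pair, sp, method, pub, db
    manifest = WorldManifest(enriched_term=spec.enriched_term)
    db_names = sorted(SOURCE_DIALECTS)
    for pair, plan in planted:
        chosen_species = [species_names[i] for i in
                          sorted(rng.choice(len(species_names), size=plan.s, replace=False))]
        chosen_pubs = [pubs[i] for i in rng.choice(len(pubs), size=plan.r, replace=False)]
        chosen_methods = [spec.methods[i] for i in rng.choice(len(spec.methods), size=plan.e, replace=False)]
        for sp_name in chosen_species:
            ref_id(sp_by_name[sp_name], pair[0])
            ref_id(sp_by_name[sp_name], pair[1])
        rows: set[tuple] = set()
        n_rows = max(plan.r, plan.e, plan.s)
        for i in range(n_rows):
            db = db_names[int(rng.integers(len(db_names)))]
            rows.add((pair, chosen_species[i % plan.s], chosen_methods[i % plan.e],
                      chosen_pubs[i % plan.r], db))
        evidence_rows.extend(sorted(rows))
        manifest.interactions.append({
            "moss_a": pair[0], "moss_b": pair[1], "n_evidence": len(rows),
            "R": plan.r, "E": plan.e, "S": plan.s, "CV": plan.cv,
        })
    manifest.n_raw_predictions = sum(m["n_evidence"] for m in manifest.interactions)
    manifest.n_unique_interactions = len(manifest.interactions)
    manifest.n_proteins = len({p for m in manifest.interactions
                               for p in (m["moss_a"], m["moss_b"])})

    # ---- top up orthologs to the per-species fractions ----
    rng_orth = _stream(spec.seed, "orthologs")
    for sp in spec.species:
        want = round(sp.ortholog_fraction * spec.n_target_proteins)
        pool = [p for p in proteins if p not in orthologs[sp.name]]
        extra = max(0, want - len(orthologs[sp.name]))
        for i in rng_orth.choice(len(pool), size=min(extra, len(pool)), replace=False):
            ref_id(sp, pool[i])
    manifest.ortholog_counts = {s.name: len(orthologs[s.name]) for s in spec.species}

    # ---- cluster table (with inparalogs that must be excluded) ----
    rng_cl = _stream(spec.seed, "clusters")
    cluster_rows: list[list[str]] = []
    cid = 0
    for sp in spec.species:
        unmapped = [p for p in proteins if p not in orthologs[sp.name]]
        for moss in sorted(orthologs[sp.name]):
            cid += 1
            cluster_id = f"c{cid:05d}"
            cluster_rows.append([cluster_id, "moss", "1.0", moss])
            cluster_rows.append([cluster_id, sp.name, "1.0", orthologs[sp.name][moss]])
            if unmapped and rng_cl.random() < spec.inparalog_rate:
                inp = unmapped[int(rng_cl.integers(len(unmapped)))]
                cluster_rows.append([cluster_id, "moss", f"{rng_cl.uniform(0.2, 0.9):.3f}", inp])
            if rng_cl.random() < spec.inparalog_rate:
                ref_counter[sp.name] += 1
                cluster_rows.append([cluster_id, sp.name, f"{rng_cl.uniform(0.2, 0.9):.3f}",
                                     f"{sp.id_prefix}{ref_counter[sp.name]:05d}"])
    _write_tsv(out / "clusters.tsv", ["cluster_id", "species", "score", "protein_id"], cluster_rows)

    # ---- reference interaction tables per source database ----
    rng_db = _stream(spec.seed, "databases")
    db_rows: dict[str, list[tuple]] = {db: [] for db in SOURCE_DIALECTS}
    for pair, sp_name, method, pub, db in evidence_rows:
        ra = orthologs[sp_name][pair[0]]
        rb = orthologs[sp_name][pair[1]]
        db_rows[db].append((ra, rb, sp_name, method, pub))
        if rng_db.random() < spec.same_db_duplicate_rate:
            db_rows[db].append((ra, rb, sp_name, method, pub))  # collapses at merge
    # decoys: one partner has no target ortholog, so nothing transfers
    for sp in spec.species:
        mapped_refs = sorted(orthologs[sp.name].values())
        for i in range(sp.n_decoy_interactions):
            ref_counter[sp.name] += 1
            lone = f"{sp.id_prefix}{ref_counter[sp.name]:05d}"
            partner = (mapped_refs[int(rng_db.integers(len(mapped_refs)))]
                       if mapped_refs and rng_db.random() < 0.5
                       else f"{sp.id_prefix}X{i:04d}")
            db = db_names[int(rng_db.integers(len(db_names)))]
            method = spec.methods[int(rng_db.integers(len(spec.methods)))]
            pub = pubs[int(rng_db.integers(len(pubs)))]
            db_rows[db].append((lone, partner, sp.name, method, pub))
    _write_interaction_tables(out, db_rows)

    # ---- identifier mapping tables ----
    all_refs: set[str] = set()
    for rows in db_rows.values():
        for ra, rb, *_ in rows:
            all_refs.update((ra, rb))
    mapping_rows = []
    for ref in sorted(all_refs):
        if "X" in ref:
            continue  # decoy ids with no cross-reference: dropped at merge
        mapping_rows.append([f"entrez:E{ref}", f"uniprot:{ref}"])
        mapping_rows.append([f"native:B{ref}", f"uniprot:{ref}"])
    _write_tsv(out / "mappings.tsv", ["source", "target"], mapping_rows)

    # ---- GO annotations with one planted enriched term ----
    rng_go = _stream(spec.seed, "annotations")
    study_idx = rng_go.choice(len(proteins), size=spec.n_study_genes, replace=False)
    study = sorted(proteins[i] for i in study_idx)
    manifest.study_genes = study
    study_set = set(study)
    terms = [f"GO:{i:07d}" for i in range(1, spec.n_go_terms + 1)]
    if spec.enriched_term not in terms:
        terms.append(spec.enriched_term)
    ann_rows = []
    p_enriched = min(1.0, spec.enrichment_fold * spec.go_background_rate)
    for gene in proteins:
        for term in terms:
            p = spec.go_background_rate
            if term == spec.enriched_term:
                p = p_enriched if gene in study_set else spec.go_background_rate
            if rng_go.random() < p:
                ann_rows.append([gene, term])
    _write_tsv(out / "annotations.tsv", ["gene", "term"], ann_rows)
    (out / "study_genes.txt").write_text("".join(g + "\n" for g in study))

    # ---- manifest ----
    _write_tsv(out / "manifest.tsv",
               ["moss_a", "moss_b", "n_evidence", "R", "E", "S", "CV"],
               [[m["moss_a"], m["moss_b"], m["n_evidence"], m["R"], m["E"], m["S"], m["CV"]]
                for m in manifest.interactions])
    _write_tsv(out / "world_summary.tsv",
               ["n_raw_predictions", "n_unique_interactions", "n_proteins", "enriched_term"],
               [[manifest.n_raw_predictions, manifest.n_unique_interactions,
                 manifest.n_proteins, manifest.enriched_term]])
    return manifest


def _write_tsv(path: Path, header: list[str], rows) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(header)
        w.writerows(rows)


def _write_interaction_tables(out: Path, db_rows: dict[str, list[tuple]]) -> None:
    """Write each database's rows in its dialect (ids re-namespaced per db)."""
    for db, rows in db_rows.items():
        path = out / f"interactions_{db.lower()}.tsv"
        if db == "BioGrid":
            header = ["interactor_a", "interactor_b", "experimental_system", "pubmed_id", "organism"]
            body = [[f"E{ra}", f"E{rb}", method, pub, sp] for ra, rb, sp, method, pub in rows]
        elif db == "IntAct":
            header = ["id_a", "id_b", "detection_method", "publication", "taxon"]
            body = [[f"uniprotkb:{ra}", f"uniprotkb:{rb}", method, pub, sp]
                    for ra, rb, sp, method, pub in rows]
        elif db == "BIND":
            header = ["id_a", "id_b", "species", "method", "publication"]
            body = [[f"B{ra}", f"B{rb}", sp, method, pub] for ra, rb, sp, method, pub in rows]
        else:  # DIP, generic-tsv
            header = ["interactor_a", "interactor_b", "species", "method", "publication", "source_db"]
            body = [[f"uniprot:{ra}", f"uniprot:{rb}", sp, method, pub, "DIP"]
                    for ra, rb, sp, method, pub in rows]
        _write_tsv(path, header, body)


def world_files(out_dir: Path | str) -> dict[str, Path]:
    """Paths of the standard artifacts of a generated world."""
    out = Path(out_dir)
    files = {
        "clusters": out / "clusters.tsv",
        "mappings": out / "mappings.tsv",
        "annotations": out / "annotations.tsv",
        "study_genes": out / "study_genes.txt",
        "manifest": out / "manifest.tsv",
    }
    for db, dialect in SOURCE_DIALECTS.items():
        files[f"interactions_{db}"] = out / f"interactions_{db.lower()}.tsv"
    return files


def generate_scale_free_graph(n: int, attachment: int, seed: int):
    """Preferential-attachment (Barabási–Albert) graph, deterministic under seed.

    Each of the n − m added nodes attaches m = *attachment* edges, giving
    m·(n − m) edges.
    """
    import networkx as nx

    if not (1 <= attachment < n):
        raise ValueError("need n > attachment >= 1")
    return nx.barabasi_albert_graph(n, attachment, seed=seed)
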