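# Methods

## The interolog model

The package predicts protein–protein interactions in a target species by
transferring experimentally observed interactions from reference species
through orthology.  The underlying assumption is that one-to-one orthologs —
genes related purely by speciation, without intervening duplication — retain
their interaction partners over long evolutionary distances.  This is a
conservative model: it deliberately excludes inparalogs (post-speciation
duplicates), because after duplication the relaxed selection pressure makes
neo- or sub-functionalization likely, and a duplicate cannot be assumed to
keep all of its ancestor's partners.  The prediction is therefore a
*conserved skeleton* of the real interactome: interactions involving
lineage-specific proteins are invisible to the method by construction, and
the output is biased toward deeply conserved processes (metabolism,
translation, DNA/RNA machinery).  Enrichment analyses run on predicted
networks must be read with that ascertainment bias in mind.

## Pipeline stages and their contracts

**Identifier translation.** Reference databases export interactors under
different identifier systems.  The translator loads direct cross-references
between UniProt, Entrez and Ensembl identifiers and rewrites every
interactor to the highest-priority namespace (uniprot > entrez > ensembl)
reachable in a *single* hop.  Transitive closure is intentionally not taken:
chaining noisy cross-references (a→b, b→c ⇒ a→c) is the classic way to merge
two distinct proteins.  Ambiguous multi-mappings are kept and flagged; the
canonical choice among them is the lexicographically smallest accession,
which is a documented determinism convention, not a biological claim.

**Merge.** Records whose interactors cannot be expressed in any chosen
namespace are dropped (each interactor must carry at least one of the three
identifiers).  The dedup key is (canonical unordered pair, species, method,
publication, source database) — deliberately *including* the source
database, so that the same experiment indexed by two databases survives to
the evidence stage as two records with distinct provenance.  Pooling across
databases happens only in the confidence computation, which counts distinct
publications, so double-indexed experiments never inflate the score.

**Ortholog selection.** From each two-species cluster exactly one (target,
reference) pair is taken: the highest inparalog score on each side, ties by
smallest protein id.  If two clusters of the same species pair claim the
same protein, the cluster with the larger combined seed score wins (then
smallest cluster id) and the loser contributes nothing; conflicts are
logged.  The result is a strict bijection on the mapped subset per species.

**Transfer and deduplication.** A reference record in species *s* transfers
iff both interactors are in *s*'s mapping.  Transferred pairs are stored
unordered (lexicographic canonical form); self-loops are retained — true
homodimers are biologically meaningful — and heterodimers that collapse onto
one target protein (both partners mapping to the same ortholog) are kept but
flagged.  Deduplication groups raw predictions by pair; evidence lists
partition the raw list exactly (conservation is asserted in the pipeline).

**Confidence value.** For each unique interaction, R = distinct publication
ids, E = distinct canonical method codes, S = distinct reference species,
and CV = R·E·S.  R counts publications, not rows, so databases that index
the same PubMed record do not raise confidence.  Method strings are
normalized through a shipped, table-driven dictionary of experimental-system
codes (unknowns map to NR, "not reported"); publication ids are compared as
trimmed case-sensitive strings.  Classes partition the integers:
CV = 1 low, 2 ≤ CV ≤ 10 medium (both ends inclusive — the only reading under
which the three classes partition all attainable values), CV > 10 high.

## Network analysis choices

Degrees are computed on the deduplicated network (edge multiplicity one,
confidence ignored); a self-loop contributes one interaction by default
(switchable).  Node classes by degree: 1 free end, 2 pipe, 3–5 minor hub,
6–10 small hub, 11–50 medium hub, 51–100 major hub, > 100 super hub.  The
free-end/pipe/medium/major boundaries are the field's established hub
nomenclature for these interactomes; the minor/small cutoffs are a repo
convention and are configurable.

The power-law check is a least-squares line on log10(count) versus log10(bin
midpoint) over the nonzero bins of a width-10 degree histogram — the way
such distributions are conventionally presented — rather than a
maximum-likelihood exponent estimate.  It requires ≥ 3 nonzero bins and
recovers a planted exponent exactly (to 1e-6) when counts are exactly
power-law; the r² is a descriptive goodness number, not a hypothesis test.

Robustness to hub loss deletes the k highest-degree nodes (ties broken
lexicographically, so ranking is deterministic) and compares component
structure: a "party/date-hub" topology fragments, a "stratus" topology with
densely overlapping neighborhoods keeps a giant component.

Bait–prey capture takes the induced subgraph over the baits present in the
network plus all their first neighbors; prey–prey edges are included, since
intermediates connecting baits are part of the captured process.  A node's
connectivity ratio is its induced degree over its full-network degree; the
average is taken over *all* subnetwork nodes (baits and prey) — the
prey-only mean is available by filtering the per-node table.

Enrichment is a one-sided hypergeometric test per annotated term (over:
P(X ≥ k); under: P(X ≤ k)) against a background universe defaulting to all
annotated genes, with Benjamini–Hochberg adjustment across the tested terms
and a 0.05 default threshold on adjusted values.  GO-graph propagation (the
true-path rule) is not performed; a slim projection, if supplied, is assumed
pre-propagated.  This is a known limitation: terms are tested exactly as
annotated.

Overlap validation exposes the pair-universe size as an explicit parameter:
the chance expectation n1·n2/P of two random pair sets is meaningless
without stating P, so the caller must choose it (e.g. C(N, 2) over a defined
proteome).

## The synthetic worlds

`fixtures.generate_world` emulates the full input suite at desk scale: a toy
target proteome (default 200 proteins), four reference species with ortholog
fractions 0.50/0.35/0.30/0.15 (falling from a close, data-rich reference to
a distant prokaryote), ortholog clusters salted with inparalogs that the
selection stage must discard, reference interactions split across four
source-database dialects (including identifier indirection through Entrez
and native ids, same-database duplicate rows, and decoy interactions that
must not transfer), a GO annotation table with one term planted at 5× the
0.15 background rate in a 30-gene study set, and a manifest recording every
planted interaction's true evidence count and (R, E, S, CV).  Evidence
structure is dominated by single-reference CV = 1 interactions with a small
planted multi-species tail, mirroring the heavily low-confidence-skewed
distributions that interolog predictions show in practice.  Each artifact
type draws from its own seeded stream, so worlds are byte-identical across
platforms and adding an artifact never perturbs the others.

What the worlds do **not** emulate: real sequence-level orthology (clusters
are planted, not inferred), realistic GO DAG structure, the size and
redundancy of real reference databases, and study-specific identifier
pathologies (obsolete accessions, secondary ids).  Passing tests therefore
demonstrate the correctness of the bookkeeping and statistics, not the
biological accuracy of any particular predicted interactome.

Default problem sizes throughout the tests (hundreds of proteins, tens of
planted interactions, 10,000 Monte-Carlo draws, exhaustive hypergeometric
enumeration up to N = 12) were chosen so the full suite verifies every
contract exhaustively at small n where exhaustive oracles are available.

## Numerical and degeneracy conventions

- All pair canonicalization is lexicographic; every ranking (hubs, merge
  output, enrichment results) has a total deterministic order.
- The preferential-attachment generator follows the standard construction in
  which each of the n − m added nodes attaches m edges, giving m·(n − m)
  edges; for attachment m ≥ 2 the seed component is a star rather than a
  clique, so the "complete graph" limit at n = m + 1 holds only for m = 1.
- Degree-0 nodes are excluded from classification with a warning; empty
  networks refuse to export; empty evidence lists and empty study sets are
  errors, not silent zeros.
- BH adjustment delegates to the standard step-up implementation and is
  cross-checked against a brute-force oracle in the tests; the
  hypergeometric tail likewise delegates to the standard distribution and is
  cross-checked against exhaustive enumeration for all instances with
  N ≤ 12.
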