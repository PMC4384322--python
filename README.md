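# mossnet

Interolog-based protein–protein interaction prediction and network analysis,
built around the workflow used to construct the predicted interactome of the
moss *Physcomitrella patens*.

## The problem

Experimental interactome maps exist for only a handful of model organisms.
For everything else, interactions can be *transferred*: if proteins A′ and B′
interact in a well-studied reference species, and a target-species protein A
is the one-to-one ortholog of A′ while B is the ortholog of B′, then A–B is a
predicted interaction (an **interolog**). `mossnet` implements this transfer
end to end:

1. **Merge** reference interaction records exported from multiple databases
   (BioGrid / DIP / IntAct / BIND-style tables), unifying UniProt, Entrez and
   Ensembl identifiers through a one-hop cross-reference translator.
2. **Select orthologs**: strict one-to-one pairs per reference species from
   InParanoid-style clusters, deliberately excluding inparalogs.
3. **Transfer** every reference interaction whose two partners both have
   orthologs in that species; canonicalize and deduplicate the resulting
   target-species pairs.
4. **Score** each unique interaction with the multiplicative confidence value

   CV = R × E × S

   where R = distinct supporting publications, E = distinct experimental
   method codes, S = distinct reference species.  Evidence from 4
   publications over 2 methods in 3 species gives CV = 4 × 2 × 3 = 24; four
   publications with one method in one species give CV = 4.  Classes:
   CV = 1 low, 2–10 medium, > 10 high.
5. **Analyze** the network: degree classes (free ends, pipes, hub tiers),
   binned degree distributions with a log–log power-law fit, top-hub ranking
   and hub-deletion robustness, bait–prey subnetwork capture with
   connectivity ratios, hypergeometric GO enrichment with Benjamini–Hochberg
   FDR, and overlap validation against an experimental interaction set.

A deterministic synthetic-world generator (`mossnet.fixtures`) emulates all
inputs with planted ground truth, so the whole pipeline is testable offline.

## Worked example

```sh
mossnet simulate --seed 5 --out world --n-proteins 80
mossnet merge \
    --table generic-tsv:world/interactions_dip.tsv \
    --table biogrid-tab:world/interactions_biogrid.tsv \
    --table mitab:world/interactions_intact.tsv \
    --table bind-flat:world/interactions_bind.tsv \
    --mappings world/mappings.tsv --out merged.tsv
mossnet orthologs --clusters world/clusters.tsv --out orthologs.tsv
mossnet predict --merged merged.tsv --ortholog-map orthologs.tsv \
    --evidence-out evidence.tsv --unique-out unique.tsv
```

which prints (to stderr):

```
merged 120 records -> 106 (7 dropped, 7 collapsed)
ortholog pairs per species: ecoli=31, fruitfly=24, human=40, yeast=29
75 raw predictions, 65 unique (low=60, medium=3, high=2)
```

120 database rows lose 7 records whose interactors have no UniProt/Entrez/
Ensembl identifier and 7 exact duplicates; 75 of the merged records transfer
(both partners orthologous), collapsing to 65 unique moss pairs, most with a
single piece of evidence (low confidence, CV = 1) and a planted tail of
multi-evidence medium/high-confidence interactions.  `unique.tsv` lists each
pair with its R, E, S, CV and class; `mossnet topology`, `subnet`, `enrich`
and `validate` consume these intermediates.

The same chain is available as a single command from a YAML config
(`mossnet run --config config.yaml --out out/`), and as plain library calls.

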