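"""Interolog transfer, deduplication, and the multiplicative confidence value."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from mossnet.interolog import (
    canonicalize_pair,
    class_counts,
    classify_confidence,
    compute_cv,
    deduplicate,
    predict_interologs,
)
from mossnet.records import (
    EvidenceRecord,
    IdentifierRef,
    OrthologMap,
    RawPrediction,
    SourceInteractionRecord,
)


def ev(pub="pm1", method="Y2H", species="human", db="DIP"):
    return EvidenceRecord(species, method, pub, db, ("r1", "r2"))


ids = st.text(alphabet="abcdefgh", min_size=1, max_size=4)


class TestCanonicalPair:
    def test_orders_lexicographically(self):
        assert canonicalize_pair("B", "A") == ("A", "B")

    def test_self_pair_allowed(self):
        assert canonicalize_pair("A", "A") == ("A", "A")

    @given(ids, ids)
    def test_idempotent_and_unordered(self, a, b):
        once = canonicalize_pair(a, b)
        assert canonicalize_pair(*once) == once == canonicalize_pair(b, a)

    def test_empty_id_rejected(self):
        with pytest.raises(ValueError):
            canonicalize_pair("", "A")


class TestComputeCv:
    def test_four_pubs_two_methods_three_species_gives_24(self):
        evidence = [
            ev("pm1", "Y2H", "human"), ev("pm2", "AC", "yeast"),
            ev("pm3", "Y2H", "fly"), ev("pm4", "AC", "human"),
        ]
        s = compute_cv(evidence)
        assert (s.R, s.E, s.S, s.cv) == (4, 2, 3, 24)
        assert s.confidence_class == "high"

    def test_four_pubs_same_method_same_species_gives_4(self):
        evidence = [ev(f"pm{i}") for i in range(4)]
        s = compute_cv(evidence)
        assert (s.R, s.E, s.S, s.cv) == (4, 1, 1, 4)
        assert s.confidence_class == "medium"

    def test_singleton_evidence_gives_cv_1(self):
        s = compute_cv([ev()])
        assert (s.R, s.E, s.S, s.cv) == (1, 1, 1, 1)
        assert s.confidence_class == "low"

    def test_duplicate_publications_do_not_inflate_R(self):
        # the same PubMed id reported by two source databases counts once
        s = compute_cv([ev("pm1", db="DIP"), ev("pm1", db="BioGrid")])
        assert s.R == 1 and s.cv == 1

    def test_empty_evidence_rejected(self):
        with pytest.raises(ValueError):
            compute_cv([])

    @settings(deadline=None, max_examples=60)
    @given(st.lists(st.tuples(st.integers(0, 5), st.integers(0, 3), st.integers(0, 3)),
                    min_size=1, max_size=12))
    def test_cv_monotone_under_appended_evidence(self, items):
        evidence = [ev(f"pm{r}", f"M{m}", f"sp{s}") for r, m, s in items]
        prev = compute_cv(evidence[:1])
        for i in range(2, len(evidence) + 1):
            cur = compute_cv(evidence[:i])
            assert cur.R >= prev.R and cur.E >= prev.E and cur.S >= prev.S
            assert cur.cv >= prev.cv >= max(prev.R, prev.E, prev.S)
            prev = cur


class TestClassify:
    @pytest.mark.parametrize("cv,expected", [
        (1, "low"), (2, "medium"), (10, "medium"), (11, "high"), (24, "high"),
    ])
    def test_printed_class_definitions(self, cv, expected):
        assert classify_confidence(cv) == expected

    def test_cv_below_one_invalid(self):
        with pytest.raises(ValueError):
            classify_confidence(0)

    @given(st.integers(1, 10_000))
    def test_every_cv_maps_to_exactly_one_class(self, cv):
        assert classify_confidence(cv) in ("low", "medium", "high")


def _omap(mapping, species="human"):
    return OrthologMap("moss", {species: {r: (t, "c") for r, t in mapping.items()}})


def _ref(a, b, species="human", method="Y2H", pub="pm1", db="DIP"):
    return SourceInteractionRecord(IdentifierRef("uniprot", a), IdentifierRef("uniprot", b),
                                   species, method, pub, db)


class TestPredict:
    def test_direct_transfer_with_provenance(self):
        result = predict_interologs([_ref("h1", "h2")], _omap({"h1": "m1", "h2": "m2"}))
        [p] = result.predictions
        assert p.pair == ("m1", "m2")
        assert p.evidence.species == "human" and p.evidence.source_pair == ("h1", "h2")

    def test_both_partners_must_map(self):
        result = predict_interologs([_ref("h1", "h3")], _omap({"h1": "m1", "h2": "m2"}))
        assert result.predictions == [] and result.n_unmapped == 1

    def test_species_mapping_is_respected(self):
        # ortholog exists, but in the wrong species' mapping
        result = predict_interologs([_ref("h1", "h2", species="yeast")],
                                    _omap({"h1": "m1", "h2": "m2"}, species="human"))
        assert result.predictions == []

    def test_collapsed_heterodimer_flagged_as_self_loop(self):
        result = predict_interologs([_ref("h1", "h2")], _omap({"h1": "m1", "h2": "m1"}))
        [p] = result.predictions
        assert p.pair == ("m1", "m1") and p.collapsed

    def test_homodimer_self_loop_not_flagged(self):
        result = predict_interologs([_ref("h1", "h1")], _omap({"h1": "m1"}))
        [p] = result.predictions
        assert p.pair == ("m1", "m1") and not p.collapsed

    def test_matches_brute_force_double_lookup(self):
        rng = random.Random(17)
        mapping = {f"h{i}": f"m{i}" for i in rng.sample(range(40), 25)}
        omap = _omap(mapping)
        refs = [_ref(f"h{rng.randrange(40)}", f"h{rng.randrange(40)}",
                     pub=f"pm{rng.randrange(10)}") for _ in range(500)]
        result = predict_interologs(refs, omap)
        expected = []
        for r in refs:
            a, b = r.interactor_a.accession, r.interactor_b.accession
            if a in mapping and b in mapping:
                expected.append(tuple(sorted((mapping[a], mapping[b]))))
        assert [p.pair for p in result.predictions] == expected


class TestDeduplicate:
    def test_grouping_by_pair(self):
        raw = [RawPrediction(("A", "B"), ev("pm1")),
               RawPrediction(("A", "B"), ev("pm2")),
               RawPrediction(("A", "C"), ev("pm3"))]
        unique = deduplicate(raw)
        assert [u.pair for u in unique] == [("A", "B"), ("A", "C")]
        assert len(unique[0].evidence) == 2

    def test_empty_input(self):
        assert deduplicate([]) == []

    def test_unique_count_matches_independent_set_and_conserves_evidence(self):
        rng = random.Random(23)
        raw = [RawPrediction(tuple(sorted((f"m{rng.randrange(12)}", f"m{rng.randrange(12)}"))),
                             ev(f"pm{rng.randrange(6)}")) for _ in range(300)]
        unique = deduplicate(raw)
        assert len(unique) == len({p.pair for p in raw})
        assert sum(len(u.evidence) for u in unique) == len(raw)

    def test_class_counts_partition_unique_set(self, world):
        counts = class_counts(world["unique"])
        assert sum(counts.values()) == len(world["unique"])
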