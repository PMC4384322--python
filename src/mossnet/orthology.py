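"""Strict one-to-one ortholog selection from InParanoid-style clusters.

Each cluster pairs members of the target species (the moss) with members of
one reference species, every member carrying an inparalog score in [0, 1]
with the seed ortholog at 1.0.  Exactly one (target, reference) protein pair
is selected per cluster — the highest-scoring member on each side, ties
broken by lexicographically smallest protein id — so inparalogs never enter
the map.  If two clusters of the same species pair would claim the same
protein, the cluster with the higher combined seed score wins (then the
lexicographically smaller cluster id) and the loser contributes nothing.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from typing import Iterable, Sequence

from .records import OrthologCluster, OrthologMap

log = logging.getLogger(__name__)


def _best_member(members: Sequence[tuple[str, float]]) -> tuple[str, float]:
    # highest score first, then lexicographically smallest id
    return min(members, key=lambda m: (-m[1], m[0]))


def select_one_to_one(clusters: Iterable[OrthologCluster]) -> OrthologMap:
    """Pick one (target, reference) pair per cluster, enforcing bijectivity."""
    clusters = list(clusters)
    if not clusters:
        return OrthologMap(target_species="")
    target_species = clusters[0].species_pair[0]
    candidates: dict[str, list[tuple[float, str, str, str]]] = defaultdict(list)
    for cl in clusters:
        tsp, rsp = cl.species_pair
        if tsp != target_species:
            raise ValueError(f"mixed target species: {tsp!r} vs {target_species!r}")
        t_id, t_score = _best_member(cl.side(tsp))
        r_id, r_score = _best_member(cl.side(rsp))
        candidates[rsp].append((t_score + r_score, cl.cluster_id, t_id, r_id))

    omap = OrthologMap(target_species=target_species)
    for rsp in sorted(candidates):
        used_t: set[str] = set()
        used_r: set[str] = set()
        mapping: dict[str, tuple[str, str]] = {}
        # higher combined score first; cluster_id breaks ties deterministically
        for combined, cid, t_id, r_id in sorted(candidates[rsp], key=lambda c: (-c[0], c[1])):
            if t_id in used_t or r_id in used_r:
                omap.conflicts.append(cid)
                log.warning("cluster %s (%s) skipped: %s or %s already mapped", cid, rsp, t_id, r_id)
                continue
            used_t.add(t_id)
            used_r.add(r_id)
            mapping[r_id] = (t_id, cid)
        omap.pairs[rsp] = mapping
    return omap


def ortholog_counts(omap: OrthologMap) -> dict[str, int]:
    """Mapped-pair count per reference species."""
    return {sp: len(omap.pairs[sp]) for sp in omap.reference_species}


def shared_targets(omap: OrthologMap, species_a: str, species_b: str) -> set[str]:
    """Target proteins mapped in both of two reference species."""
    ta = {t for t, _ in omap.pairs.get(species_a, {}).values()}
    tb = {t for t, _ in omap.pairs.get(species_b, {}).values()}
    return ta & tb
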