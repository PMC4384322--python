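"""Overlap validation of a predicted interaction set against an experimental set.

Two canonical pair sets are intersected; the observed match count is put in
context by the overlap expected if both were uniform random draws of the
same sizes from a universe of P possible pairs:

    E[|A ∩ B|] = n1 * n2 / P

The universe size is an explicit caller-supplied parameter (for a proteome
of N proteins, P = C(N, 2), or C(N, 2) + N if self-pairs count) because the
choice materially changes the expectation and should never be implicit.
Match rates are additionally stratified by confidence class; the
high-versus-low rate ratio is the fold enrichment that indicates whether
higher confidence values actually mark better-supported predictions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .interolog import canonicalize_pair
from .records import UniqueInteraction

Pair = tuple[str, str]


def overlap(predicted: Iterable[Pair], experimental: Iterable[Pair]) -> int:
    """Size of the intersection of two canonical unordered pair sets."""
    return len(set(predicted) & set(experimental))


def expected_random_overlap(n1: int, n2: int, universe_pairs: int) -> float:
    """Expected intersection of two uniform random pair sets of fixed sizes."""
    if universe_pairs < 1:
        raise ValueError("universe_pairs must be >= 1")
    if n1 > universe_pairs or n2 > universe_pairs:
        raise ValueError("set sizes cannot exceed the pair universe")
    if n1 < 0 or n2 < 0:
        raise ValueError("set sizes must be >= 0")
    return n1 * n2 / universe_pairs


@dataclass
class OverlapReport:
    n_predicted: int
    n_experimental: int
    n_matched: int
    universe_pairs: int
    expected_by_chance: float
    fold_over_chance: float
    per_class_rates: dict[str, tuple[int, int]]  # class -> (matched, total)
    fold_high_vs_low: Optional[float]


def stratified_enrichment(
    predicted: Sequence[UniqueInteraction],
    experimental: Iterable[Pair],
) -> dict[str, tuple[int, int]]:
    """Per-confidence-class (matched, total) counts against the experimental set.

    Classes with zero members are absent from the result (their rate is
    undefined).
    """
    exp = {canonicalize_pair(*p) for p in experimental}
    per_class: dict[str, list[int]] = {}
    for ia in predicted:
        cls = ia.summary.confidence_class
        matched, total = per_class.setdefault(cls, [0, 0])
        per_class[cls][1] = total + 1
        if ia.pair in exp:
            per_class[cls][0] = matched + 1
    return {c: (m, t) for c, (m, t) in per_class.items()}


def overlap_report(
    predicted: Sequence[UniqueInteraction],
    experimental: Iterable[Pair],
    universe_pairs: int,
) -> OverlapReport:
    """Full validation report: match count, chance expectation, class folds."""
    exp = {canonicalize_pair(*p) for p in experimental}
    pred_pairs = {ia.pair for ia in predicted}
    matched = overlap(pred_pairs, exp)
    expected = expected_random_overlap(len(pred_pairs), len(exp), universe_pairs)
    per_class = stratified_enrichment(predicted, exp)
    fold_high_low = None
    if "high" in per_class and "low" in per_class:
        mh, th = per_class["high"]
        ml, tl = per_class["low"]
        if tl > 0 and ml > 0:
            fold_high_low = (mh / th) / (ml / tl)
    return OverlapReport(
        n_predicted=len(pred_pairs),
        n_experimental=len(exp),
        n_matched=matched,
        universe_pairs=universe_pairs,
        expected_by_chance=expected,
        fold_over_chance=(matched / expected) if expected > 0 else float("inf"),
        per_class_rates=per_class,
        fold_high_vs_low=fold_high_low,
    )
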