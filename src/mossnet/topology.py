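"""Network construction and topology statistics for the predicted interactome.

The network is an undirected :class:`networkx.Graph` over protein ids with
edge multiplicity 1 (self-loops permitted).  Nodes are classified by degree:

    1            free end
    2            pipe
    3–5          minor hub
    6–10         small hub
    11–50        medium hub
    51–100       major hub
    > 100        super hub

The free-end/pipe/medium/major boundaries follow the hub nomenclature used
for this interactome; the minor/small cutoffs are a configurable repo
convention.  Degree counts a self-loop as one interaction by default.

Scale-freeness is assessed the way such interactomes are usually presented:
degrees are binned (default width 10), and a least-squares line is fitted to
log10(count) vs log10(bin midpoint) over the nonzero bins.  Robustness to
hub loss is probed by deleting the top-k highest-degree nodes and comparing
component structure before and after — a "party/date-hub" (altocumulus)
topology shatters, a stratus topology with pervasively overlapping
neighborhoods stays connected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from .records import UniqueInteraction

log = logging.getLogger(__name__)

#: (upper degree bound inclusive, class name); np.inf closes the last class
DEFAULT_CLASS_BOUNDS: tuple[tuple[float, str], ...] = (
    (1, "free_end"),
    (2, "pipe"),
    (5, "minor_hub"),
    (10, "small_hub"),
    (50, "medium_hub"),
    (100, "major_hub"),
    (np.inf, "super_hub"),
)

NODE_CLASSES = tuple(name for _, name in DEFAULT_CLASS_BOUNDS)


def build_network(interactions: Iterable[UniqueInteraction]) -> nx.Graph:
    """Undirected graph over canonical pairs, one edge per unique interaction."""
    g = nx.Graph()
    for ia in interactions:
        a, b = ia.pair
        g.add_edge(a, b, cv=ia.summary.cv)
    return g


def degree_table(network: nx.Graph, count_self_loops: bool = True) -> dict[str, int]:
    """Per-node degree; a self-loop contributes 1 by default (0 when disabled).

    networkx counts a self-loop as 2, hence the correction.
    """
    loops = {n for n, _ in nx.selfloop_edges(network)}
    table = {}
    for node, deg in network.degree():
        if node in loops:
            deg = deg - 1 if count_self_loops else deg - 2
        table[node] = deg
    return table


def classify_degree(degree: int, bounds: Sequence[tuple[float, str]] = DEFAULT_CLASS_BOUNDS) -> str:
    if degree < 1:
        raise ValueError("degree must be >= 1 (isolated nodes are excluded)")
    for upper, name in bounds:
        if degree <= upper:
            return name
    raise AssertionError("class bounds do not cover this degree")


def classify_nodes(
    degrees: dict[str, int],
    bounds: Sequence[tuple[float, str]] = DEFAULT_CLASS_BOUNDS,
) -> dict[str, str]:
    """Degree class per node; degree-0 nodes are excluded with a warning."""
    out: dict[str, str] = {}
    for node, deg in degrees.items():
        if deg < 1:
            log.warning("node %s has degree 0, excluded from classification", node)
            continue
        out[node] = classify_degree(deg, bounds)
    return out


def class_histogram(classes: dict[str, str]) -> dict[str, int]:
    hist = {name: 0 for name in NODE_CLASSES}
    for c in classes.values():
        hist[c] = hist.get(c, 0) + 1
    return hist


def binned_distribution(degrees: dict[str, int], bin_width: int = 10) -> list[tuple[int, int, int]]:
    """Degree histogram in bins [1..w], [w+1..2w], …, as (lo, hi, count).

    Counts over all bins sum to the node count; trailing empty bins are not
    emitted.
    """
    if bin_width < 1:
        raise ValueError("bin_width must be >= 1")
    if not degrees:
        return []
    max_deg = max(degrees.values())
    n_bins = (max_deg + bin_width - 1) // bin_width if max_deg >= 1 else 1
    counts = [0] * max(n_bins, 1)
    for deg in degrees.values():
        if deg < 1:
            continue
        counts[(deg - 1) // bin_width] += 1
    return [(i * bin_width + 1, (i + 1) * bin_width, c) for i, c in enumerate(counts)]


@dataclass
class PowerLawFit:
    """Log-log least-squares fit to a binned degree distribution."""

    slope: float
    intercept: float
    r_squared: float
    bin_width: int
    n_bins: int


def fit_power_law(dist: Sequence[tuple[int, int, int]]) -> PowerLawFit:
    """Least squares on (log10 bin midpoint, log10 count) over nonzero bins.

    A scale-free degree distribution appears as a straight line of negative
    slope (the exponent estimate).  Requires at least 3 nonzero bins.
    """
    pts = [((lo + hi) / 2.0, c) for lo, hi, c in dist if c > 0]
    if len(pts) < 3:
        raise ValueError(f"need >= 3 nonzero bins for a power-law fit, got {len(pts)}")
    x = np.log10([m for m, _ in pts])
    y = np.log10([c for _, c in pts])
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    bin_width = dist[0][1] - dist[0][0] + 1
    return PowerLawFit(float(slope), float(intercept), r2, bin_width, len(pts))


def top_hubs(network: nx.Graph, k: int, count_self_loops: bool = True) -> list[str]:
    """The k highest-degree nodes, ties broken lexicographically."""
    if k < 1:
        raise ValueError("k must be >= 1")
    degrees = degree_table(network, count_self_loops)
    ranked = sorted(degrees, key=lambda n: (-degrees[n], n))
    return ranked[:k]


@dataclass
class RobustnessReport:
    """Component structure and class histogram before/after hub deletion."""

    removed: list[str]
    n_components_before: int
    n_components_after: int
    largest_component_before: int
    largest_component_after: int
    class_histogram_before: dict[str, int]
    class_histogram_after: dict[str, int]


def hub_deletion_robustness(network: nx.Graph, k: int) -> RobustnessReport:
    """Delete the top-k hubs and report how the component structure changes."""
    if k >= network.number_of_nodes():
        raise ValueError("k must be smaller than the node count")
    removed = top_hubs(network, k)
    before_cc = list(nx.connected_components(network))
    hist_before = class_histogram(classify_nodes(degree_table(network)))
    reduced = network.copy()
    reduced.remove_nodes_from(removed)
    after_cc = list(nx.connected_components(reduced))
    degrees_after = {n: d for n, d in degree_table(reduced).items() if d >= 1}
    hist_after = class_histogram(classify_nodes(degrees_after))
    return RobustnessReport(
        removed=removed,
        n_components_before=len(before_cc),
        n_components_after=len(after_cc),
        largest_component_before=max((len(c) for c in before_cc), default=0),
        largest_component_after=max((len(c) for c in after_cc), default=0),
        class_histogram_before=hist_before,
        class_histogram_after=hist_after,
    )
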