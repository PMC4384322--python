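"""Bait-prey subnetwork capture and the connectivity-ratio statistic.

Given a set of bait proteins (members of a process of interest, e.g. the
Calvin-Benson-Bassham cycle), the captured subnetwork is the induced
subgraph over the baits plus their first neighbors (the prey).  Edges among
prey are retained, since prey often connect baits as intermediates.

A node's connectivity ratio is its degree inside the subnetwork divided by
its degree in the full network; a ratio of 1.0 marks a protein whose every
interaction lies inside the captured process (a subnetwork-exclusive
member), while low ratios mark promiscuous proteins shared with the rest of
the interactome.  The average ratio is taken over all subnetwork nodes,
baits and prey alike.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import networkx as nx

from .topology import degree_table


@dataclass
class BaitPreyResult:
    network: nx.Graph
    baits: set[str]
    missing_baits: set[str]
    prey: set[str]
    subnetwork: nx.Graph

    @property
    def members(self) -> set[str]:
        return self.baits | self.prey


def bait_prey_capture(network: nx.Graph, bait_ids: Iterable[str]) -> BaitPreyResult:
    """Induced first-neighbor subnetwork around the baits found in the network."""
    requested = set(bait_ids)
    if not requested:
        raise ValueError("empty bait list")
    baits = {b for b in requested if b in network}
    missing = requested - baits
    prey: set[str] = set()
    for b in baits:
        prey.update(network.neighbors(b))
    prey -= baits
    sub = network.subgraph(baits | prey).copy()
    return BaitPreyResult(network=network, baits=baits, missing_baits=missing,
                          prey=prey, subnetwork=sub)


def connectivity_ratio(result: BaitPreyResult, node: str) -> float:
    """Degree within the subnetwork over degree in the full network, in (0, 1]."""
    if node not in result.subnetwork:
        raise KeyError(f"{node!r} is not in the captured subnetwork")
    sub_deg = degree_table(result.subnetwork)[node]
    full_deg = degree_table(result.network)[node]
    if full_deg == 0:
        raise ValueError(f"{node!r} has degree 0 in the full network")
    return sub_deg / full_deg


def connectivity_ratios(result: BaitPreyResult) -> dict[str, float]:
    sub_deg = degree_table(result.subnetwork)
    full_deg = degree_table(result.network)
    return {n: sub_deg[n] / full_deg[n] for n in sorted(result.members) if full_deg.get(n, 0) > 0}


def average_connectivity_ratio(result: BaitPreyResult) -> float:
    """Arithmetic mean connectivity ratio over all subnetwork nodes."""
    ratios = connectivity_ratios(result)
    if not ratios:
        raise ValueError("empty subnetwork")
    return sum(ratios.values()) / len(ratios)


def exclusive_members(result: BaitPreyResult) -> list[str]:
    """Nodes whose every interaction lies inside the subnetwork (ratio 1.0)."""
    return sorted(n for n, r in connectivity_ratios(result).items() if r == 1.0)
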