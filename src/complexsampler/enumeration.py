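"""Brute-force enumeration of the chain's state space on tiny networks.

Independent reference for validating the sampler: enumerate every feasible
cluster set (all collections of connected, size-bounded clusters whose
pairwise overlap penalty is finite), score each with the full scoring
function, and form the exact Boltzmann distribution exp(-f/T)/Z.  Only
usable on networks with a handful of nodes; the enumeration is exponential
by design.
"""

from __future__ import annotations

import math
from itertools import combinations
from typing import Iterable

from .network_io import Cluster, PPINetwork, induced_subgraph_connected
from . import scoring
from .scoring import INF, ScoreParams

__all__ = [
    "connected_subsets",
    "enumerate_feasible_cluster_sets",
    "boltzmann_distribution",
    "total_variation",
]


def connected_subsets(net: PPINetwork, max_size: int) -> list[Cluster]:
    """All node subsets of size 2..max_size inducing a connected subgraph."""
    nodes = sorted(net.nodes)
    out = []
    for size in range(2, max_size + 1):
        for combo in combinations(nodes, size):
            x = frozenset(combo)
            if induced_subgraph_connected(net, x):
                out.append(x)
    return out


def enumerate_feasible_cluster_sets(net: PPINetwork, params: ScoreParams
                                    ) -> list[frozenset]:
    """Every cluster set with finite score: clusters connected, sizes
    <= S_max, pairwise overlap penalties finite, no duplicates.

    Returned as frozensets of clusters (the state key used by the chain's
    occupancy counter); includes the empty state.
    """
    candidates = connected_subsets(net, params.s_max)
    compat = {}
    for a, b in combinations(candidates, 2):
        compat[(a, b)] = scoring.pair_dissimilarity(a, b, params.beta) < INF
    states: list[frozenset] = []

    def extend(chosen: list[Cluster], start: int) -> None:
        states.append(frozenset(chosen))
        for i in range(start, len(candidates)):
            c = candidates[i]
            if all(compat[(x, c) if (x, c) in compat else (c, x)]
                   for x in chosen):
                chosen.append(c)
                extend(chosen, i + 1)
                chosen.pop()

    extend([], 0)
    return states


def boltzmann_distribution(net: PPINetwork, states: Iterable[frozenset],
                           gamma: float, params: ScoreParams,
                           t: float = 1.0) -> dict[frozenset, float]:
    """Exact stationary distribution exp(-f(X, gamma)/T) / Z over states."""
    scores = {s: scoring.total_score(net, s, gamma, params).total
              for s in states}
    fmin = min(scores.values())
    weights = {s: math.exp(-(f - fmin) / t) for s, f in scores.items()}
    z = sum(weights.values())
    return {s: w / z for s, w in weights.items()}


def total_variation(p: dict, q: dict) -> float:
    """TV distance 0.5 * sum |p - q| over the union of supports."""
    keys = set(p) | set(q)
    return 0.5 * sum(abs(p.get(k, 0.0) - q.get(k, 0.0)) for k in keys)
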