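"""Weighted protein-protein interaction (PPI) network container and I/O.

The network is an undirected, edge-weighted graph ``G = (V, E, w)`` whose
nodes are protein identifiers (opaque strings) and whose edge weights are
interaction reliabilities in ``(0, 1]`` after normalization.  Self-loops are
never stored; the weight of a non-edge is 0 by convention.

A predicted complex ("cluster") is a :class:`frozenset` of at least two
protein identifiers.  :class:`ClusterSet` holds a duplicate-free collection
of clusters; clusters inside a set may overlap.
"""

from __future__ import annotations

import logging
import math
from collections import deque
from typing import Iterable, Iterator

logger = logging.getLogger(__name__)

Cluster = frozenset  # a set of >= 2 protein identifiers

__all__ = [
    "Cluster",
    "ClusterSet",
    "PPINetwork",
    "NetworkParseError",
    "NetworkValidationError",
    "load_ppi_network",
    "write_network_tsv",
    "read_cluster_file",
    "write_cluster_file",
    "cluster_weight",
    "node_to_cluster_weight",
    "cluster_neighbors",
    "induced_subgraph_connected",
]


class NetworkParseError(ValueError):
    """A malformed line in an edge-list or cluster file."""


class NetworkValidationError(ValueError):
    """Input that parses but violates a model invariant."""


class PPINetwork:
    """Undirected, edge-weighted PPI network.

    Parameters
    ----------
    edges
        Iterable of ``(u, v, weight)`` triples.  Self-loops are rejected,
        duplicate edges collapse to the maximum weight.
    extra_nodes
        Nodes to register even if they have no incident edge (e.g. isolated
        background proteins of a synthetic benchmark).
    """

    __slots__ = ("_adj", "_nodes")

    def __init__(self, edges: Iterable[tuple[str, str, float]] = (),
                 extra_nodes: Iterable[str] = ()):
        self._adj: dict[str, dict[str, float]] = {}
        self._nodes: set[str] = set()
        for u in extra_nodes:
            self.add_node(u)
        for u, v, w in edges:
            self.add_edge(u, v, w)

    # -- construction -----------------------------------------------------

    def add_node(self, u: str) -> None:
        if u not in self._nodes:
            self._nodes.add(u)
            self._adj[u] = {}

    def add_edge(self, u: str, v: str, w: float) -> None:
        if u == v:
            raise NetworkValidationError(f"self-loop on {u!r} is not allowed")
        if not (w > 0):
            raise NetworkValidationError(
                f"edge ({u!r}, {v!r}) has non-positive weight {w!r}")
        self.add_node(u)
        self.add_node(v)
        old = self._adj[u].get(v)
        if old is not None and old != w:
            w = max(old, w)
        self._adj[u][v] = w
        self._adj[v][u] = w

    # -- basic queries -----------------------------------------------------

    @property
    def nodes(self) -> frozenset:
        return frozenset(self._nodes)

    @property
    def n_nodes(self) -> int:
        return len(self._nodes)

    @property
    def n_edges(self) -> int:
        return sum(len(nbrs) for nbrs in self._adj.values()) // 2

    def __contains__(self, u: str) -> bool:
        return u in self._nodes

    def has_edge(self, u: str, v: str) -> bool:
        return v in self._adj.get(u, ())

    def weight(self, u: str, v: str) -> float:
        """w({u, v}); by convention 0 for a non-edge."""
        return self._adj.get(u, {}).get(v, 0.0)

    def adjacency(self, u: str) -> dict[str, float]:
        """Neighbors of ``u`` with edge weights (read-only use)."""
        try:
            return self._adj[u]
        except KeyError:
            raise NetworkValidationError(f"unknown protein {u!r}") from None

    def edges(self) -> Iterator[tuple[str, str, float]]:
        """Each undirected edge once, as (u, v, w) with u < v."""
        for u, nbrs in self._adj.items():
            for v, w in nbrs.items():
                if u < v:
                    yield u, v, w

    def total_edge_weight(self) -> float:
        return sum(w for _, _, w in self.edges())

    def max_weight(self) -> float:
        return max((w for _, _, w in self.edges()), default=0.0)

    def _require_members(self, members: Iterable[str]) -> None:
        for u in members:
            if u not in self._nodes:
                raise NetworkValidationError(f"unknown protein {u!r}")


class ClusterSet:
    """A duplicate-free, order-stable collection of clusters.

    Clusters may overlap (share proteins); two clusters with identical
    member sets are forbidden.
    """

    __slots__ = ("_clusters", "_index")

    def __init__(self, clusters: Iterable[Iterable[str]] = ()):
        self._clusters: tuple[Cluster, ...] = ()
        self._index: set[Cluster] = set()
        out = []
        for c in clusters:
            fs = frozenset(c)
            if len(fs) < 2:
                raise NetworkValidationError(
                    f"cluster {sorted(fs)!r} has fewer than 2 members")
            if fs in self._index:
                raise NetworkValidationError(
                    f"duplicate cluster {sorted(fs)!r}")
            self._index.add(fs)
            out.append(fs)
        self._clusters = tuple(out)

    @property
    def clusters(self) -> tuple[Cluster, ...]:
        return self._clusters

    def __iter__(self) -> Iterator[Cluster]:
        return iter(self._clusters)

    def __len__(self) -> int:
        return len(self._clusters)

    def __contains__(self, c) -> bool:
        return frozenset(c) in self._index

    def __eq__(self, other) -> bool:
        if isinstance(other, ClusterSet):
            return self._index == other._index
        return NotImplemented

    def __hash__(self):
        return hash(frozenset(self._index))

    def __repr__(self) -> str:
        return f"ClusterSet({len(self)} clusters)"


# -- edge-list I/O ---------------------------------------------------------

def load_ppi_network(path, weight_threshold: float | None = None,
                     normalize: bool = True) -> PPINetwork:
    """Load a PPI network from a 2- or 3-column edge list.

    Columns are whitespace/tab separated: ``proteinA  proteinB  [weight]``;
    a missing weight column means 1.0.  Lines starting with ``#`` and blank
    lines are skipped.  Self-loops are dropped, duplicate edges keep the
    maximum weight (a reliability score reading).

    ``weight_threshold`` filters edges on RAW weights, before
    normalization, matching how published reliability cutoffs refer to the
    raw scores.  With ``normalize`` the surviving weights are divided by
    their maximum so the largest is exactly 1.
    """
    raw: dict[tuple[str, str], float] = {}
    n_dup = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) == 2:
                u, v = parts
                w = 1.0
            elif len(parts) == 3:
                u, v = parts[:2]
                try:
                    w = float(parts[2])
                except ValueError:
                    raise NetworkParseError(
                        f"{path}: line {lineno}: non-numeric weight "
                        f"{parts[2]!r}") from None
                if math.isnan(w):
                    raise NetworkParseError(
                        f"{path}: line {lineno}: NaN weight")
            else:
                raise NetworkParseError(
                    f"{path}: line {lineno}: expected 2 or 3 columns, "
                    f"got {len(parts)}")
            if w < 0:
                raise NetworkValidationError(
                    f"{path}: line {lineno}: negative weight {w}")
            if u == v:
                continue  # self-loops removed in preprocessing
            key = (u, v) if u < v else (v, u)
            if key in raw:
                n_dup += 1
                raw[key] = max(raw[key], w)
            else:
                raw[key] = w
    if n_dup:
        logger.warning("%s: %d duplicate edge rows collapsed "
                       "(maximum weight kept)", path, n_dup)
    if weight_threshold is not None:
        raw = {k: w for k, w in raw.items() if w >= weight_threshold}
    raw = {k: w for k, w in raw.items() if w > 0}
    if not raw:
        raise NetworkValidationError(
            f"{path}: no edges remain after filtering")
    if normalize:
        wmax = max(raw.values())
        raw = {k: w / wmax for k, w in raw.items()}
    return PPINetwork((u, v, w) for (u, v), w in raw.items())


def write_network_tsv(net: PPINetwork, path, header: str | None = None) -> None:
    """Write the network as a 3-column tab-separated edge list."""
    with open(path, "w") as fh:
        if header:
            for ln in header.splitlines():
                fh.write(f"# {ln}\n")
        for u, v, w in sorted(net.edges()):
            fh.write(f"{u}\t{v}\t{w:.6g}\n")


# -- cluster / complex list I/O -------------------------------------------

def read_cluster_file(path) -> ClusterSet:
    """Read a line-per-complex membership list (members tab-separated).

    ``#``-prefixed comment lines and blank lines are skipped.  The same
    format is used for predicted clusters and gold-standard catalogues.
    """
    clusters = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            members = frozenset(line.split())
            if len(members) < 2:
                raise NetworkParseError(
                    f"{path}: line {lineno}: a complex needs >= 2 distinct "
                    "members")
            clusters.append(members)
    try:
        return ClusterSet(clusters)
    except NetworkValidationError as exc:
        raise NetworkValidationError(f"{path}: {exc}") from None


def write_cluster_file(clusters: Iterable[Cluster], path,
                       header: str | None = None) -> None:
    with open(path, "w") as fh:
        if header:
            for ln in header.splitlines():
                fh.write(f"# {ln}\n")
        for c in clusters:
            fh.write("\t".join(sorted(c)) + "\n")


# -- graph primitives used by scoring and proposals ------------------------

def cluster_weight(net: PPINetwork, x: Iterable[str]) -> float:
    """w(x): sum of the weights of edges with both endpoints in ``x``.

    Each undirected edge is counted exactly once.
    """
    members = frozenset(x)
    net._require_members(members)
    # sorted iteration keeps float summation order process-independent
    total = 0.0
    for u in sorted(members):
        adj = net.adjacency(u)
        for v, w in adj.items():
            if v in members and u < v:
                total += w
    return total


def node_to_cluster_weight(net: PPINetwork, u: str, x: Iterable[str]) -> float:
    """w(u, x): sum of edge weights between ``u`` and the members of ``x``.

    Valid whether or not ``u`` is itself a member (self-loops are absent, so
    a member contributes nothing through itself).
    """
    members = frozenset(x)
    net._require_members(members)
    adj = net.adjacency(u)
    return sum(w for v, w in adj.items() if v in members)


def cluster_neighbors(net: PPINetwork, x: Iterable[str]) -> set[str]:
    """N(x): nodes outside ``x`` adjacent to at least one member of ``x``."""
    members = frozenset(x)
    net._require_members(members)
    out: set[str] = set()
    for u in members:
        out.update(net.adjacency(u))
    out -= members
    return out


def induced_subgraph_connected(net: PPINetwork, x: Iterable[str]) -> bool:
    """True iff the subgraph induced by ``x`` is connected (BFS)."""
    members = frozenset(x)
    net._require_members(members)
    if not members:
        return True
    start = min(members)
    seen = {start}
    queue = deque([start])
    while queue:
        u = queue.popleft()
        for v in net.adjacency(u):
            if v in members and v not in seen:
                seen.add(v)
                queue.append(v)
    return len(seen) == len(members)
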