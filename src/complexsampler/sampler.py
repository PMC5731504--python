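"""Metropolis-Hastings simulated annealing over cluster sets.

The chain explores states ``(X, gamma)`` under the Boltzmann target
``P(X, gamma) ~ exp(-f(X, gamma) / T)`` while the temperature decays
geometrically, so sampling turns into optimization and the lowest-score
state ever visited is returned.

Each iteration draws one of four cluster moves (add a two-protein cluster,
grow a cluster by one neighbor, remove a two-protein cluster, shrink a
cluster by one member), then perturbs gamma with Gaussian noise, and
accepts or rejects the joint candidate.  The moves are asymmetric
(weight-proportional and inverse-weight-proportional selection), so the
acceptance ratio carries the Hastings correction ``q_reverse / q_forward``
by default; the gamma perturbation is treated as symmetric.

Random draws come from a single seeded generator in a fixed order per
iteration: move kind, move-internal choices, gamma noise, acceptance
uniform.  Runs are fully reproducible from the seed.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .network_io import (
    Cluster,
    ClusterSet,
    PPINetwork,
    induced_subgraph_connected,
)
from . import scoring
from .scoring import INF, ScoreParams

__all__ = [
    "SamplerParams",
    "Proposal",
    "RunResult",
    "ChainConsistencyError",
    "MOVE_ADD_CLUSTER",
    "MOVE_ADD_PROTEIN",
    "MOVE_REMOVE_CLUSTER",
    "MOVE_REMOVE_PROTEIN",
    "MOVE_NOOP",
    "propose_add_cluster",
    "propose_add_protein",
    "propose_remove_cluster",
    "propose_remove_protein",
    "propose_gamma",
    "acceptance_probability",
    "cool",
    "run_sampler",
]

MOVE_ADD_CLUSTER = "add-cluster"
MOVE_ADD_PROTEIN = "add-protein"
MOVE_REMOVE_CLUSTER = "remove-cluster"
MOVE_REMOVE_PROTEIN = "remove-protein"
MOVE_NOOP = "no-op"

_GAMMA_STEP_SD = math.sqrt(0.001)  # N(0, 0.001) gamma perturbation


class ChainConsistencyError(RuntimeError):
    """The chain reached a state its invariants forbid (e.g. a cluster
    member with zero connection weight, or incremental/full score
    disagreement)."""


@dataclass(frozen=True)
class SamplerParams:
    """Knobs of the annealed chain.

    ``move_probs`` is ``(alpha_add_cluster, alpha_add_protein,
    alpha_remove_cluster, alpha_remove_protein)``; the source study never
    reports numeric values, so the default is symmetric.  ``n_iterations``
    defaults to the study's production value of 5,000,000; desk-scale runs
    use 1e4-1e5.  ``gamma_step_sd = 0`` freezes gamma (useful for
    fixed-exponent runs and exact-distribution checks).
    """

    move_probs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    n_iterations: int = 5_000_000
    t0: float = 1.0
    cooling_factor: float = 0.999999
    gamma_step_sd: float = _GAMMA_STEP_SD
    gamma_floor: float = 1e-10
    seed: int | None = None
    use_hastings_correction: bool = True
    joint_gamma_update: bool = True
    trace_every: int = 1000
    consistency_check_every: int = 10_000
    collect_state_counts: bool = False
    burn_in: int = 0  # iterations excluded from state counts

    def __post_init__(self):
        if len(self.move_probs) != 4 or any(p < 0 for p in self.move_probs):
            raise ValueError("move_probs must be four nonnegative reals")
        if abs(sum(self.move_probs) - 1.0) > 1e-12:
            raise ValueError("move_probs must sum to 1")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if not (0 < self.cooling_factor <= 1):
            raise ValueError("cooling_factor must lie in (0, 1]")
        if self.t0 <= 0:
            raise ValueError("t0 must be > 0")
        if self.gamma_step_sd < 0:
            raise ValueError("gamma_step_sd must be >= 0")


@dataclass(frozen=True)
class Proposal:
    """A candidate cluster-set move with its proposal densities.

    ``q_forward`` is the probability of generating this candidate from the
    current state (including the move-kind probability); ``q_reverse`` is
    the probability of the paired inverse move regenerating the current
    state from the candidate.  ``removed``/``added`` describe the change:
    both None for a no-op, only ``added`` for a new cluster, only
    ``removed`` for a deleted cluster, both for a one-protein resize.
    """

    move_kind: str
    candidate: tuple[Cluster, ...]
    q_forward: float
    q_reverse: float
    removed: Cluster | None = None
    added: Cluster | None = None
    added_weight: float = 0.0  # w(added); meaningful when added is not None


@dataclass
class RunResult:
    best_clusters: ClusterSet
    best_gamma: float
    best_score: float
    trace: list[tuple[int, float]]
    acceptance_rate: float
    n_iterations: int
    final_temperature: float
    final_score: float
    max_consistency_error: float
    state_counts: Counter | None = None
    params: SamplerParams | None = None
    score_params: ScoreParams | None = None


# -- proposal machinery ----------------------------------------------------

class EdgeSampler:
    """Weight-proportional edge sampling, precomputed once per network."""

    def __init__(self, net: PPINetwork):
        self.edges = list(net.edges())
        w = np.array([e[2] for e in self.edges], dtype=float)
        self.total_weight = float(w.sum())
        self.cum = np.cumsum(w)

    def draw(self, rng) -> tuple[str, str, float]:
        r = rng.random() * self.total_weight
        i = int(np.searchsorted(self.cum, r, side="right"))
        if i >= len(self.edges):
            i = len(self.edges) - 1
        return self.edges[i]


def _as_list(X: Iterable[Cluster]) -> list[Cluster]:
    return [c if isinstance(c, frozenset) else frozenset(c) for c in X]


def _noop(X: list[Cluster]) -> Proposal:
    return Proposal(MOVE_NOOP, tuple(X), 1.0, 1.0)


def _weighted_pick(rng, items: Sequence, weights: Sequence[float]):
    total = 0.0
    for w in weights:
        total += w
    r = rng.random() * total
    acc = 0.0
    for item, w in zip(items, weights):
        acc += w
        if r < acc:
            return item, w, total
    return items[-1], weights[-1], total


def _dimer_inverse_weights(net: PPINetwork, clusters: Iterable[Cluster]):
    """Size-2 clusters with their 1/w(x); raises on zero-weight dimers."""
    dimers, inv = [], []
    for x in clusters:
        if len(x) == 2:
            u, v = x
            w = net.weight(u, v)
            if w <= 0:
                raise ChainConsistencyError(
                    f"size-2 cluster {sorted(x)!r} has zero weight "
                    "(disconnected clusters are infeasible)")
            dimers.append(x)
            inv.append(1.0 / w)
    return dimers, inv


def _member_weights(net: PPINetwork, x: Cluster) -> dict[str, float]:
    """w(v, x) for every member v; raises if a member is disconnected.

    Iterates members in sorted order so draws depending on the mapping
    order are reproducible across processes (set order is hash-dependent).
    """
    out = {}
    for v in sorted(x):
        adj = net.adjacency(v)
        w = sum(wt for nb, wt in adj.items() if nb in x)
        if w <= 0:
            raise ChainConsistencyError(
                f"member {v!r} has zero connection weight inside "
                f"{sorted(x)!r} (infeasible state)")
        out[v] = w
    return out


def _neighbor_weights(net: PPINetwork, x: Cluster) -> dict[str, float]:
    """w(u, x) for every u in N(x), in a process-independent order."""
    out: dict[str, float] = {}
    for v in sorted(x):
        for nb, wt in net.adjacency(v).items():
            if nb not in x:
                out[nb] = out.get(nb, 0.0) + wt
    return out


def propose_add_cluster(net: PPINetwork, X: Iterable[Cluster], rng,
                        move_probs: Sequence[float] = (0.25,) * 4,
                        edge_sampler: EdgeSampler | None = None) -> Proposal:
    """Add a two-protein cluster on an edge drawn with probability ~ w(e).

    If the drawn cluster already exists the proposal is a no-op (the
    candidate equals the current state).  ``q_reverse`` is the probability
    that the remove-cluster move deletes the new dimer from the candidate.
    """
    X = _as_list(X)
    if edge_sampler is None:
        if net.n_edges == 0:
            return _noop(X)
        edge_sampler = EdgeSampler(net)
    u, v, w = edge_sampler.draw(rng)
    x_e = frozenset((u, v))
    if x_e in set(X):
        return _noop(X)
    candidate = tuple(X) + (x_e,)
    q_forward = move_probs[0] * w / edge_sampler.total_weight
    _, inv = _dimer_inverse_weights(net, candidate)
    q_reverse = move_probs[2] * (1.0 / w) / sum(inv)
    return Proposal(MOVE_ADD_CLUSTER, candidate, q_forward, q_reverse,
                    added=x_e, added_weight=w)


def propose_add_protein(net: PPINetwork, X: Iterable[Cluster], rng,
                        move_probs: Sequence[float] = (0.25,) * 4) -> Proposal:
    """Grow a uniformly chosen cluster by a neighbor drawn with
    probability ~ w(u, x).

    No-op when X is empty, the chosen cluster has no neighbors, or the
    grown cluster would duplicate an existing one.  ``q_reverse`` is the
    probability that remove-protein deletes ``u`` again from the candidate.
    """
    X = _as_list(X)
    if not X:
        return _noop(X)
    idx = int(rng.integers(len(X)))
    x = X[idx]
    nw = _neighbor_weights(net, x)
    if not nw:
        return _noop(X)
    names = list(nw)
    u, w_u, total_nw = _weighted_pick(rng, names, [nw[n] for n in names])
    x_new = x | {u}
    if x_new in set(X):
        return _noop(X)
    candidate = tuple(c if i != idx else x_new for i, c in enumerate(X))
    q_forward = move_probs[1] * (1.0 / len(X)) * (w_u / total_nw)
    # reverse: remove-protein picks x_new uniformly among >=3-clusters of
    # the candidate, then u with probability ~ 1/w(u, x_new)
    n_ge3 = sum(1 for c in candidate if len(c) >= 3)
    mw = _member_weights(net, x_new)
    inv_sum = sum(1.0 / w for w in mw.values())
    q_reverse = (move_probs[3] * (1.0 / n_ge3)
                 * (1.0 / mw[u]) / inv_sum)
    return Proposal(MOVE_ADD_PROTEIN, candidate, q_forward, q_reverse,
                    removed=x, added=x_new,
                    added_weight=0.5 * sum(mw.values()))


def propose_remove_cluster(net: PPINetwork, X: Iterable[Cluster], rng,
                           move_probs: Sequence[float] = (0.25,) * 4,
                           edge_sampler: EdgeSampler | None = None
                           ) -> Proposal:
    """Remove a size-2 cluster drawn with probability ~ 1/w(x).

    No-op when X has no size-2 cluster.  ``q_reverse`` is the probability
    that add-cluster re-creates the dimer from the candidate.
    """
    X = _as_list(X)
    dimers, inv = _dimer_inverse_weights(net, X)
    if not dimers:
        return _noop(X)
    x, inv_w, inv_total = _weighted_pick(rng, dimers, inv)
    candidate = tuple(c for c in X if c != x)
    q_forward = move_probs[2] * inv_w / inv_total
    u, v = x
    w = net.weight(u, v)
    total_w = (edge_sampler.total_weight if edge_sampler is not None
               else net.total_edge_weight())
    q_reverse = move_probs[0] * w / total_w
    return Proposal(MOVE_REMOVE_CLUSTER, candidate, q_forward, q_reverse,
                    removed=x)


def propose_remove_protein(net: PPINetwork, X: Iterable[Cluster], rng,
                           move_probs: Sequence[float] = (0.25,) * 4
                           ) -> Proposal:
    """Shrink a uniformly chosen >=3-member cluster by a member drawn with
    probability ~ 1/w(u, x).

    No-op when no cluster has three or more members, or when the shrunk
    cluster would duplicate an existing one.  ``q_reverse`` is the
    probability that add-protein re-attaches ``u`` in the candidate.
    """
    X = _as_list(X)
    big = [c for c in X if len(c) >= 3]
    if not big:
        return _noop(X)
    x = big[int(rng.integers(len(big)))]
    mw = _member_weights(net, x)
    members = list(mw)
    inv = [1.0 / mw[v] for v in members]
    u, inv_w, inv_total = _weighted_pick(rng, members, inv)
    x_new = x - {u}
    if x_new in set(X):
        return _noop(X)
    idx = X.index(x)
    candidate = tuple(c if i != idx else x_new for i, c in enumerate(X))
    q_forward = move_probs[3] * (1.0 / len(big)) * inv_w / inv_total
    # reverse: add-protein picks x_new uniformly from the candidate, then
    # u from N(x_new) with probability ~ w(u, x_new)
    nw = _neighbor_weights(net, x_new)
    q_reverse = (move_probs[1] * (1.0 / len(candidate))
                 * (mw[u] / sum(nw.values())))
    return Proposal(MOVE_REMOVE_PROTEIN, candidate, q_forward, q_reverse,
                    removed=x, added=x_new,
                    added_weight=0.5 * sum(mw.values()) - mw[u])


def propose_gamma(gamma: float, gamma_step_sd: float, gamma_floor: float,
                  rng) -> float:
    """max(floor, gamma + eps) with eps ~ N(0, gamma_step_sd^2)."""
    return max(gamma_floor, gamma + gamma_step_sd * rng.standard_normal())


def acceptance_probability(f_current: float, f_candidate: float, t: float,
                           q_forward: float, q_reverse: float,
                           use_hastings: bool = True) -> float:
    """min(1, exp((f_cur - f_cand)/T) * q_rev/q_fwd) (ratio 1 without the
    Hastings correction).  Infeasible candidates are rejected surely."""
    if t <= 0:
        raise ValueError("temperature must be > 0")
    if f_candidate == INF:
        return 0.0
    log_a = (f_current - f_candidate) / t
    if use_hastings:
        if q_reverse <= 0.0:
            return 0.0
        log_a += math.log(q_reverse) - math.log(q_forward)
    if log_a >= 0:
        return 1.0
    return math.exp(log_a)


def cool(t: float, cooling_factor: float) -> float:
    """Geometric cooling step T <- T * factor."""
    return t * cooling_factor


# -- incremental chain state ----------------------------------------------

class _Chain:
    """Incrementally scored chain state.

    Maintains w(x) per cluster, the density sum, the cluster-size
    histogram, per-protein membership counts, and the finite pairwise
    overlap sum, so a one-cluster move is re-scored in O(|X| + S_max)
    instead of O(|X|^2).  A periodic full recomputation via
    :func:`scoring.total_score` guards against drift.
    """

    def __init__(self, net: PPINetwork, sp: ScoreParams, gamma: float):
        self.net = net
        self.sp = sp
        self.clusters: list[Cluster] = []
        self.w_of: dict[Cluster, float] = {}
        self.density_sum = 0.0
        self.hist: Counter = Counter()
        self.prot: Counter = Counter()
        self.pair_sum = 0.0
        self.gamma = gamma
        self._pmf_cache: tuple[float, np.ndarray, float] | None = None

    # scoring pieces ------------------------------------------------------

    def _pmf(self, gamma: float) -> tuple[np.ndarray, float]:
        c = self._pmf_cache
        if c is not None and c[0] == gamma:
            return c[1], c[2]
        pmf = scoring.powerlaw_pmf_vector(gamma, self.sp.s_max)
        sq = float((pmf ** 2).sum())
        self._pmf_cache = (gamma, pmf, sq)
        return pmf, sq

    def _assemble(self, density_sum: float, pair_sum: float,
                  hist: dict[int, int], n_clusters: int, n_prot: int,
                  gamma: float) -> float:
        pmf, sq = self._pmf(gamma)
        h_size = scoring._size_term_from_hist(hist, n_clusters, pmf, sq)
        return (-density_sum
                + self.sp.c_clu_dis * pair_sum
                + self.sp.c_clu_size * h_size
                + self.sp.c_hy * (gamma - self.sp.gamma0) ** 2
                + self.sp.c_pro_num * float(n_prot) ** 2)

    def score(self) -> float:
        return self._assemble(self.density_sum, self.pair_sum, self.hist,
                              len(self.clusters), len(self.prot), self.gamma)

    def _pair_row(self, x: Cluster, skip: Cluster | None) -> float:
        total = 0.0
        for y in self.clusters:
            if y == x or (skip is not None and y == skip):
                continue
            d = scoring.pair_dissimilarity(x, y, self.sp.beta)
            if d == INF:
                return INF
            total += d
        return total

    # candidate evaluation -------------------------------------------------

    def evaluate(self, prop: Proposal, gamma_new: float):
        """Score the joint candidate (prop.candidate, gamma_new).

        Returns ``(f_candidate, delta)`` where ``delta`` is the commit
        payload (None for a no-op).
        """
        removed, added = prop.removed, prop.added
        if removed is None and added is None:
            f = self._assemble(self.density_sum, self.pair_sum, self.hist,
                               len(self.clusters), len(self.prot), gamma_new)
            return f, None
        # hard constraints on the modified cluster
        if added is not None:
            if len(added) > self.sp.s_max:
                return INF, None
            if prop.move_kind == MOVE_REMOVE_PROTEIN and \
                    not induced_subgraph_connected(self.net, added):
                return INF, None
        density_sum = self.density_sum
        pair_sum = self.pair_sum
        n_clusters = len(self.clusters)
        hist_delta: list[tuple[int, int]] = []
        prot_delta: Counter = Counter()
        if removed is not None:
            old_row = self._pair_row(removed, skip=None)
            if old_row == INF:  # pragma: no cover - infeasible states never occupied
                raise ChainConsistencyError("current state has infinite "
                                            "overlap term")
            pair_sum -= old_row
            density_sum -= self.w_of[removed] / math.sqrt(len(removed))
            hist_delta.append((len(removed), -1))
            for p in removed:
                prot_delta[p] -= 1
            n_clusters -= 1
        if added is not None:
            new_row = self._pair_row(added, skip=removed)
            if new_row == INF:
                return INF, None
            pair_sum += new_row
            density_sum += prop.added_weight / math.sqrt(len(added))
            hist_delta.append((len(added), +1))
            for p in added:
                prot_delta[p] += 1
            n_clusters += 1
        hist = dict(self.hist)
        for s, d in hist_delta:
            hist[s] = hist.get(s, 0) + d
            if hist[s] == 0:
                del hist[s]
        n_prot = len(self.prot)
        for p, d in prot_delta.items():
            c = self.prot.get(p, 0)
            if c == 0 and c + d > 0:
                n_prot += 1
            elif c > 0 and c + d == 0:
                n_prot -= 1
        f = self._assemble(density_sum, pair_sum, hist, n_clusters, n_prot,
                           gamma_new)
        delta = (prop, density_sum, pair_sum, hist, prot_delta)
        return f, delta

    def commit(self, delta, gamma_new: float) -> None:
        self.gamma = gamma_new
        if delta is None:
            return
        prop, density_sum, pair_sum, hist, prot_delta = delta
        self.density_sum = density_sum
        self.pair_sum = pair_sum
        self.hist = Counter(hist)
        for p, d in prot_delta.items():
            c = self.prot[p] + d
            if c:
                self.prot[p] = c
            else:
                del self.prot[p]
        removed, added = prop.removed, prop.added
        if removed is not None and added is not None:
            i = self.clusters.index(removed)
            self.clusters[i] = added
            del self.w_of[removed]
            self.w_of[added] = prop.added_weight
        elif added is not None:
            self.clusters.append(added)
            self.w_of[added] = prop.added_weight
        elif removed is not None:
            self.clusters.remove(removed)
            del self.w_of[removed]

    def resync(self) -> float:
        """Full recompute; returns |incremental - full| of the total."""
        bd = scoring.total_score(self.net, self.clusters, self.gamma, self.sp)
        if not math.isfinite(bd.total):  # pragma: no cover
            raise ChainConsistencyError("occupied state scored infeasible "
                                        "on full recompute")
        err = abs(self.score() - bd.total)
        from .network_io import cluster_weight
        self.w_of = {x: cluster_weight(self.net, x) for x in self.clusters}
        self.density_sum = sum(w / math.sqrt(len(x))
                               for x, w in self.w_of.items())
        self.pair_sum = bd.h_dis
        self.hist = Counter(len(x) for x in self.clusters)
        self.prot = Counter()
        for x in self.clusters:
            for p in x:
                self.prot[p] += 1
        return err


# -- the annealing loop ----------------------------------------------------

def run_sampler(net: PPINetwork, score_params: ScoreParams | None = None,
                sampler_params: SamplerParams | None = None) -> RunResult:
    """Run the annealed Metropolis-Hastings chain and return the best
    state visited.

    The chain starts from the empty cluster set with gamma at the prior
    center; the empty state is always feasible.  Each iteration proposes a
    joint candidate (X', gamma'), accepts it with the (optionally
    Hastings-corrected) Metropolis probability at the current temperature,
    then cools.  No-op proposals count as iterations and are accepted
    whenever gamma is unchanged.
    """
    sp = score_params or ScoreParams()
    pp = sampler_params or SamplerParams()
    if net.n_nodes == 0:
        raise ValueError("network is empty")
    rng = np.random.default_rng(pp.seed)
    edge_sampler = EdgeSampler(net) if net.n_edges else None
    move_cum = np.cumsum(pp.move_probs)

    chain = _Chain(net, sp, sp.gamma0)
    f_cur = chain.score()
    t = pp.t0
    best_score = f_cur
    best_clusters: tuple[Cluster, ...] = ()
    best_gamma = chain.gamma
    trace: list[tuple[int, float]] = [(0, f_cur)]
    counts: Counter | None = Counter() if pp.collect_state_counts else None
    n_accept = 0
    max_err = 0.0

    for it in range(1, pp.n_iterations + 1):
        r = rng.random()
        kind = int(np.searchsorted(move_cum, r, side="right"))
        if kind == 0:
            if edge_sampler is None:
                prop = _noop(chain.clusters)
            else:
                prop = propose_add_cluster(net, chain.clusters, rng,
                                           pp.move_probs, edge_sampler)
        elif kind == 1:
            prop = propose_add_protein(net, chain.clusters, rng,
                                       pp.move_probs)
        elif kind == 2:
            prop = propose_remove_cluster(net, chain.clusters, rng,
                                          pp.move_probs, edge_sampler)
        else:
            prop = propose_remove_protein(net, chain.clusters, rng,
                                          pp.move_probs)

        if pp.gamma_step_sd > 0:
            gamma_new = propose_gamma(chain.gamma, pp.gamma_step_sd,
                                      pp.gamma_floor, rng)
        else:
            gamma_new = chain.gamma

        if pp.joint_gamma_update or pp.gamma_step_sd == 0:
            # one joint candidate (X', gamma'), one accept/reject
            f_cand, delta = chain.evaluate(prop, gamma_new)
            a = acceptance_probability(f_cur, f_cand, t, prop.q_forward,
                                       prop.q_reverse,
                                       pp.use_hastings_correction)
            u = rng.random()
            if u < a:
                chain.commit(delta, gamma_new)
                f_cur = f_cand
                n_accept += 1
        else:
            # sequential composition of two MH kernels with the same
            # target: the cluster move, then the symmetric gamma move
            f_cand, delta = chain.evaluate(prop, chain.gamma)
            a = acceptance_probability(f_cur, f_cand, t, prop.q_forward,
                                       prop.q_reverse,
                                       pp.use_hastings_correction)
            u = rng.random()
            if u < a:
                chain.commit(delta, chain.gamma)
                f_cur = f_cand
                n_accept += 1
            f_gam, _ = chain.evaluate(_noop(chain.clusters), gamma_new)
            a = acceptance_probability(f_cur, f_gam, t, 1.0, 1.0, False)
            u = rng.random()
            if u < a:
                chain.commit(None, gamma_new)
                f_cur = f_gam

        t = cool(t, pp.cooling_factor)

        if f_cur < best_score:
            best_score = f_cur
            best_clusters = tuple(chain.clusters)
            best_gamma = chain.gamma
        if pp.trace_every and it % pp.trace_every == 0:
            trace.append((it, f_cur))
        if counts is not None and it > pp.burn_in:
            counts[frozenset(chain.clusters)] += 1
        if pp.consistency_check_every and \
                it % pp.consistency_check_every == 0:
            err = chain.resync()
            max_err = max(max_err, err)
            if err > 1e-8:
                raise ChainConsistencyError(
                    f"incremental score drifted by {err:.3e} at iteration "
                    f"{it}")
            f_cur = chain.score()

    return RunResult(
        best_clusters=ClusterSet(best_clusters),
        best_gamma=best_gamma,
        best_score=best_score,
        trace=trace,
        acceptance_rate=n_accept / pp.n_iterations,
        n_iterations=pp.n_iterations,
        final_temperature=t,
        final_score=f_cur,
        max_consistency_error=max_err,
        state_counts=counts,
        params=pp,
        score_params=sp,
    )
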