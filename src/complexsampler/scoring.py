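"""The regularized scoring function f(X, gamma) over cluster sets.

``f`` is a linear combination of six terms, minimized by the sampler::

    f(X, g) = b(X) + h_den(X) + c_dis * h_dis(X)
              + c_size * sum_s (psi_X(s) - psi_g(s))^2
              + c_hy * (g - g0)^2 + c_pro * |union(X)|^2

* ``b`` — hard feasibility: every cluster connected and of size <= S_max,
  else +inf (probability zero).
* ``h_den`` — negative generalized density, ``-sum w(x)/sqrt(|x|)``.
* ``h_dis`` — Jaccard-based overlap penalty with hard caps on the allowed
  intersection (small clusters may share at most one protein; larger ones
  at most a fraction ``beta`` of the smaller cluster).
* size term — squared error between the empirical cluster-size histogram
  and a truncated power law ``psi_g(s) ~ s^-g`` on [2, S_max].
* ``h_hy`` — quadratic prior pulling the scaling exponent toward g0.
* ``h_pro`` — squared count of distinct proteins placed in any cluster.

Infeasibility is represented as IEEE ``+inf``; it is exact and absorbing
under addition, so a breakdown total is infinite iff ``b`` or the overlap
term is.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .network_io import (
    Cluster,
    PPINetwork,
    induced_subgraph_connected,
    cluster_weight,
)

INF = math.inf

__all__ = [
    "ScoreParams",
    "ScoreBreakdown",
    "boolean_term",
    "cluster_density",
    "density_term",
    "pair_dissimilarity",
    "overlap_term",
    "powerlaw_pmf",
    "powerlaw_pmf_vector",
    "empirical_size_fraction",
    "size_term",
    "hyper_prior_term",
    "protein_count_term",
    "total_score",
]


@dataclass(frozen=True)
class ScoreParams:
    """Coefficients and constants of the scoring function.

    Defaults are the values selected for the large weighted yeast network
    in the original study: ``c_clu_dis=110, beta=0.2, c_clu_size=500,
    c_hy=10, c_pro_num=5e-5``, with ``S_max=100`` and the prior center
    ``gamma0=2.5`` (the median of (2, 3), the typical power-law exponent
    range).
    """

    s_max: int = 100
    beta: float = 0.2
    c_clu_dis: float = 110.0
    c_clu_size: float = 500.0
    c_hy: float = 10.0
    c_pro_num: float = 5e-5
    gamma0: float = 2.5

    def __post_init__(self):
        if self.s_max < 2:
            raise ValueError("s_max must be >= 2")
        if not (0 < self.beta < 1):
            raise ValueError("beta must lie in (0, 1)")
        for name in ("c_clu_dis", "c_clu_size", "c_hy", "c_pro_num"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class ScoreBreakdown:
    """Raw value of each term plus the coefficient-weighted total."""

    b: float
    h_den: float
    h_dis: float
    h_size: float
    h_hy: float
    h_pro: float
    total: float

    @property
    def feasible(self) -> bool:
        return math.isfinite(self.total)


def _as_clusters(X: Iterable[Iterable[str]]) -> list[Cluster]:
    return [c if isinstance(c, frozenset) else frozenset(c) for c in X]


def boolean_term(net: PPINetwork, X: Iterable[Cluster], s_max: int) -> float:
    """b(X): 0 if every cluster is connected and of size <= s_max, else inf."""
    for x in _as_clusters(X):
        if len(x) > s_max or not induced_subgraph_connected(net, x):
            return INF
    return 0.0


def cluster_density(net: PPINetwork, x: Cluster) -> float:
    """Generalized density w(x)/sqrt(|x|).

    The sqrt denominator (instead of the |x|(|x|-1)/2 of the standard
    density) avoids penalizing large complexes for not being cliques.
    """
    x = frozenset(x)
    return cluster_weight(net, x) / math.sqrt(len(x))


def density_term(net: PPINetwork, X: Iterable[Cluster]) -> float:
    """h_den(X) = -sum of generalized densities (0 for empty X)."""
    return -sum(cluster_density(net, x) for x in _as_clusters(X))


def pair_dissimilarity(x: Cluster, x2: Cluster, beta: float) -> float:
    """Overlap penalty between two clusters.

    With ``m = min(|x|, |x2|)``: if ``m <= 3`` the pair may share at most
    one protein; if ``m >= 4`` the intersection may be at most ``beta * m``.
    Within the allowed region the penalty is the Jaccard index; outside it
    the pair is forbidden (+inf).  Disjoint clusters cost 0.
    """
    x, x2 = frozenset(x), frozenset(x2)
    inter = len(x & x2)
    if inter == 0:
        return 0.0
    m = min(len(x), len(x2))
    if m <= 3:
        allowed = inter <= 1
    else:
        allowed = inter / m <= beta
    if not allowed:
        return INF
    return inter / len(x | x2)


def overlap_term(X: Iterable[Cluster], beta: float) -> float:
    """h_dis(X): sum of pair_dissimilarity over unordered distinct pairs.

    Self-pairs are excluded (a self-pair would always be infinite and
    forbid every non-empty state); ordered counting would only rescale the
    coefficient.
    """
    clusters = _as_clusters(X)
    total = 0.0
    for i in range(len(clusters)):
        for j in range(i + 1, len(clusters)):
            d = pair_dissimilarity(clusters[i], clusters[j], beta)
            if d == INF:
                return INF
            total += d
    return total


def powerlaw_pmf_vector(gamma: float, s_max: int) -> np.ndarray:
    """psi_gamma over s = 2..s_max as a vector (normalized)."""
    if s_max < 2:
        raise ValueError("s_max must be >= 2")
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    s = np.arange(2, s_max + 1, dtype=float)
    p = s ** (-gamma)
    return p / p.sum()


def powerlaw_pmf(s: int, gamma: float, s_max: int) -> float:
    """psi_gamma(s) = s^-gamma / sum_{t=2}^{S_max} t^-gamma."""
    if not 2 <= s <= s_max:
        raise ValueError(f"size {s} outside [2, {s_max}]")
    return float(powerlaw_pmf_vector(gamma, s_max)[s - 2])


def empirical_size_fraction(X: Iterable[Cluster], s: int) -> float:
    """psi_X(s): fraction of clusters with exactly s members (0 if X empty)."""
    if s < 2:
        raise ValueError("cluster sizes start at 2")
    clusters = _as_clusters(X)
    if not clusters:
        return 0.0
    return sum(1 for x in clusters if len(x) == s) / len(clusters)


def size_term(X: Iterable[Cluster], gamma: float, s_max: int) -> float:
    """sum_{s=2}^{S_max} (psi_X(s) - psi_gamma(s))^2.

    For empty X the empirical histogram is taken as identically zero,
    giving the finite penalty sum(psi_gamma^2) that pushes the sampler away
    from the empty state.
    """
    clusters = _as_clusters(X)
    pmf = powerlaw_pmf_vector(gamma, s_max)
    emp = np.zeros_like(pmf)
    n = len(clusters)
    if n:
        for x in clusters:
            if 2 <= len(x) <= s_max:
                emp[len(x) - 2] += 1.0
        emp /= n
    return float(((emp - pmf) ** 2).sum())


def _size_term_from_hist(hist: dict[int, int], n_clusters: int,
                         pmf: np.ndarray, pmf_sq_sum: float) -> float:
    """Size term from a size histogram; O(distinct sizes) given the pmf.

    Identity: sum (psi_X - psi_g)^2 = sum psi_g^2
              + sum_{s: psi_X(s)>0} (psi_X(s)^2 - 2 psi_X(s) psi_g(s)).
    """
    total = pmf_sq_sum
    if n_clusters:
        inv = 1.0 / n_clusters
        for s, c in hist.items():
            f = c * inv
            total += f * f - 2.0 * f * float(pmf[s - 2])
    return total


def hyper_prior_term(gamma: float, gamma0: float) -> float:
    """h_hy(gamma) = (gamma - gamma0)^2."""
    return (gamma - gamma0) ** 2


def protein_count_term(X: Iterable[Cluster]) -> float:
    """h_pro(X) = |union of all clusters|^2."""
    members: set[str] = set()
    for x in _as_clusters(X):
        members |= x
    return float(len(members)) ** 2


def total_score(net: PPINetwork, X: Iterable[Cluster], gamma: float,
                params: ScoreParams) -> ScoreBreakdown:
    """Evaluate every term of f(X, gamma) and the weighted total."""
    clusters = _as_clusters(X)
    b = boolean_term(net, clusters, params.s_max)
    h_den = density_term(net, clusters)
    h_dis = overlap_term(clusters, params.beta)
    h_size = size_term(clusters, gamma, params.s_max)
    h_hy = hyper_prior_term(gamma, params.gamma0)
    h_pro = protein_count_term(clusters)
    if b == INF or h_dis == INF:
        total = INF
    else:
        total = (b + h_den + params.c_clu_dis * h_dis
                 + params.c_clu_size * h_size + params.c_hy * h_hy
                 + params.c_pro_num * h_pro)
    return ScoreBreakdown(b=b, h_den=h_den, h_dis=h_dis, h_size=h_size,
                          h_hy=h_hy, h_pro=h_pro, total=total)
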