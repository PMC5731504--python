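"""Size-stratified matching of predicted clusters against a catalogue.

Small predicted clusters are easy to match by chance: two random dimers
sharing one protein already have Jaccard 1/3.  The measure therefore
splits predictions and known complexes into three size strata and matches
within each stratum only: sizes 2 and 3 require an exact match (Jaccard
threshold 1), sizes >= 4 require Jaccard >= 0.5.  Precision is the
fraction of predictions matched somewhere in their stratum, recall the
fraction of known complexes matched, and F the harmonic mean.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable

from .network_io import Cluster

__all__ = [
    "jaccard",
    "matched_predictions",
    "matched_complexes",
    "evaluate",
    "overlap_histogram",
    "EvalReport",
    "OverlapStats",
]


def jaccard(x: Iterable[str], k: Iterable[str]) -> float:
    """J(x, k) = |intersection| / |union|."""
    x, k = frozenset(x), frozenset(k)
    if not x or not k:
        raise ValueError("Jaccard index of an empty set is undefined")
    return len(x & k) / len(x | k)


def _as_sets(clusters: Iterable[Iterable[str]]) -> list[Cluster]:
    return [c if isinstance(c, frozenset) else frozenset(c) for c in clusters]


def matched_predictions(Xs: Iterable[Cluster], Ks: Iterable[Cluster],
                        eta: float) -> set[Cluster]:
    """Predicted clusters in Xs matching >= 1 complex in Ks at threshold eta."""
    if not (0 < eta <= 1):
        raise ValueError("eta must lie in (0, 1]")
    Xs, Ks = _as_sets(Xs), _as_sets(Ks)
    return {x for x in Xs if any(jaccard(x, k) >= eta for k in Ks)}


def matched_complexes(Xs: Iterable[Cluster], Ks: Iterable[Cluster],
                      eta: float) -> set[Cluster]:
    """Known complexes in Ks matched by >= 1 cluster in Xs at threshold eta."""
    if not (0 < eta <= 1):
        raise ValueError("eta must lie in (0, 1]")
    Xs, Ks = _as_sets(Xs), _as_sets(Ks)
    return {k for k in Ks if any(jaccard(x, k) >= eta for x in Xs)}


@dataclass(frozen=True)
class EvalReport:
    precision: float
    recall: float
    f_measure: float
    matched_predictions_by_stratum: dict = field(default_factory=dict)
    matched_complexes_by_stratum: dict = field(default_factory=dict)
    n_predicted: int = 0
    n_known: int = 0

    def as_dict(self) -> dict:
        return {
            "precision": self.precision,
            "recall": self.recall,
            "f_measure": self.f_measure,
            "n_predicted": self.n_predicted,
            "n_known": self.n_known,
            **{f"matched_predictions_size_{s}": c
               for s, c in self.matched_predictions_by_stratum.items()},
            **{f"matched_complexes_size_{s}": c
               for s, c in self.matched_complexes_by_stratum.items()},
        }


# stratum label -> (size filter, matching threshold eta)
_STRATA: list[tuple[str, float]] = [("2", 1.0), ("3", 1.0), ("ge4", 0.5)]


def _stratum(clusters: list[Cluster], label: str) -> list[Cluster]:
    if label == "ge4":
        return [c for c in clusters if len(c) >= 4]
    return [c for c in clusters if len(c) == int(label)]


def evaluate(X: Iterable[Cluster], K: Iterable[Cluster]) -> EvalReport:
    """Size-stratified precision / recall / F of predictions X against
    catalogue K.

    Strata are hard-partitioned: a size-2 prediction is never compared to
    a size-3 complex.  Empty X (or K) gives precision (recall) 0, and F is
    0 when both are 0.
    """
    Xs, Ks = _as_sets(X), _as_sets(K)
    pred_matches: dict[str, int] = {}
    known_matches: dict[str, int] = {}
    for label, eta in _STRATA:
        xs = _stratum(Xs, label)
        ks = _stratum(Ks, label)
        pred_matches[label] = len(matched_predictions(xs, ks, eta)) \
            if xs and ks else 0
        known_matches[label] = len(matched_complexes(xs, ks, eta)) \
            if xs and ks else 0
    precision = sum(pred_matches.values()) / len(Xs) if Xs else 0.0
    recall = sum(known_matches.values()) / len(Ks) if Ks else 0.0
    if precision + recall > 0:
        f = 2 * precision * recall / (precision + recall)
    else:
        f = 0.0
    return EvalReport(precision=precision, recall=recall, f_measure=f,
                      matched_predictions_by_stratum=pred_matches,
                      matched_complexes_by_stratum=known_matches,
                      n_predicted=len(Xs), n_known=len(Ks))


@dataclass(frozen=True)
class OverlapStats:
    """Overlap structure of a complex catalogue.

    ``histogram`` maps intersection size (>= 1) to the number of unordered
    complex pairs with that intersection; ``n_overlapping_pairs`` is the
    total and ``n_complexes_involved`` counts distinct complexes that take
    part in at least one overlapping pair.
    """

    histogram: dict
    n_overlapping_pairs: int
    n_complexes_involved: int


def overlap_histogram(K: Iterable[Cluster]) -> OverlapStats:
    Ks = _as_sets(K)
    hist: Counter = Counter()
    involved: set[Cluster] = set()
    for i in range(len(Ks)):
        for j in range(i + 1, len(Ks)):
            inter = len(Ks[i] & Ks[j])
            if inter:
                hist[inter] += 1
                involved.add(Ks[i])
                involved.add(Ks[j])
    return OverlapStats(histogram=dict(sorted(hist.items())),
                        n_overlapping_pairs=sum(hist.values()),
                        n_complexes_involved=len(involved))
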