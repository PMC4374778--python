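"""Familial-relationship classification from CNV sharing rates.

If a caller's output is specific, pairwise sharing rates alone should
separate monozygotic twins (identical genomes), parent-child pairs (half
the CNV complement transmitted) and unrelated individuals (only population
CNVs in common).  The test clusters the 1-D sharing rates with k-means
(k = 3), labels clusters by rank of their mean rate, and scores the result
with a support-weighted F1; random or biased call sets collapse the
separation and drive F1 down.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Optional, Sequence

import numpy as np
from sklearn.cluster import KMeans

from .cnv_core import DEFAULT_RO_THRESHOLD
from .family_metrics import pair_sharing_rate
from .types import CallSet, Pedigree

logger = logging.getLogger(__name__)


class Relationship(str, enum.Enum):
    TWIN = "twin"
    PARENT_CHILD = "parent_child"
    UNRELATED = "unrelated"


#: cluster rank (by mean sharing rate, descending) -> relationship label
RANK_TO_LABEL = (Relationship.TWIN, Relationship.PARENT_CHILD, Relationship.UNRELATED)


@dataclass(frozen=True)
class PairObservation:
    sample_a: str
    sample_b: str
    true_label: Relationship
    sharing_rate: float

    def __post_init__(self) -> None:
        if self.sample_a == self.sample_b:
            raise ValueError("a pair must consist of two distinct samples")
        if not 0 <= self.sharing_rate <= 1:
            raise ValueError(f"sharing rate {self.sharing_rate} outside [0, 1]")


@dataclass(frozen=True)
class ClassificationResult:
    labels: tuple[Relationship, ...]
    degenerate: bool  # all rates identical: clustering carries no signal


def build_pair_table(
    callsets: Mapping[str, CallSet],
    pedigree: Pedigree,
    threshold: float = DEFAULT_RO_THRESHOLD,
    n_unrelated: Optional[int] = None,
    seed: int = 0,
    child: str = "twin1",
) -> list[PairObservation]:
    """Assemble the pair table for the classification test.

    Per family: one twin pair and two child-parent pairs (child vs each
    parent; ``child`` picks which twin, immaterial for identical twins).
    ``n_unrelated`` cross-family pairs (default: one per family) are drawn
    uniformly without replacement with the given seed.  Sharing rates come
    from :func:`family_metrics.pair_sharing_rate`; a pair with two empty
    call sets gets rate 0 and a warning.
    """
    if n_unrelated is None:
        n_unrelated = len(pedigree)
    for s in pedigree.samples:
        if s not in callsets:
            raise KeyError(f"no call set supplied for pedigree sample {s!r}")

    def rate(a: str, b: str) -> float:
        r = pair_sharing_rate(callsets[a], callsets[b], threshold)
        if r is None:
            logger.warning("pair (%s, %s): both call sets empty; rate set to 0", a, b)
            return 0.0
        return r

    obs: list[PairObservation] = []
    for fam in pedigree:
        kid = fam.twin1 if child == "twin1" else fam.twin2
        obs.append(
            PairObservation(fam.twin1, fam.twin2, Relationship.TWIN, rate(fam.twin1, fam.twin2))
        )
        obs.append(
            PairObservation(kid, fam.parent1, Relationship.PARENT_CHILD, rate(kid, fam.parent1))
        )
        obs.append(
            PairObservation(kid, fam.parent2, Relationship.PARENT_CHILD, rate(kid, fam.parent2))
        )

    if n_unrelated > 0:
        if len(pedigree) < 2:
            raise ValueError("unrelated pairs require at least 2 families")
        family_of = {s: fam.family_id for fam in pedigree for s in fam.members}
        samples = list(pedigree.samples)
        cross = [
            (a, b)
            for a, b in combinations(samples, 2)
            if family_of[a] != family_of[b]
        ]
        rng = np.random.default_rng(seed)
        picks = rng.choice(len(cross), size=min(n_unrelated, len(cross)), replace=False)
        for i in sorted(picks):
            a, b = cross[i]
            obs.append(PairObservation(a, b, Relationship.UNRELATED, rate(a, b)))
    return obs


def kmeans_relationship(
    observations: Sequence[PairObservation],
    k: int = 3,
    seed: int = 0,
    n_restarts: int = 10,
) -> ClassificationResult:
    """Cluster 1-D sharing rates with k-means and map clusters to labels by
    rank of the cluster mean (highest -> twin, middle -> parent-child,
    lowest -> unrelated).  Deterministic given the seed; the best of
    ``n_restarts`` initialisations by within-cluster sum of squares is kept.
    """
    if len(observations) < k:
        raise ValueError(f"need at least k={k} observations, got {len(observations)}")
    rates = np.array([o.sharing_rate for o in observations]).reshape(-1, 1)
    if np.ptp(rates) == 0:
        # no separation at all: flag degenerate, everything one class
        return ClassificationResult(
            labels=tuple(RANK_TO_LABEL[0] for _ in observations), degenerate=True
        )
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    assignment = km.fit_predict(rates)
    order = np.argsort(-km.cluster_centers_.ravel())  # descending mean rate
    label_of_cluster = {int(cl): RANK_TO_LABEL[rank] for rank, cl in enumerate(order)}
    return ClassificationResult(
        labels=tuple(label_of_cluster[int(c)] for c in assignment), degenerate=False
    )


def weighted_f1(true_labels: Sequence, predicted_labels: Sequence) -> float:
    """Support-weighted mean of per-class F1 = 2PR/(P+R).

    A class with no true and no predicted members contributes F1 = 0 (and a
    logged note); precision/recall with empty denominators are taken as 0.
    """
    if len(true_labels) != len(predicted_labels) or len(true_labels) == 0:
        raise ValueError("label vectors must be non-empty and of equal length")
    true = list(true_labels)
    pred = list(predicted_labels)
    classes = sorted(set(true) | set(pred), key=str)
    total = len(true)
    score = 0.0
    for cls in classes:
        tp = sum(1 for t, p in zip(true, pred) if t == cls and p == cls)
        n_true = sum(1 for t in true if t == cls)
        n_pred = sum(1 for p in pred if p == cls)
        if n_true == 0 and n_pred == 0:
            logger.info("class %r absent from both label vectors; F1 taken as 0", cls)
            continue
        precision = tp / n_pred if n_pred else 0.0
        recall = tp / n_true if n_true else 0.0
        f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
        score += (n_true / total) * f1
    return score


def classification_f1(
    callsets: Mapping[str, CallSet],
    pedigree: Pedigree,
    threshold: float = DEFAULT_RO_THRESHOLD,
    seed: int = 0,
) -> float:
    """Full familial-relationship classification test for one source:
    pair table -> k-means -> weighted F1."""
    obs = build_pair_table(callsets, pedigree, threshold=threshold, seed=seed)
    result = kmeans_relationship(obs, seed=seed)
    return weighted_f1([o.true_label for o in obs], result.labels)
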