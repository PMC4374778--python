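"""Mendelian-consistency metrics on twin quartets.

The central quality metric is the *inherited CNV rate*: the fraction of the
twins' calls validated by presence in both monozygotic twins and at least
one parent, computed per family as 2×shared/(N1+N2) where N1, N2 are the
twins' call counts.  Because the twins carry identical genomes, any call
failing this filter is attributable to caller error rather than biology.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .cnv_core import DEFAULT_RO_THRESHOLD, ROIndex
from .types import CallSet, Quartet


@dataclass(frozen=True)
class QuartetCalls:
    """The four call sets of one family from one source, normalized with
    identical parameters."""

    quartet: Quartet
    twin1: CallSet
    twin2: CallSet
    parent1: CallSet
    parent2: CallSet

    @property
    def parent_union(self) -> CallSet:
        return CallSet.from_iter(
            tuple(self.parent1) + tuple(self.parent2),
            sample_id=f"{self.quartet.family_id}:parents",
            source=self.parent1.source or self.parent2.source,
        )


@dataclass(frozen=True)
class InheritedRateResult:
    """Per-family inherited-CNV-rate tally.

    ``shared`` is the symmetric validated count (|I1| + |I2|) / 2, so that
    ``rate = 2 * shared / (n1 + n2)``; ``rate`` is None when the twins
    called no CNVs at all (undefined, not zero).
    """

    family_id: str
    n1: int
    n2: int
    inherited1: int
    inherited2: int

    @property
    def shared(self) -> float:
        return (self.inherited1 + self.inherited2) / 2

    @property
    def rate(self) -> Optional[float]:
        if self.n1 + self.n2 == 0:
            return None
        return 2 * self.shared / (self.n1 + self.n2)


def shared_calls(
    a: CallSet, b: CallSet, threshold: float = DEFAULT_RO_THRESHOLD
) -> CallSet:
    """Subset of ``a`` whose calls have at least one RO match in ``b``.

    Many-to-one matching: a call is shared as soon as any counterpart
    matches; no one-to-one assignment is enforced.
    """
    index = ROIndex(b, threshold)
    return a.with_calls([c for c in a if index.has_match(c)])


def inherited_calls(
    q: QuartetCalls, threshold: float = DEFAULT_RO_THRESHOLD
) -> tuple[CallSet, CallSet]:
    """Per-twin subsets of calls present in the co-twin and in at least one
    parent (evaluated against the union of the parents' call sets)."""
    parent_index = ROIndex(q.parent_union, threshold)
    t1_index = ROIndex(q.twin1, threshold)
    t2_index = ROIndex(q.twin2, threshold)
    i1 = q.twin1.with_calls(
        [c for c in q.twin1 if t2_index.has_match(c) and parent_index.has_match(c)]
    )
    i2 = q.twin2.with_calls(
        [c for c in q.twin2 if t1_index.has_match(c) and parent_index.has_match(c)]
    )
    return i1, i2


def inherited_rate(
    q: QuartetCalls, threshold: float = DEFAULT_RO_THRESHOLD
) -> InheritedRateResult:
    """Inherited CNV rate of one quartet: 2×shared/(N1+N2)."""
    i1, i2 = inherited_calls(q, threshold)
    return InheritedRateResult(
        family_id=q.quartet.family_id,
        n1=len(q.twin1),
        n2=len(q.twin2),
        inherited1=len(i1),
        inherited2=len(i2),
    )


def pair_sharing_rate(
    a: CallSet, b: CallSet, threshold: float = DEFAULT_RO_THRESHOLD
) -> Optional[float]:
    """Symmetric sharing rate of two call sets:
    (|shared(a,b)| + |shared(b,a)|) / (|a| + |b|); None when both empty."""
    if len(a) + len(b) == 0:
        return None
    n_ab = len(shared_calls(a, b, threshold))
    n_ba = len(shared_calls(b, a, threshold))
    return (n_ab + n_ba) / (len(a) + len(b))
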