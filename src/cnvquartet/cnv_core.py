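"""Interval arithmetic on CNV calls.

Two calls are compared by *reciprocal overlap* (RO): the pair of fractions
(overlapping bases / size of each call).  Two calls "match" at threshold t
when they share chromosome and status and both fractions reach t; the
working default, 0.70, follows common practice for declaring two CNV regions
identical.  Call sets are normalized before any comparison by merging
same-status calls separated by less than 5 kb, which undoes caller-side
fragmentation of single biological events.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from intervaltree import IntervalTree

from .types import CallSet, CNVCall, GenomeContext

DEFAULT_RO_THRESHOLD = 0.70
DEFAULT_MERGE_GAP = 5_000


@dataclass(frozen=True)
class ROPair:
    """Reciprocal-overlap fractions of a compared pair of calls:
    overlap/size(a) and overlap/size(b)."""

    r_a: float
    r_b: float

    def min(self) -> float:
        return min(self.r_a, self.r_b)

    def swap(self) -> "ROPair":
        return ROPair(self.r_b, self.r_a)


@dataclass(frozen=True)
class CallSetStats:
    """Descriptive statistics of one normalized call set."""

    n_calls: int
    mean_size: Optional[float]  # bp
    mean_adjacent_distance: Optional[float]  # bp; None when < 2 calls on every chrom
    genome_coverage: float  # fraction of the genome covered by the call union


def overlap_bases(a: CNVCall, b: CNVCall) -> int:
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def reciprocal_overlap(a: CNVCall, b: CNVCall) -> ROPair:
    """RO tuple of two calls: zero in both components when the calls sit on
    different chromosomes or do not overlap."""
    ov = overlap_bases(a, b)
    return ROPair(ov / a.size(), ov / b.size())


def ro_match(a: CNVCall, b: CNVCall, threshold: float = DEFAULT_RO_THRESHOLD) -> bool:
    """True iff a and b share chromosome and status and min(RO) >= threshold.

    The comparison is inclusive to avoid floating-point knife edges at the
    threshold itself.
    """
    if not 0 < threshold <= 1:
        raise ValueError(f"RO threshold must be in (0, 1], got {threshold}")
    if a.chrom != b.chrom or a.status != b.status:
        return False
    ov = overlap_bases(a, b)
    return ov >= threshold * a.size() and ov >= threshold * b.size()


def merge_adjacent(callset: CallSet, max_gap: int = DEFAULT_MERGE_GAP) -> CallSet:
    """Merge same-status calls separated by less than ``max_gap`` bases.

    Within each (chromosome, status) group, consecutive calls whose gap
    (next start - previous end) is < max_gap are replaced by one call
    spanning the group; overlapping same-status calls are likewise unified.
    Opposite-status calls are never merged.  Idempotent; output canonical.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    merged = [m for group in _merge_groups(callset, max_gap) for m in [_span_call(group)]]
    return callset.with_calls(merged)


def merged_fraction(callset: CallSet, max_gap: int = DEFAULT_MERGE_GAP) -> float:
    """Fraction of input calls that participate in at least one merge event
    at the given gap threshold (0 for an empty call set)."""
    if len(callset) == 0:
        return 0.0
    affected = sum(len(g) for g in _merge_groups(callset, max_gap) if len(g) > 1)
    return affected / len(callset)


def _merge_groups(callset: CallSet, max_gap: int) -> list[list[CNVCall]]:
    """Group calls into merge components: maximal runs of same-(chrom,
    status) calls chained by gaps < max_gap (overlap counts as adjacency)."""
    by_group: dict[tuple, list[CNVCall]] = {}
    for c in callset:
        by_group.setdefault((c.chrom, c.status), []).append(c)
    groups: list[list[CNVCall]] = []
    for calls in by_group.values():
        calls.sort(key=lambda c: (c.start, c.end))
        run = [calls[0]]
        run_end = calls[0].end
        for c in calls[1:]:
            if c.start - run_end < max_gap:
                run.append(c)
                run_end = max(run_end, c.end)
            else:
                groups.append(run)
                run = [c]
                run_end = c.end
        groups.append(run)
    return groups


def _span_call(group: list[CNVCall]) -> CNVCall:
    first = group[0]
    if len(group) == 1:
        return first
    scores = [c.score for c in group if c.score is not None]
    return CNVCall(
        chrom=first.chrom,
        start=min(c.start for c in group),
        end=max(c.end for c in group),
        status=first.status,
        sample_id=first.sample_id,
        source=first.source,
        score=max(scores) if scores else None,
    )


def union_covered_bases(callset: CallSet) -> int:
    """Total bases covered by the union of all call intervals (statuses
    pooled)."""
    total = 0
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for c in callset:
        by_chrom.setdefault(c.chrom, []).append((c.start, c.end))
    for ivs in by_chrom.values():
        ivs.sort()
        cur_s, cur_e = ivs[0]
        for s, e in ivs[1:]:
            if s > cur_e:
                total += cur_e - cur_s
                cur_s, cur_e = s, e
            else:
                cur_e = max(cur_e, e)
        total += cur_e - cur_s
    return total


def callset_stats(
    callset: CallSet, context: GenomeContext, within_status: bool = False
) -> CallSetStats:
    """Per-sample descriptive statistics: call count, mean size, mean gap
    between adjacent calls on the same chromosome, and genome coverage.

    Adjacent distances are taken across all calls per chromosome by default
    (``within_status=True`` restricts pairs to same-status neighbours);
    negative gaps from overlapping opposite-status calls are clamped to 0.
    """
    n = len(callset)
    if n == 0:
        return CallSetStats(0, None, None, 0.0)
    mean_size = sum(c.size() for c in callset) / n

    gaps: list[int] = []
    groups: dict[tuple, list[CNVCall]] = {}
    for c in callset:
        key = (c.chrom, c.status) if within_status else (c.chrom,)
        groups.setdefault(key, []).append(c)
    for calls in groups.values():
        calls.sort(key=lambda c: (c.start, c.end))
        for prev, nxt in zip(calls, calls[1:]):
            gaps.append(max(0, nxt.start - prev.end))
    mean_gap = sum(gaps) / len(gaps) if gaps else None

    for c in callset:
        context.check_call(c)
    coverage = union_covered_bases(callset) / context.genome_length
    return CallSetStats(n, mean_size, mean_gap, coverage)


class ROIndex:
    """Interval index over a call set for fast RO-threshold match queries."""

    def __init__(self, callset: CallSet, threshold: float = DEFAULT_RO_THRESHOLD):
        if not 0 < threshold <= 1:
            raise ValueError(f"RO threshold must be in (0, 1], got {threshold}")
        self.threshold = threshold
        self._trees: dict[tuple, IntervalTree] = {}
        for c in callset:
            tree = self._trees.setdefault((c.chrom, c.status), IntervalTree())
            tree.addi(c.start, c.end, c)

    def matches(self, call: CNVCall) -> list[CNVCall]:
        """All indexed calls that ro_match ``call`` at the index threshold."""
        tree = self._trees.get((call.chrom, call.status))
        if tree is None:
            return []
        hits = []
        for iv in tree.overlap(call.start, call.end):
            other: CNVCall = iv.data
            ov = min(call.end, other.end) - max(call.start, other.start)
            if ov >= self.threshold * call.size() and ov >= self.threshold * other.size():
                hits.append(other)
        return hits

    def has_match(self, call: CNVCall) -> bool:
        tree = self._trees.get((call.chrom, call.status))
        if tree is None:
            return False
        for iv in tree.overlap(call.start, call.end):
            other: CNVCall = iv.data
            ov = min(call.end, other.end) - max(call.start, other.start)
            if ov >= self.threshold * call.size() and ov >= self.threshold * other.size():
                return True
        return False
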