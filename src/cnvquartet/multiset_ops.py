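"""Cross-caller agreement: region components, Venn tables, set operations.

RO matching is not transitive, so "the same CNV seen by several tools" is
resolved as a connected component of the match graph: vertices are all calls
of one sample across sources, edges are RO matches at the working threshold.
A component counts once in the Venn cell indexed by its set of contributing
sources, regardless of per-source multiplicity.  Pairwise union/intersection
call sets emit one call per kept component, spanning its members.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

from intervaltree import IntervalTree

from .cnv_core import DEFAULT_RO_THRESHOLD
from .family_metrics import QuartetCalls, inherited_calls, inherited_rate, InheritedRateResult
from .types import CallSet, CNVCall, Pedigree, Status


@dataclass(frozen=True)
class RegionComponent:
    """One cross-source equivalence class of calls for one sample."""

    member_calls: tuple[CNVCall, ...]
    sources: frozenset[str]
    chrom: str
    start: int  # min start over members
    end: int  # max end over members
    status: Status

    def span_call(self, sample_id: str = "", source: str = "") -> CNVCall:
        return CNVCall(
            chrom=self.chrom,
            start=self.start,
            end=self.end,
            status=self.status,
            sample_id=sample_id or self.member_calls[0].sample_id,
            source=source,
        )


@dataclass
class VennTable:
    """Mean per-sample component counts indexed by source subset.

    ``cells`` averages over all samples; when Mendelian filtering was
    requested, ``filtered_cells`` and the raw twin-only baseline behind
    ``loss_ratio`` (1 - filtered/unfiltered) average over twin samples only,
    because the inherited-call filter is defined for twins.
    """

    cells: dict[frozenset, float]
    filtered_cells: dict[frozenset, float] = field(default_factory=dict)
    loss_ratio: dict[frozenset, float] = field(default_factory=dict)


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def match_components(
    callsets_by_source: Mapping[str, CallSet],
    threshold: float = DEFAULT_RO_THRESHOLD,
) -> list[RegionComponent]:
    """Connected components of the RO-match graph over one sample's calls
    from all sources.  The components partition the input calls."""
    if not 0 < threshold <= 1:
        raise ValueError(f"RO threshold must be in (0, 1], got {threshold}")
    calls: list[tuple[str, CNVCall]] = []
    for source, cs in callsets_by_source.items():
        calls.extend((source, c) for c in cs)
    if not calls:
        return []
    uf = _UnionFind(len(calls))
    trees: dict[tuple, IntervalTree] = {}
    for i, (_, c) in enumerate(calls):
        trees.setdefault((c.chrom, c.status), IntervalTree()).addi(c.start, c.end, i)
    for i, (_, a) in enumerate(calls):
        for iv in trees[(a.chrom, a.status)].overlap(a.start, a.end):
            j = iv.data
            if j <= i:
                continue
            b = calls[j][1]
            ov = min(a.end, b.end) - max(a.start, b.start)
            if ov >= threshold * a.size() and ov >= threshold * b.size():
                uf.union(i, j)
    groups: dict[int, list[int]] = {}
    for i in range(len(calls)):
        groups.setdefault(uf.find(i), []).append(i)
    components = []
    for members in groups.values():
        mcalls = tuple(calls[i][1] for i in members)
        components.append(
            RegionComponent(
                member_calls=mcalls,
                sources=frozenset(calls[i][0] for i in members),
                chrom=mcalls[0].chrom,
                start=min(c.start for c in mcalls),
                end=max(c.end for c in mcalls),
                status=mcalls[0].status,
            )
        )
    components.sort(key=lambda comp: (comp.chrom, comp.start, comp.end, comp.status.value))
    return components


def _cell_counts(components: list[RegionComponent]) -> dict[frozenset, int]:
    counts: dict[frozenset, int] = {}
    for comp in components:
        counts[comp.sources] = counts.get(comp.sources, 0) + 1
    return counts


def _mean_cells(per_sample: list[dict[frozenset, int]]) -> dict[frozenset, float]:
    cells: dict[frozenset, float] = {}
    n = len(per_sample)
    for counts in per_sample:
        for key, v in counts.items():
            cells[key] = cells.get(key, 0.0) + v
    return {k: v / n for k, v in cells.items()}


def _inherited_subsets(
    calls_by_sample: Mapping[str, CallSet],
    pedigree: Pedigree,
    threshold: float,
) -> dict[str, CallSet]:
    """Per-twin inherited subsets for one source, keyed by twin sample id."""
    out: dict[str, CallSet] = {}
    for fam in pedigree:
        q = QuartetCalls(
            quartet=fam,
            twin1=calls_by_sample[fam.twin1],
            twin2=calls_by_sample[fam.twin2],
            parent1=calls_by_sample[fam.parent1],
            parent2=calls_by_sample[fam.parent2],
        )
        i1, i2 = inherited_calls(q, threshold)
        out[fam.twin1] = i1
        out[fam.twin2] = i2
    return out


def venn_counts(
    callsets: Mapping[str, Mapping[str, CallSet]],
    pedigree: Optional[Pedigree] = None,
    threshold: float = DEFAULT_RO_THRESHOLD,
    filtered: bool = False,
) -> VennTable:
    """Venn table of cross-source agreement.

    ``callsets`` maps source -> sample -> CallSet; all sources must cover
    the same samples.  With ``filtered=True`` (requires a pedigree) each
    twin call set is first replaced by its Mendelian-consistent subset and
    the per-cell loss ratio 1 - B/A is reported against the twin-only raw
    baseline.
    """
    sources = list(callsets)
    samples_per_source = [set(callsets[s]) for s in sources]
    samples = samples_per_source[0]
    if any(sp != samples for sp in samples_per_source):
        raise ValueError("all sources must cover the same samples")

    def counts_for(sample_ids, per_source):
        per_sample = []
        for sid in sorted(sample_ids):
            comp = match_components(
                {src: per_source[src][sid] for src in sources}, threshold
            )
            per_sample.append(_cell_counts(comp))
        return per_sample

    table = VennTable(cells=_mean_cells(counts_for(samples, callsets)))
    if not filtered:
        return table
    if pedigree is None:
        raise ValueError("Mendelian filtering requires a pedigree")
    twin_ids = {s for fam in pedigree for s in (fam.twin1, fam.twin2)}
    if not twin_ids <= samples:
        raise ValueError("pedigree twins missing from the call sets")
    filtered_by_source = {
        src: _inherited_subsets(callsets[src], pedigree, threshold) for src in sources
    }
    raw_twin = _mean_cells(counts_for(twin_ids, callsets))
    table.filtered_cells = _mean_cells(counts_for(twin_ids, filtered_by_source))
    table.loss_ratio = {
        key: 1.0 - table.filtered_cells.get(key, 0.0) / a
        for key, a in raw_twin.items()
        if a > 0
    }
    return table


def pairwise_setop(
    a_by_sample: Mapping[str, CallSet],
    b_by_sample: Mapping[str, CallSet],
    op: str,
    threshold: float = DEFAULT_RO_THRESHOLD,
) -> dict[str, CallSet]:
    """Per-sample union or intersection of two sources.

    Components are built from the two call sets; ``intersection`` keeps only
    components containing both sources, ``union`` keeps all.  Each kept
    component is emitted as one call spanning its members.
    """
    if op not in ("union", "intersection"):
        raise ValueError(f"op must be 'union' or 'intersection', got {op!r}")
    if set(a_by_sample) != set(b_by_sample):
        raise ValueError("the two sources must cover the same samples")
    out: dict[str, CallSet] = {}
    for sid in a_by_sample:
        a, b = a_by_sample[sid], b_by_sample[sid]
        name_a = a.source or "A"
        name_b = b.source or "B"
        if name_a == name_b:
            name_b += "'"
        components = match_components({name_a: a, name_b: b}, threshold)
        sym = "∪" if op == "union" else "∩"
        combined_name = f"{name_a}{sym}{name_b}"
        kept = [
            comp.span_call(sample_id=sid, source=combined_name)
            for comp in components
            if op == "union" or len(comp.sources) == 2
        ]
        out[sid] = CallSet.from_iter(kept, sample_id=sid, source=combined_name)
    return out


def combined_inherited_rate(
    a_by_sample: Mapping[str, CallSet],
    b_by_sample: Mapping[str, CallSet],
    op: str,
    pedigree: Pedigree,
    threshold: float = DEFAULT_RO_THRESHOLD,
) -> tuple[dict[str, InheritedRateResult], float]:
    """Inherited rate of the pairwise union/intersection call set.

    Returns per-family :class:`InheritedRateResult` plus the mean per-sample
    call count of the combined set.
    """
    combined = pairwise_setop(a_by_sample, b_by_sample, op, threshold)
    rates: dict[str, InheritedRateResult] = {}
    for fam in pedigree:
        q = QuartetCalls(
            quartet=fam,
            twin1=combined[fam.twin1],
            twin2=combined[fam.twin2],
            parent1=combined[fam.parent1],
            parent2=combined[fam.parent2],
        )
        rates[fam.family_id] = inherited_rate(q, threshold)
    mean_count = sum(len(cs) for cs in combined.values()) / len(combined)
    return rates, mean_count
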