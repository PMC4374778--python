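"""Independent brute-force reference implementations used only by tests.

Each function recomputes a toolkit quantity by the most literal method
available (all-pairs scans, per-base bitmaps, graph closure via networkx,
confusion-matrix arithmetic) without touching the production code paths.
"""

from __future__ import annotations

import numpy as np
import networkx as nx


def brute_ro(a, b) -> tuple[float, float]:
    """Reciprocal-overlap tuple by direct interval arithmetic."""
    if a.chrom != b.chrom:
        ov = 0
    else:
        ov = len(set(range(a.start, a.end)) & set(range(b.start, b.end)))
    return ov / (a.end - a.start), ov / (b.end - b.start)


def brute_match(a, b, threshold: float) -> bool:
    if a.chrom != b.chrom or a.status != b.status:
        return False
    ra, rb = brute_ro(a, b)
    return min(ra, rb) >= threshold


def brute_merge_groups(calls, max_gap: int) -> list[frozenset]:
    """Merge components via an explicit gap graph + networkx closure."""
    g = nx.Graph()
    g.add_nodes_from(range(len(calls)))
    for i, a in enumerate(calls):
        for j, b in enumerate(calls):
            if j <= i:
                continue
            if a.chrom == b.chrom and a.status == b.status:
                gap = max(a.start, b.start) - min(a.end, b.end)
                if gap < max_gap:
                    g.add_edge(i, j)
    return [frozenset(c) for c in nx.connected_components(g)]


def brute_merge(calls, max_gap: int) -> set[tuple]:
    """Expected merged intervals as (chrom, start, end, status) tuples."""
    out = set()
    for comp in brute_merge_groups(calls, max_gap):
        members = [calls[i] for i in comp]
        out.add(
            (
                members[0].chrom,
                min(c.start for c in members),
                max(c.end for c in members),
                members[0].status.value,
            )
        )
    return out


def brute_coverage(calls, chrom_lengths: dict[str, int]) -> float:
    """Genome coverage by per-base bitmap (genomes must be small)."""
    covered = 0
    for chrom, length in chrom_lengths.items():
        mask = np.zeros(length, dtype=bool)
        for c in calls:
            if c.chrom == chrom:
                mask[c.start : c.end] = True
        covered += int(mask.sum())
    return covered / sum(chrom_lengths.values())


def brute_shared(a_calls, b_calls, threshold: float):
    """Subset of a matched in b, by an O(|a||b|) all-pairs scan."""
    return [x for x in a_calls if any(brute_match(x, y, threshold) for y in b_calls)]


def brute_components(calls_with_source, threshold: float) -> list[frozenset]:
    """Connected components over (source, call) pairs via networkx."""
    g = nx.Graph()
    g.add_nodes_from(range(len(calls_with_source)))
    for i, (_, a) in enumerate(calls_with_source):
        for j, (_, b) in enumerate(calls_with_source):
            if j <= i:
                continue
            if brute_match(a, b, threshold):
                g.add_edge(i, j)
    return [frozenset(c) for c in nx.connected_components(g)]


def brute_weighted_f1(true_labels, predicted_labels) -> float:
    """Support-weighted F1 from the explicit confusion matrix."""
    classes = sorted(set(true_labels) | set(predicted_labels), key=str)
    idx = {c: i for i, c in enumerate(classes)}
    cm = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(true_labels, predicted_labels):
        cm[idx[t], idx[p]] += 1
    n = cm.sum()
    score = 0.0
    for i in range(len(classes)):
        tp = cm[i, i]
        support = cm[i, :].sum()
        predicted = cm[:, i].sum()
        p = tp / predicted if predicted else 0.0
        r = tp / support if support else 0.0
        f1 = 2 * p * r / (p + r) if (p + r) else 0.0
        score += support / n * f1
    return score


def random_calls(rng, n, chrom_lengths, statuses, CNVCall, max_size=2_000):
    """Small random call fixture on a tiny genome."""
    chroms = list(chrom_lengths)
    out = []
    for _ in range(n):
        chrom = chroms[rng.integers(0, len(chroms))]
        length = chrom_lengths[chrom]
        size = int(rng.integers(50, max_size))
        size = min(size, length - 1)
        start = int(rng.integers(0, length - size))
        out.append(
            CNVCall(
                chrom=chrom,
                start=start,
                end=start + size,
                status=statuses[rng.integers(0, len(statuses))],
            )
        )
    return out
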