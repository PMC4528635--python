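"""Intra-tool duplicate collapse and inter-tool method-aware clustering.

Two calls of the same type are the *same event* when their reciprocal
overlap reaches a threshold or both breakpoints agree within a wiggle;
insertions (point loci) compare by locus distance only.  Clustering is
single-linkage (transitive closure of the pairwise relation), and the
consensus breakpoints of a cluster come from the most precise detection
method present, so one precise split-read call outvotes several fuzzy
read-pair calls.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .model import METHOD_PRIORITY_DEFAULT, GenomeInterval, SVCall, SVCluster, sorted_calls


@dataclass(frozen=True)
class MergeParams:
    """Clustering thresholds.

    ``reciprocal_overlap_min`` is deliberately looser (0.5) than the 0.9
    used for truth-matching in benchmarks: merging has to tolerate
    method-specific breakpoint imprecision (read-pair, depth) while
    evaluation stays strict.
    """

    reciprocal_overlap_min: float = 0.5
    wiggle: int = 100
    method_priority: tuple[str, ...] = METHOD_PRIORITY_DEFAULT

    def __post_init__(self) -> None:
        if not (0.0 <= self.reciprocal_overlap_min <= 1.0):
            raise ValueError("reciprocal_overlap_min must be in [0, 1]")
        if self.wiggle < 0:
            raise ValueError("wiggle must be >= 0")
        if len(set(self.method_priority)) != len(self.method_priority):
            raise ValueError("method_priority must not repeat methods")

    def method_rank(self, method: str) -> int:
        try:
            return self.method_priority.index(method)
        except ValueError:
            return len(self.method_priority)  # unknown methods rank last


def reciprocal_overlap(a: GenomeInterval, b: GenomeInterval) -> float:
    """min(|a∩b|/|a|, |a∩b|/|b|); 1.0 for co-located zero-length pairs."""
    if a.chrom != b.chrom:
        raise ValueError(f"different chromosomes: {a.chrom} vs {b.chrom}")
    if a.length() == 0 and b.length() == 0:
        return 1.0 if a.start == b.start else 0.0
    if a.length() == 0 or b.length() == 0:
        return 0.0
    ov = max(0, min(a.end, b.end) - max(a.start, b.start))
    return min(ov / a.length(), ov / b.length())


def same_event(a: SVCall, b: SVCall, p: MergeParams) -> bool:
    if a.sv_type != b.sv_type or a.chrom != b.chrom:
        return False
    if a.sv_type == "INS":
        return abs(a.start - b.start) <= p.wiggle
    if (abs(a.start - b.start) <= p.wiggle
            and abs(a.end - b.end) <= p.wiggle):
        return True
    return reciprocal_overlap(a.interval, b.interval) >= p.reciprocal_overlap_min


def _components(calls: Sequence[SVCall], p: MergeParams) -> list[list[int]]:
    """Single-linkage connected components via union-find.

    Calls are pre-sorted by position, so linkage checks can stop once the
    next call starts beyond any possible overlap/wiggle reach.
    """
    n = len(calls)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: int, y: int) -> None:
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[max(rx, ry)] = min(rx, ry)

    for i in range(n):
        a = calls[i]
        reach = a.end + p.wiggle  # no linkage is possible past this point
        for j in range(i + 1, n):
            b = calls[j]
            if b.chrom != a.chrom or b.start > reach:
                break
            if same_event(a, b, p):
                union(i, j)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    return [groups[r] for r in sorted(groups)]


def _weighted_median(values_weights: list[tuple[int, int]]) -> int:
    """Support-weighted median; ties resolve to the lower coordinate."""
    pairs = sorted(values_weights)
    total = sum(w for _, w in pairs)
    acc = 0
    for v, w in pairs:
        acc += w
        if 2 * acc >= total:
            return v
    return pairs[-1][0]


def merge_intra_tool(calls: Sequence[SVCall], p: MergeParams) -> list[SVCall]:
    """Collapse duplicate calls from one tool.

    Each single-linkage component collapses to one call at the
    support-weighted median breakpoints; support is summed over members.
    Collapsing can move representatives into linkage range of each other,
    so the collapse is iterated to a fixpoint (guaranteeing idempotence).
    """
    calls = sorted_calls(calls)
    while True:
        merged = _collapse_once(calls, p)
        if len(merged) == len(calls):
            return merged
        calls = merged


def _collapse_once(calls: list[SVCall], p: MergeParams) -> list[SVCall]:
    out: list[SVCall] = []
    for comp in _components(calls, p):
        members = [calls[i] for i in comp]
        if len(members) == 1:
            out.append(members[0])
            continue
        start = _weighted_median([(m.start, m.support) for m in members])
        if members[0].sv_type == "INS":
            interval = GenomeInterval(members[0].chrom, start, start + 1)
            known = [m.sv_length for m in members if m.sv_length is not None]
            length = _weighted_median(
                [(m.sv_length, m.support) for m in members
                 if m.sv_length is not None]) if known else None
        else:
            end = _weighted_median([(m.end, m.support) for m in members])
            end = max(end, start + 1)
            interval = GenomeInterval(members[0].chrom, start, end)
            length = interval.length()
        out.append(SVCall(
            interval=interval,
            sv_type=members[0].sv_type,
            sv_length=length,
            tool=members[0].tool,
            method=members[0].method,
            support=sum(m.support for m in members),
        ))
    return sorted_calls(out)


def cluster_inter_tool(per_tool: Mapping[str, Sequence[SVCall]],
                       p: MergeParams) -> list[SVCluster]:
    """Pool intra-merged per-tool callsets and cluster across tools.

    Returns clusters with consensus breakpoints already selected; a
    cluster is high-confidence iff >= 2 distinct tools contributed.
    """
    pooled: list[SVCall] = []
    for tool in sorted(per_tool):
        pooled.extend(per_tool[tool])
    pooled = sorted_calls(pooled)
    clusters: list[SVCluster] = []
    for comp in _components(pooled, p):
        members = [pooled[i] for i in comp]
        cluster = SVCluster(members=members, sv_type=members[0].sv_type)
        cluster.consensus = select_breakpoints(cluster, p)
        if cluster.sv_type == "INS":
            lengths = [(m.sv_length, m.support) for m in members
                       if m.sv_length is not None]
            cluster.sv_length = _weighted_median(lengths) if lengths else None
        else:
            cluster.sv_length = cluster.consensus.length()
        clusters.append(cluster)
    clusters.sort(key=SVCluster.sort_key)
    return clusters


def select_breakpoints(cluster: SVCluster, p: MergeParams) -> GenomeInterval:
    """Consensus interval from the most precise method tier present.

    Among members whose method ranks highest in ``p.method_priority``,
    take the coordinate-wise (support-weighted) median; ties resolve to
    the lower coordinate.
    """
    best_rank = min(p.method_rank(m.method) for m in cluster.members)
    tier = [m for m in cluster.members if p.method_rank(m.method) == best_rank]
    start = _weighted_median([(m.start, m.support) for m in tier])
    if cluster.sv_type == "INS":
        return GenomeInterval(cluster.chrom, start, start + 1)
    end = _weighted_median([(m.end, m.support) for m in tier])
    return GenomeInterval(cluster.chrom, start, max(end, start + 1))
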