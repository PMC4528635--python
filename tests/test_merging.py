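"""Merging: reciprocal overlap, event identity, clustering, consensus."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from svmeld.merging import (MergeParams, cluster_inter_tool, merge_intra_tool,
                            reciprocal_overlap, same_event,
                            select_breakpoints)
from svmeld.model import GenomeInterval, SVCall, SVCluster

P = MergeParams()


def dele(start, end, tool="t", method="split_read", support=1):
    return SVCall(interval=GenomeInterval("chr1", start, end), sv_type="DEL",
                  sv_length=end - start, tool=tool, method=method,
                  support=support)


def ins(pos, tool="t", method="split_read"):
    return SVCall(interval=GenomeInterval("chr1", pos, pos + 1),
                  sv_type="INS", sv_length=None, tool=tool, method=method)


@pytest.mark.parametrize("a,b,expected", [
    ((100, 200), (100, 200), 1.0),
    ((100, 200), (300, 400), 0.0),
    ((100, 200), (150, 350), 0.25),  # min(50/100, 50/200)
    ((100, 100), (100, 100), 1.0),   # co-located zero-length
    ((100, 100), (120, 120), 0.0),
])
def test_reciprocal_overlap(a, b, expected):
    assert reciprocal_overlap(GenomeInterval("chr1", *a),
                              GenomeInterval("chr1", *b)) == expected


def test_reciprocal_overlap_requires_same_chrom():
    with pytest.raises(ValueError):
        reciprocal_overlap(GenomeInterval("chr1", 0, 10),
                           GenomeInterval("chr2", 0, 10))


def test_same_event_rules():
    assert same_event(dele(1000, 2000), dele(1000, 2000), P)
    # both breakpoint deltas within wiggle
    assert same_event(dele(1000, 2000), dele(1050, 2080), P)
    # type mismatch never merges
    assert not same_event(dele(1000, 2000), ins(1500), P)
    # insertions compare by locus distance only
    assert same_event(ins(1500), ins(1590), P)
    assert not same_event(ins(1500), ins(1601), P)
    # reciprocal-overlap clause alone can link big intervals
    assert same_event(dele(0, 10000), dele(150, 10300), P)


def test_merge_intra_tool_examples():
    one = [dele(100, 600)]
    assert merge_intra_tool(one, P) == one

    two = merge_intra_tool([dele(100, 600), dele(100, 600)], P)
    assert len(two) == 1 and two[0].support == 2

    # transitive closure: A-B and B-C linked, A-C not directly
    a, b, c = dele(100, 200), dele(180, 290), dele(270, 380)
    assert same_event(a, b, P) and same_event(b, c, P)
    merged = merge_intra_tool([a, b, c], P)
    assert len(merged) == 1
    assert merged[0].support == 3


def test_merge_intra_tool_idempotent_on_random_sets():
    rng = random.Random(0)
    for _ in range(20):
        calls = [dele(s, s + rng.randint(50, 400))
                 for s in (rng.randint(0, 5000) for _ in range(12))]
        once = merge_intra_tool(calls, P)
        twice = merge_intra_tool(once, P)
        assert [c.interval for c in once] == [c.interval for c in twice]
        assert sum(c.support for c in once) == len(calls)


def test_cluster_inter_tool_confidence():
    single = cluster_inter_tool({"a": [dele(100, 600, "a")]}, P)
    assert len(single) == 1 and single[0].confidence == "low"

    same = {t: [dele(100, 600, t)] for t in ("a", "b", "c")}
    clusters = cluster_inter_tool(same, P)
    assert len(clusters) == 1
    assert clusters[0].tools == {"a", "b", "c"}
    assert clusters[0].confidence == "high"


def test_select_breakpoints_method_priority():
    cluster = SVCluster(members=[
        dele(1000, 2000, "p", "split_read"),
        dele(960, 2040, "b", "read_pair"),
    ], sv_type="DEL")
    assert select_breakpoints(cluster, P) == GenomeInterval("chr1", 1000, 2000)

    # singleton keeps its own interval
    solo = SVCluster(members=[dele(5, 50, "b", "read_pair")], sv_type="DEL")
    assert select_breakpoints(solo, P) == GenomeInterval("chr1", 5, 50)

    # coordinate-wise median within the winning tier, ties to lower
    tri = SVCluster(members=[
        dele(1000, 2000, "a"), dele(1004, 1996, "b"), dele(1010, 2008, "c"),
    ], sv_type="DEL")
    assert select_breakpoints(tri, P) == GenomeInterval("chr1", 1004, 2000)


def test_unknown_method_ranks_last():
    cluster = SVCluster(members=[
        dele(900, 2100, "x", "mystery_method"),
        dele(1000, 2000, "p", "read_pair"),
    ], sv_type="DEL")
    assert select_breakpoints(cluster, P) == GenomeInterval("chr1", 1000, 2000)


# ---------------------------------------------------------------------------
# property suite: idempotence, permutation invariance, oracle equivalence

interval_st = st.tuples(st.integers(0, 3000), st.integers(50, 500)).map(
    lambda t: (t[0], t[0] + t[1]))


def brute_force_components(calls, p):
    """Transitive closure over the pairwise same_event matrix."""
    n = len(calls)
    adj = {i: {i} for i in range(n)}
    for i in range(n):
        for j in range(i + 1, n):
            if same_event(calls[i], calls[j], p):
                adj[i].add(j)
                adj[j].add(i)
    seen, comps = set(), []
    for i in range(n):
        if i in seen:
            continue
        stack, comp = [i], set()
        while stack:
            x = stack.pop()
            if x in comp:
                continue
            comp.add(x)
            stack.extend(adj[x] - comp)
        seen |= comp
        comps.append(frozenset(calls[k].interval for k in comp))
    return set(comps)


@settings(max_examples=150, deadline=None, derandomize=True)
@given(st.lists(interval_st, min_size=1, max_size=30), st.randoms())
def test_clustering_matches_brute_force_and_is_permutation_invariant(
        intervals, rnd):
    calls = [dele(s, e, tool=f"t{i % 3}") for i, (s, e) in
             enumerate(intervals)]
    per_tool = {}
    for c in calls:
        per_tool.setdefault(c.tool, []).append(c)
    clusters = cluster_inter_tool(per_tool, P)
    got = {frozenset(m.interval for m in c.members) for c in clusters}
    assert got == brute_force_components(calls, P)

    # permutation invariance of the cluster set
    shuffled = list(calls)
    rnd.shuffle(shuffled)
    per_tool2 = {}
    for c in shuffled:
        per_tool2.setdefault(c.tool, []).append(c)
    clusters2 = cluster_inter_tool(per_tool2, P)
    assert ([c.consensus for c in clusters]
            == [c.consensus for c in clusters2])
    assert ({frozenset(m.interval for m in c.members) for c in clusters2}
            == got)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.lists(interval_st, min_size=1, max_size=25))
def test_intra_merge_idempotent_and_conservative(intervals):
    calls = [dele(s, e) for s, e in intervals]
    once = merge_intra_tool(calls, P)
    assert len(once) <= len(calls)
    assert sum(c.support for c in once) == len(calls)  # provenance kept
    twice = merge_intra_tool(once, P)
    assert [(c.interval, c.support) for c in once] == \
           [(c.interval, c.support) for c in twice]
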