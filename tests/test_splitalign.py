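"""Split-alignment DP: oracle equivalence, breakpoint recovery, refinement."""

import random

import numpy as np
import pytest

from svmeld.model import GenomeInterval, SVCall, SVCluster
from svmeld.splitalign import (ScoringScheme, confirm_insertion,
                               refine_cluster, split_align)

S = ScoringScheme()


def rand_seq(rng, n):
    return "".join(rng.choice("ACGT") for _ in range(n))


def plain_sw(q, r, s=S):
    """Reference affine Smith-Waterman, straightforward triple-state DP."""
    NEG = -(10 ** 9)
    H = [[0] * (len(r) + 1) for _ in range(len(q) + 1)]
    E = [[NEG] * (len(r) + 1) for _ in range(len(q) + 1)]
    F = [[NEG] * (len(r) + 1) for _ in range(len(q) + 1)]
    for i in range(1, len(q) + 1):
        for j in range(1, len(r) + 1):
            E[i][j] = max(H[i][j - 1] + s.gap_open + s.gap_extend,
                          E[i][j - 1] + s.gap_extend)
            F[i][j] = max(H[i - 1][j] + s.gap_open + s.gap_extend,
                          F[i - 1][j] + s.gap_extend)
            diag = H[i - 1][j - 1] + (s.match if q[i - 1] == r[j - 1]
                                      else s.mismatch)
            H[i][j] = max(0, diag, E[i][j], F[i][j])
    return H


def oracle_best_split(ctg, ref, s=S):
    """Exhaustive max over all anchor quadruples i<=i', j<=j'."""
    n, m = len(ctg), len(ref)
    Hf = np.array(plain_sw(ctg, ref, s))
    Hr = np.array(plain_sw(ctg[::-1], ref[::-1], s))
    R = Hr[::-1, ::-1]
    G = np.maximum.accumulate(np.maximum.accumulate(Hf, axis=0), axis=1)
    return int((G + R).max())


def test_identity_alignment():
    rng = random.Random(0)
    seq = rand_seq(rng, 80)
    sa = split_align(seq, seq)
    assert sa.score == 80 * S.match
    assert sa.implied is None


def test_clean_deletion_breakpoints():
    rng = random.Random(1)
    A, B, C = rand_seq(rng, 300), rand_seq(rng, 200), rand_seq(rng, 300)
    ref = A + B + C
    sa = split_align(A + C, ref)
    assert sa.implied == "DEL"
    assert sa.implied_length == 200
    # exact up to leftmost-equivalent shifts through junction homology
    shift = 300 - sa.ref_left_end
    assert 0 <= shift <= 5
    assert ref[sa.ref_left_end:300] == ref[sa.ref_right_start:500]
    assert sa.ctg_right_start - sa.ctg_left_end < 25


def test_clean_insertion_breakpoints():
    rng = random.Random(2)
    A, C, X = rand_seq(rng, 300), rand_seq(rng, 300), rand_seq(rng, 150)
    sa = split_align(A + X + C, A + C)
    assert sa.implied == "INS"
    assert sa.implied_length == 150
    assert (sa.ctg_left_end, sa.ctg_right_start) == (300, 450)
    assert sa.ref_left_end == 300


def test_oracle_equivalence_random_instances():
    """The O(nm) row-maxima formulation equals exhaustive split-point
    enumeration on 1000 random instances up to 60 bp."""
    rng = random.Random(42)
    for _ in range(1000):
        n, m = rng.randint(1, 60), rng.randint(1, 60)
        ctg, ref = rand_seq(rng, n), rand_seq(rng, m)
        assert split_align(ctg, ref, min_sv_size=5).score == \
            oracle_best_split(ctg, ref)


def test_score_monotone_under_matching_extension():
    rng = random.Random(3)
    ctg, ref = rand_seq(rng, 40), rand_seq(rng, 50)
    base = split_align(ctg, ref).score
    ext = rand_seq(rng, 25)
    assert split_align(ctg + ext, ref + ext).score >= base


def test_breakpoints_left_aligned_in_repeats():
    """An excision inside a tandem repeat resolves to the leftmost
    equivalent position."""
    rng = random.Random(4)
    A, C = rand_seq(rng, 120), rand_seq(rng, 120)
    unit = rand_seq(rng, 40)
    # ref has three repeat units, contig has one: 80 bp deletion,
    # placeable at any unit boundary; leftmost wins
    sa = split_align(A + unit + C, A + unit * 3 + C, min_sv_size=25)
    assert sa.implied == "DEL"
    assert sa.implied_length == 80
    assert sa.ref_left_end == 120  # start of the first repeat copy


def test_exact_recovery_over_random_deletions():
    """Error-free contigs recover simulated deletion breakpoints to the
    base pair (up to junction-repeat ambiguity, resolved leftmost)."""
    rng = random.Random(5)
    for trial in range(100):
        flank = rng.randint(80, 250)
        del_len = rng.randint(100, 5000)
        ref = rand_seq(rng, flank * 2 + del_len)
        contig = ref[:flank] + ref[flank + del_len:]
        sa = split_align(contig, ref)
        assert sa.implied == "DEL"
        assert sa.implied_length == del_len
        # leftmost-equivalent shift bounded by any homology at the junction
        shift = flank - sa.ref_left_end
        assert 0 <= shift <= 25
        if shift:
            assert ref[sa.ref_left_end:flank] == \
                ref[sa.ref_right_start:sa.ref_right_start + shift]


def test_refine_cluster_updates_del_breakpoints():
    rng = random.Random(6)
    ref = rand_seq(rng, 3000)
    true_start, true_end = 1200, 1800
    contig = ref[900:true_start] + ref[true_end:2100]

    def fetch(chrom, start, end):
        return ref[start:end]

    call = SVCall(interval=GenomeInterval("c", 1150, 1850), sv_type="DEL",
                  sv_length=700, tool="t", method="read_pair")
    cluster = SVCluster(members=[call], sv_type="DEL",
                        consensus=call.interval, sv_length=700)
    from svmeld.assembly import Contig
    refined = refine_cluster(cluster, [Contig(contig, None, 10)], fetch,
                             chrom_length=3000)
    assert refined.assembly_confirmed
    assert refined.consensus == GenomeInterval("c", true_start, true_end)
    assert refined.sv_length == 600
    assert "softclip_assembly" in refined.methods
    assert refined.confidence == "high"


def test_refine_cluster_rejects_type_mismatch_and_empty():
    rng = random.Random(7)
    ref = rand_seq(rng, 2000)

    def fetch(chrom, start, end):
        return ref[start:end]

    call = SVCall(interval=GenomeInterval("c", 800, 1200), sv_type="DEL",
                  sv_length=400, tool="t", method="read_pair")
    cluster = SVCluster(members=[call], sv_type="DEL",
                        consensus=call.interval, sv_length=400)
    # no contigs: unchanged, unconfirmed
    out = refine_cluster(cluster, [], fetch, chrom_length=2000)
    assert not out.assembly_confirmed
    assert out.consensus == call.interval

    # contig implying INS must not confirm a DEL cluster
    from svmeld.assembly import Contig
    ins_contig = ref[600:1000] + rand_seq(rng, 300) + ref[1000:1400]
    out = refine_cluster(cluster, [Contig(ins_contig, None, 10)], fetch,
                         chrom_length=2000)
    assert not out.assembly_confirmed
    assert out.consensus == call.interval


def test_confirm_insertion_two_anchor_and_novelty():
    rng = random.Random(8)
    ref = rand_seq(rng, 6000)
    pos = 3000
    X = rand_seq(rng, 400)

    def fetch(chrom, start, end):
        return ref[start:end]

    from svmeld.assembly import Contig
    spanning = ref[2600:pos] + X + ref[pos:3400]
    hit = confirm_insertion(pos, "c", [Contig(spanning, None, 10)], fetch,
                            chrom_length=6000)
    assert hit is not None
    assert hit[0] == pos
    assert hit[1] == 400

    # one-sided contig of a long insertion: position found, length unknown
    one_sided = ref[2600:pos] + X
    hit = confirm_insertion(pos, "c", [Contig(one_sided, None, 10)], fetch,
                            chrom_length=6000)
    assert hit == (pos, None)

    # a tandem-duplication junction contig must NOT confirm an insertion:
    # its "overhang" realigns upstream within the neighborhood
    dup_junction = ref[2700:pos] + ref[2500:2900]
    hit = confirm_insertion(pos, "c", [Contig(dup_junction, None, 10)],
                            fetch, chrom_length=6000)
    assert hit is None


def test_window_size_guard():
    with pytest.raises(ValueError, match="too large|nonempty"):
        split_align("A" * 30000, "C" * 30000)
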