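"""Synthetic-data generator: genome construction, read alignments,
mock callsets, benchmarking arithmetic."""

import math

import numpy as np
import pysam
import pytest

from svmeld.bench import benchmark
from svmeld.model import GenomeInterval, SVCall
from svmeld.simdata import (SimConfig, ToolProfile, default_tool_profiles,
                            mock_callsets, simulate_genome, simulate_reads)


def small_cfg(**kw):
    base = dict(genome_length=100_000, n_chroms=1, n_del=2, n_ins=2,
                n_inv=1, n_dup=1, coverage=20, seed=3,
                size_range={"DEL": (200, 800), "INS": (200, 800),
                            "INV": (200, 800), "DUP": (200, 800)})
    base.update(kw)
    return SimConfig(**base)


def test_haplotype_length_identity():
    cfg = small_cfg(n_del=3, n_ins=3, n_inv=2, n_dup=2, seed=5)
    genome = simulate_genome(cfg)
    # expected length change per haplotype: +INS +DUP sizes, -DEL sizes
    for (chrom, hap_idx), hap in genome.haplotypes.items():
        delta = sum(
            (t.sv_length if t.sv_type in ("INS", "DUP") else
             -t.sv_length if t.sv_type == "DEL" else 0)
            for t in genome.truth
            if t.chrom == chrom and _applies(genome, t, hap_idx))
        assert len(hap.seq) == len(genome.reference[chrom]) + delta


def _applies(genome, truth_call, hap_idx):
    """Reconstruct hap application from the block structure."""
    if truth_call.genotype == "hom_alt":
        return True
    # het: check whether this haplotype's blocks skip/insert at the locus
    hap = genome.haplotypes[(truth_call.chrom, hap_idx)]
    if truth_call.sv_type == "DEL":
        return not any(b.ref_start is not None
                       and b.ref_start <= truth_call.start < b.ref_end
                       and b.strand == "+"
                       for b in hap.blocks)
    if truth_call.sv_type == "INS":
        return any(b.ref_start is None and _novel_at(hap, b, truth_call)
                   for b in hap.blocks)
    if truth_call.sv_type == "INV":
        return any(b.strand == "-" and b.ref_start == truth_call.start
                   for b in hap.blocks)
    if truth_call.sv_type == "DUP":
        starts = [b for b in hap.blocks if b.ref_start == truth_call.start
                  and b.ref_end == truth_call.end]
        return len(starts) >= 1
    return False


def _novel_at(hap, block, truth_call):
    prev = [b for b in hap.blocks if b.hap_end == block.hap_start
            and b.ref_start is not None]
    return bool(prev) and prev[0].ref_end == truth_call.start


def test_no_svs_means_identical_haplotypes():
    cfg = small_cfg(n_del=0, n_ins=0, n_inv=0, n_dup=0)
    genome = simulate_genome(cfg)
    for (chrom, _), hap in genome.haplotypes.items():
        assert hap.seq == genome.reference[chrom]


def test_determinism_from_seed(tmp_path):
    cfg = small_cfg(coverage=5)
    g1 = simulate_genome(cfg)
    g2 = simulate_genome(cfg)
    assert g1.reference == g2.reference
    assert [c.interval for c in g1.truth] == [c.interval for c in g2.truth]
    p1 = g1.write_reference(str(tmp_path / "r1.fa"))
    p2 = g2.write_reference(str(tmp_path / "r2.fa"))
    assert open(p1).read() == open(p2).read()
    b1 = simulate_reads(g1, str(tmp_path / "a.bam"))
    b2 = simulate_reads(g2, str(tmp_path / "b.bam"))
    with pysam.AlignmentFile(b1) as f1, pysam.AlignmentFile(b2) as f2:
        r1 = [(r.query_name, r.flag, r.reference_start, r.cigarstring,
               r.query_sequence) for r in f1]
        r2 = [(r.query_name, r.flag, r.reference_start, r.cigarstring,
               r.query_sequence) for r in f2]
    assert r1 == r2


def test_reads_without_svs_align_full_length(tmp_path):
    cfg = small_cfg(n_del=0, n_ins=0, n_inv=0, n_dup=0, error_rate=0.0,
                    coverage=5)
    genome = simulate_genome(cfg)
    bam_path = simulate_reads(genome, str(tmp_path / "clean.bam"))
    ref = genome.reference["chr1"]
    n = 0
    with pysam.AlignmentFile(bam_path) as bam:
        for read in bam:
            n += 1
            assert read.cigarstring == "100M"
            assert read.query_sequence == \
                ref[read.reference_start:read.reference_start + 100]
    expected_pairs = round(len(ref) * (cfg.coverage / 2) / 200) * 2
    assert n == 2 * expected_pairs


def test_read_count_tracks_coverage(tmp_path):
    cfg = small_cfg(coverage=20, genome_length=100_000)
    genome = simulate_genome(cfg)
    bam_path = simulate_reads(genome, str(tmp_path / "cov.bam"))
    with pysam.AlignmentFile(bam_path) as bam:
        n = bam.count(until_eof=True)
    expected = cfg.genome_length * cfg.coverage / cfg.read_length
    assert abs(n - expected) / expected < 0.05


def test_reads_crossing_hom_deletion_carry_junction_signal(tmp_path):
    cfg = SimConfig(genome_length=50_000, n_chroms=1, n_del=1, n_ins=0,
                    n_inv=0, n_dup=0, het_fraction=0.0, error_rate=0.0,
                    coverage=30, seed=13,
                    size_range={"DEL": (500, 500), "INS": (100, 200),
                                "INV": (100, 200), "DUP": (100, 200)})
    genome = simulate_genome(cfg)
    (truth,) = genome.truth
    bam_path = simulate_reads(genome, str(tmp_path / "del.bam"))
    signal = 0
    with pysam.AlignmentFile(bam_path) as bam:
        for read in bam.fetch("chr1", truth.start - 80, truth.start + 80):
            if read.cigartuples and any(op in (2, 4) for op, _ in
                                        read.cigartuples):
                signal += 1
            # depth inside a hom deletion must be zero
        inside = np.asarray(bam.count_coverage(
            "chr1", truth.start + 50, truth.end - 50)).sum()
    assert signal >= 5
    assert inside == 0


def test_mock_callsets_perfect_profile_equals_truth():
    genome = simulate_genome(small_cfg())
    perfect = ToolProfile(tool="perfect", method="split_read",
                          detects=("DEL", "INS", "INV", "DUP"),
                          sensitivity={t: ((10 ** 9, 1.0),) for t in
                                       ("DEL", "INS", "INV", "DUP")},
                          fdr=0.0, jitter_sd=0.0)
    calls = mock_callsets(genome.truth, [perfect], genome.chrom_lengths,
                          seed=1)["perfect"]
    assert [(c.interval, c.sv_type) for c in calls] == \
        [(t.interval, t.sv_type) for t in genome.truth]

    blind = ToolProfile(tool="blind", method="split_read", detects=(),
                        sensitivity={}, fdr=0.0, jitter_sd=0.0)
    assert mock_callsets(genome.truth, [blind], genome.chrom_lengths,
                         seed=1)["blind"] == []


def test_mock_callsets_jitter_magnitude():
    """Breakpoint jitter matches the configured half-normal scale:
    E|err| = sd * sqrt(2/pi)."""
    truth = [SVCall(interval=GenomeInterval("chr1", s, s + 1000),
                    sv_type="DEL", sv_length=1000, tool="x", method="truth")
             for s in range(10_000, 1_010_000, 2000)]
    prof = ToolProfile(tool="j", method="read_pair", detects=("DEL",),
                       sensitivity={"DEL": ((10 ** 9, 1.0),)},
                       fdr=0.0, jitter_sd=150.0)
    calls = mock_callsets(truth, [prof], {"chr1": 2_000_000}, seed=2)["j"]
    errs = [abs(c.start - t.start) for c, t in zip(calls, truth)]
    assert len(errs) >= 500
    expected = 150.0 * math.sqrt(2 / math.pi)  # ~120
    assert abs(np.mean(errs) - expected) / expected < 0.1


def test_benchmark_arithmetic():
    def mk(s, e, tool="x", gt="unknown"):
        return SVCall(interval=GenomeInterval("chr1", s, e), sv_type="DEL",
                      sv_length=e - s, tool=tool, method="split_read",
                      genotype=gt)

    truth = [mk(i * 10_000, i * 10_000 + 500, "truth") for i in range(10)]
    # 8 perfect matches + 1 false call
    calls = [mk(i * 10_000, i * 10_000 + 500) for i in range(8)]
    calls.append(mk(500_000, 500_500))
    m = benchmark(calls, truth).per_type["DEL"]
    assert m.sensitivity == pytest.approx(0.8)
    assert m.precision == pytest.approx(8 / 9)
    assert m.f1 == pytest.approx(2 * 0.8 * (8 / 9) / (0.8 + 8 / 9))

    # identity: all metrics 1.0
    m = benchmark(truth, truth).per_type["DEL"]
    assert (m.sensitivity, m.precision, m.f1) == (1.0, 1.0, 1.0)

    # empty callset: degenerate convention, all zeros
    m = benchmark([], truth).per_type["DEL"]
    assert (m.sensitivity, m.precision, m.f1) == (0.0, 0.0, 0.0)


def test_benchmark_strictness_and_one_to_one():
    def mk(s, e):
        return SVCall(interval=GenomeInterval("chr1", s, e), sv_type="DEL",
                      sv_length=e - s, tool="x", method="split_read")

    truth = [mk(10_000, 11_000)]
    # breakpoints within wiggle but reciprocal overlap below 0.9
    assert benchmark([mk(10_095, 10_905)], truth,
                     ro_min=0.9, wiggle=100).per_type["DEL"].n_matched == 0
    # good overlap and wiggle
    assert benchmark([mk(10_050, 11_040)], truth,
                     ro_min=0.9, wiggle=100).per_type["DEL"].n_matched == 1
    # two duplicate calls: only one may match (one-to-one)
    m = benchmark([mk(10_000, 11_000), mk(10_010, 11_010)], truth)
    assert m.per_type["DEL"].n_matched == 1
    assert m.per_type["DEL"].precision == 0.5
    # events below the size cutoff are excluded on both sides
    small = [mk(5000, 5080)]
    m = benchmark(small, small, min_size=100)
    assert "DEL" not in m.per_type or m.per_type["DEL"].n_truth == 0
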