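"""Greedy OLC assembler, read gathering, external-assembler adapter."""

import os
import random

import pytest

from svmeld.assembly import (AssemblyParams, assemble_greedy, gather_reads,
                             read_fasta_contigs, revcomp,
                             run_external_assembler)
from svmeld.model import GenomeInterval

P = AssemblyParams(min_read_count=2)


def rand_seq(rng, n):
    return "".join(rng.choice("ACGT") for _ in range(n))


def tile(source, read_len, step):
    reads = [source[i:i + read_len]
             for i in range(0, len(source) - read_len + 1, step)]
    if (len(source) - read_len) % step:
        reads.append(source[-read_len:])
    return reads


def test_single_read_repeated():
    contigs = assemble_greedy(["ACGT" * 20] * 5, AssemblyParams())
    assert len(contigs) == 1
    assert contigs[0].seq == "ACGT" * 20
    assert contigs[0].n_reads == 5


def test_no_overlap_yields_no_contig():
    rng = random.Random(0)
    a, b = rand_seq(rng, 80), rand_seq(rng, 80)
    assert assemble_greedy([a, b], AssemblyParams(min_read_count=2)) == []


def test_reconstructs_tiled_source():
    rng = random.Random(1)
    source = rand_seq(rng, 400)
    contigs = assemble_greedy(tile(source, 100, 50), P)
    assert contigs and contigs[0].seq == source


@pytest.mark.parametrize("seed", range(50))
def test_reconstruction_property_over_seeds(seed):
    """Error-free reads tiling a random 300-800 bp source at >= 50%
    overlap reassemble it exactly."""
    rng = random.Random(seed)
    source = rand_seq(rng, rng.randint(300, 800))
    step = rng.randint(20, 50)
    contigs = assemble_greedy(tile(source, 100, step), P)
    assert contigs and contigs[0].seq == source


def test_determinism_under_input_order():
    rng = random.Random(2)
    source = rand_seq(rng, 500)
    reads = tile(source, 100, 30)
    expected = [(c.seq, c.n_reads) for c in assemble_greedy(reads, P)]
    for _ in range(5):
        rng.shuffle(reads)
        got = [(c.seq, c.n_reads) for c in assemble_greedy(reads, P)]
        assert got == expected


def test_mixed_strand_reads_assemble():
    rng = random.Random(3)
    source = rand_seq(rng, 400)
    reads = tile(source, 100, 40)
    reads = [revcomp(r) if i % 2 else r for i, r in enumerate(reads)]
    contigs = assemble_greedy(reads, P)
    assert contigs
    assert contigs[0].seq in (source, revcomp(source))


def test_external_adapter_contract(tmp_path):
    rng = random.Random(4)
    source = rand_seq(rng, 300)
    reads = tile(source, 100, 50)
    fasta = tmp_path / "pre.fa"
    fasta.write_text(">ctg1\n" + source[:250] + "\n")

    # adapter echoing a precomputed FASTA: contigs parsed from it
    adapter = f"cp {fasta} {{out}}"
    contigs = run_external_assembler(reads, str(tmp_path / "w1"), adapter, P)
    assert [c.seq for c in contigs] == [source[:250]]

    # failing adapter: greedy fallback result
    contigs = run_external_assembler(reads, str(tmp_path / "w2"), "exit 1", P)
    assert contigs and contigs[0].seq == source


def test_gather_reads_recruits_far_mates(tmp_path):
    import pysam

    rng = random.Random(5)
    seq = rand_seq(rng, 100)
    rows = []
    # 3 pairs fully inside the window
    for i in range(3):
        rows.append((f"p{i}", 0x1 | 0x40, "chrZ", 5000 + i * 10, 60,
                     "100M", seq))
        rows.append((f"p{i}", 0x1 | 0x80 | 0x10, "chrZ", 5200 + i * 10, 60,
                     "100M", seq))
    # one pair with the mate 2 kb away: mate must be recruited
    rows.append(("far", 0x1 | 0x40, "chrZ", 5050, 60, "100M", seq))
    rows.append(("far", 0x1 | 0x80 | 0x10, "chrZ", 7300, 60, "100M",
                 rand_seq(rng, 100)))
    mate_pos = {}
    for q, f, c, p, m, cg, s in rows:
        mate_pos.setdefault(q, []).append(p)
    header = {"HD": {"VN": "1.6"},
              "SQ": [{"SN": "chrZ", "LN": 100_000}]}
    path2 = str(tmp_path / "t2.bam")
    with pysam.AlignmentFile(path2 + ".un", "wb", header=header) as out:
        for q, f, c, p, m, cg, s in rows:
            a = pysam.AlignedSegment(out.header)
            a.query_name, a.flag, a.reference_start = q, f, p
            a.reference_name = c
            a.mapping_quality, a.cigarstring, a.query_sequence = m, cg, s
            a.query_qualities = pysam.qualitystring_to_array("I" * len(s))
            other = [x for x in mate_pos[q] if x != p]
            a.next_reference_id = 0
            a.next_reference_start = other[0] if other else p
            out.write(a)
    pysam.sort("--no-PG", "-o", path2, path2 + ".un")
    pysam.index(path2)
    with pysam.AlignmentFile(path2) as bam:
        seqs = gather_reads(bam, GenomeInterval("chrZ", 5000, 5400),
                            AssemblyParams(region_pad=0))
    assert len(seqs) == 8  # 3 full pairs + window read + recruited far mate

    # empty region
    with pysam.AlignmentFile(path2) as bam:
        assert gather_reads(bam, GenomeInterval("chrZ", 90_000, 90_100),
                            AssemblyParams()) == []
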