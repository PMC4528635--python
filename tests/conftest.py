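import os

import pysam
import pytest

from svmeld.simdata import (SimConfig, default_tool_profiles, mock_callsets,
                            simulate_genome, simulate_reads)
from svmeld.vcfio import write_calls_vcf


@pytest.fixture(scope="session")
def mini_sim(tmp_path_factory):
    """A small but complete simulated dataset shared across tests:
    400 kb diploid genome, 30 implanted SVs, 50x reads, mock callsets."""
    d = tmp_path_factory.mktemp("mini_sim")
    cfg = SimConfig(genome_length=400_000, n_chroms=2, n_del=12, n_ins=12,
                    n_inv=3, n_dup=3, coverage=50, seed=7)
    genome = simulate_genome(cfg)
    ref = genome.write_reference(str(d / "ref.fa"))
    bam = simulate_reads(genome, str(d / "reads.bam"))
    callsets = mock_callsets(genome.truth, default_tool_profiles(),
                             genome.chrom_lengths, seed=9)
    vcfs = {}
    for tool, calls in callsets.items():
        path = str(d / f"{tool}.vcf")
        write_calls_vcf(path, calls, genome.chrom_lengths, reference=ref)
        vcfs[tool] = path
    return {"dir": str(d), "config": cfg, "genome": genome, "ref": ref,
            "bam": bam, "callsets": callsets, "vcfs": vcfs}


@pytest.fixture(scope="session")
def acceptance_run(tmp_path_factory):
    """The scaled-down evaluation protocol: 2 Mb diploid genome, ~60 DEL
    + ~60 INS (plus INV/DUP), 2x100 bp pairs at 50x, four mock tool
    profiles, full pipeline, strict benchmark (90% reciprocal overlap,
    100 bp wiggle, 100 bp size cutoff) over PASS records."""
    from svmeld.bench import benchmark
    from svmeld.pipeline import PipelineConfig, run

    d = tmp_path_factory.mktemp("acceptance")
    cfg = SimConfig(seed=1)
    genome = simulate_genome(cfg)
    ref = genome.write_reference(str(d / "ref.fa"))
    bam = simulate_reads(genome, str(d / "reads.bam"))
    profiles = default_tool_profiles()
    callsets = mock_callsets(genome.truth, profiles, genome.chrom_lengths,
                             seed=3)
    vcfs = {}
    for tool, calls in callsets.items():
        path = str(d / f"{tool}.vcf")
        write_calls_vcf(path, calls, genome.chrom_lengths, reference=ref)
        vcfs[tool] = path
    import time
    t0 = time.time()
    config = PipelineConfig(vcfs=vcfs,
                            tool_methods={p.tool: p.method
                                          for p in profiles},
                            bam=bam, reference=ref)
    result = run(config, out_vcf=str(d / "final.vcf"))
    calls = [r.to_call() for r in result.pass_records]
    bench = benchmark(calls, genome.truth, ro_min=0.90, wiggle=100,
                      min_size=100)
    elapsed = time.time() - t0
    return {"genome": genome, "result": result, "bench": bench,
            "elapsed": elapsed}


def make_bam(path: str, chrom_lengths: dict, rows: list) -> str:
    """Write a tiny BAM from (qname, flag, chrom, pos, mapq, cigar, seq)
    tuples, then sort + index."""
    header = {"HD": {"VN": "1.6"},
              "SQ": [{"SN": c, "LN": l} for c, l in chrom_lengths.items()]}
    unsorted = path + ".unsorted.bam"
    with pysam.AlignmentFile(unsorted, "wb", header=header) as out:
        for qname, flag, chrom, pos, mapq, cigar, seq in rows:
            a = pysam.AlignedSegment(out.header)
            a.query_name = qname
            a.flag = flag
            a.reference_name = chrom
            a.reference_start = pos
            a.mapping_quality = mapq
            a.cigarstring = cigar
            a.query_sequence = seq
            a.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
            out.write(a)
    pysam.sort("--no-PG", "-o", path, unsorted)
    os.remove(unsorted)
    pysam.index(path)
    return path
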