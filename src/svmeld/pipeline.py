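"""End-to-end orchestration: intake -> merge -> soft-clip scan ->
assembly -> split-alignment refinement -> genotyping -> VCF.

Work is partitioned by chromosome; each chromosome unit is an
independent pure function of (paths, parameters, calls), so units can
run in a process pool and the multi-process result is identical to the
single-threaded one.  Stages degrade gracefully: with no BAM the
pipeline runs in merge-only mode; with assembly disabled clusters keep
their merged breakpoints and soft-clip candidates stay unconfirmed.
"""

from __future__ import annotations

import logging
import multiprocessing
from dataclasses import dataclass, field, replace
from typing import Optional

import pysam

from .assembly import (AssemblyParams, assemble_greedy,
                       gather_reads_prioritized)
from .genotype import GenotypeParams, genotype_call
from .merging import MergeParams, cluster_inter_tool, merge_intra_tool
from .model import GenomeInterval, SVCall, SVCluster
from .softclip import (InsertionCandidate, SoftClipParams, cluster_softclips,
                       extract_softclips, pair_clusters)
from .splitalign import ScoringScheme, confirm_insertion, refine_cluster
from .vcf_out import MIN_SV_SIZE_OUT, FinalRecord, emit_vcf, passes_size_filter
from .vcfio import contigs_from_fasta, read_tool_vcf

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """Run configuration; every stage's knobs are addressable here.

    ``assembly.max_reads`` defaults to 150 in the pipeline (down from
    the module default): the greedy assembler is quadratic in read
    count, and 150 reads cover a breakpoint window many times over at
    typical depth.
    """

    vcfs: dict = field(default_factory=dict)        # tool -> VCF path
    tool_methods: dict = field(default_factory=dict)  # tool -> method
    bam: Optional[str] = None
    reference: Optional[str] = None
    merge: MergeParams = MergeParams()
    softclip: SoftClipParams = SoftClipParams()
    assembly: AssemblyParams = AssemblyParams(max_reads=150)
    scoring: ScoringScheme = ScoringScheme()
    genotype: GenotypeParams = GenotypeParams()
    enable_assembly: bool = True
    enable_softclip: bool = True
    #: "builtin" or "external:<command template>" with {reads}/{out}
    #: placeholders (FASTQ in, FASTA out; falls back to builtin on failure)
    assembler: str = "builtin"
    max_refine_contigs: int = 6
    min_sv_size_out: int = MIN_SV_SIZE_OUT
    threads: int = 1


@dataclass
class RunResult:
    records: list[FinalRecord]
    report: dict
    out_vcf: Optional[str] = None

    @property
    def pass_records(self) -> list[FinalRecord]:
        return [r for r in self.records if r.filter == "PASS"]


def run(config: PipelineConfig, out_vcf: Optional[str] = None) -> RunResult:
    """Execute the full pipeline and optionally write the final VCF."""
    if not config.vcfs and not config.bam:
        raise ValueError("need at least one input callset or a BAM")
    if config.enable_assembly and config.bam and not config.reference:
        log.warning("no reference given: assembly/refinement disabled")
        config = replace(config, enable_assembly=False)

    per_tool: dict[str, list[SVCall]] = {}
    for tool in sorted(config.vcfs):
        per_tool[tool] = read_tool_vcf(
            config.vcfs[tool], tool,
            default_method=config.tool_methods.get(tool, "unknown"))

    chrom_lengths = _chrom_lengths(config)
    chroms = sorted(chrom_lengths)
    payloads = []
    for chrom in chroms:
        calls = {tool: [c for c in calls if c.chrom == chrom]
                 for tool, calls in per_tool.items()}
        payloads.append((chrom, calls, chrom_lengths[chrom], config))

    if config.threads > 1 and len(payloads) > 1:
        with multiprocessing.Pool(config.threads) as pool:
            results = pool.map(_chrom_worker, payloads)
    else:
        results = [_chrom_worker(p) for p in payloads]

    records: list[FinalRecord] = []
    report: dict = {"per_chrom": {}, "n_input_calls": sum(
        len(v) for v in per_tool.values())}
    for chrom, (chrom_records, chrom_report) in zip(chroms, results):
        records.extend(chrom_records)
        report["per_chrom"][chrom] = chrom_report
    records.sort(key=lambda r: r.cluster.sort_key())
    report["n_records"] = len(records)
    report["n_pass"] = sum(1 for r in records if r.filter == "PASS")
    result = RunResult(records=records, report=report)
    if out_vcf:
        emit_vcf(records, out_vcf, chrom_lengths,
                 reference=config.reference)
        result.out_vcf = out_vcf
    return result


def _chrom_lengths(config: PipelineConfig) -> dict[str, int]:
    if config.reference:
        return contigs_from_fasta(config.reference)
    if config.bam:
        with pysam.AlignmentFile(config.bam) as bam:
            return dict(zip(bam.references, bam.lengths))
    # fallback: span of the input calls
    lengths: dict[str, int] = {}
    for tool in sorted(config.vcfs):
        for call in read_tool_vcf(config.vcfs[tool], tool):
            lengths[call.chrom] = max(lengths.get(call.chrom, 0),
                                      call.end + 1000)
    return lengths


def _chrom_worker(payload) -> tuple[list[FinalRecord], dict]:
    chrom, calls_by_tool, chrom_len, config = payload
    report: dict = {}

    # 1-2. intra-tool collapse, then inter-tool clustering
    merged = {tool: merge_intra_tool(calls, config.merge)
              for tool, calls in calls_by_tool.items()}
    report["calls_in"] = sum(len(v) for v in calls_by_tool.values())
    report["calls_after_intra"] = sum(len(v) for v in merged.values())
    clusters = cluster_inter_tool(merged, config.merge)
    report["clusters"] = len(clusters)

    bam = pysam.AlignmentFile(config.bam) if config.bam else None
    fa = pysam.FastaFile(config.reference) if config.reference else None
    try:
        # 3. soft-clip scan for candidate insertion loci
        candidates: list[InsertionCandidate] = []
        if bam is not None and config.enable_softclip:
            events = extract_softclips(bam, config.softclip, chrom=chrom)
            sc_clusters = cluster_softclips(events, config.softclip,
                                            {chrom: chrom_len})
            candidates = pair_clusters(sc_clusters, config.softclip)
            candidates = _suppress_near_breakpoints(
                candidates, clusters, config.merge.wiggle)
        report["softclip_candidates"] = len(candidates)
        report["softclip_loci"] = [
            (cand.locus.chrom, cand.locus.start, cand.support, cand.paired)
            for cand in candidates]

        clusters = _merge_candidates(clusters, candidates, config)

        # 4. local assembly + split-alignment breakpoint refinement
        n_confirmed = 0
        if bam is not None and fa is not None and config.enable_assembly:
            for cluster in clusters:
                if cluster.sv_type == "DEL":
                    _refine_del(cluster, bam, fa, chrom_len, config)
                elif cluster.sv_type == "INS":
                    _refine_ins(cluster, bam, fa, chrom_len, config)
                n_confirmed += cluster.assembly_confirmed
        report["assembly_confirmed"] = n_confirmed

        # drop soft-clip-only candidates that assembly rejected
        clusters = [c for c in clusters
                    if not (c.tools == {"softclip"}
                            and not c.assembly_confirmed)]

        # refinement standardizes breakpoints, which can reveal that two
        # clusters (e.g. a precise split-read one and a fuzzy read-pair
        # one that missed the linkage pre-refinement) are the same event
        clusters = _dedup_clusters(clusters, config.merge)

        # 5. genotyping from read coverage
        exclude = [c.consensus for c in clusters if c.consensus]
        records = []
        for cluster in clusters:
            genotype = "unknown"
            if bam is not None:
                call = SVCall(interval=cluster.consensus,
                              sv_type=cluster.sv_type,
                              sv_length=cluster.sv_length,
                              tool="cluster", method="merged",
                              support=cluster.support)
                genotype = genotype_call(bam, call, config.genotype, exclude)
            records.append(FinalRecord(cluster=cluster, genotype=genotype))
    finally:
        if bam is not None:
            bam.close()
        if fa is not None:
            fa.close()

    # 6. size filter (events below the cutoff are indel-caller territory)
    records = [r for r in records
               if passes_size_filter(r, config.min_sv_size_out)]
    report["records_out"] = len(records)
    return records, report


def _dedup_clusters(clusters: list[SVCluster],
                    merge: MergeParams) -> list[SVCluster]:
    """Single-linkage merge of final clusters whose consensus intervals
    are the same event; assembly-confirmed breakpoints win."""
    from .merging import same_event, select_breakpoints

    def proxy(c: SVCluster) -> SVCall:
        return SVCall(interval=c.consensus, sv_type=c.sv_type,
                      sv_length=c.sv_length, tool="x", method="merged")

    clusters = sorted(clusters, key=SVCluster.sort_key)
    out: list[SVCluster] = []
    used = [False] * len(clusters)
    for i, ci in enumerate(clusters):
        if used[i]:
            continue
        group = [ci]
        used[i] = True
        frontier = [ci]
        while frontier:
            cur = frontier.pop()
            for j in range(i + 1, len(clusters)):
                if used[j]:
                    continue
                cj = clusters[j]
                if same_event(proxy(cur), proxy(cj), merge):
                    used[j] = True
                    group.append(cj)
                    frontier.append(cj)
        if len(group) == 1:
            out.append(ci)
            continue
        merged = SVCluster(
            members=[m for c in group for m in c.members],
            sv_type=ci.sv_type)
        confirmed = [c for c in group if c.assembly_confirmed]
        if confirmed:
            best = max(confirmed, key=lambda c: c.support)
            merged.consensus = best.consensus
            merged.sv_length = best.sv_length
            merged.assembly_confirmed = True
            merged.refined = any(c.refined for c in confirmed)
        else:
            merged.consensus = select_breakpoints(merged, merge)
            merged.sv_length = (merged.consensus.length()
                                if merged.sv_type != "INS" else ci.sv_length)
        out.append(merged)
    out.sort(key=SVCluster.sort_key)
    return out


def _suppress_near_breakpoints(candidates: list[InsertionCandidate],
                               clusters: list[SVCluster],
                               wiggle: int) -> list[InsertionCandidate]:
    """Drop candidate insertion loci sitting on a non-INS breakpoint.

    Tandem-duplication and inversion junctions produce the same clipped
    read pileups as insertions; a candidate within the wiggle of a
    detected non-INS cluster breakpoint is explained by that event.
    """
    breakpoints: list[int] = []
    for c in clusters:
        if c.sv_type != "INS" and c.consensus is not None:
            breakpoints.extend((c.consensus.start, c.consensus.end))
    out = []
    for cand in candidates:
        pos = cand.locus.start
        if any(abs(pos - bp) <= wiggle for bp in breakpoints):
            continue
        out.append(cand)
    return out


def _merge_candidates(clusters: list[SVCluster],
                      candidates: list[InsertionCandidate],
                      config: PipelineConfig) -> list[SVCluster]:
    """Attach candidate loci to existing INS clusters or open new ones."""
    ins_clusters = [c for c in clusters if c.sv_type == "INS"]
    for cand in candidates:
        call = SVCall(interval=cand.locus, sv_type="INS", sv_length=None,
                      tool="softclip", method="softclip_assembly",
                      support=cand.support)
        host = None
        for c in ins_clusters:
            if abs(c.consensus.start - cand.locus.start) <= config.merge.wiggle:
                host = c
                break
        if host is not None:
            host.members.append(call)
        else:
            cluster = SVCluster(members=[call], sv_type="INS",
                                consensus=cand.locus, sv_length=None)
            clusters.append(cluster)
            ins_clusters.append(cluster)
    clusters.sort(key=SVCluster.sort_key)
    return clusters


def _assemble(reads, config: PipelineConfig, region):
    if config.assembler.startswith("external:"):
        import tempfile

        from .assembly import run_external_assembler
        with tempfile.TemporaryDirectory(prefix="svmeld_asm_") as wd:
            return run_external_assembler(
                reads, wd, config.assembler[len("external:"):],
                config.assembly, region)
    return assemble_greedy(reads, config.assembly, region)


def _refine_del(cluster: SVCluster, bam, fa, chrom_len: int,
                config: PipelineConfig) -> None:
    iv = cluster.consensus
    pad = config.assembly.region_pad
    win = 300  # junction-spanning evidence sits within a read length
    # each gather window covers the members' spread for that breakpoint,
    # not just the consensus: fuzzy-method clusters can be hundreds of
    # bp off and the junction reads sit at the true position
    s_lo = min([iv.start] + [m.start for m in cluster.members])
    s_hi = max([iv.start] + [m.start for m in cluster.members])
    e_lo = min([iv.end] + [m.end for m in cluster.members])
    e_hi = max([iv.end] + [m.end for m in cluster.members])
    windows = [GenomeInterval(iv.chrom, max(0, s_lo - win),
                              min(chrom_len, s_hi + win)),
               GenomeInterval(iv.chrom, max(0, e_lo - win),
                              min(chrom_len, e_hi + win))]
    if windows[1].start <= windows[0].end:
        windows = [GenomeInterval(iv.chrom, windows[0].start,
                                  windows[1].end)]
    reads = gather_reads_prioritized(bam, windows, config.assembly)
    contigs = _assemble(reads, config, iv)[:config.max_refine_contigs]
    refine_cluster(cluster, contigs, fa.fetch, config.scoring,
                   region_pad=pad, chrom_length=chrom_len)


def _refine_ins(cluster: SVCluster, bam, fa, chrom_len: int,
                config: PipelineConfig) -> None:
    pos = cluster.consensus.start
    pad = config.assembly.region_pad
    window = GenomeInterval(cluster.chrom, max(0, pos - pad),
                            min(chrom_len, pos + pad))
    reads = gather_reads_prioritized(bam, [window], config.assembly)
    contigs = _assemble(reads, config, window)[:config.max_refine_contigs]
    hit = confirm_insertion(pos, cluster.chrom, contigs, fa.fetch,
                            config.scoring,
                            tolerance=config.merge.wiggle,
                            chrom_length=chrom_len)
    if hit is not None:
        refined_pos, length = hit
        cluster.consensus = GenomeInterval(cluster.chrom, refined_pos,
                                           refined_pos + 1)
        if length is not None:  # assembly-measured length wins;
            cluster.sv_length = length  # else keep any tool-reported length
        cluster.assembly_confirmed = True
        cluster.refined = True
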