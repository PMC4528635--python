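"""Synthetic diploid genomes, aligned paired-end reads, and mock callsets.

This module generates everything the pipeline consumes, so the whole
method is testable end to end without external data:

* a random diploid genome with implanted DEL/INS/INV/DUP events and a
  truth set with genotypes;
* 2 x 100 bp paired-end reads at a chosen coverage, emitted directly as
  a coordinate-sorted indexed BAM *with the alignments a correct aligner
  would produce* — reads crossing a deletion get D or soft-clipped
  CIGARs, reads running into inserted sequence get terminal soft clips,
  reads inside inversions map to the reverse strand, pairs bridging
  events become discordant.  Emitting alignments directly (instead of
  FASTQ plus a real aligner) keeps the exact clip/discordance signals
  the soft-clip scanner and genotyper rely on under test control;
* mock per-tool callsets with method-specific sensitivity, breakpoint
  jitter and false-call rates, emulating the qualitative behavior of
  split-read, read-pair, depth-of-coverage and junction-mapping callers
  (depth callers blind below 500 bp, read-pair callers blind to
  insertions, junction/split callers near-base-pair precise).

Everything is deterministic given the seed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pysam

from .model import GenomeInterval, SVCall, sorted_calls

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the scaled-down simulation protocol.

    Defaults: a 2 Mb diploid genome over 2 chromosomes carrying ~60
    deletions and ~60 insertions (plus a handful of inversions and
    tandem duplications), sequenced as 2 x 100 bp pairs at 50x total
    coverage with a 400 +/- 50 bp insert and 0.1% base error.
    """

    genome_length: int = 2_000_000
    n_chroms: int = 2
    n_del: int = 60
    n_ins: int = 60
    n_inv: int = 8
    n_dup: int = 8
    size_range: dict = field(default_factory=lambda: {
        "DEL": (100, 10_000), "INS": (100, 5_000),
        "INV": (100, 5_000), "DUP": (100, 5_000)})
    het_fraction: float = 0.5
    read_length: int = 100
    coverage: float = 50.0
    insert_mean: int = 400
    insert_sd: int = 50
    error_rate: float = 0.001
    min_spacing: int = 1000
    seed: int = 0


@dataclass(frozen=True)
class Block:
    """A haplotype segment: reference-derived (with strand) or novel."""

    hap_start: int
    hap_end: int
    ref_start: Optional[int]  # None => novel inserted sequence
    ref_end: Optional[int]
    strand: str  # '+' or '-' (reference-derived blocks only)


@dataclass
class Haplotype:
    chrom: str
    seq: str
    blocks: list[Block]
    block_starts: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.block_starts = np.array([b.hap_start for b in self.blocks])


@dataclass
class SimulatedGenome:
    config: SimConfig
    reference: dict[str, str]
    haplotypes: dict[tuple[str, int], Haplotype]  # (chrom, 0/1) -> Haplotype
    truth: list[SVCall]

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.reference.items()}

    def write_reference(self, path: str) -> str:
        with open(path, "w") as fh:
            for chrom in self.reference:
                fh.write(f">{chrom}\n")
                seq = self.reference[chrom]
                for i in range(0, len(seq), 60):
                    fh.write(seq[i:i + 60] + "\n")
        pysam.faidx(path)
        return path


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, length)].tobytes().decode()


def _log_uniform_size(rng: np.random.Generator, lo: int, hi: int) -> int:
    return int(round(np.exp(rng.uniform(np.log(lo), np.log(hi)))))


def simulate_genome(cfg: SimConfig) -> SimulatedGenome:
    """Random reference + two haplotypes with implanted SVs + truth set."""
    rng = np.random.default_rng(cfg.seed)
    chrom_len = cfg.genome_length // cfg.n_chroms
    chroms = [f"chr{i + 1}" for i in range(cfg.n_chroms)]
    reference = {c: _random_seq(rng, chrom_len) for c in chroms}

    # place events without overlap, min_spacing apart, away from ends
    events: list[dict] = []
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    wanted = ([("DEL", cfg.n_del), ("INS", cfg.n_ins),
               ("INV", cfg.n_inv), ("DUP", cfg.n_dup)])
    for sv_type, count in wanted:
        lo, hi = cfg.size_range[sv_type]
        placed = 0
        attempts = 0
        while placed < count and attempts < count * 500:
            attempts += 1
            size = _log_uniform_size(rng, lo, hi)
            chrom = chroms[int(rng.integers(0, cfg.n_chroms))]
            span = 1 if sv_type == "INS" else size
            margin = cfg.min_spacing + cfg.insert_mean
            if chrom_len - span - 2 * margin <= 0:
                continue
            start = int(rng.integers(margin, chrom_len - span - margin))
            end = start + span
            if any(start - cfg.min_spacing < e and s < end + cfg.min_spacing
                   for s, e in occupied[chrom]):
                continue
            occupied[chrom].append((start, end))
            genotype = "het" if rng.random() < cfg.het_fraction else "hom_alt"
            hap_mask = ((True, True) if genotype == "hom_alt" else
                        ((True, False) if rng.random() < 0.5
                         else (False, True)))
            ev = dict(sv_type=sv_type, chrom=chrom, start=start, end=end,
                      size=size, genotype=genotype, hap_mask=hap_mask,
                      ins_seq=_random_seq(rng, size) if sv_type == "INS"
                      else None)
            events.append(ev)
            placed += 1
        if placed < count:
            import warnings
            warnings.warn(f"placed only {placed}/{count} {sv_type} events")
    events.sort(key=lambda e: (e["chrom"], e["start"]))

    haplotypes: dict[tuple[str, int], Haplotype] = {}
    for chrom in chroms:
        ref = reference[chrom]
        for hap_idx in (0, 1):
            haplotypes[(chrom, hap_idx)] = _build_haplotype(
                chrom, ref, [e for e in events if e["chrom"] == chrom
                             and e["hap_mask"][hap_idx]])

    truth = []
    for ev in events:
        if ev["sv_type"] == "INS":
            interval = GenomeInterval(ev["chrom"], ev["start"],
                                      ev["start"] + 1)
        else:
            interval = GenomeInterval(ev["chrom"], ev["start"], ev["end"])
        truth.append(SVCall(interval=interval, sv_type=ev["sv_type"],
                            sv_length=ev["size"], tool="truth",
                            method="truth", genotype=ev["genotype"]))
    return SimulatedGenome(config=cfg, reference=reference,
                           haplotypes=haplotypes, truth=sorted_calls(truth))


def _build_haplotype(chrom: str, ref: str, events: list[dict]) -> Haplotype:
    blocks: list[Block] = []
    parts: list[str] = []
    hap_pos = 0
    cur = 0

    def add_ref_block(s: int, e: int, strand: str = "+") -> None:
        nonlocal hap_pos
        if e <= s:
            return
        seq = ref[s:e] if strand == "+" else _revcomp(ref[s:e])
        blocks.append(Block(hap_pos, hap_pos + (e - s), s, e, strand))
        parts.append(seq)
        hap_pos += e - s

    def add_novel_block(seq: str) -> None:
        nonlocal hap_pos
        blocks.append(Block(hap_pos, hap_pos + len(seq), None, None, "+"))
        parts.append(seq)
        hap_pos += len(seq)

    for ev in events:
        s, e = ev["start"], ev["end"]
        if ev["sv_type"] == "DEL":
            add_ref_block(cur, s)
            cur = e
        elif ev["sv_type"] == "INS":
            add_ref_block(cur, s)
            add_novel_block(ev["ins_seq"])
            cur = s
        elif ev["sv_type"] == "INV":
            add_ref_block(cur, s)
            add_ref_block(s, e, "-")
            cur = e
        elif ev["sv_type"] == "DUP":
            add_ref_block(cur, e)  # first copy inside the colinear block
            add_ref_block(s, e)    # tandem second copy
            cur = e
    add_ref_block(cur, len(ref))
    return Haplotype(chrom=chrom, seq="".join(parts), blocks=blocks)


# ---------------------------------------------------------------------------
# Read simulation

_MIN_ANCHOR = 20  # terminal aligned segments shorter than this are clipped


def _map_segments(hap: Haplotype, a: int, b: int) -> list[tuple]:
    """Decompose hap interval [a, b) into (read_off, length, ref_pos, strand)
    segments; ref_pos is None for novel sequence."""
    segs = []
    i = int(np.searchsorted(hap.block_starts, a, side="right")) - 1
    pos = a
    while pos < b:
        blk = hap.blocks[i]
        take = min(b, blk.hap_end) - pos
        off = pos - a
        if blk.ref_start is None:
            segs.append((off, take, None, None))
        elif blk.strand == "+":
            segs.append((off, take, blk.ref_start + (pos - blk.hap_start),
                         "+"))
        else:
            d = pos - blk.hap_start
            segs.append((off, take, blk.ref_end - d - take, "-"))
        pos += take
        i += 1
    return segs


def _colinear_runs(segs: list[tuple], max_del: int = 100_000) -> list[list]:
    runs: list[list] = []
    cur: list = []
    for seg in segs:
        off, length, ref_pos, strand = seg
        if ref_pos is None:
            if cur:
                runs.append(cur)
            cur = []
            continue
        if cur:
            p_off, p_len, p_ref, p_strand = cur[-1]
            if strand == p_strand == "+":
                gap = ref_pos - (p_ref + p_len)
            elif strand == p_strand == "-":
                gap = p_ref - (ref_pos + length)
            else:
                gap = -1
            if 0 <= gap <= max_del:
                cur.append(seg)
                continue
            runs.append(cur)
            cur = []
        cur.append(seg)
    if cur:
        runs.append(cur)
    return runs


def _align_read(hap: Haplotype, a: int, b: int):
    """Alignment of hap interval [a, b) against the reference.

    Returns (pos, strand, cigar_ops, aligned_len) with cigar_ops in
    *haplotype* orientation as [(op, len), ...] using 'M'/'D', or None
    when the read has no anchorable reference segment.  Terminal M
    segments shorter than the anchor minimum are soft-clipped.
    """
    segs = _map_segments(hap, a, b)
    best = None
    for run in _colinear_runs(segs):
        run = list(run)
        while run and run[0][1] < _MIN_ANCHOR:
            run = run[1:]
        while run and run[-1][1] < _MIN_ANCHOR:
            run = run[:-1]
        if not run:
            continue
        score = sum(sg[1] for sg in run)
        if best is None or score > best[0]:
            best = (score, run)
    if best is None:
        return None
    run = best[1]
    strand = run[0][3]
    ops: list[tuple[str, int]] = []
    for k, seg in enumerate(run):
        if k:
            prev = run[k - 1]
            if strand == "+":
                gap = seg[2] - (prev[2] + prev[1])
            else:
                gap = prev[2] - (seg[2] + seg[1])
            if gap > 0:
                ops.append(("D", gap))
        if ops and ops[-1][0] == "M":
            ops[-1] = ("M", ops[-1][1] + seg[1])
        else:
            ops.append(("M", seg[1]))
    if strand == "+":
        pos = run[0][2]
    else:
        pos = run[-1][2]
    pre = run[0][0]
    post = (b - a) - (run[-1][0] + run[-1][1])
    return pos, strand, ops, pre, post


def _cigar_string(pre: int, post: int, ops: list[tuple[str, int]],
                  strand: str) -> str:
    if strand == "-":
        ops = ops[::-1]
        pre, post = post, pre
    parts = []
    if pre:
        parts.append(f"{pre}S")
    parts.extend(f"{l}{op}" for op, l in ops)
    if post:
        parts.append(f"{post}S")
    return "".join(parts)


def _ref_span(ops: list[tuple[str, int]]) -> int:
    return sum(l for _, l in ops)


def simulate_reads(genome: SimulatedGenome, bam_path: str,
                   seed: Optional[int] = None,
                   fastq_prefix: Optional[str] = None) -> str:
    """Simulate paired-end reads and write a sorted, indexed BAM.

    Fragments are drawn uniformly from each haplotype at half the total
    coverage each; alignments against the reference are computed from
    the haplotype block structure.  ``fastq_prefix`` additionally writes
    the raw pairs as FASTQ for users who want to run a real aligner.
    """
    cfg = genome.config
    rng = np.random.default_rng(cfg.seed + 1 if seed is None else seed)
    rl = cfg.read_length
    qual = "I" * rl
    header_lines = ["@HD\tVN:1.6"]
    tids = {}
    for chrom, length in genome.chrom_lengths.items():
        tids[chrom] = len(tids)
        header_lines.append(f"@SQ\tSN:{chrom}\tLN:{length}")
    records: list[tuple[int, int, str]] = []  # (tid, pos, sam_line)
    fq1 = open(fastq_prefix + "_1.fastq", "w") if fastq_prefix else None
    fq2 = open(fastq_prefix + "_2.fastq", "w") if fastq_prefix else None
    try:
        for (chrom, hap_idx) in sorted(genome.haplotypes):
            hap = genome.haplotypes[(chrom, hap_idx)]
            L = len(hap.seq)
            n_pairs = int(round(L * (cfg.coverage / 2) / (2 * rl)))
            frag_lens = np.clip(
                np.round(rng.normal(cfg.insert_mean, cfg.insert_sd,
                                    n_pairs)).astype(np.int64),
                rl, L)
            starts = (rng.random(n_pairs)
                      * (L - frag_lens + 1)).astype(np.int64)
            n_err = rng.binomial(rl, cfg.error_rate, size=(n_pairs, 2))
            for pi in range(n_pairs):
                fs = int(starts[pi])
                fe = fs + int(frag_lens[pi])
                qname = f"sim_{chrom}_{hap_idx}_{pi}"
                h1 = hap.seq[fs:fs + rl]
                h2 = hap.seq[fe - rl:fe]
                if n_err[pi, 0]:
                    h1 = _mutate(h1, rng, int(n_err[pi, 0]))
                if n_err[pi, 1]:
                    h2 = _mutate(h2, rng, int(n_err[pi, 1]))
                aln1 = _align_read(hap, fs, fs + rl)
                aln2 = _align_read(hap, fe - rl, fe)
                if aln1 is None and aln2 is None:
                    continue
                lines = _pair_sam(qname, chrom, h1, h2, aln1, aln2, qual,
                                  cfg, tids)
                records.extend(lines)
                if fq1 is not None:
                    fq1.write(f"@{qname}\n{h1}\n+\n{qual}\n")
                    fq2.write(f"@{qname}\n{_revcomp(h2)}\n+\n{qual}\n")
    finally:
        if fq1 is not None:
            fq1.close()
        if fq2 is not None:
            fq2.close()
    records.sort(key=lambda r: (r[0], r[1]))
    sam_path = bam_path + ".tmp.sam"
    with open(sam_path, "w") as fh:
        fh.write("\n".join(header_lines) + "\n")
        for _, _, line in records:
            fh.write(line + "\n")
    pysam.sort("--no-PG", "-O", "bam", "-o", bam_path, sam_path)
    os.remove(sam_path)
    pysam.index(bam_path)
    return bam_path


def _mutate(seq: str, rng: np.random.Generator, n: int) -> str:
    chars = list(seq)
    for pos in rng.integers(0, len(chars), n):
        old = chars[pos]
        choices = [b for b in "ACGT" if b != old]
        chars[pos] = choices[int(rng.integers(0, 3))]
    return "".join(chars)


def _pair_sam(qname: str, chrom: str, h1: str, h2: str, aln1, aln2,
              qual: str, cfg: SimConfig, tids: dict[str, int]) -> list:
    """Build the two SAM lines for one pair; returns (tid, pos, line)."""
    out = []
    infos = []
    for is_r2, (h, aln) in enumerate([(h1, aln1), (h2, aln2)]):
        if aln is None:
            infos.append(None)
            continue
        pos, strand, ops, pre, post = aln
        reverse = bool(is_r2) != (strand == "-")
        seq = h if strand == "+" else _revcomp(h)
        cigar = _cigar_string(pre, post, ops, strand)
        infos.append(dict(pos=pos, end=pos + _ref_span(ops),
                          reverse=reverse, seq=seq, cigar=cigar))
    both = infos[0] is not None and infos[1] is not None
    tlen1 = tlen2 = 0
    proper = False
    if both:
        lo = min(infos[0]["pos"], infos[1]["pos"])
        hi = max(infos[0]["end"], infos[1]["end"])
        span = hi - lo
        if infos[0]["pos"] <= infos[1]["pos"]:
            tlen1, tlen2 = span, -span
        else:
            tlen1, tlen2 = -span, span
        proper = (infos[0]["reverse"] != infos[1]["reverse"]
                  and span <= cfg.insert_mean + 4 * cfg.insert_sd)
    for idx in (0, 1):
        mate = infos[1 - idx]
        info = infos[idx]
        flag = 0x1 | (0x40 if idx == 0 else 0x80)
        if proper:
            flag |= 0x2
        if info is None:
            flag |= 0x4
            if mate["reverse"]:
                flag |= 0x20
            seq = h1 if idx == 0 else _revcomp(h2)
            line = "\t".join([qname, str(flag), chrom, str(mate["pos"] + 1),
                              "0", "*", "=", str(mate["pos"] + 1), "0",
                              seq, qual])
            out.append((tids[chrom], mate["pos"], line))
            continue
        if info["reverse"]:
            flag |= 0x10
        if mate is None:
            flag |= 0x8
            pnext = info["pos"]
        else:
            if mate["reverse"]:
                flag |= 0x20
            pnext = mate["pos"]
        tlen = (tlen1 if idx == 0 else tlen2) if both else 0
        line = "\t".join([qname, str(flag), chrom, str(info["pos"] + 1),
                          "60", info["cigar"], "=", str(pnext + 1),
                          str(tlen), info["seq"], qual])
        out.append((tids[chrom], info["pos"], line))
    return out


# ---------------------------------------------------------------------------
# Mock tool callsets


@dataclass(frozen=True)
class ToolProfile:
    """Error model for one mock SV caller.

    ``sensitivity`` maps sv_type to a step function as a tuple of
    ``(max_size, sens)`` pairs (first bin whose max_size >= event size
    applies); types absent from ``detects`` are never emitted.
    """

    tool: str
    method: str
    detects: tuple[str, ...]
    sensitivity: dict
    fdr: float
    jitter_sd: float

    def sens(self, sv_type: str, size: int) -> float:
        if sv_type not in self.detects:
            return 0.0
        for max_size, s in self.sensitivity.get(sv_type, ()):
            if size <= max_size:
                return s
        return 0.0


_BIG = 10 ** 9


def default_tool_profiles() -> list[ToolProfile]:
    """Four personas mirroring the qualitative niches of the methods:
    junction mapping and split-read are precise; read-pair is fuzzy and
    blind to insertions; depth-of-coverage is very fuzzy, blind below
    500 bp and to balanced events."""
    return [
        ToolProfile(
            tool="juncmap", method="junction_mapping",
            detects=("DEL",),
            sensitivity={"DEL": ((_BIG, 0.60),)},
            fdr=0.02, jitter_sd=2.0),
        ToolProfile(
            tool="splitread", method="split_read",
            detects=("DEL", "INS", "INV", "DUP"),
            sensitivity={"DEL": ((1000, 0.90), (_BIG, 0.75)),
                         "INS": ((500, 0.30), (_BIG, 0.0)),
                         "INV": ((_BIG, 0.70),),
                         "DUP": ((_BIG, 0.50),)},
            fdr=0.05, jitter_sd=5.0),
        ToolProfile(
            tool="readpair", method="read_pair",
            detects=("DEL", "INV", "DUP"),
            sensitivity={"DEL": ((300, 0.30), (_BIG, 0.85)),
                         "INV": ((_BIG, 0.75),),
                         "DUP": ((_BIG, 0.60),)},
            fdr=0.05, jitter_sd=150.0),
        ToolProfile(
            tool="depthcov", method="depth_of_coverage",
            detects=("DEL", "DUP"),
            sensitivity={"DEL": ((500, 0.0), (_BIG, 0.80)),
                         "DUP": ((500, 0.0), (_BIG, 0.70))},
            fdr=0.05, jitter_sd=300.0),
    ]


def mock_callsets(truth: Sequence[SVCall],
                  profiles: Sequence[ToolProfile],
                  chrom_lengths: dict[str, int],
                  seed: int = 0,
                  false_size_range: tuple[int, int] = (100, 5000),
                  ) -> dict[str, list[SVCall]]:
    """Per-tool noisy callsets derived from the truth set."""
    out: dict[str, list[SVCall]] = {}
    chroms = sorted(chrom_lengths)
    for t_idx, prof in enumerate(profiles):
        rng = np.random.default_rng([seed, t_idx])
        calls: list[SVCall] = []
        n_detectable = 0
        for sv in truth:
            size = sv.sv_length or 0
            p = prof.sens(sv.sv_type, size)
            if sv.sv_type in prof.detects:
                n_detectable += 1
            if rng.random() >= p:
                continue
            calls.append(_jittered(sv, prof, rng, chrom_lengths))
        n_false = int(rng.poisson(prof.fdr * max(1, n_detectable)))
        for _ in range(n_false):
            sv_type = prof.detects[int(rng.integers(0, len(prof.detects)))]
            size = _log_uniform_size(rng, *false_size_range)
            chrom = chroms[int(rng.integers(0, len(chroms)))]
            span = 1 if sv_type == "INS" else size
            limit = chrom_lengths[chrom] - span - 1
            if limit <= 1:
                continue
            start = int(rng.integers(1, limit))
            interval = GenomeInterval(chrom, start, start + span)
            calls.append(SVCall(
                interval=interval, sv_type=sv_type,
                sv_length=size if sv_type == "INS" else span,
                tool=prof.tool, method=prof.method,
                support=max(2, int(rng.poisson(8)))))
        out[prof.tool] = sorted_calls(calls)
    return out


def _jittered(sv: SVCall, prof: ToolProfile, rng: np.random.Generator,
              chrom_lengths: dict[str, int]) -> SVCall:
    L = chrom_lengths[sv.chrom]
    ds = int(round(rng.normal(0, prof.jitter_sd)))
    de = int(round(rng.normal(0, prof.jitter_sd)))
    if sv.sv_type == "INS":
        start = min(max(0, sv.start + ds), L - 2)
        interval = GenomeInterval(sv.chrom, start, start + 1)
        length = sv.sv_length
    else:
        start = min(max(0, sv.start + ds), L - 2)
        end = min(max(start + 1, sv.end + de), L - 1)
        interval = GenomeInterval(sv.chrom, start, end)
        length = interval.length()
    return SVCall(interval=interval, sv_type=sv.sv_type, sv_length=length,
                  tool=prof.tool, method=prof.method,
                  support=max(2, int(rng.poisson(15))))
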