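"""Local assembly of reads around candidate SV regions.

The built-in assembler is a deterministic greedy overlap-layout
consensus: repeatedly merge the pair of sequences with the longest exact
suffix-prefix overlap, considering both strands.  It is dependency-free
and adequate for the <= a-few-kb windows this pipeline assembles; an
adapter contract (:func:`run_external_assembler`) lets users plug in a
real paired-end assembler for production data, falling back to the
greedy assembler on any failure.
"""

from __future__ import annotations

import logging
import os
import random
import subprocess
from dataclasses import dataclass
from typing import Optional, Sequence

import pysam

from .model import GenomeInterval

log = logging.getLogger(__name__)

#: Fixed downsampling seed, so identical inputs give identical contigs.
DOWNSAMPLE_SEED = 53


@dataclass(frozen=True)
class AssemblyParams:
    region_pad: int = 500
    kmer: int = 31  # minimum contig length / seed length
    min_overlap: int = 50
    min_read_count: int = 4
    max_reads: int = 10000

    def __post_init__(self) -> None:
        if self.kmer % 2 == 0 or self.kmer < 11:
            raise ValueError("kmer must be odd and >= 11")
        if self.min_overlap < 1 or self.min_read_count < 1:
            raise ValueError("min_overlap and min_read_count must be >= 1")


@dataclass
class Contig:
    seq: str
    region: Optional[GenomeInterval]
    n_reads: int


_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def gather_reads(bam: pysam.AlignmentFile, region: GenomeInterval,
                 p: AssemblyParams) -> list[str]:
    """Collect read sequences overlapping ``region`` +/- ``region_pad``.

    Mates of in-window reads are recruited as well (one-end-anchored
    recruitment pulls in reads from inserted sequence whose own alignment
    is elsewhere or unmapped); sequences are returned as stored in the
    BAM.  The result is downsampled to ``max_reads`` with a fixed seed.
    """
    chrom_len = bam.get_reference_length(region.chrom)
    start = max(0, region.start - p.region_pad)
    end = min(chrom_len, region.end + p.region_pad)
    if end <= start:
        return []
    seen: dict[tuple[str, bool], str] = {}
    want_mates: list[tuple[str, str, int]] = []
    for read in bam.fetch(region.chrom, start, end):
        if read.is_secondary or read.is_supplementary or read.is_duplicate:
            continue
        seq = read.query_sequence
        if not seq:
            continue
        key = (read.query_name, read.is_read1)
        seen[key] = seq
        mate_key = (read.query_name, not read.is_read1)
        if (read.is_paired and not read.mate_is_unmapped
                and mate_key not in seen
                and read.next_reference_id == read.reference_id
                and not (start <= read.next_reference_start < end)):
            want_mates.append((read.query_name, read.reference_name,
                               read.next_reference_start))
    for qname, chrom, mate_pos in want_mates:
        for mate in bam.fetch(chrom, mate_pos, mate_pos + 1):
            if mate.query_name == qname and not (mate.is_secondary
                                                 or mate.is_supplementary):
                key = (mate.query_name, mate.is_read1)
                if key not in seen and mate.query_sequence:
                    seen[key] = mate.query_sequence
    # deterministic order independent of fetch order
    ordered = [seq for _, seq in sorted(seen.items())]
    if len(ordered) > p.max_reads:
        rng = random.Random(DOWNSAMPLE_SEED)
        ordered = sorted(rng.sample(ordered, p.max_reads))
    return ordered


def gather_reads_prioritized(bam: pysam.AlignmentFile,
                             windows: Sequence[GenomeInterval],
                             p: AssemblyParams, *,
                             min_clip: int = 20, min_del: int = 25,
                             max_insert: int = 800) -> list[str]:
    """Gather reads for breakpoint assembly, keeping SV evidence first.

    Uniform downsampling starves the (rare) junction-spanning reads a
    breakpoint contig needs, so reads carrying SV signal — terminal
    clips, deletion gaps in the CIGAR, discordant or broken pairs,
    unmapped reads placed at their mate — bypass the ``max_reads`` cap
    budget first; ordinary reads fill the remainder, downsampled with
    the fixed seed.
    """
    interesting: dict[tuple[str, bool], str] = {}
    plain: dict[tuple[str, bool], str] = {}
    for w in windows:
        start = max(0, w.start)
        end = min(bam.get_reference_length(w.chrom), w.end)
        if end <= start:
            continue
        for read in bam.fetch(w.chrom, start, end):
            if read.is_secondary or read.is_supplementary or read.is_duplicate:
                continue
            seq = read.query_sequence
            if not seq:
                continue
            key = (read.query_name, read.is_read1)
            cig = read.cigartuples or ()
            signal = read.is_unmapped
            if not signal and cig:
                if (cig[0][0] in (4, 5) and cig[0][1] >= min_clip) or \
                        (cig[-1][0] in (4, 5) and cig[-1][1] >= min_clip):
                    signal = True
                elif any(op == 2 and ln >= min_del for op, ln in cig):
                    signal = True
            if not signal and read.is_paired:
                if (read.mate_is_unmapped
                        or read.next_reference_id != read.reference_id
                        or abs(read.template_length) > max_insert
                        or read.is_reverse == read.mate_is_reverse):
                    signal = True
            (interesting if signal else plain)[key] = seq
    for key in interesting:
        plain.pop(key, None)
    rng = random.Random(DOWNSAMPLE_SEED)
    keep = [seq for _, seq in sorted(interesting.items())]
    if len(keep) > p.max_reads:
        keep = sorted(rng.sample(keep, p.max_reads))
    budget = p.max_reads - len(keep)
    filler = [seq for _, seq in sorted(plain.items())]
    if len(filler) > budget:
        filler = sorted(rng.sample(filler, max(0, budget)))
    return keep + filler


def _best_overlap(a: str, b: str, min_overlap: int) -> int:
    """Longest k >= min_overlap with a[-k:] == b[:k], else 0.

    Seeded by locating the last ``min_overlap`` characters of ``a``
    inside ``b``: an overlap of length k implies that probe occurs in b
    at offset k - min_overlap.
    """
    probe = a[-min_overlap:]
    if len(probe) < min_overlap:
        return 0
    limit = min(len(a), len(b))
    best = 0
    idx = b.find(probe)
    while idx != -1:
        k = idx + min_overlap
        if k > limit:
            break
        if k > best and a[-k:] == b[:k]:
            best = k
        idx = b.find(probe, idx + 1)
    return best


class _Node:
    __slots__ = ("seq", "count", "alive")

    def __init__(self, seq: str, count: int):
        self.seq = seq
        self.count = count
        self.alive = True


def assemble_greedy(reads: Sequence[str], p: AssemblyParams,
                    region: Optional[GenomeInterval] = None) -> list[Contig]:
    """Greedy suffix-prefix OLC assembly of ``reads``.

    Repeatedly merges the pair with the longest exact overlap >=
    ``min_overlap`` (both strands considered; ties resolve to the
    lexicographically smaller merged string), then returns contigs built
    from >= ``min_read_count`` reads, longest first.  Deterministic for
    any input order.
    """
    counts: dict[str, int] = {}
    for r in reads:
        if len(r) >= p.kmer:
            counts[r.upper()] = counts.get(r.upper(), 0) + 1
    nodes = [_Node(seq, counts[seq]) for seq in sorted(counts)]
    n = len(nodes)
    # best[i][j]: (overlap, mode) for the best merge of pair (i, j)
    best: dict[tuple[int, int], tuple[int, int]] = {}

    def pair_best(i: int, j: int) -> tuple[int, int]:
        a, b = nodes[i].seq, nodes[j].seq
        rb = revcomp(b)
        cand = (
            (_best_overlap(a, b, p.min_overlap), 0),   # a -> b
            (_best_overlap(b, a, p.min_overlap), 1),   # b -> a
            (_best_overlap(a, rb, p.min_overlap), 2),  # a -> rc(b)
            (_best_overlap(rb, a, p.min_overlap), 3),  # rc(b) -> a
        )
        return max(cand, key=lambda t: (t[0], -t[1]))

    def merged_seq(i: int, j: int, k: int, mode: int) -> str:
        a, b = nodes[i].seq, nodes[j].seq
        rb = revcomp(b)
        if mode == 0:
            return a + b[k:]
        if mode == 1:
            return b + a[k:]
        if mode == 2:
            return a + rb[k:]
        return rb + a[k:]

    for i in range(n):
        for j in range(i + 1, n):
            ov = pair_best(i, j)
            if ov[0] >= p.min_overlap:
                best[(i, j)] = ov

    while best:
        # pick the pair with the longest overlap; break ties on the
        # lexicographically smaller merged string, then on indices
        top_k = max(v[0] for v in best.values())
        tied = [(ij, v) for ij, v in best.items() if v[0] == top_k]
        tied.sort(key=lambda t: (merged_seq(t[0][0], t[0][1], t[1][0],
                                            t[1][1]), t[0]))
        (i, j), (k, mode) = tied[0]
        new_seq = merged_seq(i, j, k, mode)
        new_count = nodes[i].count + nodes[j].count
        nodes[i].alive = False
        nodes[j].alive = False
        for key in [key for key in best if i in key or j in key]:
            del best[key]
        nodes.append(_Node(new_seq, new_count))
        new_idx = len(nodes) - 1
        for other in range(len(nodes) - 1):
            if nodes[other].alive:
                ov = pair_best(other, new_idx)
                if ov[0] >= p.min_overlap:
                    best[(other, new_idx)] = ov

    contigs = [Contig(seq=nd.seq, region=region, n_reads=nd.count)
               for nd in nodes
               if nd.alive and nd.count >= p.min_read_count
               and len(nd.seq) >= p.kmer]
    contigs.sort(key=lambda c: (-len(c.seq), c.seq))
    return contigs


def write_fastq(reads: Sequence[str], path: str) -> None:
    with open(path, "w") as fh:
        for i, seq in enumerate(reads):
            fh.write(f"@read{i}\n{seq}\n+\n{'I' * len(seq)}\n")


def read_fasta_contigs(path: str, region: Optional[GenomeInterval],
                       n_reads: int) -> list[Contig]:
    contigs: list[Contig] = []
    name, parts = None, []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip()
            if line.startswith(">"):
                if name is not None and parts:
                    contigs.append(Contig("".join(parts), region, n_reads))
                name, parts = line[1:], []
            elif line:
                parts.append(line.upper())
    if name is not None and parts:
        contigs.append(Contig("".join(parts), region, n_reads))
    contigs.sort(key=lambda c: (-len(c.seq), c.seq))
    return contigs


def run_external_assembler(reads: Sequence[str], workdir: str,
                           adapter: str, p: AssemblyParams,
                           region: Optional[GenomeInterval] = None,
                           ) -> list[Contig]:
    """Run an external assembler through a command-template adapter.

    ``adapter`` is a shell template with ``{reads}`` and ``{out}``
    placeholders (FASTQ in, FASTA out).  Any failure — nonzero exit,
    missing or empty output — falls back to the greedy assembler with a
    logged warning.
    """
    os.makedirs(workdir, exist_ok=True)
    reads_path = os.path.join(workdir, "reads.fastq")
    out_path = os.path.join(workdir, "contigs.fasta")
    write_fastq(reads, reads_path)
    cmd = adapter.format(reads=reads_path, out=out_path)
    try:
        proc = subprocess.run(cmd, shell=True, capture_output=True, text=True)
        if proc.returncode != 0:
            raise RuntimeError(f"exit {proc.returncode}: {proc.stderr[:200]}")
        contigs = read_fasta_contigs(out_path, region, n_reads=len(reads))
        if not contigs:
            raise RuntimeError("no contigs produced")
        return contigs
    except Exception as exc:
        log.warning("external assembler failed (%s); using greedy fallback",
                    exc)
        return assemble_greedy(reads, p, region)
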