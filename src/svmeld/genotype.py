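"""Coverage-based genotyping of structural variants.

Deletions and duplications are genotyped from the ratio of read depth
inside the event to the depth in the flanks (a het deletion halves the
inside depth, a hom deletion empties it; a tandem duplication raises it
to ~1.5x / ~2x).  Insertions are genotyped from the fraction of read
ends at the junction that support the inserted allele (clipped at the
junction) versus reads spanning the junction on the reference allele.
Inversions are copy-neutral, so depth is uninformative; the fraction of
orientation-discordant pairs at the breakpoints is used instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pysam

from .model import GenomeInterval, SVCall


@dataclass(frozen=True)
class GenotypeParams:
    flank: int = 1000
    het_low: float = 0.2     # depth-ratio bands for DEL
    het_high: float = 0.8
    min_flank_depth: float = 5.0
    ins_alt_frac_het: float = 0.2
    ins_alt_frac_hom: float = 0.8
    dup_het_low: float = 1.25  # depth-ratio bands for DUP (ideal 1.5 / 2.0)
    dup_hom_low: float = 1.75
    min_clip_len: int = 20
    wiggle: int = 100

    def __post_init__(self) -> None:
        if not (0 < self.het_low < self.het_high < 1):
            raise ValueError("require 0 < het_low < het_high < 1")
        if not (0 < self.ins_alt_frac_het < self.ins_alt_frac_hom < 1):
            raise ValueError("require 0 < het < hom insertion fractions")


def _mean_depth(bam: pysam.AlignmentFile, chrom: str, start: int,
                end: int) -> float:
    start = max(0, start)
    end = min(end, bam.get_reference_length(chrom))
    if end <= start:
        return 0.0
    cov = bam.count_coverage(chrom, start, end, quality_threshold=0)
    return float(np.asarray(cov).sum() / (end - start))


def _subtract(intervals: list[tuple[int, int]],
              exclude: Sequence[GenomeInterval], chrom: str,
              ) -> list[tuple[int, int]]:
    """Remove excluded spans (other SVs) from flank intervals."""
    out = intervals
    for ex in exclude:
        if ex.chrom != chrom:
            continue
        nxt: list[tuple[int, int]] = []
        for s, e in out:
            if ex.end <= s or ex.start >= e:
                nxt.append((s, e))
                continue
            if s < ex.start:
                nxt.append((s, ex.start))
            if ex.end < e:
                nxt.append((ex.end, e))
        out = nxt
    return out


def _flank_depth(bam: pysam.AlignmentFile, sv: SVCall, p: GenotypeParams,
                 exclude: Sequence[GenomeInterval]) -> float:
    chrom_len = bam.get_reference_length(sv.chrom)
    flanks = [(max(0, sv.start - p.flank), sv.start),
              (sv.end, min(chrom_len, sv.end + p.flank))]
    flanks = [(s, e) for s, e in flanks if e > s]
    flanks = _subtract(flanks, [ex for ex in exclude
                                if not (ex.start == sv.start
                                        and ex.end == sv.end)], sv.chrom)
    total_bp = sum(e - s for s, e in flanks)
    if total_bp == 0:
        return 0.0
    total = sum(_mean_depth(bam, sv.chrom, s, e) * (e - s) for s, e in flanks)
    return total / total_bp


def _depth_ratio_genotype(ratio: float, p: GenotypeParams) -> str:
    if ratio < p.het_low:
        return "hom_alt"
    if ratio <= p.het_high:
        return "het"
    return "hom_ref"


def genotype_del(bam: pysam.AlignmentFile, sv: SVCall, p: GenotypeParams,
                 exclude: Sequence[GenomeInterval] = ()) -> str:
    """Deletion zygosity from inside/flank depth ratio."""
    flank_depth = _flank_depth(bam, sv, p, exclude)
    if flank_depth < p.min_flank_depth:
        return "unknown"
    inside = _mean_depth(bam, sv.chrom, sv.start, sv.end)
    return _depth_ratio_genotype(inside / flank_depth, p)


def genotype_dup(bam: pysam.AlignmentFile, sv: SVCall, p: GenotypeParams,
                 exclude: Sequence[GenomeInterval] = ()) -> str:
    """Tandem-duplication zygosity from inside/flank depth ratio."""
    flank_depth = _flank_depth(bam, sv, p, exclude)
    if flank_depth < p.min_flank_depth:
        return "unknown"
    ratio = _mean_depth(bam, sv.chrom, sv.start, sv.end) / flank_depth
    if ratio >= p.dup_hom_low:
        return "hom_alt"
    if ratio >= p.dup_het_low:
        return "het"
    return "hom_ref"


def genotype_ins(bam: pysam.AlignmentFile, sv: SVCall,
                 p: GenotypeParams) -> str:
    """Insertion zygosity from the clipped fraction of junction reads.

    Numerator: reads clipped (>= ``min_clip_len``) within ``wiggle`` of
    the locus.  Denominator adds reads spanning the locus with >= 20 bp
    of aligned sequence on both sides (reference-allele evidence).
    """
    locus = sv.start
    chrom_len = bam.get_reference_length(sv.chrom)
    margin = 20
    alt = 0
    ref_span = 0
    for read in bam.fetch(sv.chrom, max(0, locus - p.wiggle),
                          min(chrom_len, locus + p.wiggle + 1)):
        if (read.is_unmapped or read.is_secondary or read.is_supplementary
                or read.is_duplicate):
            continue
        cig = read.cigartuples
        if not cig:
            continue
        clipped_here = False
        if cig[0][0] in (4, 5) and cig[0][1] >= p.min_clip_len \
                and abs(read.reference_start - locus) <= p.wiggle:
            clipped_here = True
        if cig[-1][0] in (4, 5) and cig[-1][1] >= p.min_clip_len \
                and abs(read.reference_end - locus) <= p.wiggle:
            clipped_here = True
        if clipped_here:
            alt += 1
        elif (read.reference_start <= locus - margin
              and read.reference_end >= locus + margin):
            ref_span += 1
    denom = alt + ref_span
    if denom < p.min_flank_depth:
        return "unknown"
    frac = alt / denom
    if frac > p.ins_alt_frac_hom:
        return "hom_alt"
    if frac >= p.ins_alt_frac_het:
        return "het"
    return "hom_ref"


def genotype_inv(bam: pysam.AlignmentFile, sv: SVCall,
                 p: GenotypeParams) -> str:
    """Inversion zygosity from orientation-discordant pair fraction.

    Pairs bridging an inversion breakpoint align FF/RR instead of FR; a
    het inversion discords about half the bridging pairs, a hom one all
    of them.
    """
    chrom_len = bam.get_reference_length(sv.chrom)
    window = 500
    discordant = 0
    total = 0
    for bp in (sv.start, sv.end):
        for read in bam.fetch(sv.chrom, max(0, bp - window),
                              min(chrom_len, bp + window)):
            if (read.is_unmapped or read.is_secondary or read.is_supplementary
                    or read.is_duplicate or not read.is_paired
                    or read.mate_is_unmapped
                    or read.next_reference_id != read.reference_id
                    or not read.is_read1):
                continue
            lo = min(read.reference_start, read.next_reference_start)
            hi = max(read.reference_end or read.reference_start,
                     read.next_reference_start)
            if not (lo <= bp <= hi):
                continue
            total += 1
            if read.is_reverse == read.mate_is_reverse:
                discordant += 1
    if total < p.min_flank_depth:
        return "unknown"
    frac = discordant / total
    if frac > p.ins_alt_frac_hom:
        return "hom_alt"
    if frac >= p.ins_alt_frac_het:
        return "het"
    return "hom_ref"


def genotype_call(bam: pysam.AlignmentFile, sv: SVCall, p: GenotypeParams,
                  exclude: Sequence[GenomeInterval] = ()) -> str:
    if sv.sv_type == "DEL":
        return genotype_del(bam, sv, p, exclude)
    if sv.sv_type == "DUP":
        return genotype_dup(bam, sv, p, exclude)
    if sv.sv_type == "INS":
        return genotype_ins(bam, sv, p)
    if sv.sv_type == "INV":
        return genotype_inv(bam, sv, p)
    return "unknown"
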