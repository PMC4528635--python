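"""Candidate insertion loci from soft-clipped read alignments.

Reads that run off the edge of an insertion are aligned with their
flank-matching part only; the inserted sequence shows up as a terminal
soft-clip (CIGAR ``S``).  Reads entering the insertion from the left
clip on their right end, reads leaving it clip on their left end, and
both clip positions pile up at the junction.  Clustering same-orientation
clip positions and pairing right-clip with left-clip pileups therefore
yields candidate insertion loci, which downstream local assembly and
split alignment either confirm or reject.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Optional

import pysam

from .model import GenomeInterval

LEFT_CLIP = "left_clip"
RIGHT_CLIP = "right_clip"

_SOFT = 4  # CIGAR op codes
_HARD = 5


@dataclass(frozen=True)
class SoftClipParams:
    min_clip_len: int = 20
    min_mapq: int = 5
    min_support: int = 2
    merge_distance: int = 100
    pad: int = 500
    count_hard_clips: bool = True  # some aligners hard-clip supplementary pieces
    max_candidates: Optional[int] = None  # per-chrom cap, best-supported first

    def __post_init__(self) -> None:
        if self.min_support < 1:
            raise ValueError("min_support must be >= 1")
        if min(self.min_clip_len, self.min_mapq, self.merge_distance,
               self.pad) < 0:
            raise ValueError("parameters must be >= 0")


@dataclass(frozen=True)
class ClipEvent:
    chrom: str
    position: int
    orientation: str  # LEFT_CLIP / RIGHT_CLIP
    clip_length: int


@dataclass
class SoftClipCluster:
    chrom: str
    positions: list[int]
    orientation: str
    locus: GenomeInterval  # merged span padded by `pad`

    @property
    def support(self) -> int:
        return len(self.positions)

    @property
    def center(self) -> int:
        mid = sorted(self.positions)
        return mid[(len(mid) - 1) // 2]


@dataclass
class InsertionCandidate:
    """A candidate insertion locus with its supporting clip evidence."""

    locus: GenomeInterval  # 1 bp junction locus
    support: int
    paired: bool  # right-clip + left-clip pileups flank the junction


def extract_softclips(bam: pysam.AlignmentFile, p: SoftClipParams,
                      chrom: Optional[str] = None) -> Iterator[ClipEvent]:
    """Stream clip events from primary alignments, sorted by position.

    One event per alignment end whose CIGAR starts (left clip, at the
    alignment start) or ends (right clip, at the alignment end) with a
    soft clip of length >= ``min_clip_len``.  Secondary, supplementary
    and duplicate-flagged reads are excluded, as are MAPQ < ``min_mapq``.
    """
    ops = {_SOFT, _HARD} if p.count_hard_clips else {_SOFT}
    reads = bam.fetch(chrom) if chrom is not None else bam.fetch()
    for read in reads:
        if (read.is_unmapped or read.is_secondary or read.is_supplementary
                or read.is_duplicate or read.mapping_quality < p.min_mapq):
            continue
        cig = read.cigartuples
        if not cig:
            continue
        if cig[0][0] in ops and cig[0][1] >= p.min_clip_len:
            yield ClipEvent(read.reference_name, read.reference_start,
                            LEFT_CLIP, cig[0][1])
        if cig[-1][0] in ops and cig[-1][1] >= p.min_clip_len:
            yield ClipEvent(read.reference_name, read.reference_end,
                            RIGHT_CLIP, cig[-1][1])


def cluster_softclips(events: Iterable[ClipEvent], p: SoftClipParams,
                      chrom_lengths: Optional[dict[str, int]] = None,
                      ) -> list[SoftClipCluster]:
    """Chain same-chrom same-orientation clip positions into pileups.

    Successive positions <= ``merge_distance`` apart join the same chain
    (transitive, so a long jittery pileup stays together); chains with
    support < ``min_support`` are dropped.
    """
    by_key: dict[tuple[str, str], list[int]] = {}
    for ev in events:
        by_key.setdefault((ev.chrom, ev.orientation), []).append(ev.position)
    clusters: list[SoftClipCluster] = []
    for (chrom, orientation) in sorted(by_key):
        positions = sorted(by_key[(chrom, orientation)])
        chain: list[int] = []
        for pos in positions + [None]:  # type: ignore[list-item]
            if chain and (pos is None or pos - chain[-1] > p.merge_distance):
                if len(chain) >= p.min_support:
                    clusters.append(_make_cluster(chrom, chain, orientation,
                                                  p, chrom_lengths))
                chain = []
            if pos is not None:
                chain.append(pos)
    clusters.sort(key=lambda c: (c.chrom, c.locus.start, c.orientation))
    return clusters


def _make_cluster(chrom: str, chain: list[int], orientation: str,
                  p: SoftClipParams,
                  chrom_lengths: Optional[dict[str, int]]) -> SoftClipCluster:
    lo, hi = chain[0], chain[-1]
    start = max(0, lo - p.pad)
    end = hi + p.pad
    if chrom_lengths and chrom in chrom_lengths:
        end = min(end, chrom_lengths[chrom])
    return SoftClipCluster(chrom=chrom, positions=list(chain),
                           orientation=orientation,
                           locus=GenomeInterval(chrom, start, end))


def pair_clusters(clusters: list[SoftClipCluster],
                  p: SoftClipParams) -> list[InsertionCandidate]:
    """Pair right-clip pileups with nearby left-clip pileups into loci.

    A right-clip cluster within ``merge_distance`` of a left-clip cluster
    marks a canonical insertion signature; the candidate locus is the
    midpoint of the two centers.  Unpaired clusters still emit a
    (lower-confidence) locus at their own center.  Candidates closer than
    ``merge_distance`` are deduplicated (supports summed).
    """
    by_chrom: dict[str, dict[str, list[SoftClipCluster]]] = {}
    for c in clusters:
        by_chrom.setdefault(c.chrom, {LEFT_CLIP: [], RIGHT_CLIP: []})[
            c.orientation].append(c)
    candidates: list[InsertionCandidate] = []
    for chrom in sorted(by_chrom):
        rights = sorted(by_chrom[chrom][RIGHT_CLIP], key=lambda c: c.center)
        lefts = sorted(by_chrom[chrom][LEFT_CLIP], key=lambda c: c.center)
        used_left: set[int] = set()
        for r in rights:
            best = None
            for li, l in enumerate(lefts):
                if li in used_left:
                    continue
                d = abs(l.center - r.center)
                if d <= p.merge_distance and (best is None or d < best[0]):
                    best = (d, li)
            if best is not None:
                li = best[1]
                used_left.add(li)
                l = lefts[li]
                mid = (r.center + l.center) // 2
                candidates.append(InsertionCandidate(
                    locus=GenomeInterval(chrom, mid, mid + 1),
                    support=r.support + l.support, paired=True))
            else:
                candidates.append(InsertionCandidate(
                    locus=GenomeInterval(chrom, r.center, r.center + 1),
                    support=r.support, paired=False))
        for li, l in enumerate(lefts):
            if li not in used_left:
                candidates.append(InsertionCandidate(
                    locus=GenomeInterval(chrom, l.center, l.center + 1),
                    support=l.support, paired=False))
    candidates.sort(key=lambda c: (c.locus.chrom, c.locus.start))
    # deduplicate nearby candidates
    merged: list[InsertionCandidate] = []
    for cand in candidates:
        if (merged and merged[-1].locus.chrom == cand.locus.chrom
                and cand.locus.start - merged[-1].locus.start <= p.merge_distance):
            prev = merged[-1]
            prev.support += cand.support
            prev.paired = prev.paired or cand.paired
        else:
            merged.append(cand)
    if p.max_candidates is not None and len(merged) > p.max_candidates:
        keep = sorted(merged, key=lambda c: (-c.support, c.locus.chrom,
                                             c.locus.start))
        merged = sorted(keep[:p.max_candidates],
                        key=lambda c: (c.locus.chrom, c.locus.start))
    return merged
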