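"""Split alignment of an assembled contig against a reference window.

The breakpoint-resolution model: a contig that spans a simple SV aligns
to the reference as two anchors separated by exactly one excision — a
skipped reference segment (deletion) or a skipped contig segment
(insertion).  We compute a forward local-alignment matrix ``F`` (best
alignment *ending* at each cell) and a reverse matrix ``R`` (best
alignment *starting* at each cell) with affine gaps, then maximize
``F[i, j] + R[i', j']`` over all ``i <= i', j <= j'``.  The maximizing
quadruple gives the two anchors and hence the breakpoints, in O(nm).

Ties resolve to the smallest ``(j, i)``, which left-aligns breakpoints
in repeat/homopolymer runs (the VCF left-alignment convention).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .model import GenomeInterval, SVCluster, UNKNOWN_LENGTH

#: implied excisions shorter than this are treated as alignment noise
#: (indel-caller territory); the pipeline-level 100 bp size filter is
#: applied separately at output.
MIN_IMPLIED_SV = 25

_MAX_CELLS = 400_000_000  # DP matrix guard (int32 cells)


@dataclass(frozen=True)
class ScoringScheme:
    """Alignment scores; defaults strongly prefer anchored exact matches."""

    match: int = 1
    mismatch: int = -4
    gap_open: int = -6
    gap_extend: int = -1

    def __post_init__(self) -> None:
        if self.match <= 0:
            raise ValueError("match score must be > 0")
        if max(self.mismatch, self.gap_open, self.gap_extend) > 0:
            raise ValueError("penalties must be <= 0")


@dataclass
class SplitAlignment:
    """Two-piece alignment result (contig vs reference window).

    ``ref_left_end``/``ctg_left_end`` are the (exclusive) end coordinates
    of the left anchor; ``ref_right_start``/``ctg_right_start`` the start
    of the right anchor.  The excisions ``ref_right_start - ref_left_end``
    (reference) and ``ctg_right_start - ctg_left_end`` (contig) imply a
    DEL or an INS respectively when exactly one exceeds the minimum size.
    """

    ref_left_end: int
    ref_right_start: int
    ctg_left_end: int
    ctg_right_start: int
    score: int
    left_score: int
    right_score: int
    implied: Optional[str]  # "DEL", "INS" or None
    implied_length: int

    @property
    def ref_excision(self) -> int:
        return self.ref_right_start - self.ref_left_end

    @property
    def ctg_excision(self) -> int:
        return self.ctg_right_start - self.ctg_left_end


def sw_matrix(query: str, ref: str, s: ScoringScheme) -> np.ndarray:
    """Smith–Waterman score matrix with affine gaps.

    ``H[i, j]`` is the best score of a local alignment ending exactly at
    ``query[i-1]``/``ref[j-1]`` (0 allows the empty alignment).  Gap of
    length L costs ``gap_open + L * gap_extend``.  Row-wise vectorized:
    the within-row (horizontal) affine gap is a prefix-maximum scan,
    which is exact because re-opening a gap inside a gap never pays.
    """
    n, m = len(query), len(ref)
    if (n + 1) * (m + 1) > _MAX_CELLS:
        raise ValueError(
            f"window too large for split alignment ({n} x {m}); "
            "shrink the region padding")
    q = np.frombuffer(query.upper().encode(), dtype=np.uint8)
    r = np.frombuffer(ref.upper().encode(), dtype=np.uint8)
    go_ge = s.gap_open + s.gap_extend
    ge = s.gap_extend
    H = np.zeros((n + 1, m + 1), dtype=np.int32)
    NEG = -(1 << 30)
    jidx = np.arange(m + 1, dtype=np.int64)
    Fv = np.full(m + 1, NEG, dtype=np.int64)  # vertical-gap state
    Hprev = np.zeros(m + 1, dtype=np.int64)
    sub_match = np.int64(s.match)
    sub_mis = np.int64(s.mismatch)
    for i in range(1, n + 1):
        sub = np.where(r == q[i - 1], sub_match, sub_mis)
        diag = Hprev[:-1] + sub
        Fv = np.maximum(Hprev + go_ge, Fv + ge)
        Hno = np.empty(m + 1, dtype=np.int64)
        Hno[0] = 0
        np.maximum(diag, Fv[1:], out=Hno[1:])
        np.maximum(Hno, 0, out=Hno)
        # horizontal affine gap via prefix max of Hno[k] - ge*k
        t = Hno - ge * jidx
        pref = np.empty(m + 1, dtype=np.int64)
        pref[0] = NEG
        np.maximum.accumulate(t[:-1], out=pref[1:])
        E = pref + ge * jidx + go_ge
        Hrow = np.maximum(Hno, E)
        H[i] = Hrow
        Hprev = Hrow
    return H


def split_align(contig: str, ref_window: str, s: ScoringScheme = ScoringScheme(),
                min_sv_size: int = MIN_IMPLIED_SV) -> SplitAlignment:
    """Optimal one-excision split alignment of ``contig`` to ``ref_window``."""
    if not contig or not ref_window:
        raise ValueError("sequences must be nonempty")
    n, m = len(contig), len(ref_window)
    F = sw_matrix(contig, ref_window, s)
    Hr = sw_matrix(contig[::-1], ref_window[::-1], s)
    R = Hr[::-1, ::-1]  # R[i', j'] = best alignment starting at (i', j')
    G = np.maximum.accumulate(np.maximum.accumulate(F, axis=0), axis=1)
    total = G.astype(np.int64) + R
    best = int(total.max())
    # smallest (j', i') among maxima, then smallest (j, i) in the prefix box
    cand = np.argwhere(total == best)
    order = np.lexsort((cand[:, 0], cand[:, 1]))
    ip, jp = (int(v) for v in cand[order[0]])
    box = F[: ip + 1, : jp + 1]
    left_best = int(G[ip, jp])
    lc = np.argwhere(box == left_best)
    lorder = np.lexsort((lc[:, 0], lc[:, 1]))
    i, j = (int(v) for v in lc[lorder[0]])
    left_score = int(F[i, j])
    right_score = int(R[ip, jp])
    ref_exc = jp - j
    ctg_exc = ip - i
    implied: Optional[str] = None
    implied_length = 0
    if ref_exc >= min_sv_size and ctg_exc < min_sv_size:
        implied, implied_length = "DEL", ref_exc
    elif ctg_exc >= min_sv_size and ref_exc < min_sv_size:
        implied, implied_length = "INS", ctg_exc
    return SplitAlignment(ref_left_end=j, ref_right_start=jp,
                          ctg_left_end=i, ctg_right_start=ip,
                          score=best, left_score=left_score,
                          right_score=right_score, implied=implied,
                          implied_length=implied_length)


def best_local(contig: str, ref_window: str, s: ScoringScheme,
               ) -> tuple[int, int, int]:
    """Best single local alignment: (score, ctg_end, ref_end)."""
    F = sw_matrix(contig, ref_window, s)
    flat = int(np.argmax(F))
    i, j = divmod(flat, F.shape[1])
    return int(F[i, j]), i, j


# ---------------------------------------------------------------------------
# Cluster refinement


def refine_cluster(cluster: SVCluster, contigs, ref_fetch,
                   s: ScoringScheme = ScoringScheme(), *,
                   region_pad: int = 500,
                   min_sv_size: int = MIN_IMPLIED_SV,
                   min_anchor_score: int = 40,
                   chrom_length: Optional[int] = None) -> SVCluster:
    """Refine a DEL or INS cluster's breakpoints from assembled contigs.

    The best-scoring split alignment whose implied SV matches the cluster
    type replaces the consensus breakpoints and marks the cluster
    assembly-confirmed; with no matching alignment the cluster keeps its
    merged breakpoints and stays unconfirmed.  ``ref_fetch(chrom, start,
    end)`` must return reference sequence (0-based half-open).
    """
    if cluster.consensus is None or not contigs:
        return cluster
    # the window must cover the true junctions, which can sit anywhere in
    # the members' breakpoint spread when only fuzzy methods contributed
    lo = min([cluster.consensus.start] + [m.start for m in cluster.members])
    hi = max([cluster.consensus.end] + [m.end for m in cluster.members])
    window = GenomeInterval(cluster.consensus.chrom, lo, hi).padded(
        region_pad, chrom_length)
    ref_seq = ref_fetch(window.chrom, window.start, window.end)
    if not ref_seq:
        return cluster
    from .assembly import revcomp

    best_sa: Optional[SplitAlignment] = None
    for contig in contigs:
        for seq in (contig.seq, revcomp(contig.seq)):
            if not seq:
                continue
            sa = split_align(seq, ref_seq, s, min_sv_size)
            if sa.implied != cluster.sv_type:
                continue
            if min(sa.left_score, sa.right_score) < min_anchor_score:
                continue
            if best_sa is None or sa.score > best_sa.score:
                best_sa = sa
    if best_sa is None:
        return cluster
    if cluster.sv_type == "DEL":
        cluster.consensus = GenomeInterval(
            window.chrom, window.start + best_sa.ref_left_end,
            window.start + best_sa.ref_right_start)
        cluster.sv_length = cluster.consensus.length()
    else:  # INS
        pos = window.start + best_sa.ref_left_end
        cluster.consensus = GenomeInterval(window.chrom, pos, pos + 1)
        cluster.sv_length = best_sa.implied_length
    cluster.assembly_confirmed = True
    cluster.refined = True
    return cluster


def confirm_insertion(candidate_pos: int, chrom: str, contigs, ref_fetch,
                      s: ScoringScheme = ScoringScheme(), *,
                      window_pad: int = 1000,
                      tolerance: int = 100,
                      min_sv_size: int = MIN_IMPLIED_SV,
                      min_anchor_score: int = 30,
                      novelty_window: int = 12000,
                      novelty_probe: int = 300,
                      novelty_frac: float = 0.6,
                      chrom_length: Optional[int] = None,
                      ) -> Optional[tuple[int, Optional[int]]]:
    """Confirm a candidate insertion locus from assembled contigs.

    Returns ``(refined_position, length)`` on success, ``length`` being
    ``None`` when the insertion is too long to assemble through, or
    ``None`` when no contig supports an insertion at the locus.

    Two routes, tried in order:

    1. *Two-anchor*: a split alignment implying an INS within
       ``tolerance`` of the candidate gives position and length.
    2. *One-sided*: a contig whose alignment ends (or starts) at the
       junction and then runs >= ``min_sv_size`` bases past it.  The
       overhang must be genuinely novel — a probe adjacent to the
       junction is realigned (both strands) against a wide reference
       neighborhood, and any strong hit rejects the contig.  This is
       what separates real insertions from the clipped-read pileups that
       tandem-duplication and inversion junctions also produce.
    """
    from .assembly import revcomp

    wstart = max(0, candidate_pos - window_pad)
    wend = candidate_pos + window_pad
    if chrom_length is not None:
        wend = min(wend, chrom_length)
    ref_seq = ref_fetch(chrom, wstart, wend)
    if not ref_seq or not contigs:
        return None

    # route 1: two-anchor split alignment
    best: Optional[tuple[int, int, int]] = None  # (score, pos, length)
    for contig in contigs:
        for seq in (contig.seq, revcomp(contig.seq)):
            sa = split_align(seq, ref_seq, s, min_sv_size)
            if sa.implied != "INS":
                continue
            pos = wstart + sa.ref_left_end
            if abs(pos - candidate_pos) > tolerance:
                continue
            if min(sa.left_score, sa.right_score) < min_anchor_score:
                continue
            if best is None or sa.score > best[0]:
                best = (sa.score, pos, sa.implied_length)
    if best is not None:
        return best[1], best[2]

    # route 2: one-sided novel overhang
    nov_start = max(0, candidate_pos - novelty_window)
    nov_end = candidate_pos + novelty_window
    if chrom_length is not None:
        nov_end = min(nov_end, chrom_length)
    neighborhood: Optional[str] = None
    one_sided: Optional[tuple[int, int]] = None  # (anchor_score, pos)
    for contig in contigs:
        for seq in (contig.seq, revcomp(contig.seq)):
            n = len(seq)
            # anchor on the left, overhang running right past the junction
            score, i, j = best_local(seq, ref_seq, s)
            if (score >= min_anchor_score and n - i >= min_sv_size
                    and abs(wstart + j - candidate_pos) <= tolerance):
                probe = seq[i:i + novelty_probe]
                if neighborhood is None:
                    neighborhood = ref_fetch(chrom, nov_start, nov_end)
                if _is_novel(probe, neighborhood, s, novelty_frac):
                    if one_sided is None or score > one_sided[0]:
                        one_sided = (score, wstart + j)
            # anchor on the right, overhang running left past the junction
            score, ir, jr = best_local(seq[::-1], ref_seq[::-1], s)
            i0, j0 = n - ir, len(ref_seq) - jr
            if (score >= min_anchor_score and i0 >= min_sv_size
                    and abs(wstart + j0 - candidate_pos) <= tolerance):
                probe = seq[max(0, i0 - novelty_probe):i0]
                if neighborhood is None:
                    neighborhood = ref_fetch(chrom, nov_start, nov_end)
                if _is_novel(probe, neighborhood, s, novelty_frac):
                    if one_sided is None or score > one_sided[0]:
                        one_sided = (score, wstart + j0)
    if one_sided is not None:
        return one_sided[1], UNKNOWN_LENGTH
    return None


def _is_novel(probe: str, neighborhood: str, s: ScoringScheme,
              novelty_frac: float) -> bool:
    """True when ``probe`` has no strong alignment in the neighborhood."""
    if len(probe) < MIN_IMPLIED_SV:
        return False
    from .assembly import revcomp

    threshold = novelty_frac * s.match * len(probe)
    for q in (probe, revcomp(probe)):
        score, _, _ = best_local(q, neighborhood, s)
        if score >= threshold:
            return False
    return True
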