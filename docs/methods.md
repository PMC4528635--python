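# Methods

This note documents the models, algorithms and numerical choices behind
`svmeld`, what the synthetic-data generator does and does not emulate,
and the known limitations.

## Coordinates and records

All intervals are 0-based half-open `[start, end)`. Only the VCF
boundary converts: POS is the 1-based first affected base, END the
half-open end (so a deletion at POS=1001 with END=2000 is `[1000,
2000)`, length 1000). An insertion is a 1 bp junction locus `[p, p+1)`
(POS = p+1); its length is carried separately and may be the unknown
sentinel `None` — deliberately not 0, which is a legal degenerate
length. Long insertions cannot be assembled through with short reads,
so the locus, not the length, is the reliable quantity; unknown-length
insertions are flagged `INSLEN_UNKNOWN` and written with `SVLEN=0`.

VCF reading goes through `pysam.VariantFile`. Writing is deterministic
plain text with the same INFO vocabulary: htslib ≥ 1.21 recomputes a
symbolic record's END from SVLEN under the VCF 4.4 padding-base
convention, one base off the convention above, so the writer keeps
byte-level control and its output is validated in tests by re-parsing
through pysam and `bcftools`. When both END and SVLEN are present on
input, SVLEN wins (END as stored by htslib is then unreliable).
Chromosome names match by exact string equality; no "chr"-prefix
normalization is attempted, because silent renaming is a classic
wrong-genome bug.

## Merging model

Two calls are the *same event* iff same type, same chromosome, and
either reciprocal overlap `min(|a∩b|/|a|, |a∩b|/|b|) ≥ 0.5` or both
breakpoint deltas ≤ 100 bp (wiggle); insertions compare by locus
distance ≤ wiggle only. The merge threshold 0.5 is deliberately looser
than the 0.9 used for benchmark truth-matching: merging must absorb
method-specific breakpoint error (read-pair ±150 bp, depth ±300 bp),
while evaluation is strict. Clustering is single-linkage (transitive
closure), the simplest deterministic rule; intra-tool collapse iterates
to a fixpoint because collapsing members to representatives can move
two previously-unlinked representatives into linkage range —
idempotence then holds by construction.

Consensus breakpoints come only from the most precise method tier
present, ranked `junction_mapping > split_read > softclip_assembly >
read_pair > depth_of_coverage` (unknown methods rank last), as the
support-weighted coordinate-wise median with ties to the lower
coordinate. Median (not mean) keeps one outlier caller from dragging
the consensus. DUP and INV cluster under the same rules as DEL; types
never merge across. All outputs are sorted `(chrom, start, end, type,
tool)`, making the cluster set invariant under input permutation.

After assembly refinement (below) a second, identical single-linkage
pass deduplicates final clusters: refinement standardizes breakpoints,
which can reveal that a precise split-read cluster and a fuzzy
read-pair cluster that failed to link pre-refinement are one event.
Assembly-confirmed breakpoints win inside a merged group.

## Soft-clip insertion candidates

Reads running off an insertion edge align with their flank part only;
the inserted part is a terminal soft clip. Clips of ≥ 20 bp from
primary alignments with MAPQ ≥ 5 are collected (hard clips counted too,
since some aligners hard-clip supplementary pieces; disable with
`count_hard_clips=False`), chained transitively at ≤ 100 bp spacing,
and pileups with < 2 reads dropped. A right-clip pileup paired with a
left-clip pileup within 100 bp is the canonical junction signature; the
candidate locus is their midpoint. Unpaired pileups still emit
(lower-confidence) candidates. Candidates within the wiggle of a
detected non-insertion cluster breakpoint are suppressed: tandem-
duplication and inversion junctions produce the same clip pileups, and
those candidates are explained by the already-detected event.

All five thresholds are package choices (exposed as `SoftClipParams`);
they are conservative for ≥ 20× data, where a real junction
contributes ~10+ clipped reads. An optional per-chromosome candidate
cap (`max_candidates`, best-supported first) exists for pathological
inputs and defaults to unlimited.

## Local assembly

The built-in assembler is greedy overlap-layout consensus: repeatedly
merge the pair of sequences with the longest *exact* suffix–prefix
overlap ≥ 50 bp, considering both strands, ties broken by the
lexicographically smaller merged string; contigs need ≥ 4 supporting
reads. Exact overlaps are intentional: at the 0.1% error rate of the
target data, erroneous reads simply fail to merge and fall below the
read-count floor, acting as a free error filter. The assembler is
deterministic for any input order, which the refinement stage depends
on. A command-template adapter (`{reads}`/`{out}` placeholders, FASTQ
in / FASTA out) plugs in an external assembler for real data; any
failure falls back to the greedy assembler with a logged warning.

Read gathering for refinement prioritizes SV-informative reads —
terminal clips ≥ 20 bp, deletion CIGAR gaps ≥ 25 bp, discordant or
broken pairs, unmapped reads placed at their mates — before ordinary
reads when filling the `max_reads` budget (150 in the pipeline; the
assembler is quadratic in read count and 150 reads cover a breakpoint
window many times at 50×). Uniform downsampling would starve the
junction-spanning minority that breakpoint contigs are built from.
Downsampling uses a fixed documented seed (53), so identical inputs
give identical contigs.

## Split-alignment breakpoint resolution

A contig spanning a simple SV aligns to the reference window as two
anchors separated by exactly one excision. Let `F[i,j]` be the best
local-alignment score ending at contig position i / window position j
and `R[i',j']` the best score starting at (i',j') (Smith–Waterman with
affine gaps: match +1, mismatch −4, gap open −6, extend −1 — chosen to
strongly prefer anchored exact matches). The optimum of `F[i,j] +
R[i',j']` over `i ≤ i', j ≤ j'` is found in O(nm) via 2-D running
maxima; the maximizing quadruple gives the anchors. The reference
excision `j'−j` implies a deletion, the contig excision `i'−i` an
insertion; excisions < 25 bp are alignment noise (indel-caller
territory — the separate 100 bp pipeline filter governs output), and
if both excisions exceed the floor the contig is ambiguous and
confirms nothing. Ties resolve to the smallest `(j, i)`, which
left-aligns breakpoints in repeats (VCF convention). The row-wise
affine-gap DP uses the prefix-maximum identity for within-row gaps
(exact, because re-opening a gap inside a gap never pays); the
implementation is verified against exhaustive enumeration on 1000
random instances in the test suite.

A refining alignment is accepted when it implies the cluster's own
type and *both* anchor scores are ≥ 40. An earlier relative criterion
(score ≥ 0.9 × the contig-length-derived maximum) was abandoned: a
contig legitimately extending past the DP window cannot reach it, and
those are precisely the contigs of fuzzily-merged read-pair/depth
clusters that need refinement most. Under this scoring, 40 requires
~40 well-matched bases per anchor, far above the empirical chance
score (~15–25) for a random contig in a ≤ 12 kb window. Inversions
and duplications are never split-aligned (one-excision model does not
fit them); they keep their merged breakpoints, and clusters are never
re-typed by assembly evidence — a contig contradicting the cluster
type leaves it unconfirmed.

Insertion confirmation runs two routes. *Two-anchor*: a split
alignment implying INS within 100 bp of the candidate gives position
and length. *One-sided* (long insertions): a contig whose alignment
ends at the junction and continues ≥ 25 bp past it confirms the locus
with unknown length — provided the overhang is genuinely novel. The
novelty check realigns the 300 bp of overhang adjacent to the junction
(both strands) against a ±12 kb reference neighborhood and rejects the
contig on any hit ≥ 0.6 × the perfect score; this is what separates
real inserted sequence from the overhangs at duplication junctions
(which realign upstream) and inversion boundaries (which realign
reverse-complemented). 12 kb covers duplications up to the simulated
maximum with margin.

## Genotyping

Deletions: r = mean depth inside / mean depth in 1 kb flanks (flanks
trimmed of other final SV intervals to avoid biased baselines in
SV-dense regions). r < 0.2 → hom-alt, 0.2–0.8 → het, > 0.8 → hom-ref;
flank depth < 5 → unknown. The bands are symmetric around the ideal
het ratio 0.5. Duplications use the same ratio with bands around the
ideal 1.5/2.0 (het ≥ 1.25, hom ≥ 1.75). Insertions: among read ends at
the junction, the fraction clipped there versus spanning it with ≥ 20
aligned bp both sides; > 0.8 → hom-alt, 0.2–0.8 → het, < 0.2 →
hom-ref. Inversions are copy-neutral, so depth is uninformative; the
fraction of orientation-discordant (FF/RR) pairs bridging a breakpoint
is banded the same way. All thresholds sit in `GenotypeParams`.

## Synthetic data

`simdata` emulates the evaluation protocol at desk scale: a 2 Mb
random diploid genome over 2 chromosomes (uniform base composition),
~60 deletions (100 bp–10 kb, log-uniform) and ~60 insertions (100
bp–5 kb), plus 8 inversions and 8 tandem duplications; half the events
heterozygous; 2×100 bp pairs at 50× total coverage, insert 400 ± 50
bp, 0.1% uniform base error. Events keep ≥ 1 kb spacing. Reads are
emitted directly as an aligned, sorted, indexed BAM with the
alignments a correct aligner would produce, derived from the
haplotype→reference block map: colinear runs become M/D CIGARs
(deletion gaps included when both flanking anchors are ≥ 20 bp),
non-colinear overhangs become soft clips, reads inside inversions map
to the reverse strand, reads wholly inside novel insertions are
unmapped-but-placed at their mate, and pairs bridging events become
discordant in span or orientation. Emitting alignments directly keeps
the clip/discordance signals under exact test control and removes the
aligner from the loop; a FASTQ export exists for users who want a real
aligner.

Mock caller profiles encode the qualitative niches of the four method
families: junction mapping (±2 bp, DEL only, sensitivity 0.6), split
read (±5 bp; DEL 0.90/0.75 by size, small-INS 0.3, INV 0.7, DUP 0.5),
read pair (±150 bp; DEL 0.30 below 300 bp else 0.85, INV 0.75, DUP
0.6, blind to insertions), depth of coverage (±300 bp; blind below 500
bp, DEL 0.8, DUP 0.7, blind to balanced events). Each tool adds
Poisson false calls at 2–5% of its detectable-truth count. Insertion
detection in the evaluation is therefore carried almost entirely by
the soft-clip + assembly path, mirroring the real-data situation the
integrative design targets.

What the generator does *not* emulate — repeats and segmental
duplications, GC/coverage bias, quality-score error profiles,
multi-nucleotide and clustered variation, alignment ambiguity from a
real aligner — bounds what passing tests show: they validate the
integration, refinement and genotyping logic under clean mappability,
not robustness to repeat-rich genomes.

The benchmark matches greedily one-to-one in position order:
DEL/INV/DUP need reciprocal overlap ≥ 0.90 *and* both breakpoints
within 100 bp; insertions match by locus distance only, length
excluded; events < 100 bp are excluded on both sides; unknown-length
insertions are kept. Precision on an empty callset is reported as 0.
Evaluation uses the PASS records — the high-confidence callset is the
product; LowQual records are annotations for downstream users, and are
emitted rather than dropped.

## Problem sizes and determinism

The end-to-end evaluation (2 Mb, 50×, ~1M reads, ~140 SVs) was sized
so the full pipeline plus benchmark completes in ~2 minutes on one
CPU; the test suite's property checks (1000-instance DP oracle,
50-seed assembler reconstruction, ≤ 30-interval clustering closure)
each stay under a minute. Every random draw — genome, reads, mock
callsets, read downsampling — derives from explicit seeds; reruns are
byte-identical (BAMs are written with `--no-PG` so htslib adds no
command-line provenance lines).

## Known limitations

* Inversion and duplication breakpoints are never assembly-refined, so
  their accuracy is bounded by the best input caller; balanced-event
  genotyping relies on orientation discordance alone.
* The one-excision split alignment cannot represent multi-SV contigs;
  such contigs are left unconfirmed rather than mis-refined.
* Insertion lengths beyond ~1.5 kb are usually unknown (one-sided
  confirmation); lengths reported by input tools are recorded but not
  reconciled across tools.
* Genotyping is threshold-based, not likelihood-based; at depths well
  below 20× the unknown rate rises quickly.
* The greedy assembler assumes low error and modest window sizes; for
  real data with higher error, plug in an external assembler through
  the adapter.
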