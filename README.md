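# svmeld

Integrative structural-variant (SV) calling for short-read sequencing.

No single SV detection signal — split reads, discordant read pairs,
depth of coverage, junction mapping — covers all SV types and sizes:
each has a niche where it is sensitive and precise and large blind
spots elsewhere (depth callers cannot see events below a few hundred
bp or balanced events; read-pair callers give ±150 bp breakpoints and
miss insertions almost entirely). `svmeld` melds the callsets of
several such tools into one high-confidence, breakpoint-precise
callset, and adds an insertion-detection path of its own, because
insertions are the weak spot of nearly every individual caller.

The pipeline:

1. **Intra-tool merging** — duplicate calls from the same tool are
   collapsed (single-linkage under "same event": reciprocal overlap
   ≥ 0.5 or both breakpoints within a 100 bp wiggle; insertions by
   locus distance).
2. **Inter-tool merging** — calls are clustered across tools; the
   consensus breakpoints are the coordinate-wise median of the *most
   precise method present* (junction mapping > split read >
   soft-clip/assembly > read pair > depth of coverage), so one precise
   call outvotes several fuzzy ones.
3. **Soft-clip scan** — pileups of soft-clipped alignment ends mark
   candidate insertion loci that no input tool reported.
4. **Local assembly** — reads around every candidate breakpoint
   (junction-spanning, clipped, discordant and one-end-anchored mates
   first) are assembled by a deterministic greedy overlap-layout
   assembler; an adapter contract plugs in an external assembler.
5. **Breakpoint resolution** — each contig is aligned to the reference
   window by a split-alignment dynamic program that allows exactly one
   excision: a skipped reference segment implies a deletion, a skipped
   contig segment an insertion. Confirmed alignments replace the
   merged breakpoints with base-pair-precise ones, left-aligned in
   repeats. For long insertions that cannot be assembled through, a
   one-sided contig overhang — checked to be genuinely novel sequence —
   confirms the locus with unknown length.
6. **Genotyping** — deletion/duplication zygosity from the inside/flank
   depth ratio (het ≈ 0.5, hom ≈ 0 for DEL); insertion zygosity from
   the clipped fraction of junction-spanning read ends; inversions
   from orientation-discordant pairs.
7. **VCF output** — FILTER is `PASS` exactly when ≥ 2 tools agree or
   assembly confirmed the breakpoints; provenance (`SOURCES`,
   `NUM_TOOLS`, `ASSEMBLY_CONFIRMED`) is annotated, and events under
   100 bp are left to indel callers.

A first-class synthetic-data module (`svmeld.simdata`) generates
everything the pipeline consumes — diploid genomes with implanted
DEL/INS/INV/DUP, paired-end reads emitted directly as aligned BAM with
the correct clip/split/discordance signals, mock per-tool callsets
with method-specific jitter and error rates — plus a strict benchmark
(reciprocal overlap ≥ 0.90 **and** breakpoints within 100 bp; insertions
by locus, length ignored; F1 = 2PR/(P+R)).

## Worked example

```
$ python examples/simulate_and_call.py
simulated 24 SVs; reads at 50x -> example_out/reads.bam
  juncmap: 9 calls
  splitread: 15 calls
  readpair: 9 calls
  depthcov: 8 calls
pipeline: 30 records, 21 PASS -> example_out/final.vcf
{
  "DEL": {"sensitivity": 1.0, "precision": 1.0, "f1": 1.0,
          "genotype_accuracy": 1.0, "n_truth": 10, ...},
  "INS": {"sensitivity": 1.0, "precision": 1.0, "f1": 1.0,
          "genotype_accuracy": 1.0, "n_truth": 10, ...},
  ...
}
```

Each mock caller sees only part of the truth (and with its own
breakpoint error — some callsets include false calls), yet the
integrated PASS callset recovers all 10 deletions and all 10
insertions with exact breakpoints and genotypes — the central claim of
the ensemble approach. The two inversions and two duplications in this
small run score 0 at the strict 90%-reciprocal-overlap criterion:
their breakpoints are never assembly-refined, so accuracy is bounded
by the fuzzier input callers. The same flow is available from the shell:

```
svmeld simulate --out sim/ --seed 42
svmeld run --ref sim/ref.fa --bam sim/reads.bam \
    --vcf splitread=sim/splitread.vcf --method splitread=split_read \
    ... --out out/
svmeld benchmark --calls out/final.vcf --truth sim/truth.vcf
```

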