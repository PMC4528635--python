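"""Final annotation and VCF 4.2 emission.

Each final record carries the integrated evidence: SOURCES lists every
contributing ``tool:method:start-end`` triplet, NUM_TOOLS/NUM_METHODS
count the distinct evidence classes, ASSEMBLY_CONFIRMED marks clusters
whose breakpoints were validated by local assembly + split alignment.
FILTER is PASS exactly when the cluster is high-confidence (>= 2 tools,
or assembly-confirmed); LowQual records are emitted, not dropped, so
downstream users choose their own stringency.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import pysam

from .model import SVCall, SVCluster
from .vcfio import _ref_base, format_record, header_lines

#: events smaller than this are left to indel callers
MIN_SV_SIZE_OUT = 100


@dataclass
class FinalRecord:
    cluster: SVCluster
    genotype: str = "unknown"

    @property
    def filter(self) -> str:
        return "PASS" if self.cluster.confidence == "high" else "LowQual"

    @property
    def sv_type(self) -> str:
        return self.cluster.sv_type

    def to_call(self, tool: str = "svmeld") -> SVCall:
        return SVCall(interval=self.cluster.consensus,
                      sv_type=self.cluster.sv_type,
                      sv_length=self.cluster.sv_length,
                      tool=tool, method="merged",
                      genotype=self.genotype,
                      support=self.cluster.support)


def passes_size_filter(record: FinalRecord,
                       min_size: int = MIN_SV_SIZE_OUT) -> bool:
    length = record.cluster.sv_length
    if length is None:
        return record.sv_type == "INS"
    return length >= min_size


def emit_vcf(records: Sequence[FinalRecord], out_path: str,
             contigs: dict[str, int],
             reference: Optional[str] = None,
             sample: str = "SAMPLE") -> str:
    """Write final records as VCF 4.2 with symbolic ALTs.

    Byte-identical for identical inputs; REF bases come from the
    reference when available ('N' otherwise).
    """
    fa = pysam.FastaFile(reference) if reference else None
    try:
        with open(out_path, "w") as out:
            out.write("\n".join(header_lines(contigs, sample)) + "\n")
            for idx, record in enumerate(
                    sorted(records, key=lambda r: r.cluster.sort_key())):
                cluster = record.cluster
                iv = cluster.consensus
                if iv.end > contigs.get(iv.chrom, iv.end):
                    raise ValueError(
                        f"record end {iv} beyond chromosome length")
                sources = ",".join(
                    f"{m.tool}:{m.method}:{m.start}-{m.end}"
                    for m in sorted(cluster.members, key=SVCall.sort_key))
                extra = [f"SOURCES={sources}",
                         f"NUM_TOOLS={len(cluster.tools)}",
                         f"NUM_METHODS={len(cluster.methods)}",
                         f"SUPPORT={cluster.support}"]
                if cluster.assembly_confirmed:
                    extra.append("ASSEMBLY_CONFIRMED")
                out.write(format_record(
                    iv.chrom, iv.start, iv.end, cluster.sv_type,
                    cluster.sv_length, f"svmeld_{cluster.sv_type}_{idx}",
                    _ref_base(fa, iv.chrom, iv.start), record.filter,
                    extra, record.genotype) + "\n")
    finally:
        if fa is not None:
            fa.close()
    return out_path
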