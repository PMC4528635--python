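"""VCF 4.2 and BED readers/writers for SV callsets.

All parsing/writing goes through :mod:`pysam`; this module only converts
between VCF's 1-based coordinates and the package's 0-based half-open
intervals, and maps the package's INFO vocabulary:

``SVTYPE``, ``END``, ``SVLEN`` (signed: negative for DEL), ``SVMETHOD``,
``SUPPORT``, ``SOURCES``, ``NUM_TOOLS``, ``NUM_METHODS``,
``ASSEMBLY_CONFIRMED`` (flag), ``INSLEN_UNKNOWN`` (flag).
"""

from __future__ import annotations

import logging
import os
from typing import Optional, Sequence

import pysam

from .model import SVCall, GenomeInterval, UNKNOWN_LENGTH

log = logging.getLogger(__name__)

_GT_TO_TUPLE = {
    "hom_ref": (0, 0),
    "het": (0, 1),
    "hom_alt": (1, 1),
    "unknown": (None, None),
}
_TUPLE_TO_GT = {v: k for k, v in _GT_TO_TUPLE.items()}

_SYMBOLIC = {"<DEL>": "DEL", "<INS>": "INS", "<INV>": "INV", "<DUP>": "DUP",
             "<DUP:TANDEM>": "DUP"}


def _info_get(rec, key):
    """Like rec.info.get, but tolerant of keys absent from the header
    (pysam raises 'Invalid header' for those)."""
    if key not in rec.info:
        return None
    return rec.info.get(key)


def _record_sv_type(rec: "pysam.VariantRecord") -> Optional[str]:
    svtype = _info_get(rec, "SVTYPE")
    if isinstance(svtype, tuple):
        svtype = svtype[0]
    if svtype in ("DEL", "INS", "INV", "DUP", "DUP:TANDEM"):
        return "DUP" if svtype.startswith("DUP") else svtype
    for alt in rec.alts or ():
        if alt in _SYMBOLIC:
            return _SYMBOLIC[alt]
    # explicit REF/ALT sequences: infer from length difference
    if rec.alts and all(c in "ACGTNacgtn" for c in (rec.ref or "") + rec.alts[0]):
        dlen = len(rec.alts[0]) - len(rec.ref)
        if dlen < 0:
            return "DEL"
        if dlen > 0:
            return "INS"
    return None


def _scalar(value):
    if isinstance(value, (tuple, list)):
        return value[0] if value else None
    return value


def read_tool_vcf(path: str, tool: str, default_method: str = "unknown") -> list[SVCall]:
    """Read one tool's SV callset from a VCF 4.x file.

    1-based POS is converted so a DEL with POS=1001, END=2000 becomes the
    interval [1000, 2000); an INS at POS=500 becomes the locus [499, 500).
    Records without a resolvable type/length are skipped with a logged
    warning.  Missing file or malformed header is fatal.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    calls: list[SVCall] = []
    skipped = 0
    with pysam.VariantFile(path) as vf:
        for rec in vf:
            try:
                call = _parse_record(rec, tool, default_method)
            except Exception as exc:  # per-record failure: skip + count
                log.warning("skipping %s:%s (%s)", rec.chrom, rec.pos, exc)
                skipped += 1
                continue
            if call is None:
                log.warning("skipping %s:%s: no resolvable SVTYPE/length",
                            rec.chrom, rec.pos)
                skipped += 1
                continue
            calls.append(call)
    if skipped:
        log.warning("%s: skipped %d unparseable record(s)", path, skipped)
    return calls


def _parse_record(rec, tool: str, default_method: str) -> Optional[SVCall]:
    sv_type = _record_sv_type(rec)
    if sv_type is None:
        return None
    start = rec.start  # pysam: 0-based POS-1
    svlen = _scalar(_info_get(rec, "SVLEN"))
    if svlen is not None:
        svlen = abs(int(svlen))
    if sv_type == "INS":
        interval = GenomeInterval(rec.chrom, start, start + 1)
        if "INSLEN_UNKNOWN" in rec.info or (svlen is None and rec.alts
                                            and rec.alts[0] == "<INS>"):
            length: Optional[int] = UNKNOWN_LENGTH
        elif svlen is not None:
            length = svlen
        elif rec.alts and len(rec.alts[0]) > len(rec.ref or ""):
            length = len(rec.alts[0]) - len(rec.ref)
        else:
            length = UNKNOWN_LENGTH
    else:
        # SVLEN takes priority: htslib >= 1.21 recomputes rec.stop from
        # SVLEN under the padding-base convention, off by one from this
        # package's POS-is-first-affected-base convention.
        if svlen:
            end = start + svlen
        else:
            end = rec.stop  # resolves INFO/END or ref-allele length
        if end <= start:
            return None
        interval = GenomeInterval(rec.chrom, start, end)
        length = interval.length()
    method = _scalar(_info_get(rec, "SVMETHOD")) or default_method
    support = int(_scalar(_info_get(rec, "SUPPORT")) or 1)
    genotype = "unknown"
    if rec.samples:
        gt = rec.samples[0].get("GT")
        if gt is not None:
            genotype = _TUPLE_TO_GT.get(tuple(gt), "unknown")
    return SVCall(interval=interval, sv_type=sv_type, sv_length=length,
                  tool=tool, method=str(method), genotype=genotype,
                  support=max(1, support))


def read_bed_calls(path: str, tool: str, sv_type: str,
                   method: str = "unknown") -> list[SVCall]:
    """Adapter for tools emitting BED3+ tables (0-based half-open).

    Optional column 4 = length, column 5 = support.  Non-numeric
    coordinates are fatal with the line number; an ``end < start`` line is
    reported and skipped.
    """
    calls: list[SVCall] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: non-numeric coordinates") from exc
            if end < start:
                log.error("%s:%d: end < start, line skipped", path, lineno)
                continue
            length = int(fields[3]) if len(fields) > 3 and fields[3] not in (".", "") \
                else None
            support = int(fields[4]) if len(fields) > 4 and fields[4] not in (".", "") \
                else 1
            if sv_type == "INS":
                interval = GenomeInterval(chrom, start, min(end, start + 1))
                if interval.end == interval.start:
                    interval = GenomeInterval(chrom, start, start + 1)
            else:
                interval = GenomeInterval(chrom, start, end)
                length = interval.length()
            calls.append(SVCall(interval=interval, sv_type=sv_type,
                                sv_length=length, tool=tool, method=method,
                                support=max(1, support)))
    return calls


# ---------------------------------------------------------------------------
# Writing.
#
# Written as plain text rather than through pysam.VariantFile: htslib
# (>= 1.21) recomputes symbolic-SV END from SVLEN under the VCF 4.4
# padding-base convention, shifting every END one base off this
# package's coordinate contract.  The text writer keeps full control,
# is byte-deterministic, and its output re-parses through
# read_tool_vcf / bcftools unchanged.

_GT_STRING = {"hom_ref": "0/0", "het": "0/1", "hom_alt": "1/1",
              "unknown": "./."}


def header_lines(contigs: dict[str, int],
                 sample: Optional[str] = "SAMPLE") -> list[str]:
    lines = ["##fileformat=VCFv4.2", "##source=svmeld"]
    for name, length in contigs.items():
        lines.append(f"##contig=<ID={name},length={length}>")
    lines += [
        '##ALT=<ID=DEL,Description="Deletion">',
        '##ALT=<ID=INS,Description="Insertion">',
        '##ALT=<ID=INV,Description="Inversion">',
        '##ALT=<ID=DUP,Description="Tandem duplication">',
        '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">',
        '##INFO=<ID=END,Number=1,Type=Integer,Description="End of SV">',
        '##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="SV length, negative for deletions">',
        '##INFO=<ID=SVMETHOD,Number=1,Type=String,Description="Detection method">',
        '##INFO=<ID=SUPPORT,Number=1,Type=Integer,Description="Supporting read/call count">',
        '##INFO=<ID=SOURCES,Number=.,Type=String,Description="tool:method:start-end provenance">',
        '##INFO=<ID=NUM_TOOLS,Number=1,Type=Integer,Description="Distinct source tools">',
        '##INFO=<ID=NUM_METHODS,Number=1,Type=Integer,Description="Distinct detection methods">',
        '##INFO=<ID=ASSEMBLY_CONFIRMED,Number=0,Type=Flag,Description="Breakpoints confirmed by local assembly + split alignment">',
        '##INFO=<ID=INSLEN_UNKNOWN,Number=0,Type=Flag,Description="Insertion length could not be determined">',
        '##FILTER=<ID=LowQual,Description="Single-tool call without assembly confirmation">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    ]
    cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO"]
    if sample:
        cols += ["FORMAT", sample]
    lines.append("\t".join(cols))
    return lines


def contigs_from_fasta(reference: str) -> dict[str, int]:
    with pysam.FastaFile(reference) as fa:
        return dict(zip(fa.references, fa.lengths))


def _signed_svlen(sv_type: str, length: Optional[int]) -> int:
    if length is None:
        return 0
    return -length if sv_type == "DEL" else length


def format_record(chrom: str, start: int, end: int, sv_type: str,
                  length: Optional[int], rec_id: str, ref_base: str,
                  filter_field: str, extra_info: list[str],
                  genotype: Optional[str]) -> str:
    """One VCF data line under the package's coordinate convention:
    POS = start + 1 (first affected base), END = end."""
    info = [f"SVTYPE={sv_type}",
            f"END={start + 1 if sv_type == 'INS' else end}",
            f"SVLEN={_signed_svlen(sv_type, length)}"]
    if sv_type == "INS" and length is None:
        info.append("INSLEN_UNKNOWN")
    info.extend(extra_info)
    fields = [chrom, str(start + 1), rec_id, ref_base, f"<{sv_type}>",
              ".", filter_field, ";".join(info)]
    if genotype is not None:
        fields += ["GT", _GT_STRING[genotype]]
    return "\t".join(fields)


def write_calls_vcf(path: str, calls: Sequence[SVCall],
                    contigs: dict[str, int],
                    reference: Optional[str] = None,
                    sample: Optional[str] = "SAMPLE") -> None:
    """Write plain SVCalls (truth sets, mock per-tool callsets) as VCF 4.2."""
    fa = pysam.FastaFile(reference) if reference else None
    try:
        with open(path, "w") as out:
            out.write("\n".join(header_lines(contigs, sample)) + "\n")
            for idx, call in enumerate(sorted(calls, key=SVCall.sort_key)):
                extra = [f"SVMETHOD={call.method}",
                         f"SUPPORT={call.support}"]
                out.write(format_record(
                    call.chrom, call.start, call.end, call.sv_type,
                    call.sv_length, f"{call.sv_type}_{idx}",
                    _ref_base(fa, call.chrom, call.start), ".", extra,
                    call.genotype if sample else None) + "\n")
    finally:
        if fa is not None:
            fa.close()


def _ref_base(fa: Optional[pysam.FastaFile], chrom: str, pos: int) -> str:
    if fa is None:
        return "N"
    base = fa.fetch(chrom, pos, pos + 1)
    return base.upper() if base else "N"
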