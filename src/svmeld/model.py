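"""Core domain types for integrative structural-variant calling.

Coordinate convention: every interval in this package is 0-based,
half-open ``[start, end)`` (BED-style).  Only the VCF reader/writer
converts to and from VCF's 1-based inclusive POS/END.

An insertion is represented as a 1 bp locus interval ``[p, p+1)`` at the
junction; its length lives in :attr:`SVCall.sv_length` and may be the
unknown sentinel ``None`` (long insertions cannot be fully assembled
from short reads, so the locus, not the length, is the reliable output).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

SV_TYPES = ("DEL", "INS", "INV", "DUP")

#: Detection-method vocabulary, most precise first.  Breakpoint
#: precision drives consensus selection during inter-tool merging.
METHOD_PRIORITY_DEFAULT = (
    "junction_mapping",
    "split_read",
    "softclip_assembly",
    "read_pair",
    "depth_of_coverage",
)

GENOTYPES = ("hom_ref", "het", "hom_alt", "unknown")

#: Sentinel for an insertion whose length could not be determined.
#: Deliberately not 0 — a 0 bp event is a legal degenerate length.
UNKNOWN_LENGTH = None


@dataclass(frozen=True, order=True)
class GenomeInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start <= self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )

    def length(self) -> int:
        return self.end - self.start

    def overlap_len(self, other: "GenomeInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def intersects(self, other: "GenomeInterval") -> bool:
        return self.overlap_len(other) > 0

    def padded(self, pad: int, chrom_length: Optional[int] = None) -> "GenomeInterval":
        start = max(0, self.start - pad)
        end = self.end + pad
        if chrom_length is not None:
            end = min(end, chrom_length)
            start = min(start, end)
        return GenomeInterval(self.chrom, start, end)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass
class SVCall:
    """One structural-variant call from a single source.

    ``sv_length`` equals ``interval.length()`` for DEL/INV/DUP; for INS the
    interval is the 1 bp junction locus and ``sv_length`` is the inserted
    length, or :data:`UNKNOWN_LENGTH` when undeterminable.
    """

    interval: GenomeInterval
    sv_type: str
    sv_length: Optional[int]
    tool: str
    method: str
    genotype: str = "unknown"
    support: int = 1

    def __post_init__(self) -> None:
        if self.sv_type not in SV_TYPES:
            raise ValueError(f"unknown SV type {self.sv_type!r}")
        if self.sv_type != "INS":
            if self.sv_length is None:
                self.sv_length = self.interval.length()
            elif self.sv_length != self.interval.length():
                raise ValueError(
                    f"{self.sv_type} length {self.sv_length} != interval "
                    f"length {self.interval.length()}"
                )
        if self.support < 1:
            raise ValueError("support must be >= 1")

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end

    def sort_key(self):
        return (self.chrom, self.start, self.end, self.sv_type, self.tool)


@dataclass
class SVCluster:
    """A group of calls deemed the same event across tools.

    ``consensus`` holds the resolved breakpoints (method-priority median at
    first, possibly replaced later by assembly/split-alignment refinement).
    Confidence is *high* when at least two distinct tools agree, or when
    soft-clip/assembly evidence was confirmed by breakpoint resolution.
    """

    members: list[SVCall]
    sv_type: str
    consensus: Optional[GenomeInterval] = None
    sv_length: Optional[int] = None
    assembly_confirmed: bool = False
    refined: bool = False

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("cluster must have >= 1 member")
        if any(m.sv_type != self.sv_type for m in self.members):
            raise ValueError("cluster members must share sv_type")

    @property
    def chrom(self) -> str:
        return self.members[0].chrom

    @property
    def tools(self) -> set[str]:
        return {m.tool for m in self.members}

    @property
    def methods(self) -> set[str]:
        out = {m.method for m in self.members}
        if self.assembly_confirmed:
            out.add("softclip_assembly")
        return out

    @property
    def support(self) -> int:
        return sum(m.support for m in self.members)

    @property
    def confidence(self) -> str:
        if len(self.tools) >= 2 or self.assembly_confirmed:
            return "high"
        return "low"

    def sort_key(self):
        iv = self.consensus or self.members[0].interval
        return (iv.chrom, iv.start, iv.end, self.sv_type)


def sorted_calls(calls: Iterable[SVCall]) -> list[SVCall]:
    """Deterministic canonical ordering used throughout the pipeline."""
    return sorted(calls, key=SVCall.sort_key)
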