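"""Benchmarking SV callsets against a truth set.

Matching criteria follow the standard strict protocol: deletions,
inversions and duplications match a truth event of the same type when
reciprocal overlap >= ``ro_min`` (default 0.90) *and* both breakpoints
agree within ``wiggle`` (default 100 bp); insertions match by locus
distance <= ``wiggle`` only, with insertion length excluded (long
insertions cannot be fully assembled from short reads).  Events below
``min_size`` are excluded on both sides.  Matching is greedy one-to-one
in position order.  F1 is the harmonic mean of sensitivity and
precision; genotype accuracy is computed over matched pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .merging import reciprocal_overlap
from .model import SVCall

DEFAULT_SIZE_BINS = (250, 500, 1000, 10_000)


@dataclass
class TypeMetrics:
    n_truth: int = 0
    n_calls: int = 0
    n_matched: int = 0
    n_genotype_correct: int = 0

    @property
    def sensitivity(self) -> float:
        return self.n_matched / self.n_truth if self.n_truth else 0.0

    @property
    def precision(self) -> float:
        return self.n_matched / self.n_calls if self.n_calls else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.sensitivity
        return 2 * p * r / (p + r) if p + r else 0.0

    @property
    def genotype_accuracy(self) -> float:
        return (self.n_genotype_correct / self.n_matched
                if self.n_matched else 0.0)


@dataclass
class BenchmarkResult:
    per_type: dict[str, TypeMetrics] = field(default_factory=dict)
    per_size_bin: dict[str, dict[str, TypeMetrics]] = field(
        default_factory=dict)

    def summary(self) -> dict:
        return {
            sv_type: {
                "sensitivity": m.sensitivity, "precision": m.precision,
                "f1": m.f1, "genotype_accuracy": m.genotype_accuracy,
                "n_truth": m.n_truth, "n_calls": m.n_calls,
                "n_matched": m.n_matched,
            } for sv_type, m in sorted(self.per_type.items())
        }


def _size_of(call: SVCall) -> Optional[int]:
    return call.sv_length


def _passes_size(call: SVCall, min_size: int) -> bool:
    size = _size_of(call)
    if size is None:
        return call.sv_type == "INS"  # unknown-length insertions kept
    return size >= min_size


def _compatible(call: SVCall, truth: SVCall, ro_min: float,
                wiggle: int) -> bool:
    if call.sv_type != truth.sv_type or call.chrom != truth.chrom:
        return False
    if call.sv_type == "INS":
        return abs(call.start - truth.start) <= wiggle
    return (abs(call.start - truth.start) <= wiggle
            and abs(call.end - truth.end) <= wiggle
            and reciprocal_overlap(call.interval, truth.interval) >= ro_min)


def _bin_label(size: Optional[int], bins: Sequence[int]) -> str:
    if size is None:
        return "unknown"
    prev = 0
    for b in bins:
        if size <= b:
            return f"{prev + 1}-{b}"
        prev = b
    return f">{bins[-1]}"


def benchmark(calls: Sequence[SVCall], truth: Sequence[SVCall],
              ro_min: float = 0.90, wiggle: int = 100, min_size: int = 100,
              size_bins: Sequence[int] = DEFAULT_SIZE_BINS,
              ) -> BenchmarkResult:
    """Greedy one-to-one matching of ``calls`` to ``truth``; per-type and
    per-size-bin sensitivity/precision/F1 plus genotype accuracy."""
    calls = sorted((c for c in calls if _passes_size(c, min_size)),
                   key=SVCall.sort_key)
    truth = sorted((t for t in truth if _passes_size(t, min_size)),
                   key=SVCall.sort_key)
    result = BenchmarkResult()
    types = sorted({c.sv_type for c in calls} | {t.sv_type for t in truth})
    for sv_type in types:
        metrics = TypeMetrics()
        bin_metrics: dict[str, TypeMetrics] = {}
        t_list = [t for t in truth if t.sv_type == sv_type]
        c_list = [c for c in calls if c.sv_type == sv_type]
        metrics.n_truth = len(t_list)
        metrics.n_calls = len(c_list)
        for t in t_list:
            bm = bin_metrics.setdefault(_bin_label(t.sv_length, size_bins),
                                        TypeMetrics())
            bm.n_truth += 1
        matched: set[int] = set()
        for call in c_list:
            hit = None
            for ti, t in enumerate(t_list):
                if ti in matched:
                    continue
                if _compatible(call, t, ro_min, wiggle):
                    hit = ti
                    break
            label = _bin_label(call.sv_length
                               if hit is None else t_list[hit].sv_length,
                               size_bins)
            bm = bin_metrics.setdefault(label, TypeMetrics())
            bm.n_calls += 1
            if hit is None:
                continue
            matched.add(hit)
            metrics.n_matched += 1
            bm.n_matched += 1
            t = t_list[hit]
            if call.genotype == t.genotype:
                metrics.n_genotype_correct += 1
                bm.n_genotype_correct += 1
        result.per_type[sv_type] = metrics
        result.per_size_bin[sv_type] = bin_metrics
    return result
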