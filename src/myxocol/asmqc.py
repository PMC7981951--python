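"""Assembly summary statistics: contig count, total length, N50, GC."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

from .seqio import SeqRecord

__all__ = ["AssemblyStats", "n50", "gc_fraction", "summarize"]

_UNAMBIGUOUS = set("ACGT")


@dataclass(frozen=True)
class AssemblyStats:
    n_contigs: int
    total_len: int
    n50: int
    gc_fraction: float

    def to_row(self) -> dict:
        return {
            "n_contigs": self.n_contigs,
            "total_len": self.total_len,
            "n50": self.n50,
            "gc_pct": round(self.gc_fraction * 100, 2),
        }


def n50(lengths: Iterable[int]) -> int:
    """Smallest contig length L such that contigs of length >= L sum to >= half the total.

    Computed by sorting descending and taking the length at which the
    cumulative sum first reaches total/2 (inclusive).  Empty input -> 0.
    """
    lens = sorted(lengths, reverse=True)
    if not lens:
        warnings.warn("n50 of empty length set is 0", stacklevel=2)
        return 0
    if any(l < 1 for l in lens):
        raise ValueError("all contig lengths must be >= 1")
    half = sum(lens) / 2
    acc = 0
    for l in lens:
        acc += l
        if acc >= half:
            return l
    raise AssertionError("unreachable")


def gc_fraction(seqs: Iterable[str | SeqRecord]) -> float:
    """(G+C)/(A+C+G+T) pooled over all sequences; ambiguity codes excluded."""
    gc = 0
    total = 0
    for s in seqs:
        seq = s.seq if isinstance(s, SeqRecord) else s
        seq = seq.upper()
        for base in seq:
            if base in _UNAMBIGUOUS:
                total += 1
                if base in ("G", "C"):
                    gc += 1
    if total == 0:
        raise ValueError("no unambiguous bases — GC fraction undefined")
    return gc / total


def summarize(assembly: Sequence[SeqRecord]) -> AssemblyStats:
    if not assembly:
        return AssemblyStats(n_contigs=0, total_len=0, n50=0, gc_fraction=0.0)
    lengths = [len(r.seq) for r in assembly]
    return AssemblyStats(
        n_contigs=len(assembly),
        total_len=sum(lengths),
        n50=n50(lengths),
        gc_fraction=gc_fraction(assembly),
    )
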