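"""Locate introns by exact comparison of a genomic amplicon with its transcript.

The transcript must be reconstructable from the genomic sequence by deleting
disjoint blocks (the introns); matching is mismatch-free.  Blocks are found
by anchored scanning: exon prefixes are extended as far as they match, each
intron is then the shortest insert after which the next exon re-anchors, and
ambiguous junction placements (repeats spanning the boundary) are normalised
to the leftmost equivalent position.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .seqio import SeqRecord

__all__ = ["IntronCall", "locate_introns", "splice_out"]

_ANCHOR = 20  # re-anchor length; long enough that chance re-anchoring inside an intron is negligible


class IntronAlignmentError(ValueError):
    pass


@dataclass(frozen=True)
class IntronCall:
    """One intron; genomic coordinates are 1-based inclusive."""

    transcript_pos: int  # transcript position after which the intron inserts
    genomic_start: int
    genomic_end: int
    length: int
    donor_acceptor: str  # e.g. "GT..AG"
    canonical: bool

    def __post_init__(self) -> None:
        if self.length != self.genomic_end - self.genomic_start + 1:
            raise ValueError("intron length inconsistent with coordinates")
        if self.length < 1:
            raise ValueError("intron length must be >= 1")


def _as_seq(x: str | SeqRecord) -> str:
    return x.seq if isinstance(x, SeqRecord) else x


def splice_out(genomic: str | SeqRecord, introns: Sequence[IntronCall]) -> str:
    """Remove the intron intervals from the genomic sequence."""
    g = _as_seq(genomic)
    out: list[str] = []
    prev = 0
    for call in sorted(introns, key=lambda c: c.genomic_start):
        out.append(g[prev : call.genomic_start - 1])
        prev = call.genomic_end
    out.append(g[prev:])
    return "".join(out)


def _blocks_with_anchor(t: str, g: str, anchor: int) -> list[tuple[int, int, int]] | None:
    """Minimal set of deletion blocks as (transcript_pos0, genomic_start0, length).

    Exons are extended maximally left-to-right; at each mismatch every block
    length after which the next exon re-anchors (min(anchor, rest) exact
    matches) is a candidate, and the completion with the fewest blocks wins.
    Memoised on the (transcript, genomic) cursor pair; block placements come
    out rightmost and are normalised to leftmost by the caller.
    """
    nt, ng = len(t), len(g)
    memo: dict[tuple[int, int], list[tuple[int, int, int]] | None] = {}

    def align(i: int, j: int) -> list[tuple[int, int, int]] | None:
        key = (i, j)
        if key in memo:
            return memo[key]
        while i < nt and j < ng and t[i] == g[j]:
            i += 1
            j += 1
        if i == nt:
            result = [(i, j, ng - j)] if j < ng else []
            memo[key] = result
            return result
        if j == ng:
            memo[key] = None
            return None
        best: list[tuple[int, int, int]] | None = None
        k = min(anchor, nt - i)
        for L in range(1, ng - j - k + 1):
            if g[j + L : j + L + k] != t[i : i + k]:
                continue
            rest = align(i, j + L)
            if rest is not None and (best is None or len(rest) + 1 < len(best)):
                best = [(i, j, L)] + rest
                if len(best) == 1:
                    break
        memo[key] = best
        return best

    return align(0, 0)


def _rightmost_blocks(t: str, g: str) -> list[tuple[int, int, int]]:
    # strict anchoring first (fast, resists chance re-anchoring inside introns),
    # then shorter anchors for short internal exons
    for anchor in (_ANCHOR, 10, 1):
        blocks = _blocks_with_anchor(t, g, anchor)
        if blocks is not None:
            return blocks
    raise IntronAlignmentError("sequences do not align exon-exact")


def locate_introns(
    transcript: str | SeqRecord, genomic: str | SeqRecord
) -> list[IntronCall]:
    """Report the deletion blocks turning the genomic sequence into the transcript.

    Blocks are reported left to right in genomic order; junction-ambiguous
    placements are shifted to the leftmost equivalent position.  Raises
    :class:`IntronAlignmentError` when the transcript is not reconstructable
    by exact exon matching.
    """
    t = _as_seq(transcript).upper()
    g = _as_seq(genomic).upper()
    if len(g) < len(t):
        raise IntronAlignmentError("genomic sequence shorter than transcript")
    if t == g:
        return []

    blocks = _rightmost_blocks(t, g)

    # normalise each block to its leftmost equivalent placement
    normalised: list[tuple[int, int, int]] = []
    prev_end0 = 0  # exclusive genomic end of previous block
    for tp, gs, ln in blocks:
        while gs > prev_end0 and g[gs - 1] == g[gs + ln - 1]:
            gs -= 1
            tp -= 1
        normalised.append((tp, gs, ln))
        prev_end0 = gs + ln

    calls: list[IntronCall] = []
    for tp, gs, ln in normalised:
        block = g[gs : gs + ln]
        if ln >= 4:
            donor_acceptor = f"{block[:2]}..{block[-2:]}"
        else:
            donor_acceptor = block
        calls.append(
            IntronCall(
                transcript_pos=tp,
                genomic_start=gs + 1,
                genomic_end=gs + ln,
                length=ln,
                donor_acceptor=donor_acceptor,
                canonical=block.startswith("GT") and block.endswith("AG"),
            )
        )

    if splice_out(g, calls) != t:
        raise IntronAlignmentError("sequences do not align exon-exact")
    return calls
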