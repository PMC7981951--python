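"""Prepare minicollagen proteins for alignment by excising polyproline linkers."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .ncolscan import MinicollagenArchitecture
from .seqio import GffFeature, SeqRecord

__all__ = ["TrimSpec", "excise_regions", "build_alignment_set"]


@dataclass(frozen=True)
class TrimSpec:
    seq_id: str
    excise_intervals: tuple[tuple[int, int], ...]  # 1-based inclusive, sorted, disjoint

    def __post_init__(self) -> None:
        prev_end = 0
        for start, end in self.excise_intervals:
            if start < 1 or start > end:
                raise ValueError(f"invalid interval [{start},{end}] for {self.seq_id}")
            if start <= prev_end:
                raise ValueError(
                    f"overlapping or unsorted excise intervals for {self.seq_id}"
                )
            prev_end = end


@dataclass(frozen=True)
class CoordinateMap:
    """Maps trimmed 1-based positions back to original 1-based positions."""

    retained: tuple[int, ...]  # original position of each trimmed residue

    def to_original(self, trimmed_pos: int) -> int:
        return self.retained[trimmed_pos - 1]


def excise_regions(
    protein: SeqRecord, trimspec: TrimSpec
) -> tuple[SeqRecord, CoordinateMap]:
    """Remove the trim intervals; returns the trimmed record and a coordinate map."""
    if trimspec.seq_id != protein.id:
        raise ValueError(f"trimspec is for {trimspec.seq_id!r}, not {protein.id!r}")
    n = len(protein.seq)
    for start, end in trimspec.excise_intervals:
        if end > n:
            raise ValueError(
                f"interval [{start},{end}] exceeds length {n} of {protein.id!r}"
            )
    cut = set()
    for start, end in trimspec.excise_intervals:
        cut.update(range(start, end + 1))
    retained = [pos for pos in range(1, n + 1) if pos not in cut]
    if not retained:
        raise ValueError(f"excision removes the whole sequence {protein.id!r}")
    trimmed = "".join(protein.seq[pos - 1] for pos in retained)
    return (
        SeqRecord(id=protein.id, seq=trimmed, description=protein.description),
        CoordinateMap(retained=tuple(retained)),
    )


def _polyp_intervals_from_arch(arch: MinicollagenArchitecture) -> list[tuple[int, int]]:
    return [
        (d.start, d.end)
        for d in arch.domains
        if d.dtype == "linker" and d.attributes.get("class") == "polyP"
    ]


def _polyp_intervals_from_gff(
    features: Iterable[GffFeature], seq_id: str
) -> list[tuple[int, int]]:
    return [
        (f.start, f.end)
        for f in features
        if f.seqid == seq_id
        and f.ftype == "linker"
        and f.attributes.get("class") == "polyP"
    ]


def build_alignment_set(
    proteins: Sequence[SeqRecord],
    architectures: Sequence[MinicollagenArchitecture] = (),
    annotations: Sequence[GffFeature] = (),
    excise_all_linkers: bool = False,
) -> list[SeqRecord]:
    """One trimmed record per input protein, polyproline linkers excised.

    Trim intervals come from scanner architectures and/or linker features in
    a GFF3; records without polyP annotations pass through unchanged.  With
    ``excise_all_linkers`` every linker is removed regardless of class.
    """
    arch_by_id = {a.seq_id: a for a in architectures}
    out: list[SeqRecord] = []
    for prot in proteins:
        intervals: list[tuple[int, int]] = []
        arch = arch_by_id.get(prot.id)
        if arch is not None:
            if excise_all_linkers:
                intervals += [
                    (d.start, d.end) for d in arch.domains if d.dtype == "linker"
                ]
            else:
                intervals += _polyp_intervals_from_arch(arch)
        if excise_all_linkers:
            intervals += [
                (f.start, f.end)
                for f in annotations
                if f.seqid == prot.id and f.ftype == "linker"
            ]
        else:
            intervals += _polyp_intervals_from_gff(annotations, prot.id)
        intervals = sorted(set(intervals))
        if not intervals:
            out.append(prot)
            continue
        trimmed, _ = excise_regions(prot, TrimSpec(prot.id, tuple(intervals)))
        out.append(trimmed)
    return out
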