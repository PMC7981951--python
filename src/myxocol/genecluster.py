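"""Gene-pair geometry on genome scaffolds: intergenic distance and orientation."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .seqio import FormatError, GffFeature

__all__ = [
    "GeneLocus",
    "ClusterReport",
    "igr_length",
    "orientation",
    "cluster_scan",
    "read_loci",
]


@dataclass(frozen=True)
class GeneLocus:
    scaffold: str
    start: int  # 1-based inclusive
    end: int
    strand: str  # "+" | "-"
    name: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"locus {self.name}: start {self.start} > end {self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"locus {self.name}: strand must be '+' or '-'")


@dataclass(frozen=True)
class ClusterReport:
    pair: tuple[str, str]
    scaffold: str
    igr_len: int
    orientation: str  # co_directional | head_to_head | tail_to_tail
    order: tuple[str, str]  # names sorted by coordinate


def _sorted_pair(a: GeneLocus, b: GeneLocus) -> tuple[GeneLocus, GeneLocus]:
    if a.scaffold != b.scaffold:
        raise ValueError(
            f"loci {a.name} and {b.name} are not co-localized "
            f"({a.scaffold} vs {b.scaffold})"
        )
    return (a, b) if (a.start, a.end) <= (b.start, b.end) else (b, a)


def igr_length(a: GeneLocus, b: GeneLocus) -> int:
    """Bases strictly between the two genes; 0 when adjacent or overlapping."""
    first, second = _sorted_pair(a, b)
    return max(0, second.start - first.end - 1)


def orientation(a: GeneLocus, b: GeneLocus) -> str:
    """Orientation class of the coordinate-sorted pair.

    (+,+)/(−,−) co-directional; (−,+) divergent head-to-head;
    (+,−) convergent tail-to-tail.
    """
    first, second = _sorted_pair(a, b)
    if first.strand == second.strand:
        return "co_directional"
    if first.strand == "-":
        return "head_to_head"
    return "tail_to_tail"


def cluster_scan(loci: Sequence[GeneLocus], max_igr: int) -> list[ClusterReport]:
    """All same-scaffold gene pairs with IGR <= max_igr, in coordinate order."""
    by_scaffold: dict[str, list[GeneLocus]] = {}
    for locus in loci:
        by_scaffold.setdefault(locus.scaffold, []).append(locus)
    reports: list[ClusterReport] = []
    for scaffold in sorted(by_scaffold):
        genes = sorted(by_scaffold[scaffold], key=lambda g: (g.start, g.end))
        for i in range(len(genes)):
            for j in range(i + 1, len(genes)):
                a, b = genes[i], genes[j]
                igr = igr_length(a, b)
                if igr <= max_igr:
                    reports.append(
                        ClusterReport(
                            pair=(a.name, b.name),
                            scaffold=scaffold,
                            igr_len=igr,
                            orientation=orientation(a, b),
                            order=(a.name, b.name),
                        )
                    )
    return reports


def read_loci(path: str | Path) -> list[GeneLocus]:
    """Read gene loci from a 5/6-column TSV (scaffold start end strand name) or GFF3."""
    path = Path(path)
    with open(path) as fh:
        head = fh.readline()
    if head.startswith("##gff-version"):
        from .seqio import read_gff3

        loci = []
        for f in read_gff3(path):
            if f.ftype.lower() != "gene":
                continue
            name = f.attributes.get("Name") or f.attributes.get("ID") or f.ftype
            loci.append(GeneLocus(f.seqid, f.start, f.end, f.strand, name))
        return loci
    loci = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 5:
                raise FormatError(
                    f"{path}: line {lineno}: expected >=5 columns "
                    "(scaffold, start, end, strand, name)"
                )
            try:
                loci.append(
                    GeneLocus(
                        scaffold=cols[0],
                        start=int(cols[1]),
                        end=int(cols[2]),
                        strand=cols[3],
                        name=cols[4],
                    )
                )
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
    return loci
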