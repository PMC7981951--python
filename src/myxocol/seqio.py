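"""Readers/writers for the standard formats the toolkit touches.

All external coordinates (FASTA annotations, BLAST tabular, GFF3) are
1-based inclusive; internal interval arithmetic elsewhere in the package is
0-based half-open.  The conversion helpers here are the single boundary
between the two conventions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from Bio import SeqIO as _BioSeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

__all__ = [
    "SeqRecord",
    "HspRecord",
    "GffFeature",
    "read_fasta",
    "write_fasta",
    "parse_blast_tab",
    "write_blast_tab",
    "write_gff3",
    "read_gff3",
    "to_internal",
    "to_external",
]


class FormatError(ValueError):
    """Raised for malformed input files."""


def to_internal(start_1based: int, end_1based: int) -> tuple[int, int]:
    """1-based inclusive -> 0-based half-open."""
    return start_1based - 1, end_1based


def to_external(start0: int, end0: int) -> tuple[int, int]:
    """0-based half-open -> 1-based inclusive."""
    return start0 + 1, end0


@dataclass(frozen=True)
class SeqRecord:
    """A single sequence with its header.

    ``id`` is the first whitespace-delimited token of the FASTA header;
    ``description`` is the full header line without the leading ``>``.
    """

    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if len(self.seq) < 1:
            raise ValueError(f"sequence {self.id!r} is empty")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class HspRecord:
    """One parsed BLAST tabular hit (default 12-column outfmt 6 dialect)."""

    query_id: str
    subject_id: str
    pct_identity: float
    aln_len: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.pct_identity <= 100.0):
            raise ValueError(
                f"pct_identity {self.pct_identity} outside [0,100] "
                f"for {self.query_id}->{self.subject_id}"
            )
        if self.q_start < 1:
            raise ValueError(f"q_start {self.q_start} < 1 for {self.query_id}")
        if self.q_start > self.q_end:
            raise ValueError(
                f"query coordinates must be ascending "
                f"(q_start={self.q_start} > q_end={self.q_end}) for {self.query_id}"
            )
        if self.evalue < 0:
            raise ValueError(f"negative evalue for {self.query_id}")

    @property
    def q_interval(self) -> tuple[int, int]:
        """Query interval in internal 0-based half-open coordinates."""
        return to_internal(self.q_start, self.q_end)

    def to_line(self) -> str:
        return "\t".join(
            [
                self.query_id,
                self.subject_id,
                repr(self.pct_identity),
                str(self.aln_len),
                str(self.mismatches),
                str(self.gap_opens),
                str(self.q_start),
                str(self.q_end),
                str(self.s_start),
                str(self.s_end),
                repr(self.evalue),
                f"{self.bitscore:g}",
            ]
        )


def read_fasta(path: str | Path, *, allow_duplicates: bool = False) -> list[SeqRecord]:
    """Read a FASTA file into a list of :class:`SeqRecord`.

    Sequences are uppercased; record order is preserved.  Duplicate ids
    raise unless ``allow_duplicates`` — downstream hit tables key on ids.
    """
    path = Path(path)
    records: list[SeqRecord] = []
    seen: set[str] = set()
    with open(path) as fh:
        first = fh.read(1)
        if not first:
            warnings.warn(f"empty FASTA file: {path}", stacklevel=2)
            return []
        if first != ">":
            raise FormatError(f"{path}: line 1: sequence data before first '>' header")
        fh.seek(0)
        for rec in _BioSeqIO.parse(fh, "fasta"):
            if not rec.id:
                raise FormatError(f"{path}: record with empty header")
            if rec.id in seen and not allow_duplicates:
                raise FormatError(f"{path}: duplicate sequence id {rec.id!r}")
            seen.add(rec.id)
            records.append(
                SeqRecord(id=rec.id, seq=str(rec.seq).upper(), description=rec.description)
            )
    return records


def write_fasta(records: Iterable[SeqRecord], path: str | Path, width: int = 70) -> None:
    path = Path(path)
    bio = [
        _BioSeqRecord(Seq(r.seq), id=r.id, description=_desc_tail(r))
        for r in records
    ]
    with open(path, "w") as fh:
        writer = _BioSeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


def _desc_tail(rec: SeqRecord) -> str:
    # biopython prints "id description"; strip a leading duplicate of the id
    if rec.description.startswith(rec.id):
        return rec.description[len(rec.id):].strip()
    return rec.description


def parse_blast_tab(path: str | Path) -> list[HspRecord]:
    """Parse a 12-column BLAST tabular (outfmt 6) file.

    Column order: qseqid sseqid pident length mismatch gapopen qstart qend
    sstart send evalue bitscore.  Lines are preserved in input order;
    ``#``-prefixed comment lines are skipped.
    """
    path = Path(path)
    hsps: list[HspRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise FormatError(
                    f"{path}: line {lineno}: expected 12 tab-separated columns, "
                    f"got {len(fields)}"
                )
            try:
                hsp = HspRecord(
                    query_id=fields[0],
                    subject_id=fields[1],
                    pct_identity=float(fields[2]),
                    aln_len=int(fields[3]),
                    mismatches=int(fields[4]),
                    gap_opens=int(fields[5]),
                    q_start=int(fields[6]),
                    q_end=int(fields[7]),
                    s_start=int(fields[8]),
                    s_end=int(fields[9]),
                    evalue=float(fields[10]),
                    bitscore=float(fields[11]),
                )
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
            hsps.append(hsp)
    return hsps


def write_blast_tab(hsps: Iterable[HspRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for hsp in hsps:
            fh.write(hsp.to_line() + "\n")


@dataclass(frozen=True)
class GffFeature:
    """One GFF3 feature row (1-based inclusive coordinates)."""

    seqid: str
    ftype: str
    start: int
    end: int
    strand: str = "+"
    score: str = "."
    source: str = "myxocol"
    attributes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"feature start {self.start} > end {self.end} on {self.seqid}"
            )


_GFF_ESCAPES = {";": "%3B", "=": "%3D", "&": "%26", ",": "%2C", "\t": "%09", "\n": "%0A"}


def _escape_attr(value: str) -> str:
    for raw, esc in _GFF_ESCAPES.items():
        value = value.replace(raw, esc)
    return value


def write_gff3(features: Iterable[GffFeature], path: str | Path) -> None:
    """Serialize features as GFF3, sorted by (seqid, start, end)."""
    feats = sorted(features, key=lambda f: (f.seqid, f.start, f.end))
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, f in enumerate(feats):
            attrs = dict(f.attributes)
            attrs.setdefault("ID", f"{f.seqid}.{f.ftype}.{i + 1}")
            attr_str = ";".join(
                f"{_escape_attr(str(k))}={_escape_attr(str(v))}" for k, v in attrs.items()
            )
            fh.write(
                "\t".join(
                    [
                        f.seqid,
                        f.source,
                        f.ftype,
                        str(f.start),
                        str(f.end),
                        f.score,
                        f.strand,
                        ".",
                        attr_str,
                    ]
                )
                + "\n"
            )


def _unescape_attr(value: str) -> str:
    for raw, esc in _GFF_ESCAPES.items():
        value = value.replace(esc, raw)
    return value


def read_gff3(path: str | Path) -> list[GffFeature]:
    path = Path(path)
    feats: list[GffFeature] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(f"{path}: line {lineno}: expected 9 columns")
            attrs: dict = {}
            if cols[8] != ".":
                for pair in cols[8].split(";"):
                    if not pair:
                        continue
                    key, _, val = pair.partition("=")
                    attrs[_unescape_attr(key)] = _unescape_attr(val)
            try:
                feats.append(
                    GffFeature(
                        seqid=cols[0],
                        source=cols[1],
                        ftype=cols[2],
                        start=int(cols[3]),
                        end=int(cols[4]),
                        score=cols[5],
                        strand=cols[6],
                        attributes=attrs,
                    )
                )
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
    return feats
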