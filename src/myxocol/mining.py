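"""Ortholog mining logic: CRD query extraction, E-value gating, reciprocal best hits.

BLAST execution is external; these operations work on parsed hit tables and
domain annotations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .seqio import GffFeature, HspRecord, SeqRecord

__all__ = [
    "CrdQuery",
    "QuerySet",
    "extract_crd_queries",
    "filter_hits_evalue",
    "reciprocal_check",
]

_CRD_TYPES = {"N_CRD", "C_CRD"}


@dataclass(frozen=True)
class CrdQuery:
    source_id: str
    group: str
    region: str  # "N_CRD" | "C_CRD"
    subsequence: str
    start: int  # 1-based inclusive on the source protein
    end: int

    @property
    def query_id(self) -> str:
        return f"{self.source_id}|{self.group}|{self.region}"


@dataclass(frozen=True)
class QuerySet:
    entries: tuple[CrdQuery, ...]

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)


def extract_crd_queries(
    proteins: Sequence[SeqRecord],
    annotations: Sequence[GffFeature],
    groups: Mapping[str, str] | None = None,
) -> QuerySet:
    """Extract one query per annotated CRD span.

    ``annotations`` are GFF3 features with type ``N_CRD``/``C_CRD`` keyed on
    the protein id; ``groups`` optionally maps protein id -> minicollagen
    group label (defaults to the feature's ``ncol_group`` attribute or
    ``"unknown"``).  Proteins without any CRD annotation are skipped with a
    warning.
    """
    by_protein: dict[str, list[GffFeature]] = {}
    for feat in annotations:
        if feat.ftype in _CRD_TYPES:
            by_protein.setdefault(feat.seqid, []).append(feat)

    entries: list[CrdQuery] = []
    for prot in proteins:
        feats = by_protein.get(prot.id, [])
        if not feats:
            warnings.warn(f"protein {prot.id!r} has no CRD annotation; skipped", stacklevel=2)
            continue
        for feat in sorted(feats, key=lambda f: (f.start, f.end)):
            if feat.end > len(prot.seq):
                raise ValueError(
                    f"CRD [{feat.start},{feat.end}] exceeds protein {prot.id!r} "
                    f"length {len(prot.seq)}"
                )
            group = (
                (groups or {}).get(prot.id)
                or feat.attributes.get("ncol_group")
                or "unknown"
            )
            entries.append(
                CrdQuery(
                    source_id=prot.id,
                    group=group,
                    region=feat.ftype,
                    subsequence=prot.seq[feat.start - 1 : feat.end],
                    start=feat.start,
                    end=feat.end,
                )
            )
    return QuerySet(entries=tuple(entries))


def filter_hits_evalue(
    hits: Sequence[HspRecord], cutoff: float = 1e-5
) -> list[HspRecord]:
    """Retain hits with evalue <= cutoff (inclusive boundary), preserving order."""
    if cutoff <= 0:
        raise ValueError("E-value cutoff must be > 0")
    return [h for h in hits if h.evalue <= cutoff]


def _best_subject(hits: Iterable[HspRecord]) -> dict[str, str]:
    """Best subject per query: bitscore desc, evalue asc, subject id lexicographic."""
    best: dict[str, HspRecord] = {}
    for h in hits:
        cur = best.get(h.query_id)
        if cur is None or (-h.bitscore, h.evalue, h.subject_id) < (
            -cur.bitscore,
            cur.evalue,
            cur.subject_id,
        ):
            best[h.query_id] = h
    return {q: h.subject_id for q, h in best.items()}


def reciprocal_check(
    forward_hits: Sequence[HspRecord], reverse_hits: Sequence[HspRecord]
) -> list[tuple[str, str]]:
    """Confirmed pairs (q, s): s is q's best forward subject and q is s's best reverse subject."""
    fwd_best = _best_subject(forward_hits)
    rev_best = _best_subject(reverse_hits)
    confirmed = [
        (q, s) for q, s in fwd_best.items() if rev_best.get(s) == q
    ]
    return sorted(confirmed)
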