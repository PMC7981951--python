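"""Per-contig hit-coverage/identity scoring and contamination filtering.

A contig's *similarity score* is its identity-weighted hit coverage: each
base covered by at least one HSP contributes the best (maximum) identity of
any HSP covering it, uncovered bases contribute zero, and the sum is
normalised by the contig length.  Scores therefore live in [0, 1] and hit
pooling is across all subjects of the contaminant reference.

Two removal policies exist: ``any_hit`` (a single HSP is enough, used for
host hits) and ``similarity_threshold`` (score strictly greater than the
threshold, used for the closely related contaminant at 0.90).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

from .seqio import HspRecord, SeqRecord

__all__ = [
    "CoverageProfile",
    "FilterDecision",
    "FilterPolicy",
    "CleanReport",
    "merge_hsps",
    "filter_contigs",
    "two_stage_clean",
]


class FilterPolicy(str, Enum):
    ANY_HIT = "any_hit"
    SIMILARITY_THRESHOLD = "similarity_threshold"


class ScoreMode(str, Enum):
    WEIGHTED = "weighted"
    COVERAGE_ONLY = "coverage_only"


@dataclass(frozen=True)
class Segment:
    """Covered interval in 0-based half-open coordinates with best identity."""

    start: int
    end: int
    best_identity: float

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class CoverageProfile:
    contig_id: str
    contig_len: int
    segments: tuple[Segment, ...]
    similarity_score: float

    def coverage_fraction(self, identity_floor: float = 0.0) -> float:
        """Fraction of bases covered by segments with identity >= floor."""
        covered = sum(len(s) for s in self.segments if s.best_identity >= identity_floor)
        return covered / self.contig_len


@dataclass(frozen=True)
class FilterDecision:
    contig_id: str
    score: float
    n_hits: int
    policy: FilterPolicy
    threshold: float
    removed: bool


@dataclass(frozen=True)
class CleanReport:
    kept: tuple[str, ...]
    host_removed: tuple[str, ...]
    contaminant_removed: tuple[str, ...]
    host_decisions: tuple[FilterDecision, ...]
    contaminant_decisions: tuple[FilterDecision, ...]

    @property
    def counts(self) -> dict[str, int]:
        return {
            "kept": len(self.kept),
            "host_removed": len(self.host_removed),
            "contaminant_removed": len(self.contaminant_removed),
        }


def merge_hsps(
    hsps: Sequence[HspRecord],
    contig_len: int,
    contig_id: str | None = None,
) -> CoverageProfile:
    """Merge HSPs of one contig into a per-base best-identity profile.

    Implemented as a breakpoint sweep over HSP query intervals, not a
    per-base array, so the brute-force per-base oracle remains independent.
    Pools HSPs across all subjects; subject strand is ignored.
    """
    if contig_len < 1:
        raise ValueError("contig_len must be positive")
    if hsps:
        ids = {h.query_id for h in hsps}
        if len(ids) > 1:
            raise ValueError(f"mixed query_ids in one merge: {sorted(ids)}")
        qid = hsps[0].query_id
        if contig_id is not None and contig_id != qid:
            raise ValueError(f"hits are for {qid!r}, not contig {contig_id!r}")
        contig_id = qid
    elif contig_id is None:
        raise ValueError("contig_id required when no HSPs are given")

    intervals: list[tuple[int, int, float]] = []
    for h in hsps:
        s0, e0 = h.q_interval
        if e0 > contig_len:
            raise ValueError(
                f"HSP {h.query_id}->{h.subject_id} q[{h.q_start},{h.q_end}] "
                f"exceeds contig length {contig_len}"
            )
        intervals.append((s0, e0, h.pct_identity / 100.0))

    segments: list[Segment] = []
    if intervals:
        points = sorted({p for s, e, _ in intervals for p in (s, e)})
        starts = sorted(intervals)
        for lo, hi in zip(points, points[1:]):
            best = 0.0
            covered = False
            for s, e, ident in starts:
                if s >= hi:
                    break
                if e > lo:  # overlaps [lo, hi)
                    covered = True
                    if ident > best:
                        best = ident
            if covered:
                if segments and segments[-1].end == lo and segments[-1].best_identity == best:
                    segments[-1] = Segment(segments[-1].start, hi, best)
                else:
                    segments.append(Segment(lo, hi, best))

    score = sum(len(s) * s.best_identity for s in segments) / contig_len
    return CoverageProfile(
        contig_id=contig_id,
        contig_len=contig_len,
        segments=tuple(segments),
        similarity_score=score,
    )


def _group_hits(hits: Iterable[HspRecord]) -> dict[str, list[HspRecord]]:
    by_contig: dict[str, list[HspRecord]] = {}
    for h in hits:
        by_contig.setdefault(h.query_id, []).append(h)
    return by_contig


def _contig_lengths(contigs: Sequence[SeqRecord] | Mapping[str, int]) -> dict[str, int]:
    if isinstance(contigs, Mapping):
        return dict(contigs)
    return {c.id: len(c.seq) for c in contigs}


def filter_contigs(
    contigs: Sequence[SeqRecord] | Mapping[str, int],
    hits: Sequence[HspRecord],
    policy: FilterPolicy | str = FilterPolicy.SIMILARITY_THRESHOLD,
    threshold: float = 0.90,
    mode: ScoreMode | str = ScoreMode.WEIGHTED,
    identity_floor: float = 0.90,
    max_evalue: float | None = None,
) -> tuple[list[str], list[str], list[FilterDecision]]:
    """Partition contigs into kept/removed under the given policy.

    Contig lengths come from the assembly (never inferred from hits), so
    uncovered tails count against the score.  No E-value gate is applied
    unless ``max_evalue`` is set.
    """
    policy = FilterPolicy(policy)
    mode = ScoreMode(mode)
    if not (0.0 <= threshold <= 1.0):
        raise ValueError(f"threshold {threshold} outside [0,1]")
    lengths = _contig_lengths(contigs)
    if max_evalue is not None:
        hits = [h for h in hits if h.evalue <= max_evalue]
    by_contig = _group_hits(hits)
    unknown = sorted(set(by_contig) - set(lengths))
    if unknown:
        raise ValueError(f"hits reference unknown contigs: {unknown}")

    kept: list[str] = []
    removed: list[str] = []
    decisions: list[FilterDecision] = []
    for cid, clen in lengths.items():
        chits = by_contig.get(cid, [])
        if chits:
            profile = merge_hsps(chits, clen)
            if mode is ScoreMode.WEIGHTED:
                score = profile.similarity_score
            else:
                score = profile.coverage_fraction(identity_floor)
        else:
            score = 0.0
        if policy is FilterPolicy.ANY_HIT:
            is_removed = len(chits) > 0
        else:
            is_removed = score > threshold
        decisions.append(
            FilterDecision(
                contig_id=cid,
                score=score,
                n_hits=len(chits),
                policy=policy,
                threshold=threshold,
                removed=is_removed,
            )
        )
        (removed if is_removed else kept).append(cid)
    return kept, removed, decisions


def two_stage_clean(
    contigs: Sequence[SeqRecord] | Mapping[str, int],
    host_hits: Sequence[HspRecord],
    contaminant_hits: Sequence[HspRecord],
    threshold: float = 0.90,
    mode: ScoreMode | str = ScoreMode.WEIGHTED,
    identity_floor: float = 0.90,
) -> CleanReport:
    """Host any-hit filter first, then contaminant similarity filter on survivors."""
    lengths = _contig_lengths(contigs)
    survivors, host_removed, host_dec = filter_contigs(
        lengths, host_hits, FilterPolicy.ANY_HIT
    )
    surviving_lengths = {cid: lengths[cid] for cid in survivors}
    surviving_set = set(survivors)
    stage2_hits = [h for h in contaminant_hits if h.query_id in surviving_set]
    unknown = sorted({h.query_id for h in contaminant_hits} - set(lengths))
    if unknown:
        raise ValueError(f"contaminant hits reference unknown contigs: {unknown}")
    kept, contam_removed, contam_dec = filter_contigs(
        surviving_lengths,
        stage2_hits,
        FilterPolicy.SIMILARITY_THRESHOLD,
        threshold=threshold,
        mode=mode,
        identity_floor=identity_floor,
    )
    return CleanReport(
        kept=tuple(kept),
        host_removed=tuple(host_removed),
        contaminant_removed=tuple(contam_removed),
        host_decisions=tuple(host_dec),
        contaminant_decisions=tuple(contam_dec),
    )
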