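"""Minicollagen domain-architecture scanner.

Locates cysteine-rich domains (CRDs) by inter-cysteine spacing patterns,
counts Gly-X-Y collagen triplet repeats, classifies linker composition,
checks the propeptide KR cleavage dipeptide and applies a heuristic rule
table to call the minicollagen type.

CRD motifs are six cysteines with five characteristic inter-cysteine gaps.
The default motifs are::

    canonical        C xxx C xxx C xxx C xxx CC      gaps (3,3,3,3,0)
    noncanonical_C   C xxx C x{9,10} C xxx C xxx CC  gaps (3,9-10,3,3,0)

with a +/-1 residue tolerance applied to every gap range (floored at 0).
All gap ranges are config-overridable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

from .seqio import GffFeature, SeqRecord

__all__ = [
    "CrdMotif",
    "CrdMatch",
    "DomainAnnotation",
    "MinicollagenArchitecture",
    "CANONICAL",
    "NONCANONICAL_C",
    "find_crd",
    "find_interrupted_crd",
    "count_gxy",
    "classify_linker",
    "detect_kr",
    "build_architecture",
    "classify_ncol",
]


@dataclass(frozen=True)
class CrdMotif:
    """Allowed residue counts between consecutive cysteines C1..C6."""

    gap_ranges: tuple[tuple[int, int], ...]
    label: str

    def __post_init__(self) -> None:
        if len(self.gap_ranges) != 5:
            raise ValueError("CRD motif requires exactly 5 gap ranges (6 cysteines)")
        for lo, hi in self.gap_ranges:
            if lo < 0 or hi < lo:
                raise ValueError(f"invalid gap range ({lo},{hi})")

    def widened(self, tolerance: int) -> tuple[tuple[int, int], ...]:
        return tuple(
            (max(0, lo - tolerance), hi + tolerance) for lo, hi in self.gap_ranges
        )


CANONICAL = CrdMotif(((3, 3), (3, 3), (3, 3), (3, 3), (0, 0)), "canonical")
NONCANONICAL_C = CrdMotif(((3, 3), (9, 10), (3, 3), (3, 3), (0, 0)), "noncanonical_C")


@dataclass(frozen=True)
class CrdMatch:
    """One CRD match; coordinates are 1-based inclusive residue positions."""

    start: int
    end: int
    gaps: tuple[int, ...]
    label: str
    cys_positions: tuple[int, ...]  # 1-based
    interrupted: bool = False
    interrupted_gap_index: int | None = None


def find_crd(
    protein: str | SeqRecord,
    motif: CrdMotif,
    tolerance: int = 1,
) -> list[CrdMatch]:
    """All 6-cysteine arrangements whose gaps satisfy the motif's ranges.

    Gap ranges are widened by +/-``tolerance`` (floored at 0).  Residues
    inside gaps are unconstrained.  Matches are reported left to right and
    may overlap.
    """
    seq = protein.seq if isinstance(protein, SeqRecord) else protein
    ranges = motif.widened(tolerance)
    cys = [i for i, aa in enumerate(seq) if aa == "C"]
    matches: list[CrdMatch] = []

    def extend(chain: list[int]) -> None:
        depth = len(chain) - 1
        if depth == 5:
            gaps = tuple(b - a - 1 for a, b in zip(chain, chain[1:]))
            matches.append(
                CrdMatch(
                    start=chain[0] + 1,
                    end=chain[-1] + 1,
                    gaps=gaps,
                    label=motif.label,
                    cys_positions=tuple(p + 1 for p in chain),
                )
            )
            return
        lo, hi = ranges[depth]
        last = chain[-1]
        for pos in cys:
            if pos <= last:
                continue
            gap = pos - last - 1
            if gap > hi:
                break
            if gap >= lo:
                extend(chain + [pos])

    for start in cys:
        extend([start])
    matches.sort(key=lambda m: (m.start, m.end))
    return matches


def find_interrupted_crd(
    protein: str | SeqRecord,
    motif: CrdMotif = CANONICAL,
    tolerance: int = 1,
    min_pro_fraction: float = 0.30,
    max_insert: int = 60,
) -> list[CrdMatch]:
    """CRD matches in which exactly one gap is oversized by a proline-rich insert.

    A match is reported when all gaps but one satisfy the (widened) motif
    ranges, the remaining gap exceeds its range, and that gap's residues are
    at least ``min_pro_fraction`` proline.
    """
    seq = protein.seq if isinstance(protein, SeqRecord) else protein
    ranges = motif.widened(tolerance)
    cys = [i for i, aa in enumerate(seq) if aa == "C"]
    matches: list[CrdMatch] = []

    def extend(chain: list[int], broken: int | None) -> None:
        depth = len(chain) - 1
        if depth == 5:
            if broken is None:
                return
            gaps = tuple(b - a - 1 for a, b in zip(chain, chain[1:]))
            matches.append(
                CrdMatch(
                    start=chain[0] + 1,
                    end=chain[-1] + 1,
                    gaps=gaps,
                    label=motif.label,
                    cys_positions=tuple(p + 1 for p in chain),
                    interrupted=True,
                    interrupted_gap_index=broken,
                )
            )
            return
        lo, hi = ranges[depth]
        last = chain[-1]
        for pos in cys:
            if pos <= last:
                continue
            gap = pos - last - 1
            if gap > hi + max_insert:
                break
            if lo <= gap <= hi:
                extend(chain + [pos], broken)
            elif gap > hi and broken is None:
                segment = seq[last + 1 : pos]
                pro = segment.count("P") / len(segment)
                if pro >= min_pro_fraction:
                    extend(chain + [pos], depth)

    for start in cys:
        extend([start], None)
    matches.sort(key=lambda m: (m.start, m.end))
    return matches


def count_gxy(
    protein: str | SeqRecord,
    search_region: tuple[int, int] | None = None,
) -> tuple[int, int | None, int | None]:
    """Longest run of consecutive complete triplets each beginning with glycine.

    Returns ``(count, start, end)`` with 1-based inclusive coordinates of the
    leftmost best run, or ``(0, None, None)`` when no G-led triplet exists.
    ``search_region`` restricts the scan (1-based inclusive).
    """
    seq = protein.seq if isinstance(protein, SeqRecord) else protein
    offset = 0
    if search_region is not None:
        lo, hi = search_region
        seq = seq[lo - 1 : hi]
        offset = lo - 1
    best = (0, None, None)
    n = len(seq)
    for i in range(n):
        if seq[i] != "G":
            continue
        k = 0
        while i + 3 * k + 2 < n and seq[i + 3 * k] == "G":
            k += 1
        if k > best[0]:
            best = (k, offset + i + 1, offset + i + 3 * k)
    return best


def classify_linker(
    segment: str,
    theta_p: float = 0.30,
    theta_sg: float = 0.50,
) -> tuple[str, dict[str, float]]:
    """Classify a linker segment as polyP, SG_rich or other by composition."""
    if not segment:
        raise ValueError("empty linker segment")
    counts: dict[str, int] = {}
    for aa in segment:
        counts[aa] = counts.get(aa, 0) + 1
    n = len(segment)
    composition = {aa: c / n for aa, c in sorted(counts.items())}
    if composition.get("P", 0.0) >= theta_p:
        return "polyP", composition
    if composition.get("S", 0.0) + composition.get("G", 0.0) >= theta_sg:
        return "SG_rich", composition
    return "other", composition


def detect_kr(propeptide_segment: str, anywhere: bool = False) -> bool:
    """True iff the KR dipeptide terminates the propeptide (or occurs anywhere)."""
    if len(propeptide_segment) < 2:
        warnings.warn("propeptide shorter than 2 residues; KR undetectable", stacklevel=2)
        return False
    if anywhere:
        return "KR" in propeptide_segment
    return propeptide_segment.endswith("KR")


@dataclass(frozen=True)
class DomainAnnotation:
    """One located domain; coordinates 1-based inclusive."""

    seq_id: str
    dtype: str  # signal | propeptide | N_CRD | linker | GXY | C_CRD
    start: int
    end: int
    attributes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"domain start {self.start} > end {self.end}")

    def to_gff(self) -> GffFeature:
        return GffFeature(
            seqid=self.seq_id,
            ftype=self.dtype,
            start=self.start,
            end=self.end,
            attributes={k: v for k, v in self.attributes.items()},
        )


@dataclass(frozen=True)
class MinicollagenArchitecture:
    seq_id: str
    length: int
    domains: tuple[DomainAnnotation, ...]
    gxy_repeat_count: int
    kr_present: bool
    linker_classes: tuple[str, ...]
    ncol_call: str = "unclassified"
    confidence: float = 0.0
    rule_hits: tuple[str, ...] = ()

    def domain(self, dtype: str) -> DomainAnnotation | None:
        for d in self.domains:
            if d.dtype == dtype:
                return d
        return None

    def linkers_after(self, dtype: str) -> list[DomainAnnotation]:
        ref = self.domain(dtype)
        if ref is None:
            return []
        return [d for d in self.domains if d.dtype == "linker" and d.start > ref.end]


@dataclass(frozen=True)
class ScanConfig:
    n_crd_motifs: tuple[CrdMotif, ...] = (CANONICAL, NONCANONICAL_C)
    c_crd_motifs: tuple[CrdMotif, ...] = (CANONICAL, NONCANONICAL_C)
    tolerance: int = 1
    theta_p: float = 0.30
    theta_sg: float = 0.50
    kr_anywhere: bool = False
    call_threshold: float = 0.8


def _first_match_in(
    matches: list[CrdMatch], lo: int | None = None, hi: int | None = None
) -> CrdMatch | None:
    for m in matches:
        if lo is not None and m.start < lo:
            continue
        if hi is not None and m.end > hi:
            continue
        return m
    return None


def build_architecture(
    protein: SeqRecord | str,
    config: ScanConfig | None = None,
    annotations: Sequence[GffFeature] = (),
) -> MinicollagenArchitecture:
    """Locate domains in order signal?, propeptide?, N-CRD, linker, GXY, linker, C-CRD.

    Signal/propeptide boundaries are taken from external annotations when
    given; otherwise the propeptide is the span from position 1 to the
    residue before the N-CRD.  Gaps between located domains become linker
    annotations.  Deterministic for a given input.
    """
    cfg = config or ScanConfig()
    if isinstance(protein, str):
        protein = SeqRecord(id="query", seq=protein)
    seq = protein.seq
    if len(seq) < 30:
        raise ValueError(f"protein {protein.id!r} shorter than 30 residues")

    ext = {f.ftype: f for f in annotations if f.seqid == protein.id}

    gxy_count, gxy_start, gxy_end = count_gxy(seq)
    has_gxy = gxy_count >= 2  # single G-led triplets are noise, not a collagen domain

    # N-CRD: leftmost motif match ending before the GXY domain (or anywhere).
    n_crd: CrdMatch | None = None
    n_limit = gxy_start - 1 if has_gxy else None
    for motif in cfg.n_crd_motifs:
        cand = _first_match_in(find_crd(seq, motif, cfg.tolerance), hi=n_limit)
        if cand is not None and (n_crd is None or cand.start < n_crd.start):
            n_crd = cand

    # C-CRD: leftmost match starting after the GXY domain (or after the N-CRD).
    c_lo = (gxy_end + 1) if has_gxy else (n_crd.end + 1 if n_crd else None)
    c_crd: CrdMatch | None = None
    if c_lo is not None:
        for motif in cfg.c_crd_motifs:
            cand = _first_match_in(find_crd(seq, motif, cfg.tolerance), lo=c_lo)
            if cand is not None and (c_crd is None or cand.start < c_crd.start):
                c_crd = cand
        if c_crd is None:
            cand = _first_match_in(
                find_interrupted_crd(seq, CANONICAL, cfg.tolerance), lo=c_lo
            )
            if cand is not None:
                c_crd = cand

    if n_crd is None and not has_gxy:
        return MinicollagenArchitecture(
            seq_id=protein.id,
            length=len(seq),
            domains=(),
            gxy_repeat_count=0,
            kr_present=False,
            linker_classes=(),
        )

    domains: list[DomainAnnotation] = []
    kr_present = False

    if "signal" in ext:
        f = ext["signal"]
        domains.append(DomainAnnotation(protein.id, "signal", f.start, f.end))

    if n_crd is not None:
        if "propeptide" in ext:
            f = ext["propeptide"]
            pro_span = (f.start, f.end)
        else:
            pro_start = ext["signal"].end + 1 if "signal" in ext else 1
            pro_span = (pro_start, n_crd.start - 1) if n_crd.start > pro_start else None
        if pro_span is not None:
            pro_seq = seq[pro_span[0] - 1 : pro_span[1]]
            kr_present = detect_kr(pro_seq, cfg.kr_anywhere) if len(pro_seq) >= 2 else False
            domains.append(
                DomainAnnotation(
                    protein.id,
                    "propeptide",
                    pro_span[0],
                    pro_span[1],
                    {"kr_present": kr_present},
                )
            )
        domains.append(
            DomainAnnotation(
                protein.id,
                "N_CRD",
                n_crd.start,
                n_crd.end,
                {"motif": n_crd.label, "gaps": ",".join(map(str, n_crd.gaps))},
            )
        )

    linker_classes: list[str] = []

    def add_linker(lo: int, hi: int) -> None:
        if hi < lo:
            return
        segment = seq[lo - 1 : hi]
        cls, comp = classify_linker(segment, cfg.theta_p, cfg.theta_sg)
        linker_classes.append(cls)
        domains.append(
            DomainAnnotation(protein.id, "linker", lo, hi, {"class": cls})
        )

    if has_gxy:
        if n_crd is not None:
            add_linker(n_crd.end + 1, gxy_start - 1)
        domains.append(
            DomainAnnotation(
                protein.id, "GXY", gxy_start, gxy_end, {"repeat_count": gxy_count}
            )
        )
        if c_crd is not None:
            add_linker(gxy_end + 1, c_crd.start - 1)
    elif n_crd is not None and c_crd is not None:
        add_linker(n_crd.end + 1, c_crd.start - 1)

    if c_crd is not None:
        attrs = {"motif": c_crd.label, "gaps": ",".join(map(str, c_crd.gaps))}
        if c_crd.interrupted:
            attrs["interrupted"] = "polyproline"
        domains.append(
            DomainAnnotation(protein.id, "C_CRD", c_crd.start, c_crd.end, attrs)
        )

    domains.sort(key=lambda d: (d.start, d.end))
    arch = MinicollagenArchitecture(
        seq_id=protein.id,
        length=len(seq),
        domains=tuple(domains),
        gxy_repeat_count=gxy_count if has_gxy else 0,
        kr_present=kr_present,
        linker_classes=tuple(linker_classes),
    )
    call, confidence, hits = classify_ncol(arch, call_threshold=cfg.call_threshold)
    return replace(arch, ncol_call=call, confidence=confidence, rule_hits=tuple(hits))


# ---------------------------------------------------------------------------
# Ncol typing rules


def _crd_label(arch: MinicollagenArchitecture, dtype: str) -> str | None:
    d = arch.domain(dtype)
    if d is None:
        return None
    return d.attributes.get("motif")


def _c_crd_interrupted(arch: MinicollagenArchitecture) -> bool:
    d = arch.domain("C_CRD")
    return d is not None and "interrupted" in d.attributes


def _no_polyp_after_gxy(arch: MinicollagenArchitecture) -> bool:
    return all(
        d.attributes.get("class") != "polyP" for d in arch.linkers_after("GXY")
    )


_RuleTable = dict[str, list[tuple[str, Callable[[MinicollagenArchitecture], bool]]]]

DEFAULT_RULES: _RuleTable = {
    "Ncol-5": [
        ("canonical_N_CRD", lambda a: _crd_label(a, "N_CRD") == "canonical"),
        (
            "noncanonical_C_CRD",
            lambda a: _crd_label(a, "C_CRD") == "noncanonical_C"
            and not _c_crd_interrupted(a),
        ),
        ("gxy_16_24", lambda a: 16 <= a.gxy_repeat_count <= 24),
        ("sg_rich_linker", lambda a: "SG_rich" in a.linker_classes),
        ("kr_absent", lambda a: not a.kr_present),
    ],
    "Ncol-4": [
        ("gxy_4_7", lambda a: 4 <= a.gxy_repeat_count <= 7),
        ("no_polyP_after_gxy", _no_polyp_after_gxy),
        ("C_CRD_interrupted_by_polyproline", _c_crd_interrupted),
    ],
    "Ncol-1/2/3-group": [
        ("canonical_N_CRD", lambda a: _crd_label(a, "N_CRD") == "canonical"),
        (
            "canonical_C_CRD",
            lambda a: _crd_label(a, "C_CRD") == "canonical"
            and not _c_crd_interrupted(a),
        ),
        ("gxy_12_16", lambda a: 12 <= a.gxy_repeat_count <= 16),
        ("polyP_linker", lambda a: "polyP" in a.linker_classes),
    ],
}

_CALL_PRIORITY = ("Ncol-5", "Ncol-4", "Ncol-1/2/3-group")


def classify_ncol(
    arch: MinicollagenArchitecture,
    rules: _RuleTable | None = None,
    call_threshold: float = 0.8,
) -> tuple[str, float, list[str]]:
    """Apply the rule table; call = rule set with highest confidence >= threshold.

    Confidence of a candidate class is satisfied/total rules; ties break by
    the fixed priority Ncol-5, Ncol-4, Ncol-1/2/3-group.
    """
    table = rules or DEFAULT_RULES
    best_call = "unclassified"
    best_conf = 0.0
    best_hits: list[str] = []
    order = [c for c in _CALL_PRIORITY if c in table] + [
        c for c in table if c not in _CALL_PRIORITY
    ]
    for cls in order:
        cls_rules = table[cls]
        hits = [name for name, pred in cls_rules if pred(arch)]
        conf = len(hits) / len(cls_rules)
        if conf > best_conf:
            best_call, best_conf, best_hits = cls, conf, hits
    if best_conf < call_threshold:
        return "unclassified", best_conf, best_hits
    return best_call, best_conf, best_hits
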