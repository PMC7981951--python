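"""Deterministic seeded generators for every fixture the toolkit needs.

Contamination is substitution-only (no indels), so each derived contig's
true identity to its source is exactly ``1 - substitutions/length`` and a
single full-length HSP describes it; this keeps filter acceptance analytic
rather than aligner-dependent.  All randomness flows from one numpy
``default_rng`` seeded explicitly, and the seed is recorded in output
headers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .genecluster import GeneLocus
from .seqio import GffFeature, HspRecord, SeqRecord

__all__ = [
    "SynthSpec",
    "ArchitectureParams",
    "TruthRow",
    "make_transcriptome",
    "emit_hsps",
    "make_minicollagen",
    "make_architecture_grid",
    "make_gene_fixture",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class ArchitectureParams:
    """Planted minicollagen architecture parameters."""

    name: str
    gxy_count: int
    n_crd_gaps: tuple[int, ...] = (3, 3, 3, 3, 0)
    c_crd_gaps: tuple[int, ...] = (3, 3, 3, 3, 0)
    c_crd_interrupted: bool = False
    linker_class: str = "SG_rich"  # linker before GXY
    linker2_class: str | None = None  # linker after GXY; defaults to linker_class
    kr: bool = False
    expected_call: str | None = None

    @property
    def linker2(self) -> str:
        return self.linker2_class if self.linker2_class is not None else self.linker_class


@dataclass(frozen=True)
class SynthSpec:
    seed: int = 0
    n_target: int = 10
    n_contaminant: int = 5
    n_host: int = 0
    length_range: tuple[int, int] = (200, 1000)
    gc: float = 0.40
    divergence: float = 0.02  # contaminant vs its source
    target_divergence: float = 0.15  # target "noise" divergence vs its source
    architecture_grid: tuple[ArchitectureParams, ...] = ()
    intron_plantings: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if not (0.0 <= self.divergence <= 1.0):
            raise ValueError("divergence must be in [0,1]")
        if not (0.0 <= self.gc <= 1.0):
            raise ValueError("gc must be in [0,1]")


@dataclass(frozen=True)
class TruthRow:
    contig_id: str
    cls: str  # target | contaminant | host
    length: int
    source_id: str | None
    n_substitutions: int
    identity: float  # exactly 1 - n_substitutions/length


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(_BASES, size=length, p=p))


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> tuple[str, int]:
    """Substitution-only mutation; returns mutated sequence and exact count.

    Exactly ``round(rate * length)`` positions are substituted (uniformly
    chosen without replacement) rather than a Bernoulli draw per base, so the
    realised divergence never strays from the requested rate and identity
    thresholds separate target from contaminant deterministically.
    """
    arr = np.array(list(seq))
    n = int(round(rate * len(arr)))
    positions = rng.choice(len(arr), size=n, replace=False) if n else []
    for i in positions:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return "".join(arr), n


def make_transcriptome(spec: SynthSpec) -> tuple[list[SeqRecord], list[TruthRow]]:
    """Labelled target/contaminant/host contigs with an exact truth table.

    Target and contaminant contigs are each derived from their own random
    source sequence by per-base substitution at ``target_divergence`` and
    ``divergence`` respectively; host contigs are independent random
    sequences.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.length_range
    records: list[SeqRecord] = []
    truth: list[TruthRow] = []

    def derived(prefix: str, count: int, rate: float) -> None:
        for i in range(count):
            length = int(rng.integers(lo, hi + 1))
            source = _random_seq(rng, length, spec.gc)
            seq, n_subs = _mutate(rng, source, rate)
            cid = f"{prefix}_{i + 1}"
            records.append(
                SeqRecord(
                    id=cid,
                    seq=seq,
                    description=f"{cid} class={prefix} seed={spec.seed}",
                )
            )
            truth.append(
                TruthRow(
                    contig_id=cid,
                    cls=prefix,
                    length=length,
                    source_id=f"{prefix}_src_{i + 1}",
                    n_substitutions=n_subs,
                    identity=1.0 - n_subs / length,
                )
            )

    derived("target", spec.n_target, spec.target_divergence)
    derived("contaminant", spec.n_contaminant, spec.divergence)
    for i in range(spec.n_host):
        length = int(rng.integers(lo, hi + 1))
        cid = f"host_{i + 1}"
        records.append(
            SeqRecord(
                id=cid,
                seq=_random_seq(rng, length, spec.gc),
                description=f"{cid} class=host seed={spec.seed}",
            )
        )
        truth.append(
            TruthRow(
                contig_id=cid,
                cls="host",
                length=length,
                source_id=None,
                n_substitutions=0,
                identity=0.0,
            )
        )
    return records, truth


def emit_hsps(
    truth: Sequence[TruthRow],
    include_target_noise: bool = False,
) -> tuple[list[HspRecord], list[HspRecord]]:
    """Stand-in for external BLAST: (host_hits, contaminant_hits).

    Each contaminant contig gets one full-length HSP against its source with
    ``pident`` equal to its exact true identity x100; host contigs get one
    arbitrary host hit; target contigs get none unless ``include_target_noise``
    adds their full-length source hit at the (lower) target identity.
    """
    host_hits: list[HspRecord] = []
    contaminant_hits: list[HspRecord] = []

    def full_length(row: TruthRow) -> HspRecord:
        return HspRecord(
            query_id=row.contig_id,
            subject_id=row.source_id or "subject",
            pct_identity=row.identity * 100.0,
            aln_len=row.length,
            mismatches=row.n_substitutions,
            gap_opens=0,
            q_start=1,
            q_end=row.length,
            s_start=1,
            s_end=row.length,
            evalue=1e-50,
            bitscore=2.0 * row.length,
        )

    for row in truth:
        if row.cls == "contaminant":
            contaminant_hits.append(full_length(row))
        elif row.cls == "host":
            host_hits.append(
                HspRecord(
                    query_id=row.contig_id,
                    subject_id="host_genome",
                    pct_identity=99.0,
                    aln_len=min(row.length, 100),
                    mismatches=1,
                    gap_opens=0,
                    q_start=1,
                    q_end=min(row.length, 100),
                    s_start=1,
                    s_end=min(row.length, 100),
                    evalue=1e-40,
                    bitscore=180.0,
                )
            )
        elif row.cls == "target" and include_target_noise:
            contaminant_hits.append(full_length(row))
    return host_hits, contaminant_hits


# ---------------------------------------------------------------------------
# Minicollagen protein fixtures

_SIGNAL_AA = "LIVFAMW"
_PRO_AA = "ASTNQDE"
_GAP_FILL = "ANTQ"
_XY_AA = "PAQ"
_POLYP_UNIT = "PPPQ"
_SG_UNIT = "SSGS"  # G never 3k residues from a linker boundary: no run extension
_S_UNIT = "SSST"  # G-free SG-class filler used when no collagen domain is planted
_LINKER_LEN = 12
_INTERRUPT = "P" * 12


def _linker_seq(cls: str, allow_g: bool) -> str:
    if cls == "polyP":
        unit = _POLYP_UNIT
    elif cls == "SG_rich":
        unit = _SG_UNIT if allow_g else _S_UNIT
    else:
        raise ValueError(f"unsupported planted linker class {cls!r}")
    return (unit * ((_LINKER_LEN // len(unit)) + 1))[:_LINKER_LEN]


def _crd_seq(
    rng: np.random.Generator, gaps: Sequence[int], interrupted: bool
) -> str:
    parts = ["C"]
    for gi, gap in enumerate(gaps):
        fill = "".join(rng.choice(list(_GAP_FILL), size=gap))
        if interrupted and gi == 1:
            mid = gap // 2
            fill = fill[:mid] + _INTERRUPT + fill[mid:]
        parts.append(fill)
        parts.append("C")
    return "".join(parts)


def make_minicollagen(
    params: ArchitectureParams, seed: int = 0
) -> tuple[SeqRecord, list[GffFeature]]:
    """Assemble a protein with the planted architecture plus its truth GFF3 features.

    Layout: signal (15-20 aa), propeptide (6-12 aa, optionally KR-terminal),
    N-CRD with the exact chosen gaps, linker, Gly-X-Y run of the exact planted
    count, linker, C-CRD.  Fill alphabets avoid cysteine outside the CRDs and
    glycine outside the collagen domain and SG linkers, so the scanner's
    recovery is exact by construction.
    """
    if params.gxy_count < 0:
        raise ValueError("gxy_count must be >= 0")
    if len(params.n_crd_gaps) != 5 or len(params.c_crd_gaps) != 5:
        raise ValueError("CRD gap tuples must have 5 entries")
    rng = np.random.default_rng(seed)
    allow_g = params.gxy_count > 0

    signal = "".join(rng.choice(list(_SIGNAL_AA), size=int(rng.integers(15, 21))))
    pro = "".join(rng.choice(list(_PRO_AA), size=int(rng.integers(6, 13))))
    if params.kr:
        pro = pro[:-2] + "KR"
    n_crd = _crd_seq(rng, params.n_crd_gaps, interrupted=False)
    linker1 = _linker_seq(params.linker_class, allow_g)
    gxy = "".join(
        "G" + "".join(rng.choice(list(_XY_AA), size=2)) for _ in range(params.gxy_count)
    )
    linker2 = _linker_seq(params.linker2, allow_g)
    c_crd = _crd_seq(rng, params.c_crd_gaps, interrupted=params.c_crd_interrupted)

    if params.gxy_count > 0:
        segments = [
            ("signal", signal),
            ("propeptide", pro),
            ("N_CRD", n_crd),
            ("linker", linker1),
            ("GXY", gxy),
            ("linker", linker2),
            ("C_CRD", c_crd),
        ]
    else:
        segments = [
            ("signal", signal),
            ("propeptide", pro),
            ("N_CRD", n_crd),
            ("linker", linker1),
            ("C_CRD", c_crd),
        ]

    seq_parts: list[str] = []
    features: list[GffFeature] = []
    pos = 1
    for dtype, segment in segments:
        seq_parts.append(segment)
        attrs: dict = {"planted": "true"}
        if dtype == "GXY":
            attrs["repeat_count"] = params.gxy_count
        if dtype == "linker":
            attrs["class"] = params.linker_class if not features or all(
                f.ftype != "GXY" for f in features
            ) else params.linker2
        if dtype == "propeptide":
            attrs["kr_present"] = str(params.kr).lower()
        if dtype == "N_CRD":
            attrs["gaps"] = ",".join(map(str, params.n_crd_gaps))
        if dtype == "C_CRD":
            attrs["gaps"] = ",".join(map(str, params.c_crd_gaps))
            if params.c_crd_interrupted:
                attrs["interrupted"] = "polyproline"
        features.append(
            GffFeature(
                seqid=params.name,
                ftype=dtype,
                start=pos,
                end=pos + len(segment) - 1,
                attributes=attrs,
            )
        )
        pos += len(segment)

    record = SeqRecord(
        id=params.name,
        seq="".join(seq_parts),
        description=f"{params.name} planted seed={seed}",
    )
    return record, features


def make_architecture_grid(seed: int = 0) -> list[ArchitectureParams]:
    """A grid of >=200 planted architectures spanning the rule space.

    Covers Gly-X-Y counts 4-24, CRD gap variants within tolerance, linker
    classes and KR on/off, each tagged with the class label the rule table
    must recover.
    """
    rng = np.random.default_rng(seed)
    grid: list[ArchitectureParams] = []
    idx = 0

    def vary3(base: int = 3) -> int:
        return base + int(rng.integers(-1, 2))

    # Ncol-5: canonical N-CRD, noncanonical C-CRD, 16-24 repeats, SG linkers, no KR
    for gxy in range(16, 25):
        for rep in range(8):
            idx += 1
            grid.append(
                ArchitectureParams(
                    name=f"ncol5_{idx}",
                    gxy_count=gxy,
                    n_crd_gaps=(vary3(), vary3(), vary3(), vary3(), 0),
                    c_crd_gaps=(vary3(), int(rng.integers(9, 11)), vary3(), vary3(), 0),
                    linker_class="SG_rich",
                    kr=False,
                    expected_call="Ncol-5",
                )
            )
    # Ncol-4: 4-7 repeats, no polyP after GXY, C-CRD interrupted by polyproline
    for gxy in range(4, 8):
        for rep in range(16):
            idx += 1
            grid.append(
                ArchitectureParams(
                    name=f"ncol4_{idx}",
                    gxy_count=gxy,
                    n_crd_gaps=(vary3(), vary3(), vary3(), vary3(), 0),
                    c_crd_gaps=(vary3(), vary3(), vary3(), vary3(), 0),
                    c_crd_interrupted=True,
                    linker_class="SG_rich",
                    kr=bool(rng.integers(0, 2)),
                    expected_call="Ncol-4",
                )
            )
    # Ncol-1/2/3-group: canonical CRDs, 12-16 repeats, polyP linkers
    for gxy in range(12, 17):
        for rep in range(14):
            idx += 1
            grid.append(
                ArchitectureParams(
                    name=f"ncol123_{idx}",
                    gxy_count=gxy,
                    n_crd_gaps=(vary3(), vary3(), vary3(), vary3(), 0),
                    c_crd_gaps=(vary3(), vary3(), vary3(), vary3(), 0),
                    linker_class="polyP",
                    kr=True,
                    expected_call="Ncol-1/2/3-group",
                )
            )
    return grid


# ---------------------------------------------------------------------------
# Genomic fixtures: planted introns and gene clusters


def make_gene_fixture(
    seed: int = 0,
    transcript_len: int = 400,
    intron_lengths: Sequence[int] = (32, 40),
    gc: float = 0.40,
    igr: int = 250,
    strands: tuple[str, str] = ("+", "-"),
    canonical: bool = True,
    min_anchor: int = 15,
) -> dict:
    """Genomic+transcript pair with planted introns, plus a two-gene locus table.

    Returns a dict with keys ``transcript`` (SeqRecord), ``genomic``
    (SeqRecord), ``introns`` (list of (transcript_pos, length)), ``loci``
    (list of GeneLocus) and ``igr``.
    """
    rng = np.random.default_rng(seed)
    for L in intron_lengths:
        if L < 4:
            raise ValueError("intron length must be >= 4 (room for GT..AG)")
    n = len(intron_lengths)
    if transcript_len < (n + 1) * min_anchor + 2:
        raise ValueError("transcript too short for the requested plantings")
    transcript = _random_seq(rng, transcript_len, gc)

    # insertion points separated by >= min_anchor exon bases, away from ends
    usable = transcript_len - 2 * min_anchor
    offsets = sorted(
        rng.choice(np.arange(usable - (n - 1) * min_anchor), size=n, replace=False)
    ) if n else []
    positions = [int(off) + min_anchor + i * min_anchor for i, off in enumerate(offsets)]

    genomic_parts: list[str] = []
    introns: list[tuple[int, int]] = []
    prev = 0
    for pos, length in zip(positions, intron_lengths):
        genomic_parts.append(transcript[prev:pos])
        if canonical:
            body = "GT" + _random_seq(rng, length - 4, gc) + "AG"
        else:
            body = _random_seq(rng, length, gc)
        genomic_parts.append(body)
        introns.append((pos, length))
        prev = pos
    genomic_parts.append(transcript[prev:])
    genomic = "".join(genomic_parts)

    gene1_len = int(rng.integers(300, 800))
    gene2_len = int(rng.integers(300, 800))
    g1_start = 100
    g1_end = g1_start + gene1_len - 1
    g2_start = g1_end + igr + 1
    loci = [
        GeneLocus("scaffold_1", g1_start, g1_end, strands[0], "geneA"),
        GeneLocus("scaffold_1", g2_start, g2_start + gene2_len - 1, strands[1], "geneB"),
    ]
    return {
        "transcript": SeqRecord("transcript_1", transcript, f"transcript_1 seed={seed}"),
        "genomic": SeqRecord("genomic_1", genomic, f"genomic_1 seed={seed}"),
        "introns": introns,
        "loci": loci,
        "igr": igr,
    }
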