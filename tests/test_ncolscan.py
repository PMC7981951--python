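import itertools

import numpy as np
import pytest

from myxocol import synth
from myxocol.ncolscan import (
    CANONICAL,
    NONCANONICAL_C,
    CrdMotif,
    build_architecture,
    classify_linker,
    classify_ncol,
    count_gxy,
    detect_kr,
    find_crd,
    find_interrupted_crd,
)
from myxocol.seqio import SeqRecord


def brute_force_crd(seq, motif, tolerance):
    """All 6-cysteine combinations checked against the widened gap ranges."""
    ranges = [(max(0, lo - tolerance), hi + tolerance) for lo, hi in motif.gap_ranges]
    cys = [i for i, aa in enumerate(seq) if aa == "C"]
    out = set()
    for combo in itertools.combinations(cys, 6):
        gaps = [b - a - 1 for a, b in zip(combo, combo[1:])]
        if all(lo <= g <= hi for g, (lo, hi) in zip(gaps, ranges)):
            out.add((combo[0] + 1, combo[-1] + 1, tuple(gaps)))
    return out


def brute_force_gxy(seq):
    """Independent maximal-run search over all start offsets."""
    best = (0, None, None)
    for i in range(len(seq)):
        count = 0
        for j in range(i, len(seq) - 2, 3):
            if seq[j] == "G":
                count += 1
            else:
                break
        if count > best[0]:
            best = (count, i + 1, i + 3 * count)
    return best


class TestFindCrd:
    def test_constructed_exact_canonical(self):
        seq = "CAAACAAACAAACAAACC"
        matches = find_crd(seq, CANONICAL, tolerance=0)
        assert len(matches) == 1
        assert (matches[0].start, matches[0].end) == (1, 18)
        assert matches[0].gaps == (3, 3, 3, 3, 0)

    def test_noncanonical_9_10_spacing(self):
        seq = "CAAAC" + "A" * 9 + "CAAACAAACC"
        matches = find_crd(seq, NONCANONICAL_C, tolerance=0)
        assert len(matches) == 1
        assert matches[0].gaps == (3, 9, 3, 3, 0)

    def test_five_cysteines_no_match(self):
        assert find_crd("CAAACAAACAAACC", CANONICAL) == []

    def test_bad_motif_rejected(self):
        with pytest.raises(ValueError):
            CrdMotif(((3, 3), (3, 3)), "broken")

    def test_tolerance_widens_gaps(self):
        seq = "CAACAAACAAAACAAACC"  # gaps 2,3,4,3,0
        assert find_crd(seq, CANONICAL, tolerance=0) == []
        assert len(find_crd(seq, CANONICAL, tolerance=1)) == 1

    def test_x_never_matches_cysteine(self):
        seq = "XAAACAAACAAACAAACC"  # X in C1 position
        assert find_crd(seq, CANONICAL, tolerance=0) == []

    @pytest.mark.parametrize("motif", [CANONICAL, NONCANONICAL_C])
    @pytest.mark.parametrize("tolerance", [0, 1])
    def test_brute_force_equivalence(self, rng, motif, tolerance):
        alphabet = list("ACDEFGAAC")  # C-enriched to exercise the search
        for _ in range(100):
            # short enough that the C(n_cys, 6) enumeration stays tractable
            seq = "".join(rng.choice(alphabet, size=int(rng.integers(10, 90))))
            got = {(m.start, m.end, m.gaps) for m in find_crd(seq, motif, tolerance)}
            assert got == brute_force_crd(seq, motif, tolerance)

    def test_matches_left_to_right(self, rng):
        seq = "CAAACAAACAAACAAACC" + "AAA" + "CAAACAAACAAACAAACC"
        matches = find_crd(seq, CANONICAL, tolerance=0)
        starts = [m.start for m in matches]
        assert starts == sorted(starts)
        assert len(matches) == 2


class TestInterruptedCrd:
    def test_polyproline_insert_detected(self):
        seq = "CAAAC" + "A" + "PPPPPPPPPPPP" + "AA" + "CAAACAAACC"
        matches = find_interrupted_crd(seq, CANONICAL, tolerance=0)
        assert len(matches) == 1
        assert matches[0].interrupted
        assert matches[0].interrupted_gap_index == 1

    def test_non_proline_insert_rejected(self):
        seq = "CAAAC" + "A" + "EEEEEEEEEEEE" + "AA" + "CAAACAAACC"
        assert find_interrupted_crd(seq, CANONICAL, tolerance=0) == []

    def test_intact_crd_not_reported_as_interrupted(self):
        assert find_interrupted_crd("CAAACAAACAAACAAACC", CANONICAL) == []


class TestCountGxy:
    def test_four_repeats(self):
        assert count_gxy("GPPGPQGAPGQA") == (4, 1, 12)

    def test_no_glycine(self):
        assert count_gxy("AAAA") == (0, None, None)

    def test_broken_run(self):
        assert count_gxy("GPPAPPGPP")[0] == 1

    def test_trailing_partial_triplet_not_counted(self):
        assert count_gxy("GPPGP")[0] == 1

    def test_search_region_restriction(self):
        seq = "AAAGPPGPPAAA"
        assert count_gxy(seq, search_region=(4, 9)) == (2, 4, 9)

    def test_brute_force_equivalence(self, rng):
        for _ in range(300):
            seq = "".join(rng.choice(list("GAP"), size=int(rng.integers(1, 120))))
            assert count_gxy(seq) == brute_force_gxy(seq)


class TestClassifyLinker:
    def test_polyp(self):
        cls, comp = classify_linker("PPQPPAPPSP")
        assert cls == "polyP"
        assert comp["P"] == pytest.approx(0.7)

    def test_sg_rich(self):
        cls, _ = classify_linker("SGSGSGGSSG")
        assert cls == "SG_rich"

    def test_other(self):
        assert classify_linker("ALKVMNDE")[0] == "other"

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            classify_linker("")

    def test_polyp_takes_precedence(self):
        # 4/10 P and 6/10 S+G satisfy both thresholds; polyP checked first
        assert classify_linker("PPPPSSGGSG")[0] == "polyP"


class TestDetectKr:
    def test_terminal_kr(self):
        assert detect_kr("MASFVKR") is True

    def test_no_kr(self):
        assert detect_kr("MASFVKA") is False

    def test_non_terminal_kr_rejected_by_default(self):
        assert detect_kr("KRAAAA") is False
        assert detect_kr("KRAAAA", anywhere=True) is True

    def test_too_short_warns(self):
        with pytest.warns(UserWarning):
            assert detect_kr("K") is False


class TestBuildArchitecture:
    def test_planted_ncol5_recovered_at_planted_coordinates(self):
        params = synth.ArchitectureParams(
            name="p5", gxy_count=20, c_crd_gaps=(3, 9, 3, 3, 0), kr=False,
            expected_call="Ncol-5",
        )
        rec, truth = synth.make_minicollagen(params, seed=7)
        arch = build_architecture(rec)
        truth_spans = {f.ftype: (f.start, f.end) for f in truth}
        for dtype in ("N_CRD", "GXY", "C_CRD"):
            d = arch.domain(dtype)
            assert (d.start, d.end) == truth_spans[dtype], dtype
        assert arch.gxy_repeat_count == 20
        assert not arch.kr_present
        assert arch.ncol_call == "Ncol-5"

    def test_random_sequence_without_cysteines_unclassified(self, rng):
        seq = "".join(rng.choice(list("ADEFHIKLMNQRSTVWY"), size=200))
        arch = build_architecture(SeqRecord("rand", seq))
        assert arch.ncol_call == "unclassified"
        assert arch.confidence < 0.8

    def test_planted_ncol4_interrupted_c_crd(self):
        params = synth.ArchitectureParams(
            name="p4", gxy_count=4, c_crd_interrupted=True, kr=True,
            expected_call="Ncol-4",
        )
        rec, _ = synth.make_minicollagen(params, seed=11)
        arch = build_architecture(rec)
        assert arch.gxy_repeat_count == 4
        assert "C_CRD_interrupted_by_polyproline" in arch.rule_hits
        assert arch.ncol_call == "Ncol-4"

    def test_domains_ordered_and_nonoverlapping(self):
        for params in synth.make_architecture_grid(1)[:30]:
            rec, _ = synth.make_minicollagen(params, seed=5)
            arch = build_architecture(rec)
            prev_end = 0
            for d in arch.domains:
                assert d.start > prev_end
                prev_end = d.end

    def test_too_short_protein_rejected(self):
        with pytest.raises(ValueError):
            build_architecture(SeqRecord("tiny", "ACDEF"))

    def test_prefix_shift_stability(self):
        params = synth.ArchitectureParams(
            name="p5", gxy_count=18, c_crd_gaps=(3, 10, 3, 3, 0),
        )
        rec, _ = synth.make_minicollagen(params, seed=3)
        shifted = SeqRecord(rec.id, "WWWWWWWWWW" + rec.seq)
        base = build_architecture(rec)
        moved = build_architecture(shifted)
        base_spans = [(d.dtype, d.start, d.end) for d in base.domains
                      if d.dtype != "propeptide"]
        moved_spans = [(d.dtype, d.start - 10, d.end - 10) for d in moved.domains
                       if d.dtype != "propeptide"]
        assert moved_spans == base_spans
        assert moved.gxy_repeat_count == base.gxy_repeat_count


class TestClassifyNcol:
    def test_planted_ncol5_grid_all_called(self):
        for gxy in range(16, 25):
            params = synth.ArchitectureParams(
                name=f"g{gxy}", gxy_count=gxy, c_crd_gaps=(3, 9, 3, 3, 0)
            )
            rec, _ = synth.make_minicollagen(params, seed=gxy)
            arch = build_architecture(rec)
            assert arch.ncol_call == "Ncol-5", gxy

    def test_gxy5_interrupted_is_ncol4(self):
        params = synth.ArchitectureParams(
            name="k", gxy_count=5, c_crd_interrupted=True
        )
        rec, _ = synth.make_minicollagen(params, seed=2)
        assert build_architecture(rec).ncol_call == "Ncol-4"

    def test_canonical_polyp_gxy14_is_group(self):
        params = synth.ArchitectureParams(
            name="g", gxy_count=14, linker_class="polyP", kr=True
        )
        rec, _ = synth.make_minicollagen(params, seed=2)
        arch = build_architecture(rec)
        assert arch.ncol_call == "Ncol-1/2/3-group"

    def test_unclassified_confidence_below_threshold(self):
        params = synth.ArchitectureParams(
            name="odd", gxy_count=9, linker_class="polyP", kr=True
        )
        rec, _ = synth.make_minicollagen(params, seed=2)
        arch = build_architecture(rec)
        call, conf, _ = classify_ncol(arch)
        assert call == "unclassified"
        assert conf < 0.8
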