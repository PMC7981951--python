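import numpy as np
import pytest

from myxocol import hitcov
from myxocol.hitcov import FilterPolicy, filter_contigs, merge_hsps, two_stage_clean
from myxocol.seqio import SeqRecord

from conftest import make_hsp


def brute_force_score(hsps, contig_len):
    """Independent per-base max-identity oracle."""
    arr = np.zeros(contig_len)
    for h in hsps:
        s, e = h.q_start - 1, h.q_end
        arr[s:e] = np.maximum(arr[s:e], h.pct_identity / 100.0)
    return arr.sum() / contig_len


def random_hsps(rng, contig_id, contig_len, max_hsps=20):
    hsps = []
    for _ in range(int(rng.integers(0, max_hsps + 1))):
        s = int(rng.integers(1, contig_len + 1))
        e = int(rng.integers(s, contig_len + 1))
        hsps.append(
            make_hsp(
                query_id=contig_id,
                subject_id=f"s{rng.integers(0, 4)}",
                pct_identity=float(rng.uniform(0, 100)),
                q_start=s,
                q_end=e,
            )
        )
    return hsps


class TestMergeHsps:
    def test_no_hsps_score_zero(self):
        p = merge_hsps([], 200, contig_id="c1")
        assert p.similarity_score == 0.0
        assert p.segments == ()

    def test_full_identical_coverage(self):
        p = merge_hsps([make_hsp(pct_identity=100.0, q_start=1, q_end=200)], 200)
        assert p.similarity_score == 1.0

    def test_overlapping_hsps_per_base_max(self):
        # bases 1-100 at 0.95, 101-150 at 0.85 -> (100*0.95 + 50*0.85)/200
        a = make_hsp(q_start=1, q_end=100, pct_identity=95.0)
        b = make_hsp(q_start=51, q_end=150, pct_identity=85.0, subject_id="s2")
        p = merge_hsps([a, b], 200)
        assert p.similarity_score == pytest.approx(0.6875, abs=1e-15)

    def test_mixed_query_ids_error(self):
        with pytest.raises(ValueError, match="mixed"):
            merge_hsps([make_hsp(query_id="a"), make_hsp(query_id="b")], 500)

    def test_hsp_beyond_contig_error(self):
        with pytest.raises(ValueError, match="exceeds contig length"):
            merge_hsps([make_hsp(q_start=1, q_end=300)], 200)

    def test_segments_disjoint_sorted_within_bounds(self, rng):
        for _ in range(50):
            clen = int(rng.integers(50, 500))
            hsps = random_hsps(rng, "c1", clen)
            if not hsps:
                continue
            p = merge_hsps(hsps, clen)
            prev_end = 0
            for seg in p.segments:
                assert 0 <= seg.start < seg.end <= clen
                assert seg.start >= prev_end
                prev_end = seg.end
                assert 0.0 <= seg.best_identity <= 1.0

    def test_oracle_equivalence_500_random_contigs(self, rng):
        for i in range(500):
            clen = int(rng.integers(20, 800))
            hsps = random_hsps(rng, f"c{i}", clen)
            score = merge_hsps(hsps, clen, contig_id=f"c{i}").similarity_score
            assert score == pytest.approx(brute_force_score(hsps, clen), abs=1e-12)

    def test_order_independent_and_idempotent(self, rng):
        clen = 300
        hsps = random_hsps(rng, "c1", clen, max_hsps=15)
        if not hsps:
            hsps = [make_hsp(q_start=3, q_end=200)]
        ref = merge_hsps(hsps, clen)
        for _ in range(10):
            perm = list(rng.permutation(len(hsps)))
            assert merge_hsps([hsps[i] for i in perm], clen) == ref


def contigs_of(lengths):
    return {f"c{i}": l for i, l in enumerate(lengths)}


class TestFilterContigs:
    def test_above_threshold_removed(self):
        hits = [make_hsp(query_id="c0", q_start=1, q_end=92, pct_identity=100.0)]
        kept, removed, _ = filter_contigs({"c0": 100}, hits, threshold=0.90)
        assert removed == ["c0"]

    def test_boundary_score_kept(self):
        # score exactly 0.90 -> kept (strict inequality)
        hits = [make_hsp(query_id="c0", q_start=1, q_end=90, pct_identity=100.0)]
        kept, removed, decisions = filter_contigs({"c0": 100}, hits, threshold=0.90)
        assert decisions[0].score == pytest.approx(0.90, abs=1e-15)
        assert kept == ["c0"]

    def test_any_hit_policy(self):
        hits = [make_hsp(query_id="c0", pct_identity=40.0, q_start=1, q_end=50)]
        kept, removed, _ = filter_contigs(
            {"c0": 500, "c1": 500}, hits, policy=FilterPolicy.ANY_HIT
        )
        assert removed == ["c0"]
        assert kept == ["c1"]

    def test_unknown_contig_error(self):
        with pytest.raises(ValueError, match="ghost"):
            filter_contigs({"c0": 100}, [make_hsp(query_id="ghost", q_end=50)])

    def test_partition_and_decision_for_every_contig(self, rng):
        lengths = contigs_of(rng.integers(50, 400, size=30))
        hits = []
        for cid, clen in lengths.items():
            hits.extend(random_hsps(rng, cid, clen, max_hsps=5))
        kept, removed, decisions = filter_contigs(lengths, hits)
        assert set(kept) | set(removed) == set(lengths)
        assert not (set(kept) & set(removed))
        assert {d.contig_id for d in decisions} == set(lengths)

    def test_threshold_monotonicity(self, rng):
        lengths = contigs_of(rng.integers(50, 400, size=40))
        hits = []
        for cid, clen in lengths.items():
            hits.extend(random_hsps(rng, cid, clen, max_hsps=8))
        thresholds = [0.1, 0.3, 0.5, 0.7, 0.9, 0.95]
        removed_sets = [
            set(filter_contigs(lengths, hits, threshold=t)[1]) for t in thresholds
        ]
        for lower, higher in zip(removed_sets, removed_sets[1:]):
            assert higher <= lower

    def test_coverage_only_mode(self):
        # 50% of bases covered at identity above the floor
        hits = [make_hsp(query_id="c0", q_start=1, q_end=50, pct_identity=95.0)]
        _, _, decisions = filter_contigs(
            {"c0": 100}, hits, mode="coverage_only", identity_floor=0.90
        )
        assert decisions[0].score == pytest.approx(0.5)
        # below the floor the covered bases do not count
        hits = [make_hsp(query_id="c0", q_start=1, q_end=50, pct_identity=50.0)]
        _, _, decisions = filter_contigs(
            {"c0": 100}, hits, mode="coverage_only", identity_floor=0.90
        )
        assert decisions[0].score == 0.0


class TestTwoStageClean:
    def test_hand_enumerated_counts(self):
        # 10 contigs: 2 with host hits; of the rest, scores {0.95, 0.91, 0.50}
        lengths = {f"c{i}": 100 for i in range(10)}
        host = [
            make_hsp(query_id="c0", q_start=1, q_end=10),
            make_hsp(query_id="c1", q_start=1, q_end=10),
        ]
        contam = [
            make_hsp(query_id="c2", q_start=1, q_end=95, pct_identity=100.0),
            make_hsp(query_id="c3", q_start=1, q_end=91, pct_identity=100.0),
            make_hsp(query_id="c4", q_start=1, q_end=50, pct_identity=100.0),
        ]
        rep = two_stage_clean(lengths, host, contam, threshold=0.90)
        assert rep.counts == {"kept": 6, "host_removed": 2, "contaminant_removed": 2}
        assert set(rep.contaminant_removed) == {"c2", "c3"}

    def test_empty_hit_tables_keep_all(self):
        lengths = {f"c{i}": 100 for i in range(5)}
        rep = two_stage_clean(lengths, [], [])
        assert set(rep.kept) == set(lengths)
        assert rep.host_removed == () and rep.contaminant_removed == ()

    def test_stage_precedence_host_first(self):
        lengths = {"c0": 100}
        host = [make_hsp(query_id="c0", q_start=1, q_end=10)]
        contam = [make_hsp(query_id="c0", q_start=1, q_end=99, pct_identity=100.0)]
        rep = two_stage_clean(lengths, host, contam)
        assert rep.host_removed == ("c0",)
        assert rep.contaminant_removed == ()

    def test_counts_partition_input(self, rng):
        lengths = contigs_of(rng.integers(50, 300, size=25))
        host, contam = [], []
        for cid, clen in lengths.items():
            if rng.random() < 0.3:
                host.extend(random_hsps(rng, cid, clen, max_hsps=2))
            contam.extend(random_hsps(rng, cid, clen, max_hsps=4))
        rep = two_stage_clean(lengths, host, contam)
        assert (
            len(rep.kept) + len(rep.host_removed) + len(rep.contaminant_removed)
            == len(lengths)
        )
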