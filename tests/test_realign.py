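"""Tests for synteny-based exon realignment and the score filter."""

import edlib
import numpy as np
import pytest

from splicecons.genome_align_io import Exon, ExonSet, Genome, load_maf
from splicecons.realign import (
    RealignmentCandidate,
    ScoreBaseline,
    accept_candidate,
    completeness_report,
    compute_score_baseline,
    find_syntenic_unaligned,
    merge_alignment,
    realign_exon,
    realign_missing_exons,
    target_segment,
)

from conftest import infix_dp_oracle


def _mutate(rng, seq, n_edits):
    """Apply up to n random substitutions/insertions/deletions."""
    s = list(seq)
    for _ in range(n_edits):
        op = rng.integers(0, 3)
        pos = int(rng.integers(0, len(s))) if s else 0
        if op == 0 and s:
            s[pos] = "ACGT"[rng.integers(0, 4)]
        elif op == 1:
            s.insert(pos, "ACGT"[rng.integers(0, 4)])
        elif s:
            del s[pos]
    return "".join(s)


class TestRealignExon:
    def test_exact_substring_maps_everything(self):
        offsets, score = realign_exon("ACGTAC", "TTACGTACTT")
        assert score == 1.0
        assert offsets.tolist() == [2, 3, 4, 5, 6, 7]

    def test_substitution_keeps_columns_mapped(self):
        offsets, score = realign_exon("ACGTAC", "TTACGAACTT")
        assert score == 1.0
        assert offsets.tolist() == [2, 3, 4, 5, 6, 7]

    def test_deletion_in_target_unmaps_one_position(self):
        # segment lacks the exon's central base
        offsets, score = realign_exon("ACGTAC", "TTACGACTT")
        assert score == pytest.approx(5 / 6)
        assert (offsets >= 0).sum() == 5

    def test_leftmost_placement_on_repeated_substring(self):
        offsets, _ = realign_exon("ACG", "ACGACGACG")
        assert offsets.tolist() == [0, 1, 2]

    def test_empty_sequences_rejected(self):
        with pytest.raises(ValueError):
            realign_exon("", "ACGT")
        with pytest.raises(ValueError):
            realign_exon("ACGT", "")

    @pytest.mark.parametrize("seed", range(4))
    def test_random_instances_match_dp_oracle(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(50):
            elen = int(rng.integers(5, 50))
            exon = "".join("ACGT"[b] for b in rng.integers(0, 4, elen))
            flank_l = "".join("ACGT"[b] for b in rng.integers(0, 4, rng.integers(0, 200)))
            flank_r = "".join("ACGT"[b] for b in rng.integers(0, 4, rng.integers(0, 200)))
            core = _mutate(rng, exon, int(rng.integers(0, 4)))
            segment = (flank_l + core + flank_r)[:500]
            if not segment:
                continue
            offsets, score = realign_exon(exon, segment)
            o_offsets, o_score, o_dist = infix_dp_oracle(exon, segment)
            assert offsets.tolist() == o_offsets
            assert score == pytest.approx(o_score)
            # independent check of the optimal distance via edlib infix mode
            ed = edlib.align(exon, segment, mode="HW")["editDistance"]
            assert ed == o_dist

    def test_mapped_offsets_strictly_increase(self):
        rng = np.random.default_rng(99)
        for _ in range(50):
            exon = "".join("ACGT"[b] for b in rng.integers(0, 4, 30))
            segment = "".join("ACGT"[b] for b in rng.integers(0, 4, 120))
            offsets, score = realign_exon(exon, segment)
            mapped = offsets[offsets >= 0]
            assert (np.diff(mapped) > 0).all()
            assert score == pytest.approx(len(mapped) / len(exon))


class TestBaselineAndFilter:
    def test_mean_of_two_scores(self):
        baseline = ScoreBaseline("t", np.array([1.0, 0.5]), 0.75, 0.25)
        assert baseline.threshold == 0.5

    def test_identical_scores_have_zero_sd(self, tmp_path):
        text = (
            "##maf version=1\n\n"
            "a score=1\ns ref.chr1 0 10 + 100 AAAAAAAAAA\ns t.c 0 10 + 100 AAAAAAAAAA\n\n"
            "a score=1\ns ref.chr1 20 10 + 100 AAAAAAAAAA\ns t.c 20 10 + 100 AAAAAAAAAA\n\n"
        )
        path = tmp_path / "b.maf"
        path.write_text(text)
        aln = load_maf(path, "ref")
        exons = ExonSet([Exon("chr1", 0, 10), Exon("chr1", 20, 30)])
        baseline = compute_score_baseline(aln, exons, "t")
        assert baseline.mean == 1.0
        assert baseline.sd == 0.0
        assert baseline.threshold == 1.0

    def test_baseline_matches_textbook_mean_sd(self):
        rng = np.random.default_rng(3)
        scores = rng.random(50)
        mean = sum(scores) / len(scores)
        sd = (sum((x - mean) ** 2 for x in scores) / len(scores)) ** 0.5
        baseline = ScoreBaseline("t", scores, float(np.mean(scores)), float(np.std(scores)))
        assert baseline.mean == pytest.approx(mean)
        assert baseline.sd == pytest.approx(sd)

    def test_accept_strictly_above_threshold(self):
        cand = RealignmentCandidate(
            Exon("chr1", 0, 10), "t", Exon("chr1", 20, 30), Exon("chr1", 40, 50)
        )
        baseline = ScoreBaseline("t", np.array([]), 0.8, 0.1)
        cand.score_rprime = 0.9
        assert accept_candidate(cand, baseline)
        cand.score_rprime = 0.7  # exactly mu - sigma: rejected
        assert not accept_candidate(cand, baseline)

    def test_random_triples_match_inequality(self):
        rng = np.random.default_rng(8)
        for _ in range(200):
            r, mu, sd = rng.random(3)
            cand = RealignmentCandidate(
                Exon("chr1", 0, 5), "t", Exon("chr1", 10, 15), Exon("chr1", 20, 25)
            )
            cand.score_rprime = r
            assert accept_candidate(cand, ScoreBaseline("t", np.array([]), mu, sd)) == (
                r > mu - sd
            )


def three_exon_maf(tmp_path, withhold_middle=True):
    """Three exons at [10,20), [40,50), [70,80); middle optionally unaligned."""
    rows = [
        "##maf version=1",
        "",
        "a score=1",
        "s ref.chr1 10 10 + 200 ACGTACGTAC",
        "s t.c1 110 10 + 400 ACGTACGTAC",
        "",
    ]
    if not withhold_middle:
        rows += [
            "a score=1",
            "s ref.chr1 40 10 + 200 GGGGCCCCAA",
            "s t.c1 140 10 + 400 GGGGCCCCAA",
            "",
        ]
    rows += [
        "a score=1",
        "s ref.chr1 70 10 + 200 TTTTGGGGCC",
        "s t.c1 170 10 + 400 TTTTGGGGCC",
        "",
        # a half-covered region: gives the score baseline a non-zero spread
        "a score=1",
        "s ref.chr1 100 5 + 200 ACGTA",
        "s t.c1 200 5 + 400 ACGTA",
        "",
    ]
    path = tmp_path / "three.maf"
    path.write_text("\n".join(rows) + "\n")
    return load_maf(path, "ref")


class TestSyntenyAndSegments:
    def test_middle_unaligned_exon_is_syntenic(self, tmp_path):
        aln = three_exon_maf(tmp_path)
        exons = ExonSet(
            [Exon("chr1", 10, 20), Exon("chr1", 40, 50), Exon("chr1", 70, 80)]
        )
        triples = find_syntenic_unaligned(aln, exons, "t")
        assert len(triples) == 1
        exon, ea, eb = triples[0]
        assert exon.key() == ("chr1", 40, 50)
        assert ea.key() == ("chr1", 10, 20)
        assert eb.key() == ("chr1", 70, 80)

    def test_first_exon_without_upstream_flank_omitted(self, tmp_path):
        aln = three_exon_maf(tmp_path, withhold_middle=False)
        exons = ExonSet(
            [Exon("chr1", 0, 5), Exon("chr1", 10, 20), Exon("chr1", 40, 50)]
        )
        triples = find_syntenic_unaligned(aln, exons, "t")
        assert triples == []

    def test_target_segment_from_anchor_extremes(self, tmp_path):
        aln = three_exon_maf(tmp_path)
        seg = target_segment(aln, Exon("chr1", 10, 20), Exon("chr1", 70, 80), "t")
        # A(e_a) = {110..119}, A(e_b) = {170..179} -> u = [120, 169] inclusive
        assert seg == ("c1", 120, 170)

    def test_inverted_anchor_order_is_invalid(self, tmp_path):
        aln = three_exon_maf(tmp_path)
        assert target_segment(aln, Exon("chr1", 70, 80), Exon("chr1", 10, 20), "t") is None

    def test_segment_matches_set_extremes_oracle(self, maf_fixture):
        path, _t, oracle = maf_fixture(seed=21, n_blocks=20, allow_minus=False)
        aln = load_maf(path, "ref")
        rng = np.random.default_rng(5)
        for _ in range(100):
            a = int(rng.integers(0, 1_800))
            ea = Exon("chr1", a, a + 30)
            b = a + 30 + int(rng.integers(1, 100))
            eb = Exon("chr1", b, b + 30)
            for target in ("tgA", "tgB"):
                pa = aln.aligned_positions(ea, target)
                pb = aln.aligned_positions(eb, target)
                got = target_segment(aln, ea, eb, target)
                if pa.size == 0 or pb.size == 0:
                    continue
                ca = aln.aligned_target_contigs(ea, target)
                cb = aln.aligned_target_contigs(eb, target)
                if len(ca) != 1 or ca != cb or pa.max() + 1 > pb.min() - 1:
                    assert got is None
                else:
                    assert got == (ca[0], int(pa.max()) + 1, int(pb.min()))


class TestMergeAndReport:
    def test_empty_candidate_list_is_identity(self, tmp_path):
        aln = three_exon_maf(tmp_path)
        merged = merge_alignment(aln, [])
        m1 = aln.map_arrays("chr1", "t")
        m2 = merged.map_arrays("chr1", "t")
        assert np.array_equal(m1.tpos, m2.tpos)

    def test_merge_recovers_withheld_exon_and_is_monotone(self, tmp_path):
        aln = three_exon_maf(tmp_path)
        reference = Genome(
            "ref", {"chr1": "T" * 40 + "GGGGCCCCAA" + "T" * 150}
        )
        # target carries the same exon sequence inside the segment
        tseq = "A" * 140 + "GGGGCCCCAA" + "A" * 250
        target = Genome("t", {"c1": tseq})
        exons = ExonSet(
            [
                Exon("chr1", 10, 20),
                Exon("chr1", 40, 50),
                Exon("chr1", 70, 80),
                Exon("chr1", 100, 110),  # r = 0.5: baseline sd > 0
            ]
        )
        candidates, baselines = realign_missing_exons(
            aln, exons, reference, {"t": target}
        )
        assert len(candidates) == 1
        assert candidates[0].accepted
        assert candidates[0].score_rprime == 1.0
        merged = merge_alignment(aln, candidates)
        exon = Exon("chr1", 40, 50)
        assert not aln.exon_alignment_status(exon, "t")
        assert merged.exon_alignment_status(exon, "t")
        assert merged.map_position("chr1", 40, "t").position == 140
        assert merged.map_position("chr1", 40, "t").provenance == "recovered"
        # monotone: no mapped position lost anywhere
        before = aln.map_arrays("chr1", "t").tpos
        after = merged.map_arrays("chr1", "t").tpos
        assert ((before >= 0) <= (after >= 0)).all()
        assert (after[before >= 0] == before[before >= 0]).all()

    def test_completeness_report_counts(self, tmp_path):
        aln = three_exon_maf(tmp_path)
        exons = ExonSet(
            [
                Exon("chr1", 10, 20, gene_type="coding", chrom_label="chr1"),
                Exon("chr1", 40, 50, gene_type="coding", chrom_label="chr1"),
                Exon("chr1", 70, 80, gene_type="coding", chrom_label="chr1"),
            ]
        )
        report = completeness_report(aln, None, exons)
        row = report.iloc[0]
        assert row["s_a"] == 2
        assert row["s_m"] == 1
        assert row["s_r"] == 0
        assert row["s_a"] + row["s_m"] == len(exons) * len(aln.targets)


class TestWorldRecovery:
    def test_withheld_exons_found_as_candidates(self, mini_world, mini_result):
        withheld = {
            (c, s, e, sp) for c, s, e, sp in map(tuple, mini_world.truth.withheld)
        }
        found = {
            (c.exon.contig, c.exon.start, c.exon.end, c.target)
            for c in mini_result.candidates
        }
        assert withheld <= found

    def test_segment_cap_skips_candidate(self, tmp_path):
        aln = three_exon_maf(tmp_path)
        reference = Genome("ref", {"chr1": "A" * 200})
        target = Genome("t", {"c1": "A" * 400})
        exons = ExonSet(
            [Exon("chr1", 10, 20), Exon("chr1", 40, 50), Exon("chr1", 70, 80)]
        )
        candidates, _ = realign_missing_exons(
            aln, exons, reference, {"t": target}, segment_cap=10
        )
        assert candidates[0].reason == "segment-too-long"
        assert not candidates[0].accepted
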