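"""Arm-level loss calling and scar-score correctness on hand-built genomes."""

import numpy as np
import pandas as pd
import pytest

import ptscore as pt
from ptscore.cna import arm_coverage, classify_arm_loss, score_loh, score_lst, score_tai
from ptscore.genome import MB

from conftest import seg_frame, seg_row


def base_wise_coverage(segments, arm, pred, step=10_000):
    """Oracle: enumerate positions on the arm and count covered ones."""
    positions = np.arange(int(arm["start"]), int(arm["end"]), step)
    covered = np.zeros(len(positions), dtype=bool)
    for _, s in segments.iterrows():
        if str(s["chrom"]) != str(arm["chrom"]):
            continue
        if not pred(np.array([s["major_cn"]]), np.array([s["minor_cn"]]))[0]:
            continue
        covered |= (positions >= s["start"]) & (positions < s["end"])
    return covered.mean()


class TestArmCoverage:
    def test_no_segments_is_zero(self, tiny_arms):
        arm = tiny_arms.arm_row("A", "p")
        assert arm_coverage(seg_frame([]), arm, lambda M, m: m == 0) == 0.0

    def test_full_span_is_one(self, tiny_arms):
        arm = tiny_arms.arm_row("A", "p")
        segs = seg_frame([seg_row("S", "A", 0, MB, 1, 0)])
        assert arm_coverage(segs, arm, lambda M, m: m == 0) == 1.0

    def test_disjoint_fractions_add(self, tiny_arms):
        # 60% + 35% of a 1-Mb arm
        arm = tiny_arms.arm_row("A", "p")
        segs = seg_frame([
            seg_row("S", "A", 0, 600_000, 1, 0),
            seg_row("S", "A", 650_000, 1_000_000, 2, 0),
        ])
        assert arm_coverage(segs, arm, lambda M, m: m == 0) == pytest.approx(0.95)

    def test_overlaps_not_double_counted(self, tiny_arms):
        arm = tiny_arms.arm_row("A", "p")
        segs = seg_frame([
            seg_row("S", "A", 0, 700_000, 1, 0),
            seg_row("S", "A", 500_000, 900_000, 1, 0),
        ])
        assert arm_coverage(segs, arm, lambda M, m: m == 0) == pytest.approx(0.9)

    def test_matches_base_wise_oracle_on_random_sets(self, tiny_arms):
        rng = np.random.default_rng(4)
        pred = lambda M, m: m == 0
        for arm_key in (("A", "p"), ("B", "q")):
            arm = tiny_arms.arm_row(*arm_key)
            for _ in range(25):
                n = rng.integers(0, 8)
                rows = []
                for i in range(n):
                    # 10-kb grid keeps the enumeration oracle exact
                    s = rng.integers(0, 250) * 10_000
                    e = s + rng.integers(1, 60) * 10_000
                    rows.append(seg_row("S", arm["chrom"], s, e, rng.integers(0, 3), 0)
                                if rng.random() < 0.7 else
                                seg_row("S", arm["chrom"], s, e, 1, 1))
                segs = seg_frame(rows)
                got = arm_coverage(segs, arm, pred)
                want = base_wise_coverage(segs, arm, pred)
                assert got == pytest.approx(want, abs=1e-12)


class TestClassifyArmLoss:
    @pytest.mark.parametrize(
        "major,minor,category",
        [(0, 0, "homozygous_loss"), (1, 0, "loh"), (2, 0, "cnloh"), (3, 0, "loh_high_ploidy")],
    )
    def test_four_categories_full_coverage(self, tiny_arms, major, minor, category):
        arm = tiny_arms.arm_row("A", "q")
        segs = seg_frame([seg_row("S", "A", arm["start"], arm["end"], major, minor)])
        call = classify_arm_loss(segs, arm)
        assert call is not None and call["category"] == category

    def test_95_percent_loh(self, tiny_arms):
        arm = tiny_arms.arm_row("A", "p")
        segs = seg_frame([seg_row("S", "A", 0, 950_000, 1, 0)])
        assert classify_arm_loss(segs, arm)["category"] == "loh"

    def test_85_percent_is_no_call(self, tiny_arms):
        arm = tiny_arms.arm_row("A", "p")
        segs = seg_frame([seg_row("S", "A", 0, 850_000, 1, 0)])
        assert classify_arm_loss(segs, arm) is None


class TestScarScores:
    def test_diploid_genome_all_zero(self, arms):
        rows = [
            seg_row("S", a["chrom"], a["start"], a["end"], 1, 1)
            for _, a in arms.arms.iterrows()
        ]
        segs = seg_frame(rows)
        assert score_loh(segs, arms) == 0
        assert score_tai(segs, arms) == 0
        assert score_lst(segs, arms) == 0

    def test_loh_counts_only_long_interstitial(self, arms):
        # chr1: p [0,125 Mb), q [128,252 Mb)
        segs = seg_frame([
            seg_row("S", "1", 0, 30 * MB, 1, 1),
            seg_row("S", "1", 30 * MB, 50 * MB, 1, 0),  # 20 Mb -> counted
            seg_row("S", "1", 50 * MB, 125 * MB, 1, 1),
            seg_row("S", "2", 0, 30 * MB, 1, 1),
            seg_row("S", "2", 30 * MB, 50 * MB, 2, 0),  # 20 Mb -> counted
            seg_row("S", "2", 50 * MB, 93 * MB, 1, 1),
            seg_row("S", "3", 0, 10 * MB, 1, 0),  # 10 Mb -> too short
            seg_row("S", "3", 10 * MB, 91 * MB, 1, 1),
        ])
        assert score_loh(segs, arms) == 2

    def test_whole_chromosome_loh_excluded(self, arms):
        cs, ce = arms.chrom_bounds("21")
        segs = seg_frame([seg_row("S", "21", cs, ce, 1, 0)])
        assert score_loh(segs, arms) == 0
        # same region on a sub-chromosomal span does count
        segs2 = seg_frame([seg_row("S", "21", cs, ce - MB, 1, 0)])
        assert score_loh(segs2, arms) == 1

    def test_adjacent_loh_segments_merge(self, arms):
        # two abutting 10-Mb LOH segments with different major CN form one
        # 20-Mb region
        segs = seg_frame([
            seg_row("S", "1", 30 * MB, 40 * MB, 1, 0),
            seg_row("S", "1", 40 * MB, 50 * MB, 2, 0),
        ])
        assert score_loh(segs, arms) == 1

    def test_tai_telomeric_only(self, arms):
        q_start, q_end = 128 * MB, 252 * MB  # chr1 q
        segs = seg_frame([
            seg_row("S", "1", q_end - 20 * MB, q_end, 2, 1),  # reaches q telomere
            seg_row("S", "2", 100 * MB, 120 * MB, 2, 1),  # interstitial
        ])
        assert score_tai(segs, arms) == 1

    def test_tai_centromere_crossing_excluded(self, arms):
        cs, ce = arms.chrom_bounds("1")
        # imbalance from p telomere across the centromere into q
        segs = seg_frame([
            seg_row("S", "1", 0, 125 * MB, 2, 1),
            seg_row("S", "1", 125 * MB, 150 * MB, 2, 1),
        ])
        # one contiguous region 0..150 Mb crossing centromere [125,128)
        assert score_tai(segs, arms) == 0

    def test_tai_balanced_regions_ignored(self, arms):
        segs = seg_frame([seg_row("S", "1", 232 * MB, 252 * MB, 2, 2)])
        assert score_tai(segs, arms) == 0

    def test_tai_minimum_size(self, arms):
        q_end = 252 * MB
        segs = seg_frame([seg_row("S", "1", q_end - 10 * MB, q_end, 2, 1)])
        assert score_tai(segs, arms) == 0  # 10 Mb <= 11 Mb threshold

    def test_lst_breakpoint_between_long_segments(self, arms):
        # chr1 q starts at 128 Mb: two adjacent 12-Mb segments, distinct states
        segs = seg_frame([
            seg_row("S", "1", 128 * MB, 140 * MB, 2, 1),
            seg_row("S", "1", 140 * MB, 152 * MB, 1, 1),
        ])
        assert score_lst(segs, arms) == 1

    def test_lst_smoothing_bridges_small_interruption(self, arms):
        # 12 Mb (2,1) | 2 Mb (3,0) | 12 Mb (1,1): smoothing removes the 2-Mb
        # piece and one transition remains
        segs = seg_frame([
            seg_row("S", "1", 128 * MB, 140 * MB, 2, 1),
            seg_row("S", "1", 140 * MB, 142 * MB, 3, 0),
            seg_row("S", "1", 142 * MB, 154 * MB, 1, 1),
        ])
        assert score_lst(segs, arms) == 1

    def test_lst_smoothing_rejoins_equal_flanks(self, arms):
        # 6 Mb (1,1) | 2 Mb (2,1) | 6 Mb (1,1) | 12 Mb (2,0): the equal flanks
        # merge into 14 Mb >= 10 Mb, so the final breakpoint counts
        segs = seg_frame([
            seg_row("S", "1", 128 * MB, 134 * MB, 1, 1),
            seg_row("S", "1", 134 * MB, 136 * MB, 2, 1),
            seg_row("S", "1", 136 * MB, 142 * MB, 1, 1),
            seg_row("S", "1", 142 * MB, 154 * MB, 2, 0),
        ])
        assert score_lst(segs, arms) == 1

    def test_lst_short_flank_does_not_count(self, arms):
        segs = seg_frame([
            seg_row("S", "1", 128 * MB, 136 * MB, 2, 1),  # 8 Mb < 10 Mb
            seg_row("S", "1", 136 * MB, 150 * MB, 1, 1),
        ])
        assert score_lst(segs, arms) == 0

    def test_one_segment_per_chromosome_no_lst(self, arms):
        rows = [
            seg_row("S", a["chrom"], a["start"], a["end"], 2, 1)
            for _, a in arms.arms.iterrows()
        ]
        assert score_lst(seg_frame(rows), arms) == 0


class TestScarInvariances:
    @staticmethod
    def random_segments(rng, arms, n_chrom=4):
        chroms = [c for c in arms.chroms[: n_chrom]]
        rows = []
        for chrom in chroms:
            cs, ce = arms.chrom_bounds(chrom)
            cuts = np.sort(rng.choice(np.arange(cs + MB, ce, MB), size=rng.integers(1, 7), replace=False))
            bounds = [cs, *cuts.tolist(), ce]
            for s, e in zip(bounds, bounds[1:]):
                maj = int(rng.integers(0, 4))
                mnr = int(rng.integers(0, maj + 1))
                rows.append(seg_row("S", chrom, s, e, maj, mnr))
        return rows

    def scores(self, segs, arms):
        return (score_loh(segs, arms), score_tai(segs, arms), score_lst(segs, arms))

    def test_permutation_and_split_invariance(self, arms):
        rng = np.random.default_rng(17)
        for _ in range(60):
            rows = self.random_segments(rng, arms)
            segs = seg_frame(rows)
            base = self.scores(segs, arms)
            # permutation of input order
            perm = seg_frame([rows[i] for i in rng.permutation(len(rows))])
            assert self.scores(perm, arms) == base
            # split one segment into two abutting same-state pieces
            i = int(rng.integers(0, len(rows)))
            r = rows[i]
            if r["end"] - r["start"] >= 2:
                mid = (r["start"] + r["end"]) // 2
                split = rows[:i] + [
                    {**r, "end": mid}, {**r, "start": mid},
                ] + rows[i + 1:]
                assert self.scores(seg_frame(split), arms) == base

    def test_counts_non_negative_ints(self, arms):
        rng = np.random.default_rng(23)
        segs = seg_frame(self.random_segments(rng, arms))
        for v in self.scores(segs, arms):
            assert isinstance(v, int) and v >= 0


class TestScarScoresTable:
    def test_hrd_score_is_sum(self, small_cohort, arms):
        table = pt.scar_scores(small_cohort.segments, arms)
        assert (table["hrd_score"] == table[["n_loh", "n_tai", "n_lst"]].sum(axis=1)).all()
        assert (pt.hrd_sum(table) == table["hrd_score"]).all()

    def test_planted_counts_recovered(self, small_cohort, arms):
        table = pt.scar_scores(small_cohort.segments, arms)
        truth = small_cohort.truth.set_index("sample")
        joined = table.join(truth)
        assert (joined["n_loh"] == joined["planted_loh"]).all()
        assert (joined["n_tai"] == joined["planted_tai"]).all()
        assert (joined["n_lst"] == joined["planted_lst"]).all()

    def test_empty_segments(self):
        table = pt.scar_scores(seg_frame([]), samples=["X"])
        assert table.loc["X"].tolist() == [0, 0, 0, 0]


class TestSegmentValidation:
    def test_rejects_inverted_interval(self):
        with pytest.raises(ValueError):
            pt.cna.validate_segments(seg_frame([seg_row("S", "1", 10, 5, 1, 1)]))

    def test_rejects_minor_above_major(self):
        with pytest.raises(ValueError):
            pt.cna.validate_segments(seg_frame([seg_row("S", "1", 0, 10, 1, 2)]))
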