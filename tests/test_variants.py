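"""Somatic filter, bi-allelic mechanism typing, and pathway flags."""

import itertools

import numpy as np
import pandas as pd
import pytest

import ptscore as pt
from ptscore.variants import (
    classify_biallelic,
    filter_population_af,
    filter_somatic_variants,
    passes_missense_criteria,
    pathway_flags,
    GenePanel,
    DEFAULT_PANELS,
)

from conftest import seg_frame, seg_row, variant_frame, variant_row


class TestMissenseCriteria:
    def test_two_criteria_retained(self):
        v = pd.Series(variant_row(sift_score=0.03, polyphen="probably_damaging"))
        assert passes_missense_criteria(v) == (True, 2)

    def test_single_criterion_not_retained(self):
        v = pd.Series(variant_row(sift_score=0.03))
        assert passes_missense_criteria(v) == (False, 1)

    def test_no_annotations(self):
        v = pd.Series(variant_row())
        assert passes_missense_criteria(v) == (False, 0)

    def test_sift_boundary_closed(self):
        assert passes_missense_criteria(
            pd.Series(variant_row(sift_score=0.05, polyphen="possibly_damaging"))
        ) == (True, 2)
        assert passes_missense_criteria(
            pd.Series(variant_row(sift_score=0.051, polyphen="possibly_damaging"))
        ) == (False, 1)

    def test_fathmm_needs_cosmic_and_strict_half(self):
        # FATHMM > 0.5 alone is not enough without COSMIC presence
        v = pd.Series(variant_row(fathmm_mkl=0.9, in_cosmic=False, sift_score=0.01))
        assert passes_missense_criteria(v) == (False, 1)
        v = pd.Series(variant_row(fathmm_mkl=0.5, in_cosmic=True, sift_score=0.01))
        assert passes_missense_criteria(v) == (False, 1)  # 0.5 is not > 0.5
        v = pd.Series(variant_row(fathmm_mkl=0.51, in_cosmic=True, sift_score=0.01))
        assert passes_missense_criteria(v) == (True, 2)

    def test_rejects_non_missense(self):
        with pytest.raises(ValueError):
            passes_missense_criteria(pd.Series(variant_row(consequence="nonsense")))


class TestSomaticFilter:
    def test_truncating_retained_without_annotations(self):
        df = variant_frame([variant_row(consequence=c) for c in
                            ("nonsense", "splice_site", "frameshift_indel", "inframe_indel")])
        assert len(filter_somatic_variants(df)) == 4

    def test_missense_without_cosmic_removed(self):
        df = variant_frame([variant_row(fathmm_mkl=0.6, in_cosmic=False, sift_score=0.5)])
        assert len(filter_somatic_variants(df)) == 0

    def test_other_consequence_dropped(self):
        df = variant_frame([variant_row(consequence="other")])
        assert len(filter_somatic_variants(df)) == 0

    def test_germline_passthrough(self):
        df = variant_frame([variant_row(origin="germline", consequence="other")])
        assert len(filter_somatic_variants(df)) == 1

    def test_empty_input(self):
        assert len(filter_somatic_variants(variant_frame([]))) == 0

    def test_idempotent(self, small_cohort):
        once = filter_somatic_variants(small_cohort.variants)
        twice = filter_somatic_variants(once)
        pd.testing.assert_frame_equal(once, twice)

    def test_monotone_in_annotations(self):
        # adding a satisfying annotation never drops a retained missense
        base = variant_row(sift_score=0.01, polyphen="probably_damaging")
        assert len(filter_somatic_variants(variant_frame([base]))) == 1
        richer = dict(base, in_cosmic=True, fathmm_mkl=0.9)
        assert len(filter_somatic_variants(variant_frame([richer]))) == 1

    def test_population_af_prefilter(self):
        df = variant_frame([
            variant_row(gene="COMMON", population_af=0.2, consequence="nonsense"),
            variant_row(gene="RARE", population_af=0.001, consequence="nonsense"),
            variant_row(gene="UNKNOWN", consequence="nonsense"),
        ])
        kept = filter_population_af(df)
        assert set(kept["gene"]) == {"RARE", "UNKNOWN"}


class TestBiallelicClassifier:
    LOCUS = dict(gene="BRCA1", chrom="17", pos=47_000_000)

    def loh_segment(self):
        return seg_frame([seg_row("S1", "17", 45_000_000, 50_000_000, 1, 0)])

    def het_segment(self):
        return seg_frame([seg_row("S1", "17", 45_000_000, 50_000_000, 1, 1)])

    def test_germline_plus_loh(self):
        v = variant_frame([variant_row(
            origin="germline", consequence="frameshift_indel",
            germline_pathogenic=True, **self.LOCUS)])
        assert classify_biallelic(v, self.loh_segment(), "BRCA1") == "germline+LOH"

    def test_two_somatic_hits_heterozygous(self):
        v = variant_frame([
            variant_row(consequence="nonsense", **self.LOCUS),
            variant_row(consequence="nonsense", **{**self.LOCUS, "pos": 47_000_100}),
        ])
        assert classify_biallelic(v, self.het_segment(), "BRCA1") == "somatic+somatic"

    def test_single_germline_hit_diploid_is_none(self):
        v = variant_frame([variant_row(
            origin="germline", consequence="missense",
            germline_pathogenic=True, **self.LOCUS)])
        assert classify_biallelic(v, self.het_segment(), "BRCA1") is None

    def test_benign_germline_never_counts(self):
        v = variant_frame([variant_row(
            origin="germline", consequence="missense",
            germline_pathogenic=False, **self.LOCUS)])
        assert classify_biallelic(v, self.loh_segment(), "BRCA1") is None

    def test_exhaustive_hit_patterns(self):
        """All 2^4 combinations of {germline hit, somatic hit 1, somatic hit 2,
        LOH at the locus}: a mechanism is returned iff two hits (or one hit
        with LOH) exist, with precedence germline+LOH > germline+somatic >
        somatic+LOH > somatic+somatic."""
        for germ, som1, som2, loh in itertools.product([0, 1], repeat=4):
            rows = []
            if germ:
                rows.append(variant_row(origin="germline", germline_pathogenic=True,
                                        **self.LOCUS))
            if som1:
                rows.append(variant_row(consequence="nonsense", **self.LOCUS))
            if som2:
                rows.append(variant_row(consequence="nonsense",
                                        **{**self.LOCUS, "pos": 47_000_200}))
            segs = self.loh_segment() if loh else self.het_segment()
            got = classify_biallelic(variant_frame(rows), segs, "BRCA1")
            n_som = som1 + som2
            if germ and loh:
                want = "germline+LOH"
            elif germ and n_som:
                want = "germline+somatic"
            elif n_som and loh:
                want = "somatic+LOH"
            elif n_som >= 2:
                want = "somatic+somatic"
            else:
                want = None
            assert got == want, (germ, som1, som2, loh)

    def test_loh_requires_overlap(self):
        v = variant_frame([variant_row(consequence="nonsense", **self.LOCUS)])
        far = seg_frame([seg_row("S1", "17", 60_000_000, 65_000_000, 1, 0)])
        assert classify_biallelic(v, far, "BRCA1") is None

    def test_batch_matches_single(self, small_cohort):
        retained = filter_somatic_variants(filter_population_af(small_cohort.variants))
        genes = sorted(DEFAULT_PANELS["hr"].genes)
        calls = pt.biallelic_calls(retained, small_cohort.segments, genes)
        for _, row in calls.iterrows():
            v = retained[retained["sample"] == row["sample"]]
            s = small_cohort.segments[small_cohort.segments["sample"] == row["sample"]]
            assert classify_biallelic(v, s, row["gene"]) == row["mechanism"]


class TestPathwayFlags:
    def test_ddr_multi_needs_two_mutations(self):
        one = variant_frame([variant_row(gene="ERCC6", consequence="nonsense")])
        two = variant_frame([
            variant_row(gene="ERCC6", consequence="nonsense"),
            variant_row(gene="PTEN", consequence="nonsense", pos=2_000_000),
        ])
        assert pathway_flags(one).loc["S1", "ddr_multi"] == 0
        assert pathway_flags(two).loc["S1", "ddr_multi"] == 1

    def test_two_hits_same_gene_qualify(self):
        two = variant_frame([
            variant_row(gene="ERCC6", consequence="nonsense"),
            variant_row(gene="ERCC6", consequence="nonsense", pos=2_000_000),
        ])
        assert pathway_flags(two).loc["S1", "ddr_multi"] == 1

    def test_microtubule_single_hit(self):
        df = variant_frame([variant_row(gene="MAP2", consequence="nonsense")])
        flags = pathway_flags(df)
        assert flags.loc["S1", "microtubule"] == 1 and flags.loc["S1", "ddr_multi"] == 0

    def test_no_variants_all_false(self):
        flags = pathway_flags(variant_frame([]), samples=["S9"])
        assert flags.loc["S9"].sum() == 0

    def test_unknown_panel_errors(self):
        with pytest.raises(KeyError):
            pathway_flags(variant_frame([]), panels={"ddr": DEFAULT_PANELS["ddr"]})

    def test_empty_panel_rejected(self):
        with pytest.raises(ValueError):
            GenePanel("empty", set())
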