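import numpy as np
import pandas as pd
import pytest

import ptscore as pt


def seg_row(sample, chrom, start, end, major, minor):
    return {
        "sample": sample, "chrom": str(chrom), "start": int(start),
        "end": int(end), "major_cn": int(major), "minor_cn": int(minor),
    }


def seg_frame(rows):
    return pd.DataFrame(rows, columns=pt.cna.SEGMENT_COLUMNS)


def variant_row(sample="S1", gene="G", chrom="1", pos=1_000_000, origin="somatic",
                consequence="missense", germline_pathogenic=False, sift_score=np.nan,
                polyphen=None, fathmm_mkl=np.nan, in_cosmic=False, snv_context=None,
                indel_class=None, population_af=np.nan):
    return dict(
        sample=sample, gene=gene, chrom=str(chrom), pos=pos, origin=origin,
        consequence=consequence, germline_pathogenic=germline_pathogenic,
        sift_score=sift_score, polyphen=polyphen, fathmm_mkl=fathmm_mkl,
        in_cosmic=in_cosmic, snv_context=snv_context, indel_class=indel_class,
        population_af=population_af,
    )


def variant_frame(rows):
    return pd.DataFrame(rows, columns=pt.variants.MAF_COLUMNS)


@pytest.fixture(scope="session")
def arms():
    return pt.toy_genome()


@pytest.fixture(scope="session")
def tiny_arms():
    """Two-chromosome toy genome with 1-Mb-scale arms for brute-force oracles."""
    table = pd.DataFrame(
        [
            {"chrom": "A", "arm": "p", "start": 0, "end": 1_000_000},
            {"chrom": "A", "arm": "q", "start": 1_100_000, "end": 2_600_000},
            {"chrom": "B", "arm": "p", "start": 0, "end": 800_000},
            {"chrom": "B", "arm": "q", "start": 900_000, "end": 2_000_000},
        ]
    )
    return pt.GenomeArms(table)


@pytest.fixture(scope="session")
def small_cohort():
    """Session-wide default synthetic cohort (n=80, seed 11)."""
    return pt.generate_cohort(pt.default_config(n_patients=80, seed=11))


@pytest.fixture(scope="session")
def small_features(small_cohort):
    return pt.extract_features(
        small_cohort.segments,
        small_cohort.variants,
        samples=small_cohort.clinical["sample"],
    )
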