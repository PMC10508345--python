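"""Somatic-variant filtering, bi-allelic inactivation typing, pathway flags.

Variant tables are MAF-like DataFrames with pre-computed annotations
(SIFT, PolyPhen-2, FATHMM-MKL, COSMIC presence, germline pathogenicity);
running those annotators is upstream of this package.

Filtering retains somatic nonsense, splice-site and in-frame/frameshift
indel mutations unconditionally, and somatic missense mutations meeting
at least two of three in-silico damage criteria:

1. SIFT score in [0, 0.05];
2. PolyPhen-2 call "possibly_damaging" or "probably_damaging";
3. present in COSMIC with FATHMM-MKL score > 0.5.

Germline records pass through untouched (they feed the bi-allelic
classifier).  An optional population allele-frequency pre-filter drops
common variants first (default cutoff 0.01; the cutoff is a placeholder
and should be set to match the upstream annotation source).

Bi-allelic ("double hit") inactivation of a gene is typed as one of four
mechanisms, in precedence order:

a. germline pathogenic mutation with LOH;
b. germline pathogenic mutation plus a somatic pathogenic mutation;
c. somatic pathogenic mutation with LOH;
d. two or more somatic pathogenic mutations.

A variant has LOH support when it lies inside a segment whose minor
allele copy number is 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MAF_COLUMNS",
    "CONSEQUENCES",
    "MECHANISMS",
    "GenePanel",
    "DEFAULT_PANELS",
    "passes_missense_criteria",
    "filter_population_af",
    "filter_somatic_variants",
    "classify_biallelic",
    "biallelic_calls",
    "pathway_flags",
]

MAF_COLUMNS = [
    "sample",
    "gene",
    "chrom",
    "pos",
    "origin",
    "consequence",
    "germline_pathogenic",
    "sift_score",
    "polyphen",
    "fathmm_mkl",
    "in_cosmic",
    "snv_context",
    "indel_class",
    "population_af",
]

CONSEQUENCES = {
    "missense",
    "nonsense",
    "splice_site",
    "frameshift_indel",
    "inframe_indel",
    "other",
}

# retained without further annotation evidence
_TRUNCATING = {"nonsense", "splice_site", "frameshift_indel", "inframe_indel"}

_DAMAGING_POLYPHEN = {"possibly_damaging", "probably_damaging"}

MECHANISMS = [
    "germline+LOH",
    "germline+somatic",
    "somatic+LOH",
    "somatic+somatic",
]


@dataclass(frozen=True)
class GenePanel:
    """A named, non-empty set of gene symbols."""

    name: str
    genes: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        object.__setattr__(self, "genes", frozenset(self.genes))
        if not self.genes:
            raise ValueError(f"panel {self.name!r} is empty")

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes


def _default_panels() -> dict[str, GenePanel]:
    # Placeholder catalogues: a handful of well-known HR/DDR/microtubule
    # genes sufficient for development and testing.  Override via
    # configuration with real curated panels for any actual analysis.
    hr = {
        "BRCA1", "BRCA2", "FANCE", "CDK12", "RAD51C", "RAD51D",
        "ATM", "CHEK2", "FAN1",
    }
    ddr = {
        "ATM", "ASCC3", "CDH11", "DNAH10", "DYNC1H1", "ERCC6", "PTEN",
        "RIF1", "POLD2", "PRKDC", "SMARCA4", "TDG", "TTK", "YWHAE",
    }
    microtubule = {"MAP2", "DYNC1H1", "DNAH10"}
    drivers = {"TP53", "FAT3", "RYR2", "MAP2"}
    return {
        "hr": GenePanel("hr", hr),
        "brca": GenePanel("brca", {"BRCA1", "BRCA2"}),
        "ddr": GenePanel("ddr", ddr),
        "microtubule": GenePanel("microtubule", microtubule),
        "drivers": GenePanel("drivers", drivers),
    }


DEFAULT_PANELS = _default_panels()


def passes_missense_criteria(v: pd.Series) -> tuple[bool, int]:
    """Evaluate the three in-silico damage criteria for a missense variant.

    Returns ``(retained, n_criteria_met)``; retained iff at least two of
    the three criteria hold.  Raises for non-missense input.
    """
    if v["consequence"] != "missense":
        raise ValueError("passes_missense_criteria requires a missense variant")
    n = int(_missense_criteria_count(pd.DataFrame([v]))[0])
    return n >= 2, n


def _missense_criteria_count(df: pd.DataFrame) -> np.ndarray:
    sift = pd.to_numeric(df.get("sift_score"), errors="coerce")
    c1 = sift.notna() & (sift >= 0.0) & (sift <= 0.05)
    polyphen = df.get("polyphen")
    c2 = polyphen.isin(_DAMAGING_POLYPHEN) if polyphen is not None else False
    fathmm = pd.to_numeric(df.get("fathmm_mkl"), errors="coerce")
    in_cosmic = df.get("in_cosmic")
    in_cosmic = in_cosmic.fillna(False).astype(bool) if in_cosmic is not None else False
    c3 = in_cosmic & fathmm.notna() & (fathmm > 0.5)
    return (
        np.asarray(c1, dtype=int) + np.asarray(c2, dtype=int) + np.asarray(c3, dtype=int)
    )


def filter_population_af(variants: pd.DataFrame, max_af: float = 0.01) -> pd.DataFrame:
    """Drop variants common in the population (allele frequency > cutoff).

    Records without a population_af annotation are kept.
    """
    if "population_af" not in variants.columns or not len(variants):
        return variants
    af = pd.to_numeric(variants["population_af"], errors="coerce")
    return variants[af.isna() | (af <= max_af)]


def filter_somatic_variants(variants: pd.DataFrame) -> pd.DataFrame:
    """Consequence/annotation filter for somatic variants.

    Somatic truncating-class variants are retained unconditionally,
    somatic missense variants when >= 2 in-silico criteria hold, and
    germline records pass through untouched.  ``consequence == "other"``
    somatic records are dropped.  Idempotent.
    """
    if not len(variants):
        return variants
    somatic = variants["origin"] == "somatic"
    keep = ~somatic  # germline passthrough
    keep |= somatic & variants["consequence"].isin(_TRUNCATING)
    missense = somatic & (variants["consequence"] == "missense")
    if missense.any():
        counts = np.zeros(len(variants), dtype=int)
        counts[np.asarray(missense)] = _missense_criteria_count(variants[missense])
        keep |= missense & (counts >= 2)
    return variants[keep]


def _has_loh_support(pos: int, chrom: str, segments: pd.DataFrame) -> bool:
    if not len(segments):
        return False
    sel = segments[
        (segments["chrom"].astype(str) == str(chrom))
        & (segments["minor_cn"] == 0)
        & (segments["major_cn"] > 0)
        & (segments["start"] <= pos)
        & (segments["end"] > pos)
    ]
    return bool(len(sel))


def classify_biallelic(
    variants: pd.DataFrame, segments: pd.DataFrame, gene: str
) -> str | None:
    """Type the bi-allelic inactivation mechanism of one gene in one sample.

    ``variants`` must already be filtered (retained somatic mutations
    count as pathogenic somatic hits; germline hits require the
    germline_pathogenic flag).  Returns one of :data:`MECHANISMS` or
    ``None`` when no two-hit combination exists.  When several
    mechanisms apply the first in the listed precedence order wins.
    """
    hits = variants[variants["gene"] == gene]
    germ = hits[
        (hits["origin"] == "germline")
        & hits["germline_pathogenic"].fillna(False).astype(bool)
    ]
    som = hits[hits["origin"] == "somatic"]
    germ_loh = any(
        _has_loh_support(int(r["pos"]), r["chrom"], segments) for _, r in germ.iterrows()
    )
    som_loh = any(
        _has_loh_support(int(r["pos"]), r["chrom"], segments) for _, r in som.iterrows()
    )
    if len(germ) and germ_loh:
        return "germline+LOH"
    if len(germ) and len(som):
        return "germline+somatic"
    if len(som) and som_loh:
        return "somatic+LOH"
    if len(som) >= 2:
        return "somatic+somatic"
    return None


def biallelic_calls(
    variants: pd.DataFrame, segments: pd.DataFrame, genes
) -> pd.DataFrame:
    """Bi-allelic calls for every sample × gene; long-format table.

    Only variants in ``genes`` and minor-allele-zero segments are
    consulted, so the inputs may be full cohort tables.
    """
    genes = set(genes)
    v_rel = variants[variants["gene"].isin(genes)] if len(variants) else variants
    if len(segments):
        s_rel = segments[(segments["minor_cn"] == 0) & (segments["major_cn"] > 0)]
    else:
        s_rel = segments

    # per-sample minor-zero segment intervals, keyed by chromosome
    loh_ivals: dict[str, dict[str, tuple[np.ndarray, np.ndarray]]] = {}
    if len(s_rel):
        for (sample, chrom), grp in s_rel.groupby(
            ["sample", s_rel["chrom"].astype(str)]
        ):
            loh_ivals.setdefault(sample, {})[chrom] = (
                grp["start"].to_numpy(np.int64),
                grp["end"].to_numpy(np.int64),
            )

    records = []
    if len(v_rel):
        for sample, v in v_rel.groupby("sample", sort=True):
            gene_arr = v["gene"].to_numpy()
            germline = (v["origin"] == "germline").to_numpy()
            germ_path = germline & v["germline_pathogenic"].fillna(False).to_numpy(bool)
            somatic = (v["origin"] == "somatic").to_numpy()
            chrom_arr = v["chrom"].astype(str).to_numpy()
            pos_arr = v["pos"].to_numpy(np.int64)
            ivals = loh_ivals.get(sample, {})
            has_loh = np.zeros(len(v), dtype=bool)
            for i, (c, p) in enumerate(zip(chrom_arr, pos_arr)):
                iv = ivals.get(c)
                if iv is not None:
                    has_loh[i] = bool(np.any((iv[0] <= p) & (p < iv[1])))
            for gene in np.unique(gene_arr):
                g = gene_arr == gene
                n_germ = int((g & germ_path).sum())
                n_som = int((g & somatic).sum())
                if n_germ and (g & germ_path & has_loh).any():
                    mech = "germline+LOH"
                elif n_germ and n_som:
                    mech = "germline+somatic"
                elif n_som and (g & somatic & has_loh).any():
                    mech = "somatic+LOH"
                elif n_som >= 2:
                    mech = "somatic+somatic"
                else:
                    continue
                records.append({"sample": sample, "gene": gene, "mechanism": mech})
    return pd.DataFrame(records, columns=["sample", "gene", "mechanism"])


def pathway_flags(
    retained: pd.DataFrame,
    panels: dict[str, GenePanel] | None = None,
    samples=None,
) -> pd.DataFrame:
    """Per-sample pathway/driver feature flags from filtered variants.

    * ``ddr_multi`` — at least two retained somatic mutations in the DDR
      panel (counted per mutation: two hits in one gene qualify);
    * ``microtubule`` — at least one retained somatic mutation in the
      microtubule panel;
    * one column per configured driver gene (``mut_<GENE>``).
    """
    panels = panels or DEFAULT_PANELS
    for required in ("ddr", "microtubule"):
        if required not in panels:
            raise KeyError(f"panel {required!r} not configured")
    som = retained[retained["origin"] == "somatic"] if len(retained) else retained
    if samples is None:
        samples = sorted(set(retained["sample"])) if len(retained) else []
    index = pd.Index(sorted(set(samples)), name="sample")
    out = pd.DataFrame(index=index)
    if len(som):
        ddr_counts = (
            som[som["gene"].isin(panels["ddr"].genes)].groupby("sample").size()
        )
        mt_counts = (
            som[som["gene"].isin(panels["microtubule"].genes)].groupby("sample").size()
        )
    else:
        ddr_counts = mt_counts = pd.Series(dtype=int)
    out["ddr_multi"] = (ddr_counts.reindex(index).fillna(0) >= 2).astype(int)
    out["microtubule"] = (mt_counts.reindex(index).fillna(0) >= 1).astype(int)
    if "drivers" in panels:
        for gene in sorted(panels["drivers"].genes):
            if len(som):
                has = som[som["gene"] == gene].groupby("sample").size()
            else:
                has = pd.Series(dtype=int)
            out[f"mut_{gene}"] = (has.reindex(index).fillna(0) >= 1).astype(int)
    return out
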