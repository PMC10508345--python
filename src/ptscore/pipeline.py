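"""End-to-end orchestration: simulate -> extract -> associate -> train -> compare.

:func:`extract_features` turns the three raw inputs (allelic segments,
annotated variants, clinical table) into the per-sample feature matrix
the integration model consumes.  :func:`run_pipeline` executes the full
study design on one cohort: candidate screening on a training split,
lasso Pt-score fitting, and a DeLong comparison of Pt-score vs the
unweighted LOH+TAI+LST scar sum on the held-out split, returning a
machine-readable report.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .cna import ScarParams, arm_loss_calls, scar_scores
from .genome import GenomeArms, toy_genome
from .model import PtScoreModel, PtScoreResults, delong_test, roc_auc
from .signatures import (
    SignatureSet,
    build_indel_catalog,
    build_sbs_catalog,
    fit_exposures,
    retain_signatures,
    synthetic_id_reference,
    synthetic_sbs_reference,
)
from .simulate import CohortConfig, SyntheticCohort, default_config, generate_cohort
from .stats import select_candidates
from .variants import (
    DEFAULT_PANELS,
    biallelic_calls,
    filter_population_af,
    filter_somatic_variants,
    pathway_flags,
)

__all__ = [
    "BINARY_FEATURES",
    "CONTINUOUS_FEATURES",
    "extract_features",
    "assemble_features",
    "run_pipeline",
    "golden_tables",
    "RunReport",
]

logger = logging.getLogger("ptscore")

BINARY_FEATURES = [
    "brca12_biallelic",
    "hr_biallelic",
    "ddr_multi",
    "microtubule",
    "chr4p_loss",
    "chr5q_or_4p_loss",
]
CONTINUOUS_FEATURES = ["sbs39_abs", "id6_rel", "n_loh", "n_tai", "n_lst"]


def extract_features(
    segments: pd.DataFrame,
    variants: pd.DataFrame,
    samples=None,
    arms: GenomeArms | None = None,
    panels=None,
    sbs_reference: SignatureSet | None = None,
    id_reference: SignatureSet | None = None,
    scar_params: ScarParams = ScarParams(),
    max_population_af: float = 0.01,
    arm_loss_min_coverage: float = 0.9,
) -> pd.DataFrame:
    """Per-sample feature matrix from raw segments and variants.

    Binary columns: BRCA1/2 bi-allelic inactivation, any-HR-gene
    bi-allelic inactivation, DDR multi-mutation, microtubule-gene
    mutation, chr4p arm loss, chr5q-or-4p arm loss.  Continuous columns:
    absolute SBS39 exposure, relative ID6 exposure, and the three scar
    counts.  Samples missing from an input contribute zeros.
    """
    arms = arms or toy_genome()
    panels = panels or DEFAULT_PANELS
    sbs_reference = sbs_reference or synthetic_sbs_reference()
    id_reference = id_reference or synthetic_id_reference()
    if samples is None:
        samples = sorted(set(segments["sample"]) | set(variants["sample"]))
    index = pd.Index(sorted(set(samples)), name="sample")

    rare = filter_population_af(variants, max_population_af)
    retained = filter_somatic_variants(rare)
    logger.info(
        "variant filter: %d -> %d (AF) -> %d (consequence)",
        len(variants), len(rare), len(retained),
    )

    out = pd.DataFrame(index=index)
    calls = biallelic_calls(retained, segments, sorted(panels["hr"].genes))
    brca_samples = set(calls[calls["gene"].isin(panels["brca"].genes)]["sample"])
    hr_samples = set(calls["sample"])
    out["brca12_biallelic"] = [int(s in brca_samples) for s in index]
    out["hr_biallelic"] = [int(s in hr_samples) for s in index]

    pathway = pathway_flags(retained, panels, samples=index)
    out["ddr_multi"] = pathway["ddr_multi"]
    out["microtubule"] = pathway["microtubule"]

    arm_calls = arm_loss_calls(segments, arms, arm_loss_min_coverage)
    lost_4p = set(arm_calls[arm_calls["arm"] == "4p"]["sample"])
    lost_5q = set(arm_calls[arm_calls["arm"] == "5q"]["sample"])
    out["chr4p_loss"] = [int(s in lost_4p) for s in index]
    out["chr5q_or_4p_loss"] = [int(s in lost_4p or s in lost_5q) for s in index]

    # signature exposures from (AF-prefiltered) somatic calls, before the
    # consequence filter
    som = rare[rare["origin"] == "somatic"] if len(rare) else rare
    snvs = som[som["snv_context"].notna()] if len(som) else som
    indels = som[som["indel_class"].notna()] if len(som) else som
    sbs_cat, sbs_skipped = build_sbs_catalog(snvs, samples=index)
    id_cat, id_skipped = build_indel_catalog(indels, samples=index)
    if sbs_skipped or id_skipped:
        logger.warning("skipped malformed contexts: %d SNV, %d indel", sbs_skipped, id_skipped)
    sbs_exp = fit_exposures(sbs_cat, sbs_reference)
    id_exp = fit_exposures(id_cat, id_reference)
    out["sbs39_abs"] = sbs_exp["SBS39_abs"].reindex(index).fillna(0.0)
    out["id6_rel"] = id_exp["ID6_rel"].reindex(index).fillna(0.0)

    scars = scar_scores(segments, arms, scar_params, samples=index)
    for col in ("n_loh", "n_tai", "n_lst", "hrd_score"):
        out[col] = scars[col].reindex(index).fillna(0).astype(int)
    return out


def assemble_features(
    feature_table: pd.DataFrame, clinical: pd.DataFrame
) -> pd.DataFrame:
    """Inner-join features with clinical outcome into a modelling frame.

    Keeps samples present in both inputs; logs the number dropped.
    Raises when no samples overlap.
    """
    clin = clinical.set_index("sample") if "sample" in clinical.columns else clinical
    feats = (
        feature_table.set_index("sample")
        if "sample" in feature_table.columns
        else feature_table
    )
    common = feats.index.intersection(clin.index)
    if len(common) == 0:
        raise ValueError("no overlapping samples between features and clinical data")
    dropped = (len(feats) - len(common)) + (len(clin) - len(common))
    if dropped:
        logger.info("assemble_features: dropped %d non-overlapping rows", dropped)
    out = feats.loc[common].copy()
    out["pt_sensitive"] = clin.loc[common, "pt_sensitive"].astype(int)
    return out.sort_index()


@dataclass
class RunReport:
    """Machine-readable record of one pipeline run."""

    config: dict
    seed: int
    stage_counts: dict = field(default_factory=dict)
    candidates: list = field(default_factory=list)
    association: list = field(default_factory=list)
    model_summary: str = ""
    auc: dict = field(default_factory=dict)
    delong: dict = field(default_factory=dict)
    version: str = __version__

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)


def run_pipeline(
    config: CohortConfig | None = None,
    seed: int = 0,
    train_fraction: float = 0.6,
    cv_folds: int = 10,
    feature_columns=None,
    use_candidates: bool = True,
    outdir=None,
) -> tuple[RunReport, PtScoreResults]:
    """Execute simulate -> extract -> associate -> train -> compare.

    The cohort is split (stratified by outcome) into a training part for
    candidate screening and model fitting and a held-out part on which
    Pt-score and HRD-sum AUCs are compared with DeLong's test.
    Deterministic given ``config.seed`` and ``seed`` (model/split seed).
    """
    config = config if config is not None else default_config(seed=seed)
    if config.n_patients == 0:
        raise ValueError("cannot run the pipeline on an empty cohort (n_patients=0)")
    cohort = generate_cohort(config)
    report = RunReport(config={"n_patients": config.n_patients, "seed": config.seed}, seed=seed)
    report.stage_counts["patients"] = int(config.n_patients)
    report.stage_counts["segments"] = int(len(cohort.segments))
    report.stage_counts["variants"] = int(len(cohort.variants))

    feats = extract_features(
        cohort.segments, cohort.variants, samples=cohort.clinical["sample"]
    )
    df = assemble_features(feats, cohort.clinical)
    report.stage_counts["modelled_samples"] = int(len(df))

    rng = np.random.default_rng(seed)
    y = df["pt_sensitive"].to_numpy()
    idx = np.arange(len(df))
    train_mask = np.zeros(len(df), dtype=bool)
    for cls in (0, 1):
        cls_idx = idx[y == cls]
        n_tr = int(round(train_fraction * len(cls_idx)))
        train_mask[rng.permutation(cls_idx)[:n_tr]] = True
    train, test = df[train_mask], df[~train_mask]
    report.stage_counts["train"] = int(len(train))
    report.stage_counts["test"] = int(len(test))

    all_features = list(feature_columns or (BINARY_FEATURES + CONTINUOUS_FEATURES))
    clin_indexed = cohort.clinical.set_index("sample")
    assoc = select_candidates(train[all_features], clin_indexed.loc[train.index])
    report.association = assoc.to_dict(orient="records")
    candidates = list(assoc[assoc["candidate"]]["feature"])
    model_features = candidates if (use_candidates and len(candidates) >= 2) else all_features
    report.candidates = candidates

    model = PtScoreModel(train[model_features], train["pt_sensitive"])
    results = model.fit(folds=cv_folds, seed=seed)
    report.model_summary = results.summary()

    for name, part in (("train", train), ("test", test)):
        if part["pt_sensitive"].nunique() < 2:
            continue
        pt = results.pt_score(part)
        hrd = part["hrd_score"].to_numpy(dtype=float)
        report.auc[name] = {
            "pt_score": roc_auc(pt, part["pt_sensitive"]),
            "hrd_sum": roc_auc(hrd, part["pt_sensitive"]),
        }
        cmp = delong_test(pt, hrd, part["pt_sensitive"])
        report.delong[name] = {
            "auc_pt": cmp.auc_a, "auc_hrd": cmp.auc_b,
            "z": cmp.z, "p_value": cmp.p_value, "comparable": cmp.comparable,
        }

    if outdir is not None:
        import json
        import pathlib

        outdir = pathlib.Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        cohort.write(outdir)
        feats.to_csv(outdir / "features.tsv", sep="\t")
        assoc.to_csv(outdir / "association.tsv", sep="\t", index=False)
        results.to_json(outdir / "pt_model.json")
        with open(outdir / "report.json", "w") as fh:
            json.dump(report.to_dict(), fh, indent=2, default=float)
    return report, results


def golden_tables() -> list[tuple[str, tuple, float]]:
    """The six published platinum-sensitivity contingency tables.

    Each entry is (feature name, ((sensitive_with, resistant_with),
    (sensitive_without, resistant_without)), printed p-value); all six
    tables total 196 patients.  Used as a built-in regression fixture
    for the two-sided Fisher implementation.
    """
    return [
        ("brca12_biallelic", ((35, 6), (101, 54)), 0.013),
        ("hr_biallelic", ((43, 10), (93, 50)), 0.036),
        ("ddr_multi", ((12, 0), (124, 60)), 0.019),
        ("microtubule", ((14, 0), (122, 60)), 0.006),
        ("chr4p_loss", ((15, 1), (121, 59)), 0.025),
        ("chr5q_or_4p_loss", ((33, 4), (103, 56)), 0.003),
    ]
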