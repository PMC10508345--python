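"""Synthetic ovarian-cancer cohort generator with planted genomic structure.

Every downstream stage of the pipeline (variant filtering, bi-allelic
typing, arm-loss calling, scar scoring, signature refitting, candidate
selection, model fitting) is exercised on cohorts produced here, so the
generator plants each feature in the *raw* data representation the
corresponding extractor consumes:

* bi-allelic BRCA1 inactivation -> a germline pathogenic BRCA1 record
  plus a 5-Mb minor-allele-zero segment over the BRCA1 locus;
* other-HR-gene inactivation -> a somatic pathogenic RAD51C record plus
  a 5-Mb LOH segment (somatic+LOH mechanism);
* DDR multi-mutation -> two retained somatic hits in DDR-panel genes;
* microtubule-gene mutation -> one somatic MAP2 hit;
* chr4p / chr5q arm loss -> whole-arm (0,0) segments (homozygous loss
  contributes to none of the three scar statistics, keeping arm-loss
  features statistically independent of scar burden);
* HRD-like genomes -> Poisson numbers of interstitial-LOH, telomeric-AI
  and LST events carved into designated arms with small (< 10 Mb)
  flanks so each planted event increments exactly one scar score;
* signature structure -> per-patient multinomial channel counts from a
  mixture over the reference signatures, with SBS39 / ID6 weight boosts
  for the planted "high exposure" indicators.

Platinum sensitivity is drawn from a logistic model over the planted
indicators with configured odds ratios; OS/DFS are exponential
proportional-hazards times under uniform administrative censoring.
Randomness uses one root seed with per-patient spawned substreams, so
enlarging the cohort never perturbs earlier patients.
"""

from __future__ import annotations

import itertools

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cna import SEGMENT_COLUMNS
from .genome import MB, GenomeArms, toy_genes, toy_genome
from .signatures import (
    ID83_CHANNELS,
    SBS96_CHANNELS,
    SignatureSet,
    synthetic_id_reference,
    synthetic_sbs_reference,
)
from .variants import MAF_COLUMNS

__all__ = [
    "FeatureSpec",
    "ScarModel",
    "SignatureMixModel",
    "SurvivalModel",
    "CohortConfig",
    "SyntheticCohort",
    "default_config",
    "generate_cohort",
    "generate_segments",
    "generate_variants",
]

# arm pools for scar-event placement; disjoint from the gene-carve arm
# (17q) and the arm-loss feature arms (4p, 5q)
LOH_ARM_POOL = [("1", "p"), ("2", "p"), ("3", "p"), ("6", "p"), ("7", "p"),
                ("8", "p"), ("9", "p"), ("12", "p"), ("16", "p"), ("20", "p")]
TAI_ARM_POOL = [("1", "q"), ("3", "q"), ("4", "q"), ("6", "q"), ("7", "q"),
                ("8", "q"), ("9", "q"), ("14", "q"), ("15", "q"), ("18", "q")]
LST_ARM_POOL = [("5", "p"), ("10", "p"), ("11", "p"), ("12", "q"), ("16", "q"),
                ("19", "p"), ("19", "q"), ("20", "q"), ("21", "q"), ("22", "q")]


@dataclass(frozen=True)
class FeatureSpec:
    """One plantable patient-level feature.

    ``odds_ratio`` acts on platinum sensitivity; ``os_hr``/``dfs_hr``
    are multiplicative hazards on the survival outcomes.
    """

    name: str
    prevalence: float
    odds_ratio: float = 1.0
    os_hr: float = 1.0
    dfs_hr: float = 1.0

    def __post_init__(self):
        if not 0.0 <= self.prevalence <= 1.0:
            raise ValueError(f"{self.name}: prevalence must be in [0,1]")
        if self.odds_ratio <= 0 or self.os_hr <= 0 or self.dfs_hr <= 0:
            raise ValueError(f"{self.name}: odds/hazard ratios must be > 0")


@dataclass(frozen=True)
class ScarModel:
    """Mean planted scar-event counts (Poisson) per genome class."""

    quiet_means: tuple = (1.0, 1.0, 1.0)  # (LOH, TAI, LST) for HRD-quiet
    hrd_means: tuple = (6.0, 6.0, 5.0)  # for HRD-like


@dataclass(frozen=True)
class SignatureMixModel:
    """Per-patient signature mixing weights and mutation burden."""

    sbs_weights: dict = field(
        default_factory=lambda: {"SBS1": 0.35, "SBS3": 0.15, "SBS5": 0.40, "SBS39": 0.10}
    )
    id_weights: dict = field(
        default_factory=lambda: {"ID1": 0.45, "ID2": 0.35, "ID6": 0.20}
    )
    sbs39_high_weight: float = 0.35  # SBS39 weight when sbs39_high is planted
    id6_high_weight: float = 0.50  # ID6 weight when id6_high is planted
    snv_burden: int = 120
    indel_burden: int = 50


@dataclass(frozen=True)
class SurvivalModel:
    """Exponential baseline rates (events/month) and follow-up window."""

    baseline_os_rate: float = 0.0173  # median OS ~ 40 months
    baseline_dfs_rate: float = 0.039  # median DFS ~ 18 months
    max_followup_months: float = 120.0  # uniform administrative censoring


@dataclass(frozen=True)
class CohortConfig:
    """Full specification of a synthetic cohort."""

    n_patients: int = 196
    features: tuple = ()
    baseline_sensitive_rate: float = 0.35
    scar: ScarModel = ScarModel()
    signatures: SignatureMixModel = SignatureMixModel()
    survival: SurvivalModel = SurvivalModel()
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 0:
            raise ValueError("n_patients must be >= 0")
        if not 0.0 <= self.baseline_sensitive_rate <= 1.0:
            raise ValueError("baseline_sensitive_rate must be in [0,1]")
        names = [f.name for f in self.features]
        if len(names) != len(set(names)):
            raise ValueError("duplicate feature names")

    def feature(self, name: str) -> FeatureSpec | None:
        for f in self.features:
            if f.name == name:
                return f
        return None


def default_config(n_patients: int = 196, seed: int = 0, **overrides) -> CohortConfig:
    """Study-scale default cohort: 196 patients, Table-1-like prevalences.

    Prevalences and odds ratios mirror the published contingency tables
    (e.g. BRCA1/2 double hit in 41/196 patients with sample odds ratio
    ~3.1); features with zero resistant carriers in print get a large
    finite odds ratio.  Survival hazard ratios mirror the reported KM
    comparisons.  Override any field via keyword arguments.
    """
    features = (
        FeatureSpec("brca_biallelic", 41 / 196, odds_ratio=3.1, os_hr=0.47),
        FeatureSpec("hr_other_biallelic", 12 / 196, odds_ratio=2.3, os_hr=0.53),
        FeatureSpec("ddr_multi", 12 / 196, odds_ratio=6.0, os_hr=0.53),
        FeatureSpec("microtubule", 14 / 196, odds_ratio=6.0),
        FeatureSpec("chr4p_loss", 16 / 196, odds_ratio=5.0, dfs_hr=0.54),
        FeatureSpec("chr5q_loss", 21 / 196, odds_ratio=3.0, dfs_hr=0.59),
        FeatureSpec("hrd_like", 0.45, odds_ratio=3.0),
        FeatureSpec("sbs39_high", 0.50, odds_ratio=1.6, os_hr=0.57),
        FeatureSpec("id6_high", 0.50, odds_ratio=1.5, os_hr=0.59),
    )
    return CohortConfig(n_patients=n_patients, features=features, seed=seed, **overrides)


@dataclass
class SyntheticCohort:
    """Generated cohort: raw inputs plus the planted ground truth."""

    segments: pd.DataFrame
    variants: pd.DataFrame
    clinical: pd.DataFrame
    truth: pd.DataFrame
    config: CohortConfig

    def write(self, outdir) -> None:
        from . import io as _io

        _io.write_segments(self.segments, f"{outdir}/segments.seg.tsv")
        _io.write_variants(self.variants, f"{outdir}/variants.maf.tsv")
        self.clinical.to_csv(f"{outdir}/clinical.tsv", sep="\t", index=False)
        self.truth.to_csv(f"{outdir}/truth.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# segment construction helpers


def _carve(pieces: list[list], start: int, end: int, major: int, minor: int) -> None:
    """Replace [start, end) within an arm's piece list with a new state."""
    out = []
    for s, e, maj, mnr in pieces:
        if e <= start or s >= end:
            out.append([s, e, maj, mnr])
            continue
        if s < start:
            out.append([s, start, maj, mnr])
        if e > end:
            out.append([end, e, maj, mnr])
    out.append([start, end, major, minor])
    out.sort()
    pieces[:] = out


def generate_segments(
    truth_row: dict,
    scar_counts: tuple[int, int, int],
    arms: GenomeArms,
    rng: np.random.Generator,
    genes: pd.DataFrame | None = None,
) -> list[dict]:
    """Allelic segments for one patient from their planted truth.

    Every arm starts as one heterozygous diploid (1,1) segment; planted
    events are carved in.  Scar events are placed on shuffled designated
    arm pools (one event per arm, counts truncated at pool size) with
    flank geometry that confines each event to a single scar statistic.
    """
    sample = truth_row["sample"]
    return [
        {"sample": sample, "chrom": chrom, "start": s, "end": e,
         "major_cn": maj, "minor_cn": mnr}
        for chrom, s, e, maj, mnr in _segment_tuples(
            truth_row, scar_counts, arms, rng, genes
        )
    ]


def _baseline_tuples(arms: GenomeArms) -> list[tuple]:
    return [
        (str(a["chrom"]), int(a["start"]), int(a["end"]), 1, 1)
        for _, a in arms.arms.iterrows()
    ]


def _segment_tuples(
    truth_row: dict,
    scar_counts: tuple[int, int, int],
    arms: GenomeArms,
    rng: np.random.Generator,
    genes: pd.DataFrame | None = None,
    baseline: list[tuple] | None = None,
) -> list[tuple]:
    """(chrom, start, end, major, minor) tuples for one patient."""
    has_events = (
        any(scar_counts)
        or truth_row.get("chr4p_loss")
        or truth_row.get("chr5q_loss")
        or truth_row.get("brca_biallelic")
        or truth_row.get("hr_other_biallelic")
    )
    if not has_events:
        return baseline if baseline is not None else _baseline_tuples(arms)
    genes = genes if genes is not None else toy_genes()
    pieces: dict[tuple[str, str], list[list]] = {}
    for _, arm in arms.arms.iterrows():
        pieces[(str(arm["chrom"]), arm["arm"])] = [
            [int(arm["start"]), int(arm["end"]), 1, 1]
        ]

    def arm_bounds(key):
        row = arms.arm_row(*key)
        return int(row["start"]), int(row["end"])

    if truth_row.get("chr4p_loss"):
        s, e = arm_bounds(("4", "p"))
        _carve(pieces[("4", "p")], s, e, 0, 0)
    if truth_row.get("chr5q_loss"):
        s, e = arm_bounds(("5", "q"))
        _carve(pieces[("5", "q")], s, e, 0, 0)
    if truth_row.get("brca_biallelic"):
        g = genes[genes["gene"] == "BRCA1"].iloc[0]
        pos = int(g["pos"])
        _carve(pieces[(str(g["chrom"]), "q")], pos - 2 * MB, pos + 3 * MB, 1, 0)
    if truth_row.get("hr_other_biallelic"):
        g = genes[genes["gene"] == "RAD51C"].iloc[0]
        pos = int(g["pos"])
        _carve(pieces[(str(g["chrom"]), "q")], pos - 2 * MB, pos + 3 * MB, 1, 0)

    n_loh, n_tai, n_lst = scar_counts
    loh_arms = [LOH_ARM_POOL[i] for i in rng.permutation(len(LOH_ARM_POOL))[: n_loh]]
    tai_arms = [TAI_ARM_POOL[i] for i in rng.permutation(len(TAI_ARM_POOL))[: n_tai]]
    lst_arms = [LST_ARM_POOL[i] for i in rng.permutation(len(LST_ARM_POOL))[: n_lst]]
    for key in loh_arms:
        s, e = arm_bounds(key)
        # interstitial LOH with 4-Mb flanks: > 15 Mb, no telomere contact,
        # flanks below the LST flank threshold
        _carve(pieces[key], s + 4 * MB, e - 4 * MB, 1, 0)
    for key in tai_arms:
        s, e = arm_bounds(key)
        if key[1] == "q":  # event reaches the q telomere, 4-Mb centromeric flank
            _carve(pieces[key], s + 4 * MB, e, 2, 1)
        else:
            _carve(pieces[key], s, e - 4 * MB, 2, 1)
    for key in lst_arms:
        s, e = arm_bounds(key)
        if key[1] == "q":  # 12-Mb event abutting the centromere: one transition
            _carve(pieces[key], s, s + 12 * MB, 2, 1)
        else:
            _carve(pieces[key], e - 12 * MB, e, 2, 1)

    rows = []
    for (chrom, _arm), plist in pieces.items():
        for s, e, maj, mnr in plist:
            rows.append((chrom, int(s), int(e), int(maj), int(mnr)))
    return rows


# ---------------------------------------------------------------------------
# variant construction


def _mixture_channel_probs(reference: SignatureSet, weights: dict) -> np.ndarray:
    w = np.array([weights.get(lab, 0.0) for lab in reference.labels], dtype=float)
    if w.sum() <= 0:
        raise ValueError("signature mixture weights sum to zero")
    w = w / w.sum()
    return reference.matrix.to_numpy(dtype=float) @ w


def _blank_variant(sample: str, gene: str, chrom: str, pos: int) -> dict:
    return {
        "sample": sample, "gene": gene, "chrom": chrom, "pos": pos,
        "origin": "somatic", "consequence": "other",
        "germline_pathogenic": False, "sift_score": np.nan, "polyphen": None,
        "fathmm_mkl": np.nan, "in_cosmic": False, "snv_context": None,
        "indel_class": None, "population_af": np.nan,
    }


def _pathogenic_somatic(sample, gene, chrom, pos, context):
    v = _blank_variant(sample, gene, chrom, pos)
    v.update(consequence="nonsense", snv_context=context)
    return v


def generate_variants(
    truth_row: dict,
    mix: SignatureMixModel,
    sbs_reference: SignatureSet,
    id_reference: SignatureSet,
    rng: np.random.Generator,
    genes: pd.DataFrame | None = None,
    gene_positions: dict | None = None,
) -> list[dict]:
    """Variant records for one patient.

    Emits (a) background somatic SNVs/indels with channel counts drawn
    multinomially from the patient's signature mixture, (b) pathogenic
    hits implementing the planted gene-level features with annotation
    fields the filter retains, and (c) a small amount of annotation
    noise the filter must remove (a benign missense, a common variant,
    a consequence="other" record).
    """
    if gene_positions is not None:
        gpos = gene_positions
    else:
        genes = genes if genes is not None else toy_genes()
        gpos = {r["gene"]: (str(r["chrom"]), int(r["pos"])) for _, r in genes.iterrows()}
    sample = truth_row["sample"]
    rows: list[dict] = []

    sbs_w = dict(mix.sbs_weights)
    if truth_row.get("sbs39_high"):
        other = {k: v for k, v in sbs_w.items() if k != "SBS39"}
        scale = (1.0 - mix.sbs39_high_weight) / sum(other.values())
        sbs_w = {k: v * scale for k, v in other.items()}
        sbs_w["SBS39"] = mix.sbs39_high_weight
    id_w = dict(mix.id_weights)
    if truth_row.get("id6_high"):
        other = {k: v for k, v in id_w.items() if k != "ID6"}
        scale = (1.0 - mix.id6_high_weight) / sum(other.values())
        id_w = {k: v * scale for k, v in other.items()}
        id_w["ID6"] = mix.id6_high_weight

    p_sbs = _mixture_channel_probs(sbs_reference, sbs_w)
    p_id = _mixture_channel_probs(id_reference, id_w)

    def random_context() -> str:
        return SBS96_CHANNELS[rng.choice(len(SBS96_CHANNELS), p=p_sbs)]

    if mix.snv_burden > 0:
        counts = rng.multinomial(mix.snv_burden, p_sbs)
        pos = 1
        for ch_idx in np.nonzero(counts)[0]:
            for _ in range(int(counts[ch_idx])):
                v = _blank_variant(sample, ".", "1", pos)
                v["snv_context"] = SBS96_CHANNELS[ch_idx]
                rows.append(v)
                pos += 1
    if mix.indel_burden > 0:
        counts = rng.multinomial(mix.indel_burden, p_id)
        pos = 1
        for ch_idx in np.nonzero(counts)[0]:
            for _ in range(int(counts[ch_idx])):
                v = _blank_variant(sample, ".", "2", pos)
                v["indel_class"] = ID83_CHANNELS[ch_idx]
                rows.append(v)
                pos += 1

    if truth_row.get("brca_biallelic"):
        chrom, pos = gpos["BRCA1"]
        v = _blank_variant(sample, "BRCA1", chrom, pos)
        v.update(origin="germline", consequence="frameshift_indel", germline_pathogenic=True)
        rows.append(v)
    if truth_row.get("hr_other_biallelic"):
        chrom, pos = gpos["RAD51C"]
        rows.append(_pathogenic_somatic(sample, "RAD51C", chrom, pos, random_context()))
    if truth_row.get("ddr_multi"):
        for gene in ("ERCC6", "PTEN"):
            chrom, pos = gpos[gene]
            rows.append(_pathogenic_somatic(sample, gene, chrom, pos, random_context()))
    if truth_row.get("microtubule"):
        chrom, pos = gpos["MAP2"]
        rows.append(_pathogenic_somatic(sample, "MAP2", chrom, pos, random_context()))
    if truth_row.get("tp53_mut"):
        chrom, pos = gpos["TP53"]
        v = _blank_variant(sample, "TP53", chrom, pos)
        v.update(consequence="missense", sift_score=0.01,
                 polyphen="probably_damaging", snv_context=random_context())
        rows.append(v)

    # annotation noise the filter must drop
    noise = _blank_variant(sample, "NOISE1", "3", 5 * MB)
    noise.update(consequence="missense", sift_score=0.8, polyphen="benign")
    rows.append(noise)
    common = _blank_variant(sample, "NOISE2", "3", 6 * MB)
    common.update(origin="germline", consequence="missense", population_af=0.12)
    rows.append(common)
    benign_germ = _blank_variant(sample, "BRCA2", *gpos["BRCA2"])
    benign_germ.update(origin="germline", consequence="missense",
                       germline_pathogenic=False)
    rows.append(benign_germ)
    return rows


# ---------------------------------------------------------------------------
# cohort assembly


def generate_cohort(config: CohortConfig, arms: GenomeArms | None = None) -> SyntheticCohort:
    """Draw a complete synthetic cohort; deterministic given config.seed."""
    arms = arms or toy_genome()
    genes = toy_genes()
    sbs_ref = synthetic_sbs_reference()
    id_ref = synthetic_id_reference()
    n = config.n_patients
    root = np.random.SeedSequence(config.seed)
    streams = [np.random.default_rng(s) for s in root.spawn(n)]
    baseline = _baseline_tuples(arms)
    gene_positions = {
        r["gene"]: (str(r["chrom"]), int(r["pos"])) for _, r in genes.iterrows()
    }

    truth_rows, var_rows, clin_rows = [], [], []
    seg_chunks: list[tuple[str, list[tuple]]] = []
    base_logit = _logit(config.baseline_sensitive_rate)
    for i in range(n):
        rng = streams[i]
        sample = f"P{i + 1:04d}"
        truth: dict = {"sample": sample}
        eta = base_logit
        os_hazard = config.survival.baseline_os_rate
        dfs_hazard = config.survival.baseline_dfs_rate
        for spec in config.features:
            has = bool(rng.random() < spec.prevalence)
            truth[spec.name] = int(has)
            if has:
                eta += np.log(spec.odds_ratio)
                os_hazard *= spec.os_hr
                dfs_hazard *= spec.dfs_hr
        truth["tp53_mut"] = int(rng.random() < 0.83)  # common driver, no outcome link
        truth["eta"] = eta

        quiet, hrd = config.scar.quiet_means, config.scar.hrd_means
        means = hrd if truth.get("hrd_like") else quiet
        scar_counts = tuple(
            min(int(rng.poisson(m)), pool_size)
            for m, pool_size in zip(
                means, (len(LOH_ARM_POOL), len(TAI_ARM_POOL), len(LST_ARM_POOL))
            )
        )
        truth["planted_loh"], truth["planted_tai"], truth["planted_lst"] = scar_counts

        seg_chunks.append(
            (sample, _segment_tuples(truth, scar_counts, arms, rng, genes, baseline))
        )
        var_rows.extend(
            generate_variants(
                truth, config.signatures, sbs_ref, id_ref, rng,
                gene_positions=gene_positions,
            )
        )

        sensitive = int(rng.random() < _expit(eta))
        os_time = rng.exponential(1.0 / os_hazard) if os_hazard > 0 else np.inf
        dfs_time = rng.exponential(1.0 / dfs_hazard) if dfs_hazard > 0 else np.inf
        c_os = rng.uniform(0, config.survival.max_followup_months)
        c_dfs = rng.uniform(0, config.survival.max_followup_months)
        response = sensitive if rng.random() < 0.9 else 1 - sensitive
        clin_rows.append(
            {
                "sample": sample,
                "pt_sensitive": sensitive,
                "response": "CR_PR" if response else "none",
                "os_months": round(min(os_time, c_os), 3),
                "os_event": int(os_time <= c_os),
                "dfs_months": round(min(dfs_time, c_dfs), 3),
                "dfs_event": int(dfs_time <= c_dfs),
                "age": int(np.clip(rng.normal(58, 9), 35, 90)),
                "grade": rng.choice(["G1-G2", "G3-G4", "unknown"], p=[0.14, 0.61, 0.25]),
            }
        )
        truth_rows.append(truth)

    all_tuples = list(itertools.chain.from_iterable(rows for _, rows in seg_chunks))
    segments = pd.DataFrame(
        all_tuples, columns=["chrom", "start", "end", "major_cn", "minor_cn"]
    )
    segments.insert(
        0,
        "sample",
        np.repeat(
            [s for s, _ in seg_chunks], [len(rows) for _, rows in seg_chunks]
        ) if seg_chunks else np.array([], dtype=object),
    )
    segments = segments[SEGMENT_COLUMNS]
    variants = pd.DataFrame(var_rows, columns=MAF_COLUMNS)
    clinical = pd.DataFrame(
        clin_rows,
        columns=["sample", "pt_sensitive", "response", "os_months", "os_event",
                 "dfs_months", "dfs_event", "age", "grade"],
    )
    truth_cols = ["sample"] + [f.name for f in config.features] + [
        "tp53_mut", "planted_loh", "planted_tai", "planted_lst", "eta"]
    truth = pd.DataFrame(truth_rows, columns=truth_cols)
    return SyntheticCohort(segments, variants, clinical, truth, config)


def _logit(p: float) -> float:
    return float(np.log(p / (1.0 - p)))


def _expit(x: float) -> float:
    return float(1.0 / (1.0 + np.exp(-x)))
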