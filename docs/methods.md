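# Methods

This note documents the models and procedures implemented in
`ptscore`, the choices made where the design was genuinely open, and
what the synthetic-data experiments do and do not demonstrate.

## Coordinates and genome model

All in-memory coordinates are 0-based half-open; SEG-style input files
declared 1-based inclusive are converted on read and back on write.
The bundled genome is a reduced 22-autosome model: arm lengths rounded
to the megabase (approximating the human reference) with a uniform
3-Mb centromere gap between p and q. Scar statistics and arm-loss
calls need only arm boundaries, centromere extent and telomere
positions, so this is sufficient for development and testing; a real
centromere table in the same TSV layout can be supplied instead. The
acrocentric p arms are retained for simplicity. Gene positions in the
bundled table are single-point anchors used for variant/segment
overlap, not real coordinates.

## Variant filtering and bi-allelic typing

The somatic filter keeps truncating-class variants (nonsense, splice
site, frameshift/in-frame indel) unconditionally and missense variants
meeting at least two of three in-silico criteria: SIFT in the closed
interval [0, 0.05]; PolyPhen-2 "possibly" or "probably damaging";
COSMIC presence together with FATHMM-MKL strictly greater than 0.5.
Germline records pass through untouched; germline pathogenicity is an
input annotation (ClinVar-style), not something this package derives.
An optional population-allele-frequency pre-filter removes common
variants first; the default cutoff of 0.01 is an explicit placeholder
— set it to match the annotation source.

Bi-allelic inactivation of a gene is typed from filtered variants plus
the sample's allelic segments. A variant has LOH support when it lies
in a segment with minor copy number 0 (and positive total copy).  The
four mechanisms are evaluated in fixed precedence: germline
pathogenic + LOH, then germline + somatic, then somatic + LOH, then
two somatic hits. The precedence is a package decision — one
mechanism is reported per gene and no canonical tie-break exists in
the literature. "Heterozygous" in mechanisms b/d is not re-verified
against copy number; any qualifying second hit counts.

The DDR "multiple mutations" feature counts retained somatic
*mutations* (two hits in one gene qualify), not distinct genes.  The
bundled DDR/microtubule/driver panels are small placeholder lists of
well-known genes; supply real curated catalogues via configuration. The default DDR panel excludes the
hypermutated drivers (TP53, FAT3, RYR2, MAP2), without which a
two-mutation rule would be nearly always true in a TP53-driven cancer.

## Arm-level loss and scar scores

Arm-level loss is called when one of four allele-specific states covers
at least 90% (configurable) of an arm, measured as the union of
segment∩arm intersections over arm length: homozygous loss (0,0),
classic LOH (1,0), copy-neutral LOH (2,0), and LOH at high ploidy
(major > 2, minor 0), evaluated in that order. The composite
"chr5q-or-4p loss" feature is the logical OR of the two arm calls.

The three scar statistics follow the conventions of the HRD-score
literature; none of the thresholds is asserted to match any one
group's exact dialect, and all are parameters:

* **LOH score** — regions with minor copy 0 and total copy > 0, merged
  across contiguous segments, counted when longer than 15 Mb unless
  they span an entire (modeled) chromosome.
* **TAI score** — allelic-imbalance regions (major ≠ minor) longer
  than 11 Mb that touch a telomere and do not span the centromere.
* **LST score** — per arm, segments shorter than 3 Mb are iteratively
  removed (smallest first; equal-state flanks that abutted the removed
  piece are re-joined), then state changes between adjacent segments
  each ≥ 10 Mb with a gap < 3 Mb are counted.

Uncovered gaps between segments are treated as state-unknown: they
break LOH/TAI region merges and count as gap distance for LST.  The
HRD score is the unweighted sum of the three counts. The published
weighted HRDetect model is deliberately out of scope; wherever a
weighted HRD comparator might be expected, this package uses the
unweighted scar sum.

## Mutational signatures

SBS catalogs use the canonical 96-channel pyrimidine-centred
trinucleotide taxonomy (purine-centred contexts are
reverse-complemented on binning); indel catalogs use the standard
83-channel taxonomy with the channel label supplied on input
(classifying indels from raw sequence is out of scope). Catalogs are
built from somatic calls *before* the consequence filter (after the
population-AF pre-filter). Exposures are per-sample non-negative
least squares against a reference matrix whose columns sum to one —
plain NNLS with no sparsity penalty or signature pre-selection.
Relative exposures normalise the absolute vector. The retention rule
keeps signatures whose pooled absolute exposure exceeds 1% of all
attributed mutations, strict inequality, computed cohort-wide on
absolute exposures by default (a per-sample mode exists; neither
choice is canonical).

The bundled reference profiles (SBS1/3/5/39, ID1/2/6/8) are
**synthetic** stand-ins generated from sparse Dirichlet draws — well
separated (pairwise cosine ≤ 0.37) and in the exact COSMIC-format
layout, but not the real COSMIC profiles, which are not redistributed
here. Real profiles load through `SignatureSet.from_tsv`.

## Statistics

Fisher's exact test is two-sided by the minimum-likelihood convention
(sum of hypergeometric point probabilities not exceeding the observed
table's); this reproduces the published contingency-table p-values and
equals exhaustive enumeration on all small tables (verified in the
tests). Mann-Whitney uses exact enumeration for pooled n ≤ 12 without
ties and the tie-corrected normal approximation otherwise.
Kaplan-Meier and the log-rank test come from lifelines; the reported
hazard ratio is the observed/expected ratio (O1/E1)/(O2/E2) with a
log-scale CI from var(log HR) ≈ 1/E1 + 1/E2, with a single-covariate
Cox fit available behind a flag (clinical reports often print HRs
without stating the estimator). No multiple-testing correction is
applied anywhere — a deliberate design choice matching common
single-cohort biomarker practice; all screening is at raw p < 0.05
and should be read accordingly.

Candidate screening marks a feature when it (1) differs between
sensitive and resistant patients (Fisher for binary, Mann-Whitney for
continuous) and (2) separates OS or DFS by log-rank after
median-dichotomisation (values strictly above the cohort median are
"high"; the median itself is "low" — the cutpoint is a package
default, not an asserted reproduction).

## The Pt-score model

`PtScoreModel.fit` minimises `(1/n)·deviance + λ·‖β‖₁` with an
unpenalised intercept (saga solver; exact KKT shortcut to the null
model for λ ≥ λ_max; unpenalised lbfgs for λ = 0). Continuous
features are standardised inside the fit (population SD); binary
features enter as 0/1. Standardisation parameters, coefficients, λ
and seeds are stored on the results object, which serialises to a
self-contained JSON document. λ is selected by stratified K-fold
(default 10) cross-validated deviance over a log-spaced grid from
λ_max down 2.5 decades, ties resolved toward the sparser model.
Standardisation is computed once on the fitting data (not re-estimated
per CV fold), a standard simplification at these scales.

The Pt-score is the linear predictor. AUC uses the rank formula with
ties counted half. DeLong's test estimates the variance/covariance of
two correlated AUCs from placement values (ties at half weight,
consistent with the AUC convention); identical score vectors give
z = 0, p = 1, and degenerate placement variance with unequal AUCs is
reported as non-comparable rather than raised.

## Synthetic cohorts

The generator's defaults emulate a 196-patient platinum-treated
ovarian-cancer cohort. Feature prevalences mirror the published
contingency tables (e.g. BRCA1/2 double hit 41/196); odds ratios are
their sample odds ratios, with features whose printed tables contain a
zero cell given a large finite OR (5–6). Survival uses an exponential
baseline (median OS ≈ 40 months, DFS ≈ 18 months) with multiplicative
per-feature hazards matching the published KM hazard ratios, under
uniform administrative censoring over a 120-month follow-up window —
the realised censoring fraction follows from the window rather than
being dialled directly. The baseline sensitivity rate (0.35 before
feature effects) was set so the marginal sensitive fraction lands near
the published 136/196. Mutation burden defaults to 120 SNVs + 50
indels per patient — intentionally modest so NNLS refitting is
non-trivial but desk-fast.

Each planted feature is realised in raw data: a germline pathogenic
BRCA1 record over a 5-Mb minor-zero segment; a somatic RAD51C hit with
LOH; two DDR-panel somatic hits; one MAP2 hit; whole-arm chr4p/chr5q
events; SBS39/ID6 mixture-weight boosts. Scar events are carved into
designated arm pools with flank geometry (flanks ≥ 3 Mb but < 10 Mb)
chosen so one planted event increments exactly one scar statistic —
this makes planted (k₁,k₂,k₃) recoverable exactly and keeps the three
scores interpretable in tests. Arm-loss features are planted as
whole-arm homozygous loss (0,0): biologically a caricature, but the
only allele-specific state that touches none of the three scar
statistics, which keeps the arm-loss features statistically
independent of scar burden — exactly the property the head-to-head
model comparison needs. Randomness uses one root seed with
per-patient spawned substreams, so enlarging a cohort never perturbs
existing patients.

What the generator does **not** emulate: subclonal copy-number
mixtures, purity/ploidy error, read-level noise, germline population
structure, linkage between features, or realistic per-gene mutation
rates. Passing tests therefore demonstrate correctness of the
*pipeline mechanics and statistics* under the stated generative model,
not clinical performance on real tumours.

## Experiment scales

Test and acceptance problem sizes are package choices balancing Monte
Carlo resolution against desk-scale runtimes: label-model calibration
at n = 20,000 (log-OR within ±0.1); Fisher power on a planted OR = 5
feature at n = 2,000 over 25 seeds; signature recovery at burden 5,000
over 100 samples (mean |error| ≤ 0.02); DeLong variance vs a
2,000-replicate bootstrap at n = 200 (within 10%); lasso recovery of a
planted OR = 10 feature at n = 1,000 over 20 seeds; and the Pt-score
vs HRD-sum comparison on 100 cohorts of n = 500 (stratified 50/50
train/held-out split, 5-fold CV), with a 40-cohort scar-only null
branch confirming no systematic superiority when only scar-linked
signal exists.

## Known limitations

* Gene panels, the population-AF cutoff and the signature reference
  are placeholders; results on real data depend on supplying the real
  catalogues.
* The scar-score thresholds implement the common literature dialect;
  other dialects (e.g. different LST smoothing rules) are expressible
  via parameters but not individually validated against their original
  implementations.
* In-cohort AUC of a CV-tuned model is optimistic; use the held-out
  numbers in `run_pipeline` reports for comparisons.
* The O/E hazard ratio is biased toward the null in small samples with
  heavy censoring; prefer the Cox option when effect-size accuracy
  matters.
* `classify_biallelic` trusts phase-free two-hit logic; without
  phasing, two somatic hits on the same allele would be miscalled as
  bi-allelic.
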