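# ptscore

Genomic-feature integration for predicting platinum sensitivity in
ovarian cancer.

Platinum-based chemotherapy is the standard of care for ovarian cancer,
and response tracks DNA-repair competence: tumours with homologous
recombination deficiency (HRD) — classically via *BRCA1/2* inactivation
— respond better. The popular HRD score summarises three genomic scars
as an unweighted sum,

```
HRD = N_LOH + N_TAI + N_LST
```

(counts of long interstitial loss-of-heterozygosity regions, telomeric
allelic imbalances, and large-scale copy-state transitions). But HRD is
not the only determinant of platinum response. `ptscore` derives a
broader panel of features from allele-specific copy-number segments and
annotated variant tables —

* bi-allelic ("double hit") inactivation of *BRCA1/2* and other
  homologous-recombination genes, typed as one of four mechanisms
  (germline+LOH, germline+somatic, somatic+LOH, somatic+somatic);
* multiple somatic mutations in DNA-damage-repair (DDR) genes and
  mutations in microtubule-function genes, after a consequence/in-silico
  damage filter (SIFT ≤ 0.05, damaging PolyPhen-2, COSMIC + FATHMM-MKL
  > 0.5; missense kept when ≥ 2 criteria hold);
* arm-level copy-number loss (four categories incl. copy-neutral LOH,
  called at ≥ 90% arm coverage), in particular chr4p and chr5q loss;
* SBS-96 / ID-83 mutational-signature exposures refitted by
  non-negative least squares against a reference catalogue (signatures
  kept when they explain > 1% of cohort mutations);
* the three scar counts themselves —

and integrates them into a **Pt-score**: the linear predictor of an
L1-penalised (lasso) logistic regression of platinum sensitivity on the
feature matrix, with the penalty chosen by stratified cross-validated
deviance. Pt-score and HRD-sum ROC curves are compared on the same
samples with DeLong's test for correlated AUCs.

Because real platinum-response cohorts are access-controlled, the
package ships a synthetic cohort generator that plants every feature in
the raw data representation its extractor consumes, with configurable
prevalences, odds ratios and survival hazard ratios — so the entire
pipeline is testable end to end at desk scale.

Intended users: statistical-genomics researchers and bioinformaticians
prototyping HRD-adjacent biomarkers or benchmarking scar-score dialects.

## Worked example

```python
import ptscore as pt

# a 196-patient synthetic cohort with Table-1-like feature prevalences
cohort = pt.generate_cohort(pt.default_config(n_patients=196, seed=7))
feats = pt.extract_features(cohort.segments, cohort.variants,
                            samples=cohort.clinical["sample"])
df = pt.assemble_features(feats, cohort.clinical)

model = pt.PtScoreModel(df.drop(columns=["pt_sensitive"]), df["pt_sensitive"])
results = model.fit(folds=10, seed=0)
print(results.summary())

cmp = results.compare_roc(df, df["pt_sensitive"], df["hrd_score"])
print(f"AUC(Pt-score)={cmp.auc_a:.3f}  AUC(HRD sum)={cmp.auc_b:.3f}  "
      f"z={cmp.z:.2f}  p={cmp.p_value:.4f}")
```

prints (abridged):

```
Pt-score model (L1-penalised logistic regression)
  lambda = 0.00245435   CV folds = 10   seed = 0
  intercept = +0.0445
  feature                    coef       mean      scale
  brca12_biallelic        -0.1623     0.0000     1.0000
  hr_biallelic            +1.1273     0.0000     1.0000
  ddr_multi               +2.0826     0.0000     1.0000
  microtubule             +3.3936     0.0000     1.0000
  ...
  n_lst                   -0.0879     2.6837     2.4789
  non-zero coefficients: 10/12
AUC(Pt-score)=0.826  AUC(HRD sum)=0.570  z=6.03  p=0.0000
```

The coefficients are on standardised feature scales (binary features
enter as 0/1); the Pt-score is the linear predictor, a monotone
transform of the predicted sensitivity probability. Here the
integrated score separates sensitive from resistant patients markedly
better than the raw scar sum, and DeLong's test says the in-cohort AUC
difference is unlikely under equal discrimination. (In-cohort AUC of a
tuned model is optimistic; `run_pipeline` also reports a held-out
split.)

The same flow is available from a shell:

```bash
ptscore simulate --outdir cohort --n-patients 196 --seed 7
ptscore extract --segments cohort/segments.seg.tsv \
                --variants cohort/variants.maf.tsv --out features.tsv
ptscore associate --features features.tsv --clinical cohort/clinical.tsv --out assoc.tsv
ptscore train --features features.tsv --clinical cohort/clinical.tsv --model-out model.json
ptscore compare-roc --model model.json --features features.tsv --clinical cohort/clinical.tsv
# or everything at once:
ptscore run-all --outdir run --n-patients 500 --seed 7
```

## Layout

| module | contents |
| --- | --- |
| `ptscore.genome` | reduced 22-autosome arm/centromere model, gene anchors |
| `ptscore.cna` | arm-level loss calls, LOH/TAI/LST scar scores, HRD sum |
| `ptscore.variants` | AF + consequence filter, bi-allelic typing, pathway flags |
| `ptscore.signatures` | SBS-96/ID-83 catalogs, NNLS exposures, 1% retention |
| `ptscore.stats` | Fisher, Mann-Whitney, KM, log-rank, candidate screening |
| `ptscore.model` | `PtScoreModel`/`PtScoreResults`, ROC AUC, DeLong test |
| `ptscore.simulate` | synthetic cohort generator with planted truth |
| `ptscore.pipeline` | feature extraction/assembly, end-to-end runs, reports |
| `ptscore.cli` | `ptscore` command-line interface |

Methodological details, parameter tables and known limitations are in
[`docs/methods.md`](docs/methods.md).
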