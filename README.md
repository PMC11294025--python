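# peradiomics

CT radiomics of skeletal muscle (SM) and intramuscular adipose tissue
(IMAT) for short-term mortality prognosis in acute pulmonary embolism
(APE), as a tested, reusable Python pipeline.

Body-composition markers at vertebral level Th12 — muscle mass, muscle
attenuation, intramuscular fat — carry prognostic information in acute
disease. This package implements the full radiomics analysis chain for
that question on a single axial CT slice: per patient, 234 IBSI-style
features (25 morphology, 57 first-order, 95 second-order texture on a
24-level fixed-bin-number discretization, and 57 first-order features of
an averaged 1–5 mm Laplacian-of-Gaussian response) are extracted from the
SM (−29…150 HU), IMAT (−190…−30 HU) and combined SM+IMAT (−190…150 HU)
compartments; features unstable under image perturbation (Gaussian noise
with the in-image SD plus ±10% ROI volume changes) are removed when the
lower 95% bound of their one-way ICC falls below 0.8; redundant features
are collapsed by average-linkage Spearman clustering at |ρ| ≥ 0.8 with
mutual-information representatives; a prognostic signature is derived by
10×3-fold stratified cross-validation with three feature selectors (MRMR,
MIM, univariate logistic) and three learners (logistic regression,
gradient-boosted linear model, random forest), keeping features that enter
a selector's top-5 in more than 50% of the 30 runs for at least two
selectors, pruned at training |ρ| > 0.5; the final model is refit on the
training split and evaluated on the held-out 30% — AUC with bias-corrected
bootstrap CI, Youden cut-off transferred from training, Hosmer–Lemeshow
calibration, DeLong comparison against the sPESI clinical score.

Because no patient imaging is publicly available for this problem, the
package ships a synthetic cohort generator (`peradiomics.synthetic`) that
renders CT-like slices with outcome-dependent intramuscular fat burden,
muscle-attenuation shape (positive skew in decedents, negative in
survivors) and compartment elongation, nested 7-/30-day mortality at
8.4%/14.6%, and frailty-driven sPESI components. Every pipeline stage is
tested against it; see `docs/methods.md` for the generator model and its
limitations.

## Worked example

```bash
peradiomics run-all --n 200 --seed 11 --roi SM_IMAT --endpoint 30d \
    --repeats 3 --out demo_run
```

prints

```
run complete: demo_run
  SM_IMAT/30d: signature=ih_skew_fbn_n24 morph_pca_eccentricity cm_info_corr1_d1_2d_s_mrg_fbn test AUC 1.00
```

and writes `demo_run/summary.csv`:

```
signature,features,mortality,train_auc,test_auc,sens_spec_train,sens_spec_test,cutoff
Radiomics SM_IMAT,ih_skew_fbn_n24 morph_pca_eccentricity cm_info_corr1_d1_2d_s_mrg_fbn,30d,1.00 (1.00-1.00),1.00 (1.00-1.00),1.00/1.00,1.00/1.00,0.50
Clinical sPESI,sPESI,30d,0.80 (0.66-0.90),0.66 (0.43-0.86),0.89/0.29,0.75/0.37,1.00
```

Reading this: on a 200-patient synthetic cohort, the occurrence-consensus
rule selected a three-feature SM+IMAT signature — the skewness of the
discretized intensity histogram (`ih_skew_fbn_n24`, the myosteatosis
marker the generator plants), a compartment-shape descriptor
(`morph_pca_eccentricity`) and a co-occurrence information measure
(`cm_info_corr1…`). The radiomic model separates the synthetic outcome
groups completely (the planted image signal is deliberately strong), while
the sPESI baseline, which sees the outcome only through the shared latent
frailty, reaches a held-out AUC of 0.66 at its conventional cut-off of 1
with the typical high-sensitivity/low-specificity pattern. The run
directory also contains the per-stage artifacts: the ICC robustness
report, cluster assignments, per-selector occurrence tables, CV AUC
summaries, the fitted model parameters (Yeo–Johnson λ, z-scaling and
linear coefficients), full evaluation JSONs, ROC-curve and
calibration-plot coordinates as CSV, the frozen feature manifest, and a
provenance manifest recording every threshold, seed and library version.

The same stages are available individually (`generate`, `prep`, `extract`,
`screen`, `cluster`, `cv`, `finalize`, `evaluate`, `spesi`) and as library
functions.

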