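# trisomics

Molecular-subtype discovery for trisomy 21 (T21) multiomics cohorts, packaged
as a tested, reusable pipeline together with a synthetic cohort generator that
plants the statistical structure the analysis is designed to detect.

The pipeline covers:

- **Synthetic cohorts** (`trisomics.sim`) — whole-blood expression with a
  1.5x chromosome-21 dosage effect (per-gene and per-individual variation),
  two anti-correlated chr21 co-expression clusters (97 + 29 genes), three
  latent molecular subtypes (107/95/102 individuals) with graded cluster
  expression, an inflammatory analyte signature, graded amino-acid depletion
  (9 planted MS3-vs-MS1 analytes), a 31-gene transporter panel (18 up / 12
  down), immune-cell composition and CBC shifts, covariate effects, and
  longitudinal revisits with analyte-specific stability. Ground truth is
  returned alongside every layer.
- **Preprocessing** (`trisomics.preprocess`) — zero replacement, global-median
  normalisation, 3x-IQR outlier masking per karyotype, covariate (age/sex/
  source) adjustment, z-scores against euploid controls.
- **Co-expression structure** (`trisomics.coexpression`) — gene-gene Spearman
  correlation matrices with BH-adjusted q-values and average-linkage
  hierarchical clustering on 1 - rho.
- **Consensus subtypes** (`trisomics.consensus`) — from-scratch resampling
  consensus clustering (100-fold subsampling, Spearman distance, average
  linkage), CDF/delta-area k-selection, anchored subtype assignment, PCA.
- **Composite scores** (`trisomics.scores`) — polygenic cluster scores and
  the inflammatory cytokine score with data-driven analyte selection.
- **Stats engine** (`trisomics.stats`) — per-feature log2 linear models with
  covariates, exact/approximate Wilcoxon rank-sum, Fisher's exact test,
  Benjamini-Hochberg adjustment, feature-vs-layer correlation screens,
  longitudinal stability, preranked GSEA.
- **Ratio classifiers** (`trisomics.classifier`) — inflammatory-marker /
  lymphocyte ratio indexes with 90th-percentile euploid cutoffs,
  sensitivity/specificity, and AND/majority index combination.
- **IO + CLI** (`trisomics.io`, `trisomics.cli`, `trisomics.pipeline`) — TSV
  matrices ("NA" for missing), GMT gene sets, YAML configs, a subcommand CLI
  and a full-pipeline orchestrator with a reproducibility manifest.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (planted-structure
recovery on the default cohort plus independent-oracle suites); the whole run
takes well under a minute after the session cohort is built.

## CLI

```sh
trisomics simulate --out cohort/ --seed 1
trisomics preprocess --matrix cohort/layer_metabolome.tsv --samples cohort/samples.tsv \
    --recipe replace-zeros,median-normalize,log2,mask-outliers,adjust --out metab.tsv
trisomics subtype --zmatrix z_hsa21.tsv --max-k 6 --iters 100 --p-item 0.8 --seed 1 --out subtypes/
trisomics run-all --out run/ --seed 1
```

`run-all` simulates a default cohort, executes every stage, and writes all
artefacts plus `manifest.json` (version, seeds, output hashes, per-stage
dimensions). See `trisomics --help` for the remaining subcommands
(genecluster, score, diff, gsea, classify, stability).

## Notes

- All matrices are features x samples, tab-delimited, `NA` = missing.
- Quantiles use linear interpolation between order statistics ("type 7");
  standard deviations use the n-1 denominator.
- log2 fold changes follow the "B vs A" = B minus A sign convention.
- Cell-proportion contrasts are fitted on logit-transformed frequencies by
  the generic linear engine (a documented stand-in for beta regression).
- Not in scope: count-level RNA-seq models (DESeq2), vendor normalisation
  (SomaScan/MSD), read processing, mass-cytometry gating, figure rendering.
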