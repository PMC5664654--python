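# longgxe

Set-based gene–environment interaction analysis for longitudinal cohorts.

`longgxe` implements a staged analysis of repeatedly measured outcomes
(e.g., BMI across exams) against regions of common genetic variants and
dichotomous social/psychosocial exposures:

1. **Exposure construction** — questionnaire battery scoring (reverse coding,
   missingness caps, relationship-domain averaging), adverse-category
   dichotomization (group-median / zero-count / education cut-points),
   outcome outlier exclusion, and a rank-based inverse-normal transform for
   sensitivity analyses (`longgxe.phenotypes`).
2. **Region construction** — variant sets anchored on GWAS index SNPs: the
   containing gene (most-inclusive transcript span, 5 kb containment buffer)
   or a ±50 kb window, with strict INFO > 0.5 and MAF > 0.01 filters
   (`longgxe.regions`).
3. **Marginal exposure models** — Gaussian GEE with subject-clustered
   sandwich covariance (`longgxe.gee`, backed by statsmodels).
4. **Set-based score tests** — the core machinery: longitudinal
   score/dispersion tests of (a) all variant-by-exposure interaction
   coefficients and (b) all marginal variant coefficients in a region,
   against a semiparametric null with a B-spline main exposure effect and a
   weighted-PCA genotype main-effect adjustment that reverts to
   all-variant adjustment for small regions (`longgxe.settest`).  Null
   p-values come from weighted chi-square mixtures (`longgxe.quadform`,
   Liu-type moment matching plus characteristic-function inversion).
5. **Meta-analysis & multiplicity** — inverse-variance fixed-effect pooling,
   Fisher's method, Benjamini–Hochberg FDR, Bonferroni thresholds
   (`longgxe.meta`).
6. **Single-variant follow-up** — per-SNP GEE interaction scans and
   covariate-adjusted genotype × exposure cell means (`longgxe.scan`).
7. **Synthetic cohorts** — AR(1)-copula LD-structured genotypes and
   unbalanced longitudinal phenotypes with configurable main and interaction
   effects, so the full pipeline is testable without restricted data
   (`longgxe.simulate`).

## Command line

Each stage is a subcommand of `longgxe`:

```sh
longgxe simulate --n-subjects 500 --p-variants 30 --gamma 2.0 --seed 1 \
    --out-prefix scratch/demo
longgxe test-exposures --pheno scratch/demo_pheno.csv --exposures E \
    --out scratch/stage1.tsv
longgxe test-regions --pheno scratch/demo_pheno.csv \
    --dosage scratch/demo_dosage.tsv --variants scratch/demo_variants.tsv \
    --out scratch/stage2.tsv
longgxe test-gxe --pheno scratch/demo_pheno.csv \
    --dosage scratch/demo_dosage.tsv --variants scratch/demo_variants.tsv \
    --out scratch/stage3.tsv
longgxe snp-scan --pheno scratch/demo_pheno.csv \
    --dosage scratch/demo_dosage.tsv --variants scratch/demo_variants.tsv \
    --out scratch/stage4.tsv
```

`longgxe run-all --config config.yaml` executes the whole gated pipeline
(stage-1 Bonferroni gating of exposures, per-region marginal tests,
interaction tests with per-exposure FDR, Fisher meta across strata, and
single-SNP follow-up of FDR hits), writing per-stage TSVs, a JSON manifest
and a log of every gating decision.  See `longgxe run-all --help` and the
docstring in `longgxe/cli.py` for the YAML layout.

## Notes

- The interaction set test's score covariance is cluster-robust with a CR2
  (Bell–McCaffrey) small-sample adjustment, shrunk toward a
  pooled-within-cluster-size covariance (weight 0.45) for stable far-tail
  calibration; the marginal set test defaults to the pooled estimator (its
  tested block is constant within subjects, so pooling is exact and less
  noisy). All estimators are available via `cov_estimator=`.
- Genotype input is a dosage-matrix TSV + variant-metadata TSV, or a VCF
  with per-sample `DS` dosages (requires `cyvcf2`).
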