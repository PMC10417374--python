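# ipqtl

Backcross QTL interval mapping with intermediate-phenotype integration, and
bootstrap-LASSO SNV risk scores for human case-control cohorts.

The package covers two linked analyses:

- **Mouse side** — simulate or load a genetically heterogeneous backcross
  cohort; compute conditional genotype probabilities on a pseudomarker grid
  (two-state HMM, step 2.5 cM, error prob 0.001); run genome scans by EM
  interval mapping or Haley–Knott regression; classify LOD peaks
  (significant > 3, suggestive 1.5–2.99) and consolidate them across
  conditions; fit additive multi-QTL models with percent-variance
  decomposition and drop-one F-tests, comparing a basal locus model against
  models extended with loci linked to intermediate molecular phenotypes.
- **Human side** — filter SNVs by imputation quality (R² ≥ 0.7), label
  cases by a ≥ 5-point drop in cardiac function, test five genetic models
  (codominant, dominant, recessive, overdominant, log-additive), select
  SNVs by a seeded 80/20 bootstrap (p < 0.05 in both portions, ≥ 5 hits of
  100), fit an L1-penalized logistic risk score with cross-validated
  penalty, pick the probability cutoff by Youden's J, and evaluate on a
  held-out 20% test split.

A first-class simulator generates both cohort types with recorded ground
truth (ipQTL → IMP → phenotype mediation, direct QTL effects, HWE SNVs with
logistic risk), which drives all property and recovery tests.

## CLI

```bash
# synthetic cohorts (mouse cross/IMP/phenotype CSVs, human dosage CSV + truth)
ipqtl simulate --seed 1 --out runs/sim                 # defaults
ipqtl simulate --config sim.yaml --seed 1 --out runs/sim --kind mouse

# mouse analysis: IMP selection -> scans -> peak registry -> model comparison
ipqtl mouse --cross runs/sim/cross.csv --imps runs/sim/imps.csv \
    --pheno runs/sim/phenotypes.csv --seed 1 --out runs/mouse

# human analysis: R^2 filter -> bootstrap selection -> LASSO -> Youden -> test
ipqtl human --genotypes runs/sim/human_cohort.csv --r2 runs/sim/human_r2.csv \
    --r2-min 0.7 --iters 100 --min-hits 5 --seed 42 --out runs/human
```

Outputs are tidy CSVs plus a `manifest.json` per run (scan curves, peak
registry, consolidated QTLs, model-comparison table, bootstrap hit counts,
risk-model JSON, metrics).

### Cross-file dialect

CSV with three header rows — marker names, chromosome labels, cM positions —
then one row per individual: id followed by one letter per marker,
`A` (recurrent homozygote), `H` (heterozygote), `-` (missing). Files
round-trip bit-exactly through `ipqtl.io.read_cross_csv`/`write_cross_csv`.

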