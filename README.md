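# metabalance

Radiogenomic metabolism scoring for FDG-avid liver tumors. The package links
a PET-derived uptake phenotype (the tumor-to-normal-liver SUV ratio, TLR) to
glucose- and lipid-metabolism gene expression, and validates the derived
signatures against survival:

- **`io_formats`** — readers/writers for counts TSV, GMT gene sets, clinical
  TSV, MAF-style mutation tables, and the YAML run configuration.
- **`normalize`** — TMM scaling factors, CPM, paired tumor/normal log2 fold
  changes, per-gene z-scores.
- **`screen`** — per-gene Pearson correlation of expression change against
  log2 TLR, sign-split gene programs, hypergeometric over-representation.
- **`scoring`** — TLR computation and median phenotype split, gene-set
  signature scores (mean z-score), the glucose-minus-lipid balance score,
  cutoff stratification.
- **`survival_stats`** — Cox proportional hazards (own Newton-Raphson on the
  Efron/Breslow partial likelihood), univariable screening, candidate
  intersection, greedy collinearity exclusion, prognostic index, median-split
  risk groups, Kaplan-Meier, log-rank, t-tests, 2x2 chi-square.
- **`simulate`** — synthetic paired cohorts with planted expression programs,
  uptake coupling, proportional-hazards survival and mutation labels, all
  driven by one latent axis and a single seed.
- **`pipeline`** — `discover` and `validate` runs from a YAML config, with a
  JSON manifest of input/output digests for bit-reproducibility.

## CLI

```bash
# generate a synthetic cohort in pipeline-ready formats
metabalance simulate --out cohort/ --seed 7

# discovery arm: counts + TLR -> gene programs + signature scores
metabalance discover --config discover.yaml

# validation arm: expression + survival -> Cox tables, PI, KM, chi-square
metabalance validate --config validate.yaml
```

A minimal `discover.yaml`:

```yaml
counts: cohort/counts.tsv
pairing: cohort/pairing.tsv
clinical: cohort/clinical.tsv
candidates_gmt: cohort/gene_sets.gmt
outdir: out/
seed: 7
```

and `validate.yaml`:

```yaml
expression: expression.tsv      # gene x sample, raw scale
clinical: clinical.tsv          # needs dfs_time/dfs_event, os_time/os_event
gene_sets_gmt: gene_sets.gmt    # GLUCOSE_PROGRAM / LIPID_PROGRAM sets
mutations: mutations.maf.tsv    # optional; enables the TP53/CTNNB1 chi-square
outdir: out/
```

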