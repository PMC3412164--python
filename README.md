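# sigrank

Gene-set signature scoring and rank-ordering of expression profiles for
cell-line model selection, with the companion analyses that motivate the
ranking: GSEA against a **gene-set resampling** null, GI50-based
chemosensitivity signature mining, and survival stratification by
signature score. A synthetic-data module with planted ground truth makes
every stage testable without downloads.

## What it does

- **I/O + preprocessing** (`sigrank.io_expression`): TSV / GEO
  series-matrix expression readers, GMT gene sets, probe→gene and
  sample→group maps; quantile normalization; probe collapse keeping the
  max-SD probe per gene.
- **Scoring + ranking** (`sigrank.signature_scoring`): gene-wise
  zero-centering across the compendium, set-average scores per sample,
  replicate averaging per group, per-signature descending ranks (rank 1 =
  strongest); rule-based fold-change signature derivation; PCA projection.
- **GSEA** (`sigrank.gsea`): weighted KS running-sum enrichment score;
  p/NES/FDR from random same-size gene sets resampled from the ranked
  list (not phenotype permutation).
- **GI50 mining** (`sigrank.drug_sensitivity`): drug-panel filtering,
  gene × drug correlations of log2 expression vs −log(GI50), selection of
  genes with |r| > threshold for ≥ k drugs, average-linkage two-cluster
  split into positively / negatively response-associated signatures,
  median-correlation and rank-vs-response summaries.
- **Survival** (`sigrank.survival_analysis`): mean- or zero-split score
  dichotomization, Kaplan–Meier curves, two-group log-rank test
  (via lifelines).
- **Simulation** (`sigrank.synthetic_data`): replicate-structured
  compendia with planted set shifts and probe multiplicity, GI50 panels
  with planted positively/negatively coupled genes, survival cohorts with
  score-dependent hazard — all pure functions of (spec, seed).
- **Pipeline** (`sigrank.cli_pipeline`): YAML-configured multi-stage runs
  with a checksummed manifest.

## CLI

```sh
sigrank simulate --seed 3 --out-dir sim/            # synthetic fixtures + truth.json
sigrank rank --expr sim/expression.tsv --groups sim/groups.tsv \
    --gmt sim/sets.gmt --probe-map sim/probe_map.tsv --out table.tsv
sigrank gsea --expr sim/expression.tsv --groups sim/groups.tsv \
    --a GRP00 --b GRP03 --gmt sim/sets.gmt --probe-map sim/probe_map.tsv \
    --resamples 1000 --seed 17 --out gsea.tsv
sigrank gi50-mine --expr sim/panel_expression.tsv --gi50 sim/gi50_neglog.tsv \
    --already-neglog --threshold 0.5 --min-drugs 3 --out signatures.gmt
sigrank survival --cohort sim/cohort.tsv --split zero --out km.tsv
sigrank run --config cfg.yaml                       # multi-stage pipeline
```

Pipeline config (`cfg.yaml`):

```yaml
stages: [rank, gsea, survival]
inputs:
  expression: sim/expression.tsv
  groups: sim/groups.tsv
  gene_sets: sim/sets.gmt
  probe_map: sim/probe_map.tsv
  cohort: sim/cohort.tsv
params: {gsea_a: GRP00, gsea_b: GRP03, split_mode: zero_split}
out_dir: out
seed: 17
```

## Conventions worth knowing

- Centering is computed across **all** samples supplied; changing
  compendium membership changes every score.
- Rank ties break by group input order; probe-collapse SD ties break by
  lexicographic probe id; scores exactly at a survival split boundary go
  to the **low** group.
- ES magnitude ties between the positive and negative running-sum extreme
  resolve to the positive extreme.
- −log(GI50) uses base 10; raw GI50 files are converted on read
  (`--already-neglog` to skip).
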