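# coexkit

Weighted gene co-expression network analysis for clinically annotated
transcriptome cohorts: RPKM cleaning, signed biweight-midcorrelation networks
with topological-overlap module detection, module-eigengene/trait inference,
four-group differential expression, gene-set over-representation, cross-cohort
module preservation, and relapse/survival prognostics (ROC, prognostic-ratio
combination screening, Kaplan–Meier with log-rank tests and optimal
cutpoints). A synthetic-cohort generator with planted modules and trait
effects makes every stage verifiable offline.

## Package layout

| module | contents |
|---|---|
| `coexkit.synthetic` | cohort simulator: planted co-expression modules, zero-inflated RPKM, logistic relapse link, exponential survival with censoring, sex/age confounders |
| `coexkit.preprocessing` | zero-fraction gene filter, `log2(x + 0.05)` transform, iterative z.k outlier-sample removal, PCA QC |
| `coexkit.network` | bicor, signed soft-threshold adjacency, scale-free fit, TOM, average-linkage module detection, module eigengenes, kME, eigengene merging |
| `coexkit.trait_stats` | module–trait correlation (bicor/Pearson + Student p), ME dendrogram (Newick), sample clustering on ME profiles, variance partitioning |
| `coexkit.diffexp` | one-way ANOVA + Tukey HSD, Mann–Whitney rank-sum, hub-biomarker gate (p < 0.05, kME ≥ 0.7, |LFC| ≥ 0.5), volcano table |
| `coexkit.enrichment` | one-sided Fisher (hypergeometric) over-representation with BH adjustment and analytic z |
| `coexkit.preservation` | permutation Z_density / Z_connectivity / Z_summary and medianRank across cohorts |
| `coexkit.prognostics` | nonparametric AUC with Hanley–McNeil z-test, prognostic-ratio combinations at fixed relapse horizons (456/548/1095/1826 days), KM curves, log-rank + Pike HR, optimal cutpoints |
| `coexkit.pipeline`, `coexkit.cli` | end-to-end orchestration, reproducibility manifest, `coexkit` console entry point |

## CLI

Every stage is a subcommand of `coexkit`:

```bash
coexkit simulate --config cohort.json --out data/ --seed 7
coexkit preprocess --expr data/expression.tsv --max-zero-frac 0.5 \
    --offset 0.05 --zk-threshold 3 --out clean/
coexkit network --expr clean/cleaned.tsv --beta 5.5 --min-module-size 30 \
    --merge-height 0.25 --out net/
coexkit traits --me net/eigengenes.tsv --traits data/traits.tsv --out traits/
coexkit enrich --query genes.txt --gmt sets.gmt --background universe.txt --out enr/
coexkit preserve --ref clean/cleaned.tsv --test other_cleaned.tsv \
    --assignment net/modules.tsv --n-perm 100 --seed 7 --out pres/
coexkit prognose --expr clean/cleaned.tsv --traits data/traits.tsv \
    --genes markers.txt --out prog/
coexkit pipeline --config pipeline.json   # full run with manifest
```

`pipeline.json` minimal example:

```json
{
  "expr": "data/expression.tsv",
  "traits": "data/traits.tsv",
  "outdir": "run/",
  "seed": 7,
  "network": {"beta": 5.5, "min_module_size": 30}
}
```

Inputs are plain TSV (gene × sample expression with a `gene_id` first column;
sample × trait table) and standard GMT gene-set files. All stage outputs are
TSV/JSON/Newick; the manifest records per-stage output checksums so identical
config + seed reproduces identical files.

## Notes on conventions

- **Zero filter** removes a gene when its exact-zero fraction is ≥ the
  threshold (inclusive at 0.5).
- **Module labels** are 1..M by decreasing size (0 = unassigned), with the
  conventional color aliases (1 = turquoise, 2 = blue, …).
- **Module detection** uses a deterministic static cut of the average-linkage
  tree on 1 − TOM at a configurable fraction of the maximum merge height
  (default 0.95), minimum module size 30, optional kME ≥ 0.7 reassignment of
  unassigned genes, then eigengene merging at dissimilarity 0.25.
- **Prognostic ratio** defaults to the difference of set means of z-scored
  expression (robust); a literal ratio mode is available behind a flag and
  warns near zero denominators.
- Bulk differential expression computes the Tukey p for the focal pair
  (stage-A relapse vs stage-A no-relapse) only; `anova_tukey` returns every
  pair when called directly.

## Tests and acceptance

```bash
python -m pytest -q tests/            # unit + property + acceptance suites
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

`tests/test_acceptance.py` holds the acceptance criteria (oracle equivalence
of the core statistics, planted-module recovery, trait-inference recovery,
preservation calibration, statistical calibration, filter-rule boundary
fidelity). `scripts/acceptance.py` runs an end-to-end pipeline smoke check
and writes the (empty) numeric-target report; no numeric reference values are
bundled because results of this kind of analysis depend on controlled-access
patient cohorts.
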