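# metabiomark

Cross-study discovery and validation of stool-metagenome biomarkers of
melanoma immunotherapy response, built on compositional data analysis.

The package re-implements, as a tested pipeline, a cross-cohort biomarker
workflow over species- and gene-group-level metagenome profiles:

* **Differential ranking** — per-dataset multinomial regression of
  compositional counts against the responder/nonresponder label
  (per-feature intercept + binary covariate, softmax link, L2 penalty);
  the mean-centered response coefficients ("differentials") are ranked and
  the top-k per direction become association calls.
* **Cross-study consolidation** — plain set logic: a feature is kept when
  called in the same direction in ≥2 datasets and never called in the
  opposite direction; validation then requires its differential to stay
  ≥0.1 in every validation dataset; denominator features for log-ratio
  assessment are those with differentials < −0.5.
* **Log-ratio and permutation statistics** — per-sample log-ratios with
  drop-and-count zero handling, Wilcoxon rank-sum (exact or normal),
  Benjamini-Hochberg, Aitchison and Bray-Curtis distances, PERMANOVA
  (free permutations with the +1 correction, or exhaustive enumeration).
* **FMT colonization analysis** — profile-level donor-derived species
  detection (a documented proxy for read-level origin attribution),
  donor-vs-response variance decomposition, and differential ranking of
  donor-derived profiles.
* **Function-taxon linking** — ranking species by linked biomarker gene
  groups, coverage of taxon combinations, phylum contrasts and a
  phylum-aggregated edge-list export.
* **Synthetic data** — a multi-study case-control generator with planted
  log-fold effects, study bias and overdispersion, plus FMT cohorts with
  response-modulated engraftment, all with recorded ground truth so every
  pipeline stage is verifiable without any downloads.

Everything is plain-text TSV/JSON/YAML: feature tables are
features-as-rows (a MetaPhlAn-style merged-table dialect is supported),
metadata carries study/response/subject/role/timepoint/donor columns, and
the taxon-gene link table is a two-column TSV.

## CLI

```sh
# generate a synthetic multi-study bundle with planted truth
metabiomark simulate --seed 1 --out demo/

# run discovery + FMT + consolidation + validation end to end
metabiomark run-all --config demo/config.yaml

# or drive the stages individually
metabiomark rank --table demo/table_disc1.tsv --metadata demo/metadata_disc1.tsv --out out/
metabiomark consolidate out/calls_*.tsv --out out/ledger.tsv
metabiomark validate --ledger out/ledger.tsv out/differentials_valid*.tsv --out out/final.tsv
metabiomark link --links demo/links.tsv --biomarkers biomarkers.txt --out out/
```

Every verb accepts `--seed`; all randomness flows from one integer seed
through a deterministic splitting scheme, and reruns are byte-identical.

## Layout

```
src/metabiomark/
  data_model.py        feature tables, metadata, prevalence, TSV IO
  synthetic_data.py    generators with planted truth
  ranking.py           multinomial differential ranking + top-k calls
  coda_stats.py        log-ratios, Wilcoxon, BH, distances, PERMANOVA
  consistency.py       consolidation/validation rule system
  fmt_colonization.py  donor-derived species analysis
  function_linking.py  taxon-gene-group coverage and contrasts
  pipeline.py, cli.py  orchestration and command line
  reference.py, data/  bundled published cohort tables
```
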