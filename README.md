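# senemeth

Analysis toolkit for beta-value methylation arrays in a long-term-culture /
donor-aging study design: per-CpG differential methylation calling,
cross-contrast concordance statistics, hypergeometric gene-set and
cytogenetic-band enrichment, methylation–expression integration, and an
array-vs-pyrosequencing consistency check — together with a synthetic
data generator that reproduces the statistical structure of such a study
(16 samples: 8 donors × early/late passage, donors split young/elderly)
with full ground truth for calibration and recovery testing.

## Pipeline

Stages hand off through plain TSV/JSON files, so any stage can be re-run
standalone from the previous stage's outputs and measured data can enter
at the preprocess stage.

```sh
# everything in one go, on simulated data
senemeth run --seed 1 --outdir out/

# or stage by stage
senemeth simulate  --seed 1 --outdir out/
senemeth preprocess --beta out/fixtures/beta.tsv --out out/norm.tsv
senemeth diffmeth  --beta out/norm.tsv --design out/fixtures/design.tsv \
                   --contrast culture --out out/culture.tsv
senemeth diffmeth  --beta out/norm.tsv --design out/fixtures/design.tsv \
                   --contrast aging --out out/aging.tsv
senemeth concord   --culture out/culture.tsv --aging out/aging.tsv \
                   --out-prefix out/conc
senemeth enrich    --result out/culture.tsv \
                   --annotation out/fixtures/annotation.tsv \
                   --sets out/fixtures/gene_sets.gmt --direction hyper \
                   --out out/enrichment.tsv
senemeth integrate --beta out/norm.tsv --design out/fixtures/design.tsv \
                   --annotation out/fixtures/annotation.tsv \
                   --expression out/fixtures/expression.tsv \
                   --out-prefix out/int
senemeth pyrocheck --beta out/norm.tsv --design out/fixtures/design.tsv \
                   --pyro out/fixtures/pyro.csv --out out/platforms.tsv
```

`senemeth run` accepts a TOML or YAML config (`--config`) with sections
`simulation` *or* `inputs`, plus `thresholds` (delta 0.20, shared delta
0.15, p 0.01, detection, present-call fraction, beta bins) and `options`
(paired t-test, chi-square continuity correction, skip normalization).
Unknown keys and out-of-range thresholds are rejected with the offending
key path. Exit codes: 0 success, 1 data error, 2 config error.

Default analysis conventions: unpaired pooled-variance Student's t
(paired mode available for the same-donor early/late design),
Benjamini–Hochberg q-values always reported, strict `>` at the delta
thresholds, chi-square on the sign 2×2 table without continuity
correction, hypergeometric upper tail over the universe of genes with at
least one analyzed CpG.

## Layout

```
src/senemeth/
  io_formats.py      TSV/GMT/GEO-series-matrix/pyro-CSV readers & writers,
                     core data model (BetaMatrix, StudyDesign, ...)
  synthetic_data.py  seeded study generator with ground-truth table
  preprocess.py      beta from channel intensities, detection filter,
                     quantile normalization
  diffmeth.py        contrast statistics, DM labels, hierarchical clustering
  concordance.py     cross-contrast deltas: r, sign chi-square, subgroups
  enrichment.py      hypergeometric over-representation, band sets
  integration.py     expression linkage, platform comparison
  geo_study.py       deposited-dataset reproduction recipe
  pipeline.py, cli.py
tests/               unit, property and acceptance suites
scripts/acceptance.py
```
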