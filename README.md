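# scarray

Single-cell two-color microarray concordance pipeline: does a single-cell
expression profile recapitulate pooled-cell profiles?

`scarray` implements the full analysis chain for two-color (sample/reference)
array experiments on 1-, 5- and 10-cell inputs:

* **array_io** — TSV readers/writers for probe × sample two-channel signal
  matrices, sample metadata, GMT gene sets, and a converter from
  per-channel matrix layouts.
* **synthetic_data** — a generative model of low-input amplification
  experiments (Poisson transcript counts, binomial capture dropout,
  nonspecific background floor, day batch shifts, lognormal noise, shared
  reference channel) with exact ground truth, plus triplicate qPCR plates
  and electropherogram traces.
* **qc** — Dixon's Q outlier test with Monte-Carlo critical values (any
  `n`, any alpha), multi-criteria sample scans (yield, labeling efficiency,
  housekeeping Cq, log2-signal distribution summaries), Abs260/280 purity
  check, and 50%-cumulative-area fragment sizing for electropherograms.
* **preprocess** — day-effect correction, normal+exponential background
  correction (offset 50), within-array loess normalization of M on A, and
  between-array quantile normalization within each cell-count group.
* **concordance** — mean-signal detection calls (threshold 300),
  sensitivity/specificity with Beta-posterior credible intervals (uniform
  prior), M-ratio Pearson/Spearman correlations, seeded random-pair
  difference-of-M-ratio correlation, pairwise-correlation outlier scans,
  top-variable-gene hierarchical clustering with Newick export, and
  rank-percentile tables.
* **gsea** — weighted-KS enrichment on mean-centered log2 profiles with
  gene-permutation NES/p/FDR-q and cross-group NES correlation.
* **qpcr** — triplicate Cq aggregation, ΔCq vs RPL13A, 2^(−ΔCq) relative
  expression, detection-count tables, housekeeping-based failure flags.
* **pipeline / cli** — end-to-end orchestration with one config, one seed,
  deterministic per-stage seed fan-out, and reports stamped with the config
  hash.

## Test

```sh
python -m pytest tests/
```

`tests/test_acceptance.py` holds one test per acceptance criterion
(quantile-normalization exactness, truth recovery, Beta-CI closed forms,
Dixon calibration, GSEA oracles, exhaustive pair statistics, day-effect
recovery, patient clustering, full-run determinism).

## CLI

```sh
scarray simulate --n-probes 2000 --seed 1 --out runs/sim
scarray qc runs/sim/signals.tsv runs/sim/samples.tsv --out runs/qc.tsv
scarray normalize runs/sim/signals.tsv runs/sim/samples.tsv --out runs/norm
scarray detect runs/sim/signals.tsv runs/sim/samples.tsv --out runs/det
scarray concord runs/sim/signals.tsv runs/sim/samples.tsv \
    --gold 10 --test 1 --out runs/concordance.json
scarray run config.yaml --out runs/full
```

`config.yaml` mirrors `scarray.pipeline.RunConfig`; every analysis constant
(detection threshold 300, normexp offset 50, loess span 0.30, 10,000 random
pairs, top 1,000 variable genes, 46 qPCR cycles) is a config field with
those defaults.

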