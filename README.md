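# plasmodebench

Plasmode-based benchmarking of negative-binomial differential-expression (DE)
inference for RNA-seq count data, with emphasis on low-count transcripts.

The package provides:

- **`synthetic`** — seeded generation of transcripts × samples NB count
  matrices with a heavy low-count tail (≥60 % of transcripts holding <10 % of
  reads), a mean-decreasing dispersion trend with transcript-level scatter,
  unequal library sizes, optional group-only (all-zero in one group)
  transcripts and known log2 fold changes.
- **`count_prep`** — abundance stratification into low/mid/high classes by
  total-count percentiles (ties join the class), and the two filtering rules:
  reads-present (RP) and counts-per-million (CPM).
- **`plasmode`** — exhaustive balanced repartitioning of one condition's
  samples into null plasmodes, effect-size harvesting from a DE result at a
  given FDR, and DE plasmodes spiked multiplicatively on the log2 scale
  (zeros stay zero; counts rounded half-away-from-zero).
- **`nb_core`** — NB GLM machinery: median-of-ratios size factors, NB
  log-likelihood with a stable Poisson limit, IRLS fitting with offsets and
  observation weights (scalar and vectorized), Wald and likelihood-ratio
  tests.
- **`de_engines`** — the two DE methods under comparison:
  - `shrink`: Cox–Reid genewise dispersions → Gamma-GLM 1/mean trend →
    empirical-Bayes MAP dispersions → ridge-style LFC shrinkage toward a
    zero-centered normal prior → Wald test (LRT available);
  - `robust` / `classic`: library-size offsets, conditional-likelihood
    common dispersion, tagwise dispersions moderated by a prior-DF weight on
    the shared likelihood (prior DF fixed at 4/10/50 or moment-matching
    estimated), Huber observation weights on Pearson residuals iterated with
    the fit (`classic` = no weights), LRT.
- **`metrics`** — Benjamini–Hochberg step-up adjustment and confusion-matrix
  performance (FPR/TPR/PPV/NPV/accuracy), overall and per abundance stratum.
- **`bench`** / CLI — the full experiment grid (engines × prior-DF × filters
  × plasmodes) with mean ± SEM aggregation, call-set overlap, filter-impact
  and MA-plot reports, and soft directional checks.

## Test

```sh
python -m pytest tests/
```

`tests/test_acceptance.py` holds the acceptance criteria, including a
~25-replicate false-positive-rate control study (a few minutes on one CPU).

## CLI

All formats are plain TSV; configs are YAML.

```sh
plasmodebench simulate --out-counts counts.tsv --out-groups groups.tsv --seed 1
plasmodebench classify --counts counts.tsv --groups groups.tsv --out classes.tsv
plasmodebench filter   --counts counts.tsv --groups groups.tsv --rule cpm --out mask.tsv
plasmodebench plasmode null  --counts one.tsv --groups onegrp.tsv --group X --out-dir nulls/
plasmodebench plasmode spike --counts nulls/null_0.counts.tsv --groups nulls/null_0.groups.tsv \
    --pool pool.tsv --out-dir spiked/ --pi 0.2 --reps 5 --seed 1
plasmodebench de --counts counts.tsv --groups groups.tsv --engine robust --prior-df auto --out res.tsv
plasmodebench evaluate --results res.tsv --truth truth.tsv --out perf.tsv
plasmodebench benchmark --out-dir bench/ --seed 1
plasmodebench report --metrics-long bench/metrics_long.tsv --out-dir report/
```

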