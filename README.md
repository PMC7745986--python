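# nanopam

Toolkit for NanoString nCounter count normalization and nearest-shrunken-centroid
(PAM) molecular subtyping, built around the basal/luminal two-class setting:

- **`nanopam.io`** — RCC raw files, probe × sample count tables, panel
  definitions (YAML/TSV) and sample metadata, with strict integer-count
  contracts.
- **`nanopam.normalization`** — per-sample negative-control background
  thresholding, housekeeping QC exclusion, geometric-mean scaling to 100, log
  transform and median centering. Every step uses only within-sample
  quantities, so classification is single-sample: a result never depends on
  which other samples were run alongside.
- **`nanopam.pam`** — de novo nearest-shrunken-centroid training and
  prediction with discriminant scores, posteriors, Pearson centroid
  correlations and a 0–1 basal score; JSON model serialization;
  cross-validated shrinkage selection.
- **`nanopam.stats`** — Monte Carlo cross-validation (random 2/3 train / 1/3
  test splits), exact/asymptotic McNemar concordance, replicate coefficient
  of variance, Pearson correlation, Fisher/chi-square enrichment tests, and
  UPGMA cluster ordering under a centered-correlation distance.
- **`nanopam.simulate`** — synthetic two-subtype cohorts with known truth:
  blocked expression shifts, lane scale factors, Poisson count noise,
  negative-control background, technical replicates, and a correlated paired
  pseudo-RNAseq layer for in-silico cross-platform label transfer.
- **`nanopam.panel`** — the bundled 47-gene basal/luminal signature panel
  with the four housekeeping genes (AMMECR1L, SRPRA, XRCC6, EIF2B4) used for
  scaling. Gene-node annotations are metadata only; supply your own panel
  file for a different codeset.

## Command line

```sh
nanopam simulate --seed 7 --out cohort/
nanopam normalize cohort/counts.tsv --panel cohort/panel.yaml --out norm/
nanopam train norm/normalized_log.tsv --labels cohort/truth.tsv --out model.json
nanopam classify sample.rcc --model model.json --panel cohort/panel.yaml --out calls/
nanopam crossvalidate norm/normalized_log.tsv --labels cohort/truth.tsv \
    --iterations 10000 --seed 0 --out cv/
nanopam validate --calls-a calls/calls.tsv --truth cohort/truth.tsv --out report/
```

`classify` accepts a count table, a set of single-sample RCC files, or (with
`--normalized`) a pre-normalized log-expression TSV; batch output equals the
concatenation of single-sample runs. Every command records the tool version,
seed and a parameter hash in a `run.json` sidecar.

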