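# mrmediate

Two-sample Mendelian randomization and two-step mediation analysis for
GWAS summary statistics, with a synthetic summary-statistics generator
so the whole pipeline can be exercised and validated at desk scale.

## What it does

- **`mrmediate.sumstats`** — read/write/validate GWAS summary-statistics
  tables (TSV/CSV) and harmonize exposure/outcome effect alleles
  (sign flips, strand complements, EAF-resolved palindromic SNPs).
- **`mrmediate.instruments`** — instrument selection: p-value
  thresholding, greedy LD clumping (r² < 0.001 in a 10,000 kb window by
  default), per-SNP variance explained, F-statistic screening
  (F = (N−2)·R²/(1−R²), screen at F > 10), and Steiger direction
  filtering.
- **`mrmediate.mr`** — Wald ratio, IVW (fixed / multiplicative
  random-effects), MR-Egger with pleiotropy intercept, weighted median,
  simple and weighted mode; Cochran's Q, leave-one-out, odds-ratio
  reporting.
- **`mrmediate.presso`** — MR-PRESSO global, outlier, and distortion
  tests (seeded parametric simulation).
- **`mrmediate.mediation`** — two-step mediation: indirect effect
  beta12 = beta1·beta2, direct = total − indirect, proportion mediated
  with first-order delta-method CIs and the standard suppression rules
  (no proportion when directions disagree; no proportion CI when the
  indirect-effect CI spans zero). Step-2 adjustment by instrument
  exclusion or multivariable MR.
- **`mrmediate.synthgwas`** — three-trait (exposure → mediator →
  outcome) summary-statistics simulator with known causal structure,
  optional horizontal pleiotropy, and block LD; sampling SEs follow
  1/sqrt(2·MAF·(1−MAF)·N).
- **`mrmediate.pipeline`** — multi-exposure screening with sensitivity
  gates, reverse MR, and report-data generation (volcano/forest/funnel/
  leave-one-out TSVs plus a YAML run manifest).

## Test

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria, including the
seeded statistical-calibration suites (IVW CI coverage, Egger-intercept
type-I error, weighted-median robustness, MR-PRESSO power, mediation
proportion recovery, Steiger direction accuracy); it takes about a
minute.

## CLI

```sh
# generate a synthetic study
mrmediate simulate --config sim.yaml --seed 1 --outdir study/

# five-estimator battery for one exposure/outcome pair
mrmediate mr --exposure study/exposure.tsv --outcome study/outcome.tsv \
    --seed 1 --out results.tsv

# multi-exposure screen / reverse MR / mediation scan / full report
mrmediate screen  --config screen.yaml --seed 1 --outdir out/
mrmediate reverse --config screen.yaml --seed 1 --outdir out/
mrmediate mediate --config mediation.yaml --seed 1 --outdir out/
mrmediate report  --config screen.yaml --seed 1 --outdir out/
```

A screen config YAML maps trait names to summary-statistics files:

```yaml
exposures:
  lipidX: study/exposure.tsv
outcome: study/outcome.tsv
outcome_trait: disease
ld: study/ld.tsv            # optional LD matrix for clumping
```

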