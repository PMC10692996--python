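# malines

Analysis toolkit for mutation-accumulation (MA) line experiments:
de novo SNP identification across replicate lines, callable-site
accounting, per-site per-generation mutation-rate estimation,
substitution-spectrum statistics with Monte-Carlo p-values, and a minimal
variant-effect predictor — exercised end-to-end on synthetic MA
experiments with known ground truth.

## What it does

- **`malines.simulate`** — forward-simulates an MA experiment: a founder
  genome, several age-at-reproduction regimes × replicate lines ×
  generations of single-pair transmission, per-line read evidence
  (negative-binomial depth, binomial heterozygous allele balance,
  uniform sequencing error), per-regime callable masks, a toy gene
  annotation and a line-survival table. Ground truth is recorded for
  every simulated mutation.
- **`malines.consensus`** — the consensus calling rule (a candidate is
  heterozygous in exactly one jointly genotyped line and
  homozygous-reference in all others, at callable sites) plus hard
  curation filters (depth, allele balance, cluster, multiallelic,
  other-line depth), each rejection tagged with one primary reason.
- **`malines.probabilistic`** — a simplified probabilistic caller:
  per site, the posterior that exactly one line carries a de novo
  heterozygote given all lines' read counts (binomial likelihoods,
  log-space). Candidate cohorts from the two callers can be merged as
  their intersection (`shared`, default) or `union`.
- **`malines.rates`** — mu = m/(L·n·T) in exact rational arithmetic,
  regime means ± SE, and likelihood-ratio regime contrasts from binomial
  and Poisson GLMs (the Poisson model uses a log(n·T) exposure offset —
  using callable sites as prior weights instead produces a degenerate
  statistic and is deliberately not reproduced).
- **`malines.spectrum`** — the six strand-collapsed substitution classes,
  transition/transversion pools, and chi-squared tests (goodness of fit
  and contingency) with seeded Monte-Carlo simulated p-values
  (B = 10,000 by default).
- **`malines.effects`** — a minimal effect predictor over a toy GFF3
  annotation (splice donor, stop gained, missense, synonymous, intron,
  up/downstream within a W bp window, intergenic; one most-severe
  consequence per variant) with the fixed consequence → impact mapping
  (HIGH/MODERATE/LOW/MODIFIER) and per-category goodness-of-fit
  comparisons across regimes.
- **`malines.io_formats`** — VCF (GT/AD/DP), BED, FASTA, GFF3 and TSV
  readers/writers; in-memory coordinates are 1-based inclusive
  everywhere, BED is converted at the boundary; only biallelic SNPs enter
  the pipeline.
- **`malines.pipeline` / `malines.cli`** — seeded end-to-end
  orchestration and a `ref-check` mode that re-runs the entire statistics
  layer on published count tables (bundled under `malines/data/`) without
  any sequence data.

## CLI

```sh
malines simulate  --config sim.yaml --out out/            # synthetic experiment
malines run       --config sim.yaml --out out/            # simulate→call→stats
malines call      --vcf calls.vcf --bed callable.bed --out cand.tsv
malines rates     --counts counts.tsv --out rates.tsv
malines spectrum  --mutations muts.tsv --out spectrum.json
malines effects   --mutations muts.tsv --gff genes.gff3 --fasta ref.fa --out effects.tsv
malines ref-check --out check.json                        # stats on bundled counts
```

`sim.yaml` holds the `SimulationConfig` fields (`seed` is mandatory), e.g.

```yaml
seed: 1
genome_length: 1000000
n_regimes: 3
lines_per_regime: 6
generations: 3
mu_per_regime: [0.74e-8, 0.30e-8, 1.20e-8]
mean_depth_per_regime: [68.5, 76.6, 52.9]
callable_fraction_target: 0.74
extinction_prob_per_regime: [0.02, 0.05, 0.3]
```

Caller/merge behaviour: `--caller consensus|probabilistic|both` and
`--merge shared|union`; filter thresholds are exposed as flags on
`call`/`run`.

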