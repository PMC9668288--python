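# rvburden

A rare-variant gene-level collapsing association toolkit with a synthetic
exome-cohort generator, so the whole method can be exercised and validated
at desk scale.

What it does:

- **Synthetic cohorts** (`rvburden.simulate`): ancestry strata, rare
  autosomal and X-linked variants at target carrier frequencies
  (Hardy–Weinberg within ancestry; hemizygous X males), per-call
  sequencing metrics, binary phenotypes from a logistic model with the
  intercept solved to hit a configured prevalence, quantitative traits
  with effects in SD units, and a common risk haplotype whose carriers
  modify gene effects through a log-odds interaction. Phase is retained
  internally, so compound-het and LD truth are exact, and every
  generative parameter lands in a truth table.
- **Quality control** (`rvburden.qc`): per-genotype (depth, GQ, het
  alt-read fraction, exact binomial alt-proportion test, homozygous
  alt-fraction rule) and per-site (strand bias, mapping quality, QUAL,
  rank sums, caller status, external-reference coverage/z/pass-fraction,
  missingness, fail fraction) filters, with separate `collapsing` and
  `exwas` profiles. Failing genotypes are set to missing, not dropped.
- **Qualifying-variant models** (`rvburden.qvmodels`): SnpEff-style
  consequence classes and a registry of 11 collapsing models (9 dominant
  nonsynonymous, 1 recessive, 1 synonymous negative control), all
  config-overridable; the registry used is echoed into results headers.
- **Collapsing burden tests** (`rvburden.collapsing`): dominant and
  recessive carrier matrices (homozygous, hemizygous X-male, phase-blind
  putative compound het), seeded sex-matching of controls, Fisher's exact
  two-sided test with Haldane–Anscombe-corrected Woolf CIs, rank-based
  inverse-normal transformation (Blom), and covariate-adjusted linear
  models for quantitative traits.
- **ExWAS** (`rvburden.exwas`): variant-level allelic / dominant /
  recessive / genotypic tests with the ≥6-carrier rule.
- **Meta-analysis** (`rvburden.meta`): Cochran–Mantel–Haenszel 2×2×N
  combination with Robins–Breslow–Greenland CIs, a χ²(1) heterogeneity
  test for effect modification, genomic-inflation λ, pooled pan-ancestry
  regression with ancestry dummies + principal components, QQ data.
- **Follow-up** (`rvburden.followup`): joint conditional regressions with
  separation flagging, leave-variants-out collapsing, risk-haplotype
  stratification with heterogeneity, and pairwise LD (closed form from
  phased haplotypes, EM from unphased genotypes).
- **Pipeline** (`rvburden.pipeline`): simulate-or-load → qc → qv →
  collapse (→ exwas) with a checksummed run manifest; reruns are
  byte-identical given the same config and seed.

## Command line

```sh
rvburden simulate --config sim.yaml --seed 1 --out-prefix out/cohort
rvburden qc --vcf out/cohort.vcf --annotations out/cohort.annotations.tsv \
            --phenotypes out/cohort.phenotypes.tsv --profile collapsing \
            --out-prefix out/qc
rvburden run --config pipeline.yaml --out-dir out/run
rvburden meta --input EUR=eur/collapsing.tsv --input AFR=afr/collapsing.tsv \
              --out meta.tsv
rvburden followup ld --vcf out/cohort.vcf --var1 17-7041768-G-T --var2 17-7042164-C-T
```

A pipeline config is YAML with keys `seed`, either a `simulate` block
(fields of `rvburden.simulate.SimulationConfig`: `n_samples` per
ancestry, `genes` with per-gene `carrier_freq` / `zygosity` / `log_or` /
`beta`, `haplotypes` with `interactions`, phenotype blocks) or an
`inputs` block (`vcf`, `annotations`, `phenotypes` paths), plus
`qc_profile` (`collapsing` | `exwas`), optional `models` (subset of the
registry, or `models_config` for a custom registry YAML) and
`phenotypes` (name, kind, covariates, `sex_match`,
`medication_indicator`). `tests/test_pipeline.py::_toy_config` is a
complete working example.

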