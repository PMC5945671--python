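# scarsig

Analysis toolkit for multiregion tumor/normal whole-exome data:

- **catalogue** — turns somatic SNV/indel calls into 96-channel trinucleotide
  mutational catalogues (strand-bias filtering, functional filtering,
  target-capture triplet correction) and counts 2–10 bp indels.
- **signatures** — supervised decomposition of catalogues into a predefined
  signature matrix by two-pass non-negative least squares with
  signature-specific relative-exposure cutoffs, plus ROC-based cutoff
  calibration (Youden's J).
- **cna_purity** — tumor-cell-content and ploidy estimation by a 2-D grid
  search over a coverage-ratio/BAF mixture model, with allele-specific copy
  numbers, decrease-of-heterozygosity, exclusion rules and an independent
  purity estimate from the somatic mutant-allele-fraction mode.
- **genome_scars** — copy-number profile smoothing and the HRD-LOH
  (>15 Mb LOH segments shorter than a chromosome) and LST (>10 Mb
  non-whole-arm state switches) genomic-scar scores.
- **heterogeneity** — gene-level mutation sharing between primary-tumor and
  thrombus compartments, and the Wilcoxon rank-sum association between
  signature exposure and small-indel burden.
- **synthetic_data** — simulators for every input (multinomial catalogues,
  segmented genomes with binomial allele reads and lognormal coverage noise,
  multiregion cohorts with planted sharing fractions), all deterministic
  given a seed.

A 30-column signature fixture matrix and a GRCh37 chromosome-arm map ship
with the package (`src/scarsig/data/`). The fixture matrix is synthetic
(generated by `scripts/make_signature_fixture.py`), not the published
signature catalog; substitute a real signature TSV via `--signatures`
for production use.

## Command-line interface

All functionality is exposed through one umbrella command:

```sh
scarsig --seed 7 simulate cohort --out sim/          # synthetic inputs + truth.json
scarsig catalogue --vcf tumor.vcf --out cat.tsv --indels-out indels.tsv
scarsig signatures --catalogue cat.tsv --out exposures.tsv --min-snvs 25
scarsig purity --segments segs.tsv --snps snps.tsv --out fits.tsv
scarsig scars --profile cn.tsv --out scores.tsv      # packaged GRCh37 arms
scarsig heterogeneity --variants vars.tsv --samples sheet.tsv --out sharing.tsv
scarsig assoc --indels indels.tsv --exposures ac3.tsv --out assoc.tsv
```

Subcommands log to stderr, write results only to files, and exit nonzero on
error. `--config config.yaml` presets options; explicit flags win.
Manual-rescue overrides for difficult samples are available on `purity`
(`--force-tcc`, `--force-ploidy`, `--reclassify-balanced`) and `scars`
(`--single-copy-mode` for profiles without allele-specific copy numbers).

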