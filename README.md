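# eocrc

Reusable, tested building blocks for germline variant prioritization and
replication statistics in early-onset colorectal cancer (CRC) exome
studies.

Early-onset CRC cohorts (diagnosis at or before 50, mismatch-repair
proficient, no known Mendelian cause) are analysed by calling germline
variants with two independent algorithms, funnelling the calls through a
prioritization cascade, and following up candidate genes by pooled-DNA
resequencing and external cohorts. This package implements that whole
analysis path as a library plus a small CLI, for analysts who consume
caller output (VCF or ANNOVAR-style annotation tables) rather than raw
reads:

* **Prioritization cascade** (`eocrc.prioritization`) — per-caller QC
  (depth ≥ 30×, ≥ 4 alternate reads, ≥ 20 % alternate fraction,
  quality ≥ 30, strand-bias test), dual-caller concordance requiring the
  same patient and genotype, removal of synonymous/unknown classes,
  restriction to exonic and splicing variants, population rarity
  (gnomAD-style MAF ≤ 0.1 % heterozygous / ≤ 1 % homozygous), high
  functional impact (truncating, canonical splice site ± 2, or missense
  with PolyPhen-2 ∈ {D, P} ∧ CADD ≥ 15 ∧ DANN ≥ 0.995, and/or
  GERP++ ≥ 2), and subtraction of control-cohort and artifact sites.
  Every stage count is recorded in a `FilterTrace` and every dropped
  record is attributable to exactly one stage.
* **Pooled resequencing** (`eocrc.pooled_seq`) — for a DNA pool of *n*
  samples with high-quality alternate-read fraction *f*, the estimated
  number of mutated alleles is **ENMA = f · 2n**. Detection requires
  ENMA ≥ 0.65, alternate reads on both strands, a one-sided binomial
  test against the background error rate at p < 10⁻⁶, and population
  MAF < 1 %; detected calls then pass through the same prioritization
  rules as discovery.
* **Cohort statistics** (`eocrc.cohort_stats`) — per-patient burden
  (heterozygous = 1 allele, homozygous = 2), burden-vs-age-at-diagnosis
  trend (OLS slope *t*-test by default; Spearman/Pearson available),
  exact 2×2 carrier burden tests (two-sided by the point-probability
  rule), one-sided pathway over-representation against a configurable
  background universe, and candidate-gene evidence scoring over boolean
  relevance criteria.
* **Mutational signatures** (`eocrc.signatures`) — standard 96-channel
  pyrimidine-centric substitution profiles and refitting against a fixed
  catalog (COSMIC-v2-style columns) by nonnegative least squares,
  `min‖Mw − p‖₂ s.t. w ≥ 0`, with exposures renormalized to sum to 1.
* **Synthetic data** (`eocrc.synthetic`) — generators for every input
  above with full ground-truth bookkeeping: an age-dependent Poisson
  burden model λ(age) = a + b · (50 − age), planted background variants
  that each fail exactly one cascade stage, two callers with
  configurable discordance, binomially sampled pool pileups, and
  Poisson-noise signature mixtures. The published candidate-gene tables
  ship as machine-readable fixtures (`eocrc.tables`).

## Worked example

```python
from eocrc.pipeline import load_config, run_discovery

config = load_config({"seed": 7, "simulate": {}})   # default study conditions
report = run_discovery(config, out_dir="demo_run")
print(report.to_markdown())
```

prints (abridged):

```
| stage | surviving |
| --- | --- |
| unique | 1073 |
| concordant | 1015 |
| non_synonymous | 842 |
| exonic_splicing | 668 |
| rare | 515 |
| high_impact | 331 |
| after_control_subtraction | 258 |

- patients: 20
- median qualifying variants per patient: 12.0
- median qualifying alleles per patient: 16.0

- age trend (n_variants): linear_regression, slope -0.3927, p = 0.0122 (n = 20)
- age trend (n_alleles): linear_regression, slope -0.4782, p = 0.01126 (n = 20)
```

Reading the output: of 1,073 unique (variant, patient) calls passing
per-caller QC, 1,015 were made by both callers with the same genotype;
the functional, rarity, impact and control-subtraction stages then cut
the set to 258 prioritized variants. The per-patient burden of those
variants falls by ~0.39 variants per year of age at diagnosis (OLS,
p = 0.012): in this simulated cohort, as in the study design it
emulates, younger patients carry more rare high-impact variants. The
run directory contains the same numbers as TSV tables, a VCF of the
prioritized variants, and `report.md`.

The CLI exposes the same operations:

```
eocrc simulate --seed 7 --out sim/           # synthetic two-caller cohort
eocrc discovery --config run.yaml            # cascade + burden + trends
eocrc replication --config repl.yaml         # pool detection + prioritization
eocrc poolseq detect pileups.tsv             # ENMA-based pool calls
eocrc signatures fit --catalog cat.tsv --profile prof.tsv
eocrc fixtures --out fixtures/               # packaged study tables
```

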