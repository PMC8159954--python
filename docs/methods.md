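# Methods

This note documents the models, rules and numerical choices behind the
package, and what the synthetic-data generator does and does not
emulate.

## The prioritization cascade

The cascade operates on `AnnotatedVariant` records — one called variant
in one patient, with caller QC metrics and functional/frequency/
predictor annotations — and applies seven stages in a fixed order. The
stage counts form a `FilterTrace`; counts are non-increasing from the
concordance stage onward, and the union of per-stage drop lists plus the
survivors reconstructs the input exactly (both properties are asserted
in tests).

1. **Per-caller QC** (before the trace proper): depth ≥ 30, alternate
   reads ≥ 4, alternate fraction ≥ 0.20, caller quality ≥ 30, and a
   strand-bias gate. The two calling algorithms this pipeline was built
   around document opposite inequalities for their strand-bias filters;
   since removing *unbiased* calls is self-defeating, the default for
   every caller removes calls whose strand-bias test indicates bias
   (p < 0.05), with a per-caller override (`strand_bias_direction`)
   for pipelines that genuinely publish the opposite convention. A call
   missing a required metric fails QC with reason `missing_metric`, and
   all failing rules are reported, not just the first.
2. **Unique**: the number of distinct (variant, patient) pairs across
   both QC-passing call sets.
3. **Concordance**: a call survives only if the other caller made it in
   the same patient with the same genotype. Annotations are taken from
   the first call set; they are assumed identical per variant, checked,
   and a mismatch warns rather than aborts. Conflicting duplicate
   genotypes within one call set are a hard data error.
4. **Functional class**: synonymous and unknown exonic classes are
   removed first, then regions are restricted to exonic and splicing —
   in that order, so both trace counts are defined.
5. **Rarity**: reference-population MAF ≤ 0.001 for heterozygous and
   ≤ 0.01 for homozygous calls. A missing frequency means the variant
   was not observed in the reference population, which is the strongest
   form of rarity, so NA passes. Frequencies are never imputed as 0.
6. **Impact**: stopgain or frameshift always qualify; splicing variants
   qualify within ±2 bases of the exon boundary (the canonical splice
   window, taken from the supplied transcript annotation — gene models
   are not recomputed); missense SNVs qualify if the three in-silico
   predictors agree (PolyPhen-2 D/P *and* CADD ≥ 15 *and* DANN ≥ 0.995)
   and/or the site is conserved (GERP++ ≥ 2). The "and/or" is resolved
   as OR by default and is configurable to AND. A missing predictor
   value counts as non-damaging, so NA can only make the filter
   stricter.
7. **Control subtraction**: any variant seen in the control cohort or on
   the recurrent-artifact blacklist is removed regardless of genotype.

Coordinates are 1-based and closed, matching VCF. Multi-allelic inputs
are split one record per alternate allele, and allele pairs are
parsimony-trimmed (shared suffix, then shared prefix) so equivalent
indel representations compare equal without a reference genome. Ploidy
is fixed at 2; hemizygous calls are treated as homozygous-alternate.

## Pooled-amplicon detection and ENMA

A pool of *n* samples carries 2*n* alleles, so with *k* heterozygous
carriers the expected alternate-read fraction is *k*/(2*n*) and the
estimated number of mutated alleles is **ENMA = f̂ · 2n**, where f̂ is
the fraction of base-quality-filtered (Q30) reads supporting the
alternate allele. The estimator is deterministic, linear in both f̂ and
*n*, and unbiased under binomial read sampling without sequencing error.

Detecting one allele among up to 192 against a Q30-scale error floor
needs more than the point estimate, so a pool call is reported only if
all of the following hold (each gate configurable):

* ENMA ≥ 0.65 — below two thirds of one allele is indistinguishable
  from noise at the depths involved;
* alternate reads on both strands;
* a one-sided binomial test of the alternate count against the
  background error rate (default 0.001) rejects at p < 10⁻⁶;
* annotated population MAF < 0.01 (common polymorphisms are not
  replication targets).

At the study's operating point (pools of 48, depth 10,000, error
0.001), these gates give sensitivity ≈ 1 for a single carrier and no
detections across 10,000 error-only positions (both recomputed by the
acceptance script). Carrier identity within a pool is not recoverable;
downstream genotyping is out of scope. Detected calls are then filtered
by the same functional/rarity/impact rules as discovery, with the
heterozygous rarity bound (pool calls are heterozygous by construction).

## Burden and age-trend statistics

Per-patient burden counts qualifying variants and alleles (het = 1,
hom = 2); patients without qualifying variants are kept with zeros so
totals are conserved. The burden-age association defaults to the OLS
slope of burden on age at diagnosis with a two-sided *t*-test, matching
a scatter-plus-trend presentation; Spearman and Pearson correlations
are selectable because the underlying study literature rarely names the
test. Zero variance in either variable raises a degenerate-input error
rather than returning a meaningless p-value; the pipeline records such
runs as "not testable".

With burden counts of order 15 the Poisson discreteness is mild and the
*t*-test holds its nominal level: across 10,000 null simulations
(n = 20 patients) the type-I error is within 0.05 ± 0.01, and a planted
effect of b = 0.5 extra variants per year below 50 is recovered with
correct sign at p < 0.05 in well over 80 % of 1,000 replicates (both
recomputed by the acceptance script and the test suite).

Gene-level case-control comparisons use the exact conditional
hypergeometric test on the 2×2 carrier table. The two-sided p-value
follows the point-probability (minimum-likelihood) rule; the odds ratio
reported is the unconditional cross-product ratio, with ∞ on a single
zero cell and NaN for 0/0. Pathway over-representation uses the
one-sided (greater) exact test over a background universe defaulting to
19,000 protein-coding genes (a config parameter — the right universe
depends on the capture design). No multiple-testing correction is
applied by default, mirroring the nominal-significance convention of
candidate-gene studies; Benjamini-Hochberg is available via
`correction="bh"`. Both tests are verified against an exact-integer
enumeration of the hypergeometric support on every 2×2 table with total
n ≤ 30.

Candidate genes are ranked by the number of satisfied boolean relevance
criteria (early-onset literature, cancer-pathway membership, expression
in healthy colonic mucosa, a carrier under 40, a loss-of-function
variant); literature and expression flags are externally curated inputs
consumed as booleans, never computed. Ties break alphabetically so the
ranking is stable.

## Signature refitting

Profiles use the standard 96-channel order: six pyrimidine-centric
substitution types × 16 flanking contexts, contexts alphabetical within
each type. Purine-reference substitutions are reverse-complemented into
the pyrimidine channel; the mapping is the identity on already-
pyrimidine input. Refitting solves nonnegative least squares against a
fixed catalog and renormalizes the weights to sum to 1 — de-novo
extraction (NMF) is deliberately out of scope, since single tumours are
refit against a published dictionary. Catalog files are rejected unless
their channel labels match the standard order exactly, which catches
silently permuted catalogs. Exposures are ranked descending with
alphabetical tie-breaks, and weights below 0.01 are flagged marginal.

For linearly independent catalog columns the noiseless solution is
unique: mixtures are recovered to ≤ 10⁻⁶ max-abs weight error with
reconstruction cosine ≥ 1 − 10⁻⁹. Under Poisson counting noise at 500
mutations, a 0.6-weight dominant signature is identified in ≥ 95 % of
replicates on the packaged ten-signature synthetic catalog. No
published catalog is shipped: the synthetic catalog (symmetric
Dirichlet(0.3) columns) is a stand-in dictionary for testing the
machinery, and any real catalog in the same TSV layout can be supplied.

## The synthetic cohort generator

The generator emulates the structure of a dual-caller early-onset exome
study, not its content:

* ages uniform on 25-50; qualifying variants per patient drawn
  Poisson(a + b·(50 − age)) with defaults a = 8.75, b = 0.5, chosen so
  the mean planted load is ~15 qualifying variants per patient — the
  scale reported for such cohorts — with a clearly negative age trend;
* background variants per patient (default 40) split between labels
  that each fail exactly one cascade stage: synonymous/unknown class,
  non-exonic region, common (MAF 2-20 %), benign missense drawn just
  outside the predictor cutoffs (e.g. CADD up to 14.9 against the
  cutoff of 15, exercising boundary behavior), artifact-blacklisted and
  control-shared sites (planted both in a case and in the respective
  key set);
* a second caller that drops or genotype-flips each record with the
  configured discordance probability (default 5 %).

The planted per-stage survivor counts are derived purely from this
label bookkeeping — never by running the cascade — so they are an
independent oracle for the `FilterTrace`. Ground-truth labels tie to
the *default* thresholds; a run with non-default thresholds is still
valid but its trace is no longer predicted by the labels.

What the generator does not emulate, and therefore what passing tests
do not establish about real data: linkage and recurrence structure
(every simulated variant is private to one patient), annotation errors
and caller-specific systematic biases (annotations are noise-free, so
cascade recall of planted variants is exactly 1), indel representation
divergence between callers, and realistic gene-level clustering. The
pool simulator draws alternate reads Binomial(depth, p) with
p = f(1 − e) + (1 − f)·e/3 (carrier alleles can miscall away, errors
miscall toward the variant a third of the time); it does not model
strand-specific error, PCR jackpotting or amplicon-edge effects, which
inflate real-world false-positive floors. ENMA calibration checks run
at e = 0, where the binomial expectation is exactly the carrier count;
with e > 0 the raw estimator carries a known upward bias of about
2n(1 − f)e/3 (≈ 0.03 alleles at the defaults), far below the 0.65
detection gate.

All sampling flows from `numpy.random.default_rng(seed)`; a fixed seed
reproduces byte-identical outputs, and end-to-end reruns with the same
configuration produce byte-identical report bodies (no timestamps are
written).

## Configuration and defaults

Run configuration is YAML with full threshold defaults matching the
values above; unknown keys are rejected at load time, and any deviation
from the default thresholds is logged at WARN. The discovery cohort
filter keeps patients diagnosed at or before 50 by default
(`max_age_discovery`). The packaged study tables (8 candidate genes
with evidence flags, 13 replication variants, 21 external-cohort
variants, and the 8/1006-vs-4/1609 independent case-control counts) are
data constants in `eocrc.tables`; positions and predictor scores for
the replication fixture are synthetic stand-ins consistent with each
variant's printed consequence class, since the published tables print
genes, protein changes and ages only.

## Known limitations

* The cascade consumes caller output; it cannot compensate for
  upstream calling or annotation errors, and annotation harmonization
  between callers is limited to parsimony allele trimming.
* The exact burden test conditions on both margins; for very sparse
  tables, mid-p or unconditional alternatives would be less
  conservative but are not implemented.
* The OLS age-trend test treats counts as continuous; a Poisson GLM
  would be the natural refinement for small counts.
* Signature refitting assumes the catalog spans the observed spectrum;
  exposures are not penalized for sparsity, so near-collinear catalog
  columns can trade weight.
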