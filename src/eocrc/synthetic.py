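"""Synthetic cohorts, pools and signature mixtures with known ground truth.

Every input the pipeline consumes can be generated here, with full
bookkeeping of what was planted, so that each stage of the analysis can
be tested against an independent oracle without any sequencing data:

* an exome cohort with an age-dependent per-patient load of qualifying
  variants (Poisson with rate ``a + b * (age_max - age)``, so younger
  patients carry more), a configurable mix of background variants that
  each fail exactly one cascade stage, two callers with a configurable
  discordance rate, planted control-cohort and recurrent-artifact sites;
* pooled-amplicon pileups with binomial read sampling at a stated
  sequencing-error rate;
* signature catalogs and Poisson-noise profile mixtures.

Background annotation values are drawn just outside the filter
thresholds (e.g. CADD up to 14.9 against a cutoff of 15) so boundary
behavior is exercised. All sampling flows from one seeded generator;
the same seed reproduces identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from eocrc.cohort_stats import CohortPatient
from eocrc.errors import ConfigurationError
from eocrc.pooled_seq import PoolCall, PoolPileup, compute_enma
from eocrc.prioritization import STAGE_ORDER, FilterTrace
from eocrc.signatures import MutationalProfile, SignatureCatalog
from eocrc.tables import CASE_CONTROL_COUNTS, TABLE1, TABLE2, TABLE3
from eocrc.variant_io import AnnotatedVariant, Annotation, VariantCall, VariantKey

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SimulatedCohort",
    "simulate_cohort",
    "PoolSimConfig",
    "PoolGroundTruth",
    "simulate_pools",
    "make_catalog",
    "sample_profile_from_mixture",
    "make_paper_fixtures",
    "table2_pool_calls",
    "LABELS",
]

#: labels partitioning every simulated variant by the cascade stage it is
#: planted to fail (qualifying variants fail none)
LABELS = (
    "qualifying",
    "synonymous",
    "intronic",
    "common",
    "low_impact",
    "artifact",
    "control_shared",
)

_BASES = ("A", "C", "G", "T")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic discovery cohort.

    The defaults emulate the study setting: 20 patients diagnosed at or
    before 50, and a qualifying-variant rate ``a + b * (age_max - age)``
    whose defaults give a mean load of about 15 qualifying variants per
    patient with a negative age trend. ``seed`` is mandatory.
    """

    seed: int
    n_patients: int = 20
    age_min: int = 25
    age_max: int = 50
    burden_a: float = 8.75
    burden_b: float = 0.5
    n_background_variants: int = 40
    fraction_common: float = 0.20
    fraction_synonymous: float = 0.20
    fraction_artifact: float = 0.05
    fraction_control_shared: float = 0.05
    caller_discordance_rate: float = 0.05
    hom_fraction: float = 0.15

    def __post_init__(self):
        if self.n_patients < 1:
            raise ConfigurationError("n_patients must be >= 1")
        if not 0 < self.age_min <= self.age_max <= 120:
            raise ConfigurationError("require 0 < age_min <= age_max <= 120")
        if self.burden_a < 0 or self.burden_b < 0:
            raise ConfigurationError("burden rates must be non-negative")
        fracs = (
            self.fraction_common,
            self.fraction_synonymous,
            self.fraction_artifact,
            self.fraction_control_shared,
        )
        if any(not 0 <= f <= 1 for f in fracs) or sum(fracs) > 1:
            raise ConfigurationError("background fractions must lie in [0,1] and sum to <= 1")
        if not 0 <= self.caller_discordance_rate <= 1:
            raise ConfigurationError("caller_discordance_rate must lie in [0, 1]")

    def rate(self, age: float) -> float:
        return self.burden_a + self.burden_b * (self.age_max - age)


@dataclass
class GroundTruth:
    """Planted labels and the survivor counts they imply per stage."""

    labels: dict[tuple[VariantKey, str], str]
    concordant: set[tuple[VariantKey, str]]
    trace: FilterTrace
    burden_planted: dict[str, tuple[int, int]]  # sample -> (variants, alleles), all qualifying
    burden_expected: dict[str, tuple[int, int]]  # qualifying AND caller-concordant

    def __post_init__(self):
        if any(label not in LABELS for label in self.labels.values()):
            raise ValueError("unknown ground-truth label")


@dataclass
class SimulatedCohort:
    callset_a: list[AnnotatedVariant]
    callset_b: list[AnnotatedVariant]
    patients: list[CohortPatient]
    control_keys: set[VariantKey]
    artifact_keys: set[VariantKey]
    truth: GroundTruth


def _qc_metrics(rng: np.random.Generator, genotype: str) -> dict:
    """Caller metrics comfortably inside every QC gate."""
    depth = int(rng.integers(40, 200))
    alt = depth if genotype == "hom_alt" else depth // 2
    fwd = alt // 2
    return dict(
        depth=depth,
        alt_reads=alt,
        alt_fwd=fwd,
        alt_rev=alt - fwd,
        qual=float(np.round(rng.uniform(40, 100), 2)),
        strand_bias_p=float(np.round(rng.uniform(0.2, 1.0), 4)),
    )


def _rare_maf(rng: np.random.Generator) -> float | None:
    """A heterozygous-rare frequency, or NA for half the variants."""
    if rng.random() < 0.5:
        return None
    return float(np.round(rng.uniform(0.0, 0.0005), 6))


def _qualifying_annotation(rng: np.random.Generator, gene: str) -> tuple[Annotation, str]:
    """An annotation passing the functional, rarity and impact filters.

    Returns (annotation, allele_style) where allele_style is 'snv' or
    'indel' so the caller can draw matching alleles.
    """
    flavor = rng.choice(
        ["stopgain", "frameshift", "splicing", "missense_predicted", "missense_conserved"]
    )
    maf = _rare_maf(rng)
    if flavor == "stopgain":
        return Annotation(gene=gene, region_class="exonic", exonic_class="stopgain",
                          maf_ref=maf), "snv"
    if flavor == "frameshift":
        return Annotation(gene=gene, region_class="exonic", exonic_class="frameshift",
                          maf_ref=maf), "indel"
    if flavor == "splicing":
        return Annotation(
            gene=gene, region_class="splicing",
            splice_offset=int(rng.choice([-2, -1, 1, 2])), maf_ref=maf,
        ), "snv"
    if flavor == "missense_predicted":
        return Annotation(
            gene=gene, region_class="exonic", exonic_class="nonsynonymous",
            polyphen=str(rng.choice(["D", "P"])),
            cadd_phred=float(np.round(rng.uniform(15.0, 45.0), 2)),
            dann=float(np.round(rng.uniform(0.995, 1.0), 5)),
            gerp_pp=float(np.round(rng.uniform(2.0, 6.0), 2)),
            maf_ref=maf,
        ), "snv"
    # conserved-only missense: benign on the predictors but GERP++ >= 2,
    # qualifying through the default "and/or" = or conservation rule
    return Annotation(
        gene=gene, region_class="exonic", exonic_class="nonsynonymous",
        polyphen="B",
        cadd_phred=float(np.round(rng.uniform(5.0, 14.9), 2)),
        dann=float(np.round(rng.uniform(0.2, 0.99), 4)),
        gerp_pp=float(np.round(rng.uniform(2.0, 6.0), 2)),
        maf_ref=maf,
    ), "snv"


def _background_annotation(
    rng: np.random.Generator, gene: str, label: str
) -> tuple[Annotation, str]:
    """An annotation planted to fail exactly the stage its label names."""
    if label == "synonymous":
        return Annotation(
            gene=gene, region_class="exonic",
            exonic_class=str(rng.choice(["synonymous", "unknown"])),
            maf_ref=_rare_maf(rng),
        ), "snv"
    if label == "intronic":
        return Annotation(
            gene=gene, region_class=str(rng.choice(["intronic", "UTR", "intergenic"])),
            maf_ref=_rare_maf(rng),
        ), "snv"
    if label == "common":
        # damaging-looking but frequent: dies at the rarity stage
        return Annotation(
            gene=gene, region_class="exonic", exonic_class="nonsynonymous",
            polyphen="D",
            cadd_phred=float(np.round(rng.uniform(15.0, 45.0), 2)),
            dann=float(np.round(rng.uniform(0.995, 1.0), 5)),
            gerp_pp=float(np.round(rng.uniform(2.0, 6.0), 2)),
            maf_ref=float(np.round(rng.uniform(0.02, 0.2), 4)),
        ), "snv"
    if label == "low_impact":
        # benign on every predictor, drawn just outside the cutoffs
        return Annotation(
            gene=gene, region_class="exonic", exonic_class="nonsynonymous",
            polyphen="B",
            cadd_phred=float(np.round(rng.uniform(5.0, 14.9), 2)),
            dann=float(np.round(rng.uniform(0.2, 0.99), 4)),
            gerp_pp=float(np.round(rng.uniform(-3.0, 1.9), 2)),
            maf_ref=_rare_maf(rng),
        ), "snv"
    # artifact / control_shared look fully qualifying; they die at subtraction
    ann, style = _qualifying_annotation(rng, gene)
    return ann, style


class _KeyFactory:
    """Hands out unique, left-normalized variant keys."""

    def __init__(self, rng: np.random.Generator):
        self.rng = rng
        self.counter = 0

    def next_key(self, style: str) -> VariantKey:
        self.counter += 1
        chrom = str(1 + (self.counter % 22))
        pos = 10_000 + 10 * self.counter
        ref = str(self.rng.choice(_BASES))
        if style == "indel":
            tail = str(self.rng.choice(_BASES))
            return VariantKey(chrom, pos, ref + tail, ref)
        alt = str(self.rng.choice([b for b in _BASES if b != ref]))
        return VariantKey(chrom, pos, ref, alt)


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Generate a two-caller discovery cohort with ground truth.

    Qualifying variants are drawn per patient from Poisson(a + b *
    (age_max - age)); background variants are split between labels that
    each fail one specific cascade stage. The second caller drops or
    genotype-flips records at the configured discordance rate. The
    planted per-stage survivor counts are derived purely from the labels
    and concordance bookkeeping, never by running the cascade.
    """
    rng = np.random.default_rng(config.seed)
    keys = _KeyFactory(rng)
    genes = [f"GENE{i:04d}" for i in range(300)]

    patients = [
        CohortPatient(
            sample_id=f"SIM-{i:03d}",
            age_at_dx=int(rng.integers(config.age_min, config.age_max + 1)),
            cohort="discovery",
        )
        for i in range(config.n_patients)
    ]

    # remaining background mass is split evenly between intronic and
    # benign-missense so both mid-cascade stages see casualties
    leftover = 1.0 - (
        config.fraction_common
        + config.fraction_synonymous
        + config.fraction_artifact
        + config.fraction_control_shared
    )
    probs = np.array(
        [
            config.fraction_synonymous,
            leftover / 2,  # intronic
            config.fraction_common,
            leftover / 2,  # low_impact
            config.fraction_artifact,
            config.fraction_control_shared,
        ]
    )
    background_labels = LABELS[1:]

    callset_a: list[AnnotatedVariant] = []
    callset_b: list[AnnotatedVariant] = []
    labels: dict[tuple[VariantKey, str], str] = {}
    concordant: set[tuple[VariantKey, str]] = set()
    control_keys: set[VariantKey] = set()
    artifact_keys: set[VariantKey] = set()
    burden_planted: dict[str, tuple[int, int]] = {}
    burden_expected: dict[str, tuple[int, int]] = {}

    for patient in patients:
        planted = [0, 0]
        expected = [0, 0]
        n_qual = int(rng.poisson(config.rate(patient.age_at_dx)))
        plan: list[str] = ["qualifying"] * n_qual
        if config.n_background_variants:
            if probs.sum() <= 0:
                counts = np.zeros(len(background_labels), dtype=int)
            else:
                counts = rng.multinomial(config.n_background_variants, probs / probs.sum())
            for label, count in zip(background_labels, counts):
                plan.extend([label] * int(count))
        for label in plan:
            gene = genes[int(rng.integers(len(genes)))]
            if label == "qualifying":
                ann, style = _qualifying_annotation(rng, gene)
            else:
                ann, style = _background_annotation(rng, gene, label)
            key = keys.next_key(style)
            genotype = "hom_alt" if rng.random() < config.hom_fraction else "het"
            if label == "common":
                genotype = "het"  # frequent sites fail the stricter het bound too
            call = VariantCall(
                key=key, sample_id=patient.sample_id, genotype=genotype,
                caller="lifescope", **_qc_metrics(rng, genotype),
            )
            record = AnnotatedVariant(call=call, annotation=ann)
            callset_a.append(record)
            labels[(key, patient.sample_id)] = label
            if label == "artifact":
                artifact_keys.add(key)
            elif label == "control_shared":
                control_keys.add(key)

            is_discordant = rng.random() < config.caller_discordance_rate
            if is_discordant:
                if rng.random() < 0.5:
                    flipped = "het" if genotype == "hom_alt" else "hom_alt"
                    callset_b.append(
                        AnnotatedVariant(
                            call=replace(call, caller="gatk", genotype=flipped),
                            annotation=ann,
                        )
                    )
                # else: missing from the second caller entirely
            else:
                callset_b.append(
                    AnnotatedVariant(call=replace(call, caller="gatk"), annotation=ann)
                )
                concordant.add((key, patient.sample_id))
            if label == "qualifying":
                weight = 2 if genotype == "hom_alt" else 1
                planted[0] += 1
                planted[1] += weight
                if not is_discordant:
                    expected[0] += 1
                    expected[1] += weight
        burden_planted[patient.sample_id] = tuple(planted)
        burden_expected[patient.sample_id] = tuple(expected)

    def surviving(stage_labels: set[str]) -> int:
        return sum(1 for ks, lab in labels.items() if lab in stage_labels and ks in concordant)

    all_labels = set(LABELS)
    n_unique = len(labels)
    n_concordant = surviving(all_labels)
    n_non_syn = n_concordant - surviving({"synonymous"})
    n_exonic = n_non_syn - surviving({"intronic"})
    n_rare = n_exonic - surviving({"common"})
    n_high = n_rare - surviving({"low_impact"})
    n_final = n_high - surviving({"artifact", "control_shared"})
    trace = FilterTrace(
        stages=list(
            zip(
                STAGE_ORDER,
                [n_unique, n_concordant, n_non_syn, n_exonic, n_rare, n_high, n_final],
            )
        )
    )
    truth = GroundTruth(
        labels=labels, concordant=concordant, trace=trace,
        burden_planted=burden_planted, burden_expected=burden_expected,
    )
    return SimulatedCohort(
        callset_a=callset_a, callset_b=callset_b, patients=patients,
        control_keys=control_keys, artifact_keys=artifact_keys, truth=truth,
    )


# ---------------------------------------------------------------------------
# pooled sequencing


@dataclass(frozen=True)
class PoolSimConfig:
    """Study conditions for pooled-amplicon simulation: pools of 48-96
    samples sequenced to a median depth in the thousands, with a
    Q30-scale base-error rate."""

    seed: int
    n_samples: int = 48
    depth: int = 10_000
    error_rate: float = 0.001

    def __post_init__(self):
        if self.n_samples < 1 or self.depth < 1:
            raise ConfigurationError("n_samples and depth must be >= 1")
        if not 0 <= self.error_rate <= 0.01:
            raise ConfigurationError("error_rate must lie in [0, 0.01]")


@dataclass
class PoolGroundTruth:
    carriers: dict[str, int]  # pool_id -> planted heterozygous carriers


def simulate_pools(
    config: PoolSimConfig,
    carriers: Sequence[int],
    annotation: Annotation | None = None,
) -> tuple[list[PoolPileup], PoolGroundTruth]:
    """Simulate one assayed position per pool with the given carrier counts.

    With k heterozygous carriers among n samples the true alternate-allele
    fraction is f = k / (2n); reads are drawn Binomial(depth, p) with
    p = f (1 - e) + (1 - f) e / 3, i.e. carrier alleles can miscall away
    from the variant and the error rate e miscalls toward it one third of
    the time. Strand assignment is Binomial(alt, 1/2). Entries with k = 0
    are error-only positions.
    """
    rng = np.random.default_rng(config.seed)
    if annotation is None:
        annotation = Annotation(
            gene="POOLGENE", region_class="exonic", exonic_class="stopgain", maf_ref=None
        )
    pileups: list[PoolPileup] = []
    truth = PoolGroundTruth(carriers={})
    for i, k in enumerate(carriers):
        if not 0 <= k <= 2 * config.n_samples:
            raise ConfigurationError(
                f"pool {i}: carriers must lie in [0, 2*n_samples], got {k}"
            )
        f = k / (2 * config.n_samples)
        e = config.error_rate
        p = f * (1 - e) + (1 - f) * e / 3
        alt = int(rng.binomial(config.depth, p))
        fwd = int(rng.binomial(alt, 0.5)) if alt else 0
        pool_id = f"POOL-{i:04d}"
        pileups.append(
            PoolPileup(
                pool_id=pool_id,
                n_samples=config.n_samples,
                key=VariantKey("1", 1_000 + i, "C", "T"),
                depth_hq=config.depth,
                alt_hq=alt,
                alt_fwd=fwd,
                alt_rev=alt - fwd,
                annotation=annotation,
            )
        )
        truth.carriers[pool_id] = int(k)
    return pileups, truth


# ---------------------------------------------------------------------------
# signatures


def make_catalog(n_signatures: int = 10, seed: int = 0, concentration: float = 0.3
                 ) -> SignatureCatalog:
    """A synthetic signature catalog: columns drawn from a symmetric
    Dirichlet over the 96 channels (sparse, mutually distinct spectra).
    This is a stand-in dictionary for testing the refitting machinery,
    not a reproduction of any published catalog."""
    rng = np.random.default_rng(seed)
    cols = rng.dirichlet([concentration] * 96, size=n_signatures)
    cols = cols / cols.sum(axis=1, keepdims=True)
    names = tuple(f"Signature {i + 1}" for i in range(n_signatures))
    return SignatureCatalog(names=names, matrix=tuple(tuple(map(float, c)) for c in cols))


def sample_profile_from_mixture(
    catalog: SignatureCatalog,
    weights: Sequence[float],
    n_mutations: int,
    rng: np.random.Generator,
) -> MutationalProfile:
    """Draw a noisy profile: channel counts are independent Poisson with
    mean ``n_mutations`` times the catalog mixture."""
    w = np.asarray(weights, dtype=float)
    if len(w) != len(catalog) or np.any(w < 0):
        raise ConfigurationError("weights must be nonnegative, one per catalog signature")
    w = w / w.sum()
    mean = n_mutations * (catalog.as_array() @ w)
    counts = rng.poisson(mean)
    return MutationalProfile(counts=tuple(float(c) for c in counts))


# ---------------------------------------------------------------------------
# packaged study tables and replication fixtures

_GENE_CHROM = {
    "CHAD": ("17", 50_000_000),
    "CHD1L": ("1", 147_000_000),
    "ERCC6": ("10", 49_000_000),
    "ITGB7": ("12", 53_000_000),
    "PTPN13": ("4", 86_000_000),
    "SPATA20": ("17", 50_200_000),
    "TDG": ("12", 104_000_000),
    "TGS1": ("8", 55_000_000),
}


def make_paper_fixtures(outdir) -> dict[str, Path]:
    """Write the packaged study tables as TSV files and return their paths.

    Emits the candidate-gene table (8 genes with evidence flags), the
    replication-cohort variant table (13 variants with ages), the
    external-cohort variant table (21 variants with ages), and the
    independent case-control carrier counts.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    p = outdir / "table1_candidate_genes.tsv"
    with open(p, "w") as fh:
        fh.write(
            "gene\tvariant\tpatients\tin_early_onset_literature\tin_cancer_kegg\t"
            "expressed_in_colonic_mucosa\tcarrier_under_40\thas_lof_variant\n"
        )
        for gene, variant, pats, flags in TABLE1:
            fh.write(
                "\t".join([gene, variant, ";".join(pats), *(str(int(f)) for f in flags)]) + "\n"
            )
    paths["table1"] = p

    p = outdir / "table2_replication_variants.tsv"
    with open(p, "w") as fh:
        fh.write("gene\tvariant\tconsequence\tages\n")
        for gene, variant, consequence, ages in TABLE2:
            fh.write("\t".join([gene, variant, consequence, ";".join(map(str, ages))]) + "\n")
    paths["table2"] = p

    p = outdir / "table3_external_variants.tsv"
    with open(p, "w") as fh:
        fh.write("gene\tvariant\tage_at_dx\n")
        for gene, variant, age in TABLE3:
            fh.write(f"{gene}\t{variant}\t{age}\n")
    paths["table3"] = p

    p = outdir / "case_control_counts.tsv"
    with open(p, "w") as fh:
        fh.write("gene\tcase_carriers\tcase_n\tcontrol_carriers\tcontrol_n\n")
        for gene, (a, b, c, d) in CASE_CONTROL_COUNTS.items():
            fh.write(f"{gene}\t{a}\t{b}\t{c}\t{d}\n")
    paths["case_control"] = p
    return paths


def table2_pool_calls(n_samples: int = 96, depth: int = 9_421) -> list[PoolCall]:
    """Detected pool calls modeled on the replication-cohort variant table.

    Variant positions and annotation scores are synthetic (the published
    table prints genes, protein changes and ages, not coordinates or
    predictor scores); each call carries an annotation consistent with
    its printed consequence class, one heterozygous carrier's worth of
    alternate reads, and an ENMA near 1.
    """
    calls: list[PoolCall] = []
    for i, (gene, variant, consequence, ages) in enumerate(TABLE2):
        chrom, base = _GENE_CHROM[gene]
        if consequence == "stopgain":
            ann = Annotation(
                gene=gene, region_class="exonic", exonic_class="stopgain",
                hgvs_p=variant, maf_ref=None,
            )
        else:
            ann = Annotation(
                gene=gene, region_class="exonic", exonic_class="nonsynonymous",
                hgvs_p=variant, polyphen="D", cadd_phred=25.0, dann=0.998,
                gerp_pp=4.5, maf_ref=None,
            )
        n_carriers = len(ages)
        alt = round(depth * n_carriers / (2 * n_samples))
        pileup = PoolPileup(
            pool_id=f"REPL-{i:02d}",
            n_samples=n_samples,
            key=VariantKey(chrom, base + 100 * i + 1, "C", "A"),
            depth_hq=depth,
            alt_hq=alt,
            alt_fwd=alt // 2,
            alt_rev=alt - alt // 2,
            annotation=ann,
        )
        call = compute_enma(pileup)
        calls.append(replace(call, detected=True, error_p=0.0))
    return calls
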