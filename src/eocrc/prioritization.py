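"""The variant-prioritization cascade.

Starting from two QC-filtered call sets (one per calling algorithm), the
cascade keeps, in a fixed order:

1. ``unique`` — distinct (variant, patient) pairs across both callers;
2. ``concordant`` — calls made by both callers in the same patient with
   the same genotype;
3. ``non_synonymous`` — drops synonymous and unknown exonic classes;
4. ``exonic_splicing`` — restricts to exonic and splicing regions;
5. ``rare`` — reference-population MAF at most 0.1% for heterozygous and
   1% for homozygous calls (NA counts as unobserved, hence rare);
6. ``high_impact`` — protein-truncating (stopgain/frameshift), canonical
   splice-site, or missense predicted damaging by PolyPhen-2 + CADD +
   DANN jointly and/or at a conserved position (GERP++);
7. ``after_control_subtraction`` — removes variants seen in a non-cancer
   control cohort or on a recurrent-artifact blacklist.

Every stage count is recorded in a :class:`FilterTrace`, and each dropped
record is attributable to exactly one stage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from eocrc.errors import DataError
from eocrc.variant_io import AnnotatedVariant, VariantCall, VariantKey, record_sort_key

__all__ = [
    "QCThresholds",
    "RarityThresholds",
    "ImpactThresholds",
    "CascadeConfig",
    "FilterTrace",
    "CascadeResult",
    "STAGE_ORDER",
    "apply_caller_qc",
    "caller_concordance",
    "functional_class_filter",
    "rarity_filter",
    "impact_filter",
    "control_subtraction",
    "run_cascade",
    "recurrence_summary",
]

STAGE_ORDER = (
    "unique",
    "concordant",
    "non_synonymous",
    "exonic_splicing",
    "rare",
    "high_impact",
    "after_control_subtraction",
)


@dataclass(frozen=True)
class QCThresholds:
    """Per-caller quality gates applied before the cascade.

    ``strand_bias_direction`` maps a caller name to ``remove_low_p``
    (drop calls whose strand-bias test p-value is below ``alpha``, i.e.
    calls that look biased) or ``remove_high_p``. The default removes
    biased calls for every caller.
    """

    min_depth: int = 30
    min_alt_reads: int = 4
    min_alt_fraction: float = 0.20
    min_qual: float = 30.0
    strand_bias_alpha: float = 0.05
    strand_bias_direction: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if min(self.min_depth, self.min_alt_reads, self.min_alt_fraction, self.min_qual) < 0:
            raise ValueError("QC thresholds must be non-negative")
        if not 0.0 < self.strand_bias_alpha < 1.0:
            raise ValueError("strand_bias_alpha must lie in (0, 1)")
        for direction in self.strand_bias_direction.values():
            if direction not in ("remove_low_p", "remove_high_p"):
                raise ValueError(f"unknown strand-bias direction {direction!r}")

    def direction_for(self, caller: str) -> str:
        return self.strand_bias_direction.get(caller, "remove_low_p")


@dataclass(frozen=True)
class RarityThresholds:
    """Population-frequency bounds: 0.1% for het and 1% for hom calls."""

    max_maf_het: float = 0.001
    max_maf_hom: float = 0.01

    def __post_init__(self):
        if not 0.0 <= self.max_maf_het <= self.max_maf_hom <= 1.0:
            raise ValueError("require 0 <= max_maf_het <= max_maf_hom <= 1")


@dataclass(frozen=True)
class ImpactThresholds:
    """High-functional-impact rules.

    A record qualifies if it is protein truncating (stopgain or
    frameshift), sits at a canonical splice site (|offset| within
    ``splice_window``), or is a nonsynonymous SNV that the three
    in-silico predictors jointly call damaging (PolyPhen-2 category in
    ``polyphen_damaging``, CADD phred >= ``min_cadd``, DANN >=
    ``min_dann``) and/or lies at a conserved position (GERP++ >=
    ``min_gerp``), combined per ``conservation_rule``. A missing
    predictor value counts as non-damaging.
    """

    min_cadd: float = 15.0
    min_dann: float = 0.995
    polyphen_damaging: frozenset[str] = frozenset({"D", "P"})
    min_gerp: float = 2.0
    splice_window: int = 2
    conservation_rule: str = "or"

    def __post_init__(self):
        if self.splice_window < 1:
            raise ValueError("splice_window must be >= 1")
        if self.conservation_rule not in ("or", "and"):
            raise ValueError("conservation_rule must be 'or' or 'and'")


@dataclass(frozen=True)
class CascadeConfig:
    """Bundle of all cascade thresholds."""

    qc: QCThresholds = QCThresholds()
    rarity: RarityThresholds = RarityThresholds()
    impact: ImpactThresholds = ImpactThresholds()


@dataclass
class FilterTrace:
    """Ordered record of (stage name, surviving count) for one run."""

    stages: list[tuple[str, int]]

    def __post_init__(self):
        names = [s for s, _ in self.stages]
        if names != list(STAGE_ORDER):
            raise ValueError(f"stages must follow the fixed order {STAGE_ORDER}, got {names}")
        counts = [c for _, c in self.stages]
        if any(c < 0 for c in counts):
            raise ValueError("stage counts must be non-negative")
        # "unique" may be below "concordant" only never: monotone from concordant on
        for prev, nxt in zip(counts[1:], counts[2:]):
            if nxt > prev:
                raise ValueError("stage counts must be non-increasing from 'concordant' onward")

    def __getitem__(self, stage: str) -> int:
        for name, count in self.stages:
            if name == stage:
                return count
        raise KeyError(stage)

    def as_dict(self) -> dict[str, int]:
        return dict(self.stages)

    @property
    def final_count(self) -> int:
        return self.stages[-1][1]


@dataclass
class CascadeResult:
    """Survivors, the stage trace, and per-stage drop lists.

    ``dropped`` maps each stage from ``concordant`` onward to the records
    eliminated at that stage; together with ``records`` they partition
    the deduplicated QC-passing records of the first call set.
    """

    records: list[AnnotatedVariant]
    trace: FilterTrace
    dropped: dict[str, list[AnnotatedVariant]]


# ---------------------------------------------------------------------------
# stage operations


def apply_caller_qc(call: VariantCall, thresholds: QCThresholds) -> tuple[bool, list[str]]:
    """Evaluate every QC rule on one call; returns (passed, failure reasons).

    All failing rules are reported, not only the first; a missing metric
    required by a rule fails with reason ``missing_metric``.
    """
    reasons: list[str] = []

    def require(value, rule: str) -> bool:
        if value is None:
            if "missing_metric" not in reasons:
                reasons.append("missing_metric")
            return False
        return True

    if require(call.depth, "depth") and call.depth < thresholds.min_depth:
        reasons.append("depth")
    if require(call.alt_reads, "alt_reads") and call.alt_reads < thresholds.min_alt_reads:
        reasons.append("alt_reads")
    frac = call.alt_fraction
    if require(frac, "alt_fraction") and frac < thresholds.min_alt_fraction:
        reasons.append("alt_fraction")
    if require(call.qual, "qual") and call.qual < thresholds.min_qual:
        reasons.append("qual")
    if require(call.strand_bias_p, "strand_bias"):
        direction = thresholds.direction_for(call.caller)
        p, alpha = call.strand_bias_p, thresholds.strand_bias_alpha
        if (direction == "remove_low_p" and p < alpha) or (
            direction == "remove_high_p" and p > alpha
        ):
            reasons.append("strand_bias")
    return (not reasons, reasons)


def qc_filter(
    records: Iterable[AnnotatedVariant], thresholds: QCThresholds
) -> list[AnnotatedVariant]:
    """Keep records whose call passes :func:`apply_caller_qc`."""
    return [r for r in records if apply_caller_qc(r.call, thresholds)[0]]


def _dedupe(records: Sequence[AnnotatedVariant], label: str) -> dict[tuple, AnnotatedVariant]:
    out: dict[tuple, AnnotatedVariant] = {}
    for rec in records:
        ks = (rec.key, rec.sample_id)
        prev = out.get(ks)
        if prev is None:
            out[ks] = rec
        elif prev.genotype != rec.genotype:
            raise DataError(
                f"{label}: duplicate call for {rec.key} in sample {rec.sample_id} "
                f"with conflicting genotypes ({prev.genotype} vs {rec.genotype})"
            )
    return out


def caller_concordance(
    callset_a: Sequence[AnnotatedVariant], callset_b: Sequence[AnnotatedVariant]
) -> list[AnnotatedVariant]:
    """Keep calls present in both call sets for the same patient with the
    same genotype; annotations are taken from ``callset_a``.

    Both inputs are assumed QC-filtered. Duplicate (variant, patient)
    pairs with conflicting genotypes within one call set are a data
    error; consistent duplicates are collapsed.
    """
    a = _dedupe(callset_a, "callset_a")
    b = _dedupe(callset_b, "callset_b")
    kept: list[AnnotatedVariant] = []
    for ks, rec in a.items():
        other = b.get(ks)
        if other is None or other.genotype != rec.genotype:
            continue
        if other.annotation.gene is not None and other.annotation.gene != rec.annotation.gene:
            warnings.warn(
                f"annotation mismatch at {rec.key}: gene {rec.annotation.gene!r} vs "
                f"{other.annotation.gene!r}; keeping callset_a's annotation",
                stacklevel=2,
            )
        kept.append(rec)
    return kept


def functional_class_filter(
    records: Sequence[AnnotatedVariant],
) -> tuple[list[AnnotatedVariant], list[AnnotatedVariant]]:
    """Apply the two functional-class stages in their fixed order.

    Returns ``(after_non_synonymous, after_exonic_splicing)``: first the
    records left after removing synonymous/unknown exonic classes, then
    those additionally restricted to exonic and splicing regions.
    """
    non_syn = [
        r for r in records if r.annotation.exonic_class not in ("synonymous", "unknown")
    ]
    exonic_splicing = [
        r for r in non_syn if r.annotation.region_class in ("exonic", "splicing")
    ]
    return non_syn, exonic_splicing


def rarity_filter(record: AnnotatedVariant, thresholds: RarityThresholds) -> bool:
    """True if the record is rare for its genotype; NA frequency passes."""
    maf = record.annotation.maf_ref
    if maf is None:
        return True
    bound = thresholds.max_maf_hom if record.genotype == "hom_alt" else thresholds.max_maf_het
    return maf <= bound


def impact_filter(record: AnnotatedVariant, thresholds: ImpactThresholds) -> bool:
    """True if the record is high-functional-impact (see ImpactThresholds)."""
    ann = record.annotation
    if ann.exonic_class in ("stopgain", "frameshift"):
        return True
    if (
        ann.region_class == "splicing"
        and ann.splice_offset is not None
        and abs(ann.splice_offset) <= thresholds.splice_window
    ):
        return True
    if ann.exonic_class == "nonsynonymous" and record.key.is_snv:
        predicted = (
            ann.polyphen in thresholds.polyphen_damaging
            and ann.cadd_phred is not None
            and ann.cadd_phred >= thresholds.min_cadd
            and ann.dann is not None
            and ann.dann >= thresholds.min_dann
        )
        conserved = ann.gerp_pp is not None and ann.gerp_pp >= thresholds.min_gerp
        if thresholds.conservation_rule == "or":
            return predicted or conserved
        return predicted and conserved
    return False


def control_subtraction(
    records: Sequence[AnnotatedVariant],
    control_keys: Iterable[VariantKey],
    artifact_keys: Iterable[VariantKey] = (),
) -> list[AnnotatedVariant]:
    """Remove any record whose variant was seen in the control cohort or
    on the artifact blacklist, regardless of genotype."""
    excluded = set(control_keys) | set(artifact_keys)
    return [r for r in records if r.key not in excluded]


# ---------------------------------------------------------------------------
# cascade driver


def run_cascade(
    callset_a: Sequence[AnnotatedVariant],
    callset_b: Sequence[AnnotatedVariant],
    config: CascadeConfig = CascadeConfig(),
    control_keys: Iterable[VariantKey] = (),
    artifact_keys: Iterable[VariantKey] = (),
) -> CascadeResult:
    """Run the full prioritization cascade.

    QC is applied per caller first; the ``unique`` stage then counts the
    distinct (variant, patient) pairs across both QC-passing call sets,
    and the remaining stages run in the fixed :data:`STAGE_ORDER`.
    Survivors are returned in deterministic coordinate order together
    with the trace and per-stage drop lists.
    """
    qc_a = qc_filter(callset_a, config.qc)
    qc_b = qc_filter(callset_b, config.qc)
    unique_pairs = {(r.key, r.sample_id) for r in qc_a} | {(r.key, r.sample_id) for r in qc_b}

    concordant = caller_concordance(qc_a, qc_b)
    deduped_a = list(_dedupe(qc_a, "callset_a").values())
    concordant_set = {(r.key, r.sample_id) for r in concordant}
    dropped = {
        "concordant": [r for r in deduped_a if (r.key, r.sample_id) not in concordant_set]
    }

    non_syn, exonic_splicing = functional_class_filter(concordant)
    non_syn_set = {id(r) for r in non_syn}
    dropped["non_synonymous"] = [r for r in concordant if id(r) not in non_syn_set]
    es_set = {id(r) for r in exonic_splicing}
    dropped["exonic_splicing"] = [r for r in non_syn if id(r) not in es_set]

    rare = [r for r in exonic_splicing if rarity_filter(r, config.rarity)]
    dropped["rare"] = [r for r in exonic_splicing if not rarity_filter(r, config.rarity)]

    high = [r for r in rare if impact_filter(r, config.impact)]
    dropped["high_impact"] = [r for r in rare if not impact_filter(r, config.impact)]

    final = control_subtraction(high, control_keys, artifact_keys)
    final_set = {id(r) for r in final}
    dropped["after_control_subtraction"] = [r for r in high if id(r) not in final_set]

    final = sorted(final, key=record_sort_key)
    trace = FilterTrace(
        stages=[
            ("unique", len(unique_pairs)),
            ("concordant", len(concordant)),
            ("non_synonymous", len(non_syn)),
            ("exonic_splicing", len(exonic_splicing)),
            ("rare", len(rare)),
            ("high_impact", len(high)),
            ("after_control_subtraction", len(final)),
        ]
    )
    return CascadeResult(records=final, trace=trace, dropped=dropped)


def recurrence_summary(
    records: Sequence[AnnotatedVariant],
) -> tuple[dict[VariantKey, int], dict[str, int]]:
    """Per-variant distinct-carrier counts and per-gene distinct-variant
    counts for a post-cascade record set."""
    carriers: dict[VariantKey, set[str]] = {}
    gene_variants: dict[str, set[VariantKey]] = {}
    for rec in records:
        carriers.setdefault(rec.key, set()).add(rec.sample_id)
        if rec.gene is not None:
            gene_variants.setdefault(rec.gene, set()).add(rec.key)
    return (
        {k: len(s) for k, s in carriers.items()},
        {g: len(s) for g, s in gene_variants.items()},
    )
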