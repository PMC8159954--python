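"""Cohort-level statistics on prioritized variants.

Covers four analyses downstream of the prioritization cascade:

* per-patient burden of qualifying variants (variants, and alleles with
  heterozygous calls weighted 1 and homozygous 2) and its trend with age
  at diagnosis (OLS slope test by default; Spearman/Pearson available);
* gene-level case-control carrier burden via an exact 2x2 test;
* pathway over-representation of the candidate-gene list against gene
  sets (one-sided exact test over a configurable background universe of
  protein-coding genes, no multiple-testing correction by default);
* candidate-gene evidence scoring (counting boolean relevance criteria)
  and summary counting of external-cohort variant tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
from scipy import stats

from eocrc.errors import DataError, DegenerateInputError
from eocrc.variant_io import AnnotatedVariant, GeneSet

__all__ = [
    "CohortPatient",
    "BurdenRow",
    "ContingencyResult",
    "AgeTrendResult",
    "EvidenceRow",
    "EVIDENCE_CRITERIA",
    "TableSummary",
    "per_patient_burden",
    "age_trend_test",
    "gene_burden_test",
    "pathway_enrichment",
    "select_candidate_genes",
    "tcga_table_summary",
]

COHORTS = ("discovery", "replication", "external")


@dataclass(frozen=True)
class CohortPatient:
    """A study patient with age at diagnosis."""

    sample_id: str
    age_at_dx: float
    cohort: str = "discovery"

    def __post_init__(self):
        if not 0 < self.age_at_dx <= 120:
            raise ValueError(f"age_at_dx out of range: {self.age_at_dx}")
        if self.cohort not in COHORTS:
            raise ValueError(f"cohort must be one of {COHORTS}")


@dataclass(frozen=True)
class BurdenRow:
    """Qualifying-variant burden of one patient (het = 1, hom = 2 alleles)."""

    sample_id: str
    n_variants: int
    n_alleles: int

    def __post_init__(self):
        if not 0 <= self.n_variants <= self.n_alleles <= 2 * self.n_variants:
            raise ValueError(
                f"require n_variants <= n_alleles <= 2*n_variants, got "
                f"{self.n_variants}/{self.n_alleles}"
            )


@dataclass(frozen=True)
class ContingencyResult:
    """A 2x2 table with its unconditional odds ratio and exact p-values.

    The odds ratio is the cross-product ratio ad/bc (inf when bc = 0 with
    ad > 0, NaN for 0/0); two-sided p follows the point-probability rule
    on the conditional hypergeometric distribution.
    """

    table: tuple[tuple[int, int], tuple[int, int]]
    odds_ratio: float
    p_two_sided: float
    p_greater: float
    method: str = "fisher_exact"

    def __post_init__(self):
        if any(x < 0 for row in self.table for x in row):
            raise ValueError("table entries must be non-negative")
        for p in (self.p_two_sided, self.p_greater):
            if not 0.0 <= p <= 1.0 + 1e-12:
                raise ValueError(f"p-value out of [0, 1]: {p}")


@dataclass(frozen=True)
class AgeTrendResult:
    """Association between per-patient burden and age at diagnosis."""

    method: str
    statistic: float
    p_value: float
    n: int
    slope: float | None = None
    intercept: float | None = None

    def __post_init__(self):
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value out of [0, 1]: {self.p_value}")
        if self.n < 3:
            raise ValueError("age-trend test needs n >= 3")


EVIDENCE_CRITERIA = (
    "in_early_onset_literature",
    "in_cancer_kegg",
    "expressed_in_colonic_mucosa",
    "carrier_under_40",
    "has_lof_variant",
)


@dataclass(frozen=True)
class EvidenceRow:
    """Boolean relevance criteria for one candidate gene."""

    gene: str
    in_early_onset_literature: bool = False
    in_cancer_kegg: bool = False
    expressed_in_colonic_mucosa: bool = False
    carrier_under_40: bool = False
    has_lof_variant: bool = False
    n_candidate_variants: int = 1

    def __post_init__(self):
        if self.n_candidate_variants < 1:
            raise ValueError("a gene under consideration needs >= 1 candidate variant")

    @property
    def score(self) -> int:
        return sum(getattr(self, c) for c in EVIDENCE_CRITERIA)

    @property
    def satisfied(self) -> tuple[str, ...]:
        return tuple(c for c in EVIDENCE_CRITERIA if getattr(self, c))


class TableSummary(NamedTuple):
    n_variants: int
    n_genes: int
    n_at_or_under_cutoff: int


# ---------------------------------------------------------------------------
# burden and age trend


def per_patient_burden(
    records: Sequence[AnnotatedVariant], patients: Sequence[CohortPatient]
) -> list[BurdenRow]:
    """Count qualifying variants and alleles per patient.

    Patients with no qualifying variant appear with zeros; a record whose
    sample is not in the patient table is a data error.
    """
    known = {p.sample_id for p in patients}
    counts: dict[str, list[int]] = {s: [0, 0] for s in known}
    for rec in records:
        if rec.sample_id not in known:
            raise DataError(f"record sample {rec.sample_id!r} not in the patient table")
        counts[rec.sample_id][0] += 1
        counts[rec.sample_id][1] += 2 if rec.genotype == "hom_alt" else 1
    return [
        BurdenRow(sample_id=p.sample_id, n_variants=counts[p.sample_id][0],
                  n_alleles=counts[p.sample_id][1])
        for p in patients
    ]


def age_trend_test(
    burden: Sequence[BurdenRow],
    patients: Sequence[CohortPatient],
    method: str = "linear_regression",
    value: str = "n_variants",
) -> AgeTrendResult:
    """Test whether burden varies with age at diagnosis.

    Default is the ordinary least-squares slope of burden on age with a
    two-sided t-test (matching a scatter-plus-trend presentation);
    ``spearman`` and ``pearson`` rank/linear correlations are available.
    A negative slope/statistic means younger patients carry more.
    """
    if value not in ("n_variants", "n_alleles"):
        raise ValueError("value must be 'n_variants' or 'n_alleles'")
    ages_by_id = {p.sample_id: p.age_at_dx for p in patients}
    pairs = [(ages_by_id[b.sample_id], getattr(b, value)) for b in burden
             if b.sample_id in ages_by_id]
    if len(pairs) < 3:
        raise DegenerateInputError(f"age-trend test needs >= 3 patients, got {len(pairs)}")
    x = np.array([a for a, _ in pairs], dtype=float)
    y = np.array([v for _, v in pairs], dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("age-trend test undefined: zero variance in age or burden")
    if method == "linear_regression":
        fit = stats.linregress(x, y)
        t = fit.slope / fit.stderr if fit.stderr > 0 else math.inf
        return AgeTrendResult(
            method=method, statistic=float(t), p_value=float(fit.pvalue), n=len(pairs),
            slope=float(fit.slope), intercept=float(fit.intercept),
        )
    if method == "spearman":
        rho, p = stats.spearmanr(x, y)
        return AgeTrendResult(method=method, statistic=float(rho), p_value=float(p), n=len(pairs))
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
        return AgeTrendResult(method=method, statistic=float(r), p_value=float(p), n=len(pairs))
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# exact 2x2 tests


def _exact_2x2(table) -> tuple[float, float, float]:
    """Unconditional odds ratio plus two-sided (point-probability rule)
    and one-sided-greater exact hypergeometric p-values."""
    (a, b), (c, d) = table
    if a * d == 0 and b * c == 0:
        odds = math.nan
    elif b * c == 0:
        odds = math.inf
    else:
        odds = (a * d) / (b * c)
    p_two = float(stats.fisher_exact(table, alternative="two-sided")[1])
    p_greater = float(stats.fisher_exact(table, alternative="greater")[1])
    return odds, min(p_two, 1.0), min(p_greater, 1.0)


def gene_burden_test(
    case_carriers: int, case_n: int, control_carriers: int, control_n: int
) -> ContingencyResult:
    """Exact case-control carrier burden test for one gene.

    Builds [[case carriers, case non-carriers], [control carriers,
    control non-carriers]] and applies the exact conditional
    hypergeometric test, two-sided by the point-probability rule.
    """
    for name, value in (
        ("case_carriers", case_carriers),
        ("case_n", case_n),
        ("control_carriers", control_carriers),
        ("control_n", control_n),
    ):
        if value < 0:
            raise ValueError(f"{name} must be non-negative")
    if case_carriers > case_n or control_carriers > control_n:
        raise ValueError("carriers cannot exceed cohort size")
    table = (
        (case_carriers, case_n - case_carriers),
        (control_carriers, control_n - control_carriers),
    )
    odds, p_two, p_greater = _exact_2x2(table)
    return ContingencyResult(
        table=table, odds_ratio=odds, p_two_sided=p_two, p_greater=p_greater,
        method="fisher_exact",
    )


@dataclass(frozen=True)
class EnrichmentRow:
    """One gene set's over-representation result."""

    gene_set: GeneSet
    overlap: int
    result: ContingencyResult
    significant: bool


def pathway_enrichment(
    candidate_genes: Iterable[str],
    gene_sets: Sequence[GeneSet],
    background_size: int = 19_000,
    alpha: float = 0.05,
    correction: str | None = None,
) -> list[EnrichmentRow]:
    """One-sided over-representation of candidate genes in each gene set.

    The 2x2 table per set is [[overlap, candidates - overlap],
    [set - overlap, background - candidates - set + overlap]] over a
    background universe of ``background_size`` genes. Significance is a
    nominal p < ``alpha`` with no multiple-testing correction by default;
    ``correction='bh'`` applies Benjamini-Hochberg across the sets.
    """
    candidates = set(candidate_genes)
    n_cand = len(candidates)
    if background_size < n_cand:
        raise ValueError("background_size must be >= number of candidate genes")
    rows: list[EnrichmentRow] = []
    for gs in gene_sets:
        if len(gs) > background_size:
            raise ValueError(f"gene set {gs.set_id} larger than the background universe")
        overlap = len(candidates & gs.genes)
        table = (
            (overlap, n_cand - overlap),
            (len(gs) - overlap, background_size - n_cand - len(gs) + overlap),
        )
        if min(table[1]) < 0:
            raise ValueError(
                f"inconsistent background: set {gs.set_id} does not fit the universe"
            )
        odds, p_two, p_greater = _exact_2x2(table)
        rows.append(
            EnrichmentRow(
                gene_set=gs,
                overlap=overlap,
                result=ContingencyResult(
                    table=table, odds_ratio=odds, p_two_sided=p_two,
                    p_greater=p_greater, method="fisher_exact_greater",
                ),
                significant=p_greater < alpha,
            )
        )
    if correction == "bh":
        adjusted = stats.false_discovery_control([r.result.p_greater for r in rows], method="bh")
        rows = [
            EnrichmentRow(r.gene_set, r.overlap, r.result, significant=adj < alpha)
            for r, adj in zip(rows, adjusted)
        ]
    elif correction is not None:
        raise ValueError(f"unknown correction {correction!r}")
    return rows


# ---------------------------------------------------------------------------
# candidate-gene selection and external tables


def select_candidate_genes(
    evidence: Sequence[EvidenceRow], min_score: int = 2
) -> list[tuple[str, int, tuple[str, ...]]]:
    """Rank genes by the number of satisfied relevance criteria.

    Returns (gene, score, satisfied criteria) for genes with score >=
    ``min_score``, ordered by score descending then gene name (ties are
    broken alphabetically, so the ranking is stable).
    """
    selected = [(e.gene, e.score, e.satisfied) for e in evidence if e.score >= min_score]
    return sorted(selected, key=lambda t: (-t[1], t[0]))


def tcga_table_summary(
    rows: Sequence[tuple[str, str, float]], age_cutoff: float = 50
) -> TableSummary:
    """Summarize an external (gene, variant, age-at-diagnosis) table:
    total variants, distinct genes, and variants in patients diagnosed
    at or under the age cutoff."""
    if not rows:
        raise ValueError("summary of an empty variant table is undefined")
    if age_cutoff <= 0:
        raise ValueError("age_cutoff must be positive")
    genes = {gene for gene, _, _ in rows}
    under = sum(1 for _, _, age in rows if age <= age_cutoff)
    return TableSummary(n_variants=len(rows), n_genes=len(genes), n_at_or_under_cutoff=under)
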