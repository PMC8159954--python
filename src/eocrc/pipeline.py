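"""End-to-end orchestration: configuration, discovery and replication runs.

A run is driven by a :class:`RunConfig` (loadable from YAML; unknown keys
are rejected so typos cannot silently disable a filter). The discovery
run executes cascade -> per-patient burden -> age trend -> recurrence ->
pathway enrichment -> candidate-gene evidence scoring and writes TSV
tables, a VCF of the prioritized variants and a Markdown summary; the
replication run executes pool detection -> prioritization -> per-gene
summary and flags variants recurrent across the two phases. Report
bodies contain no timestamps, so reruns with the same seed and
configuration are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Any, Mapping, Sequence

import yaml

from eocrc import __version__
from eocrc.cohort_stats import (
    AgeTrendResult,
    CohortPatient,
    EnrichmentRow,
    EvidenceRow,
    age_trend_test,
    pathway_enrichment,
    per_patient_burden,
    select_candidate_genes,
)
from eocrc.errors import ConfigurationError, DegenerateInputError
from eocrc.pooled_seq import (
    PoolCall,
    detect_pool_variants,
    prioritize_pool_variants,
    read_pileup_table,
)
from eocrc.prioritization import (
    CascadeConfig,
    FilterTrace,
    ImpactThresholds,
    QCThresholds,
    RarityThresholds,
    recurrence_summary,
    run_cascade,
)
from eocrc.variant_io import (
    AnnotatedVariant,
    VariantKey,
    read_callset,
    read_gene_sets,
    write_callset,
)

log = logging.getLogger("eocrc")

__all__ = ["RunConfig", "RunReport", "run_discovery", "run_replication", "load_config"]


def _dataclass_from_dict(cls, data: Mapping[str, Any], context: str):
    allowed = {f.name for f in fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ConfigurationError(f"{context}: unknown keys {sorted(unknown)}")
    return cls(**data)


@dataclass(frozen=True)
class PoolGates:
    error_rate: float = 0.001
    enma_min: float = 0.65
    maf_max: float = 0.01
    alpha: float = 1e-6


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration for a pipeline run.

    ``simulate`` holds synthetic-cohort parameters (seed defaults to the
    run seed); alternatively ``inputs`` names call-set files. Threshold
    blocks default to the study's printed values; any deviation from the
    defaults is logged at WARN.
    """

    seed: int = 0
    out_dir: str = "eocrc_out"
    log_level: str = "INFO"
    max_age_discovery: float = 50.0
    background_size: int = 19_000
    qc: QCThresholds = field(default_factory=QCThresholds)
    rarity: RarityThresholds = field(default_factory=RarityThresholds)
    impact: ImpactThresholds = field(default_factory=ImpactThresholds)
    pool: PoolGates = field(default_factory=PoolGates)
    simulate: Mapping[str, Any] | None = None
    inputs: Mapping[str, Any] | None = None
    gene_sets: str | None = None
    literature_genes: tuple[str, ...] = ()
    mucosa_genes: tuple[str, ...] = ()

    def cascade_config(self) -> CascadeConfig:
        return CascadeConfig(qc=self.qc, rarity=self.rarity, impact=self.impact)

    def config_hash(self) -> str:
        def enc(obj):
            if isinstance(obj, frozenset):
                return sorted(obj)
            return str(obj)

        payload = json.dumps(asdict(self), sort_keys=True, default=enc)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


_ALLOWED_TOP = {
    "seed",
    "out_dir",
    "log_level",
    "max_age_discovery",
    "background_size",
    "qc",
    "rarity",
    "impact",
    "pool",
    "simulate",
    "inputs",
    "gene_sets",
    "literature_genes",
    "mucosa_genes",
}


def load_config(source) -> RunConfig:
    """Build a RunConfig from a YAML file path or a plain mapping,
    validating every key before any work is done."""
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            data = yaml.safe_load(fh) or {}
    else:
        data = dict(source)
    unknown = set(data) - _ALLOWED_TOP
    if unknown:
        raise ConfigurationError(f"run config: unknown keys {sorted(unknown)}")
    kwargs: dict[str, Any] = {}
    for key, value in data.items():
        if key == "qc":
            if "strand_bias_direction" in value:
                value = {**value, "strand_bias_direction": dict(value["strand_bias_direction"])}
            if "polyphen_damaging" in value:
                raise ConfigurationError("polyphen_damaging belongs to the impact block")
            kwargs["qc"] = _dataclass_from_dict(QCThresholds, value, "qc")
        elif key == "rarity":
            kwargs["rarity"] = _dataclass_from_dict(RarityThresholds, value, "rarity")
        elif key == "impact":
            if "polyphen_damaging" in value:
                value = {**value, "polyphen_damaging": frozenset(value["polyphen_damaging"])}
            kwargs["impact"] = _dataclass_from_dict(ImpactThresholds, value, "impact")
        elif key == "pool":
            kwargs["pool"] = _dataclass_from_dict(PoolGates, value, "pool")
        elif key in ("literature_genes", "mucosa_genes"):
            kwargs[key] = tuple(value)
        else:
            kwargs[key] = value
    config = RunConfig(**kwargs)
    for block, default in (
        (config.qc, QCThresholds()),
        (config.rarity, RarityThresholds()),
        (config.impact, ImpactThresholds()),
    ):
        if block != default:
            log.warning("threshold block deviates from the study defaults: %s", block)
    return config


@dataclass
class RunReport:
    """Everything a run produced, each number traceable to one operation."""

    kind: str
    config_hash: str
    version: str
    trace: FilterTrace | None = None
    burden: list = field(default_factory=list)
    age_trends: dict[str, AgeTrendResult | None] = field(default_factory=dict)
    recurrence_variants: dict[VariantKey, int] = field(default_factory=dict)
    recurrence_genes: dict[str, int] = field(default_factory=dict)
    enrichment: list[EnrichmentRow] = field(default_factory=list)
    candidates: list[tuple[str, int, tuple[str, ...]]] = field(default_factory=list)
    pool_detections: list[PoolCall] = field(default_factory=list)
    pool_qualifying: list[PoolCall] = field(default_factory=list)
    recurrent_with_discovery: list[VariantKey] = field(default_factory=list)
    records: list[AnnotatedVariant] = field(default_factory=list)

    def to_markdown(self) -> str:
        lines = [f"# {self.kind} run", "", f"- pipeline version: {self.version}",
                 f"- config hash: {self.config_hash}", ""]
        if self.trace is not None:
            lines += ["## Prioritization trace", "", "| stage | surviving |", "| --- | --- |"]
            lines += [f"| {name} | {count} |" for name, count in self.trace.stages]
            lines.append("")
        if self.burden:
            import statistics

            med_v = statistics.median(b.n_variants for b in self.burden)
            med_a = statistics.median(b.n_alleles for b in self.burden)
            lines += [
                "## Per-patient burden",
                "",
                f"- patients: {len(self.burden)}",
                f"- median qualifying variants per patient: {med_v}",
                f"- median qualifying alleles per patient: {med_a}",
                "",
            ]
        for label, trend in self.age_trends.items():
            if trend is None:
                lines.append(f"- age trend ({label}): not testable (degenerate input)")
            else:
                slope = f", slope {trend.slope:.4f}" if trend.slope is not None else ""
                lines.append(
                    f"- age trend ({label}): {trend.method}{slope}, "
                    f"p = {trend.p_value:.4g} (n = {trend.n})"
                )
        if self.age_trends:
            lines.append("")
        if self.enrichment:
            lines += ["## Pathway over-representation", "",
                      "| set | overlap | odds ratio | p (greater) | significant |",
                      "| --- | --- | --- | --- | --- |"]
            for row in self.enrichment:
                lines.append(
                    f"| {row.gene_set.set_id} | {row.overlap} | "
                    f"{row.result.odds_ratio:.3g} | {row.result.p_greater:.4g} | "
                    f"{'yes' if row.significant else 'no'} |"
                )
            lines.append("")
        if self.candidates:
            lines += ["## Candidate genes", ""]
            for gene, score, satisfied in self.candidates[:10]:
                lines.append(f"- {gene} (score {score}): {', '.join(satisfied)}")
            if len(self.candidates) > 10:
                lines.append(f"- ... and {len(self.candidates) - 10} more (see candidates.tsv)")
            lines.append("")
        if self.pool_detections:
            lines += [
                "## Pooled-sequencing detections",
                "",
                f"- detected pool calls: {len(self.pool_detections)}",
                f"- qualifying after prioritization: {len(self.pool_qualifying)}",
                f"- genes with qualifying variants: "
                f"{len({c.pileup.annotation.gene for c in self.pool_qualifying})}",
                f"- variants recurrent with discovery: {len(self.recurrent_with_discovery)}",
                "",
            ]
        return "\n".join(lines) + "\n"


def _read_key_table(path) -> set[VariantKey]:
    keys = set()
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("chrom"):
            raise ConfigurationError(f"{path}: expected a chrom/pos/ref/alt header")
        for line in fh:
            chrom, pos, ref, alt = line.rstrip("\n").split("\t")[:4]
            keys.add(VariantKey(chrom, int(pos), ref, alt))
    return keys


def _write_key_table(keys, path) -> None:
    from eocrc.variant_io import chrom_sort_key

    with open(path, "w") as fh:
        fh.write("chrom\tpos\tref\talt\n")
        for k in sorted(keys, key=lambda k: (chrom_sort_key(k.chrom), k.pos, k.ref, k.alt)):
            fh.write(f"{k.chrom}\t{k.pos}\t{k.ref}\t{k.alt}\n")


def build_evidence(
    records: Sequence[AnnotatedVariant],
    patients: Sequence[CohortPatient],
    gene_sets=(),
    literature_genes: Sequence[str] = (),
    mucosa_genes: Sequence[str] = (),
) -> list[EvidenceRow]:
    """Derive candidate-gene evidence rows from post-cascade records.

    Loss-of-function and under-40-carrier flags are computed from the
    records; pathway membership comes from the provided gene sets, and
    literature / colonic-mucosa expression are externally curated boolean
    inputs (empty by default).
    """
    ages = {p.sample_id: p.age_at_dx for p in patients}
    kegg_genes = set().union(*(gs.genes for gs in gene_sets)) if gene_sets else set()
    by_gene: dict[str, list[AnnotatedVariant]] = {}
    for rec in records:
        if rec.gene is not None:
            by_gene.setdefault(rec.gene, []).append(rec)
    rows = []
    for gene, recs in sorted(by_gene.items()):
        rows.append(
            EvidenceRow(
                gene=gene,
                in_early_onset_literature=gene in set(literature_genes),
                in_cancer_kegg=gene in kegg_genes,
                expressed_in_colonic_mucosa=gene in set(mucosa_genes),
                carrier_under_40=any(ages.get(r.sample_id, 999) < 40 for r in recs),
                has_lof_variant=any(
                    r.annotation.exonic_class in ("stopgain", "frameshift") for r in recs
                ),
                n_candidate_variants=len({r.key for r in recs}),
            )
        )
    return rows


def _discovery_inputs(config: RunConfig):
    if config.simulate is not None:
        from eocrc.synthetic import SimulationConfig, simulate_cohort

        params = dict(config.simulate)
        params.setdefault("seed", config.seed)
        sim = simulate_cohort(_dataclass_from_dict(SimulationConfig, params, "simulate"))
        return sim.callset_a, sim.callset_b, sim.patients, sim.control_keys, sim.artifact_keys
    if config.inputs is None:
        raise ConfigurationError("a discovery run needs either 'simulate' or 'inputs'")
    inputs = dict(config.inputs)
    dialect = inputs.pop("dialect", "annotation_table")
    callset_a = read_callset(inputs.pop("callset_a"), dialect)
    callset_b = read_callset(inputs.pop("callset_b"), dialect)
    patients = []
    patients_path = inputs.pop("patients")
    with open(patients_path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            row = dict(zip(header, line.rstrip("\n").split("\t")))
            patients.append(
                CohortPatient(
                    sample_id=row["sample_id"],
                    age_at_dx=float(row["age_at_dx"]),
                    cohort=row.get("cohort", "discovery"),
                )
            )
    control_keys = _read_key_table(inputs.pop("control_keys")) if "control_keys" in inputs else set()
    artifact_keys = (
        _read_key_table(inputs.pop("artifact_keys")) if "artifact_keys" in inputs else set()
    )
    unknown = set(inputs) - {"pileups", "annotations", "discovery_keys"}
    if unknown:
        raise ConfigurationError(f"inputs: unknown keys {sorted(unknown)}")
    return callset_a, callset_b, patients, control_keys, artifact_keys


def run_discovery(config: RunConfig, out_dir=None) -> RunReport:
    """Execute the discovery-phase pipeline and write its outputs."""
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    callset_a, callset_b, patients, control_keys, artifact_keys = _discovery_inputs(config)
    patients = [p for p in patients if p.age_at_dx <= config.max_age_discovery]
    kept_ids = {p.sample_id for p in patients}
    callset_a = [r for r in callset_a if r.sample_id in kept_ids]
    callset_b = [r for r in callset_b if r.sample_id in kept_ids]

    log.info("cascade over %d + %d calls, %d patients", len(callset_a), len(callset_b),
             len(patients))
    result = run_cascade(
        callset_a, callset_b, config.cascade_config(),
        control_keys=control_keys, artifact_keys=artifact_keys,
    )
    burden = per_patient_burden(result.records, patients)
    trends: dict[str, AgeTrendResult | None] = {}
    for value in ("n_variants", "n_alleles"):
        try:
            trends[value] = age_trend_test(burden, patients, value=value)
        except DegenerateInputError:
            trends[value] = None
    carrier_counts, gene_counts = recurrence_summary(result.records)

    enrichment: list[EnrichmentRow] = []
    gene_sets = read_gene_sets(config.gene_sets) if config.gene_sets else []
    candidate_genes = sorted({r.gene for r in result.records if r.gene is not None})
    if gene_sets and candidate_genes:
        enrichment = pathway_enrichment(candidate_genes, gene_sets, config.background_size)
    evidence = build_evidence(
        result.records, patients, gene_sets, config.literature_genes, config.mucosa_genes
    )
    candidates = select_candidate_genes(evidence)

    report = RunReport(
        kind="discovery",
        config_hash=config.config_hash(),
        version=__version__,
        trace=result.trace,
        burden=burden,
        age_trends=trends,
        recurrence_variants=carrier_counts,
        recurrence_genes=gene_counts,
        enrichment=enrichment,
        candidates=candidates,
        records=result.records,
    )
    _write_discovery_outputs(report, out)
    return report


def _write_discovery_outputs(report: RunReport, out: Path) -> None:
    with open(out / "filter_trace.tsv", "w") as fh:
        fh.write("stage\tsurviving\n")
        for name, count in report.trace.stages:
            fh.write(f"{name}\t{count}\n")
    with open(out / "burden.tsv", "w") as fh:
        fh.write("sample_id\tn_variants\tn_alleles\n")
        for b in sorted(report.burden, key=lambda b: b.sample_id):
            fh.write(f"{b.sample_id}\t{b.n_variants}\t{b.n_alleles}\n")
    with open(out / "age_trend.tsv", "w") as fh:
        fh.write("value\tmethod\tstatistic\tslope\tp_value\tn\n")
        for label, t in report.age_trends.items():
            if t is None:
                fh.write(f"{label}\tNA\tNA\tNA\tNA\tNA\n")
            else:
                slope = "NA" if t.slope is None else f"{t.slope:.6g}"
                fh.write(
                    f"{label}\t{t.method}\t{t.statistic:.6g}\t{slope}\t"
                    f"{t.p_value:.6g}\t{t.n}\n"
                )
    with open(out / "candidates.tsv", "w") as fh:
        fh.write("gene\tscore\tsatisfied_criteria\n")
        for gene, score, satisfied in report.candidates:
            fh.write(f"{gene}\t{score}\t{';'.join(satisfied)}\n")
    _write_key_table({k for k in report.recurrence_variants}, out / "prioritized_keys.tsv")
    if report.records:
        write_callset(report.records, out / "prioritized.vcf", dialect="vcf_plus_info")
        write_callset(report.records, out / "prioritized.tsv", dialect="annotation_table")
    with open(out / "report.md", "w") as fh:
        fh.write(report.to_markdown())


def run_replication(
    config: RunConfig,
    discovery_keys: set[VariantKey] | None = None,
    out_dir=None,
) -> RunReport:
    """Execute the replication-phase pipeline: pool detection, the same
    prioritization rules as discovery (minus concordance), a per-gene
    summary, and recurrence flags against the discovery variants."""
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    inputs = dict(config.inputs or {})
    if discovery_keys is None and "discovery_keys" in inputs:
        discovery_keys = _read_key_table(inputs["discovery_keys"])
    discovery_keys = discovery_keys or set()

    if inputs.get("pileups") == "table2_fixture":
        from eocrc.synthetic import table2_pool_calls

        detected = table2_pool_calls()
    else:
        if "pileups" not in inputs:
            raise ConfigurationError("a replication run needs inputs.pileups")
        pileups = read_pileup_table(inputs["pileups"])
        if "annotations" in inputs:
            ann_records = read_callset(inputs["annotations"], "annotation_table")
            by_key = {r.key: r.annotation for r in ann_records}
            pileups = [
                p if p.annotation is not None else _with_annotation(p, by_key.get(p.key))
                for p in pileups
            ]
        detected = detect_pool_variants(
            pileups,
            error_rate=config.pool.error_rate,
            enma_min=config.pool.enma_min,
            maf_max=config.pool.maf_max,
            alpha=config.pool.alpha,
        )
    qualifying = prioritize_pool_variants(detected, config.rarity, config.impact)
    recurrent = sorted(
        {c.key for c in qualifying} & discovery_keys,
        key=lambda k: (k.chrom, k.pos, k.ref, k.alt),
    )
    report = RunReport(
        kind="replication",
        config_hash=config.config_hash(),
        version=__version__,
        pool_detections=list(detected),
        pool_qualifying=qualifying,
        recurrent_with_discovery=recurrent,
    )
    with open(out / "replication_variants.tsv", "w") as fh:
        fh.write("pool_id\tgene\tchrom\tpos\tref\talt\tenma\talt_fraction\trecurrent\n")
        for call in sorted(qualifying, key=lambda c: (c.pileup.pool_id, c.key.pos)):
            gene = call.pileup.annotation.gene if call.pileup.annotation else "NA"
            fh.write(
                f"{call.pileup.pool_id}\t{gene}\t{call.key.chrom}\t{call.key.pos}\t"
                f"{call.key.ref}\t{call.key.alt}\t{call.enma:.4f}\t"
                f"{call.alt_fraction:.6g}\t{int(call.key in discovery_keys)}\n"
            )
    with open(out / "report.md", "w") as fh:
        fh.write(report.to_markdown())
    return report


def _with_annotation(pileup, annotation):
    from dataclasses import replace

    return pileup if annotation is None else replace(pileup, annotation=annotation)
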