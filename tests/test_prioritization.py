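"""The prioritization cascade: QC, concordance, filters, trace bookkeeping."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eocrc.errors import DataError
from eocrc.prioritization import (
    CascadeConfig,
    FilterTrace,
    ImpactThresholds,
    QCThresholds,
    RarityThresholds,
    apply_caller_qc,
    caller_concordance,
    control_subtraction,
    functional_class_filter,
    impact_filter,
    rarity_filter,
    recurrence_summary,
    run_cascade,
)
from eocrc.variant_io import AnnotatedVariant, Annotation, VariantCall, VariantKey


def make_call(pos=100, alt="G", sample="S1", gt="het", caller="lifescope",
              depth=100, alt_reads=45, qual=60.0, sbp=0.5):
    fwd = alt_reads // 2
    return VariantCall(
        key=VariantKey("1", pos, "A", alt), sample_id=sample, genotype=gt, caller=caller,
        depth=depth, alt_reads=alt_reads, alt_fwd=fwd, alt_rev=alt_reads - fwd,
        qual=qual, strand_bias_p=sbp,
    )


def make_record(pos=100, sample="S1", gt="het", region="exonic", exonic="nonsynonymous",
                splice_offset=None, maf=None, cadd=None, dann=None, polyphen=None,
                gerp=None, gene="GENE1", alt="G", **call_over):
    return AnnotatedVariant(
        call=make_call(pos=pos, sample=sample, gt=gt, alt=alt, **call_over),
        annotation=Annotation(
            gene=gene, region_class=region, exonic_class=exonic, splice_offset=splice_offset,
            maf_ref=maf, cadd_phred=cadd, dann=dann, polyphen=polyphen, gerp_pp=gerp,
        ),
    )


class TestCallerQC:
    def test_low_depth_fails_with_reason(self):
        ok, reasons = apply_caller_qc(make_call(depth=29, alt_reads=20), QCThresholds())
        assert not ok and reasons == ["depth"]

    def test_few_alt_reads_fail(self):
        ok, reasons = apply_caller_qc(make_call(depth=100, alt_reads=3), QCThresholds())
        assert not ok and "alt_reads" in reasons and "alt_fraction" in reasons

    def test_clean_call_passes(self):
        ok, reasons = apply_caller_qc(make_call(), QCThresholds())
        assert ok and reasons == []

    def test_missing_metric_fails(self):
        call = VariantCall(key=VariantKey("1", 1, "A", "G"), sample_id="S1",
                           genotype="het", caller="gatk")
        ok, reasons = apply_caller_qc(call, QCThresholds())
        assert not ok and "missing_metric" in reasons

    def test_all_failed_rules_reported(self):
        ok, reasons = apply_caller_qc(make_call(depth=20, alt_reads=2, qual=5.0),
                                      QCThresholds())
        assert set(reasons) >= {"depth", "alt_reads", "qual"}

    def test_strand_bias_direction_per_caller(self):
        biased = make_call(sbp=0.01)
        thresholds = QCThresholds(strand_bias_direction={"other": "remove_high_p"})
        # default direction removes calls whose test says "biased" (low p)
        assert not apply_caller_qc(biased, thresholds)[0]
        unbiased_for_other = make_call(sbp=0.01, caller="other")
        assert apply_caller_qc(unbiased_for_other, thresholds)[0]
        assert not apply_caller_qc(make_call(sbp=0.9, caller="other"), thresholds)[0]


class TestConcordance:
    def test_same_variant_same_genotype_kept(self):
        a = [make_record(caller="lifescope")]
        b = [make_record(caller="gatk")]
        assert len(caller_concordance(a, b)) == 1

    def test_single_caller_variant_dropped(self):
        assert caller_concordance([make_record()], []) == []

    def test_genotype_mismatch_dropped(self):
        a = [make_record(gt="het")]
        b = [make_record(gt="hom_alt", alt_reads=100, depth=100)]
        assert caller_concordance(a, b) == []

    def test_conflicting_duplicates_are_a_data_error(self):
        a = [make_record(gt="het"), make_record(gt="hom_alt", alt_reads=100, depth=100)]
        with pytest.raises(DataError):
            caller_concordance(a, a)

    def test_annotation_taken_from_first_callset_with_warning(self):
        a = [make_record(gene="GENE_A")]
        b = [make_record(gene="GENE_B", caller="gatk")]
        with pytest.warns(UserWarning, match="annotation mismatch"):
            (kept,) = caller_concordance(a, b)
        assert kept.gene == "GENE_A"


class TestFunctionalClass:
    def test_synonymous_removed_then_regions_restricted(self):
        records = [
            make_record(pos=1, exonic="synonymous"),
            make_record(pos=2, exonic="unknown"),
            make_record(pos=3, region="intronic", exonic=None),
            make_record(pos=4, exonic="stopgain"),
            make_record(pos=5, region="splicing", exonic=None, splice_offset=1),
        ]
        non_syn, exonic_splicing = functional_class_filter(records)
        assert {r.key.pos for r in non_syn} == {3, 4, 5}
        assert {r.key.pos for r in exonic_splicing} == {4, 5}


class TestRarity:
    @pytest.mark.parametrize(
        "gt,maf,kept",
        [
            ("het", 0.002, False),   # above the 0.1% het bound
            ("hom_alt", 0.005, True),  # below the 1% hom bound
            ("het", 0.0005, True),
            ("hom_alt", 0.02, False),
            ("het", None, True),     # NA means "not observed": rare
        ],
    )
    def test_genotype_specific_bounds(self, gt, maf, kept):
        rec = make_record(gt=gt, maf=maf,
                          alt_reads=100 if gt == "hom_alt" else 45,
                          depth=100)
        assert rarity_filter(rec, RarityThresholds()) is kept


class TestImpact:
    def test_truncating_variants_qualify(self):
        assert impact_filter(make_record(exonic="stopgain"), ImpactThresholds())
        assert impact_filter(make_record(exonic="frameshift"), ImpactThresholds())

    def test_canonical_splice_site_qualifies_within_window(self):
        splice = make_record(region="splicing", exonic=None, splice_offset=2)
        deep = make_record(region="splicing", exonic=None, splice_offset=5)
        assert impact_filter(splice, ImpactThresholds())
        assert not impact_filter(deep, ImpactThresholds())

    def test_missense_predicted_damaging_by_all_three_tools(self):
        rec = make_record(polyphen="D", cadd=16.0, dann=0.996, gerp=1.0)
        assert impact_filter(rec, ImpactThresholds())

    def test_conserved_only_missense_qualifies_under_or_rule(self):
        rec = make_record(polyphen="B", cadd=10.0, dann=0.5, gerp=3.0)
        assert impact_filter(rec, ImpactThresholds(conservation_rule="or"))
        assert not impact_filter(rec, ImpactThresholds(conservation_rule="and"))

    def test_benign_everywhere_fails(self):
        rec = make_record(polyphen="B", cadd=10.0, dann=0.5, gerp=1.0)
        assert not impact_filter(rec, ImpactThresholds())

    def test_na_predictor_counts_as_non_damaging(self):
        rec = make_record(polyphen="D", cadd=20.0, dann=None, gerp=None)
        assert not impact_filter(rec, ImpactThresholds())


class TestControlSubtraction:
    def test_membership_in_either_set_removes(self):
        rec = make_record()
        assert control_subtraction([rec], {rec.key}, set()) == []
        assert control_subtraction([rec], set(), {rec.key}) == []
        assert control_subtraction([rec], set(), set()) == [rec]

    def test_removal_ignores_genotype(self):
        het = make_record(gt="het")
        hom = make_record(sample="S2", gt="hom_alt", alt_reads=100, depth=100)
        assert control_subtraction([het, hom], {het.key}) == []


class TestCascade:
    def test_empty_callsets_give_zero_trace(self):
        result = run_cascade([], [], CascadeConfig())
        assert result.records == []
        assert all(count == 0 for _, count in result.trace.stages)

    def test_trace_matches_planted_ground_truth(self, sim_cohort):
        result = run_cascade(
            sim_cohort.callset_a, sim_cohort.callset_b, CascadeConfig(),
            sim_cohort.control_keys, sim_cohort.artifact_keys,
        )
        assert result.trace.as_dict() == sim_cohort.truth.trace.as_dict()

    def test_removing_control_subtraction_never_decreases_final_count(self, sim_cohort):
        with_controls = run_cascade(
            sim_cohort.callset_a, sim_cohort.callset_b, CascadeConfig(),
            sim_cohort.control_keys, sim_cohort.artifact_keys,
        )
        without = run_cascade(sim_cohort.callset_a, sim_cohort.callset_b, CascadeConfig())
        assert without.trace.final_count >= with_controls.trace.final_count

    def test_every_dropped_record_is_attributable(self, sim_cohort):
        result = run_cascade(
            sim_cohort.callset_a, sim_cohort.callset_b, CascadeConfig(),
            sim_cohort.control_keys, sim_cohort.artifact_keys,
        )
        pieces = [result.records] + list(result.dropped.values())
        union = [(r.key, r.sample_id) for part in pieces for r in part]
        assert len(union) == len(set(union))  # disjoint
        assert set(union) == {(r.key, r.sample_id) for r in sim_cohort.callset_a}

    def test_trace_counts_non_increasing_after_concordance(self, sim_cohort):
        result = run_cascade(sim_cohort.callset_a, sim_cohort.callset_b, CascadeConfig())
        counts = [c for _, c in result.trace.stages]
        assert all(a >= b for a, b in zip(counts[1:], counts[2:]))

    def test_trace_rejects_wrong_stage_order(self):
        with pytest.raises(ValueError):
            FilterTrace(stages=[("concordant", 1), ("unique", 2)])


@st.composite
def _filterable_record(draw):
    return make_record(
        pos=draw(st.integers(1, 10_000)),
        gt=draw(st.sampled_from(["het", "hom_alt"])),
        maf=draw(st.sampled_from([None, 0.0001, 0.003, 0.02])),
        cadd=draw(st.sampled_from([None, 10.0, 20.0])),
        dann=draw(st.sampled_from([None, 0.5, 0.999])),
        polyphen=draw(st.sampled_from([None, "D", "B"])),
        gerp=draw(st.sampled_from([None, 1.0, 3.0])),
        exonic=draw(st.sampled_from(["nonsynonymous", "stopgain", "synonymous"])),
    )


class TestFilterAlgebra:
    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(record=_filterable_record())
    def test_rarity_and_impact_filters_commute(self, record):
        rarity, impact = RarityThresholds(), ImpactThresholds()
        one_way = rarity_filter(record, rarity) and impact_filter(record, impact)
        other_way = impact_filter(record, impact) and rarity_filter(record, rarity)
        assert one_way == other_way


class TestRecurrence:
    def test_variant_shared_by_discovery_and_replication_patient(self):
        tdg_key = VariantKey("12", 104_000_067, "C", "T")  # a truncating variant
        records = [
            AnnotatedVariant(
                call=VariantCall(key=tdg_key, sample_id=s, genotype="het", caller="x",
                                 depth=100, alt_reads=50, alt_fwd=25, alt_rev=25,
                                 qual=60.0, strand_bias_p=0.5),
                annotation=Annotation(gene="TDG", region_class="exonic",
                                      exonic_class="stopgain"),
            )
            for s in ("PC-018", "I-XXXX-01")
        ]
        carriers, genes = recurrence_summary(records)
        assert carriers[tdg_key] == 2
        assert genes["TDG"] == 1

    def test_singletons_have_carrier_count_one(self, sim_cohort):
        carriers, _ = recurrence_summary(sim_cohort.callset_a)
        assert set(carriers.values()) == {1}  # simulated keys are unique per patient

    def test_matches_brute_force_tally(self, sim_cohort):
        records = sim_cohort.callset_a[:200]
        carriers, genes = recurrence_summary(records)
        for key, count in carriers.items():
            assert count == len({r.sample_id for r in records if r.key == key})
        for gene, count in genes.items():
            assert count == len({r.key for r in records if r.gene == gene})
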