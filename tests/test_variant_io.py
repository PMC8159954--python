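"""Call-set and gene-set I/O: parsing, allele splitting, round trips."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eocrc.errors import CallsetFormatError, ConfigurationError
from eocrc.variant_io import (
    AnnotatedVariant,
    Annotation,
    GeneSet,
    VariantCall,
    VariantKey,
    read_callset,
    read_gene_sets,
    trim_allele_pair,
    write_callset,
    write_gene_sets,
)

HEADER = (
    "chrom\tpos\tref\talt\tsample_id\tgenotype\tcaller\tdepth\talt_reads\talt_fwd\t"
    "alt_rev\tqual\tstrand_bias_p\tgene\ttranscript\thgvs_c\thgvs_p\tregion_class\t"
    "exonic_class\tsplice_offset\tmaf_ref\tcadd_phred\tdann\tpolyphen\tgerp_pp"
)


def _row(chrom="1", pos="100", ref="A", alt="G", sample="S1", gt="het", **over):
    fields = {
        "chrom": chrom, "pos": pos, "ref": ref, "alt": alt, "sample_id": sample,
        "genotype": gt, "caller": "lifescope", "depth": "60", "alt_reads": "30",
        "alt_fwd": "15", "alt_rev": "15", "qual": "50.0", "strand_bias_p": "0.5",
        "gene": "GENE1", "transcript": "NM_1", "hgvs_c": "NA", "hgvs_p": "NA",
        "region_class": "exonic", "exonic_class": "nonsynonymous", "splice_offset": "NA",
        "maf_ref": "NA", "cadd_phred": "20.0", "dann": "0.999", "polyphen": "D",
        "gerp_pp": "3.0",
    }
    fields.update(over)
    return "\t".join(fields[c] for c in HEADER.split("\t"))


class TestVariantKey:
    def test_rejects_symbolic_and_identical_alleles(self):
        with pytest.raises(ValueError):
            VariantKey("1", 100, "A", "<DEL>")
        with pytest.raises(ValueError):
            VariantKey("1", 100, "A", "A")
        with pytest.raises(ValueError):
            VariantKey("1", 0, "A", "G")

    @pytest.mark.parametrize(
        "pos,ref,alt,expected",
        [
            (100, "A", "G", (100, "A", "G")),
            (100, "CAT", "CGT", (101, "A", "G")),  # shared prefix and suffix
            (100, "ATT", "AT", (100, "AT", "A")),  # left-aligned deletion in a run
            (100, "TAAA", "TAA", (100, "TA", "T")),
        ],
    )
    def test_parsimony_trimming(self, pos, ref, alt, expected):
        assert trim_allele_pair(pos, ref, alt) == expected


class TestAnnotationInvariants:
    def test_exonic_class_required_iff_exonic(self):
        with pytest.raises(ValueError):
            Annotation(region_class="exonic")  # missing exonic_class
        with pytest.raises(ValueError):
            Annotation(region_class="intronic", exonic_class="nonsynonymous")

    def test_dann_bounds(self):
        with pytest.raises(ValueError):
            Annotation(region_class="intronic", dann=1.2)


class TestTableDialect:
    def test_empty_file_with_header(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text(HEADER + "\n")
        assert read_callset(path) == []

    def test_multiallelic_site_splits_and_conserves_alt_count(self, tmp_path):
        path = tmp_path / "calls.tsv"
        rows = [
            _row(pos="100"),
            _row(pos="200", alt="C,T", alt_reads="10,20", alt_fwd="5,10", alt_rev="5,10",
                 exonic_class="nonsynonymous,stopgain"),
            _row(pos="300", ref="G", alt="T"),
        ]
        path.write_text(HEADER + "\n" + "\n".join(rows) + "\n")
        records = read_callset(path)
        assert len(records) == 4  # 3 rows, one of them bi-allelic
        at_200 = [r for r in records if r.key.pos == 200]
        assert {r.key.alt for r in at_200} == {"C", "T"}
        # allele splitting conserves the total alternate read count
        assert sum(r.call.alt_reads for r in at_200) == 30
        assert {r.annotation.exonic_class for r in at_200} == {"nonsynonymous", "stopgain"}

    def test_missing_fields_become_na_not_zero(self, tmp_path):
        path = tmp_path / "calls.tsv"
        path.write_text(HEADER + "\n" + _row(maf_ref="NA", cadd_phred=".") + "\n")
        (rec,) = read_callset(path)
        assert rec.annotation.maf_ref is None
        assert rec.annotation.cadd_phred is None

    def test_malformed_row_names_file_line_and_field(self, tmp_path):
        path = tmp_path / "calls.tsv"
        path.write_text(HEADER + "\n" + _row(pos="not-a-number") + "\n")
        with pytest.raises(CallsetFormatError) as err:
            read_callset(path)
        message = str(err.value)
        assert "calls.tsv" in message and ":2:" in message and "pos" in message

    def test_unknown_dialect_is_configuration_error(self, tmp_path):
        path = tmp_path / "calls.tsv"
        path.write_text(HEADER + "\n")
        with pytest.raises(ConfigurationError):
            read_callset(path, dialect="maf_table")

    def test_column_map_remaps_annovar_style_names(self, tmp_path):
        header = HEADER.replace("chrom", "Chr").replace("\tpos\t", "\tStart\t")
        path = tmp_path / "annovar.tsv"
        path.write_text(header + "\n" + _row() + "\n")
        (rec,) = read_callset(path, column_map={"chrom": "Chr", "pos": "Start"})
        assert rec.key == VariantKey("1", 100, "A", "G")


def _records_strategy():
    """Distinct-key records with VCF-safe numeric precision."""

    @st.composite
    def records(draw):
        n = draw(st.integers(1, 12))
        out = []
        for i in range(n):
            ref, alt = draw(st.sampled_from([("A", "G"), ("C", "T"), ("G", "A"), ("AT", "A")]))
            depth = draw(st.integers(30, 500))
            alt_reads = draw(st.integers(0, depth))
            fwd = draw(st.integers(0, alt_reads))
            region = draw(st.sampled_from(["exonic", "splicing", "intronic"]))
            exonic = (
                draw(st.sampled_from(["nonsynonymous", "stopgain", "synonymous"]))
                if region == "exonic"
                else None
            )
            call = VariantCall(
                key=VariantKey(draw(st.sampled_from(["1", "2", "X"])), 1000 + i, ref, alt),
                sample_id=draw(st.sampled_from(["S1", "S2", "S3"])),
                genotype=draw(st.sampled_from(["het", "hom_alt"])),
                caller=draw(st.sampled_from(["lifescope", "gatk"])),
                depth=depth,
                alt_reads=alt_reads,
                alt_fwd=fwd,
                alt_rev=alt_reads - fwd,
                qual=draw(st.integers(0, 9999)) / 100,
                strand_bias_p=draw(st.integers(0, 10000)) / 10000,
            )
            ann = Annotation(
                gene=draw(st.sampled_from(["BRCA1", "TDG", None])),
                region_class=region,
                exonic_class=exonic,
                splice_offset=draw(st.sampled_from([None, -2, 1])) if region == "splicing" else None,
                maf_ref=draw(st.sampled_from([None, 0.001, 0.05])),
                cadd_phred=draw(st.sampled_from([None, 12.5, 22.75])),
                dann=draw(st.sampled_from([None, 0.5, 0.9995])),
                polyphen=draw(st.sampled_from([None, "D", "P", "B"])),
                gerp_pp=draw(st.sampled_from([None, -1.5, 4.25])),
            )
            out.append(AnnotatedVariant(call, ann))
        return out

    return records()


class TestRoundTrip:
    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(records=_records_strategy())
    def test_table_round_trip_is_identity(self, records, tmp_path_factory):
        path = tmp_path_factory.mktemp("io") / "rt.tsv"
        write_callset(records, path)
        back = read_callset(path)
        assert sorted(back, key=repr) == sorted(records, key=repr)

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(records=_records_strategy())
    def test_vcf_round_trip_is_identity(self, records, tmp_path_factory):
        # one record per (key, sample): the VCF writer merges samples per site
        unique = {}
        for rec in records:
            unique.setdefault((rec.key, rec.sample_id), rec)
        records = list(unique.values())
        path = tmp_path_factory.mktemp("io") / "rt.vcf"
        write_callset(records, path, dialect="vcf_plus_info")
        back = read_callset(path, dialect="vcf_plus_info")
        assert sorted(back, key=repr) == sorted(records, key=repr)

    def test_write_is_deterministic(self, tmp_path, sim_cohort):
        a, b = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_callset(sim_cohort.callset_a, a)
        write_callset(list(reversed(sim_cohort.callset_a)), b)
        assert a.read_bytes() == b.read_bytes()

    def test_empty_write_produces_header_only(self, tmp_path):
        path = tmp_path / "empty.tsv"
        write_callset([], path)
        assert path.read_text() == HEADER + "\n"


KEGG_18 = [
    "hsa04310", "hsa04350", "hsa03430", "hsa03410", "hsa03420", "hsa03440",
    "map03450", "hsa03460", "hsa05200", "hsa04210", "hsa04514", "hsa05210",
    "hsa03030", "hsa04390", "hsa04010", "hsa05206", "hsa04151", "hsa03320",
]


class TestGeneSets:
    def test_single_line(self, tmp_path):
        path = tmp_path / "sets.gmt"
        path.write_text("hsa05210\tColorectal cancer\tA\tB\tC\n")
        (gs,) = read_gene_sets(path)
        assert gs.set_id == "hsa05210" and gs.genes == {"A", "B", "C"}

    def test_duplicate_members_collapse(self, tmp_path):
        path = tmp_path / "sets.gmt"
        path.write_text("s1\tdesc\tA\tA\tB\n")
        (gs,) = read_gene_sets(path)
        assert len(gs) == 2

    def test_short_line_is_parse_error(self, tmp_path):
        path = tmp_path / "sets.gmt"
        path.write_text("s1\tdesc-without-genes\n")
        with pytest.raises(CallsetFormatError):
            read_gene_sets(path)

    def test_eighteen_pathway_fixture_round_trips(self, tmp_path):
        sets = [
            GeneSet(set_id=sid, name=f"pathway {i}", genes=frozenset({f"G{i}A", f"G{i}B"}))
            for i, sid in enumerate(KEGG_18)
        ]
        path = tmp_path / "kegg.gmt"
        write_gene_sets(sets, path)
        back = read_gene_sets(path)
        assert len(back) == 18
        assert [gs.set_id for gs in back] == KEGG_18
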