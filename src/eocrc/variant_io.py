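"""Reading and writing of call sets, annotations and gene sets.

Two call-set dialects are supported:

``annotation_table``
    A tab-separated table with one row per called variant per patient,
    carrying the caller QC metrics alongside functional, frequency and
    in-silico predictor annotations (ANNOVAR-style; column names can be
    remapped through a configurable mapping, e.g. loaded from YAML).

``vcf_plus_info``
    VCF 4.2 with site-level annotations in INFO and per-sample QC metrics
    in FORMAT, read and written through :mod:`pysam`.

Coordinates are 1-based and fully closed, matching VCF. Multi-allelic
sites are split into one record per alternate allele on ingest, and
indel alleles are parsimony-trimmed (shared suffix, then shared prefix)
so that equivalent representations compare equal. Missing annotation
values are kept as ``None`` (NA), never coerced to 0: downstream, an NA
population frequency means "not observed" and passes rarity filters.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from eocrc.errors import CallsetFormatError, ConfigurationError

__all__ = [
    "VariantKey",
    "VariantCall",
    "Annotation",
    "AnnotatedVariant",
    "GeneSet",
    "GENOTYPES",
    "REGION_CLASSES",
    "EXONIC_CLASSES",
    "read_callset",
    "write_callset",
    "read_gene_sets",
    "chrom_sort_key",
    "record_sort_key",
]

_VALID_BASES = frozenset("ACGT")
GENOTYPES = ("het", "hom_alt")
REGION_CLASSES = ("exonic", "splicing", "intronic", "intergenic", "UTR", "unknown")
EXONIC_CLASSES = (
    "synonymous",
    "nonsynonymous",
    "stopgain",
    "stoploss",
    "frameshift",
    "nonframeshift_indel",
    "unknown",
)

#: canonical column order of the annotation_table dialect
TABLE_COLUMNS = (
    "chrom",
    "pos",
    "ref",
    "alt",
    "sample_id",
    "genotype",
    "caller",
    "depth",
    "alt_reads",
    "alt_fwd",
    "alt_rev",
    "qual",
    "strand_bias_p",
    "gene",
    "transcript",
    "hgvs_c",
    "hgvs_p",
    "region_class",
    "exonic_class",
    "splice_offset",
    "maf_ref",
    "cadd_phred",
    "dann",
    "polyphen",
    "gerp_pp",
)

_NA_STRINGS = frozenset({"", ".", "NA", "na", "nan", "None"})

# fields whose value is allele-specific and may be comma-separated on a
# multi-allelic table row
_PER_ALT_FIELDS = (
    "alt_reads",
    "alt_fwd",
    "alt_rev",
    "hgvs_c",
    "hgvs_p",
    "exonic_class",
    "maf_ref",
    "cadd_phred",
    "dann",
    "polyphen",
    "gerp_pp",
)


def trim_allele_pair(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Parsimony-trim an allele pair: drop the shared suffix, then the
    shared prefix (keeping at least one base of each allele), adjusting
    the 1-based position for trimmed leading bases.

    This left-aligns the common padded representations of indels without
    needing the reference sequence.
    """
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


@dataclass(frozen=True, order=True)
class VariantKey:
    """Identity of a called variant: chromosome, 1-based position and the
    reference/alternate allele pair. Used for concordance matching,
    control subtraction and recurrence counting."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        for name, allele in (("ref", self.ref), ("alt", self.alt)):
            if not allele or not set(allele) <= _VALID_BASES:
                raise ValueError(
                    f"{name} allele {allele!r} is not a non-empty A/C/G/T string "
                    "(symbolic alleles are rejected)"
                )
        if self.ref == self.alt:
            raise ValueError(f"ref and alt alleles are identical ({self.ref!r})")

    @classmethod
    def normalized(cls, chrom: str, pos: int, ref: str, alt: str) -> "VariantKey":
        """Build a key with parsimony-trimmed alleles."""
        pos, ref, alt = trim_allele_pair(pos, ref, alt)
        return cls(chrom, pos, ref, alt)

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1


@dataclass(frozen=True)
class VariantCall:
    """One variant called in one patient by one caller, with QC metrics.

    ``None`` marks a metric the caller did not report; QC rules that need
    it will fail the call with reason ``missing_metric``. Ploidy is fixed
    at 2; hemizygous calls are ingested as ``hom_alt``.
    """

    key: VariantKey
    sample_id: str
    genotype: str
    caller: str
    depth: int | None = None
    alt_reads: int | None = None
    alt_fwd: int | None = None
    alt_rev: int | None = None
    qual: float | None = None
    strand_bias_p: float | None = None

    def __post_init__(self):
        if self.genotype not in GENOTYPES:
            raise ValueError(f"genotype must be one of {GENOTYPES}, got {self.genotype!r}")
        if self.depth is not None and self.depth < 0:
            raise ValueError("depth must be >= 0")
        if self.qual is not None and self.qual < 0:
            raise ValueError("qual must be >= 0")
        if (
            self.alt_reads is not None
            and self.depth is not None
            and self.alt_reads > self.depth
        ):
            raise ValueError(f"alt_reads {self.alt_reads} exceeds depth {self.depth}")
        if (
            self.alt_fwd is not None
            and self.alt_rev is not None
            and self.alt_reads is not None
            and self.alt_fwd + self.alt_rev != self.alt_reads
        ):
            raise ValueError("alt_fwd + alt_rev must equal alt_reads")
        if self.strand_bias_p is not None and not 0.0 <= self.strand_bias_p <= 1.0:
            raise ValueError("strand_bias_p must lie in [0, 1]")

    @property
    def alt_fraction(self) -> float | None:
        if self.depth in (None, 0) or self.alt_reads is None:
            return None
        return self.alt_reads / self.depth


@dataclass(frozen=True)
class Annotation:
    """Functional, frequency and in-silico predictor annotations.

    ``exonic_class`` must be set exactly when ``region_class`` is
    ``exonic``; ``splice_offset`` is the signed distance to the nearest
    exon boundary and is only meaningful for splicing variants.
    """

    gene: str | None = None
    transcript: str | None = None
    hgvs_c: str | None = None
    hgvs_p: str | None = None
    region_class: str = "unknown"
    exonic_class: str | None = None
    splice_offset: int | None = None
    maf_ref: float | None = None
    cadd_phred: float | None = None
    dann: float | None = None
    polyphen: str | None = None
    gerp_pp: float | None = None

    def __post_init__(self):
        if self.region_class not in REGION_CLASSES:
            raise ValueError(f"unknown region_class {self.region_class!r}")
        if self.region_class == "exonic":
            if self.exonic_class is None:
                raise ValueError("exonic variants require an exonic_class")
            if self.exonic_class not in EXONIC_CLASSES:
                raise ValueError(f"unknown exonic_class {self.exonic_class!r}")
        elif self.exonic_class is not None:
            raise ValueError("exonic_class must be NA unless region_class is exonic")
        if self.dann is not None and not 0.0 <= self.dann <= 1.0:
            raise ValueError("DANN score must lie in [0, 1]")
        if self.maf_ref is not None and not 0.0 <= self.maf_ref <= 1.0:
            raise ValueError("maf_ref must lie in [0, 1]")
        if self.polyphen is not None and self.polyphen not in ("D", "P", "B"):
            raise ValueError(f"polyphen must be D, P, B or NA, got {self.polyphen!r}")


@dataclass(frozen=True)
class AnnotatedVariant:
    """A variant call paired with its annotations."""

    call: VariantCall
    annotation: Annotation

    @property
    def key(self) -> VariantKey:
        return self.call.key

    @property
    def sample_id(self) -> str:
        return self.call.sample_id

    @property
    def genotype(self) -> str:
        return self.call.genotype

    @property
    def gene(self) -> str | None:
        return self.annotation.gene


@dataclass(frozen=True)
class GeneSet:
    """A named gene set (e.g. one KEGG pathway) read from GMT."""

    set_id: str
    name: str
    genes: frozenset[str]

    def __post_init__(self):
        if not self.genes:
            raise ValueError(f"gene set {self.set_id} is empty")

    def __len__(self) -> int:
        return len(self.genes)


# ---------------------------------------------------------------------------
# sorting helpers


def chrom_sort_key(chrom: str) -> tuple[int, int | str]:
    """Natural chromosome ordering: 1..22, X, Y, MT, then lexicographic."""
    c = chrom[3:] if chrom.lower().startswith("chr") else chrom
    if c.isdigit():
        return (0, int(c))
    special = {"X": 23, "Y": 24, "MT": 25, "M": 25}
    if c.upper() in special:
        return (0, special[c.upper()])
    return (1, c)


def record_sort_key(rec: AnnotatedVariant):
    k = rec.call.key
    return (chrom_sort_key(k.chrom), k.pos, k.ref, k.alt, rec.call.sample_id)


# ---------------------------------------------------------------------------
# annotation_table dialect


def _na(value: str) -> str | None:
    return None if value is None or value.strip() in _NA_STRINGS else value.strip()


def _parse_typed(raw: str | None, typ, path, lineno, field):
    if raw is None:
        return None
    try:
        return typ(raw)
    except (TypeError, ValueError) as exc:
        raise CallsetFormatError(path, lineno, field, f"cannot parse {raw!r}") from exc


def _split_per_alt(raw: str | None, n_alts: int, path, lineno, field) -> list[str | None]:
    """Expand a possibly comma-separated per-allele value to one entry per
    alternate allele; a single value is shared by all alleles."""
    if raw is None:
        return [None] * n_alts
    parts = raw.split(",")
    if len(parts) == n_alts:
        return [_na(p) for p in parts]
    if len(parts) == 1:
        return [_na(raw)] * n_alts
    raise CallsetFormatError(
        path, lineno, field, f"{len(parts)} values for {n_alts} alternate alleles"
    )


def _row_to_records(row: dict, path, lineno) -> list[AnnotatedVariant]:
    alts = [a.strip() for a in row["alt"].split(",") if a.strip()]
    if not alts:
        raise CallsetFormatError(path, lineno, "alt", "no alternate allele")
    per_alt = {
        f: _split_per_alt(_na(row.get(f)), len(alts), path, lineno, f)
        for f in _PER_ALT_FIELDS
    }
    records = []
    for i, alt in enumerate(alts):
        try:
            key = VariantKey.normalized(
                row["chrom"].strip(),
                _parse_typed(_na(row["pos"]), int, path, lineno, "pos"),
                row["ref"].strip(),
                alt,
            )
            call = VariantCall(
                key=key,
                sample_id=row["sample_id"].strip(),
                genotype=row["genotype"].strip(),
                caller=row["caller"].strip(),
                depth=_parse_typed(_na(row.get("depth")), int, path, lineno, "depth"),
                alt_reads=_parse_typed(per_alt["alt_reads"][i], int, path, lineno, "alt_reads"),
                alt_fwd=_parse_typed(per_alt["alt_fwd"][i], int, path, lineno, "alt_fwd"),
                alt_rev=_parse_typed(per_alt["alt_rev"][i], int, path, lineno, "alt_rev"),
                qual=_parse_typed(_na(row.get("qual")), float, path, lineno, "qual"),
                strand_bias_p=_parse_typed(
                    _na(row.get("strand_bias_p")), float, path, lineno, "strand_bias_p"
                ),
            )
            ann = Annotation(
                gene=_na(row.get("gene")),
                transcript=_na(row.get("transcript")),
                hgvs_c=per_alt["hgvs_c"][i],
                hgvs_p=per_alt["hgvs_p"][i],
                region_class=_na(row.get("region_class")) or "unknown",
                exonic_class=per_alt["exonic_class"][i],
                splice_offset=_parse_typed(
                    _na(row.get("splice_offset")), int, path, lineno, "splice_offset"
                ),
                maf_ref=_parse_typed(per_alt["maf_ref"][i], float, path, lineno, "maf_ref"),
                cadd_phred=_parse_typed(
                    per_alt["cadd_phred"][i], float, path, lineno, "cadd_phred"
                ),
                dann=_parse_typed(per_alt["dann"][i], float, path, lineno, "dann"),
                polyphen=per_alt["polyphen"][i],
                gerp_pp=_parse_typed(per_alt["gerp_pp"][i], float, path, lineno, "gerp_pp"),
            )
        except CallsetFormatError:
            raise
        except (KeyError, ValueError) as exc:
            raise CallsetFormatError(path, lineno, "row", str(exc)) from exc
        records.append(AnnotatedVariant(call, ann))
    return records


def _read_table(path: Path, column_map: Mapping[str, str] | None) -> list[AnnotatedVariant]:
    records: list[AnnotatedVariant] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            return []
        if column_map:
            # column_map: canonical name -> name used in the file
            inverse = {v: k for k, v in column_map.items()}
            reader.fieldnames = [inverse.get(c, c) for c in reader.fieldnames]
        missing = {"chrom", "pos", "ref", "alt", "sample_id", "genotype", "caller"} - set(
            reader.fieldnames
        )
        if missing:
            raise CallsetFormatError(
                path, 1, ",".join(sorted(missing)), "required column(s) missing from header"
            )
        for lineno, row in enumerate(reader, start=2):
            records.extend(_row_to_records(row, path, lineno))
    return records


def _format_value(value) -> str:
    if value is None:
        return "NA"
    if isinstance(value, float):
        return repr(value)
    return str(value)


def _write_table(records: Sequence[AnnotatedVariant], path: Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(TABLE_COLUMNS)
        for rec in sorted(records, key=record_sort_key):
            c, a = rec.call, rec.annotation
            writer.writerow(
                [
                    _format_value(v)
                    for v in (
                        c.key.chrom,
                        c.key.pos,
                        c.key.ref,
                        c.key.alt,
                        c.sample_id,
                        c.genotype,
                        c.caller,
                        c.depth,
                        c.alt_reads,
                        c.alt_fwd,
                        c.alt_rev,
                        c.qual,
                        c.strand_bias_p,
                        a.gene,
                        a.transcript,
                        a.hgvs_c,
                        a.hgvs_p,
                        a.region_class,
                        a.exonic_class,
                        a.splice_offset,
                        a.maf_ref,
                        a.cadd_phred,
                        a.dann,
                        a.polyphen,
                        a.gerp_pp,
                    )
                ]
            )


# ---------------------------------------------------------------------------
# vcf_plus_info dialect (pysam)

_INFO_FIELDS = [
    ("GENE", "1", "String", "Gene symbol"),
    ("TRANSCRIPT", "1", "String", "Transcript accession"),
    ("REGION", "1", "String", "Region class"),
    ("SPLICE_OFFSET", "1", "Integer", "Signed distance to nearest exon boundary"),
    ("HGVSC", "A", "String", "HGVS coding description"),
    ("HGVSP", "A", "String", "HGVS protein description"),
    ("EXONIC", "A", "String", "Exonic functional class"),
    ("MAF", "A", "Float", "Reference-population minor allele frequency"),
    ("CADD", "A", "Float", "CADD phred score"),
    ("DANN", "A", "Float", "DANN score"),
    ("POLYPHEN", "A", "String", "PolyPhen-2 category (D/P/B)"),
    ("GERP", "A", "Float", "GERP++ conservation score"),
]

_FORMAT_FIELDS = [
    ("GT", "1", "String", "Genotype"),
    ("DP", "1", "Integer", "Total read depth"),
    ("AD", "R", "Integer", "Allelic read depths"),
    ("ADF", "R", "Integer", "Allelic forward-strand depths"),
    ("ADR", "R", "Integer", "Allelic reverse-strand depths"),
    ("VQ", "1", "Float", "Per-call caller quality"),
    ("SB", "1", "Float", "Strand-bias test p-value"),
    ("CL", "1", "String", "Caller identifier"),
]


def _vcf_na(value):
    return None if value in (None, ".", "") else value


def _f32(value):
    """Undo float32 storage: VCF floats are carried at 6 significant digits."""
    return None if value is None else float(f"{value:.6g}")


def _read_vcf(path: Path) -> list[AnnotatedVariant]:
    import pysam

    records: list[AnnotatedVariant] = []
    with pysam.VariantFile(str(path)) as vcf:
        for site in vcf:
            alts = site.alts or ()
            info = site.info

            def per_alt(tag, i, cast=None):
                raw = info.get(tag)
                if raw is None:
                    return None
                if isinstance(raw, tuple):
                    raw = raw[i] if i < len(raw) else None
                raw = _vcf_na(raw)
                if raw is None:
                    return None
                return cast(raw) if cast else raw

            for sample_name, sample in site.samples.items():
                gt = tuple(a for a in (sample.get("GT") or ()) if a is not None)
                alt_indices = sorted({a for a in gt if a and a >= 1})
                if not alt_indices:
                    continue
                for ai in alt_indices:
                    alt = alts[ai - 1]
                    n_copies = sum(1 for a in gt if a == ai)
                    genotype = "hom_alt" if n_copies >= max(len(gt), 2) else "het"
                    ad = sample.get("AD")
                    adf = sample.get("ADF")
                    adr = sample.get("ADR")

                    def allele_depth(arr):
                        if arr is None or ai >= len(arr):
                            return None
                        return _vcf_na(arr[ai])

                    key = VariantKey.normalized(site.chrom, site.pos, site.ref, alt)
                    vq = _vcf_na(sample.get("VQ"))
                    sb = _vcf_na(sample.get("SB"))
                    call = VariantCall(
                        key=key,
                        sample_id=sample_name,
                        genotype=genotype,
                        caller=_vcf_na(sample.get("CL")) or "unknown",
                        depth=_vcf_na(sample.get("DP")),
                        alt_reads=allele_depth(ad),
                        alt_fwd=allele_depth(adf),
                        alt_rev=allele_depth(adr),
                        qual=_f32(vq),
                        strand_bias_p=_f32(sb),
                    )
                    i = ai - 1
                    so = _vcf_na(info.get("SPLICE_OFFSET"))
                    ann = Annotation(
                        gene=_vcf_na(info.get("GENE")),
                        transcript=_vcf_na(info.get("TRANSCRIPT")),
                        hgvs_c=per_alt("HGVSC", i),
                        hgvs_p=per_alt("HGVSP", i),
                        region_class=_vcf_na(info.get("REGION")) or "unknown",
                        exonic_class=per_alt("EXONIC", i),
                        splice_offset=int(so) if so is not None else None,
                        maf_ref=_f32(per_alt("MAF", i, float)),
                        cadd_phred=_f32(per_alt("CADD", i, float)),
                        dann=_f32(per_alt("DANN", i, float)),
                        polyphen=per_alt("POLYPHEN", i),
                        gerp_pp=_f32(per_alt("GERP", i, float)),
                    )
                    records.append(AnnotatedVariant(call, ann))
    return records


def _write_vcf(records: Sequence[AnnotatedVariant], path: Path) -> None:
    import pysam

    header = pysam.VariantHeader()
    contigs = sorted({r.key.chrom for r in records}, key=chrom_sort_key)
    for contig in contigs:
        header.contigs.add(contig)
    for name, number, typ, desc in _INFO_FIELDS:
        header.info.add(name, number, typ, desc)
    for name, number, typ, desc in _FORMAT_FIELDS:
        header.formats.add(name, number, typ, desc)
    samples = sorted({r.sample_id for r in records})
    for s in samples:
        header.add_sample(s)

    by_key: dict[VariantKey, list[AnnotatedVariant]] = {}
    for rec in sorted(records, key=record_sort_key):
        by_key.setdefault(rec.key, []).append(rec)

    with pysam.VariantFile(str(path), "w", header=header) as out:
        for key, recs in by_key.items():
            site = out.new_record(
                contig=key.chrom, start=key.pos - 1, alleles=(key.ref, key.alt)
            )
            ann = recs[0].annotation
            if ann.gene is not None:
                site.info["GENE"] = ann.gene
            if ann.transcript is not None:
                site.info["TRANSCRIPT"] = ann.transcript
            site.info["REGION"] = ann.region_class
            if ann.splice_offset is not None:
                site.info["SPLICE_OFFSET"] = ann.splice_offset
            for tag, value in (
                ("HGVSC", ann.hgvs_c),
                ("HGVSP", ann.hgvs_p),
                ("EXONIC", ann.exonic_class),
                ("MAF", ann.maf_ref),
                ("CADD", ann.cadd_phred),
                ("DANN", ann.dann),
                ("POLYPHEN", ann.polyphen),
                ("GERP", ann.gerp_pp),
            ):
                if value is not None:
                    site.info[tag] = (value,)
            for rec in recs:
                c = rec.call
                fmt = site.samples[c.sample_id]
                fmt["GT"] = (1, 1) if c.genotype == "hom_alt" else (0, 1)
                if c.depth is not None:
                    fmt["DP"] = c.depth
                if c.alt_reads is not None:
                    fmt["AD"] = (max((c.depth or 0) - c.alt_reads, 0), c.alt_reads)
                if c.alt_fwd is not None and c.alt_rev is not None:
                    fmt["ADF"] = (0, c.alt_fwd)
                    fmt["ADR"] = (0, c.alt_rev)
                if c.qual is not None:
                    fmt["VQ"] = c.qual
                if c.strand_bias_p is not None:
                    fmt["SB"] = c.strand_bias_p
                fmt["CL"] = c.caller
            out.write(site)


# ---------------------------------------------------------------------------
# public API

DIALECTS = ("annotation_table", "vcf_plus_info")


def read_callset(
    path, dialect: str = "annotation_table", column_map: Mapping[str, str] | None = None
) -> list[AnnotatedVariant]:
    """Read a call set into a list of :class:`AnnotatedVariant`.

    Parameters
    ----------
    path
        Input file.
    dialect
        ``annotation_table`` (TSV) or ``vcf_plus_info`` (VCF 4.2).
    column_map
        For the table dialect: mapping from canonical column names to the
        names used in the file (e.g. loaded from a YAML dialect config).

    Multi-allelic rows are split into one record per alternate allele;
    missing annotation fields become NA (``None``), never 0.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "annotation_table":
        return _read_table(path, column_map)
    if dialect == "vcf_plus_info":
        return _read_vcf(path)
    raise ConfigurationError(f"unknown call-set dialect {dialect!r}; expected one of {DIALECTS}")


def write_callset(
    records: Iterable[AnnotatedVariant], path, dialect: str = "annotation_table"
) -> None:
    """Write records in deterministic (chrom, pos, ref, alt, sample) order.

    The output is byte-identical across runs for the same record set and
    round-trips through :func:`read_callset`.
    """
    records = list(records)
    path = Path(path)
    if dialect == "annotation_table":
        _write_table(records, path)
    elif dialect == "vcf_plus_info":
        _write_vcf(records, path)
    else:
        raise ConfigurationError(
            f"unknown call-set dialect {dialect!r}; expected one of {DIALECTS}"
        )


def read_gene_sets(path) -> list[GeneSet]:
    """Read gene sets from a GMT file (set id, description, member genes).

    Duplicate members within a set are collapsed; a line with fewer than
    three fields (hence an empty set) is a parse error.
    """
    path = Path(path)
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise CallsetFormatError(
                    path, lineno, "line", f"expected >= 3 tab-separated fields, got {len(fields)}"
                )
            genes = frozenset(g.strip() for g in fields[2:] if g.strip())
            if not genes:
                raise CallsetFormatError(path, lineno, "genes", "gene set has no members")
            sets.append(GeneSet(set_id=fields[0].strip(), name=fields[1].strip(), genes=genes))
    return sets


def write_gene_sets(sets: Iterable[GeneSet], path) -> None:
    """Write gene sets in GMT format with members sorted alphabetically."""
    with open(path, "w") as fh:
        for gs in sets:
            fh.write("\t".join([gs.set_id, gs.name, *sorted(gs.genes)]) + "\n")


def strip_annotation(record: AnnotatedVariant) -> AnnotatedVariant:
    """Return the record with a blank annotation (used when a caller's raw
    output carries no annotations of its own)."""
    return replace(record, annotation=Annotation())
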