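"""Published candidate-gene tables of the study, as machine-readable data.

Three small tables are packaged:

* ``TABLE1`` — the eight discovery-phase candidate genes selected for
  replication, with their variants, carrier patients and the boolean
  relevance criteria behind their selection.
* ``TABLE2`` — the thirteen rare high-impact variants found in six of
  the eight genes by pooled-DNA resequencing of the replication cohort,
  with carrier ages at diagnosis.
* ``TABLE3`` — the twenty-one rare high-impact germline variants found
  in five of the eight genes in an external tumour-sequencing cohort,
  with ages at diagnosis.
* ``CASE_CONTROL_COUNTS`` — published carrier counts for the one gene showing
  case-control enrichment in an independent early-onset series
  (8 carriers of 1006 cases vs 4 of 1609 controls).

The expressed-in-colonic-mucosa flag in TABLE1 reflects a selection
criterion stated for the candidate list as a whole rather than printed
per gene; it is set for all eight genes.
"""

from __future__ import annotations

from eocrc.cohort_stats import EvidenceRow

__all__ = ["TABLE1", "TABLE1_EVIDENCE", "TABLE2", "TABLE3", "CASE_CONTROL_COUNTS"]

# gene, variant description, carrier patients, evidence flags
# (in_early_onset_literature, in_cancer_kegg, expressed_in_colonic_mucosa,
#  carrier_under_40, has_lof_variant)
TABLE1 = (
    ("CHAD", "NM_001267:c.1049C>T:p.(T350I)", ("PC-005", "PC-015"),
     (True, True, True, True, False)),
    ("CHD1L", "NM_004284:c.2398delT:p.(L800X)", ("PC-012",),
     (True, False, True, False, True)),
    ("ERCC6", "NM_000124:c.3437_3438insAAG:p.(S1146delinsRS)", ("PC-013",),
     (True, True, True, False, True)),
    ("ITGB7", "NM_000889:c.1063_1066del:p.(V355fs)", ("PC-008",),
     (True, True, True, False, True)),
    ("PTPN13", "NM_080685:c.4258+2T>C", ("PC-008",),
     (False, True, True, False, False)),
    ("SPATA20", "NM_022827:c.151C>T:p.(R51X)", ("PC-015",),
     (True, False, True, True, True)),
    ("TDG", "NM_003211:c.67C>T:p.(Q23X)", ("PC-018",),
     (True, True, True, False, True)),
    ("TGS1", "NM_024831:c.439_444del:p.(147_148del)", ("PC-017",),
     (True, True, True, False, False)),
)

TABLE1_EVIDENCE = tuple(
    EvidenceRow(
        gene=gene,
        in_early_onset_literature=flags[0],
        in_cancer_kegg=flags[1],
        expressed_in_colonic_mucosa=flags[2],
        carrier_under_40=flags[3],
        has_lof_variant=flags[4],
        n_candidate_variants=1,
    )
    for gene, _, _, flags in TABLE1
)

# gene, variant description, consequence class, ages at diagnosis
# (the first variant was found in two patients)
TABLE2 = (
    ("CHAD", "NM_001267:c.735C>A:p.(Y245X)", "stopgain", (37, 41)),
    ("CHD1L", "NM_004284:c.607G>A:p.(G203R)", "nonsynonymous", (50,)),
    ("CHD1L", "NM_004284:c.2273G>A:p.(R758Q)", "nonsynonymous", (50,)),
    ("CHD1L", "NM_004284:c.2320G>A:p.(D774N)", "nonsynonymous", (39,)),
    ("CHD1L", "NM_004284:c.263T>G:p.(L88W)", "nonsynonymous", (45,)),
    ("PTPN13", "NM_080685:c.1916G>A:p.(G639E)", "nonsynonymous", (49,)),
    ("PTPN13", "NM_080685:c.2015A>G:p.(H672R)", "nonsynonymous", (50,)),
    ("PTPN13", "NM_080685:c.5837G>A:p.(G1946E)", "nonsynonymous", (34,)),
    ("SPATA20", "NM_022827:c.1177G>A:p.(G393R)", "nonsynonymous", (46,)),
    ("SPATA20", "NM_022827:c.1426C>T:p.(R476W)", "nonsynonymous", (38,)),
    ("TDG", "NM_003211:c.67C>T:p.(Q23X)", "stopgain", (49,)),
    ("TDG", "NM_003211:c.1175T>G:p.(I392S)", "nonsynonymous", (43,)),
    ("TGS1", "NM_024831:c.107G>A:p.(R36Q)", "nonsynonymous", (42,)),
)

# gene, protein change, age at diagnosis (external tumour cohort)
TABLE3 = (
    ("CHD1L", "NM_004284:p.(M383I)", 66),
    ("CHD1L", "NM_004284:p.(R468W)", 49),
    ("ERCC6", "NM_000124:p.(L224F)", 70),
    ("ERCC6", "NM_000124:p.(G601S)", 46),
    ("ERCC6", "NM_000124:p.(R683Q)", 50),
    ("ERCC6", "NM_000124:p.(F1437I)", 43),
    ("ITGB7", "NM_000889:p.(Y753C)", 60),
    ("ITGB7", "NM_000889:p.(Y758fs)", 76),
    ("PTPN13", "NM_080685:p.(S348T)", 75),
    ("PTPN13", "NM_080685:p.(F724L)", 89),
    ("PTPN13", "NM_080685:p.(R782X)", 60),
    ("PTPN13", "NM_080685:p.(R817C)", 74),
    ("PTPN13", "NM_080685:p.(E1047G)", 68),
    ("PTPN13", "NM_080685:p.(T1383M)", 47),
    ("PTPN13", "NM_080685:p.(G1420R)", 74),
    ("PTPN13", "NM_080685:p.(D2110G)", 41),
    ("PTPN13", "NM_080685:p.(R2371H)", 78),
    ("PTPN13", "NM_080685:p.(R2446H)", 43),
    ("PTPN13", "NM_080685:p.(Q2482X)", 73),
    ("SPATA20", "NM_022827:p.(R51X)", 77),
    ("SPATA20", "NM_022827:p.(V596M)", 78),
)

#: gene -> (case carriers, cases, control carriers, controls)
CASE_CONTROL_COUNTS = {"TDG": (8, 1006, 4, 1609)}
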