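"""Deterministic reference cohort reconstructed from published aggregate counts.

This module builds, entirely in code, a synthetic 220-couple (440
participant) expanded-carrier-screening cohort whose aggregate structure
matches the published summary tables of a Fujian Province ECS pilot cohort:

* subgroup sizes (GS 79, MAR-A 20, MAR-B 94, MAR-C 27 couples);
* per sex × subgroup carrier counts and retained-variant counts
  (304 carriers, 511 retained P/LP calls overall; 154 female carriers with
  260 calls, 150 male carriers with 251 calls);
* per-gene allele structure for the acceptance-relevant genes — GJB2 with
  88 alleles of which 78 are the low-penetrance c.109G>A, 8 G6PD calls in
  females (one homozygote), the full CNV genotype table (43 CNV calls;
  alpha-globin allele mix 14 × --SEA / 7 × -a3.7 / 2 × -a4.2), and the
  published per-gene allele totals for the other high-frequency genes;
* the 14 at-risk couples: 6 couples sharing an AR gene (ARSA, SMN1,
  SLC26A4, GALC, PAH, HBA1/HBA2) and 8 couples with a G6PD female carrier,
  split 5 GS / 9 MAR.

Individual-level assignments (which exact participant carries which filler
variant) are NOT published; they are reconstructed deterministically so
that every published marginal is met while no unintended at-risk couple is
created (partners never share a gene except in the six designated couples,
and no female outside the designated eight carries an X-linked variant).

The panel is likewise a synthetic stand-in for the unavailable 332-gene
design: the genes named in the published tables carry their real
conditions and categories; remaining entries are real recessive-disease
genes or clearly synthetic placeholder symbols (``ECSG###``).

The burden histogram over carriers is (156, 105, 29, 12, 2) for 1..5
variants: the published percentages (51.64 / 34.54 / 9.54 / 4.28) are
mutually inconsistent with the published totals (they imply 506 calls, not
511), so the reconstruction keeps the 2- and 3-variant classes exactly at
the printed proportions and the others within 0.4 percentage points.
"""

from __future__ import annotations

from typing import Optional

from .model import (
    AcmgClass,
    Cohort,
    Couple,
    Participant,
    PanelEntry,
    Inheritance,
    Sex,
    Subgroup,
    UNKNOWN_ETHNICITY,
    VariantCall,
    VariantType,
    Zygosity,
)

AR = Inheritance.AR
XLR = Inheritance.XLR
SNV = VariantType.SNV
INDEL = VariantType.INDEL
CNV_EXON = VariantType.CNV_EXON
CNV_ALLELE = VariantType.CNV_ALLELE
HET = Zygosity.HET
HOM = Zygosity.HOM

#: Couples per screening-indication subgroup.
SUBGROUP_COUPLES = {
    Subgroup.GS: 79,
    Subgroup.MAR_A: 20,
    Subgroup.MAR_B: 94,
    Subgroup.MAR_C: 27,
}

#: Carriers-with-k-variants composition per (sex, subgroup) cell. Row sums
#: give the published carrier counts; weighted sums the published variant
#: counts (e.g. females overall: 154 carriers, 260 variants).
CELL_BURDEN: dict[tuple[Sex, Subgroup], dict[int, int]] = {
    (Sex.FEMALE, Subgroup.GS): {1: 24, 2: 18, 3: 5, 4: 3},
    (Sex.FEMALE, Subgroup.MAR_A): {1: 7, 2: 6, 3: 2},
    (Sex.FEMALE, Subgroup.MAR_B): {1: 37, 2: 20, 3: 8, 4: 3},
    (Sex.FEMALE, Subgroup.MAR_C): {1: 12, 2: 6, 3: 1, 4: 2},
    (Sex.MALE, Subgroup.GS): {1: 26, 2: 18, 3: 5, 4: 3},
    (Sex.MALE, Subgroup.MAR_A): {1: 9, 2: 5, 3: 2},
    (Sex.MALE, Subgroup.MAR_B): {1: 32, 2: 25, 3: 4, 4: 1, 5: 1},
    (Sex.MALE, Subgroup.MAR_C): {1: 9, 2: 7, 3: 2, 5: 1},
}

# ---------------------------------------------------------------------------
# Panel definition (synthetic stand-in; see module docstring)
# ---------------------------------------------------------------------------

_MET = "metabolic/endocrine"
_AUD = "auditory"
_HEM = "hematological"
_NER = "nervous"
_OPH = "ophthalmologic"
_MUS = "musculoskeletal"
_REN = "renal"
_IMM = "immune"
_DER = "dermatological"
_RES = "respiratory"
_HEP = "hepatic"
_MUL = "multisystem"

# Genes named in the published tables, with their printed conditions.
_NAMED_PANEL: list[tuple[str, Inheritance, str, str, tuple[str, ...]]] = [
    ("GJB2", AR, "Non-syndromic hearing loss, GJB2-related", _AUD, ("c.109G>A",)),
    ("HBA1/HBA2", AR, "Alpha-thalassemia", _HEM, ()),
    ("HBB", AR, "Beta-thalassemia", _HEM, ()),
    ("UGT1A1", AR, "Crigler-Najjar syndrome", _MET, ("c.1091C>T",)),
    ("SLC26A4", AR, "Pendred syndrome", _AUD, ()),
    ("PAH", AR, "Phenylalanine hydroxylase deficiency", _MET, ()),
    ("ATP7B", AR, "Wilson disease", _MET, ()),
    ("USH2A", AR, "Usher syndrome", _AUD, ()),
    ("CLRN1", AR, "Usher syndrome", _AUD, ()),
    ("GALC", AR, "Krabbe disease", _NER, ()),
    ("HFE", AR, "HFE-associated hemochromatosis", _HEM, ("c.187C>G",)),
    ("EYS", AR, "Retinitis pigmentosa", _OPH, ()),
    ("CERKL", AR, "Retinitis pigmentosa", _OPH, ()),
    ("FAM161A", AR, "Retinitis pigmentosa", _OPH, ()),
    ("SLC25A13", AR, "Citrin deficiency", _MET, ()),
    ("CYP21A2", AR, "Congenital adrenal hyperplasia, 21-hydroxylase deficiency", _MET, ()),
    ("SKIC3", AR, "Tricho-hepato-enteric syndrome", _NER, ()),
    ("SMN1", AR, "Spinal muscular atrophy", _MUS, ()),
    ("G6PD", XLR, "Glucose-6-phosphate dehydrogenase deficiency", _MET, ()),
    ("SLC22A5", AR, "Primary carnitine deficiency", _MET, ()),
    ("GALT", AR, "Galactosemia", _MET, ()),
    ("POLG", AR, "POLG-related progressive external ophthalmoplegia", _NER, ()),
    ("GAA", AR, "Pompe disease", _MET, ()),
    ("SLC12A3", AR, "Gitelman syndrome", _REN, ()),
    ("MEFV", AR, "Familial Mediterranean fever", _IMM, ()),
    ("CFTR", AR, "Cystic fibrosis", _MET, ()),
    ("CYP1B1", AR, "Primary congenital glaucoma", _OPH, ()),
    ("ARSA", AR, "Metachromatic leukodystrophy", _NER, ()),
    ("GLDC", AR, "Glycine encephalopathy", _NER, ()),
    ("NPHP1", AR, "Joubert syndrome / nephronophthisis", _REN, ()),
    ("DCLRE1C", AR, "Severe combined immunodeficiency with radiosensitivity", _IMM, ()),
    ("FANCA", AR, "Fanconi anemia", _HEM, ()),
    ("PMM2", AR, "Congenital disorder of glycosylation type Ia", _MUL, ()),
    ("SACS", AR, "Spastic ataxia of Charlevoix-Saguenay", _NER, ()),
    ("SGCG", AR, "Limb-girdle muscular dystrophy type 2C", _MUS, ()),
    ("VPS13B", AR, "Cohen syndrome", _MUL, ()),
]

# Real recessive-disease genes used as filler; the first 97 carry the 182
# low-frequency filler calls (1-2 each), the rest are screened but variant-free.
_FILLER_AR: list[tuple[str, str]] = [
    ("HEXA", _MET), ("HEXB", _MET), ("ASPA", _NER), ("SMPD1", _MET),
    ("NPC1", _MET), ("NPC2", _MET), ("GBA1", _MET), ("IDUA", _MET),
    ("SGSH", _MET), ("NAGLU", _MET), ("GLB1", _MET), ("NEU1", _MET),
    ("FUCA1", _MET), ("MAN2B1", _MET), ("AGA", _MET), ("PPT1", _NER),
    ("TPP1", _NER), ("MCOLN1", _NER), ("ACADM", _MET), ("ACADVL", _MET),
    ("ACADS", _MET), ("HADHA", _MET), ("HADHB", _MET), ("ETFA", _MET),
    ("ETFDH", _MET), ("CPT2", _MET), ("MUT", _MET), ("MMAA", _MET),
    ("MMACHC", _MET), ("PCCA", _MET), ("PCCB", _MET), ("IVD", _MET),
    ("MCCC1", _MET), ("MCCC2", _MET), ("GCDH", _MET), ("BCKDHA", _MET),
    ("BCKDHB", _MET), ("DBT", _MET), ("ASS1", _MET), ("ASL", _MET),
    ("CPS1", _MET), ("FAH", _MET), ("CBS", _MET), ("GALK1", _MET),
    ("ALDOB", _MET), ("G6PC1", _MET), ("SLC37A4", _MET), ("AGL", _MET),
    ("PYGM", _MUS), ("FBP1", _MET),
    ("MYO7A", _AUD), ("CDH23", _AUD), ("PCDH15", _AUD), ("USH1C", _AUD),
    ("TMC1", _AUD), ("TMPRSS3", _AUD), ("OTOF", _AUD), ("MYO15A", _AUD),
    ("SLC26A5", _AUD), ("TECTA", _AUD),
    ("RPE65", _OPH), ("CRB1", _OPH), ("CEP290", _OPH), ("AIPL1", _OPH),
    ("GUCY2D", _OPH), ("PDE6A", _OPH), ("PDE6B", _OPH), ("CNGB1", _OPH),
    ("PLA2G6", _NER), ("TH", _NER), ("DDC", _NER), ("SUOX", _NER),
    ("NDUFS4", _NER), ("SURF1", _NER), ("SCO2", _NER), ("COQ2", _NER),
    ("CAPN3", _MUS), ("DYSF", _MUS), ("SGCA", _MUS), ("SGCB", _MUS),
    ("FKRP", _MUS), ("LAMA2", _MUS), ("ANO5", _MUS), ("NEB", _MUS),
    ("PKHD1", _REN), ("NPHS1", _REN), ("NPHS2", _REN), ("AGXT", _REN),
    ("CTNS", _REN),
    ("RAG1", _IMM), ("RAG2", _IMM), ("ADA", _IMM), ("IL7R", _IMM),
    ("LIG4", _IMM),
    ("PKLR", _HEM), ("ITGA2B", _HEM), ("F11", _HEM), ("FGA", _HEM),
    ("ABCA12", _DER), ("TGM1", _DER), ("SPINK5", _DER), ("COL7A1", _DER),
    ("DNAH5", _RES), ("DNAI1", _RES), ("CCDC39", _RES), ("CCDC40", _RES),
    ("ABCB11", _HEP), ("ATP8B1", _HEP), ("SERPINA1", _HEP),
    ("PEX1", _MUL), ("PEX6", _MUL), ("BBS1", _MUL), ("BBS2", _MUL),
    ("TMEM67", _MUL), ("ALG6", _MUL),
]

# Variant-free XLR genes completing the screened X-linked set.
_FILLER_XLR: list[tuple[str, str]] = [
    ("DMD", _MUS), ("OTC", _MET), ("ABCD1", _NER), ("F8", _HEM),
    ("F9", _HEM), ("BTK", _IMM), ("IL2RG", _IMM), ("PDHA1", _NER),
    ("OCRL", _REN), ("ATP7A", _NER), ("IDS", _MET), ("MTM1", _MUS),
    ("L1CAM", _NER), ("NR0B1", _MET),
]

PANEL_SIZE = 332
N_FILLER_CALL_GENES = 97  # filler genes that carry the 182 low-frequency calls


def reference_panel() -> list[PanelEntry]:
    """The 332-entry synthetic stand-in panel (AR + XLR genes, 12 categories)."""
    entries = [
        PanelEntry(g, mode, cond, cat, frozenset(lp))
        for g, mode, cond, cat, lp in _NAMED_PANEL
    ]
    for g, cat in _FILLER_AR:
        entries.append(PanelEntry(g, AR, f"{g}-related disorder", cat))
    for g, cat in _FILLER_XLR:
        entries.append(PanelEntry(g, XLR, f"{g}-related disorder", cat))
    categories = sorted(
        {_MET, _AUD, _HEM, _NER, _OPH, _MUS, _REN, _IMM, _DER, _RES, _HEP, _MUL}
    )
    i = 1
    while len(entries) < PANEL_SIZE:
        # synthetic placeholder entries to reach the screened-gene count
        entries.append(
            PanelEntry(
                f"ECSG{i:03d}", AR,
                "synthetic placeholder condition",
                categories[(i - 1) % len(categories)],
            )
        )
        i += 1
    return entries[:PANEL_SIZE]


# ---------------------------------------------------------------------------
# Participants
# ---------------------------------------------------------------------------

_FEMALE_AGES = [26.0, 28.0, 30.0, 31.0, 32.0, 33.0, 34.0, 36.0]
_MALE_AGES = [28.0, 30.0, 32.0, 33.0, 34.0, 35.0, 36.0, 38.0]
_MINORITIES = ["Manchu", "Miao", "She", "Zhuang"]


def _ethnicity(index: int, sex: Sex) -> str:
    if sex is Sex.FEMALE:
        if index in (30, 60, 90, 120, 150, 180, 210):
            return _MINORITIES[index // 60]
        if index % 8 == 3 and index < 216:  # 27 unreported females
            return UNKNOWN_ETHNICITY
    else:
        if index in (25, 65, 105, 145, 185):
            return _MINORITIES[index // 55]
        if index % 8 == 5 or index == 214:  # 28 unreported males
            return UNKNOWN_ETHNICITY
    return "Han"


def _build_participants() -> tuple[list[Participant], list[Couple]]:
    participants: list[Participant] = []
    couples: list[Couple] = []
    order = [Subgroup.GS, Subgroup.MAR_A, Subgroup.MAR_B, Subgroup.MAR_C]
    idx = 0
    for sg in order:
        for _ in range(SUBGROUP_COUPLES[sg]):
            cid = f"C{idx + 1:04d}"
            fid, mid = f"{cid}F", f"{cid}M"
            participants.append(
                Participant(fid, Sex.FEMALE, sg, _FEMALE_AGES[idx % 8],
                            _ethnicity(idx, Sex.FEMALE), cid)
            )
            participants.append(
                Participant(mid, Sex.MALE, sg, _MALE_AGES[idx % 8],
                            _ethnicity(idx, Sex.MALE), cid)
            )
            couples.append(Couple(cid, fid, mid, sg))
            idx += 1
    return participants, couples


# ---------------------------------------------------------------------------
# Variant tokens
# ---------------------------------------------------------------------------

Token = tuple[str, str, VariantType, Zygosity]


def _pinned_calls() -> list[tuple[str, Token]]:
    """Calls pinned to designated participants (ARC couples + G6PD females)."""
    pins: list[tuple[str, Token]] = []
    # six couples sharing an AR gene
    for cid, gene, allele, vtype in [
        ("C0001", "GALC", "c.1901T>C", SNV),
        ("C0002", "PAH", "c.728G>A", SNV),
        ("C0100", "HBA1/HBA2", "--SEA", CNV_ALLELE),
        ("C0194", "ARSA", "c.465+1G>A", SNV),
        ("C0195", "SMN1", "ex.7_8del", CNV_EXON),
        ("C0196", "SLC26A4", "c.919-2A>G", SNV),
    ]:
        pins.append((f"{cid}F", (gene, allele, vtype, HET)))
        pins.append((f"{cid}M", (gene, allele, vtype, HET)))
    # eight G6PD female carriers (3 GS / 1 MAR-A / 2 MAR-B / 2 MAR-C), one homozygote
    g6pd = [
        ("C0003F", "c.1388G>A", HET),
        ("C0004F", "c.1388G>A", HET),
        ("C0005F", "c.1376G>T", HET),
        ("C0080F", "c.1388G>A", HET),
        ("C0101F", "c.1388G>A", HET),
        ("C0102F", "c.1376G>T", HET),
        ("C0197F", "c.1388G>A", HOM),
        ("C0198F", "c.1388G>A", HET),
    ]
    pins.extend((pid, ("G6PD", allele, SNV, zyg)) for pid, allele, zyg in g6pd)
    return pins


def _sex_constrained_tokens() -> dict[Sex, list[Token]]:
    """CNV calls (sex split published) plus the sex-split CFTR c.4056G>C."""
    female: list[Token] = []
    male: list[Token] = []
    # alpha-globin structural alleles beyond the pinned C0100 couple
    female += [("HBA1/HBA2", "--SEA", CNV_ALLELE, HET)] * 7
    female += [("HBA1/HBA2", "-a3.7", CNV_ALLELE, HET)] * 4
    female += [("HBA1/HBA2", "-a4.2", CNV_ALLELE, HET)] * 1
    male += [("HBA1/HBA2", "--SEA", CNV_ALLELE, HET)] * 5
    male += [("HBA1/HBA2", "-a3.7", CNV_ALLELE, HET)] * 3
    male += [("HBA1/HBA2", "-a4.2", CNV_ALLELE, HET)] * 1
    # SMN1 exon 7-8 deletions beyond the pinned C0195 couple
    female += [("SMN1", "ex.7_8del", CNV_EXON, HET)] * 4
    male += [("SMN1", "ex.7_8del", CNV_EXON, HET)] * 2
    # singleton exon-level CNVs
    female += [
        ("GLDC", "ex.2del", CNV_EXON, HET),
        ("NPHP1", "ex.1_20del", CNV_EXON, HET),
        ("NPHP1", "ex.1_20del", CNV_EXON, HET),
        ("FANCA", "ex.7_14del", CNV_EXON, HET),
        ("PMM2", "ex.2del", CNV_EXON, HET),
        ("VPS13B", "ex.17del", CNV_EXON, HET),
    ]
    male += [
        ("GLDC", "ex.1_8del", CNV_EXON, HET),
        ("CYP21A2", "ex.1_10del", CNV_EXON, HET),
        ("DCLRE1C", "ex.1_3del", CNV_EXON, HET),
        ("FAM161A", "ex.4_5del", CNV_EXON, HET),
        ("SACS", "ex.1_8del", CNV_EXON, HET),
        ("SGCG", "ex.5_10del", CNV_EXON, HET),
    ]
    # CFTR c.4056G>C: one female, two males
    female.append(("CFTR", "c.4056G>C", SNV, HET))
    male += [("CFTR", "c.4056G>C", SNV, HET)] * 2
    return {Sex.FEMALE: female, Sex.MALE: male}


def _free_tokens() -> list[Token]:
    """Unconstrained SNV/indel tokens reproducing the published per-gene allele totals."""
    tokens: list[Token] = []

    def add(gene: str, allele: str, vtype: VariantType, n: int, zyg: Zygosity = HET):
        tokens.extend([(gene, allele, vtype, zyg)] * n)

    # GJB2: 88 alleles = 78 low-penetrance c.109G>A (incl. one homozygote)
    # + 10 other alleles carried by 10 distinct participants
    add("GJB2", "c.109G>A", SNV, 76)
    add("GJB2", "c.109G>A", SNV, 1, HOM)
    add("GJB2", "c.235delC", INDEL, 10)
    # non-deletional alpha-globin alleles completing the published 25
    add("HBA1/HBA2", "c.427T>C", SNV, 2)
    add("HBB", "c.126_129del", INDEL, 4)
    add("HBB", "c.316-197C>T", SNV, 3)
    add("HBB", "c.52A>T", SNV, 3)
    add("UGT1A1", "c.1091C>T", SNV, 14)
    add("UGT1A1", "c.1091C>T", SNV, 1, HOM)
    add("UGT1A1", "c.211G>A", SNV, 1)
    add("SLC26A4", "c.919-2A>G", SNV, 6)
    add("SLC26A4", "c.2168A>G", SNV, 7)
    add("PAH", "c.728G>A", SNV, 5)
    add("PAH", "c.611A>G", SNV, 8)
    add("ATP7B", "c.2333G>T", SNV, 8)
    add("ATP7B", "c.2975C>T", SNV, 7)
    add("USH2A", "c.8559-2A>G", SNV, 6)
    add("USH2A", "c.2802T>G", SNV, 6)
    add("CLRN1", "c.606T>G", SNV, 1)
    add("GALC", "c.1901T>C", SNV, 4)
    add("GALC", "c.136G>T", SNV, 6)
    add("HFE", "c.187C>G", SNV, 9)
    add("HFE", "c.845G>A", SNV, 1)
    add("EYS", "c.6416G>A", SNV, 6)
    add("CERKL", "c.847C>T", SNV, 2)
    add("SLC25A13", "c.852_855del", INDEL, 9)
    add("CYP21A2", "c.293-13C>G", SNV, 3)
    add("CYP21A2", "c.518T>A", SNV, 3)
    add("CYP21A2", "c.955C>T", SNV, 2)
    add("SKIC3", "c.1320+1G>A", SNV, 8)
    add("SLC22A5", "c.1400C>G", SNV, 6)
    add("SLC22A5", "c.1400C>G", SNV, 1, HOM)
    add("GALT", "c.404C>T", SNV, 7)
    add("POLG", "c.2890C>T", SNV, 7)
    add("GAA", "c.2238G>C", SNV, 7)
    add("SLC12A3", "c.1456G>A", SNV, 5)
    add("MEFV", "c.2282G>A", SNV, 5)
    add("CFTR", "c.1521_1523del", INDEL, 2)
    add("CYP1B1", "c.319C>G", SNV, 2)
    add("CYP1B1", "c.1064_1076del", INDEL, 3)
    # 182 low-frequency filler calls over 97 genes (85 genes x2, 12 genes x1)
    filler_genes = [g for g, _ in _FILLER_AR[:N_FILLER_CALL_GENES]]
    for i, gene in enumerate(filler_genes):
        add(gene, "c.101G>A", SNV, 1)
        if i < 85:
            add(gene, "c.202C>T", SNV, 1)
    return tokens


def _dropped_examples() -> list[VariantCall]:
    """Extra raw calls that the prioritization chain must remove."""
    extras: list[VariantCall] = []
    vus_carriers = [f"C{i:04d}{s}" for i, s in
                    [(10, "F"), (20, "M"), (30, "F"), (40, "M"), (50, "F"),
                     (60, "M"), (70, "F"), (85, "M"), (110, "F"), (120, "M"),
                     (130, "F"), (140, "M"), (150, "F"), (160, "M"), (170, "F"),
                     (180, "M"), (200, "F"), (205, "M"), (210, "F"), (215, "M")]]
    for pid in vus_carriers:
        extras.append(VariantCall(pid, "ATP7B", "c.3889G>A", SNV, HET, AcmgClass.VUS))
    for pid, gene in [("C0011F", "BRCA2"), ("C0012M", "TTN"), ("C0013F", "MYH7")]:
        extras.append(VariantCall(pid, gene, "c.1000A>G", SNV, HET, AcmgClass.P))
    extras.append(VariantCall("C0014F", "PAH", "c.158G>A", SNV, HET, AcmgClass.LB))
    extras.append(VariantCall("C0015M", "GALT", "c.940A>G", SNV, HET, AcmgClass.B))
    return extras


# ---------------------------------------------------------------------------
# Assignment of tokens to carriers
# ---------------------------------------------------------------------------


def _carrier_plan(couples: list[Couple]) -> list[tuple[str, Sex, int]]:
    """Ordered (participant_id, sex, burden) carrier slots for every cell.

    Within each cell, carriers are the earliest couples of the subgroup
    (which places the pinned at-risk participants first) and burdens are
    assigned in descending order so pinned carriers can absorb filler calls.
    """
    by_subgroup: dict[Subgroup, list[Couple]] = {}
    for c in couples:
        by_subgroup.setdefault(c.subgroup, []).append(c)
    plan: list[tuple[str, Sex, int]] = []
    for sg in [Subgroup.GS, Subgroup.MAR_A, Subgroup.MAR_B, Subgroup.MAR_C]:
        for sex in (Sex.FEMALE, Sex.MALE):
            comp = CELL_BURDEN[(sex, sg)]
            burdens = sorted(
                (k for k, n in comp.items() for _ in range(n)), reverse=True
            )
            members = [
                (c.female_id if sex is Sex.FEMALE else c.male_id)
                for c in by_subgroup[sg]
            ]
            for pid, burden in zip(members, burdens):
                plan.append((pid, sex, burden))
    return plan


def _assign_tokens(
    plan: list[tuple[str, Sex, int]],
    pinned: list[tuple[str, Token]],
    sex_tokens: dict[Sex, list[Token]],
    free_tokens: list[Token],
    partner: dict[str, str],
) -> dict[str, list[VariantCall]]:
    assigned: dict[str, list[VariantCall]] = {}
    genes_of: dict[str, set[str]] = {}

    def give(pid: str, token: Token) -> None:
        gene, allele, vtype, zyg = token
        assigned.setdefault(pid, []).append(
            VariantCall(pid, gene, allele, vtype, zyg, AcmgClass.P)
        )
        genes_of.setdefault(pid, set()).add(gene)

    for pid, token in pinned:
        give(pid, token)

    free_by_gene: dict[str, list[Token]] = {}
    for t in free_tokens:
        free_by_gene.setdefault(t[0], []).append(t)

    def excluded(pid: str) -> set[str]:
        return genes_of.get(pid, set()) | genes_of.get(partner[pid], set())

    def take_sex_token(pid: str, sex: Sex) -> Optional[Token]:
        pool = sex_tokens[sex]
        bad = excluded(pid)
        for i, t in enumerate(pool):
            if t[0] not in bad:
                return pool.pop(i)
        return None

    def take_free_token(pid: str) -> Optional[Token]:
        bad = excluded(pid)
        candidates = [g for g in free_by_gene if g not in bad]
        if not candidates:
            return None
        gene = max(candidates, key=lambda g: (len(free_by_gene[g]), g))
        t = free_by_gene[gene].pop()
        if not free_by_gene[gene]:
            del free_by_gene[gene]
        return t

    deferred: list[tuple[str, Sex]] = []
    for pid, sex, burden in plan:
        while len(assigned.get(pid, [])) < burden:
            token = take_sex_token(pid, sex) or take_free_token(pid)
            if token is None:
                deferred.append((pid, sex))
                break
            give(pid, token)

    # repair pass: swap a compatible already-assigned call if a participant
    # could not be filled directly (all remaining genes collide with the
    # couple's gene sets); deterministic and rarely needed
    for pid, sex in deferred:
        leftovers = [t for pool in free_by_gene.values() for t in pool] + sex_tokens[sex]
        for token in leftovers:
            moved = False
            for other, calls in assigned.items():
                if other in (pid, partner[pid]):
                    continue
                for call in calls:
                    t_other = (call.gene, call.allele_id, call.variant_type, call.zygosity)
                    if (
                        call.gene not in excluded(pid)
                        and token[0] not in (genes_of[other] - {call.gene})
                        and token[0] not in genes_of.get(partner[other], set())
                    ):
                        calls.remove(call)
                        genes_of[other].discard(call.gene)
                        give(pid, t_other)
                        give(other, token)
                        _remove_token(free_by_gene, sex_tokens, sex, token)
                        moved = True
                        break
                if moved:
                    break
            if moved:
                break
        else:
            raise AssertionError(f"could not complete assignment for {pid}")

    remaining = sum(len(v) for v in free_by_gene.values())
    remaining += len(sex_tokens[Sex.FEMALE]) + len(sex_tokens[Sex.MALE])
    if remaining:
        raise AssertionError(f"{remaining} variant tokens left unassigned")
    return assigned


def _remove_token(free_by_gene, sex_tokens, sex, token) -> None:
    if token in sex_tokens[sex]:
        sex_tokens[sex].remove(token)
        return
    pool = free_by_gene.get(token[0], [])
    if token in pool:
        pool.remove(token)
        if not pool:
            del free_by_gene[token[0]]


# ---------------------------------------------------------------------------
# Public entry point
# ---------------------------------------------------------------------------


def reference_cohort(include_unfiltered: bool = True) -> Cohort:
    """Build the deterministic reference cohort.

    With ``include_unfiltered`` (default) the call set also contains the
    VUS / benign / off-panel rows that the prioritization chain is expected
    to drop; after filtering, exactly 511 P/LP calls remain.
    """
    participants, couples = _build_participants()
    partner: dict[str, str] = {}
    for c in couples:
        partner[c.female_id] = c.male_id
        partner[c.male_id] = c.female_id

    plan = _carrier_plan(couples)
    assigned = _assign_tokens(
        plan, _pinned_calls(), _sex_constrained_tokens(), _free_tokens(), partner
    )
    calls: list[VariantCall] = []
    for p in participants:  # manifest order keeps the file deterministic
        calls.extend(assigned.get(p.id, []))
    if include_unfiltered:
        calls.extend(_dropped_examples())

    return Cohort.from_records(participants, couples, calls, reference_panel())
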