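"""Parsing, validation and round-trip behaviour of the cohort formats."""

import pytest

from ecscreen.io import (
    read_calls,
    read_manifest,
    read_panel,
    write_calls,
    write_cohort,
    write_manifest,
    write_panel,
    load_cohort,
)
from ecscreen.model import (
    AcmgClass,
    Cohort,
    FormatError,
    Inheritance,
    Participant,
    ReferentialError,
    Sex,
    Subgroup,
    ValidationError,
    VariantCall,
    VariantType,
    Zygosity,
    normalize_cnv_allele,
)


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text, encoding="utf-8")
    return p


PANEL_HEADER = "gene\tinheritance\tcondition\tcategory\tlow_penetrance_alleles\n"
MANIFEST_HEADER = "participant_id\tsex\tage\tethnicity\tsubgroup\tcouple_id\n"
CALLS_HEADER = "participant_id\tgene\tallele_id\tvariant_type\tzygosity\tacmg_class\n"


class TestReadPanel:
    def test_parses_both_inheritance_modes(self, tmp_path):
        p = _write(
            tmp_path, "panel.tsv",
            PANEL_HEADER
            + "GJB2\tAR\tHearing loss\tauditory\tc.109G>A\n"
            + "G6PD\tXLR\tG6PD deficiency\tmetabolic/endocrine\t.\n",
        )
        entries = read_panel(p)
        assert [e.inheritance for e in entries] == [Inheritance.AR, Inheritance.XLR]
        assert entries[0].low_penetrance_alleles == {"c.109G>A"}
        assert entries[1].low_penetrance_alleles == frozenset()

    def test_duplicate_gene_rejected_by_name(self, tmp_path):
        p = _write(
            tmp_path, "panel.tsv",
            PANEL_HEADER
            + "GJB2\tAR\tx\tauditory\t.\nGJB2\tAR\ty\tauditory\t.\n",
        )
        with pytest.raises(ValidationError, match="GJB2"):
            read_panel(p)

    def test_missing_column_named(self, tmp_path):
        p = _write(tmp_path, "panel.tsv", "gene\tinheritance\tcondition\tcategory\nA\tAR\tc\tauditory\n")
        with pytest.raises(FormatError, match="low_penetrance_alleles"):
            read_panel(p)

    def test_unknown_inheritance_reports_row(self, tmp_path):
        p = _write(
            tmp_path, "panel.tsv",
            PANEL_HEADER + "GJB2\tAD\tx\tauditory\t.\n",
        )
        with pytest.raises(ValidationError, match="row 2"):
            read_panel(p)


class TestReadManifest:
    def test_couple_assembled_from_shared_id(self, tmp_path):
        p = _write(
            tmp_path, "m.tsv",
            MANIFEST_HEADER
            + "P1\tfemale\t30\tHan\tGS\tC1\nP2\tmale\t32\t.\tGS\tC1\n",
        )
        participants, couples = read_manifest(p)
        assert len(participants) == 2 and len(couples) == 1
        assert couples[0].female_id == "P1" and couples[0].male_id == "P2"
        assert participants[1].ethnicity is None

    def test_same_sex_couple_rejected(self, tmp_path):
        p = _write(
            tmp_path, "m.tsv",
            MANIFEST_HEADER
            + "P1\tfemale\t30\tHan\tGS\tC1\nP2\tfemale\t31\tHan\tGS\tC1\n",
        )
        with pytest.raises(ValidationError, match="C1"):
            read_manifest(p)

    def test_unknown_subgroup_rejected(self, tmp_path):
        p = _write(tmp_path, "m.tsv", MANIFEST_HEADER + "P1\tfemale\t30\tHan\tMAR_D\t.\n")
        with pytest.raises(ValidationError, match="MAR_D"):
            read_manifest(p)


class TestReadCalls:
    PARTICIPANTS = [Participant("P1", Sex.FEMALE, Subgroup.GS)]

    def test_empty_file_with_header(self, tmp_path):
        p = _write(tmp_path, "c.tsv", CALLS_HEADER)
        assert read_calls(p, self.PARTICIPANTS) == []

    def test_single_call_parsed(self, tmp_path):
        p = _write(tmp_path, "c.tsv", CALLS_HEADER + "P1\tGJB2\tc.235delC\tindel\thet\tP\n")
        (call,) = read_calls(p, self.PARTICIPANTS)
        assert call.gene == "GJB2" and call.acmg_class is AcmgClass.P
        assert call.zygosity is Zygosity.HET

    def test_unknown_acmg_token_rejected(self, tmp_path):
        p = _write(
            tmp_path, "c.tsv", CALLS_HEADER + "P1\tGJB2\tc.1A>G\tSNV\thet\tpathogenicish\n"
        )
        with pytest.raises(ValidationError, match="pathogenicish"):
            read_calls(p, self.PARTICIPANTS)

    def test_orphan_participant_lists_rows(self, tmp_path):
        p = _write(tmp_path, "c.tsv", CALLS_HEADER + "P9\tGJB2\tc.1A>G\tSNV\thet\tP\n")
        with pytest.raises(ReferentialError, match="rows 2"):
            read_calls(p, self.PARTICIPANTS)


@pytest.mark.parametrize(
    "raw,canonical",
    [
        ("αα/--^SEA^", "--SEA"),
        ("--^SEA^", "--SEA"),
        ("-α^3.7^", "-a3.7"),
        ("αα/-α^4.2^", "-a4.2"),
        ("HKαα", "HKaa"),
        ("c.109G>A", "c.109G>A"),
        ("ex.7_8del", "ex.7_8del"),
    ],
)
def test_cnv_allele_normalization(raw, canonical):
    assert normalize_cnv_allele(raw) == canonical


class TestVcfIngestion:
    VCF = (
        "##fileformat=VCFv4.2\n"
        '##INFO=<ID=GENE,Number=1,Type=String,Description="Gene">\n'
        '##INFO=<ID=ACMG,Number=1,Type=String,Description="Class">\n'
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        "##contig=<ID=13>\n"
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tP1\tP2\n"
        "13\t20763612\t.\tG\tA\t.\tPASS\tGENE=GJB2;ACMG=P\tGT\t0/1\t1/1\n"
    )

    def test_genotypes_become_calls(self, tmp_path):
        from ecscreen.io import read_calls_vcf

        path = _write(tmp_path, "calls.vcf", self.VCF)
        parts = [
            Participant("P1", Sex.FEMALE, Subgroup.GS),
            Participant("P2", Sex.MALE, Subgroup.GS),
        ]
        het, hom = read_calls_vcf(path, parts)
        assert het.gene == hom.gene == "GJB2"
        assert het.zygosity is Zygosity.HET and hom.zygosity is Zygosity.HOM
        assert het.acmg_class is AcmgClass.P

    def test_unknown_sample_rejected(self, tmp_path):
        from ecscreen.io import read_calls_vcf

        path = _write(tmp_path, "calls.vcf", self.VCF)
        with pytest.raises(ReferentialError, match="P2"):
            read_calls_vcf(path, [Participant("P1", Sex.FEMALE, Subgroup.GS)])


class TestCohortInvariants:
    def test_hemizygous_only_xlr_males(self, toy_panel):
        parts = [Participant("F1", Sex.FEMALE, Subgroup.GS)]
        bad = VariantCall("F1", "G6PD", "c.1388G>A", VariantType.SNV,
                          Zygosity.HEMI, AcmgClass.P)
        with pytest.raises(ValidationError, match="hemizygous"):
            Cohort.from_records(parts, [], [bad], toy_panel.values())

    def test_call_must_reference_participant(self, toy_panel):
        call = VariantCall("NOPE", "PAH", "c.1A>G", VariantType.SNV,
                           Zygosity.HET, AcmgClass.P)
        with pytest.raises(ReferentialError, match="NOPE"):
            Cohort.from_records([], [], [call], toy_panel.values())


class TestRoundTrip:
    def test_study_cohort_round_trips_identically(self, study_cohort, tmp_path):
        """Write-then-read reproduces every record field-for-field."""
        paths = write_cohort(study_cohort, tmp_path)
        back = load_cohort(paths["panel"], paths["manifest"], paths["calls"])
        assert list(back.panel.values()) == list(study_cohort.panel.values())
        assert list(back.participants.values()) == list(study_cohort.participants.values())
        assert back.couples == study_cohort.couples
        assert back.calls == study_cohort.calls


class TestStudyFixtureShape:
    def test_manifest_marginals(self, study_cohort):
        """220 couples / 440 participants split 79+20+94+27 by indication."""
        assert study_cohort.n_participants == 440
        assert study_cohort.n_couples == 220
        assert len(study_cohort.females()) == 220
        assert len(study_cohort.males()) == 220
        by_sg = {}
        for c in study_cohort.couples:
            by_sg[c.subgroup] = by_sg.get(c.subgroup, 0) + 1
        assert by_sg == {
            Subgroup.GS: 79, Subgroup.MAR_A: 20,
            Subgroup.MAR_B: 94, Subgroup.MAR_C: 27,
        }

    def test_panel_size(self, study_cohort):
        assert len(study_cohort.panel) == 332

    def test_ethnicity_composition(self, study_cohort):
        from ecscreen.model import UNKNOWN_ETHNICITY

        unknown = sum(
            1 for p in study_cohort.participants.values()
            if p.ethnicity == UNKNOWN_ETHNICITY
        )
        han = sum(1 for p in study_cohort.participants.values() if p.ethnicity == "Han")
        assert unknown == 55
        assert han == 373
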