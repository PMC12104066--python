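"""Carrier rates, burden, per-gene summaries, CCR and HWE projection."""

import math

import pytest
from hypothesis import given, strategies as st

from ecscreen.carrier import (
    allele_share,
    burden_histogram,
    by_sex,
    carrier_rate,
    cnv_genotype_table,
    cumulative_carrier_rate,
    gene_summary,
    hwe_incidence,
    mean_burden,
    one_in_n,
    variant_type_breakdown,
)
from ecscreen.model import (
    AcmgClass,
    Cohort,
    EcsError,
    Inheritance,
    Participant,
    Sex,
    Subgroup,
    UndefinedRateError,
    VariantCall,
    VariantType,
    Zygosity,
)


def _toy_cohort(panel, n=30, call_spec=()):
    parts = [Participant(f"P{i}", Sex.FEMALE if i % 2 else Sex.MALE, Subgroup.GS)
             for i in range(n)]
    calls = [
        VariantCall(pid, gene, allele, VariantType.SNV, zyg, AcmgClass.P)
        for pid, gene, allele, zyg in call_spec
    ]
    return Cohort.from_records(parts, [], calls, panel.values())


class TestCarrierRate:
    def test_subset_with_no_calls_is_zero(self, toy_panel):
        cohort = _toy_cohort(toy_panel)
        s = carrier_rate(cohort, [])
        assert s.n_carriers == 0 and s.carrier_rate == 0.0

    def test_empty_subset_raises(self, toy_panel):
        cohort = _toy_cohort(toy_panel)
        with pytest.raises(UndefinedRateError):
            carrier_rate(cohort, [], predicate=lambda p: False)

    def test_one_participant_three_calls(self, toy_panel):
        spec = [("P0", "GJB2", "c.235delC", Zygosity.HET),
                ("P0", "PAH", "c.1A>G", Zygosity.HET),
                ("P0", "SLC26A4", "c.2A>G", Zygosity.HET)]
        cohort = _toy_cohort(toy_panel, n=1, call_spec=spec)
        s = mean_burden(cohort, cohort.calls)
        assert s.mean_burden == 3.0 and s.n_carriers == 1

    def test_rate_never_exceeds_burden(self, study_cohort, study_retained):
        for pred in (None, by_sex(Sex.FEMALE), by_sex(Sex.MALE)):
            s = carrier_rate(study_cohort, study_retained, pred)
            assert s.carrier_rate <= s.mean_burden


class TestBurdenHistogram:
    def test_small_example(self, toy_panel):
        spec = [("P0", "GJB2", "a", Zygosity.HET),
                ("P1", "PAH", "a", Zygosity.HET),
                ("P2", "GJB2", "a", Zygosity.HET),
                ("P2", "PAH", "a", Zygosity.HET)]
        cohort = _toy_cohort(toy_panel, n=5, call_spec=spec)
        hist = burden_histogram(cohort.calls, cohort.participants.values())
        assert hist == {1: 2 / 3, 2: 1 / 3}

    def test_no_carriers_empty(self, toy_panel):
        cohort = _toy_cohort(toy_panel)
        assert burden_histogram([], cohort.participants.values()) == {}

    def test_proportions_sum_to_one(self, study_cohort, study_retained):
        hist = burden_histogram(study_retained, study_cohort.participants.values())
        assert math.isclose(sum(hist.values()), 1.0)


class TestGeneSummary:
    def test_three_het_carriers_among_thirty(self, toy_panel):
        # brute-force oracle: 3 distinct carriers / 30 participants
        spec = [(f"P{i}", "PAH", "c.1A>G", Zygosity.HET) for i in (0, 7, 13)]
        cohort = _toy_cohort(toy_panel, n=30, call_spec=spec)
        (summary,) = gene_summary(cohort, cohort.calls)
        assert summary.carrier_count == 3
        assert summary.carrier_frequency == pytest.approx(0.1)
        assert summary.one_in_n == 10

    def test_homozygote_counts_two_alleles_one_carrier(self, toy_panel):
        spec = [("P0", "PAH", "c.1A>G", Zygosity.HOM)]
        cohort = _toy_cohort(toy_panel, n=10, call_spec=spec)
        (summary,) = gene_summary(cohort, cohort.calls)
        assert summary.allele_count == 2 and summary.carrier_count == 1

    def test_xlr_gene_uses_female_denominator(self, toy_panel):
        spec = [("P1", "G6PD", "c.1388G>A", Zygosity.HET)]  # P1 is female
        cohort = _toy_cohort(toy_panel, n=30, call_spec=spec)
        (summary,) = gene_summary(cohort, cohort.calls)
        assert summary.denominator == 15

    def test_zero_carriers_one_in_n_is_null(self):
        assert one_in_n(0, 440) is None

    def test_adjusted_equals_unadjusted_without_registry(self, toy_panel):
        spec = [("P0", "PAH", "c.1A>G", Zygosity.HET)]
        cohort = _toy_cohort(toy_panel, n=10, call_spec=spec)
        (summary,) = gene_summary(cohort, cohort.calls)
        assert summary.adjusted_carrier_count == summary.carrier_count
        assert summary.adjusted_allele_count == summary.allele_count

    def test_conservation_over_study_cohort(self, study_cohort, study_retained, study_filtered):
        summaries = gene_summary(study_cohort, study_retained,
                                 study_filtered.low_penetrance_flags)
        assert sum(s.allele_count for s in summaries) == \
            sum(c.allele_dose for c in study_retained)
        for s in summaries:
            assert s.carrier_count <= s.allele_count <= 2 * s.carrier_count

    def test_subgroup_carriers_sum_to_overall(self, study_cohort, study_retained):
        total = carrier_rate(study_cohort, study_retained).n_carriers
        parts = sum(
            carrier_rate(study_cohort, study_retained,
                         lambda p, sg=sg: p.subgroup is sg).n_carriers
            for sg in Subgroup
        )
        assert parts == total == 304


class TestCumulativeCarrierRate:
    def test_single_gene_identity(self):
        assert cumulative_carrier_rate({"A": 0.2}) == pytest.approx(0.2)

    def test_two_genes(self):
        assert cumulative_carrier_rate({"A": 0.1, "B": 0.2}) == pytest.approx(0.28)

    def test_28_genes_at_one_percent(self):
        # direct product evaluation as oracle
        expected = 1 - 0.99 ** 28
        assert cumulative_carrier_rate([0.01] * 28) == pytest.approx(expected)

    def test_domain_error(self):
        with pytest.raises(EcsError):
            cumulative_carrier_rate([0.5, 1.2])

    @given(st.lists(st.floats(0, 1), max_size=12))
    def test_bounds_and_order_invariance(self, cfs):
        ccr = cumulative_carrier_rate(cfs)
        assert 0.0 <= ccr <= 1.0
        if cfs:
            assert ccr >= max(cfs) - 1e-12
            assert ccr <= min(1.0, sum(cfs)) + 1e-12
        assert cumulative_carrier_rate(sorted(cfs)) == pytest.approx(ccr)

    @given(st.lists(st.floats(0, 0.99), min_size=1, max_size=8), st.floats(0, 0.01))
    def test_monotone_in_each_frequency(self, cfs, bump):
        base = cumulative_carrier_rate(cfs)
        bumped = cfs.copy()
        bumped[0] = min(1.0, bumped[0] + bump)
        assert cumulative_carrier_rate(bumped) >= base - 1e-12


class TestHweIncidence:
    def test_ar_small_cf(self):
        est = hwe_incidence(0.02, Inheritance.AR)
        assert est.allele_frequency == pytest.approx(0.01)
        assert est.birth_incidence == pytest.approx(1e-4)

    def test_zero_cf(self):
        assert hwe_incidence(0.0, Inheritance.AR).birth_incidence == 0.0

    def test_xlr_male_incidence(self):
        est = hwe_incidence(0.0364, Inheritance.XLR)
        assert est.birth_incidence == pytest.approx(0.0182)

    def test_exact_mode_raises_allele_frequency(self):
        approx = hwe_incidence(0.2, Inheritance.AR)
        exact = hwe_incidence(0.2, Inheritance.AR, exact=True)
        # exact q solves 1-(1-q)^2 = cf, i.e. q = cf/2 + q^2/2 > cf/2
        assert exact.allele_frequency > approx.allele_frequency
        assert exact.birth_incidence <= exact.carrier_frequency

    def test_bad_mode(self):
        with pytest.raises(EcsError):
            hwe_incidence(0.1, "autosomal")


class TestVariantTypes:
    def test_all_snv(self, toy_panel):
        cohort = _toy_cohort(toy_panel, n=2,
                             call_spec=[("P0", "PAH", "c.1A>G", Zygosity.HET)])
        out = variant_type_breakdown(cohort.calls)
        assert out == {"SNV": (1, 1.0)}

    def test_even_split(self, toy_panel):
        calls = [
            VariantCall("P0", "PAH", "c.1A>G", VariantType.SNV, Zygosity.HET, AcmgClass.P),
            VariantCall("P1", "GJB2", "ex.1del", VariantType.CNV_EXON, Zygosity.HET, AcmgClass.P),
        ]
        out = variant_type_breakdown(calls, join_snv_indel=True)
        assert out["CNV"] == (1, 0.5) and out["SNV/indel"] == (1, 0.5)


class TestCnvTable:
    def test_empty_without_cnv_calls(self, toy_panel):
        cohort = _toy_cohort(toy_panel, n=2,
                             call_spec=[("P0", "PAH", "c.1A>G", Zygosity.HET)])
        assert cnv_genotype_table(cohort, cohort.calls).empty

    def test_study_smn1_and_sea_share(self, study_cohort, study_retained):
        table = cnv_genotype_table(study_cohort, study_retained)
        smn1 = table[table.gene == "SMN1"]
        assert int(smn1["count"].sum()) == 8
        assert set(smn1.allele_id) == {"ex.7_8del"}
        assert allele_share(table, "HBA1/HBA2", "--SEA") == pytest.approx(14 / 23)


@given(st.integers(1, 440), st.integers(1, 440))
def test_one_in_n_rounding_sanity(carriers, denom):
    carriers = min(carriers, denom)
    n = one_in_n(carriers, denom)
    cf = carriers / denom
    assert 0.5 <= n * cf <= 1.5
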