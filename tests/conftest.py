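import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
)
settings.load_profile("ci")

from ecscreen.fixtures import reference_cohort
from ecscreen.filtering import apply_filters
from ecscreen.model import (
    AcmgClass,
    Cohort,
    Couple,
    Inheritance,
    PanelEntry,
    Participant,
    Sex,
    Subgroup,
    VariantCall,
    VariantType,
    Zygosity,
)


@pytest.fixture(scope="session")
def study_cohort():
    """Deterministic reconstruction of the published study cohort (raw calls)."""
    return reference_cohort()


@pytest.fixture(scope="session")
def study_filtered(study_cohort):
    return apply_filters(study_cohort.calls, study_cohort.panel)


@pytest.fixture(scope="session")
def study_retained(study_filtered):
    return study_filtered.retained


@pytest.fixture()
def toy_panel():
    return {
        e.gene: e
        for e in [
            PanelEntry("GJB2", Inheritance.AR, "Hearing loss", "auditory",
                       frozenset({"c.109G>A"})),
            PanelEntry("PAH", Inheritance.AR, "PKU", "metabolic/endocrine"),
            PanelEntry("SLC26A4", Inheritance.AR, "Pendred syndrome", "auditory"),
            PanelEntry("G6PD", Inheritance.XLR, "G6PD deficiency", "metabolic/endocrine"),
        ]
    }


def make_couple_cohort(panel, couple_calls):
    """Small fully-paired cohort; couple_calls maps couple index -> list of
    (sex, gene, allele, zygosity)."""
    participants, couples, calls = [], [], []
    n = max(couple_calls, default=0) + 1
    for i in range(n):
        cid = f"C{i}"
        fid, mid = f"{cid}F", f"{cid}M"
        participants.append(Participant(fid, Sex.FEMALE, Subgroup.GS, couple_id=cid))
        participants.append(Participant(mid, Sex.MALE, Subgroup.GS, couple_id=cid))
        couples.append(Couple(cid, fid, mid, Subgroup.GS))
        for sex, gene, allele, zyg in couple_calls.get(i, []):
            pid = fid if sex is Sex.FEMALE else mid
            vtype = VariantType.CNV_EXON if allele.startswith("ex.") else VariantType.SNV
            calls.append(VariantCall(pid, gene, allele, vtype, zyg, AcmgClass.P))
    return Cohort.from_records(participants, couples, calls, panel.values())


@pytest.fixture()
def make_cohort(toy_panel):
    def _make(couple_calls):
        return make_couple_cohort(toy_panel, couple_calls)

    return _make
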