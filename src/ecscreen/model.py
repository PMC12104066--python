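"""Domain types for expanded carrier screening (ECS) cohorts.

An ECS analysis operates on four kinds of records: a *panel* of screened
genes (each with an inheritance mode, an associated condition, a disease
category, and an optional registry of low-penetrance alleles), a *manifest*
of participants paired into couples, classified *variant calls* (one
observation of one allele in one participant, already assigned an ACMG
class), and the :class:`Cohort` container that ties them together and
enforces referential integrity.

All record types are immutable dataclasses; validation happens at
construction and again cohort-wide in :meth:`Cohort.validate`.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Callable, Iterable, Iterator, Optional


class EcsError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(EcsError):
    """A tabular input file is malformed (e.g. a required column is missing)."""


class ValidationError(EcsError):
    """A record violates a domain invariant (closed enum, duplicate key, ...)."""


class ReferentialError(EcsError):
    """A record references an entity that does not exist in the cohort."""


class UndefinedRateError(EcsError):
    """A rate was requested over an empty denominator."""


class DegenerateTableError(EcsError):
    """A contingency table has a zero row or column marginal."""


class Inheritance(str, enum.Enum):
    """Mode of inheritance of a screened condition."""

    AR = "AR"
    XLR = "XLR"


class Sex(str, enum.Enum):
    FEMALE = "female"
    MALE = "male"


class Subgroup(str, enum.Enum):
    """Screening indication.

    GS: genetic-screening indication. MAR_A/B/C: medically assisted
    reproduction subgroups (infertility; spontaneous abortion; second/third
    trimester or postnatal abnormality).
    """

    GS = "GS"
    MAR_A = "MAR_A"
    MAR_B = "MAR_B"
    MAR_C = "MAR_C"

    @property
    def is_mar(self) -> bool:
        return self is not Subgroup.GS


class VariantType(str, enum.Enum):
    SNV = "SNV"
    INDEL = "indel"
    CNV_EXON = "CNV_exon"
    CNV_ALLELE = "CNV_allele"

    @property
    def is_cnv(self) -> bool:
        return self in (VariantType.CNV_EXON, VariantType.CNV_ALLELE)


class Zygosity(str, enum.Enum):
    HET = "het"
    HOM = "hom"
    HEMI = "hemi"

    @property
    def allele_dose(self) -> int:
        """Number of non-reference alleles implied by this zygosity."""
        return 2 if self is Zygosity.HOM else 1


class AcmgClass(str, enum.Enum):
    """Five-tier ACMG/AMP classification."""

    P = "P"
    LP = "LP"
    VUS = "VUS"
    LB = "LB"
    B = "B"


#: Closed set of disease-category labels used by the panel.
DISEASE_CATEGORIES: frozenset[str] = frozenset(
    {
        "metabolic/endocrine",
        "auditory",
        "hematological",
        "nervous",
        "ophthalmologic",
        "musculoskeletal",
        "renal",
        "immune",
        "dermatological",
        "respiratory",
        "hepatic",
        "multisystem",
    }
)

#: Reserved manifest token for unreported ethnicity.
UNKNOWN_ETHNICITY = "unknown"

# Alpha-globin structural haplotypes are printed with superscripts and an
# explicit reference allele (e.g. "αα/--^SEA^"); we store only the
# non-reference allele in a controlled ASCII vocabulary.
CNV_ALLELE_VOCABULARY: frozenset[str] = frozenset(
    {"--SEA", "--THAI", "-a3.7", "-a4.2", "HKaa"}
)

_CNV_ALLELE_ALIASES = {
    "--^SEA^": "--SEA",
    "-^-SEA^": "--SEA",
    "--^THAI^": "--THAI",
    "-α^3.7^": "-a3.7",
    "-α3.7": "-a3.7",
    "-a^3.7^": "-a3.7",
    "-α^4.2^": "-a4.2",
    "-α4.2": "-a4.2",
    "-a^4.2^": "-a4.2",
    "HKαα": "HKaa",
}


def normalize_cnv_allele(allele: str) -> str:
    """Map a typographic CNV-allele spelling to its ASCII canonical form.

    Accepts forms with the reference haplotype prefix ("αα/--^SEA^") and
    superscript markup; returns canonical tokens like "--SEA". Strings that
    are not recognised alpha-globin haplotypes are returned unchanged.
    """
    a = allele.strip()
    for prefix in ("αα/", "aa/"):
        if a.startswith(prefix):
            a = a[len(prefix):]
    return _CNV_ALLELE_ALIASES.get(a, a)


@dataclass(frozen=True)
class PanelEntry:
    """One screened gene: inheritance mode, condition, category, low-penetrance alleles."""

    gene: str
    inheritance: Inheritance
    condition: str
    category: str
    low_penetrance_alleles: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.gene:
            raise ValidationError("panel entry with empty gene symbol")
        if self.category not in DISEASE_CATEGORIES:
            raise ValidationError(
                f"unknown disease category {self.category!r} for gene {self.gene}"
            )


@dataclass(frozen=True)
class Participant:
    id: str
    sex: Sex
    subgroup: Subgroup
    age: Optional[float] = None
    ethnicity: Optional[str] = None
    couple_id: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("participant with empty id")
        if self.age is not None and self.age < 0:
            raise ValidationError(f"negative age for participant {self.id}")


@dataclass(frozen=True)
class Couple:
    couple_id: str
    female_id: str
    male_id: str
    subgroup: Subgroup


@dataclass(frozen=True)
class VariantCall:
    """One classified variant observation in one participant."""

    participant_id: str
    gene: str
    allele_id: str
    variant_type: VariantType
    zygosity: Zygosity
    acmg_class: AcmgClass

    def __post_init__(self) -> None:
        if not self.allele_id:
            raise ValidationError(
                f"call with empty allele_id in gene {self.gene} "
                f"for participant {self.participant_id}"
            )

    @property
    def allele_dose(self) -> int:
        return self.zygosity.allele_dose


@dataclass
class Cohort:
    """Participants, couples, calls and panel, with referential integrity."""

    participants: dict[str, Participant] = field(default_factory=dict)
    couples: list[Couple] = field(default_factory=list)
    calls: list[VariantCall] = field(default_factory=list)
    panel: dict[str, PanelEntry] = field(default_factory=dict)

    # -- construction helpers -------------------------------------------------

    @classmethod
    def from_records(
        cls,
        participants: Iterable[Participant],
        couples: Iterable[Couple],
        calls: Iterable[VariantCall],
        panel: Iterable[PanelEntry],
        validate: bool = True,
    ) -> "Cohort":
        cohort = cls()
        for entry in panel:
            if entry.gene in cohort.panel:
                raise ValidationError(f"duplicate gene symbol on panel: {entry.gene}")
            cohort.panel[entry.gene] = entry
        for p in participants:
            if p.id in cohort.participants:
                raise ValidationError(f"duplicate participant id: {p.id}")
            cohort.participants[p.id] = p
        cohort.couples = list(couples)
        cohort.calls = list(calls)
        if validate:
            cohort.validate()
        return cohort

    # -- accessors ------------------------------------------------------------

    def iter_participants(self, predicate: Optional[Callable[[Participant], bool]] = None) -> Iterator[Participant]:
        for p in self.participants.values():
            if predicate is None or predicate(p):
                yield p

    def females(self) -> list[Participant]:
        return [p for p in self.participants.values() if p.sex is Sex.FEMALE]

    def males(self) -> list[Participant]:
        return [p for p in self.participants.values() if p.sex is Sex.MALE]

    def partner_of(self, participant_id: str) -> Optional[str]:
        for c in self.couples:
            if c.female_id == participant_id:
                return c.male_id
            if c.male_id == participant_id:
                return c.female_id
        return None

    def couple_of(self, participant_id: str) -> Optional[Couple]:
        for c in self.couples:
            if participant_id in (c.female_id, c.male_id):
                return c
        return None

    @property
    def n_participants(self) -> int:
        return len(self.participants)

    @property
    def n_couples(self) -> int:
        return len(self.couples)

    def calls_for(self, participant_id: str) -> list[VariantCall]:
        return [c for c in self.calls if c.participant_id == participant_id]

    # -- validation -----------------------------------------------------------

    def validate(self) -> None:
        """Check cohort-wide invariants; raise on the first violation."""
        for c in self.couples:
            for pid in (c.female_id, c.male_id):
                if pid not in self.participants:
                    raise ReferentialError(
                        f"couple {c.couple_id} references unknown participant {pid}"
                    )
            f, m = self.participants[c.female_id], self.participants[c.male_id]
            if f.sex is not Sex.FEMALE or m.sex is not Sex.MALE:
                raise ValidationError(
                    f"couple {c.couple_id} must pair one female and one male"
                )
            if f.subgroup is not c.subgroup or m.subgroup is not c.subgroup:
                raise ValidationError(
                    f"couple {c.couple_id}: members' subgroups disagree with couple subgroup"
                )
        seen: dict[str, str] = {}
        for c in self.couples:
            for pid in (c.female_id, c.male_id):
                if pid in seen:
                    raise ValidationError(
                        f"participant {pid} appears in couples {seen[pid]} and {c.couple_id}"
                    )
                seen[pid] = c.couple_id

        orphans = sorted(
            {call.participant_id for call in self.calls} - set(self.participants)
        )
        if orphans:
            raise ReferentialError(
                f"calls reference unknown participants: {', '.join(orphans)}"
            )
        for call in self.calls:
            if call.zygosity is Zygosity.HEMI:
                entry = self.panel.get(call.gene)
                carrier = self.participants[call.participant_id]
                if entry is None or entry.inheritance is not Inheritance.XLR or carrier.sex is not Sex.MALE:
                    raise ValidationError(
                        f"hemizygous call in {call.gene} for {call.participant_id}: "
                        "hemizygosity is only valid for XLR genes in males"
                    )
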