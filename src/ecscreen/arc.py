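"""At-risk couple (ARC) detection and offspring-risk arithmetic.

Two mechanisms qualify a couple as at risk:

* ``AR_shared_gene`` — both partners carry a retained P/LP variant in the
  same autosomal recessive gene; each pregnancy has a 1/4 risk of an
  affected child.
* ``XLR_female_carrier`` — the female partner carries a retained P/LP
  variant in an X-linked recessive gene; the transmission risk is recorded
  as 1/2 (the convention under which the risk figure is quoted — per
  pregnancy vs per male pregnancy — is documented, not resolved, in the
  methods note).

Matching for the AR mechanism is by gene symbol, not by allele: trans/cis
phasing of distinct alleles is outside a screening report's scope.
Low-penetrance alleles do not qualify a couple by default (they are not
reportable for reproductive risk), but the switch is exposed.

Couples where the *male* is hemizygous for an XLR variant indicate an
affected or at-risk partner rather than a carrier couple; they are surfaced
by :func:`hemizygous_partner_notes`, never as ARC records.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .model import (
    Cohort,
    EcsError,
    Inheritance,
    UndefinedRateError,
    VariantCall,
    Zygosity,
)

logger = logging.getLogger(__name__)

AR_OFFSPRING_RISK = 0.25
XLR_OFFSPRING_RISK = 0.5


class Mechanism(str, enum.Enum):
    AR_SHARED_GENE = "AR_shared_gene"
    XLR_FEMALE_CARRIER = "XLR_female_carrier"


@dataclass(frozen=True)
class ARCRecord:
    couple_id: str
    mechanism: Mechanism
    gene: str
    condition: str
    offspring_risk: float
    female_calls: tuple[VariantCall, ...]
    male_calls: tuple[VariantCall, ...] = ()
    #: set when the qualifying female is homozygous (grouped with the
    #: heterozygous XLR carriers, flagged rather than a distinct mechanism)
    female_homozygous: bool = False


def _qualifying_calls(
    calls: Iterable[VariantCall],
    flags: Optional[Mapping[VariantCall, bool]],
    include_low_penetrance: bool,
) -> dict[str, dict[str, list[VariantCall]]]:
    """participant -> gene -> qualifying calls."""
    out: dict[str, dict[str, list[VariantCall]]] = {}
    for c in calls:
        if not include_low_penetrance and flags is not None and flags.get(c, False):
            continue
        out.setdefault(c.participant_id, {}).setdefault(c.gene, []).append(c)
    return out


def detect_arcs(
    cohort: Cohort,
    retained_calls: Sequence[VariantCall],
    low_penetrance_flags: Optional[Mapping[VariantCall, bool]] = None,
    include_low_penetrance: bool = False,
) -> list[ARCRecord]:
    """Detect at-risk couples from the retained call set.

    One record per couple × mechanism × gene, ordered by (couple id, gene);
    a couple can appear multiple times. Carriers without a registered
    partner are skipped with a logged warning.
    """
    if low_penetrance_flags is None and not include_low_penetrance:
        from .filtering import flag_low_penetrance

        low_penetrance_flags = {
            c: flag_low_penetrance(c, cohort.panel)
            for c in retained_calls
            if c.gene in cohort.panel
        }
    by_person = _qualifying_calls(retained_calls, low_penetrance_flags, include_low_penetrance)

    paired = {c.female_id for c in cohort.couples} | {c.male_id for c in cohort.couples}
    for pid in sorted(set(by_person) - paired):
        logger.warning("participant %s carries variants but has no partner; skipped", pid)

    records: list[ARCRecord] = []
    for couple in cohort.couples:
        f_genes = by_person.get(couple.female_id, {})
        m_genes = by_person.get(couple.male_id, {})
        for gene in sorted(set(f_genes) | set(m_genes)):
            entry = cohort.panel.get(gene)
            if entry is None:
                raise EcsError(f"retained call in gene {gene} absent from panel")
            if entry.inheritance is Inheritance.AR:
                if gene in f_genes and gene in m_genes:
                    records.append(
                        ARCRecord(
                            couple_id=couple.couple_id,
                            mechanism=Mechanism.AR_SHARED_GENE,
                            gene=gene,
                            condition=entry.condition,
                            offspring_risk=AR_OFFSPRING_RISK,
                            female_calls=tuple(f_genes[gene]),
                            male_calls=tuple(m_genes[gene]),
                        )
                    )
            else:  # XLR: the female partner's carrier status drives the risk
                if gene in f_genes:
                    records.append(
                        ARCRecord(
                            couple_id=couple.couple_id,
                            mechanism=Mechanism.XLR_FEMALE_CARRIER,
                            gene=gene,
                            condition=entry.condition,
                            offspring_risk=XLR_OFFSPRING_RISK,
                            female_calls=tuple(f_genes[gene]),
                            female_homozygous=any(
                                c.zygosity is Zygosity.HOM for c in f_genes[gene]
                            ),
                        )
                    )
    records.sort(key=lambda r: (r.couple_id, r.gene))
    return records


def hemizygous_partner_notes(
    cohort: Cohort, retained_calls: Sequence[VariantCall]
) -> list[tuple[str, str, VariantCall]]:
    """Informational (couple_id, gene, call) rows for hemizygous male partners."""
    notes = []
    for c in retained_calls:
        if c.zygosity is Zygosity.HEMI:
            couple = cohort.couple_of(c.participant_id)
            if couple is not None:
                notes.append((couple.couple_id, c.gene, c))
    notes.sort(key=lambda t: (t[0], t[1]))
    return notes


def arc_rate(
    arcs: Sequence[ARCRecord],
    cohort: Cohort,
    couple_predicate=None,
    exclude_genes: Optional[Iterable[str]] = None,
) -> tuple[int, int, float]:
    """(numerator, denominator, proportion) of at-risk couples.

    The numerator counts distinct couples with ≥1 qualifying record after
    removing records in ``exclude_genes``; the denominator is the couple
    subset size.
    """
    excluded = set(exclude_genes) if exclude_genes else set()
    couples = [c for c in cohort.couples if couple_predicate is None or couple_predicate(c)]
    if not couples:
        raise UndefinedRateError("ARC rate over empty couple subset")
    eligible_ids = {c.couple_id for c in couples}
    hit = {
        r.couple_id
        for r in arcs
        if r.gene not in excluded and r.couple_id in eligible_ids
    }
    n, d = len(hit), len(couples)
    return n, d, n / d


def expected_arc_fraction(
    gene_frequencies: Mapping[str, float],
    panel: Mapping[str, "object"],
) -> float:
    """Analytic ARC probability under gene- and partner-independence.

    For an AR gene with carrier frequency cf, both random partners carry it
    with probability cf²; for an XLR gene the female carries it with
    probability cf. The couple is at risk unless every mechanism misses:
    1 − Π_AR (1 − cf²) · Π_XLR (1 − cf). Used as the oracle that simulated
    cohorts must converge to.
    """
    prob_clear = 1.0
    for gene, cf in gene_frequencies.items():
        if not 0.0 <= cf <= 1.0:
            raise EcsError(f"carrier frequency for {gene} outside [0, 1]")
        entry = panel[gene]
        if entry.inheritance is Inheritance.AR:
            prob_clear *= 1.0 - cf * cf
        else:
            prob_clear *= 1.0 - cf
    return 1.0 - prob_clear
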