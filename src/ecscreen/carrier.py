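"""Carrier rates, variant burden, per-gene carrier frequencies, cumulative
carrier rate (CCR), and Hardy-Weinberg incidence projection.

Conventions
-----------
* A *carrier* is a participant with at least one retained P/LP call in a
  screened gene.
* Allele counting is zygosity-weighted (het/hemi = 1, hom = 2) while
  carrier counting is per person; both views are exported because panel
  reports print allele totals next to per-person carrier rates.
* Carrier-frequency denominators: the whole cohort for autosomal genes;
  females only for X-linked recessive (XLR) genes, since male hemizygotes
  are affected rather than carriers.
* "1 in N" is the reciprocal presentation of a carrier frequency, with N
  rounded half away from zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Optional, Sequence

import numpy as np

from .model import (
    Cohort,
    EcsError,
    Inheritance,
    Participant,
    Sex,
    UndefinedRateError,
    VariantCall,
    VariantType,
)

Predicate = Optional[Callable[[Participant], bool]]


@dataclass(frozen=True)
class BurdenSummary:
    """Carrier rate and mean variant burden for one participant subset."""

    label: str
    n_samples: int
    n_carriers: int
    total_variants: int

    @property
    def carrier_rate(self) -> float:
        return self.n_carriers / self.n_samples

    @property
    def mean_burden(self) -> float:
        """Mean number of retained variants per sample (MBP)."""
        return self.total_variants / self.n_samples


@dataclass(frozen=True)
class CarrierSummary:
    """Per-gene allele and carrier tallies, unadjusted and low-penetrance-adjusted."""

    gene: str
    inheritance: Inheritance
    condition: str
    category: str
    denominator: int
    allele_count: int
    carrier_count: int
    adjusted_allele_count: int
    adjusted_carrier_count: int

    @property
    def carrier_frequency(self) -> float:
        return self.carrier_count / self.denominator

    @property
    def adjusted_carrier_frequency(self) -> float:
        return self.adjusted_carrier_count / self.denominator

    @property
    def one_in_n(self) -> Optional[int]:
        return one_in_n(self.carrier_count, self.denominator)

    @property
    def adjusted_one_in_n(self) -> Optional[int]:
        return one_in_n(self.adjusted_carrier_count, self.denominator)


@dataclass(frozen=True)
class IncidenceEstimate:
    """Hardy-Weinberg projection of birth incidence from a carrier frequency."""

    gene: str
    mode: Inheritance
    carrier_frequency: float
    allele_frequency: float
    birth_incidence: float


def one_in_n(carriers: int, denominator: int) -> Optional[int]:
    """Reciprocal "1 in N" with N rounded half away from zero; None if no carriers."""
    if carriers == 0:
        return None
    return int(math.floor(denominator / carriers + 0.5))


def _subset(cohort: Cohort, predicate: Predicate) -> list[Participant]:
    return list(cohort.iter_participants(predicate))


def _calls_by_participant(calls: Iterable[VariantCall]) -> dict[str, list[VariantCall]]:
    out: dict[str, list[VariantCall]] = {}
    for c in calls:
        out.setdefault(c.participant_id, []).append(c)
    return out


def carrier_rate(
    cohort: Cohort,
    retained_calls: Sequence[VariantCall],
    predicate: Predicate = None,
    label: str = "all",
) -> BurdenSummary:
    """Carrier rate over a participant subset (carrier = ≥1 retained call)."""
    subset = _subset(cohort, predicate)
    if not subset:
        raise UndefinedRateError(f"carrier rate over empty subset {label!r}")
    ids = {p.id for p in subset}
    per_person = _calls_by_participant(c for c in retained_calls if c.participant_id in ids)
    total = sum(len(v) for v in per_person.values())
    return BurdenSummary(label, len(subset), len(per_person), total)


def mean_burden(
    cohort: Cohort,
    retained_calls: Sequence[VariantCall],
    predicate: Predicate = None,
    label: str = "all",
) -> BurdenSummary:
    """Mean variant burden per sample; same summary object as carrier_rate."""
    return carrier_rate(cohort, retained_calls, predicate, label)


def burden_histogram(
    retained_calls: Sequence[VariantCall],
    subset: Iterable[Participant],
) -> dict[int, float]:
    """Proportion of *carriers* harbouring exactly k retained variants.

    The denominator is the number of carriers, not samples; the returned
    proportions sum to 1 (empty dict when there are no carriers).
    """
    ids = {p.id for p in subset}
    per_person = _calls_by_participant(c for c in retained_calls if c.participant_id in ids)
    if not per_person:
        return {}
    counts: dict[int, int] = {}
    for calls in per_person.values():
        counts[len(calls)] = counts.get(len(calls), 0) + 1
    n = len(per_person)
    return {k: v / n for k, v in sorted(counts.items())}


def gene_summary(
    cohort: Cohort,
    retained_calls: Sequence[VariantCall],
    low_penetrance_flags: Optional[Mapping[VariantCall, bool]] = None,
    include_low_penetrance: bool = True,
) -> list[CarrierSummary]:
    """Per-gene allele and carrier tallies over the retained call set.

    ``low_penetrance_flags`` usually comes from
    :class:`~ecscreen.filtering.FilteredCallSet`; when omitted, flags are
    recomputed from the panel's registries. The adjusted fields exclude
    calls whose allele is low-penetrance; with ``include_low_penetrance``
    False the unadjusted fields exclude them as well (the two views then
    coincide).
    """
    from .filtering import flag_low_penetrance

    n_all = cohort.n_participants
    n_female = len(cohort.females())
    by_gene: dict[str, list[VariantCall]] = {}
    for c in retained_calls:
        by_gene.setdefault(c.gene, []).append(c)

    summaries: list[CarrierSummary] = []
    for gene in sorted(by_gene):
        entry = cohort.panel.get(gene)
        if entry is None:
            raise EcsError(f"retained call in gene {gene} absent from panel")
        denom = n_female if entry.inheritance is Inheritance.XLR else n_all
        calls = by_gene[gene]
        flags = {
            c: (low_penetrance_flags[c] if low_penetrance_flags is not None
                else flag_low_penetrance(c, cohort.panel))
            for c in calls
        }
        if not include_low_penetrance:
            calls = [c for c in calls if not flags[c]]
        allele_count = sum(c.allele_dose for c in calls)
        carrier_count = len({c.participant_id for c in calls})
        kept = [c for c in calls if not flags[c]]
        adj_alleles = sum(c.allele_dose for c in kept)
        adj_carriers = len({c.participant_id for c in kept})
        summaries.append(
            CarrierSummary(
                gene=gene,
                inheritance=entry.inheritance,
                condition=entry.condition,
                category=entry.category,
                denominator=denom,
                allele_count=allele_count,
                carrier_count=carrier_count,
                adjusted_allele_count=adj_alleles,
                adjusted_carrier_count=adj_carriers,
            )
        )
    summaries.sort(key=lambda s: (-s.allele_count, s.gene))
    return summaries


def cumulative_carrier_rate(gene_frequencies: Mapping[str, float] | Iterable[float]) -> float:
    """Cumulative carrier rate across a gene set: 1 − Π_g (1 − cf_g).

    The probability of carrying at least one variant across independent
    genes; bounded below by max(cf) and above by Σ cf.
    """
    values = (
        list(gene_frequencies.values())
        if isinstance(gene_frequencies, Mapping)
        else list(gene_frequencies)
    )
    arr = np.asarray(values, dtype=float)
    if arr.size and (arr.min() < 0 or arr.max() > 1):
        raise EcsError("carrier frequencies must lie in [0, 1]")
    return float(1.0 - np.prod(1.0 - arr)) if arr.size else 0.0


def hwe_incidence(
    carrier_frequency: float,
    mode: Inheritance,
    gene: str = "",
    exact: bool = False,
) -> IncidenceEstimate:
    """Project birth incidence from a carrier frequency under Hardy-Weinberg.

    AR: allele frequency q ≈ cf/2 (carriers ≈ heterozygotes when q is
    small) and incidence = q². With ``exact`` True, q = 1 − sqrt(1 − cf),
    treating cf as the probability of carrying ≥1 allele including
    homozygotes. XLR: cf is measured in females, q ≈ cf/2, and the male
    birth incidence is q (affected males are hemizygous).
    """
    if not isinstance(mode, Inheritance):
        raise EcsError(f"unknown inheritance mode: {mode!r}")
    cf = float(carrier_frequency)
    if not 0.0 <= cf <= 1.0:
        raise EcsError("carrier frequency must lie in [0, 1]")
    q = 1.0 - math.sqrt(1.0 - cf) if exact else cf / 2.0
    incidence = q * q if mode is Inheritance.AR else q
    return IncidenceEstimate(gene, mode, cf, q, incidence)


def variant_type_breakdown(
    retained_calls: Sequence[VariantCall],
    join_snv_indel: bool = False,
) -> dict[str, tuple[int, float]]:
    """Counts and proportions of retained calls by variant type.

    With ``join_snv_indel`` True, SNVs and indels are pooled under
    "SNV/indel" and both CNV flavours under "CNV", matching how panel
    reports usually print the split.
    """
    total = len(retained_calls)
    counts: dict[str, int] = {}
    for c in retained_calls:
        if join_snv_indel:
            key = "CNV" if c.variant_type.is_cnv else "SNV/indel"
        else:
            key = c.variant_type.value
        counts[key] = counts.get(key, 0) + 1
    return {k: (v, v / total) for k, v in sorted(counts.items())} if total else {}


def cnv_genotype_table(
    cohort: Cohort,
    retained_calls: Sequence[VariantCall],
    gene_filter: Optional[Iterable[str]] = None,
):
    """Aggregate CNV calls by gene × sex × allele.

    Returns a pandas DataFrame with columns gene, sex, allele_id, count,
    sorted by descending per-gene total then gene/sex/allele — the shape of
    a CNV genotype table.
    """
    import pandas as pd

    genes = set(gene_filter) if gene_filter is not None else None
    rows: dict[tuple[str, str, str], int] = {}
    for c in retained_calls:
        if not c.variant_type.is_cnv:
            continue
        if genes is not None and c.gene not in genes:
            continue
        sex = cohort.participants[c.participant_id].sex.value
        key = (c.gene, sex, c.allele_id)
        rows[key] = rows.get(key, 0) + 1
    df = pd.DataFrame(
        [(g, s, a, n) for (g, s, a), n in rows.items()],
        columns=["gene", "sex", "allele_id", "count"],
    )
    if df.empty:
        return df
    totals = df.groupby("gene")["count"].transform("sum")
    df = df.assign(_total=totals).sort_values(
        ["_total", "gene", "sex", "allele_id"], ascending=[False, True, True, True]
    )
    return df.drop(columns="_total").reset_index(drop=True)


def allele_share(table, gene: str, allele_id: str) -> float:
    """Share of one allele among a gene's CNV observations in a genotype table."""
    sub = table[table["gene"] == gene]
    total = int(sub["count"].sum())
    if total == 0:
        raise UndefinedRateError(f"no CNV observations for gene {gene}")
    return int(sub.loc[sub["allele_id"] == allele_id, "count"].sum()) / total


# -- common subset predicates -------------------------------------------------


def by_sex(sex: Sex) -> Callable[[Participant], bool]:
    return lambda p: p.sex is sex


def by_subgroup(*subgroups) -> Callable[[Participant], bool]:
    wanted = set(subgroups)
    return lambda p: p.subgroup in wanted


def mar_only(p: Participant) -> bool:
    return p.subgroup.is_mar
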