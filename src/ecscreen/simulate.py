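"""Seedable synthetic ECS cohort generator.

The generator draws the statistical structure the downstream analysis
assumes: per gene, each participant is an independent Bernoulli carrier at
the gene's carrier frequency; the carried allele is drawn from the gene's
allele mix; homozygous carriage follows the Hardy-Weinberg-consistent
conditional probability; X-linked recessive genes are sampled in females
only (male hemizygotes optional, off by default). Couples are formed by
random pairing within subgroup. Genes are independent of each other and of
partner status — which is exactly what makes the analytic oracles
(cumulative carrier rate, expected ARC fraction) exact.

Reproducibility: one root seed; each gene draws from its own substream
derived by stable hashing, so adding a gene to the configuration does not
perturb any other gene's draws.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np

from .model import (
    AcmgClass,
    Cohort,
    Couple,
    EcsError,
    Inheritance,
    Participant,
    PanelEntry,
    Sex,
    Subgroup,
    VariantCall,
    VariantType,
    Zygosity,
)

#: Disease-category fallback for genes without one in the config.
_DEFAULT_CATEGORY = "metabolic/endocrine"


@dataclass(frozen=True)
class GeneSimParams:
    """Per-gene simulation parameters.

    carrier_frequency is the probability that a screened individual
    (a female, for XLR genes) carries at least one pathogenic allele.
    allele_mix maps allele id -> proportion (must sum to 1). hom_rate is
    the conditional probability of homozygosity given carriage; None means
    the Hardy-Weinberg-consistent value q^2 / (2q(1-q) + q^2) with
    q = 1 - sqrt(1 - cf). Alleles named in low_penetrance are registered on
    the generated panel entry.
    """

    inheritance: Inheritance
    carrier_frequency: float
    allele_mix: Mapping[str, float] = field(default_factory=lambda: {"c.100A>G": 1.0})
    hom_rate: Optional[float] = None
    low_penetrance: frozenset[str] = frozenset()
    condition: str = ""
    category: str = _DEFAULT_CATEGORY

    def __post_init__(self) -> None:
        if not 0.0 <= self.carrier_frequency <= 1.0:
            raise EcsError("carrier_frequency must lie in [0, 1]")
        total = sum(self.allele_mix.values())
        if self.allele_mix and not math.isclose(total, 1.0, abs_tol=1e-9):
            raise EcsError(f"allele mix proportions must sum to 1 (got {total})")
        if self.hom_rate is not None and not 0.0 <= self.hom_rate <= 1.0:
            raise EcsError("hom_rate must lie in [0, 1]")

    def effective_hom_rate(self) -> float:
        cf = self.carrier_frequency
        if self.hom_rate is not None:
            return self.hom_rate
        if cf in (0.0, 1.0):
            return cf
        q = 1.0 - math.sqrt(1.0 - cf)
        return q * q / cf


@dataclass(frozen=True)
class SimConfig:
    n_couples: int
    seed: int = 0
    gene_params: Mapping[str, GeneSimParams] = field(default_factory=dict)
    subgroup_proportions: Mapping[Subgroup, float] = field(
        default_factory=lambda: {
            Subgroup.GS: 79 / 220,
            Subgroup.MAR_A: 20 / 220,
            Subgroup.MAR_B: 94 / 220,
            Subgroup.MAR_C: 27 / 220,
        }
    )
    male_hemizygotes: bool = False

    def __post_init__(self) -> None:
        if self.n_couples <= 0:
            raise EcsError("n_couples must be positive")
        total = sum(self.subgroup_proportions.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise EcsError(f"subgroup proportions must sum to 1 (got {total})")


def _gene_rng(seed: int, gene: str, purpose: str = "calls") -> np.random.Generator:
    # stable across runs and insertion order: substream keyed by CRC32
    key = zlib.crc32(f"{purpose}:{gene}".encode())
    return np.random.default_rng([seed & 0x7FFFFFFF, key])


def _variant_type_for(allele: str) -> VariantType:
    if allele.startswith("ex."):
        return VariantType.CNV_EXON
    if allele.startswith(("--", "-a", "HK")):
        return VariantType.CNV_ALLELE
    if "del" in allele or "dup" in allele or "ins" in allele or "_" in allele:
        return VariantType.INDEL
    return VariantType.SNV


def generate_cohort(config: SimConfig, seed: Optional[int] = None) -> Cohort:
    """Generate a synthetic cohort; fully reproducible from (config, seed)."""
    root = config.seed if seed is None else seed
    rng = _gene_rng(root, "__cohort__", "structure")

    subgroups = list(config.subgroup_proportions)
    probs = np.array([config.subgroup_proportions[s] for s in subgroups])
    couple_groups = rng.choice(len(subgroups), size=config.n_couples, p=probs)

    participants: list[Participant] = []
    couples: list[Couple] = []
    for i, gi in enumerate(couple_groups):
        sg = subgroups[int(gi)]
        cid = f"S{i + 1:05d}"
        fid, mid = f"{cid}F", f"{cid}M"
        f_age = float(np.round(rng.normal(31.3, 3.5), 1))
        m_age = float(np.round(rng.normal(32.9, 3.5), 1))
        participants.append(Participant(fid, Sex.FEMALE, sg, max(f_age, 18.0), "Han", cid))
        participants.append(Participant(mid, Sex.MALE, sg, max(m_age, 18.0), "Han", cid))
        couples.append(Couple(cid, fid, mid, sg))

    panel: list[PanelEntry] = []
    calls: list[VariantCall] = []
    female_ids = np.array([p.id for p in participants if p.sex is Sex.FEMALE])
    male_ids = np.array([p.id for p in participants if p.sex is Sex.MALE])
    all_ids = np.array([p.id for p in participants])

    for gene in sorted(config.gene_params):
        gp = config.gene_params[gene]
        panel.append(
            PanelEntry(
                gene,
                gp.inheritance,
                gp.condition or f"{gene}-related disorder",
                gp.category,
                gp.low_penetrance,
            )
        )
        grng = _gene_rng(root, gene)
        if gp.inheritance is Inheritance.XLR:
            ids = female_ids
        else:
            ids = all_ids
        if gp.carrier_frequency == 0.0 or ids.size == 0:
            continue
        carrier_mask = grng.random(ids.size) < gp.carrier_frequency
        carrier_ids = ids[carrier_mask]
        if carrier_ids.size == 0:
            continue
        alleles = list(gp.allele_mix)
        mix = np.array([gp.allele_mix[a] for a in alleles])
        chosen = grng.choice(len(alleles), size=carrier_ids.size, p=mix)
        hom = grng.random(carrier_ids.size) < gp.effective_hom_rate()
        is_p = grng.random(carrier_ids.size) < 0.7
        for pid, ai, is_hom, p_cls in zip(carrier_ids, chosen, hom, is_p):
            allele = alleles[int(ai)]
            cls = AcmgClass.P if p_cls else AcmgClass.LP
            calls.append(
                VariantCall(
                    str(pid),
                    gene,
                    allele,
                    _variant_type_for(allele),
                    Zygosity.HOM if is_hom else Zygosity.HET,
                    cls,
                )
            )
        if gp.inheritance is Inheritance.XLR and config.male_hemizygotes:
            q = 1.0 - math.sqrt(1.0 - gp.carrier_frequency)
            hemi_mask = grng.random(male_ids.size) < q
            for pid in male_ids[hemi_mask]:
                ai = int(grng.choice(len(alleles), p=mix))
                calls.append(
                    VariantCall(
                        str(pid), gene, alleles[ai],
                        _variant_type_for(alleles[ai]),
                        Zygosity.HEMI, AcmgClass.P,
                    )
                )

    return Cohort.from_records(participants, couples, calls, panel)


def recover_frequencies(cohort: Cohort) -> dict[str, float]:
    """Estimate per-gene carrier frequencies from a (simulated) cohort.

    Carrier count over the appropriate denominator: all participants for
    autosomal genes, females for XLR genes (hemizygous males excluded).
    """
    n_all = cohort.n_participants
    females = {p.id for p in cohort.females()}
    carriers: dict[str, set[str]] = {g: set() for g in cohort.panel}
    for c in cohort.calls:
        if c.zygosity is Zygosity.HEMI:
            continue
        carriers.setdefault(c.gene, set()).add(c.participant_id)
    out: dict[str, float] = {}
    for gene, entry in cohort.panel.items():
        if entry.inheritance is Inheritance.XLR:
            denom = len(females)
        else:
            denom = n_all
        out[gene] = len(carriers.get(gene, set())) / denom if denom else 0.0
    return out


def study_sim_config(n_couples: int = 220, seed: int = 0) -> SimConfig:
    """Simulation configuration parameterized from the reference cohort.

    Per-gene carrier frequencies and allele mixes are measured from the
    deterministic reference cohort (which reproduces the published
    per-gene allele totals), so a simulated cohort of 220 couples has the
    same expected carrier rate (~69%), burden (~1.16) and ARC fraction as
    the study conditions.
    """
    from .filtering import apply_filters
    from .fixtures import reference_cohort

    cohort = reference_cohort()
    retained = apply_filters(cohort.calls, cohort.panel).retained

    by_gene: dict[str, list[VariantCall]] = {}
    for c in retained:
        by_gene.setdefault(c.gene, []).append(c)

    n_all = cohort.n_participants
    n_female = len(cohort.females())
    gene_params: dict[str, GeneSimParams] = {}
    for gene, calls in by_gene.items():
        entry = cohort.panel[gene]
        denom = n_female if entry.inheritance is Inheritance.XLR else n_all
        carriers = len({c.participant_id for c in calls})
        allele_counts: dict[str, int] = {}
        for c in calls:
            allele_counts[c.allele_id] = allele_counts.get(c.allele_id, 0) + c.allele_dose
        total_alleles = sum(allele_counts.values())
        gene_params[gene] = GeneSimParams(
            inheritance=entry.inheritance,
            carrier_frequency=carriers / denom,
            allele_mix={a: n / total_alleles for a, n in allele_counts.items()},
            low_penetrance=entry.low_penetrance_alleles,
            condition=entry.condition,
            category=entry.category,
        )
    return SimConfig(n_couples=n_couples, seed=seed, gene_params=gene_params)
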