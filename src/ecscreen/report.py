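"""Pipeline orchestration and report rendering.

``run_pipeline`` composes filter → summarize → ARC detection → subgroup
comparison over one cohort and writes a bundle of tabular outputs (burden
table, per-gene carrier summary, CNV genotype table, ARC list) plus a
``stats.json`` whose numbers are exactly the module-level operations'
outputs (raw fractions alongside 2-decimal formatted percents).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import arc as arc_mod
from . import carrier as carrier_mod
from . import stats as stats_mod
from .filtering import FilterConfig, apply_filters
from .io import load_cohort, write_calls
from .model import Cohort, DegenerateTableError, Inheritance, Sex, Subgroup

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    panel_path: Optional[str] = None
    manifest_path: Optional[str] = None
    calls_path: Optional[str] = None
    out_dir: str = "ecs_out"
    include_low_penetrance: bool = True
    arc_exclude_genes: frozenset[str] = frozenset()
    yates: bool = False
    seed: int = 0


@dataclass
class ReportBundle:
    burden: pd.DataFrame
    genes: pd.DataFrame
    cnv: pd.DataFrame
    arcs: pd.DataFrame
    stats: dict = field(default_factory=dict)


def _pct(x: float) -> str:
    return f"{100.0 * x:.2f}%"


def _rate_entry(numerator: int, denominator: int) -> dict:
    frac = numerator / denominator
    return {
        "numerator": numerator,
        "denominator": denominator,
        "fraction": frac,
        "percent": _pct(frac),
    }


def build_report(cohort: Cohort, config: RunConfig | None = None) -> ReportBundle:
    """Run the full downstream analysis on an in-memory cohort."""
    config = config or RunConfig()
    filtered = apply_filters(cohort.calls, cohort.panel, FilterConfig())
    retained = filtered.retained
    logger.info("filter: %d calls in, %d retained, %d dropped",
                len(cohort.calls), len(retained), len(filtered.dropped))

    # burden table (per sex and per sex x subgroup)
    rows = []
    subsets: list[tuple[str, object]] = [
        ("female", carrier_mod.by_sex(Sex.FEMALE)),
        ("male", carrier_mod.by_sex(Sex.MALE)),
    ]
    for sg in Subgroup:
        for sex in (Sex.FEMALE, Sex.MALE):
            subsets.append(
                (f"{sg.value}/{sex.value}",
                 lambda p, sg=sg, sex=sex: p.subgroup is sg and p.sex is sex)
            )
    for label, pred in subsets:
        s = carrier_mod.carrier_rate(cohort, retained, pred, label)
        rows.append(
            {
                "group": label,
                "n_samples": s.n_samples,
                "n_carriers": s.n_carriers,
                "total_variants": s.total_variants,
                "carrier_rate": s.carrier_rate,
                "mean_burden": s.mean_burden,
            }
        )
    burden_df = pd.DataFrame(rows)

    summaries = carrier_mod.gene_summary(
        cohort, retained, filtered.low_penetrance_flags,
        include_low_penetrance=config.include_low_penetrance,
    )
    genes_df = pd.DataFrame(
        {
            "gene": s.gene,
            "inheritance": s.inheritance.value,
            "condition": s.condition,
            "category": s.category,
            "allele_count": s.allele_count,
            "carrier_count": s.carrier_count,
            "carrier_frequency": s.carrier_frequency,
            "one_in_n": s.one_in_n,
            "adjusted_carrier_count": s.adjusted_carrier_count,
            "adjusted_one_in_n": s.adjusted_one_in_n,
        }
        for s in summaries
    )

    cnv_df = carrier_mod.cnv_genotype_table(cohort, retained)

    arcs = arc_mod.detect_arcs(cohort, retained, filtered.low_penetrance_flags)
    arcs_df = pd.DataFrame(
        {
            "couple_id": r.couple_id,
            "mechanism": r.mechanism.value,
            "gene": r.gene,
            "condition": r.condition,
            "offspring_risk": r.offspring_risk,
            "female_homozygous": r.female_homozygous,
        }
        for r in arcs
    )

    overall = carrier_mod.carrier_rate(cohort, retained)
    female = carrier_mod.carrier_rate(cohort, retained, carrier_mod.by_sex(Sex.FEMALE))
    male = carrier_mod.carrier_rate(cohort, retained, carrier_mod.by_sex(Sex.MALE))
    xlr_calls = [c for c in retained
                 if cohort.panel[c.gene].inheritance is Inheritance.XLR]
    n_female = len(cohort.females())
    type_split = carrier_mod.variant_type_breakdown(retained, join_snv_indel=True)

    stats: dict = {
        "n_participants": cohort.n_participants,
        "n_couples": cohort.n_couples,
        "retained_calls": len(retained),
        "dropped_calls": len(filtered.dropped),
        "carrier_rate": _rate_entry(overall.n_carriers, overall.n_samples),
        "female_carrier_rate": _rate_entry(female.n_carriers, female.n_samples),
        "male_carrier_rate": _rate_entry(male.n_carriers, male.n_samples),
        "mean_burden": overall.mean_burden,
        "female_mean_burden": female.mean_burden,
        "male_mean_burden": male.mean_burden,
        "xlinked_female_rate": _rate_entry(len(xlr_calls), n_female) if n_female else None,
        "burden_histogram": {
            str(k): v
            for k, v in carrier_mod.burden_histogram(
                retained, cohort.participants.values()
            ).items()
        },
        "variant_types": {
            k: {"count": n, "fraction": f, "percent": _pct(f)}
            for k, (n, f) in type_split.items()
        },
        "cumulative_carrier_rate": carrier_mod.cumulative_carrier_rate(
            {s.gene: s.carrier_frequency for s in summaries}
        ),
    }

    if cohort.couples:
        n, d, f = arc_mod.arc_rate(arcs, cohort)
        stats["arc_rate"] = _rate_entry(n, d)
        if config.arc_exclude_genes:
            n, d, f = arc_mod.arc_rate(arcs, cohort, exclude_genes=config.arc_exclude_genes)
            stats["arc_rate_excluding"] = {
                "genes": sorted(config.arc_exclude_genes),
                **_rate_entry(n, d),
            }
        # GS vs MAR comparisons (carriers by sex; ARC by couple) where possible
        comparisons = {}
        for sex, label in ((Sex.FEMALE, "female"), (Sex.MALE, "male")):
            try:
                gs = carrier_mod.carrier_rate(
                    cohort, retained,
                    lambda p, sex=sex: p.sex is sex and p.subgroup is Subgroup.GS)
                mar = carrier_mod.carrier_rate(
                    cohort, retained,
                    lambda p, sex=sex: p.sex is sex and p.subgroup.is_mar)
            except Exception:
                continue
            table = stats_mod.carrier_table(
                gs.n_carriers, gs.n_samples, mar.n_carriers, mar.n_samples
            )
            try:
                plain = stats_mod.pearson_chi2(table)
                yates = stats_mod.pearson_chi2(table, yates=True)
            except DegenerateTableError:
                continue  # e.g. a cohort with no carriers at all
            comparisons[f"{label}_gs_vs_mar"] = {
                "table": plain.table,
                "chi2": plain.chi2,
                "p_value": plain.p_value,
                "chi2_yates": yates.chi2,
                "p_value_yates": yates.p_value,
            }
        stats["subgroup_comparisons"] = comparisons

    return ReportBundle(burden_df, genes_df, cnv_df, arcs_df, stats)


def write_bundle(bundle: ReportBundle, out_dir) -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "burden": out / "burden.tsv",
        "genes": out / "gene_summary.tsv",
        "cnv": out / "cnv_genotypes.tsv",
        "arcs": out / "arcs.tsv",
        "stats": out / "stats.json",
        "report": out / "report.md",
    }
    bundle.burden.to_csv(paths["burden"], sep="\t", index=False)
    bundle.genes.to_csv(paths["genes"], sep="\t", index=False)
    bundle.cnv.to_csv(paths["cnv"], sep="\t", index=False)
    bundle.arcs.to_csv(paths["arcs"], sep="\t", index=False)
    with open(paths["stats"], "w", encoding="utf-8") as fh:
        json.dump(bundle.stats, fh, indent=2, sort_keys=True)
        fh.write("\n")
    paths["report"].write_text(render_markdown_report(bundle), encoding="utf-8")
    return paths


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Load a cohort from TSV inputs, analyse it, and write the report bundle."""
    for name in ("panel_path", "manifest_path", "calls_path"):
        value = getattr(config, name)
        if value is None or not Path(value).exists():
            raise FileNotFoundError(f"{name.replace('_path', '')} file not found: {value}")
    cohort = load_cohort(config.panel_path, config.manifest_path, config.calls_path)
    bundle = build_report(cohort, config)
    write_bundle(bundle, config.out_dir)
    return bundle


def render_markdown_report(bundle: ReportBundle) -> str:
    """Deterministic human-readable report over one bundle."""
    s = bundle.stats
    lines = [
        "# Expanded carrier screening report",
        "",
        f"Participants: {s['n_participants']}  |  Couples: {s['n_couples']}  |  "
        f"Retained P/LP calls: {s['retained_calls']} "
        f"(dropped: {s['dropped_calls']})",
        "",
        "## Carrier rates and burden",
        "",
        "| group | n | carriers | variants | carrier rate | mean burden |",
        "|---|---|---|---|---|---|",
    ]
    for _, row in bundle.burden.iterrows():
        lines.append(
            f"| {row['group']} | {row['n_samples']} | {row['n_carriers']} | "
            f"{row['total_variants']} | {100 * row['carrier_rate']:.2f}% | "
            f"{row['mean_burden']:.2f} |"
        )
    lines += ["", "## Per-gene carrier frequencies", "",
              "| gene | condition | alleles | carriers | 1 in N | adjusted 1 in N |",
              "|---|---|---|---|---|---|"]
    for _, row in bundle.genes.head(30).iterrows():
        adj = row["adjusted_one_in_n"]
        lines.append(
            f"| {row['gene']} | {row['condition']} | {row['allele_count']} | "
            f"{row['carrier_count']} | {row['one_in_n']} | "
            f"{'-' if pd.isna(adj) else int(adj)} |"
        )
    lines += ["", "## CNV genotypes", ""]
    if bundle.cnv.empty:
        lines.append("none detected")
    else:
        lines += ["| gene | sex | allele | count |", "|---|---|---|---|"]
        for _, row in bundle.cnv.iterrows():
            lines.append(
                f"| {row['gene']} | {row['sex']} | {row['allele_id']} | {row['count']} |"
            )
    lines += ["", "## At-risk couples", ""]
    if bundle.arcs.empty:
        lines.append("none detected")
    else:
        lines += ["| couple | mechanism | gene | condition | offspring risk |",
                  "|---|---|---|---|---|"]
        for _, row in bundle.arcs.iterrows():
            lines.append(
                f"| {row['couple_id']} | {row['mechanism']} | {row['gene']} | "
                f"{row['condition']} | {row['offspring_risk']} |"
            )
    if "arc_rate" in s:
        lines.append("")
        lines.append(f"ARC rate: {s['arc_rate']['percent']} "
                     f"({s['arc_rate']['numerator']}/{s['arc_rate']['denominator']})")
    lines += [
        "",
        "---",
        "Note: chi-squared statistics are reported both uncorrected (Pearson) and",
        "with the Yates continuity correction; published tables sometimes mix the",
        "two conventions, so both are emitted rather than guessing intent.",
        "",
    ]
    return "\n".join(lines)
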