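"""Readers and writers for the tabular cohort formats.

Dialect: UTF-8, tab-separated, one header row, ``.`` for missing optional
fields. Three files describe a cohort:

* ``panel.tsv`` — gene, inheritance, condition, category,
  low_penetrance_alleles (comma-joined, may be empty or ``.``)
* ``manifest.tsv`` — participant_id, sex, age, ethnicity, subgroup, couple_id
* ``calls.tsv`` — participant_id, gene, allele_id, variant_type, zygosity,
  acmg_class

A minimal VCF ingestion path (gene/class from INFO keys ``GENE``/``ACMG``)
is provided in :func:`read_calls_vcf` for convenience; TSV is the primary
interchange format.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Union

from .model import (
    AcmgClass,
    Couple,
    FormatError,
    Inheritance,
    Participant,
    PanelEntry,
    ReferentialError,
    Sex,
    Subgroup,
    UNKNOWN_ETHNICITY,
    ValidationError,
    VariantCall,
    VariantType,
    Zygosity,
    normalize_cnv_allele,
)

MISSING = "."

PANEL_COLUMNS = ["gene", "inheritance", "condition", "category", "low_penetrance_alleles"]
MANIFEST_COLUMNS = ["participant_id", "sex", "age", "ethnicity", "subgroup", "couple_id"]
CALLS_COLUMNS = ["participant_id", "gene", "allele_id", "variant_type", "zygosity", "acmg_class"]

PathLike = Union[str, Path]


def _read_rows(path: PathLike, required: list[str]) -> list[dict[str, str]]:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"input file not found: {path}")
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        header = reader.fieldnames or []
        for col in required:
            if col not in header:
                raise FormatError(f"{path}: missing required column {col!r}")
        return list(reader)


def _parse_enum(enum_cls, token: str, field: str, row_no: int):
    try:
        return enum_cls(token)
    except ValueError:
        valid = ", ".join(e.value for e in enum_cls)
        raise ValidationError(
            f"row {row_no}: unknown {field} token {token!r} (expected one of: {valid})"
        ) from None


def read_panel(path: PathLike) -> list[PanelEntry]:
    """Read a gene panel table; duplicate gene symbols are rejected."""
    entries: list[PanelEntry] = []
    seen: set[str] = set()
    for i, row in enumerate(_read_rows(path, PANEL_COLUMNS), start=2):
        gene = row["gene"].strip()
        if gene in seen:
            raise ValidationError(f"duplicate gene symbol in panel: {gene}")
        seen.add(gene)
        lp_raw = (row.get("low_penetrance_alleles") or "").strip()
        lp = frozenset(
            a.strip() for a in lp_raw.split(",") if a.strip() and a.strip() != MISSING
        ) if lp_raw not in ("", MISSING) else frozenset()
        entries.append(
            PanelEntry(
                gene=gene,
                inheritance=_parse_enum(Inheritance, row["inheritance"].strip(), "inheritance", i),
                condition=row["condition"].strip(),
                category=row["category"].strip(),
                low_penetrance_alleles=lp,
            )
        )
    return entries


def read_manifest(path: PathLike) -> tuple[list[Participant], list[Couple]]:
    """Read a sample manifest and assemble couples from shared couple_id.

    Each couple_id must be shared by exactly one female and one male with
    the same subgroup.
    """
    participants: list[Participant] = []
    by_couple: dict[str, list[Participant]] = {}
    for i, row in enumerate(_read_rows(path, MANIFEST_COLUMNS), start=2):
        age_tok = row["age"].strip()
        eth_tok = row["ethnicity"].strip()
        cid_tok = row["couple_id"].strip()
        p = Participant(
            id=row["participant_id"].strip(),
            sex=_parse_enum(Sex, row["sex"].strip(), "sex", i),
            subgroup=_parse_enum(Subgroup, row["subgroup"].strip(), "subgroup", i),
            age=None if age_tok == MISSING else float(age_tok),
            ethnicity=None if eth_tok == MISSING else eth_tok,
            couple_id=None if cid_tok == MISSING else cid_tok,
        )
        participants.append(p)
        if p.couple_id is not None:
            by_couple.setdefault(p.couple_id, []).append(p)

    ids = [p.id for p in participants]
    if len(ids) != len(set(ids)):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValidationError(f"duplicate participant ids in manifest: {', '.join(dupes)}")

    couples: list[Couple] = []
    for cid, members in by_couple.items():
        if len(members) != 2:
            raise ValidationError(
                f"couple {cid} has {len(members)} members (expected exactly 2)"
            )
        sexes = {m.sex for m in members}
        if sexes != {Sex.FEMALE, Sex.MALE}:
            raise ValidationError(
                f"couple {cid} must pair one female and one male"
            )
        female = next(m for m in members if m.sex is Sex.FEMALE)
        male = next(m for m in members if m.sex is Sex.MALE)
        if female.subgroup is not male.subgroup:
            raise ValidationError(f"couple {cid}: members' subgroups disagree")
        couples.append(Couple(cid, female.id, male.id, female.subgroup))
    couples.sort(key=lambda c: c.couple_id)
    return participants, couples


def read_calls(path: PathLike, participants: Iterable[Participant]) -> list[VariantCall]:
    """Read classified variant calls, resolving participant ids against the manifest."""
    known = {p.id for p in participants}
    calls: list[VariantCall] = []
    orphan_rows: list[int] = []
    for i, row in enumerate(_read_rows(path, CALLS_COLUMNS), start=2):
        pid = row["participant_id"].strip()
        if pid not in known:
            orphan_rows.append(i)
            continue
        calls.append(
            VariantCall(
                participant_id=pid,
                gene=row["gene"].strip(),
                allele_id=normalize_cnv_allele(row["allele_id"].strip()),
                variant_type=_parse_enum(VariantType, row["variant_type"].strip(), "variant_type", i),
                zygosity=_parse_enum(Zygosity, row["zygosity"].strip(), "zygosity", i),
                acmg_class=_parse_enum(AcmgClass, row["acmg_class"].strip(), "acmg_class", i),
            )
        )
    if orphan_rows:
        raise ReferentialError(
            f"{path}: rows reference participants absent from the manifest: "
            f"rows {', '.join(map(str, orphan_rows))}"
        )
    return calls


def read_calls_vcf(path: PathLike, participants: Iterable[Participant]) -> list[VariantCall]:
    """Ingest calls from a VCF with one sample column per participant.

    Gene and ACMG class are taken from INFO keys ``GENE`` and ``ACMG``;
    symbolic ALT alleles (e.g. ``<--SEA>``) are treated as CNV alleles and
    ``<DEL>``-style exon events should instead carry their ``ex.`` label in
    an ``ALLELE`` INFO key. Secondary to the TSV path.
    """
    from cyvcf2 import VCF  # deferred: optional dependency

    known = {p.id for p in participants}
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    unknown = sorted(set(samples) - known)
    if unknown:
        raise ReferentialError(
            f"{path}: VCF samples absent from the manifest: {', '.join(unknown)}"
        )
    calls: list[VariantCall] = []
    for variant in vcf:
        gene = variant.INFO.get("GENE")
        acmg = variant.INFO.get("ACMG")
        if gene is None or acmg is None:
            raise FormatError(f"{path}: record without GENE/ACMG INFO keys")
        alt = variant.ALT[0] if variant.ALT else ""
        if alt.startswith("<") and alt.endswith(">"):
            allele = normalize_cnv_allele(alt[1:-1])
            vtype = VariantType.CNV_EXON if allele.startswith("ex.") else VariantType.CNV_ALLELE
        else:
            allele = variant.INFO.get("ALLELE") or f"c.{variant.POS}{variant.REF}>{alt}"
            vtype = VariantType.SNV if len(variant.REF) == len(alt) == 1 else VariantType.INDEL
        for sample, gt in zip(samples, variant.gt_types):
            # cyvcf2 gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
            if gt == 1:
                zyg = Zygosity.HET
            elif gt == 3:
                zyg = Zygosity.HOM
            else:
                continue
            calls.append(
                VariantCall(sample, gene, allele, vtype, zyg, AcmgClass(acmg))
            )
    return calls


# -- writers ------------------------------------------------------------------


def _write_rows(path: PathLike, columns: list[str], rows: Iterable[list[str]]) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(columns)
        writer.writerows(rows)


def write_panel(path: PathLike, entries: Iterable[PanelEntry]) -> None:
    _write_rows(
        path,
        PANEL_COLUMNS,
        (
            [
                e.gene,
                e.inheritance.value,
                e.condition,
                e.category,
                ",".join(sorted(e.low_penetrance_alleles)) or MISSING,
            ]
            for e in entries
        ),
    )


def write_manifest(path: PathLike, participants: Iterable[Participant]) -> None:
    _write_rows(
        path,
        MANIFEST_COLUMNS,
        (
            [
                p.id,
                p.sex.value,
                MISSING if p.age is None else f"{p.age:g}",
                p.ethnicity if p.ethnicity is not None else MISSING,
                p.subgroup.value,
                p.couple_id if p.couple_id is not None else MISSING,
            ]
            for p in participants
        ),
    )


def write_calls(path: PathLike, calls: Iterable[VariantCall]) -> None:
    _write_rows(
        path,
        CALLS_COLUMNS,
        (
            [
                c.participant_id,
                c.gene,
                c.allele_id,
                c.variant_type.value,
                c.zygosity.value,
                c.acmg_class.value,
            ]
            for c in calls
        ),
    )


def load_cohort(
    panel_path: PathLike, manifest_path: PathLike, calls_path: PathLike
):
    """Load a full cohort from its three TSV files and validate it."""
    from .model import Cohort

    panel = read_panel(panel_path)
    participants, couples = read_manifest(manifest_path)
    calls = read_calls(calls_path, participants)
    return Cohort.from_records(participants, couples, calls, panel)


def write_cohort(cohort, out_dir: PathLike) -> dict[str, Path]:
    """Write a cohort's three TSV files into ``out_dir``; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "panel": out / "panel.tsv",
        "manifest": out / "manifest.tsv",
        "calls": out / "calls.tsv",
    }
    write_panel(paths["panel"], cohort.panel.values())
    write_manifest(paths["manifest"], cohort.participants.values())
    write_calls(paths["calls"], cohort.calls)
    return paths
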