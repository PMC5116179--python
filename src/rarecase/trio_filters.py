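"""Trio-aware variant selection rules and whole-set classification.

Four procedures are applied to each variant site joined across the
family (tumor, patient leukocyte, mother, father):

* **somatic** — depth >= 10x in both tumor and patient leukocyte,
  tumor alternate fraction >= 20%, and no alternate support in the
  leukocyte.
* **de novo** — depth >= 10x in all three leukocyte samples, patient
  alternate fraction >= 30%, and neither parent carrying the allele.
* **rare homozygous** — patient homozygous for the alternate allele,
  both parents heterozygous, population MAF <= 10%.
* **compound heterozygous** — a gene with two distinct patient-het
  variants, each exclusively inherited from a different parent, each
  with MAF <= 10%.

All stated thresholds are inclusive (the somatic table contains an
exactly-20% variant), and every failure is reported with a
machine-readable reason code so exclusions stay auditable.
"""

from __future__ import annotations

import itertools
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .variant_io import TrioRecord, VariantCall

#: Classification outcome when required samples are absent: distinct
#: from False — the rule simply cannot be evaluated.
INDETERMINATE = None


@dataclass(frozen=True)
class FilterThresholds:
    """Thresholds of the selection rules.

    ``somatic_max_normal_vaf`` (tolerated alternate support in the
    normal for somatic/de novo absence checks) defaults to strict 0
    because the design leaves it unstated; it is exposed for noisier
    callers.  The het/hom genotype bounds are used only when a record
    carries no explicit genotype call.
    """

    min_depth: int = 10
    somatic_min_tumor_vaf: float = 0.20
    denovo_min_vaf: float = 0.30
    rare_maf_max: float = 0.10
    het_vaf_low: float = 0.15
    het_vaf_high: float = 0.80  # also the hom_alt minimum
    hom_vaf_min: float = 0.80
    somatic_max_normal_vaf: float = 0.0

    def __post_init__(self) -> None:
        if not 0 < self.het_vaf_low < self.het_vaf_high <= self.hom_vaf_min <= 1:
            raise ValueError("require 0 < het_low < het_high <= hom_min <= 1")
        for name in (
            "somatic_min_tumor_vaf", "denovo_min_vaf", "rare_maf_max",
            "somatic_max_normal_vaf",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.min_depth < 0:
            raise ValueError("min_depth must be >= 0")


@dataclass
class ClassifiedVariant:
    """A record with every class it satisfies, and why others failed."""

    record: TrioRecord
    classes: set[str] = field(default_factory=set)
    failure_reasons: dict[str, str] = field(default_factory=dict)
    comphet_partners: list[tuple[str, int, str, str]] = field(default_factory=list)


def genotype_class(call: VariantCall, thresholds: FilterThresholds) -> str:
    """Explicit genotype when present, else derived from the alt fraction."""
    if call.genotype_class is not None:
        return call.genotype_class
    if call.depth == 0:
        return "missing"
    f = call.alt_fraction
    if f >= thresholds.hom_vaf_min:
        return "hom_alt"
    if f >= thresholds.het_vaf_low:
        return "het"
    return "hom_ref"


def _maf_is_rare(maf: float | None, thresholds: FilterThresholds) -> bool:
    # Unreported population frequency is treated as rare: several
    # confirmed germline hits carry dbSNP IDs with no published MAF.
    return maf is None or maf <= thresholds.rare_maf_max


def call_somatic(
    record: TrioRecord, thresholds: FilterThresholds = FilterThresholds()
) -> tuple[bool | None, str]:
    """Somatic rule on the tumor / patient-leukocyte pair."""
    tumor = record.call("tumor")
    normal = record.call("patient")
    if tumor is None or normal is None:
        return INDETERMINATE, "missing_sample"
    if tumor.depth < thresholds.min_depth:
        return False, "low_depth_tumor"
    if normal.depth < thresholds.min_depth:
        return False, "low_depth_normal"
    if tumor.alt_fraction < thresholds.somatic_min_tumor_vaf:
        return False, "low_vaf"
    if normal.alt_fraction > thresholds.somatic_max_normal_vaf:
        return False, "normal_support"
    return True, "ok"


def call_de_novo(
    record: TrioRecord, thresholds: FilterThresholds = FilterThresholds()
) -> tuple[bool | None, str]:
    """De novo rule on the three leukocyte samples."""
    patient = record.call("patient")
    mother = record.call("mother")
    father = record.call("father")
    if patient is None or mother is None or father is None:
        return INDETERMINATE, "missing_sample"
    for role, call in (("patient", patient), ("mother", mother), ("father", father)):
        if call.depth < thresholds.min_depth:
            return False, f"low_depth_{role}"
    if patient.alt_fraction < thresholds.denovo_min_vaf:
        return False, "low_vaf"
    if mother.alt_fraction > thresholds.somatic_max_normal_vaf:
        return False, "inherited_maternal"
    if father.alt_fraction > thresholds.somatic_max_normal_vaf:
        return False, "inherited_paternal"
    return True, "ok"


def call_rare_homozygous(
    record: TrioRecord, thresholds: FilterThresholds = FilterThresholds()
) -> tuple[bool | None, str]:
    """Recessive rule: patient hom-alt, both parents het, MAF <= max."""
    patient = record.call("patient")
    mother = record.call("mother")
    father = record.call("father")
    if patient is None or mother is None or father is None:
        return INDETERMINATE, "missing_sample"
    for role, call in (("patient", patient), ("mother", mother), ("father", father)):
        if call.depth < thresholds.min_depth:
            return False, f"low_depth_{role}"
    if genotype_class(patient, thresholds) != "hom_alt":
        return False, "patient_not_homozygous"
    if genotype_class(mother, thresholds) != "het":
        return False, "mother_not_het"
    if genotype_class(father, thresholds) != "het":
        return False, "father_not_het"
    if not _maf_is_rare(record.population_maf, thresholds):
        return False, "common_maf"
    return True, "ok"


def _comphet_origin(
    record: TrioRecord, thresholds: FilterThresholds
) -> tuple[str | None, str]:
    """Parental origin of a candidate compound-het member.

    Returns ``("maternal"|"paternal", "ok")`` for an eligible variant:
    patient het, carrier parent het, and the other parent free of the
    alternate allele ("exclusively present in one of his parents").
    A variant het in both parents is unphasable and simply ineligible.
    """
    patient = record.call("patient")
    mother = record.call("mother")
    father = record.call("father")
    if patient is None or mother is None or father is None:
        return None, "missing_sample"
    for role, call in (("patient", patient), ("mother", mother), ("father", father)):
        if call.depth < thresholds.min_depth:
            return None, f"low_depth_{role}"
    if genotype_class(patient, thresholds) != "het":
        return None, "patient_not_het"
    if not _maf_is_rare(record.population_maf, thresholds):
        return None, "common_maf"
    mother_carries = mother.alt_fraction > thresholds.somatic_max_normal_vaf
    father_carries = father.alt_fraction > thresholds.somatic_max_normal_vaf
    if mother_carries and father_carries:
        return None, "both_parents_carry"
    if mother_carries and genotype_class(mother, thresholds) == "het":
        return "maternal", "ok"
    if father_carries and genotype_class(father, thresholds) == "het":
        return "paternal", "ok"
    return None, "no_parental_het"


def call_compound_het(
    records_by_gene: Mapping[str, Sequence[TrioRecord]],
    thresholds: FilterThresholds = FilterThresholds(),
) -> dict[str, list[tuple[TrioRecord, TrioRecord]]]:
    """Report genes with >=1 maternal-only and >=1 paternal-only het.

    Returns gene -> list of all valid (maternal, paternal) variant
    pairs.  Genes whose eligible variants all share one parental origin
    (cis candidates) are not reported.
    """
    out: dict[str, list[tuple[TrioRecord, TrioRecord]]] = {}
    for gene, records in records_by_gene.items():
        maternal, paternal = [], []
        for rec in records:
            origin, _ = _comphet_origin(rec, thresholds)
            if origin == "maternal":
                maternal.append(rec)
            elif origin == "paternal":
                paternal.append(rec)
        if maternal and paternal:
            out[gene] = [
                (m, p) for m, p in itertools.product(maternal, paternal)
            ]
    return out


def group_by_gene(records: Iterable[TrioRecord]) -> dict[str, list[TrioRecord]]:
    grouped: dict[str, list[TrioRecord]] = defaultdict(list)
    for rec in records:
        if rec.gene:
            grouped[rec.gene].append(rec)
    return dict(grouped)


def classify_all(
    records: Sequence[TrioRecord],
    thresholds: FilterThresholds = FilterThresholds(),
) -> tuple[list[ClassifiedVariant], dict[str, int]]:
    """Apply every rule to every record and summarize the counts.

    The summary reports per-class counts and the protein-affecting
    subset (consequence other than synonymous), plus the number of
    compound-het genes.
    """
    classified = [ClassifiedVariant(rec) for rec in records]
    by_id = {id(rec): cv for rec, cv in zip(records, classified)}

    for cv in classified:
        for name, rule in (
            ("somatic", call_somatic),
            ("de_novo", call_de_novo),
            ("rare_homozygous", call_rare_homozygous),
        ):
            verdict, reason = rule(cv.record, thresholds)
            if verdict:
                cv.classes.add(name)
            else:
                cv.failure_reasons[name] = reason

    comphet = call_compound_het(group_by_gene(records), thresholds)
    for gene, pairs in comphet.items():
        for m_rec, p_rec in pairs:
            by_id[id(m_rec)].classes.add("compound_het_member")
            by_id[id(m_rec)].comphet_partners.append(p_rec.key)
            by_id[id(p_rec)].classes.add("compound_het_member")
            by_id[id(p_rec)].comphet_partners.append(m_rec.key)

    def count(cls: str, protein_affecting: bool = False) -> int:
        return sum(
            1
            for cv in classified
            if cls in cv.classes
            and (not protein_affecting or cv.record.consequence != "synonymous")
        )

    summary = {
        "n_records": len(classified),
        "somatic": count("somatic"),
        "somatic_protein_affecting": count("somatic", protein_affecting=True),
        "de_novo": count("de_novo"),
        "rare_homozygous": count("rare_homozygous"),
        "compound_het_members": count("compound_het_member"),
        "compound_het_genes": len(comphet),
    }
    return classified, summary
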