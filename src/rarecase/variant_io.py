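"""Variant containers, multi-sample VCF I/O and the case-study table fixtures.

The central container is :class:`TrioRecord` — one variant site joined
across the four samples of the family design (tumor, patient leukocyte,
mother, father) together with its annotations (gene, functional
consequence, population minor-allele frequency).

VCFs are read and written through :mod:`pysam` using a minimal v4.2
profile with ``GT:DP:AF`` per sample; ``AF`` carries the alternate-read
fraction directly so that printed percentages survive a round trip.
Alternate-allele fractions are rounded to 4 decimals on input, matching
the precision of the published tables.

``build_fixture`` reconstructs the three published variant tables of the
case study (somatic mutations; rare homozygous polymorphisms; compound
heterozygous pairs) as :class:`TrioRecord` lists, plus deterministic
decoy records that each violate exactly one selection criterion.
Genomic positions for the germline tables are synthetic placeholders —
the published tables print gene and genotype evidence, not coordinates —
and the classification rules never consume positions.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd
import pysam

ROLES = ("tumor", "patient", "mother", "father")

CONSEQUENCES = ("synonymous", "missense", "nonsense", "splice_site", "other")


@dataclass(frozen=True)
class VariantCall:
    """Read evidence for one variant in one sample."""

    chrom: str
    pos: int
    ref: str
    alt: str
    sample: str
    depth: int
    alt_fraction: float
    genotype_class: str | None = None  # hom_ref / het / hom_alt / missing

    def __post_init__(self) -> None:
        if self.depth < 0:
            raise ValueError("depth must be >= 0")
        if not 0.0 <= self.alt_fraction <= 1.0:
            raise ValueError("alt_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class TrioRecord:
    """One variant site joined across the family samples.

    ``calls`` maps role name to a :class:`VariantCall`; absent roles are
    simply missing from the mapping (e.g. the somatic table prints only
    tumor and patient leukocyte evidence).
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    consequence: str = "other"
    population_maf: float | None = None
    dbsnp: str | None = None
    hgvs_c: str | None = None
    hgvs_p: str | None = None
    calls: tuple[tuple[str, VariantCall], ...] = ()

    def __post_init__(self) -> None:
        roles = [r for r, _ in self.calls]
        if len(roles) != len(set(roles)):
            raise ValueError("at most one call per role")
        if self.population_maf is not None and not 0.0 <= self.population_maf <= 0.5:
            raise ValueError("population_maf must lie in [0, 0.5]")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    def call(self, role: str) -> VariantCall | None:
        return dict(self.calls).get(role)


@dataclass(frozen=True)
class Fixture:
    """A published-table fixture plus criterion-violating decoys."""

    name: str
    records: tuple[TrioRecord, ...]
    decoys: tuple[TrioRecord, ...] = ()

    @property
    def all_records(self) -> tuple[TrioRecord, ...]:
        return self.records + self.decoys


@dataclass(frozen=True)
class AnnotationKeys:
    """INFO key names used for annotations in VCF input/output."""

    gene: str = "GENE"
    consequence: str = "CSQ"
    maf: str = "MAF"
    dbsnp: str = "DBSNP"


def _round_af(x: float) -> float:
    return round(float(x), 4)


def _info_get(info, key: str, default=None):
    # pysam raises rather than returning None for keys absent from the
    # header; treat either situation as "annotation not provided"
    try:
        return info.get(key, default)
    except (KeyError, ValueError):
        return default


def _genotype_class_from_gt(gt: tuple | None) -> str | None:
    if gt is None or all(a is None for a in gt):
        return None
    alleles = [a for a in gt if a is not None]
    if not alleles:
        return None
    n_alt = sum(1 for a in alleles if a > 0)
    if n_alt == 0:
        return "hom_ref"
    if n_alt == len(alleles):
        return "hom_alt"
    return "het"


_GT_FOR_CLASS = {
    "hom_ref": (0, 0),
    "het": (0, 1),
    "hom_alt": (1, 1),
    "missing": (None, None),
    None: (None, None),
}


# ---------------------------------------------------------------------------
# VCF reading / writing


def read_vcf(
    path: str,
    roles: Mapping[str, str] | None = None,
    keys: AnnotationKeys = AnnotationKeys(),
) -> list[TrioRecord]:
    """Read a multi-sample VCF into :class:`TrioRecord` objects.

    ``roles`` maps role name -> sample ID in the VCF header; when
    omitted, sample IDs are assumed to be role names already.  The
    alternate fraction is taken from FORMAT ``AF`` when present, else
    computed as alt ``AD`` / ``DP``.  A sample with no genotype and no
    depth is treated as absent from the record; a malformed or missing
    ``AD``/``AF`` with a genotype present yields a ``missing`` call.
    """
    with pysam.VariantFile(path) as vcf:
        header_samples = list(vcf.header.samples)
        if roles is None:
            roles = {s: s for s in header_samples if s in ROLES}
        for role, sample_id in roles.items():
            if sample_id not in header_samples:
                raise ValueError(f"sample {sample_id!r} (role {role!r}) not in VCF")
        records = []
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                raise ValueError(
                    f"record {rec.chrom}:{rec.pos} is not biallelic; "
                    "normalize upstream"
                )
            info = rec.info
            maf = _info_get(info, keys.maf)
            calls = []
            for role, sample_id in roles.items():
                s = rec.samples[sample_id]
                gt = s.get("GT")
                dp = s.get("DP")
                gclass = _genotype_class_from_gt(gt)
                if gclass is None and dp is None:
                    continue  # sample absent at this site
                depth = int(dp) if dp is not None else 0
                af = s.get("AF")
                if af is not None:
                    if isinstance(af, tuple):
                        af = af[0]
                    frac = _round_af(af)
                elif s.get("AD") is not None and depth > 0:
                    ad = s.get("AD")
                    try:
                        frac = _round_af(ad[1] / depth)
                    except (IndexError, TypeError):
                        frac, gclass = 0.0, "missing"
                else:
                    frac = 0.0
                if depth == 0:
                    gclass = "missing"
                calls.append(
                    (
                        role,
                        VariantCall(
                            rec.chrom, rec.pos, rec.ref, rec.alts[0],
                            sample=role, depth=depth, alt_fraction=frac,
                            genotype_class=gclass,
                        ),
                    )
                )
            records.append(
                TrioRecord(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=rec.ref,
                    alt=rec.alts[0],
                    gene=_info_get(info, keys.gene, ""),
                    consequence=_info_get(info, keys.consequence, "other"),
                    population_maf=_round_af(maf) if maf is not None else None,
                    dbsnp=_info_get(info, keys.dbsnp),
                    calls=tuple(calls),
                )
            )
    return records


def write_vcf(
    records: Sequence[TrioRecord],
    path: str,
    roles: Mapping[str, str] | None = None,
    keys: AnnotationKeys = AnnotationKeys(),
    contig_lengths: Mapping[str, int] | None = None,
) -> None:
    """Write records as a minimal VCF v4.2 with ``GT:DP:AF`` per sample."""
    if roles is None:
        roles = {r: r for r in ROLES}
    header = pysam.VariantHeader()
    contigs: dict[str, int] = dict(contig_lengths or {})
    for rec in records:
        need = rec.pos + 1000
        if contigs.get(rec.chrom, 0) < need:
            contigs[rec.chrom] = need
    for chrom, length in contigs.items():
        header.contigs.add(chrom, length=length)
    header.info.add(keys.gene, 1, "String", "Gene symbol")
    header.info.add(keys.consequence, 1, "String", "Functional consequence")
    header.info.add(keys.maf, 1, "Float", "Population minor allele frequency")
    header.info.add(keys.dbsnp, 1, "String", "dbSNP identifier")
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("DP", 1, "Integer", "Read depth")
    header.formats.add("AF", 1, "Float", "Alternate read fraction")
    for role in roles:
        header.add_sample(roles[role])

    with pysam.VariantFile(path, "w", header=header) as out:
        for rec in sorted(records, key=lambda r: (r.chrom, r.pos)):
            vrec = out.new_record(
                contig=rec.chrom, start=rec.pos - 1, alleles=(rec.ref, rec.alt)
            )
            vrec.info[keys.gene] = rec.gene or "."
            vrec.info[keys.consequence] = rec.consequence
            if rec.population_maf is not None:
                vrec.info[keys.maf] = rec.population_maf
            if rec.dbsnp is not None:
                vrec.info[keys.dbsnp] = rec.dbsnp
            for role, sample_id in roles.items():
                call = rec.call(role)
                s = vrec.samples[sample_id]
                if call is None:
                    s["GT"] = (None, None)
                    continue
                s["GT"] = _GT_FOR_CLASS[call.genotype_class]
                s["DP"] = call.depth
                s["AF"] = call.alt_fraction
            out.write(vrec)


def records_from_sim(variants: pd.DataFrame) -> list[TrioRecord]:
    """Join the long per-sample table from ``simulate_trio`` into records."""
    records = []
    for (chrom, pos, ref, alt), grp in variants.groupby(
        ["chrom", "pos", "ref", "alt"], sort=True
    ):
        first = grp.iloc[0]
        maf = first["population_maf"]
        calls = []
        for _, row in grp.iterrows():
            calls.append(
                (
                    row["role"],
                    VariantCall(
                        chrom, int(pos), ref, alt,
                        sample=row["role"],
                        depth=int(row["depth"]),
                        alt_fraction=_round_af(row["alt_fraction"]),
                        genotype_class="missing" if row["depth"] == 0 else None,
                    ),
                )
            )
        records.append(
            TrioRecord(
                chrom=chrom,
                pos=int(pos),
                ref=ref,
                alt=alt,
                gene=first["gene"],
                consequence=first["consequence"],
                population_maf=None if pd.isna(maf) else _round_af(maf),
                calls=tuple(calls),
            )
        )
    return records


# ---------------------------------------------------------------------------
# fixtures from the published tables

_CDNA_RE = re.compile(r"(?:c\.)?[\d+*-]+([ACGT]+)>([ACGT]+)$")


def _alleles(cdna: str) -> tuple[str, str]:
    m = _CDNA_RE.search(cdna.replace(" ", ""))
    if m is None:
        raise ValueError(f"cannot parse alleles from {cdna!r}")
    return m.group(1), m.group(2)


# Somatic table: (chrom:pos, gene, cDNA, consequence,
#                 tumor VAF %, tumor depth, leukocyte depth, dbSNP)
_TABLE1 = (
    ("chr3:436494", "CHL1", "c.3033A>G", "p.A111A", "synonymous", 35, 55, 53, None),
    ("chr6:134305546", "TBPL1", "c.315T>G", "p.V105V", "synonymous", 23, 31, 28, None),
    ("chr12:34179763", "ALG10", "c.1335A>T", "p.A445A", "synonymous", 43, 82, 66, None),
    ("chr1:45808899", "TOE1", "c.1058C>T", "p.P353L", "missense", 20, 15, 18, "rs145913038"),
    ("chr2:162875307", "DPP4", "c.1352C>T", "p.P451L", "missense", 37, 41, 46, None),
    ("chr5:126753368", "MEGF10", "c.1169G>C", "p.G390C", "missense", 22, 82, 39, None),
    ("chr5:26915867", "CDH9", "c.394G>C", "p.D132Y", "missense", 25, 71, 75, None),
    ("chr6:123319098", "CLVS2", "c.176G>A", "p.R59Q", "missense", 40, 25, 20, None),
    ("chr8:106813312", "ZFPM2", "c.1002T>A", "p.S334R", "missense", 28, 36, 44, None),
    ("chr8:72983969", "TRPA1", "c.245T>C", "p.I82T", "missense", 36, 45, 35, None),
    ("chr15:37385900", "MEIS2", "c.521G>A", "p.R86Q", "missense", 26, 31, 23, None),
    ("chr16:76495948", "CNTNAP4", "c.1210G>T", "p.A404S", "missense", 33, 42, 43, None),
    ("chr17:10300120", "MYH8", "c.4362G>T", "p.K1454N", "missense", 26, 38, 33, None),
    ("chr19:53057457", "ZNF808", "c.1288G>T", "p.E430Ter", "nonsense", 43, 30, 27, None),
    ("chr20:43385680", "RIMS4", "c.455-2T>A", None, "splice_site", 28, 29, 37, None),
)

# Rare homozygous polymorphisms: (gene, chrom, placeholder pos, cDNA,
#   protein, dbSNP, MAF, patient %/cov, mother %/cov, father %/cov)
_TABLE2 = (
    ("VEZT", "chr12", 95_700_001, "c.1486G>A", "p.V496I", "rs10507051", 0.0302,
     (100.0, 17), (17.9, 28), (35.0, 80)),
    ("ISX", "chr22", 35_462_001, "c.248G>A", "p.R83Q", "rs8140287", 0.0308,
     (100.0, 13), (37.5, 24), (50.0, 70)),
    ("RASSF1", "chr3", 50_378_001, "c.409G>T", "p.A137S", "rs2073498", 0.0711,
     (83.3, 12), (27.5, 40), (53.1, 32)),
    ("ADAMTS12", "chr5", 33_590_001, "c.3529T>C", "p.W1177R", "rs3813474", 0.0513,
     (100.0, 51), (42.0, 88), (45.0, 40)),
)

# Compound heterozygotes: gene -> ((cDNA, protein, dbSNP, MAF, origin,
#   carrier-parent VAF %, patient VAF %), ...); first member maternal.
_TABLE3 = (
    ("C2CD3", "chr11", 73_750_001,
     ("c.5653T>C", "p.S1885P", "rs142277857", 0.001, "maternal", 43.1, 53.57),
     ("c.3223A>C", "p.S1075R", None, None, "paternal", 50.91, 41.67)),
    ("FAM13C", "chr10", 61_000_001,
     ("c.1361G>A", "p.R454H", "rs369226393", None, "maternal", 56.4, 50.0),
     ("c.439C>T", "p.P147S", "rs73299227", 0.0092, "paternal", 51.43, 36.36)),
    ("GOLGA3", "chr12", 133_350_001,
     ("c.209G>A", "p.G70E", "rs2291256", 0.0581, "maternal", 52.3, 47.06),
     ("c.3728G>A", "p.R1243Q", "rs140646528", 0.0134, "paternal", 60.0, 25.0)),
    ("LAMB2", "chr3", 49_160_001,
     ("c.1424G>A", "p.R475Q", "rs370565848", None, "maternal", 36.4, 60.0),
     ("c.5293G>A", "p.A1765T", "rs74951356", 0.0130, "paternal", 55.81, 41.18)),
    ("MTMR6", "chr13", 25_790_001,
     ("c.685C>G", "p.P229A", "rs149526134", 0.0002, "maternal", 60.9, 26.32),
     ("c.1795G>A", "p.A599T", "rs62619824", 0.0571, "paternal", 35.09, 51.85)),
    ("RSPH1", "chr21", 43_890_001,
     ("c.742G>A", "p.G248R", "rs117385282", 0.0839, "maternal", 50.0, 31.25),
     ("c.733G>A", "p.G245R", "rs151158140", 0.0026, "paternal", 50.77, 58.33)),
    ("SLC9A9", "chr3", 142_980_001,
     ("c.1765A>G", "p.I589V", "rs2289491", 0.0290, "maternal", 31.1, 28.0),
     ("c.1618A>G", "p.I540V", "rs16853300", 0.0066, "paternal", 48.62, 36.36)),
    ("SPICE1", "chr3", 113_150_001,
     ("c.2470A>C", "p.T824P", "rs57006145", 0.0313, "maternal", 40.4, 62.16),
     ("c.850G>A", "p.V284M", "rs73239152", 0.0078, "paternal", 47.54, 29.27)),
    ("SYNE1", "chr6", 152_440_001,
     ("c.16277C>T", "p.T5426M", "rs2306914", 0.0463, "maternal", 39.1, 41.07),
     ("c.12442G>C", "p.D4148H", "rs117501809", 0.0124, "paternal", 49.15, 28.57)),
    ("TAF5L", "chr1", 229_730_001,
     ("c.721G>A", "p.V241I", "rs55655740", 0.0042, "maternal", 36.0, 48.0),
     ("c.1123A>G", "p.T375A", "rs41304137", 0.0008, "paternal", 20.0, 40.0)),
    ("TTN", "chr2", 179_390_001,
     ("c.106619T>C", "p.I35540T", "rs55880440", 0.0046, "maternal", 40.0, 57.69),
     ("c.65147C>T", "p.S21716L", "rs13021201", 0.0108, "paternal", 42.86, 58.14)),
)

#: Leukocyte depth for the compound-het table, whose source prints
#: genotypes and frequencies but not coverage; all rows passed the 10x
#: floor upstream, so a uniform passing depth is used.
TABLE3_DEPTH = 50


def _vc(chrom, pos, ref, alt, role, depth, pct, gclass) -> tuple[str, VariantCall]:
    return role, VariantCall(
        chrom, pos, ref, alt, sample=role, depth=depth,
        alt_fraction=_round_af(pct / 100.0), genotype_class=gclass,
    )


def _table1_records() -> list[TrioRecord]:
    out = []
    for locus, gene, cdna, prot, csq, vaf, tdp, ldp, dbsnp in _TABLE1:
        chrom, pos_s = locus.split(":")
        pos = int(pos_s)
        ref, alt = _alleles(cdna)
        out.append(
            TrioRecord(
                chrom, pos, ref, alt, gene=gene, consequence=csq,
                population_maf=None, dbsnp=dbsnp, hgvs_c=cdna, hgvs_p=prot,
                calls=(
                    _vc(chrom, pos, ref, alt, "tumor", tdp, vaf, "het"),
                    _vc(chrom, pos, ref, alt, "patient", ldp, 0.0, "hom_ref"),
                ),
            )
        )
    return out


def _table1_decoys() -> list[TrioRecord]:
    def somatic_like(gene, pos, tvaf, tdp, lvaf, ldp):
        chrom = "chr7"
        return TrioRecord(
            chrom, pos, "A", "G", gene=gene, consequence="missense",
            calls=(
                _vc(chrom, pos, "A", "G", "tumor", tdp, tvaf, "het"),
                _vc(chrom, pos, "A", "G", "patient", ldp, lvaf,
                    "hom_ref" if lvaf == 0 else "het"),
            ),
        )

    return [
        somatic_like("DECOY_LOW_TUMOR_DEPTH", 1_000_001, 40.0, 9, 0.0, 30),
        somatic_like("DECOY_LOW_NORMAL_DEPTH", 1_100_001, 40.0, 50, 0.0, 9),
        somatic_like("DECOY_LOW_VAF", 1_200_001, 19.0, 100, 0.0, 40),
        somatic_like("DECOY_NORMAL_SUPPORT", 1_300_001, 45.0, 60, 10.0, 50),
    ]


def _table2_records() -> list[TrioRecord]:
    out = []
    for gene, chrom, pos, cdna, prot, dbsnp, maf, pt, mo, fa in _TABLE2:
        ref, alt = _alleles(cdna)
        out.append(
            TrioRecord(
                chrom, pos, ref, alt, gene=gene, consequence="missense",
                population_maf=maf, dbsnp=dbsnp, hgvs_c=cdna, hgvs_p=prot,
                calls=(
                    _vc(chrom, pos, ref, alt, "patient", pt[1], pt[0], "hom_alt"),
                    _vc(chrom, pos, ref, alt, "mother", mo[1], mo[0], "het"),
                    _vc(chrom, pos, ref, alt, "father", fa[1], fa[0], "het"),
                ),
            )
        )
    return out


def _table2_decoys() -> list[TrioRecord]:
    def hom_like(gene, pos, maf, pclass, pvaf, mdp=40, fdp=40):
        chrom = "chr9"
        return TrioRecord(
            chrom, pos, "G", "A", gene=gene, consequence="missense",
            population_maf=maf,
            calls=(
                _vc(chrom, pos, "G", "A", "patient", 30, pvaf, pclass),
                _vc(chrom, pos, "G", "A", "mother", mdp, 50.0, "het"),
                _vc(chrom, pos, "G", "A", "father", fdp, 50.0, "het"),
            ),
        )

    return [
        hom_like("DECOY_COMMON_MAF", 2_000_001, 0.25, "hom_alt", 100.0),
        hom_like("DECOY_PATIENT_HET", 2_100_001, 0.05, "het", 50.0),
        hom_like("DECOY_LOW_PARENT_DEPTH", 2_200_001, 0.05, "hom_alt", 100.0, mdp=8),
    ]


def _comphet_record(
    gene: str, chrom: str, pos: int, cdna: str, prot: str | None,
    dbsnp: str | None, maf: float | None, origin: str,
    carrier_vaf: float, patient_vaf: float,
    other_parent_het: bool = False,
) -> TrioRecord:
    ref, alt = _alleles(cdna)
    carrier = "mother" if origin == "maternal" else "father"
    other = "father" if origin == "maternal" else "mother"
    calls = [
        _vc(chrom, pos, ref, alt, "patient", TABLE3_DEPTH, patient_vaf, "het"),
        _vc(chrom, pos, ref, alt, carrier, TABLE3_DEPTH, carrier_vaf, "het"),
        _vc(chrom, pos, ref, alt, other, TABLE3_DEPTH,
            50.0 if other_parent_het else 0.0,
            "het" if other_parent_het else "hom_ref"),
    ]
    return TrioRecord(
        chrom, pos, ref, alt, gene=gene, consequence="missense",
        population_maf=maf, dbsnp=dbsnp, hgvs_c=cdna, hgvs_p=prot,
        calls=tuple(sorted(calls, key=lambda c: ROLES.index(c[0]))),
    )


def _table3_records() -> list[TrioRecord]:
    out = []
    for gene, chrom, pos0, *members in _TABLE3:
        for i, (cdna, prot, dbsnp, maf, origin, cvaf, pvaf) in enumerate(members):
            out.append(
                _comphet_record(
                    gene, chrom, pos0 + 10_000 * i, cdna, prot, dbsnp, maf,
                    origin, cvaf, pvaf,
                )
            )
    return out


def _table3_decoys() -> list[TrioRecord]:
    out = [
        # two maternal-only hets: cis candidate, not compound het
        _comphet_record("DECOY_CIS", "chr4", 3_000_001, "c.100A>G", None, None,
                        0.01, "maternal", 50.0, 50.0),
        _comphet_record("DECOY_CIS", "chr4", 3_010_001, "c.200C>T", None, None,
                        0.01, "maternal", 45.0, 45.0),
        # trans pair but one member is a common polymorphism
        _comphet_record("DECOY_COMMON", "chr4", 3_100_001, "c.300G>A", None, None,
                        0.01, "maternal", 50.0, 50.0),
        _comphet_record("DECOY_COMMON", "chr4", 3_110_001, "c.400T>C", None, None,
                        0.30, "paternal", 50.0, 50.0),
        # one member het in both parents (unphasable), other paternal-only
        _comphet_record("DECOY_BIPARENTAL", "chr4", 3_200_001, "c.500A>T", None,
                        None, 0.01, "maternal", 50.0, 50.0,
                        other_parent_het=True),
        _comphet_record("DECOY_BIPARENTAL", "chr4", 3_210_001, "c.600G>C", None,
                        None, 0.01, "paternal", 50.0, 50.0),
    ]
    return out


_FIXTURE_BUILDERS = {
    "table1": (_table1_records, _table1_decoys),
    "table2": (_table2_records, _table2_decoys),
    "table3": (_table3_records, _table3_decoys),
}


def build_fixture(name: str) -> Fixture:
    """Build one of the published-table fixtures (``table1``..``table3``).

    ``table1``: 15 somatic point mutations (tumor VAF/coverage and
    leukocyte coverage as printed; leukocyte alternate fraction 0).
    ``table2``: 4 rare polymorphisms homozygous in the patient.
    ``table3``: 11 genes x 2 compound-heterozygous variants.
    Decoys are deterministic records failing exactly one criterion each.
    """
    try:
        records_fn, decoys_fn = _FIXTURE_BUILDERS[name]
    except KeyError:
        raise ValueError(
            f"unknown fixture {name!r}; expected one of {sorted(_FIXTURE_BUILDERS)}"
        ) from None
    return Fixture(name, tuple(records_fn()), tuple(decoys_fn()))


def combined_fixture_records(include_decoys: bool = True) -> list[TrioRecord]:
    """All three table fixtures merged into one record list."""
    out: list[TrioRecord] = []
    for name in ("table1", "table2", "table3"):
        fx = build_fixture(name)
        out.extend(fx.all_records if include_decoys else fx.records)
    return out


def fixture_to_table(fixture: Fixture, include_decoys: bool = False) -> pd.DataFrame:
    """Flatten a fixture into a tab-separable table mirroring its source."""
    rows = []
    records = fixture.all_records if include_decoys else fixture.records
    for rec in records:
        row = {
            "chrom": rec.chrom,
            "pos": rec.pos,
            "gene": rec.gene,
            "cdna_change": rec.hgvs_c,
            "protein_change": rec.hgvs_p,
            "consequence": rec.consequence,
            "dbsnp": rec.dbsnp,
            "population_maf": rec.population_maf,
        }
        for role in ROLES:
            call = rec.call(role)
            row[f"{role}_vaf"] = call.alt_fraction if call else None
            row[f"{role}_depth"] = call.depth if call else None
            row[f"{role}_genotype"] = call.genotype_class if call else None
        rows.append(row)
    return pd.DataFrame(rows)


def write_fixture_tables(out_prefix: str, include_decoys: bool = False) -> None:
    for name in ("table1", "table2", "table3"):
        fx = build_fixture(name)
        fixture_to_table(fx, include_decoys=include_decoys).to_csv(
            f"{out_prefix}{name}.tsv", sep="\t", index=False
        )
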