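"""Synthetic inputs with known ground truth for every pipeline stage.

Generates a trio (patient leukocyte, mother, father) plus tumor variant
set with planted variants of each inheritance class, probe-level copy
number profiles, mate-pair read tables spanning an interchromosomal
junction, and Poisson-partitioned droplet counts.  All generators are
deterministic under a fixed seed.

The default parameters mirror the sequencing regime of the case study
this package models: ~30x exome depth with a 10x floor applied
downstream, ~2 kb mate-pair inserts with 60 bp reads, and a 180K-array
style probe density.  Chromosomes are a small synthetic genome (three
10 Mb chromosomes); real coordinates appear only in the printed-table
fixtures of :mod:`rarecase.variant_io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

ROLES = ("tumor", "patient", "mother", "father")

INHERITANCE_CLASSES = (
    "somatic",
    "de_novo",
    "rare_hom",
    "comphet_maternal",
    "comphet_paternal",
    "common_benign",
)

#: Expected alternate-allele fraction per sample implied by each
#: inheritance class (tumor is high-purity, so germline variants appear
#: in the tumor at their leukocyte fraction).
DEFAULT_CLASS_VAFS: Mapping[str, Mapping[str, float]] = {
    "somatic": {"tumor": 0.40, "patient": 0.0, "mother": 0.0, "father": 0.0},
    "de_novo": {"tumor": 0.50, "patient": 0.5, "mother": 0.0, "father": 0.0},
    "rare_hom": {"tumor": 1.00, "patient": 1.0, "mother": 0.5, "father": 0.5},
    "comphet_maternal": {"tumor": 0.50, "patient": 0.5, "mother": 0.5, "father": 0.0},
    "comphet_paternal": {"tumor": 0.50, "patient": 0.5, "mother": 0.0, "father": 0.5},
}

DEFAULT_CHROM_LENGTHS: Mapping[str, int] = {
    "chr1": 10_000_000,
    "chr2": 10_000_000,
    "chr3": 10_000_000,
}

#: Log2 ratio reported for a homozygous deletion; arrays saturate well
#: above -inf, so the simulated signal is truncated here.
HOMDEL_LOG2_FLOOR = -3.0

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class PlantedVariant:
    """A ground-truth variant planted into the simulated trio.

    ``inheritance_class`` fully determines which samples carry the
    allele unless ``vafs`` overrides the per-role expected fractions.
    Compound-heterozygous variants must be planted in >=2-per-gene
    pairs with opposite parental origin for the gene to be recoverable.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    inheritance_class: str
    gene: str
    consequence: str = "missense"
    population_maf: float | None = None
    vafs: tuple[tuple[str, float], ...] | None = None

    def true_vafs(self) -> Mapping[str, float]:
        if self.vafs is not None:
            return dict(self.vafs)
        if self.inheritance_class not in DEFAULT_CLASS_VAFS:
            raise ValueError(
                f"no default VAFs for class {self.inheritance_class!r}; "
                "supply explicit vafs"
            )
        return DEFAULT_CLASS_VAFS[self.inheritance_class]


@dataclass
class SimConfig:
    """Parameters of the synthetic case.

    Depth per sample/variant is Poisson around ``depth_mean``;
    alternate read counts are binomial at the variant's true VAF.
    ``cna_truth`` holds non-overlapping ``(chrom, start, end, copies)``
    intervals (1-based, closed) on the diploid background.
    """

    seed: int = 0
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CHROM_LENGTHS)
    )
    n_background_variants: int = 1000
    depth_mean: float = 30.0
    planted: list[PlantedVariant] = field(default_factory=list)
    cna_truth: list[tuple[str, int, int, int]] = field(default_factory=list)
    cna_noise_sd: float = 0.15
    insert_size_mean: float = 2000.0
    insert_size_sd: float = 150.0
    read_length: int = 60
    n_matepairs: int = 50
    n_concordant_pairs: int = 10_000
    droplet_count: int = 20_000
    droplet_volume_nl: float = 0.85

    def validate(self) -> None:
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be positive")
        if self.insert_size_sd < 0:
            raise ValueError("insert_size_sd must be non-negative")
        seen: set[tuple[str, int]] = set()
        for pv in self.planted:
            key = (pv.chrom, pv.pos)
            if key in seen:
                raise ValueError(f"duplicate planted position {key}")
            seen.add(key)
            if pv.chrom not in self.chrom_lengths:
                raise ValueError(f"planted variant on unknown chromosome {pv.chrom}")
            if not 1 <= pv.pos <= self.chrom_lengths[pv.chrom]:
                raise ValueError(
                    f"planted position {pv.chrom}:{pv.pos} outside chromosome"
                )


def _rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# trio / variant simulation


def plant_default_variants(
    n_per_class: int,
    rng: np.random.Generator,
    chrom_lengths: Mapping[str, int] = DEFAULT_CHROM_LENGTHS,
) -> list[PlantedVariant]:
    """Plant ``n_per_class`` variants for each recoverable class.

    Compound-het classes are planted as maternal/paternal pairs sharing
    a gene, so ``n_per_class`` comphet variants of each origin yield
    ``n_per_class`` comphet genes.  Positions are unique across classes.
    """
    chroms = list(chrom_lengths)
    used: set[tuple[str, int]] = set()

    def fresh_site() -> tuple[str, int]:
        while True:
            chrom = chroms[int(rng.integers(len(chroms)))]
            pos = int(rng.integers(1, chrom_lengths[chrom] + 1))
            if (chrom, pos) not in used:
                used.add((chrom, pos))
                return chrom, pos

    def alleles() -> tuple[str, str]:
        ref, alt = rng.choice(4, size=2, replace=False)
        return str(_BASES[ref]), str(_BASES[alt])

    planted: list[PlantedVariant] = []
    for i in range(n_per_class):
        for cls in ("somatic", "de_novo", "rare_hom"):
            chrom, pos = fresh_site()
            ref, alt = alleles()
            maf = 0.02 if cls == "rare_hom" else None
            planted.append(
                PlantedVariant(
                    chrom, pos, ref, alt, cls,
                    gene=f"{cls.upper()}{i:03d}", population_maf=maf,
                )
            )
        # one comphet gene = one maternal + one paternal rare het
        gene = f"COMPHET{i:03d}"
        for cls in ("comphet_maternal", "comphet_paternal"):
            chrom, pos = fresh_site()
            ref, alt = alleles()
            planted.append(
                PlantedVariant(
                    chrom, pos, ref, alt, cls, gene=gene, population_maf=0.01,
                )
            )
    return planted


_BENIGN_PATTERNS: Sequence[Mapping[str, float]] = (
    {"tumor": 0.5, "patient": 0.5, "mother": 0.5, "father": 0.0},
    {"tumor": 0.5, "patient": 0.5, "mother": 0.0, "father": 0.5},
    {"tumor": 0.5, "patient": 0.5, "mother": 0.5, "father": 0.5},
    {"tumor": 1.0, "patient": 1.0, "mother": 0.5, "father": 0.5},
    {"tumor": 0.0, "patient": 0.0, "mother": 0.5, "father": 0.5},
)


def simulate_trio(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate per-sample read evidence for planted + background variants.

    Returns ``(variants, truth)``.  ``variants`` is a long table with one
    row per (variant, sample role): columns ``chrom, pos, ref, alt, gene,
    consequence, population_maf, role, depth, alt_reads, alt_fraction``.
    ``truth`` lists every planted variant with its inheritance class.

    Background variants are common Mendelian-consistent polymorphisms
    (MAF 0.12-0.50, one gene each) that no selection rule should retain.
    """
    config.validate()
    rng = _rng(config.seed)

    planted = list(config.planted)
    chroms = list(config.chrom_lengths)
    used = {(pv.chrom, pv.pos) for pv in planted}
    for i in range(config.n_background_variants):
        while True:
            chrom = chroms[int(rng.integers(len(chroms)))]
            pos = int(rng.integers(1, config.chrom_lengths[chrom] + 1))
            if (chrom, pos) not in used:
                used.add((chrom, pos))
                break
        ref_i, alt_i = rng.choice(4, size=2, replace=False)
        pattern = _BENIGN_PATTERNS[int(rng.integers(len(_BENIGN_PATTERNS)))]
        planted.append(
            PlantedVariant(
                chrom,
                pos,
                str(_BASES[ref_i]),
                str(_BASES[alt_i]),
                "common_benign",
                gene=f"BG{i:05d}",
                population_maf=float(np.round(rng.uniform(0.12, 0.50), 4)),
                vafs=tuple(pattern.items()),
            )
        )

    rows = []
    truth_rows = []
    for pv in planted:
        vafs = pv.true_vafs()
        truth_rows.append(
            {
                "chrom": pv.chrom,
                "pos": pv.pos,
                "ref": pv.ref,
                "alt": pv.alt,
                "gene": pv.gene,
                "inheritance_class": pv.inheritance_class,
            }
        )
        for role in ROLES:
            depth = int(rng.poisson(config.depth_mean))
            vaf = vafs.get(role, 0.0)
            alt_reads = int(rng.binomial(depth, vaf)) if depth > 0 else 0
            rows.append(
                {
                    "chrom": pv.chrom,
                    "pos": pv.pos,
                    "ref": pv.ref,
                    "alt": pv.alt,
                    "gene": pv.gene,
                    "consequence": pv.consequence,
                    "population_maf": pv.population_maf,
                    "role": role,
                    "depth": depth,
                    "alt_reads": alt_reads,
                    "alt_fraction": alt_reads / depth if depth > 0 else 0.0,
                }
            )

    variants = pd.DataFrame(
        rows,
        columns=[
            "chrom", "pos", "ref", "alt", "gene", "consequence",
            "population_maf", "role", "depth", "alt_reads", "alt_fraction",
        ],
    )
    truth = pd.DataFrame(
        truth_rows,
        columns=["chrom", "pos", "ref", "alt", "gene", "inheritance_class"],
    )
    if len(variants):
        variants = variants.sort_values(
            ["chrom", "pos", "role"], kind="stable"
        ).reset_index(drop=True)
        truth = truth.sort_values(["chrom", "pos"], kind="stable").reset_index(
            drop=True
        )
    return variants, truth


# ---------------------------------------------------------------------------
# copy-number profile simulation


def default_cna_truth(
    chrom_lengths: Mapping[str, int] = DEFAULT_CHROM_LENGTHS,
) -> list[tuple[str, int, int, int]]:
    """Event spectrum of the modeled case on the synthetic genome.

    One chromosome-scale single-copy gain (aneuploidy), two arm-level
    single-copy losses, and one focal ~1.34 Mb homozygous deletion.
    """
    l1 = chrom_lengths["chr1"]
    l2 = chrom_lengths["chr2"]
    return [
        ("chr1", 1, l1, 3),
        ("chr2", 1, 4_500_000, 1),
        ("chr2", 6_500_001, l2, 1),
        ("chr3", 4_000_001, 5_342_705, 0),
    ]


def expected_log2(copies: int) -> float:
    """Noise-free log2 ratio for an integer copy state on a diploid."""
    if copies < 0:
        raise ValueError("copy number must be >= 0")
    if copies == 0:
        return HOMDEL_LOG2_FLOOR
    return float(np.log2(copies / 2.0))


def simulate_cna_profile(
    config: SimConfig,
    probe_spacing: int,
    noise_sd: float | None = None,
) -> pd.DataFrame:
    """Probe-level log2 ratios: truth-segment means plus Gaussian noise.

    Probes are evenly spaced every ``probe_spacing`` bp on each
    chromosome; probes inside a truth segment take mean
    ``log2(copies/2)`` (floored at -3 for homozygous loss), elsewhere 0.
    """
    if probe_spacing <= 0:
        raise ValueError("probe_spacing must be positive")
    sd = config.cna_noise_sd if noise_sd is None else noise_sd
    # reject overlapping truth segments
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end, copies in config.cna_truth:
        if chrom not in config.chrom_lengths:
            raise ValueError(f"truth segment on unknown chromosome {chrom}")
        if not 1 <= start <= end <= config.chrom_lengths[chrom]:
            raise ValueError(f"truth segment {chrom}:{start}-{end} out of bounds")
        by_chrom.setdefault(chrom, []).append((start, end))
    for chrom, ivals in by_chrom.items():
        ivals.sort()
        for (s1, e1), (s2, e2) in zip(ivals, ivals[1:]):
            if s2 <= e1:
                raise ValueError(f"overlapping truth segments on {chrom}")

    rng = _rng(config.seed + 1)
    frames = []
    for chrom, length in config.chrom_lengths.items():
        pos = np.arange(probe_spacing, length + 1, probe_spacing, dtype=int)
        mean = np.zeros(len(pos))
        for c, start, end, copies in config.cna_truth:
            if c != chrom:
                continue
            mask = (pos >= start) & (pos <= end)
            mean[mask] = expected_log2(copies)
        log2 = mean + rng.normal(0.0, sd, size=len(pos))
        frames.append(pd.DataFrame({"chrom": chrom, "pos": pos, "log2": log2}))
    return pd.concat(frames, ignore_index=True)


def simulate_region_depths(
    config: SimConfig,
    region_size: int = 15_000,
    exclude: Sequence[tuple[str, int, int]] = (),
    residual_fraction: float = 0.05,
) -> pd.DataFrame:
    """Tumor/normal read depth per tiled region for exome-style CNA calling.

    Normal depth is Poisson around ``depth_mean`` scaled by region size;
    tumor depth is Poisson around normal expectation times
    ``copies / 2`` from ``cna_truth``, floored at ``residual_fraction``
    — tumor samples are never perfectly pure, so homozygous deletions
    retain a residual of normal-cell reads rather than dropping to
    zero coverage.  Regions overlapping ``exclude`` intervals are
    dropped, emulating capture designs that miss part of the genome.
    """
    if region_size <= 0:
        raise ValueError("region_size must be positive")
    rng = _rng(config.seed + 2)
    lam = max(config.depth_mean, 1.0) * 10.0  # aggregate reads per region
    rows = []
    for chrom, length in config.chrom_lengths.items():
        for start in range(1, length - region_size + 2, region_size):
            end = start + region_size - 1
            mid = (start + end) // 2
            if any(c == chrom and s <= mid <= e for c, s, e in exclude):
                continue
            copies = 2
            for c, s, e, k in config.cna_truth:
                if c == chrom and s <= mid <= e:
                    copies = k
            normal = int(rng.poisson(lam))
            tumor = int(rng.poisson(lam * max(copies / 2.0, residual_fraction)))
            rows.append(
                {
                    "chrom": chrom,
                    "start": start,
                    "end": end,
                    "tumor_depth": tumor,
                    "normal_depth": normal,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# mate-pair simulation


def simulate_matepairs(
    config: SimConfig,
    junction: tuple[str, int, str, int],
) -> pd.DataFrame:
    """Mate pairs: genome-wide concordant pairs plus junction-spanning pairs.

    The junction fuses ``chromA`` sequence up to ``posA`` with ``chromB``
    sequence from ``posB`` onward.  Each of the ``n_matepairs``
    discordant fragments straddles the junction, leaving one 60 bp read
    on each side; read strands encode which direction the junction lies
    (``+``: downstream of the read, ``-``: upstream).  Output is BEDPE
    ordered: 0-based half-open read intervals.
    """
    config.validate()
    chrom_a, pos_a, chrom_b, pos_b = junction
    for chrom, pos in ((chrom_a, pos_a), (chrom_b, pos_b)):
        if chrom not in config.chrom_lengths:
            raise ValueError(f"junction on unknown chromosome {chrom}")
        if not 1 <= pos <= config.chrom_lengths[chrom]:
            raise ValueError(f"junction position {chrom}:{pos} out of bounds")

    rng = _rng(config.seed + 3)
    rl = config.read_length
    rows = []
    chroms = list(config.chrom_lengths)
    for i in range(config.n_concordant_pairs):
        chrom = chroms[int(rng.integers(len(chroms)))]
        insert = max(
            2 * rl + 10,
            int(rng.normal(config.insert_size_mean, config.insert_size_sd)),
        )
        start1 = int(rng.integers(0, config.chrom_lengths[chrom] - insert))
        start2 = start1 + insert - rl
        rows.append(
            (chrom, start1, start1 + rl, chrom, start2, start2 + rl,
             f"conc{i:06d}", ".", "+", "-")
        )
    for i in range(config.n_matepairs):
        insert = max(
            2 * rl + 20,
            int(rng.normal(config.insert_size_mean, config.insert_size_sd)),
        )
        off_a = int(rng.integers(rl, insert - rl + 1))
        off_b = insert - off_a
        start1 = pos_a - off_a  # read ends before the junction on A
        start2 = pos_b + off_b - rl  # read begins after the junction on B
        rows.append(
            (chrom_a, start1, start1 + rl, chrom_b, start2, start2 + rl,
             f"disc{i:06d}", ".", "+", "-")
        )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom1", "start1", "end1", "chrom2", "start2", "end2",
            "name", "score", "strand1", "strand2",
        ],
    )


def simulate_genome(
    config: SimConfig, seed_offset: int = 4
) -> dict[str, str]:
    """Random nucleotide sequences for the synthetic chromosomes."""
    rng = _rng(config.seed + seed_offset)
    return {
        chrom: "".join(_BASES[rng.integers(0, 4, size=length)])
        for chrom, length in config.chrom_lengths.items()
    }


# ---------------------------------------------------------------------------
# droplet simulation


def simulate_droplets(
    lambda_per_droplet: float,
    n_droplets: int,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[int, int]:
    """Partition template at ``lambda_per_droplet`` mean copies per droplet.

    Each droplet is positive with probability ``1 - exp(-lambda)``;
    returns ``(n_positive, n_total)``.
    """
    if lambda_per_droplet < 0:
        raise ValueError("lambda_per_droplet must be >= 0")
    if n_droplets <= 0:
        raise ValueError("n_droplets must be positive")
    if rng is None:
        rng = _rng(0 if seed is None else seed)
    p = 1.0 - float(np.exp(-lambda_per_droplet))
    return int(rng.binomial(n_droplets, p)), int(n_droplets)
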