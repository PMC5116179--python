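"""Interchromosomal breakpoint detection from discordant mate pairs.

Mate-pair libraries (~2 kb circularized fragments, 60 bp reads) yield
read pairs whose mapped distance follows the insert distribution; a
pair on two different chromosomes — or at an aberrant same-chromosome
distance — is discordant and evidence of structural rearrangement.
Discordant pairs sharing a chromosome pair are clustered by
single-linkage on both read coordinates; clusters with enough
supporting pairs become breakpoint calls whose per-chromosome intervals
delimit the junction to within one insert span, tight enough to design
a PCR assay across the fused sequence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd


@dataclass(frozen=True)
class MatePair:
    """One mate pair: two mapped reads with orientation."""

    chrom1: str
    start1: int
    end1: int
    strand1: str
    chrom2: str
    start2: int
    end2: int
    strand2: str
    name: str = "."


@dataclass(frozen=True)
class BreakpointCall:
    """A candidate junction between two chromosomes.

    ``interval_a``/``interval_b`` are closed coordinate ranges expected
    to contain the junction base on each chromosome; their width never
    exceeds the insert span used for clustering.
    """

    chrom_a: str
    interval_a: tuple[int, int]
    chrom_b: str
    interval_b: tuple[int, int]
    supporting_pairs: int
    orientation: str  # e.g. "+-": strand class of the supporting reads


def pairs_from_bedpe(df: pd.DataFrame) -> list[MatePair]:
    """Build pairs from a BEDPE table (0-based half-open intervals)."""
    cols = df.columns
    strand1 = df["strand1"] if "strand1" in cols else pd.Series("+", index=df.index)
    strand2 = df["strand2"] if "strand2" in cols else pd.Series("-", index=df.index)
    names = df["name"] if "name" in cols else pd.Series(".", index=df.index)
    return [
        MatePair(c1, int(s1), int(e1), str(t1), c2, int(s2), int(e2), str(t2),
                 name=str(nm))
        for c1, s1, e1, t1, c2, s2, e2, t2, nm in zip(
            df["chrom1"], df["start1"], df["end1"], strand1,
            df["chrom2"], df["start2"], df["end2"], strand2, names,
        )
    ]


def find_discordant(
    pairs: Sequence[MatePair],
    insert_mean: float,
    insert_sd: float,
    k: float = 5.0,
) -> list[MatePair]:
    """Pairs on different chromosomes or at an aberrant insert distance.

    Same-chromosome pairs are discordant when the outer distance falls
    outside ``insert_mean +/- k * insert_sd``.
    """
    if insert_sd < 0:
        raise ValueError("insert_sd must be >= 0")
    lo = insert_mean - k * insert_sd
    hi = insert_mean + k * insert_sd
    out = []
    for p in pairs:
        if p.chrom1 != p.chrom2:
            out.append(p)
            continue
        span = max(p.end1, p.end2) - min(p.start1, p.start2)
        if not lo <= span <= hi:
            out.append(p)
    return out


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def _side_interval(
    starts: Sequence[int], ends: Sequence[int], strands: Sequence[str], span: int
) -> tuple[int, int]:
    """Junction interval for one side of a cluster.

    Reads on ``+`` strand point at a junction downstream of them: it
    lies within one insert span beyond the rightmost read start.  Reads
    on ``-`` point upstream: within one span before the leftmost read
    end.  Mixed clusters fall back to the majority strand.
    """
    plus = sum(1 for s in strands if s == "+")
    if plus * 2 >= len(strands):
        lo = max(starts)
        return lo, lo + span
    hi = min(ends)
    return hi - span, hi


def cluster_breakpoint(
    discordant: Sequence[MatePair],
    window: float,
    min_support: int = 3,
) -> list[BreakpointCall]:
    """Single-linkage clustering of interchromosomal discordant pairs.

    Two pairs on the same (ordered) chromosome pair join a cluster when
    both their read-1 and read-2 starts lie within ``window`` of each
    other; clusters with at least ``min_support`` members are reported.
    ``window`` doubles as the insert span delimiting the junction
    interval on each side.  Output is sorted by coordinates, so the
    result is invariant under permutation of the input pairs.
    """
    by_chrompair: dict[tuple[str, str], list[MatePair]] = {}
    for p in discordant:
        if p.chrom1 == p.chrom2:
            continue  # same-chromosome discordants are out of scope here
        if (p.chrom2, p.chrom1) in by_chrompair:
            # normalize orientation of the chromosome pair
            p = MatePair(
                p.chrom2, p.start2, p.end2, p.strand2,
                p.chrom1, p.start1, p.end1, p.strand1, p.name,
            )
        by_chrompair.setdefault((p.chrom1, p.chrom2), []).append(p)

    span = int(window)
    calls = []
    for (chrom_a, chrom_b), members in sorted(by_chrompair.items()):
        members = sorted(members, key=lambda p: (p.start1, p.start2, p.name))
        uf = _UnionFind(len(members))
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                if (
                    abs(members[i].start1 - members[j].start1) <= window
                    and abs(members[i].start2 - members[j].start2) <= window
                ):
                    uf.union(i, j)
        clusters: dict[int, list[MatePair]] = {}
        for i, p in enumerate(members):
            clusters.setdefault(uf.find(i), []).append(p)
        for root in sorted(clusters):
            group = clusters[root]
            if len(group) < min_support:
                continue
            ia = _side_interval(
                [p.start1 for p in group], [p.end1 for p in group],
                [p.strand1 for p in group], span,
            )
            ib = _side_interval(
                [p.start2 for p in group], [p.end2 for p in group],
                [p.strand2 for p in group], span,
            )
            strand_a = max(set(p.strand1 for p in group),
                           key=[p.strand1 for p in group].count)
            strand_b = max(set(p.strand2 for p in group),
                           key=[p.strand2 for p in group].count)
            calls.append(
                BreakpointCall(
                    chrom_a=chrom_a, interval_a=ia,
                    chrom_b=chrom_b, interval_b=ib,
                    supporting_pairs=len(group),
                    orientation=strand_a + strand_b,
                )
            )
    return calls


@dataclass(frozen=True)
class AssayDesign:
    """Flanking sequences around a called junction for primer design."""

    chrom_a: str
    flank_a: str  # sequence ending at the putative junction on side A
    chrom_b: str
    flank_b: str  # sequence starting at the putative junction on side B
    fused_contig: str  # flank_a + flank_b: the rearranged reference


def assay_region(
    call: BreakpointCall,
    genome: Mapping[str, str],
    flank: int = 400,
) -> AssayDesign:
    """Extract ~``flank`` bp each side of a breakpoint call.

    The junction base is approximated by the midpoint of each interval;
    ``genome`` maps chromosome name to sequence (load a FASTA with
    ``pyfaidx`` or ``Bio.SeqIO`` and pass the mapping).  Amplicons of
    ~2x ``flank`` suit Sanger-scale validation of the fused sequence.
    """
    for chrom in (call.chrom_a, call.chrom_b):
        if chrom not in genome:
            raise KeyError(f"no sequence for {chrom}")
    mid_a = (call.interval_a[0] + call.interval_a[1]) // 2
    mid_b = (call.interval_b[0] + call.interval_b[1]) // 2
    seq_a, seq_b = str(genome[call.chrom_a]), str(genome[call.chrom_b])
    if mid_a - flank < 0 or mid_a > len(seq_a):
        raise ValueError("interval A flank extends outside the sequence")
    if mid_b < 0 or mid_b + flank > len(seq_b):
        raise ValueError("interval B flank extends outside the sequence")
    flank_a = seq_a[mid_a - flank : mid_a]
    flank_b = seq_b[mid_b : mid_b + flank]
    return AssayDesign(
        chrom_a=call.chrom_a,
        flank_a=flank_a,
        chrom_b=call.chrom_b,
        flank_b=flank_b,
        fused_contig=flank_a + flank_b,
    )


def calls_to_bedpe(calls: Sequence[BreakpointCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom1": c.chrom_a,
                "start1": c.interval_a[0],
                "end1": c.interval_a[1],
                "chrom2": c.chrom_b,
                "start2": c.interval_b[0],
                "end2": c.interval_b[1],
                "name": f"bp{i}",
                "score": c.supporting_pairs,
                "strand1": c.orientation[0],
                "strand2": c.orientation[1],
            }
            for i, c in enumerate(calls)
        ]
    )
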