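"""Copy-number segmentation, exome read-depth calling and concordance.

Probe-level log2 tumor/reference ratios are segmented by recursive
binary splitting: within each segment the best single change-point is
the position maximizing the two-sample t statistic between left and
right means, and the split is accepted when its (Bonferroni-corrected)
p value falls below a stringent significance threshold (default 1e-8,
the array-analysis setting of the modeled case).  Segments are then
classified against four log2 thresholds: gain 0.33, loss -0.3, high
copy gain 1.2, homozygous loss -1.1, with non-neutral calls requiring
at least five consecutive probes (~70 kb effective resolution on a
180K design).

Exome copy number is called from paired tumor/normal per-region read
depths: median-centered log2(tumor/normal) per region, then the same
segmentation on region midpoints.

``concordance`` scores one platform's events against another's: an
event is validated when an event of the same sign on the other platform
overlaps it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

Call = Literal["gain", "loss", "high_gain", "homozygous_loss", "neutral"]

#: The focal homozygous deletion of the modeled case (hg19, 1-based
#: closed): a ~1.3 Mb two-copy loss on 9p encompassing CNTLN and SH3GL2.
FOCAL_DELETION_9P = ("chr9", 17_106_384, 18_449_088)


def interval_length_mb(start: int, end: int) -> float:
    """Length in megabases of a 1-based closed genomic interval."""
    if end < start:
        raise ValueError("end must be >= start")
    return (end - start + 1) / 1e6


@dataclass(frozen=True)
class CnaParams:
    """Segmentation and classification settings.

    Log2 thresholds follow the array-analysis settings of the modeled
    case; ``mosaic_log2`` marks sub-threshold ("low-level mosaic")
    segments for the advisory tier without promoting them to calls.
    """

    min_probes: int = 5
    alpha: float = 1e-8
    gain: float = 0.33
    loss: float = -0.3
    high_gain: float = 1.2
    hom_loss: float = -1.1
    mosaic_log2: float = 0.1
    min_normal_depth: int = 10

    def classify(self, mean_log2: float) -> Call:
        if mean_log2 >= self.high_gain:
            return "high_gain"
        if mean_log2 >= self.gain:
            return "gain"
        if mean_log2 <= self.hom_loss:
            return "homozygous_loss"
        if mean_log2 <= self.loss:
            return "loss"
        return "neutral"


@dataclass(frozen=True)
class CnaSegment:
    """A contiguous run of probes with one copy-number state.

    ``start``/``end`` are 1-based closed probe coordinates.
    ``advisory`` flags segments that are suggestive but not callable:
    ``mosaic`` (shifted mean below the call thresholds) or
    ``few_probes`` (call-level mean over fewer than ``min_probes``).
    """

    chrom: str
    start: int
    end: int
    n_probes: int
    mean_log2: float
    call: Call
    advisory: str | None = None


@dataclass(frozen=True)
class ConcordanceReport:
    n_array_events: int
    n_validated: int
    overlaps: tuple[tuple[CnaSegment, CnaSegment | None], ...]

    @property
    def fraction_validated(self) -> float:
        if self.n_array_events == 0:
            return float("nan")
        return self.n_validated / self.n_array_events


def _t_to_p(t_best: float, df: int, n_candidates: int) -> float:
    if np.isinf(t_best):
        return 0.0
    if df <= 0 or t_best == 0.0:
        return 1.0
    p = 2.0 * stats.t.sf(t_best, df=df) * n_candidates
    return float(min(p, 1.0))


def _best_arc(values: np.ndarray, min_seg: int) -> tuple[int, int, float]:
    """Most significant interval-vs-complement contrast of a segment.

    Tests every interval ``[i, j)`` with at least ``min_seg`` probes on
    both sides of the contrast against its complement with a pooled
    two-sample t; this is what lets short focal events inside a long
    segment be isolated.  Returns ``(i, j, p)`` with p Bonferroni
    corrected over the candidate intervals.
    """
    n = len(values)
    if n < 2 * min_seg:
        return 0, 0, 1.0
    s = np.concatenate([[0.0], np.cumsum(values)])
    s2 = np.concatenate([[0.0], np.cumsum(values**2)])
    total, total2 = s[-1], s2[-1]
    sum_in = s[None, :] - s[:, None]  # [i, j] -> sum over [i, j)
    sq_in = s2[None, :] - s2[:, None]
    i_idx, j_idx = np.triu_indices(n + 1, k=min_seg)
    m = (j_idx - i_idx).astype(float)
    m_out = n - m
    valid = m_out >= min_seg
    i_idx, j_idx, m, m_out = i_idx[valid], j_idx[valid], m[valid], m_out[valid]
    if len(i_idx) == 0:
        return 0, 0, 1.0
    sin = sum_in[i_idx, j_idx]
    qin = sq_in[i_idx, j_idx]
    mean_in = sin / m
    mean_out = (total - sin) / m_out
    ss_in = np.clip(qin - sin**2 / m, 0.0, None)
    ss_out = np.clip((total2 - qin) - (total - sin) ** 2 / m_out, 0.0, None)
    pooled_var = (ss_in + ss_out) / (n - 2)
    se = np.sqrt(pooled_var * (1.0 / m + 1.0 / m_out))
    diff = np.abs(mean_in - mean_out)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / se
    # cumulative-sum round-off can make diff ~1e-16 with se exactly 0
    t = np.where(np.isnan(t) | (diff < 1e-9), 0.0, t)
    best = int(np.argmax(t))
    p = _t_to_p(float(t[best]), n - 2, len(i_idx))
    return int(i_idx[best]), int(j_idx[best]), p


def _best_binary(values: np.ndarray, min_seg: int) -> tuple[int, int, float]:
    """Single change-point scan (left vs right), for long segments where
    the all-intervals test would be quadratic in size."""
    n = len(values)
    if n < 2 * min_seg:
        return 0, 0, 1.0
    csum = np.cumsum(values)
    csum2 = np.cumsum(values**2)
    total, total2 = csum[-1], csum2[-1]
    ks = np.arange(min_seg, n - min_seg + 1)
    left_n = ks.astype(float)
    right_n = n - left_n
    left_sum = csum[ks - 1]
    left_mean = left_sum / left_n
    right_mean = (total - left_sum) / right_n
    ss_left = np.clip(csum2[ks - 1] - left_sum**2 / left_n, 0.0, None)
    ss_right = np.clip(
        (total2 - csum2[ks - 1]) - (total - left_sum) ** 2 / right_n, 0.0, None
    )
    pooled_var = (ss_left + ss_right) / (n - 2)
    se = np.sqrt(pooled_var * (1.0 / left_n + 1.0 / right_n))
    diff = np.abs(left_mean - right_mean)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / se
    t = np.where(np.isnan(t) | (diff < 1e-9), 0.0, t)
    best = int(np.argmax(t))
    p = _t_to_p(float(t[best]), n - 2, len(ks))
    k = int(ks[best])
    return k, k, p


#: Above this many probes in one segment the quadratic all-intervals
#: scan is replaced by the linear single-change-point scan.
_MAX_ARC_PROBES = 3000


def _segment_one_chrom(
    values: np.ndarray, params: CnaParams, min_seg: int = 2
) -> list[tuple[int, int]]:
    """Recursive segmentation; returns half-open index ranges."""
    out: list[tuple[int, int]] = []
    stack = [(0, len(values))]
    while stack:
        lo, hi = stack.pop()
        window = values[lo:hi]
        if len(window) > _MAX_ARC_PROBES:
            i, j, p = _best_binary(window, min_seg)
        else:
            i, j, p = _best_arc(window, min_seg)
        if p < params.alpha and 0 < j - i < hi - lo:
            for a, b in ((lo, lo + i), (lo + i, lo + j), (lo + j, hi)):
                if b > a:
                    stack.append((a, b))
        else:
            out.append((lo, hi))
    return sorted(out)


def segment_probes(
    probes: pd.DataFrame, params: CnaParams = CnaParams()
) -> list[CnaSegment]:
    """Segment a probe table (columns ``chrom, pos, log2``) into calls.

    Probes must be position-sorted within each chromosome.  The output
    segments partition each chromosome's probes exactly.  Non-neutral
    mean levels spanning fewer than ``min_probes`` probes are demoted
    to neutral with a ``few_probes`` advisory.
    """
    required = {"chrom", "pos", "log2"}
    if not required.issubset(probes.columns):
        raise ValueError(f"probe table must have columns {sorted(required)}")
    segments: list[CnaSegment] = []
    for chrom, grp in probes.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        if np.any(np.diff(pos) <= 0):
            raise ValueError(f"probes on {chrom} are not strictly increasing")
        values = grp["log2"].to_numpy(dtype=float)
        for lo, hi in _segment_one_chrom(values, params):
            mean = float(values[lo:hi].mean())
            call = params.classify(mean)
            advisory = None
            if call != "neutral" and hi - lo < params.min_probes:
                call, advisory = "neutral", "few_probes"
            elif call == "neutral" and abs(mean) >= params.mosaic_log2:
                advisory = "mosaic"
            segments.append(
                CnaSegment(
                    chrom=chrom,
                    start=int(pos[lo]),
                    end=int(pos[hi - 1]),
                    n_probes=hi - lo,
                    mean_log2=mean,
                    call=call,
                    advisory=advisory,
                )
            )
    return segments


def call_depth_cna(
    regions: pd.DataFrame, params: CnaParams = CnaParams()
) -> list[CnaSegment]:
    """Call CNAs from paired tumor/normal read depth per region.

    ``regions`` needs columns ``chrom, start, end, tumor_depth,
    normal_depth`` with one shared region set for both samples.
    Regions with normal depth below ``min_normal_depth`` are excluded;
    log2(tumor/normal) ratios are median-centered and segmented on
    region midpoints.
    """
    required = {"chrom", "start", "end", "tumor_depth", "normal_depth"}
    if not required.issubset(regions.columns):
        raise ValueError(f"region table must have columns {sorted(required)}")
    usable = regions[regions["normal_depth"] >= params.min_normal_depth].copy()
    usable = usable[usable["tumor_depth"] > 0]
    if usable.empty:
        return []
    ratio = np.log2(
        usable["tumor_depth"].to_numpy(float)
        / usable["normal_depth"].to_numpy(float)
    )
    ratio -= np.median(ratio)
    probes = pd.DataFrame(
        {
            "chrom": usable["chrom"].to_numpy(),
            "pos": ((usable["start"] + usable["end"]) // 2).to_numpy(),
            "log2": ratio,
        }
    ).sort_values(["chrom", "pos"], kind="stable")
    return segment_probes(probes, params)


_GAINS = {"gain", "high_gain"}
_LOSSES = {"loss", "homozygous_loss"}


def _same_sign(a: Call, b: Call) -> bool:
    return (a in _GAINS and b in _GAINS) or (a in _LOSSES and b in _LOSSES)


def _overlap(a: CnaSegment, b: CnaSegment) -> int:
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start) + 1)


def concordance(
    array_events: Sequence[CnaSegment],
    wes_events: Sequence[CnaSegment],
    min_reciprocal_overlap: float = 0.0,
) -> ConcordanceReport:
    """Validate array events against an independent platform's events.

    An array event is validated when some event of the same sign
    (gain-type vs loss-type) overlaps it by at least one base, or, when
    ``min_reciprocal_overlap`` > 0, by that fraction of both events.
    Neutral segments on either side are ignored.
    """
    array_calls = [s for s in array_events if s.call != "neutral"]
    wes_calls = [s for s in wes_events if s.call != "neutral"]
    overlaps: list[tuple[CnaSegment, CnaSegment | None]] = []
    n_validated = 0
    for ev in array_calls:
        match = None
        for other in wes_calls:
            if not _same_sign(ev.call, other.call):
                continue
            ov = _overlap(ev, other)
            if ov <= 0:
                continue
            if min_reciprocal_overlap > 0:
                len_a = ev.end - ev.start + 1
                len_b = other.end - other.start + 1
                if (
                    ov / len_a < min_reciprocal_overlap
                    or ov / len_b < min_reciprocal_overlap
                ):
                    continue
            match = other
            break
        if match is not None:
            n_validated += 1
        overlaps.append((ev, match))
    return ConcordanceReport(
        n_array_events=len(array_calls),
        n_validated=n_validated,
        overlaps=tuple(overlaps),
    )


def segments_to_frame(segments: Sequence[CnaSegment]) -> pd.DataFrame:
    """BED-like table of segments (also the SEG writer's backbone)."""
    return pd.DataFrame(
        [
            {
                "chrom": s.chrom,
                "start": s.start,
                "end": s.end,
                "n_probes": s.n_probes,
                "mean_log2": s.mean_log2,
                "call": s.call,
                "advisory": s.advisory or "",
            }
            for s in segments
        ]
    )


def write_seg(
    segments: Sequence[CnaSegment], path: str, sample_id: str = "tumor"
) -> None:
    """Write segments in SEG format (ID, chrom, loc.start, loc.end,
    num.mark, seg.mean)."""
    df = pd.DataFrame(
        {
            "ID": sample_id,
            "chrom": [s.chrom for s in segments],
            "loc.start": [s.start for s in segments],
            "loc.end": [s.end for s in segments],
            "num.mark": [s.n_probes for s in segments],
            "seg.mean": [s.mean_log2 for s in segments],
        }
    )
    df.to_csv(path, sep="\t", index=False)
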