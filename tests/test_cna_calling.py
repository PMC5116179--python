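"""Segmentation, read-depth calling and cross-platform concordance."""

import numpy as np
import pandas as pd
import pytest

from rarecase import synthetic_data as sd
from rarecase.cna_calling import (
    CnaParams,
    CnaSegment,
    call_depth_cna,
    concordance,
    segment_probes,
    segments_to_frame,
    write_seg,
)


def probe_frame(values, chrom="chr1", spacing=15_000):
    pos = np.arange(spacing, spacing * (len(values) + 1), spacing)
    return pd.DataFrame({"chrom": chrom, "pos": pos, "log2": values})


def seg(chrom, start, end, call, n=50, mean=None):
    default_mean = {"gain": 0.58, "loss": -1.0, "high_gain": 1.5,
                    "homozygous_loss": -3.0, "neutral": 0.0}[call]
    return CnaSegment(chrom, start, end, n, mean if mean is not None else
                      default_mean, call)


class TestSegmentProbes:
    def test_flat_series_is_single_neutral_segment(self):
        rng = np.random.default_rng(0)
        probes = probe_frame(rng.normal(0, 0.1, 600))
        segments = segment_probes(probes)
        assert len(segments) == 1
        assert segments[0].call == "neutral"
        assert segments[0].n_probes == 600

    def test_whole_chromosome_gain_called_in_one_segment(self):
        cfg = sd.SimConfig(seed=1, cna_truth=[("chr1", 1, 10_000_000, 3)])
        probes = sd.simulate_cna_profile(cfg, 15_000, noise_sd=0.1)
        chr1 = probes[probes["chrom"] == "chr1"]
        segments = [s for s in segment_probes(chr1) if s.chrom == "chr1"]
        assert len(segments) == 1
        assert segments[0].call == "gain"

    def test_focal_homozygous_loss_boundaries_within_one_probe(self):
        spacing = 15_000
        truth_start, truth_end = 4_000_001, 5_342_705
        cfg = sd.SimConfig(
            seed=2, cna_truth=[("chr3", truth_start, truth_end, 0)]
        )
        probes = sd.simulate_cna_profile(cfg, spacing, noise_sd=0.1)
        chr3 = probes[probes["chrom"] == "chr3"]
        calls = [s for s in segment_probes(chr3) if s.call == "homozygous_loss"]
        assert len(calls) == 1
        inside = chr3[chr3["pos"].between(truth_start, truth_end)]["pos"]
        assert abs(calls[0].start - inside.iloc[0]) <= spacing
        assert abs(calls[0].end - inside.iloc[-1]) <= spacing

    def test_segments_partition_each_chromosome(self, sim_config):
        probes = sd.simulate_cna_profile(sim_config, 15_000)
        segments = segment_probes(probes)
        for chrom, grp in probes.groupby("chrom"):
            own = sorted(
                (s for s in segments if s.chrom == chrom), key=lambda s: s.start
            )
            assert sum(s.n_probes for s in own) == len(grp)
            assert own[0].start == grp["pos"].iloc[0]
            assert own[-1].end == grp["pos"].iloc[-1]
            for a, b in zip(own, own[1:]):
                assert a.end < b.start

    def test_noise_free_breakpoints_exact(self):
        values = np.concatenate([np.zeros(100), np.full(50, 0.58), np.zeros(100)])
        segments = segment_probes(probe_frame(values))
        gain = next(s for s in segments if s.call == "gain")
        assert gain.start == 15_000 * 101
        assert gain.end == 15_000 * 150
        assert gain.n_probes == 50

    def test_short_shifted_run_demoted_with_advisory(self):
        values = np.zeros(200)
        values[100:103] = 2.0  # 3 probes, below min_probes=5
        segments = segment_probes(probe_frame(values))
        short = next(s for s in segments if s.n_probes == 3)
        assert short.call == "neutral"
        assert short.advisory == "few_probes"

    def test_mosaic_level_flagged_not_called(self):
        values = np.full(300, 0.2)  # below the 0.33 gain threshold
        segments = segment_probes(probe_frame(values))
        assert len(segments) == 1
        assert segments[0].call == "neutral"
        assert segments[0].advisory == "mosaic"

    def test_unsorted_probes_rejected(self):
        probes = probe_frame(np.zeros(10))
        probes.loc[3, "pos"] = probes.loc[7, "pos"]
        with pytest.raises(ValueError, match="increasing"):
            segment_probes(probes.sort_index())

    def test_classification_is_pure_threshold_function(self):
        params = CnaParams()
        assert params.classify(0.58) == "gain"
        assert params.classify(1.2) == "high_gain"
        assert params.classify(-0.3) == "loss"
        assert params.classify(-1.1) == "homozygous_loss"
        assert params.classify(0.32) == "neutral"


class TestDepthCna:
    def _regions(self, ratio_by_chrom, n=400, lam=300):
        rng = np.random.default_rng(5)
        rows = []
        for chrom, ratio in ratio_by_chrom.items():
            for i in range(n):
                start = 1 + i * 15_000
                rows.append(
                    {
                        "chrom": chrom,
                        "start": start,
                        "end": start + 14_999,
                        "tumor_depth": rng.poisson(lam * ratio),
                        "normal_depth": rng.poisson(lam),
                    }
                )
        return pd.DataFrame(rows)

    def test_uniform_ratio_gain_called(self):
        regions = self._regions({"chr1": 1.5, "chr2": 1.0, "chr3": 1.0})
        calls = [s for s in call_depth_cna(regions) if s.call != "neutral"]
        assert len(calls) == 1
        assert calls[0].chrom == "chr1" and calls[0].call == "gain"
        assert calls[0].mean_log2 == pytest.approx(np.log2(1.5), abs=0.1)

    def test_equal_depths_yield_no_calls(self):
        regions = self._regions({"chr1": 1.0, "chr2": 1.0})
        assert all(s.call == "neutral" for s in call_depth_cna(regions))

    def test_half_ratio_loss_called(self):
        regions = self._regions({"chr1": 0.5, "chr2": 1.0, "chr3": 1.0})
        calls = [s for s in call_depth_cna(regions) if s.call != "neutral"]
        assert len(calls) == 1
        assert calls[0].call == "loss"
        assert calls[0].mean_log2 == pytest.approx(-1.0, abs=0.1)

    def test_shallow_normal_regions_excluded(self):
        regions = self._regions({"chr1": 1.0}, n=50)
        regions.loc[:24, "normal_depth"] = 5
        segments = call_depth_cna(regions)
        assert sum(s.n_probes for s in segments) == 25


class TestConcordance:
    def test_identical_event_lists_fully_validated(self):
        events = [seg("chr1", 1, 10_000_000, "gain"),
                  seg("chr2", 1, 4_500_000, "loss")]
        report = concordance(events, events)
        assert report.fraction_validated == 1.0

    def test_disjoint_event_lists_unvalidated(self):
        a = [seg("chr1", 1, 1_000_000, "gain")]
        b = [seg("chr2", 1, 1_000_000, "gain")]
        assert concordance(a, b).fraction_validated == 0.0

    def test_opposite_sign_overlap_does_not_validate(self):
        a = [seg("chr1", 1, 1_000_000, "gain")]
        b = [seg("chr1", 1, 1_000_000, "loss")]
        assert concordance(a, b).fraction_validated == 0.0

    def test_loss_classes_validate_each_other(self):
        a = [seg("chr1", 1, 1_000_000, "homozygous_loss")]
        b = [seg("chr1", 500_000, 2_000_000, "loss")]
        assert concordance(a, b).fraction_validated == 1.0

    def test_events_in_uncovered_regions_drop_fraction(self):
        array = [seg("chr1", 1, 10_000_000, "gain"),
                 seg("chr2", 1, 4_500_000, "loss"),
                 seg("chr3", 4_000_001, 5_342_705, "homozygous_loss")]
        wes = [s for s in array if s.chrom != "chr3"]  # chr3 not covered
        report = concordance(array, wes)
        assert report.n_array_events == 3
        assert report.n_validated == 2
        missed = [ev for ev, match in report.overlaps if match is None]
        assert [ev.chrom for ev in missed] == ["chr3"]

    def test_reciprocal_overlap_rule(self):
        a = [seg("chr1", 1, 1_000_000, "gain")]
        b = [seg("chr1", 999_000, 5_000_000, "gain")]
        assert concordance(a, b).fraction_validated == 1.0
        assert concordance(a, b, min_reciprocal_overlap=0.5).fraction_validated == 0.0


def test_seg_writer_layout(tmp_path):
    segments = [seg("chr1", 1, 100, "gain", n=7)]
    path = tmp_path / "out.seg"
    write_seg(segments, str(path))
    frame = pd.read_csv(path, sep="\t")
    assert list(frame.columns) == ["ID", "chrom", "loc.start", "loc.end",
                                   "num.mark", "seg.mean"]
    assert frame.loc[0, "num.mark"] == 7
    assert segments_to_frame(segments).loc[0, "call"] == "gain"
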