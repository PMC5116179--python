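"""End-to-end case orchestration: one config, one report.

``run_case`` wires the stages together — trio variant classification,
array and exome copy-number calling with cross-platform concordance,
mate-pair breakpoint delimitation, and ddPCR monitoring — writing each
stage's tables under an output directory plus a single JSON case
report.  Stages whose inputs are absent are marked ``skipped`` rather
than failing, so a tumor/patient-only case still yields the somatic,
CNA and SV sections.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import cna_calling, ctdna_monitor, sv_breakpoint, trio_filters, variant_io

logger = logging.getLogger(__name__)


@dataclass
class SvParams:
    insert_mean: float = 2000.0
    insert_sd: float = 150.0
    min_support: int = 3
    window: float | None = None  # default: insert_mean + 3 * insert_sd

    def effective_window(self) -> float:
        if self.window is not None:
            return self.window
        return self.insert_mean + 3.0 * self.insert_sd


@dataclass
class DdpcrParams:
    droplet_volume_nl: float = ctdna_monitor.DEFAULT_DROPLET_VOLUME_NL
    min_positive: int = ctdna_monitor.DEFAULT_MIN_POSITIVE
    control_samples: list[str] = field(default_factory=list)


@dataclass
class CaseConfig:
    """Inputs, sample roles and per-stage parameters for one case."""

    out_dir: str = "case_out"
    seed: int = 0
    roles: dict[str, str] = field(
        default_factory=lambda: {r: r for r in variant_io.ROLES}
    )
    vcf: str | None = None
    probes: str | None = None  # TSV: chrom, pos, log2
    regions: str | None = None  # TSV: chrom, start, end, tumor_depth, normal_depth
    bedpe: str | None = None
    genome_fasta: str | None = None
    droplets_csv: str | None = None
    case_sample: str = "patient_plasma"
    thresholds: trio_filters.FilterThresholds = field(
        default_factory=trio_filters.FilterThresholds
    )
    cna: cna_calling.CnaParams = field(default_factory=cna_calling.CnaParams)
    sv: SvParams = field(default_factory=SvParams)
    ddpcr: DdpcrParams = field(default_factory=DdpcrParams)

    @classmethod
    def from_yaml(cls, path: str) -> "CaseConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs: dict[str, Any] = {}
        for key in (
            "out_dir", "seed", "roles", "vcf", "probes", "regions",
            "bedpe", "genome_fasta", "droplets_csv", "case_sample",
        ):
            if key in raw:
                kwargs[key] = raw[key]
        if "thresholds" in raw:
            kwargs["thresholds"] = trio_filters.FilterThresholds(**raw["thresholds"])
        if "cna" in raw:
            kwargs["cna"] = cna_calling.CnaParams(**raw["cna"])
        if "sv" in raw:
            kwargs["sv"] = SvParams(**raw["sv"])
        if "ddpcr" in raw:
            kwargs["ddpcr"] = DdpcrParams(**raw["ddpcr"])
        return cls(**kwargs)


def _classified_frame(
    classified: list[trio_filters.ClassifiedVariant],
) -> pd.DataFrame:
    rows = []
    for cv in classified:
        rec = cv.record
        row = {
            "chrom": rec.chrom,
            "pos": rec.pos,
            "ref": rec.ref,
            "alt": rec.alt,
            "gene": rec.gene,
            "consequence": rec.consequence,
            "population_maf": rec.population_maf,
            "classes": ",".join(sorted(cv.classes)) or ".",
            "failure_reasons": ";".join(
                f"{k}:{v}" for k, v in sorted(cv.failure_reasons.items())
            ),
        }
        for role in variant_io.ROLES:
            call = rec.call(role)
            row[f"{role}_vaf"] = call.alt_fraction if call else None
            row[f"{role}_depth"] = call.depth if call else None
        rows.append(row)
    return pd.DataFrame(rows)


def run_case(config: CaseConfig) -> dict[str, Any]:
    """Run every stage with available inputs; return the case report."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {"seed": config.seed, "stages": {}}

    # --- variant classification ------------------------------------------
    if config.vcf:
        records = variant_io.read_vcf(config.vcf, roles=config.roles)
        have_parents = any(
            rec.call("mother") or rec.call("father") for rec in records
        )
        classified, summary = trio_filters.classify_all(records, config.thresholds)
        frame = _classified_frame(classified)
        frame.to_csv(out_dir / "classified.tsv", sep="\t", index=False)
        for cls, fname in (
            ("somatic", "somatic.tsv"),
            ("rare_homozygous", "rare_homozygous.tsv"),
            ("compound_het_member", "compound_het.tsv"),
        ):
            sub = frame[frame["classes"].str.contains(cls)]
            sub.to_csv(out_dir / fname, sep="\t", index=False)
        report["stages"]["classify"] = {"status": "ok", "summary": summary}
        if not have_parents:
            report["stages"]["classify"]["germline"] = "skipped_no_parents"
    else:
        report["stages"]["classify"] = {"status": "skipped"}

    # --- copy number ------------------------------------------------------
    array_segments = wes_segments = None
    if config.probes:
        probes = pd.read_csv(config.probes, sep="\t")
        array_segments = cna_calling.segment_probes(probes, config.cna)
        cna_calling.segments_to_frame(array_segments).to_csv(
            out_dir / "segments_array.tsv", sep="\t", index=False
        )
        cna_calling.write_seg(array_segments, str(out_dir / "segments_array.seg"))
        report["stages"]["cna_array"] = {
            "status": "ok",
            "n_events": sum(1 for s in array_segments if s.call != "neutral"),
        }
    else:
        report["stages"]["cna_array"] = {"status": "skipped"}
    if config.regions:
        regions = pd.read_csv(config.regions, sep="\t")
        wes_segments = cna_calling.call_depth_cna(regions, config.cna)
        cna_calling.segments_to_frame(wes_segments).to_csv(
            out_dir / "segments_wes.tsv", sep="\t", index=False
        )
        report["stages"]["cna_wes"] = {
            "status": "ok",
            "n_events": sum(1 for s in wes_segments if s.call != "neutral"),
        }
    else:
        report["stages"]["cna_wes"] = {"status": "skipped"}
    if array_segments is not None and wes_segments is not None:
        conc = cna_calling.concordance(array_segments, wes_segments)
        report["stages"]["concordance"] = {
            "status": "ok",
            "n_array_events": conc.n_array_events,
            "n_validated": conc.n_validated,
            "fraction_validated": conc.fraction_validated,
        }
    else:
        report["stages"]["concordance"] = {"status": "skipped"}

    # --- breakpoint -------------------------------------------------------
    if config.bedpe:
        bedpe = pd.read_csv(config.bedpe, sep="\t")
        pairs = sv_breakpoint.pairs_from_bedpe(bedpe)
        discordant = sv_breakpoint.find_discordant(
            pairs, config.sv.insert_mean, config.sv.insert_sd
        )
        calls = sv_breakpoint.cluster_breakpoint(
            discordant, config.sv.effective_window(), config.sv.min_support
        )
        sv_breakpoint.calls_to_bedpe(calls).to_csv(
            out_dir / "breakpoints.bedpe", sep="\t", index=False
        )
        report["stages"]["breakpoint"] = {
            "status": "ok",
            "n_discordant": len(discordant),
            "calls": [dataclasses.asdict(c) for c in calls],
        }
        if config.genome_fasta and calls:
            import pyfaidx

            fasta = pyfaidx.Fasta(config.genome_fasta)
            genome = {name: str(fasta[name][:]) for name in fasta.keys()}
            designs = [sv_breakpoint.assay_region(c, genome) for c in calls]
            with open(out_dir / "fused_contigs.fa", "w") as fh:
                for i, d in enumerate(designs):
                    fh.write(
                        f">fusion_{i}_{d.chrom_a}_{d.chrom_b}\n{d.fused_contig}\n"
                    )
            report["stages"]["breakpoint"]["n_assay_designs"] = len(designs)
    else:
        report["stages"]["breakpoint"] = {"status": "skipped"}

    # --- ctDNA monitoring -------------------------------------------------
    if config.droplets_csv:
        by_sample = ctdna_monitor.read_assay_csv(config.droplets_csv)
        min_pos = config.ddpcr.min_positive
        controls: list[ctdna_monitor.QuantResult] = []
        for name in config.ddpcr.control_samples:
            for assay in by_sample.get(name, []):
                controls.append(ctdna_monitor.quantify(assay, min_pos))
        monitoring = {}
        for sample, assays in by_sample.items():
            if sample in config.ddpcr.control_samples:
                continue
            by_channel = {}
            for channel in ("fusion", "wildtype"):
                wells = [a for a in assays if a.channel == channel]
                if wells:
                    pooled = ctdna_monitor.pool_replicates(wells)
                    by_channel[channel] = ctdna_monitor.quantify(pooled, min_pos)
            if {"fusion", "wildtype"} <= by_channel.keys():
                verdict = ctdna_monitor.detection_call(
                    by_channel["fusion"], by_channel["wildtype"], controls,
                    min_pos,
                )
            else:
                verdict = "invalid"
            monitoring[sample] = {
                "call": verdict,
                **{
                    ch: dataclasses.asdict(q) for ch, q in by_channel.items()
                },
            }
        report["stages"]["monitor"] = {"status": "ok", "samples": monitoring}
    else:
        report["stages"]["monitor"] = {"status": "skipped"}

    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    return report
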