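# Methods

This note documents the models and procedures implemented in
`rarecase`, the parameters that matter, the assumptions behind the
synthetic-data generators, and the numerical and design choices made
where the problem left them open.

## Study design

The pipeline models a family-based tumor case study: one patient's
tumor and leukocyte DNA plus leukocyte DNA from both parents are
exome-sequenced; the tumor is additionally profiled by oligonucleotide
array CGH and mate-pair whole-genome sequencing; and a tumor-specific
fusion junction is tracked in plasma by droplet digital PCR during
follow-up. The pipeline starts downstream of alignment and raw variant
calling: its inputs are annotated multi-sample VCFs, probe-level log2
ratio tables, per-region read depths, mate-pair coordinates (BEDPE) and
droplet counts.

## Trio variant classification

Each variant site is joined across the four samples into a
`TrioRecord` carrying depth, alternate-read fraction (VAF), genotype,
gene, functional consequence and population minor-allele frequency
(MAF). Four rules are evaluated per record (`trio_filters`):

* **Somatic**: tumor and patient-leukocyte depth ≥ `min_depth` (10
  reads), tumor VAF ≥ 20%, leukocyte VAF ≤ `somatic_max_normal_vaf`.
* **De novo**: all three leukocyte depths ≥ 10, patient VAF ≥ 30%,
  both parents' VAF ≤ `somatic_max_normal_vaf`.
* **Rare homozygous**: patient hom-alt, both parents het, MAF ≤ 10%.
* **Compound heterozygous** (per gene): at least one maternal-only and
  one paternal-only patient-het variant, each with MAF ≤ 10%, where
  "exclusively present in one parent" means the other parent shows no
  alternate support. A variant het in both parents is unphasable from
  a trio and is simply ineligible. With more than two eligible
  variants, every maternal×paternal pair is reported.

Choices a reader should know about:

* All thresholds are **inclusive**: the somatic evidence tables contain
  a variant at exactly 20% VAF and the depth floor is "≥10×".
* `somatic_max_normal_vaf` defaults to **0** (strict absence of the
  allele in the comparison sample). The tolerated level of normal
  support is not specified by the study design, so it is exposed as a
  parameter for noisier callers; raising it trades somatic specificity
  for sensitivity to contamination/artifacts.
* When a record carries no explicit genotype call, genotype is derived
  from VAF: hom-ref < 0.15 ≤ het < 0.80 ≤ hom-alt. These bounds are
  dictated by the reference tables themselves, which count 83.3% as
  homozygous and 17.9% as heterozygous; the exact boundaries used by
  the original callers are unknown, so these are a documented package
  decision.
* A variant with **no reported MAF is treated as rare**: several
  confirmed germline hits carry dbSNP identifiers without a published
  frequency, so treating absence as commonness would discard true
  positives. When several population databases disagree upstream, the
  conservative (maximum) frequency should be supplied in the single
  MAF annotation the pipeline consumes.
* Records missing a required sample return an *indeterminate* verdict,
  distinct from a failed one; every failure carries a machine-readable
  reason code so exclusions are auditable.

Missing from scope by design: genotype-likelihood models, multiallelic
sites (assumed split upstream), phasing beyond trio logic, and
pathogenicity prediction (PolyPhen/SIFT-style columns are pass-through
annotations).

## Copy-number analysis

`segment_probes` performs recursive CBS-style segmentation of
position-sorted probe log2 ratios. Within a segment, every interval
with ≥2 probes on both sides of the contrast is tested against its
complement with a pooled two-sample t statistic; the most significant
interval is split out (three-way) when its Bonferroni-corrected p value
falls below `alpha = 1e-8`, and recursion continues on the parts. The
interval-vs-complement form (rather than a single change-point scan) is
what allows a short focal event inside a chromosome-length segment to
be isolated. For segments longer than 3000 probes the quadratic
interval scan is replaced by the linear single-change-point scan; at
the probe densities this package targets (~70 kb effective resolution,
hundreds of probes per synthetic chromosome) the exact scan always
applies. Mean differences below 1e-9 are treated as zero to keep
cumulative-sum round-off from fabricating infinitely significant splits
on constant data.

Segments are classified purely from their mean log2 against four
thresholds — gain ≥ 0.33, loss ≤ −0.3, high gain ≥ 1.2, homozygous
loss ≤ −1.1 — and a non-neutral level spanning fewer than
`min_probes = 5` probes is demoted to neutral with a `few_probes`
advisory. Sub-threshold but shifted segments (|mean| ≥ 0.1) carry a
`mosaic` advisory: low-level mosaic alterations are reported but never
promoted to calls.

`call_depth_cna` converts paired tumor/normal per-region depths to
log2(tumor/normal), drops regions with normal depth < 10, median-centers
the ratios and segments the region midpoints with the same machinery.
Median centering assumes most of the genome is copy-neutral; when a
large fraction is aberrant the baseline shifts accordingly (visible as
a small bias in segment means, not in calls).

`concordance` validates each non-neutral event from one platform
against the other: same sign (gain-type vs loss-type) and ≥1 bp overlap
by default, with an optional reciprocal-overlap fraction. The overlap
criterion behind published concordance figures is generally unstated;
any-overlap is the most permissive defensible default and the
reciprocal rule is provided for stricter analyses.

The package also records the case's focal homozygous deletion
coordinates (`FOCAL_DELETION_9P`, chr9:17,106,384–18,449,088, hg19,
~1.3 Mb). The source material places this event in two different bands
in different figures; the base-pair coordinates are taken as
authoritative.

## Breakpoint detection

`find_discordant` flags pairs on different chromosomes, or
same-chromosome pairs whose outer distance falls outside
`insert_mean ± k·sd` (k = 5). `cluster_breakpoint` groups
interchromosomal discordants per chromosome pair by single-linkage:
two pairs join when both read-1 and read-2 starts lie within `window`
of each other. `window` defaults to `insert_mean + 3·sd` (~2.45 kb for
a 2 kb ± 150 bp library) and doubles as the insert span delimiting the
junction. Clusters with ≥ `min_support` (3) pairs become calls.

The junction interval on each side is oriented by read strand: reads on
`+` point at a junction downstream (interval = [max start, max start +
span]), reads on `-` upstream. Interval width is therefore bounded by
the insert span, and the true junction is contained whenever supporting
fragments straddle it. Clustering output is coordinate-sorted, so it is
invariant under permutation of the input pairs; ties break leftmost.
Orientation classes are reported but not used to filter — the target
junction type is validated by PCR across the junction, not by
orientation logic. Split-read base-pair refinement and general SV
typing are out of scope.

`assay_region` extracts ~400 bp of flank on each side of the interval
midpoints and concatenates them into a fused reference contig (~800 bp,
Sanger-amplicon scale) for primer design.

## ddPCR quantification and monitoring

For `k` positive of `n` droplets, `λ̂ = −ln(1 − k/n)` copies per
droplet (Poisson occupancy), concentration `λ̂ / v` with droplet volume
`v = 0.85 nL` (QX200-class instruments; the volume is configurable
because it is instrument-specific). The 95% CI is a Wilson binomial
interval on `k/n` mapped through the same transform. A fully positive
well is *saturated*: only the lower bound is meaningful. A channel is
*detected* at ≥ `min_positive = 2` droplets; single-droplet events are
treated as inconclusive rather than positive. Replicate wells are
pooled by summing counts before estimation.

`detection_call` encodes the monitoring logic: a well is **invalid**
when the wild-type reference channel is undetected (no amplifiable
cell-free DNA) or when any negative control shows fusion signal;
**negative** when valid with no fusion detected; **positive**
otherwise.

`lod_simulation` maps detection probability over input mass × tumor
fraction. Genome copies = mass / 3.3 pg per haploid genome
(configurable constant); expected fusion copies = copies × fraction,
spread over `n_droplets`. The default grid follows the assay-validation
design: masses 60 ng → 6 pg in tenfold steps and fractions 100%, 1%,
0.1%. Detection probability of ≥1 positive droplet has the closed form
`1 − exp(−expected copies)`, reported alongside the empirical estimate;
the 6 pg point (~1.8 haploid copies) sits in the single-molecule regime
where detection is possible but not guaranteed.

## Synthetic data: what it emulates and what it does not

The generators (`synthetic_data`) define the conditions under which the
pipeline is validated:

* **Genome**: three synthetic 10 Mb chromosomes. Real (hg19)
  coordinates appear only in the published-table fixtures.
* **Trio variants**: per-sample depth ~ Poisson(`depth_mean`, default
  30, floor of 10 applied downstream), alternate reads ~
  Binomial(depth, true VAF). Class-typical VAFs: somatic 0.40 in tumor
  only (high purity with some normal admixture), de novo/comphet 0.5
  het, rare-hom 1.0 patient / 0.5 parents. Background variants are
  Mendelian-consistent common polymorphisms (MAF 0.12–0.50, one gene
  each).
* **CNA profiles**: probes every `probe_spacing` bp; segment mean
  log2(copies/2), floored at −3 for homozygous loss (arrays saturate),
  Gaussian noise sd 0.15. The default truth emulates the case's event
  spectrum: one chromosome-scale single-copy gain, two arm-level
  losses, one focal ~1.34 Mb homozygous deletion. Exome region depths
  add tumor impurity: deleted regions retain 5% residual normal-cell
  reads, without which a depth-based caller would have no observations
  in homozygous deletions.
* **Mate pairs**: ~2 kb ± 150 bp inserts, 60 bp reads; discordant
  fragments straddle a declared junction with the split point uniform
  over the fragment.
* **Droplets**: each positive with probability 1 − exp(−λ).

Not modeled: read-level sequences (no FASTQ), sequencing error,
mapping artifacts, GC bias, probe-specific array effects, ddPCR "rain".
Passing recovery suites therefore demonstrates correctness of the
decision rules and estimators under clean sampling noise — not
robustness to platform artifacts, which real data would add on top.

## Validation problem sizes

The recovery suites run at: 10 simulation seeds × (20 planted variants
per class + 1000 background) at 30× for trio classification
(sensitivity ≥0.95, FDR ≤0.05 per class, pooled); 15 kb probe spacing
with noise sd 0.15 for segmentation recovery (every event recovered
with correct class, boundaries within one probe spacing); 100 seeds ×
(50 junction + 10,000 concordant pairs) for breakpoint recovery
(junction contained in ≥99); 10⁶ droplets for quantification
calibration (λ recovered within 1%). These sizes were chosen so the
binomial uncertainty of each metric is well below its acceptance
margin.

## Known limitations

* Biallelic records only; multiallelic sites must be normalized
  upstream.
* The compound-het rule cannot phase variants het in both parents;
  such variants are conservatively ineligible.
* Median centering of depth ratios biases segment means when a large
  genome fraction is aberrant (calls are threshold-robust to this at
  the simulated effect sizes, but near-threshold events could flip).
* Single-linkage clustering can chain two junctions closer than the
  window into one call; junctions separated by more than the window
  are always distinct.
* Saturated ddPCR wells carry no upper concentration bound; dilution
  is the practical remedy.
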