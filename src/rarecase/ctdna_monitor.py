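"""Droplet-digital-PCR quantification and ctDNA detection calls.

A sample is partitioned into ~20,000 droplets; each droplet is PCR
positive when it received at least one template copy.  With copies
Poisson-distributed across droplets at mean ``lambda`` per droplet,
the positive fraction ``p`` satisfies ``p = 1 - exp(-lambda)``, so

    lambda_hat = -ln(1 - n_positive / n_total)

and the concentration is ``lambda_hat / droplet_volume``.  Confidence
intervals propagate a binomial (Wilson) interval on ``p`` through the
same transform.

Two channels are assayed: the tumor-specific gene-fusion junction
(marker) and a non-rearranged wild-type reference that reports whether
amplifiable cell-free DNA is present at all.  ``detection_call``
combines both channels with negative controls into a
positive/negative/invalid verdict, and ``lod_simulation`` maps the
limit of detection over an input-mass x tumor-fraction grid.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic_data import simulate_droplets

logger = logging.getLogger(__name__)

#: Mass of one haploid human genome equivalent, in nanograms (3.3 pg).
HAPLOID_GENOME_NG = 3.3e-3

#: Droplet volume of a QX200-class instrument, in nanoliters.
DEFAULT_DROPLET_VOLUME_NL = 0.85

#: Minimum positive droplets for a marker to count as detected; single
#: positive droplets are treated as inconclusive.
DEFAULT_MIN_POSITIVE = 2


@dataclass(frozen=True)
class DropletAssay:
    """Positive/negative droplet counts for one channel of one well."""

    channel: str  # "fusion" or "wildtype"
    n_positive: int
    n_total: int
    droplet_volume_nl: float = DEFAULT_DROPLET_VOLUME_NL
    replicate: str = "1"

    def __post_init__(self) -> None:
        if self.n_total <= 0:
            raise ValueError("n_total must be positive")
        if not 0 <= self.n_positive <= self.n_total:
            raise ValueError("need 0 <= n_positive <= n_total")
        if self.droplet_volume_nl <= 0:
            raise ValueError("droplet_volume_nl must be positive")


@dataclass(frozen=True)
class QuantResult:
    """Poisson concentration estimate for one channel."""

    channel: str
    lambda_hat: float  # mean copies per droplet
    ci_low: float
    ci_high: float
    concentration: float  # copies per nanoliter
    n_positive: int
    n_total: int
    detected: bool
    saturated: bool = False


def pool_replicates(assays: Sequence[DropletAssay]) -> DropletAssay:
    """Pool droplet counts across replicate wells of one channel."""
    if not assays:
        raise ValueError("no assays to pool")
    channels = {a.channel for a in assays}
    if len(channels) != 1:
        raise ValueError(f"cannot pool across channels {sorted(channels)}")
    return DropletAssay(
        channel=assays[0].channel,
        n_positive=sum(a.n_positive for a in assays),
        n_total=sum(a.n_total for a in assays),
        droplet_volume_nl=assays[0].droplet_volume_nl,
        replicate="pooled",
    )


def quantify(
    assay: DropletAssay, min_positive: int = DEFAULT_MIN_POSITIVE
) -> QuantResult:
    """Poisson point estimate with binomial-propagated 95% CI.

    A fully positive well is saturated: the point estimate and upper
    bound are unbounded and only the lower bound is meaningful.
    """
    k, n = assay.n_positive, assay.n_total
    p_low, p_high = stats.binomtest(k, n).proportion_ci(
        confidence_level=0.95, method="wilson"
    )
    ci_low = -math.log(max(1.0 - p_low, 1e-300))
    if k == n:
        lam = math.inf
        ci_high = math.inf
        saturated = True
    else:
        lam = -math.log(1.0 - k / n)
        ci_high = -math.log(max(1.0 - p_high, 1e-300))
        saturated = False
    return QuantResult(
        channel=assay.channel,
        lambda_hat=lam,
        ci_low=ci_low,
        ci_high=ci_high,
        concentration=lam / assay.droplet_volume_nl,
        n_positive=k,
        n_total=n,
        detected=k >= min_positive,
        saturated=saturated,
    )


def fusion_fraction(fusion: QuantResult, wildtype: QuantResult) -> float:
    """Fraction of template carrying the fusion junction."""
    total = fusion.lambda_hat + wildtype.lambda_hat
    if total == 0:
        return 0.0
    return fusion.lambda_hat / total


def detection_call(
    fusion: QuantResult,
    wildtype: QuantResult,
    controls: Sequence[QuantResult] = (),
    min_positive: int = DEFAULT_MIN_POSITIVE,
) -> str:
    """Combine marker, reference and controls into one verdict.

    ``invalid``: the wild-type reference is undetected (no amplifiable
    cell-free DNA in the well) or a negative control shows fusion
    signal at or above ``min_positive`` droplets (contamination).
    ``negative``: valid assay, no fusion detected.  ``positive``
    otherwise.
    """
    if not controls:
        logger.warning("detection_call proceeding without negative controls")
    if not wildtype.detected:
        return "invalid"
    for ctrl in controls:
        if ctrl.channel == "fusion" and ctrl.n_positive >= min_positive:
            return "invalid"
    return "positive" if fusion.detected else "negative"


def read_assay_csv(path: str) -> dict[str, list[DropletAssay]]:
    """Read wells from a CSV of (sample, channel, n_positive, n_total,
    replicate[, droplet_volume_nl]); returns sample -> assays."""
    df = pd.read_csv(path)
    out: dict[str, list[DropletAssay]] = {}
    for _, row in df.iterrows():
        out.setdefault(str(row["sample"]), []).append(
            DropletAssay(
                channel=str(row["channel"]),
                n_positive=int(row["n_positive"]),
                n_total=int(row["n_total"]),
                droplet_volume_nl=float(
                    row.get("droplet_volume_nl", DEFAULT_DROPLET_VOLUME_NL)
                ),
                replicate=str(row.get("replicate", "1")),
            )
        )
    return out


#: Input-mass series of the assay robustness experiment: 60 ng followed
#: by tenfold dilutions down to the single-genome-copy regime (6 pg).
DEFAULT_MASS_SERIES_NG = (60.0, 6.0, 0.6, 0.06, 0.006)

#: Tumor fractions of the spike-in mixtures (1:100 and 1:1000).
DEFAULT_TUMOR_FRACTIONS = (1.0, 0.01, 0.001)


def lod_simulation(
    input_mass_series_ng: Sequence[float] = DEFAULT_MASS_SERIES_NG,
    tumor_fractions: Sequence[float] = DEFAULT_TUMOR_FRACTIONS,
    n_droplets: int = 20_000,
    replicates: int = 200,
    seed: int = 0,
    haploid_genome_ng: float = HAPLOID_GENOME_NG,
) -> pd.DataFrame:
    """Detection probability over an input-mass x tumor-fraction grid.

    Genome copies are ``mass / haploid_genome_ng``; the expected fusion
    copies are ``copies * fraction`` spread over ``n_droplets``
    droplets.  For each condition, ``replicates`` wells are simulated
    and the empirical probability of >=1 positive droplet reported,
    alongside the closed form ``1 - exp(-expected_copies)``.
    """
    for mass in input_mass_series_ng:
        if mass <= 0:
            raise ValueError("input masses must be positive")
    for frac in tumor_fractions:
        if not 0.0 <= frac <= 1.0:
            raise ValueError("tumor fractions must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    rows = []
    for mass in input_mass_series_ng:
        copies = mass / haploid_genome_ng
        for frac in tumor_fractions:
            expected = copies * frac
            lam = expected / n_droplets
            hits = 0
            for _ in range(replicates):
                n_pos, _ = simulate_droplets(lam, n_droplets, rng=rng)
                hits += n_pos >= 1
            rows.append(
                {
                    "input_mass_ng": mass,
                    "tumor_fraction": frac,
                    "expected_fusion_copies": expected,
                    "detection_probability": hits / replicates,
                    "detection_probability_analytic": 1.0 - math.exp(-expected),
                }
            )
    return pd.DataFrame(rows)
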