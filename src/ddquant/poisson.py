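"""Poisson partition statistics for droplet digital PCR.

A ddPCR well partitions a reaction into roughly 20,000 nanoliter droplets
and classifies each as positive or negative after end-point amplification.
Template molecules land in droplets independently, so occupancy follows a
Poisson law: with true rate λ copies per droplet, the probability a droplet
is positive is ``1 - exp(-λ)``. Inverting the observed positive fraction
``P/N`` gives the maximum-likelihood rate

    λ̂ = -ln(1 - P/N)

which this module converts to absolute concentrations (copies/μL) using the
droplet volume. No standard curve is involved; that is the point of digital
PCR.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats

from .errors import InvalidInputError, SaturatedPartitionError

#: Conventional droplet volume (nL) for the 20k-droplet instrument class.
#: Only concentration *ratios* matter downstream, so this default never
#: affects transfer coefficients or mass fractions.
DEFAULT_DROPLET_VOLUME_NL = 0.85


@dataclass(frozen=True)
class DropletPartition:
    """Raw positive/accepted droplet counts from a single well.

    Parameters
    ----------
    positives : int
        Number of droplets classified positive (P).
    accepted : int
        Number of accepted droplets (N).
    well_id, assay_id : str
        Opaque labels; ``assay_id`` names the species/target-gene channel
        (e.g. porcine ACTB, chicken TGFB3, bovine ACTB).
    """

    positives: int
    accepted: int
    well_id: str = ""
    assay_id: str = ""

    def __post_init__(self) -> None:
        if self.accepted <= 0:
            raise InvalidInputError(
                f"well {self.well_id!r}: accepted droplet count must be positive, "
                f"got {self.accepted}"
            )
        if not 0 <= self.positives <= self.accepted:
            raise InvalidInputError(
                f"well {self.well_id!r}: positives must satisfy 0 <= P <= N, "
                f"got P={self.positives}, N={self.accepted}"
            )

    @property
    def positive_fraction(self) -> float:
        return self.positives / self.accepted


@dataclass(frozen=True)
class ConcentrationEstimate:
    """Copy-number concentration recovered from one partition.

    ``copies_per_ul = cpd / (droplet_volume_nl * 1e-3)`` with a 95 %
    (by default) interval on the same scale.
    """

    cpd: float
    copies_per_ul: float
    ci_low: float
    ci_high: float
    droplet_volume_nl: float = DEFAULT_DROPLET_VOLUME_NL
    well_id: str = ""
    assay_id: str = ""


def estimate_cpd(partition: DropletPartition) -> float:
    """Maximum-likelihood copies-per-droplet rate ``-ln(1 - P/N)``.

    Raises
    ------
    SaturatedPartitionError
        If every droplet is positive (P = N); the rate is then unbounded.
    """
    if partition.positives == partition.accepted:
        raise SaturatedPartitionError(
            f"well {partition.well_id!r}: all {partition.accepted} droplets "
            "positive; copies-per-droplet rate is unbounded"
        )
    return -math.log1p(-partition.positive_fraction)


def cpd_to_concentration(
    cpd: float, droplet_volume_nl: float = DEFAULT_DROPLET_VOLUME_NL
) -> float:
    """Convert a copies-per-droplet rate to copies per microliter."""
    if droplet_volume_nl <= 0:
        raise InvalidInputError(f"droplet volume must be positive, got {droplet_volume_nl}")
    if cpd < 0:
        raise InvalidInputError(f"copies-per-droplet rate must be non-negative, got {cpd}")
    return cpd / (droplet_volume_nl * 1e-3)


def concentration_to_cpd(
    copies_per_ul: float, droplet_volume_nl: float = DEFAULT_DROPLET_VOLUME_NL
) -> float:
    """Inverse of :func:`cpd_to_concentration`."""
    if droplet_volume_nl <= 0:
        raise InvalidInputError(f"droplet volume must be positive, got {droplet_volume_nl}")
    return copies_per_ul * droplet_volume_nl * 1e-3


def concentration_interval(
    partition: DropletPartition,
    droplet_volume_nl: float = DEFAULT_DROPLET_VOLUME_NL,
    confidence: float = 0.95,
) -> tuple[float, float]:
    """Confidence interval on copies/μL for one well.

    A normal-approximation binomial interval on the positive fraction is
    transformed through the Poisson link ``-ln(1 - p)`` and scaled by the
    droplet volume. This is a reporting aid: per-well sampling uncertainty,
    not the replicate-to-replicate spread laboratories usually quote.

    For P = 0 the lower bound is 0 and the upper bound uses the rule of
    three (``3/N`` copies per droplet at 95 %), since the Wald width
    collapses there.
    """
    if not 0 < confidence < 1:
        raise InvalidInputError(f"confidence must be in (0, 1), got {confidence}")
    n = partition.accepted
    p_hat = partition.positive_fraction
    if p_hat == 1.0:
        raise SaturatedPartitionError(
            f"well {partition.well_id!r}: saturated partition has no finite interval"
        )
    z = stats.norm.ppf(0.5 + confidence / 2)
    if partition.positives == 0:
        # exact one-sided bound: P(no positives | lam) = exp(-lam*N) = 1 - conf
        lam_hi = -math.log(1 - confidence) / n
        return 0.0, cpd_to_concentration(lam_hi, droplet_volume_nl)
    se = math.sqrt(p_hat * (1 - p_hat) / n)
    p_lo = max(p_hat - z * se, 0.0)
    p_hi = min(p_hat + z * se, 1 - 0.5 / n)
    return (
        cpd_to_concentration(-math.log1p(-p_lo), droplet_volume_nl),
        cpd_to_concentration(-math.log1p(-p_hi), droplet_volume_nl),
    )


def estimate_concentration(
    partition: DropletPartition,
    droplet_volume_nl: float = DEFAULT_DROPLET_VOLUME_NL,
    confidence: float = 0.95,
) -> ConcentrationEstimate:
    """Full point-plus-interval concentration estimate for one well."""
    cpd = estimate_cpd(partition)
    low, high = concentration_interval(partition, droplet_volume_nl, confidence)
    return ConcentrationEstimate(
        cpd=cpd,
        copies_per_ul=cpd_to_concentration(cpd, droplet_volume_nl),
        ci_low=low,
        ci_high=high,
        droplet_volume_nl=droplet_volume_nl,
        well_id=partition.well_id,
        assay_id=partition.assay_id,
    )
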