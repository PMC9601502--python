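"""Copy-ratio to mass-fraction conversion and label screening.

The core identity: for a binary mixture of a target species in a beef
background, the mass ratio is

    M_T / M_B = K * Q_T / Q_B

where Q_T, Q_B are the measured copies/μL of the species-specific
single-copy assays and K is the transfer coefficient (the ratio of
per-unit-mass copy densities, C_B/C_T) determined once per species pair by
the calibration module. The binary-mixture assumption then turns the mass
ratio r into a mass fraction 100·r/(1+r).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import (
    InsufficientDataError,
    InvalidInputError,
    ReferenceAbsentError,
    UndefinedDeviationError,
)
from .rounding import relative_deviation_percent, round_half_up

#: Default tolerance (percentage points) beyond which a measured composition
#: is considered to contradict the label. Conservative: confirmed
#: mislabelling cases in practice exceed declared values by >12 points.
DEFAULT_ADULTERATION_TOLERANCE_PP = 5.0


@dataclass
class QuantResult:
    """Quantification outcome for one sample/species channel."""

    sample_id: str
    mass_ratio: float
    mass_fraction_percent: float
    declared_percent: float | None = None
    deviation_percent: float | None = None
    adulteration_flag: bool = False
    species: str = ""
    notes: str = ""


def mass_ratio(q_target: float, q_reference: float, k: float) -> float:
    """Target-to-reference mass ratio ``k * q_target / q_reference``."""
    if k <= 0:
        raise InvalidInputError(f"transfer coefficient must be positive, got {k}")
    if q_target < 0:
        raise InvalidInputError(f"target concentration must be non-negative, got {q_target}")
    if q_reference <= 0:
        raise ReferenceAbsentError(
            "no reference-species copies detected; sample is not a "
            "reference-background mixture and the mass ratio is undefined"
        )
    return k * q_target / q_reference


def mass_fraction(ratio: float) -> float:
    """Mass fraction (percent of total) of the target: ``100 * r / (1 + r)``.

    Assumes a binary mixture (target + reference species only); for
    multi-species samples the pairwise ratio is the meaningful quantity.
    """
    if ratio < 0:
        raise InvalidInputError(f"mass ratio must be non-negative, got {ratio}")
    return 100.0 * ratio / (1.0 + ratio)


def fraction_to_ratio(fraction_percent: float) -> float:
    """Inverse of :func:`mass_fraction`: ``(w/100) / (1 - w/100)``."""
    if not 0 <= fraction_percent < 100:
        raise InvalidInputError(
            f"mass fraction percent must be in [0, 100), got {fraction_percent}"
        )
    w = fraction_percent / 100.0
    return w / (1.0 - w)


def deviation(measured_percent: float, actual_percent: float) -> float:
    """Signed relative deviation ``100 * (measured - actual) / actual``.

    Reported to 2 decimals (half-up on the exact decimal value), matching
    the convention of published validation tables.
    """
    if actual_percent == 0:
        raise UndefinedDeviationError(
            "relative deviation vs a zero expected value is undefined; "
            "report the absolute difference instead"
        )
    return relative_deviation_percent(measured_percent, actual_percent)


def mean_abs_deviation(deviations: list[float]) -> float:
    """Arithmetic mean of absolute deviations, 2-decimal report."""
    if not deviations:
        raise InsufficientDataError("mean absolute deviation of an empty list")
    return round_half_up(sum(abs(d) for d in deviations) / len(deviations))


@dataclass
class ScreeningRow:
    """One product/species line of an adulteration screen."""

    sample_id: str
    species: str
    declared_percent: float | None  # None = label lacks a defined content
    measured_percent: float
    flagged: bool
    status: str  # "ok" | "flagged" | "LC"


@dataclass
class ScreeningReport:
    tolerance_pp: float
    rows: list[ScreeningRow] = field(default_factory=list)

    @property
    def flagged(self) -> list[ScreeningRow]:
        return [r for r in self.rows if r.flagged]


def quantify_sample(
    sample_id: str,
    q_target: float,
    q_reference: float,
    k: float,
    declared_percent: float | None = None,
    species: str = "",
    tolerance_pp: float = DEFAULT_ADULTERATION_TOLERANCE_PP,
) -> QuantResult:
    """End-to-end quantification of one sample against an optional label claim."""
    ratio = mass_ratio(q_target, q_reference, k)
    fraction = mass_fraction(ratio)
    dev = None
    flag = False
    if declared_percent is not None:
        flag = abs(fraction - declared_percent) > tolerance_pp
        if declared_percent > 0:
            dev = deviation(fraction, declared_percent)
    return QuantResult(
        sample_id=sample_id,
        mass_ratio=ratio,
        mass_fraction_percent=fraction,
        declared_percent=declared_percent,
        deviation_percent=dev,
        adulteration_flag=flag,
        species=species,
    )


def screen_products(
    samples: list[dict],
    tolerance_pp: float = DEFAULT_ADULTERATION_TOLERANCE_PP,
) -> ScreeningReport:
    """Compare measured compositions with declared label contents.

    Each sample dict carries ``sample_id``, ``species``, ``measured_percent``
    and ``declared_percent`` (a float, or ``None`` when the label lacks a
    defined content). A row is flagged when the measured fraction differs
    from the declared one by more than ``tolerance_pp`` percentage points.
    Rows without a declared content are reported with status ``"LC"``
    (lacking content) and never flagged: there is no claim to contradict.
    """
    report = ScreeningReport(tolerance_pp=tolerance_pp)
    for s in samples:
        declared = s.get("declared_percent")
        measured = float(s["measured_percent"])
        if declared is None:
            report.rows.append(
                ScreeningRow(
                    sample_id=s["sample_id"],
                    species=s.get("species", ""),
                    declared_percent=None,
                    measured_percent=measured,
                    flagged=False,
                    status="LC",
                )
            )
            continue
        declared = float(declared)
        flagged = abs(measured - declared) > tolerance_pp
        report.rows.append(
            ScreeningRow(
                sample_id=s["sample_id"],
                species=s.get("species", ""),
                declared_percent=declared,
                measured_percent=measured,
                flagged=flagged,
                status="flagged" if flagged else "ok",
            )
        )
    return report
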