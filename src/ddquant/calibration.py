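"""Transfer-coefficient (K) determination and verification.

Single-copy nuclear assays report copies/μL, but a copy-number ratio is not
a mass ratio: genome size and copy density per gram differ between species.
For a fixed extraction/assay protocol the per-unit-mass copy densities C_T
(target meat) and C_B (beef) are constants, so their ratio K = C_B/C_T is a
constant too, and

    M_T / M_B = K * (Q_T / Q_B).

K is estimated from gravimetric calibration mixtures of known target mass
fraction w: each mixture yields

    K = (w / (1 - w)) * mean(Q_B replicates) / mean(Q_T replicates)

and the per-mixture values are pooled by arithmetic mean, with their RSD
quantifying stability across the composition range.

Conventions (chosen to reproduce published calibration tables exactly):
replicates are aggregated by the mean of copies/μL before taking the ratio
(ratio of means, not mean of ratios); per-mixture K is rounded to 2
decimals *before* pooling; the RSD uses the sample (n-1) standard
deviation. Unrounded per-mixture values are retained for transparency.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import fmean

from .errors import InsufficientDataError, InvalidInputError
from .quantify import QuantResult, deviation, mass_fraction, mass_ratio, mean_abs_deviation
from .rounding import round_half_up


@dataclass(frozen=True)
class CalibrationMixture:
    """A gravimetric binary mixture with replicate ddPCR concentrations.

    ``mass_fraction_target`` is the true adulterant proportion w (w/w, in
    (0,1)); ``target_conc`` and ``reference_conc`` are replicate copies/μL
    for the adulterant and beef assays.
    """

    mass_fraction_target: float
    target_conc: tuple[float, ...]
    reference_conc: tuple[float, ...]
    label: str = ""

    def __post_init__(self) -> None:
        if not 0 < self.mass_fraction_target < 1:
            raise InvalidInputError(
                f"mixture {self.label!r}: mass fraction must be in (0, 1), "
                f"got {self.mass_fraction_target}"
            )
        object.__setattr__(self, "target_conc", tuple(self.target_conc))
        object.__setattr__(self, "reference_conc", tuple(self.reference_conc))
        for name, values in (("target", self.target_conc), ("reference", self.reference_conc)):
            if not values:
                raise InvalidInputError(f"mixture {self.label!r}: empty {name} replicate list")
            if any(v <= 0 for v in values):
                raise InvalidInputError(
                    f"mixture {self.label!r}: non-positive {name} concentration"
                )


@dataclass
class TransferCoefficient:
    """Pooled K for one (target, reference) species pair."""

    target: str
    reference: str
    per_mixture_k: list[tuple[float, float]]  # (w, K rounded to 2 dp)
    per_mixture_k_unrounded: list[tuple[float, float]]
    k_mean: float
    k_rsd_percent: float

    @property
    def species_pair(self) -> tuple[str, str]:
        return (self.target, self.reference)


def k_for_mixture(mixture: CalibrationMixture, *, ndigits: int = 2) -> float:
    """Per-mixture transfer coefficient, rounded to ``ndigits`` decimals."""
    return round_half_up(k_for_mixture_unrounded(mixture), ndigits)


def k_for_mixture_unrounded(mixture: CalibrationMixture) -> float:
    """Per-mixture transfer coefficient at full precision."""
    w = mixture.mass_fraction_target
    q_target = fmean(mixture.target_conc)
    q_reference = fmean(mixture.reference_conc)
    if q_target <= 0 or q_reference <= 0:
        raise InvalidInputError("mean replicate concentration must be positive")
    return (w / (1.0 - w)) * q_reference / q_target


def estimate_k(
    mixtures: list[CalibrationMixture],
    target: str = "target",
    reference: str = "reference",
) -> TransferCoefficient:
    """Pool per-mixture K values into a single coefficient with its RSD.

    Requires at least two mixtures (the RSD is undefined otherwise).
    """
    if len(mixtures) < 2:
        raise InsufficientDataError(
            f"need >=2 calibration mixtures to pool K, got {len(mixtures)}"
        )
    rounded = [(m.mass_fraction_target, k_for_mixture(m)) for m in mixtures]
    unrounded = [(m.mass_fraction_target, k_for_mixture_unrounded(m)) for m in mixtures]
    ks = [k for _, k in rounded]
    k_mean = fmean(ks)
    # sample SD, n-1 denominator
    var = sum((k - k_mean) ** 2 for k in ks) / (len(ks) - 1)
    k_rsd = 100.0 * var**0.5 / k_mean
    return TransferCoefficient(
        target=target,
        reference=reference,
        per_mixture_k=rounded,
        per_mixture_k_unrounded=unrounded,
        k_mean=k_mean,
        k_rsd_percent=k_rsd,
    )


@dataclass
class VerificationSummary:
    """Per-mixture quantification results against known compositions."""

    results: list[QuantResult] = field(default_factory=list)
    min_abs_deviation: float = 0.0
    max_abs_deviation: float = 0.0
    mean_abs_deviation: float = 0.0


def verify_k(
    coefficient: TransferCoefficient | float,
    mixtures: list[CalibrationMixture],
) -> VerificationSummary:
    """Quantify known mixtures with a calibrated K and summarise deviations.

    For each mixture the measured mass fraction is computed from the mean
    replicate concentrations via the mass-ratio formula, and the signed
    relative deviation against the true composition is reported. The pooled
    K is applied at its 2-decimal reporting precision, the form in which a
    coefficient is shipped and reused.
    """
    k = coefficient if isinstance(coefficient, float) else round_half_up(coefficient.k_mean)
    results: list[QuantResult] = []
    for m in mixtures:
        ratio = mass_ratio(fmean(m.target_conc), fmean(m.reference_conc), k)
        measured = mass_fraction(ratio)
        actual = 100.0 * m.mass_fraction_target
        dev = deviation(round_half_up(measured), round_half_up(actual))
        results.append(
            QuantResult(
                sample_id=m.label,
                mass_ratio=ratio,
                mass_fraction_percent=measured,
                declared_percent=actual,
                deviation_percent=dev,
            )
        )
    devs = [r.deviation_percent for r in results]
    abs_devs = [abs(d) for d in devs]
    return VerificationSummary(
        results=results,
        min_abs_deviation=min(abs_devs),
        max_abs_deviation=max(abs_devs),
        mean_abs_deviation=mean_abs_deviation(devs),
    )


def verification_from_fractions(
    measured_percent: list[float], actual_percent: list[float]
) -> VerificationSummary:
    """Summarise deviations when measured mass fractions are given directly
    (e.g. from a report table rather than raw droplet data)."""
    if len(measured_percent) != len(actual_percent) or not measured_percent:
        raise InvalidInputError("measured and actual lists must be non-empty and equal length")
    results = [
        QuantResult(
            sample_id=f"{a:g}%",
            mass_ratio=(m / 100.0) / (1.0 - m / 100.0) if m < 100 else float("inf"),
            mass_fraction_percent=m,
            declared_percent=a,
            deviation_percent=deviation(m, a),
        )
        for m, a in zip(measured_percent, actual_percent)
    ]
    devs = [r.deviation_percent for r in results]
    abs_devs = [abs(d) for d in devs]
    return VerificationSummary(
        results=results,
        min_abs_deviation=min(abs_devs),
        max_abs_deviation=max(abs_devs),
        mean_abs_deviation=mean_abs_deviation(devs),
    )
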