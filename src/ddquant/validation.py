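"""Assay-performance battery: linearity, LOD, LOQ, precision.

Definitions follow standard DNA-method validation guidance for food
testing:

* LOD — the lowest adulterant mass fraction at which every replicate gives
  a positive qualitative result, stably (all higher tested levels must also
  be fully detected).
* LOQ — the lowest mass fraction quantifiable with acceptable precision
  *and* trueness: 100 % detection, replicate RSD <= 25 % and absolute mean
  bias <= 25 %, again with all higher levels also passing. The bias arm is
  essential: near the detection limit single-droplet quantisation keeps the
  replicate spread small while the estimate itself is badly biased, so RSD
  alone would admit unquantifiable levels.
* Repeatability — RSD among replicates within one run; reproducibility —
  RSD of run means across independent runs (days/operators). Acceptance
  threshold 25 % for both.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from statistics import fmean, stdev

from scipy import stats

from .errors import InsufficientDataError, InvalidInputError, SingularFitError

#: Precision/trueness acceptance threshold (percent) for quantification.
RSD_ACCEPTANCE_PERCENT = 25.0
BIAS_ACCEPTANCE_PERCENT = 25.0


@dataclass
class DilutionSeriesLevel:
    """One spiked level of a sensitivity dilution series.

    Either per-replicate measured fractions (``replicate_measured``) or a
    published mean ± SD summary (``measured_mean``/``measured_sd``) may be
    supplied; ``deviation_percent`` optionally carries a pre-computed bias.
    """

    actual_percent: float
    detections: int
    total_replicates: int
    replicate_measured: tuple[float, ...] | None = None
    measured_mean: float | None = None
    measured_sd: float | None = None
    deviation_percent: float | None = None

    def __post_init__(self) -> None:
        if self.actual_percent < 0:
            raise InvalidInputError(f"actual percent must be >= 0, got {self.actual_percent}")
        if self.total_replicates <= 0:
            raise InvalidInputError("total replicate count must be positive")
        if not 0 <= self.detections <= self.total_replicates:
            raise InvalidInputError(
                f"detections must satisfy 0 <= d <= {self.total_replicates}, "
                f"got {self.detections}"
            )
        if self.replicate_measured is not None:
            object.__setattr__(self, "replicate_measured", tuple(self.replicate_measured))
            if self.measured_mean is None:
                self.measured_mean = fmean(self.replicate_measured)
            if self.measured_sd is None and len(self.replicate_measured) >= 2:
                self.measured_sd = stdev(self.replicate_measured)

    def rsd_percent(self) -> float | None:
        """Replicate RSD (percent), or None when not computable."""
        if self.measured_mean in (None, 0) or self.measured_sd is None:
            return None
        return 100.0 * self.measured_sd / self.measured_mean

    def bias_percent(self) -> float | None:
        """Signed mean bias vs the true level (percent)."""
        if self.deviation_percent is not None:
            return self.deviation_percent
        if self.measured_mean is None or self.actual_percent == 0:
            return None
        return 100.0 * (self.measured_mean - self.actual_percent) / self.actual_percent


@dataclass
class LinearFit:
    slope: float
    intercept: float
    r2: float
    range_low: float
    range_high: float


@dataclass
class ValidationSummary:
    """Aggregated validation report for one species pair."""

    lod_percent: float | None = None
    loq_percent: float | None = None
    linearity: LinearFit | None = None
    repeatability_rsd: dict = field(default_factory=dict)
    reproducibility_rsd: dict = field(default_factory=dict)


def detection_rate(level: DilutionSeriesLevel) -> float:
    """Percent of replicates with a positive qualitative result."""
    return 100.0 * level.detections / level.total_replicates


def determine_lod(series: list[DilutionSeriesLevel]) -> float | None:
    """Lowest level with 100 % detection, all higher levels also fully detected.

    Returns None when no level qualifies (undefined LOD, flagged not raised).
    """
    if not series:
        raise InsufficientDataError("empty dilution series")
    ordered = sorted(series, key=lambda lv: lv.actual_percent)
    lod = None
    for level in reversed(ordered):
        if level.detections == level.total_replicates:
            lod = level.actual_percent
        else:
            break
    return lod


def _level_quantifiable(level: DilutionSeriesLevel) -> bool:
    if level.detections != level.total_replicates:
        return False
    rsd_val = level.rsd_percent()
    bias = level.bias_percent()
    if rsd_val is None or bias is None:
        return False
    return rsd_val <= RSD_ACCEPTANCE_PERCENT and abs(bias) <= BIAS_ACCEPTANCE_PERCENT


def determine_loq(series: list[DilutionSeriesLevel]) -> float | None:
    """Lowest level passing detection, RSD and bias criteria stably.

    A level qualifies when detection is 100 %, replicate RSD <= 25 % and
    absolute bias <= 25 %; every higher tested level must also qualify.
    Returns None when no level does.
    """
    if not series:
        raise InsufficientDataError("empty dilution series")
    ordered = sorted(series, key=lambda lv: lv.actual_percent)
    loq = None
    for level in reversed(ordered):
        if _level_quantifiable(level):
            loq = level.actual_percent
        else:
            break
    return loq


def rsd(values: list[float]) -> float:
    """Relative standard deviation: ``100 * sample SD / mean`` (percent)."""
    if len(values) < 2:
        raise InsufficientDataError(f"RSD needs >=2 values, got {len(values)}")
    mean = fmean(values)
    if mean == 0:
        raise InsufficientDataError("RSD undefined for zero mean")
    return 100.0 * stdev(values) / mean


@dataclass
class PrecisionLevel:
    """Precision summary for one composition level across runs."""

    level_percent: float
    within_run_rsd: dict  # run_id -> repeatability RSD (percent)
    between_run_rsd: float | None  # reproducibility RSD of run means
    acceptable: bool


def repeatability_reproducibility(
    runs: dict[float, dict[str, list[float]]],
    acceptance_percent: float = RSD_ACCEPTANCE_PERCENT,
) -> list[PrecisionLevel]:
    """Within-run (repeatability) and between-run (reproducibility) RSDs.

    ``runs`` maps composition level (percent) -> run id -> replicate
    measured fractions. Each run needs >=2 replicates; reproducibility
    needs >=2 runs per level (None otherwise, and the level cannot pass).
    """
    out: list[PrecisionLevel] = []
    for level, by_run in sorted(runs.items()):
        if not by_run:
            raise InsufficientDataError(f"level {level}: no runs supplied")
        within = {}
        means = []
        for run_id, values in by_run.items():
            if len(values) < 2:
                raise InsufficientDataError(
                    f"level {level}, run {run_id!r}: repeatability needs >=2 replicates"
                )
            within[run_id] = rsd(values)
            means.append(fmean(values))
        between = rsd(means) if len(means) >= 2 else None
        ok = all(v <= acceptance_percent for v in within.values()) and (
            between is not None and between <= acceptance_percent
        )
        out.append(
            PrecisionLevel(
                level_percent=level,
                within_run_rsd=within,
                between_run_rsd=between,
                acceptable=ok,
            )
        )
    return out


def fit_linearity(pairs: list[tuple[float, float]]) -> LinearFit:
    """OLS fit of measured on actual mass fraction with r².

    ``pairs`` is (actual_percent, measured_percent); needs >=3 distinct
    actual levels. r² is the squared Pearson correlation of the fit.
    """
    if len(pairs) < 3 or len({a for a, _ in pairs}) < 3:
        raise SingularFitError("linearity fit needs >=3 distinct actual levels")
    x = [a for a, _ in pairs]
    y = [m for _, m in pairs]
    if len(set(x)) < 2 or math.isclose(min(x), max(x)):
        raise SingularFitError("degenerate x values")
    res = stats.linregress(x, y)
    return LinearFit(
        slope=res.slope,
        intercept=res.intercept,
        r2=res.rvalue**2,
        range_low=min(x),
        range_high=max(x),
    )
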