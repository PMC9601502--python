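"""Generative model for ddPCR experiments on binary meat mixtures.

The simulator produces droplet-level data with the statistical structure
the analysis assumes, so calibration, quantification and validation can be
exercised end to end without laboratory data:

* a well at true rate λ copies/droplet yields
  ``positives ~ Binomial(N, 1 - exp(-λ))`` over N accepted droplets
  (Poisson occupancy, thresholding assumed perfect — no "rain");
* the expected copies/μL of the target assay in a mixture of target mass
  fraction w is ``w · C_T`` and of the beef reference ``(1-w) · C_B``,
  where C_T, C_B are the latent per-unit-mass copy densities whose ratio
  is the transfer coefficient K = C_B/C_T;
* replicate-to-replicate pipetting/extraction error is multiplicative
  lognormal noise (spreads in real replicate tables scale with magnitude);
* thermal degradation is an optional multiplicative copy-loss factor,
  equal for both channels by default (ratio-based quantification is then
  unaffected), with an optional differential factor to emulate unequal
  degradation.

Default copy densities are anchored to the magnitudes real single-copy
assays report (tens to hundreds of copies/μL from 50 ng template), so
simulated tables look like laboratory ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .calibration import CalibrationMixture
from .errors import InvalidInputError
from .poisson import DropletPartition, cpd_to_concentration, estimate_cpd
from .quantify import mass_fraction, mass_ratio
from .validation import DilutionSeriesLevel


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the generative model.

    ``c_target``/``c_reference`` are copies/μL contributed per unit mass
    fraction of target meat and beef (the latent C_T and C_B); their ratio
    is the implied transfer coefficient ``k_true``. ``replicate_cv`` is the
    lognormal coefficient of variation of per-well pipetting noise.
    ``degradation_factor`` multiplies both channels (1.0 = untreated);
    ``reference_degradation_factor`` overrides it for the beef channel to
    emulate differential thermal damage. ``expected_value_mode`` disables
    all sampling and returns closed-form expectations — a deterministic
    oracle for pipeline tests.
    """

    c_target: float = 300.0
    c_reference: float = 357.0
    droplets_per_well: int = 20_000
    droplet_volume_nl: float = 0.85
    replicate_cv: float = 0.05
    degradation_factor: float = 1.0
    reference_degradation_factor: float | None = None
    qc_min_droplets: int = 10_000
    expected_value_mode: bool = False

    def __post_init__(self) -> None:
        if self.c_target <= 0 or self.c_reference <= 0:
            raise InvalidInputError("copy densities must be positive")
        if not 0 < self.degradation_factor <= 1:
            raise InvalidInputError("degradation factor must be in (0, 1]")
        if self.replicate_cv < 0:
            raise InvalidInputError("replicate CV must be >= 0")
        if self.droplets_per_well <= 0 or self.droplet_volume_nl <= 0:
            raise InvalidInputError("droplet count and volume must be positive")

    @property
    def k_true(self) -> float:
        """Implied transfer coefficient C_B/C_T."""
        return self.c_reference / self.c_target

    def with_k_true(self, k: float) -> "SimulationConfig":
        """Copy of the config with ``c_reference`` set to give ``k_true = k``."""
        if k <= 0:
            raise InvalidInputError("k must be positive")
        return replace(self, c_reference=k * self.c_target)


def pork_like_config(**overrides) -> SimulationConfig:
    """Defaults resembling a porcine-ACTB-in-beef assay (K ≈ 1.19)."""
    return SimulationConfig(**{"c_target": 300.0, "c_reference": 357.0, **overrides})


def chicken_like_config(**overrides) -> SimulationConfig:
    """Defaults resembling a chicken-TGFB3-in-beef assay (K ≈ 0.38)."""
    return SimulationConfig(**{"c_target": 2300.0, "c_reference": 874.0, **overrides})


@dataclass(frozen=True)
class SimulatedWell:
    """One simulated reaction well with its generating truth."""

    true_mass_fraction_percent: float
    assay_id: str
    partition: DropletPartition
    lambda_true: float


def _as_rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def simulate_partition(
    lambda_true: float, n_droplets: int, seed=None, well_id: str = "", assay_id: str = ""
) -> DropletPartition:
    """Draw a droplet partition at true rate ``lambda_true`` copies/droplet."""
    if lambda_true < 0:
        raise InvalidInputError(f"rate must be non-negative, got {lambda_true}")
    if n_droplets <= 0:
        raise InvalidInputError(f"droplet count must be positive, got {n_droplets}")
    rng = _as_rng(seed)
    p_positive = -math.expm1(-lambda_true)
    positives = int(rng.binomial(n_droplets, p_positive))
    return DropletPartition(
        positives=positives, accepted=n_droplets, well_id=well_id, assay_id=assay_id
    )


def _expected_conc(w_t: float, config: SimulationConfig, assay: str) -> float:
    ref_deg = (
        config.reference_degradation_factor
        if config.reference_degradation_factor is not None
        else config.degradation_factor
    )
    if assay == "target":
        return w_t * config.c_target * config.degradation_factor
    if assay == "reference":
        return (1.0 - w_t) * config.c_reference * ref_deg
    raise InvalidInputError(f"assay must be 'target' or 'reference', got {assay!r}")


def _noise_multiplier(cv: float, rng: np.random.Generator) -> float:
    if cv == 0:
        return 1.0
    sigma = math.sqrt(math.log1p(cv**2))
    return float(rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma))  # unit mean


def simulate_mixture_well(
    w_t: float, config: SimulationConfig, assay: str, seed=None, well_id: str = ""
) -> SimulatedWell:
    """Simulate one well of one assay channel for a mixture of fraction ``w_t``."""
    if not 0 <= w_t <= 1:
        raise InvalidInputError(f"mass fraction must be in [0, 1], got {w_t}")
    rng = _as_rng(seed)
    conc = _expected_conc(w_t, config, assay) * _noise_multiplier(config.replicate_cv, rng)
    lam = conc * config.droplet_volume_nl * 1e-3
    partition = simulate_partition(
        lam, config.droplets_per_well, rng, well_id=well_id, assay_id=assay
    )
    return SimulatedWell(
        true_mass_fraction_percent=100.0 * w_t,
        assay_id=assay,
        partition=partition,
        lambda_true=lam,
    )


def _measure_conc(well: SimulatedWell, config: SimulationConfig) -> float:
    """Run the analysis path (Poisson inversion) on a simulated well."""
    return cpd_to_concentration(estimate_cpd(well.partition), config.droplet_volume_nl)


def simulate_calibration_series(
    levels: list[float],
    replicates: int,
    config: SimulationConfig,
    seed=None,
) -> list[CalibrationMixture]:
    """Simulate a gravimetric calibration series, one mixture per level.

    In ``expected_value_mode`` the replicate concentrations are the exact
    expectations (no droplet quantisation), making the downstream K
    estimate a closed-form oracle.
    """
    if replicates < 2:
        raise InvalidInputError(f"need >=2 replicates, got {replicates}")
    rng = _as_rng(seed)
    mixtures = []
    for w in levels:
        if not 0 < w < 1:
            raise InvalidInputError(f"calibration level must be in (0, 1), got {w}")
        if config.expected_value_mode:
            target = [_expected_conc(w, config, "target")] * replicates
            reference = [_expected_conc(w, config, "reference")] * replicates
        else:
            target, reference = [], []
            for i in range(replicates):
                for assay, out in (("target", target), ("reference", reference)):
                    well = simulate_mixture_well(
                        w, config, assay, rng, well_id=f"w{100 * w:g}-r{i}-{assay}"
                    )
                    out.append(_measure_conc(well, config))
        mixtures.append(
            CalibrationMixture(
                mass_fraction_target=w,
                target_conc=tuple(target),
                reference_conc=tuple(reference),
                label=f"{100 * w:g}%",
            )
        )
    return mixtures


def simulate_dilution_series(
    levels: list[float],
    replicates: int,
    config: SimulationConfig,
    seed=None,
    k: float | None = None,
) -> list[DilutionSeriesLevel]:
    """Simulate a sensitivity dilution series down to sub-detection levels.

    Detection per replicate follows the positivity rule: at least one
    positive target droplet in a well passing the accepted-droplet QC.
    Measured fractions are produced by the full quantification pipeline
    using ``k`` (defaults to the generative ``k_true``); non-detects score
    a measured fraction of 0.
    """
    rng = _as_rng(seed)
    k_use = k if k is not None else config.k_true
    out = []
    for w in levels:
        if not 0 <= w < 1:
            raise InvalidInputError(f"dilution level must be in [0, 1), got {w}")
        detections = 0
        measured = []
        for i in range(replicates):
            t_well = simulate_mixture_well(w, config, "target", rng, well_id=f"d{i}t")
            r_well = simulate_mixture_well(w, config, "reference", rng, well_id=f"d{i}r")
            qc_ok = t_well.partition.accepted >= config.qc_min_droplets
            detected = qc_ok and t_well.partition.positives > 0
            if detected:
                detections += 1
                q_t = _measure_conc(t_well, config)
                q_r = _measure_conc(r_well, config)
                measured.append(mass_fraction(mass_ratio(q_t, q_r, k_use)))
            else:
                measured.append(0.0)
        out.append(
            DilutionSeriesLevel(
                actual_percent=100.0 * w,
                detections=detections,
                total_replicates=replicates,
                replicate_measured=tuple(measured),
            )
        )
    return out
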