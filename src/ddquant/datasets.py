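"""Bundled reference datasets from the assay-development study.

Four small CSVs ship with the package:

* ``reference_calibration.csv`` — replicate copies/μL for the gravimetric
  calibration series (pork/beef and chicken/beef at 10–90 % w/w, six
  replicates per channel), the input from which the transfer coefficients
  are determined.
* ``reference_verification.csv`` — measured mass fractions (mean ± SD) of
  independent known mixtures (20–80 % w/w) used to verify the coefficients,
  with the deviations as originally reported.
* ``reference_dilution.csv`` — the sensitivity dilution series
  (0.01–10 % w/w) with detection counts and measured summaries, the input
  to LOD/LOQ determination.
* ``reference_products.csv`` — declared vs measured compositions of sixteen
  commercial beef products ("LC" marks a label lacking a defined content).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .calibration import CalibrationMixture
from .validation import DilutionSeriesLevel

SPECIES = ("pork", "chicken")
REFERENCE_SPECIES = "beef"


def _read(name: str) -> pd.DataFrame:
    with resources.files(__package__).joinpath("data", name).open("rb") as fh:
        return pd.read_csv(fh)


def load_calibration_mixtures(species: str) -> list[CalibrationMixture]:
    """Calibration series for ``species`` ('pork' or 'chicken') in beef."""
    _check_species(species)
    df = _read("reference_calibration.csv")
    df = df[df["species"] == species]
    mixtures = []
    for level, grp in df.groupby("mass_fraction_percent", sort=True):
        target = tuple(grp.loc[grp["channel"] == "target", "copies_per_ul"])
        reference = tuple(grp.loc[grp["channel"] == "reference", "copies_per_ul"])
        mixtures.append(
            CalibrationMixture(
                mass_fraction_target=level / 100.0,
                target_conc=target,
                reference_conc=reference,
                label=f"{species} {level:g}%",
            )
        )
    return mixtures


def load_verification_table(species: str) -> pd.DataFrame:
    """Known-mixture verification results (actual, measured, reported deviation)."""
    _check_species(species)
    df = _read("reference_verification.csv")
    return df[df["species"] == species].reset_index(drop=True)


def load_dilution_series(species: str) -> list[DilutionSeriesLevel]:
    """Sensitivity dilution series as :class:`DilutionSeriesLevel` records."""
    _check_species(species)
    df = _read("reference_dilution.csv")
    levels = []
    for row in df[df["species"] == species].itertuples():
        sd = None if pd.isna(row.measured_sd) else float(row.measured_sd)
        levels.append(
            DilutionSeriesLevel(
                actual_percent=float(row.actual_percent),
                detections=int(row.detections),
                total_replicates=int(row.total_replicates),
                measured_mean=float(row.measured_mean),
                measured_sd=sd,
                deviation_percent=float(row.reported_deviation_percent),
            )
        )
    return levels


def load_commercial_products() -> pd.DataFrame:
    """Declared vs measured compositions of commercial beef products.

    Declared columns hold floats or the string ``"LC"`` (lacking defined
    content on the label).
    """
    return _read("reference_products.csv")


def commercial_screen_records(species: str) -> list[dict]:
    """Rows of the commercial-product table shaped for ``screen_products``."""
    _check_species(species)
    df = load_commercial_products()
    records = []
    for row in df.itertuples():
        declared = getattr(row, f"{species}_declared_percent")
        declared = None if str(declared).strip() == "LC" else float(declared)
        records.append(
            {
                "sample_id": row.sample_id,
                "species": species,
                "declared_percent": declared,
                "measured_percent": float(getattr(row, f"{species}_measured_percent")),
            }
        )
    return records


def calibration_csv_path() -> str:
    """Filesystem path of the bundled calibration CSV (for CLI use)."""
    return str(resources.files(__package__).joinpath("data", "reference_calibration.csv"))


def _check_species(species: str) -> None:
    if species not in SPECIES:
        raise ValueError(f"species must be one of {SPECIES}, got {species!r}")
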