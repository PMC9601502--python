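"""Tabular readers/writers and assay configuration.

Input convention: a droplet table is a CSV with one row per well and
channel, carrying either raw droplet counts (``positives``, ``accepted``)
or a pre-computed concentration (``copies_per_ul``). Raw counts are the
preferred input; concentrations are accepted directly because published
tables are typically reported at that level.

Percentages and concentrations are kept at full precision internally;
rounding to 2 decimals happens only at the report boundary.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .calibration import CalibrationMixture, TransferCoefficient
from .errors import SchemaError
from .poisson import DEFAULT_DROPLET_VOLUME_NL, DropletPartition, estimate_concentration

#: Minimum accepted droplets for a well to pass QC.
DEFAULT_QC_MIN_DROPLETS = 10_000


@dataclass
class AssayConfig:
    """Shipping form of a calibrated assay: species pair plus constants."""

    target: str
    reference: str
    k: float
    k_rsd_percent: float | None = None
    per_mixture_k: list = field(default_factory=list)
    droplet_volume_nl: float = DEFAULT_DROPLET_VOLUME_NL
    qc_min_droplets: int = DEFAULT_QC_MIN_DROPLETS
    adulteration_tolerance_percent: float = 5.0
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise SchemaError(f"transfer coefficient must be positive, got {self.k}")
        if self.qc_min_droplets <= 0:
            raise SchemaError("qc_min_droplets must be positive")

    @classmethod
    def from_coefficient(cls, coeff: TransferCoefficient, **kwargs) -> "AssayConfig":
        from .rounding import round_half_up

        return cls(
            target=coeff.target,
            reference=coeff.reference,
            k=round_half_up(coeff.k_mean),
            k_rsd_percent=round_half_up(coeff.k_rsd_percent),
            per_mixture_k=[list(pair) for pair in coeff.per_mixture_k],
            **kwargs,
        )


def write_assay_config(config: AssayConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(asdict(config), sort_keys=False))


def read_assay_config(path: str | Path) -> AssayConfig:
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict) or "k" not in raw:
        raise SchemaError(f"{path}: not a valid assay configuration")
    return AssayConfig(**raw)


def write_k_config(configs: list[AssayConfig], path: str | Path) -> None:
    """Write a multi-assay K configuration (one entry per species pair)."""
    payload = {"assays": [asdict(c) for c in configs]}
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def read_k_config(path: str | Path) -> dict[str, AssayConfig]:
    """Read a multi-assay K configuration, keyed by target species."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict) or "assays" not in raw:
        raise SchemaError(f"{path}: not a valid K configuration (missing 'assays')")
    out = {}
    for entry in raw["assays"]:
        cfg = AssayConfig(**entry)
        out[cfg.target] = cfg
    return out


@dataclass
class WellRecord:
    """One validated row of a droplet table."""

    sample_id: str
    well_id: str
    assay_id: str
    positives: int | None
    accepted: int | None
    copies_per_ul: float | None
    qc_pass: bool


def read_droplet_table(
    path: str | Path, qc_min_droplets: int = DEFAULT_QC_MIN_DROPLETS
) -> list[WellRecord]:
    """Read and validate a droplet-count / concentration CSV.

    Each row needs ``sample_id``, ``assay_id`` and either both of
    ``positives``/``accepted`` or ``copies_per_ul``. Wells with fewer
    accepted droplets than ``qc_min_droplets`` are flagged (``qc_pass``
    False), not dropped. Malformed rows raise :class:`SchemaError` naming
    the offending row.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: empty file") from None
    if df.empty:
        raise SchemaError(f"{path}: no data rows")
    cols = set(df.columns)
    if "sample_id" not in cols or "assay_id" not in cols:
        raise SchemaError(f"{path}: missing required columns sample_id/assay_id")
    has_counts = {"positives", "accepted"} <= cols
    has_conc = "copies_per_ul" in cols
    if not (has_counts or has_conc):
        raise SchemaError(
            f"{path}: need either positives+accepted or copies_per_ul columns"
        )
    if "well_id" in cols:
        dup = df["well_id"].dropna()
        dup = dup[dup.duplicated()]
        if not dup.empty:
            raise SchemaError(f"{path}: duplicate well_id {dup.iloc[0]!r}")

    records: list[WellRecord] = []
    for idx, row in df.iterrows():
        rowno = idx + 2  # 1-based, after header
        positives = accepted = None
        conc = None
        if has_counts and not (pd.isna(row["positives"]) or pd.isna(row["accepted"])):
            try:
                positives = int(row["positives"])
                accepted = int(row["accepted"])
            except (TypeError, ValueError):
                raise SchemaError(f"{path}: row {rowno}: non-numeric droplet counts") from None
            try:
                DropletPartition(positives=positives, accepted=accepted)
            except ValueError as exc:
                raise SchemaError(f"{path}: row {rowno}: {exc}") from None
        elif has_conc and not pd.isna(row["copies_per_ul"]):
            try:
                conc = float(row["copies_per_ul"])
            except (TypeError, ValueError):
                raise SchemaError(f"{path}: row {rowno}: non-numeric copies_per_ul") from None
            if conc < 0:
                raise SchemaError(f"{path}: row {rowno}: negative concentration")
        else:
            raise SchemaError(f"{path}: row {rowno}: neither droplet counts nor concentration")
        qc_pass = accepted is None or accepted >= qc_min_droplets
        records.append(
            WellRecord(
                sample_id=str(row["sample_id"]),
                well_id=str(row.get("well_id", "") or ""),
                assay_id=str(row["assay_id"]),
                positives=positives,
                accepted=accepted,
                copies_per_ul=conc,
                qc_pass=qc_pass,
            )
        )
    return records


def records_to_concentrations(
    records: list[WellRecord],
    droplet_volume_nl: float = DEFAULT_DROPLET_VOLUME_NL,
) -> pd.DataFrame:
    """Concentration table (one row per well) from validated records."""
    rows = []
    for rec in records:
        if rec.copies_per_ul is not None:
            rows.append(
                {
                    "sample_id": rec.sample_id,
                    "well_id": rec.well_id,
                    "assay_id": rec.assay_id,
                    "cpd": None,
                    "copies_per_ul": rec.copies_per_ul,
                    "ci_low": None,
                    "ci_high": None,
                    "qc_pass": rec.qc_pass,
                }
            )
        else:
            est = estimate_concentration(
                DropletPartition(
                    positives=rec.positives,
                    accepted=rec.accepted,
                    well_id=rec.well_id,
                    assay_id=rec.assay_id,
                ),
                droplet_volume_nl,
            )
            rows.append(
                {
                    "sample_id": rec.sample_id,
                    "well_id": rec.well_id,
                    "assay_id": rec.assay_id,
                    "cpd": est.cpd,
                    "copies_per_ul": est.copies_per_ul,
                    "ci_low": est.ci_low,
                    "ci_high": est.ci_high,
                    "qc_pass": rec.qc_pass,
                }
            )
    return pd.DataFrame(rows)


def read_calibration_design(
    path: str | Path,
    species: str | None = None,
    qc_min_droplets: int = DEFAULT_QC_MIN_DROPLETS,
    droplet_volume_nl: float = DEFAULT_DROPLET_VOLUME_NL,
) -> list[CalibrationMixture]:
    """Read a calibration-design CSV into mixtures.

    Long format: ``species`` (optional filter column), ``mass_fraction_percent``,
    ``channel`` (target|reference) and either ``copies_per_ul`` or droplet
    counts.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: empty file") from None
    required = {"mass_fraction_percent", "channel"}
    if not required <= set(df.columns):
        raise SchemaError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    if species is not None and "species" in df.columns:
        df = df[df["species"] == species]
        if df.empty:
            raise SchemaError(f"{path}: no rows for species {species!r}")
    if "copies_per_ul" not in df.columns:
        if not {"positives", "accepted"} <= set(df.columns):
            raise SchemaError(f"{path}: need copies_per_ul or positives+accepted")
        from .poisson import cpd_to_concentration, estimate_cpd

        df = df.copy()
        df["copies_per_ul"] = [
            cpd_to_concentration(
                estimate_cpd(DropletPartition(positives=int(p), accepted=int(n))),
                droplet_volume_nl,
            )
            for p, n in zip(df["positives"], df["accepted"])
        ]
    mixtures = []
    for level, grp in df.groupby("mass_fraction_percent", sort=True):
        mixtures.append(
            CalibrationMixture(
                mass_fraction_target=float(level) / 100.0,
                target_conc=tuple(grp.loc[grp["channel"] == "target", "copies_per_ul"]),
                reference_conc=tuple(grp.loc[grp["channel"] == "reference", "copies_per_ul"]),
                label=f"{level:g}%",
            )
        )
    return mixtures
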