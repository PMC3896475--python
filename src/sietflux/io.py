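"""File formats and experiment configuration.

No standard interchange format exists for SIET recordings, so the package
defines plain-text schemas, documented here and in the README:

* scan CSV (RFC 4180, UTF-8, dot decimal) — one row per voltage sample:
  ``preparation_id,treatment,ion,site_id,ordinal,region_hint,is_reference,
  measurement,cycle,position,time_s,voltage_uV``
* calibration CSV — ``ion,concentration_mM,voltage_uV``, one row per point
* selectivity JSON — ``{"primary": "K", "log10_k": {"Na": -3.9, ...}}``
* flux TSV — one row per site with every FluxEstimate field
* comparison TSV — one row per region with every TreatmentComparison field

Stored voltages may be amplifier outputs; the configured gain (the
instrument amplifies 1000-fold) is divided out on ingest so everything in
memory is true electrode µV.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Iterable, Literal, Mapping, Optional, Sequence

import pandas as pd
from pydantic import BaseModel, Field, field_validator

from .electrode import (
    ElectrodeCalibration,
    IonSpecies,
    POTASSIUM,
    SODIUM,
    SelectivityProfile,
)
from .pipeline import FluxEstimate, ScanDataset, SiteRecording, VoltageSample
from .regions import TreatmentComparison
from .synthetic import ScanProtocol, SyntheticTruth

__all__ = [
    "ScanParseError",
    "ExperimentConfig",
    "SCAN_COLUMNS",
    "ion_from_name",
    "read_calibration_csv",
    "write_calibration_csv",
    "read_selectivity_json",
    "write_selectivity_json",
    "read_scan_csv",
    "write_scan_csv",
    "write_flux_tsv",
    "read_flux_tsv",
    "write_comparison_tsv",
    "write_truth_json",
    "read_truth_json",
]


class ScanParseError(ValueError):
    """A recording or calibration file violates its documented schema."""


SCAN_COLUMNS = [
    "preparation_id",
    "treatment",
    "ion",
    "site_id",
    "ordinal",
    "region_hint",
    "is_reference",
    "measurement",
    "cycle",
    "position",
    "time_s",
    "voltage_uV",
]

_KNOWN_IONS = {"K": POTASSIUM, "Na": SODIUM}


class IonConfig(BaseModel):
    diffusion_coefficient: float = Field(gt=0)  # cm² s⁻¹
    bath_concentration: float = Field(gt=0)  # mmol L⁻¹


class ExperimentConfig(BaseModel):
    """Analysis configuration, loadable from JSON."""

    amplifier_gain: float = Field(default=1.0, gt=0)
    cb_mode: Literal["measured", "nominal"] = "measured"
    surface: Literal["basal", "apical"] = "basal"
    aggregation: Literal["mean", "median"] = "mean"
    significance_threshold: float = Field(default=0.05, gt=0, lt=1)
    seed: int = 0
    ions: dict[str, IonConfig] = Field(default_factory=dict)
    protocol: dict[str, float | int] = Field(default_factory=dict)

    @classmethod
    def from_json(cls, path: str | Path) -> "ExperimentConfig":
        return cls.model_validate_json(Path(path).read_text(encoding="utf-8"))

    def build_protocol(self) -> ScanProtocol:
        return ScanProtocol(**self.protocol)

    def ion_species(self, name: str) -> IonSpecies:
        return ion_from_name(name, self.ions)


def ion_from_name(
    name: str, overrides: Optional[Mapping[str, IonConfig]] = None
) -> IonSpecies:
    """Resolve an ion identifier to its physical constants."""
    if overrides and name in overrides:
        cfg = overrides[name]
        return IonSpecies(
            name, 1, cfg.diffusion_coefficient, cfg.bath_concentration
        )
    try:
        return _KNOWN_IONS[name]
    except KeyError:
        raise ScanParseError(
            f"unknown ion {name!r}: provide diffusion coefficient and bath "
            "concentration in the experiment config"
        ) from None


# ---------------------------------------------------------------- calibration


def read_calibration_csv(
    path: str | Path,
    ion: Optional[IonSpecies] = None,
    gain: float = 1.0,
) -> ElectrodeCalibration:
    """Load calibration points (``ion,concentration_mM,voltage_uV``).

    Two points give the exact two-point slope; more reduce to least squares.
    Stored voltages are divided by ``gain``.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"ion", "concentration_mM", "voltage_uV"}
    missing = required - set(df.columns)
    if missing:
        raise ScanParseError(
            f"{path}: calibration file missing column(s) {sorted(missing)}"
        )
    names = df["ion"].unique()
    if len(names) != 1:
        raise ScanParseError(f"{path}: calibration must cover exactly one ion")
    species = ion or ion_from_name(str(names[0]))
    return ElectrodeCalibration.from_table(
        species,
        df["concentration_mM"].to_list(),
        (df["voltage_uV"] / gain).to_list(),
    )


def write_calibration_csv(
    calibration: ElectrodeCalibration, path: str | Path, gain: float = 1.0
) -> None:
    pd.DataFrame(
        {
            "ion": [calibration.ion.name] * 2,
            "concentration_mM": [
                calibration.low_concentration,
                calibration.high_concentration,
            ],
            "voltage_uV": [
                calibration.low_voltage * gain,
                calibration.high_voltage * gain,
            ],
        }
    ).to_csv(path, index=False)


def read_selectivity_json(path: str | Path) -> SelectivityProfile:
    data = json.loads(Path(path).read_text(encoding="utf-8"))
    try:
        return SelectivityProfile(data["primary"], dict(data["log10_k"]))
    except KeyError as exc:
        raise ScanParseError(f"{path}: selectivity JSON missing key {exc}") from None


def write_selectivity_json(profile: SelectivityProfile, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(
            {"primary": profile.primary_ion, "log10_k": dict(profile.log10_selectivity)},
            indent=2,
        )
        + "\n",
        encoding="utf-8",
    )


# ----------------------------------------------------------------------- scan


def write_scan_csv(
    datasets: Sequence[ScanDataset], path: str | Path, gain: float = 1.0
) -> None:
    """Write one or more preparations to a single scan CSV."""
    rows = []
    for ds in datasets:
        for rec in (*ds.reference_recordings, *ds.site_recordings):
            for s in rec.samples:
                rows.append(
                    {
                        "preparation_id": ds.preparation_id,
                        "treatment": ds.treatment_label,
                        "ion": ds.ion.name,
                        "site_id": rec.site_id,
                        "ordinal": rec.ordinal,
                        "region_hint": rec.region_hint,
                        "is_reference": int(rec.is_reference),
                        "measurement": s.measurement,
                        "cycle": s.cycle,
                        "position": s.position,
                        "time_s": s.time_s,
                        "voltage_uV": s.voltage_uv * gain,
                    }
                )
    pd.DataFrame(rows, columns=SCAN_COLUMNS).to_csv(path, index=False)


def read_scan_csv(
    path: str | Path,
    calibration: ElectrodeCalibration,
    protocol: Optional[ScanProtocol] = None,
    gain: float = 1.0,
    ion_overrides: Optional[Mapping[str, IonConfig]] = None,
) -> list[ScanDataset]:
    """Load a scan CSV into validated datasets (one per preparation).

    Voltages are de-amplified by ``gain`` on ingest.  All SiteRecording
    invariants (inner/outer pairing, strictly increasing times) are enforced
    and violations raise :class:`ScanParseError` naming the offending site.
    """
    protocol = protocol or ScanProtocol()
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # noqa: BLE001 - surface as a parse error
        raise ScanParseError(f"{path}: cannot read CSV ({exc})") from exc
    missing = set(SCAN_COLUMNS) - set(df.columns)
    if missing:
        raise ScanParseError(f"{path}: missing column(s) {sorted(missing)}")
    if df["position"].map(lambda p: p not in ("inner", "outer")).any():
        raise ScanParseError(f"{path}: position must be 'inner' or 'outer'")
    datasets = []
    for prep_id, prep_df in df.groupby("preparation_id", sort=False):
        ions = prep_df["ion"].unique()
        if len(ions) != 1:
            raise ScanParseError(
                f"{path}: preparation {prep_id} mixes ions {sorted(ions)}"
            )
        treatments = prep_df["treatment"].unique()
        if len(treatments) != 1:
            raise ScanParseError(
                f"{path}: preparation {prep_id} mixes treatment labels"
            )
        species = ion_from_name(str(ions[0]), ion_overrides)
        refs, sites = [], []
        for site_id, site_df in prep_df.groupby("site_id", sort=False):
            samples = tuple(
                VoltageSample(
                    int(r.measurement),
                    int(r.cycle),
                    r.position,
                    float(r.time_s),
                    float(r.voltage_uV) / gain,
                )
                for r in site_df.itertuples()
            )
            try:
                rec = SiteRecording(
                    site_id=str(site_id),
                    region_hint=str(site_df["region_hint"].iloc[0]),
                    ordinal=int(site_df["ordinal"].iloc[0]),
                    samples=samples,
                    is_reference=bool(site_df["is_reference"].iloc[0]),
                )
            except ValueError as exc:
                first_line = int(site_df.index[0]) + 2  # header + 1-based
                raise ScanParseError(
                    f"{path}: near line {first_line}: {exc}"
                ) from exc
            (refs if rec.is_reference else sites).append(rec)
        try:
            datasets.append(
                ScanDataset(
                    ion=species,
                    calibration=calibration,
                    protocol=protocol,
                    reference_recordings=tuple(refs),
                    site_recordings=tuple(sites),
                    treatment_label=str(treatments[0]),
                    preparation_id=str(prep_id),
                )
            )
        except ValueError as exc:
            raise ScanParseError(f"{path}: {exc}") from exc
    if not datasets:
        raise ScanParseError(f"{path}: no preparations found")
    return datasets


# -------------------------------------------------------------------- results


def write_flux_tsv(
    estimates_by_preparation: Mapping[str, Sequence[FluxEstimate]],
    path: str | Path,
    treatment_labels: Optional[Mapping[str, str]] = None,
    ion: str = "",
) -> None:
    rows = []
    for prep_id, estimates in estimates_by_preparation.items():
        for e in estimates:
            rows.append(
                {
                    "preparation_id": prep_id,
                    "treatment": (treatment_labels or {}).get(prep_id, ""),
                    "ion": ion,
                    "site_id": e.site_id,
                    "region_hint": e.region_hint,
                    "ordinal": e.ordinal,
                    "region": e.region,
                    "dv_raw_uV": e.dv_raw,
                    "dv_reference_uV": e.dv_reference,
                    "dv_corrected_uV": e.dv_corrected,
                    "background_concentration_mM": e.background_concentration,
                    "concentration_gradient_umol_cm3": e.concentration_gradient,
                    "flux_pmol_cm2_s": e.flux,
                    "direction": e.direction,
                    "signal_to_noise": (
                        "" if e.signal_to_noise is None else e.signal_to_noise
                    ),
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_flux_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"preparation_id", "region", "flux_pmol_cm2_s"}
    missing = required - set(df.columns)
    if missing:
        raise ScanParseError(f"{path}: flux TSV missing column(s) {sorted(missing)}")
    return df


def write_comparison_tsv(
    comparisons: Sequence[TreatmentComparison], path: str | Path
) -> None:
    rows = [
        {
            "region": c.region,
            "n_control": c.n_control,
            "n_treatment": c.n_treatment,
            "control_mean_flux": c.control_mean,
            "control_sem": "" if c.control_sem is None else c.control_sem,
            "treatment_mean_flux": c.treatment_mean,
            "treatment_sem": "" if c.treatment_sem is None else c.treatment_sem,
            "percent_change": c.percent_change,
            "sign_reversed": int(c.sign_reversed),
            "anova_F": c.anova_f,
            "anova_p": c.anova_p,
            "bonferroni_adjusted_p": c.bonferroni_adjusted_p,
            "significant": int(c.significant),
        }
        for c in comparisons
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------- ground truth


def write_truth_json(
    truth: SyntheticTruth, path: str | Path, extra: Optional[Mapping] = None
) -> None:
    payload = {
        "region_flux": dict(truth.region_flux),
        "n_sites": dict(truth.n_sites),
        "drift_rate_uv_min": truth.drift_rate_uv_min,
        "noise_sd_uv": truth.noise_sd_uv,
        "n_preparations": truth.n_preparations,
        "seed": truth.seed,
    }
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")


def read_truth_json(path: str | Path) -> SyntheticTruth:
    data = json.loads(Path(path).read_text(encoding="utf-8"))
    return SyntheticTruth(
        region_flux=data["region_flux"],
        n_sites=data["n_sites"],
        drift_rate_uv_min=data["drift_rate_uv_min"],
        noise_sd_uv=data["noise_sd_uv"],
        n_preparations=data["n_preparations"],
        seed=data["seed"],
    )
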