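"""Voltage gradients to Fick's-law ion fluxes.

The measurement: an ion-selective microelectrode shuttles between two points
50 µm apart on a line perpendicular to the tissue surface, inside the
unstirred layer.  The voltage difference between the inner and outer
positions (ΔV = V_inner − V_outer) encodes the local concentration gradient
sustained by transepithelial ion transport.  A reference recording far from
the tissue captures electrode noise and drift and is subtracted.  The
corrected gradient is converted to a concentration gradient

    ΔC = C_B · (10^(ΔV/S) − 1)          [µmol cm⁻³]

and then to a net flux by Fick's first law over the excursion distance Δx:

    J = D · ΔC / Δx                      [reported in pmol cm⁻² s⁻¹]

Sign convention: ΔV = V_inner − V_outer, so a cation source at the surface
(efflux into the bath) gives a positive gradient.  At the basal
(haemolymph-facing) surface a positive flux is absorption, a negative flux
secretion; an ``apical`` surface flag flips the labels.
"""

from __future__ import annotations

import math
import statistics
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, NamedTuple, Optional, Sequence

from .electrode import (
    CalibrationError,
    ElectrodeCalibration,
    IonSpecies,
    voltage_to_concentration,
)

__all__ = [
    "MalformedRecordingError",
    "VoltageSample",
    "SiteRecording",
    "ScanDataset",
    "FluxEstimate",
    "site_gradient",
    "reference_gradient",
    "correct_gradient",
    "background_concentration",
    "concentration_gradient",
    "fick_flux",
    "signal_to_noise",
    "estimate_fluxes",
]


class MalformedRecordingError(ValueError):
    """A site recording violates the move-wait-sample protocol structure."""


class VoltageSample(NamedTuple):
    measurement: int
    cycle: int
    position: Literal["inner", "outer"]
    time_s: float
    voltage_uv: float


@dataclass(frozen=True)
class SiteRecording:
    """All voltage samples collected at one tissue (or reference) site."""

    site_id: str
    region_hint: str  # "ileum" | "rectum" | "unknown"
    ordinal: int  # position along the tissue axis
    samples: tuple[VoltageSample, ...]
    is_reference: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", tuple(self.samples))
        if not self.samples:
            raise MalformedRecordingError(f"site {self.site_id}: no samples")
        times = [s.time_s for s in self.samples]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise MalformedRecordingError(
                f"site {self.site_id}: sample times must be strictly increasing"
            )
        for (meas, cyc), positions in self._cycles().items():
            if sorted(positions) != ["inner", "outer"]:
                raise MalformedRecordingError(
                    f"site {self.site_id}: measurement {meas} cycle {cyc} "
                    "must have exactly one inner and one outer sample"
                )

    def _cycles(self) -> dict[tuple[int, int], list[str]]:
        cycles: dict[tuple[int, int], list[str]] = {}
        for s in self.samples:
            cycles.setdefault((s.measurement, s.cycle), []).append(s.position)
        return cycles

    def cycle_gradients(self) -> list[float]:
        """Per-cycle ΔV = V_inner − V_outer, in sample order."""
        inner: dict[tuple[int, int], float] = {}
        outer: dict[tuple[int, int], float] = {}
        for s in self.samples:
            (inner if s.position == "inner" else outer)[
                (s.measurement, s.cycle)
            ] = s.voltage_uv
        return [inner[key] - outer[key] for key in sorted(inner)]


@dataclass(frozen=True)
class ScanDataset:
    """One preparation's scan: calibration, reference and tissue recordings.

    K+ and Na+ are scanned in separate preparations, so a dataset carries a
    single ion.
    """

    ion: IonSpecies
    calibration: ElectrodeCalibration
    protocol: "ScanProtocol"  # noqa: F821 - forward ref to synthetic.ScanProtocol
    reference_recordings: tuple[SiteRecording, ...]
    site_recordings: tuple[SiteRecording, ...]
    treatment_label: str = "control"
    preparation_id: str = "prep"

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "reference_recordings", tuple(self.reference_recordings)
        )
        object.__setattr__(self, "site_recordings", tuple(self.site_recordings))
        if not self.reference_recordings:
            raise ValueError(
                f"preparation {self.preparation_id}: no reference recordings"
            )
        if not self.site_recordings:
            raise ValueError(
                f"preparation {self.preparation_id}: no tissue site recordings"
            )
        if any(not r.is_reference for r in self.reference_recordings):
            raise ValueError("reference_recordings must all be flagged is_reference")
        if any(r.is_reference for r in self.site_recordings):
            raise ValueError("site_recordings must not be flagged is_reference")


@dataclass(frozen=True)
class FluxEstimate:
    """Per-site chain of derived quantities, raw ΔV through flux and QC."""

    site_id: str
    region: str
    region_hint: str
    ordinal: int
    dv_raw: float  # µV, tissue-surface gradient
    dv_reference: float  # µV
    dv_corrected: float  # µV
    background_concentration: float  # µmol cm⁻³ (≡ mM)
    concentration_gradient: float  # µmol cm⁻³
    flux: float  # pmol cm⁻² s⁻¹
    direction: Literal["absorption", "secretion", "none"]
    signal_to_noise: Optional[float]  # None when the reference gradient is 0


Aggregation = Literal["mean", "median"]


def site_gradient(rec: SiteRecording, aggregation: Aggregation = "mean") -> float:
    """Aggregate voltage gradient at one site, µV.

    Grand mean (or median) of the per-cycle gradients pooled over both
    independent measurements — identical to the mean of measurement means at
    equal cycle counts.
    """
    gradients = rec.cycle_gradients()
    if aggregation == "median":
        return float(statistics.median(gradients))
    return float(statistics.fmean(gradients))


def reference_gradient(
    dataset: ScanDataset, aggregation: Aggregation = "mean"
) -> float:
    """Mean gradient over all reference recordings, µV."""
    return float(
        statistics.fmean(
            site_gradient(r, aggregation) for r in dataset.reference_recordings
        )
    )


def correct_gradient(dv_site: float, dv_ref: float) -> float:
    """Reference-corrected gradient: subtract electrode noise/drift, µV."""
    return dv_site - dv_ref


def background_concentration(
    dataset: ScanDataset,
    mode: Literal["measured", "nominal"] = "measured",
) -> float:
    """Background ion concentration C_B, µmol cm⁻³.

    ``measured``: the average of the concentrations converted from every
    voltage sample at every tissue site (the definition used in the flux
    equation).  ``nominal``: the bath concentration of the scanned ion, for
    recordings without absolute calibration anchoring.
    """
    if mode == "nominal":
        return dataset.ion.bath_concentration
    concentrations = [
        voltage_to_concentration(s.voltage_uv, dataset.calibration)
        for rec in dataset.site_recordings
        for s in rec.samples
    ]
    return float(statistics.fmean(concentrations))


def concentration_gradient(dv_corrected: float, c_b: float, slope: float) -> float:
    """ΔC = C_B·(10^(ΔV/S) − 1), µmol cm⁻³; strictly increasing in ΔV."""
    if slope == 0:
        raise CalibrationError("zero slope: cannot convert voltage gradient")
    if c_b <= 0:
        raise ValueError("background concentration must be positive")
    return c_b * (10.0 ** (dv_corrected / slope) - 1.0)


def fick_flux(delta_c: float, diffusion_coefficient: float, dx_cm: float) -> float:
    """Fick's first law: J = D·ΔC/Δx, returned in pmol cm⁻² s⁻¹.

    ΔC in µmol cm⁻³ and Δx in cm give J in µmol cm⁻² s⁻¹; the 1e6 factor
    rescales to pmol.
    """
    if diffusion_coefficient <= 0:
        raise ValueError("diffusion coefficient must be positive")
    if dx_cm <= 0:
        raise ValueError("excursion distance must be positive")
    return delta_c * diffusion_coefficient / dx_cm * 1e6


def signal_to_noise(dv_site: float, dv_ref: float) -> Optional[float]:
    """|tissue gradient| / |reference gradient|; None when undefined.

    Ratios below 1 mean the tissue signal is smaller than electrode
    noise/drift — retained but flagged by callers.
    """
    if dv_ref == 0:
        return None
    return abs(dv_site) / abs(dv_ref)


def _direction(
    flux: float, surface: Literal["basal", "apical"]
) -> Literal["absorption", "secretion", "none"]:
    if flux == 0:
        return "none"
    toward_bath = flux > 0
    if surface == "basal":
        return "absorption" if toward_bath else "secretion"
    return "secretion" if toward_bath else "absorption"


def estimate_fluxes(
    dataset: ScanDataset,
    *,
    cb_mode: Literal["measured", "nominal"] = "measured",
    surface: Literal["basal", "apical"] = "basal",
    aggregation: Aggregation = "mean",
) -> list[FluxEstimate]:
    """Run the full per-site chain for one preparation.

    site gradient → reference correction → concentration gradient (with the
    dataset-wide C_B) → Fick flux → direction label and signal:noise.
    Output order matches the input site order.
    """
    dv_ref = reference_gradient(dataset, aggregation)
    c_b = background_concentration(dataset, cb_mode)
    dx_cm = dataset.protocol.excursion_um * 1e-4
    estimates = []
    for rec in dataset.site_recordings:
        try:
            dv_raw = site_gradient(rec, aggregation)
            dv_corr = correct_gradient(dv_raw, dv_ref)
            delta_c = concentration_gradient(
                dv_corr, c_b, dataset.calibration.slope
            )
            flux = fick_flux(delta_c, dataset.ion.diffusion_coefficient, dx_cm)
        except (ValueError, CalibrationError) as exc:
            raise type(exc)(
                f"preparation {dataset.preparation_id}, site {rec.site_id}: {exc}"
            ) from exc
        estimates.append(
            FluxEstimate(
                site_id=rec.site_id,
                region=rec.region_hint,
                region_hint=rec.region_hint,
                ordinal=rec.ordinal,
                dv_raw=dv_raw,
                dv_reference=dv_ref,
                dv_corrected=dv_corr,
                background_concentration=c_b,
                concentration_gradient=delta_c,
                flux=flux,
                direction=_direction(flux, surface),
                signal_to_noise=signal_to_noise(dv_raw, dv_ref),
            )
        )
    return estimates
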