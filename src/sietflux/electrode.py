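"""Ion-selective microelectrode physics.

An ion-selective microelectrode develops a voltage proportional to the
logarithm of the activity of its primary ion.  Calibrating the electrode in
two solutions of known concentration fixes the Nernst slope ``S`` (µV per
tenfold concentration change) and an absolute voltage-to-concentration
mapping.  Real ionophore cocktails also respond to interfering ions; the
Nicolsky-Eisenman form models this with selectivity coefficients ``k_j``:

    V = V_high + S * log10( (C_primary + sum_j k_j * C_j) / C_high )

Concentrations stand in for activities throughout: calibration and
experimental solutions are assumed to have similar ionic strength, so the
activity coefficients cancel.  No activity-coefficient parameter exists
anywhere in the package.  Temperature is not modelled; slopes are empirical
per-electrode values, never theoretical Nernst slopes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from types import MappingProxyType
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "CalibrationError",
    "IonSpecies",
    "ElectrodeCalibration",
    "SelectivityProfile",
    "POTASSIUM",
    "SODIUM",
    "K_SELECTIVITY",
    "NA_SELECTIVITY",
    "fit_slope",
    "fit_slope_least_squares",
    "electrode_voltage",
    "voltage_to_concentration",
]


class CalibrationError(ValueError):
    """Calibration points cannot define a usable electrode response."""


@dataclass(frozen=True)
class IonSpecies:
    """Physical constants of a measured ion.

    ``bath_concentration`` is in mmol/L, numerically equal to µmol/cm³ —
    the unit identity the flux arithmetic relies on.
    """

    name: str
    valence: int
    diffusion_coefficient: float  # cm² s⁻¹
    bath_concentration: float  # mmol L⁻¹ ≡ µmol cm⁻³

    def __post_init__(self) -> None:
        if self.diffusion_coefficient <= 0:
            raise ValueError("diffusion_coefficient must be positive")
        if self.bath_concentration <= 0:
            raise ValueError("bath_concentration must be positive")
        if self.valence != 1:
            raise ValueError("only monovalent cations are supported")


#: K+ in Ca2+-free Aedes saline (3.4 mM KCl).
POTASSIUM = IonSpecies("K", 1, 1.92e-5, 3.4)
#: Na+ in the low-sodium saline used for Na+ scans (20 mM, NMDG-substituted).
SODIUM = IonSpecies("Na", 1, 1.55e-5, 20.0)


def fit_slope(
    low_concentration: float,
    low_voltage: float,
    high_concentration: float,
    high_voltage: float,
) -> float:
    """Two-point Nernst slope in µV per tenfold concentration change.

    When the calibration points span exactly one decade the slope equals the
    voltage difference between them.
    """
    if low_concentration <= 0 or high_concentration <= 0:
        raise CalibrationError("calibration concentrations must be positive")
    if low_concentration == high_concentration:
        raise CalibrationError("calibration concentrations must be distinct")
    return (high_voltage - low_voltage) / math.log10(
        high_concentration / low_concentration
    )


def fit_slope_least_squares(
    concentrations: Sequence[float], voltages: Sequence[float]
) -> float:
    """Least-squares slope of voltage against log10(concentration).

    Used when a calibration table carries three or more points; with exactly
    two points it reduces to :func:`fit_slope`.
    """
    conc = np.asarray(concentrations, dtype=float)
    volt = np.asarray(voltages, dtype=float)
    if conc.size != volt.size or conc.size < 2:
        raise CalibrationError("need matching concentration/voltage arrays, n >= 2")
    if np.any(conc <= 0):
        raise CalibrationError("calibration concentrations must be positive")
    if np.unique(conc).size < 2:
        raise CalibrationError("calibration concentrations must be distinct")
    slope, _ = np.polyfit(np.log10(conc), volt, 1)
    return float(slope)


@dataclass(frozen=True)
class ElectrodeCalibration:
    """Two-point calibration of an ion-selective microelectrode.

    Voltages are stored de-amplified (true electrode µV); any amplifier gain
    is removed on file ingest, not here.
    """

    ion: IonSpecies
    low_concentration: float  # mmol L⁻¹
    high_concentration: float  # mmol L⁻¹
    low_voltage: float  # µV
    high_voltage: float  # µV
    slope: float  # µV per decade

    def __post_init__(self) -> None:
        if self.low_concentration <= 0 or self.high_concentration <= 0:
            raise CalibrationError("calibration concentrations must be positive")
        if self.high_concentration <= self.low_concentration:
            raise CalibrationError(
                "high_concentration must exceed low_concentration"
            )
        if not math.isfinite(self.slope):
            raise CalibrationError("slope must be finite")

    @classmethod
    def from_points(
        cls,
        ion: IonSpecies,
        low_concentration: float,
        low_voltage: float,
        high_concentration: float,
        high_voltage: float,
    ) -> "ElectrodeCalibration":
        slope = fit_slope(
            low_concentration, low_voltage, high_concentration, high_voltage
        )
        return cls(
            ion=ion,
            low_concentration=low_concentration,
            high_concentration=high_concentration,
            low_voltage=low_voltage,
            high_voltage=high_voltage,
            slope=slope,
        )

    @classmethod
    def from_table(
        cls,
        ion: IonSpecies,
        concentrations: Sequence[float],
        voltages: Sequence[float],
    ) -> "ElectrodeCalibration":
        """Build a calibration from >=2 points.

        Two points use the exact two-point slope; three or more reduce to the
        least-squares slope, anchored at the highest-concentration point.
        """
        pairs = sorted(zip(concentrations, voltages))
        if len(pairs) < 2:
            raise CalibrationError("need at least two calibration points")
        if len(pairs) == 2:
            (cl, vl), (ch, vh) = pairs
            return cls.from_points(ion, cl, vl, ch, vh)
        slope = fit_slope_least_squares(
            [c for c, _ in pairs], [v for _, v in pairs]
        )
        (cl, vl), (ch, vh) = pairs[0], pairs[-1]
        return cls(
            ion=ion,
            low_concentration=cl,
            high_concentration=ch,
            low_voltage=vl,
            high_voltage=vh,
            slope=slope,
        )


@dataclass(frozen=True)
class SelectivityProfile:
    """log10 selectivity coefficients of an ionophore cocktail.

    Negative values mean good rejection of the interferent (e.g. −3.9 means
    the electrode prefers its primary ion by a factor of 10^3.9).  An ion
    absent from the map is treated as perfectly rejected (coefficient 0).
    """

    primary_ion: str
    log10_selectivity: Mapping[str, float]

    def __post_init__(self) -> None:
        for ion, logk in self.log10_selectivity.items():
            if not math.isfinite(logk):
                raise ValueError(f"non-finite selectivity for {ion!r}")
        object.__setattr__(
            self, "log10_selectivity", MappingProxyType(dict(self.log10_selectivity))
        )

    def coefficient(self, interferent: str) -> float:
        logk = self.log10_selectivity.get(interferent)
        return 0.0 if logk is None else 10.0**logk

    def effective_concentration(self, concentrations: Mapping[str, float]) -> float:
        """Nicolsky-Eisenman effective concentration seen by the electrode."""
        primary = concentrations.get(self.primary_ion)
        if primary is None or primary <= 0:
            raise ValueError(
                f"primary ion {self.primary_ion!r} must be present and positive"
            )
        total = primary
        for ion, conc in concentrations.items():
            if ion != self.primary_ion:
                total += self.coefficient(ion) * conc
        return total


#: K+ ionophore I cocktail B: rejection of Na+, Ca2+, Mg2+ by 10^3.9/10^4.9/10^4.9.
K_SELECTIVITY = SelectivityProfile("K", {"Na": -3.9, "Ca": -4.9, "Mg": -4.9})
#: Na+ ionophore X cocktail; coefficients reported for a closely related
#: cocktail (10^2.6 over K+) — a documented stand-in, not a measured value
#: for this exact mixture.
NA_SELECTIVITY = SelectivityProfile("Na", {"K": -2.6, "Ca": -3.5, "Mg": -3.7})


def electrode_voltage(
    concentrations: Mapping[str, float],
    calibration: ElectrodeCalibration,
    selectivity: SelectivityProfile,
) -> float:
    """Forward Nicolsky-Eisenman electrode reading in µV.

    Anchored at the calibration high point (assumed interferent-free), so a
    pure solution at ``high_concentration`` reads ``high_voltage`` exactly.
    Deterministic; noise and drift belong to the scan simulator.
    """
    effective = selectivity.effective_concentration(concentrations)
    if effective <= 0:
        raise ValueError("effective concentration must be positive")
    return calibration.high_voltage + calibration.slope * math.log10(
        effective / calibration.high_concentration
    )


def voltage_to_concentration(
    voltage: float, calibration: ElectrodeCalibration
) -> float:
    """Invert the calibration curve: µV reading → apparent concentration (mM).

    ``C = C_high * 10**((V − V_high) / S)``; strictly monotone in V for a
    positive slope.  With interferents present the result overestimates the
    primary-ion concentration by exactly Σ k_j·C_j.
    """
    if calibration.slope == 0:
        raise CalibrationError("zero slope: electrode non-responsive")
    return calibration.high_concentration * 10.0 ** (
        (voltage - calibration.high_voltage) / calibration.slope
    )
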