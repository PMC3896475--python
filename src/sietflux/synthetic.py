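"""Synthetic SIET experiments with known ground truth.

The generator emulates the physics the analysis pipeline inverts, so the
pipeline's accuracy is measurable by parameter recovery:

* a planar steady-state concentration profile in the unstirred layer — for a
  true flux J* the gradient across the electrode excursion is
  ΔC = J*·Δx/D, linear in depth; the outer excursion point sits at the
  unstirred-layer boundary and therefore at the bath concentration, the
  inner point at bath + ΔC — exactly the profile the analysis equation
  ΔC = C_B·10^(ΔV/S) − C_B inverts;
* the electrode's Nicolsky-Eisenman response with finite selectivity
  (interfering bath ions shift both excursion endpoints);
* linear common-mode voltage drift shared by reference and tissue
  recordings, mimicking slow evaporation of the backfilling solution;
* i.i.d. Gaussian noise on every 0.5 s voltage sample.

The protocol schedule reproduces the instrument timing: position the tip
5 µm from the surface, wait 4.0 s, sample 0.5 s, travel 50 µm outward at
200 µm/s, wait, sample — one ~9.5 s cycle, three cycles per measurement, two
measurements per site (~57 s).  Sample timestamps follow this schedule, so
drift-induced bias is produced by the same geometry the real instrument has.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from types import MappingProxyType
from typing import Literal, Mapping, Optional, Sequence

import numpy as np

from .electrode import (
    ElectrodeCalibration,
    IonSpecies,
    K_SELECTIVITY,
    NA_SELECTIVITY,
    POTASSIUM,
    SODIUM,
    SelectivityProfile,
    electrode_voltage,
)
from .pipeline import ScanDataset, SiteRecording, VoltageSample

__all__ = [
    "ProtocolError",
    "InfeasibleTruthError",
    "ScanProtocol",
    "SyntheticTruth",
    "REGIONS",
    "DEFAULT_BATH",
    "DEFAULT_SLOPES",
    "protocol_duration",
    "default_calibration",
    "default_selectivity",
    "default_experiment_config",
    "simulate_calibration",
    "simulate_scan",
    "simulate_condition",
]


class ProtocolError(ValueError):
    """Scan protocol parameters are inconsistent."""


class InfeasibleTruthError(ValueError):
    """Ground-truth flux implies a negative concentration in the gradient."""


REGIONS = ("ileum", "anterior_rectum", "posterior_rectum")

#: Bath composition (mM) per scanned ion: K+ scans in Ca2+-free Aedes saline
#: (3.4 mM K+, 155.2 mM Na+ from NaCl + NaHCO3); Na+ scans in 20 mM Na+
#: saline (equimolar N-methyl-D-glucamine substitution).
DEFAULT_BATH: Mapping[str, Mapping[str, float]] = MappingProxyType(
    {
        "K": MappingProxyType({"K": 3.4, "Na": 155.2}),
        "Na": MappingProxyType({"Na": 20.0, "K": 3.4}),
    }
)

#: Mean measured electrode slopes, µV per decade.
DEFAULT_SLOPES: Mapping[str, float] = MappingProxyType({"K": 55_600.0, "Na": 59_000.0})


@dataclass(frozen=True)
class ScanProtocol:
    """Geometry and timing of the move-wait-sample excursion protocol."""

    excursion_um: float = 50.0  # Δx
    inner_offset_um: float = 5.0  # tip-to-surface distance at the inner point
    wait_s: float = 4.0
    sample_s: float = 0.5
    move_speed_um_s: float = 200.0
    cycles_per_measurement: int = 3
    measurements_per_site: int = 2
    site_spacing_um: float = 40.0

    def __post_init__(self) -> None:
        if self.excursion_um <= 0:
            raise ProtocolError("excursion must be positive")
        if self.cycles_per_measurement < 1 or self.measurements_per_site < 1:
            raise ProtocolError("cycle and measurement counts must be >= 1")
        if min(self.wait_s, self.sample_s, self.inner_offset_um) < 0:
            raise ProtocolError("durations and offsets must be non-negative")
        if self.move_speed_um_s <= 0:
            raise ProtocolError("move speed must be positive with a nonzero excursion")

    @property
    def travel_s(self) -> float:
        """One-way travel time across the excursion."""
        return self.excursion_um / self.move_speed_um_s

    @property
    def cycle_time_s(self) -> float:
        """Duration of one move-wait-sample cycle (defaults: 9.5 s)."""
        return 2.0 * (self.wait_s + self.sample_s) + 2.0 * self.travel_s

    @property
    def excursion_cm(self) -> float:
        return self.excursion_um * 1e-4


def protocol_duration(protocol: ScanProtocol, n_measurements: int) -> float:
    """Total sampling time for ``n_measurements`` at one site, seconds.

    Defaults give 9.5 s per cycle and 57 s for the standard two measurements
    of three cycles each.
    """
    if n_measurements < 1:
        raise ValueError("n_measurements must be >= 1")
    return n_measurements * protocol.cycles_per_measurement * protocol.cycle_time_s


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth for one simulated condition."""

    region_flux: Mapping[str, float]  # pmol cm⁻² s⁻¹, + = efflux toward bath
    n_sites: Mapping[str, int] = field(
        default_factory=lambda: {"ileum": 5, "rectum": 10}
    )
    drift_rate_uv_min: float = 30.0  # common-mode, applied to all recordings
    noise_sd_uv: float = 15.0  # per 0.5 s voltage sample
    n_preparations: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "region_flux", MappingProxyType(dict(self.region_flux))
        )
        object.__setattr__(self, "n_sites", MappingProxyType(dict(self.n_sites)))
        if self.noise_sd_uv < 0:
            raise ValueError("noise_sd_uv must be non-negative")
        if self.n_preparations < 1:
            raise ValueError("n_preparations must be >= 1")
        if any(n < 0 for n in self.n_sites.values()):
            raise ValueError("site counts must be non-negative")
        missing = set(REGIONS) - set(self.region_flux)
        if missing:
            raise ValueError(f"region_flux missing regions: {sorted(missing)}")


#: Control-condition true fluxes (pmol cm⁻² s⁻¹).  The ileal values are the
#: fluxes implied by the mean corrected gradients of control scans
#: (+49.4 µV K+, −22.0 µV Na+) at nominal bath concentrations; rectal Na+ is
#: a small absorption consistent with the sub-unity Na+ signal:noise there.
_CONTROL_FLUX = {
    "K": {"ileum": 26.7, "anterior_rectum": 26.7, "posterior_rectum": 26.7},
    "Na": {"ileum": -53.2, "anterior_rectum": 8.0, "posterior_rectum": 8.0},
}

#: Fractional flux remaining after 200 nM GPA2/GPB5, per ion and region, for
#: the regions where the hormone effect reached significance; all other
#: regions keep their control flux.
_TREATMENT_SCALE = {
    "K": {"ileum": 0.32, "anterior_rectum": 0.21},
    "Na": {"ileum": 0.25},
}

Condition = Literal["control", "GPA2/GPB5"]


def default_experiment_config(
    ion: str, condition: Condition, seed: int = 0
) -> SyntheticTruth:
    """Documented default ground truths for the two study conditions."""
    if ion not in _CONTROL_FLUX:
        raise ValueError(f"unknown ion {ion!r}; expected 'Na' or 'K'")
    if condition not in ("control", "GPA2/GPB5"):
        raise ValueError(f"unknown condition {condition!r}")
    flux = dict(_CONTROL_FLUX[ion])
    if condition == "GPA2/GPB5":
        for region, scale in _TREATMENT_SCALE[ion].items():
            flux[region] *= scale
    return SyntheticTruth(region_flux=flux, seed=seed)


def default_calibration(ion: str, high_voltage: float = 0.0) -> ElectrodeCalibration:
    """Noise-free calibration at the mean measured slope (15 ↔ 150 mM)."""
    species = {"K": POTASSIUM, "Na": SODIUM}[ion]
    slope = DEFAULT_SLOPES[ion]
    return ElectrodeCalibration.from_points(
        species, 15.0, high_voltage - slope, 150.0, high_voltage
    )


def default_selectivity(ion: str) -> SelectivityProfile:
    return {"K": K_SELECTIVITY, "Na": NA_SELECTIVITY}[ion]


def simulate_calibration(
    true_slope: float,
    concentrations: tuple[float, float] = (15.0, 150.0),
    noise_sd: float = 950.0,
    n: int = 20,
    seed: Optional[int] = None,
    high_voltage: float = 0.0,
) -> list[tuple[float, float, float, float]]:
    """Simulate ``n`` independent two-point calibrations.

    Each endpoint voltage gets i.i.d. Gaussian noise; returns
    ``(low_c, low_v, high_c, high_v)`` tuples ready for slope fitting.  The
    noise level sets the between-electrode scatter of the fitted slopes
    (SD = noise_sd·√2 for a one-decade pair).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    low_c, high_c = sorted(concentrations)
    if low_c <= 0 or low_c == high_c:
        raise ValueError("concentrations must be positive and distinct")
    rng = np.random.default_rng(seed)
    decades = math.log10(high_c / low_c)
    low_v_true = high_voltage - true_slope * decades
    out = []
    for _ in range(n):
        lv = low_v_true + rng.normal(0.0, noise_sd)
        hv = high_voltage + rng.normal(0.0, noise_sd)
        out.append((low_c, lv, high_c, hv))
    return out


def _site_plan(truth: SyntheticTruth) -> list[tuple[str, str, int]]:
    """(site_id, region_hint, ordinal) with rectum halves split like the
    analysis: first half (extra site included) anterior."""
    plan = []
    ordinal = 0
    for _ in range(truth.n_sites.get("ileum", 0)):
        plan.append((f"ileum-{ordinal}", "ileum", ordinal))
        ordinal += 1
    n_rect = truth.n_sites.get("rectum", 0)
    for k in range(n_rect):
        plan.append((f"rectum-{k}", "rectum", ordinal))
        ordinal += 1
    return plan


def _true_region(hint: str, rectum_index: int, n_rectum: int) -> str:
    if hint == "ileum":
        return "ileum"
    return "anterior_rectum" if rectum_index < math.ceil(n_rectum / 2) else "posterior_rectum"


def simulate_scan(
    truth: SyntheticTruth,
    protocol: ScanProtocol,
    calibration: ElectrodeCalibration,
    selectivity: SelectivityProfile,
    bath: Mapping[str, float],
    *,
    preparation_id: str = "prep-01",
    treatment_label: str = "control",
    n_reference_measurements: int = 10,
    reference_offset_uv: float = 0.0,
    rng: Optional[np.random.Generator] = None,
) -> ScanDataset:
    """Generate one preparation's complete scan from ground truth.

    Reference samples see bath concentrations everywhere; tissue sites see a
    linear unstirred-layer profile with endpoint difference ΔC = J*·Δx/D,
    the outer point at the bath concentration and the inner point at
    bath + ΔC.  Every sample receives the shared linear drift plus Gaussian
    noise.  ``reference_offset_uv`` adds a
    constant offset to reference samples only, emulating imperfect
    correction.  Reproducible for a fixed seed.

    The reference recording defaults to ten three-cycle measurements
    (~285 s, matching the roughly five minutes the reference site occupies
    before tissue scanning).
    """
    ion = calibration.ion
    primary = selectivity.primary_ion
    if primary not in bath:
        raise ValueError(f"bath must contain the primary ion {primary!r}")
    if rng is None:
        rng = np.random.default_rng(truth.seed)
    dx_cm = protocol.excursion_cm
    drift_per_s = truth.drift_rate_uv_min / 60.0

    def sample_voltage(conc: Mapping[str, float], t: float, offset: float) -> float:
        v = electrode_voltage(conc, calibration, selectivity)
        return v + drift_per_s * t + offset + rng.normal(0.0, truth.noise_sd_uv)

    clock = 0.0

    def record_site(
        site_id: str,
        hint: str,
        ordinal: int,
        inner_conc: Mapping[str, float],
        outer_conc: Mapping[str, float],
        n_measurements: int,
        is_reference: bool,
        offset: float,
    ) -> SiteRecording:
        nonlocal clock
        samples = []
        for meas in range(n_measurements):
            for cyc in range(protocol.cycles_per_measurement):
                t_inner = (
                    clock + protocol.travel_s + protocol.wait_s + protocol.sample_s / 2
                )
                t_outer = (
                    t_inner
                    + protocol.sample_s / 2
                    + protocol.travel_s
                    + protocol.wait_s
                    + protocol.sample_s / 2
                )
                samples.append(
                    VoltageSample(
                        meas, cyc, "inner", t_inner,
                        sample_voltage(inner_conc, t_inner, offset),
                    )
                )
                samples.append(
                    VoltageSample(
                        meas, cyc, "outer", t_outer,
                        sample_voltage(outer_conc, t_outer, offset),
                    )
                )
                clock += protocol.cycle_time_s
        return SiteRecording(
            site_id=site_id,
            region_hint=hint,
            ordinal=ordinal,
            samples=tuple(samples),
            is_reference=is_reference,
        )

    reference = record_site(
        "reference", "unknown", -1, bath, bath,
        n_reference_measurements, True, reference_offset_uv,
    )

    n_rectum = truth.n_sites.get("rectum", 0)
    sites = []
    rect_idx = 0
    for site_id, hint, ordinal in _site_plan(truth):
        region = _true_region(hint, rect_idx, n_rectum)
        if hint == "rectum":
            rect_idx += 1
        j_true = truth.region_flux[region]
        delta_c = j_true * 1e-6 * dx_cm / ion.diffusion_coefficient  # µmol cm⁻³
        c_bath = bath[primary]
        if abs(delta_c) >= 2.0 * c_bath or c_bath + delta_c <= 0:
            raise InfeasibleTruthError(
                f"true flux {j_true} pmol/cm²/s implies a gradient "
                f"{delta_c:.3g} mM that is non-physical at bath "
                f"{c_bath} mM"
            )
        inner = dict(bath)
        outer = dict(bath)
        inner[primary] = c_bath + delta_c
        sites.append(
            record_site(
                site_id, hint, ordinal, inner, outer,
                protocol.measurements_per_site, False, 0.0,
            )
        )

    return ScanDataset(
        ion=ion,
        calibration=calibration,
        protocol=protocol,
        reference_recordings=(reference,),
        site_recordings=tuple(sites),
        treatment_label=treatment_label,
        preparation_id=preparation_id,
    )


def simulate_condition(
    truth: SyntheticTruth,
    *,
    ion: str,
    treatment_label: str,
    protocol: Optional[ScanProtocol] = None,
    calibration: Optional[ElectrodeCalibration] = None,
    selectivity: Optional[SelectivityProfile] = None,
    bath: Optional[Mapping[str, float]] = None,
    seed: Optional[int] = None,
) -> list[ScanDataset]:
    """Simulate ``truth.n_preparations`` independent preparations.

    One generator seeded once drives every preparation, so the whole
    condition is reproducible from a single seed.
    """
    protocol = protocol or ScanProtocol()
    calibration = calibration or default_calibration(ion)
    selectivity = selectivity or default_selectivity(ion)
    bath = bath or DEFAULT_BATH[ion]
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    return [
        simulate_scan(
            truth, protocol, calibration, selectivity, bath,
            preparation_id=f"{treatment_label}-{i + 1:02d}",
            treatment_label=treatment_label,
            rng=rng,
        )
        for i in range(truth.n_preparations)
    ]
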