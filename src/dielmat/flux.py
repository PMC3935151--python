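"""Concentration time series → area-normalized net fluxes.

Microcosm vials (mat cores under a gas headspace with a small liquid
phase) and benthic flux chambers both yield concentration time series
over a diel cycle.  This module converts those series into net fluxes
per unit mat area (mmol m⁻²) for a given time window, aggregates
replicates, and compares treatments.

Sign convention: positive flux = accumulation in the overlying
compartment (release from the mat); negative = uptake into the mat.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "GAS_CONSTANT_L_ATM",
    "DielTimeSeries",
    "Geometry",
    "AreaFlux",
    "TestResult",
    "core_area",
    "headspace_amount",
    "net_flux",
    "dic_flux",
    "sulfide_calibration",
    "sulfide_concentration",
    "aggregate_replicates",
    "treatment_comparison",
]

#: Ideal gas constant in L·atm·mol⁻¹·K⁻¹.
GAS_CONSTANT_L_ATM = 0.0820573661

COMPARTMENTS = ("headspace", "liquid", "chamber_water")


@dataclass(frozen=True)
class DielTimeSeries:
    """One analyte's concentration series for one treatment/replicate.

    ``values`` are ppm by volume for the ``headspace`` compartment and
    mmol L⁻¹ for ``liquid`` and ``chamber_water``.  ``times`` are hours
    since dawn and must be strictly increasing.
    """

    analyte: str
    treatment: str
    replicate: str
    compartment: str
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.compartment not in COMPARTMENTS:
            raise ValueError(
                f"unknown compartment {self.compartment!r}; "
                f"expected one of {COMPARTMENTS}"
            )
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise ValueError("times and values must be 1-D arrays of equal length")
        if len(self.times) and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.values < 0):
            raise ValueError("concentrations must be non-negative")


@dataclass(frozen=True)
class Geometry:
    """Microcosm-vial and flux-chamber geometry.

    Defaults mirror the study setup: 11 mm mat cores in 14 mL serum
    vials with 4 mL site water, and 1.5 L flux chambers.  The mat area
    enclosed by a chamber is site-specific and therefore has no
    default; it must be configured before :func:`dic_flux` can run.
    """

    vial_volume_mL: float = 14.0
    liquid_volume_mL: float = 4.0
    core_diameter_mm: float = 11.0
    chamber_volume_L: float = 1.5
    chamber_area_m2: float | None = None
    temperature_K: float = 298.15
    pressure_atm: float = 1.0

    def __post_init__(self) -> None:
        if self.vial_volume_mL <= self.liquid_volume_mL:
            raise ValueError("headspace volume (vial − liquid) must be positive")
        for name in ("vial_volume_mL", "liquid_volume_mL", "core_diameter_mm",
                     "chamber_volume_L", "temperature_K", "pressure_atm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.chamber_area_m2 is not None and self.chamber_area_m2 <= 0:
            raise ValueError("chamber_area_m2 must be positive")

    @property
    def headspace_mL(self) -> float:
        return self.vial_volume_mL - self.liquid_volume_mL

    @property
    def core_area_m2(self) -> float:
        return core_area(self.core_diameter_mm)


@dataclass(frozen=True)
class AreaFlux:
    """A net areal flux (mmol m⁻²) for one species over one diel phase.

    Negative values denote uptake into the mat.
    """

    species: str
    phase: str
    flux_mmol_m2: float
    sd_mmol_m2: float = 0.0
    n_replicates: int = 1
    treatment: str = ""

    def __post_init__(self) -> None:
        if self.phase not in ("day", "night", "diel_avg"):
            raise ValueError(f"unknown phase {self.phase!r}")
        if self.sd_mmol_m2 < 0:
            raise ValueError("sd must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


def core_area(diameter_mm: float) -> float:
    """Area (m²) of a circular mat core of the given diameter (mm)."""
    if diameter_mm <= 0:
        raise ValueError("core diameter must be positive")
    radius_m = diameter_mm / 2.0 / 1000.0
    return math.pi * radius_m**2


def headspace_amount(ppm: float, headspace_mL: float,
                     temperature_K: float = 298.15,
                     pressure_atm: float = 1.0) -> float:
    """Amount (mmol) of a trace gas in a vial headspace, by ideal gas law.

    ``ppm`` is the mixing ratio by volume; n = x·PV/RT.
    """
    if temperature_K <= 0:
        raise ValueError("temperature must be positive (K)")
    if headspace_mL <= 0 or pressure_atm <= 0:
        raise ValueError("headspace volume and pressure must be positive")
    if ppm < 0:
        raise ValueError("mixing ratio must be non-negative")
    volume_L = headspace_mL / 1000.0
    mol = ppm * 1e-6 * pressure_atm * volume_L / (GAS_CONSTANT_L_ATM * temperature_K)
    return mol * 1000.0


def _amount_mmol(series: DielTimeSeries, value: float, geometry: Geometry) -> float:
    """Convert one concentration sample to an absolute amount (mmol)."""
    if series.compartment == "headspace":
        return headspace_amount(value, geometry.headspace_mL,
                                geometry.temperature_K, geometry.pressure_atm)
    if series.compartment == "liquid":
        return value * geometry.liquid_volume_mL / 1000.0
    if series.compartment == "chamber_water":
        return value * geometry.chamber_volume_L
    raise ValueError(f"unknown compartment {series.compartment!r}")


def _normalizing_area(series: DielTimeSeries, geometry: Geometry) -> float:
    if series.compartment == "chamber_water":
        if geometry.chamber_area_m2 is None:
            raise ValueError(
                "chamber_area_m2 is not set; configure the mat area enclosed "
                "by the flux chamber before computing chamber fluxes"
            )
        return geometry.chamber_area_m2
    return geometry.core_area_m2


def net_flux(series: DielTimeSeries, geometry: Geometry,
             window: tuple[float, float], phase: str = "night") -> AreaFlux:
    """Net areal flux over a time window by endpoint differencing.

    The amount present in the overlying compartment is evaluated at the
    two window edges (linear interpolation between samples) and the
    difference is normalized by mat area.  Accumulation between time
    points, not a regression slope, is what the window reports.
    """
    t0, t1 = window
    tmin, tmax = series.times[0], series.times[-1]
    lo, hi = min(t0, t1), max(t0, t1)
    if lo < tmin or hi > tmax:
        raise ValueError(
            f"window ({t0}, {t1}) outside sampled range ({tmin}, {tmax})"
        )
    in_window = np.sum((series.times >= lo) & (series.times <= hi))
    if in_window < 2:
        raise ValueError("need at least 2 samples inside the window")
    c0 = float(np.interp(t0, series.times, series.values))
    c1 = float(np.interp(t1, series.times, series.values))
    delta = _amount_mmol(series, c1, geometry) - _amount_mmol(series, c0, geometry)
    area = _normalizing_area(series, geometry)
    return AreaFlux(species=series.analyte, phase=phase,
                    flux_mmol_m2=delta / area, treatment=series.treatment)


def dic_flux(series: DielTimeSeries, geometry: Geometry,
             windows: Sequence[tuple[float, float]],
             phases: Sequence[str] | None = None) -> list[AreaFlux]:
    """Per-window net DIC fluxes from a flux-chamber series.

    Each window yields Δconcentration × chamber volume / chamber area;
    negative values mean DIC moved into the mat (daytime fixation).
    """
    if geometry.chamber_area_m2 is None:
        raise ValueError(
            "chamber_area_m2 is not set; configure the mat area enclosed "
            "by the flux chamber before computing DIC fluxes"
        )
    if phases is None:
        phases = ["diel_avg"] * len(windows)
    return [net_flux(series, geometry, w, phase=p)
            for w, p in zip(windows, phases)]


@dataclass(frozen=True)
class LinearCalibration:
    slope: float
    intercept: float
    r_squared: float


def sulfide_calibration(
        standards: Sequence[tuple[float, float]]) -> LinearCalibration:
    """Least-squares line through (concentration, absorbance) standards.

    Used for the methylene-blue colorimetric sulfide assay read at
    670 nm against sodium sulfide standards.
    """
    if len(standards) < 2:
        raise ValueError("need at least 2 calibration standards")
    conc = np.array([s[0] for s in standards], dtype=float)
    absb = np.array([s[1] for s in standards], dtype=float)
    if np.ptp(conc) == 0:
        raise ValueError("calibration standards must span distinct concentrations")
    res = stats.linregress(conc, absb)
    if res.slope == 0:
        raise ValueError("singular calibration: zero slope")
    return LinearCalibration(slope=float(res.slope),
                             intercept=float(res.intercept),
                             r_squared=float(res.rvalue**2))


def sulfide_concentration(absorbance: float,
                          calibration: LinearCalibration) -> float:
    """Inverse-predict concentration (mmol L⁻¹) from absorbance."""
    return (absorbance - calibration.intercept) / calibration.slope


def aggregate_replicates(fluxes: Sequence[AreaFlux]) -> AreaFlux:
    """Mean and sample SD (n−1) across replicate fluxes of one species/phase."""
    if not fluxes:
        raise ValueError("no fluxes to aggregate")
    species = {f.species for f in fluxes}
    phases = {f.phase for f in fluxes}
    if len(species) > 1:
        raise ValueError(f"mixed species in aggregation: {sorted(species)}")
    if len(phases) > 1:
        raise ValueError(f"mixed phases in aggregation: {sorted(phases)}")
    vals = np.array([f.flux_mmol_m2 for f in fluxes], dtype=float)
    n = len(vals)
    sd = float(np.std(vals, ddof=1)) if n > 1 else 0.0
    return AreaFlux(species=fluxes[0].species, phase=fluxes[0].phase,
                    flux_mmol_m2=float(np.mean(vals)), sd_mmol_m2=sd,
                    n_replicates=n, treatment=fluxes[0].treatment)


@dataclass(frozen=True)
class TestResult:
    statistic: float
    pvalue: float
    significant: bool
    test_name: str = "t-test"


def treatment_comparison(control: Sequence[float], treatment: Sequence[float],
                         alpha: float = 0.05) -> TestResult:
    """Unpaired two-tailed Student's t-test between replicate flux groups."""
    control = np.asarray(control, dtype=float)
    treatment = np.asarray(treatment, dtype=float)
    if len(control) < 2 or len(treatment) < 2:
        raise ValueError("each group needs at least 2 replicates")
    if np.array_equal(control, treatment) and np.ptp(control) == 0:
        # degenerate: both groups identical constants
        return TestResult(statistic=0.0, pvalue=1.0, significant=False)
    stat, p = stats.ttest_ind(control, treatment, equal_var=True)
    if math.isnan(p):  # zero variance in both groups, equal means
        stat, p = 0.0, 1.0
    return TestResult(statistic=float(stat), pvalue=float(p),
                      significant=bool(p < alpha))
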