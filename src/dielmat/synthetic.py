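"""Synthetic microcosm, OTU-table, and NanoSIMS spot generators.

The generators emulate the statistical structure of diel microcosm
studies of hypersaline phototrophic mats so every analysis stage can
be exercised end to end without external data:

* fermentation products (acetate > formate > propionate, plus H₂)
  accumulate only during the night, at rates set by configured areal
  fluxes; DIC in a flux chamber is drawn down by day and released at
  night; glycogen accumulates by day and is depleted at night;
* treatments scale production multiplicatively (physical disruption
  roughly doubles fermentation-product flux; molybdate with sulfate-free
  medium enhances H₂; DCMU suppresses H₂ and daytime carbon fixation;
  ammonium addition has no effect);
* replicate-to-replicate variation is multiplicative log-normal with a
  configured coefficient of variation (concentrations stay positive);
* OTU abundances are log-normal with a few dominant taxa carrying most
  ribosomal (cDNA) expression; NanoSIMS ion counts are Poisson.

Everything is deterministic given the configured seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .community import OtuTable
from .flux import GAS_CONSTANT_L_ATM, AreaFlux, DielTimeSeries, Geometry
from .isotope import IsotopeSpot, ratio_from_delta

__all__ = [
    "ScenarioConfig",
    "SpotScenario",
    "DEFAULT_GEOMETRY",
    "generate_microcosm",
    "generate_glycogen",
    "generate_otu_tables",
    "generate_spots",
]

#: Study-condition microcosm/chamber geometry: 11 mm cores in 14 mL
#: vials with 4 mL site water; 1.5 L chambers.  The chamber mat area is
#: a synthetic-scenario choice (the real value is site-specific).
DEFAULT_GEOMETRY = Geometry(vial_volume_mL=14.0, liquid_volume_mL=4.0,
                            core_diameter_mm=11.0, chamber_volume_L=1.5,
                            chamber_area_m2=0.05)

# Nighttime (net, total) areal fluxes in mmol m⁻², the study-condition
# ground truth for the balance table.
_DEFAULT_TRUE_FLUXES = {
    "acetate": (14.9, 28.0),
    "formate": (8.3, 10.0),
    "propionate": (2.4, 6.6),
    "h2": (0.83, 1.77),
}


def _default_treatments() -> dict[str, dict[str, float]]:
    # disruption factors are the total/net ratios so that disrupted
    # microcosms express the configured total fluxes exactly
    disruption = {sp: tot / net for sp, (net, tot) in
                  _DEFAULT_TRUE_FLUXES.items()}
    return {
        "control": {},
        "disruption": disruption,
        "molybdate_sulfate_free": {"h2": 2.0},
        "dcmu": {"h2": 0.2, "dic_day": 0.05},
        "nh4cl": {},
    }


@dataclass(frozen=True)
class ScenarioConfig:
    """Ground-truth scenario for the microcosm generator.

    ``true_fluxes`` maps species → (net, total) nighttime areal flux in
    mmol m⁻²; net is expressed by intact microcosms, and treatment
    factors scale the net flux (the default "disruption" factors equal
    total/net).  DIC fluxes are chamber fluxes in mmol m⁻² per phase
    (day negative = uptake); glycogen is storage change in mmol
    glucosyl m⁻².  ``replicate_cv`` is the coefficient of variation of
    the multiplicative log-normal replicate noise.
    """

    species_list: tuple[str, ...] = ("acetate", "formate", "propionate", "h2")
    day_hours: float = 12.0
    night_hours: float = 12.0
    true_fluxes: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_TRUE_FLUXES))
    dic_day_flux: float = -121.4
    dic_night_flux: float = 77.5
    dic_baseline_mmol_L: float = 6.0
    glycogen_day_gain: float = 21.2
    glycogen_night_loss: float = 31.6
    treatment_effects: dict[str, dict[str, float]] = field(
        default_factory=_default_treatments)
    replicate_cv: float = 0.0
    n_replicates: int = 6
    sample_times: tuple[float, ...] = (0, 3, 6, 9, 12, 15, 18, 21, 24)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.day_hours <= 0 or self.night_hours <= 0:
            raise ValueError("phase durations must be positive")
        if self.replicate_cv < 0:
            raise ValueError("replicate_cv must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        times = np.asarray(self.sample_times, dtype=float)
        if np.any(np.diff(times) <= 0):
            raise ValueError("sample_times must be strictly increasing")
        for sp in self.species_list:
            if sp not in self.true_fluxes:
                raise ValueError(f"no true flux configured for {sp!r}")
        for sp, (net, total) in self.true_fluxes.items():
            if abs(total) < abs(net):
                raise ValueError(
                    f"total flux must be >= net flux for {sp!r} "
                    f"({total} < {net})")

    @property
    def night_window(self) -> tuple[float, float]:
        return (self.day_hours, self.day_hours + self.night_hours)

    @property
    def day_window(self) -> tuple[float, float]:
        return (0.0, self.day_hours)


def _lognormal_factor(rng: np.random.Generator, cv: float) -> float:
    """Multiplicative noise with mean 1 and the given CV; exactly 1 at cv=0."""
    if cv == 0:
        return 1.0
    sigma2 = np.log1p(cv**2)
    return float(rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2)))


def _ppm_from_mmol(amount_mmol: float, geometry: Geometry) -> float:
    volume_L = geometry.headspace_mL / 1000.0
    mol = amount_mmol / 1000.0
    return (mol * GAS_CONSTANT_L_ATM * geometry.temperature_K
            / (geometry.pressure_atm * volume_L) * 1e6)


def _night_fraction(t: float, config: ScenarioConfig) -> float:
    start, end = config.night_window
    if t <= start:
        return 0.0
    if t >= end:
        return 1.0
    return (t - start) / config.night_hours


def generate_microcosm(config: ScenarioConfig,
                       geometry: Geometry = DEFAULT_GEOMETRY,
                       treatments: list[str] | None = None
                       ) -> list[DielTimeSeries]:
    """Concentration time series for every treatment × replicate × analyte.

    Fermentation products accumulate linearly over the night window at
    the configured areal flux (scaled by the treatment factor and
    replicate noise), converted into the measuring compartment: H₂ as
    headspace ppm, organic acids as liquid mmol L⁻¹.  A chamber DIC
    series (analyte ``dic``) falls during the day and rises at night.
    """
    if treatments is None:
        treatments = list(config.treatment_effects)
    for t in treatments:
        if t not in config.treatment_effects:
            raise ValueError(
                f"unknown treatment {t!r}; configured treatments: "
                f"{sorted(config.treatment_effects)}")
    rng = np.random.default_rng(config.seed)
    times = np.asarray(config.sample_times, dtype=float)
    area = geometry.core_area_m2
    series: list[DielTimeSeries] = []
    for treatment in treatments:
        factors = config.treatment_effects[treatment]
        for rep in range(1, config.n_replicates + 1):
            for sp in config.species_list:
                net, _total = config.true_fluxes[sp]
                flux = (net * factors.get(sp, 1.0)
                        * _lognormal_factor(rng, config.replicate_cv))
                amounts = np.array([flux * area * _night_fraction(t, config)
                                    for t in times])
                if sp == "h2":
                    values = np.array([_ppm_from_mmol(a, geometry)
                                       for a in amounts])
                    compartment = "headspace"
                else:
                    values = amounts / (geometry.liquid_volume_mL / 1000.0)
                    compartment = "liquid"
                series.append(DielTimeSeries(
                    analyte=sp, treatment=treatment, replicate=f"r{rep}",
                    compartment=compartment, times=times, values=values))
            # chamber DIC series for this treatment/replicate
            day_flux = (config.dic_day_flux * factors.get("dic_day", 1.0)
                        * _lognormal_factor(rng, config.replicate_cv))
            night_flux = (config.dic_night_flux
                          * factors.get("dic_night", 1.0)
                          * _lognormal_factor(rng, config.replicate_cv))
            conc = []
            ratio = (geometry.chamber_area_m2 or DEFAULT_GEOMETRY.chamber_area_m2) \
                / geometry.chamber_volume_L
            for t in times:
                day_frac = min(t, config.day_hours) / config.day_hours
                c = (config.dic_baseline_mmol_L
                     + day_flux * ratio * day_frac
                     + night_flux * ratio * _night_fraction(t, config))
                conc.append(max(c, 0.0))
            series.append(DielTimeSeries(
                analyte="dic", treatment=treatment, replicate=f"r{rep}",
                compartment="chamber_water", times=times,
                values=np.array(conc)))
    return series


def generate_glycogen(config: ScenarioConfig,
                      seed: int | None = None
                      ) -> tuple[list[AreaFlux], list[AreaFlux]]:
    """Replicate glycogen storage changes (mmol glucosyl m⁻²) per phase.

    Returns (day, night) lists: day entries are positive accumulation,
    night entries negative depletion, with replicate noise.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    day, night = [], []
    for rep in range(1, config.n_replicates + 1):
        gain = config.glycogen_day_gain * _lognormal_factor(
            rng, config.replicate_cv)
        loss = config.glycogen_night_loss * _lognormal_factor(
            rng, config.replicate_cv)
        day.append(AreaFlux("glycogen", "day", gain, treatment="control"))
        night.append(AreaFlux("glycogen", "night", -loss, treatment="control"))
    return day, night


_PHYLA = ("Proteobacteria", "Cyanobacteria", "Chloroflexi",
          "Bacteroidetes", "Spirochaetes")


def generate_otu_tables(n_otus: int = 200, n_dominant: int = 5,
                        depth_dna: int = 11500, depth_cdna: int = 11500,
                        dominance_factor: float = 20.0,
                        seed: int = 0) -> tuple[OtuTable, OtuTable]:
    """Paired DNA/cDNA OTU tables with log-normal abundance structure.

    DNA counts are multinomial over a log-normal abundance profile;
    cDNA counts concentrate mass on the ``n_dominant`` most abundant
    OTUs by ``dominance_factor`` (ribosomal expression dominated by a
    few clades).  Column sums equal the requested depths exactly.
    """
    if n_dominant > n_otus:
        raise ValueError("n_dominant must be <= n_otus")
    if depth_dna <= 0 or depth_cdna <= 0:
        raise ValueError("library depths must be positive")
    rng = np.random.default_rng(seed)
    abundance = np.sort(rng.lognormal(mean=0.0, sigma=1.5, size=n_otus))[::-1]
    p_dna = abundance / abundance.sum()
    weights = abundance.copy()
    weights[:n_dominant] *= dominance_factor
    p_cdna = weights / weights.sum()
    otu_ids = [f"OTU_{i:04d}" for i in range(n_otus)]
    taxonomy = {}
    for i, otu in enumerate(otu_ids):
        phylum = _PHYLA[1] if i < n_dominant else _PHYLA[i % len(_PHYLA)]
        taxonomy[otu] = (phylum, f"Class_{i % 7}", f"Order_{i % 11}",
                         f"Family_{i % 23}", f"Genus_{i:04d}")
    dna_counts = rng.multinomial(depth_dna, p_dna)
    cdna_counts = rng.multinomial(depth_cdna, p_cdna)
    dna = OtuTable(pd.DataFrame({"sample_1": dna_counts}, index=otu_ids),
                   taxonomy)
    cdna = OtuTable(pd.DataFrame({"sample_1": cdna_counts}, index=otu_ids),
                    taxonomy)
    return dna, cdna


@dataclass(frozen=True)
class SpotScenario:
    """Ground truth for NanoSIMS spot-count generation.

    ``target_delta_permil`` is the δ¹³C of the labeled population,
    ``control_delta_permil`` of the unlabeled/PFA-fixed reference;
    ``mean_counts`` is the expected ¹²C¹²C ion count per spot.
    """

    target_delta_permil: float = 500.0
    control_delta_permil: float = -10.0
    mean_counts: float = 1e5
    n_spots: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_counts <= 0:
            raise ValueError("mean_counts must be positive")
        if self.n_spots < 2:
            raise ValueError("n_spots must be >= 2")
        for d in (self.target_delta_permil, self.control_delta_permil):
            if d <= -1000.0:
                raise ValueError("delta must exceed -1000 permil "
                                 "(atom fraction would be <= 0)")


def generate_spots(scenario: SpotScenario
                   ) -> tuple[list[IsotopeSpot], list[IsotopeSpot]]:
    """Poisson dimer counts for a labeled and a control spot group.

    ¹²C¹²C counts are Poisson(mean_counts); ¹³C¹²C counts are Poisson
    with mean mean_counts × 2r, the binomial dimer expectation for the
    group's atom ratio r.  ¹²C¹²C draws of zero (possible only at tiny
    mean counts) are clipped to 1 so every spot yields a ratio.
    """
    rng = np.random.default_rng(scenario.seed)
    groups = []
    for label, delta in (("labeled", scenario.target_delta_permil),
                         ("control", scenario.control_delta_permil)):
        r = ratio_from_delta(delta)
        spots = []
        for i in range(scenario.n_spots):
            n12 = max(int(rng.poisson(scenario.mean_counts)), 1)
            n13 = int(rng.poisson(scenario.mean_counts * 2.0 * r))
            spots.append(IsotopeSpot(
                region_id=f"{label}_{i:03d}", probe="CFX",
                treatment=label, counts_12C12C=n12, counts_13C12C=n13))
        groups.append(spots)
    return groups[0], groups[1]
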