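"""Electron-equivalent mass balance over the diel cycle.

Daytime photosynthetic carbon fixation and nighttime release of
fermentation products (organic acids, H₂) are compared on a common
currency of "electron equivalents": moles of a species times the
electrons transferable per mole, based on total charge state
(acetate = 8, formate = 1, propionate = 13, H₂ = 2, glycogen = 24 per
glucosyl unit; photoautotrophy fixes 4 e⁻ per carbon).

Two headline statistics summarize the balance:

* % fixed e⁻ fermented = 100 × Σ(total fermentation e⁻) / fixed-C e⁻
* % fixed e⁻ taken up by accessory microbes
    = 100 × (Σ total e⁻ − Σ net e⁻) / fixed-C e⁻

"Net" product fluxes come from intact control microcosms (internal
consumption still operating); "total" fluxes from physically disrupted
microcosms (consumption by spatially associated accessory organisms
minimized).  Their difference estimates uptake by accessory microbes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .flux import AreaFlux

__all__ = [
    "ElectronCoefficients",
    "PAPER_COEFFS",
    "REDOX_COEFFS",
    "BalanceRow",
    "ElectronBalanceTable",
    "diel_average",
    "electron_equivalents",
    "build_balance_table",
    "percent_fermented",
    "percent_accessory",
    "propagate_uncertainty",
    "stoichiometric_electron_ratio",
    "round_half_up",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ElectronCoefficients:
    """Electrons transferable per mole of each species.

    ``fixed_carbon`` is the per-carbon coefficient applied to DIC
    uptake (4 e⁻ per C fixed as CH₂O).
    """

    per_species: dict[str, float]
    fixed_carbon: float = 4.0
    name: str = "custom"

    def __post_init__(self) -> None:
        for sp, c in self.per_species.items():
            if c <= 0:
                raise ValueError(f"coefficient for {sp!r} must be positive")
        if self.fixed_carbon <= 0:
            raise ValueError("fixed_carbon coefficient must be positive")

    def __getitem__(self, species: str) -> float:
        try:
            return self.per_species[species]
        except KeyError:
            raise KeyError(
                f"no electron coefficient for {species!r}; known species: "
                f"{sorted(self.per_species)}"
            ) from None


#: Total-charge-state coefficients used in the balance table.
PAPER_COEFFS = ElectronCoefficients(
    per_species={"acetate": 8, "formate": 1, "propionate": 13,
                 "h2": 2, "glycogen": 24},
    fixed_carbon=4.0, name="paper")

#: Strict redox-bookkeeping alternative (formate 2, propionate 14).
REDOX_COEFFS = ElectronCoefficients(
    per_species={"acetate": 8, "formate": 2, "propionate": 14,
                 "h2": 2, "glycogen": 24},
    fixed_carbon=4.0, name="redox")

COEFF_PRESETS = {"paper": PAPER_COEFFS, "redox": REDOX_COEFFS}


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round half away from zero (presentation rounding for reports)."""
    factor = 10.0**decimals
    return float(np.sign(x) * np.floor(abs(x) * factor + 0.5) / factor)


def diel_average(day_value: float, day_sd: float,
                 night_value: float, night_sd: float,
                 sd_method: str = "mean_sd") -> tuple[float, float]:
    """Average of |day| and |night| fluxes with combined SD.

    The diel average treats uptake and release magnitudes
    symmetrically: avg = (|day| + |night|)/2.  The default SD combines
    day/night SDs by their arithmetic mean; ``quadrature`` combines as
    √(sd_d² + sd_n²)/2 instead.
    """
    if day_sd < 0 or night_sd < 0:
        raise ValueError("standard deviations must be >= 0")
    avg = (abs(day_value) + abs(night_value)) / 2.0
    if sd_method == "mean_sd":
        sd = (day_sd + night_sd) / 2.0
    elif sd_method == "quadrature":
        sd = float(np.hypot(day_sd, night_sd)) / 2.0
    else:
        raise ValueError(f"unknown sd_method {sd_method!r}")
    return avg, sd


def electron_equivalents(species: str, amount_mmol_m2: float,
                         coeffs: ElectronCoefficients = PAPER_COEFFS) -> float:
    """Convert an areal amount (mmol m⁻²) to mmol e⁻ m⁻²."""
    return amount_mmol_m2 * coeffs[species]


@dataclass(frozen=True)
class BalanceRow:
    species: str
    category: str  # "fixed_c" | "storage" | "net" | "total"
    day_flux: float | None
    day_sd: float | None
    night_flux: float | None
    night_sd: float | None
    diel_avg: float
    diel_avg_sd: float
    e_coeff: float
    e_flux: float
    e_flux_sd: float


@dataclass(frozen=True)
class ElectronBalanceTable:
    rows: tuple[BalanceRow, ...]
    pct_fermented: float
    pct_fermented_sd: float
    pct_accessory: float
    pct_accessory_sd: float
    sd_method: str
    coeffs: ElectronCoefficients

    def row(self, species: str, category: str) -> BalanceRow:
        for r in self.rows:
            if r.species == species and r.category == category:
                return r
        raise KeyError(f"no row for species={species!r} category={category!r}")

    @property
    def fixed_c_e_flux(self) -> float:
        return self.row("fixed_c", "fixed_c").e_flux

    def to_dataframe(self):
        import pandas as pd

        df = pd.DataFrame([vars(r) for r in self.rows])
        return df

    def format_text(self) -> str:
        """Human-readable balance report, rounded to 1 decimal."""
        lines = [
            f"{'Species':<18}{'Cat.':<9}{'Day':>9}{'Night':>9}"
            f"{'Diel avg (SD)':>17}{'e-':>5}{'e- flux (SD)':>17}",
        ]
        fmt = lambda v: "-" if v is None else f"{round_half_up(v):.1f}"
        for r in self.rows:
            lines.append(
                f"{r.species:<18}{r.category:<9}{fmt(r.day_flux):>9}"
                f"{fmt(r.night_flux):>9}"
                f"{round_half_up(r.diel_avg):>9.1f} ({round_half_up(r.diel_avg_sd):.1f})"
                f"{r.e_coeff:>5.0f}"
                f"{round_half_up(r.e_flux):>9.1f} ({round_half_up(r.e_flux_sd):.1f})"
            )
        lines.append(
            f"% fixed e- fermented: {round_half_up(self.pct_fermented):.1f} "
            f"({round_half_up(self.pct_fermented_sd):.1f})")
        lines.append(
            f"% fixed e- taken up by accessory microbes: "
            f"{round_half_up(self.pct_accessory):.1f} "
            f"({round_half_up(self.pct_accessory_sd):.1f})")
        return "\n".join(lines)


def _product_row(species: str, category: str, flux: AreaFlux,
                 coeffs: ElectronCoefficients, sd_method: str) -> BalanceRow:
    # fermentation products accumulate at night only; diel avg is the
    # night flux magnitude
    avg, sd = abs(flux.flux_mmol_m2), flux.sd_mmol_m2
    coeff = coeffs[species]
    return BalanceRow(species=species, category=category,
                      day_flux=None, day_sd=None,
                      night_flux=flux.flux_mmol_m2, night_sd=flux.sd_mmol_m2,
                      diel_avg=avg, diel_avg_sd=sd,
                      e_coeff=coeff, e_flux=avg * coeff, e_flux_sd=sd * coeff)


def build_balance_table(fixed_c: tuple[AreaFlux, AreaFlux],
                        glycogen: tuple[AreaFlux, AreaFlux] | None,
                        net_products: dict[str, AreaFlux],
                        total_products: dict[str, AreaFlux],
                        coeffs: ElectronCoefficients = PAPER_COEFFS,
                        sd_method: str = "mean_sd") -> ElectronBalanceTable:
    """Assemble the full diel electron balance table.

    Parameters
    ----------
    fixed_c
        (day, night) DIC fluxes in mmol C m⁻² (day negative = uptake).
    glycogen
        (day, night) storage changes in mmol glucosyl m⁻², or None.
        The glycogen row is informational: it does not enter the
        percentage statistics (the DIC-derived fixed-C flux is the
        denominator throughout).
    net_products, total_products
        Nighttime product fluxes from intact (net) and disrupted
        (total) microcosms, keyed by species.
    """
    if fixed_c is None:
        raise ValueError("fixed-C (DIC) day/night fluxes are required: they "
                         "define the percentage denominator")
    missing = set(net_products) - set(total_products)
    if missing:
        raise ValueError(f"species in net but not total: {sorted(missing)}")
    for sp in net_products:
        if abs(total_products[sp].flux_mmol_m2) < abs(net_products[sp].flux_mmol_m2):
            logger.warning(
                "total flux for %s (%.3g) below net flux (%.3g); "
                "possible replicate noise", sp,
                total_products[sp].flux_mmol_m2, net_products[sp].flux_mmol_m2)

    day, night = fixed_c
    avg, sd = diel_average(day.flux_mmol_m2, day.sd_mmol_m2,
                           night.flux_mmol_m2, night.sd_mmol_m2, sd_method)
    rows: list[BalanceRow] = [BalanceRow(
        species="fixed_c", category="fixed_c",
        day_flux=day.flux_mmol_m2, day_sd=day.sd_mmol_m2,
        night_flux=night.flux_mmol_m2, night_sd=night.sd_mmol_m2,
        diel_avg=avg, diel_avg_sd=sd, e_coeff=coeffs.fixed_carbon,
        e_flux=avg * coeffs.fixed_carbon, e_flux_sd=sd * coeffs.fixed_carbon)]

    if glycogen is not None:
        gday, gnight = glycogen
        gavg, gsd = diel_average(gday.flux_mmol_m2, gday.sd_mmol_m2,
                                 gnight.flux_mmol_m2, gnight.sd_mmol_m2,
                                 sd_method)
        coeff = coeffs["glycogen"]
        rows.append(BalanceRow(
            species="glycogen", category="storage",
            day_flux=gday.flux_mmol_m2, day_sd=gday.sd_mmol_m2,
            night_flux=gnight.flux_mmol_m2, night_sd=gnight.sd_mmol_m2,
            diel_avg=gavg, diel_avg_sd=gsd, e_coeff=coeff,
            e_flux=gavg * coeff, e_flux_sd=gsd * coeff))

    for sp in net_products:
        rows.append(_product_row(sp, "net", net_products[sp], coeffs, sd_method))
    for sp in total_products:
        rows.append(_product_row(sp, "total", total_products[sp], coeffs,
                                 sd_method))

    table = ElectronBalanceTable(
        rows=tuple(rows), pct_fermented=0.0, pct_fermented_sd=0.0,
        pct_accessory=0.0, pct_accessory_sd=0.0,
        sd_method=sd_method, coeffs=coeffs)
    pf, pf_sd = percent_fermented(table, sd_method=sd_method)
    pa, pa_sd = percent_accessory(table, sd_method=sd_method)
    logger.info("balance table built: coeffs=%s sd_method=%s "
                "pct_fermented=%.1f pct_accessory=%.1f",
                coeffs.name, sd_method, pf, pa)
    return replace(table, pct_fermented=pf, pct_fermented_sd=pf_sd,
                   pct_accessory=pa, pct_accessory_sd=pa_sd)


def _sums(table: ElectronBalanceTable, category: str) -> tuple[float, float, float]:
    """(Σ e_flux, linear Σ sd, quadrature Σ sd) over a row category."""
    rows = [r for r in table.rows if r.category == category]
    total = sum(r.e_flux for r in rows)
    sd_lin = sum(r.e_flux_sd for r in rows)
    sd_quad = float(np.sqrt(sum(r.e_flux_sd**2 for r in rows)))
    return total, sd_lin, sd_quad


def _ratio_sd(num: float, num_sd: float, den: float, den_sd: float,
              sd_method: str) -> float:
    """First-order SD of 100·num/den under the chosen combination rule."""
    if num == 0:
        return 0.0
    pct = 100.0 * num / den
    if sd_method == "mean_sd":
        # linear (worst-case) combination of relative errors
        return abs(pct) * (num_sd / abs(num) + den_sd / abs(den))
    return abs(pct) * float(np.hypot(num_sd / num, den_sd / den))


def percent_fermented(table: ElectronBalanceTable,
                      sd_method: str | None = None) -> tuple[float, float]:
    """% of photosynthetically fixed e⁻ released as total fermentation products."""
    sd_method = sd_method or table.sd_method
    fixed = table.row("fixed_c", "fixed_c")
    if fixed.e_flux <= 0:
        raise ValueError("fixed-C electron flux must be positive "
                         "(zero denominator)")
    total, sd_lin, sd_quad = _sums(table, "total")
    pct = 100.0 * total / fixed.e_flux
    num_sd = sd_lin if sd_method == "mean_sd" else sd_quad
    sd = _ratio_sd(total, num_sd, fixed.e_flux, fixed.e_flux_sd, sd_method)
    return pct, sd


def percent_accessory(table: ElectronBalanceTable,
                      sd_method: str | None = None) -> tuple[float, float]:
    """% of fixed e⁻ consumed by accessory microbes (total − net products)."""
    sd_method = sd_method or table.sd_method
    fixed = table.row("fixed_c", "fixed_c")
    if fixed.e_flux <= 0:
        raise ValueError("fixed-C electron flux must be positive "
                         "(zero denominator)")
    total, t_lin, t_quad = _sums(table, "total")
    net, n_lin, n_quad = _sums(table, "net")
    diff = total - net
    if sd_method == "mean_sd":
        num_sd = t_lin + n_lin
    else:
        num_sd = float(np.hypot(t_quad, n_quad))
    pct = 100.0 * diff / fixed.e_flux
    sd = _ratio_sd(diff, num_sd, fixed.e_flux, fixed.e_flux_sd, sd_method)
    return pct, sd


def propagate_uncertainty(table: ElectronBalanceTable, method: str = "mean_sd",
                          n_draws: int = 10000,
                          seed: int | None = None) -> ElectronBalanceTable:
    """Recompute the table's SDs under a chosen propagation method.

    ``mean_sd``
        Per-row e⁻ SD = coefficient × diel-average SD; ratio statistics
        combine relative errors linearly.
    ``quadrature``
        Day/night SDs and row sums combine in quadrature; ratios use
        first-order quadrature propagation.
    ``monte_carlo``
        Day/night fluxes are resampled as independent normals with the
        stored SDs; all derived quantities are recomputed per draw and
        their SDs taken over draws.  Deterministic given ``seed``.
    """
    if method in ("mean_sd", "quadrature"):
        rows = []
        for r in table.rows:
            if r.category in ("fixed_c", "storage"):
                avg, sd = diel_average(r.day_flux, r.day_sd, r.night_flux,
                                       r.night_sd, sd_method=method)
            else:
                avg, sd = r.diel_avg, r.night_sd
            rows.append(replace(r, diel_avg=avg, diel_avg_sd=sd,
                                e_flux=avg * r.e_coeff,
                                e_flux_sd=sd * r.e_coeff))
        out = replace(table, rows=tuple(rows), sd_method=method)
        pf, pf_sd = percent_fermented(out, sd_method=method)
        pa, pa_sd = percent_accessory(out, sd_method=method)
        return replace(out, pct_fermented=pf, pct_fermented_sd=pf_sd,
                       pct_accessory=pa, pct_accessory_sd=pa_sd)
    if method != "monte_carlo":
        raise ValueError(f"unknown propagation method {method!r}")

    if n_draws < 1000:
        raise ValueError("monte_carlo requires n_draws >= 1000")
    rng = np.random.default_rng(seed)
    e_draws = []
    for r in table.rows:
        if r.category in ("fixed_c", "storage"):
            d = rng.normal(r.day_flux, r.day_sd, size=n_draws)
            n = rng.normal(r.night_flux, r.night_sd, size=n_draws)
            avg = (np.abs(d) + np.abs(n)) / 2.0
        else:
            avg = np.abs(rng.normal(r.night_flux, r.night_sd, size=n_draws))
        e_draws.append(avg * r.e_coeff)
    fixed = next(e for e, r in zip(e_draws, table.rows)
                 if r.category == "fixed_c")
    tot = sum(e for e, r in zip(e_draws, table.rows) if r.category == "total")
    net = sum(e for e, r in zip(e_draws, table.rows) if r.category == "net")
    pf_draws = 100.0 * tot / fixed
    pa_draws = 100.0 * (tot - net) / fixed
    rows = tuple(replace(r, e_flux_sd=float(np.std(e_draws[i], ddof=1)))
                 for i, r in enumerate(table.rows))
    return replace(table, rows=rows, sd_method="monte_carlo",
                   pct_fermented_sd=float(np.std(pf_draws, ddof=1)),
                   pct_accessory_sd=float(np.std(pa_draws, ddof=1)))


def stoichiometric_electron_ratio(product_stoichiometry: dict[str, float],
                                  coeffs: ElectronCoefficients,
                                  species_a: str, species_b: str) -> float:
    """Electron ratio of two products of a fermentation stoichiometry.

    E.g. glucose → 2 acetate + 2 CO₂ + 4 H₂ gives an acetate:H₂
    electron ratio of (2×8)/(4×2) = 2.
    """
    for sp in (species_a, species_b):
        if sp not in product_stoichiometry:
            raise ValueError(f"{sp!r} not in the product stoichiometry")
    num = product_stoichiometry[species_a] * coeffs[species_a]
    den = product_stoichiometry[species_b] * coeffs[species_b]
    if den == 0:
        raise ValueError(f"zero electron flux for denominator {species_b!r}")
    return num / den
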