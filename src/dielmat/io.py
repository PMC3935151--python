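"""File formats, pipeline configuration, and the end-to-end driver.

All interchange formats are plain text:

* time-series CSV — analyte, treatment, replicate, compartment,
  time_h, value, unit (ppmv for headspace; mmol_per_L otherwise);
* flux CSV — species, treatment, phase, flux_mmol_m2, sd, n;
* spot CSV — region_id, probe, treatment, counts_12C12C, counts_13C12C;
* OTU TSV — otu_id, one count column per sample, taxonomy
  (semicolon-delimited levels) last.

:func:`run_pipeline` ties the stages together: (optional) simulate →
flux → balance, plus isotope and diversity stages when their inputs
are present.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import balance as bal
from . import community as comm
from . import flux as fx
from . import isotope as iso
from . import synthetic as syn

__all__ = [
    "PipelineConfig",
    "read_timeseries_csv",
    "write_timeseries_csv",
    "read_flux_csv",
    "write_flux_csv",
    "read_spot_csv",
    "write_spot_csv",
    "read_otu_tsv",
    "write_otu_tsv",
    "write_report",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

TIMESERIES_COLUMNS = ("analyte", "treatment", "replicate", "compartment",
                      "time_h", "value", "unit")
FLUX_COLUMNS = ("species", "treatment", "phase", "flux_mmol_m2", "sd", "n")
SPOT_COLUMNS = ("region_id", "probe", "treatment",
                "counts_12C12C", "counts_13C12C")

_UNIT_FOR_COMPARTMENT = {"headspace": "ppmv", "liquid": "mmol_per_L",
                         "chamber_water": "mmol_per_L"}
_UNIT_ALIASES = {"ppm": "ppmv", "ppmv": "ppmv",
                 "mmol/l": "mmol_per_L", "mmol_per_l": "mmol_per_L"}


def _require_columns(df: pd.DataFrame, required: Sequence[str],
                     path: Path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): "
                         f"{', '.join(missing)}")


def read_timeseries_csv(path: str | Path) -> list[fx.DielTimeSeries]:
    """Parse a concentration time-series CSV into DielTimeSeries objects.

    Rows are grouped by (analyte, treatment, replicate, compartment)
    and sorted by time; malformed numeric fields are reported with
    their line numbers, and units must match the compartment.
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, TIMESERIES_COLUMNS, path)
    for col in ("time_h", "value"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            lines = [int(i) + 2 for i in bad[:5]]  # header is line 1
            raise ValueError(f"{path}: non-numeric {col!r} at line(s) {lines}")
        df[col] = coerced
    out = []
    keys = ["analyte", "treatment", "replicate", "compartment"]
    for (analyte, treatment, replicate, compartment), g in df.groupby(
            keys, sort=True):
        units = {_UNIT_ALIASES.get(str(u).strip().lower(), str(u))
                 for u in g["unit"]}
        expected = _UNIT_FOR_COMPARTMENT.get(compartment)
        if expected is None:
            raise ValueError(f"{path}: unknown compartment {compartment!r}")
        if units != {expected}:
            raise ValueError(
                f"{path}: unit mismatch for {analyte}/{compartment}: "
                f"found {sorted(units)}, expected {expected}")
        g = g.sort_values("time_h")
        out.append(fx.DielTimeSeries(
            analyte=str(analyte), treatment=str(treatment),
            replicate=str(replicate), compartment=str(compartment),
            times=g["time_h"].to_numpy(), values=g["value"].to_numpy()))
    return out


def write_timeseries_csv(series: Sequence[fx.DielTimeSeries],
                         path: str | Path) -> None:
    rows = []
    for s in series:
        unit = _UNIT_FOR_COMPARTMENT[s.compartment]
        for t, v in zip(s.times, s.values):
            rows.append({"analyte": s.analyte, "treatment": s.treatment,
                         "replicate": s.replicate,
                         "compartment": s.compartment,
                         "time_h": t, "value": repr(float(v)), "unit": unit})
    pd.DataFrame(rows, columns=TIMESERIES_COLUMNS).to_csv(path, index=False)


def write_flux_csv(fluxes: Sequence[fx.AreaFlux], path: str | Path) -> None:
    rows = [{"species": f.species, "treatment": f.treatment, "phase": f.phase,
             "flux_mmol_m2": repr(float(f.flux_mmol_m2)),
             "sd": repr(float(f.sd_mmol_m2)), "n": f.n_replicates}
            for f in fluxes]
    pd.DataFrame(rows, columns=FLUX_COLUMNS).to_csv(path, index=False)


def read_flux_csv(path: str | Path) -> list[fx.AreaFlux]:
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, FLUX_COLUMNS, path)
    return [fx.AreaFlux(species=str(r.species), phase=str(r.phase),
                        flux_mmol_m2=float(r.flux_mmol_m2),
                        sd_mmol_m2=float(r.sd), n_replicates=int(r.n),
                        treatment="" if pd.isna(r.treatment)
                        else str(r.treatment))
            for r in df.itertuples()]


def write_spot_csv(spots: Sequence[iso.IsotopeSpot], path: str | Path) -> None:
    rows = [{"region_id": s.region_id, "probe": s.probe,
             "treatment": s.treatment, "counts_12C12C": s.counts_12C12C,
             "counts_13C12C": s.counts_13C12C} for s in spots]
    pd.DataFrame(rows, columns=SPOT_COLUMNS).to_csv(path, index=False)


def read_spot_csv(path: str | Path) -> list[iso.IsotopeSpot]:
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, SPOT_COLUMNS, path)
    return [iso.IsotopeSpot(region_id=str(r.region_id), probe=str(r.probe),
                            treatment=str(r.treatment),
                            counts_12C12C=float(r.counts_12C12C),
                            counts_13C12C=float(r.counts_13C12C))
            for r in df.itertuples()]


def write_otu_tsv(table: comm.OtuTable, path: str | Path) -> None:
    df = table.counts.copy()
    df.insert(0, "otu_id", df.index)
    df["taxonomy"] = [";".join(table.taxonomy[o]) for o in table.counts.index]
    df.to_csv(path, sep="\t", index=False)


def read_otu_tsv(path: str | Path) -> comm.OtuTable:
    """First column otu_id, last column taxonomy, samples in between."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 3:
        raise ValueError(f"{path}: need otu_id, >=1 sample, and taxonomy "
                         "columns")
    if df.columns[0] != "otu_id":
        raise ValueError(f"{path}: first column must be 'otu_id'")
    if df.columns[-1] != "taxonomy":
        raise ValueError(f"{path}: last column must be 'taxonomy'")
    counts = df.iloc[:, 1:-1].copy()
    counts.index = df["otu_id"].astype(str)
    taxonomy = {str(o): tuple(str(t).split(";"))
                for o, t in zip(df["otu_id"], df["taxonomy"])}
    return comm.OtuTable(counts=counts, taxonomy=taxonomy)


def write_report(table: bal.ElectronBalanceTable, csv_path: str | Path,
                 txt_path: str | Path | None = None) -> None:
    """Write the balance table as CSV (full precision) and text (1 dp)."""
    df = table.to_dataframe()
    summary = pd.DataFrame([
        {"species": "% fixed e- fermented", "category": "summary",
         "e_flux": table.pct_fermented, "e_flux_sd": table.pct_fermented_sd},
        {"species": "% fixed e- accessory", "category": "summary",
         "e_flux": table.pct_accessory, "e_flux_sd": table.pct_accessory_sd},
    ])
    pd.concat([df, summary], ignore_index=True).to_csv(csv_path, index=False)
    if txt_path is not None:
        Path(txt_path).write_text(table.format_text() + "\n")


# --------------------------------------------------------------------------
# pipeline driver


@dataclass
class PipelineConfig:
    """Configuration for :func:`run_pipeline` (YAML-loadable)."""

    out_dir: str = "dielmat_out"
    seed: int = 0
    geometry: fx.Geometry = field(default_factory=lambda: syn.DEFAULT_GEOMETRY)
    coefficients: str = "paper"  # paper | redox | path to YAML map
    sd_method: str = "mean_sd"
    day_hours: float = 12.0
    night_hours: float = 12.0
    control_treatment: str = "control"
    total_treatment: str = "disruption"
    simulate: syn.ScenarioConfig | None = None
    timeseries_path: str | None = None
    glycogen_path: str | None = None
    spots_path: str | None = None
    otu_dna_path: str | None = None
    otu_cdna_path: str | None = None
    rarefaction_depth: int | None = None
    rarefaction_iters: int = 100
    chao1_variant: str = "classic-unless-F2-zero"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "geometry" in raw:
            raw["geometry"] = fx.Geometry(**raw["geometry"])
        if "simulate" in raw and raw["simulate"] is not None:
            sim = dict(raw["simulate"])
            for key in ("species_list", "sample_times"):
                if key in sim:
                    sim[key] = tuple(sim[key])
            if "true_fluxes" in sim:
                sim["true_fluxes"] = {k: tuple(v)
                                      for k, v in sim["true_fluxes"].items()}
            raw["simulate"] = syn.ScenarioConfig(**sim)
        return cls(**raw)

    def resolve_coefficients(self) -> bal.ElectronCoefficients:
        if self.coefficients in bal.COEFF_PRESETS:
            return bal.COEFF_PRESETS[self.coefficients]
        raw = yaml.safe_load(Path(self.coefficients).read_text())
        return bal.ElectronCoefficients(
            per_species={k: float(v) for k, v in raw["per_species"].items()},
            fixed_carbon=float(raw.get("fixed_carbon", 4.0)),
            name=str(raw.get("name", "file")))


def _stage(name: str):
    """Decorator: prefix stage failures with the stage name."""
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") \
                    from exc
        return inner
    return wrap


@_stage("simulate")
def _run_simulate(config: PipelineConfig, out: Path) -> None:
    sim = dataclasses.replace(config.simulate, seed=config.seed)
    series = syn.generate_microcosm(sim, geometry=config.geometry)
    write_timeseries_csv(series, out / "timeseries.csv")
    gday, gnight = syn.generate_glycogen(sim, seed=config.seed + 1)
    rows = [{"replicate": f"r{i + 1}", "phase": f.phase,
             "value_mmol_m2": repr(float(f.flux_mmol_m2))}
            for i, f in enumerate(gday)]
    rows += [{"replicate": f"r{i + 1}", "phase": f.phase,
              "value_mmol_m2": repr(float(f.flux_mmol_m2))}
             for i, f in enumerate(gnight)]
    pd.DataFrame(rows).to_csv(out / "glycogen.csv", index=False)
    spots = syn.generate_spots(syn.SpotScenario(seed=config.seed + 2))
    write_spot_csv(spots[0] + spots[1], out / "spots.csv")
    dna, cdna = syn.generate_otu_tables(seed=config.seed + 3)
    write_otu_tsv(dna, out / "otu_dna.tsv")
    write_otu_tsv(cdna, out / "otu_cdna.tsv")
    config.timeseries_path = str(out / "timeseries.csv")
    config.glycogen_path = str(out / "glycogen.csv")
    config.spots_path = str(out / "spots.csv")
    config.otu_dna_path = str(out / "otu_dna.tsv")
    config.otu_cdna_path = str(out / "otu_cdna.tsv")
    logger.info("simulate: wrote synthetic inputs to %s (seed=%d)",
                out, config.seed)


@_stage("flux")
def _run_flux(config: PipelineConfig, out: Path) -> list[fx.AreaFlux]:
    series = read_timeseries_csv(config.timeseries_path)
    day_window = (0.0, config.day_hours)
    night_window = (config.day_hours, config.day_hours + config.night_hours)
    grouped: dict[tuple, list[fx.AreaFlux]] = {}
    for s in series:
        if s.analyte == "dic":
            windows = [day_window, night_window]
            phases = ["day", "night"]
            for f in fx.dic_flux(s, config.geometry, windows, phases):
                grouped.setdefault((s.analyte, s.treatment, f.phase),
                                   []).append(f)
        else:
            f = fx.net_flux(s, config.geometry, night_window, phase="night")
            grouped.setdefault((s.analyte, s.treatment, "night"),
                               []).append(f)
    fluxes = [fx.aggregate_replicates(v) for v in grouped.values()]
    if config.glycogen_path:
        gdf = pd.read_csv(config.glycogen_path)
        for phase, g in gdf.groupby("phase"):
            reps = [fx.AreaFlux("glycogen", str(phase), float(v),
                                treatment=config.control_treatment)
                    for v in g["value_mmol_m2"]]
            fluxes.append(fx.aggregate_replicates(reps))
    write_flux_csv(fluxes, out / "fluxes.csv")
    logger.info("flux: %d aggregated fluxes -> %s", len(fluxes),
                out / "fluxes.csv")
    return fluxes


@_stage("balance")
def _run_balance(config: PipelineConfig, fluxes: list[fx.AreaFlux],
                 out: Path) -> bal.ElectronBalanceTable:
    coeffs = config.resolve_coefficients()

    def pick(species: str, treatment: str, phase: str) -> fx.AreaFlux | None:
        for f in fluxes:
            if (f.species == species and f.treatment == treatment
                    and f.phase == phase):
                return f
        return None

    dic_day = pick("dic", config.control_treatment, "day")
    dic_night = pick("dic", config.control_treatment, "night")
    if dic_day is None or dic_night is None:
        raise ValueError("missing DIC day/night fluxes for the control "
                         "treatment (denominator undefined)")
    gly_day = pick("glycogen", config.control_treatment, "day")
    gly_night = pick("glycogen", config.control_treatment, "night")
    glycogen = (gly_day, gly_night) if gly_day and gly_night else None
    products = sorted({f.species for f in fluxes
                       if f.species not in ("dic", "glycogen")})
    net = {sp: f for sp in products
           if (f := pick(sp, config.control_treatment, "night")) is not None}
    total = {sp: f for sp in products
             if (f := pick(sp, config.total_treatment, "night")) is not None}
    net = {sp: f for sp, f in net.items() if sp in total}
    table = bal.build_balance_table(
        fixed_c=(dic_day, dic_night), glycogen=glycogen,
        net_products=net, total_products={sp: total[sp] for sp in net},
        coeffs=coeffs, sd_method=config.sd_method)
    if config.sd_method == "monte_carlo":
        table = bal.propagate_uncertainty(table, "monte_carlo",
                                          seed=config.seed)
    write_report(table, out / "balance.csv", out / "balance.txt")
    logger.info("balance: coeffs=%s sd_method=%s pct_fermented=%.1f "
                "pct_accessory=%.1f", coeffs.name, config.sd_method,
                table.pct_fermented, table.pct_accessory)
    return table


@_stage("isotope")
def _run_isotope(config: PipelineConfig, out: Path) -> pd.DataFrame:
    spots = read_spot_csv(config.spots_path)
    by_treatment: dict[str, list[iso.IsotopeSpot]] = {}
    for s in spots:
        by_treatment.setdefault(s.treatment, []).append(s)
    if "control" not in by_treatment:
        raise ValueError("spot table has no 'control' treatment group")
    control = by_treatment.pop("control")
    rows = []
    for name, group in sorted(by_treatment.items()):
        summ = iso.enrichment_vs_control(group, control)
        deltas = iso.spot_deltas(group)
        q1, q2, q3 = np.percentile(deltas, [25, 50, 75])
        rows.append({
            "group": name, "n": summ.n_labeled,
            "delta_mean": summ.labeled_mean,
            "delta_median": summ.labeled_median,
            "q1": q1, "q3": q3,
            "control_mean": summ.control_mean,
            "mean_difference": summ.mean_difference,
            "median_difference": summ.median_difference,
            "test": summ.test.test_name, "pvalue": summ.test.pvalue,
            "significant": summ.test.significant,
            "n_outliers": int(summ.labeled_outliers.sum())})
    df = pd.DataFrame(rows)
    df.to_csv(out / "isotope_summary.csv", index=False)
    logger.info("isotope: %d group(s) compared against control", len(rows))
    return df


@_stage("diversity")
def _run_diversity(config: PipelineConfig, out: Path) -> pd.DataFrame:
    dna = read_otu_tsv(config.otu_dna_path)
    cdna = read_otu_tsv(config.otu_cdna_path)
    merged = comm.OtuTable(
        counts=pd.concat(
            [dna.counts.add_prefix("dna_"), cdna.counts.add_prefix("cdna_")],
            axis=1).fillna(0).astype(np.int64),
        taxonomy={**dna.taxonomy, **cdna.taxonomy})
    depth = config.rarefaction_depth or int(merged.depths().min())
    ests = comm.richness_summary(merged, depth=depth,
                                 n_iter=config.rarefaction_iters,
                                 seed=config.seed)
    div = pd.DataFrame([vars(e) for e in ests])
    div.to_csv(out / "diversity.csv", index=False)
    ratios, excluded = comm.expression_ratio(dna, cdna)
    ratios.to_csv(out / "expression_ratios.csv", index=False)
    excluded.to_csv(out / "expression_excluded.csv", index=False)
    logger.info("diversity: depth=%d iters=%d; %d expression ratio(s), "
                "%d excluded (chao1 variant: %s)", depth,
                config.rarefaction_iters, len(ratios), len(excluded),
                config.chao1_variant)
    return div


def run_pipeline(config: PipelineConfig) -> dict:
    """Run simulate (optional) → flux → balance (+ isotope, diversity).

    Returns a dict of stage results; all artifacts are written under
    ``config.out_dir``.  Deterministic given ``config.seed``.
    """
    if config.simulate is None and config.timeseries_path is None:
        raise ValueError("nothing to do: provide a 'simulate' scenario or a "
                         "timeseries_path input")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    if config.simulate is not None:
        _run_simulate(config, out)
    fluxes = _run_flux(config, out)
    results["fluxes"] = fluxes
    results["balance"] = _run_balance(config, fluxes, out)
    if config.spots_path:
        results["isotope"] = _run_isotope(config, out)
    if config.otu_dna_path and config.otu_cdna_path:
        results["diversity"] = _run_diversity(config, out)
    return results
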