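"""Stage orchestration: tables in, rate/quota/population/yield report out."""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import asdict
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import __version__
from .config import AnalysisConfig, ConfigError
from .energetics import (
    Reaction,
    ThermoConditions,
    biomass_yield,
    energy_flux,
    gibbs_free_energy,
)
from .isotope import NaturalAbundance
from .morphology import AllometryParams, CellShape, DEFAULT_ALLOMETRY, REDFIELD_CN, quota_from_shape
from .population import (
    c_assim_from_count_increase,
    doubling_time,
    growth_rate_counts,
    mean_abundance,
    per_cell_bulk_rate,
    population_assimilation,
    population_carbon,
)
from .rates import fit_rate
from .singlecell import cell_rates, combine_substrates
from . import tables

logger = logging.getLogger("sipcell")

__all__ = ["run_pipeline", "validate_tables", "yield_table"]


def yield_table(entries: list[Mapping[str, Any]]) -> list[dict[str, Any]]:
    """Deterministic energy-flux / biomass-yield chain for given inputs.

    Each entry provides: taxon, abundance_per_l, carbon_fg_cell,
    bulk_rate_nmol_l_d, delta_g_kj_mol, c_assim_from_n_nmol_l_d and
    optionally c_assim_measured_nmol_l_d. Returns one result row per
    entry with the energy flux and both yields.
    """
    rows = []
    for e in entries:
        flux = energy_flux(e["bulk_rate_nmol_l_d"], e["delta_g_kj_mol"])
        row = {
            "taxon": e["taxon"],
            "abundance_per_l": e.get("abundance_per_l"),
            "carbon_fg_cell": e.get("carbon_fg_cell"),
            "bulk_rate_nmol_l_d": e["bulk_rate_nmol_l_d"],
            "delta_g_kj_mol": e["delta_g_kj_mol"],
            "energy_flux_j_l_d": flux,
            "c_assim_from_n_nmol_l_d": e.get("c_assim_from_n_nmol_l_d"),
            "yield_from_n_nmol_c_per_j": None,
            "c_assim_measured_nmol_l_d": e.get("c_assim_measured_nmol_l_d"),
            "yield_measured_nmol_c_per_j": None,
        }
        if e.get("c_assim_from_n_nmol_l_d") is not None:
            row["yield_from_n_nmol_c_per_j"] = biomass_yield(e["c_assim_from_n_nmol_l_d"], flux)
        if e.get("c_assim_measured_nmol_l_d") is not None:
            row["yield_measured_nmol_c_per_j"] = biomass_yield(
                e["c_assim_measured_nmol_l_d"], flux
            )
        if row["abundance_per_l"] is not None and row["carbon_fg_cell"] is not None:
            row["population_carbon_ug_l"] = population_carbon(
                row["abundance_per_l"], row["carbon_fg_cell"]
            )
        rows.append(row)
    return rows


def validate_tables(paths: Mapping[str, str | Path]) -> list[dict[str, str]]:
    """Schema/invariant checks; returns machine-readable diagnostics.

    ``paths`` maps table kind ('roi', 'timeseries', 'counts') to a file.
    An empty list means every table passed.
    """
    diagnostics: list[dict[str, str]] = []
    readers = {
        "roi": tables.read_roi_table,
        "timeseries": tables.read_timeseries,
        "counts": tables.read_count_table,
    }
    for kind, path in paths.items():
        if kind not in readers:
            diagnostics.append({"table": kind, "error": f"unknown table kind {kind!r}"})
            continue
        if not Path(path).exists():
            diagnostics.append({"table": kind, "error": f"file not found: {path}"})
            continue
        try:
            readers[kind](path)
        except Exception as exc:  # surface the reader's message verbatim
            diagnostics.append({"table": kind, "error": str(exc)})
    return diagnostics


def _config_hash(config: AnalysisConfig) -> str:
    canonical = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def run_pipeline(config: AnalysisConfig, output_dir: str | Path | None = None) -> dict:
    """Execute rates -> cells -> quotas -> population -> energetics.

    Reads the tables named in the config, runs every stage, writes CSV
    outputs plus a JSON report to the output directory, and returns the
    report as a dict. Raises on schema violations before any output is
    written.
    """
    out_dir = Path(output_dir or config.paths.get("output_dir", "."))
    paths = {k: v for k, v in config.paths.items() if k in ("roi", "timeseries", "counts")}
    # accept the documented path keys
    key_map = {"roi_table": "roi", "timeseries": "timeseries", "counts": "counts"}
    paths = {
        key_map[k]: v for k, v in config.paths.items() if k in key_map and v is not None
    }
    diagnostics = validate_tables(paths)
    if diagnostics:
        raise ConfigError(f"input validation failed: {diagnostics}")

    alpha = config.constant("alpha", 0.05)
    threshold = config.constant("poisson_threshold", 0.05)
    cn_ratio = config.constant("cn_ratio", REDFIELD_CN)
    t_days = float(config.incubation.get("t_days", 1.0))
    allometry = AllometryParams(
        a=config.constant("allometry_a", DEFAULT_ALLOMETRY.a),
        b=config.constant("allometry_b", DEFAULT_ALLOMETRY.b),
    )
    baseline = NaturalAbundance(
        n15_fraction=config.constant("n15_natural_fraction", 0.0037),
        c13_fraction=config.constant("c13_natural_fraction", 0.0111),
    )
    growth_model = config.mode("growth_model", "linear")

    report: dict[str, Any] = {
        "schema_version": 1,
        "provenance": {
            "config_hash": _config_hash(config),
            "seed": config.seed,
            "version": __version__,
        },
        "warnings": [],
    }

    # ---- bulk rates ------------------------------------------------------
    estimates = []
    series_by_id = {}
    if "timeseries" in paths:
        series_by_id = tables.read_timeseries(paths["timeseries"])
        for inc_id in sorted(series_by_id):
            estimates.append(fit_rate(series_by_id[inc_id], alpha=alpha))
        n_below = sum(not e.detected for e in estimates)
        logger.info("bulk rates: %d incubations, %d below detection", len(estimates), n_below)
        if n_below:
            report["warnings"].append(f"{n_below} incubation(s) below detection")
    report["bulk_rates"] = [asdict(e) for e in estimates]
    rate_by_substrate = {e.substrate: e for e in estimates}

    # ---- quotas ----------------------------------------------------------
    quotas = {}
    for pop in config.populations:
        shape = CellShape(
            shape=pop["shape"], length=float(pop["length_um"]), width=float(pop["width_um"])
        )
        quotas[pop["taxon"]] = quota_from_shape(shape, allometry, cn_ratio)
    report["quotas"] = {t: asdict(q) for t, q in quotas.items()}

    # ---- single cells ----------------------------------------------------
    per_cell = []
    cell_substrates: list[str] = []
    if "roi" in paths:
        rois = tables.read_roi_table(paths["roi"])
        skipped = 0
        for roi in rois:
            if roi.taxon not in quotas:
                skipped += 1
                continue
            series = series_by_id.get(roi.incubation_id)
            if series is None:
                skipped += 1
                continue
            cell_substrates.append(series.substrate)
            per_cell.append(
                cell_rates(
                    roi,
                    label_excess=series.label_excess,
                    fg_n_cell=quotas[roi.taxon].nitrogen_fg,
                    t_days=t_days,
                    baseline=baseline,
                    threshold=threshold,
                    cn_ratio=cn_ratio,
                    growth_model=growth_model,
                    dilution_correction=float(
                        config.constants.get("dilution_correction", 1.0)
                    ),
                )
            )
        n_filtered = sum(not r.passed_filter for r in per_cell)
        logger.info(
            "cells: %d rated, %d failed the counting-error filter, %d skipped",
            len(per_cell),
            n_filtered,
            skipped,
        )
        if n_filtered:
            report["warnings"].append(f"{n_filtered} cell(s) failed the counting-error filter")
    report["cells_rated"] = len(per_cell)

    # per-taxon, per-substrate means over cells passing the filter
    cell_summary: dict[str, dict[str, float]] = {}
    if per_cell:
        df = pd.DataFrame(
            {
                "taxon": [r.taxon for r in per_cell],
                "substrate": cell_substrates,
                "n_assim_fmol": [r.n_assim_fmol for r in per_cell],
                "growth_rate": [r.growth_rate_n for r in per_cell],
                "passed": [r.passed_filter for r in per_cell],
            }
        )
        df = df[df["passed"]]
        for taxon, grp in df.groupby("taxon"):
            per_substrate = grp.groupby("substrate")["n_assim_fmol"].mean().to_dict()
            combined_n = combine_substrates(per_substrate)
            cell_summary[taxon] = {
                "per_substrate_n_assim_fmol": per_substrate,
                "combined_n_assim_fmol": combined_n,
                "combined_c_assim_fmol": combined_n * cn_ratio,
                "combined_growth_rate_d": float(
                    grp.groupby("substrate")["growth_rate"].mean().sum()
                ),
            }
    report["cell_rates_summary"] = cell_summary

    # ---- population ------------------------------------------------------
    pop_rows = []
    snapshots = {}
    if "counts" in paths:
        for snap in tables.read_count_table(paths["counts"], t_days=t_days):
            snapshots[snap.taxon] = snap
    for pop in config.populations:
        taxon = pop["taxon"]
        row: dict[str, Any] = {"taxon": taxon}
        snap = snapshots.get(taxon)
        if snap is not None:
            row["abundance_t0_per_l"] = snap.abundance_t0
            row["abundance_t1_per_l"] = snap.abundance_t1
            row["growth_rate_counts_d"] = growth_rate_counts(
                snap.abundance_t0, snap.abundance_t1, snap.t_days
            )
            row["doubling_time_d"] = doubling_time(row["growth_rate_counts_d"])
            row["mean_abundance_per_l"] = mean_abundance(snap.abundance_t0, snap.abundance_t1)
            if taxon in quotas:
                row["population_carbon_ug_l"] = population_carbon(
                    snap.abundance_t0, quotas[taxon].carbon_fg
                )
                row["c_assim_from_counts_nmol_l_d"] = c_assim_from_count_increase(
                    snap.abundance_t0, snap.abundance_t1, quotas[taxon].carbon_fg, snap.t_days
                )
        substrate = pop.get("substrate")
        if substrate and substrate in rate_by_substrate and snap is not None:
            est = rate_by_substrate[substrate]
            row["bulk_rate_nmol_l_d"] = est.rate
            row["per_cell_bulk_rate_fmol_d"] = per_cell_bulk_rate(
                max(est.rate, 0.0), row["mean_abundance_per_l"]
            )
        if taxon in cell_summary and snap is not None:
            row["population_c_assim_nmol_l_d"] = population_assimilation(
                cell_summary[taxon]["combined_c_assim_fmol"], row["mean_abundance_per_l"]
            )
        pop_rows.append(row)
    report["population"] = pop_rows

    # ---- energetics ------------------------------------------------------
    thermo = config.thermo
    cond = None
    if thermo.get("concentrations"):
        cond = ThermoConditions(
            temperature_k=float(thermo.get("temperature_k", 301.15)),
            concentrations={k: float(v) for k, v in thermo["concentrations"].items()},
            ph=float(thermo.get("ph", 8.1)),
        )
    yield_rows = []
    pop_by_taxon = {r["taxon"]: r for r in pop_rows}
    for rxn_cfg in thermo.get("reactions", []):
        taxon = rxn_cfg.get("taxon")
        if rxn_cfg.get("delta_g_kj_mol") is not None:
            dg = float(rxn_cfg["delta_g_kj_mol"])
        else:
            rxn = Reaction(
                name=rxn_cfg["name"],
                stoichiometry=rxn_cfg["stoichiometry"],
                formation_energies=rxn_cfg.get("formation_energies", {}),
            )
            if cond is None:
                raise ConfigError("thermo.concentrations required to compute delta G")
            dg = gibbs_free_energy(rxn, cond)
        row = pop_by_taxon.get(taxon, {})
        bulk = row.get("bulk_rate_nmol_l_d")
        c_assim = row.get("population_c_assim_nmol_l_d")
        entry = {
            "reaction": rxn_cfg["name"],
            "taxon": taxon,
            "delta_g_kj_mol": dg,
        }
        if bulk is not None:
            entry["energy_flux_j_l_d"] = energy_flux(max(bulk, 0.0), dg)
            if c_assim is not None and entry["energy_flux_j_l_d"] > 0:
                entry["yield_nmol_c_per_j"] = biomass_yield(c_assim, entry["energy_flux_j_l_d"])
        yield_rows.append(entry)
    report["yields"] = yield_rows

    # ---- outputs ---------------------------------------------------------
    out_dir.mkdir(parents=True, exist_ok=True)
    if estimates:
        tables.write_rate_table(estimates, out_dir / "bulk_rates.csv")
    if quotas:
        tables.write_quota_table(quotas, out_dir / "quotas.csv")
    if per_cell:
        tables.write_cell_rates(per_cell, out_dir / "cell_rates.csv")
    if pop_rows:
        pd.DataFrame(pop_rows).to_csv(out_dir / "population.csv", index=False)
    if yield_rows:
        pd.DataFrame(yield_rows).to_csv(out_dir / "yields.csv", index=False)
    (out_dir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True, default=float))
    return report
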