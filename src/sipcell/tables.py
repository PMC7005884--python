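"""Header-keyed delimited-text readers and writers for all table schemas.

Units are encoded in column names to keep them visible at the file level.
ROI tables are TSV (one row per acquisition plane); everything else is CSV.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .isotope import IonCountPair
from .morphology import CellQuota
from .population import PopulationSnapshot
from .rates import RateEstimate, TracerTimeSeries
from .singlecell import CellRates, CellROI

__all__ = [
    "ROI_COLUMNS",
    "TIMESERIES_COLUMNS",
    "COUNT_COLUMNS",
    "read_roi_table",
    "write_roi_table",
    "read_timeseries",
    "write_timeseries",
    "read_count_table",
    "write_count_table",
    "write_rate_table",
    "read_rate_table",
    "write_quota_table",
    "write_cell_rates",
]

ROI_COLUMNS = [
    "cell_id",
    "taxon",
    "plane",
    "area_um2",
    "n15_counts",
    "n14_counts",
    "c13_counts",
    "c12_counts",
    "incubation_id",
]

TIMESERIES_COLUMNS = [
    "incubation_id",
    "substrate",
    "replicate",
    "time_h",
    "product_15N_nmol_L",
    "label_excess_at_percent",
]

COUNT_COLUMNS = [
    "station",
    "depth_m",
    "taxon",
    "timepoint",
    "cells_per_ml",
    "filter_fields_counted",
]


class SchemaError(ValueError):
    """A table is missing required columns or violates an invariant."""


def _require_columns(df: pd.DataFrame, required: Sequence[str], path: str | Path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")


# ---------------------------------------------------------------- ROI table


def write_roi_table(cells: Iterable[CellROI], path: str | Path) -> None:
    rows = []
    for cell in cells:
        c_by_plane = {p.plane_index: p for p in cell.c_counts}
        for p in cell.n_counts:
            c = c_by_plane.get(p.plane_index)
            rows.append(
                {
                    "cell_id": cell.cell_id,
                    "taxon": cell.taxon,
                    "plane": p.plane_index,
                    "area_um2": cell.roi_area_um2,
                    "n15_counts": p.minor,
                    "n14_counts": p.major,
                    "c13_counts": c.minor if c else 0,
                    "c12_counts": c.major if c else 0,
                    "incubation_id": cell.incubation_id,
                }
            )
    pd.DataFrame(rows, columns=ROI_COLUMNS).to_csv(path, sep="\t", index=False)


def read_roi_table(path: str | Path) -> list[CellROI]:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ROI_COLUMNS[:6], path)
    if (df[["n15_counts", "n14_counts"]] < 0).any().any():
        raise SchemaError(f"{path}: negative ion counts")
    cells = []
    for (cell_id, _), grp in df.groupby(["cell_id", "incubation_id"], sort=True, dropna=False):
        grp = grp.sort_values("plane")
        has_c = "c13_counts" in grp.columns and "c12_counts" in grp.columns
        n_counts = [
            IonCountPair(int(r.n15_counts), int(r.n14_counts), int(r.plane))
            for r in grp.itertuples()
        ]
        c_counts = []
        if has_c and (grp["c13_counts"].sum() + grp["c12_counts"].sum()) > 0:
            c_counts = [
                IonCountPair(int(r.c13_counts), int(r.c12_counts), int(r.plane))
                for r in grp.itertuples()
            ]
        first = grp.iloc[0]
        cells.append(
            CellROI(
                cell_id=str(cell_id),
                taxon=str(first["taxon"]),
                roi_area_um2=float(first["area_um2"]),
                n_counts=n_counts,
                c_counts=c_counts,
                incubation_id=str(first["incubation_id"]) if "incubation_id" in grp.columns else "",
            )
        )
    return cells


# ---------------------------------------------------------- time series table


def write_timeseries(series: Iterable[TracerTimeSeries], path: str | Path) -> None:
    rows = []
    for s in series:
        reps = s.replicate if s.replicate is not None else [""] * len(s.times_h)
        for t, y, r in zip(s.times_h, s.product_nmol_l, reps):
            rows.append(
                {
                    "incubation_id": s.incubation_id,
                    "substrate": s.substrate,
                    "replicate": r,
                    "time_h": t,
                    "product_15N_nmol_L": y,
                    "label_excess_at_percent": s.label_excess,
                }
            )
    pd.DataFrame(rows, columns=TIMESERIES_COLUMNS).to_csv(path, index=False)


def read_timeseries(path: str | Path) -> dict[str, TracerTimeSeries]:
    df = pd.read_csv(path)
    _require_columns(df, TIMESERIES_COLUMNS[:5], path)
    out: dict[str, TracerTimeSeries] = {}
    for inc_id, grp in df.groupby("incubation_id", sort=True):
        excess = (
            float(grp["label_excess_at_percent"].iloc[0])
            if "label_excess_at_percent" in grp.columns
            else 100.0
        )
        out[str(inc_id)] = TracerTimeSeries(
            times_h=grp["time_h"].tolist(),
            product_nmol_l=grp["product_15N_nmol_L"].tolist(),
            replicate=grp["replicate"].astype(str).tolist(),
            substrate=str(grp["substrate"].iloc[0]),
            label_excess=excess,
            incubation_id=str(inc_id),
        )
    return out


# ------------------------------------------------------------- count table


def write_count_table(
    snapshots: Iterable[PopulationSnapshot],
    path: str | Path,
    station: str = "sim",
    depth_m: float = 0.0,
) -> None:
    rows = []
    for s in snapshots:
        for tp, abundance, counted in (
            ("t0", s.abundance_t0, s.counted_t0),
            ("t24", s.abundance_t1, s.counted_t1),
        ):
            rows.append(
                {
                    "station": station,
                    "depth_m": depth_m,
                    "taxon": s.taxon,
                    "timepoint": tp,
                    "cells_per_ml": abundance / 1000.0,
                    "filter_fields_counted": counted if counted is not None else "",
                }
            )
    pd.DataFrame(rows, columns=COUNT_COLUMNS).to_csv(path, index=False)


def read_count_table(path: str | Path, t_days: float = 1.0) -> list[PopulationSnapshot]:
    df = pd.read_csv(path)
    _require_columns(df, COUNT_COLUMNS[:5], path)
    if (df["cells_per_ml"] < 0).any():
        raise SchemaError(f"{path}: negative cell counts")
    out = []
    for (station, depth, taxon), grp in df.groupby(["station", "depth_m", "taxon"], sort=True):
        by_tp = {str(r.timepoint): r for r in grp.itertuples()}
        if "t0" not in by_tp or "t24" not in by_tp:
            raise SchemaError(f"{path}: {taxon} at {station}/{depth} lacks a t0/t24 pair")

        def _counted(row):
            v = getattr(row, "filter_fields_counted", None)
            try:
                return int(v) if v == v and v != "" else None  # NaN-safe
            except (TypeError, ValueError):
                return None

        out.append(
            PopulationSnapshot(
                taxon=str(taxon),
                abundance_t0=float(by_tp["t0"].cells_per_ml) * 1000.0,
                abundance_t1=float(by_tp["t24"].cells_per_ml) * 1000.0,
                t_days=t_days,
                counted_t0=_counted(by_tp["t0"]),
                counted_t1=_counted(by_tp["t24"]),
            )
        )
    return out


# ------------------------------------------------------------ result tables


def write_rate_table(estimates: Iterable[RateEstimate], path: str | Path) -> None:
    rows = [
        {
            "incubation_id": e.incubation_id,
            "substrate": e.substrate,
            "slope_nmol_L_h": e.slope,
            "slope_se_nmol_L_h": e.slope_se,
            "p_value_one_sided": e.p_value,
            "rate_nmol_L_d": e.rate,
            "rate_se_nmol_L_d": e.rate_se,
            "detected": e.detected,
            "label_excess_at_percent": e.label_excess,
            "n_obs": e.n_obs,
        }
        for e in estimates
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_rate_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_quota_table(quotas: dict[str, CellQuota], path: str | Path) -> None:
    rows = [
        {
            "taxon": taxon,
            "volume_um3": q.volume_um3,
            "carbon_fg": q.carbon_fg,
            "nitrogen_fg": q.nitrogen_fg,
            "nitrogen_fmol": q.nitrogen_fmol,
        }
        for taxon, q in quotas.items()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_cell_rates(rates: Iterable[CellRates], path: str | Path) -> None:
    rows = [
        {
            "cell_id": r.cell_id,
            "taxon": r.taxon,
            "n15_excess_at_percent": r.n15_excess,
            "c13_excess_at_percent": r.c13_excess,
            "n_assim_fg_cell_d": r.n_assim_fg,
            "n_assim_fmol_cell_d": r.n_assim_fmol,
            "c_assim_fmol_cell_d": r.c_assim_fmol,
            "growth_rate_n_d": r.growth_rate_n,
            "passed_filter": r.passed_filter,
        }
        for r in rates
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
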