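"""Station grouping and campaign summary tables.

Stations are classed as river (~0 psu), plume, or ocean by salinity
interval; day-24 changes in DOC, components C1-C6 and a_CDOM(350) are
summarized as mean +/- sd per parameter x class x treatment.  Standard
deviations are taken between stations for river and plume classes and
between replicate bottles for the (single-station) ocean class.  Spectral
slopes are summarized as absolute changes in nm^-1, never percent.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

DEFAULT_CLASS_BOUNDS = {"river_max_psu": 1.0, "plume_max_psu": 30.0}


@dataclass
class StationClass:
    label: str                       # "river" | "plume" | "ocean"
    salinity_rule: tuple[float, float]


@dataclass
class SummaryCell:
    mean: float
    sd: float | None                 # None when n == 1
    n: int
    basis: str                       # "between_stations" | "between_replicates"


def classify_station(
    salinity: float,
    rules: dict[str, float] | None = None,
) -> StationClass:
    """River below ``river_max_psu``, ocean at/above ``plume_max_psu``,
    plume in between.  Classes are disjoint and exhaustive."""
    if salinity < 0:
        raise ValueError("salinity must be nonnegative")
    rules = rules or DEFAULT_CLASS_BOUNDS
    river_max = rules["river_max_psu"]
    plume_max = rules["plume_max_psu"]
    if salinity < river_max:
        return StationClass("river", (0.0, river_max))
    if salinity < plume_max:
        return StationClass("plume", (river_max, plume_max))
    return StationClass("ocean", (plume_max, np.inf))


def _cell(values_by_station: pd.DataFrame, basis: str) -> SummaryCell:
    """Aggregate a (station, replicate, value) frame into one cell."""
    if basis == "between_stations":
        # average replicates within station first, then spread across stations
        per_station = values_by_station.groupby("station")["value"].mean()
        vals = per_station.to_numpy()
    else:
        vals = values_by_station["value"].to_numpy()
    n = vals.size
    mean = float(np.mean(vals))
    sd = float(np.std(vals, ddof=1)) if n > 1 else None
    return SummaryCell(mean=mean, sd=sd, n=n, basis=basis)


def summarize_changes(
    changes: pd.DataFrame,
    salinities: dict | pd.Series,
    parameters: list[str] | None = None,
    final_timepoint: float = 24.0,
    rules: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Campaign summary of final-timepoint changes.

    ``changes`` is tidy with columns station/treatment/replicate/parameter/
    timepoint_days/delta (percent for DOC, components and a_CDOM; absolute
    nm^-1 for slope parameters, whose names must start with ``S``).
    Empty class x treatment cells are omitted.
    """
    required = {"station", "treatment", "replicate", "parameter",
                "timepoint_days", "delta"}
    if not required <= set(changes.columns):
        raise ValueError(f"changes table must have columns {sorted(required)}")
    final = changes[changes["timepoint_days"] == final_timepoint].copy()
    final["loc"] = [
        classify_station(salinities[st], rules).label for st in final["station"]
    ]
    parameters = parameters or sorted(final["parameter"].unique())
    rows = []
    for param in parameters:
        sub = final[final["parameter"] == param]
        for (loc, treat), grp in sub.groupby(["loc", "treatment"]):
            basis = ("between_replicates" if loc == "ocean"
                     else "between_stations")
            cell = _cell(grp.rename(columns={"delta": "value"}), basis)
            rows.append({
                "parameter": param, "loc": loc, "treatment": treat,
                "mean": cell.mean, "sd": cell.sd, "n": cell.n,
                "basis": cell.basis,
                "units": "nm^-1" if param.startswith("S") else "%",
            })
    return pd.DataFrame(rows)


def format_table1(summary: pd.DataFrame) -> pd.DataFrame:
    """Pivot the tidy summary into the wide campaign-report layout:
    one row per parameter x location, one column per treatment."""
    def fmt(row):
        if row["sd"] is None or (isinstance(row["sd"], float) and np.isnan(row["sd"])):
            return f"{row['mean']:.4g}"
        return f"{row['mean']:.4g} ± {row['sd']:.4g}"

    work = summary.copy()
    work["cell"] = work.apply(fmt, axis=1)
    wide = work.pivot_table(index=["parameter", "loc"], columns="treatment",
                            values="cell", aggfunc="first")
    return wide.reset_index()


def exclude_doc_anomalies(
    doc_pairs: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop bottle DOC pairs where the final value exceeds the initial.

    ``doc_pairs`` needs columns doc_t0 and doc_t24 (plus any keys).
    Returns (retained, exclusion log).  The rule is a strict inequality.
    """
    if not {"doc_t0", "doc_t24"} <= set(doc_pairs.columns):
        raise ValueError("doc_pairs must have doc_t0 and doc_t24 columns")
    bad = doc_pairs["doc_t24"] > doc_pairs["doc_t0"]
    return (doc_pairs[~bad].reset_index(drop=True),
            doc_pairs[bad].reset_index(drop=True))
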