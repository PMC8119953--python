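"""Per-component fluorescence metrics and change statistics.

Fmax is the model peak intensity of a component in a sample (score times
the spectral loading maxima, Raman units); percent contribution divides a
sample's Fmax values by their sum; percent change relates a value at time
t to its day-0 baseline; an iterative two-sided Grubbs test screens change
populations for outliers.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .parafac import ParafacModel


@dataclass
class ChangeRecord:
    station: int | str
    treatment: str
    parameter: str          # component name or e.g. "a_cdom_300"
    timepoint_days: float
    delta_percent: float
    replicate: int | str | None = None


def fmax(model: ParafacModel, manifest: pd.DataFrame | None = None) -> pd.DataFrame:
    """Fmax table: sample x component, Raman units.

    ``Fmax(i, f) = score(i, f) * max(em_loading_f) * max(ex_loading_f)``;
    with unit-norm loadings this is the modeled peak intensity of the
    component in the sample.  Manifest columns are joined when provided.
    """
    peak = model.em_loadings.max(axis=0) * model.ex_loadings.max(axis=0)
    values = model.scores * peak[None, :]
    cols = [f"C{f+1}" for f in range(model.n_components)]
    ids = model.sample_ids or [f"sample{i:03d}" for i in range(values.shape[0])]
    table = pd.DataFrame(values, columns=cols)
    table.insert(0, "sample_id", ids)
    if manifest is not None:
        table = table.merge(manifest, on="sample_id", how="left",
                            suffixes=("", "_manifest"))
    return table


def percent_contribution(fmax_row: np.ndarray) -> np.ndarray:
    """Percent of total fluorescence per component; sums to 100."""
    row = np.asarray(fmax_row, dtype=float)
    total = row.sum()
    if total <= 0:
        raise ValueError("percent contribution undefined for an all-zero row")
    return 100.0 * row / total


def percent_change(initial: float, value: float) -> float:
    """Percent change relative to the day-0 baseline: 100*(C_t - C_0)/C_0."""
    if initial <= 0:
        raise ValueError("baseline value must be positive")
    return 100.0 * (value - initial) / initial


def _grubbs_critical(n: int, alpha: float) -> float:
    t = stats.t.ppf(1.0 - alpha / (2.0 * n), n - 2)
    return (n - 1) / np.sqrt(n) * np.sqrt(t * t / (n - 2 + t * t))


def grubbs_filter(
    deltas: np.ndarray | list[float], alpha: float = 0.05,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Iterative two-sided Grubbs outlier screen.

    Removes the most extreme value while its Grubbs statistic exceeds the
    critical value at level ``alpha``, one value per iteration.  Returns
    (retained values, removal log with test statistics).  Fewer than three
    values pass through with a warning; identical values are never removed
    (zero-variance guard).
    """
    values = np.asarray(deltas, dtype=float)
    removed_rows = []
    if values.size < 3:
        warnings.warn("Grubbs test needs n >= 3; passing data through",
                      stacklevel=2)
        return values, pd.DataFrame(columns=["value", "G", "G_critical", "n"])
    work = values.copy()
    while work.size >= 3:
        mean = work.mean()
        sd = work.std(ddof=1)
        if sd == 0:
            break
        idx = int(np.argmax(np.abs(work - mean)))
        G = abs(work[idx] - mean) / sd
        G_crit = _grubbs_critical(work.size, alpha)
        if G > G_crit:
            removed_rows.append({"value": work[idx], "G": G,
                                 "G_critical": G_crit, "n": int(work.size)})
            work = np.delete(work, idx)
        else:
            break
    return work, pd.DataFrame(removed_rows,
                              columns=["value", "G", "G_critical", "n"])


def changes_table(
    fmax_table: pd.DataFrame,
    components: list[str] | None = None,
) -> pd.DataFrame:
    """Per-bottle percent change of each component vs its day-0 value.

    Expects manifest columns station/treatment/timepoint_days/replicate in
    ``fmax_table`` (as produced by :func:`fmax` with a manifest).
    """
    required = {"station", "treatment", "timepoint_days", "replicate"}
    if not required <= set(fmax_table.columns):
        raise ValueError(f"fmax table lacks manifest columns {sorted(required)}")
    components = components or [c for c in fmax_table.columns
                                if c.startswith("C") and c[1:].isdigit()]
    rows = []
    for (st, treat, rep), grp in fmax_table.groupby(
            ["station", "treatment", "replicate"]):
        grp = grp.sort_values("timepoint_days")
        base = grp[grp["timepoint_days"] == 0]
        if base.empty:
            raise ValueError(f"no day-0 baseline for ({st}, {treat}, {rep})")
        base = base.iloc[0]
        for _, row in grp.iterrows():
            if row["timepoint_days"] == 0:
                continue
            for comp in components:
                rows.append({
                    "station": st, "treatment": treat, "replicate": rep,
                    "parameter": comp, "timepoint_days": row["timepoint_days"],
                    "delta_percent": percent_change(base[comp], row[comp]),
                })
    return pd.DataFrame(rows)


def contribution_by_salinity(
    fmax_table: pd.DataFrame,
) -> pd.DataFrame:
    """Per-station component percent contributions, ordered by salinity.

    Uses day-0 samples (field-condition proxy) averaged over replicates.
    """
    if "salinity_psu" not in fmax_table.columns:
        raise ValueError("salinity_psu missing from the table")
    components = [c for c in fmax_table.columns
                  if c.startswith("C") and c[1:].isdigit()]
    day0 = fmax_table[fmax_table.get("timepoint_days", 0) == 0] \
        if "timepoint_days" in fmax_table.columns else fmax_table
    rows = []
    for (st, sal), grp in day0.groupby(["station", "salinity_psu"]):
        mean_fmax = grp[components].mean().to_numpy()
        contrib = percent_contribution(mean_fmax)
        row = {"station": st, "salinity_psu": sal}
        row.update({c: v for c, v in zip(components, contrib)})
        rows.append(row)
    out = pd.DataFrame(rows).sort_values("salinity_psu").reset_index(drop=True)
    return out
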