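"""End-to-end pipeline: simulate/ingest -> preprocess -> PARAFAC ->
metrics -> kinetics -> summary table.

A validated configuration (unknown keys rejected) drives a fixed stage
order; every output table carries the config hash in a header comment and
a run manifest records per-file checksums so identical config+seed runs
are verifiably identical.  The single global seed is split hierarchically
per stage so stages are independently reproducible.
"""
from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import io as ckio
from .kinetics import DecaySeries, fit_decay
from .metrics import changes_table, contribution_by_salinity, fmax, grubbs_filter
from .optics import absorbance_to_absorption, fit_spectral_slope, S275_295, S350_400
from .parafac import detect_outliers, fit_parafac, select_n_components
from .synthetic import CampaignConfig, simulate_campaign
from .tables import exclude_doc_anomalies, format_table1, summarize_changes

log = logging.getLogger("cdomkit.pipeline")

__version__ = "0.1.0"


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


class CampaignOptions(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_stations: int = 10
    treatments: list[str] = ["PB", "MD0.2", "MD0.7", "MD3.0", "PB3.0"]
    noise_multiplicative: float = 0.005
    noise_additive: float = 1e-4
    replicates: dict[str, int] | None = None
    ex_step: float = 5.0     # nm, excitation grid 240-650
    em_step: float = 2.0     # nm, emission grid 300-600

    def to_campaign_config(self, seed: int) -> CampaignConfig:
        kwargs = dict(
            n_stations=self.n_stations,
            treatments=tuple(self.treatments),
            noise_multiplicative=self.noise_multiplicative,
            noise_additive=self.noise_additive,
            seed=seed,
            ex_grid=np.arange(240.0, 650.0 + self.ex_step / 2, self.ex_step),
            em_grid=np.arange(300.0, 600.0 + self.em_step / 2, self.em_step),
        )
        if self.replicates:
            kwargs["replicates"] = self.replicates
        return CampaignConfig(**kwargs)


class ParafacOptions(BaseModel):
    model_config = ConfigDict(extra="forbid")
    f_candidates: list[int] = [6]
    n_starts: int = 10
    split_starts: int = 3
    tol: float = 1e-8
    max_iter: int = 2500
    split_threshold: float = 0.95
    leverage_cut: float = 0.2


class KineticsOptions(BaseModel):
    model_config = ConfigDict(extra="forbid")
    acdom_wavelengths: list[float] = [300.0, 350.0]
    delta_aic: float = 4.0


class GroupingOptions(BaseModel):
    model_config = ConfigDict(extra="forbid")
    river_max_psu: float = 1.0
    plume_max_psu: float = 30.0


class PipelineConfig(BaseModel):
    """Schema-validated pipeline configuration (unknown keys rejected)."""

    model_config = ConfigDict(extra="forbid")
    mode: str = "synthetic"              # "synthetic" | "files"
    input_dir: str | None = None         # files mode: dataset directory
    seed: int = 0
    output_dir: str = "cdomkit_run"
    campaign: CampaignOptions = Field(default_factory=CampaignOptions)
    parafac: ParafacOptions = Field(default_factory=ParafacOptions)
    kinetics: KineticsOptions = Field(default_factory=KineticsOptions)
    grouping: GroupingOptions = Field(default_factory=GroupingOptions)
    grubbs_alpha: float = 0.05

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.model_validate(yaml.safe_load(fh) or {})

    def config_hash(self) -> str:
        # output_dir is a run location, not part of the scientific config
        doc = self.model_dump(exclude={"output_dir"})
        return hashlib.sha256(
            json.dumps(doc, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage_seeds(seed: int) -> dict[str, int]:
    children = np.random.SeedSequence(seed).spawn(4)
    names = ("simulate", "fit", "kinetics", "misc")
    return {n: int(np.random.default_rng(c).integers(2**31))
            for n, c in zip(names, children)}


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages in order; returns the run manifest dict."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    comment = f"config_hash={chash}"
    seeds = _stage_seeds(config.seed)
    stage_log: list[dict] = []
    t_start = time.time()

    def _stage(name):
        log.info("stage %s starting", name)
        stage_log.append({"stage": name, "t": time.time() - t_start})

    # --- simulate / ingest -------------------------------------------------
    _stage("simulate" if config.mode == "synthetic" else "ingest")
    try:
        if config.mode == "synthetic":
            ccfg = config.campaign.to_campaign_config(seeds["simulate"])
            campaign = simulate_campaign(ccfg)
            ds = campaign.dataset
            absorbance = campaign.absorbance
            doc = campaign.doc
            ckio.write_dataset(ds, out / "eems", header_comment=comment)
            ckio.write_absorbance_csv(absorbance, out / "absorbance.csv", comment)
            with open(out / "doc.csv", "w") as fh:
                fh.write(f"# {comment}\n")
                doc.to_csv(fh, index=False)
            campaign.truth.to_yaml(out / "ground_truth.yaml")
        else:
            if not config.input_dir:
                raise ValueError("files mode requires input_dir")
            ds = ckio.read_dataset(config.input_dir)
            absorbance = ckio.read_absorbance_csv(
                Path(config.input_dir) / "absorbance.csv")
            doc_path = Path(config.input_dir) / "doc.csv"
            doc = pd.read_csv(doc_path, comment="#") if doc_path.exists() else None
    except Exception as exc:
        raise PipelineStageError("simulate", exc) from exc

    # --- preprocess --------------------------------------------------------
    _stage("preprocess")
    # synthetic campaigns emit corrected EEMs; raw file input would carry an
    # empty state and go through the full correction chain here
    try:
        if ds.state == ():
            raise ValueError(
                "raw EEMs require per-sample blank and absorbance links; "
                "run the correction chain before assembly"
            )
    except Exception as exc:
        raise PipelineStageError("preprocess", exc) from exc

    # --- PARAFAC -----------------------------------------------------------
    _stage("fit")
    try:
        popt = config.parafac
        selected, diag = select_n_components(
            ds, popt.f_candidates, n_starts=popt.n_starts, tol=popt.tol,
            max_iter=popt.max_iter, split_threshold=popt.split_threshold,
            split_starts=popt.split_starts, seed=seeds["fit"],
        )
        fit_f = selected if selected is not None else max(popt.f_candidates)
        model = fit_parafac(ds, fit_f, n_starts=popt.n_starts, tol=popt.tol,
                            max_iter=popt.max_iter, seed=seeds["fit"])
        outliers = detect_outliers(ds, model, popt.leverage_cut)
        ckio.write_model(model, out / "model", diagnostics={
            "selected_f": selected,
            "selection_table": diag.to_dict(orient="records"),
            "outliers_flagged": outliers.flagged,
        }, header_comment=comment)
    except Exception as exc:
        raise PipelineStageError("fit", exc) from exc

    # --- metrics -----------------------------------------------------------
    _stage("metrics")
    try:
        fmax_table = fmax(model, ds.manifest)
        changes = changes_table(fmax_table)
        # a_CDOM changes at the configured wavelengths
        acdom_rows = []
        for _, row in ds.manifest.iterrows():
            sid = row["sample_id"]
            if sid not in absorbance:
                continue
            a = absorbance_to_absorption(absorbance[sid])
            for wl in config.kinetics.acdom_wavelengths:
                acdom_rows.append({
                    "station": row["station"], "treatment": row["treatment"],
                    "replicate": row["replicate"],
                    "timepoint_days": row["timepoint_days"],
                    "parameter": f"a_cdom_{int(wl)}", "value": a.value_at(wl),
                })
        acdom = pd.DataFrame(acdom_rows)
        acdom_changes = []
        if len(acdom):
            for (st, tr, rep, par), grp in acdom.groupby(
                    ["station", "treatment", "replicate", "parameter"]):
                grp = grp.sort_values("timepoint_days")
                base = grp[grp["timepoint_days"] == 0]["value"].iloc[0]
                for _, r in grp.iterrows():
                    if r["timepoint_days"] == 0:
                        continue
                    acdom_changes.append({
                        "station": st, "treatment": tr, "replicate": rep,
                        "parameter": par, "timepoint_days": r["timepoint_days"],
                        "delta_percent": 100.0 * (r["value"] - base) / base,
                    })
        # spectral-slope trajectories; changes are absolute (nm^-1)
        slope_rows = []
        for _, row in ds.manifest.iterrows():
            sid = row["sample_id"]
            if sid not in absorbance:
                continue
            a = absorbance_to_absorption(absorbance[sid])
            for name, window in (("S275_295", S275_295), ("S350_400", S350_400)):
                slope_rows.append({
                    "station": row["station"], "treatment": row["treatment"],
                    "replicate": row["replicate"],
                    "timepoint_days": row["timepoint_days"],
                    "parameter": name,
                    "value": fit_spectral_slope(a, window).S,
                })
        slopes = pd.DataFrame(slope_rows)
        slope_changes = []
        if len(slopes):
            for (st, tr, rep, par), grp in slopes.groupby(
                    ["station", "treatment", "replicate", "parameter"]):
                grp = grp.sort_values("timepoint_days")
                base = grp[grp["timepoint_days"] == 0]["value"].iloc[0]
                for _, r in grp.iterrows():
                    if r["timepoint_days"] == 0:
                        continue
                    slope_changes.append({
                        "station": st, "treatment": tr, "replicate": rep,
                        "parameter": par, "timepoint_days": r["timepoint_days"],
                        "delta_abs": r["value"] - base,
                    })
        slope_changes = pd.DataFrame(slope_changes)
        all_changes = pd.concat(
            [changes, pd.DataFrame(acdom_changes)], ignore_index=True)
        # Grubbs screen per component x treatment change population
        filtered_parts = []
        for (par, tr), grp in all_changes.groupby(["parameter", "treatment"]):
            retained, _removed = grubbs_filter(
                grp["delta_percent"].to_numpy(), config.grubbs_alpha)
            keep = grp[grp["delta_percent"].isin(retained)]
            filtered_parts.append(keep)
        filtered = pd.concat(filtered_parts, ignore_index=True)
        contributions = contribution_by_salinity(fmax_table) \
            if "salinity_psu" in fmax_table.columns else None
        for name, frame in (("fmax.csv", fmax_table),
                            ("changes.csv", filtered),
                            ("slopes.csv", slopes),
                            ("contributions.csv", contributions)):
            if frame is None:
                continue
            with open(out / name, "w") as fh:
                fh.write(f"# {comment}\n")
                frame.to_csv(fh, index=False)
    except Exception as exc:
        raise PipelineStageError("metrics", exc) from exc

    # --- kinetics ----------------------------------------------------------
    _stage("kinetics")
    try:
        kin_rows = []
        pb = ds.manifest[ds.manifest["treatment"] == "PB"]
        for wl in config.kinetics.acdom_wavelengths:
            par = f"a_cdom_{int(wl)}"
            for st, grp in pb.groupby("station"):
                series = acdom[(acdom["station"] == st)
                               & (acdom["treatment"] == "PB")
                               & (acdom["parameter"] == par)]
                mean = series.groupby("timepoint_days")["value"].mean()
                if len(mean) < 3 or mean.iloc[0] <= 0:
                    continue
                s = DecaySeries(t=mean.index.to_numpy(dtype=float),
                                y=(mean / mean.iloc[0]).to_numpy(),
                                label=f"station{st}_{par}").normalize()
                fit = fit_decay(s, delta_aic=config.kinetics.delta_aic)
                kin_rows.append({
                    "series": s.label, "model": fit.model, **{
                        f"param_{k}": v for k, v in fit.params.items()},
                    "rss": fit.rss, "aic": fit.aic,
                    "degenerate": fit.degenerate,
                })
        kinetics_df = pd.DataFrame(kin_rows)
        with open(out / "kinetics.csv", "w") as fh:
            fh.write(f"# {comment}\n")
            kinetics_df.to_csv(fh, index=False)
    except Exception as exc:
        raise PipelineStageError("kinetics", exc) from exc

    # --- summary table -----------------------------------------------------
    _stage("table")
    try:
        salinities = dict(zip(ds.manifest["station"], ds.manifest["salinity_psu"]))
        tidy = filtered.rename(columns={"delta_percent": "delta"})
        if len(slope_changes):
            tidy = pd.concat(
                [tidy, slope_changes.rename(columns={"delta_abs": "delta"})],
                ignore_index=True)
        if doc is not None and len(doc):
            doc_wide = doc.pivot_table(
                index=["station", "treatment", "replicate"],
                columns="timepoint_days", values="doc_mg_l").reset_index()
            doc_wide = doc_wide.rename(columns={0: "doc_t0", 24: "doc_t24"})
            if "doc_t24" in doc_wide.columns:
                retained_doc, _excluded = exclude_doc_anomalies(doc_wide)
                doc_changes = retained_doc.assign(
                    parameter="DOC", timepoint_days=24.0,
                    delta=100.0 * (retained_doc["doc_t24"] - retained_doc["doc_t0"])
                    / retained_doc["doc_t0"],
                )[["station", "treatment", "replicate", "parameter",
                   "timepoint_days", "delta"]]
                tidy = pd.concat([tidy, doc_changes], ignore_index=True)
        summary = summarize_changes(
            tidy, salinities,
            rules={"river_max_psu": config.grouping.river_max_psu,
                   "plume_max_psu": config.grouping.plume_max_psu})
        wide = format_table1(summary)
        for name, frame in (("summary.csv", summary), ("table1.csv", wide)):
            with open(out / name, "w") as fh:
                fh.write(f"# {comment}\n")
                frame.to_csv(fh, index=False)
    except Exception as exc:
        raise PipelineStageError("table", exc) from exc

    # --- run manifest ------------------------------------------------------
    checksums = {
        str(p.relative_to(out)): _sha256(p)
        for p in sorted(out.rglob("*"))
        if p.is_file() and p.name != "run_manifest.json"
    }
    manifest = {
        "config_hash": chash,
        "config": config.model_dump(),
        "version": __version__,
        "checksums": checksums,
        "stages": [s["stage"] for s in stage_log],
    }
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2,
                                                      default=str))
    log.info("pipeline complete: %d output files", len(checksums))
    return manifest
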