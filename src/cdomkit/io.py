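"""CSV dialects for EEMs, absorbance spectra, manifests and model exports.

EEM files are wide matrices: first column ``emission_nm``, header row the
excitation wavelengths, one file per sample.  Absorbance files are long
(wavelength_nm, absorbance, sample_id).  All round-trips are lossless to
float precision; decimal commas are rejected explicitly.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .optics import AbsorbanceSpectrum
from .parafac import ParafacModel
from .preprocess import EEM, EEMDataset

_FLOAT_FMT = "%.17g"


class ParseError(ValueError):
    """A file does not conform to the expected dialect."""


def _check_no_decimal_commas(path: Path) -> None:
    # locale dialects write ';' separators with ',' decimals; comma-decimal
    # values in a comma-separated file surface as field-count or float()
    # errors below, with messages that name the cause
    first = Path(path).read_text().splitlines()[0]
    if ";" in first:
        raise ParseError(
            f"{path}: semicolon-delimited file with locale decimal commas "
            "is not supported; use '.' decimals and ',' separators"
        )


def write_eem_csv(eem: EEM, path: str | Path, header_comment: str | None = None) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write("emission_nm," + ",".join(_FLOAT_FMT % x for x in eem.ex) + "\n")
        for j, em in enumerate(eem.em):
            row = ",".join(_FLOAT_FMT % v for v in eem.intensity[j])
            fh.write((_FLOAT_FMT % em) + "," + row + "\n")


def read_eem_csv(path: str | Path, state: tuple[str, ...] = (),
                 meta: dict | None = None) -> EEM:
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines()
             if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise ParseError(f"{path}: empty file")
    _check_no_decimal_commas(path)
    header = lines[0].split(",")
    if header[0].strip() != "emission_nm":
        raise ParseError(
            f"{path}, line 1: header must start with 'emission_nm' "
            f"(got {header[0]!r}); excitation header row missing?"
        )
    try:
        ex = np.array([float(tok) for tok in header[1:]])
    except ValueError as exc:
        raise ParseError(f"{path}, line 1: non-numeric excitation header "
                         f"({exc}); decimal commas are not supported") from exc
    em = []
    rows = []
    for lineno, line in enumerate(lines[1:], start=2):
        toks = line.split(",")
        if len(toks) != ex.size + 1:
            raise ParseError(f"{path}, line {lineno}: expected {ex.size + 1} "
                             f"fields, got {len(toks)}")
        try:
            em.append(float(toks[0]))
            rows.append([float(t) for t in toks[1:]])
        except ValueError as exc:
            raise ParseError(f"{path}, line {lineno}: non-numeric value "
                             f"({exc}); decimal commas are not supported") from exc
    em = np.array(em)
    if not np.all(np.diff(ex) > 0):
        raise ParseError(f"{path}: excitation grid not strictly increasing")
    if not np.all(np.diff(em) > 0):
        raise ParseError(f"{path}: emission grid not strictly increasing")
    return EEM(ex=ex, em=em, intensity=np.array(rows), state=state,
               meta=meta or {})


def write_absorbance_csv(spectra: dict[str, AbsorbanceSpectrum],
                         path: str | Path,
                         header_comment: str | None = None) -> None:
    frames = []
    for sid, spec in spectra.items():
        frames.append(pd.DataFrame({
            "sample_id": sid,
            "wavelength_nm": spec.wavelengths,
            "absorbance": spec.absorbance,
            "pathlength_m": spec.pathlength,
        }))
    out = pd.concat(frames, ignore_index=True)
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        out.to_csv(fh, index=False, float_format=_FLOAT_FMT)


def read_absorbance_csv(path: str | Path) -> dict[str, AbsorbanceSpectrum]:
    df = pd.read_csv(path, comment="#")
    out = {}
    for sid, grp in df.groupby("sample_id", sort=False):
        grp = grp.sort_values("wavelength_nm")
        out[str(sid)] = AbsorbanceSpectrum(
            wavelengths=grp["wavelength_nm"].to_numpy(),
            absorbance=grp["absorbance"].to_numpy(),
            pathlength=float(grp["pathlength_m"].iloc[0]),
        )
    return out


def write_dataset(ds: EEMDataset, directory: str | Path,
                  header_comment: str | None = None) -> None:
    """One EEM CSV per sample plus manifest.csv under ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for i, sid in enumerate(ds.sample_ids):
        eem = EEM(ex=ds.ex, em=ds.em, intensity=ds.tensor[i],
                  state=ds.state, meta={"sample_id": sid})
        write_eem_csv(eem, directory / f"{sid}.csv", header_comment)
    manifest = ds.manifest.copy()
    manifest["state"] = ";".join(ds.state)
    with open(directory / "manifest.csv", "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        manifest.to_csv(fh, index=False)


def read_dataset(directory: str | Path) -> EEMDataset:
    from .preprocess import assemble_dataset

    directory = Path(directory)
    manifest = pd.read_csv(directory / "manifest.csv", comment="#")
    state_col = manifest.pop("state") if "state" in manifest else None
    state = tuple(s for s in str(state_col.iloc[0]).split(";") if s) \
        if state_col is not None else ()
    eems = []
    for _, row in manifest.iterrows():
        meta = {k: row[k] for k in manifest.columns if pd.notna(row.get(k))}
        eems.append(read_eem_csv(directory / f"{row['sample_id']}.csv",
                                 state=state, meta=meta))
    return assemble_dataset(eems)


def write_model(model: ParafacModel, directory: str | Path,
                diagnostics: dict | None = None,
                header_comment: str | None = None) -> None:
    """OpenFluor-style loading export plus scores and a diagnostics report."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    F = model.n_components

    def _write(path: Path, grid: np.ndarray, loadings: np.ndarray, prefix: str):
        with open(path, "w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            fh.write("wavelength," + ",".join(f"{prefix}{f+1}" for f in range(F)) + "\n")
            for i, wl in enumerate(grid):
                fh.write((_FLOAT_FMT % wl) + "," +
                         ",".join(_FLOAT_FMT % v for v in loadings[i]) + "\n")

    _write(directory / "ex_loadings.csv", model.ex_grid, model.ex_loadings, "ex")
    _write(directory / "em_loadings.csv", model.em_grid, model.em_loadings, "em")
    scores = pd.DataFrame(model.scores,
                          columns=[f"C{f+1}" for f in range(F)])
    scores.insert(0, "sample_id", model.sample_ids or range(len(scores)))
    with open(directory / "scores.csv", "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        scores.to_csv(fh, index=False, float_format=_FLOAT_FMT)
    report = {
        "n_components": F,
        "explained_variance": model.explained_variance,
        "rss": model.rss,
        "n_iterations": model.n_iterations,
        "converged": model.converged,
        "start_seed": model.start_seed,
    }
    if diagnostics:
        report.update(diagnostics)
    (directory / "diagnostics.json").write_text(json.dumps(report, indent=2))
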