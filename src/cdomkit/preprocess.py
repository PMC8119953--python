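"""EEM correction chain and dataset assembly.

Raw excitation-emission matrices are turned into corrected, Raman-unit,
scatter-masked EEMs in a fixed order: blank subtraction -> inner-filter
correction -> Raman normalization -> scatter masking.  The order is
enforced through an append-only ``state`` tuple on each EEM; applying a
step out of order (or twice) raises :class:`StateError`.

Intensity matrices are stored emission x excitation (rows = emission
wavelengths), matching the on-disk wide-CSV layout.  Missing cells
(scatter bands) are NaN in the intensity matrix; the assembled dataset
additionally carries an explicit boolean observation mask which is the
single source of truth for downstream fits.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .optics import AbsorbanceSpectrum

STATE_ORDER = (
    "blank_subtracted",
    "ife_corrected",
    "raman_normalized",
    "scatter_masked",
)

#: Raman shift of the water OH-stretch band, nm^-1 (3400 cm^-1).
RAMAN_SHIFT = 3.4e-4


class StateError(RuntimeError):
    """A correction step was applied out of order or twice."""


class GridError(ValueError):
    """Wavelength grids do not match or do not cover a required range."""


def raman_emission(ex: np.ndarray | float) -> np.ndarray | float:
    """Emission wavelength (nm) of the water Raman band excited at ``ex``."""
    return 1.0 / (1.0 / np.asarray(ex, dtype=float) - RAMAN_SHIFT)


@dataclass
class EEM:
    """One excitation-emission matrix with its processing state.

    ``intensity`` has shape (len(em), len(ex)).
    """

    ex: np.ndarray
    em: np.ndarray
    intensity: np.ndarray
    state: tuple[str, ...] = ()
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ex = np.asarray(self.ex, dtype=float)
        self.em = np.asarray(self.em, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if not np.all(np.diff(self.ex) > 0) or not np.all(np.diff(self.em) > 0):
            raise GridError("excitation and emission grids must be strictly increasing")
        if self.intensity.shape != (self.em.size, self.ex.size):
            raise GridError(
                f"intensity shape {self.intensity.shape} != (em={self.em.size}, ex={self.ex.size})"
            )
        for step in self.state:
            if step not in STATE_ORDER:
                raise StateError(f"unknown processing step {step!r}")

    def _require_next(self, step: str) -> tuple[str, ...]:
        """State tuple after appending ``step``, enforcing the fixed order."""
        idx = STATE_ORDER.index(step)
        expected = STATE_ORDER[:idx]
        if step in self.state:
            raise StateError(f"step {step!r} already applied")
        if self.state != expected:
            raise StateError(
                f"cannot apply {step!r}: state is {self.state}, expected {expected}"
            )
        return self.state + (step,)

    def copy(self) -> "EEM":
        return EEM(self.ex.copy(), self.em.copy(), self.intensity.copy(),
                   self.state, dict(self.meta))


@dataclass
class RamanReference:
    """Integrated water Raman peak area of a blank scan."""

    raman_area: float
    ex_line: float = 350.0
    integration_em_range: tuple[float, float] = (371.0, 428.0)
    date: str | None = None

    def __post_init__(self) -> None:
        if self.raman_area <= 0:
            raise ValueError("raman_area must be positive")


def _check_grids(a: EEM, b: EEM) -> None:
    if not (np.array_equal(a.ex, b.ex) and np.array_equal(a.em, b.em)):
        raise GridError("EEM grids do not match")


def subtract_blank(sample: EEM, blank: EEM) -> EEM:
    """Subtract a same-day MilliQ blank EEM; negatives are retained."""
    _check_grids(sample, blank)
    state = sample._require_next("blank_subtracted")
    out = sample.copy()
    out.intensity = sample.intensity - blank.intensity
    out.state = state
    return out


def inner_filter_correct(
    sample: EEM,
    abs_spec: AbsorbanceSpectrum,
    total_absorbance_limit: float = 1.5,
) -> EEM:
    """Absorbance-based inner-filter correction (ABA method).

    Multiplies each cell by ``10**((A(ex)+A(em))/2)`` with ``A`` the decadal
    absorbance per cm (1-cm fluorescence cuvette assumed).  When the total
    absorbance ``A(ex)+A(em)`` exceeds ``total_absorbance_limit`` anywhere
    on the grid, the correction is applied but flagged as unreliable.
    """
    state = sample._require_next("ife_corrected")
    wl = abs_spec.wavelengths
    if sample.ex[0] < wl[0] or sample.ex[-1] > wl[-1] or \
            sample.em[0] < wl[0] or sample.em[-1] > wl[-1]:
        raise GridError("absorbance spectrum does not cover the EEM grids")
    # decadal absorbance per cm of the 1-cm fluorescence pathlength
    a_percm = abs_spec.absorbance / (abs_spec.pathlength * 100.0)
    a_ex = np.interp(sample.ex, wl, a_percm)
    a_em = np.interp(sample.em, wl, a_percm)
    total = a_em[:, None] + a_ex[None, :]
    out = sample.copy()
    out.intensity = sample.intensity * 10.0 ** (total / 2.0)
    out.state = state
    if float(np.nanmax(total)) > total_absorbance_limit:
        out.meta["ife_unreliable"] = True
        warnings.warn(
            "total absorbance exceeds %.2f; inner-filter correction unreliable"
            % total_absorbance_limit,
            stacklevel=2,
        )
    return out


def compute_raman_area(
    blank: EEM,
    ex_line: float = 350.0,
    em_range: tuple[float, float] = (371.0, 428.0),
) -> RamanReference:
    """Trapezoidal integral of the blank emission scan at ``ex_line``."""
    idx = np.where(np.isclose(blank.ex, ex_line))[0]
    if idx.size == 0:
        raise GridError(f"excitation line {ex_line} nm not on the blank grid")
    window = (blank.em >= em_range[0]) & (blank.em <= em_range[1])
    if window.sum() < 2:
        raise GridError("integration range outside the emission grid")
    scan = blank.intensity[window, idx[0]]
    area = float(np.trapezoid(scan, blank.em[window]))
    if area <= 0:
        raise ValueError("nonpositive Raman peak area")
    return RamanReference(raman_area=area, ex_line=ex_line,
                          integration_em_range=em_range,
                          date=blank.meta.get("date"))


def raman_normalize(sample: EEM, ref: RamanReference) -> EEM:
    """Divide by the blank Raman peak area; intensities become Raman Units."""
    state = sample._require_next("raman_normalized")
    out = sample.copy()
    out.intensity = sample.intensity / ref.raman_area
    out.state = state
    out.meta["units"] = "R.U."
    return out


def mask_scatter(
    sample: EEM,
    rayleigh1_width: float = 10.0,
    raman1_width: float = 5.0,
    rayleigh2_width: float = 10.0,
    raman2_width: float = 10.0,
    below_diagonal: str = "missing",
    diagonal_offset: float = 5.0,
) -> EEM:
    """Mask first/second-order Rayleigh and Raman scatter bands as missing.

    Half-widths are in nm; a width <= 0 disables that band (widths must not
    be negative).  Cells inside a band become NaN (missing, never
    interpolated).  The physically meaningless region
    ``em <= ex + diagonal_offset`` is handled per ``below_diagonal``:
    ``"missing"`` (default; the wedge violates the trilinear component
    structure, so leaving it in biases the decomposition), ``"zero"`` or
    ``"keep"``.  The masked cell fraction is recorded in
    ``meta['mask_fraction']``.
    """
    for w in (rayleigh1_width, raman1_width, rayleigh2_width, raman2_width):
        if w < 0:
            raise ValueError("scatter band widths must be nonnegative")
    if below_diagonal not in ("missing", "zero", "keep"):
        raise ValueError("below_diagonal must be 'missing', 'zero' or 'keep'")
    state = sample._require_next("scatter_masked")
    em = sample.em[:, None]
    ex = sample.ex[None, :]
    ram = raman_emission(sample.ex)[None, :]
    bands = np.zeros((sample.em.size, sample.ex.size), dtype=bool)
    if rayleigh1_width > 0:
        bands |= np.abs(em - ex) <= rayleigh1_width
    if raman1_width > 0:
        bands |= np.abs(em - ram) <= raman1_width
    if rayleigh2_width > 0:
        bands |= np.abs(em - 2.0 * ex) <= rayleigh2_width
    if raman2_width > 0:
        bands |= np.abs(em - 2.0 * ram) <= raman2_width
    out = sample.copy()
    wedge = (em - ex) <= diagonal_offset
    if below_diagonal == "missing":
        bands |= wedge
    elif below_diagonal == "zero":
        out.intensity[wedge & ~bands] = 0.0
    out.intensity[bands] = np.nan
    out.state = state
    out.meta["mask_fraction"] = float(bands.mean())
    return out


@dataclass
class EEMDataset:
    """A stack of identically gridded, identically processed EEMs.

    ``tensor`` has shape (n_samples, n_em, n_ex); ``mask`` is True where a
    cell is observed (shared across samples).  Downstream fits must consult
    ``mask`` — never the NaN pattern — so that masked cells are provably
    inert.
    """

    tensor: np.ndarray
    mask: np.ndarray
    ex: np.ndarray
    em: np.ndarray
    manifest: pd.DataFrame
    state: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.tensor.ndim != 3:
            raise ValueError("tensor must be sample x em x ex")
        n, j, k = self.tensor.shape
        if self.mask.shape != (j, k):
            raise ValueError("mask must be em x ex")
        if j != self.em.size or k != self.ex.size:
            raise ValueError("tensor dims inconsistent with grids")
        if len(self.manifest) != n:
            raise ValueError("manifest length != number of samples")

    @property
    def n_samples(self) -> int:
        return self.tensor.shape[0]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.manifest["sample_id"])

    def subset(self, indices: np.ndarray | list[int]) -> "EEMDataset":
        idx = np.asarray(indices, dtype=int)
        return EEMDataset(
            tensor=self.tensor[idx].copy(),
            mask=self.mask.copy(),
            ex=self.ex.copy(),
            em=self.em.copy(),
            manifest=self.manifest.iloc[idx].reset_index(drop=True),
            state=self.state,
        )


def assemble_dataset(samples: list[EEM]) -> EEMDataset:
    """Stack EEMs into a dataset tensor with a shared observation mask."""
    if not samples:
        raise ValueError("no samples to assemble")
    ref = samples[0]
    for i, s in enumerate(samples[1:], start=1):
        if not (np.array_equal(s.ex, ref.ex) and np.array_equal(s.em, ref.em)):
            raise GridError(f"sample {i} grid differs from sample 0")
        if s.state != ref.state:
            missing = set(ref.state).symmetric_difference(s.state)
            raise StateError(
                f"sample {i} processing state differs (steps {sorted(missing)})"
            )
    tensor = np.stack([s.intensity for s in samples])
    observed = np.isfinite(tensor)
    mask = observed[0]
    if not np.all(observed == mask[None, :, :]):
        raise ValueError("missing-value pattern differs across samples")
    rows = []
    for i, s in enumerate(samples):
        row = {"sample_id": s.meta.get("sample_id", f"sample{i:03d}")}
        for key in ("station", "salinity_psu", "treatment", "timepoint_days",
                    "replicate", "blank_id", "absorbance_id"):
            if key in s.meta:
                row[key] = s.meta[key]
        rows.append(row)
    manifest = pd.DataFrame(rows)
    return EEMDataset(tensor=tensor, mask=mask, ex=ref.ex.copy(),
                      em=ref.em.copy(), manifest=manifest, state=ref.state)
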