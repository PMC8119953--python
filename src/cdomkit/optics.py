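"""CDOM absorbance handling.

Replicate quality control, conversion of decadal absorbance to Napierian
absorption coefficients, exponential spectral-slope fits over the 275-295
and 350-400 nm windows, and SUVA254.

The absorption coefficient is ``a(lambda) = 2.303 * A(lambda) / l`` with
``A`` the (blank-corrected) decadal absorbance and ``l`` the cuvette
pathlength in meters.  Spectral slopes come from a nonlinear least-squares
fit of ``a(lambda) = a(lambda0) * exp(-S * (lambda - lambda0))`` where
``lambda0`` is the midpoint of the fit window (285 or 375 nm for the two
standard windows).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import curve_fit

#: Decadal -> Napierian conversion constant (ln 10, to field precision).
LN10 = 2.303

#: Standard slope-fit windows, nm.
S275_295 = (275.0, 295.0)
S350_400 = (350.0, 400.0)


class QualityError(ValueError):
    """All replicate scans were flagged as outliers."""


class ConvergenceError(RuntimeError):
    """A nonlinear fit failed to converge."""


@dataclass
class AbsorbanceSpectrum:
    """Decadal absorbance vs wavelength for one measurement.

    ``pathlength`` is in meters (0.05 m for a 5-cm cuvette).
    """

    wavelengths: np.ndarray
    absorbance: np.ndarray
    pathlength: float = 0.05
    replicate_id: str | None = None
    blank_corrected: bool = True
    n_retained: int | None = None

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.wavelengths.ndim != 1 or self.wavelengths.shape != self.absorbance.shape:
            raise ValueError("wavelengths and absorbance must be 1-D and equal length")
        if not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if self.pathlength <= 0:
            raise ValueError("pathlength must be positive (meters)")

    def value_at(self, wavelength: float) -> float:
        """Linearly interpolated absorbance at ``wavelength`` (nm)."""
        lo, hi = self.wavelengths[0], self.wavelengths[-1]
        if not (lo <= wavelength <= hi):
            raise ValueError(f"wavelength {wavelength} nm outside grid [{lo}, {hi}]")
        return float(np.interp(wavelength, self.wavelengths, self.absorbance))


@dataclass
class AbsorptionSpectrum:
    """Napierian CDOM absorption coefficients a_CDOM(lambda), m^-1."""

    wavelengths: np.ndarray
    a_cdom: np.ndarray

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.a_cdom = np.asarray(self.a_cdom, dtype=float)
        if self.wavelengths.shape != self.a_cdom.shape:
            raise ValueError("grid/value length mismatch")
        if not np.all(np.isfinite(self.a_cdom)):
            raise ValueError("non-finite absorption values")

    def value_at(self, wavelength: float) -> float:
        lo, hi = self.wavelengths[0], self.wavelengths[-1]
        if not (lo <= wavelength <= hi):
            raise ValueError(f"wavelength {wavelength} nm outside grid [{lo}, {hi}]")
        return float(np.interp(wavelength, self.wavelengths, self.a_cdom))


@dataclass
class SlopeFit:
    """Result of an exponential spectral-slope fit over one window."""

    S: float
    a_ref: float
    lambda0: float
    fit_range: tuple[float, float]
    rss: float
    converged: bool
    n_points: int = 0


def average_replicates(
    spectra: list[AbsorbanceSpectrum],
    qc_range: tuple[float, float] = (250.0, 500.0),
    mad_factor: float = 5.0,
) -> AbsorbanceSpectrum:
    """Average replicate scans after flagging outlying scans.

    A scan is dropped when its mean absolute deviation from the pointwise
    median spectrum (over ``qc_range``) exceeds ``mad_factor`` times the
    median of those deviations across scans.  Robust and scale-free; a
    single scan passes through unchanged.
    """
    if not spectra:
        raise ValueError("need at least one spectrum")
    first = spectra[0]
    for s in spectra[1:]:
        if not np.array_equal(s.wavelengths, first.wavelengths):
            raise ValueError("replicate scans must share a wavelength grid")
        if s.pathlength != first.pathlength:
            raise ValueError("replicate scans must share a pathlength")
    if len(spectra) == 1:
        return replace(first, n_retained=1)

    wl = first.wavelengths
    window = (wl >= qc_range[0]) & (wl <= qc_range[1])
    stack = np.stack([s.absorbance for s in spectra])
    median = np.median(stack[:, window], axis=0)
    devs = np.mean(np.abs(stack[:, window] - median), axis=1)
    med_dev = np.median(devs)
    # floor guards the all-identical case (med_dev == 0)
    keep = devs <= np.maximum(mad_factor * med_dev, 1e-10)
    if not keep.any():
        raise QualityError("all replicate scans flagged as outliers")
    mean_abs = stack[keep].mean(axis=0)
    return AbsorbanceSpectrum(
        wavelengths=wl.copy(),
        absorbance=mean_abs,
        pathlength=first.pathlength,
        blank_corrected=all(s.blank_corrected for s in spectra),
        n_retained=int(keep.sum()),
    )


def absorbance_to_absorption(spec: AbsorbanceSpectrum) -> AbsorptionSpectrum:
    """Convert decadal absorbance to Napierian absorption, a = 2.303*A/l."""
    if not spec.blank_corrected:
        raise ValueError("absorbance must be blank-corrected before conversion")
    return AbsorptionSpectrum(
        wavelengths=spec.wavelengths.copy(),
        a_cdom=LN10 * spec.absorbance / spec.pathlength,
    )


def fit_spectral_slope(
    a: AbsorptionSpectrum, fit_range: tuple[float, float]
) -> SlopeFit:
    """Fit a(lambda) = a(lambda0)*exp(-S*(lambda-lambda0)) over ``fit_range``.

    ``lambda0`` is the arithmetic mean of the window endpoints.  Unweighted
    nonlinear least squares on the absorption values; the starting point
    comes from a log-linear regression.  Nonpositive absorption inside the
    window aborts the fit (no silent masking).
    """
    lo, hi = float(fit_range[0]), float(fit_range[1])
    if lo >= hi:
        raise ValueError("fit_range must be an increasing interval")
    wl = a.wavelengths
    if lo < wl[0] or hi > wl[-1]:
        raise ValueError("fit_range outside the spectrum grid")
    window = (wl >= lo) & (wl <= hi)
    x = wl[window]
    y = a.a_cdom[window]
    if x.size < 3:
        raise ValueError("fewer than 3 points in fit range")
    if np.any(y <= 0):
        raise ValueError("nonpositive absorption inside fit range; aborting slope fit")

    lambda0 = 0.5 * (lo + hi)
    # log-linear start (exact when the spectrum is a pure exponential)
    coeffs = np.polyfit(x - lambda0, np.log(y), 1)
    s0, loga0 = -coeffs[0], coeffs[1]

    def model(lam: np.ndarray, a0: float, s: float) -> np.ndarray:
        return a0 * np.exp(-s * (lam - lambda0))

    try:
        popt, _ = curve_fit(
            model, x, y, p0=(np.exp(loga0), s0), maxfev=10000
        )
    except RuntimeError as exc:  # pragma: no cover - hard to trigger
        raise ConvergenceError(f"slope fit failed over {fit_range}") from exc
    a0_hat, s_hat = float(popt[0]), float(popt[1])
    rss = float(np.sum((y - model(x, a0_hat, s_hat)) ** 2))
    return SlopeFit(
        S=s_hat,
        a_ref=a0_hat,
        lambda0=lambda0,
        fit_range=(lo, hi),
        rss=rss,
        converged=True,
        n_points=int(x.size),
    )


def fit_spectral_slope_loglinear(
    a: AbsorptionSpectrum, fit_range: tuple[float, float]
) -> SlopeFit:
    """Log-linear slope estimate over ``fit_range`` (cross-check utility)."""
    lo, hi = float(fit_range[0]), float(fit_range[1])
    wl = a.wavelengths
    window = (wl >= lo) & (wl <= hi)
    x = wl[window]
    y = a.a_cdom[window]
    if np.any(y <= 0):
        raise ValueError("nonpositive absorption inside fit range")
    lambda0 = 0.5 * (lo + hi)
    coeffs = np.polyfit(x - lambda0, np.log(y), 1)
    s_hat, a0_hat = -float(coeffs[0]), float(np.exp(coeffs[1]))
    rss = float(np.sum((y - a0_hat * np.exp(-s_hat * (x - lambda0))) ** 2))
    return SlopeFit(S=s_hat, a_ref=a0_hat, lambda0=lambda0,
                    fit_range=(lo, hi), rss=rss, converged=True,
                    n_points=int(x.size))


def suva254(a254: float, pathlength: float, doc: float) -> float:
    """Specific UV absorbance at 254 nm, L mg-C^-1 m^-1.

    ``a254`` is decadal absorbance at 254 nm, ``pathlength`` in meters,
    ``doc`` in mg C L^-1.
    """
    if doc <= 0:
        raise ValueError("DOC concentration must be positive")
    if pathlength <= 0:
        raise ValueError("pathlength must be positive")
    return (a254 / pathlength) / doc
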