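"""Photodegradation decay kinetics.

Single- and double-exponential least-squares fits of CDOM absorption or
component-fluorescence time series, model selection between them, and the
wavelength of peak absolute absorption loss.

The double exponential is ``y(t) = a*(f1*exp(-k1 t) + (1-f1)*exp(-k2 t))``
with ``k1 >= k2 >= 0`` and ``f1`` in [0,1] — a fast photolabile pool plus
a slow pool.  The fit is multi-start over rate decades.  Selection prefers
the double model only when its AIC improvement exceeds a threshold and the
fitted pools are physically distinguishable (rates separated at least
threefold, both fractions at least 0.1); the AIC small-sample (AICc)
correction is deliberately not applied because it is degenerate for a
four-parameter model at the six-timepoint incubation schedule.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .optics import AbsorptionSpectrum


@dataclass
class DecaySeries:
    """One quantity observed over incubation time, day 0 first."""

    t: np.ndarray
    y: np.ndarray
    y0: float | None = None
    normalized: bool = False
    label: str = ""

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.t.shape != self.y.shape or self.t.ndim != 1:
            raise ValueError("t and y must be 1-D and equal length")
        if self.t[0] != 0 or not np.all(np.diff(self.t) > 0):
            raise ValueError("t must be strictly increasing from 0")
        if np.any(self.y < 0):
            raise ValueError("y must be nonnegative")

    def normalize(self) -> "DecaySeries":
        if self.normalized:
            return self
        y0 = self.y[0]
        if y0 <= 0:
            raise ValueError("cannot normalize a series with zero baseline")
        return DecaySeries(t=self.t.copy(), y=self.y / y0, y0=float(y0),
                          normalized=True, label=self.label)


@dataclass
class DecayFit:
    """Fitted decay model with its selection bookkeeping."""

    model: str                       # "single" | "double"
    params: dict = field(default_factory=dict)
    rss: float = np.nan
    dof: int = 0
    n_points: int = 0
    aic: float = np.nan
    degenerate: bool = False
    chosen: bool = False
    label: str = ""

    @property
    def n_params(self) -> int:
        return 2 if self.model == "single" else 4

    def predict(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        p = self.params
        if self.model == "single":
            return p["a"] * np.exp(-p["k"] * t)
        return p["a"] * (p["f1"] * np.exp(-p["k1"] * t)
                         + (1.0 - p["f1"]) * np.exp(-p["k2"] * t))


def _aic(rss: float, n: int, k: int) -> float:
    # RSS-based AIC; a tiny floor keeps log finite on exact fits
    return n * np.log(max(rss, 1e-300) / n) + 2 * k


def fit_single_exponential(series: DecaySeries) -> DecayFit:
    """Least-squares fit of ``y = a*exp(-k t)`` (k >= 0)."""
    if series.t.size < 3:
        raise ValueError("need at least 3 timepoints")
    t, y = series.t, series.y
    pos = y > 0
    if pos.sum() >= 2:
        slope, loga = np.polyfit(t[pos], np.log(y[pos]), 1)
        p0 = (float(np.exp(loga)), max(-float(slope), 0.0))
    else:
        p0 = (max(float(y[0]), 1e-12), 0.1)

    def resid(p):
        return p[0] * np.exp(-p[1] * t) - y

    sol = least_squares(resid, p0, bounds=([0.0, 0.0], [np.inf, np.inf]))
    a, k = float(sol.x[0]), float(sol.x[1])
    rss = float(np.sum(sol.fun ** 2))
    n = t.size
    return DecayFit(model="single", params={"a": a, "k": k}, rss=rss,
                    dof=n - 2, n_points=n, aic=_aic(rss, n, 3),
                    label=series.label)


def fit_double_exponential(
    series: DecaySeries,
    rate_ratio_floor: float = 3.0,
    fraction_floor: float = 0.1,
) -> DecayFit:
    """Multi-start least-squares fit of the two-pool decay.

    Starts sweep rate decades (k1 in {1, 0.1, ...} x k2 below it); the
    parameterization enforces k1 >= k2 >= 0 and f1 in [0,1] and the result
    is canonicalized to the fast-pool-first convention.  A fit with rates
    closer than ``rate_ratio_floor`` or a pool fraction below
    ``fraction_floor`` is flagged degenerate (indistinguishable from a
    single exponential).
    """
    if series.t.size < 5:
        raise ValueError("need at least 5 timepoints for a double exponential")
    t, y = series.t, series.y
    a0 = max(float(y[0]), 1e-12)

    def resid(p):
        a, f1, k1, k2 = p
        return a * (f1 * np.exp(-k1 * t) + (1 - f1) * np.exp(-k2 * t)) - y

    best = None
    for k1_0, k2_0 in itertools.product((2.0, 0.5, 0.1), (0.2, 0.02, 0.002)):
        if k2_0 >= k1_0:
            continue
        for f0 in (0.3, 0.6):
            sol = least_squares(
                resid, (a0, f0, k1_0, k2_0),
                bounds=([0.0, 0.0, 0.0, 0.0], [np.inf, 1.0, np.inf, np.inf]),
            )
            rss = float(np.sum(sol.fun ** 2))
            if best is None or rss < best[0]:
                best = (rss, sol.x)
    rss, x = best
    a, f1, k1, k2 = (float(v) for v in x)
    if k1 < k2:  # canonicalize: fast pool first
        k1, k2 = k2, k1
        f1 = 1.0 - f1
    degenerate = (
        (k2 > 0 and k1 < rate_ratio_floor * k2)
        or min(f1, 1.0 - f1) < fraction_floor
    )
    n = t.size
    return DecayFit(model="double",
                    params={"a": a, "f1": f1, "k1": k1, "k2": k2},
                    rss=rss, dof=n - 4, n_points=n, aic=_aic(rss, n, 5),
                    degenerate=degenerate, label=series.label)


def select_decay_model(
    single: DecayFit, double: DecayFit, delta_aic: float = 4.0,
) -> DecayFit:
    """Choose between nested decay models.

    The double exponential wins only when it is non-degenerate and its AIC
    improvement over the single model exceeds ``delta_aic``; the selection
    is invariant to rescaling of y (AIC differences depend on the RSS
    ratio only).
    """
    if single.n_points != double.n_points:
        raise ValueError("fits must be on the same series")
    prefer_double = (
        not double.degenerate
        and double.dof >= 1
        and (single.aic - double.aic) > delta_aic
    )
    chosen = double if prefer_double else single
    chosen.chosen = True
    other = single if prefer_double else double
    other.chosen = False
    return chosen


def fit_decay(series: DecaySeries, delta_aic: float = 4.0) -> DecayFit:
    """Convenience: fit both models where possible and select."""
    single = fit_single_exponential(series)
    if series.t.size < 5:
        single.chosen = True      # double under-determined: dof guard
        return single
    double = fit_double_exponential(series)
    return select_decay_model(single, double, delta_aic=delta_aic)


def peak_loss_wavelength(
    a_t0: AbsorptionSpectrum,
    a_t: AbsorptionSpectrum,
    search_range: tuple[float, float] = (250.0, 450.0),
) -> float | None:
    """Wavelength of maximum absolute absorption loss ``a_t0 - a_t``.

    Returns None when no wavelength in the range shows a positive loss;
    ties resolve to the lowest wavelength.
    """
    if not np.array_equal(a_t0.wavelengths, a_t.wavelengths):
        raise ValueError("spectra must share a grid")
    wl = a_t0.wavelengths
    window = (wl >= search_range[0]) & (wl <= search_range[1])
    loss = a_t0.a_cdom[window] - a_t.a_cdom[window]
    if loss.size == 0 or np.all(loss <= 0):
        return None
    peak = loss.max()
    # lowest wavelength among ties
    idx = int(np.flatnonzero(loss == peak)[0])
    return float(wl[window][idx])
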