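"""Enzyme-assay post-processing: calibration, initial velocities,
Michaelis-Menten fits, and turnover numbers.

Units are fixed throughout: fluorescence in RFU, product concentration in
uM, time in seconds, substrate in mM, velocity in uM/min, kcat in 1/s.
All unit conversions are centralized in :func:`turnover_number` and
:func:`initial_velocity` to avoid the x60 trap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from scipy.stats import linregress

logger = logging.getLogger(__name__)

# calibration grid of the fluorophore standard, uM
STANDARD_GRID_UM = (0.0, 2.5, 5.0, 10.0, 20.0, 30.0, 40.0, 50.0)
# default linear window of the progress curves, seconds
DEFAULT_WINDOW_S = (1620.0, 1905.0)
# substrate grid for kinetic parameter determination, mM
SUBSTRATE_GRID_MM = (0.05, 0.1, 0.2, 0.5, 1.0, 2.0, 5.0, 10.0, 15.0, 20.0)

__all__ = [
    "STANDARD_GRID_UM",
    "DEFAULT_WINDOW_S",
    "SUBSTRATE_GRID_MM",
    "ProgressCurve",
    "StandardCurve",
    "MMFit",
    "initial_velocity",
    "fit_michaelis_menten",
    "turnover_number",
]


@dataclass(frozen=True)
class ProgressCurve:
    """Blank-subtracted signal vs time (seconds, strictly increasing)."""

    time_s: np.ndarray
    signal_rfu: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.time_s, dtype=float)
        s = np.asarray(self.signal_rfu, dtype=float)
        if len(t) < 2 or len(t) != len(s):
            raise ValueError("need >= 2 matched (time, signal) points")
        if np.any(np.diff(t) <= 0):
            raise ValueError("time must be strictly increasing")
        object.__setattr__(self, "time_s", t)
        object.__setattr__(self, "signal_rfu", s)


@dataclass(frozen=True)
class StandardCurve:
    """Linear RFU-vs-concentration calibration (intercept retained since the
    standard grid includes zero)."""

    slope: float            # RFU per uM
    intercept: float        # RFU

    def __post_init__(self):
        if self.slope <= 0:
            raise ValueError("a valid calibration has positive slope")

    @classmethod
    def fit(cls, concentrations_um, signals_rfu) -> "StandardCurve":
        res = linregress(np.asarray(concentrations_um, dtype=float),
                         np.asarray(signals_rfu, dtype=float))
        return cls(slope=float(res.slope), intercept=float(res.intercept))

    def to_concentration(self, signal_rfu) -> np.ndarray:
        return (np.asarray(signal_rfu, dtype=float) - self.intercept) / self.slope


@dataclass(frozen=True)
class MMFit:
    vmax: float             # uM/min
    km: float               # mM
    rss: float
    vmax_se: float
    km_se: float


def initial_velocity(curve: ProgressCurve, calibration: StandardCurve,
                     window_s: tuple[float, float] = DEFAULT_WINDOW_S) -> float:
    """OLS slope of calibrated concentration vs time over the linear window,
    in uM/min."""
    t0, t1 = window_s
    sel = (curve.time_s >= t0) & (curve.time_s <= t1)
    if sel.sum() < 2:
        raise ValueError(
            f"window [{t0}, {t1}] s contains fewer than 2 samples")
    conc_um = calibration.to_concentration(curve.signal_rfu[sel])
    res = linregress(curve.time_s[sel], conc_um)
    return float(res.slope) * 60.0      # uM/s -> uM/min


def _mm(s, vmax, km):
    return vmax * s / (km + s)


def fit_michaelis_menten(substrate_mm, v0_um_min) -> MMFit:
    """Nonlinear least squares of v = Vmax S / (Km + S).

    Multi-start initialization from the data (Vmax0 = max v; Km0 = substrate
    at half-max, bracketed by x0.2/1/5); raises RuntimeError if no start
    converges.
    """
    s = np.asarray(substrate_mm, dtype=float)
    v = np.asarray(v0_um_min, dtype=float)
    if len(np.unique(s)) < 3:
        raise ValueError("need >= 3 distinct substrate levels")
    vmax0 = float(v.max())
    half = vmax0 / 2.0
    km0 = float(s[np.argmin(np.abs(v - half))])
    km0 = max(km0, 1e-6)
    best = None
    for fac in (1.0, 0.2, 5.0):
        try:
            popt, pcov = curve_fit(
                _mm, s, v, p0=[vmax0, km0 * fac],
                bounds=([1e-12, 1e-12], [np.inf, np.inf]), maxfev=10000)
        except RuntimeError:
            continue
        rss = float(np.sum((v - _mm(s, *popt)) ** 2))
        if best is None or rss < best[2]:
            best = (popt, pcov, rss)
    if best is None:
        raise RuntimeError("Michaelis-Menten fit failed to converge "
                           "from every start")
    (vmax, km), pcov, rss = best
    se = np.sqrt(np.diag(pcov))
    return MMFit(vmax=float(vmax), km=float(km), rss=rss,
                 vmax_se=float(se[0]), km_se=float(se[1]))


def turnover_number(vmax_um_min: float, enzyme_total_um: float) -> float:
    """kcat in 1/s from Vmax (uM/min) and total enzyme concentration (uM)."""
    if enzyme_total_um <= 0:
        raise ValueError("enzyme concentration must be positive")
    return vmax_um_min / enzyme_total_um / 60.0
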