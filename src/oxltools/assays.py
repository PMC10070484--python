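"""Thermal-shift melting curves, Gibbs–Helmholtz fits and initial rates.

A fluorescence thermal-shift experiment reports the fraction of folded
protein that survives heating to each temperature. After normalising the
signal (unheated sample = 1, background = 0), the curve is fitted with a
two-state unfolding model in which the unfolding free energy follows the
Gibbs–Helmholtz relation

    ΔG_unf(T) = ΔH·(1 − T/Tm) − ΔCp·[(Tm − T) + T·ln(T/Tm)]

with unfolding enthalpy ΔH (kcal/mol, at Tm), heat-capacity change ΔCp
(kcal/mol/K) and melting temperature Tm (K) as free parameters, and the
folded fraction f(T) = 1 / (1 + exp(−ΔG_unf/(R·T))). Ligand binding
raises the apparent Tm; ΔTm between paired curves quantifies binding.

Transport time courses are summarised by their initial velocity: an
ordinary least-squares slope over the first part of the trace (600 s by
default).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.stats import linregress

__all__ = [
    "GAS_CONSTANT_KCAL",
    "MeltingCurve",
    "GHFit",
    "RateFit",
    "normalize_curve",
    "gh_model",
    "fit_gh",
    "delta_tm",
    "initial_rate",
    "read_curve_table",
]

#: Gas constant in kcal/mol/K.
GAS_CONSTANT_KCAL = 1.987204e-3


@dataclass
class MeltingCurve:
    """Temperature–signal pairs for one condition; temperatures stored in K."""

    temperatures_k: np.ndarray
    signal: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.temperatures_k = np.asarray(self.temperatures_k, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.temperatures_k.size != self.signal.size:
            raise ValueError("temperature and signal lengths differ")
        if self.temperatures_k.size < 6:
            raise ValueError("a melting curve needs at least 6 points")
        if np.any(np.diff(self.temperatures_k) <= 0):
            raise ValueError("temperatures must be strictly increasing")

    @classmethod
    def from_celsius(cls, temperatures_c, signal, label: str = "") -> "MeltingCurve":
        return cls(np.asarray(temperatures_c, dtype=float) + 273.15, signal, label)


@dataclass
class GHFit:
    """Fitted (Tm, ΔH, ΔCp) with standard errors and convergence state."""

    tm: float  # K
    dh: float  # kcal/mol
    dcp: float  # kcal/mol/K
    se_tm: float
    se_dh: float
    se_dcp: float
    rss: float
    converged: bool
    n_points: int = 0

    def to_json(self) -> str:
        return json.dumps({
            "Tm_K": self.tm, "dH_kcal_mol": self.dh, "dCp_kcal_mol_K": self.dcp,
            "se_Tm": self.se_tm, "se_dH": self.se_dh, "se_dCp": self.se_dcp,
            "rss": self.rss, "converged": self.converged, "n_points": self.n_points,
        }, indent=2)


@dataclass
class RateFit:
    """Initial-velocity linear fit over a leading time window."""

    slope: float  # signal per second
    intercept: float
    window_s: float
    r_squared: float
    n_points: int

    def to_json(self) -> str:
        return json.dumps({
            "slope_per_s": self.slope, "intercept": self.intercept,
            "window_s": self.window_s, "r_squared": self.r_squared,
            "n_points": self.n_points,
        }, indent=2)


def normalize_curve(
    raw: np.ndarray, no_heat_value: float, background_value: float
) -> np.ndarray:
    """Anchor a raw signal to [0, 1]: unheated sample → 1, background → 0.

    Values outside [0, 1] are preserved (a warning is emitted), since
    clamping would bias the downstream fit.
    """
    if no_heat_value == background_value:
        raise ValueError("no-heat and background reference values are equal")
    out = (np.asarray(raw, dtype=float) - background_value) / (no_heat_value - background_value)
    if np.any((out < 0) | (out > 1)):
        import warnings

        warnings.warn("normalized signal has values outside [0, 1]; kept unclamped")
    return out


def gh_model(t_k, tm: float, dh: float, dcp: float = 0.0):
    """Folded fraction at temperature(s) ``t_k`` under two-state unfolding.

    ΔG_unf(T) = ΔH·(1 − T/Tm) − ΔCp·[(Tm − T) + T·ln(T/Tm)];
    f = 1 / (1 + exp(−ΔG_unf / (R·T))). At T = Tm, f = 0.5 exactly.
    """
    t_k = np.asarray(t_k, dtype=float)
    if np.any(t_k <= 0) or tm <= 0:
        raise ValueError("temperatures must be positive (Kelvin)")
    dg = dh * (1.0 - t_k / tm) - dcp * ((tm - t_k) + t_k * np.log(t_k / tm))
    # clip the exponent so extreme dH values saturate instead of overflowing
    z = np.clip(-dg / (GAS_CONSTANT_KCAL * t_k), -700, 700)
    f = 1.0 / (1.0 + np.exp(z))
    return f if f.shape else float(f)


def fit_gh(
    curve: MeltingCurve,
    fix_dcp: bool = False,
    min_transition: float = 0.3,
) -> GHFit:
    """Nonlinear least-squares Gibbs–Helmholtz fit of a normalized curve.

    The initial Tm is the temperature where the signal crosses 0.5 (linear
    interpolation), initial ΔH = 100 kcal/mol, initial ΔCp = 0. A curve
    whose signal spans less than ``min_transition`` carries no usable
    transition and returns an unconverged fit with NaN parameters. With
    ``fix_dcp`` the heat-capacity term is pinned at 0, a useful guard on
    short temperature ranges where ΔCp is ill-conditioned.
    """
    t = curve.temperatures_k
    y = curve.signal
    span = float(y.max() - y.min())
    if span < min_transition:
        return GHFit(np.nan, np.nan, np.nan, np.nan, np.nan, np.nan,
                     rss=float(np.sum((y - y.mean()) ** 2)), converged=False,
                     n_points=t.size)

    tm0 = _half_crossing(t, y)
    try:
        if fix_dcp:
            popt, pcov = curve_fit(
                lambda tt, tm, dh: gh_model(tt, tm, dh, 0.0), t, y,
                p0=[tm0, 100.0], maxfev=10000,
            )
            tm, dh = popt
            dcp = 0.0
            se = np.sqrt(np.diag(pcov))
            se_tm, se_dh, se_dcp = se[0], se[1], 0.0
            resid = y - gh_model(t, tm, dh, 0.0)
        else:
            popt, pcov = curve_fit(gh_model, t, y, p0=[tm0, 100.0, 0.0], maxfev=10000)
            tm, dh, dcp = popt
            se = np.sqrt(np.diag(pcov))
            se_tm, se_dh, se_dcp = se
            resid = y - gh_model(t, tm, dh, dcp)
    except (RuntimeError, ValueError):
        return GHFit(np.nan, np.nan, np.nan, np.nan, np.nan, np.nan,
                     rss=np.nan, converged=False, n_points=t.size)

    converged = bool(np.isfinite([tm, dh, dcp]).all()
                     and t.min() - 10.0 <= tm <= t.max() + 10.0)
    return GHFit(
        tm=float(tm), dh=float(dh), dcp=float(dcp),
        se_tm=float(se_tm), se_dh=float(se_dh), se_dcp=float(se_dcp),
        rss=float(np.sum(resid ** 2)), converged=converged, n_points=t.size,
    )


def _half_crossing(t: np.ndarray, y: np.ndarray) -> float:
    """Temperature where the signal first crosses 0.5, by linear interpolation."""
    for i in range(t.size - 1):
        y0, y1 = y[i], y[i + 1]
        if (y0 - 0.5) * (y1 - 0.5) <= 0 and y0 != y1:
            return float(t[i] + (0.5 - y0) * (t[i + 1] - t[i]) / (y1 - y0))
    return float(t[t.size // 2])


def delta_tm(fit_with_ligand: GHFit, fit_without: GHFit) -> tuple[float, float]:
    """Melting-temperature shift (K) and its propagated standard error.

    Positive values mean the ligand stabilises the protein.
    """
    if not (fit_with_ligand.converged and fit_without.converged):
        raise ValueError("delta_tm requires two converged fits")
    shift = fit_with_ligand.tm - fit_without.tm
    se = float(np.sqrt(fit_with_ligand.se_tm ** 2 + fit_without.se_tm ** 2))
    return float(shift), se


def initial_rate(
    time_s: np.ndarray, signal: np.ndarray, window_s: float = 600.0
) -> RateFit:
    """Ordinary least-squares slope over the first ``window_s`` seconds.

    The slope of the leading linear portion of a product-formation trace is
    the initial velocity of the reaction.
    """
    time_s = np.asarray(time_s, dtype=float)
    signal = np.asarray(signal, dtype=float)
    mask = time_s <= window_s
    if mask.sum() < 3:
        raise ValueError(f"need at least 3 points with t <= {window_s} s, got {mask.sum()}")
    res = linregress(time_s[mask], signal[mask])
    return RateFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        window_s=float(window_s),
        r_squared=float(res.rvalue ** 2) if np.isfinite(res.rvalue) else 0.0,
        n_points=int(mask.sum()),
    )


def read_curve_table(path: str | Path, unit: str = "K") -> tuple[np.ndarray, np.ndarray]:
    """Read a two-column delimited table (x, signal) with a header row.

    ``unit='C'`` converts the first column from Celsius to Kelvin; use
    ``unit='s'`` (no conversion) for time courses.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected at least two columns")
    x = df.iloc[:, 0].to_numpy(dtype=float)
    y = df.iloc[:, 1].to_numpy(dtype=float)
    if unit.upper() == "C":
        x = x + 273.15
    return x, y
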