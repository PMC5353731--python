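"""Eyring transition-state analysis of rate-temperature series.

The protein-gated rate follows

    k(T) = (k_B T / h) * exp(dS/R) * exp(-dH / (R T)),

so ln(k/T) is linear in 1/T with slope -dH/R and intercept
ln(k_B/h) + dS/R (transmission coefficient taken as 1; any deviation is
absorbed into dS).  Measured series level off near the physiological
temperature; the plateau is located by a continuous two-segment
(linear-then-constant in 1/T) grid search over observed temperatures.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "R_GAS",
    "KB_OVER_H",
    "RateSeries",
    "EyringFit",
    "fit_eyring",
    "detect_leveling",
    "activation_free_energy",
    "predict_ln_k_over_T",
    "read_rate_series_csv",
]

#: Molar gas constant, J mol^-1 K^-1.
R_GAS = 8.314
#: Boltzmann constant over Planck constant, K^-1 s^-1.
KB_OVER_H = 2.0836612e10


@dataclass(frozen=True)
class RateSeries:
    """(temperature K, rate s^-1) observations for one strain."""

    temperatures: np.ndarray
    rates: np.ndarray
    strain_id: str = ""
    site: str = ""
    residue: str = ""
    residue_volume: float = float("nan")  # A^3

    def __post_init__(self):
        T = np.asarray(self.temperatures, dtype=float)
        k = np.asarray(self.rates, dtype=float)
        if T.ndim != 1 or k.shape != T.shape:
            raise ValueError("temperatures and rates must be 1-D, equal length")
        if np.any(T <= 0) or np.any(k <= 0):
            raise ValueError("temperatures and rates must be positive")
        if len(np.unique(T)) != T.size:
            raise ValueError("temperatures must be distinct")
        order = np.argsort(T)
        object.__setattr__(self, "temperatures", T[order])
        object.__setattr__(self, "rates", k[order])

    def __len__(self) -> int:
        return self.temperatures.size

    @property
    def inv_T(self) -> np.ndarray:
        return 1.0 / self.temperatures

    @property
    def ln_k_over_T(self) -> np.ndarray:
        return np.log(self.rates / self.temperatures)


@dataclass(frozen=True)
class EyringFit:
    """Linear Eyring parameters: ln(k/T) = a + b * (1/T)."""

    intercept: float  # a, dimensionless
    slope: float      # b, Kelvin
    r_squared: float
    fit_range: tuple[float, float]  # (T_min, T_max) of points used
    T_break: float | None = None    # leveling-off temperature, K

    def __post_init__(self):
        if not -1e-9 <= self.r_squared <= 1 + 1e-9:
            raise ValueError("r_squared must lie in [0, 1]")
        if self.T_break is not None:
            lo, hi = self.fit_range
            if not lo <= self.T_break <= hi:
                raise ValueError("T_break must lie inside the observed range")

    @property
    def delta_H(self) -> float:
        """Activation enthalpy dH (J mol^-1)."""
        return -self.slope * R_GAS

    @property
    def delta_S(self) -> float:
        """Activation entropy dS (J mol^-1 K^-1)."""
        return (self.intercept - np.log(KB_OVER_H)) * R_GAS

    def to_dict(self) -> dict:
        return {
            "a": self.intercept,
            "b_K": self.slope,
            "delta_H_J_mol": self.delta_H,
            "delta_S_J_molK": self.delta_S,
            "r_squared": self.r_squared,
            "T_break_K": self.T_break,
            "fit_range_K": list(self.fit_range),
        }


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Least-squares line y = a + b x; returns (a, b, r_squared).

    r^2 is defined through residuals (1 - SSE/SST) with the convention that a
    perfectly fit constant series has r^2 = 1.
    """
    if np.ptp(x) == 0:
        raise np.linalg.LinAlgError("zero variance in 1/T: singular fit")
    b, a = np.polyfit(x, y, 1)
    resid = y - (a + b * x)
    sse = float(resid @ resid)
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0:
        r2 = 1.0 if sse < 1e-20 else 0.0
    else:
        r2 = max(0.0, 1.0 - sse / sst)
    return float(a), float(b), min(r2, 1.0)


def fit_eyring(series: RateSeries, exclude_above_break: bool = False) -> EyringFit:
    """OLS of ln(k/T) on 1/T over the linear regime.

    With ``exclude_above_break`` a plateau is searched first and points above
    it are dropped from the linear fit.
    """
    if len(series) < 2:
        raise ValueError("need >= 2 observations to fit the Eyring line")
    T_break = None
    T, x, y = series.temperatures, series.inv_T, series.ln_k_over_T
    if exclude_above_break:
        T_break = detect_leveling(series)
        if T_break is not None:
            keep = T <= T_break
            T, x, y = T[keep], x[keep], y[keep]
            if T.size < 2:
                raise ValueError("fewer than 2 points below the plateau")
    a, b, r2 = _ols(x, y)
    return EyringFit(intercept=a, slope=b, r_squared=r2,
                     fit_range=(float(series.temperatures.min()),
                                float(series.temperatures.max())),
                     T_break=T_break)


def detect_leveling(series: RateSeries, min_improvement: float = 0.10) -> float | None:
    """Locate the leveling-off temperature of ln(k/T), if any.

    The two-segment model is linear in 1/T below the breakpoint and constant
    above it, continuous at the break:  y = a + b * max(1/T, 1/T_break).
    Candidates are the observed temperatures (with >= 2 points on each side);
    the best candidate is reported only if it reduces the SSE of the pure
    linear fit by at least ``min_improvement`` (fractional).
    """
    if len(series) < 5:
        raise ValueError("plateau detection needs >= 5 observations")
    x, y = series.inv_T, series.ln_k_over_T

    def sse_of(z: np.ndarray) -> float:
        b, a = np.polyfit(z, y, 1)
        r = y - (a + b * z)
        return float(r @ r)

    sse_linear = sse_of(x)
    if sse_linear <= 1e-18 * max(1.0, float(y @ y)):
        return None  # already perfectly linear (includes the all-flat case)

    best_T, best_sse = None, np.inf
    for i in range(1, len(series) - 1):  # >=2 points in the cold (linear) arm
        T_c = series.temperatures[i]
        z = np.maximum(x, 1.0 / T_c)
        if np.ptp(z) == 0:
            continue
        s = sse_of(z)
        if s < best_sse:
            best_T, best_sse = float(T_c), s
    if best_T is not None and best_sse <= (1.0 - min_improvement) * sse_linear:
        return best_T
    return None


def activation_free_energy(fit: EyringFit, T: float) -> float:
    """Activation free energy dG(T) = dH - T*dS, J mol^-1."""
    if T <= 0:
        raise ValueError(f"temperature must be positive, got {T}")
    return fit.delta_H - T * fit.delta_S


def predict_ln_k_over_T(fit: EyringFit, T: float) -> float:
    """ln(k/T) on the linear Eyring segment (explicit extrapolation allowed)."""
    if np.any(np.asarray(T) <= 0):
        raise ValueError(f"temperature must be positive, got {T}")
    return fit.intercept + fit.slope / T


def read_rate_series_csv(path: str | Path | io.TextIOBase) -> list[RateSeries]:
    """Read rate series from CSV with columns
    strain, site, residue, volume_A3, temperature_K, rate_per_s."""
    df = pd.read_csv(path, comment="#")
    required = {"strain", "site", "residue", "volume_A3", "temperature_K", "rate_per_s"}
    if not required <= set(df.columns):
        raise ValueError(f"rate-series CSV must have columns {sorted(required)}")
    out = []
    for (strain, site), grp in df.groupby(["strain", "site"], sort=False):
        out.append(RateSeries(
            temperatures=grp["temperature_K"].to_numpy(),
            rates=grp["rate_per_s"].to_numpy(),
            strain_id=str(strain), site=str(site),
            residue=str(grp["residue"].iloc[0]),
            residue_volume=float(grp["volume_A3"].iloc[0]),
        ))
    return out
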