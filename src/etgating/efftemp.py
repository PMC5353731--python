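"""Effective-temperature calibration: residue volume as a thermostat.

A mutant's 298 K gating rate is placed on the extrapolated wild-type Eyring
line; the temperature at which the wild type would show that rate is the
mutant's *effective temperature* T_eff.  Across a mutant panel, inverse
effective temperature is linear in residue volume,

    1/T_eff = alpha * V_res + beta,

with 1/T in 10^3 K^-1 and V in Å³ (so T_eff = 1000 / (alpha*V + beta)).
For the printed ln(k/T_298)-vs-volume regressions the volume is expressed
in 10^3 Å³; both unit conventions are fixed here and documented.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .eyring import EyringFit
from .scales import ResidueVolumeScale, classify_group, default_scale

__all__ = [
    "VolumeRateRegression",
    "EffTempCalibration",
    "NonInvertibleError",
    "EffectiveTemperatureRangeError",
    "fit_volume_regression",
    "map_to_effective_temperature",
    "calibrate_inverse_T_vs_volume",
    "predict_effective_temperature",
    "delta_T",
    "calibrate_site",
]


class NonInvertibleError(RuntimeError):
    """Wild-type Eyring line has zero slope: cannot map rate to temperature."""


class EffectiveTemperatureRangeError(RuntimeError):
    """The mapped effective temperature is non-positive (rate off the line)."""


@dataclass(frozen=True)
class VolumeRateRegression:
    """OLS of ln(k/T_ref) on residue volume, volume in 10^3 Å³."""

    site: str
    slope: float        # per 10^3 A^3
    intercept: float
    r_squared: float
    T_ref: float        # K
    points: tuple[tuple[str, float, float], ...]  # (residue, volume A^3, ln(k/T_ref))

    def predict(self, volume_A3: float) -> float:
        return self.slope * (volume_A3 / 1000.0) + self.intercept

    def to_dict(self) -> dict:
        return {
            "site": self.site,
            "slope_per_1e3_A3": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "T_ref_K": self.T_ref,
            "points": [{"residue": r, "volume_A3": v, "ln_k_over_Tref": y}
                       for r, v, y in self.points],
        }


@dataclass(frozen=True)
class EffTempCalibration:
    """The volume -> inverse-effective-temperature map 1/T = alpha*V + beta."""

    site: str
    alpha: float  # (10^3 K^-1) per A^3
    beta: float   # 10^3 K^-1
    r_squared: float
    points: tuple[tuple[str, float, float], ...]  # (residue, volume A^3, T_eff K)

    def __post_init__(self):
        for _, v, _ in self.points:
            if self.alpha * v + self.beta <= 0:
                raise ValueError(
                    f"calibration predicts non-positive 1/T at V={v} A^3"
                )

    def to_dict(self) -> dict:
        return {
            "site": self.site,
            "alpha_per_A3_1e3K": self.alpha,
            "beta_1e3K": self.beta,
            "r_squared": self.r_squared,
            "points": [{"residue": r, "volume_A3": v, "T_eff_K": t}
                       for r, v, t in self.points],
        }


def _ols_xy(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    if np.ptp(x) == 0:
        raise np.linalg.LinAlgError("all volumes equal: singular fit")
    b, a = np.polyfit(x, y, 1)
    resid = y - (a + b * x)
    sse = float(resid @ resid)
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if sst == 0 and sse < 1e-20 else (
        0.0 if sst == 0 else max(0.0, 1.0 - sse / sst))
    return float(b), float(a), min(r2, 1.0)


def fit_volume_regression(
    points: Iterable[tuple[str, float, float]],
    site: str = "",
    T_ref: float = 298.0,
) -> VolumeRateRegression:
    """Regress ln(k/T_ref) on residue volume (expressed in 10^3 Å³).

    ``points`` are (residue, volume Å³, ln(k/T_ref)) triples.
    """
    pts = tuple((str(r), float(v), float(y)) for r, v, y in points)
    if len(pts) < 2:
        raise ValueError("need >= 2 points")
    v = np.array([p[1] for p in pts]) / 1000.0
    y = np.array([p[2] for p in pts])
    slope, intercept, r2 = _ols_xy(v, y)
    return VolumeRateRegression(site=site, slope=slope, intercept=intercept,
                                r_squared=r2, T_ref=float(T_ref), points=pts)


def map_to_effective_temperature(ln_kT_mut: float, wt_fit: EyringFit) -> float:
    """Invert the wild-type Eyring line: the T at which the wild type would
    show the mutant's ln(k/T)."""
    if wt_fit.slope == 0:
        raise NonInvertibleError("wild-type Eyring slope is zero")
    inv_T = (ln_kT_mut - wt_fit.intercept) / wt_fit.slope
    if inv_T <= 0:
        raise EffectiveTemperatureRangeError(
            f"mapped 1/T_eff = {inv_T:.4g} K^-1 is non-positive; "
            "the mutant rate lies outside the wild-type line's range"
        )
    return 1.0 / inv_T


def calibrate_inverse_T_vs_volume(
    points: Iterable[tuple[str, float, float]],
    site: str = "",
) -> EffTempCalibration:
    """OLS of 1000/T_eff on volume; (residue, volume Å³, T_eff K) points."""
    pts = tuple((str(r), float(v), float(t)) for r, v, t in points)
    if len(pts) < 2:
        raise ValueError("need >= 2 points")
    if any(t <= 0 for _, _, t in pts):
        raise ValueError("effective temperatures must be positive")
    v = np.array([p[1] for p in pts])
    y = 1000.0 / np.array([p[2] for p in pts])
    alpha, beta, r2 = _ols_xy(v, y)
    return EffTempCalibration(site=site, alpha=alpha, beta=beta,
                              r_squared=r2, points=pts)


def predict_effective_temperature(volume: float, cal: EffTempCalibration) -> float:
    """T_eff(V) = 1000 / (alpha*V + beta), Kelvin."""
    denom = cal.alpha * volume + cal.beta
    if denom <= 0:
        raise ValueError(
            f"alpha*V + beta = {denom:.4g} <= 0 at V = {volume} A^3"
        )
    return 1000.0 / denom


def delta_T(volume1: float, volume2: float, cal: EffTempCalibration) -> float:
    """Effective cooling (K) when moving from volume1 to volume2."""
    return (predict_effective_temperature(volume2, cal)
            - predict_effective_temperature(volume1, cal))


def calibrate_site(
    wt_fit: EyringFit,
    panel: Sequence[tuple[str, float, float]],
    site: str = "",
    T_ref: float = 298.0,
    scale: ResidueVolumeScale | None = None,
    groups: tuple[str, ...] = ("I",),
) -> EffTempCalibration:
    """Full mapping chain for one site.

    ``panel`` holds (residue one-letter, volume Å³, rate s^-1 at T_ref).
    Each mutant rate is converted to ln(k/T_ref), placed on the extrapolated
    wild-type line to get T_eff, and the panel is regressed per Eq. (1).
    By default only group I residues enter the calibration (the only viable
    class at the crossing-point site); pass ``groups=("I", "II")`` to keep all.
    """
    scale = scale or default_scale()
    pts = []
    for residue, volume, rate in panel:
        if classify_group(residue, scale).label not in groups:
            continue
        ln_kT = float(np.log(rate / T_ref))
        pts.append((residue, volume, map_to_effective_temperature(ln_kT, wt_fit)))
    if len(pts) < 2:
        raise ValueError("fewer than 2 panel members after group filtering")
    return calibrate_inverse_T_vs_volume(pts, site=site)
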