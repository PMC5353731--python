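"""Dynamic force spectroscopy of the d1/d2 helix pair.

Force-distance cycles pull one helix off its partner through a compliant
linker.  Ruptures appear as abrupt force drops on the retract trace; the
unbinding forces, collected over a range of loading rates, yield

* the Bell zero-force extrapolation -- mean unbinding force is linear in the
  log of the loading rate r, F* = (kBT/x_b) ln(r x_b / (k_off0 kBT)), giving
  the zero-force off-rate k_off0 and the barrier distance x_b; and
* the Dudko-Hummer-Szabo transform -- a rupture-force histogram at one
  loading rate maps bin-by-bin onto force-dependent lifetimes tau(F),
  which the nu-model

      tau(F) = tau0 (1 - nu F x / dG)^(1 - 1/nu)
               * exp(-dG [1 - (1 - nu F x / dG)^(1/nu)])        (dG in kBT)

  fits for the zero-force lifetime tau0, barrier distance x and barrier
  height dG; nu = 1/2 is the harmonic-cusp well, nu = 2/3 linear-cubic,
  and nu = 1 recovers Bell.

Forces in pN, distances in nm, loading rates in pN/s, lifetimes in s.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "KB_PN_NM",
    "ForceDistanceCycle",
    "RuptureEvent",
    "ForceHistogram",
    "BellFit",
    "DudkoFit",
    "ForceFitError",
    "detect_ruptures",
    "summarize_forces",
    "fit_bell",
    "histogram_to_lifetimes",
    "fit_dudko",
]

#: Boltzmann constant in pN nm / K.
KB_PN_NM = 1.380649e-2


class ForceFitError(RuntimeError):
    """A force-spectroscopy fit failed or produced unphysical parameters."""


@dataclass(frozen=True)
class ForceDistanceCycle:
    """Retract segment of one force-distance cycle."""

    separation: np.ndarray      # nm
    force: np.ndarray           # pN
    sweep_frequency: float      # Hz
    sweep_amplitude: float = 100.0   # nm
    spring_constant: float = 40.0    # pN / nm
    cycle_id: str = ""

    def __post_init__(self):
        s = np.asarray(self.separation, dtype=float)
        f = np.asarray(self.force, dtype=float)
        if s.ndim != 1 or f.shape != s.shape or s.size < 50:
            raise ValueError("separation/force must be equal-length 1-D, >= 50 points")
        if np.any(np.diff(s) <= 0):
            raise ValueError("separation must be monotone within the retract segment")
        object.__setattr__(self, "separation", s)
        object.__setattr__(self, "force", f)

    @property
    def loading_rate(self) -> float:
        """Nominal loading rate: spring constant x tip velocity (pN/s)."""
        velocity = 2.0 * self.sweep_amplitude * self.sweep_frequency  # nm/s
        return self.spring_constant * velocity


@dataclass(frozen=True)
class RuptureEvent:
    force: float         # pN
    loading_rate: float  # pN/s
    cycle_id: str = ""

    def __post_init__(self):
        if not (np.isfinite(self.force) and self.force > 0):
            raise ValueError(f"rupture force must be positive, got {self.force}")
        if not (np.isfinite(self.loading_rate) and self.loading_rate > 0):
            raise ValueError("loading rate must be positive")


@dataclass(frozen=True)
class ForceHistogram:
    """Unbinding forces binned at uniform 5 pN width (edges at multiples)."""

    bin_edges: np.ndarray  # pN, len = n_bins + 1
    counts: np.ndarray     # int
    loading_rate: float    # pN/s

    def __post_init__(self):
        e = np.asarray(self.bin_edges, dtype=float)
        c = np.asarray(self.counts, dtype=int)
        if c.size != e.size - 1:
            raise ValueError("counts must have one fewer entry than edges")
        w = np.diff(e)
        if np.any(w <= 0) or not np.allclose(w, w[0]):
            raise ValueError("bin edges must increase with constant spacing")
        if np.any(c < 0):
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "bin_edges", e)
        object.__setattr__(self, "counts", c)

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    @property
    def midpoints(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def n_total(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class BellFit:
    k_off0: float       # s^-1
    x_beta: float       # nm
    temperature: float  # K

    def __post_init__(self):
        if self.k_off0 <= 0 or self.x_beta <= 0:
            raise ValueError("Bell parameters must be positive")

    def to_dict(self) -> dict:
        return {"k_off0_per_s": self.k_off0, "x_beta_nm": self.x_beta,
                "temperature_K": self.temperature}


@dataclass(frozen=True)
class DudkoFit:
    tau0: float         # s
    x_dagger: float     # nm
    delta_G: float      # in kB*T units
    nu: float
    temperature: float  # K

    def __post_init__(self):
        if min(self.tau0, self.x_dagger, self.delta_G) <= 0:
            raise ValueError("Dudko parameters must be positive")

    def to_dict(self) -> dict:
        return {"tau0_s": self.tau0, "x_dagger_nm": self.x_dagger,
                "delta_G_kT": self.delta_G, "nu": self.nu,
                "temperature_K": self.temperature}


# ---------------------------------------------------------------------------


def detect_ruptures(
    cycle: ForceDistanceCycle,
    noise_sd: float,
    min_jump_multiple: float = 4.0,
) -> list[RuptureEvent]:
    """Find rupture events on a retract trace.

    An event is a single-step force drop of magnitude at least
    ``min_jump_multiple * noise_sd`` whose post-drop level returns to the
    trace baseline (estimated as the median of the lower half of the force
    samples).  Returns events in separation order; an event-free trace gives
    an empty list.
    """
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    f = cycle.force
    baseline = float(np.median(np.sort(f)[: max(2, f.size // 2)]))
    threshold = min_jump_multiple * noise_sd

    # windowed step statistic: mean of w samples before vs after each gap,
    # which suppresses single-sample noise excursions
    w = 3
    kernel = np.ones(w) / w
    smooth = np.convolve(f, kernel, mode="valid")  # mean of f[i..i+w-1]
    pre = smooth[: f.size - 2 * w + 1]             # mean f[i-w+1..i] at i=w-1..
    post = smooth[w:]                              # mean f[i+1..i+w]
    jump = pre - post
    near_base = np.abs(post - baseline) <= max(4.0 * noise_sd, 0.5 * threshold)
    candidate = (jump >= threshold) & near_base

    idx = np.flatnonzero(candidate)
    runs: list[list[int]] = []
    for i in idx:
        if runs and i - runs[-1][-1] <= w:
            runs[-1].append(int(i))
        else:
            runs.append([int(i)])
    events: list[RuptureEvent] = []
    for run in runs:
        # one event per run; peak sample just before the drop
        lo = run[0] + w - 1
        hi = min(run[-1] + w, f.size)
        peak = lo + int(np.argmax(f[lo:hi]))
        force = float(f[peak] - baseline)
        if force >= threshold:
            events.append(RuptureEvent(force=force,
                                       loading_rate=cycle.loading_rate,
                                       cycle_id=cycle.cycle_id))
    return events


def summarize_forces(
    events: Iterable[RuptureEvent],
    bin_width: float = 5.0,
) -> dict[float, tuple[float, ForceHistogram]]:
    """Group events by nominal loading rate; mean force and histogram per group.

    Bin edges are aligned to multiples of ``bin_width`` (5 pN per the
    binning convention for unbinding-force histograms).
    """
    groups: dict[float, list[float]] = defaultdict(list)
    for ev in events:
        groups[ev.loading_rate].append(ev.force)
    out: dict[float, tuple[float, ForceHistogram]] = {}
    for rate, forces in sorted(groups.items()):
        if not forces:
            warnings.warn(f"empty group at loading rate {rate}; dropped")
            continue
        arr = np.asarray(forces)
        lo = np.floor(arr.min() / bin_width) * bin_width
        hi = np.ceil(arr.max() / bin_width) * bin_width
        if hi <= lo:
            hi = lo + bin_width
        edges = np.arange(lo, hi + 0.5 * bin_width, bin_width)
        counts, _ = np.histogram(arr, bins=edges)
        out[rate] = (float(arr.mean()),
                     ForceHistogram(bin_edges=edges, counts=counts,
                                    loading_rate=rate))
    return out


def fit_bell(
    means: Sequence[tuple[float, float]],
    temperature: float = 298.0,
) -> BellFit:
    """Bell extrapolation of mean unbinding forces to zero force.

    ``means`` holds (loading rate pN/s, mean force pN) pairs.  The line
    F = s ln(r) + c with s = kBT/x_beta yields x_beta = kBT/s and
    k_off0 = exp(-c/s)/s (rates in pN/s).
    """
    if len(means) < 2:
        raise ValueError("need >= 2 loading rates")
    r = np.array([m[0] for m in means], dtype=float)
    F = np.array([m[1] for m in means], dtype=float)
    if np.any(r <= 0):
        raise ValueError("loading rates must be positive")
    if np.ptp(np.log(r)) == 0:
        raise ValueError("loading rates must be distinct")
    s, c = np.polyfit(np.log(r), F, 1)
    if s <= 1e-9:
        raise ForceFitError(
            "forces do not increase with loading rate: x_beta diverges"
        )
    kBT = KB_PN_NM * temperature
    x_beta = kBT / s
    k_off0 = np.exp(-c / s) / s
    if not (np.isfinite(k_off0) and k_off0 > 0):
        raise ForceFitError("Bell extrapolation produced a degenerate off-rate")
    return BellFit(k_off0=float(k_off0), x_beta=float(x_beta),
                   temperature=temperature)


def histogram_to_lifetimes(
    hist: ForceHistogram,
    min_total: int = 50,
) -> list[tuple[float, float]]:
    """Dudko-Hummer-Szabo transform of a rupture-force histogram.

    For bin i with count h_i, width dF, at constant loading rate r:

        tau(F_i) = (sum_{j>i} h_j + h_i/2) * dF / (r * h_i)

    evaluated at the bin midpoint F_i; empty bins are skipped.
    """
    if hist.n_total < min_total:
        raise ValueError(f"histogram needs >= {min_total} events, has {hist.n_total}")
    if hist.loading_rate <= 0:
        raise ValueError("loading rate must be positive")
    h = hist.counts.astype(float)
    if not np.any(h > 0):
        raise ValueError("all histogram bins are empty")
    dF = hist.bin_width
    tail = np.concatenate([np.cumsum(h[::-1])[::-1][1:], [0.0]])  # sum_{j>i} h_j
    out = []
    for Fmid, hi, ti in zip(hist.midpoints, h, tail):
        if hi > 0:
            out.append((float(Fmid), float((ti + hi / 2.0) * dF
                                           / (hist.loading_rate * hi))))
    return out


def _dudko_log_tau(F: np.ndarray, tau0: float, x: float, dG: float,
                   nu: float, kBT: float) -> np.ndarray:
    u = 1.0 - nu * F * x / (dG * kBT)
    u = np.clip(u, 1e-9, None)  # constrained search: stay inside the well
    return (np.log(tau0) + (1.0 - 1.0 / nu) * np.log(u)
            - dG * (1.0 - u ** (1.0 / nu)))


def fit_dudko(
    lifetime_points: Sequence[tuple[float, float]],
    temperature: float = 298.0,
    nu: float = 0.5,
) -> DudkoFit:
    """Fit the nu-model to (force pN, lifetime s) points by least squares
    on log-lifetime.

    ``nu`` = 1/2 (harmonic cusp, default), 2/3 (linear-cubic) or 1 (Bell;
    then dG is unidentifiable and reported at its initialization value).
    """
    if nu not in (0.5, 2.0 / 3.0, 1.0):
        raise ValueError("nu must be 1/2, 2/3 or 1")
    pts = [(float(F), float(t)) for F, t in lifetime_points]
    if len(pts) < 4:
        raise ValueError("need >= 4 lifetime points")
    if any(t <= 0 for _, t in pts):
        raise ValueError("lifetimes must be positive")
    F = np.array([p[0] for p in pts])
    log_tau = np.log([p[1] for p in pts])
    kBT = KB_PN_NM * temperature

    # Bell-limit warm start: ln tau = ln tau0 - F x / kBT
    slope, intercept = np.polyfit(F, log_tau, 1)
    x0 = max(-slope * kBT, 1e-3)
    tau00 = float(np.exp(intercept))

    if nu == 1.0:
        if slope >= 0:
            raise ForceFitError("lifetimes do not decrease with force")
        return DudkoFit(tau0=tau00, x_dagger=x0, delta_G=10.0, nu=1.0,
                        temperature=temperature)

    def residuals(theta):
        ltau0, x, dG = theta
        return _dudko_log_tau(F, np.exp(ltau0), x, dG, nu, kBT) - log_tau

    best, best_cost = None, np.inf
    for dG0 in (3.0, 5.0, 8.0, 12.0, 20.0, 40.0):
        res = least_squares(
            residuals, x0=[np.log(tau00), x0, dG0],
            bounds=([-np.inf, 1e-4, 0.5], [np.inf, 100.0, 500.0]),
            method="trf", xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=5000,
        )
        if res.cost < best_cost:
            best, best_cost = res, res.cost
    if best is None or not best.success:
        raise ForceFitError("Dudko fit did not converge")
    ltau0, x, dG = best.x
    return DudkoFit(tau0=float(np.exp(ltau0)), x_dagger=float(x),
                    delta_G=float(dG), nu=nu, temperature=temperature)
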