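"""Chlorophyll fluorescence decay deconvolution.

After a single-turnover saturating flash, variable fluorescence relaxes as
the reduced primary quinone is reoxidised.  The relaxation is modelled as a
sum of exponentials

    F(t) = sum_i A_i * exp(-k_i * t) + offset,  A_i >= 0, k_i > 0,

conventionally three components in whole cells; the largest rate constant is
assigned to the protein-gated QA- -> QB electron transfer.

Fitting uses a separable warm start (log-spaced trial rates, non-negative
linear least squares for the amplitudes) followed by a bounded trust-region
refinement of all parameters.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import least_squares, nnls

__all__ = [
    "DecayTrace",
    "MultiExpFit",
    "DecayFitError",
    "GatingAssignmentError",
    "normalize_trace",
    "fit_multiexponential",
    "extract_gating_rate",
    "read_decay_csv",
    "write_decay_csv",
]

MIN_TRACE_POINTS = 10


class DecayFitError(RuntimeError):
    """Fit failure; carries the best parameters found so far, if any."""

    def __init__(self, message: str, best_fit: "MultiExpFit | None" = None):
        super().__init__(message)
        self.best_fit = best_fit


class GatingAssignmentError(RuntimeError):
    """No component qualifies for the gating-rate assignment."""


@dataclass(frozen=True)
class DecayTrace:
    """A fluorescence decay: times in seconds, dimensionless signal."""

    times: np.ndarray
    fluorescence: np.ndarray
    temperature: float  # Kelvin
    strain_id: str = ""

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        f = np.asarray(self.fluorescence, dtype=float)
        if t.ndim != 1 or f.shape != t.shape:
            raise ValueError("times and fluorescence must be 1-D, equal length")
        if t.size < MIN_TRACE_POINTS:
            raise ValueError(f"trace needs >= {MIN_TRACE_POINTS} points, got {t.size}")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(f))):
            raise ValueError("non-finite values in trace")
        if np.any(t < 0) or np.any(np.diff(t) <= 0):
            raise ValueError("times must be non-negative and strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "fluorescence", f)

    def __len__(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class MultiExpFit:
    """Result of a multi-exponential fit, components sorted by rate (desc)."""

    components: tuple[tuple[float, float], ...]  # (amplitude, rate s^-1)
    offset: float
    rss: float
    converged: bool
    n_iter: int
    degenerate: bool = False

    def __post_init__(self):
        rates = [k for _, k in self.components]
        if any(k <= 0 for k in rates):
            raise ValueError("rates must be positive")
        if any(a < 0 for a, _ in self.components):
            raise ValueError("amplitudes must be non-negative")
        if any(r2 >= r1 for r1, r2 in zip(rates, rates[1:])):
            raise ValueError("components must be strictly descending in rate")
        if self.rss < 0:
            raise ValueError("rss must be non-negative")

    @property
    def rates(self) -> tuple[float, ...]:
        return tuple(k for _, k in self.components)

    @property
    def amplitudes(self) -> tuple[float, ...]:
        return tuple(a for a, _ in self.components)

    def evaluate(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        out = np.full_like(t, self.offset, dtype=float)
        for a, k in self.components:
            out += a * np.exp(-k * t)
        return out

    def to_dict(self) -> dict:
        return {
            "components": [{"amplitude": a, "rate_per_s": k} for a, k in self.components],
            "offset": self.offset,
            "rss": self.rss,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "degenerate": self.degenerate,
        }


def normalize_trace(trace: DecayTrace) -> DecayTrace:
    """Scale a trace so that its first sample equals 1."""
    f0 = trace.fluorescence[0]
    if f0 <= 0:
        raise ValueError(f"cannot normalize: first fluorescence value {f0} <= 0")
    return replace(trace, fluorescence=trace.fluorescence / f0)


def _sorted_components(amps: np.ndarray, rates: np.ndarray,
                       merge_rtol: float = 1e-6) -> tuple[tuple[float, float], ...]:
    # merge (sum amplitudes of) components with effectively equal rates
    order = np.argsort(rates)[::-1]
    merged: list[list[float]] = []
    for i in order:
        a, k = float(amps[i]), float(rates[i])
        if merged and abs(merged[-1][1] - k) <= merge_rtol * merged[-1][1]:
            merged[-1][0] += a
        else:
            merged.append([a, k])
    return tuple((a, k) for a, k in merged)


def _design(t: np.ndarray, rates: np.ndarray) -> np.ndarray:
    return np.column_stack([np.exp(-np.outer(t, rates)), np.ones_like(t)])


def fit_multiexponential(
    trace: DecayTrace,
    n_components: int = 3,
    seed: int = 0,
    max_iter: int = 2000,
    tol: float = 1e-12,
    n_restarts: int = 4,
) -> MultiExpFit:
    """Fit ``F(t) = sum A_i exp(-k_i t) + offset`` by constrained least squares.

    Rates are optimised on a log scale (positivity), amplitudes and offset are
    bounded below by 0 and -inf respectively.  The warm start places trial
    rates log-spaced across the reciprocal time window and solves the
    amplitudes by NNLS; seeded jittered restarts guard against local minima.

    Raises
    ------
    ValueError
        If the trace has fewer than ``3 * n_components + 1`` points.
    DecayFitError
        If no restart converges; the error carries the best fit found.
    """
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    t = trace.times
    f = trace.fluorescence
    if t.size < 3 * n_components + 1:
        raise ValueError(
            f"trace with {t.size} points cannot constrain {n_components} components"
        )

    # degenerate (no decay) input: constant signal
    if np.ptp(f) <= 1e-12 * max(1.0, abs(f[0])):
        comps = tuple((0.0, 10.0 ** (n_components - 1 - i)) for i in range(n_components))
        return MultiExpFit(components=comps, offset=float(np.mean(f)),
                           rss=float(np.sum((f - np.mean(f)) ** 2)),
                           converged=True, n_iter=0, degenerate=True)

    t_pos = t[t > 0]
    k_hi = 1.0 / t_pos.min()
    k_lo = 1.0 / t_pos.max()
    rng = np.random.default_rng(seed)

    def residuals(params: np.ndarray) -> np.ndarray:
        logk = params[:n_components]
        amps = params[n_components:2 * n_components]
        offset = params[-1]
        model = _design(t, np.exp(logk)) @ np.append(amps, offset)
        return model - f

    best = None
    best_cost = np.inf
    total_nfev = 0
    for attempt in range(n_restarts + 1):
        if n_components == 1:
            rates0 = np.array([np.sqrt(k_lo * k_hi)])
        else:
            rates0 = np.geomspace(k_lo, k_hi, n_components)
        if attempt > 0:
            rates0 = rates0 * np.exp(rng.normal(0.0, 0.5, size=n_components))
        amps0, _ = nnls(_design(t, rates0)[:, :-1], f - f.min())
        x0 = np.concatenate([np.log(rates0), amps0, [f.min()]])
        lb = np.concatenate([np.full(n_components, -np.inf),
                             np.zeros(n_components), [-np.inf]])
        ub = np.full(2 * n_components + 1, np.inf)
        res = least_squares(residuals, x0, bounds=(lb, ub), method="trf",
                            max_nfev=max_iter, xtol=tol, ftol=tol, gtol=tol)
        total_nfev += res.nfev
        if res.cost < best_cost:
            best, best_cost = res, res.cost
        # accept early if the fit explains the data essentially exactly
        if res.success and 2 * res.cost <= 1e-20 * np.sum(f**2):
            break

    assert best is not None
    comps = _sorted_components(best.x[n_components:2 * n_components],
                               np.exp(best.x[:n_components]))
    fit = MultiExpFit(components=comps, offset=float(best.x[-1]),
                      rss=float(2 * best.cost), converged=bool(best.success),
                      n_iter=total_nfev)
    if not best.success:
        raise DecayFitError(f"fit did not converge: {best.message}", best_fit=fit)
    return fit


def extract_gating_rate(fit: MultiExpFit, amplitude_floor: float = 0.01) -> float:
    """Largest rate constant among non-negligible components (the QA-->QB rate).

    ``amplitude_floor`` is a fraction of the total fitted amplitude; components
    below it are treated as numerical artefacts and ignored.
    """
    total = sum(fit.amplitudes)
    if not fit.components or total <= 0:
        raise GatingAssignmentError("no components with positive amplitude")
    eligible = [k for a, k in fit.components if a > amplitude_floor * total]
    if not eligible:
        raise GatingAssignmentError(
            f"no component above amplitude floor {amplitude_floor:g} of total"
        )
    return max(eligible)


# ---------------------------------------------------------------------------
# CSV I/O: columns time_s, fluorescence; '#'-prefixed key=value metadata lines.

def read_decay_csv(path: str | Path) -> DecayTrace:
    text = Path(path).read_text()
    meta: dict[str, str] = {}
    body_lines = []
    for line in text.splitlines():
        if line.startswith("#"):
            key, _, value = line.lstrip("# ").partition("=")
            if _:
                meta[key.strip()] = value.strip()
        else:
            body_lines.append(line)
    df = pd.read_csv(io.StringIO("\n".join(body_lines)),
                     float_precision="round_trip")
    if not {"time_s", "fluorescence"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns time_s, fluorescence")
    return DecayTrace(
        times=df["time_s"].to_numpy(),
        fluorescence=df["fluorescence"].to_numpy(),
        temperature=float(meta.get("temperature_K", "298.0")),
        strain_id=meta.get("strain", ""),
    )


def write_decay_csv(trace: DecayTrace, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# temperature_K={trace.temperature}\n")
        fh.write(f"# strain={trace.strain_id}\n")
        fh.write("time_s,fluorescence\n")
        for t, f in zip(trace.times, trace.fluorescence):
            fh.write(f"{float(t)!r},{float(f)!r}\n")
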