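"""Seeded synthetic-data generators for every input class of the pipeline.

Each generator draws from a single ``numpy.random.default_rng(seed)`` stream
(no global state) and returns ``(data, truth)`` where ``truth`` is a
machine-readable dict of the generating parameters, consumed by round-trip
tests and written to simulation manifests.

The generators emulate the statistical structure the analyses assume: a
three-exponential fluorescence decay with additive Gaussian noise, Eyring
rate-temperature series with an optional high-temperature plateau, mutant
rate panels consistent with a volume -> effective-temperature map,
Bell-Evans rupture forces sampled by inverse CDF, force-distance retract
traces with embedded ruptures, trajectory frames with prescribed H-bond
occupancy, and aligned sequence sets with prescribed triplet composition.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

from .decay import DecayTrace
from .eyring import KB_OVER_H, R_GAS, RateSeries
from .forcespec import KB_PN_NM, ForceDistanceCycle, RuptureEvent

__all__ = [
    "gen_decay_trace",
    "gen_rate_series",
    "gen_mutant_panel",
    "gen_rupture_forces",
    "gen_force_distance_cycles",
    "gen_trajectory",
    "gen_alignment",
]


def gen_decay_trace(
    components: Sequence[tuple[float, float]],
    offset: float = 0.0,
    t_max: float | None = None,
    n_points: int = 200,
    noise_sd: float = 0.0,
    seed: int = 0,
    temperature: float = 298.0,
    strain_id: str = "synthetic",
) -> tuple[DecayTrace, dict]:
    """Multi-exponential decay on a log-spaced time grid.

    ``components`` are (amplitude, rate s^-1) pairs; the grid spans three
    decades around the slowest/fastest rates unless ``t_max`` is given.
    """
    if any(k <= 0 for _, k in components) or any(a < 0 for a, _ in components):
        raise ValueError("rates must be positive and amplitudes non-negative")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    k_min = min(k for _, k in components)
    k_max = max(k for _, k in components)
    t_hi = t_max if t_max is not None else 5.0 / k_min
    t_lo = 0.01 / k_max
    t = np.concatenate([[0.0], np.geomspace(t_lo, t_hi, n_points - 1)])
    f = np.full_like(t, float(offset))
    for a, k in components:
        f = f + a * np.exp(-k * t)
    if noise_sd > 0:
        f = f + rng.normal(0.0, noise_sd, size=t.size)
    trace = DecayTrace(times=t, fluorescence=f, temperature=temperature,
                       strain_id=strain_id)
    truth = {"components": [[float(a), float(k)] for a, k in components],
             "offset": float(offset), "noise_sd": float(noise_sd), "seed": seed}
    return trace, truth


def gen_rate_series(
    delta_H: float,
    delta_S: float,
    T_grid: Iterable[float],
    T_break: float | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    strain_id: str = "synthetic-wt",
    site: str = "",
    residue: str = "G",
    residue_volume: float = 67.5,
) -> tuple[RateSeries, dict]:
    """Eyring-distributed rates: ln(k/T) = ln(kB/h) + dS/R - dH/(R T),
    held constant above ``T_break`` (the leveling-off plateau).

    ``noise_sd`` is additive Gaussian noise on ln k.
    """
    T = np.asarray(list(T_grid), dtype=float)
    if np.any(T <= 0):
        raise ValueError("temperature grid must be positive")
    rng = np.random.default_rng(seed)
    a = np.log(KB_OVER_H) + delta_S / R_GAS
    b = -delta_H / R_GAS
    T_eff = T if T_break is None else np.minimum(T, T_break)
    ln_k_over_T = a + b / T_eff
    ln_k = ln_k_over_T + np.log(T)
    if noise_sd > 0:
        ln_k = ln_k + rng.normal(0.0, noise_sd, size=T.size)
    series = RateSeries(temperatures=T, rates=np.exp(ln_k), strain_id=strain_id,
                        site=site, residue=residue, residue_volume=residue_volume)
    truth = {"delta_H_J_mol": float(delta_H), "delta_S_J_molK": float(delta_S),
             "a": float(a), "b_K": float(b),
             "T_break_K": None if T_break is None else float(T_break),
             "noise_sd": float(noise_sd), "seed": seed}
    return series, truth


def gen_mutant_panel(
    wt_a: float,
    wt_b: float,
    alpha: float,
    beta: float,
    volumes: Sequence[float],
    residues: Sequence[str] | None = None,
    T_ref: float = 298.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[list[tuple[str, float, float]], dict]:
    """Mutant panel of T_ref rates consistent with the effective-T map.

    Each volume V gets T_eff = 1000/(alpha V + beta); its rate at T_ref is
    read off the wild-type line there: ln(k/T_ref) = wt_a + wt_b / T_eff.
    Returns (residue, volume Å³, rate s^-1) triples plus the ground truth.
    ``noise_sd`` perturbs ln k.
    """
    if residues is None:
        residues = ["X"] * len(volumes)
    if len(residues) != len(volumes):
        raise ValueError("residues and volumes must have equal length")
    rng = np.random.default_rng(seed)
    panel = []
    t_eff_true = []
    for res, V in zip(residues, volumes):
        denom = alpha * V + beta
        if denom <= 0:
            raise ValueError(f"alpha*V + beta <= 0 at V={V}")
        T_eff = 1000.0 / denom
        ln_kT = wt_a + wt_b / T_eff
        ln_k = ln_kT + np.log(T_ref)
        if noise_sd > 0:
            ln_k = ln_k + rng.normal(0.0, noise_sd)
        panel.append((res, float(V), float(np.exp(ln_k))))
        t_eff_true.append(float(T_eff))
    truth = {"wt_a": float(wt_a), "wt_b_K": float(wt_b), "alpha": float(alpha),
             "beta": float(beta), "T_ref_K": float(T_ref),
             "T_eff_K": t_eff_true, "noise_sd": float(noise_sd), "seed": seed}
    return panel, truth


def bell_survival(F: np.ndarray, k_off0: float, x: float, temperature: float,
                  loading_rate: float) -> np.ndarray:
    """Closed-form Bell-Evans survival S(F) at constant loading rate."""
    kBT = KB_PN_NM * temperature
    return np.exp(-(k_off0 * kBT) / (loading_rate * x)
                  * (np.exp(F * x / kBT) - 1.0))


def gen_rupture_forces(
    k_off0: float,
    x: float,
    temperature: float,
    loading_rates: Sequence[float],
    n_per_rate: int,
    seed: int = 0,
) -> tuple[list[RuptureEvent], dict]:
    """Bell-Evans rupture forces by inverse-CDF sampling of the survival
    function S(F) = exp(-(k_off0 kBT)/(r x) (e^{F x/kBT} - 1))."""
    if min(k_off0, x, temperature) <= 0 or any(r <= 0 for r in loading_rates):
        raise ValueError("all Bell parameters and loading rates must be positive")
    rng = np.random.default_rng(seed)
    kBT = KB_PN_NM * temperature
    events = []
    for r in loading_rates:
        u = rng.uniform(size=n_per_rate)
        F = (kBT / x) * np.log1p(-(r * x) / (k_off0 * kBT) * np.log(u))
        for Fi in F:
            events.append(RuptureEvent(force=float(Fi), loading_rate=float(r)))
    truth = {"k_off0_per_s": float(k_off0), "x_nm": float(x),
             "temperature_K": float(temperature),
             "loading_rates_pN_s": [float(r) for r in loading_rates],
             "n_per_rate": int(n_per_rate), "seed": seed}
    return events, truth


def gen_force_distance_cycles(
    rupture_forces: Sequence[Sequence[float]],
    baseline_noise_sd: float = 2.0,
    sweep_frequency: float = 1.0,
    sweep_amplitude: float = 100.0,
    spring_constant: float = 40.0,
    n_points: int = 2000,
    seed: int = 0,
) -> tuple[list[ForceDistanceCycle], dict]:
    """Retract traces with linear load ramps interrupted by embedded ruptures.

    ``rupture_forces`` is one list of target forces per cycle (possibly
    empty).  Within each cycle the force ramps at the nominal loading rate,
    drops to baseline at each target force, and stays at baseline after the
    last rupture.
    """
    if min(sweep_frequency, sweep_amplitude, spring_constant) <= 0:
        raise ValueError("sweep parameters must be positive")
    rng = np.random.default_rng(seed)
    velocity = 2.0 * sweep_amplitude * sweep_frequency  # nm/s
    loading_rate = spring_constant * velocity
    cycles = []
    for ci, targets in enumerate(rupture_forces):
        sep = np.linspace(0.0, sweep_amplitude, n_points)
        t = sep / velocity
        force = np.zeros(n_points)
        t0 = 0.0
        remaining = sorted(float(f) for f in targets)
        for F_target in remaining:
            ramp = loading_rate * (t - t0)
            seg = (t >= t0) & (ramp <= F_target)
            force[seg] = ramp[seg]
            if not seg.any():
                continue
            t0 = t[seg][-1] + (t[1] - t[0])
        force = force + rng.normal(0.0, baseline_noise_sd, size=n_points)
        cycles.append(ForceDistanceCycle(
            separation=sep, force=force, sweep_frequency=sweep_frequency,
            sweep_amplitude=sweep_amplitude, spring_constant=spring_constant,
            cycle_id=f"cycle{ci:04d}"))
    truth = {"rupture_forces_pN": [[float(f) for f in tf] for tf in rupture_forces],
             "loading_rate_pN_s": float(loading_rate),
             "baseline_noise_sd_pN": float(baseline_noise_sd), "seed": seed}
    return cycles, truth


def gen_trajectory(
    n_frames: int,
    occupancy: float,
    donor: tuple[str, int, str] = ("A", 209, "OG"),
    acceptor: tuple[str, int, str] = ("D", 204, "O"),
    bonded_distance: float = 2.9,
    broken_distance: float = 5.5,
    seed: int = 0,
    exact_count: bool = False,
) -> tuple[list[dict], dict]:
    """Trajectory frames whose donor-acceptor pair is H-bonded with
    probability ``occupancy`` (independently per frame).

    With ``exact_count`` the number of bonded frames is exactly
    ``round(occupancy * n_frames)`` (deterministic placement after shuffle).
    """
    if not 0.0 <= occupancy <= 1.0:
        raise ValueError("occupancy must lie in [0, 1]")
    if n_frames < 1:
        raise ValueError("need at least one frame")
    rng = np.random.default_rng(seed)
    if exact_count:
        n_bonded = round(occupancy * n_frames)
        states = np.zeros(n_frames, dtype=bool)
        states[:n_bonded] = True
        rng.shuffle(states)
    else:
        states = rng.uniform(size=n_frames) < occupancy
    frames = []
    for bonded in states:
        d = bonded_distance if bonded else broken_distance
        jitter = rng.normal(0.0, 0.05, size=3)
        frames.append({donor: np.array([0.0, 0.0, 0.0]),
                       acceptor: np.array([d, 0.0, 0.0]) + jitter})
    truth = {"occupancy": float(occupancy), "n_frames": int(n_frames),
             "n_bonded": int(states.sum()), "donor": list(donor),
             "acceptor": list(acceptor), "seed": seed}
    return frames, truth


def gen_alignment(
    n: int,
    triplet_probs: dict[str, float],
    window: tuple[int, int, int] = (7, 8, 9),
    flank: str = "LLVPFWMLLVPFWML",
    seed: int = 0,
) -> tuple[list[str], dict]:
    """Aligned sequences with a prescribed triplet distribution at ``window``.

    The flank template (free of small residues by default, so the window
    triplet alone decides 'all-small') is overwritten at the 1-based window
    positions by a triplet drawn from ``triplet_probs``.
    """
    probs = np.array(list(triplet_probs.values()), dtype=float)
    if np.any(probs < 0) or not np.isclose(probs.sum(), 1.0):
        raise ValueError("triplet probabilities must be non-negative, sum to 1")
    if max(window) > len(flank):
        raise ValueError("window exceeds flank template length")
    rng = np.random.default_rng(seed)
    triplets = list(triplet_probs.keys())
    draws = rng.choice(len(triplets), size=n, p=probs)
    seqs = []
    for d in draws:
        chars = list(flank)
        for pos, c in zip(window, triplets[d]):
            chars[pos - 1] = c
        seqs.append("".join(chars))
    counts = {t: int((draws == i).sum()) for i, t in enumerate(triplets)}
    truth = {"triplet_probs": {k: float(v) for k, v in triplet_probs.items()},
             "counts": counts, "window": list(window), "n": int(n), "seed": seed}
    return seqs, truth
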