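"""Summary statistics of simulation output.

Conventions: a particle's pole distance is measured from the surface of the
pole's nucleation sphere (the centrosomal body on which minus ends are
anchored), clamped at zero inside it.  The concentration index is the
reciprocal of the mean centre distance to the nearest MTOC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.optimize import minimize_scalar


# ---------------------------------------------------------------------------
# Snapshot statistics
# ---------------------------------------------------------------------------

def nearest_pole_distance(positions: np.ndarray, pole_positions: np.ndarray,
                          nucleation_radius: float = 0.0) -> np.ndarray:
    """Per-particle distance to the nearest pole (surface distance when
    nucleation_radius > 0)."""
    positions = np.atleast_2d(positions)
    d = np.linalg.norm(positions[:, None, :] - np.atleast_2d(pole_positions)[None, :, :],
                       axis=2).min(axis=1)
    return np.clip(d - nucleation_radius, 0.0, None)


def nearest_pole_index(positions: np.ndarray, pole_positions: np.ndarray) -> np.ndarray:
    positions = np.atleast_2d(positions)
    d = np.linalg.norm(positions[:, None, :] - np.atleast_2d(pole_positions)[None, :, :], axis=2)
    return d.argmin(axis=1)


def sequestration_and_concentration(positions: np.ndarray, states: np.ndarray,
                                    pole_positions: np.ndarray) -> tuple[float, float]:
    """(bound fraction, concentration index = 1 / mean distance to MTOC)."""
    states = np.asarray(states)
    if states.size == 0:
        raise ValueError("empty snapshot")
    bound_fraction = float((states == 1).mean())
    mean_d = nearest_pole_distance(positions, pole_positions).mean()
    return bound_fraction, float(1.0 / mean_d)


def pole_proximity_fractions(positions: np.ndarray, pole_positions: np.ndarray,
                             nucleation_radius: float,
                             radii: Sequence[float] = (0.2, 1.0)) -> dict:
    """Fraction of particles within each radius of a pole surface."""
    d = nearest_pole_distance(positions, pole_positions, nucleation_radius)
    return {r: float((d <= r).mean()) for r in radii}


def asymmetric_index(n1: float, n2: float) -> float:
    """(N1 - N2) / (N1 + N2)."""
    if n1 + n2 <= 0:
        raise ValueError("asymmetric index undefined for N1 + N2 = 0")
    return (n1 - n2) / (n1 + n2)


def turnover_time(fraction_turned_over: float, elapsed: float) -> float:
    """Characteristic pole-to-pole turnover time from a Poisson wait model:
    prob(wait < t) = 1 - exp(-t/tau)  =>  tau = -t / ln(1 - p)."""
    p = fraction_turned_over
    if not 0.0 < p < 1.0:
        raise ValueError("fraction turned over must lie strictly in (0, 1)")
    if elapsed <= 0:
        raise ValueError("elapsed time must be positive")
    return -elapsed / np.log1p(-p)


def turnover_fraction(result, from_pole: int = 0) -> float:
    """Fraction of particles whose nearest-pole assignment switched from
    `from_pole` (their assignment at the first snapshot) to the other pole by
    the final snapshot."""
    first = nearest_pole_index(result.positions[0], result.pole_positions)
    last = nearest_pole_index(result.positions[-1], result.pole_positions)
    src = first == from_pole
    if not src.any():
        raise ValueError("no particles initially assigned to the source pole")
    return float((last[src] != from_pole).mean())


def equator_zone_count(positions: np.ndarray, half_width: float = 1.0,
                       axis: int = 0) -> int:
    """Number of particles within `half_width` of the mid-cell plane."""
    return int((np.abs(np.atleast_2d(positions)[:, axis]) <= half_width).sum())


def equalization_time(times: np.ndarray, curve_a: np.ndarray,
                      curve_b: np.ndarray, fraction: float = 0.05) -> float:
    """First time the difference between two point traces falls below
    `fraction` of its initial value (e.g. bleached vs neighbouring energid
    centres after photobleaching)."""
    diff = np.abs(np.asarray(curve_a) - np.asarray(curve_b))
    target = fraction * diff[0]
    below = np.nonzero(diff <= target)[0]
    if below.size == 0:
        return float("inf")
    i = below[0]
    if i == 0:
        return float(times[0])
    t0, t1 = times[i - 1], times[i]
    d0, d1 = diff[i - 1], diff[i]
    return float(t0 + (d0 - target) / (d0 - d1) * (t1 - t0))


@dataclass
class MetricReport:
    bound_fraction: float
    concentration_index: float
    mean_distance_to_pole: float
    turnover_time: Optional[float] = None
    asymmetric_index: Optional[float] = None
    phenomenological_D: Optional[float] = None

    def __post_init__(self):
        if not 0.0 <= self.bound_fraction <= 1.0:
            raise ValueError("bound fraction outside [0, 1]")
        if self.asymmetric_index is not None and not -1.0 <= self.asymmetric_index <= 1.0:
            raise ValueError("asymmetric index outside [-1, 1]")

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items() if v is not None}


def snapshot_report(result, t_index: int = -1) -> MetricReport:
    pos = result.positions[t_index]
    states = result.states[t_index]
    bf, ci = sequestration_and_concentration(pos, states, result.pole_positions)
    mean_d = nearest_pole_distance(pos, result.pole_positions).mean()
    n_poles = result.bound_per_pole.shape[1]
    ai = None
    if n_poles == 2:
        n1, n2 = result.bound_per_pole[t_index]
        if n1 + n2 > 0:
            ai = asymmetric_index(float(n1), float(n2))
    return MetricReport(bf, ci, float(mean_d), asymmetric_index=ai)


# ---------------------------------------------------------------------------
# Phenomenological diffusion coefficient
# ---------------------------------------------------------------------------

def fit_phenomenological_D(times: np.ndarray, curve: np.ndarray,
                           curve_factory: Callable[[float], np.ndarray],
                           D_range: tuple[float, float] = (0.5, 20.0),
                           rtol: float = 0.01, coarse_points: int = 7) -> float:
    """Pure-diffusion coefficient whose recovery curve best matches `curve`.

    `curve_factory(D)` must return the pure-diffusion recovery curve sampled
    at `times` under the same domain and protocol.  The RMS objective is
    minimized in log D to the requested relative tolerance; a coarse scan
    warns when the objective is not unimodal.
    """
    if D_range[0] <= 0 or D_range[1] <= D_range[0]:
        raise ValueError("D search range must be positive and increasing")
    curve = np.asarray(curve)

    cache: dict[float, float] = {}

    def objective(logD: float) -> float:
        key = round(float(logD), 12)
        if key not in cache:
            trial = curve_factory(float(np.exp(logD)))
            cache[key] = float(np.sqrt(np.mean((np.asarray(trial) - curve) ** 2)))
        return cache[key]

    lo, hi = np.log(D_range[0]), np.log(D_range[1])
    grid = np.linspace(lo, hi, coarse_points)
    vals = np.array([objective(g) for g in grid])
    interior = np.r_[False, (vals[1:-1] < vals[:-2]) & (vals[1:-1] < vals[2:]), False]
    if interior.sum() > 1:
        warnings.warn("non-monotone objective: multiple local minima on the "
                      "coarse grid", stacklevel=2)
    i = int(np.argmin(vals))
    blo = grid[max(i - 1, 0)]
    bhi = grid[min(i + 1, coarse_points - 1)]
    res = minimize_scalar(objective, bounds=(blo, bhi), method="bounded",
                          options={"xatol": np.log1p(rtol)})
    return float(np.exp(res.x))
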