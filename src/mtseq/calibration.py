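"""Effective mean-field binding rate from a 2D periodic-box agent simulation.

The microtubule is a disc of radius R_M at the centre of a periodic square
box whose side is density**-1/2, so one filament cross-section per box
realizes the target areal density.  A particle of radius ``r`` diffuses in
2D, reflects off the disc, binds when within ``d0`` of the contact circle
and unbinds at ``k_off``.  The stationary bound fraction f gives the
mean-field rate

    k_on = k_off * f / (1 - f),

which is the rate at which a free particle in a uniform filament field of
that density would bind.  The long-run estimate uses an ensemble of
independent walkers, a burn-in of 10/k_off, and a per-walker standard error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _kernels
from .geometry import DEFAULT_MT_RADIUS


@dataclass
class CalibrationPoint:
    mt_density: float          # µm^-2
    particle_radius: float     # µm
    k_off: float               # s^-1
    bound_fraction: float
    bound_fraction_se: float
    k_on_effective: float      # s^-1
    k_on_se: float
    mean_bound_interval: float  # s, observed 1/k_off consistency check
    mean_free_interval: float   # s
    n_bind_events: int


def k_on_from_fraction(bound_fraction: float, k_off: float) -> float:
    """Detailed balance: f = k_on/(k_on+k_off)  =>  k_on = k_off f/(1-f)."""
    if not 0.0 <= bound_fraction < 1.0:
        raise ValueError("bound fraction must lie in [0, 1)")
    return k_off * bound_fraction / (1.0 - bound_fraction)


def effective_binding_rate(
    density: float,
    particle_radius: float = 0.005,
    k_off: float = 1.0,
    d0: float = 8e-4,
    seed: int = 0,
    D: float = 2.0,
    mt_radius: float = DEFAULT_MT_RADIUS,
    dt: float = 1e-4,
    n_particles: int = 48,
    duration: float = 400.0,
) -> CalibrationPoint:
    """Estimate k_on for one (density, particle size) point.

    ``duration`` is per-walker simulated time after which the time-and-
    ensemble-averaged bound fraction is converted to a rate.
    """
    if density <= 0:
        raise ValueError("density must be positive")
    box = density ** -0.5
    contact_r = mt_radius + particle_radius
    bind_r = contact_r + d0
    if box <= 2.0 * bind_r:
        warnings.warn("box smaller than the binding cross-section: "
                      "volume-exclusion regime", stacklevel=2)
    burn = 10.0 / k_off if k_off > 0 else 0.0
    n_steps = int(round((duration + burn) / dt))
    burn_steps = int(round(burn / dt))
    (bound_steps, total_steps, n_bind, n_unbind,
     sum_bound, sum_free, per_bound) = _kernels.run_calibration_kernel(
        n_particles, n_steps, dt, seed, box, D, k_off, contact_r, bind_r,
        burn_steps)
    f = bound_steps / total_steps
    # between-walker scatter gives a conservative SE of the mean fraction
    per_f = per_bound / (n_steps - burn_steps)
    se = per_f.std(ddof=1) / np.sqrt(n_particles) if n_particles > 1 else np.nan
    k_on = k_on_from_fraction(f, k_off)
    # delta method on f -> k_on
    k_se = k_off * se / (1.0 - f) ** 2 if f < 1 else np.nan
    return CalibrationPoint(
        mt_density=density, particle_radius=particle_radius, k_off=k_off,
        bound_fraction=f, bound_fraction_se=se,
        k_on_effective=k_on, k_on_se=k_se,
        mean_bound_interval=sum_bound / n_unbind if n_unbind else np.nan,
        mean_free_interval=sum_free / n_bind if n_bind else np.nan,
        n_bind_events=int(n_bind),
    )


def calibration_curve(densities, particle_radii, k_off: float = 1.0,
                      seed: int = 0, **kwargs) -> pd.DataFrame:
    """One CalibrationPoint per (density, radius) pair, as a tidy table."""
    densities = np.atleast_1d(densities)
    particle_radii = np.atleast_1d(particle_radii)
    if densities.size == 0 or particle_radii.size == 0:
        raise ValueError("empty calibration grid")
    rows = []
    for ri, r in enumerate(particle_radii):
        for di, dens in enumerate(densities):
            pt = effective_binding_rate(
                dens, particle_radius=r, k_off=k_off,
                seed=seed + 1000 * ri + di, **kwargs)
            rows.append({
                "density": pt.mt_density, "radius": pt.particle_radius,
                "bound_fraction": pt.bound_fraction, "se": pt.bound_fraction_se,
                "k_on": pt.k_on_effective, "k_on_se": pt.k_on_se,
            })
    return pd.DataFrame(rows)


def binding_relaxation_curve(density: float, k_off: float = 1.0, seed: int = 0,
                             particle_radius: float = 0.005, d0: float = 8e-4,
                             D: float = 2.0, mt_radius: float = DEFAULT_MT_RADIUS,
                             dt: float = 1e-4, n_particles: int = 400,
                             duration: float = 3.0, record_every: float = 0.01):
    """Ensemble bound-fraction transient from an all-free start.

    Used to cross-check the agent dynamics against the mean-field kinetics
    f(t) = f_inf (1 - exp(-(k_on + k_off) t)).
    """
    box = density ** -0.5
    contact_r = mt_radius + particle_radius
    bind_r = contact_r + d0
    n_steps = int(round(duration / dt))
    stride = max(int(round(record_every / dt)), 1)
    counts = _kernels.run_calibration_transient(
        n_particles, n_steps, stride, dt, seed, box, D, k_off, contact_r, bind_r)
    times = (np.arange(counts.size) + 1) * stride * dt
    return times, counts / n_particles
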