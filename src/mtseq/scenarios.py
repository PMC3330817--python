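"""Config-driven reproductions of the package's reference simulation
experiments: spindle sequestration, one-pole release, density and affinity
sweeps, centrosome-maturation asymmetry, FRAP/FLIP on the energid domain,
microtubule-length effects and kinesin accumulation at the equator.

Every scenario takes a ``scale`` factor on the particle count (full scale is
1000 particles) and optionally its own duration, so desk-scale runs with a
handful of replicate seeds finish in seconds to minutes while preserving the
geometry and the Table-style kinetics.  Results carry the full configuration
used, and identical (config, seed) pairs reproduce output bitwise.
"""

from __future__ import annotations

from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from . import metrics
from .engine import (KineticParams, ScenarioResult, run_agent_sim,
                     run_maturation_sim, uniform_positions_in_sphere)
from .geometry import (EnergidDomain, MaturationSchedule, SpindleSpec,
                       build_aster, build_spindle, merge,
                       DEFAULT_CELL_RADIUS)
from .mean_field import FieldParams, run_flip, run_frap

FULL_SCALE_PARTICLES = 1000


class ScenarioSpec(BaseModel):
    """Aggregated settings for one registered scenario run."""
    model_config = ConfigDict(extra="forbid")

    name: str
    scale: float = Field(1.0, gt=0)
    duration: Optional[float] = Field(None, gt=0)
    seeds: tuple[int, ...] = (1, 2, 3)
    snapshot_stride: int = Field(10_000, gt=0)
    kinetics: KineticParams = KineticParams()
    overrides: dict = {}


def _n_particles(scale: float) -> int:
    return max(int(round(FULL_SCALE_PARTICLES * scale)), 1)


def _init_uniform(n: int, seed: int, radius: float = DEFAULT_CELL_RADIUS) -> np.ndarray:
    rng = np.random.default_rng(seed + 77_000)
    return uniform_positions_in_sphere(n, radius, rng)


# ---------------------------------------------------------------------------
# Individual scenarios (each returns {seed: ScenarioResult} plus a report)
# ---------------------------------------------------------------------------

def fig1_symmetric(scale=1.0, duration=None, seeds=(1, 2, 3),
                   kinetics: Optional[KineticParams] = None,
                   snapshot_stride=10_000, **spindle_overrides):
    """Symmetric Table-style spindle, dyneins initially uniform; equilibrium
    sequestration at the two poles."""
    duration = 20.0 if duration is None else duration
    kin = kinetics or KineticParams()
    spec = SpindleSpec(**spindle_overrides)
    n = _n_particles(scale)
    results = {}
    for seed in seeds:
        mts = build_spindle(spec, seed)
        init = _init_uniform(n, seed, spec.cell_radius)
        results[seed] = run_agent_sim(mts, kin, init, duration, seed,
                                      snapshot_stride=snapshot_stride,
                                      motor="dynein", cell_radius=spec.cell_radius)
    report = _pooled_proximity_report(results)
    return results, report


def _pooled_proximity_report(results: dict) -> dict:
    """Pole-proximity fractions pooled over seeds, final snapshot."""
    fr200, fr1000, bf = [], [], []
    for res in results.values():
        pos = res.positions[-1]
        fracs = metrics.pole_proximity_fractions(
            pos, res.pole_positions, res.nucleation_radius)
        fr200.append(fracs[0.2])
        fr1000.append(fracs[1.0])
        bf.append(float((res.states[-1] == 1).mean()))
    return {
        "frac_within_200nm": float(np.mean(fr200)),
        "frac_within_1um": float(np.mean(fr1000)),
        "bound_fraction": float(np.mean(bf)),
        "per_seed_200nm": fr200, "per_seed_1um": fr1000,
    }


def fig1_one_pole_release(scale=1.0, duration=None, seeds=(1, 2, 3),
                          kinetics: Optional[KineticParams] = None,
                          release_point=(-9.0, 0.0, 0.0), snapshot_stride=10_000,
                          **spindle_overrides):
    """Dyneins released at one end of the cell near the proximal pole; capture
    should be almost entirely by that pole's half-spindle."""
    duration = 10.0 if duration is None else duration
    kin = kinetics or KineticParams()
    spec = SpindleSpec(**spindle_overrides)
    n = _n_particles(scale)
    init = np.tile(np.asarray(release_point, float), (n, 1))
    results = {}
    for seed in seeds:
        mts = build_spindle(spec, seed)
        results[seed] = run_agent_sim(mts, kin, init, duration, seed,
                                      snapshot_stride=snapshot_stride,
                                      motor="dynein", cell_radius=spec.cell_radius)
    # proximal pole = pole nearest the release point
    d = np.linalg.norm(spec.pole_positions - np.asarray(release_point), axis=1)
    proximal = int(d.argmin())
    shares, distal_counts = [], []
    for res in results.values():
        counts = res.bound_per_pole[-1]
        total_bound = counts.sum()
        shares.append(counts[proximal] / total_bound if total_bound else np.nan)
        distal_counts.append(int(counts[1 - proximal]))
    report = {
        "proximal_bound_share": float(np.nanmean(shares)),
        "distal_bound_count": float(np.mean(distal_counts)),
        "per_seed_share": shares,
    }
    return results, report


def fig2_density_sweep(counts=(10, 100, 1000), scale=0.2, duration=20.0,
                       seeds=(1, 2, 3), kinetics=None, **spindle_overrides):
    """Microtubule-density sweep: sequestration, concentration index and a
    Poisson-extrapolated pole-to-pole turnover time per density."""
    kin = kinetics or KineticParams()
    rows = []
    for c in counts:
        spec = SpindleSpec(n_spindle=int(c), n_astral=int(c), **spindle_overrides)
        n = _n_particles(scale)
        for seed in seeds:
            mts = build_spindle(spec, seed)
            init = _init_uniform(n, seed, spec.cell_radius)
            res = run_agent_sim(mts, kin, init, duration, seed,
                                motor="dynein", cell_radius=spec.cell_radius)
            bf, ci = metrics.sequestration_and_concentration(
                res.positions[-1], res.states[-1], res.pole_positions)
            # turnover measured over the second half of the run
            mid = len(res.times) // 2
            first = metrics.nearest_pole_index(res.positions[mid], res.pole_positions)
            last = metrics.nearest_pole_index(res.positions[-1], res.pole_positions)
            p = float((first != last).mean())
            elapsed = float(res.times[-1] - res.times[mid])
            tau = metrics.turnover_time(min(max(p, 1.0 / (10 * n)), 1 - 1e-9), elapsed)
            rows.append({"mt_per_pole": c, "seed": seed, "bound_fraction": bf,
                         "concentration_index": ci, "turnover_time": tau})
    df = pd.DataFrame(rows)
    return df, df.groupby("mt_per_pole").mean(numeric_only=True).reset_index()


def _maturation_schedule(delay_style: str, duration: float, seed: int,
                         cell_radius=DEFAULT_CELL_RADIUS) -> MaturationSchedule:
    """Dominant centrosome grows 200->800 filaments over the run; the second
    either stays at 20 (long maturation delay) or grows 150->750 in parallel
    (short delay).  The second centrosome migrates along a quarter-circle arc
    from beside the dominant one to the diametrically opposite point."""
    t = [0.0, duration]
    dominant = ([0.0, duration], [200.0, 800.0])
    if delay_style == "long":
        second = ([0.0, duration], [20.0, 20.0])
    elif delay_style == "short":
        second = ([0.0, duration], [150.0, 750.0])
    else:
        raise ValueError("delay_style must be 'long' or 'short'")
    r = 0.5 * cell_radius
    dom_traj = ([0.0, duration], [[-r, 0, 0], [-r, 0, 0]])
    arc_t = np.linspace(0.0, duration, 33)
    ang = np.pi * (1.0 - arc_t / duration)  # from beside the dominant pole to opposite
    sec_traj = (arc_t, np.stack([-r * np.cos(ang), r * np.sin(ang), np.zeros_like(ang)], axis=1))
    return MaturationSchedule([dominant, second], [dom_traj, sec_traj],
                              cell_radius=cell_radius, seed=seed)


def fig3_maturation(delay_style="long", scale=1.0, duration=3000.0,
                    seeds=(1,), kinetics=None, rebuild_interval=None,
                    snapshot_stride=10_000):
    """Centrosome-maturation run; report bound-count trajectories per
    centrosome and the terminal asymmetric index."""
    kin = kinetics or KineticParams()
    n = _n_particles(scale)
    rebuild = rebuild_interval or max(duration / 60.0, 1.0)
    results = {}
    for seed in seeds:
        sched = _maturation_schedule(delay_style, duration, seed)
        init = _init_uniform(n, seed)
        results[seed] = run_maturation_sim(sched, kin, init, duration, seed,
                                           snapshot_stride=snapshot_stride,
                                           motor="dynein",
                                           rebuild_interval=rebuild)
    ai = []
    second_min = []
    for res in results.values():
        n1, n2 = res.bound_per_pole[-1]
        ai.append(metrics.asymmetric_index(float(n1), float(n2))
                  if (n1 + n2) else np.nan)
        second_min.append(int(res.bound_per_pole[len(res.times) // 3:, 1].min()))
    report = {"terminal_asymmetric_index": float(np.nanmean(ai)),
              "second_centrosome_min_bound": float(np.mean(second_min))}
    return results, report


def fig3e_asymmetry_vs_distance(partitions=((800, 200), (600, 400)),
                                distances=(4.0, 10.0), scale=0.2,
                                duration=20.0, seeds=(1, 2, 3), kinetics=None):
    """Steady-state particle asymmetry vs microtubule-number asymmetry and
    inter-centrosome distance (1000 filaments split between two asters)."""
    kin = kinetics or KineticParams()
    n = _n_particles(scale)
    rows = []
    for n1, n2 in partitions:
        for dist in distances:
            half = dist / 2.0
            poles = np.array([[-half, 0, 0], [half, 0, 0]])
            for seed in seeds:
                a1 = build_aster(poles[0], int(n1), seed, pole_id=0)
                a2 = build_aster(poles[1], int(n2), seed + 1, pole_id=1)
                mts = merge([a1, a2], poles)
                init = _init_uniform(n, seed)
                res = run_agent_sim(mts, kin, init, duration, seed, motor="dynein")
                b1, b2 = res.bound_per_pole[-1]
                rows.append({"mt_1": n1, "mt_2": n2, "distance": dist, "seed": seed,
                             "mt_asymmetry": metrics.asymmetric_index(n1, n2),
                             "particle_asymmetry": metrics.asymmetric_index(float(b1), float(b2))
                             if (b1 + b2) else np.nan})
    return pd.DataFrame(rows)


def fig4_frap(pure_diffusion=False, spacing=0.5, duration=300.0, dt=0.1,
              params: Optional[FieldParams] = None, **domain_overrides):
    """Mean-field FRAP of the central energid (sequestered by default)."""
    domain = EnergidDomain(spacing=spacing, **domain_overrides)
    if params is None:
        params = FieldParams(k_on=0.0 if pure_diffusion else 5.0)
    return run_frap(domain, params, duration=duration, dt=dt)


def fig4_flip(pure_diffusion=False, spacing=0.5, duration=108.0, dt=0.1,
              gap_width=7.0, params: Optional[FieldParams] = None,
              **domain_overrides):
    """Mean-field FLIP (continuous sink at the central energid); the gap
    width between energids is the unwalled depth below the furrow walls."""
    domain = EnergidDomain(spacing=spacing, wall_depth=14.0 - gap_width,
                           **domain_overrides)
    if params is None:
        params = FieldParams(k_on=0.0 if pure_diffusion else 5.0)
    return run_flip(domain, params, duration=duration, dt=dt)


def figS3_affinity_sweep(k_offs=(0.03, 0.1, 0.3, 1.0, 3.0), n_mts=200,
                         scale=0.2, duration=20.0, seeds=(1, 2), kinetics=None):
    """Single central MTOC; concentration index vs binding affinity (lower
    unbinding rate = higher affinity), expected sigmoidal."""
    base = (kinetics or KineticParams()).model_dump()
    n = _n_particles(scale)
    rows = []
    for k_off in k_offs:
        kin = KineticParams(**{**base, "k": k_off})
        for seed in seeds:
            mts = build_aster((0.0, 0.0, 0.0), int(n_mts), seed)
            init = _init_uniform(n, seed)
            res = run_agent_sim(mts, kin, init, duration, seed, motor="dynein")
            bf, ci = metrics.sequestration_and_concentration(
                res.positions[-1], res.states[-1], res.pole_positions)
            rows.append({"k_off": k_off, "seed": seed, "bound_fraction": bf,
                         "concentration_index": ci})
    return pd.DataFrame(rows)


def figS4_length(scale=0.2, duration=120.0, seeds=(1, 2, 3), kinetics=None,
                 n_long=200, n_short=1000, short_length=2.0,
                 snapshot_stride=10_000):
    """Length-vs-number competition: one pole organizes 200 half-cell-span
    filaments, the other 1000 short (2 µm) ones; report the share of bound
    particles held by the short-filament half-spindle."""
    kin = kinetics or KineticParams()
    n = _n_particles(scale)
    poles = np.array([[-5.0, 0, 0], [5.0, 0, 0]])
    results = {}
    shares = []
    for seed in seeds:
        long_aster = build_aster(poles[0], n_long, seed, pole_id=0,
                                 truncate_plane=((0.0, 0.0, 0.0), (1.0, 0.0, 0.0)))
        short_aster = build_aster(poles[1], n_short, seed + 1, length=short_length,
                                  pole_id=1)
        mts = merge([long_aster, short_aster], poles)
        init = _init_uniform(n, seed)
        res = run_agent_sim(mts, kin, init, duration, seed, motor="dynein",
                            snapshot_stride=snapshot_stride)
        results[seed] = res
        # average the share over the last fifth of the run (plateau window)
        tail = max(len(res.times) // 5, 1)
        counts = res.bound_per_pole[-tail:]
        tot = counts.sum(axis=1)
        ok = tot > 0
        shares.append(float((counts[ok, 1] / tot[ok]).mean()))
    report = {"short_half_bound_share": float(np.mean(shares)),
              "per_seed_share": shares}
    return results, report


def infoS3_kinesin(style="point", scale=0.3, duration=30.0, seeds=(1, 2, 3),
                   kinetics=None, equator_half_width=1.0, **spindle_overrides):
    """Kinesin accumulation in the equator zone (|x| <= 1 µm), with a
    binding-disabled control; report the fold enrichment."""
    kin = kinetics or KineticParams()
    spec = SpindleSpec(midzone_style="barrel" if style == "barrel" else "point",
                       **spindle_overrides)
    n = _n_particles(scale)
    folds, zone_counts = [], []
    results = {}
    for seed in seeds:
        mts = build_spindle(spec, seed)
        init = _init_uniform(n, seed, spec.cell_radius)
        res = run_agent_sim(mts, kin, init, duration, seed, motor="kinesin",
                            cell_radius=spec.cell_radius)
        ctl = run_agent_sim(mts, kin, init, duration, seed, motor="kinesin",
                            cell_radius=spec.cell_radius, binding_enabled=False)
        # average occupancy over the last half of each run
        half = max(len(res.times) // 2, 1)
        zone = np.mean([metrics.equator_zone_count(p, equator_half_width)
                        for p in res.positions[-half:]])
        zone_ctl = np.mean([metrics.equator_zone_count(p, equator_half_width)
                            for p in ctl.positions[-half:]])
        folds.append(zone / zone_ctl if zone_ctl else np.nan)
        zone_counts.append(zone)
        results[seed] = res
    report = {"equator_fold_enrichment": float(np.nanmean(folds)),
              "per_seed_fold": folds, "mean_zone_count": float(np.mean(zone_counts))}
    return results, report


REGISTRY: dict[str, Callable] = {
    "fig1_symmetric": fig1_symmetric,
    "fig1_one_pole_release": fig1_one_pole_release,
    "fig2_density_sweep": fig2_density_sweep,
    "fig3_long_delay": lambda **kw: fig3_maturation("long", **kw),
    "fig3_short_delay": lambda **kw: fig3_maturation("short", **kw),
    "fig3e_asymmetry_vs_distance": fig3e_asymmetry_vs_distance,
    "fig4_frap": fig4_frap,
    "fig4_flip": fig4_flip,
    "figS3_affinity_sweep": figS3_affinity_sweep,
    "figS4_length": figS4_length,
    "infoS3_kinesin": infoS3_kinesin,
    "infoS3_kinesin_barrel": lambda **kw: infoS3_kinesin("barrel", **kw),
}


def run_scenario(name: str, **kwargs):
    """Dispatch a registered scenario by name."""
    if name not in REGISTRY:
        raise KeyError(f"unknown scenario {name!r}; registered: "
                       + ", ".join(sorted(REGISTRY)))
    return REGISTRY[name](**kwargs)


def sweep(scenario: str, parameter: str, grid: Sequence, seeds=(1, 2, 3), **kwargs):
    """Generic one-parameter sweep over a registered scenario; one metrics row
    per grid point per seed."""
    if len(grid) == 0:
        raise ValueError("empty sweep grid")
    rows = []
    for value in grid:
        out = run_scenario(scenario, seeds=seeds, **{parameter: value}, **kwargs)
        report = out[1] if isinstance(out, tuple) else {}
        rows.append({"parameter": parameter, "value": value, **(
            report if isinstance(report, dict) else {})})
    return pd.DataFrame(rows)
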