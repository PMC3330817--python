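"""Agent-based Brownian-dynamics engine for motor/cargo particles.

Each particle is a sphere of radius ``r`` that diffuses freely in a
spherical cell, binds a microtubule whenever the gap between its surface and
the filament surface closes below the critical distance ``d0`` (so the
centre-to-axis threshold is R_M + r + d0), unbinds with first-order rate
``k``, and — while bound — translocates at motor speed ``V`` (toward minus
ends for dynein, plus ends for kinesin) with additional on-filament
diffusion ``D_M``.  Particles do not interact.

The per-step update order is: free diffusion → binding attempt → bound-state
update, one particle at a time with a counter-based RNG, so a fixed
(geometry, parameters, seed) triple reproduces output bitwise regardless of
how particles are scheduled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, Field

from . import _kernels
from .geometry import MicrotubuleSet, MaturationSchedule, DEFAULT_CELL_RADIUS

TABLE1_DT = 1e-4  # s; resolves rotational diffusion of the motor


class KineticParams(BaseModel):
    """Kinetic constants of the particle-microtubule system (units µm, s)."""
    model_config = ConfigDict(extra="forbid")

    dt: float = Field(TABLE1_DT, gt=0)
    D_C: float = Field(2.0, ge=0, description="cytoplasmic diffusion coefficient")
    D_M: float = Field(0.01, ge=0, description="diffusion coefficient along the filament")
    V: float = Field(1.0, ge=0, description="processive motor velocity")
    k: float = Field(1.0, ge=0, description="dissociation rate")
    d0: float = Field(8e-4, gt=0, description="critical binding distance")
    r: float = Field(0.005, gt=0, description="particle radius")
    plus_end_policy: str = Field("detach", pattern="^(detach|reflect)$")

    def model_post_init(self, _ctx) -> None:
        if self.dt > TABLE1_DT * (1 + 1e-12):
            warnings.warn(
                f"dt={self.dt} s exceeds the recommended {TABLE1_DT} s; binding "
                "kinetics become step-size dependent", stacklevel=2)
        if self.k * self.dt > 0.1:
            warnings.warn("k*dt is not small; unbinding statistics will be biased",
                          stacklevel=2)


MOTOR_SIGN = {"dynein": -1.0, "kinesin": 1.0, "none": 0.0}


@dataclass
class ScenarioResult:
    """Snapshots of an agent run.

    positions[t, i] is particle i at snapshot t; state 0 free / 1 bound;
    host_pole is the organizing pole of the bound filament (-1 if free).
    """
    times: np.ndarray                 # (T,)
    positions: np.ndarray             # (T, N, 3)
    states: np.ndarray                # (T, N) int8
    host_pole: np.ndarray             # (T, N) int32
    bound_per_pole: np.ndarray        # (T, P)
    pole_positions: np.ndarray        # (P, 3)
    nucleation_radius: float
    seed: int
    config: dict = field(default_factory=dict)

    @property
    def n_particles(self) -> int:
        return self.positions.shape[1]

    def snapshot_hash(self) -> str:
        import hashlib
        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.positions).tobytes())
        h.update(np.ascontiguousarray(self.states).tobytes())
        return h.hexdigest()


class _HashedGeometry:
    """Microtubule arrays + spatial hash, ready for the kernel."""

    def __init__(self, mts: MicrotubuleSet, cell_radius: float,
                 active: Optional[np.ndarray] = None, cell_size: float = 0.25):
        self.mts = mts
        self.cell_radius = cell_radius
        self.cell_size = cell_size
        self.active = (np.ones(len(mts), bool) if active is None
                       else np.asarray(active, bool))
        pad = 2.0 * cell_size
        extent = 2.0 * (cell_radius + pad)
        self.origin = np.full(3, -(cell_radius + pad))
        if len(mts) > 0:
            ncell = int(np.ceil(extent / cell_size))
            self.dims = np.array([ncell, ncell, ncell], np.int64)
            self.start, self.entries = _kernels.build_segment_hash(
                mts.minus, mts.plus, self.origin, cell_size, self.dims)
        else:
            # no filaments: a single grid cell suffices (queries find nothing)
            self.cell_size = extent
            self.dims = np.ones(3, np.int64)
            self.start = np.zeros(2, np.int64)
            self.entries = np.empty(0, np.int32)


def uniform_positions_in_sphere(n: int, radius: float, rng: np.random.Generator) -> np.ndarray:
    pts = rng.standard_normal((n, 3))
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    u = rng.uniform(0.0, 1.0, n) ** (1.0 / 3.0)
    return pts * (radius * u[:, None])


def run_agent_sim(
    mts: MicrotubuleSet,
    params: KineticParams,
    init_positions: np.ndarray,
    duration: float,
    seed: int,
    snapshot_stride: int = 10_000,
    motor: str = "dynein",
    cell_radius: float = DEFAULT_CELL_RADIUS,
    binding_enabled: bool = True,
    active: Optional[np.ndarray] = None,
    _state: Optional[tuple] = None,
    _step0: int = 0,
) -> ScenarioResult:
    """Simulate ``duration`` seconds of non-interacting particles.

    ``init_positions`` (N, 3) must lie inside the cell.  Snapshots are taken
    every ``snapshot_stride`` steps.  Identical inputs and seed give
    bitwise-identical output.
    """
    init_positions = np.atleast_2d(np.asarray(init_positions, dtype=np.float64))
    if np.any(np.linalg.norm(init_positions, axis=1) > cell_radius):
        raise ValueError("particle initialized outside the cell")
    if motor not in MOTOR_SIGN:
        raise ValueError(f"unknown motor type {motor!r}")
    n = init_positions.shape[0]

    geom = _HashedGeometry(mts, cell_radius, active=active)
    thr = mts.radius + params.r + params.d0

    if _state is None:
        pos = init_positions.copy()
        state = np.zeros(n, np.int8)
        host = np.full(n, -1, np.int32)
        arc = np.zeros(n, np.float64)
    else:
        pos, state, host, arc = _state

    n_steps = int(round(duration / params.dt))
    n_snap = (_step0 + n_steps) // snapshot_stride - _step0 // snapshot_stride
    snap_t0 = _step0 // snapshot_stride + 1
    snap_pos = np.empty((n_snap, n, 3))
    snap_state = np.empty((n_snap, n), np.int8)
    snap_host = np.empty((n_snap, n), np.int32)

    sign = MOTOR_SIGN[motor]
    _kernels.run_agent_kernel(
        pos, state, host, arc,
        n_steps, _step0, params.dt, seed,
        params.D_C, params.D_M, params.V, sign, params.k, thr, cell_radius,
        mts.minus, mts.direction, mts.length, mts.pole_id,
        mts.prev_link, mts.next_link, geom.active,
        geom.origin, geom.cell_size, geom.dims, geom.start, geom.entries,
        snapshot_stride, snap_pos, snap_state, snap_host, snap_t0,
        binding_enabled, params.plus_end_policy == "detach",
    )

    times = (snap_t0 + np.arange(n_snap)) * snapshot_stride * params.dt
    host_pole = np.where(snap_host >= 0,
                         mts.pole_id[np.clip(snap_host, 0, max(len(mts) - 1, 0))]
                         if len(mts) else -1,
                         -1).astype(np.int32)
    n_poles = mts.n_poles
    bound_per_pole = np.stack(
        [((snap_state == 1) & (host_pole == p)).sum(axis=1) for p in range(n_poles)],
        axis=1)
    res = ScenarioResult(
        times=times, positions=snap_pos, states=snap_state, host_pole=host_pole,
        bound_per_pole=bound_per_pole, pole_positions=mts.pole_positions,
        nucleation_radius=mts.nucleation_radius, seed=seed,
        config={"motor": motor, "duration": duration, "cell_radius": cell_radius,
                "binding_enabled": binding_enabled,
                "kinetics": params.model_dump()},
    )
    res._final_state = (pos, state, host, arc)  # for segmented runs
    res._final_step = _step0 + n_steps
    return res


def run_maturation_sim(
    schedule: MaturationSchedule,
    params: KineticParams,
    init_positions: np.ndarray,
    duration: float,
    seed: int,
    snapshot_stride: int = 10_000,
    motor: str = "dynein",
    rebuild_interval: float = 10.0,
    cell_radius: float = DEFAULT_CELL_RADIUS,
) -> ScenarioResult:
    """Agent run under a centrosome-maturation schedule.

    The microtubule set is regenerated every ``rebuild_interval`` seconds of
    simulated time (new filaments appear instantly full length; a moving
    centrosome carries its filaments and their bound particles rigidly, the
    arc-length coordinate being preserved across rebuilds).
    """
    t = 0.0
    state = None
    step0 = 0
    chunks = []
    prev_mts = None
    while t < duration - 1e-9:
        dt_chunk = min(rebuild_interval, duration - t)
        mts, active = schedule.mt_set_at(t)
        if state is not None and prev_mts is not None:
            pos, st, host, arc = state
            bound = st == 1
            # rigid translation: recompute axis positions on the new geometry
            arc_c = np.clip(arc[bound], 0.0, mts.length[host[bound]])
            pos[bound] = mts.minus[host[bound]] + arc_c[:, None] * mts.direction[host[bound]]
            arc[bound] = arc_c
            state = (pos, st, host, arc)
        res = run_agent_sim(
            mts, params, init_positions, dt_chunk, seed,
            snapshot_stride=snapshot_stride, motor=motor, cell_radius=cell_radius,
            active=active, _state=state, _step0=step0,
        )
        chunks.append(res)
        state = res._final_state
        step0 = res._final_step
        prev_mts = mts
        t += dt_chunk

    out = ScenarioResult(
        times=np.concatenate([c.times for c in chunks]),
        positions=np.concatenate([c.positions for c in chunks]),
        states=np.concatenate([c.states for c in chunks]),
        host_pole=np.concatenate([c.host_pole for c in chunks]),
        bound_per_pole=np.concatenate([c.bound_per_pole for c in chunks]),
        pole_positions=chunks[-1].pole_positions,
        nucleation_radius=schedule.nucleation_radius,
        seed=seed,
        config={"motor": motor, "duration": duration,
                "rebuild_interval": rebuild_interval,
                "kinetics": params.model_dump()},
    )
    return out
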