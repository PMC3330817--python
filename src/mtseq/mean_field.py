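"""Mean-field bound/free reaction-diffusion solver on the energid domain.

Densities: rho_f (free) and rho_b (bound) on a regular finite-volume grid,

    d(rho_f)/dt = D_C lap(rho_f) - k_b rho_f + k_u rho_b
    d(rho_b)/dt = D_M lap(rho_b) - div(V n rho_b) + k_b rho_f - k_u rho_b

with no-flux outer boundaries and no-flux internal wall faces between
energids.  k_b is nonzero only inside the sequestration mask.  For the
Dorsal (cortex) scenario bound transport is off (V = 0, D_M = 0) and rho_b
is locally immobile.

Discretization: finite volume, diffusion advanced with backward Euler via a
one-time sparse LU factorization (unconditionally stable, conserves mass to
solver precision); the local binding/unbinding pair is integrated exactly
per cell; the two are combined by Strang splitting.  Optional bound-phase
advection (orientation field, velocity V) uses explicit first-order upwind.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu
from pydantic import BaseModel, ConfigDict, Field

from .geometry import EnergidDomain


class FieldParams(BaseModel):
    """Mean-field kinetic parameters (defaults: Dorsal in the embryo cortex)."""
    model_config = ConfigDict(extra="forbid")

    D_C: float = Field(20.0, ge=0)
    D_M: float = Field(0.0, ge=0)
    V: float = Field(0.0, ge=0)
    k_on: float = Field(5.0, ge=0, description="binding rate inside the mask")
    k_off: float = Field(1.0, ge=0)


@dataclass
class DensityFieldPair:
    rho_f: np.ndarray  # (nx, ny, nz)
    rho_b: np.ndarray
    time: float

    @property
    def total(self) -> np.ndarray:
        return self.rho_f + self.rho_b


def _laplacian(domain: EnergidDomain, D: float) -> sp.csc_matrix:
    """Finite-volume Laplacian with blocked wall faces (row-major x,y,z order)."""
    nx, ny, nz = domain.shape
    h = domain.spacing
    bx, by = domain.blocked_faces()
    n = nx * ny * nz
    idx = np.arange(n).reshape(nx, ny, nz)
    coef = D / h ** 2

    rows, cols, vals = [], [], []

    def couple(a_idx, b_idx, open_mask):
        t = np.where(open_mask, coef, 0.0).ravel()
        a = a_idx.ravel()
        b = b_idx.ravel()
        rows.extend([a, a, b, b])
        cols.extend([b, a, a, b])
        vals.extend([t, -t, t, -t])

    couple(idx[:-1, :, :], idx[1:, :, :], ~bx)
    couple(idx[:, :-1, :], idx[:, 1:, :], ~by)
    couple(idx[:, :, :-1], idx[:, :, 1:], np.ones((nx, ny, nz - 1), bool))

    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    vals = np.concatenate(vals)
    return sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsc()


class MeanFieldSolver:
    """Time stepper for the coupled free/bound fields on one domain."""

    def __init__(self, domain: EnergidDomain, params: FieldParams, dt: float,
                 mask: Optional[np.ndarray] = None,
                 orientation: Optional[np.ndarray] = None):
        self.domain = domain
        self.params = params
        self.dt = float(dt)
        self.shape = domain.shape
        n = int(np.prod(self.shape))
        self.mask = domain.sequestration_mask() if mask is None else np.asarray(mask, bool)
        self.k_b = np.where(self.mask.ravel(), params.k_on, 0.0)
        self.k_u = params.k_off
        self.orientation = orientation
        if params.V > 0 and orientation is None:
            raise ValueError("advection requested but no orientation field given")

        self._lu_f = None
        if params.D_C > 0:
            A = sp.identity(n, format="csc") - self.dt * _laplacian(domain, params.D_C)
            self._lu_f = splu(A)
        self._lu_b = None
        if params.D_M > 0:
            A = sp.identity(n, format="csc") - self.dt * _laplacian(domain, params.D_M)
            self._lu_b = splu(A)

        self.rho_f = np.zeros(n)
        self.rho_b = np.zeros(n)
        self.time = 0.0

    # -- state management ---------------------------------------------------
    def set_state(self, rho_f: np.ndarray, rho_b: np.ndarray, time: float = 0.0):
        self.rho_f = np.asarray(rho_f, float).ravel().copy()
        self.rho_b = np.asarray(rho_b, float).ravel().copy()
        self.time = time

    def set_steady_state(self, level: float = 1.0):
        """Analytic sequestered steady state (exact when bound transport is
        off): rho_f uniform, rho_b = (k_b/k_u) rho_f inside the mask."""
        n = int(np.prod(self.shape))
        self.rho_f = np.full(n, level)
        if self.k_u > 0:
            self.rho_b = self.k_b / self.k_u * self.rho_f
        else:
            self.rho_b = np.zeros(n)
        self.time = 0.0

    def snapshot(self) -> DensityFieldPair:
        return DensityFieldPair(self.rho_f.reshape(self.shape).copy(),
                                self.rho_b.reshape(self.shape).copy(), self.time)

    @property
    def total_mass(self) -> float:
        return float((self.rho_f.sum() + self.rho_b.sum()) * self.domain.cell_volume)

    # -- stepping -----------------------------------------------------------
    def _react(self, dt: float):
        kb, ku = self.k_b, self.k_u
        rate = kb + ku
        with np.errstate(divide="ignore", invalid="ignore"):
            frac_b = np.where(rate > 0, kb / np.where(rate > 0, rate, 1.0), 0.0)
        tot = self.rho_f + self.rho_b
        eq_b = frac_b * tot
        decay = np.exp(-rate * dt)
        self.rho_b = eq_b + (self.rho_b - eq_b) * decay
        self.rho_f = tot - self.rho_b

    def _advect(self, dt: float):
        if self.params.V == 0 or self.orientation is None:
            return
        # conservative first-order upwind; face velocity = mean of the two
        # cell velocities, zero on walls and outer boundaries
        v = self.params.V * self.orientation  # (3, nx, ny, nz)
        h = self.domain.spacing
        if np.max(np.abs(v)) * dt / h > 1.0:
            raise ValueError("advection CFL violated; reduce dt")
        rb = self.rho_b.reshape(self.shape)
        bx, by = self.domain.blocked_faces()
        blocked = {0: bx, 1: by, 2: None}
        div = np.zeros_like(rb)
        for ax in range(3):
            sl_lo = [slice(None)] * 3
            sl_hi = [slice(None)] * 3
            sl_lo[ax] = slice(None, -1)
            sl_hi[ax] = slice(1, None)
            vf = 0.5 * (v[ax][tuple(sl_lo)] + v[ax][tuple(sl_hi)])
            if blocked[ax] is not None:
                vf = np.where(blocked[ax], 0.0, vf)
            up = np.where(vf > 0, rb[tuple(sl_lo)], rb[tuple(sl_hi)])
            flux = vf * up  # face flux, outer faces are simply absent (no flux)
            div[tuple(sl_lo)] += flux / h
            div[tuple(sl_hi)] -= flux / h
        self.rho_b = (rb - dt * div).ravel()

    def step(self):
        self._react(self.dt / 2.0)
        if self._lu_f is not None:
            self.rho_f = self._lu_f.solve(self.rho_f)
        if self._lu_b is not None:
            self.rho_b = self._lu_b.solve(self.rho_b)
        self._advect(self.dt)
        self._react(self.dt / 2.0)
        self.time += self.dt
        if self.rho_f.min() < -1e-9 or self.rho_b.min() < -1e-9:
            raise RuntimeError("negative density: scheme failure")

    def run(self, duration: float, output_stride: int = 0,
            sink_mask: Optional[np.ndarray] = None) -> list[DensityFieldPair]:
        """Advance ``duration`` seconds; optionally hold ``sink_mask`` cells at
        zero (continuous photobleaching).  Returns snapshots every
        ``output_stride`` steps (none if 0)."""
        out = []
        n_steps = int(round(duration / self.dt))
        sink = None if sink_mask is None else np.asarray(sink_mask, bool).ravel()
        for s in range(n_steps):
            if sink is not None:
                self.rho_f[sink] = 0.0
                self.rho_b[sink] = 0.0
            self.step()
            if output_stride and (s + 1) % output_stride == 0:
                out.append(self.snapshot())
        if sink is not None:
            self.rho_f[sink] = 0.0
            self.rho_b[sink] = 0.0
        return out


def solve_mean_field(domain: EnergidDomain, params: FieldParams,
                     init: DensityFieldPair, duration: float,
                     output_stride: int, dt: float = 0.1,
                     mask: Optional[np.ndarray] = None) -> list[DensityFieldPair]:
    """Convenience wrapper: advance an initial field pair and return snapshots."""
    solver = MeanFieldSolver(domain, params, dt, mask=mask)
    solver.set_state(init.rho_f, init.rho_b, init.time)
    return solver.run(duration, output_stride)


# ---------------------------------------------------------------------------
# Photobleaching protocols
# ---------------------------------------------------------------------------

@dataclass
class FrapResult:
    times: np.ndarray
    curve: np.ndarray            # normalized total concentration at the monitor cell
    monitor_cell: tuple
    pre_bleach_value: float
    snapshots: list
    aux_curves: Optional[dict] = None   # extra monitor cells, same normalization

    def plateau(self, tail_fraction: float = 0.05) -> float:
        k = max(int(len(self.curve) * tail_fraction), 1)
        return float(self.curve[-k:].mean())

    def recovery_time(self, level: float = 0.9) -> float:
        """First time the curve reaches `level` x its long-time plateau."""
        target = level * self.plateau()
        above = np.nonzero(self.curve >= target)[0]
        if above.size == 0:
            return float("inf")
        i = above[0]
        if i == 0:
            return float(self.times[0])
        # linear interpolation between the bracketing samples
        t0, t1 = self.times[i - 1], self.times[i]
        c0, c1 = self.curve[i - 1], self.curve[i]
        return float(t0 + (target - c0) / (c1 - c0) * (t1 - t0))


def _region_mask(domain: EnergidDomain, box) -> np.ndarray:
    """Cell mask of an axis-aligned box ((x0,x1),(y0,y1),(z0,z1)) in µm."""
    nx, ny, nz = domain.shape
    h = domain.spacing
    (x0, x1), (y0, y1), (z0, z1) = box
    if not (0 <= x0 <= x1 <= domain.width and 0 <= y0 <= y1 <= domain.depth
            and 0 <= z0 <= z1 <= domain.height):
        raise ValueError("bleach region outside domain")
    cx = domain.cell_centers(0)
    cy = domain.cell_centers(1)
    cz = domain.cell_centers(2)
    return ((cx[:, None, None] > x0) & (cx[:, None, None] < x1)
            & (cy[None, :, None] > y0) & (cy[None, :, None] < y1)
            & (cz[None, None, :] > z0) & (cz[None, None, :] < z1))


def center_energid_box(domain: EnergidDomain) -> tuple:
    """Footprint of the central energid (full energid depth)."""
    i = j = domain.n_sub // 2
    wx = domain.width / domain.n_sub
    wy = domain.depth / domain.n_sub
    return ((i * wx, (i + 1) * wx), (j * wy, (j + 1) * wy), (0.0, domain.energid_depth))


def run_frap(domain: EnergidDomain, params: FieldParams,
             bleach_box: Optional[tuple] = None,
             bleach_depth_fraction: float = 1.0,
             duration: float = 300.0, dt: float = 0.1,
             pre_equilibrate: float = 0.0,
             snapshot_stride: int = 0,
             monitor_cell: Optional[tuple] = None,
             extra_monitor_cells: Optional[dict] = None) -> FrapResult:
    """Bleach once, watch the recovery at the bleached-energid centre.

    The system starts from its sequestered steady state (analytic, optionally
    refined by ``pre_equilibrate`` seconds of integration).  At t = 0 both
    densities inside the bleach box are scaled by (1 - bleach_depth_fraction).
    The returned curve is total concentration at the monitor cell normalized
    by its pre-bleach value.
    """
    if bleach_box is None:
        bleach_box = center_energid_box(domain)
    solver = MeanFieldSolver(domain, params, dt)
    solver.set_steady_state()
    if pre_equilibrate > 0:
        solver.run(pre_equilibrate)
        solver.time = 0.0
    if monitor_cell is None:
        monitor_cell = domain.subdomain_center_cell(domain.n_sub // 2, domain.n_sub // 2)
    flat = np.ravel_multi_index(monitor_cell, domain.shape)
    pre = solver.rho_f[flat] + solver.rho_b[flat]
    extra = {name: np.ravel_multi_index(cell, domain.shape)
             for name, cell in (extra_monitor_cells or {}).items()}

    mask = _region_mask(domain, bleach_box).ravel()
    keep = 1.0 - bleach_depth_fraction
    solver.rho_f[mask] *= keep
    solver.rho_b[mask] *= keep

    n_steps = int(round(duration / dt))
    times = np.empty(n_steps + 1)
    curve = np.empty(n_steps + 1)
    aux = {name: np.empty(n_steps + 1) for name in extra}
    times[0] = 0.0
    curve[0] = (solver.rho_f[flat] + solver.rho_b[flat]) / pre
    for name, fl in extra.items():
        aux[name][0] = (solver.rho_f[fl] + solver.rho_b[fl]) / pre
    snaps = [solver.snapshot()] if snapshot_stride else []
    for s in range(n_steps):
        solver.step()
        times[s + 1] = solver.time
        curve[s + 1] = (solver.rho_f[flat] + solver.rho_b[flat]) / pre
        for name, fl in extra.items():
            aux[name][s + 1] = (solver.rho_f[fl] + solver.rho_b[fl]) / pre
        if snapshot_stride and (s + 1) % snapshot_stride == 0:
            snaps.append(solver.snapshot())
    return FrapResult(times, curve, monitor_cell, pre, snaps, aux or None)


@dataclass
class FlipResult:
    times: np.ndarray
    total_mass: np.ndarray
    snapshots: list


def run_flip(domain: EnergidDomain, params: FieldParams,
             bleach_box: Optional[tuple] = None,
             duration: float = 108.0, dt: float = 0.1,
             snapshot_times: tuple = (108.0,)) -> FlipResult:
    """Continuous photobleaching: the bleach region is a perfect sink.

    Snapshots (e.g. the 108 s side view) are taken at the requested times.
    """
    if bleach_box is None:
        bleach_box = center_energid_box(domain)
    solver = MeanFieldSolver(domain, params, dt)
    solver.set_steady_state()
    sink = _region_mask(domain, bleach_box).ravel()

    n_steps = int(round(duration / dt))
    times = np.empty(n_steps + 1)
    mass = np.empty(n_steps + 1)
    times[0] = 0.0
    solver.rho_f[sink] = 0.0
    solver.rho_b[sink] = 0.0
    mass[0] = solver.total_mass
    snaps = []
    want = sorted(snapshot_times)
    wi = 0
    for s in range(n_steps):
        solver.rho_f[sink] = 0.0
        solver.rho_b[sink] = 0.0
        solver.step()
        solver.rho_f[sink] = 0.0
        solver.rho_b[sink] = 0.0
        times[s + 1] = solver.time
        mass[s + 1] = solver.total_mass
        while wi < len(want) and solver.time >= want[wi] - 1e-9:
            snaps.append(solver.snapshot())
            wi += 1
    return FlipResult(times, mass, snaps)
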