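"""Numba kernels: counter-based RNG, spatial hash, per-particle stepping.

The RNG is a splitmix64 counter scheme keyed on (seed, particle, step, draw),
so trajectories are reproducible and independent of particle iteration
order.  Normals come from Box-Muller on two counter draws.

Particle states: 0 = free, 1 = bound.  Bound particles live on a segment
(host index) at an arc-length coordinate from the minus end; their position
is always the axis point at that coordinate.
"""

import numpy as np
from numba import njit

U64 = np.uint64
_MASK = U64(0xFFFFFFFFFFFFFFFF)
_C1 = U64(0x9E3779B97F4A7C15)
_C2 = U64(0xBF58476D1CE4E5B9)
_C3 = U64(0x94D049BB133111EB)
_TWO53 = 1.0 / 9007199254740992.0  # 2**-53


@njit(cache=True, inline="always")
def _splitmix(z):
    z = (z + _C1) & _MASK
    z = ((z ^ (z >> U64(30))) * _C2) & _MASK
    z = ((z ^ (z >> U64(27))) * _C3) & _MASK
    return z ^ (z >> U64(31))


@njit(cache=True, inline="always")
def _step_key(seed, pid, step):
    a = _splitmix(U64(seed) ^ (U64(pid) * _C2))
    return _splitmix(a ^ (U64(step) * _C3))


@njit(cache=True, inline="always")
def _uniform(key, ctr):
    """Uniform draw in (0, 1]."""
    z = _splitmix((key + U64(ctr) * _C1) & _MASK)
    return ((z >> U64(11)) + U64(1)) * _TWO53


@njit(cache=True, inline="always")
def _normal_pair(key, ctr):
    u1 = _uniform(key, ctr)
    u2 = _uniform(key, ctr + 1)
    r = np.sqrt(-2.0 * np.log(u1))
    a = 2.0 * np.pi * u2
    return r * np.cos(a), r * np.sin(a)


# ---------------------------------------------------------------------------
# Spatial hash over microtubule segments (uniform grid, CSR layout)
# ---------------------------------------------------------------------------

@njit(cache=True)
def _traverse_cells(p0, p1, origin, h, dims, out):
    """Amanatides-Woo voxel traversal of the segment p0→p1.

    Writes linear cell indices into `out`; returns the count.  Exact: every
    grid cell the segment passes through is emitted, so a query that scans
    the 27-neighbourhood of a particle's cell sees every segment within one
    cell size of it.
    """
    nx, ny, nz = dims[0], dims[1], dims[2]
    ix = int(np.floor((p0[0] - origin[0]) / h))
    iy = int(np.floor((p0[1] - origin[1]) / h))
    iz = int(np.floor((p0[2] - origin[2]) / h))
    jx = int(np.floor((p1[0] - origin[0]) / h))
    jy = int(np.floor((p1[1] - origin[1]) / h))
    jz = int(np.floor((p1[2] - origin[2]) / h))
    ix = min(max(ix, 0), nx - 1); iy = min(max(iy, 0), ny - 1); iz = min(max(iz, 0), nz - 1)
    jx = min(max(jx, 0), nx - 1); jy = min(max(jy, 0), ny - 1); jz = min(max(jz, 0), nz - 1)

    dx = p1[0] - p0[0]; dy = p1[1] - p0[1]; dz = p1[2] - p0[2]
    sx = 1 if dx > 0 else -1; sy = 1 if dy > 0 else -1; sz = 1 if dz > 0 else -1
    big = 1e30
    tdx = abs(h / dx) if dx != 0.0 else big
    tdy = abs(h / dy) if dy != 0.0 else big
    tdz = abs(h / dz) if dz != 0.0 else big

    def _tmax(p, o, i, s, d):
        if d == 0.0:
            return big
        if s > 0:
            edge = o + (i + 1) * h
        else:
            edge = o + i * h
        return (edge - p) / d

    tmx = _tmax(p0[0], origin[0], ix, sx, dx)
    tmy = _tmax(p0[1], origin[1], iy, sy, dy)
    tmz = _tmax(p0[2], origin[2], iz, sz, dz)

    n = 0
    while True:
        out[n] = (ix * ny + iy) * nz + iz
        n += 1
        if ix == jx and iy == jy and iz == jz:
            break
        if n >= out.shape[0]:
            break
        if tmx <= tmy and tmx <= tmz:
            ix += sx; tmx += tdx
        elif tmy <= tmz:
            iy += sy; tmy += tdy
        else:
            iz += sz; tmz += tdz
        if ix < 0 or iy < 0 or iz < 0 or ix >= nx or iy >= ny or iz >= nz:
            break
    return n


@njit(cache=True)
def build_segment_hash(minus, plus, origin, h, dims):
    """CSR spatial hash: cell_start (ncells+1) and segment entries per cell.

    Two passes over an exact voxel traversal (the DDA never revisits a cell,
    so no dedup is needed)."""
    m = minus.shape[0]
    ncell = dims[0] * dims[1] * dims[2]
    scratch = np.empty(16384, np.int64)
    counts = np.zeros(ncell + 1, np.int64)
    for j in range(m):
        k = _traverse_cells(minus[j], plus[j], origin, h, dims, scratch)
        for e in range(k):
            counts[scratch[e] + 1] += 1
    start = np.cumsum(counts)
    entries = np.empty(start[-1], np.int32)
    cursor = start[:-1].copy()
    for j in range(m):
        k = _traverse_cells(minus[j], plus[j], origin, h, dims, scratch)
        for e in range(k):
            c = scratch[e]
            entries[cursor[c]] = j
            cursor[c] += 1
    return start, entries


@njit(cache=True, inline="always")
def _point_segment_dist2(px, py, pz, a, d, length, j):
    """Squared distance from point to segment j plus clamped arc coordinate."""
    wx = px - a[j, 0]; wy = py - a[j, 1]; wz = pz - a[j, 2]
    t = wx * d[j, 0] + wy * d[j, 1] + wz * d[j, 2]
    if t < 0.0:
        t = 0.0
    elif t > length[j]:
        t = length[j]
    cx = a[j, 0] + t * d[j, 0] - px
    cy = a[j, 1] + t * d[j, 1] - py
    cz = a[j, 2] + t * d[j, 2] - pz
    return cx * cx + cy * cy + cz * cz, t


@njit(cache=True)
def nearest_segment(px, py, pz, minus, dirs, length, active,
                    origin, h, dims, start, entries):
    """Nearest active segment via the hash (27-cell scan).

    Returns (index, distance, arc).  Ties broken by smaller distance then
    lower segment id (ids are scanned in increasing order per cell and the
    strict '<' keeps the first/lowest id).
    """
    nx, ny, nz = dims[0], dims[1], dims[2]
    ix = int(np.floor((px - origin[0]) / h))
    iy = int(np.floor((py - origin[1]) / h))
    iz = int(np.floor((pz - origin[2]) / h))
    best = -1
    best_d2 = 1e300
    best_t = 0.0
    for ax in range(max(ix - 1, 0), min(ix + 2, nx)):
        for ay in range(max(iy - 1, 0), min(iy + 2, ny)):
            for az in range(max(iz - 1, 0), min(iz + 2, nz)):
                c = (ax * ny + ay) * nz + az
                for e in range(start[c], start[c + 1]):
                    j = entries[e]
                    if not active[j]:
                        continue
                    d2, t = _point_segment_dist2(px, py, pz, minus, dirs, length, j)
                    if d2 < best_d2 or (d2 == best_d2 and best >= 0 and j < best):
                        best = j
                        best_d2 = d2
                        best_t = t
    return best, np.sqrt(best_d2), best_t


@njit(cache=True)
def nearest_segment_brute(px, py, pz, minus, dirs, length, active):
    """Brute-force reference for the hash query (contract test oracle)."""
    best = -1
    best_d2 = 1e300
    best_t = 0.0
    for j in range(minus.shape[0]):
        if not active[j]:
            continue
        d2, t = _point_segment_dist2(px, py, pz, minus, dirs, length, j)
        if d2 < best_d2 or (d2 == best_d2 and best >= 0 and j < best):
            best = j
            best_d2 = d2
            best_t = t
    return best, np.sqrt(best_d2), best_t


# ---------------------------------------------------------------------------
# 3D agent stepping
# ---------------------------------------------------------------------------

@njit(cache=True)
def run_agent_kernel(
    pos, state, host, arc,                       # particle arrays, mutated
    n_steps, step0, dt, seed,
    D_C, D_M, V, sign, k_off, thr, R_C,
    minus, dirs, length, pole_id, prev_link, next_link, active,
    origin, h, dims, start, entries,
    snap_stride, snap_pos, snap_state, snap_host, snap_t0,
    binding_enabled, plus_end_detach,
):
    """Advance all particles n_steps; record snapshots every snap_stride.

    Free phase: isotropic Gaussian displacement (2·D_C·dt variance per axis),
    specular reflection at the cell sphere, then proximity binding (probability
    1 when the centre-to-axis distance is within `thr` = R_M + r + d0).
    Bound phase: unbind with prob 1−exp(−k·dt); otherwise drift sign·V·dt plus
    on-filament diffusion; minus ends reflect, plus ends detach (or reflect),
    chained segments (bent filaments) transfer the walker across the joint.
    """
    n = pos.shape[0]
    sig_c = np.sqrt(2.0 * D_C * dt)
    sig_m = np.sqrt(2.0 * D_M * dt)
    p_unbind = 1.0 - np.exp(-k_off * dt)
    n_snap = snap_pos.shape[0]

    for s in range(n_steps):
        gstep = step0 + s
        for i in range(n):
            key = _step_key(seed, i, gstep)
            if state[i] == 0:
                # free diffusion
                if sig_c > 0.0:
                    g0, g1 = _normal_pair(key, 0)
                    g2, _ = _normal_pair(key, 2)
                    x = pos[i, 0] + sig_c * g0
                    y = pos[i, 1] + sig_c * g1
                    z = pos[i, 2] + sig_c * g2
                else:
                    x = pos[i, 0]; y = pos[i, 1]; z = pos[i, 2]
                rr = np.sqrt(x * x + y * y + z * z)
                if rr > R_C:
                    f = (2.0 * R_C - rr) / rr
                    x *= f; y *= f; z *= f
                pos[i, 0] = x; pos[i, 1] = y; pos[i, 2] = z
                if binding_enabled:
                    j, dist, t = nearest_segment(x, y, z, minus, dirs, length,
                                                 active, origin, h, dims, start, entries)
                    if j >= 0 and dist <= thr:
                        state[i] = 1
                        host[i] = j
                        arc[i] = t
                        pos[i, 0] = minus[j, 0] + t * dirs[j, 0]
                        pos[i, 1] = minus[j, 1] + t * dirs[j, 1]
                        pos[i, 2] = minus[j, 2] + t * dirs[j, 2]
            else:
                u = _uniform(key, 0)
                if u < p_unbind:
                    state[i] = 0
                    host[i] = -1
                    # released at the current axis point; free diffusion resumes
                    # on the next step
                else:
                    j = host[i]
                    g0, _ = _normal_pair(key, 1)
                    a = arc[i] + sign * V * dt + sig_m * g0
                    # end handling, following chain links where present
                    for _rep in range(8):
                        if a < 0.0:
                            pj = prev_link[j]
                            if pj >= 0:
                                j = pj
                                a = length[j] + a
                            else:
                                a = -a  # reflect at the minus end (pole)
                        elif a > length[j]:
                            nj = next_link[j]
                            if nj >= 0:
                                a = a - length[j]
                                j = nj
                            elif plus_end_detach:
                                a = length[j]
                                state[i] = 0
                                break
                            else:
                                a = 2.0 * length[j] - a
                        else:
                            break
                    host[i] = j if state[i] == 1 else -1
                    arc[i] = a
                    pos[i, 0] = minus[j, 0] + a * dirs[j, 0]
                    pos[i, 1] = minus[j, 1] + a * dirs[j, 1]
                    pos[i, 2] = minus[j, 2] + a * dirs[j, 2]
        if snap_stride > 0 and (gstep + 1) % snap_stride == 0:
            idx = (gstep + 1) // snap_stride - snap_t0
            if 0 <= idx < n_snap:
                for i in range(n):
                    snap_pos[idx, i, 0] = pos[i, 0]
                    snap_pos[idx, i, 1] = pos[i, 1]
                    snap_pos[idx, i, 2] = pos[i, 2]
                    snap_state[idx, i] = state[i]
                    snap_host[idx, i] = host[i]


# ---------------------------------------------------------------------------
# 2D periodic calibration box
# ---------------------------------------------------------------------------

@njit(cache=True)
def run_calibration_kernel(
    n_particles, n_steps, dt, seed,
    box, D, k_off, contact_r, bind_r,
    burn_steps,
):
    """2D periodic box with one microtubule disc at the centre.

    The particle centre reflects off the contact circle (MT radius + particle
    radius) and binds when it lands within `bind_r` = contact_r + d0 of the
    disc centre.  Unbinding releases the particle at its binding point.

    Returns (bound_steps_after_burn, total_steps_after_burn,
             n_bind_events, n_unbind_events, sum_bound_duration,
             sum_free_duration, per_particle_bound_steps).
    """
    half = box / 2.0
    sig = np.sqrt(2.0 * D * dt)
    p_unbind = 1.0 - np.exp(-k_off * dt)
    bound_steps = 0
    total_steps = 0
    n_bind = 0
    n_unbind = 0
    sum_bound = 0.0
    sum_free = 0.0
    per_bound = np.zeros(n_particles, np.int64)

    for i in range(n_particles):
        # start at a uniform position outside the contact circle
        k0 = _step_key(seed, i, 0)
        x = box * 0.49
        y = box * 0.49
        for _try in range(1000):  # bounded: tiny boxes may be fully inside bind_r
            xx = (_uniform(k0, 11) - 0.5) * box
            yy = (_uniform(k0, 12) - 0.5) * box
            k0 = _splitmix(k0)
            if xx * xx + yy * yy > bind_r * bind_r:
                x = xx
                y = yy
                break
        bound = False
        bx = 0.0
        by = 0.0
        t_enter = 0
        for s in range(1, n_steps + 1):
            key = _step_key(seed, i, s)
            if bound:
                u = _uniform(key, 0)
                if u < p_unbind:
                    bound = False
                    x = bx
                    y = by
                    sum_bound += (s - t_enter) * dt
                    n_unbind += 1
                    t_enter = s
            else:
                g0, g1 = _normal_pair(key, 1)
                x += sig * g0
                y += sig * g1
                # periodic wrap
                if x > half:
                    x -= box
                elif x < -half:
                    x += box
                if y > half:
                    y -= box
                elif y < -half:
                    y += box
                r = np.sqrt(x * x + y * y)
                if r < contact_r:
                    # specular reflection off the disc surface
                    f = (2.0 * contact_r - r) / r
                    x *= f
                    y *= f
                    r = 2.0 * contact_r - r
                if r <= bind_r:
                    bound = True
                    bx = x
                    by = y
                    sum_free += (s - t_enter) * dt
                    n_bind += 1
                    t_enter = s
            if s > burn_steps:
                total_steps += 1
                if bound:
                    bound_steps += 1
                    per_bound[i] += 1
    return bound_steps, total_steps, n_bind, n_unbind, sum_bound, sum_free, per_bound


@njit(cache=True)
def run_calibration_transient(n_particles, n_steps, record_stride, dt, seed,
                              box, D, k_off, contact_r, bind_r):
    """Bound-fraction relaxation curve from an all-free start (for the
    mean-field compatibility check)."""
    half = box / 2.0
    sig = np.sqrt(2.0 * D * dt)
    p_unbind = 1.0 - np.exp(-k_off * dt)
    n_rec = n_steps // record_stride
    bound_count = np.zeros(n_rec, np.int64)
    for i in range(n_particles):
        k0 = _step_key(seed, i + 1000003, 0)
        x = box * 0.49
        y = box * 0.49
        for _try in range(1000):
            xx = (_uniform(k0, 11) - 0.5) * box
            yy = (_uniform(k0, 12) - 0.5) * box
            k0 = _splitmix(k0)
            if xx * xx + yy * yy > bind_r * bind_r:
                x = xx
                y = yy
                break
        bound = False
        bx = 0.0
        by = 0.0
        for s in range(1, n_steps + 1):
            key = _step_key(seed, i + 1000003, s)
            if bound:
                if _uniform(key, 0) < p_unbind:
                    bound = False
                    x = bx
                    y = by
            else:
                g0, g1 = _normal_pair(key, 1)
                x += sig * g0
                y += sig * g1
                if x > half:
                    x -= box
                elif x < -half:
                    x += box
                if y > half:
                    y -= box
                elif y < -half:
                    y += box
                r = np.sqrt(x * x + y * y)
                if r < contact_r:
                    f = (2.0 * contact_r - r) / r
                    x *= f
                    y *= f
                    r = 2.0 * contact_r - r
                if r <= bind_r:
                    bound = True
                    bx = x
                    by = y
            if s % record_stride == 0:
                idx = s // record_stride - 1
                if bound:
                    bound_count[idx] += 1
    return bound_count
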