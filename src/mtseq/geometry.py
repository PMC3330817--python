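"""Static microtubule-array geometries and the energid mean-field domain.

Conventions used throughout the package:

* Lengths in micrometres, times in seconds.
* Spherical cells are centred at the origin; the spindle axis is the x axis,
  so the mid-cell ("equator") plane is x = 0 for a symmetric spindle.
* The rectangular energid block uses corner-origin axes with z measured
  *downward* from the top (cortex) surface.

Microtubules are static cylinders: a minus end anchored on a nucleation
sphere of radius ``nucleation_radius`` around the organizing pole (MTOC) and
a plus end where the nucleation ray first meets the mid-cell plane or the
cell cortex.  Filaments never change length or orientation during a run;
time-varying arrays (centrosome maturation) are modelled by regenerating the
set from a :class:`MaturationSchedule` at coarse intervals.
"""

from __future__ import annotations

import io as _io
import json
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

DEFAULT_MT_RADIUS = 0.0125  # µm, 25 nm diameter
DEFAULT_NUCLEATION_RADIUS = 1.0  # µm
DEFAULT_CELL_RADIUS = 10.0  # µm


class GeometryError(ValueError):
    """Invalid geometric specification."""


# ---------------------------------------------------------------------------
# Microtubule container
# ---------------------------------------------------------------------------

class MicrotubuleSet:
    """A fixed collection of microtubule segments.

    Stored as flat arrays so the agent engine can consume them directly.
    A filament is normally a single segment; bent filaments (barrel midzone)
    are chains of segments connected through ``prev_link``/``next_link``
    (-1 where there is no continuation).  ``pole_id`` tags the organizing
    MTOC of each segment.
    """

    def __init__(
        self,
        minus: np.ndarray,
        plus: np.ndarray,
        pole_id: np.ndarray,
        pole_positions: np.ndarray,
        radius: float = DEFAULT_MT_RADIUS,
        nucleation_radius: float = DEFAULT_NUCLEATION_RADIUS,
        prev_link: Optional[np.ndarray] = None,
        next_link: Optional[np.ndarray] = None,
    ):
        minus = np.atleast_2d(np.asarray(minus, dtype=np.float64))
        plus = np.atleast_2d(np.asarray(plus, dtype=np.float64))
        if minus.shape != plus.shape or minus.shape[1] != 3:
            raise GeometryError("minus/plus must be (n, 3) arrays of equal shape")
        if radius <= 0:
            raise GeometryError("microtubule radius must be positive")
        seg = plus - minus
        length = np.linalg.norm(seg, axis=1)
        if minus.shape[0] and np.any(length <= 0):
            raise GeometryError("degenerate microtubule: minus_end == plus_end")
        self.minus = minus
        self.plus = plus
        self.length = length
        with np.errstate(invalid="ignore"):
            self.direction = np.where(length[:, None] > 0, seg / np.where(length[:, None] == 0, 1.0, length[:, None]), 0.0)
        self.pole_id = np.asarray(pole_id, dtype=np.int32).reshape(-1)
        if self.pole_id.shape[0] != minus.shape[0]:
            raise GeometryError("pole_id length mismatch")
        self.pole_positions = np.atleast_2d(np.asarray(pole_positions, dtype=np.float64))
        self.radius = float(radius)
        self.nucleation_radius = float(nucleation_radius)
        n = minus.shape[0]
        self.prev_link = (np.full(n, -1, np.int32) if prev_link is None
                          else np.asarray(prev_link, np.int32).reshape(-1))
        self.next_link = (np.full(n, -1, np.int32) if next_link is None
                          else np.asarray(next_link, np.int32).reshape(-1))

    def __len__(self) -> int:
        return self.minus.shape[0]

    @property
    def n_poles(self) -> int:
        return self.pole_positions.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "pole_id": self.pole_id,
            "minus_x": self.minus[:, 0], "minus_y": self.minus[:, 1], "minus_z": self.minus[:, 2],
            "plus_x": self.plus[:, 0], "plus_y": self.plus[:, 1], "plus_z": self.plus[:, 2],
        })

    def to_csv(self, path) -> None:
        """Write one row per microtubule; pole positions go into '#' header lines."""
        header = {
            "radius": self.radius,
            "nucleation_radius": self.nucleation_radius,
            "pole_positions": self.pole_positions.tolist(),
        }
        with open(path, "w") as fh:
            fh.write("# mtseq-microtubules " + json.dumps(header) + "\n")
            self.to_frame().to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path) -> "MicrotubuleSet":
        with open(path) as fh:
            first = fh.readline()
            if not first.startswith("# mtseq-microtubules"):
                raise GeometryError(f"{path}: not an mtseq microtubule CSV")
            header = json.loads(first.split(" ", 2)[2])
            df = pd.read_csv(_io.StringIO(fh.read()))
        return cls(
            minus=df[["minus_x", "minus_y", "minus_z"]].to_numpy(),
            plus=df[["plus_x", "plus_y", "plus_z"]].to_numpy(),
            pole_id=df["pole_id"].to_numpy(),
            pole_positions=np.asarray(header["pole_positions"]),
            radius=header["radius"],
            nucleation_radius=header["nucleation_radius"],
        )


# ---------------------------------------------------------------------------
# Direction sampling
# ---------------------------------------------------------------------------

def _basis(axis: np.ndarray) -> np.ndarray:
    """Orthonormal frame whose third column is `axis`."""
    a = axis / np.linalg.norm(axis)
    helper = np.array([1.0, 0.0, 0.0]) if abs(a[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = np.cross(a, helper)
    u /= np.linalg.norm(u)
    v = np.cross(a, u)
    return np.stack([u, v, a], axis=1)


def _sample_directions(rng: np.random.Generator, n: int, axis: np.ndarray,
                       cos_lo: float, cos_hi: float) -> np.ndarray:
    """Directions uniform over the solid-angle band cosθ ∈ [cos_lo, cos_hi]
    about `axis` (θ measured from the axis)."""
    cos_t = rng.uniform(cos_lo, cos_hi, n)
    phi = rng.uniform(0.0, 2.0 * np.pi, n)
    sin_t = np.sqrt(np.clip(1.0 - cos_t ** 2, 0.0, None))
    local = np.stack([sin_t * np.cos(phi), sin_t * np.sin(phi), cos_t], axis=1)
    return local @ _basis(axis).T


def cone_solid_angle_fraction(half_angle_deg: float) -> float:
    """Fraction of the full sphere subtended by a cone of given half-angle."""
    return (1.0 - np.cos(np.deg2rad(half_angle_deg))) / 2.0


def _ray_sphere_exit(origin: np.ndarray, direction: np.ndarray, radius: float) -> np.ndarray:
    """Positive parameter t where origin + t·direction leaves the sphere |x| = radius."""
    b = np.einsum("ij,ij->i", origin, direction)
    c = np.einsum("ij,ij->i", origin, origin) - radius ** 2
    disc = np.sqrt(np.clip(b * b - c, 0.0, None))
    return -b + disc  # unit directions: a == 1


# ---------------------------------------------------------------------------
# Spindle / aster builders
# ---------------------------------------------------------------------------

class SpindleSpec(BaseModel):
    """Bipolar spindle specification.

    ``cone_half_angle`` of 45° corresponds to the "90° cone" that encloses
    ~15% of the solid angle; spindle microtubules are nucleated inside that
    cone (opening toward the mid-plane), astral ones outside it.
    """
    model_config = ConfigDict(extra="forbid")

    cell_radius: float = Field(DEFAULT_CELL_RADIUS, gt=0)
    pole_separation: float = Field(10.0, gt=0)
    cone_half_angle: float = Field(45.0, gt=0, lt=90)
    n_spindle: int = Field(800, ge=0)
    n_astral: int = Field(800, ge=0)
    nucleation_radius: float = Field(DEFAULT_NUCLEATION_RADIUS, gt=0)
    mt_radius: float = Field(DEFAULT_MT_RADIUS, gt=0)
    midzone_style: str = Field("point", pattern="^(point|barrel)$")
    barrel_overlap: float = Field(2.0, gt=0)
    barrel_radius: float = Field(5.0, gt=0)

    @model_validator(mode="after")
    def _poles_inside_cell(self):
        if self.pole_separation / 2.0 >= self.cell_radius:
            raise ValueError("spindle poles must lie inside the cell")
        return self

    @property
    def pole_positions(self) -> np.ndarray:
        h = self.pole_separation / 2.0
        return np.array([[-h, 0.0, 0.0], [h, 0.0, 0.0]])


def build_spindle(spec: SpindleSpec, seed: int) -> MicrotubuleSet:
    """Construct the bipolar spindle: per pole, ``n_spindle`` filaments with
    directions uniform over the solid angle inside the cone and ``n_astral``
    uniform outside it.  Minus ends sit on the nucleation sphere; each plus
    end is the first intersection of the nucleation ray with the mid-cell
    plane or the cell sphere.
    """
    if spec.pole_separation == 0:
        raise GeometryError("cone axis undefined: spindle poles coincide")
    rng = np.random.default_rng(seed)
    cos_a = np.cos(np.deg2rad(spec.cone_half_angle))
    poles = spec.pole_positions

    minus_all, plus_all, pole_all = [], [], []
    prev_all, next_all = [], []
    barrel = spec.midzone_style == "barrel"

    for pid in range(2):
        pole = poles[pid]
        axis = np.array([1.0, 0.0, 0.0]) * (1.0 if pid == 0 else -1.0)  # toward mid-plane
        d_cone = _sample_directions(rng, spec.n_spindle, axis, cos_a, 1.0)
        d_astral = _sample_directions(rng, spec.n_astral, axis, -1.0, cos_a)
        for dirs, in_cone in ((d_cone, True), (d_astral, False)):
            if dirs.shape[0] == 0:
                continue
            minus = pole[None, :] + spec.nucleation_radius * dirs
            t_sph = _ray_sphere_exit(minus, dirs, spec.cell_radius)
            # signed axial position relative to the mid-plane, measured along
            # the pole's inward axis; the plane sits at axial coordinate 0
            s_ax = minus @ axis
            dx = dirs @ axis
            with np.errstate(divide="ignore"):
                t_pln = np.where(dx > 1e-12, -s_ax / np.where(dx > 1e-12, dx, 1.0), np.inf)
            t = np.minimum(t_sph, np.clip(t_pln, 0.0, None))
            if barrel and in_cone:
                _append_barrel(spec, pid, pole, axis, dirs, minus, t_sph, t_pln,
                               minus_all, plus_all, pole_all, prev_all, next_all)
            else:
                plus = minus + t[:, None] * dirs
                minus_all.append(minus)
                plus_all.append(plus)
                pole_all.append(np.full(len(minus), pid, np.int32))
                prev_all.append(np.full(len(minus), -1, np.int32))
                next_all.append(np.full(len(minus), -1, np.int32))

    minus = np.concatenate(minus_all) if minus_all else np.empty((0, 3))
    plus = np.concatenate(plus_all) if plus_all else np.empty((0, 3))
    pole_id = np.concatenate(pole_all) if pole_all else np.empty(0, np.int32)
    prev = np.concatenate(prev_all) if prev_all else np.empty(0, np.int32)
    nxt = np.concatenate(next_all) if next_all else np.empty(0, np.int32)
    return MicrotubuleSet(minus, plus, pole_id, poles, spec.mt_radius,
                          spec.nucleation_radius, prev, nxt)


def _append_barrel(spec, pid, pole, axis, dirs, minus, t_sph, t_pln,
                   minus_all, plus_all, pole_all, prev_all, next_all):
    """Barrel midzone: each cone filament runs straight until the bend plane
    (overlap/2 before the mid-plane along the spindle axis, or earlier if it
    reaches the barrel radius), then continues axis-parallel to overlap/2
    beyond the mid-plane, giving antiparallel overlap of width `barrel_overlap`
    between the two half-spindles."""
    n = dirs.shape[0]
    half_sep = spec.pole_separation / 2.0
    # axial coordinate measured from the pole toward the mid-plane
    ax_minus = (minus - pole[None, :]) @ axis
    dx = np.clip(dirs @ axis, 1e-12, None)
    t_bend = (half_sep - spec.barrel_overlap / 2.0 - ax_minus) / dx
    # optional earlier bend when the ray reaches the barrel radius
    radial = minus - pole[None, :] - ax_minus[:, None] * axis[None, :]
    dr = dirs - dx[:, None] * axis[None, :]
    r_speed = np.linalg.norm(dr, axis=1)
    with np.errstate(divide="ignore"):
        t_rad = np.where(r_speed > 1e-12,
                         (spec.barrel_radius - np.linalg.norm(radial, axis=1)) / np.where(r_speed > 1e-12, r_speed, 1.0),
                         np.inf)
    t_bend = np.minimum(t_bend, np.clip(t_rad, 0.0, None))
    straight = t_sph <= t_bend  # hits the cortex before bending
    base = sum(arr.shape[0] for arr in minus_all)

    seg_a_minus = minus
    t_a = np.where(straight, np.minimum(t_sph, t_pln), t_bend)
    seg_a_plus = minus + t_a[:, None] * dirs
    idx_a = base + np.arange(n, dtype=np.int32)
    nxt_a = np.full(n, -1, np.int32)

    bend_idx = np.where(~straight)[0]
    if bend_idx.size:
        bp = seg_a_plus[bend_idx]
        ax_bp = (bp - pole[None, :]) @ axis
        blen = (half_sep + spec.barrel_overlap / 2.0) - ax_bp
        seg_b_minus = bp
        seg_b_plus = bp + blen[:, None] * axis[None, :]
        idx_b = base + n + np.arange(bend_idx.size, dtype=np.int32)
        nxt_a[bend_idx] = idx_b
        prev_b = idx_a[bend_idx]
        minus_all.extend([seg_a_minus, seg_b_minus])
        plus_all.extend([seg_a_plus, seg_b_plus])
        pole_all.extend([np.full(n, pid, np.int32), np.full(bend_idx.size, pid, np.int32)])
        prev_all.extend([np.full(n, -1, np.int32), prev_b])
        next_all.extend([nxt_a, np.full(bend_idx.size, -1, np.int32)])
    else:
        minus_all.append(seg_a_minus)
        plus_all.append(seg_a_plus)
        pole_all.append(np.full(n, pid, np.int32))
        prev_all.append(np.full(n, -1, np.int32))
        next_all.append(nxt_a)


def build_aster(
    center: Sequence[float],
    n: int,
    seed: int,
    length: Optional[float] = None,
    cell_radius: float = DEFAULT_CELL_RADIUS,
    nucleation_radius: float = DEFAULT_NUCLEATION_RADIUS,
    mt_radius: float = DEFAULT_MT_RADIUS,
    pole_id: int = 0,
    truncate_plane: Optional[tuple] = None,
    pole_positions: Optional[np.ndarray] = None,
) -> MicrotubuleSet:
    """Isotropic aster around one MTOC.

    length=None ("full span") extends each filament to the cell cortex;
    a fixed ``length`` truncates earlier unless the cortex is reached first.
    ``truncate_plane=(point, normal)`` additionally clips at a plane (used
    for half-cell-span arrays bounded by the cell equator).
    """
    center = np.asarray(center, dtype=np.float64)
    if np.linalg.norm(center) >= cell_radius:
        raise GeometryError("aster center must lie inside the cell")
    if length is not None and length <= 0:
        raise GeometryError("fixed microtubule length must be positive")
    rng = np.random.default_rng(seed)
    dirs = _sample_directions(rng, n, np.array([0.0, 0.0, 1.0]), -1.0, 1.0)
    minus = center[None, :] + nucleation_radius * dirs
    t = _ray_sphere_exit(minus, dirs, cell_radius)
    if length is not None:
        t = np.minimum(t, length)
    if truncate_plane is not None:
        p0, nrm = (np.asarray(a, dtype=np.float64) for a in truncate_plane)
        dn = dirs @ nrm
        with np.errstate(divide="ignore"):
            t_pl = np.where(dn > 1e-12, ((p0[None, :] - minus) @ nrm) / np.where(dn > 1e-12, dn, 1.0), np.inf)
        t = np.minimum(t, np.clip(t_pl, 1e-9, None))
    plus = minus + t[:, None] * dirs
    poles = center[None, :] if pole_positions is None else np.atleast_2d(pole_positions)
    pid = np.full(n, pole_id, np.int32)
    return MicrotubuleSet(minus, plus, pid, poles, mt_radius, nucleation_radius)


def merge(sets: Sequence[MicrotubuleSet], pole_positions: np.ndarray) -> MicrotubuleSet:
    """Concatenate several microtubule sets (links re-indexed)."""
    if not sets:
        raise GeometryError("nothing to merge")
    offs = np.cumsum([0] + [len(s) for s in sets[:-1]])
    def shift(link, off):
        out = link.copy()
        out[out >= 0] += off
        return out
    return MicrotubuleSet(
        np.concatenate([s.minus for s in sets]),
        np.concatenate([s.plus for s in sets]),
        np.concatenate([s.pole_id for s in sets]),
        np.atleast_2d(np.asarray(pole_positions, dtype=np.float64)),
        sets[0].radius,
        sets[0].nucleation_radius,
        np.concatenate([shift(s.prev_link, o) for s, o in zip(sets, offs)]),
        np.concatenate([shift(s.next_link, o) for s, o in zip(sets, offs)]),
    )


# ---------------------------------------------------------------------------
# Centrosome maturation
# ---------------------------------------------------------------------------

class MaturationSchedule:
    """Time-varying asters for centrosome-maturation scenarios.

    Each centrosome carries a piecewise-linear microtubule count and a
    piecewise-linear trajectory.  Direction unit vectors are pre-generated
    per centrosome (seeded) so filament identities are stable over time: the
    count at time t activates the first ``count(t)`` directions.  When a
    centrosome moves, its filaments translate rigidly with it.
    """

    def __init__(self, count_schedules, trajectories, cell_radius=DEFAULT_CELL_RADIUS,
                 nucleation_radius=DEFAULT_NUCLEATION_RADIUS, mt_radius=DEFAULT_MT_RADIUS,
                 seed: int = 0):
        # count_schedules: list of (times, counts); trajectories: list of (times, points)
        self.count_schedules = [(np.asarray(t, float), np.asarray(c, float)) for t, c in count_schedules]
        self.trajectories = [(np.asarray(t, float), np.atleast_2d(np.asarray(p, float))) for t, p in trajectories]
        if len(self.count_schedules) != len(self.trajectories):
            raise GeometryError("one trajectory per centrosome required")
        for t, c in self.count_schedules:
            if np.any(c < 0):
                raise GeometryError("microtubule counts must be non-negative")
        for t, p in self.trajectories:
            if np.any(np.linalg.norm(p, axis=1) >= cell_radius):
                raise GeometryError("centrosome trajectory leaves the cell")
        self.cell_radius = cell_radius
        self.nucleation_radius = nucleation_radius
        self.mt_radius = mt_radius
        rng = np.random.default_rng(seed)
        self.max_counts = [int(np.ceil(c.max())) for _, c in self.count_schedules]
        self._dirs = [_sample_directions(rng, m, np.array([0.0, 0.0, 1.0]), -1.0, 1.0)
                      for m in self.max_counts]

    @property
    def n_poles(self) -> int:
        return len(self.count_schedules)

    def count_at(self, t: float, pole: int) -> int:
        times, counts = self.count_schedules[pole]
        return int(np.floor(np.interp(t, times, counts) + 1e-9))

    def position_at(self, t: float, pole: int) -> np.ndarray:
        times, pts = self.trajectories[pole]
        return np.array([np.interp(t, times, pts[:, k]) for k in range(3)])

    def mt_set_at(self, t: float) -> tuple[MicrotubuleSet, np.ndarray]:
        """Full-capacity microtubule set at time t plus an activity mask.

        Segment ids are stable across calls (fixed per-pole blocks), so a
        particle bound to segment j stays consistently attached while the
        array grows or translates.
        """
        minus, plus, pid = [], [], []
        active = []
        poles = np.stack([self.position_at(t, p) for p in range(self.n_poles)])
        for p in range(self.n_poles):
            dirs = self._dirs[p]
            m = dirs.shape[0]
            mn = poles[p][None, :] + self.nucleation_radius * dirs
            te = _ray_sphere_exit(mn, dirs, self.cell_radius)
            minus.append(mn)
            plus.append(mn + te[:, None] * dirs)
            pid.append(np.full(m, p, np.int32))
            mask = np.zeros(m, bool)
            mask[: self.count_at(t, p)] = True
            active.append(mask)
        mts = MicrotubuleSet(np.concatenate(minus), np.concatenate(plus),
                             np.concatenate(pid), poles, self.mt_radius,
                             self.nucleation_radius)
        return mts, np.concatenate(active)


# ---------------------------------------------------------------------------
# Energid domain (syncytial-embryo cortex block)
# ---------------------------------------------------------------------------

class EnergidDomain(BaseModel):
    """Rectangular cortex block subdivided into energids.

    The top ``energid_depth`` µm are split laterally into ``n_sub`` × ``n_sub``
    subdomains by impermeable vertical walls extending from the top surface
    down to ``wall_depth``; below the walls the space is continuous.  The
    sequestration mask (where microtubule binding acts) defaults to the top
    energid layer.  The "gap" between neighbouring energids is the unwalled
    depth H − wall_depth.
    """
    model_config = ConfigDict(extra="forbid")

    width: float = 35.0
    depth: float = 35.0
    height: float = 14.0
    spacing: float = 0.5
    energid_depth: float = 7.0
    n_sub: int = 5
    wall_depth: float = 7.0

    @model_validator(mode="after")
    def _check(self):
        for name in ("width", "depth", "height", "energid_depth", "wall_depth"):
            v = getattr(self, name)
            k = v / self.spacing
            if abs(k - round(k)) > 1e-9:
                raise ValueError(f"grid spacing must divide {name} exactly")
        for name, v in (("width", self.width), ("depth", self.depth)):
            sub = v / self.n_sub
            k = sub / self.spacing
            if abs(k - round(k)) > 1e-9:
                raise ValueError(f"spacing misaligns subdomain walls with {name}")
        if self.wall_depth > self.height:
            raise ValueError("wall depth exceeds block height")
        if self.energid_depth > self.height:
            raise ValueError("energid depth exceeds block height")
        return self

    # --- grid description -------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return (int(round(self.width / self.spacing)),
                int(round(self.depth / self.spacing)),
                int(round(self.height / self.spacing)))

    @property
    def cell_volume(self) -> float:
        return self.spacing ** 3

    def wall_planes(self, axis: str) -> np.ndarray:
        """Interior wall-plane coordinates along x or y (face positions)."""
        extent = self.width if axis == "x" else self.depth
        step = extent / self.n_sub
        return np.arange(1, self.n_sub) * step

    def blocked_faces(self) -> tuple[np.ndarray, np.ndarray]:
        """Boolean masks for blocked interior faces.

        Returns (bx, by): bx has shape (nx-1, ny, nz) and marks faces between
        cells (i, j, k) and (i+1, j, k); likewise by for the y direction.
        z faces are never walled.
        """
        nx, ny, nz = self.shape
        h = self.spacing
        kz = int(round(self.wall_depth / h))  # walls span z-cells [0, kz)
        bx = np.zeros((nx - 1, ny, nz), bool)
        by = np.zeros((nx, ny - 1, nz), bool)
        for xw in self.wall_planes("x"):
            i = int(round(xw / h)) - 1  # face between cell i and i+1
            bx[i, :, :kz] = True
        for yw in self.wall_planes("y"):
            j = int(round(yw / h)) - 1
            by[:, j, :kz] = True
        return bx, by

    def n_blocked_faces(self) -> int:
        bx, by = self.blocked_faces()
        return int(bx.sum() + by.sum())

    def sequestration_mask(self) -> np.ndarray:
        """Default binding region: the top energid layer (z < energid_depth)."""
        nx, ny, nz = self.shape
        ke = int(round(self.energid_depth / self.spacing))
        mask = np.zeros((nx, ny, nz), bool)
        mask[:, :, :ke] = True
        return mask

    def subdomain_slices(self, i: int, j: int):
        """(x, y, z) cell slices of energid (i, j) in the top layer."""
        nxs = int(round(self.width / self.n_sub / self.spacing))
        nys = int(round(self.depth / self.n_sub / self.spacing))
        ke = int(round(self.energid_depth / self.spacing))
        return (slice(i * nxs, (i + 1) * nxs), slice(j * nys, (j + 1) * nys), slice(0, ke))

    def subdomain_center_cell(self, i: int, j: int) -> tuple[int, int, int]:
        sx, sy, sz = self.subdomain_slices(i, j)
        return ((sx.start + sx.stop) // 2, (sy.start + sy.stop) // 2, (sz.start + sz.stop) // 2)

    def cell_centers(self, axis: int) -> np.ndarray:
        n = self.shape[axis]
        return (np.arange(n) + 0.5) * self.spacing


def build_energid_domain(**params) -> EnergidDomain:
    """Validate-and-build wrapper around :class:`EnergidDomain`."""
    try:
        return EnergidDomain(**params)
    except ValueError as exc:
        raise GeometryError(str(exc)) from exc
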