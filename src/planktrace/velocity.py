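"""Gridded ocean velocity fields and velocity sampling.

A :class:`VelocityField` holds horizontal velocities (u eastward, v
northward, m s^-1) on a regular lon/lat grid with discrete depth levels
and time snapshots, plus a land/sea mask per level. Particle motion is
per-level and purely horizontal, so a sampler is bound to one stored
depth level and answers point queries bilinearly in space and linearly
in time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Mean Earth radius, m (spherical Earth; no ellipsoid).
EARTH_RADIUS_M = 6_371_000.0
#: Meters per degree of latitude (and of longitude at the equator).
M_PER_DEG = EARTH_RADIUS_M * np.pi / 180.0

#: Sampler status codes.
OK, BEACHED, EXITED = 0, 1, 2
STATUS_NAMES = {OK: "active", BEACHED: "beached", EXITED: "exited"}


def _check_uniform(coord: np.ndarray, name: str, tol: float = 1e-9) -> float:
    if len(coord) < 2:
        return 0.0
    steps = np.diff(coord)
    if np.any(steps <= 0):
        raise ValueError(f"{name} must be strictly increasing")
    if np.ptp(steps) > tol:
        raise ValueError(f"{name} spacing is not uniform within {tol}")
    return float(steps.mean())


@dataclass
class VelocityField:
    """Regular lon/lat x level x time grid of horizontal velocities.

    ``u``/``v`` have shape (time, level, lat, lon); ``sea`` is True where
    the cell is water, shape (level, lat, lon). Velocities must be finite
    on sea cells (land cells may hold NaN).
    """

    lons: np.ndarray
    lats: np.ndarray
    levels: np.ndarray
    times: np.ndarray
    u: np.ndarray
    v: np.ndarray
    sea: np.ndarray | None = None

    def __post_init__(self):
        self.lons = np.asarray(self.lons, dtype=float)
        self.lats = np.asarray(self.lats, dtype=float)
        self.levels = np.asarray(self.levels, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.u = np.asarray(self.u, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        shape = (len(self.times), len(self.levels), len(self.lats), len(self.lons))
        for name, arr in (("u", self.u), ("v", self.v)):
            if arr.shape != shape:
                raise ValueError(f"{name} has shape {arr.shape}, expected {shape}")
        _check_uniform(self.lons, "lons")
        _check_uniform(self.lats, "lats")
        if len(self.times) > 1:
            if np.any(np.diff(self.times) <= 0):
                raise ValueError("times must be strictly increasing")
        if self.sea is None:
            # infer: a cell is sea iff u and v are finite at every time step
            finite = np.isfinite(self.u).all(axis=0) & np.isfinite(self.v).all(axis=0)
            self.sea = finite
        else:
            self.sea = np.asarray(self.sea, dtype=bool)
            if self.sea.shape != shape[1:]:
                raise ValueError(f"sea mask has shape {self.sea.shape}, expected {shape[1:]}")
            sea4 = np.broadcast_to(self.sea, shape)
            if not (np.isfinite(self.u[sea4]).all() and np.isfinite(self.v[sea4]).all()):
                raise ValueError("u/v must be finite on sea cells")

    def level_index(self, level_m: float, tol: float = 1e-6) -> int:
        i = int(np.argmin(np.abs(self.levels - level_m)))
        if abs(self.levels[i] - level_m) > tol:
            raise ValueError(
                f"level {level_m} m is not a stored level (nearest: {self.levels[i]} m); "
                "motion is per-level, no vertical interpolation"
            )
        return i


class GriddedSampler:
    """Point velocity queries on one depth level of a :class:`VelocityField`.

    Bilinear in lon/lat with land-aware weights (land corners get zero
    weight and the remaining weights are renormalized; all four corners
    land means the query point is beached), linear in time. With
    ``steady=True`` the time axis is clamped to the stored range;
    otherwise queries outside it signal 'exited'. Longitudes are wrapped
    modulo 360 onto the grid where the grid spans the wrap point.
    """

    def __init__(self, fld: VelocityField, level_m: float, steady: bool = False):
        self.field = fld
        self.k = fld.level_index(level_m)
        self.level_m = float(fld.levels[self.k])
        self.steady = steady or len(fld.times) == 1
        self.lon0 = fld.lons[0]
        self.lat0 = fld.lats[0]
        self.dlon = _check_uniform(fld.lons, "lons") or 1.0
        self.dlat = _check_uniform(fld.lats, "lats") or 1.0
        self.u = fld.u[:, self.k]
        self.v = fld.v[:, self.k]
        self.sea = fld.sea[self.k]

    def _time_weights(self, t: float):
        times = self.field.times
        if len(times) == 1:
            return 0, 0, 1.0, True
        if t < times[0] or t > times[-1]:
            if not self.steady:
                return 0, 0, 1.0, False
            t = min(max(t, times[0]), times[-1])
        j = int(np.searchsorted(times, t, side="right") - 1)
        j = min(max(j, 0), len(times) - 2)
        w = (t - times[j]) / (times[j + 1] - times[j])
        return j, j + 1, float(w), True

    def velocity(self, lons: np.ndarray, lats: np.ndarray, t: float):
        """Velocities at points; returns (u, v, status) arrays.

        Status is OK, BEACHED (all surrounding cells are land) or EXITED
        (outside the spatial hull or, for unsteady runs, the time range).
        Velocities for non-OK points are zero.
        """
        lons = np.atleast_1d(np.asarray(lons, dtype=float))
        lats = np.atleast_1d(np.asarray(lats, dtype=float))
        n = len(lons)
        status = np.full(n, OK, dtype=np.int8)
        uo = np.zeros(n)
        vo = np.zeros(n)

        j0, j1, tw, ok_t = self._time_weights(t)
        if not ok_t:
            status[:] = EXITED
            return uo, vo, status

        # fractional grid indices; wrap longitude onto the grid
        fx = (np.mod(lons - self.lon0, 360.0)) / self.dlon
        span = (self.field.lons[-1] - self.lon0) / self.dlon
        fx = np.where(fx > span + 0.5 * (360.0 / self.dlon - span), fx - 360.0 / self.dlon, fx)
        fy = (lats - self.lat0) / self.dlat
        nx, ny = len(self.field.lons), len(self.field.lats)
        inside = (fx >= 0) & (fx <= nx - 1) & (fy >= 0) & (fy <= ny - 1)
        status[~inside] = EXITED
        if not inside.any():
            return uo, vo, status

        ix = np.clip(np.floor(fx[inside]).astype(int), 0, nx - 2) if nx > 1 else np.zeros(inside.sum(), int)
        iy = np.clip(np.floor(fy[inside]).astype(int), 0, ny - 2) if ny > 1 else np.zeros(inside.sum(), int)
        ax = fx[inside] - ix
        ay = fy[inside] - iy
        ix1 = np.minimum(ix + 1, nx - 1)
        iy1 = np.minimum(iy + 1, ny - 1)

        # corner weights, zeroed on land, renormalized
        w00 = (1 - ax) * (1 - ay) * self.sea[iy, ix]
        w10 = ax * (1 - ay) * self.sea[iy, ix1]
        w01 = (1 - ax) * ay * self.sea[iy1, ix]
        w11 = ax * ay * self.sea[iy1, ix1]
        wsum = w00 + w10 + w01 + w11
        all_sea_zero = ~(
            self.sea[iy, ix] | self.sea[iy, ix1] | self.sea[iy1, ix] | self.sea[iy1, ix1]
        )
        beached = all_sea_zero | (wsum <= 0)

        def interp(f2d):
            vals = np.where(self.sea[iy, ix], np.nan_to_num(f2d[iy, ix]), 0.0) * w00
            vals += np.where(self.sea[iy, ix1], np.nan_to_num(f2d[iy, ix1]), 0.0) * w10
            vals += np.where(self.sea[iy1, ix], np.nan_to_num(f2d[iy1, ix]), 0.0) * w01
            vals += np.where(self.sea[iy1, ix1], np.nan_to_num(f2d[iy1, ix1]), 0.0) * w11
            with np.errstate(invalid="ignore", divide="ignore"):
                return np.where(beached, 0.0, vals / np.where(wsum > 0, wsum, 1.0))

        if len(self.field.times) == 1 or tw == 0.0:
            ui = interp(self.u[j0])
            vi = interp(self.v[j0])
        else:
            ui = (1 - tw) * interp(self.u[j0]) + tw * interp(self.u[j1])
            vi = (1 - tw) * interp(self.v[j0]) + tw * interp(self.v[j1])

        idx = np.flatnonzero(inside)
        uo[idx] = ui
        vo[idx] = vi
        st = status[idx]
        st[beached] = BEACHED
        status[idx] = st
        uo[status != OK] = 0.0
        vo[status != OK] = 0.0
        return uo, vo, status


def interpolate_velocity(
    fld: VelocityField, lon: float, lat: float, t: float, level_m: float, steady: bool = False
) -> tuple[float, float]:
    """Single-point velocity query (bilinear space, linear time) at a stored level.

    Raises if the point is outside the grid hull / time range or beached.
    """
    s = GriddedSampler(fld, level_m, steady=steady)
    u, v, status = s.velocity(np.array([lon]), np.array([lat]), t)
    if status[0] == EXITED:
        raise ValueError(f"query ({lon}, {lat}, t={t}) is outside the field domain")
    if status[0] == BEACHED:
        raise ValueError(f"query ({lon}, {lat}) has no surrounding sea cell")
    return float(u[0]), float(v[0])
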