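"""Lagrangian particle backtracking through layered horizontal velocity fields.

Particles are seeded on a regular lon/lat grid around a station and
integrated backward in time with a fourth-order Runge-Kutta scheme on the
sphere, one experiment per depth level (motion is purely horizontal; no
random walk). The governing equations in geographic coordinates are

    d(lon)/dt = s * u / (R cos(lat)) * 180/pi
    d(lat)/dt = s * v / R * 180/pi

with s = -1 for backward integration and R the mean Earth radius.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Protocol, Sequence

import numpy as np
import pandas as pd

from .velocity import (
    BEACHED,
    EARTH_RADIUS_M,
    EXITED,
    OK,
    STATUS_NAMES,
    GriddedSampler,
    VelocityField,
)

DEG = 180.0 / np.pi


class VelocitySampler(Protocol):
    """Anything that answers vectorized point velocity queries."""

    def velocity(self, lons: np.ndarray, lats: np.ndarray, t: float):  # pragma: no cover
        ...


@dataclass
class ParticleSet:
    """Seeded particle positions at one depth level and start instant."""

    lons: np.ndarray
    lats: np.ndarray
    level_m: float = 0.0
    t0: float = 0.0

    def __post_init__(self):
        self.lons = np.atleast_1d(np.asarray(self.lons, dtype=float))
        self.lats = np.atleast_1d(np.asarray(self.lats, dtype=float))
        if self.lons.shape != self.lats.shape:
            raise ValueError("lons and lats must have equal length")

    def __len__(self) -> int:
        return len(self.lons)


def seed_grid(
    center: tuple[float, float],
    half_width: float,
    spacing: float,
    level_m: float = 0.0,
    t0: float = 0.0,
) -> ParticleSet:
    """Regular square seeding grid centred on ``center`` (lon, lat).

    The grid extends ``half_width`` degrees in each cardinal direction with
    node spacing ``spacing`` on both axes, giving
    (2*half_width/spacing + 1)**2 particles; ``half_width`` must be an
    integer multiple of ``spacing`` (within 1e-9 deg). half_width=0.25 with
    spacing 0.025 yields the 21 x 21 = 441-particle box used around a
    station.
    """
    if spacing <= 0:
        raise ValueError(f"spacing must be positive, got {spacing}")
    if half_width < 0:
        raise ValueError(f"half_width must be nonnegative, got {half_width}")
    m = half_width / spacing
    if abs(m - round(m)) * spacing > 1e-9:
        raise ValueError(
            f"half_width {half_width} is not an integer multiple of spacing {spacing}"
        )
    m = int(round(m))
    offsets = (np.arange(2 * m + 1) - m) * spacing
    lon_g, lat_g = np.meshgrid(center[0] + offsets, center[1] + offsets)
    return ParticleSet(lon_g.ravel(), lat_g.ravel(), level_m=level_m, t0=t0)


@dataclass
class TrajectorySet:
    """Positions of all particles at every recorded instant.

    ``times`` has length n_steps+1 (strictly decreasing for backward runs);
    ``lons``/``lats`` have shape (n_times, n_particles). ``status`` is the
    final per-particle status; beached/exited particles stay frozen at
    their last valid position from ``frozen_at`` (time index) onward.
    """

    times: np.ndarray
    lons: np.ndarray
    lats: np.ndarray
    status: np.ndarray
    frozen_at: np.ndarray
    level_m: float

    @property
    def n_particles(self) -> int:
        return self.lons.shape[1]

    def final_positions(self) -> tuple[np.ndarray, np.ndarray]:
        return self.lons[-1], self.lats[-1]

    def to_frame(self) -> pd.DataFrame:
        """Tidy frame: particle_id, time_s, lon, lat, level_m, status."""
        nt, npart = self.lons.shape
        pid = np.repeat(np.arange(npart), nt)
        tt = np.tile(self.times, npart)
        step = np.tile(np.arange(nt), npart)
        frozen = np.repeat(self.frozen_at, nt)
        final = np.repeat(self.status, nt)
        stat = np.where(step < frozen, OK, final)
        return pd.DataFrame(
            {
                "particle_id": pid,
                "time_s": tt,
                "lon": self.lons.T.ravel(),
                "lat": self.lats.T.ravel(),
                "level_m": self.level_m,
                "status": [STATUS_NAMES[s] for s in stat],
            }
        )


def _step_times(duration: float, dt: float) -> np.ndarray:
    n_full = int(np.floor(duration / dt + 1e-12))
    taus = np.arange(n_full + 1) * dt
    if taus[-1] < duration - 1e-9 * dt:
        taus = np.append(taus, duration)
    return taus


def integrate(
    sampler: VelocitySampler,
    particles: ParticleSet,
    duration: float,
    dt: float,
    direction: int = -1,
) -> TrajectorySet:
    """RK4 advection of a particle set for ``duration`` seconds.

    ``direction=-1`` integrates backward in time from ``particles.t0``
    (recorded times decrease strictly by ``dt``), ``+1`` forward. The
    scheme is deterministic; a particle whose velocity query signals
    'beached' or 'exited' at any RK stage is frozen at its last valid
    position with that status.
    """
    if duration <= 0:
        raise ValueError(f"duration must be positive, got {duration}")
    if dt <= 0 or dt > duration:
        raise ValueError(f"dt must lie in (0, duration], got dt={dt}, duration={duration}")
    if direction not in (-1, 1):
        raise ValueError("direction must be -1 (backward) or +1 (forward)")

    taus = _step_times(duration, dt)
    n = len(particles)
    lons = np.empty((len(taus), n))
    lats = np.empty((len(taus), n))
    lons[0] = particles.lons
    lats[0] = particles.lats
    status = np.full(n, OK, dtype=np.int8)
    frozen_at = np.full(n, len(taus), dtype=int)

    def rhs(lon, lat, t, active):
        """Angular velocity (deg/s); flags newly invalid particles."""
        u, v, st = sampler.velocity(lon, lat, t)
        u = np.atleast_1d(u)
        v = np.atleast_1d(v)
        st = np.atleast_1d(st)
        bad = active & (st != OK)
        if not np.all(np.isfinite(u[active & ~bad])) or not np.all(
            np.isfinite(v[active & ~bad])
        ):
            raise FloatingPointError("non-finite velocity encountered on active particle")
        coslat = np.cos(np.deg2rad(lat))
        dlon = direction * u / (EARTH_RADIUS_M * coslat) * DEG
        dlat = direction * v / EARTH_RADIUS_M * DEG
        return dlon, dlat, bad, st

    for i in range(1, len(taus)):
        h = taus[i] - taus[i - 1]
        t_a = particles.t0 + direction * taus[i - 1]
        lon0, lat0 = lons[i - 1].copy(), lats[i - 1].copy()
        active = status == OK
        newly_bad = np.zeros(n, dtype=bool)
        bad_status = np.full(n, OK, dtype=np.int8)

        def note(bad, st):
            first = bad & (bad_status == OK)
            bad_status[first] = st[first]
            return newly_bad | bad

        k1x, k1y, b, st = rhs(lon0, lat0, t_a, active)
        newly_bad = note(b, st)
        k2x, k2y, b, st = rhs(lon0 + 0.5 * h * k1x, lat0 + 0.5 * h * k1y, t_a + 0.5 * direction * h, active)
        newly_bad = note(b, st)
        k3x, k3y, b, st = rhs(lon0 + 0.5 * h * k2x, lat0 + 0.5 * h * k2y, t_a + 0.5 * direction * h, active)
        newly_bad = note(b, st)
        k4x, k4y, b, st = rhs(lon0 + h * k3x, lat0 + h * k3y, t_a + direction * h, active)
        newly_bad = note(b, st)

        step_ok = active & ~newly_bad
        lons[i] = lon0
        lats[i] = lat0
        lons[i, step_ok] = lon0[step_ok] + (h / 6.0) * (
            k1x[step_ok] + 2 * k2x[step_ok] + 2 * k3x[step_ok] + k4x[step_ok]
        )
        lats[i, step_ok] = lat0[step_ok] + (h / 6.0) * (
            k1y[step_ok] + 2 * k2y[step_ok] + 2 * k3y[step_ok] + k4y[step_ok]
        )
        just = active & newly_bad
        status[just] = bad_status[just]
        frozen_at[just] = i

    times = particles.t0 + direction * taus
    return TrajectorySet(times, lons, lats, status, frozen_at, particles.level_m)


def integrate_backward(
    field: VelocityField | VelocitySampler,
    particles: ParticleSet,
    duration: float,
    dt: float,
    steady: bool = False,
) -> TrajectorySet:
    """Backward-in-time RK4 advection (see :func:`integrate`).

    ``field`` may be a :class:`VelocityField` (sampled bilinearly at the
    particle set's level) or any velocity sampler.
    """
    sampler = (
        GriddedSampler(field, particles.level_m, steady=steady)
        if isinstance(field, VelocityField)
        else field
    )
    return integrate(sampler, particles, duration, dt, direction=-1)


def run_experiment(
    field: VelocityField,
    station: tuple[float, float],
    months: Mapping[str, float],
    levels: Sequence[float],
    half_width: float = 0.25,
    spacing: float = 0.025,
    duration: float = 90 * 86400.0,
    dt: float = 3 * 3600.0,
    steady: bool = False,
) -> dict[tuple[str, float], TrajectorySet]:
    """Seed and backtrack a particle box for every month x level combination.

    ``months`` maps a month label to its sampling instant (s, on the
    field's time axis). Every experiment integrates ``duration`` seconds
    backward (default 90 days at 3-hour steps). The archive is keyed
    (month_label, level_m).
    """
    archive: dict[tuple[str, float], TrajectorySet] = {}
    for label, t0 in months.items():
        for level in levels:
            field.level_index(level)  # validate before seeding
            particles = seed_grid(station, half_width, spacing, level_m=level, t0=t0)
            archive[(label, level)] = integrate_backward(
                field, particles, duration, dt, steady=steady
            )
    return archive
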