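"""Synthetic communities and analytic velocity fields with known truth.

The community generator plants the temporal/vertical structure the
attribution analysis assumes — persistent "seed" taxa present year-round
in the surface layer, allochthonous taxa appearing only during the
winter/spring mixing period with a controlled read share, surface SVs
re-occurring at depth with attenuation, and depth-decaying read totals —
so recovery of the planted parameters is a direct test of the pipeline.
The velocity generator samples analytic flows (uniform, solid-body
rotation, double gyre) whose trajectories have closed forms, providing
exact oracles for the particle integrator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .table import SVTable, SampleMetadata, TaxonomyMap, ZoneConfig
from .velocity import EARTH_RADIUS_M, M_PER_DEG, OK, VelocityField

DEFAULT_MONTHS = ("2010-11", "2011-02", "2011-04", "2011-07")
DEFAULT_ZONES = ("surface", "epipelagic", "mesopelagic", "bathypelagic", "abyssopelagic")
DEFAULT_FRACTIONS = ("large", "small")
#: Representative sampling depth per zone (m).
ZONE_DEPTHS = {
    "surface": 10.0,
    "epipelagic": 200.0,
    "mesopelagic": 500.0,
    "bathypelagic": 1000.0,
    "abyssopelagic": 5000.0,
}

#: Lineage pool for generated taxa; last two entries are decoys that the
#: phytoplankton filter must remove (dinoflagellates / flagged heterotrophs).
_PHYTO_LINEAGES = (
    "Eukaryota;Archaeplastida;Chlorophyta;Mamiellophyceae",
    "Eukaryota;Archaeplastida;Chlorophyta;Pycnococcaceae",
    "Eukaryota;Hacrobia;Haptophyta;Prymnesiophyceae",
    "Eukaryota;Hacrobia;Cryptophyta;Cryptophyceae",
    "Eukaryota;Rhizaria;Cercozoa;Chlorarachniophyta",
    "Eukaryota;Stramenopiles;Heterokontophyta;Mediophyceae",
    "Eukaryota;Stramenopiles;Heterokontophyta;Bacillariophyceae",
    "Eukaryota;Stramenopiles;Heterokontophyta;Dictyochophyceae",
    "Eukaryota;Stramenopiles;Heterokontophyta;Chrysophyceae",
)
_DECOY_DINO = "Eukaryota;Alveolata;Dinoflagellata;Dinophyceae"
_DECOY_HET = "Eukaryota;Stramenopiles;Heterokontophyta;Chrysophyceae"


@dataclass
class CommunityScenario:
    """Planted structure for a synthetic SV table.

    ``allochthonous_read_fraction`` is the expected share of mixing-month
    surface reads (among phytoplankton) carried by allochthonous taxa;
    ``export_prob`` gives, per deeper zone, the probability that a surface
    SV re-occurs there; ``depth_total_decay`` scales read totals per zone
    step downward; ``dispersion`` is the overdispersion of per-SV relative
    abundances (gamma shape = 1/dispersion; 0 means none).
    """

    n_seed_taxa: int = 60
    n_allochthonous: int = 20
    allochthonous_read_fraction: float = 0.5
    export_prob: dict = field(
        default_factory=lambda: {
            "epipelagic": 0.9,
            "mesopelagic": 0.6,
            "bathypelagic": 0.4,
            "abyssopelagic": 0.3,
        }
    )
    depth_total_decay: float = 0.6
    reads_per_sample: int = 10_000
    dispersion: float = 0.5
    #: 0-based month indices of the mixing period (default: months 2 and 3).
    mixing_months: tuple[int, ...] = (1, 2)
    #: taxa first appearing in each sub-surface zone, and their read share there.
    n_deep_taxa: int = 8
    deep_read_fraction: float = 0.3
    #: read share of non-phytoplankton decoys (dinoflagellates, heterotrophs).
    decoy_read_fraction: float = 0.05
    n_decoys: int = 6
    seed: int = 0

    def validate(self) -> None:
        if self.n_seed_taxa + self.n_allochthonous <= 0:
            raise ValueError("scenario must contain at least one taxon")
        for name in ("allochthonous_read_fraction", "depth_total_decay",
                     "deep_read_fraction", "decoy_read_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for z, p in self.export_prob.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"export_prob[{z!r}] must lie in [0, 1], got {p}")
        if self.reads_per_sample <= 0:
            raise ValueError("reads_per_sample must be positive")
        if self.dispersion < 0:
            raise ValueError("dispersion must be nonnegative")


class SyntheticCommunity(NamedTuple):
    table: SVTable
    meta: SampleMetadata
    taxonomy: TaxonomyMap
    truth: dict


def _sample_weights(rng: np.random.Generator, n: int, dispersion: float) -> np.ndarray:
    """Unnormalized per-taxon abundance weights (gamma-overdispersed)."""
    if n == 0:
        return np.zeros(0)
    if dispersion <= 0:
        return np.ones(n)
    shape = 1.0 / dispersion
    return rng.gamma(shape, 1.0 / shape, size=n)


def generate_community(
    scenario: CommunityScenario,
    months: Sequence[str] = DEFAULT_MONTHS,
    zones: Sequence[str] = DEFAULT_ZONES,
    fractions: Sequence[str] = DEFAULT_FRACTIONS,
    seed: int | None = None,
) -> SyntheticCommunity:
    """One sample per month x zone x fraction, with planted provenance.

    Per sample, taxon groups receive fixed total weight shares (e.g. the
    allochthonous group gets exactly ``allochthonous_read_fraction`` of the
    phytoplankton share in mixing-month surface samples); within a group,
    weights are gamma-overdispersed; reads are a single multinomial draw,
    so each sample's total is exact. Deeper zones re-use the month's
    surface community thinned by per-zone export draws, add zone-endemic
    taxa, and have totals scaled by ``depth_total_decay`` per zone step.
    """
    scenario.validate()
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    sc = scenario

    zone_rank = {z: i for i, z in enumerate(zones)}
    deep_zones = [z for z in zones if z not in ("surface",)]
    mixing = {months[i] for i in sc.mixing_months if i < len(months)}

    # --- taxon roster ------------------------------------------------------
    names, lineages, trophic, role = [], [], [], {}

    def add(prefix, n, lineage_pool, flag="phototroph"):
        start = len(names)
        for i in range(n):
            nm = f"{prefix}{i:03d}"
            names.append(nm)
            lineages.append(lineage_pool[rng.integers(len(lineage_pool))])
            trophic.append(flag)
            role[nm] = prefix.rstrip("_")
        return names[start:]

    seed_taxa = add("seed_", sc.n_seed_taxa, _PHYTO_LINEAGES)
    allo_taxa = add("allo_", sc.n_allochthonous, _PHYTO_LINEAGES[5:7])  # coastal diatoms
    deep_taxa = {
        z: add(f"deep{zone_rank[z]}_", sc.n_deep_taxa, _PHYTO_LINEAGES)
        for z in deep_zones
        if z != "epipelagic"
    }
    n_dino = sc.n_decoys // 2
    dino = add("dino_", n_dino, (_DECOY_DINO,))
    het = add("het_", sc.n_decoys - n_dino, (_DECOY_HET,), flag="heterotroph")

    index = pd.Index(names, name="sv_id")
    counts = {}
    meta_rows = {}

    # Which surface SVs each (month, fraction) carries, for export draws.
    for frac in fractions:
        surface_members: dict[str, dict[str, np.ndarray]] = {}
        for month in months:
            is_mix = month in mixing
            present_allo = np.array(allo_taxa) if (is_mix and allo_taxa) else np.array([], dtype=object)
            surface_members[month] = {
                "seed": np.array(seed_taxa, dtype=object),
                "allo": present_allo,
            }
            for zone in zones:
                sample_id = f"{month}|{zone}|{frac}"
                rank = zone_rank[zone]
                total = int(round(sc.reads_per_sample * sc.depth_total_decay ** rank))
                total = max(total, 1)
                w = pd.Series(0.0, index=index)

                phyto_share = 1.0 - sc.decoy_read_fraction
                if zone == "surface" or zone == "epipelagic":
                    if zone == "surface":
                        seed_members = surface_members[month]["seed"]
                        allo_members = surface_members[month]["allo"]
                    else:
                        p = sc.export_prob.get(zone, 1.0)
                        seed_members = surface_members[month]["seed"][
                            rng.random(len(surface_members[month]["seed"])) < p
                        ]
                        allo_members = surface_members[month]["allo"][
                            rng.random(len(surface_members[month]["allo"])) < p
                        ]
                    f = sc.allochthonous_read_fraction if len(allo_members) else 0.0
                    if len(seed_members):
                        g = _sample_weights(rng, len(seed_members), sc.dispersion)
                        w[seed_members] = (1.0 - f) * phyto_share * g / g.sum()
                    if len(allo_members):
                        g = _sample_weights(rng, len(allo_members), sc.dispersion)
                        w[allo_members] = f * phyto_share * g / g.sum()
                else:
                    p = sc.export_prob.get(zone, 0.0)
                    seed_members = surface_members[month]["seed"][
                        rng.random(len(surface_members[month]["seed"])) < p
                    ]
                    allo_members = surface_members[month]["allo"][
                        rng.random(len(surface_members[month]["allo"])) < p
                    ]
                    exported = np.concatenate([seed_members, allo_members])
                    endemic = np.array(deep_taxa.get(zone, []), dtype=object)
                    d = sc.deep_read_fraction if len(endemic) else 0.0
                    if len(exported) == 0:
                        d = 1.0 if len(endemic) else 0.0
                    if len(exported):
                        f = sc.allochthonous_read_fraction if len(allo_members) else 0.0
                        if len(seed_members):
                            g = _sample_weights(rng, len(seed_members), sc.dispersion)
                            w[seed_members] = (1 - d) * (1 - f) * phyto_share * g / g.sum()
                        if len(allo_members):
                            g = _sample_weights(rng, len(allo_members), sc.dispersion)
                            w[allo_members] = (1 - d) * f * phyto_share * g / g.sum()
                    if len(endemic):
                        g = _sample_weights(rng, len(endemic), sc.dispersion)
                        w[endemic] = d * phyto_share * g / g.sum()

                decoys = dino + het
                if decoys and sc.decoy_read_fraction > 0:
                    g = _sample_weights(rng, len(decoys), sc.dispersion)
                    w[decoys] = sc.decoy_read_fraction * g / g.sum()

                if w.sum() <= 0:
                    counts[sample_id] = np.zeros(len(index), dtype=np.int64)
                else:
                    probs = (w / w.sum()).to_numpy()
                    counts[sample_id] = rng.multinomial(total, probs)
                meta_rows[sample_id] = {
                    "month": month,
                    "depth_m": ZONE_DEPTHS.get(zone, 10.0),
                    "zone": zone,
                    "fraction": frac,
                }

    table = SVTable(pd.DataFrame(counts, index=index))
    meta = SampleMetadata(
        pd.DataFrame.from_dict(meta_rows, orient="index").rename_axis("sample_id"),
        zone_config=ZoneConfig(),
    )
    tax = TaxonomyMap(
        pd.DataFrame({"lineage": lineages, "trophic_flag": trophic}, index=index)
    )
    truth = {
        "scenario": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in vars(sc).items()
            if not isinstance(v, dict)
        },
        "export_prob": dict(sc.export_prob),
        "roles": role,
        "mixing_months": sorted(mixing),
        "intended_totals": {
            s: int(round(sc.reads_per_sample * sc.depth_total_decay ** zone_rank[m["zone"]]))
            for s, m in meta_rows.items()
        },
    }
    return SyntheticCommunity(table, meta, tax, truth)


# --------------------------------------------------------------------------
# Analytic flows
# --------------------------------------------------------------------------


class AnalyticFlow:
    """Closed-form velocity field; doubles as a sampler for the integrator."""

    def velocity_at(self, lon, lat, t):  # pragma: no cover - interface
        raise NotImplementedError

    def velocity(self, lons, lats, t):
        u, v = self.velocity_at(np.asarray(lons, float), np.asarray(lats, float), t)
        status = np.full(np.shape(u), OK, dtype=np.int8)
        return np.atleast_1d(u), np.atleast_1d(v), np.atleast_1d(status)


@dataclass
class UniformFlow(AnalyticFlow):
    """Spatially constant flow. Exact trajectory: latitude fixed, longitude

    lon(t) = lon0 + u * t * 180 / (pi * R * cos(lat)); the v component is
    handled only for v=0 in the closed form (the general case has no
    elementary solution on the sphere).
    """

    u0: float
    v0: float = 0.0

    def velocity_at(self, lon, lat, t):
        return np.full_like(np.asarray(lon, float), self.u0), np.full_like(
            np.asarray(lat, float), self.v0
        )

    def exact_lon_displacement(self, lat: float, duration: float) -> float:
        """Eastward displacement (degrees) over ``duration`` s at fixed latitude."""
        return self.u0 * duration / (M_PER_DEG * np.cos(np.deg2rad(lat)))


@dataclass
class SolidRotationFlow(AnalyticFlow):
    """Rigid rotation in longitude-latitude coordinates about a center.

    Defined so that the exact trajectory is a circle in degree space:
    with a = lon - lon_c, b = lat - lat_c (degrees),

        u = -omega * b * (pi/180) * R * cos(lat),   v = omega * a * (pi/180) * R,

    giving da/dt = -omega b, db/dt = omega a, hence
    (a + i b)(t) = (a0 + i b0) exp(i omega t): the degree-space radius
    sqrt(a^2 + b^2) is conserved exactly.
    """

    center: tuple[float, float]
    omega: float  # rad/s

    def velocity_at(self, lon, lat, t):
        a = np.asarray(lon, float) - self.center[0]
        b = np.asarray(lat, float) - self.center[1]
        u = -self.omega * b * (np.pi / 180.0) * EARTH_RADIUS_M * np.cos(np.deg2rad(lat))
        v = self.omega * a * (np.pi / 180.0) * EARTH_RADIUS_M
        return u, v

    def exact_position(self, lon0, lat0, t):
        z0 = (np.asarray(lon0, float) - self.center[0]) + 1j * (
            np.asarray(lat0, float) - self.center[1]
        )
        z = z0 * np.exp(1j * self.omega * t)
        return self.center[0] + z.real, self.center[1] + z.imag

    def radius_deg(self, lon, lat):
        return np.hypot(np.asarray(lon, float) - self.center[0], np.asarray(lat, float) - self.center[1])


@dataclass
class DoubleGyreFlow(AnalyticFlow):
    """Classic two-gyre stream-function flow mapped onto a lon/lat box.

    Stream function psi = A sin(pi f(x, t)) sin(pi y) on the unit-scaled
    domain x in [0, 2], y in [0, 1], with
    f(x, t) = eps sin(w t) x^2 + (1 - 2 eps sin(w t)) x. Velocities (m/s):
    u = -pi A sin(pi f) cos(pi y) ... the flow is divergence-free.
    """

    lon_min: float
    lon_max: float
    lat_min: float
    lat_max: float
    amplitude: float = 0.3  # m/s scale
    eps: float = 0.1
    period_s: float = 30 * 86400.0

    def _xy(self, lon, lat):
        x = 2.0 * (np.asarray(lon, float) - self.lon_min) / (self.lon_max - self.lon_min)
        y = (np.asarray(lat, float) - self.lat_min) / (self.lat_max - self.lat_min)
        return x, y

    def velocity_at(self, lon, lat, t):
        x, y = self._xy(lon, lat)
        w = 2 * np.pi / self.period_s
        e = self.eps * np.sin(w * t)
        f = e * x ** 2 + (1 - 2 * e) * x
        dfdx = 2 * e * x + (1 - 2 * e)
        u = -np.pi * self.amplitude * np.sin(np.pi * f) * np.cos(np.pi * y)
        v = np.pi * self.amplitude * np.cos(np.pi * f) * np.sin(np.pi * y) * dfdx
        return u, v


@dataclass(frozen=True)
class GridSpec:
    """Regular lon/lat grid with depth levels."""

    lon_min: float = 138.0
    lon_max: float = 152.0
    lat_min: float = 23.0
    lat_max: float = 37.0
    spacing: float = 0.1
    levels: tuple[float, ...] = (0.5, 12, 50, 100, 158, 200, 300, 480, 1000, 2000, 5000)


@dataclass(frozen=True)
class TimeSpec:
    t0: float = 0.0
    dt: float = 86400.0
    n: int = 2


def generate_field(
    kind: str,
    params: dict | None = None,
    grid: GridSpec = GridSpec(),
    time: TimeSpec = TimeSpec(),
) -> tuple[VelocityField, AnalyticFlow]:
    """Sample a named analytic flow onto a gridded velocity field.

    Returns the gridded field together with the analytic flow object,
    whose closed forms serve as trajectory oracles. Kinds: ``uniform``
    (params u, v), ``solid_rotation`` (center, omega), ``double_gyre``
    (amplitude, eps, period_s). The same flow is stored at every depth
    level; all cells are sea.
    """
    params = dict(params or {})
    if kind == "uniform":
        flow: AnalyticFlow = UniformFlow(params.get("u", 0.1), params.get("v", 0.0))
    elif kind == "solid_rotation":
        center = params.get(
            "center", ((grid.lon_min + grid.lon_max) / 2, (grid.lat_min + grid.lat_max) / 2)
        )
        flow = SolidRotationFlow(tuple(center), params.get("omega", 5e-6))
    elif kind == "double_gyre":
        flow = DoubleGyreFlow(
            grid.lon_min,
            grid.lon_max,
            grid.lat_min,
            grid.lat_max,
            amplitude=params.get("amplitude", 0.3),
            eps=params.get("eps", 0.1),
            period_s=params.get("period_s", 30 * 86400.0),
        )
    else:
        raise ValueError(f"unknown analytic field kind {kind!r}")

    lons = grid.lon_min + grid.spacing * np.arange(
        int(round((grid.lon_max - grid.lon_min) / grid.spacing)) + 1
    )
    lats = grid.lat_min + grid.spacing * np.arange(
        int(round((grid.lat_max - grid.lat_min) / grid.spacing)) + 1
    )
    times = time.t0 + time.dt * np.arange(time.n)
    lon_g, lat_g = np.meshgrid(lons, lats)
    nt, nl = len(times), len(grid.levels)
    u = np.empty((nt, nl, len(lats), len(lons)))
    v = np.empty_like(u)
    for it, t in enumerate(times):
        ug, vg = flow.velocity_at(lon_g, lat_g, t)
        u[it] = np.broadcast_to(ug, (nl,) + ug.shape)
        v[it] = np.broadcast_to(vg, (nl,) + vg.shape)
    fld = VelocityField(
        lons, lats, np.asarray(grid.levels, float), times, u, v,
        sea=np.ones((nl, len(lats), len(lons)), dtype=bool),
    )
    return fld, flow
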