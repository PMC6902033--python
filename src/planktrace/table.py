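"""Core in-memory containers for the sequence-variant pipeline.

The pipeline operates on three tabular objects — a sequence-variant (SV)
count table, per-sample metadata, and per-SV taxonomy — all backed by
pandas DataFrames, plus a small configuration object that maps sampling
depth to an oceanographic depth zone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Ordered depth-zone labels, shallow to deep. "surface" is the upper part
#: of the epipelagic that mixes separately (upper ~50 m most of the year).
ZONES = ("surface", "epipelagic", "mesopelagic", "bathypelagic", "abyssopelagic")

#: Size-fraction labels: sequential filtration, >=3 um and 0.2-3 um.
FRACTIONS = ("large", "small")


@dataclass(frozen=True)
class ZoneConfig:
    """Depth-zone boundaries in meters (inclusive upper edges).

    A depth ``d`` maps to the shallowest zone whose upper edge is >= ``d``,
    so boundary values fall in the shallower zone. Defaults follow the
    sampled-depth binning used for subtropical NW-Pacific station work:
    surface <= 50 m (100 m during deep winter mixing, configurable per
    month), epipelagic <= 300 m, mesopelagic centred on 500 m, bathypelagic
    1,000-2,000 m (standard definition up to 4,000 m), abyssopelagic below.
    """

    surface_max_m: float = 50.0
    epipelagic_max_m: float = 300.0
    mesopelagic_max_m: float = 999.0
    bathypelagic_max_m: float = 3999.0
    #: Optional per-month override of the surface boundary, e.g. {"2011-02": 100.0}.
    surface_max_by_month: Mapping[str, float] = field(default_factory=dict)

    def zone_of(self, depth_m: float, month: str | None = None) -> str:
        if not np.isfinite(depth_m) or depth_m < 0:
            raise ValueError(f"depth_m must be a nonnegative finite number, got {depth_m!r}")
        surface_max = self.surface_max_by_month.get(month, self.surface_max_m)
        if depth_m <= surface_max:
            return "surface"
        if depth_m <= self.epipelagic_max_m:
            return "epipelagic"
        if depth_m <= self.mesopelagic_max_m:
            return "mesopelagic"
        if depth_m <= self.bathypelagic_max_m:
            return "bathypelagic"
        return "abyssopelagic"


def _check_unique(values: Iterable[str], what: str) -> None:
    idx = pd.Index(values)
    if idx.has_duplicates:
        dups = sorted(idx[idx.duplicated()].unique().tolist())
        raise ValueError(f"duplicate {what}: {dups}")


class SVTable:
    """Nonnegative integer count matrix, SVs (rows) x samples (columns).

    Zero rows/columns are permitted and preserved.
    """

    def __init__(self, counts: pd.DataFrame):
        _check_unique(counts.index, "sv_ids")
        _check_unique(counts.columns, "sample_ids")
        arr = counts.to_numpy()
        if arr.size:
            if not np.issubdtype(arr.dtype, np.number):
                raise ValueError("counts must be numeric")
            if np.any(arr != np.floor(arr)) or np.any(~np.isfinite(arr.astype(float))):
                r, c = np.argwhere(arr != np.floor(arr))[0]
                raise ValueError(
                    f"non-integer count at (sv={counts.index[r]!r}, sample={counts.columns[c]!r}): {arr[r, c]!r}"
                )
            if np.any(arr < 0):
                r, c = np.argwhere(arr < 0)[0]
                raise ValueError(
                    f"negative count at (sv={counts.index[r]!r}, sample={counts.columns[c]!r}): {arr[r, c]!r}"
                )
        self.counts = counts.astype(np.int64)

    @property
    def sv_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def sample_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def select_samples(self, sample_ids: Sequence[str]) -> "SVTable":
        missing = [s for s in sample_ids if s not in self.counts.columns]
        if missing:
            raise KeyError(f"unknown sample_ids: {missing}")
        return SVTable(self.counts.loc[:, list(sample_ids)])

    def select_svs(self, sv_ids: Sequence[str]) -> "SVTable":
        missing = [s for s in sv_ids if s not in self.counts.index]
        if missing:
            raise KeyError(f"unknown sv_ids: {missing}")
        return SVTable(self.counts.loc[list(sv_ids)])

    def __eq__(self, other) -> bool:  # pragma: no cover - convenience
        return isinstance(other, SVTable) and self.counts.equals(other.counts)

    def __repr__(self) -> str:  # pragma: no cover
        return f"SVTable({self.shape[0]} SVs x {self.shape[1]} samples)"


class SampleMetadata:
    """Per-sample cruise month, depth, depth zone, and size fraction.

    Backed by a DataFrame indexed by sample_id with columns
    ``month``, ``depth_m``, ``zone``, ``fraction``. The zone column is
    derived from depth via :class:`ZoneConfig` when not supplied.
    """

    REQUIRED = ("month", "depth_m", "fraction")

    def __init__(self, frame: pd.DataFrame, zone_config: ZoneConfig | None = None):
        _check_unique(frame.index, "sample_ids")
        for col in self.REQUIRED:
            if col not in frame.columns:
                raise ValueError(f"metadata missing required column {col!r}")
        frame = frame.copy()
        frame["depth_m"] = frame["depth_m"].astype(float)
        if (frame["depth_m"] < 0).any():
            bad = frame.index[frame["depth_m"] < 0].tolist()
            raise ValueError(f"negative depth_m for samples {bad}")
        bad_frac = sorted(set(frame["fraction"]) - set(FRACTIONS))
        if bad_frac:
            raise ValueError(f"unknown size fraction labels {bad_frac}; expected {FRACTIONS}")
        cfg = zone_config or ZoneConfig()
        if "zone" not in frame.columns or frame["zone"].isna().any():
            frame["zone"] = [
                cfg.zone_of(d, m) for d, m in zip(frame["depth_m"], frame["month"])
            ]
        else:
            bad_zone = sorted(set(frame["zone"]) - set(ZONES))
            if bad_zone:
                raise ValueError(f"unknown zone labels {bad_zone}; expected {ZONES}")
        self.frame = frame
        self.zone_config = cfg

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.index)

    def months(self) -> list[str]:
        """Distinct month labels in first-appearance order."""
        return list(dict.fromkeys(self.frame["month"]))

    def select(
        self,
        month: str | None = None,
        zone: str | None = None,
        fraction: str | None = None,
        max_depth_m: float | None = None,
    ) -> list[str]:
        """Sample ids matching all given criteria."""
        m = pd.Series(True, index=self.frame.index)
        if month is not None:
            m &= self.frame["month"] == month
        if zone is not None:
            m &= self.frame["zone"] == zone
        if fraction is not None:
            m &= self.frame["fraction"] == fraction
        if max_depth_m is not None:
            m &= self.frame["depth_m"] <= max_depth_m
        return list(self.frame.index[m])

    def check_covers(self, table: SVTable) -> None:
        missing = [s for s in table.sample_ids if s not in self.frame.index]
        if missing:
            raise ValueError(f"samples in table without metadata: {missing}")

    def __repr__(self) -> str:  # pragma: no cover
        return f"SampleMetadata({len(self.frame)} samples)"


class TaxonomyMap:
    """Per-SV semicolon-delimited lineage plus optional trophic annotation."""

    TROPHIC = ("phototroph", "heterotroph", "unknown")

    def __init__(self, frame: pd.DataFrame):
        _check_unique(frame.index, "sv_ids")
        if "lineage" not in frame.columns:
            raise ValueError("taxonomy missing required column 'lineage'")
        frame = frame.copy()
        empty = frame.index[frame["lineage"].astype(str).str.len() == 0].tolist()
        if empty:
            raise ValueError(f"empty lineage for SVs {empty}")
        if "trophic_flag" not in frame.columns:
            frame["trophic_flag"] = "unknown"
        frame["trophic_flag"] = frame["trophic_flag"].fillna("unknown")
        bad = sorted(set(frame["trophic_flag"]) - set(self.TROPHIC))
        if bad:
            raise ValueError(f"unknown trophic_flag values {bad}; expected {self.TROPHIC}")
        self.frame = frame

    @property
    def sv_ids(self) -> list[str]:
        return list(self.frame.index)

    def lineage(self, sv_id: str) -> str:
        return str(self.frame.at[sv_id, "lineage"])

    def trophic(self, sv_id: str) -> str:
        return str(self.frame.at[sv_id, "trophic_flag"])

    def check_covers(self, table: SVTable) -> None:
        missing = [s for s in table.sv_ids if s not in self.frame.index]
        if missing:
            raise ValueError(f"SVs in table without taxonomy: {missing}")

    def __repr__(self) -> str:  # pragma: no cover
        return f"TaxonomyMap({len(self.frame)} SVs)"
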