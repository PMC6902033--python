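"""Readers and writers for every external representation the pipeline touches.

Tabular inputs are TSV (SV table: rows = SVs, columns = samples; metadata:
sample_id, month, depth_m, fraction[, zone]; taxonomy: sv_id, lineage
[, trophic_flag]). Representative sequences are FASTA keyed by sv_id.
Velocity fields are CF-style NetCDF (lon/lat/level/time coordinates, u/v
variables in m s^-1). Trajectories are tidy CSV.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import xarray as xr
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .backtrack import TrajectorySet
from .stats import DistanceMatrix
from .table import SVTable, SampleMetadata, TaxonomyMap, ZoneConfig
from .velocity import VelocityField


# --------------------------------------------------------------------------
# SV table / metadata / taxonomy (TSV)
# --------------------------------------------------------------------------

def read_sv_table(
    path: str | Path,
    meta_path: str | Path,
    zone_config: ZoneConfig | None = None,
) -> tuple[SVTable, SampleMetadata]:
    """Read and cross-validate an SV count matrix and its sample metadata.

    Rejects duplicate SV/sample ids (naming them), negative or non-integer
    counts (naming the cell), and samples present in the matrix but absent
    from the metadata.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0)
    table = SVTable(raw)
    meta_frame = pd.read_csv(meta_path, sep="\t", dtype={"month": str}).set_index("sample_id")
    meta = SampleMetadata(meta_frame, zone_config=zone_config)
    meta.check_covers(table)
    return table, meta


def write_sv_table(table: SVTable, path: str | Path) -> None:
    table.counts.rename_axis("sv_id").to_csv(path, sep="\t")


def write_sample_metadata(meta: SampleMetadata, path: str | Path) -> None:
    meta.frame.rename_axis("sample_id").to_csv(path, sep="\t")


def read_taxonomy(path: str | Path) -> TaxonomyMap:
    frame = pd.read_csv(path, sep="\t").set_index("sv_id")
    return TaxonomyMap(frame)


def write_taxonomy(tax: TaxonomyMap, path: str | Path) -> None:
    tax.frame.rename_axis("sv_id").to_csv(path, sep="\t")


# --------------------------------------------------------------------------
# Representative sequences (FASTA)
# --------------------------------------------------------------------------

def read_sequences(path: str | Path) -> dict[str, str]:
    """FASTA of representative SV sequences, keyed by sv_id."""
    seqs = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"duplicate sequence id {rec.id!r}")
        seqs[rec.id] = str(rec.seq)
    return seqs


def write_sequences(seqs: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=k, description="") for k, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


# --------------------------------------------------------------------------
# Velocity fields (NetCDF)
# --------------------------------------------------------------------------

_COORD_ALIASES = {
    "lon": ("lon", "longitude", "x"),
    "lat": ("lat", "latitude", "y"),
    "level": ("level", "depth", "lev", "z"),
    "time": ("time", "t"),
}


def _find_coord(ds: xr.Dataset, canonical: str) -> str:
    for name in _COORD_ALIASES[canonical]:
        if name in ds.coords or name in ds.dims:
            return name
    raise ValueError(f"velocity file is missing a {canonical!r} coordinate "
                     f"(accepted names: {_COORD_ALIASES[canonical]})")


def read_velocity_field(path: str | Path) -> VelocityField:
    """Read a CF-style NetCDF velocity file into a :class:`VelocityField`.

    Requires lon/lat/level/time coordinates and ``u``/``v`` variables in
    m s^-1 ordered (time, level, lat, lon). The land mask is taken from an
    explicit boolean ``mask`` variable (True = sea) if present, else
    inferred from NaN/fill values in u/v.
    """
    with xr.open_dataset(path, engine="scipy") as ds:
        names = {c: _find_coord(ds, c) for c in ("lon", "lat", "level", "time")}
        for var in ("u", "v"):
            if var not in ds:
                raise ValueError(f"velocity file is missing variable {var!r}")
        order = [names["time"], names["level"], names["lat"], names["lon"]]
        u = ds["u"].transpose(*order).to_numpy()
        v = ds["v"].transpose(*order).to_numpy()
        sea = None
        if "mask" in ds:
            sea = ds["mask"].transpose(*order[1:]).to_numpy().astype(bool)
        fld = VelocityField(
            lons=ds[names["lon"]].to_numpy().astype(float),
            lats=ds[names["lat"]].to_numpy().astype(float),
            levels=ds[names["level"]].to_numpy().astype(float),
            times=ds[names["time"]].to_numpy().astype(float),
            u=u,
            v=v,
            sea=sea,
        )
    return fld


def write_velocity_field(fld: VelocityField, path: str | Path) -> None:
    """Write a velocity field as NetCDF (land cells stored as NaN)."""
    dims = ("time", "level", "lat", "lon")
    sea4 = np.broadcast_to(fld.sea, fld.u.shape)
    ds = xr.Dataset(
        {
            "u": (dims, np.where(sea4, fld.u, np.nan)),
            "v": (dims, np.where(sea4, fld.v, np.nan)),
            "mask": (dims[1:], fld.sea.astype(np.int8)),
        },
        coords={
            "time": ("time", fld.times),
            "level": ("level", fld.levels),
            "lat": ("lat", fld.lats),
            "lon": ("lon", fld.lons),
        },
    )
    ds["u"].attrs["units"] = "m s-1"
    ds["v"].attrs["units"] = "m s-1"
    ds["level"].attrs["units"] = "m"
    ds["lat"].attrs["units"] = "degrees_north"
    ds["lon"].attrs["units"] = "degrees_east"
    ds.to_netcdf(path, engine="scipy")


# --------------------------------------------------------------------------
# Trajectories, distances, attribution, manifests
# --------------------------------------------------------------------------

def write_trajectories(traj: TrajectorySet, path: str | Path) -> None:
    traj.to_frame().to_csv(path, index=False)


def read_trajectories(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_distance_matrix(dm: DistanceMatrix, path: str | Path) -> None:
    dm.to_frame().to_csv(path, sep="\t")


def read_distance_matrix(path: str | Path) -> DistanceMatrix:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    return DistanceMatrix(list(frame.index), frame.to_numpy())


def write_manifest(manifest: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
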