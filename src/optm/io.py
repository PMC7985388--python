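"""Readers and writers for the pipeline's interchange formats.

Long-format CSV is the canonical interchange (station and gridded data
share one schema: time, location, metal, category, origin, sector,
value).  NetCDF is offered for dense tagged fields, with a presence mask
so that structurally absent tag combinations survive the round trip
distinct from genuinely missing values.  Reports and manifests are JSON
with numbers serialized to 10 significant digits.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from .scoring import COLUMNS, KEY_COLUMNS, ConcentrationSet, OPField, SchemaError

__all__ = [
    "read_concentrations",
    "write_concentrations",
    "read_op_field",
    "write_op_field",
    "read_emission_table",
    "write_emission_table",
    "read_region_mask",
    "write_region_mask",
    "write_json_report",
    "read_json_report",
    "SchemaError",
]

log = logging.getLogger("optm")


def _read_long_frame(path: str | Path, fmt: str | None) -> tuple[pd.DataFrame, dict]:
    path = Path(path)
    if fmt is None:
        fmt = "netcdf" if path.suffix in (".nc", ".nc4", ".cdf") else "csv"
    if fmt == "csv":
        df = pd.read_csv(path)
        attrs: dict = {}
    elif fmt == "netcdf":
        ds = xr.open_dataset(path)
        df = _dataset_to_long(ds)
        attrs = dict(ds.attrs)
        ds.close()
    else:
        raise ValueError(f"unknown format {fmt!r}; use 'csv' or 'netcdf'")
    extra = [c for c in df.columns if c not in COLUMNS]
    if extra:
        log.warning("%s: ignoring unknown columns %s", path, extra)
        df = df.drop(columns=extra)
    return df, attrs


def read_concentrations(path: str | Path, fmt: str | None = None) -> ConcentrationSet:
    """Read a tagged concentration table (CSV long format or NetCDF).

    Schema violations raise :class:`SchemaError` naming the offending
    rows; an empty file yields an empty set; unknown extra columns are
    dropped with a logged warning.
    """
    df, _ = _read_long_frame(path, fmt)
    return ConcentrationSet(df)


def read_op_field(path: str | Path, fmt: str | None = None) -> OPField:
    """Read a per-tag OP contribution field written by :func:`write_op_field`."""
    df, attrs = _read_long_frame(path, fmt)
    if fmt is None and Path(path).suffix not in (".nc", ".nc4", ".cdf"):
        side = Path(str(path) + ".meta.json")
        if side.exists():
            attrs = json.loads(side.read_text())
    return OPField(
        df,
        params_label=str(attrs.get("params_label", "CA")),
        f_applied=bool(attrs.get("f_applied", False)),
    )


def _write_long_frame(df: pd.DataFrame, path: str | Path, fmt: str | None, attrs: dict) -> None:
    path = Path(path)
    if fmt is None:
        fmt = "netcdf" if path.suffix in (".nc", ".nc4", ".cdf") else "csv"
    out = df.copy()
    out["time"] = pd.to_datetime(out["time"]).dt.strftime("%Y-%m-%dT%H:%M:%S+09:00")
    if fmt == "csv":
        out.to_csv(path, index=False, float_format="%.10g")
        if attrs:
            Path(str(path) + ".meta.json").write_text(json.dumps(attrs, indent=2) + "\n")
    elif fmt == "netcdf":
        ds = _long_to_dataset(df)
        ds.attrs.update(attrs)
        ds.to_netcdf(path)
    else:
        raise ValueError(f"unknown format {fmt!r}; use 'csv' or 'netcdf'")


def write_concentrations(conc: ConcentrationSet, path: str | Path, fmt: str | None = None) -> None:
    _write_long_frame(conc.frame, path, fmt, {})


def write_op_field(op: OPField, path: str | Path, fmt: str | None = None) -> None:
    _write_long_frame(
        op.frame, path, fmt, {"params_label": op.params_label, "f_applied": int(op.f_applied)}
    )


# ---------------------------------------------------------------------------
# dense NetCDF layout: dims (time, location, metal, tag), with per-tag
# coordinate variables category/origin/sector and an int8 presence mask

def _long_to_dataset(df: pd.DataFrame) -> xr.Dataset:
    df = df.copy()
    df["time"] = pd.to_datetime(df["time"])
    tags = (
        df[["category", "origin", "sector"]]
        .drop_duplicates()
        .sort_values(["category", "origin", "sector"])
        .reset_index(drop=True)
    )
    tag_key = tags.apply(lambda r: f"{r.category}|{r.origin}|{r.sector}", axis=1)
    df["tag"] = df["category"] + "|" + df["origin"] + "|" + df["sector"]
    idx = df.set_index(["time", "location", "metal", "tag"])
    full = pd.MultiIndex.from_product(
        [
            sorted(df["time"].unique()),
            sorted(df["location"].unique()),
            sorted(df["metal"].unique()),
            list(tag_key),
        ],
        names=["time", "location", "metal", "tag"],
    )
    values = idx["value"].reindex(full)
    present = idx["value"].notna().reindex(full)
    structural = ~present.isna()
    arr = values.to_frame().assign(present=structural.astype("int8")).to_xarray()
    ds = xr.Dataset(
        {
            "concentration": arr["value"].astype("float64"),
            "present": arr["present"],
        },
        attrs={"units": "ng m-3"},
    )
    ds = ds.assign_coords(
        category=("tag", tags["category"].to_numpy()),
        origin=("tag", tags["origin"].to_numpy()),
        sector=("tag", tags["sector"].to_numpy()),
    )
    return ds


def _dataset_to_long(ds: xr.Dataset) -> pd.DataFrame:
    df = ds["concentration"].to_dataframe().reset_index()
    mask = ds["present"].to_dataframe().reset_index()["present"].to_numpy() == 1
    df = df[mask].reset_index(drop=True)
    tag_parts = df["tag"].str.split("|", expand=True)
    df["category"], df["origin"], df["sector"] = (
        tag_parts[0],
        tag_parts[1],
        tag_parts[2],
    )
    df = df.rename(columns={"concentration": "value"})
    return df[COLUMNS]


# ---------------------------------------------------------------------------
# emission tables and region masks

def read_emission_table(path: str | Path):
    from .apportion import SectorEmissionTable

    return SectorEmissionTable(pd.read_csv(path))


def write_emission_table(table, path: str | Path) -> None:
    table.frame.to_csv(path, index=False, float_format="%.10g")


def read_region_mask(path: str | Path, total_region: str | None = None):
    """Read a (location, region) CSV into a RegionMask."""
    from .apportion import RegionMask

    df = pd.read_csv(path)
    missing = [c for c in ("location", "region") if c not in df.columns]
    if missing:
        raise SchemaError(f"region mask missing columns: {missing}")
    regions: dict[str, set] = {}
    for _, row in df.iterrows():
        regions.setdefault(str(row["region"]), set()).add(row["location"])
    return RegionMask(regions, total_region=total_region)


def write_region_mask(mask, path: str | Path) -> None:
    rows = [
        {"location": loc, "region": name}
        for name, locs in mask.regions.items()
        for loc in sorted(locs)
    ]
    pd.DataFrame(rows, columns=["location", "region"]).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# JSON reports

def _round_floats(obj, digits: int = 10):
    if isinstance(obj, dict):
        return {k: _round_floats(v, digits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, digits) for v in obj]
    if isinstance(obj, (float, np.floating)):
        x = float(obj)
        if np.isnan(x):
            return None
        return float(f"{x:.{digits}g}")
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


def write_json_report(data: dict, path: str | Path, digits: int = 10) -> None:
    """Serialize a report dict with numbers at 10 significant digits."""
    with open(path, "w") as fh:
        json.dump(_round_floats(data, digits), fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json_report(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def config_hash(data: dict) -> str:
    """Stable hash of a config mapping, for run manifests."""
    canon = json.dumps(data, sort_keys=True, default=str).encode()
    return hashlib.sha256(canon).hexdigest()[:16]
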