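"""File I/O: underway TSV dialect, bottle tables, NetCDF grids.

Underway surveys travel as tab-separated text with header columns
(lon, lat, iso_datetime, pco2_uatm, sst_c, sss, wind10_ms); SOCAT-style
files carrying fCO2 instead of pCO2 are accepted and converted with the
virial correction. Bottle tables use columns (station, depth_m, temp_c,
sal, o2_umolkg, no3_umolkg, po4_umolkg, ta_umolkg, dic_umolkg); GLODAP-
style columns are mapped via ``GLODAP_COLUMNS``.
"""

from __future__ import annotations

import os

import pandas as pd
import xarray as xr

from buscarb import carbonate

UNDERWAY_COLUMNS = {
    "lon": "lon",
    "lat": "lat",
    "iso_datetime": "time",
    "pco2_uatm": "pco2",
    "sst_c": "sst",
    "sss": "sss",
    "wind10_ms": "wind10",
}
_UNDERWAY_MANDATORY = ("lon", "lat", "iso_datetime", "sst_c", "sss", "wind10_ms")

BOTTLE_COLUMNS = (
    "station",
    "depth_m",
    "temp_c",
    "sal",
    "o2_umolkg",
    "no3_umolkg",
    "po4_umolkg",
    "ta_umolkg",
    "dic_umolkg",
)

GLODAP_COLUMNS = {
    "G2station": "station",
    "G2depth": "depth_m",
    "G2theta": "temp_c",
    "G2salinity": "sal",
    "G2oxygen": "o2_umolkg",
    "G2nitrate": "no3_umolkg",
    "G2phosphate": "po4_umolkg",
    "G2talk": "ta_umolkg",
    "G2tco2": "dic_umolkg",
}


def write_underway(df: pd.DataFrame, path) -> None:
    out = pd.DataFrame(
        {
            "lon": df["lon"],
            "lat": df["lat"],
            "iso_datetime": pd.to_datetime(df["time"]).dt.strftime("%Y-%m-%dT%H:%M:%S"),
            "pco2_uatm": df["pco2"],
            "sst_c": df["sst"],
            "sss": df["sss"],
            "wind10_ms": df["wind10"],
        }
    )
    out.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_underway(path, column_map: dict | None = None) -> pd.DataFrame:
    """Read an underway TSV; converts an fCO2 column to pCO2 when no pCO2
    column is present. Missing mandatory columns are listed by name."""
    if os.path.getsize(path) == 0:
        raise ValueError(f"empty underway file: {path}")
    df = pd.read_csv(path, sep="\t")
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in _UNDERWAY_MANDATORY if c not in df.columns]
    if "pco2_uatm" not in df.columns and "fco2_uatm" not in df.columns:
        missing.append("pco2_uatm (or fco2_uatm)")
    if missing:
        raise ValueError(f"underway file {path} missing mandatory columns: {', '.join(missing)}")
    out = pd.DataFrame(
        {
            "lon": df["lon"].astype(float),
            "lat": df["lat"].astype(float),
            "time": pd.to_datetime(df["iso_datetime"]),
            "sst": df["sst_c"].astype(float),
            "sss": df["sss"].astype(float),
            "wind10": df["wind10_ms"].astype(float),
        }
    )
    if "pco2_uatm" in df.columns:
        out["pco2"] = df["pco2_uatm"].astype(float)
    else:
        out["pco2"] = carbonate.fco2_to_pco2(
            df["fco2_uatm"].astype(float).to_numpy(), out["sst"].to_numpy()
        )
    bad = out["pco2"] <= 0
    if bad.any():
        raise ValueError(f"underway file {path}: {int(bad.sum())} records with pCO2 <= 0")
    return out


def write_bottles(df: pd.DataFrame, path) -> None:
    df[list(BOTTLE_COLUMNS)].to_csv(path, sep="\t", index=False, float_format="%.4f")


def read_bottles(path, column_map: dict | None = None) -> pd.DataFrame:
    """Read a bottle table; pass ``column_map=GLODAP_COLUMNS`` for
    GLODAP-style files."""
    if os.path.getsize(path) == 0:
        raise ValueError(f"empty bottle file: {path}")
    df = pd.read_csv(path, sep="\t" if str(path).endswith((".tsv", ".txt")) else ",")
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in BOTTLE_COLUMNS[:7] if c not in df.columns]
    if missing:
        raise ValueError(f"bottle file {path} missing mandatory columns: {', '.join(missing)}")
    return df


def write_grid(ds: xr.Dataset, path) -> None:
    """Write a gridded field as NetCDF (classic format via the scipy
    backend) with CF-style coordinates."""
    ds.to_netcdf(path, engine="scipy")


def read_grid(path) -> xr.Dataset:
    with xr.open_dataset(path, engine="scipy") as ds:
        return ds.load()
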