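"""Readers and writers for the deposited CSV schemas and GeoJSON boundaries.

Two fixed column layouts are supported: the pre-processed observation table
(``step2``-style, one row per submitted price line) and the weekly estimate
table (``step3``-style, one row per state / week / product / price type).
Column order is bit-stable, booleans serialise as ``FALSE``/``TRUE`` and the
decimal separator is always a point regardless of locale.  Paths ending in
``.gz`` are read and written gzip-compressed transparently.
"""

from __future__ import annotations

import gzip
import json
import logging
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import mapping, shape

from .admin import AdminUnit

logger = logging.getLogger(__name__)

#: Pre-processed observation table, exact field order.
STEP2_COLUMNS = [
    "id_form", "id", "deviceid", "volunteer_id", "product", "type",
    "price_type", "market_type_cat", "lat", "lon", "alt", "pre",
    "level0", "level0code", "level1", "level1code", "level2", "level2code",
    "time_start", "submission_time", "packaging", "conversion",
    "price_observed", "price_kg", "buying_purpose", "market_distance",
    "area", "population", "density", "level3urban_new",
    "outlier", "cluster", "relocation",
]

#: Weekly estimate table, exact field order (dotted names are intentional).
STEP3_COLUMNS = [
    "level1", "submission_week", "submission_month", "submission_year",
    "week_start", "product", "price_type", "price.mean", "price.ps", "CRI",
]

_BOOL_COLUMNS = ["level3urban_new", "outlier", "relocation"]
_MANDATORY_COLUMNS = [
    "id_form", "id", "volunteer_id", "product", "market_type_cat",
    "lat", "lon", "submission_time", "packaging", "price_observed",
]


class SchemaError(ValueError):
    """A required column is missing from an input file."""


class ReadResult(NamedTuple):
    observations: pd.DataFrame
    rejected: pd.DataFrame  # columns: line, reason


def _bool_out(s: pd.Series) -> pd.Series:
    out = pd.Series(pd.NA, index=s.index, dtype=object)
    notna = s.notna()
    out[notna] = np.where(s[notna].astype(bool), "TRUE", "FALSE")
    return out


def write_observations(obs: pd.DataFrame, path) -> None:
    """Write an observation table in the step2 column layout.

    Missing schema columns are emitted empty; extra columns are dropped.
    """
    out = pd.DataFrame(index=obs.index)
    for col in STEP2_COLUMNS:
        if col in obs.columns:
            out[col] = _bool_out(obs[col]) if col in _BOOL_COLUMNS else obs[col]
        else:
            out[col] = pd.NA
    out.to_csv(path, index=False)


def read_observations(path) -> ReadResult:
    """Read a step2-style CSV, validating and typing each row.

    Columns are matched by name, so permuted layouts parse identically; extra
    columns are kept and logged.  Rows with a non-positive or non-numeric
    price, an unparsable coordinate, or a coordinate outside the valid
    lat/lon range are rejected with a line-numbered reason table.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=True)
    missing = [c for c in _MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")
    extra = [c for c in df.columns if c not in STEP2_COLUMNS]
    if extra:
        logger.info("read_observations: tolerating extra columns %s", extra)

    for col in STEP2_COLUMNS:
        if col not in df.columns:
            df[col] = pd.NA
    df = df[STEP2_COLUMNS + extra]

    numeric = ["lat", "lon", "alt", "pre", "conversion", "price_observed",
               "price_kg", "market_distance", "area", "population", "density"]
    for col in numeric:
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df["cluster"] = pd.to_numeric(df["cluster"], errors="coerce").astype("Int64")
    for col in _BOOL_COLUMNS:
        df[col] = df[col].map({"TRUE": True, "FALSE": False, "True": True, "False": False})

    bad_price = df["price_observed"].isna() | (df["price_observed"] <= 0)
    bad_coord = (
        df["lat"].isna() | df["lon"].isna()
        | (df["lat"].abs() > 90) | (df["lon"].abs() > 180)
    )
    reasons = []
    for idx in df.index[bad_price | bad_coord]:
        reason = "invalid price" if bad_price[idx] else "invalid coordinates"
        reasons.append({"line": int(idx) + 2, "reason": reason})  # +2: header + 1-basing
    rejected = pd.DataFrame(reasons, columns=["line", "reason"])
    if len(rejected):
        logger.warning("read_observations: rejected %d malformed row(s)", len(rejected))
    keep = df[~(bad_price | bad_coord)].reset_index(drop=True)
    return ReadResult(keep, rejected)


def write_estimates(rows: pd.DataFrame, path) -> None:
    """Write weekly estimates with the exact step3 header."""
    out = pd.DataFrame(index=rows.index)
    for col in STEP3_COLUMNS:
        out[col] = rows[col] if col in rows.columns else pd.NA
    out.to_csv(path, index=False)


def read_estimates(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in STEP3_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")
    return df[STEP3_COLUMNS]


def _open_maybe_gzip(path, mode: str):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode + "t", encoding="utf-8")
    return open(path, mode, encoding="utf-8")


def write_boundaries(frame: Sequence[AdminUnit], path) -> None:
    """Write administrative units as a GeoJSON FeatureCollection."""
    features = [
        {
            "type": "Feature",
            "geometry": mapping(u.polygon),
            "properties": {
                "code": u.code, "name": u.name, "level": u.level,
                "population": u.population, "area": u.area,
            },
        }
        for u in frame
    ]
    with _open_maybe_gzip(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def read_boundaries(path) -> list[AdminUnit]:
    """Read a GeoJSON FeatureCollection of administrative units.

    Features without a ``code`` property are rejected (logged); invalid
    geometries are repaired with :func:`shapely.make_valid` where possible and
    otherwise rejected; a missing ``population`` property is an error.
    """
    with _open_maybe_gzip(path, "r") as fh:
        collection = json.load(fh)
    units: list[AdminUnit] = []
    for i, feature in enumerate(collection.get("features", [])):
        props = feature.get("properties", {}) or {}
        if "code" not in props or props["code"] in (None, ""):
            logger.warning("read_boundaries: feature %d has no 'code'; rejected", i)
            continue
        if "population" not in props or props["population"] is None:
            raise SchemaError(f"feature {props['code']}: missing 'population' property")
        geom = shape(feature["geometry"])
        if not geom.is_valid:
            geom = shapely.make_valid(geom)
            if not geom.is_valid or geom.is_empty:
                logger.warning("read_boundaries: feature %s unrepairable; rejected", props["code"])
                continue
        units.append(
            AdminUnit(
                code=str(props["code"]),
                name=str(props.get("name", props["code"])),
                level=int(props.get("level", 2)),
                polygon=geom,
                population=float(props["population"]),
                area=float(props.get("area", 0.0)),
            )
        )
    return units
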