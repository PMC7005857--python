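"""Readers and writers for the pipeline's file formats.

Occurrence tables are UTF-8 CSV/TSV with a header and configurable column
names. Rasters use the ESRI ASCII grid format (one text file per layer,
``BIO1.asc`` .. ``BIO19.asc``). Country polygons travel as GeoJSON
FeatureCollections with ``code``/``centroid_lon``/``centroid_lat`` properties.
Rows that fail validation are never silently dropped: readers return an
explicit rejects list with reasons.
"""

from __future__ import annotations

import json
import os
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import mapping, shape

from .types import (BIO_NAMES, AccessionRecord, ClimateStack, Country,
                    CountryMap, GridSpec, PresenceRecord, ResistanceRecord,
                    ScreeningScore, TaxonInfo)

DEFAULT_SCHEMA = {
    "record_id": "record_id",
    "taxon_id": "taxon_id",
    "lat": "lat",
    "lon": "lon",
    "source": "source",
    "country_code": "country_code",
    "georef_status": "georef_status",
}

REQUIRED_COLUMNS = ("taxon_id", "lat", "lon", "source")


class SchemaError(ValueError):
    """A required column could not be resolved in the input table."""


# ---------------------------------------------------------------- occurrences

def read_presence_table(path, schema=None, sep=","):
    """Read an occurrence table -> (records, rejects).

    ``schema`` maps the standard field names to the file's column names.
    ``rejects`` is a list of ``(row_index, reason)`` for rows violating the
    record invariants; accepted + rejected partition the input rows.
    """
    colmap = dict(DEFAULT_SCHEMA)
    if schema:
        colmap.update(schema)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    for field in REQUIRED_COLUMNS:
        if colmap[field] not in df.columns:
            raise SchemaError(f"required column {colmap[field]!r} (field {field}) "
                              f"not found in {path}")
    records, rejects = [], []
    for i, row in enumerate(df.itertuples(index=False)):
        raw = dict(zip(df.columns, row))
        try:
            lat = float(raw[colmap["lat"]])
            lon = float(raw[colmap["lon"]])
        except ValueError:
            rejects.append((i, "unparseable coordinates"))
            continue
        rid = raw.get(colmap["record_id"], "") or f"row{i:06d}"
        cc = raw.get(colmap["country_code"], "") or None
        status = raw.get(colmap["georef_status"], "") or "original"
        rec = PresenceRecord(record_id=rid, taxon_id=raw[colmap["taxon_id"]],
                             lat=lat, lon=lon, source=raw[colmap["source"]],
                             country_code=cc, georef_status=status)
        try:
            rec.validate()
        except ValueError as e:
            rejects.append((i, str(e)))
            continue
        records.append(rec)
    return records, rejects


def write_presence_table(records: Iterable[PresenceRecord], path, sep=","):
    rows = [{"record_id": r.record_id, "taxon_id": r.taxon_id,
             "lat": r.lat, "lon": r.lon, "source": r.source,
             "country_code": r.country_code or "",
             "georef_status": r.georef_status} for r in records]
    pd.DataFrame(rows, columns=list(DEFAULT_SCHEMA)).to_csv(path, sep=sep, index=False)


# -------------------------------------------------------------------- rasters

def write_ascii_grid(path, grid: GridSpec, array: np.ndarray, fmt="%.6f"):
    array = np.asarray(array)
    if array.shape != (grid.nrows, grid.ncols):
        raise ValueError("array shape does not match grid")
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.ncols}\n")
        fh.write(f"nrows {grid.nrows}\n")
        fh.write(f"xllcorner {grid.xll!r}\n")
        fh.write(f"yllcorner {grid.yll!r}\n")
        fh.write(f"cellsize {grid.cellsize!r}\n")
        fh.write(f"NODATA_value {grid.nodata!r}\n")
        np.savetxt(fh, array, fmt=fmt)


def read_ascii_grid(path):
    header = {}
    with open(path) as fh:
        pos = fh.tell()
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        data = np.loadtxt(fh)
    grid = GridSpec(nrows=int(header["nrows"]), ncols=int(header["ncols"]),
                    xll=header["xllcorner"], yll=header["yllcorner"],
                    cellsize=header["cellsize"],
                    nodata=header.get("nodata_value", -9999.0))
    data = data.reshape(grid.nrows, grid.ncols)
    return grid, data


def write_raster_stack(stack: ClimateStack, directory):
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name in BIO_NAMES:
        write_ascii_grid(directory / f"{name}.asc", stack.grid, stack.layers[name])


def read_raster_stack(paths_or_dir):
    """Read 19 ESRI ASCII layers into a ClimateStack.

    Accepts a directory containing BIO1.asc..BIO19.asc or an explicit list of
    paths whose stems are the layer names.
    """
    if isinstance(paths_or_dir, (str, os.PathLike)):
        d = Path(paths_or_dir)
        paths = sorted(d.glob("*.asc"))
    else:
        paths = [Path(p) for p in paths_or_dir]
    found = {p.stem: p for p in paths}
    if set(found) != set(BIO_NAMES):
        raise ValueError(f"expected 19 layers named BIO1..BIO19, found: {sorted(found)}")
    grid = None
    layers = {}
    for name in BIO_NAMES:
        g, arr = read_ascii_grid(found[name])
        if grid is None:
            grid = g
        elif g != grid:
            raise ValueError(f"grid of layer {name} does not match BIO1's grid")
        layers[name] = arr
    stack = ClimateStack(grid=grid, layers=layers)
    stack.validate()
    return stack


# ------------------------------------------------------------------ countries

def write_countries_geojson(countries: CountryMap, path):
    features = []
    for code in countries.codes:
        c = countries.countries[code]
        features.append({
            "type": "Feature",
            "geometry": mapping(c.polygon),
            "properties": {"code": c.code, "centroid_lon": c.centroid_lon,
                           "centroid_lat": c.centroid_lat},
        })
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def read_countries_geojson(path) -> CountryMap:
    with open(path) as fh:
        gj = json.load(fh)
    cmap = CountryMap()
    for feat in gj["features"]:
        props = feat["properties"]
        c = Country(code=props["code"], polygon=shape(feat["geometry"]),
                    centroid_lon=float(props["centroid_lon"]),
                    centroid_lat=float(props["centroid_lat"]))
        cmap.countries[c.code] = c
    cmap.validate()
    return cmap


# --------------------------------------------------------------- fixed tables

def read_accession_table(path) -> list[AccessionRecord]:
    df = pd.read_csv(path)
    recs = [AccessionRecord(r.taxon_id, r.holding_institute,
                            int(r.n_accessions), int(getattr(r, "safety_duplicated", 0)))
            for r in df.itertuples(index=False)]
    for r in recs:
        r.validate()
    return recs


def write_accession_table(records: Sequence[AccessionRecord], path):
    pd.DataFrame([vars(r) for r in records]).to_csv(path, index=False)


def read_screening_table(path) -> list[ScreeningScore]:
    df = pd.read_csv(path)
    recs = [ScreeningScore(r.taxon_id, str(r.accession_id), r.assay, int(r.score))
            for r in df.itertuples(index=False)]
    for r in recs:
        r.validate()
    return recs


def write_screening_table(records: Sequence[ScreeningScore], path):
    pd.DataFrame([vars(r) for r in records]).to_csv(path, index=False)


def read_resistance_table(path) -> list[ResistanceRecord]:
    df = pd.read_csv(path)
    recs = [ResistanceRecord(r.taxon_id, r.stressor, r.status)
            for r in df.itertuples(index=False)]
    for r in recs:
        r.validate()
    return recs


def write_resistance_table(records: Sequence[ResistanceRecord], path):
    pd.DataFrame([vars(r) for r in records]).to_csv(path, index=False)


def read_taxonomy_table(path) -> list[TaxonInfo]:
    df = pd.read_csv(path)
    recs = [TaxonInfo(r.taxon_id, r.name, r.subgenus, r.section, r.gene_pool,
                      bool(r.domesticated)) for r in df.itertuples(index=False)]
    for r in recs:
        r.validate()
    return recs


def write_taxonomy_table(records: Sequence[TaxonInfo], path):
    pd.DataFrame([vars(r) for r in records]).to_csv(path, index=False)
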