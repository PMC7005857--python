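"""Domain types shared by every stage of the pipeline.

A :class:`PresenceRecord` is one georeferenced occurrence of a taxon; a
:class:`ClimateStack` holds the 19 bioclimatic layers (BIO1..BIO19) on one
grid; a :class:`CountryMap` carries country polygons and centroids. Tabular
inputs (accessions, screening scores, resistance review) have thin record
types with validation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from shapely.geometry.base import BaseGeometry
from shapely.ops import unary_union

SOURCES = ("herbarium", "genebank", "living_collection")
GEOREF_STATUSES = ("original", "manually_georeferenced", "relocated_coast")
GENE_POOLS = ("A", "B", "C", "D")
BIO_NAMES = tuple(f"BIO{i}" for i in range(1, 20))
#: Field-standard aliases for the four ecogeographic indicator variables:
#: annual mean temperature, temperature of the wettest quarter, annual
#: precipitation, precipitation of the wettest quarter.
CLIMATE_VARS = {"AMEANT": "BIO1", "TWETQ": "BIO8", "AP": "BIO12", "PWETQ": "BIO16"}
RESISTANCE_STATUSES = ("resistant_reported", "no_resistance_reported", "not_evaluated")


@dataclass(frozen=True)
class PresenceRecord:
    record_id: str
    taxon_id: str
    lat: float
    lon: float
    source: str
    country_code: Optional[str] = None
    georef_status: str = "original"

    def validate(self) -> None:
        if not self.taxon_id:
            raise ValueError("taxon_id is empty")
        if not np.isfinite(self.lat) or not (-90.0 <= self.lat <= 90.0):
            raise ValueError("lat out of range")
        if not np.isfinite(self.lon) or not (-180.0 <= self.lon <= 180.0):
            raise ValueError("lon out of range")
        if self.source not in SOURCES:
            raise ValueError(f"unknown source {self.source!r}")
        if self.georef_status not in GEOREF_STATUSES:
            raise ValueError(f"unknown georef_status {self.georef_status!r}")

    def replace(self, **kw) -> "PresenceRecord":
        return dataclasses.replace(self, **kw)


@dataclass(frozen=True)
class TaxonInfo:
    taxon_id: str
    name: str
    subgenus: str
    section: str
    gene_pool: str
    domesticated: bool = False

    def validate(self) -> None:
        if self.gene_pool not in GENE_POOLS:
            raise ValueError(f"gene_pool must be one of {GENE_POOLS}")


@dataclass(frozen=True)
class AccessionRecord:
    taxon_id: str
    holding_institute: str
    n_accessions: int
    safety_duplicated: int = 0

    def validate(self) -> None:
        if not (self.n_accessions >= self.safety_duplicated >= 0):
            raise ValueError("need n_accessions >= safety_duplicated >= 0")


@dataclass(frozen=True)
class ScreeningScore:
    taxon_id: str
    accession_id: str
    assay: str  # "dehydration" | "salinity"
    score: int  # Likert 1 (high tolerance) .. 5 (low tolerance)

    def validate(self) -> None:
        if self.assay not in ("dehydration", "salinity"):
            raise ValueError(f"unknown assay {self.assay!r}")
        if self.score not in (1, 2, 3, 4, 5):
            raise ValueError(f"score {self.score} outside the 1-5 Likert scale")


@dataclass(frozen=True)
class ResistanceRecord:
    taxon_id: str
    stressor: str
    status: str

    def validate(self) -> None:
        if self.status not in RESISTANCE_STATUSES:
            raise ValueError(f"unknown status {self.status!r}")


@dataclass(frozen=True)
class GridSpec:
    """A north-up regular lon/lat grid.

    Row 0 is the northernmost row. Cells are half-open intervals
    ``[x0, x0+cellsize)`` in both axes measured from the lower-left corner
    (``xll``, ``yll``), so a point on a shared edge belongs to the cell that
    starts at that edge; points exactly on the top/right outer boundary are
    clamped into the last cell.
    """

    nrows: int
    ncols: int
    xll: float
    yll: float
    cellsize: float  # degrees
    nodata: float = -9999.0

    @property
    def xur(self) -> float:
        return self.xll + self.ncols * self.cellsize

    @property
    def yur(self) -> float:
        return self.yll + self.nrows * self.cellsize

    def cell_of(self, lon, lat):
        """Vectorised point -> (row, col); -1 where outside the extent."""
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        col = np.floor((lon - self.xll) / self.cellsize).astype(int)
        jrow = np.floor((lat - self.yll) / self.cellsize).astype(int)
        # clamp exact top/right boundary points into the grid
        col = np.where((lon == self.xur), self.ncols - 1, col)
        jrow = np.where((lat == self.yur), self.nrows - 1, jrow)
        row = self.nrows - 1 - jrow
        inside = (col >= 0) & (col < self.ncols) & (row >= 0) & (row < self.nrows)
        row = np.where(inside, row, -1)
        col = np.where(inside, col, -1)
        if row.ndim == 0:
            return int(row), int(col)
        return row, col

    def cell_center(self, row, col):
        """(lon, lat) of cell centres."""
        row = np.asarray(row)
        col = np.asarray(col)
        lon = self.xll + (col + 0.5) * self.cellsize
        lat = self.yll + (self.nrows - row - 0.5) * self.cellsize
        if lon.ndim == 0:
            return float(lon), float(lat)
        return lon, lat

    def center_grids(self):
        """Full (lon, lat) arrays of shape (nrows, ncols) of cell centres."""
        rows, cols = np.mgrid[0:self.nrows, 0:self.ncols]
        return self.cell_center(rows, cols)


@dataclass
class ClimateStack:
    """19 named bioclimatic layers sharing one grid.

    Temperature layers are in deg C, precipitation layers in mm. Nodata cells
    (sea / missing) are identical across layers.
    """

    grid: GridSpec
    layers: dict = field(default_factory=dict)

    def validate(self) -> None:
        missing = [n for n in BIO_NAMES if n not in self.layers]
        extra = [n for n in self.layers if n not in BIO_NAMES]
        if missing or extra:
            raise ValueError(
                f"expected 19 layers BIO1..BIO19; missing={missing} unexpected={extra}")
        shape = (self.grid.nrows, self.grid.ncols)
        for name, arr in self.layers.items():
            if arr.shape != shape:
                raise ValueError(f"layer {name} shape {arr.shape} != grid {shape}")
        masks = [arr == self.grid.nodata for arr in self.layers.values()]
        if not all(np.array_equal(masks[0], m) for m in masks[1:]):
            raise ValueError("nodata cells differ across layers")

    @property
    def nodata_mask(self) -> np.ndarray:
        return self.layers["BIO1"] == self.grid.nodata

    @property
    def data_mask(self) -> np.ndarray:
        return ~self.nodata_mask

    def values_at(self, lon, lat, variables=BIO_NAMES):
        """Layer values at points; rows of NaN for points outside / on nodata."""
        row, col = self.grid.cell_of(lon, lat)
        row = np.atleast_1d(row)
        col = np.atleast_1d(col)
        out = np.full((row.size, len(variables)), np.nan)
        ok = row >= 0
        for j, name in enumerate(variables):
            vals = self.layers[name][row[ok], col[ok]]
            out[ok, j] = np.where(vals == self.grid.nodata, np.nan, vals)
        return out


@dataclass
class Country:
    code: str
    polygon: BaseGeometry
    centroid_lon: float
    centroid_lat: float


@dataclass
class CountryMap:
    countries: dict = field(default_factory=dict)  # code -> Country
    _land: BaseGeometry = field(default=None, repr=False)

    def validate(self) -> None:
        for c in self.countries.values():
            if not c.polygon.is_valid:
                raise ValueError(f"country {c.code} polygon is invalid")
            minx, miny, maxx, maxy = c.polygon.bounds
            if not (minx <= c.centroid_lon <= maxx and miny <= c.centroid_lat <= maxy):
                raise ValueError(f"country {c.code} centroid outside its bounding box")

    @property
    def codes(self):
        return sorted(self.countries)

    @property
    def land_union(self) -> BaseGeometry:
        if self._land is None:
            self._land = unary_union([c.polygon for c in self.countries.values()])
        return self._land

    @property
    def coastline(self) -> BaseGeometry:
        return self.land_union.boundary

    def country_of(self, lon: float, lat: float):
        """Code of the country covering the point, or None (sea)."""
        from shapely.geometry import Point

        p = Point(lon, lat)
        for code in self.codes:
            if self.countries[code].polygon.covers(p):
                return code
        return None
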