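"""Synthetic world generator with known ground truth.

Emulates the six input classes of the analysis — niche-structured presence
records, 19 correlated bioclimatic layers, country polygons with centroids,
genebank accession counts, Likert screening scores, and a resistance review
table — plus an error ledger recording every injected record error, so the
cleaning pipeline's precision/recall can be measured exactly.

Layer construction: BIO1 (annual mean temperature) decreases with \|latitude\|,
BIO12 (annual precipitation) follows a longitudinal gradient; the remaining 17
layers are seeded linear mixtures ``r * z_base + sqrt(1 - r^2) * noise`` of the
standardised BIO1 or BIO12 field, which gives an empirical Pearson correlation
of about ``r`` with the base layer. Two layers (BIO4, BIO15) sit below the 0.7
pruning threshold by default so variable pruning has something to retain.
Sea cells (outside every country) are nodata in all layers.

One global seed; per-generator sub-streams are derived deterministically as
``numpy.random.SeedSequence((seed, STREAM[name]))``.
"""

from __future__ import annotations

import math
import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import Point, box
from shapely.ops import nearest_points

from .geo import angular_arcmin
from .types import (BIO_NAMES, AccessionRecord, ClimateStack, Country,
                    CountryMap, GridSpec, PresenceRecord, ResistanceRecord,
                    ScreeningScore, TaxonInfo)

# fixed sub-stream indices for seed derivation
STREAM = {"climate": 0, "countries": 1, "presences": 2, "errors": 3,
          "tables": 4}

#: (base layer, target Pearson r) for the 17 derived layers.
DEFAULT_CORRELATIONS = {
    "BIO2": ("BIO1", 0.85), "BIO3": ("BIO1", 0.75), "BIO4": ("BIO1", 0.55),
    "BIO5": ("BIO1", 0.90), "BIO6": ("BIO1", 0.80), "BIO7": ("BIO1", 0.50),
    "BIO8": ("BIO1", 0.90), "BIO9": ("BIO1", 0.60), "BIO10": ("BIO1", 0.95),
    "BIO11": ("BIO1", 0.85),
    "BIO13": ("BIO12", 0.90), "BIO14": ("BIO12", 0.60), "BIO15": ("BIO12", 0.45),
    "BIO16": ("BIO12", 0.92), "BIO17": ("BIO12", 0.80), "BIO18": ("BIO12", 0.85),
    "BIO19": ("BIO12", 0.70),
}

DEFAULT_ERROR_RATES = {
    "country_mismatch": 0.05,
    "offshore": 0.04,
    "centroid": 0.03,
    "duplicate": 0.05,
    "climate_outlier": 0.03,
}


@dataclass(frozen=True)
class NicheSpec:
    """Gaussian niche in (BIO1, BIO12) space: centre and breadth (SD)."""
    bio1_mean: float
    bio12_mean: float
    bio1_sd: float = 1.2
    bio12_sd: float = 90.0


@dataclass
class SyntheticWorldSpec:
    seed: int = 0
    lon_min: float = 0.0
    lon_max: float = 30.0
    lat_min: float = -15.0
    lat_max: float = 15.0
    res_arcmin: float = 15.0
    n_countries: int = 6
    n_taxa: int = 8
    niches: dict = field(default_factory=dict)  # taxon_id -> NicheSpec
    correlations: dict = field(default_factory=lambda: dict(DEFAULT_CORRELATIONS))
    error_rates: dict = field(default_factory=lambda: dict(DEFAULT_ERROR_RATES))
    noise_sd_temp: float = 0.8   # deg C, on BIO1
    noise_sd_precip: float = 60.0  # mm, on BIO12

    def __post_init__(self):
        for k, v in self.error_rates.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"error rate {k}={v} outside [0, 1]")
        if self.res_arcmin <= 0:
            raise ValueError("resolution must be > 0")
        if self.n_taxa < 1:
            raise ValueError("need at least one taxon")
        for layer, (_base, r) in self.correlations.items():
            if not -1.0 <= r <= 1.0:
                raise ValueError(
                    f"correlation target for {layer} is {r}: the implied "
                    "covariance is not positive definite")
        if not self.niches:
            self.niches.update(default_niches(self))

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence((self.seed, STREAM[stream])))


def default_niches(spec: SyntheticWorldSpec) -> dict:
    """Spread taxon niche centres over the realised (BIO1, BIO12) range.

    Centres run from warm-dry to cool-wet corners with two deliberate
    specialists at the extremes (hot and dry), mimicking a genus in which a
    few taxa occupy harsh climates.
    """
    taxa = [f"taxon{i:02d}" for i in range(1, spec.n_taxa + 1)]
    # realised ranges of the noise-free gradients (see make_climate_stack)
    t_hi, t_lo = 28.0, 28.0 - 0.9 * max(abs(spec.lat_min), abs(spec.lat_max))
    p_lo, p_hi = 500.0, 500.0 + 60.0 * (spec.lon_max - spec.lon_min)
    niches = {}
    for i, t in enumerate(taxa):
        f = i / max(spec.n_taxa - 1, 1)
        # stagger precipitation centres so temperature and rainfall optima are
        # not collinear across taxa
        g = ((i * 3) % spec.n_taxa) / max(spec.n_taxa - 1, 1)
        niches[t] = NicheSpec(bio1_mean=t_hi - f * (t_hi - t_lo),
                              bio12_mean=p_lo + g * (p_hi - p_lo))
    return niches


# ------------------------------------------------------------------- climate

def make_climate_stack(spec: SyntheticWorldSpec,
                       countries: CountryMap | None = None) -> ClimateStack:
    """Generate the 19-layer stack; sea cells nodata when countries given."""
    rng = spec.rng("climate")
    cs = spec.res_arcmin / 60.0
    ncols = int(round((spec.lon_max - spec.lon_min) / cs))
    nrows = int(round((spec.lat_max - spec.lat_min) / cs))
    grid = GridSpec(nrows=nrows, ncols=ncols, xll=spec.lon_min, yll=spec.lat_min,
                    cellsize=cs)
    lon, lat = grid.center_grids()

    bio1 = 28.0 - 0.9 * np.abs(lat) + rng.normal(0.0, spec.noise_sd_temp, lat.shape)
    bio12 = 500.0 + 60.0 * (lon - spec.lon_min) + rng.normal(
        0.0, spec.noise_sd_precip, lon.shape)

    def standardise(a):
        sd = a.std()
        return (a - a.mean()) / sd if sd > 0 else a - a.mean()

    z = {"BIO1": standardise(bio1), "BIO12": standardise(bio12)}
    layers = {"BIO1": bio1, "BIO12": bio12}
    for name in BIO_NAMES:
        if name in layers:
            continue
        base, r = spec.correlations[name]
        eps = rng.normal(0.0, 1.0, lat.shape)
        mix = r * z[base] + math.sqrt(1.0 - r * r) * eps
        if base == "BIO1":  # temperature-family units, deg C
            layers[name] = 18.0 + 4.0 * mix
        else:               # precipitation-family units, mm
            layers[name] = np.maximum(900.0 + 350.0 * mix, 0.0)

    if countries is not None:
        sea = land_mask(grid, countries) == 0
        for name in BIO_NAMES:
            layers[name] = np.where(sea, grid.nodata, layers[name])
    stack = ClimateStack(grid=grid, layers={n: layers[n] for n in BIO_NAMES})
    stack.validate()
    return stack


def land_mask(grid: GridSpec, countries: CountryMap) -> np.ndarray:
    """1 where the cell centre lies in some country, else 0."""
    import shapely

    lon, lat = grid.center_grids()
    mask = np.zeros(lon.shape, dtype=int)
    for code in countries.codes:
        poly = countries.countries[code].polygon
        inside = shapely.contains_xy(poly, lon.ravel(), lat.ravel()).reshape(lon.shape)
        mask |= inside
    return mask


# ----------------------------------------------------------------- countries

def make_countries(spec: SyntheticWorldSpec) -> CountryMap:
    """Tile part of the extent with rectangular countries; the rest is sea.

    Land occupies an inset rectangle (15% margin west/south, 5% east/north),
    split into a near-square grid of ``n_countries`` disjoint tiles; centroids
    are exact tile centres.
    """
    dx = spec.lon_max - spec.lon_min
    dy = spec.lat_max - spec.lat_min
    x0, x1 = spec.lon_min + 0.15 * dx, spec.lon_max - 0.05 * dx
    y0, y1 = spec.lat_min + 0.15 * dy, spec.lat_max - 0.05 * dy
    ncol = int(math.ceil(math.sqrt(spec.n_countries)))
    nrow = int(math.ceil(spec.n_countries / ncol))
    tw, th = (x1 - x0) / ncol, (y1 - y0) / nrow
    if tw <= 2 * spec.res_arcmin / 60.0 or th <= 2 * spec.res_arcmin / 60.0:
        raise ValueError("extent too small for the requested number of countries")
    cmap = CountryMap()
    k = 0
    for i in range(nrow):
        for j in range(ncol):
            if k >= spec.n_countries:
                break
            poly = box(x0 + j * tw, y0 + i * th, x0 + (j + 1) * tw, y0 + (i + 1) * th)
            code = f"C{k + 1:02d}"
            cmap.countries[code] = Country(code=code, polygon=poly,
                                           centroid_lon=x0 + (j + 0.5) * tw,
                                           centroid_lat=y0 + (i + 0.5) * th)
            k += 1
    cmap.validate()
    return cmap


# ----------------------------------------------------------------- presences

SOURCE_PROBS = (("herbarium", 0.5), ("genebank", 0.35), ("living_collection", 0.15))


def sample_presences(taxon_id: str, stack: ClimateStack, countries: CountryMap,
                     spec: SyntheticWorldSpec, n: int, seed=None) -> list[PresenceRecord]:
    """Draw ``n`` records from land cells, weighted by the taxon's niche.

    Cell probability is proportional to ``exp(-0.5 * D^2)`` where D is the
    Mahalanobis distance of the cell's (BIO1, BIO12) to the niche centre
    (diagonal covariance). Points are jittered uniformly within their cell.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    niche = spec.niches[taxon_id]
    tkey = zlib.crc32(taxon_id.encode()) % (2**31)
    rng = (spec.rng("presences") if seed is None
           else np.random.default_rng(np.random.SeedSequence((seed, tkey))))
    grid = stack.grid
    land = land_mask(grid, countries).astype(bool) & stack.data_mask
    rows, cols = np.nonzero(land)
    if rows.size == 0:
        raise ValueError("no land cell available")
    b1 = stack.layers["BIO1"][rows, cols]
    b12 = stack.layers["BIO12"][rows, cols]
    if niche.bio1_sd == 0 or niche.bio12_sd == 0:
        d2 = (b1 - niche.bio1_mean) ** 2 + (b12 - niche.bio12_mean) ** 2
        probs = np.zeros(rows.size)
        probs[np.argmin(d2)] = 1.0
    else:
        d2 = ((b1 - niche.bio1_mean) / niche.bio1_sd) ** 2 \
            + ((b12 - niche.bio12_mean) / niche.bio12_sd) ** 2
        logw = -0.5 * d2
        w = np.exp(logw - logw.max())
        if w.sum() <= 0:
            raise ValueError("no land cell with positive niche probability")
        probs = w / w.sum()
    idx = rng.choice(rows.size, size=n, p=probs)
    jit = rng.uniform(0.0, 1.0, size=(n, 2))
    srcs = rng.choice([s for s, _ in SOURCE_PROBS], size=n,
                      p=[p for _, p in SOURCE_PROBS])
    records = []
    for i in range(n):
        r, c = rows[idx[i]], cols[idx[i]]
        lon = grid.xll + (c + jit[i, 0]) * grid.cellsize
        lat = grid.yll + (grid.nrows - r - 1 + jit[i, 1]) * grid.cellsize
        records.append(PresenceRecord(
            record_id=f"{taxon_id}-{i:05d}", taxon_id=taxon_id,
            lat=lat, lon=lon, source=str(srcs[i]),
            country_code=countries.country_of(lon, lat)))
    return records


# -------------------------------------------------------------------- errors

@dataclass
class ErrorLedger:
    """One row per injected error: what was changed and the clean original."""
    frame: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["record_id", "error_type", "detail", "orig_lat", "orig_lon",
                 "orig_country"]))

    def add(self, record: PresenceRecord, error_type: str, detail: str = ""):
        self.frame.loc[len(self.frame)] = [record.record_id, error_type, detail,
                                           record.lat, record.lon,
                                           record.country_code]

    def ids(self, error_type: str, detail: str | None = None) -> set:
        f = self.frame[self.frame.error_type == error_type]
        if detail is not None:
            f = f[f.detail == detail]
        return set(f.record_id)


def inject_errors(records: list[PresenceRecord], spec: SyntheticWorldSpec,
                  countries: CountryMap, stack: ClimateStack,
                  buffer_arcmin: float = 10.0):
    """Corrupt ``floor(rate * n)`` records per error type; return the ledger.

    Victim sets are disjoint across types so every ledger entry is
    attributable to exactly one cleaning step. Offshore errors are split half
    within the coastal buffer (relocatable) and half beyond it (removable).
    """
    rng = spec.rng("errors")
    n = len(records)
    out = list(records)
    ledger = ErrorLedger()
    counts = {}
    for etype, rate in spec.error_rates.items():
        k = int(math.floor(rate * n))
        if rate > 0 and k == 0:
            warnings.warn(f"rate {rate} on n={n} yields zero {etype} injections")
        counts[etype] = k
    total = sum(counts.values())
    victims = rng.choice(n, size=min(total, n), replace=False)
    pos = 0

    def take(k):
        nonlocal pos
        sel = victims[pos:pos + k]
        pos += k
        return sel

    # country mismatch: swap the code for a country that cannot contain the point
    for i in take(counts["country_mismatch"]):
        rec = out[i]
        p = Point(rec.lon, rec.lat)
        for code in rng.permutation(countries.codes):
            poly = countries.countries[code].polygon
            if code == rec.country_code:
                continue
            near = nearest_points(poly, p)[0]
            if angular_arcmin(rec.lat, rec.lon, near.y, near.x) > 3 * buffer_arcmin:
                ledger.add(rec, "country_mismatch", code)
                out[i] = rec.replace(country_code=code)
                break

    # offshore: move the point into sea, half near the coast, half far
    sea_rows, sea_cols = np.nonzero(stack.nodata_mask)
    sea_lon, sea_lat = stack.grid.cell_center(sea_rows, sea_cols)
    land = countries.land_union

    def dist_to_geom(geom):
        out_d = np.empty(sea_lon.size)
        for k, (lo, la) in enumerate(zip(sea_lon, sea_lat)):
            np_pt = nearest_points(geom, Point(lo, la))[0]
            out_d[k] = angular_arcmin(la, lo, np_pt.y, np_pt.x)
        return out_d

    sea_dist = dist_to_geom(land)
    own_dist_cache = {}
    off = take(counts["offshore"])
    for j, i in enumerate(off):
        rec = out[i]
        near_coast = j < len(off) / 2
        if near_coast and rec.country_code:
            # stay within the coastal buffer of the *declared* country so the
            # record is relocated, not removed by the country filter
            if rec.country_code not in own_dist_cache:
                own_dist_cache[rec.country_code] = dist_to_geom(
                    countries.countries[rec.country_code].polygon)
            own_dist = own_dist_cache[rec.country_code]
            cands = np.nonzero((sea_dist > 0) & (own_dist <= buffer_arcmin - 1.0))[0]
            detail = "near"
        else:
            cands = np.nonzero(sea_dist > 2.0 * buffer_arcmin)[0]
            detail = "far"
        if cands.size == 0:
            warnings.warn(f"no sea cell for offshore/{detail} injection")
            continue
        c = cands[rng.integers(cands.size)]
        ledger.add(rec, "offshore", detail)
        out[i] = rec.replace(lat=float(sea_lat[c]), lon=float(sea_lon[c]))

    # centroid: snap to the declared country's centroid
    for i in take(counts["centroid"]):
        rec = out[i]
        code = rec.country_code or rng.choice(countries.codes)
        c = countries.countries[code]
        ledger.add(rec, "centroid", code)
        out[i] = rec.replace(lat=c.centroid_lat, lon=c.centroid_lon,
                             country_code=code)

    # duplicate: append an exact coordinate copy
    for i in take(counts["duplicate"]):
        rec = out[i]
        dup = rec.replace(record_id=rec.record_id + "-dup")
        ledger.add(dup, "duplicate", rec.record_id)
        out.append(dup)

    # climate outlier: move to a land cell violating the taxon's IQR fences
    # on >= 3 layers (selected with a 2.8xIQR margin so the 2.5xIQR fences
    # still hold after injection shifts the quartiles slightly)
    by_taxon = {}
    for rec in records:
        by_taxon.setdefault(rec.taxon_id, []).append(rec)
    fence_cache = {}
    grid = stack.grid
    land_cells = np.nonzero(land_mask(grid, countries).astype(bool) & stack.data_mask)
    cell_vals = np.stack([stack.layers[nm][land_cells] for nm in BIO_NAMES], axis=1)
    for i in take(counts["climate_outlier"]):
        rec = out[i]
        if rec.taxon_id not in fence_cache:
            vals = stack.values_at([r.lon for r in by_taxon[rec.taxon_id]],
                                   [r.lat for r in by_taxon[rec.taxon_id]])
            vals = vals[~np.isnan(vals).any(axis=1)]
            q1 = np.percentile(vals, 25, axis=0)
            q3 = np.percentile(vals, 75, axis=0)
            iqr = q3 - q1
            fence_cache[rec.taxon_id] = (q1 - 2.8 * iqr, q3 + 2.8 * iqr)
        lo, hi = fence_cache[rec.taxon_id]
        nviol = ((cell_vals < lo) | (cell_vals > hi)).sum(axis=1)
        cands = np.array([], dtype=int)
        for need in (6, 5, 4, 3):  # prefer the most extreme cells available
            cands = np.nonzero(nviol >= need)[0]
            if cands.size >= 10 or (cands.size and need == 3):
                break
        if cands.size == 0:
            warnings.warn(f"no outlier cell available for {rec.taxon_id}")
            continue
        c = cands[rng.integers(cands.size)]
        r, col = land_cells[0][c], land_cells[1][c]
        lon, lat = grid.cell_center(r, col)
        ledger.add(rec, "climate_outlier")
        out[i] = rec.replace(lat=lat, lon=lon,
                             country_code=countries.country_of(lon, lat))
    return out, ledger


# ------------------------------------------------------------- fixture tables

def make_accessions(spec: SyntheticWorldSpec, n_absent=1, n_poor=2) -> list[AccessionRecord]:
    """Genebank holdings with planted conservation categories.

    The first ``n_absent`` taxa get no rows (absent), the next ``n_poor`` get
    1-9 accessions (poorly conserved), the rest >= 10.
    """
    rng = spec.rng("tables")
    taxa = sorted(spec.niches)
    recs = []
    for i, t in enumerate(taxa):
        if i < n_absent:
            continue
        if i < n_absent + n_poor:
            total = int(rng.integers(1, 10))
        else:
            total = int(rng.integers(10, 200))
        split = int(rng.integers(0, total + 1))
        recs.append(AccessionRecord(t, "INST1", split, min(split, total // 4)))
        if total - split:
            recs.append(AccessionRecord(t, "INST2", total - split, 0))
    return recs


def make_screening(spec: SyntheticWorldSpec, frac_screened=0.6) -> list[ScreeningScore]:
    rng = spec.rng("tables")
    taxa = sorted(spec.niches)
    recs = []
    for t in taxa:
        if rng.uniform() > frac_screened:
            continue
        for assay in ("dehydration", "salinity"):
            for j in range(int(rng.integers(1, 4))):
                recs.append(ScreeningScore(t, f"{t}-acc{j}", assay,
                                           int(rng.integers(1, 6))))
    return recs


def make_resistance(spec: SyntheticWorldSpec,
                    stressors=("bruchids", "YMD")) -> list[ResistanceRecord]:
    rng = spec.rng("tables")
    statuses = ("resistant_reported", "no_resistance_reported", "not_evaluated")
    return [ResistanceRecord(t, s, str(rng.choice(statuses, p=[0.5, 0.2, 0.3])))
            for t in sorted(spec.niches) for s in stressors]


def make_taxonomy(spec: SyntheticWorldSpec) -> list[TaxonInfo]:
    taxa = sorted(spec.niches)
    pools = ["A", "B", "C", "D"]
    return [TaxonInfo(t, t, subgenus=f"subg{(i % 3) + 1}",
                      section=f"sect{(i % 4) + 1}", gene_pool=pools[i % 4],
                      domesticated=(i == 0)) for i, t in enumerate(taxa)]


# --------------------------------------------------------------- full fixture

def make_world(spec: SyntheticWorldSpec, n_per_taxon=150, inject=True):
    """Generate the complete fixture: countries, stack, records (+ledger), tables."""
    countries = make_countries(spec)
    stack = make_climate_stack(spec, countries)
    records = []
    for t in sorted(spec.niches):
        records.extend(sample_presences(t, stack, countries, spec,
                                        n=n_per_taxon, seed=spec.seed))
    if inject:
        records, ledger = inject_errors(records, spec, countries, stack)
    else:
        ledger = ErrorLedger()
    return {"spec": spec, "countries": countries, "stack": stack,
            "records": records, "ledger": ledger,
            "accessions": make_accessions(spec),
            "screening": make_screening(spec),
            "resistance": make_resistance(spec),
            "taxonomy": make_taxonomy(spec)}


def write_world(world: dict, outdir):
    """Write the full fixture set (CSV tables, ASCII rasters, GeoJSON)."""
    from pathlib import Path

    from . import io as eio

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    eio.write_presence_table(world["records"], out / "records.csv")
    eio.write_raster_stack(world["stack"], out / "rasters")
    eio.write_countries_geojson(world["countries"], out / "countries.geojson")
    eio.write_accession_table(world["accessions"], out / "accessions.csv")
    eio.write_screening_table(world["screening"], out / "screening.csv")
    eio.write_resistance_table(world["resistance"], out / "resistance.csv")
    eio.write_taxonomy_table(world["taxonomy"], out / "taxonomy.csv")
    world["ledger"].frame.to_csv(out / "ledger.csv", index=False)
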