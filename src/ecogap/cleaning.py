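"""Occurrence-record cleaning: five rules composed into an audited pipeline.

Rules, applied in this order:

1. country mismatch — drop records whose point lies outside the declared
   country's polygon dilated by a 10-arc-minute border buffer;
2. coastal relocation — move sea points within 10 arc-minutes of the coastline
   onto the nearest coastline point;
3. centroid removal — drop records at a country centroid (likely
   country-level georeferences);
4. per-taxon deduplication of identical (rounded) coordinates;
5. climate-outlier removal — drop records whose bioclimatic values fall
   outside ``Q1 - k*IQR`` / ``Q3 + k*IQR`` fences on at least ``min_vars`` of
   the 19 variables (quartiles per taxon per variable, linear-interpolation
   "type 7"; taxa with fewer than 4 records are exempt).

Relocation happens before the centroid/duplicate/outlier verdicts, and the
10-arc-minute country buffer keeps near-coast points alive through step 1, so
valid coastal collections survive. Every removal carries a reason; the report
satisfies the conservation invariant
``n_in(k+1) = n_in(k) - n_removed(k) + n_added(k)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Point
from shapely.ops import nearest_points

from .geo import angular_arcmin
from .types import ClimateStack, CountryMap, PresenceRecord

#: nudge (degrees) applied inland after coastal relocation so the point falls
#: in a land raster cell rather than the adjacent sea (nodata) cell
INLAND_NUDGE_DEG = 1e-6


@dataclass
class StepReport:
    name: str
    n_in: int
    n_removed: int = 0
    n_modified: int = 0
    n_added: int = 0
    removed: list = field(default_factory=list)   # (record_id, reason)
    modified: list = field(default_factory=list)  # record_id
    flagged: list = field(default_factory=list)   # record_id (kept but noted)

    @property
    def n_out(self) -> int:
        return self.n_in - self.n_removed + self.n_added


@dataclass
class CleaningReport:
    steps: list = field(default_factory=list)

    def add(self, step: StepReport):
        if self.steps and step.n_in != self.steps[-1].n_out:
            raise ValueError(
                f"step {step.name}: n_in={step.n_in} != previous n_out="
                f"{self.steps[-1].n_out}")
        self.steps.append(step)

    def step(self, name: str) -> StepReport:
        return next(s for s in self.steps if s.name == name)

    def removed_ids(self, name: str | None = None) -> set:
        steps = self.steps if name is None else [self.step(name)]
        return {rid for s in steps for rid, _ in s.removed}

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame([{"step": s.name, "n_in": s.n_in,
                              "n_removed": s.n_removed, "n_modified": s.n_modified,
                              "n_added": s.n_added, "n_out": s.n_out}
                             for s in self.steps])


@dataclass
class CleaningConfig:
    buffer_arcmin: float = 10.0
    centroid_tol_arcmin: float = 1.0
    dedupe_decimals: int = 4
    iqr_k: float = 2.5
    min_outlier_vars: int = 3
    min_records_for_fences: int = 4


def _arcmin_to_geom(lat: float, lon: float, geom) -> float:
    np_pt = nearest_points(geom, Point(lon, lat))[0]
    return angular_arcmin(lat, lon, np_pt.y, np_pt.x)


def filter_country_mismatch(records, countries: CountryMap, buffer_arcmin=10.0):
    """Drop records outside their declared country + border buffer.

    Records without a country code cannot be contradicted and are kept
    (flagged). Unknown codes are removed with reason "unknown country".
    """
    kept, removed, flagged = [], [], []
    for rec in records:
        if not rec.country_code:
            kept.append(rec)
            flagged.append(rec.record_id)
            continue
        country = countries.countries.get(rec.country_code)
        if country is None:
            removed.append((rec, "unknown country"))
            continue
        p = Point(rec.lon, rec.lat)
        if country.polygon.covers(p) or \
                _arcmin_to_geom(rec.lat, rec.lon, country.polygon) <= buffer_arcmin:
            kept.append(rec)
        else:
            removed.append((rec, "outside declared country + buffer"))
    return kept, removed, flagged


def relocate_coastal(records, countries: CountryMap, buffer_arcmin=10.0):
    """Move sea points within the coastal buffer onto the nearest coast point.

    Land points and sea points beyond the buffer are returned unchanged (the
    latter are the country filter's business). Relocated points are nudged a
    hair inland so raster lookups hit a data cell.
    """
    land = countries.land_union
    coast = land.boundary
    out, relocated = [], []
    for rec in records:
        p = Point(rec.lon, rec.lat)
        if land.covers(p):
            out.append(rec)
            continue
        cp = nearest_points(coast, p)[0]
        if angular_arcmin(rec.lat, rec.lon, cp.y, cp.x) <= buffer_arcmin:
            lon, lat = _nudge_inland(cp.x, cp.y, land)
            out.append(rec.replace(lon=lon, lat=lat, georef_status="relocated_coast"))
            relocated.append(rec.record_id)
        else:
            out.append(rec)
    return out, relocated


def _nudge_inland(lon, lat, land):
    if land.covers(Point(lon, lat)) and not land.boundary.intersects(
            Point(lon, lat).buffer(INLAND_NUDGE_DEG / 2)):
        return lon, lat
    for eps in (INLAND_NUDGE_DEG, 10 * INLAND_NUDGE_DEG):
        for dx, dy in ((eps, 0), (-eps, 0), (0, eps), (0, -eps),
                       (eps, eps), (-eps, -eps), (eps, -eps), (-eps, eps)):
            q = Point(lon + dx, lat + dy)
            if land.contains(q):
                return lon + dx, lat + dy
    return lon, lat


def drop_centroids(records, countries: CountryMap, tol_arcmin=1.0):
    """Drop records within ``tol_arcmin`` of any country centroid."""
    cents = [(c.centroid_lat, c.centroid_lon) for c in countries.countries.values()]
    kept, removed = [], []
    for rec in records:
        near = any(angular_arcmin(rec.lat, rec.lon, cla, clo) <= tol_arcmin
                   for cla, clo in cents)
        (removed if near else kept).append(
            (rec, "at country centroid") if near else rec)
    return kept, removed


def dedupe(records, precision_decimals=4):
    """Collapse same-taxon records sharing rounded coordinates.

    The survivor is the record with the smallest record_id (stable under
    input order).
    """
    best = {}
    for rec in records:
        key = (rec.taxon_id, round(rec.lat, precision_decimals),
               round(rec.lon, precision_decimals))
        if key not in best or rec.record_id < best[key].record_id:
            best[key] = rec
    survivors = {r.record_id for r in best.values()}
    kept = [r for r in records if r.record_id in survivors]
    removed = [(r, "duplicate coordinates") for r in records
               if r.record_id not in survivors]
    return kept, removed


def iqr_fences(values: np.ndarray, k: float = 2.5):
    """Per-column (lower, upper) Tukey fences with linear-interp quartiles."""
    q1 = np.percentile(values, 25, axis=0)
    q3 = np.percentile(values, 75, axis=0)
    iqr = q3 - q1
    return q1 - k * iqr, q3 + k * iqr


def filter_climate_outliers(records, stack: ClimateStack, k=2.5, min_vars=3,
                            min_records_for_fences=4):
    """Drop records far outside their taxon's climatic niche margins.

    A record is removed when its value violates the ``k x IQR`` fence on at
    least ``min_vars`` of the 19 variables; quartiles are computed per taxon
    per variable over that taxon's records. Records on nodata cells are
    removed with reason "no climate data".
    """
    vals = stack.values_at([r.lon for r in records], [r.lat for r in records])
    kept, removed = [], []
    on_data = ~np.isnan(vals).any(axis=1)
    by_taxon = {}
    for i, rec in enumerate(records):
        if on_data[i]:
            by_taxon.setdefault(rec.taxon_id, []).append(i)
    fences = {}
    for taxon, idx in by_taxon.items():
        if len(idx) >= min_records_for_fences:
            fences[taxon] = iqr_fences(vals[idx], k)
    for i, rec in enumerate(records):
        if not on_data[i]:
            removed.append((rec, "no climate data"))
            continue
        f = fences.get(rec.taxon_id)
        if f is None:  # too few records for quartiles: exempt
            kept.append(rec)
            continue
        lo, hi = f
        nviol = int(((vals[i] < lo) | (vals[i] > hi)).sum())
        if nviol >= min_vars:
            removed.append((rec, f"climate outlier on {nviol} variables"))
        else:
            kept.append(rec)
    return kept, removed


def clean_pipeline(records, countries: CountryMap, stack: ClimateStack,
                   config: CleaningConfig | None = None):
    """Run the five rules in order; return (cleaned records, CleaningReport)."""
    cfg = config or CleaningConfig()
    report = CleaningReport()

    cur = list(records)
    kept, rem, flagged = filter_country_mismatch(cur, countries, cfg.buffer_arcmin)
    report.add(StepReport("country_mismatch", n_in=len(cur), n_removed=len(rem),
                          removed=[(r.record_id, why) for r, why in rem],
                          flagged=flagged))
    cur = kept

    moved, relocated = relocate_coastal(cur, countries, cfg.buffer_arcmin)
    report.add(StepReport("coastal_relocation", n_in=len(cur),
                          n_modified=len(relocated), modified=relocated))
    cur = moved

    kept, rem = drop_centroids(cur, countries, cfg.centroid_tol_arcmin)
    report.add(StepReport("centroid_removal", n_in=len(cur), n_removed=len(rem),
                          removed=[(r.record_id, why) for r, why in rem]))
    cur = kept

    kept, rem = dedupe(cur, cfg.dedupe_decimals)
    report.add(StepReport("dedupe", n_in=len(cur), n_removed=len(rem),
                          removed=[(r.record_id, why) for r, why in rem]))
    cur = kept

    kept, rem = filter_climate_outliers(cur, stack, cfg.iqr_k,
                                        cfg.min_outlier_vars,
                                        cfg.min_records_for_fences)
    report.add(StepReport("climate_outliers", n_in=len(cur), n_removed=len(rem),
                          removed=[(r.record_id, why) for r, why in rem]))
    return kept, report
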