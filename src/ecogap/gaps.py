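"""Ex situ conservation status and geographic collection-gap analysis.

Per-taxon genebank holdings are summed over institutes and categorised as
absent (0 accessions), poor (1-9) or adequate (>= 10). Richness rasters count
distinct taxa per grid cell: as sampled (all records), as sampled but not
adequately conserved, and as modelled-but-unreported (binary suitability with
no record of the taxon in the cell). Priority countries are ranked by a zonal
aggregate (sum by default; mean and max available) of the gap raster over
cells whose centres fall inside the country polygon.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .types import CountryMap, GridSpec

CATEGORY_ABSENT = "absent"
CATEGORY_POOR = "poor"
CATEGORY_ADEQUATE = "adequate"


def exsitu_status(accessions, taxonomy=None) -> pd.DataFrame:
    """Per-taxon totals and conservation category.

    ``taxonomy`` (optional list of TaxonInfo or taxon ids) extends the result
    with taxa absent from the accession table (category "absent").
    """
    rows = []
    for a in accessions:
        a.validate()
        rows.append((a.taxon_id, a.n_accessions, a.safety_duplicated))
    df = pd.DataFrame(rows, columns=["taxon_id", "n", "dup"])
    totals = df.groupby("taxon_id").sum() if len(df) else \
        pd.DataFrame(columns=["n", "dup"])
    taxa = set(totals.index)
    if taxonomy is not None:
        taxa |= {getattr(t, "taxon_id", t) for t in taxonomy}
    out = []
    for t in sorted(taxa):
        n = int(totals.n.get(t, 0))
        dup = int(totals.dup.get(t, 0))
        cat = (CATEGORY_ABSENT if n == 0
               else CATEGORY_POOR if n < 10 else CATEGORY_ADEQUATE)
        out.append((t, n, dup, cat))
    return pd.DataFrame(out, columns=["taxon_id", "total_accessions",
                                      "safety_duplicated", "category"]
                        ).set_index("taxon_id")


def sampled_richness(records, grid: GridSpec, sources=None) -> np.ndarray:
    """Distinct-taxon count per cell, optionally restricted to some sources."""
    taxa_per_cell = {}
    for rec in records:
        if sources is not None and rec.source not in sources:
            continue
        row, col = grid.cell_of(rec.lon, rec.lat)
        if row < 0:
            continue
        taxa_per_cell.setdefault((row, col), set()).add(rec.taxon_id)
    out = np.zeros((grid.nrows, grid.ncols), dtype=int)
    for (row, col), taxa in taxa_per_cell.items():
        out[row, col] = len(taxa)
    return out


def unconserved_richness(records, status: pd.DataFrame, grid: GridSpec) -> np.ndarray:
    """Sampled richness of taxa that are absent or poorly conserved ex situ."""
    bad = set(status.index[status.category != CATEGORY_ADEQUATE])
    return sampled_richness([r for r in records if r.taxon_id in bad], grid)


def modelled_gap(binary_maps: dict, records, grid: GridSpec) -> np.ndarray:
    """Count taxa modelled suitable in a cell but never reported there."""
    reported = {}
    for rec in records:
        row, col = grid.cell_of(rec.lon, rec.lat)
        if row >= 0:
            reported.setdefault(rec.taxon_id, set()).add((int(row), int(col)))
    out = np.zeros((grid.nrows, grid.ncols), dtype=int)
    for taxon, bmap in binary_maps.items():
        if bmap.shape != (grid.nrows, grid.ncols):
            raise ValueError(f"binary map for {taxon} does not match the grid")
        seen = reported.get(taxon, set())
        rows, cols = np.nonzero(bmap == 1)
        for r, c in zip(rows, cols):
            if (int(r), int(c)) not in seen:
                out[r, c] += 1
    return out


def priority_countries(gap_raster: np.ndarray, grid: GridSpec,
                       countries: CountryMap, top_k: int = 10,
                       agg: str = "sum") -> pd.DataFrame:
    """Rank countries by zonal aggregate of the gap raster (ties alphabetical)."""
    import shapely

    if agg not in ("sum", "mean", "max"):
        raise ValueError("agg must be sum, mean or max")
    lon, lat = grid.center_grids()
    flat = np.asarray(gap_raster, dtype=float).ravel()
    rows = []
    for code in countries.codes:
        poly = countries.countries[code].polygon
        inside = shapely.contains_xy(poly, lon.ravel(), lat.ravel())
        vals = flat[inside]
        score = 0.0 if vals.size == 0 else float(getattr(np, agg)(vals))
        rows.append((code, score, int(vals.size)))
    df = pd.DataFrame(rows, columns=["country", "score", "n_cells"])
    df = df.sort_values(["score", "country"], ascending=[False, True],
                        kind="stable").reset_index(drop=True)
    return df.head(top_k)
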