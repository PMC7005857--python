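"""Summary tables and headline percentages, plus the end-to-end driver.

Counts are aggregated at three levels of evolutionary significant unit (ESU):
taxon, biosystematics section, and gene pool. A section or gene pool
qualifies for a criterion iff at least one member taxon qualifies, and its
denominator counts members with data for that criterion. Percentages round
half-up to integer percent; they are always recomputable from the emitted
counts.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import pandas as pd

from .types import CLIMATE_VARS


def round_half_up_pct(numerator: int, denominator: int) -> int:
    if denominator <= 0:
        raise ZeroDivisionError("zero denominator")
    return int(math.floor(100.0 * numerator / denominator + 0.5))


def _taxonomy_frame(taxonomy) -> pd.DataFrame:
    rows = [(t.taxon_id, t.section, t.gene_pool) for t in taxonomy]
    return pd.DataFrame(rows, columns=["taxon_id", "section", "gene_pool"]
                        ).set_index("taxon_id")


def summarize_counts(tolerance_matrix: pd.DataFrame, resistance, taxonomy
                     ) -> pd.DataFrame:
    """Per-section and per-gene-pool counts of evaluated / qualifying taxa.

    Columns: total taxa, evaluated (any non-nd climate column), one count per
    climate criterion (level "high"), screened / tolerant per assay, reviewed
    / resistant per stressor.
    """
    tax = _taxonomy_frame(taxonomy)
    missing = [t for t in tolerance_matrix.index if t not in tax.index]
    if missing:
        raise KeyError(f"taxa missing from the taxonomy: {missing}")
    tm = tolerance_matrix.join(tax)
    climate_cols = list(CLIMATE_VARS)
    assay_cols = ["dehydration", "salinity"]

    res_rows = [(r.taxon_id, r.stressor, r.status) for r in resistance]
    res = pd.DataFrame(res_rows, columns=["taxon_id", "stressor", "status"])
    stressors = sorted(res.stressor.unique()) if len(res) else []

    def tally(frame, group_taxa):
        sub = frame[frame.index.isin(group_taxa)]
        row = {"total_taxa": len(group_taxa),
               "evaluated": int((sub[climate_cols] != "nd").any(axis=1).sum())}
        for c in climate_cols:
            row[f"high_{c}"] = int((sub[c] == "high").sum())
        row["screened"] = int((sub[assay_cols] != "nd").any(axis=1).sum())
        for c in assay_cols:
            row[f"tolerant_{c}"] = int((sub[c] == "high").sum())
        rsub = res[res.taxon_id.isin(group_taxa)]
        for s in stressors:
            rs = rsub[(rsub.stressor == s) & (rsub.status != "not_evaluated")]
            row[f"reviewed_{s}"] = rs.taxon_id.nunique()
            row[f"resistant_{s}"] = rs[rs.status == "resistant_reported"
                                       ].taxon_id.nunique()
        return row

    out = []
    for section, group in tax.groupby("section"):
        out.append({"level": "section", "unit": section,
                    **tally(tm, set(group.index))})
    for pool, group in tax.groupby("gene_pool"):
        out.append({"level": "gene_pool", "unit": pool,
                    **tally(tm, set(group.index))})
    out.append({"level": "genus", "unit": "all", **tally(tm, set(tax.index))})
    return pd.DataFrame(out)


def summarize_percentages(tolerance_matrix: pd.DataFrame, resistance, taxonomy
                          ) -> pd.DataFrame:
    """Headline percentage table at taxon / section / gene-pool level.

    A unit qualifies iff >= 1 member taxon qualifies; the denominator counts
    units with >= 1 member evaluated (or screened / reviewed). Rows with a
    zero denominator are suppressed with a warning.
    """
    import warnings

    tax = _taxonomy_frame(taxonomy)
    tm = tolerance_matrix.join(tax, how="left")
    climate_cols = list(CLIMATE_VARS)
    res_rows = [(r.taxon_id, r.stressor, r.status) for r in resistance]
    res = pd.DataFrame(res_rows, columns=["taxon_id", "stressor", "status"])
    if len(res):
        res = res.join(tax, on="taxon_id")

    levels = {"taxon": "taxon_id", "section": "section", "gene_pool": "gene_pool"}

    def unit_sets(frame, eval_mask, qual_mask, key):
        if key == "taxon_id":
            ev = set(frame.index[eval_mask])
            qu = set(frame.index[qual_mask])
        else:
            ev = set(frame.loc[eval_mask, key].dropna())
            qu = set(frame.loc[qual_mask, key].dropna())
        return len(ev), len(qu & ev)

    rows = []

    def emit(criterion, frame, eval_mask, qual_mask):
        for level, key in levels.items():
            n_eval, n_qual = unit_sets(frame, eval_mask, qual_mask, key)
            if n_eval == 0:
                warnings.warn(f"{criterion}/{level}: zero denominator, suppressed")
                continue
            rows.append({"criterion": criterion, "level": level,
                         "n_evaluated": n_eval, "n_qualifying": n_qual,
                         "pct": round_half_up_pct(n_qual, n_eval)})

    evaluated = (tm[climate_cols] != "nd").any(axis=1)
    for c in climate_cols:
        emit(f"high_{c}" if c in ("AMEANT", "TWETQ") else f"low_{c}",
             tm, evaluated, tm[c] == "high")
    screened_any = (tm[["dehydration", "salinity"]] != "nd").any(axis=1)
    for c in ("dehydration", "salinity"):
        emit(f"tolerant_{c}", tm, screened_any, tm[c] == "high")
    for s in sorted(res.stressor.unique()) if len(res) else []:
        sub = res[res.stressor == s].set_index("taxon_id")
        frame = tax.copy()
        frame["status"] = sub.status
        emit(f"resistant_{s}", frame,
             frame.status.isin(["resistant_reported", "no_resistance_reported"]),
             frame.status == "resistant_reported")
    return pd.DataFrame(rows)


def resistance_summary(resistance) -> pd.DataFrame:
    """Per-stressor evaluated / resistant counts and integer percentage."""
    rows = [(r.taxon_id, r.stressor, r.status) for r in resistance]
    res = pd.DataFrame(rows, columns=["taxon_id", "stressor", "status"])
    out = []
    for s, sub in res.groupby("stressor"):
        ev = sub[sub.status != "not_evaluated"].taxon_id.nunique()
        rs = sub[sub.status == "resistant_reported"].taxon_id.nunique()
        out.append({"stressor": s, "n_evaluated": ev, "n_resistant": rs,
                    "pct_resistant": round_half_up_pct(rs, ev) if ev else 0})
    return pd.DataFrame(out)


# ------------------------------------------------------------------- driver

def run_pipeline(fixture_dir, out_dir, seed: int = 0, model_taxa=None,
                 n_runs: int = 3) -> dict:
    """clean -> extract -> classify -> model -> gaps -> report on a fixture
    directory written by :func:`ecogap.synth.write_world` (or equivalently
    shaped real inputs). Writes all artifacts plus a JSON run log and returns
    the in-memory bundle.
    """
    from . import io as eio
    from .cleaning import CleaningConfig, clean_pipeline
    from .climate import extract_values, prune_correlated, taxon_climate_summary
    from .ecogeo import classify_all, merge_screening
    from .gaps import (exsitu_status, modelled_gap, priority_countries,
                       sampled_richness, unconserved_richness)
    from .niche import NicheConfig, TooFewRecords, run_protocol

    fixture_dir = Path(fixture_dir)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    records, rejects = eio.read_presence_table(fixture_dir / "records.csv")
    countries = eio.read_countries_geojson(fixture_dir / "countries.geojson")
    stack = eio.read_raster_stack(fixture_dir / "rasters")
    accessions = eio.read_accession_table(fixture_dir / "accessions.csv")
    screening = eio.read_screening_table(fixture_dir / "screening.csv")
    resistance = eio.read_resistance_table(fixture_dir / "resistance.csv")
    taxonomy = eio.read_taxonomy_table(fixture_dir / "taxonomy.csv")

    cleaned, report = clean_pipeline(records, countries, stack, CleaningConfig())
    eio.write_presence_table(cleaned, out / "records_clean.csv")
    report.to_frame().to_csv(out / "cleaning_report.csv", index=False)

    matrix, _ = extract_values(cleaned, stack)
    retained = prune_correlated(matrix[[c for c in matrix.columns
                                        if c.startswith("BIO")]])
    taxon_climate_summary(cleaned, stack).to_csv(out / "climate_summary.csv")

    hsd = classify_all(cleaned, stack)
    tol = merge_screening(hsd, screening,
                          taxa=[t.taxon_id for t in taxonomy])
    tol.to_csv(out / "tolerance_matrix.csv")

    status = exsitu_status(accessions, taxonomy)
    status.to_csv(out / "exsitu_status.csv")

    by_taxon = {}
    for r in cleaned:
        by_taxon.setdefault(r.taxon_id, []).append(r)
    binary_maps, skipped = {}, []
    for taxon in sorted(model_taxa or by_taxon):
        try:
            smap = run_protocol(by_taxon.get(taxon, []), stack,
                                NicheConfig(seed=seed, n_runs=n_runs,
                                            variables=tuple(retained[:2]) or
                                            ("BIO1", "BIO12")))
        except TooFewRecords as e:
            skipped.append((taxon, str(e)))
            continue
        binary_maps[taxon] = smap.binary
        eio.write_ascii_grid(out / f"suitability_{taxon}.asc", stack.grid,
                             smap.continuous)

    grid = stack.grid
    rasters = {
        "sampled_all": sampled_richness(cleaned, grid),
        "sampled_not_conserved": unconserved_richness(cleaned, status, grid),
        "modelled_gap": modelled_gap(binary_maps, cleaned, grid),
    }
    for name, arr in rasters.items():
        eio.write_ascii_grid(out / f"richness_{name}.asc", grid, arr, fmt="%d")
    prio = priority_countries(rasters["modelled_gap"], grid, countries)
    prio.to_csv(out / "priority_countries.csv", index=False)

    counts = summarize_counts(tol, resistance, taxonomy)
    counts.to_csv(out / "summary_counts.csv", index=False)
    pcts = summarize_percentages(tol, resistance, taxonomy)
    pcts.to_csv(out / "summary_percentages.csv", index=False)

    log = {"seed": seed, "n_rejects": len(rejects),
           "retained_variables": retained,
           "cleaning": report.to_frame().to_dict(orient="records"),
           "modelled_taxa": sorted(binary_maps), "skipped_taxa": skipped,
           "categories": status.category.value_counts().to_dict()}
    (out / "run_log.json").write_text(json.dumps(log, indent=2, sort_keys=True))
    return {"records": cleaned, "report": report, "tolerance": tol,
            "status": status, "rasters": rasters, "priority": prio,
            "counts": counts, "percentages": pcts, "log": log}
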