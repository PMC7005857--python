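"""Synthetic per-taxon reconstructions of the published genus-level tables.

The *Vigna* literature provides section-level summary counts — taxa per
section, taxa evaluated ecogeographically, taxa qualifying for each
harsh-climate criterion, taxa screened in pot experiments and tolerant per
assay, and taxa reviewed/resistant per biotic stressor — but not a usable
per-taxon assignment. The builders here expand those section totals into
synthetic per-taxon tables (taxon ids like ``angulares_03``): every
section-level and genus-level count is preserved exactly, while which
*particular* taxon carries a flag is an arbitrary deterministic choice.
They exist so the reporting stage can be exercised, and its headline
percentages recomputed, without the original compiled dataset.
"""

from __future__ import annotations

import pandas as pd

from .types import AccessionRecord, ResistanceRecord, ScreeningScore, TaxonInfo

#: section name -> (region, subgenus, gene pool, totals...) where totals are
#: (n_taxa, evaluated, high AMEANT, high TWETQ, low AP, low PWETQ,
#:  screened, dehydration-tolerant, salinity-tolerant,
#:  YMD reviewed, YMD resistant, bruchid reviewed, bruchid resistant)
SECTION_TABLE = {
    "Aconitifoliae":      ("Asia", "Ceratotropis", "A", 7, 6, 1, 3, 1, 1, 7, 1, 0, 2, 2, 3, 1),
    "Angulares":          ("Asia", "Ceratotropis", "A", 14, 13, 1, 1, 0, 0, 13, 1, 3, 4, 4, 11, 9),
    "Ceratotropis":       ("Asia", "Ceratotropis", "A", 7, 5, 0, 2, 0, 0, 6, 0, 0, 3, 3, 5, 3),
    "Plectotropis":       ("Africa", "Plectotropis", "B", 7, 7, 0, 0, 0, 1, 4, 1, 3, 0, 0, 1, 1),
    "Pseudoliebrechtsia": ("Africa", "Plectotropis", "B", 1, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0),
    "Catiang":            ("Africa", "Vigna", "C", 20, 17, 0, 2, 1, 3, 3, 0, 2, 1, 1, 1, 1),
    "Macrodontae":        ("Africa", "Vigna", "C", 6, 5, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0),
    "Reticulatae":        ("Africa", "Vigna", "C", 2, 2, 0, 0, 0, 0, 0, 0, 0, 0, 0, 1, 1),
    "Vigna":              ("Africa", "Vigna", "D", 24, 22, 0, 1, 0, 0, 3, 0, 2, 0, 0, 2, 2),
}

_COLS = ("n_taxa", "evaluated", "ameant", "twetq", "ap", "pwetq", "screened",
         "dehydration", "salinity", "ymd_reviewed", "ymd_resistant",
         "bruchid_reviewed", "bruchid_resistant")


def section_counts() -> pd.DataFrame:
    rows = []
    for section, vals in SECTION_TABLE.items():
        region, subgenus, pool = vals[:3]
        rows.append({"section": section, "region": region, "subgenus": subgenus,
                     "gene_pool": pool, **dict(zip(_COLS, vals[3:]))})
    return pd.DataFrame(rows).set_index("section")


def genus_taxonomy() -> list[TaxonInfo]:
    """88 synthetic taxa distributed over the nine sections."""
    taxa = []
    for section, vals in SECTION_TABLE.items():
        region, subgenus, pool = vals[:3]
        n = vals[3]
        for i in range(n):
            tid = f"{section.lower()}_{i + 1:02d}"
            taxa.append(TaxonInfo(taxon_id=tid, name=tid, subgenus=subgenus,
                                  section=section, gene_pool=pool,
                                  domesticated=False))
    return taxa


def _section_taxa(section: str) -> list[str]:
    n = SECTION_TABLE[section][3]
    return [f"{section.lower()}_{i + 1:02d}" for i in range(n)]


def genus_tolerance_matrix() -> pd.DataFrame:
    """Six-column tolerance matrix with the section counts planted.

    Within each section the first ``evaluated`` taxa carry climate levels and
    the first ``k`` of those are "high" for each criterion (the rest "low";
    intermediate counts are not published at section level). Assay columns
    follow the screened / tolerant counts the same way.
    """
    rows = {}
    for section, vals in SECTION_TABLE.items():
        c = dict(zip(_COLS, vals[3:]))
        taxa = _section_taxa(section)
        for i, t in enumerate(taxa):
            row = {}
            evaluated = i < c["evaluated"]
            for col, key in (("AMEANT", "ameant"), ("TWETQ", "twetq"),
                             ("AP", "ap"), ("PWETQ", "pwetq")):
                row[col] = ("high" if i < c[key] else "low") if evaluated else "nd"
            screened = i < c["screened"]
            for col in ("dehydration", "salinity"):
                row[col] = ("high" if i < c[col] else "low") if screened else "nd"
            rows[t] = row
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "taxon_id"
    df["profile_count"] = (df == "high").sum(axis=1)
    return df


def genus_screening_scores() -> list[ScreeningScore]:
    """One accession score per screened taxon per assay (1 = tolerant, 3 = not)."""
    scores = []
    for section, vals in SECTION_TABLE.items():
        c = dict(zip(_COLS, vals[3:]))
        for i, t in enumerate(_section_taxa(section)[:c["screened"]]):
            scores.append(ScreeningScore(t, f"{t}-a1", "dehydration",
                                         1 if i < c["dehydration"] else 3))
            scores.append(ScreeningScore(t, f"{t}-a1", "salinity",
                                         1 if i < c["salinity"] else 3))
    return scores


def genus_resistance_table() -> list[ResistanceRecord]:
    recs = []
    for section, vals in SECTION_TABLE.items():
        c = dict(zip(_COLS, vals[3:]))
        taxa = _section_taxa(section)
        for stressor, nrev, nres in (("YMD", c["ymd_reviewed"], c["ymd_resistant"]),
                                     ("bruchids", c["bruchid_reviewed"],
                                      c["bruchid_resistant"])):
            for i, t in enumerate(taxa):
                if i < nres:
                    status = "resistant_reported"
                elif i < nrev:
                    status = "no_resistance_reported"
                else:
                    status = "not_evaluated"
                recs.append(ResistanceRecord(t, stressor, status))
    return recs


def genus_accessions(n_absent_asia=2, n_absent_africa=4,
                     n_poor_asia=9, n_poor_africa=7) -> list[AccessionRecord]:
    """Genebank holdings: 6 taxa absent, 16 with fewer than 10 accessions.

    The published compilation reports two Asian and four African taxa held by
    no genebank, and nine further Asian plus seven African taxa with fewer
    than ten accessions; counts here plant exactly those category totals with
    synthetic per-taxon assignment and accession numbers.
    """
    regions = {}
    for section, vals in SECTION_TABLE.items():
        regions.setdefault(vals[0], []).extend(_section_taxa(section))
    recs = []
    for region, (n_absent, n_poor) in (("Asia", (n_absent_asia, n_poor_asia)),
                                       ("Africa", (n_absent_africa, n_poor_africa))):
        taxa = regions[region]
        for i, t in enumerate(taxa):
            if i < n_absent:
                continue  # absent: no row at all
            if i < n_absent + n_poor:
                n = (i % 9) + 1
            else:
                n = 10 + 7 * i
            recs.append(AccessionRecord(t, "INST1", n, min(n // 3, n)))
    return recs
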