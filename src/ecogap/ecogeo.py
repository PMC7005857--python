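"""Ecogeographic classification of taxa into climate-harshness groups.

Record-level climate values are rank-transformed over the pooled data
(average ranks for ties), a one-way ANOVA with taxon as the factor is run on
the ranks, and all-pairs Tukey HSD comparisons (Tukey-Kramer for unbalanced
groups) yield a compact letter display. Group 1 ("harsh") are the taxa
sharing a letter with the taxon of most extreme mean rank (highest for
temperature indicators, lowest for rainfall indicators); group 2 shares a
letter with the most extreme taxon not already in group 1; everything else
is group 3. Four harsh-climate definitions are assessed: permanently hot
(high BIO1), seasonally hot (high BIO8), permanently dry (low BIO12), and
seasonally dry (low BIO16). Taxa with fewer than five records are excluded.

Screening scores from pot experiments (Likert 1 = high tolerance .. 5 = low)
are merged in per assay using the best accession score per taxon:
1 -> high, 2 -> intermediate, >= 3 -> low, unscreened -> nd.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .climate import extract_values
from .types import CLIMATE_VARS, ClimateStack

LEVELS = ("high", "intermediate", "low", "nd")
#: (alias, bioclim code, group-1 tail) for the four harsh-climate definitions
HARSH_DEFINITIONS = (("AMEANT", "BIO1", "high"), ("TWETQ", "BIO8", "high"),
                     ("AP", "BIO12", "low"), ("PWETQ", "BIO16", "low"))


def rank_transform(values) -> np.ndarray:
    """Ranks 1..n with average ranks for ties."""
    values = np.asarray(values, dtype=float)
    if values.size == 0 or not np.isfinite(values).all():
        raise ValueError("need at least one finite value")
    return stats.rankdata(values, method="average")


def compact_letter_display(items, significant_pairs, order):
    """Insert-absorb compact letter display.

    ``significant_pairs`` is an iterable of 2-sets of items whose means
    differ; two items share a letter iff they are never separated. Letters
    are assigned 'a', 'b', ... walking the letter groups in ``order`` of
    their best-placed member, so the most extreme item always carries 'a'.
    """
    sets = [set(items)]
    for i, j in significant_pairs:
        nxt = []
        for s in sets:
            if i in s and j in s:
                nxt.append(s - {i})
                nxt.append(s - {j})
            else:
                nxt.append(s)
        # absorb: drop empty sets, duplicates, and sets contained in another
        uniq = []
        for s in nxt:
            if s and s not in uniq:
                uniq.append(s)
        sets = [s for s in uniq if not any(s < t for t in uniq)]
    pos = {it: k for k, it in enumerate(order)}
    sets.sort(key=lambda s: min(pos[it] for it in s))
    letters = {it: "" for it in items}
    for idx, s in enumerate(sets):
        letter = chr(ord("a") + idx) if idx < 26 else f"z{idx}"
        for it in s:
            letters[it] += letter
    return {it: "".join(sorted(v)) for it, v in letters.items()}


@dataclass
class HSDResult:
    variable: str           # alias: AMEANT / TWETQ / AP / PWETQ
    bio: str
    direction: str          # which tail is "harsh": high or low
    alpha: float
    f_stat: float
    p_value: float
    mean_ranks: pd.Series = field(default_factory=pd.Series)
    letters: dict = field(default_factory=dict)
    groups: dict = field(default_factory=dict)   # taxon -> 1 | 2 | 3
    excluded: list = field(default_factory=list)  # (taxon, n_records)


def classify_values(values, taxa, direction: str, alpha: float = 0.05):
    """Rank ANOVA + Tukey HSD three-tier grouping on raw record values.

    Returns ``(mean_ranks, letters, groups, f_stat, p_value)`` where
    ``groups`` maps each taxon to tier 1 (harsh tail), 2 or 3.
    """
    if direction not in ("high", "low"):
        raise ValueError("direction must be 'high' or 'low'")
    values = np.asarray(values, dtype=float)
    taxa = np.asarray(taxa)
    ranks = rank_transform(values)
    mean_ranks = pd.Series(ranks).groupby(taxa).mean().sort_values(
        ascending=(direction == "low"))
    order = list(mean_ranks.index)  # most extreme first
    if len(order) < 2:
        raise ValueError("need at least 2 taxa")

    if np.ptp(ranks) == 0:
        warnings.warn("all values tied after ranking; no separation possible")
        return (mean_ranks, {t: "a" for t in order}, {t: 1 for t in order},
                np.nan, np.nan)

    f_stat, p_value = stats.f_oneway(*(ranks[taxa == t] for t in order))
    hsd = pairwise_tukeyhsd(ranks, taxa, alpha=alpha)
    pairs = list(itertools.combinations(hsd.groupsunique, 2))
    sig_pairs = [pair for pair, rej in zip(pairs, hsd.reject) if rej]
    letters = compact_letter_display(order, sig_pairs, order)

    groups = {}
    g1_letters = set(letters[order[0]])
    for t in order:
        if set(letters[t]) & g1_letters:
            groups[t] = 1
    second = next((t for t in order if t not in groups), None)
    if second is not None:
        g2_letters = set(letters[second])
        for t in order:
            if t not in groups and set(letters[t]) & g2_letters:
                groups[t] = 2
    for t in order:
        groups.setdefault(t, 3)
    return mean_ranks, letters, groups, float(f_stat), float(p_value)


def classify_variable(records, stack: ClimateStack, variable: str,
                      direction: str, alpha: float = 0.05,
                      min_records: int = 5) -> HSDResult:
    """Rank ANOVA + Tukey HSD three-tier grouping for one climate variable.

    ``variable`` may be a bioclim code (``BIO8``) or an alias (``TWETQ``).
    ``direction`` names the harsh tail (``high`` or ``low``). Taxa with
    fewer than ``min_records`` records are excluded from the analysis.
    """
    bio = CLIMATE_VARS.get(variable, variable)
    alias = next((a for a, b in CLIMATE_VARS.items() if b == bio), bio)
    matrix, _ = extract_values(records, stack)
    counts = matrix.groupby("taxon_id").size()
    excluded = [(t, int(n)) for t, n in counts.items() if n < min_records]
    eligible = counts[counts >= min_records].index
    if len(eligible) < 2:
        raise ValueError("need at least 2 taxa with enough records")
    sub = matrix[matrix.taxon_id.isin(eligible)]
    mean_ranks, letters, groups, f_stat, p_value = classify_values(
        sub[bio].to_numpy(dtype=float), sub.taxon_id.to_numpy(),
        direction, alpha)
    return HSDResult(variable=alias, bio=bio, direction=direction, alpha=alpha,
                     f_stat=f_stat, p_value=p_value, mean_ranks=mean_ranks,
                     letters=letters, groups=groups, excluded=excluded)


def classify_all(records, stack: ClimateStack, alpha: float = 0.05,
                 min_records: int = 5) -> dict:
    """The four harsh-climate classifications keyed by variable alias."""
    return {alias: classify_variable(records, stack, bio, direction, alpha,
                                     min_records)
            for alias, bio, direction in HARSH_DEFINITIONS}


def merge_screening(hsd_results: dict, screening_scores, taxa=None) -> pd.DataFrame:
    """Build the six-column tolerance matrix (the genus heat-map).

    Climate columns map group 1 -> high, 2 -> intermediate, 3 -> low and
    excluded/absent -> nd. Assay columns use the minimum (best) accession
    score per taxon: 1 -> high, 2 -> intermediate, >= 3 -> low, unscreened
    -> nd. ``profile_count`` counts the "high" cells per taxon.
    """
    level_of_group = {1: "high", 2: "intermediate", 3: "low"}
    all_taxa = set(taxa or [])
    for res in hsd_results.values():
        all_taxa.update(res.groups)
        all_taxa.update(t for t, _ in res.excluded)
    rows = {}
    for s in screening_scores:
        s.validate()
        all_taxa.add(s.taxon_id)
    for t in sorted(all_taxa):
        row = {}
        for alias in CLIMATE_VARS:
            res = hsd_results.get(alias)
            row[alias] = level_of_group.get(
                res.groups.get(t) if res else None, "nd")
        rows[t] = row
    best = {}
    for s in screening_scores:
        key = (s.taxon_id, s.assay)
        best[key] = min(best.get(key, 6), s.score)
    for t in rows:
        for assay in ("dehydration", "salinity"):
            score = best.get((t, assay))
            if score is None:
                rows[t][assay] = "nd"
            elif score == 1:
                rows[t][assay] = "high"
            elif score == 2:
                rows[t][assay] = "intermediate"
            else:
                rows[t][assay] = "low"
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "taxon_id"
    df["profile_count"] = (df == "high").sum(axis=1)
    return df
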