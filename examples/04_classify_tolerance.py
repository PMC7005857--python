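"""Classify taxa into climate-harshness groups and build the tolerance matrix.

Per variable: record-level values are rank-transformed, a one-way ANOVA with
taxon as factor is run, and Tukey HSD letters define group 1 (harsh tail),
group 2, and group 3. Pot-experiment Likert scores (1 = tolerant) are merged
as the dehydration and salinity columns.
"""

import warnings

from ecogap import SyntheticWorldSpec, clean_pipeline, make_world
from ecogap.ecogeo import classify_all, merge_screening

warnings.filterwarnings("ignore")

world = make_world(SyntheticWorldSpec(seed=42), n_per_taxon=125)
cleaned, _ = clean_pipeline(world["records"], world["countries"],
                            world["stack"])

hsd = classify_all(cleaned, world["stack"])
for alias, res in hsd.items():
    harsh = [t for t, g in res.groups.items() if g == 1]
    print(f"{alias} ({res.bio}, harsh = {res.direction}): "
          f"F = {res.f_stat:.0f}, group 1 = {harsh}")

tol = merge_screening(hsd, world["screening"],
                      taxa=[t.taxon_id for t in world["taxonomy"]])
print("\ntolerance matrix (high = harsh climate or tolerant in screening):")
print(tol.to_string())
# profile_count totals the 'high' cells per taxon across the six variables;
# taxa with several highs are the stress-resilience priorities.
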