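"""Ex situ conservation categories and geographic collection gaps.

Categories: absent (0 accessions), poor (1-9), adequate (>= 10). The
modelled-gap raster counts taxa whose binary suitability covers a cell with
no reported record of that taxon; countries are ranked by the zonal sum.
"""

import warnings

from ecogap import (NicheConfig, SyntheticWorldSpec, clean_pipeline,
                    exsitu_status, make_world, modelled_gap,
                    priority_countries, sampled_richness)
from ecogap.niche import run_protocol

warnings.filterwarnings("ignore")

world = make_world(SyntheticWorldSpec(seed=42), n_per_taxon=125)
cleaned, _ = clean_pipeline(world["records"], world["countries"],
                            world["stack"])
stack = world["stack"]

status = exsitu_status(world["accessions"], world["taxonomy"])
print("ex situ categories:", status.category.value_counts().to_dict())

richness = sampled_richness(cleaned, stack.grid)
print(f"sampled richness: max {richness.max()} taxa in one cell")

by_taxon = {}
for r in cleaned:
    by_taxon.setdefault(r.taxon_id, []).append(r)
binary = {t: run_protocol(rs, stack, NicheConfig(seed=0,
                                                 variables=("BIO1", "BIO12"))).binary
          for t, rs in by_taxon.items()}
gap = modelled_gap(binary, cleaned, stack.grid)
print(f"modelled-gap raster: max {gap.max()} unreported-but-suitable taxa")

print("\npriority countries (zonal sum of modelled gap):")
print(priority_countries(gap, stack.grid, world["countries"]).to_string(index=False))
# The top-ranked countries hold the most cells where taxa are modelled to
# occur but have never been reported: candidate areas for collecting missions.
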