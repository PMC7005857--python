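"""Generate a synthetic study region and inspect its ground truth.

Builds countries, 19 correlated bioclimatic layers, niche-structured presence
records for 8 taxa, and injects the five record-error classes with a ledger.
"""

import warnings

from ecogap import SyntheticWorldSpec, make_world

warnings.filterwarnings("ignore")

spec = SyntheticWorldSpec(seed=42)
world = make_world(spec, n_per_taxon=125)

print(f"countries: {world['countries'].codes}")
print(f"grid: {world['stack'].grid.nrows} x {world['stack'].grid.ncols} cells "
      f"at {spec.res_arcmin} arc-min")
print(f"records: {len(world['records'])} "
      f"({len(world['ledger'].frame)} injected errors)")
print(world["ledger"].frame.error_type.value_counts().to_string())
# Each ledger row names a corrupted record and what was changed; the cleaning
# pipeline should remove or repair essentially all of them (see example 02).
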