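"""Headline percentages from the bundled genus summary tables.

The per-taxon tables are synthetic reconstructions that preserve the
published section-level counts for the Vigna genus (taxa evaluated
ecogeographically, screened in pot experiments, reviewed for resistance,
and genebank holdings); the reporting stage recomputes the headline rates.
"""

from ecogap import datasets
from ecogap.gaps import exsitu_status
from ecogap.report import resistance_summary, summarize_percentages

tol = datasets.genus_tolerance_matrix()
tax = datasets.genus_taxonomy()
res = datasets.genus_resistance_table()

pct = summarize_percentages(tol, res, tax)
print(pct.to_string(index=False))

print("\nresistance review:")
print(resistance_summary(res).to_string(index=False))

status = exsitu_status(datasets.genus_accessions(), tax)
cats = status.category.value_counts()
print(f"\nex situ: {cats.get('absent', 0)} taxa absent, "
      f"{cats.get('poor', 0)} poorly conserved (<10 accessions), "
      f"{cats.get('adequate', 0)} adequately conserved "
      f"of {len(status)} taxa")
# e.g. 12% of evaluated taxa occur in seasonally hot climates (high
# wettest-quarter temperature) and 22 of 88 taxa need urgent collecting.
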