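# Methods

This note documents the models, conventions and design choices behind
`ecogap`, in the order the pipeline runs them.

## Coordinates, distances and grids

All coordinates are decimal degrees WGS84, longitudes normalised to
[−180, 180]. Distances are great circles on a sphere of radius 6371 km
(haversine); "arc-minute" buffers and tolerances are angular distances
(central angle in minutes). Protocol quantities quoted in
km (e.g. the longest inter-point distance) are converted to degrees using
the east–west degree length at the points' mean latitude,
111.195 · cos φ km/deg; the conversion is configurable.

Rasters are north-up regular lon/lat grids with half-open cells
[x0, x0 + res) in both axes measured from the lower-left corner: a point on
a shared edge belongs to the cell that starts at that edge, and points on
the outer top/right boundary are clamped into the last cell. Raster I/O uses
the ESRI ASCII grid format — a plain-text format that round-trips exactly
and keeps the whole artifact text-only; the 19 layers are files
`BIO1.asc` … `BIO19.asc` with a shared grid and a common nodata sentinel
(default −9999).

Point-to-polygon distances are computed by taking the planar (degree-space)
nearest point on the polygon and measuring the haversine distance to it.
For the small buffers used here (≤ tens of arc-minutes) the difference from
the exact geodesic nearest point is negligible; the tests verify decisions
against densified-boundary brute force away from knife-edge cases.

## Synthetic world

The generator emulates the six input classes with known ground truth.

* **Countries** are disjoint rectangular tiles over an inset of the extent
  (margins left as sea); centroids are exact tile centres.
* **Climate.** BIO1 (annual mean temperature, °C) decreases with |latitude|
  (28 − 0.9·|lat| + N(0, 0.8²)); BIO12 (annual precipitation, mm) increases
  eastward (500 + 60·Δlon + N(0, 60²)). The other 17 layers are linear
  mixtures r·z + √(1−r²)·ε of the standardised BIO1 or BIO12 field, giving
  empirical Pearson correlations ≈ r; two layers (BIO4, BIO15) sit below the
  0.7 pruning threshold so collinearity pruning has work to do. Sea cells
  are nodata in all layers. Requested |r| > 1 is rejected before generation.
* **Niches** live in (BIO1, BIO12) only — the other 17 layers are
  correlated distractors — so pruning and model recovery stay
  interpretable. Default breadths are σ(BIO1) = 1.2 °C and σ(BIO12) = 90 mm,
  i.e. regional specialists occupying roughly a tenth of the simulated
  climate range; centres are spread from warm-dry to cool-wet with
  precipitation staggered so temperature and rainfall optima are not
  collinear across taxa. Records are drawn per land cell with probability
  ∝ exp(−½ D²) (diagonal Mahalanobis to the niche centre), jittered
  uniformly within the cell; zero breadth degenerates to the single best
  cell.
* **Error injection** corrupts ⌊rate·n⌋ records per class with disjoint
  victim sets: country-code swaps to a country > 30′ away; offshore moves
  (half within ~9′ of the declared country's coast so they are relocatable,
  half > 20′ out so the country filter removes them); centroid snapping;
  exact-coordinate duplicates; climate-outlier moves to land cells violating
  the taxon's fences on ≥ 3 variables, selected at a 2.8×IQR margin (and
  preferring more extreme cells) so the 2.5×IQR fences still flag them after
  injection itself shifts the quartiles. Every change is ledgered with the
  original values, making precision/recall of the cleaning pipeline exactly
  measurable.
* **Determinism.** One global seed; each generator draws from
  `SeedSequence((seed, stream_index))` with fixed per-generator indices.

Default study conditions: 30° × 30° extent at 15′ resolution (120×120
cells), 6 countries, 8 taxa × 125 records (= 1000 records), error rates
5 % country-mismatch, 4 % offshore, 3 % centroid, 5 % duplicate, 3 %
climate outlier. What the generator does **not** emulate: real spatial
autocorrelation beyond smooth gradients + white noise, coastline geometry,
taxonomic uncertainty, or spatially biased collection effort. Passing tests
therefore demonstrate correctness of the algorithms under known truth, not
performance on real occurrence data.

## Cleaning

Order: country mismatch → coastal relocation → centroid removal → dedupe →
climate outliers. The 10′ border buffer keeps genuinely coastal records
alive through the country step, and relocation precedes the centroid,
duplicate and outlier verdicts. Records without a country code cannot be
contradicted and pass the country filter flagged; unknown codes are removed.
Relocated points are nudged ~10⁻⁶ deg inland after snapping to the nearest
coastline point so raster lookups hit a data cell. Quartiles use linear
interpolation between order statistics (numpy default, "type 7"); taxa with
fewer than 4 records are exempt from the outlier filter (no meaningful
quartiles); records on nodata cells are removed with their own reason.
Centroid tolerance defaults to 1′; dedupe rounds to 4 decimals (~11 m).
Deduplication keeps the smallest record id, making the pipeline
deterministic and idempotent on the standard fixtures. Strictly, a second
IQR pass could remove more records after the first changes the quartiles;
on the default conditions it removes nothing, and the suite asserts that
fixpoint.

## Niche model

The model is a presence–background maximum-entropy fit. Features are the
per-variable standardised values z and standardised z² (background moments);
the weights minimise −mean_presence(w·f) + log Σ_support exp(w·f) + β‖w‖₁
with β = 0.05. The support of the Gibbs distribution is the background
sample plus the presence samples, the Java Maxent convention: with a finite
background draw alone the objective is unbounded whenever the presence
feature mean leaves the convex hull of background features. The L1 term is
handled by the w = u − v split with non-negativity bounds, solved with
L-BFGS-B; convergence is certified by the KKT box condition — every
feature-expectation gap ≤ β — which the tests assert directly rather than
trusting the optimiser's status flag.

Protocol per taxon (defaults): ≥ 5 presences required (taxa below are
skipped and reported, mirroring the ecogeographic exclusion rule); spatial
thinning keeps one record per cell of a grid sized to 10 % of the longest
inter-point distance, then 80 % of the thinned records are kept; background
is 10 points per presence drawn uniformly (with replacement) over data cells
inside the convex hull buffered by 10 % of the same distance; three runs are
averaged cellwise; the threshold τ maximising sensitivity + specificity
(ties → smallest candidate) is computed once, on the averaged raster,
scoring all cleaned presences against a dedicated background draw; the
binary map is (mean ≥ τ) clipped to the buffered hull. Predictions are
exp(w·f) max-normalised to [0, 1] over the clip region.

On recovery: with the default specialist niches the fitted suitability
discriminates held-out presences from hull background with AUC ≥ 0.9 for
peripheral specialists, and within 0.05 of the *oracle* AUC (scoring with
the true planted niche density) for every taxon. The oracle ceiling itself
drops to ~0.85–0.91 for central generalists because the buffered hull makes
the background resemble the taxon's own climate — the well-known dependence
of presence–background AUC on evaluation extent — so model-vs-oracle
agreement, not raw AUC, is the meaningful recovery check for those taxa.

## Ecogeographic classification

Record-level values of BIO1, BIO8, BIO12, BIO16 (aliases AMEANT, TWETQ, AP,
PWETQ) are rank-transformed over the pooled data (average ranks for ties);
one-way ANOVA with taxon as factor; all-pairs Tukey HSD on the ranks with
the Tukey–Kramer adjustment for unbalanced groups at α = 0.05; compact
letters built by insert–absorb. Group 1 are taxa sharing a letter with the
extreme-mean taxon (highest ranks for the temperature variables, lowest for
the rainfall variables), group 2 shares a letter with the most extreme taxon
not already in group 1, group 3 is the remainder. Rank-basedness makes the
grouping invariant to monotone transforms of the raw variable. Taxa with
fewer than 5 records are excluded and listed. All values tied is degenerate:
everything lands in group 1 with a warning.

Screening merges by the best (minimum) accession score per taxon per assay:
1 → high, 2 → intermediate, ≥ 3 → low, unscreened → nd. The tolerance
matrix rows therefore have levels for the four climate criteria plus
dehydration and salinity, and `profile_count` totals the "high" cells.

## Gap analysis and reporting

Ex situ categories: absent (0 accessions summed over institutes), poor
(1–9), adequate (≥ 10); taxa in the taxonomy but missing from the accession
table are absent. Richness rasters count distinct taxa per cell. The
modelled-gap raster counts taxa with binary suitability 1 and no record (any
source) in the cell. Priority countries rank by the zonal **sum** of the gap
raster over cells whose centres fall inside the polygon (mean and max are
offered); ties break alphabetically.

Percentages round half-up to integer percent and are always recomputable
from the emitted counts. A section or gene pool qualifies for a criterion
iff at least one member taxon qualifies; its denominator counts units with
at least one member evaluated (screened, reviewed) for that criterion.

## Bundled genus tables

`ecogap.datasets` ships synthetic per-taxon reconstructions of the published
section-level summary counts for the genus (9 sections, 88 taxa, 77
evaluated ecogeographically, 36 screened, 24/10 reviewed for
bruchids/YMD, and genebank-holding categories of 6 absent + 16 poorly
conserved). Section- and genus-level totals are preserved exactly; which
particular taxon within a section carries a flag is an arbitrary
deterministic assignment, so only aggregate statistics computed from these
tables are meaningful. The salinity column sums to 10 tolerant taxa of 36
screened (27.8 %, half-up 28 %); published prose rounds this differently in
different places, so the taxon-level salinity rate is reported only via its
counts. Section-level rates for the seasonally-hot criterion under the
membership rule above (5 of 8 = 63 %) likewise have no published integer
counterpart and are not treated as reference values.

## Problem sizes and tolerances

The test suite and acceptance script use the default 1000-record world for
cleaning (ledger recall threshold 0.95), a 100×100-cell world with 200
presences per taxon for model recovery, 200 seeded replicates at Δ = 5 SD,
n = 30 per taxon for Tukey group recovery (≥ 99 % required), 10⁵ draws for
background-uniformity χ² (α = 0.01), and exhaustive brute-force oracles for
thresholds, distances, fences, pruning and zonal sums on small random
instances. KKT tolerance is β + 10⁻⁶ in unit tests (10⁻⁴ in the protocol's
internal convergence check); byte-identical reruns are required for the
end-to-end determinism check.

## Known limitations

* Planar-degree hulls, buffers and nearest points (spherical distances, but
  planar geometry); adequate at the simulated scales, increasingly biased
  near poles or across the antimeridian.
* The IQR outlier filter is not provably idempotent; it is in practice on
  the default conditions and the suite pins that.
* GeoTIFF is not read or written; ESRI ASCII grid is the raster format.
* No gazetteer georeferencing, no spatial autocorrelation or phylogenetic
  correction, and no cartography beyond raster export.
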