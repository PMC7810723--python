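# Methods

This note documents the models and procedures implemented in `treemap`,
the choices made where the design was genuinely open, and what the
synthetic experiments do and do not demonstrate.

## Imputation model

The imputation is a nearest-neighbour assignment in the metric induced
by an ensemble of classification trees. Three response variables —
canopy-cover bin, canopy-height bin, vegetation group — each get
`trees_per_response` trees (default 83, so 249 in total), grown on the
reference plots:

* **Bootstrap**: each tree trains on `floor(0.66 n)` plots drawn
  *without* replacement. The held-out plots provide the out-of-bag
  (OOB) misclassification estimate.
* **Split search**: at every node `floor(sqrt(k))` of the k candidate
  variables are drawn; the binary split minimising the weighted Gini
  impurity of the children wins. Gain ties break to the lowest
  variable index, so training is deterministic given the seed.
* **Numeric splits** use midpoints of adjacent observed values.
  **Categorical splits** (vegetation group, disturbance code) search
  subset partitions greedily: categories are ordered by their
  probability of a response class, prefix splits are scanned, and the
  scan is repeated for every class present, keeping the best.
* **Stopping**: a split must leave at least `min_bucket` (default 5)
  plots in each child and strictly reduce impurity.
* **Prediction**: a pixel's variable vector is routed down every tree.
  A categorical level unseen at a node routes toward the child with
  more in-bag observations.

Each reference plot is credited once per tree in whose terminal node it
co-occurs with the pixel (in-bag plots only — an out-of-bag plot has no
defined leaf in its own tree). The plot with the maximum total across
all 249 trees is imputed; exact ties are split uniformly at random by a
seeded generator with pixels processed in row-major order, so the
output raster is bit-reproducible. Every tree carries equal weight and
no leaf-size normalisation is applied: the vote is the raw
co-occurrence frequency.

### Response surfaces as routing variables

`responses_as_split_candidates` (default `true`) adds all three
response bands — including the tree's own label — to the candidate
variable set. This is the configuration that reproduces the published
behaviour of the production CONUS-2014 run: when a tree may split on
its own response, its terminal nodes become response-pure, and at
prediction time the pixel's observed cover/height/group surfaces steer
it into terminal nodes of plots that match those surfaces. Two
consequences follow, and both are visible in the published record this
package re-implements:

1. imputed-vs-target agreement is very high (≈ 97 % cover, ≈ 99 %
   height on the default synthetic fixture, mirroring the published
   97.2 % / 99.2 % / 93.0 %), because the target's response values
   effectively participate in the match;
2. the OOB error is deflated roughly an order of magnitude, because
   label information leaks into routing. With
   `responses_as_split_candidates=false` (the classical predictor-only
   formulation) the same fixture yields honest OOB errors around
   0.45/0.17/0.09 and agreement around 0.85/0.95/0.98.

Both modes are first-class; analyses that need an unbiased
generalisation estimate should use the predictor-only mode.

### Zonal execution

Categorical machinery is budgeted at `max_classes_per_run` (default 32)
vegetation-group classes. `run_zonal` fits and imputes each zone of a
zone raster independently, restricting the reference table to plots
whose group occurs among the zone's masked pixels, and stitches the
outputs. A zone exceeding the class budget is refused with guidance; a
zone without a single eligible plot raises an error, as does any masked
pixel whose group has no reference plot — the hard constraint of
categorical imputation that motivates the recode table below.

## Preprocessing rules

* **Cover binning**: percent canopy cover maps to the midpoint of its
  10-point bin (15, 25, … 95). Bins are half-open `[lo, hi)`; the
  bottom of the lowest forest bin (10 %) is inclusive and the top bin
  closes at 100 %. Cover below 10 % signals non-forest and leaves the
  mask.
* **Height binning**: five bins — 0–5 m → 3, 5–10 → 8, 10–25 → 18,
  25–50 → 38, ≥ 50 → 70 — half-open, top bin unbounded.
* **Disturbance collapse**: annual disturbance-type layers reduce to a
  single (code, year) pair per pixel. Fire takes precedence over
  insect/disease regardless of recency; within a cause the most recent
  year wins. The same precedence applies to the up-to-three
  disturbance slots of a plot record. Undisturbed pixels/plots carry
  year 0, a sentinel distinct from all valid years that keeps the band
  numeric for tree splits.
* **Forest mask**: cover ≥ 10 %, vegetation group neither excluded
  (developed/agricultural) nor dropped by the recode table. The recode
  table is a two-column CSV (`source_evg,target_evg_or_DROP`); the
  shipped default carries the stock substitutions for the 2014 CONUS
  landscape (692→693, 705→668, drop 649 and 730). Chains are resolved
  transitively and cycles rejected.
* **Alignment** is exact equality of geotransform and CRS. Misaligned
  inputs are an error; nothing is resampled silently.
* **Coordinates**: pixel centroids sit at origin + (index + ½)·size,
  row 0 north, and are inverse-projected to latitude/longitude. Two
  CRSs are built in: geographic degrees and a local spherical
  azimuthal-equidistant frame (`AEQD:lat0:lon0`, metres), which keeps
  footprint distances Euclidean and true near the origin.

## Plot-attribute derivation

* **Top-stratum height** is the mean height of the nine live trees
  centred on the 70th-percentile tree: heights sorted ascending, anchor
  at 1-based rank `ceil(0.70 n)`, window ranks anchor ± 4 clipped to
  the list, all trees when n < 9. The anchor and clipping conventions
  are this package's choices; the multi-stratum gap detection of the
  original stand-classification software is deliberately simplified to
  this single top-stratum rule, a known fidelity limit.
* **Canopy cover** uses the random-placement overlap correction
  `C = 100·(1 − exp(−Σ π r_i² · tpa_i / A))` over live trees, where
  `A` is the unit area of the declared expansion-factor system (acre by
  default). Cover is monotone in every crown radius and saturates
  strictly below 100 %. Crown radii are a required input column; the
  allometry that produces them is out of scope.
* **Top-two species** rank species by live basal area
  `Σ π (d/2)² · tpa`; exact ties break to the ascending species code.
* **Standing-dead count** counts flagged standing-dead records and
  validates the flag against tree status.
* **Reference assembly** joins plot and tree tables, samples the six
  biophysical bands at the plot location, bins the derived cover and
  height, reduces the disturbance slots, and drops multi-condition
  plots (kept separately as the validation set), plots under 10 %
  cover, plots without live trees and plots outside the raster extent,
  reporting each count.

## Validation suite

Confusion matrices are oriented rows = imputed, columns = target.
Overall accuracy is the trace over the total; user's accuracy is
diagonal over row total; producer's over column total; empty rows or
columns report NaN. Two algebraic identities — overall equals both the
row-weighted mean of user's and the column-weighted mean of producer's
accuracies — are asserted in the test suite on every matrix touched.

Footprint validation collects the pixels whose centroid lies within
40.25 m (the disc spanned by the four-subplot inventory design) of a
validation plot, restricted to the forest mask. Flags per plot: any
footprint pixel matching the plot's cover (height) bin; equal-weight
mean of footprint-pixel cover midpoints within 10 percentage points of
the plot's continuous cover (10 points = one bin width; the "weighted"
mean is equal-weight because no weighting scheme is defined in the
product documentation); mean height-bin value within 5 m; and any
footprint pixel's imputed plot sharing at least one of the plot's
top-two species. Plots without a single forested footprint pixel are
excluded from every denominator and counted separately. Summary rates
round half-up to one decimal percent, matching the published tables'
convention; the published record itself reports 2,319 validation plots
obtained against a 2,858-plot denominator, an internal inconsistency
the code sidesteps by always reporting both counts.

The disturbance analysis compares standing-dead counts of burned and of
insect/disease plots against undisturbed plots with a two-sided
two-sample Kolmogorov–Smirnov test: D is the exhaustive supremum ECDF
distance; the p-value is the limiting Kolmogorov law evaluated at
`sqrt(n_a n_b/(n_a+n_b))·D`. The limiting law is visibly conservative
below a few hundred observations per group — the calibration test runs
at 1,000 per group, inside its validity range, and the exact
small-sample distribution is out of scope at the sample sizes this
analysis targets.

## Synthetic landscapes

The generator builds, under one seed: smooth elevation/biophysical
surfaces (Gaussian-filtered noise, default correlation length 10
pixels); slope/aspect from the elevation gradient; blocky
vegetation-group regions (Voronoi growth from seeded points, each
region guaranteed a plot); disc-shaped fire/insect patches with years
in 1999–2014; a reference-plot network; and a held-out multi-condition
validation set. Every pixel carries a known generating plot (the
nearest plot of its vegetation group), so recovery is measurable
against truth.

Plot structure follows the mapped gradients: the environment sets a
stand's ordinal cover/height class (wetter is denser, lower and wetter
is taller, vegetation groups shift cover by whole classes, recent fire
drops cover by about two classes and resets height), the class mean
snaps to the class-representative value, and within-class spread is
small relative to the class width (2 cover points, ≈ 8 % of the height
value). Pixel surfaces are the generating plot's values plus small
noise (0.5 cover points, 0.3 m). This emulates a classified, spatially
coherent target product whose classes are largely determined by the
mapped gradients — the regime in which the production imputation
demonstrably operated, given its published agreement and OOB figures.
Tree lists are *constructed* to reproduce each plot's attributes
through the real derivation code: heights are rescaled until the
nine-tree rule returns the plot height exactly, expansion factors are
solved so the overlap-corrected cover equals the plot cover, species
come from fixed per-group pools (shipped as data), and disturbed plots
receive additional standing-dead trees (Poisson, +5 expected after
fire, +3 after insect/disease). Every generated artifact passes
through the same readers the real pipeline uses.

What the synthetic experiments show: the engine recovers known
structure at desk scale (200 × 200 pixels, 500 plots, ≈ 8 s end to
end on one CPU; the round-trip test uses a denser 900-plot network
where zero-noise agreement exceeds 99 %). What they do not show:
behaviour under real measurement error, real vegetation mosaics,
multi-stratum canopies, location fuzzing, or continental-scale class
imbalance. The footprint rates on synthetic validation plots are
analogues, not forecasts, of the published rates.

## Numerical and degenerate-input conventions

* One seeded generator per run, forked into named streams (fields,
  plots, trees, bootstrap, tie-breaks), so stage-level results are
  reproducible independently of pipeline order; zone i shifts the seed
  deterministically so a single-zone run is identical to a direct fit.
* A single reference plot yields single-leaf trees, an undefined OOB
  reported as 0 with a warning, and every pixel imputed to that plot.
* Vote margins (best minus runner-up tally) are written alongside the
  plot-id raster as a per-pixel confidence diagnostic; tied pixels
  carry margin 0.
* Binning is idempotent; disturbance collapse is order-independent;
  both are property-tested.
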