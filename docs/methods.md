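# Methods

## Scope and model

`farmscape` implements a farm-level assessment of non-provisioning
ecosystem-service (ES) indicators on planar landscapes. A *farm* is the set
of agricultural parcels managed by one enterprise, linked to a register
record of standardised enterprise working hours and livestock head counts.
Each farm's *study area* is the union of its parcels dilated by 50 m — the
window in which most indicators are evaluated, so that adjacent land uses
and roads count toward the farm's landscape context.

Nine indicators are computed per farm (units in brackets):

| Indicator | Definition |
|---|---|
| LanVar | length of borders between different-class land-cover patches within the study area / study area [m/ha] |
| CrpDst | mean distance from cropland-interior grid points to the nearest non-cropland habitat, excluding water and densely built-up areas [m] |
| Gra | semi-natural grassland area, with grassland also present in the quality inventory weighed by a factor of two, / total agricultural area [–] |
| SSHab | small-scale habitats (field islets, cairns, ...) inside cropland / cropland area [1/ha] |
| CrpSeq | seven-year crop-sequence quality score, area-weighted over parcels [0–1] |
| RodVar | distinct patches inside the study area intercepted by / adjacent to roads / study area [1/ha] |
| Acc | z(share of study area within 100 m of roads) + z(population density within 10 km) [–] |
| Visit | z(unique photo-upload users per km²) + z(unique species-observation users per km²) [–] |
| NatRes | per-layer sum of protected-area overlap (nature reserves, Natura 2000, national-interest areas) / study area [0–3] |

All columns are z-scaled to zero mean and unit *population* SD (dividing by
n, a pure convention fixed for testability); the two composites are built
from z-scaled component terms first and then re-scaled with the rest.

### Crop-sequence score

The cited crop-sequence indicator takes succession order, minimum return
times and crop diversity into account; its exact internals are not public,
so the score here is a declared reconstruction from those ingredients:

    score = w_pair * mean_{t=2..7} S(c_{t-1}, c_t)
          + w_return * (compliant years among t=2..7) / 6
          + w_div * (distinct crops - 1) / 6

with defaults w = (0.5, 0.3, 0.2). `S` is a pairwise succession-quality
table in [0, 1] with S(ley, ley) = 1 (a continuing perennial stand) and low
values for cereal monoculture and tight oilseed/potato successions; a year
is return-time compliant when its crop has not occurred before in the
sequence or the gap since the previous occurrence is at least the crop's
minimum return time R (R(ley) = 0). The table and weights ship in config and
are fully overridable. The defaults are chosen so that diverse, ley-rich
sequences score high — enforced by a monotonicity test, not asserted ad hoc.

### Farm typology and selection

Farms below 400 standardised hours/year are small-scale. Otherwise a farm is
a specialist type when one activity exceeds two-thirds of hours (strictly —
an exact 2/3 share falls through), mixed cattle when the combined cattle
activities do, mixed livestock when all livestock activities do, else mixed
farming. Four filters remove farms before analysis: (i) no cropland, (ii)
no parcel geometry linked to the register record, (iii) pasture present but
no ruminants or horses reported, (iv) complete seven-year crop sequences
derivable for less than 50% of cropland area. Default LSU coefficients
(dairy cow 1.0, other cattle 0.6, sheep 0.1, horse 0.8, pig 0.3, poultry
0.014) are Eurostat-style values, config-overridable.

### Local reference comparison

To control regional confounding, each farm is compared with reference farms
within 20 km of its centre point (area-weighted centroid of its unbuffered
parcels — stable under buffer-tolerance changes):

    D = I - sum(i * a) / sum(a)

with I the focal farm's scaled indicator value and i, a the scaled values
and agricultural areas of the reference farms. A reference-type focal farm
is excluded from its own reference set. Because of the area weighting, mean
D deviates from zero even for the reference cluster; cluster-level
differences in mean D against the reference cluster are tested with Welch's
unequal-variances t test (alpha = 0.01, no multiple-testing correction by
default; Benjamini–Hochberg available by config) and sized with Cohen's d
using the Welch-mirrored standardiser sqrt((s1² + s2²)/2) with sample
variances. Effect categories use strict thresholds: |d| > 0.8 large, > 0.5
moderate, > 0.2 small, else negligible.

### Clustering

Both clustered variables are scalars, so k-means is solved exactly by
dynamic programming over contiguous partitions of the sorted values (the
1-D optimum is always contiguous). This reaches the global optimum of the
same within-cluster-sum-of-squares objective that iterative k-means targets,
deterministically. Livestock-density schemes take single-species farms of
one category (cattle, sheep, horses, pigs + poultry) plus all zero-LSU farms
as reference; k is increased from 4 until at least four clusters hold more
than 20 farms each, and smaller clusters are dropped from the scheme. Farm
size uses five clusters with the most populous (normally smallest-size)
cluster as reference; a warning is raised if the most populous cluster is
not the smallest one. Whether "four clusters with > 20 farms" means exactly
four retained or at least four is open; all qualifying clusters are
retained here.

### Redundancy screening

Pairwise Spearman rank correlations (average-rank ties, pairwise-complete)
feed a deterministic codification of the indicator-exclusion judgement:
strong pairs (r_s ≥ 0.5, p < 0.01) define a graph, and within each connected
component only the highest-priority indicator survives. The default
priority list puts LanVar first (broadest ES coverage), so when the
cropland-distance and roadside indicators track landscape variation they
are the ones dropped.

### Grid and land-use summaries

Regional summaries aggregate farm values on a 15 km grid anchored at the
landscape bounding-box lower-left (config-exposed): per cell and indicator
the agricultural-area-weighted mean of farm scaled values, plus counts of
indicators above the 80th / below the 20th percentile of cell values
(inclusive linear-interpolation quantiles, strict inequalities for the
counts). Visitor densities and protected-area shares are also reported per
agricultural land-use class.

## Synthetic landscape generator

The generator emulates the statistical structure the analysis assumes on a
square planar world: rectangular parcels jittered on a 400 m lattice, farms
spatially compact (anchor cell plus nearest free cells); a non-farm matrix
from a Voronoi partition of random seed points classed
forest/water/built-up/open; straight-line road segments to a target density;
a 1 km population raster with a radial urban gradient and lognormal noise;
Poisson visitor points with user identifiers from two sources; three
protected-area layers as random rectangles to target coverage; a grassland
quality inventory covering half of a random subset of grassland parcels;
and per-parcel seven-year crop sequences from a first-order Markov chain
whose ley affinity differs by farm type. Ruminant-type farms receive higher
ley affinity and more grassland parcels, monogastric types larger parcels,
so the qualitative contrasts the analysis targets exist by construction.
All stochastic draws flow from one seed through named sub-streams;
identical seeds give byte-identical bundles.

Default conditions: 500 farms on a 70 km x 70 km world (≈ 0.1 farms/km²,
the density of the study system the generator emulates), land-cover grain
0.3 matrix seeds/km², road density 500 m/km², visitor intensities 0.5
(photo) and 1.5 (species observation) points/km², protected coverages
3/4/8% for reserves/Natura 2000/national interest.

What the generator does *not* emulate: real geography and soils,
agricultural-support rules, the sampling biases of photo platforms and
species-observation portals (observer clustering near rare species), or
spatially correlated farm management. Passing tests therefore demonstrate
the correctness and calibration of the computational machinery under the
stated generative assumptions, not ecological conclusions about real
landscapes.

### Homogeneous (null) configuration

For type-I error calibration the generator offers a configuration in which
every farm-level distribution is identical across farm types, so the type
label is pure noise and every downstream comparison is null. Four details
matter: (a) livestock is drawn from one shared option list for all types;
(b) parcel geometry is near-constant, so farm size varies only through
parcel count and no indicator co-varies with size through parcel shape; (c)
no semi-natural grassland is generated by default, because the
pasture-without-ruminants selection filter would otherwise make grassland
type- and livestock-dependent among included farms (a real, not spurious,
difference); (d) the world extent scales with the farm count at 0.05 farms
per km², sparse enough relative to the 20 km reference radius that
neighbouring farms' reference sets overlap little. Overlapping reference
sets induce positive dependence between farms' D values — shared
reference-mean noise — which the Welch test does not model; at higher farm
densities this mildly inflates the realised test level (measured ≈ 1.4% at
0.1 farms/km², ≈ 2.5% at 0.4 farms/km², at the nominal 1%). This is a
property of the local-reference design itself, not of the implementation,
and would equally apply to real register data in farm-dense regions. At
the chosen density the realised fraction of significant cluster x
indicator comparisons is statistically compatible with alpha (50-seed
experiment in the acceptance suite).

### Planted effects

`apply_planted_effects` shifts one indicator for one farm group by a chosen
number of residual standard deviations (SD of the raw indicator over the
farms that pass selection). Mechanisms per indicator: Gra — a slice of one
cropland parcel is reclassified to semi-natural grassland, computed so the
farm's raw Gra shifts *exactly* by delta·SD while total agricultural area is
unchanged (side effect: cropland-normalised indicators of target farms move
slightly); SSHab — habitat points added inside cropland; Visit — points from
new unique users; NatRes — protected rectangles inside parcels; LanVar —
cropland mosaic patches split into strips of alternating class (approximate,
quantised by strip count). No downstream compensation is applied: Cohen's d
is scale-invariant, so the z-scaling step cancels, and the only systematic
attenuation is the reference-mean noise entering the D values (≈ 4% at the
experiment's ~20 effective references per 20 km disc). The recovery
experiment (two-type world, ≈ 400 included farms per group, planted delta
= 1.0 on Gra for sheep farms) recovers d in [0.8, 1.2] in ≥ 95% of seeds,
and |d| < 0.2 without the plant. Its world uses 0.028 farms/km² and
near-constant parcel counts: with 400-farm groups the group means average
over many farms, so both the reference-set dependence (width) and the
area-weight dispersion (attenuation through the effective reference count)
must be kept small for the d estimate to centre on the planted value. The
experiment evaluates the Gra column only, and layers that do not enter Gra
are generated at minimal intensity to keep many-seed runs cheap.

## Numerical choices

- Buffers use round joins/caps; arcs are split into segments subtending
  ≤ 10° (configurable via a chord-tolerance in metres), so buffered areas
  are slightly *under* the analytic dilation (inscribed polygon), within 1%
  on the closed-form square test.
- Borders between patches of the *same* class are not counted in LanVar
  (land-cover variation, not cadastral boundaries), and edges where the
  mosaic is clipped by the study window are not borders.
- CrpDst uses grid sampling (default pitch 25 m, offset half a pitch from
  the bounding-box corner) rather than exact medial-axis integration;
  halving the pitch changes fixture values by < 5% (tested).
- RodVar adjacency distance defaults to 5 m ("intercepted by / adjacent
  to" names no distance); config-exposed.
- The population term of Acc is the raster-cell area-weighted mean within
  the 10 km buffer.
- Gra is normalised by farm agricultural area; whether the source
  definition divides by area at all is ambiguous, so raw weighted hectares
  are recoverable (multiply by the farm attribute written alongside).
- Zero-variance columns z-scale to all zeros with a warning; undefined
  indicator values are carried as NaN and excluded pairwise.
- Welch/Cohen computations use sample (n−1) variances; z-scaling uses
  population SD.
- Exact 1-D k-means is O(k·n²) dynamic programming — ample for thousands
  of farms.

## Problem sizes

The bundled experiments use 500-farm worlds (null calibration, 50 seeds)
and ≈ 800-farm two-type worlds (recovery, 20 seeds); the end-to-end
determinism check runs 200 farms. These sizes give the Monte-Carlo
precision the calibration bands need while keeping a full test run on one
CPU in the tens of minutes; all sizes are parameters, and nothing in the
implementation depends on them.

## Known limitations

- The crop-sequence score is a reconstruction, not the published original;
  only its qualitative contract (ley-rich diverse sequences score high) is
  guaranteed.
- Statistical inference is exactly the study design's: Welch tests on
  local differences with no spatial-autocorrelation adjustment beyond the
  local-reference construction itself.
- The GAM analysis of landscape variation reported alongside the original
  assessment is out of scope (an off-the-shelf smoother fit); the
  indicator matrix and farm attributes this package writes are the inputs
  such a fit would need.
- Planted effects for LanVar are quantised (whole patch-splitting strips)
  and approximate; Gra planting is exact and is the mechanism the recovery
  experiment relies on.
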