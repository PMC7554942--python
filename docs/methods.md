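# Methods

## Data model and calibration

A sample is a dual-channel raster pair: an SHG channel in which the only
strong emitter in liver tissue is fibrillar collagen, and a TPEF channel
capturing tissue autofluorescence. Pixels are isotropic; the default
calibration is 200 µm / 512 px = 0.390625 µm/px, matching the acquisition
geometry of 512 × 512 px tiles covering 200 × 200 µm. Whole-section images
are row-major mosaics of abutting tiles (top-left origin, y downward); no
registration or blending is performed, because tiles from the instrument
are already aligned. Intensities may arrive as 8/16-bit integers or floats
and are processed as non-negative floats throughout; all physical
quantities are expressed in µm and µm² through the calibration, never in
pixels.

## Segmentation

**Tissue** is segmented on the TPEF channel: Gaussian smoothing
(σ = 2 px default) followed by Otsu's threshold, then filling of interior
background holes up to 500 µm² (biopsies contain vessel lumina and
processing artifacts that should not punch holes in the region geometry).
A constant positive channel is treated as saturated foreground, a constant
zero channel as empty.

**Collagen** is segmented on the SHG channel restricted to tissue pixels
(glass background would otherwise dominate the histogram): Otsu by default,
with `fixed` and `percentile` overrides in the configuration. Because Otsu
always produces a split even on a signal-free noise histogram, the split is
accepted only if the foreground mean exceeds the background mean by at
least 8 background standard deviations; pure noise separates by about 6,
genuine SHG signal by tens, so a signal-free channel yields an empty mask
rather than percolating speckle. Components smaller than 0.5 µm² are
removed. Collagen is clipped to tissue, and every connected-component
operation in the package uses 8-connectivity so diagonally continuous
fibers stay intact.

**Portal tracts** are taken from annotation masks (nonzero = inside,
dimensions must match the slide); this is the supported path, since
automated portal-tract detection is not part of the quantification
algorithm. An experimental heuristic (high-TPEF-density blobs ≥ 2000 µm²)
exists for convenience and is labelled as such.

## Region construction

The periportal region is every tissue pixel whose Euclidean distance to the
nearest portal-tract pixel lies in (0, m] with m = 100 µm by default
(`regions.periportal_margin_um`). Distances are exact Euclidean distance
transforms of the portal mask on the pixel grid, converted to µm; the
margin is measured from the tract boundary, not its centroid, and the
boundary is inclusive. Margins of nearby tracts merge by set union —
parameters are defined per region, not per tract, so overlapping margins
are counted once. The reduced perisinusoidal (RPS) region is
tissue − portal − periportal. The three regions are therefore pairwise
disjoint and tile the tissue exactly, which the `RegionSet` type validates.

For efficiency the distance transform is evaluated on the portal bounding
box padded by the margin; this is exact for every distance up to the
margin, which is all the construction uses. On a circular tract of radius
50 µm in ample tissue at default calibration, the constructed region's area
is within 0.1 % of the analytic annulus π((r+m)² − r²) and its maximal
radial width is 100 µm to within one pixel.

## Fiber morphometry

A *fiber string* is one 8-connected component of the collagen mask. The
definition deliberately does not split branched structures: a branched
component is one fiber, and its junctions are counted separately as
intersections. Per fiber:

* **area** = pixel count × (µm/px)²;
* **length** = arc length of the morphological skeleton, summing 1-px steps
  for orthogonal and √2-px steps for diagonal skeleton adjacencies; a
  single-pixel skeleton counts as one pixel of length (a declared floor, so
  width is always finite);
* **width** = area / length, the mean width along the skeleton.

Class thresholds are configuration, not constants of nature: long ≥ 20 µm,
thick ≥ 3 µm, aggregated ≥ 200 µm² (component area), all boundary-inclusive,
and the thresholds used are embedded in every output. The complementary
classes (short, thin, distributed) are exhaustive by construction. Fibers
are assigned to the region holding the majority of their pixels; exact ties
prefer periportal, then portal, then RPS — periportal is the region of
interest and a deterministic tie rule is required for reproducibility.

**Intersections** are skeleton branch points (skeleton pixels with ≥ 3
skeleton neighbours). Multi-pixel junction clusters closer than 1 µm are
merged by single linkage, and a merged intersection is counted for the
region containing its pixel-rounded centroid.

## The 56-parameter vector

For each region R ∈ {Periportal, RPS} and stratum S ∈ {all, Agg, Dis}:
`%R_S` (collagen area of stratum-S fibers as a percentage of R's area),
`#StrR_S`, `#ShortStrR_S`, `#LongStrR_S`, `#ThinStrR_S`, `#ThickStrR_S`,
`StrAreaR_S`, `StrLengthR_S`, `StrWidthR_S`, plus `#IntersectionR` — 28
names per region, periportal block first. "Total width" literally sums
per-fiber mean widths, matching the parameter descriptions. Legacy "PS"
spellings (e.g. `#ThickStrPS`) alias the corresponding RPS names, because
both spellings occur in published outputs of the same quantities.

Two interpretation choices were genuinely open and are declared here:

* `%R` normalises by the **region's area** (collagen-proportionate-area
  convention), not by whole-slide collagen;
* portal-region collagen contributes to **no** parameter — the schema
  covers only the periportal and RPS families.

Aggregation uses exact summation (`math.fsum`), so parameter vectors are
bitwise invariant to fiber ordering. A region with zero area but assigned
fibers yields 0 for its percentages with a logged warning (keeping cohort
tables rectangular) rather than NaN.

## Statistical screen

Group contrasts use the two-sided Wilcoxon rank-sum test. The reported
statistic is the rank-sum W of the first sample over pooled midranks.

* **Exact mode** (default for pooled n ≤ 16 without ties): the permutation
  null of W is enumerated — through the classic Mann–Whitney U counting
  recursion in the tie-free case, or full enumeration of label assignments
  when ties are present — and the two-sided p-value is
  min(1, 2·min(P(W ≤ w), P(W ≥ w))).
* **Approximate mode** (used at the clinical group sizes): normal
  approximation with midrank tie correction and a 0.5 continuity
  correction toward the mean. This matches the asymptotic two-sided
  Mann–Whitney p-value of standard references to nine digits, which a test
  verifies against an independent implementation.

Significance is strict p < α with α = 0.05; a p-value exactly at the
boundary is not significant. No multiple-testing correction is applied by
default — the screen deliberately mirrors the original per-parameter
analysis — and Benjamini–Hochberg adjustment is available behind a flag for
users who want it.

The two-stage screen (`screen_and_validate`) tests all 56 parameters on a
discovery contrast, re-tests only the significant ones on the true-F1 vs
true-F2 contrast, and retains those still significant. Applied to the
published validation p-values, the retention rule keeps 26 of 28
candidates, excluding the two parameters printed at p = 0.054.

## Synthetic data

The generator emulates, at desk scale, the features the algorithm depends
on: a calibrated elliptical tissue silhouette in a 1024 × 1024 px
(400 × 400 µm) field; circular portal tracts (radius 30–50 µm) rendered as
bright TPEF disks with thin collagen rims; and stage-dependent fiber
populations. Fiber counts per region are Poisson in the region's area at
the profile's rate (fibers per 10⁴ µm²); lengths and widths are log-normal
(medians 15 µm and 1.5 µm, log-SDs 0.5 and 0.35); a profile-specific
fraction of fibers draws from an up-scaled "bundle" distribution
(length × 2, width × 6) so the aggregated class is populated. Profile
defaults:

| profile | periportal rate | RPS rate | aggregate fraction |
|---------|----------------|----------|--------------------|
| F0like  | 0              | 0        | 0                  |
| F1like  | 0.5            | 3.0      | 0.10               |
| F2like  | 6.0            | 4.5      | 0.25               |

F1-like tissue carries a small nonzero periportal rate because portal
tracts physiologically always carry some collagen; a hard zero would make
every periportal parameter an all-tied constant under the null, so rank
tests on them would measure degeneracy rather than calibration. The factor
of twelve to the F2-like rate keeps the intended stage contrast.

Two pathways share this stochastic model. The *rendered* pathway paints
each fiber as a smoothed random-walk polyline stroked to its width
(aggregated fibers with overlapping side strokes), enforces a 2-px
separation between distinct fibers so components map one-to-one to
ground-truth fibers, and adds Gaussian noise (SD 6 on a 0–255-like scale)
to both channels. The *truth* pathway skips pixel rendering and aggregates
the sampled fiber measurements directly through the same parameter code —
roughly 40 ms per sample, which is what makes replicated cohort simulations
affordable. All randomness flows from one seed; cohort members use
per-sample sub-seeds derived from the master seed.

What the generator does **not** model: photon physics (no point-spread
function, polarization, depth attenuation), fibrotic septa, central veins,
zonal architecture, staining variation, or fiber crossing/branching
(intersection counts in truth bookkeeping are an independent small-Poisson
placeholder). Passing recovery tests therefore demonstrates the geometric
and combinatorial correctness of the pipeline, not clinical segmentation
performance on real tissue.

## Simulation studies and their sizes

* **Recovery.** On noise-free rendered fixtures the full pipeline
  (segment → regions → fibers → parameters) recovers ground-truth fiber
  counts exactly and region masks at Jaccard ≥ 0.98 (in practice 1.0).
* **Power.** F1-like vs F2-like cohorts at n = 15/group, 100 replicate
  cohorts via the truth pathway: every periportal count parameter is
  significant in well over 80 % of replicates.
* **Type-I error.** Null cohorts (two F1-like groups, n = 15/group). The 56
  parameters within one cohort are correlated — they derive from the same
  30 samples — so the flagged fraction is averaged over 150 independent
  cohorts (8400 parameter tests). The measured per-test level is ≈ 0.04:
  slightly conservative, as expected from the continuity correction and
  from near-degenerate low-count parameters (aggregated-stratum counts with
  Poisson means ≪ 1 under F1-like conditions are heavily tied, and rank
  tests on them rarely reject).

## Numerical and degenerate-input conventions

* Boundary inclusivity everywhere a threshold appears: margin distance
  ≤ m; long/thick/aggregated at ≥; significance strictly <.
* Empty portal mask → empty periportal region; empty tissue is an error.
* Empty collagen mask → zero fibers → an all-zero parameter vector.
* Constant channels: constant positive = all foreground, all zero = empty.
* Otsu acceptance guard on SHG (8 background SDs) as described above.
* CSV parameter tables round-trip through the shortest-repr float format,
  preserving values to better than 1e-12 relative.

## Known limitations

* Fiber extraction treats each connected component as one fiber; touching
  fibers merge, so the fiber-count parameters depend on segmentation
  contiguity. The synthetic generator side-steps this by construction; real
  tissue does not.
* The class thresholds (20 µm / 3 µm / 200 µm²) are package defaults chosen
  to be morphometrically reasonable, not values with published provenance;
  any cross-study comparison must fix them explicitly, which is why they
  are echoed into every output.
* The heuristic portal detector is a convenience, not a validated
  replacement for annotation.
* The statistical screen reproduces a per-parameter analysis without
  multiplicity control; the optional Benjamini–Hochberg flag changes which
  parameters a panel retains and is off by default only for fidelity to the
  original procedure.
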