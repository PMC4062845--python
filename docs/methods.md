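# Methods

## Shell geometry

A segmented nucleus is divided into `k` concentric shells, shell 1
innermost.  Two analytic schemes are provided.

*Equal area*: every shell covers `1/k` of the projected nucleus area; on an
ideal disk of radius `R` the shell boundaries lie at `r_i = R·sqrt(i/k)`.

*Equal volume*: the nucleus is modelled as a sphere seen in projection.
Spherical shells of equal volume have boundary radii `r_i = R·(i/k)^(1/3)`,
so the projected area fraction of shell `i` is
`f_i = (i^(2/3) − (i−1)^(2/3)) / k^(2/3)` — for `k = 5`: 34.20, 20.09,
16.85, 15.04, 13.82 percent.  The motivation is that equal projected areas
bias spherical volume outward: the outermost of five equal-area shells
holds `1 − (4/5)^(3/2) = 28.45%` of the volume instead of 20%.

The integer proportions 34:20:17:16:13 used in earlier shell-erosion
software differ from the analytic values in shells 4–5 (16 vs 15.0 and 13
vs 13.8; likewise 29% is sometimes quoted where the closed form gives
28.45%).  The difference is consistent with rounding or pixel-grid
discretisation in that implementation, but we do not assert its origin.
The analytic closed form is the package default; `preset="paper_1"`
reproduces the 34:20:17:16:13 partition exactly for faithful replication.
Both sum to 1 and are strictly decreasing, as the scheme type enforces.

## Segmentation

Nuclei: Gaussian smoothing (default σ = 2 px in 2D; 1 px in 3D, scaled by
`pixel_size/z_step` along z so smoothing is isotropic in μm), global Otsu
threshold, hole filling, connected-component labelling.  Quality control
removes border-touching nuclei (a truncated nucleus has no meaningful
radial coordinate) and nuclei outside physical size bounds (defaults
20–1500 μm² / μm³).  Territories: the probe channel is smoothed and
thresholded *within* the nucleus (Otsu on within-nucleus intensities, or a
configurable multiple of the within-nucleus mean); components below 30 px
(2D) / 100 voxels (3D) are discarded and regions are clipped to the
nucleus.  No algorithm for the original nucleus segmentation is on record;
these defaults are ordinary FISH practice and are config keys, not claims
about any earlier analysis.  Coordinates are 0-based, a pixel/voxel is a
unit box, centroids sit at pixel centres, and all reported geometry is in
μm, honouring anisotropic voxels (e.g. 0.3-μm optical sections).

## Shell partitioning

Classic shell erosion peels binary erosions, which cannot hit arbitrary
area fractions on arbitrary shapes.  The default partition instead ranks
nucleus pixels by Euclidean distance to the nearest outside pixel
(deepest first, ties broken by scan order) and cuts the ranking at the
target cumulative counts `round(f_i·A)`, the outermost shell absorbing the
rounding remainder.  This is deterministic, shape-respecting (shell 1
contains the distance-transform maximum; shell `k` the boundary layer) and
exact to integer rounding.  `method="erosion"` substitutes the city-block
distance transform, which reproduces one-layer-per-iteration erosion
ordering.

A note on exactness: because cuts fall at exact pixel counts, a cut can
land inside a class of equidistant pixels; which members go to the inner
shell then depends on scan order, so per-shell intensity sums are
rotation-equivariant only up to those tie pixels (exact on radially
symmetric fixtures, pixel-level — observed ≲ 0.05 on `n` — otherwise).
The alternative (cutting only between distance classes) would make
achieved fractions miss their targets by entire tie classes, which is the
larger error; we keep exact counts.

## Quantification and normalization

Background correction uses the mean pixel intensity within the segmented
nucleus.  Which arithmetic the historical description intends is
ambiguous, so all readings are implemented and recorded in output
metadata: `subtract_mean` (default; subtract and clip at 0),
`threshold_mean` (zero sub-mean pixels), `divide_mean`, `none`.  The probe
channel is corrected; DAPI is used raw.

Per shell, `p_x` and `d_x` are the percentages of total within-nucleus
probe and DAPI signal (intensity-weighted by default; a `binary`
pixel-count mode is provided since "number of pixels" is the other natural
reading).  The normalized value is `n_x = (p_x/d_x)/(Σp/Σd)`.  Two
identities are asserted on every synthetic run: `Σp = Σd = 100` and the
conservation `Σ_x d_x·n_x = 100`.  A shell with DAPI but no probe gives
`n_x = 0`; a shell with probe but zero DAPI aborts the nucleus (never
silently imputed); zero total signal excludes the nucleus with a log
entry.

## Population statistics and position calls

Profiles are per-shell means with SEM = sd(ddof=1)/√n across nuclei.
Conditions are compared per shell with two-tailed Welch t-tests (the
unequal-variance form, since population variances differ between
placements), one-way ANOVA as the omnibus test for >2 groups, and no
multiple-testing correction by default (Holm optional; the ordered-series
template defaults to Holm for its onset scan, since it searches across
shells and conditions).

The interior/intermediate/peripheral call uses the signal-weighted mean
shell index `m = Σ i·n_i / Σ n_i`.  No numeric rule for the categorical
call is on record; this statistic and its thresholds are this package's
operationalization and are stamped into every output.  Defaults for k = 5:
interior m ≤ 2.6, peripheral m ≥ 3.4, symmetric about the uniform-profile
value 3; for other k the half-width scales as `0.4·(k−1)/4`.  Both entry
points exist: classify the population profile, or classify each nucleus
and tally frequencies (compared across conditions by chi-square
homogeneity, with a low-expected-count warning below 5).

## 3D measurements

Geometric centres are unweighted centroids of member voxel centres in μm
("geometric" is read as mask-based; an intensity-weighted variant sits
behind a keyword).  Distances are Euclidean in μm.  Pairwise analysis
takes all A×B centroid distances within each nucleus, pools across nuclei,
and summarises as min/Q1/median/Q3/max with quartiles by linear
interpolation (the min/max playing the box plot's whiskers).  Distance
histograms use half-open bins of width 1.0 μm by default.  Volumes are
voxel count × voxel volume.  `radial_fraction` inverts the generator's
placement coordinate: centroid offset divided by the centre-to-boundary
distance along the same ray (quarter-voxel ray marching).

## Synthetic data

The generator emulates what the analysis assumes about FISH microscopy,
not the optics of a particular instrument:

- **Nucleus**: ellipse (2D, 7 × 5 μm semi-axes at 0.3 μm/px — a flattened
  fibroblast nucleus) or ellipsoid (3D, 5 × 4 × 1.35 μm in 16-plane
  0.3-μm stacks, ≈ 9 informative sections), with per-nucleus log-normal
  semi-axis jitter (sd 0.08) and uniform orientation.
- **DAPI**: base 100 with a mild radial gradient `base·(1 + g·(1 −
  r_norm))`, g = 0.3 (heterochromatin-like central brightening), plus
  smoothed texture (sd 5).
- **Territories**: Gaussian blobs (σ 1.0 μm; 0.5 μm along z) clipped to
  the nucleus.  Placement is the radial fraction ρ — centroid offset over
  boundary intercept along the offset direction — which transfers
  unchanged between circles, ellipses and ellipsoids.  Population presets
  draw ρ from Beta distributions: interior (3,7) (mean 0.3), intermediate
  (5,5), peripheral (8,2) (mean 0.8); ρ is capped at 0.95 so centres stay
  strictly interior.
- **3D directions** concentrate about the equatorial plane (polar angle
  N(π/2, 0.35 rad)): in flattened adherent nuclei territories lie mostly
  in-plane, and uniform-sphere draws would make radial placement nearly
  unresolvable along the short axis.
- **Paired territories**: `CTSpec.follow` correlates a follower's azimuth
  with its partner's (Gaussian jitter, default sd 0.5 rad), modelling the
  conserved relative arrangement of neighbouring territories.  This is
  what makes radial relocation change pairwise distances: with fully
  independent directions, moving one territory outward *increases* the
  expected separation (E|x−y|² = r_A² + r_B²), so a pairwise-distance
  readout of relocation presupposes angular correlation.  The correlation
  is azimuthal only; the polar angle keeps its flat-nucleus draw.
- **Optics/noise**: Gaussian PSF (σ 0.25 μm xy, 0.3 μm z), then Poisson
  (scale 1.0) and Gaussian readout noise (sd 2, i.e. 2% of DAPI base) —
  gentle enough that Otsu segmentation is reliable; stress settings are
  plain parameter overrides.
- **Determinism**: nucleus `i` of a population uses substream `(seed, i)`;
  identical config + seed reproduce images and manifests bit-for-bit.

What the generator does **not** emulate: realistic chromatin texture,
diffraction PSF shapes (Gibson–Lanni), chromatic shift, touching or
overlapping nuclei, mitotic figures, hybridisation artefacts.  Passing
tests therefore demonstrate that the measurement chain is correct and
well-calibrated under the stated model, not that segmentation or
classification is robust to every pathology of real microscopy.

## Problem sizes and numerical choices

Test-suite simulations use per-nucleus fields of 80 × 80 px (2D) and
16 × 64 × 64 voxels (3D) — small enough to run populations cheaply, large
enough that shell rounding error is negligible (a ~1200-px nucleus gives
achieved-vs-target fraction errors below 0.1%).  Population checks use the
study-scale conditions: 100 nuclei per condition for classification and
inference (100 replicate populations for parameter recovery, 200 for
type-I calibration, 30 for the reversal pattern), 50 nuclei per condition
for 3D pairwise distances, and 30 replicates × 25 nuclei for the 3D
control-vs-recovered indistinguishability property.  Degenerate inputs
fail loudly: masks smaller than `k`, empty masks, zero-signal nuclei and
all-zero profiles raise typed errors rather than returning imputed values;
single-shell configurations produce profiles but refuse classification.

## Known limitations

- The equal-volume correction assumes a spherical nucleus; no
  ellipsoid-specific or aspect-ratio-dependent fraction tables.
- Shell analysis is 2D-only; 3D analysis is centroid/distance/volume.
- No deconvolution, watershed splitting of touching nuclei, or
  chromatic-shift registration.
- Category thresholds (2.6/3.4) are a convention of this package;
  downstream comparisons should treat the continuous `m` as primary.
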