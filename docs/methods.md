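# Methods

This note documents the measurement models implemented in `periscope`, the
synthetic data they are validated against, and the numerical choices made
where the underlying procedures are usually left to interactive software.

## Coordinate and distance conventions

Volumes are indexed `[z, y, x]`; voxel sizes are `(dx, dy, dz)` in μm
(default `(0.1, 0.1, 0.05)`, i.e. ~0.1 μm lateral sampling and a 0.05 μm
z-step); the physical origin is the volume corner and a voxel's coordinate
is its centre. All public interfaces use physical units (μm for images, nm
for localizations), never voxel indices.

The central quantity is the signed distance *d* from a point to the **inner
edge of the nuclear lamina**, positive toward the nuclear interior. The
lamina shell itself and everything outside it have *d* ≤ 0: a FISH signal
embedded in the lamina layer legitimately measures a negative distance. A
spot is classified *peripheral* when *d* ≤ *T*, with equality counting as
peripheral; *T* is the thickness of the peripheral heterochromatin layer,
defined as the distance from the H3K9me2 band's inner edge to the lamina
inner edge.

## Segmentation

* **Nucleus** (DNA counterstain): Gaussian smoothing (σ = 1 voxel per axis,
  configurable), Otsu threshold, largest connected component, holes filled.
  For a solid object whose rim is a step edge, a symmetric PSF moves no
  intensity across the half-maximum contour, so Otsu's between-class split
  (which lands near half-maximum on a bimodal histogram) localises the
  boundary essentially without bias.
* **Lamina** (lamin immunofluorescence) and **H3K9me2 band**: the same
  smoothing, but the default threshold is *half-peak* — background (median)
  plus half of the robust peak-to-background range (99.9th percentile). The
  lamina is a sheet near the resolution limit; for such structures Otsu's
  split systematically over-extends the mask on both faces (measured on
  synthetic ground truth: inner edge displaced ~0.06 μm into the interior
  with Otsu vs ~0.02 μm with half-peak). Both methods are selectable per
  channel (`threshold.method`).
* The segmented lamina must be a **closed shell**: the enclosed interior is
  the set of non-shell components that do not reach the volume border, and
  an open shell is a hard error. The **inner edge** is the 6-connected set
  of shell voxels facing the enclosed interior.
* The **signed distance field** is the exact Euclidean distance transform
  (anisotropic physical sampling) to the inner-edge voxel centres, negated
  on the shell and outside. It is zero exactly on the inner-edge voxels and
  matches an exhaustive nearest-inner-edge-voxel search (tested). Spot
  distances are trilinear interpolations of this field at the spot centre —
  the distance is evaluated at the centre point, not averaged over the
  250 nm spot sphere.
* **Layer thickness** *T* is the median signed distance of the H3K9me2
  band's interior-facing boundary voxels (median over edge rays; robust to
  local gaps in the band). A band whose measured inner edge does not lie at
  positive distance (e.g. a "band" identical to the lamina) is an error, and
  callers may fall back to a configured *T* (default 0.4 μm, a stand-in the
  user should override or measure — the layer thickness is cell-type
  specific).

Using the *measured* T for classification is deliberate: both the spot
distance *d* and *T* are read from the same voxelized distance field, so the
residual half-voxel placement offsets of the discretised inner edge cancel
to first order in *d − T*, which is what the classification depends on. With
a configured T that cancellation is lost and classifications near the
boundary inherit the full discretisation offset (~half a voxel).

## Spot detection

Difference-of-Gaussians band-pass matched to the expected diameter
(σ = diameter/4 and 3× that), robust threshold at median + 6·MAD·1.4826 of
the filtered values inside the (dilated) nucleus, greedy non-maximum
suppression at the expected diameter (250 nm default), then refinement to
the intensity-weighted centroid within a sphere of the expected diameter
(local median subtracted so the centroid reflects the spot, not the
background plateau). On synthetic SNR-10 data this gives recall ≥ 0.99 and
~0.02 μm mean localization error. Spots falling more than 2 μm outside the
nuclear edge are discarded with a warning (hybridization artifacts).

## Peripheral signal fractions

`fraction = Σ signal over (periphery mask ∩ nucleus) / Σ signal over
nucleus`, where the periphery mask is `{signed distance ≤ T}` within the
nucleus (lamina voxels included, consistent with the d ≤ T rule). Background
is the modal (median) intensity outside the nucleus and is removed **at the
sum level** (`Σ − bg·n_voxels`, sums clipped at zero). Subtracting per voxel
and clipping at zero would rectify zero-mean noise and inflate the fraction
of dim compartments — on synthetic SNR-10 cells that bias reached +0.05 at a
true peripheral share of 0.2, while sum-level subtraction is unbiased. Raw
(unsubtracted) mode is available (`background_subtract=False`) since
published fraction measurements do not always state which was used.

Per-condition normalisation divides each cell's fraction by the mean
fraction of a reference condition (reference mean ≡ 1.0). Line profiles are
trilinear interpolations at evenly spaced points along a segment.

## Voronoi cluster analysis of localizations

The analysis is strictly 2D (lateral x, y in nm). Voronoi cells are clipped
to the acquisition rectangle by **mirroring** the points across the four
region edges before the Voronoi construction: each original point's cell is
then finite and exactly equals its clipped cell, so the areas partition the
region (Σ areas = A to machine precision — verified to 1e-15 relative).
Cells touching the boundary are flagged so users can exclude them; points
lying exactly on the boundary are pulled inside by 1e-9 of the region extent
(a boundary point would mirror onto itself). Exact duplicate coordinates are
perturbed by 1e-6 nm with a logged note.

The uniform null is a Monte-Carlo CSR simulation: `reps` (default 100)
independent uniform draws of the same n, pooled clipped-Voronoi areas. The
partition identity forces the reference mean to δ = A/n exactly, so the
first threshold ρ₁ = δ is definitional; the Monte-Carlo sample contributes
only the distributional shape.

Subsequent thresholds: restrict both the observed and the reference areas
below the previous threshold (conditioning the reference rather than
re-simulating at reduced n — the two readings of "after applying this
threshold" are both defensible; conditioning is implemented and flagged
here), then locate the crossing of Gaussian KDEs of log-area (Scott
bandwidth, 512-point grid), scanning from small areas for the first point
where the observed density falls below the reference. Two guards make the
iteration terminate cleanly on uniform data, where the two densities
coincide and a bare crossing scan would fire on noise: a two-sample KS test
between the restricted observed and reference areas must reject at
p < 0.01, and the observed density must exceed the reference by ≥ 10%
somewhere before the crossing. If either fails at level 2 the result carries
a `uniform_flag`. Defaults: `max_levels = 4`, minimum surviving count 50.

A localization is at level k when its area < ρ_k (levels are nested since
thresholds are non-increasing); clusters at each level are connected
components over Delaunay-triangulation edges whose both endpoints are at
that level. Peripheral-band enrichment compares the fraction of high-density
localizations inside a band (annulus or arbitrary geometry, intersected with
the region) against the band's share of the region area; with no
high-density localizations the ratio is undefined and flagged rather than
invented.

## Statistics

Two groups: two-tailed Mann-Whitney U; the exact permutation null is used
when the smaller sample has ≤ 10 observations and the pooled data is
tie-free (the exact and asymptotic p differ by < 0.01 from that size on),
otherwise the normal approximation with tie and continuity corrections. The
method actually used is recorded in the result. Three or more groups:
Kruskal-Wallis H with tie correction, then Dunn's z on pooled mid-ranks with
Bonferroni adjustment over the reported contrasts, contrasts against a
designated reference condition listed first. Parametric counterparts
(Welch's t; one-way ANOVA with pairwise Welch contrasts) sit behind the same
interface because figure legends in this literature often name the
parametric test while the methods section names the nonparametric one; the
nonparametric variants are the default and the choice is recorded, not
silently resolved. Box summaries report the 5/25/50/75/95 percentiles
(linear interpolation between order statistics), mean, and sample SD (n−1).
Significance stars follow the usual convention (\*\*\*\* p < 10⁻⁴); raw p is
always emitted.

## Synthetic data generator

The generator produces the statistical structure the analysis assumes, with
exact ground truth:

* **Geometry**: an axis-aligned ellipsoid nucleus (`semi_axes`, default
  (2.2, 1.8, 1.4) μm — compact relative to real nuclei to keep volumes
  small; all measurements are resolution-limited, not size-limited). The
  ellipsoid surface is the outer nuclear boundary; the lamina shell extends
  0.25 μm inward (the apparent width of a lamin-B immunofluorescence ring in
  deconvolved confocal data); the H3K9me2 band occupies the next `T` (default
  0.4 μm) inward of the shell's inner edge. Real nuclei are irregular; the
  ellipsoid is chosen so ground-truth distances are analytic.
* **Ground-truth distances** come from the exact implicit surface: the
  nearest-point condition on the ellipsoid is solved by vectorised bisection
  on the Lagrange parameter, and since a Euclidean distance field has unit
  gradient, the distance to the offset inner edge is the ellipsoid distance
  minus the shell thickness — exact, and fully independent of the voxel
  segmentation it validates.
* **Spots**: each spot first draws its class (peripheral with probability
  `f_lad_peripheral` / `f_nonlad_peripheral`), then positions are sampled
  (surface point plus normal offset; signed distance uniform in
  [−shell, T] for peripheral, (T, centre depth] for interior) and re-sampled
  until the exact recomputed distance confirms the class — the ground-truth
  flag ⇔ (d ≤ T) equivalence is exact by construction and the empirical
  peripheral fraction is an unbiased binomial. A minimum pairwise separation
  (default 0.3 μm) keeps spots resolvable; impossible packings fail
  explicitly after a retry limit. Interior positions deeper than the local
  radius of curvature keep their exact recomputed distance, so the interior
  depth distribution is only approximately uniform at extreme depths.
* **Optics and noise**: all channels are blurred with an anisotropic
  Gaussian PSF, default σ = (0.08, 0.08, 0.12) μm, emulating *deconvolved*
  high-NA confocal stacks (the pipeline ingests pre-deconvolved data;
  deconvolution itself is out of scope). Noise is Poisson shot noise on
  (background + signal) photons plus Gaussian read noise; SNR is defined as
  peak spot amplitude over the background standard deviation
  (√(background + read σ²), with background 20 photons and read σ = 3).
  `snr=None` renders noiseless channels for oracle tests.
* **Peripheral-share channel**: when `signal_share_peripheral = s` is set,
  an extra channel mixes the blurred band and interior templates with an
  amplitude solved so that the noiseless rendered peripheral share equals
  `s` exactly — making `s` a true ground truth for fraction recovery rather
  than a nominal one.
* **STORM tables**: uniform background over the region (the CSR null),
  isotropic Gaussian clusters (σ = radius/2, truncated to the region), an
  optional uniform annulus band, and localization-precision jitter; every
  row carries its ground-truth component label.

What the generator does **not** emulate — and hence what passing tests do
not certify about real data: irregular nuclear shapes and invaginations,
chromatin texture inside the nucleus, chromatic shift between channels,
spot-intensity heterogeneity and hybridization failures, mitotic
configurations, multi-nucleus fields, and STORM drift or repeated-blinking
artifacts. The recovery results bound algorithmic error under the stated
optics, not biological or sample-preparation variability.

## Validation summary (what the tests compute)

Unit and acceptance tests check, among others: the partition identity and
ρ₁ = A/n on random configurations (to 1e-9 relative); clipped Voronoi areas
against an independent half-plane-intersection construction (1e-6
relative); the signed distance field against exhaustive nearest-voxel
search; recovery of generated peripheral-signal shares 0.2/0.5/0.8 within
±0.05 at SNR 10 (20 cells each); recovery of generating peripheral
probabilities 0.8/0.1 within ±5 percentage points on a 20-cell cohort with
spot recall ≥ 0.95; Mann-Whitney p equal to exhaustive enumeration on
tie-free samples up to n = 6; Kruskal-Wallis type-I error within
[0.03, 0.07] at α = 0.05 over 1000 null simulations; and bit-identical
re-runs of both workflows under a fixed config and seed. Problem sizes
(20-cell cohorts, ~40 spots per channel, 1000–5000 localizations) were
chosen as the smallest at which the binomial/Monte-Carlo noise floors sit
comfortably below the tolerances being checked.

## Known limitations

* Sub-resolution sheet thicknesses are not recoverable by threshold
  segmentation; the measured T carries a small negative bias (~0.04 μm at
  the default optics) that cancels in the d ≤ T classification but not in T
  itself.
* The distance field is defined to inner-edge voxel centres (required for
  the exhaustive-search equivalence), so point distances carry a voxel-scale
  quantization floor; per-spot errors are bounded by the voxel diagonal.
* The multiscale threshold iteration conditions the reference below the
  previous threshold rather than re-simulating with reduced n; with very
  heavy clustering beyond ~4 levels the conditioned reference thins out and
  iteration stops on the minimum-count guard.
* Percent-peripheral summaries weight cells equally (cohort mean of
  per-cell percentages); pooling spots instead would weight cells by spot
  count and can differ when counts vary strongly.
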