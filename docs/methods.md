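# Methods

`pfl` quantifies *pore-free islands* — nuclear-envelope (NE) subdomains
devoid of mature nuclear pore complexes (NPCs) — and the single-nucleoporin
foci (candidate NPC assembly intermediates) that appear inside them, from
two-channel immunofluorescence images of the NE bottom surface.  This note
describes the models, the numerical choices, and what the synthetic
validation does and does not show.

## Image model and inputs

Each sample is one cell: a pan-NPC channel (an mAb414-like stain whose
diffraction-limited puncta carpet the pore-rich regions), a single-Nup
counterstain channel (sparse puncta), and a binary nucleus-ROI mask.  The
ROI mask replaces interactive outlining of the nucleus; in practice an
annotator traces just inside the blurred nuclear rim, and the synthetic
generator emulates exactly that (see below).  Pixel size is a required
input with no default — published values for this imaging regime vary with
camera binning, and all areas and densities depend on it quadratically.

## Island recognition

1. **Per-pixel texture features.** Over a sliding odd window (config
   `feature_window`), three image moments are computed: the mean
   (brightness), the population variance (contrast), and the
   intensity-normalized second-order central spatial moment around the
   intensity-weighted window centroid, summarized as the trace
   mu'20 + mu'02 (intensity spread, px^2).  The trace is used because it is
   rotation invariant; windows with zero total intensity get spread 0.
   Windows that do not fit inside the ROI are excluded (`valid_mask`)
   rather than padded, to avoid fabricating intensities at the nuclear rim.
   Features are z-scored over valid pixels before clustering — the three
   features carry incommensurate units and K-means is scale sensitive.

   The window must span at least the mean NPC spacing (~0.6 um at mature
   densities): below that scale, windows centred between puncta are
   indistinguishable from island interiors and no clustering can separate
   them.  At the bundled generator's 0.129 um/px sampling this means a
   5 px window (0.65 um); the default of 3 px is appropriate for coarser
   (more heavily binned) acquisitions.

2. **K-means with an automatic cluster number.** K-means (k-means++ init,
   best of `kmeans_restarts` restarts, fixed seed) is run for every k in
   `k_range` (default 2..20).  At each k the cluster whose pixels have the
   lowest mean pan-NPC intensity is the island-bearing class (ties go to
   the smaller label id).  The within-class variation (WCV) of each
   standardized feature over that class is recorded; each feature's WCV
   sequence is min-max normalized across k, and the total WCV is the
   unweighted mean of the three (the combination weights are a design
   choice — nothing in the method constrains them, and equal weights keep
   the rule parameter-free).  The selected k is the first strict local
   minimum of total WCV: the smallest k where the successive difference
   Diff(k) = WCV(k+1) − WCV(k) changes sign from minus to plus.  Zero
   differences continue the preceding sign, so a plateau minimum selects
   the plateau's smallest k.  A monotone trace has no such point; the rule
   then falls back to the argmin and flags the sample (FALLBACK in the
   log).

3. **Mask extraction.** Island-class pixels are cleaned by 3x3 binary
   closing, hole filling, and a 3x3 opening, then split into 8-connected
   components; components smaller than `min_island_area` (default 2 um^2,
   the minute-island threshold) or touching the ROI rim are dropped.  The
   closing consolidates the pixel-noisy K-means label map, hole filling
   removes pinholes at bright interior foci, and the opening cuts the
   1-2 px bridges that closing otherwise builds between islands, label
   speckles and the rim — without it, genuine islands are regularly welded
   to the rim band and discarded by the rim rule.  Dropping rim-touching
   components reflects the definition of an island as a region *surrounded*
   by pore-rich NE.  Island boundaries are island pixels 4-adjacent to a
   non-island pixel.

## Focus detection

The counterstain image is rescaled to unit range over the evaluation
region and treated as a surface z = I(x, y); the mean curvature

    H = [(1 + Iy^2) Ixx − 2 Ix Iy Ixy + (1 + Ix^2) Iyy]
        / [2 (1 + Ix^2 + Iy^2)^(3/2)]

is evaluated with Gaussian smoothing at scale `curvature_sigma` (default
0.8 px) followed by central differences.  Two numerical choices matter
here.  First, the unit-range rescale: the surface model mixes intensity
and pixel units, and with raw camera counts the slope terms crush the
response at bright peaks; rescaling keeps the operator in the small-slope
regime and makes detection exactly invariant to affine intensity changes
a*I + b (a > 0).  Second, the derivative scheme: direct sampled
Gaussian-derivative kernels at small sigma showed ~10% curvature bias on a
spherical test surface, while smoothing + central differences is accurate
to <1% (both closed forms — the paraboloid critical point and the
hemisphere — are regression-tested).

Intensity peaks have H < 0, so −H is linearly regulated to 8 bits (min -> 0,
max -> 255, round half-up) over the evaluation region: the union of the
recognized islands in the standard mode, or the whole nucleus ROI in the
density-validation mode.  Restricting both the regulation and the Otsu
histogram to the evaluation region keeps the background from dominating
the threshold.  Otsu's threshold maximizes the between-class variance over
the 256-bin histogram (ties to the smallest threshold); foreground
components (8-connected) within [`min_focus_area`, `max_focus_area`]
(default [2, 100] px) become foci, with intensity-weighted centroids,
island assignment by centroid containment, and peak intensity recorded.
Touching foci are *not* split — a merged pair counts once.  This is the
method's main recall limit and is shared by the original procedure; at the
synthetic defaults ~95% of residual misses are pairs closer than ~0.45 um.

The whole-ROI mode reproduces the NPC-density validation: counting pan-NPC
foci over the nucleus and dividing by ROI area recovers the generator's
mature-NPC density (2.6 foci/um^2 scale) to within a few percent, and
densities 1-4 foci/um^2 within 10%.

## Quantifications

* **Island size** — area in px and um^2 (area_px * pixel_size^2).
* **Appearance frequency** — foci per um^2 of island, exactly
  n_foci / area_um2.
* **Boundary-distance profiles** — the exact Euclidean distance transform
  of each island against its complement gives every island pixel its
  distance to the pore-free/pore-rich boundary (rim pixels are at 1 px,
  not 0; distances are positive inside and undefined outside).  Foci are
  binned by the field value at their centroid's containing pixel into
  half-open unit bins (lo, hi]; per-bin counts divided by per-bin pixel
  counts give a per-island frequency.  Condition-level profiles average
  per-island frequencies bin-wise — an island contributes only to bins its
  own depth reaches — and are normalized to sum 1.0.

## Spatial-randomness null

For each observed island, the same number of foci as detected is dropped
uniformly (with replacement — observed counts are small relative to island
areas, so pixel collisions are immaterial) over the island's pixels;
distances are binned identically and averaged over `sim_reps` repetitions
(default 33,029 per island, kept as the reference procedure's constant;
its provenance is opaque and results are insensitive to it beyond ~10^3).
Coordinates come from the Mersenne Twister (MT19937), each island seeded
as `sim_seed + island_index`, so per-island results are independently
reproducible and parallelizable without changing output.  The simulated
per-island mean counts go through the identical frequency/aggregation
path as the observed counts.

## Statistics

All comparisons use the Brunner-Munzel test: a rank-based two-sample test
of the stochastic superiority p_hat = P(X < Y) + 0.5 P(X = Y), robust to
unequal variances and ties, with Satterthwaite degrees of freedom and a t
reference distribution.  It is implemented from the midrank formulas
(scipy's version does not expose p_hat or the df) and cross-checked
against both an exhaustive pair-counting oracle and
`scipy.stats.brunnermunzel` in the tests.  Completely separated samples
(zero rank variance but different means) get the exact two-sided
permutation floor 2/C(n, n_x) instead of the undefined t statistic; fully
tied samples are an error.  Significance labels follow the ladder
***P < 0.001, **P < 0.01, *P < 0.05, N.S. otherwise.  No multiplicity
correction is applied by default, matching per-panel reporting.

* **Condition comparisons** (island size, appearance frequency): one value
  per island, tested between inhibitor groups within each antibody x
  treatment-time stratum; tables carry medians, quartiles (25/75%) and
  5/95% whiskers.
* **Observed vs simulated profiles**: the aggregated profile is split into
  proximal and distal regions at `proximal_fraction` (default 0.5 — the
  reference analysis shows the split only graphically, so the cutoff is a
  declared assumption) of the maximum distance, i.e. the first
  floor(fraction * n_bins) bins (at least one).  Each island contributes
  its share of foci in the region (observed counts vs CSR mean counts) and
  the two per-island samples are compared.  Because the two regional
  shares are complementary, the proximal and distal tests are mirror
  images (equal p, opposite sign); islands with zero foci are excluded.

## Quality control

Automated flags replace visual accept/reject: SATURATED (fraction of
in-ROI pixels at the dtype maximum above `saturation_fraction_limit`,
default 0.1%), MINUTE_ISLANDS (components found but all below
`min_island_area`), NO_ISLANDS (no component at all), and EDGE_BLUR (RMS
Sobel gradient over the ROI rim band normalized by mean in-ROI intensity,
below `blur_metric_limit`).  The blur metric is reported for every sample
but its threshold defaults to 0 (disabled) because it requires
per-dataset calibration; a failed sample load yields an ERROR flag.  A
sample is accepted iff no flag is set, and every input row appears exactly
once in the QC table.

## Synthetic study conditions

The generator emulates a widefield NE-bottom acquisition and is the basis
of every recovery claim:

| parameter | default | rationale |
|---|---|---|
| pixel size | 0.129 um/px | 100x/1.35 objective, 2x2-binned CCD |
| nucleus radius | 10 um | adherent cultured cell |
| islands per cell | 2, each 16-30 um^2 | large early-G1 islands |
| island margin | 2 um | islands are surrounded by pore-rich NE |
| pore-rich NPC density | 2.6 foci/um^2 | mature-NPC density scale |
| NPC hard-core spacing | 0.35 um | NPCs are anchored, non-overlapping structures; a Poisson pattern would produce island-mimicking voids |
| island focus density | 0.25 foci/um^2 | sparse intermediates, unquantified in real data (free parameter) |
| PSF | sigma 0.8 px in focus + 30% halo at 3 px | in-focus core ~100 nm plus widefield out-of-focus light |
| background | 20 photons/px | non-specific stain, autofluorescence, offset |
| photons per focus | 2000, Poisson + read noise SD 3 | bright immunostain at 16 bit |
| annotated ROI | nucleus eroded by 1.25 um | manual ROIs trace inside the blurred rim |

Focus positions get subpixel jitter so centroid recovery is nontrivial;
island shapes are discs with low-order Fourier boundary perturbation
(areas realized within +-10%); the biased placement mode accepts candidate
positions with a logistic probability in boundary distance (steepness
`bias_strength`, centred on the median boundary distance), giving a
tunable alternative hypothesis to complete spatial randomness.  Island
pixels contain zero pan-NPC foci by construction.  The
density-validation preset (`density_validation_params`) instead emulates
an unbinned 0.0645 um/px acquisition of an island-free nucleus, where
per-punctum counting against the known density is meaningful.

What the generator does **not** emulate: chromatic shift between channels,
camera gain maps, illumination shading, z-dependence and defocus
gradients, clustered (non-logistic) focus placement, island shapes with
concavities beyond low-order Fourier modes, and biological variation in
staining efficiency.  Passing recovery tests therefore demonstrates the
pipeline's correctness and its statistical calibration under a faithful
noise and geometry model — not field performance on any particular
microscope.

## Problem sizes in the test suite

The bundled tests and the acceptance script use 20 images (40 islands) for
segmentation recovery, 10 island-free images for specificity, 10-20
experiments of 50 islands each for the bias analysis (CSR reps scaled to
1000-2000 per island, which bounds the Monte-Carlo error of a regional
share well below the between-island spread), and 200 null replicates for
test calibration.  The full-size default (33,029 reps) is used when the
pipeline is run with its out-of-the-box configuration.

## Known limitations

* Merged foci are counted once (no watershed); recall degrades above
  ~0.5 foci/um^2 at binned sampling.
* The WCV rule can select different k across restarts on near-monotone
  traces; island extraction is deliberately robust to moderate
  over-clustering, and the FALLBACK flag marks traces without a sign
  change.
* The proximal/distal split and the per-island share reduction for the
  profile comparison are declared assumptions; the mirrored structure of
  the two regional tests is a direct consequence of the share reduction.
* EDGE_BLUR is reported but not thresholded by default.
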