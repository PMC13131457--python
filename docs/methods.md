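# Methods

## Scope and data model

All analysis is 2-D: inputs are single-plane multi-channel rasters or
Z-stacks that are maximum-intensity projected before segmentation.
Coordinates are 0-based `(row, col)`; the only physical calibration is a
single pixel edge length in nm, which must be supplied explicitly (TIFF
resolution tags are accepted only as a logged fallback, because
acquisition metadata is routinely unreliable). Every nm- or μm-scale
quantity is linear or quadratic in this one number, so a calibration error
propagates multiplicatively and is never silently defaulted.

## Segmentation

Channels are binarized by global thresholding after optional Gaussian
pre-smoothing. The default is Otsu's criterion on the smoothed channel
(sigma 1 px for puncta, 2 px for the soma marker); percentile and absolute
thresholds are first-class overrides so that per-image optimization is an
auditable config choice, not an interactive step — every applied numeric
threshold is written to the run log. Otsu on a constant channel is refused
unless the caller explicitly permits an empty mask (pipelines permit it
for the EV channel, where an image may genuinely contain no puncta).

Puncta are 8-connected components restricted to a size/shape window:
area 0.03–1.5 μm², solidity ≥ 0.6, eccentricity ≤ 0.98 by default. The
window selects diffraction-limited-to-small particles and rejects
elongated or ragged fragments of labeled processes; all four bounds are
exposed in config because no universally correct values exist.

Somata are detected from the marker channel by threshold → morphological
opening and closing (disk radius 2 px) → hole filling → minimum-area
filter (50 μm² default) → labeling. Manual curation is reproduced as an
explicit include-list of label ids, never an interactive step. The
cellular ROI used for randomization defaults to the convex hull of the
union of the mitochondrial and punctum masks dilated by 20 px; a membrane
channel or a user-supplied mask can replace it. The hull is the only ROI
computable from the channels every dataset has, which is why it is the
default despite being a geometric convention rather than a biological
boundary.

## Edge-to-edge distance and contact

For punctum pixels *P* and organelle mask *M*, `d_px = min_{p∈P} EDT(p)`
where EDT is the exact Euclidean distance transform of *M* (0 on *M*).
Contact is overlap or 8-adjacency (`d_px ≤ √2`): on a pixel grid, adjacent
pixels have zero boundary separation. Otherwise the edge distance is
`(d_px − 1)·s` nm, subtracting one pixel for the two half-pixel widths
between pixel centers and boundaries. The centroid distance is the
distance from the punctum's area centroid to the nearest organelle pixel
center. Consequences worth knowing: distances are quantized at sub-pixel
scale, doubling the pixel size exactly doubles every distance, and the
definition is invariant under rigid 90° co-transformations of both masks.

## Monte Carlo randomization null

Each iteration rigidly translates every punctum's segmented pixel shape so
that its anchor (floor-rounded centroid) lands on a ROI pixel drawn
uniformly at random; placements with any pixel outside the ROI are
rejected and redrawn (error after 1000 rejections per placement). Shapes
are not rotated — preserving the segmented shape is the most conservative
reading of "random placement with organelle geometry preserved" — and
placements may overlap the organelle, since observed puncta may.

The test statistic is either the mean edge distance (proximity = smaller)
or the fraction within a threshold (proximity = larger); both are named
explicitly in every report because either is a defensible per-image
choice. Empirical p-values use the add-one convention
`p = (1 + #extreme) / (1 + n_iterations)`, so p is never 0 and the floor
at 10,000 iterations is ~1e-4. Defaults: 1,000 iterations per image,
10,000 for pooled binned enrichment. Pooling concatenates all particles of
all images per iteration, each image randomized within its own ROI with a
deterministic per-image substream spawned from the master seed; a
single-image pooled run is bit-identical to the per-image test with the
same seed.

Under the null, with n iterations the achievable p-values lie on the grid
k/(n+1); at 199 iterations P(p ≤ 0.05) is exactly 10/200 for a continuous
statistic, which the calibration suite exploits to check type-I error at
α = 0.05 over 500 simulated null images.

## Group comparisons and distribution shape

Mann-Whitney U is exact (full enumeration) when `n₁·n₂ ≤ 400` and the
pooled sample is tie-free, otherwise normal approximation with mid-rank
tie correction and continuity correction. Fisher's exact test sums
hypergeometric point probabilities at most as large as the observed
table's. Pearson correlations report the exact two-sided p from
`t = r√((n−2)/(1−r²))` with n−2 df; no multiple-testing adjustment is
applied (two planned correlations). SEM uses the n−1 sample SD.

Sarle's bimodality coefficient uses the bias-corrected sample skewness and
excess kurtosis:
`BC = (g₁²+1)/(g₂ + 3(n−1)²/((n−2)(n−3)))`. Its asymptote is 1/3 for a
normal sample, 5/9 for a continuous uniform, →1 for a symmetric two-point
mixture; the conventional decision threshold 0.555 is the uniform
benchmark, which identifies this particular formula among the published
variants.

Gaussian-mixture selection fits k = 1 and k = 2 by EM (scikit-learn
backend) — one initialization from a median split plus 10 random restarts,
best log-likelihood kept, variances regularized by (tol·sd)² against
collapse, deterministic given the seed — and compares
`BIC_k = −2·loglik + p_k ln n` with p₁ = 2, p₂ = 5 free parameters.
`ΔBIC = BIC₂ − BIC₁ < 0` selects two components. At n = 500 the k = 2
penalty margin is 3·ln 500 ≈ 18.6, which keeps the false-bimodality rate
on unimodal samples below 10%.

## Synthetic data: what it emulates and what it does not

The generator exists so every stage can be validated against exact ground
truth without microscopy data.

*Apposition fields.* The organelle channel is a union of dilated,
directionally persistent self-avoiding random walks (default 3 filaments,
width 3 px, 300 steps on 256²) — filamentous geometry with tunable
density; no attempt is made at biologically realistic network topology,
which the distance statistics do not depend on. Puncta (disks, radius 2 px)
are placed by searching a minimum-filtered distance map for centers whose
disk realizes the planned distance *under the analysis definition itself*,
so the plan is exact by construction: an explicit pixel-gap list, an exact
contact fraction with far placements (gap 6–25 px, i.e. >390 nm at the
65 nm/px default), or distances sampled from a Gaussian mixture (realized
within 0.5 px). Truth records store the recomputed distance, and a test
re-verifies every field against an independent all-pairs oracle.

*Soma fields.* Non-overlapping rotated ellipses (semi-axes 5–7 × 4–5.5 μm,
clearing the 50 μm² detection floor; 10 per 1024² frame at 65 nm/px) carry
zero-inflated punctum counts: positive with probability π = 0.67, positive
cells drawing `1 + Poisson(μ⁺ − 1)` with μ⁺ = 4.2/0.67 so the dataset mean
is 4.2. A zero-inflated model is required because a 67% positive fraction
is incompatible with a plain Poisson of mean 4.2 (which would leave only
~1.5% of cells empty). Puncta are placed inside each soma with a 3 px
boundary margin and a minimum pairwise separation of 2r + 3 px — *near*-
uniform placement. The separation constraint is deliberate: without it,
coincident puncta merge into one component and exact count recovery on
noise-free renders would be impossible; the cost is a slight negative bias
in punctum clustering that the count statistics do not see.

*Rendering.* Truth masks are scaled to channel amplitudes (EV 200,
mitochondria 150, marker 120 over background 2), blurred with a Gaussian
PSF (sigma 1 px), given Poisson shot noise and Gaussian read noise
(sd 2), and clipped at zero. This emulates shot-noise-limited widefield
data after projection. It does not emulate optical anisotropy, uneven
illumination, bleed-through, autofluorescence, or out-of-focus haze — so
passing tests demonstrate the statistics and the pipeline plumbing are
correct, not that default thresholds transfer to any particular
microscope's data (they are expected to be tuned per dataset, which the
run log makes auditable).

## Numerical and design choices

- Particle-to-soma assignment uses the label at the floor-rounded centroid
  pixel: deterministic, and the natural grid realization of "centroid
  within the mask". Sub-pixel interpolation would change no conclusions
  and cannot be checked against anything.
- Randomization anchors use the same floor-rounded centroid, keeping the
  observed configuration exactly representable under the null.
- Per-image Monte Carlo seeds derive from the master seed and image index
  (`(seed·1000003 + 7919·i + 1) mod 2³¹`), so cohorts are reproducible and
  parallel-safe without sharing streams.
- Empty or degenerate inputs fail loudly with typed exceptions
  (configuration / input / analysis / generation), and pipelines propagate
  the failing stage.
- Problem sizes in the validation suite (500 somata over 50 fields for
  parameter recovery; 500 null images at 199 iterations for calibration;
  100 random fields for the distance oracle) were chosen as the smallest
  sizes at which the targeted tolerances are statistically meaningful.

## Known limitations

- Strictly 2-D: real EV–mitochondria distances are 3-D; projection
  compresses axial separation and inflates apparent contact. Comparative
  statements (condition A vs B under identical imaging) are robust to
  this; absolute contact fractions are not.
- Global thresholds: no learned or local-adaptive segmentation, and no
  watershed splitting of touching somata.
- The hull ROI is a convention; if the true cell footprint is much larger
  than the imaged structures, the null under-disperses and the proximity
  test becomes conservative in the other direction.
- Mixture selection is restricted to k ∈ {1, 2}; the bimodality
  coefficient is known to flag heavy skew as well as true bimodality,
  which is why both diagnostics are always reported together.
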