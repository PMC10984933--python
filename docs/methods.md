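# Methods

This note documents the models, parameters and numerical choices in
`ecmquant`, and what the synthetic scenes do and do not establish.

## 1. Aggregate-size classification (2-D)

### Particle measurement

Connected components of a binary mask are labelled with 8-connectivity
(diagonal contact merges), areas are pixel counts × `pixel_size`², and
a particle touches the border iff any of its pixels lies in the first
or last row or column (0-based frame). Two filters apply before any
statistics: area < `min_area_um2` (default 1 µm², below which phase
contrast cannot distinguish cells from debris reliably) and, by
default, border contact (clipped particles have biased areas).

### Change-point model

The analysis assumes the retained particles are a mixture of three
size regimes. Sorted ascending, their log₁₀ areas indexed by rank form
an empirical quantile curve on which the debris limb, single-cell
plateau and aggregate tail are approximately linear with distinct
slopes. The signal handed to the change-point fit is exactly this
sorted rank curve; a binned density would need a bandwidth choice and
loses the one-point-per-particle resolution at the boundaries.

The fit minimizes RSS(i₁) + RSS(i₁,i₂) + RSS(i₂,n) over all pairs
min_seg ≤ i₁ < i₂ ≤ n − min_seg with i₂ − i₁ ≥ min_seg, where each
term is an ordinary least-squares line fit on [start, stop). The scan
is exact (prefix sums give each segment RSS in O(1); the full scan is
O(n²) and takes milliseconds for the few hundred particles of a
field). Ties go to the smallest i₁, then smallest i₂. `min_seg`
defaults to 5 so every fitted line has ≥ 5 points. Exactness matters
because the test suite checks the optimizer against brute-force
enumeration; heuristic binary segmentation can miss the optimum on
short plateaus.

### MAD band and labels

The middle segment [i₁, i₂) defines the single-cell population. Its
median *m* and raw MAD (median |x − m|, no 1.4826 normal-consistency
factor — the band is a descriptive cut, not a normal-σ estimate) give
the band (m − k·MAD, m + k·MAD), k default 3. Band comparisons are
strict, so with MAD = 0 only values different from the median leave
the single class. Values above the band are aggregates; values below
are non-cell debris, flagged as discarded. The MAD is computed on the
log₁₀ scale because the entire procedure operates on the
log-transformed data; an alternative reading ("|deviation| < 3 MAD is
non-cell") would empty the single-cell class and is rejected.

### Summaries

The aggregate percentage is 100·n_agg/(n_single + n_agg); debris is
excluded from the denominator because it is not part of the cell
population. Relative aggregate sizes divide each aggregate area by the
arithmetic mean single-cell area of its own image, on the linear µm²
scale (a per-image normalization, robust to illumination- or
focus-driven segmentation differences between fields). An image with
aggregates but no singles yields NaN relative sizes plus a warning.
Values just above the band can be < 1: the band is on the log scale,
the normalizing mean on the linear scale.

## 2. Biovolume quantification (3-D)

### Preprocessing

Denoising is a uniform-mean convolution with edge replication; the
default kernel is (5, 5, 3) voxels in (x, y, z), reflecting lateral
oversampling relative to the 0.25–0.5 µm z-step of confocal stacks.
Background subtraction is a white top-hat (input − grayscale opening)
with a cubic structuring element (default side 15 voxels). The top-hat
removes any structure larger than the element — including a
full-field slab — so it is meant for uneven background in real
stacks and is disabled (`tophat_size: 0`) for flat-field synthetic
scenes.

### Segmentation

Intensities are normalized to [0, 1] by the channel maximum and
histogrammed into 256 bins. A 3-class Otsu split maximizes the
between-class variance over all threshold pairs; of the three
intensity-ordered classes only the top one is foreground (the middle
class is background — dim haze and out-of-focus light). A voxel must
additionally exceed a per-channel relative floor (defaults 0.085
EPS/FITC, 0.07 cell; the floors are interpreted as channel-max–
normalized intensities and are configurable, since the GUI tool such
floors are usually typed into does not document units). Degenerate
channels with only two distinct intensity levels (noiseless synthetic
scenes) are split at the midpoint between the occupied levels; a
constant channel yields an empty foreground with a warning.

The Otsu optimizer resolves ties exactly: integer histograms tie
routinely (the between-class variance of two splits can be *equal* as
rationals), so a float scan shortlists near-optimal splits and exact
rational arithmetic picks the winner, lowest thresholds first. Without
this, float round-off makes the "optimal" split platform-dependent.

### Cubes and the ratio

The stack is tiled from the index origin into cubes (default side 20
voxels); partial edge cubes keep their actual voxel counts so that
cube sums conserve global voxel counts exactly. Per cube we store
integer counts (total, EPS, cell, overlap voxels) and the raw
EPS-channel mean intensity; `shape_biovolume` is the cube voxel count
× voxel volume, so Σ shape_biovolume·rel_class telescopes to the
class's total volume and the ratio

    (Σ sb·(rel_EPS − rel_overlap)) / (Σ sb·rel_cell)
    = (V_EPS − V_overlap) / V_cell

is dimensionless and subtracts signal bleed-through/co-localization
from the EPS numerator. Cubes with no foreground in either channel
are dropped; an optional strict mean-intensity floor (default 75 A.U.)
removes dim cubes before the ratio. All volume sums are computed from
the integer counts, so conservation holds to the last bit.

### Thickness

With the substrate at z = 0, the local thickness of a column is
(highest foreground z-index + 1) × z-pitch, zero where uncovered. Mean
thickness averages covered columns only and the coverage fraction is
reported alongside — a sparse monolayer then reads "thin but sparse"
rather than an averaged-down artifact. (The whole-field mean is
`mean_thickness * coverage` if needed.)

## 3. Synthetic scenes

### 2-D particle fields

Cells are disks; aggregates are unions of k disks (default 3–6) placed
chain-wise at 0.55–0.75 of the summed radii from an existing member —
close enough to always merge into one 8-connected component, far
enough that even minimal members keep the union area well above the
single-cell band. Debris are small disks with uniform area in
(1.5, 5) µm². Defaults: 900×900 px at 0.65 µm/px, 300 cells+aggregates
and 80 debris per field, single-cell log₁₀ area ~ N(1.2, 0.08²)
truncated at ±1.8 sd (≈ 16 µm², the scale of a small coccolithophore
or large bacterial rosette). The truncation keeps the entire single
population inside the ±3-MAD band (3·MAD of the truncated normal is
≈ 2 sd), so the designed class labels are exactly recoverable and
parameter-recovery failures indicate pipeline defects, not label
noise. Construction enforces separability: the debris range must stay
below the band's lower edge, and parameters violating this are
rejected at validation time.

Truth areas are the *realized* rendered pixel count × pixel area for
all classes (at 0.65 µm/px a 1.5 µm² debris disk spans ~4 pixels; no
binary rasterization can match an analytic area to 10 % there). The
sampled target area is recorded separately. Placement is rejection
sampling with bounding-circle separation (≥ 2 px margin); a crowded
parameterization fails after bounded retries with an error naming the
counts and image shape. All draws come from one `numpy` Generator
seeded by `seed`, so scenes are bit-reproducible.

What the 2-D scenes do **not** emulate: rod/chain morphologies,
partial-focus halos, segmentation errors (over/under-splitting),
uneven illumination. Passing recovery tests therefore shows the
*statistical* chain is correct given a faithful segmentation, not that
any particular segmentation front-end is adequate.

### 3-D stacks

Geometry "slab" occupies the first `slab_thickness`/z-pitch planes
across the field (thickness truth constant by construction); geometry
"colonies" unions substrate-attached hemispheres (radii 1.5–4 µm)
until the target cell biovolume (default 800 µm³ in a 40×64×64 grid at
0.5×0.25×0.25 µm) is reached. The EPS mask is built by exact voxel
budget: round(target_ratio × cell voxels) EPS voxels, of which
round(overlap_fraction × EPS) are taken just inside the cell surface
(smallest interior distance first, random tie-break) and the rest just
outside it — a shell, matching how lectin-stained EPS wraps cell
clusters. Truth volumes are voxel counts × voxel volume, hence the
realized ratio matches the target to rounding.

Intensity model: background `background_level` (default 40),
foreground `background_level·(1 + snr)` (snr default 5), additive
Gaussian noise with sd `noise_sd` (default = background level, so
`snr` is contrast in noise-sd units; 0 gives a noiseless scene),
clipped at zero and rounded to integer counts (16-bit storage is then
lossless). Not emulated: PSF blur, z-attenuation, Poisson photon
statistics, chromatic offsets — so segmentation-recovery results
bound algorithmic error only.

## 4. Statistics

The ECDF is right-continuous, F(q) = #{x ≤ q}/n. The two-sample KS
statistic is the sup of |F₁ − F₂| over the pooled sample points; the
p-value uses the asymptotic Kolmogorov distribution with effective
n = n₁n₂/(n₁+n₂), or the exact two-sided null distribution (via
scipy) when n₁·n₂ ≤ 10 000 (the `auto` default). Because some study
designs use one-sided tests without stating the direction, both
one-sided statistics D⁺, D⁻ with their asymptotic one-sided p-values
exp(−2·n_eff·D²) are reported alongside the two-sided D.

The carbohydrate formula is Glc.eq / (DWC × (CM/CE)) in µg per mg dry
weight; inputs must be positive and errors name the offending field.

## 5. Problem sizes and defaults in the checks

The recovery checks use 50 fields per designed fraction (300
cells+aggregates each), 200 random series for the change-point oracle,
100 random 256-bin histograms for the Otsu oracle, and 20 seeds for
noisy 3-D recovery on 40×64×64 grids — sizes chosen so each
statistical property is measured with comfortable margin while the
whole suite stays interactive. Scene generation dominates the cost;
all checks together run in a few minutes on one CPU.

## 6. Known limitations

- The change-point scan is O(n²); fine up to tens of thousands of
  particles, but a PELT-style pruning would be needed beyond that.
- The 2-D front-end accepts binary masks (plus a 2-class Otsu
  fallback for grayscale); trainable pixel classification is out of
  scope, so segmentation quality is the caller's responsibility.
- Thickness assumes the substrate at z-index 0 and one connected
  biomass per column (internal voids do not reduce local thickness).
- The manual floor thresholds are interpreted as channel-max-
  normalized intensity floors combined with top-Otsu-class
  membership; other tools may apply nominally identical numbers to
  differently scaled data, so cross-tool comparisons should calibrate
  on a shared stack.
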