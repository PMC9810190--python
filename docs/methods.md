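# Methods

`germcount` estimates the germination rate of rice grains from a single
top-down photograph of grains lying in a dark, low-reflection container.
The estimate is the ratio `n_bud / n_grain`, where both counts are
derived from colour and geometry alone — no training data, no fixed
camera distance, and no requirement that grains be separated.

## Model and procedure

### 1. Coarse segmentation

Yellow grain pixels are separated from everything else in a clipped
colour-difference space. Each pixel maps to a feature pair

```
r_b = 30 if R - B >= 60 else R - B
g_b = 30 if G - B >= 60 else G - B
```

Yellow has large `R-B` and `G-B`; the near-black background and the
white germs, droplets and specular reflections all have differences
near zero. The clip at 60 → 30 compresses the illumination-dependent
spread of the grain cluster so that darker grain pixels are not pulled
toward the background. A two-centre k-means (Lloyd iterations,
squared-Euclidean distance) with *fixed* initial centres `(0, 0)` and
`(40, 40)` labels the pixels; the cluster whose final centre lies
farther from the origin is the grain foreground. Fixed initialisation
makes segmentation fully deterministic; equidistant pixels go to the
background cluster (conservative), and an emptied cluster keeps its
stale centre so monochrome inputs cannot crash the update.

The implementation clusters the *unique* feature values with
multiplicities, which is algebraically identical to per-pixel Lloyd
but independent of image size; a per-pixel brute-force reference is
kept in the test suite and the two are asserted to agree exactly.

### 2. Refinement segmentation

The coarse mask keeps a dark shadow rim around each grain (shadow
colour is close enough to dim yellow to join the grain cluster). In
the red-channel histogram of the foreground pixels the rim and the
bright core form two modes; the valley between them is the threshold
`d`, and foreground pixels with `R < d` are returned to the
background. Finding the valley robustly takes two smoothing steps:

* convolution with a unit-sum Gaussian (nominal size 100, realised as
  a symmetric 101-tap kernel since an even tap count has no centre
  tap; σ = 7.5 bins);
* a least-squares 5th-degree polynomial trend line fitted to the
  smoothed histogram. A quintic has at most four interior critical
  points, so between its two dominant maxima there is exactly one
  interior minimum — small residual wiggles cannot create spurious
  valleys, which is the reason for preferring it over reading the
  smoothed histogram directly.

The valley search evaluates the trend line on the integer bins 0–255,
keeps the two interior strict local maxima with the largest values and
takes the argmin strictly between them. If fewer than two interior
maxima exist the histogram is unimodal (no rim mode) and refinement is
skipped — a valid outcome, not an error. Refinement is anti-extensive
by construction: it only ever removes foreground.

**Boundary handling.** The histogram smoothing uses symmetric
reflection at the ends of the 256-bin axis. For a unit-sum symmetric
kernel this preserves both the total histogram mass (exactly, because
folded kernel taps are a bijection) and constant histograms, the two
properties the later stages rely on. Truncated-kernel renormalisation
was considered and rejected: the gather form preserves constants but
leaks mass at the edges, the scatter form conserves mass but distorts
constants.

**Global vs per-region threshold.** One global histogram and one
global `d` are used by default: the rim/core contrast is a property of
the lighting, not of the individual grain. A `per_region_threshold`
configuration option computes one valley per connected region for
scenes with strongly varying illumination.

### 3. Grain counting by area division

After refinement each connected region (8-connectivity, so corner
contact merges) holds one grain or a cluster of touching grains. The
region areas sorted ascending form the *area distribution curve*:
tiny noise regions first, then a stable plateau of single-grain areas,
then the jumps of multi-grain clusters.

* **Turning point A** (plateau start): the curve is smoothed with a
  3-tap unit-sum Gaussian (σ = 0.65, truncated-renormalised edges) and
  the discrete Laplacian `g(x) = f(x+1) + f(x−1) − 2 f(x)` is taken
  (endpoints set to 0). At the noise-to-plateau jump `g` swings
  positive then negative; A is the first index `i` with
  `g(i−1) < 0`, `g(i−1) < g(i)`, `g(i+1) > 0`, `g(i+1) > g(i)` — the
  rising zero-crossing at the end of that swing. With no such pattern
  (no noise regions) A falls back to 0.
* **Turning point B** (plateau end): scanning `i` upward from A on the
  raw sorted areas, the plateau ends at the first `i` with
  `s[i+3] / s[i] > 1.2`. B is that `i` — the last point of the stable
  run; taking `i+3` would pull post-jump cluster areas into the
  single-grain candidates (available as `point_b_convention="jump"`).
  The raw rather than smoothed areas are scanned because the ratio
  test is already a windowed statistic; this too is switchable
  (`condition7_on_smoothed`). If the ratio never fires, every region
  is a single grain and B is the last index.
* **Optimal single-grain area**: among the candidate areas at sorted
  indices A..B, `s_opt` is the candidate `s_i` minimising
  `Σ_j |1 − s_j / s_i|`, found by exhaustive search (the candidate set
  is small); ties go to the smallest index. `s_A ≤ s_opt ≤ s_B` always
  holds.
* **Per-region count**: a region of area `s` holds
  `floor(s / s_opt)` grains, plus one more when the fractional part of
  `s / s_opt` strictly exceeds 0.4. For integer inputs the comparison
  is done in exact rational arithmetic (`5·(s mod s_opt) > 2·s_opt`)
  so a fractional part of exactly 0.4 never rounds up through float
  noise. The total `n_grain` is the sum over regions.

Every region passes through the fractional rule: genuine noise
regions are far below `0.4·s_opt` and contribute zero on their own.
Regions sorted below A are flagged as noise in the per-region audit,
and a configuration option (`exclude_noise_regions`) can force them to
zero, but the default keeps the plain sum: the Laplacian crossing
lands A one or a few indices *inside* the single-grain plateau
whenever areas jitter (the rising zero-crossing needs a strictly
positive Laplacian, which the plateau only supplies past the jump), so
a structural index-based exclusion would silently drop the smallest
real grains. The flag's main consumer is the candidate window for
`s_opt`, where a small inward bias is harmless.

### 4. Germ detection

Germs (the emerging white radicle) are bright regions outside the
grain foreground: pixels with Rec.601 gray value strictly above 160
and not in the refined mask, grouped by 8-connectivity. Two filters
follow:

* **area band**: accept only `s_opt/50 < s_bud < s_opt/3` (both
  strict). Smaller blobs are droplets or glints; larger ones are
  reflections or fully white grains.
* **contact geometry**: `p` is the number of inner-boundary pixels of
  the candidate (pixels with a 4-neighbour outside the candidate; the
  image border counts as outside), and `l` the number of those
  boundary pixels with an 8-neighbour in grain foreground. A counted
  germ must touch a grain (`l ≥ 1`) and satisfy `l/p < 0.4` (strict):
  a normally emerged germ contacts the grain along a small fraction of
  its circumference, while a bright patch mostly embedded in a grain —
  an incompletely emerged germ — has high contact and is excluded.

Defining both `l` and `p` as boundary-pixel counts keeps them
commensurable, so `l/p ∈ [0, 1]`; a mixed definition (say,
Crofton-style perimeter for `p`) would break the 0.4 threshold's
meaning. "Touch" means direct contact under the 8-neighbourhood; no
gap tolerance is applied. Each accepted candidate counts one
germinated grain — the scan stops at the candidate's first adjacent
grain — so two germs merged into one connected region count once, and
one grain touched by two separate accepted germs counts twice; both
are inherent, documented behaviours of the counting rule, reproduced
as-is. Adjacency is measured against the full refined mask by default
(`adjacency_excludes_noise` restricts it to non-noise regions).

The germination rate is `n_bud / n_grain`; with zero grains the rate
is flagged undefined rather than invented.

### Error metrics

`evaluate(truth A, prediction B)` returns the absolute error `|A − B|`
and the relative error `|A − B|/A × 100 %` (undefined and flagged when
`A = 0`). The batch runner aggregates mean and standard deviation of
both across a directory of images with ground-truth files.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `clip_delta`, `clip_value` | 60, 30 | colour-difference clip: differences ≥ 60 become 30 |
| `kmeans_centers` | (0,0), (40,40) | fixed initial centres, background first |
| `kmeans_max_iter` | 100 | Lloyd iteration cap (convergence is on unchanged assignments) |
| `hist_filter_size`, `hist_filter_sigma` | 100 taps, 7.5 bins | red-histogram Gaussian |
| `curve_smooth_len`, `curve_smooth_sigma` | 3 taps, 0.65 | area-curve Gaussian |
| `ratio_threshold` | 1.2 | plateau-end ratio `s[i+3]/s[i]` |
| `fraction_threshold` | 0.4 | round-up threshold for the fractional grain count |
| `gray_threshold` | 160 | germ brightness cut (strict >) |
| `area_lo_divisor`, `area_hi_divisor` | 50, 3 | germ area band relative to `s_opt` |
| `lp_ratio_max` | 0.4 | maximal contact fraction `l/p` (strict <) |
| `connectivity` | 8 | region labelling for grains and germs |

All values are in pixels or pure ratios; nothing depends on physical
scale, which is what makes the pipeline robust to camera distance.

## The synthetic scene generator

No photograph corpus ships with the package, so every claim is tested
against a seeded generator whose scenes carry exact ground truth. It
emulates the acquisition protocol: a near-black background (RGB ≈ 10
with Gaussian pixel noise, σ = 3 levels), grains as hard-edged yellow
ellipses with semi-axes 26 × 10.5 px (≈ 2.5:1, typical of rice;
±10 % area jitter), a 2-px darker shadow rim (red ≈ 85 against core
red ≈ 235) that exercises the refinement valley, adhesion clusters
rendered as side-by-side chains whose *cores* overlap by ~3 px (so the
refined region stays connected and must be counted by area division),
white germ ellipses attached at one grain tip sized to ~12 % of the
grain area, and white reflection blobs (too large for the area band)
plus detached droplets (too small). Scenes are deterministic per seed
and alias-free by default, so ground-truth masks and counts are exact;
an anti-aliased mode (2× supersampled) exists for robustness checks.
Germ geometry is self-consistent by construction: each drawn germ
passes the package's own area-band and `l/p` operators, which the test
suite verifies directly.

Choices worth recording:

* **Rim colours stay below the clip** (`R − B ≤ ~58`): the clip branch
  is for the bright core; the rim exercises the unclipped branch and
  the refinement stage.
* **Speck noise is off by default.** Tiny grain-coloured specks (the
  noise regions that turning point A exists for) are a generator
  parameter used in dedicated tests of the point-A logic. When specks
  are present they are rendered with *identical* areas: a flat noise
  run keeps the Laplacian silent until the real jump. Default scenes
  model a clean container, matching the protocol's washed-container,
  black-paper setup.
* **Cluster chains attach side-by-side** (perpendicular to the grain
  axis) so every member's tip stays free for a germ, and the realised
  germination count always equals the planned one.
* **Failure-mode scenes are deterministic constructions** (a grid of
  grains with one pathological feature each) rather than decorated
  random scenes, so the documented error directions — false germ from
  a droplet on a grain edge, merged intertwined germs, a germ hidden
  under its grain, heavily overlapping grains — reproduce on every
  seed.

What the generator does **not** model: anti-aliased soft shadows and
specular gradients of real photographs, wet-paper texture, colour
bleeding between touching grains, perspective distortion, and germs
that curl back over their own grain. Passing the synthetic recovery
suite therefore shows the pipeline implements the method faithfully
and recovers exact truth under the method's own assumptions; it does
not certify the field accuracy on real photographs, which depends on
those unmodelled effects.

## Numerical choices and degenerate inputs

* The quintic fit uses a scaled-domain least-squares (`numpy`'s
  `Polynomial.fit`) and converts back to raw coefficients; fitting raw
  powers of bins up to 255 would be badly conditioned.
* `s_opt` tie-breaks to the smallest candidate index; k-means distance
  ties go to the background cluster; both `l/p < 0.4` and the 0.4
  fractional threshold are strict.
* Degenerate inputs: an all-background image yields a zero-grain
  report with an undefined-rate flag; a single region yields
  `A = B = 0` and `s_opt` equal to its area; an empty candidate list
  for `s_opt` (impossible once a region exists) raises.
* Problem sizes: the test suite and the reproduction script run scenes
  of 18–80 grains on ~0.4–1.2 Mpx canvases, 30–50 scenes per batch —
  the package's chosen benchmark scale, matching the 20–80 grains per
  image the method targets.

## Known limitations

* The area-division rule undercounts when grains overlap heavily
  (union area < 1.4 × s_opt for a pair) and overcounts when several
  grains in one cluster are individually much larger than `s_opt`;
  both follow from counting by area alone.
* Germ counting assumes germs of different grains never merge; the
  intertwined-germ scene shows the resulting undercount.
* A bright droplet attached to a grain edge with germ-like size and
  contact is indistinguishable from a germ by the stated rules and is
  counted as one (false positive).
* The 160 gray cut and the colour-difference clip are tuned to yellow
  grains on black paper; other crops or backgrounds need re-tuning
  (all constants are exposed in `PipelineConfig`).
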