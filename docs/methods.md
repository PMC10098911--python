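# Methods

This note documents the models, estimators, numerical choices and known
limitations of the package.  It is written for a reader who wants to know
*why* each default is what it is and what the passing tests do — and do not
— demonstrate about real data.

## Data model

A volume is a float array `intensity[z, x, y]` (axial index first,
increasing with depth) with physical calibration: lateral pixel sizes
`dx, dy` (µm), axial pixel size in tissue `dz` (µm) and the refractive
index used to derive it.  The nominal geometry is 10 mm × 10 mm × 2.59 mm at
1000 × 1000 × 1024 px with tissue index 1.38, giving `dz = 2590/1024 ≈
2.53 µm`.  Intensities are arbitrary linear units; the package never relies
on an absolute scale (the acquisition hardware's units are unknown, and all
estimators are scale-invariant or normalize internally).

## Phantom simulator

The phantom emulates the A-scan structure of an air–liquid cultured
epidermal model:

* two Gaussian reflector bands in z (cuticle top, basement membrane), each
  with σ = `band_width`;
* a living-cell layer between them whose backscatter follows the
  single-scattering Beer–Lambert form `A·exp(−2 µ_s (z − z_top))`, `z` in
  mm, with `µ_s` scalar or a lateral field;
* a constant additive background floor;
* optional fully developed speckle: unit-mean exponential multiplicative
  noise on the tissue signal (intensity statistics of a coherent imaging
  system with many random scatterers per resolution cell), which leaves the
  expected signal — and hence Beer–Lambert fitting in expectation — intact;
* a planar tilt and a band-limited random surface-height field.

Key choices:

* **Roughness lives in thickness.**  The membrane (culture insert) plane is
  flat apart from tilt; surface fluctuation is carried entirely by the
  thickness field.  Thickness-derived roughness is therefore tilt-invariant
  by construction, mirroring the physical argument for measuring the
  surface profile through thickness rather than absolute height.  The
  roughness field is Gaussian white noise smoothed with a 3-px lateral
  Gaussian and rescaled so its mean absolute deviation equals
  `roughness_amplitude` exactly.
* **Band σ defaults to one axial pixel (2.53 µm)**, the in-tissue axial
  resolution of the modelled system.  A boundary detector driven by the
  axial gradient localizes a Gaussian ridge's flank about one σ away from
  its centre; with σ = 1 px that offset stays within a single pixel, which
  is what keeps gradient-based segmentation consistent with the band-centre
  ground truth.  Wider bands are supported but shift gradient-located
  boundaries proportionally.
* **Partial-volume rendering.**  The first and last voxel of the cell layer
  are scaled by their fractional coverage of the continuous layer interval.
  Without this, the discrete layer mask quantizes the cell-top edge to the
  axial grid and sub-pixel boundary estimates inherit a uniform(−dz, 0)
  bias.
* **Determinism.**  One seed per volume; the surface field and the speckle
  field are drawn from independent deterministic sub-streams
  (`default_rng([seed, k])`), so identical specs reproduce volumes
  bit-for-bit.
* Default layer parameters (~90 µm thickness, ~22 µm cuticle,
  µ_s = 2.16 mm⁻¹) represent a healthy pre-irradiation epidermal model.

What the phantom does *not* emulate: spectral-domain fringe formation,
depth-dependent focus/sensitivity roll-off, multiple scattering, absorption
as a separate channel (scattering dominates at 1310 nm in this tissue), or
biologically structured texture (speckle is the only intra-layer texture
source).  Tests passing on phantoms therefore validate the estimators'
numerics and robustness to speckle and geometry, not their behaviour under
optical effects the simulator omits.

## Thickness and peak detection

Per A-scan, local maxima above a prominence threshold (default 5× the
robust noise level, 1.4826·MAD; minimum peak separation 4 px) are found and
the two most prominent, depth-ordered, give the peak pair.  Thickness is
the peak-to-peak distance times `dz`.

Peak centres are refined to sub-pixel positions with a three-point parabola
on log intensity, which is exact for a sampled Gaussian band on a flat
background (the log of a Gaussian is a parabola).  This matters because the
axial pixel (2.53 µm) is five times the roughness scale of interest
(~0.5 µm): integer peak indices would quantize the thickness field and
swamp Sa.  Residual systematic error comes from signal underneath the
bands — chiefly the cell-layer backscatter below the membrane band, which
shifts the membrane-centre estimate by ~0.2 px.  That shift is nearly
constant across the field (it depends on the cell signal at the membrane,
which varies only weakly), so it biases absolute thickness by ~0.5 µm but
cancels in the de-meaned surface profile and in Sa.

For speckled data a lateral 5-px moving-average pre-smoothing is
recommended (and used by the pipeline); it is off by default so that
noiseless fields are not laterally blurred.

## Surface roughness Sa

With `D̄` the mean thickness over a circular ROI (centre and radius
configurable; defaults: image centroid, 0.4·min(nx, ny) — the radius is not
prescribed by the measurement definition and must be stated with results),
the per-point roughness `s(x, y)` is the w × w windowed mean of `|D − D̄|`
with windows truncated at the ROI boundary (no padding), and Sa is the mean
of `s` over the ROI.  `w` defaults to 5 px, matching the 5-px smoothing
used elsewhere in the pipeline; `w = 1` reduces Sa to the plain mean
absolute deviation.

Note that because the absolute value is taken *before* window averaging,
Sa(w) is not a low-pass-filtered (smaller) version of Sa(1): window
averaging preserves the mean of the nonnegative deviation field up to
ROI-edge reweighting, so Sa(w) ≈ Sa(1) with small fluctuations of either
sign.  The tests assert this truthful behaviour.

On speckled data the thickness field carries sub-pixel peak-jitter noise
that adds a roughness pedestal (≈1 µm at the default speckled phantom
conditions) on top of the true surface term.  Group comparisons of
roughness should therefore be made after normalization to a control group
measured under identical conditions, which is how the cohort report
presents them.

## Layer segmentation

Boundary evidence is the signed axial gradient matching a polarity
(dark→bright or bright→dark), min-max normalized to `g ∈ [0, 1]` and turned
into node weights `w = 1 − g + ε` (edge cost `2 − (g_a + g_b) + 2ε`, the
classic OCT layer-graph weighting).  The minimal-cost column-monotone path
(one axial index per column, |Δz| ≤ 1 per step, zero-weight virtual
endpoint columns) is computed by dynamic programming — Dijkstra specialized
to this DAG — with deterministic smallest-axial-index tie-breaking.

`segment_layers` finds three boundaries sequentially per B-scan, each
dark→bright (each transition of interest enters a brighter structure from
above: air → cuticle band, band trough → cell backscatter, cell → membrane
band):

1. cuticle top, unconstrained;
2. cuticle bottom, in a window 3–24 px below the cuticle top (the upper
   margin clears the band's own flank; the lower margin generously bounds
   plausible cuticle thickness at this pixel pitch and is configurable);
3. membrane top, at least 4 px (~10 µm) below the cuticle bottom.

For robustness on speckled data the gradient inside `segment_layers` is
computed at a 3-px scale (difference of 3-px means), which leaves a sharp
step's response peaked exactly on the step row while suppressing
speckle-induced spurious ridges that a 1-px gradient lets the shortest path
chase.  A boundary whose mean gradient along the path is statistically
indistinguishable from zero (one-sample t across columns below 4) is
declared undetected and the B-scan masked; more than 50% masked raises.

Sub-pixel refinements accompany the integer paths: band centres (cuticle
top, membrane) via the log-parabolic ridge interpolation, and the
cell-layer top via a parabola on the gradient (with the half-pixel offset
of the one-sided difference).  Cuticle thickness is reported from the
sub-pixel positions as (cell-top edge − cuticle band centre)·dz.

## GLCM texture

Gray mapping follows `g = clamp(floor((g₀ − g_min)/(g_max − g_min)·G), 0,
G−1) + 1` with G = 8 and the *volume-global* min/max, so contrast is never
renormalized between ROIs or groups.  By default the mapping operates on
the log-compressed image (`log10 I`, floored at 10⁻⁶ of the maximum): OCT
B-scans are displayed and visually analysed in the log domain, where
speckle contrast is range-independent; on the raw linear scale the global
range is set by the bright reflector bands and intra-tissue texture
collapses onto the lowest gray level (ASM → 1).  A `scale="linear"` option
retains the raw mapping.

The co-occurrence matrix counts ordered level pairs at the integer-lattice
offset — for d = 3, θ = 45° the partner lies 3 px right and 3 px up in
depth, with no Euclidean rounding — normalized by the pair count.  Features
are `ASM = ΣΣ P²` and `COR = ΣΣ i·j·P` over 1-based levels, exactly as
defined; this COR is a raw autocorrelation moment with range [1, G²], not
the mean-subtracted, SD-normalized GLCM correlation (available behind
`standard_correlation=True` for comparison with other toolboxes).

ROIs are 20 px (z) × 100 px (x), placed deterministically: B-scans at
25/50/75% of the y extent, three lateral positions each, vertically centred
between the segmented cuticle bottom and membrane top and clipped to
exclude both reflector bands.  Per-volume features are the mean over the
(up to) nine ROIs.

## Depth-resolved scattering

Processing chain per volume: 5-px lateral moving average (x then y, per
depth) → per-A-scan background subtraction (median of the air region above
the detected surface; the deepest voxels are not used because the membrane
band contaminates them) → cell-layer segment extraction from the
boundaries, trimmed by 1 px at the top and 3 px at the bottom to keep
reflector-band tails out → terminal coefficient → estimator.

* `naive_dr`: `µ[i] = I[i] / (2δ Σ_{m=i+1}^{N} I[m])`, δ = dz/1000 mm.  The
  right-hand discrete sum matches the printed bounds of the corrected
  recursion.  The final pixel (empty tail) is undefined.
* `fit_terminal_mu`: ordinary least squares of ln I against depth;
  µ = −slope/2.  Log-linear OLS is deterministic and closed-form; on
  smoothed data it is adequate and needs no nonlinear optimization.
* `modified_dr`: `µ[N]` from the fit, then backward recursion multiplying
  the naive estimate by `1 − exp(−2δ Σ_{m=i+1}^{N} µ[m])`.

Numerical properties, measured and tested:

* With *analytic* tail integrals and an exact terminal value the recursion
  reproduces the generating coefficient at every depth to better than 1e-6
  relative — the correction factor cancels the truncation term identically.
* With discrete right-hand sums there is an O(µδ) per-step bias that
  compounds along the recursion: +1.4% at µ = 2.16 mm⁻¹, δ = 2.53 µm and a
  ~22-px segment.  It is multiplicative and nearly condition-independent,
  so relative group contrasts are essentially unaffected.
* At the small total optical depth of a thin cell layer (~0.3), the
  correction factor is nearly linear in the accumulated tail, so an error
  in the terminal coefficient propagates strongly: a +50% terminal error
  still leaves ~+36% at the shallowest pixel.  The terminal fit therefore
  matters; see next point.
* **Terminal fit is pooled by default.**  Per-A-scan log-linear fits on
  speckled data have enormous variance (the slope is estimated over a
  ~55 µm baseline), and rejecting the non-positive ones truncates the error
  distribution and biases the volume mean upward by ~+17% at default
  speckled conditions.  The default therefore averages ln I across all
  cell-layer columns at each relative depth and fits one slope to the
  averaged profile (weighted by per-depth column count).  `per_ascan` mode
  remains available and is fine for low-noise data.

The per-volume mean coefficient is the arithmetic mean over all defined
cell-layer voxels.  Its stochastic precision is set by the lateral area:
speckle gives each depth-profile point a relative standard error of about
`1/√(number of A-scans)`, so scaled-down volumes (e.g. 128 × 32 A-scans)
carry a per-volume relative SD of ~3%.  Attenuation is reported as
scattering; absorption is neglected.

## Cohort statistics

Welch's heteroscedastic one-way ANOVA (Welch 1951 statistic, F reference
with df₂ = (k²−1)/(3Σh)) for morphological parameters across the three
groups, Welch t-tests for scattering/OD comparisons, Pearson r with an OLS
line for covariate relationships.  All tests two-sided at α = 0.05 without
multiple-testing correction (a Holm option exists, off by default, to match
the single-comparison convention of the source workflow).  Normalization
divides by the same-day NC group mean, making the NC normalized mean 1 by
construction and the operation scale-invariant.

Monte-Carlo calibration uses 3 null groups of n = 10: at n = 6 the Welch
approximation is measurably conservative (type-I ≈ 0.045), while at n = 10
the empirical rate is within half a point of nominal, so a 2000-draw
estimate sits comfortably inside [0.035, 0.065] for any seed.

The VC "inhibition of cuticle thickening" has no single standard formula;
the report prints three candidate definitions (reduction of the excess over
NC, relative day-4 reduction, growth-based reduction) without asserting
one.

## Synthetic cohorts

`synthetic_cohort` generates a three-arm study (NC, UV, UV+VC; day 1 =
pre-irradiation, day 4 = after three 3 J/cm² UVA cycles) with group/day
means emulating the published contrasts of a UVA photodamage experiment:
day 1 at ~89.5 µm thickness / 22.4 µm cuticle / 2.16 mm⁻¹ scattering for
all arms; day 4 with NC drifting by normal growth (92.2/26.9/2.12), UV
strongly affected (99.8/42.0/1.78, roughness +14%) and UV+VC intermediate
(95.2/33.6/1.87).  Replicate means are drawn around these with the
published between-model SDs, except that cuticle and *cell* thickness are
drawn independently (cell SD 2 µm) so the cell layer always remains thick
enough for the 20-px texture ROI — the sum's SD is then slightly below the
published thickness SD, a deliberate trade.  Default volumes are
128 × 32 × 168 px with speckle on: large enough for 100-px-wide ROIs and a
~3% per-volume scattering SD, small enough to analyse a full cohort in
under a minute.

## Known limitations

* The scattering recursion inherits the printed right-hand-sum
  discretization; its +1–2% multiplicative bias is documented rather than
  silently corrected, because the discrete form *is* the specified
  estimator.  (A log-form discrete estimator would be exact but is a
  different method.)
* Sub-pixel thickness carries a small constant offset from cell-layer
  signal under the membrane band; absolute thickness is accurate to ~0.5 µm,
  differences and roughness to much better.
* Speckled roughness estimates include a peak-jitter pedestal; only
  normalized comparisons are meaningful at realistic noise.
* GLCM features on phantoms characterize speckle texture, not biological
  microstructure; their absolute values are plausibility checks only.
* Boundary detection assumes the bimodal band structure; volumes without a
  membrane band are masked rather than guessed.
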