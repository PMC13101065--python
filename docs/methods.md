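# Methods

This note documents the models, estimators and numerical choices behind
qpmorph, in the order the pipeline runs.

## Phase reconstruction

**Fringe model.** An off-axis interferogram is modeled as
I(x, y) = a + b·cos(2π(f_y·y + f_x·x) + φ(x, y)) with carrier frequency
(f_y, f_x) in cycles/pixel and object phase φ. Demodulation is the
single-shot Fourier-transform method: isolate one spectral side lobe,
shift it to DC, inverse-transform, take the complex argument. The side
lobe is selected with a Gaussian window of half-width 0.4·|f_c| in
frequency space. Two refinements proved necessary in practice and are
part of the method here:

* the image is Hann-apodized before the transform. A carrier with a
  non-integer number of cycles across the frame otherwise leaks energy
  across the whole spectrum; on a pure-tone test field apodization
  reduces the recovered-phase RMS deviation from ~0.025 rad to ~2·10⁻⁴
  rad. The apodization shapes only the amplitude envelope of the
  analytic signal, not its angle.
* after shifting by an integer number of frequency bins, the sub-bin
  carrier remainder is removed as an exact linear ramp when the carrier
  is known, or estimated (twice, iterated) as the amplitude-weighted
  circular mean of the phase slope when it is auto-detected.

Auto-detection requires a dominant non-DC peak at least 3× the median
spectral magnitude in the canonical half-plane (f_x > 0, or f_x = 0 and
f_y > 0); a flat field raises "no carrier detected". Phase quality
degrades within a few pixels of the frame border, where the apodization
window vanishes — regions of interest should stay clear of the border
(the synthetic frame compositor leaves a 16 px margin for this reason).

**Goldstein unwrapping.** Residues are 2×2 loops whose wrapped-gradient
circulation is ±2π; they are detected by a vectorized loop-sum and, in
tests, cross-checked against an explicit brute-force double loop.
Branch cuts pair residues greedily by ascending Euclidean distance with
opposite-charge partners or the nearest border (ties broken row-major),
rasterized as 8-connected Bresenham chains, which 4-connected
integration paths cannot cross. Integration is breadth-first from the
first non-cut pixel in row-major order, each pixel receiving its
predecessor's value plus the wrapped difference — so the result is
congruent to the input modulo 2π everywhere. Residue-free fields take a
vectorized cumulative-sum path (any integration path is then valid) and
are recovered exactly. Cut pixels and any regions isolated by cuts are
filled afterwards from the nearest unwrapped neighbour, preserving the
mod-2π congruence, and counted in `branch_cut_px`. The global offset is
chosen so the minimum is zero; because that constant is generally not a
multiple of 2π it is recorded as `offset_rad`, and the wrap-round-trip
identity holds for `phase + offset_rad`.

**Height conversion.** h = φλ/(2π·p·Δn). Defaults: λ = 0.633 µm (red
LED), Δn = 0.037 (cytoplasm 1.370 vs medium 1.333), pass factor p = 2
(reflective Linnik geometry illuminates the sample twice). Both Δn and p
are calibration parameters, not constants, since the single-pass vs
double-pass convention differs between instruments.

## Segmentation

Cells are cropped by manually drawn bounding boxes (ImageJ "Measure" CSV
dialect; converted on import to 0-based, half-open pixel rectangles).
Each crop is thresholded by **local median**: foreground iff
img > median over the (2r+1)² window + offset, r = 50 px, edge-replicated.
The default implementation quantizes the crop to 12 bits over its own
range and runs a sliding-histogram rank filter — the exact float median
at this radius costs ~10 s per crop versus ~0.3 s — and compares image
and median in the quantized domain, so the tie case (pixel equal to its
window median, as on any smooth gradient) resolves to background exactly
as in the float path. Differences below one quantization step
(range/4095, sub-nanometre for typical height crops) are not resolved.
The rule is exactly invariant under adding a constant. An exact float
path (`method="exact"`) and an 8-bit ImageJ-compatibility mode (quantize
the crop before thresholding) are available.

The threshold **offset** defaults to 0. On noiseless synthetic
reconstructions a zero offset is degenerate — any positive fluctuation
above the local median, however small, becomes foreground — so the
synthetic protocol uses offset = 0.05 µm, roughly 2–3× the RMS
reconstruction ripple of the optical round trip; real instruments bury
this regime in axial noise and 8-bit quantization.

Cleanup is one erosion then one dilation with a 3×3 square (binary
opening, removes isolated pixels); the largest 8-connected component is
kept, ties broken by first pixel in row-major order. Background
correction subtracts the mean height over the complement of the
all-particles mask (the cleaned mask before largest-object selection),
making the background mean exactly zero and the operation idempotent.
Auto-vs-manual agreement is reported per feature as
|F_auto − F_manual|/|F_manual| × 100 (undefined entries flagged, not
averaged) plus mask IoU and boundary overlays.

## Morphometry

Bulk features integrate over the mask: projected area = N·px²,
volume = Σh·px², dry mass = V·Δn/α with α = 0.19 µm³/pg by default
(warned outside 0.15–0.25). Under the uniform-index model
dry_mass = volume·Δn/α holds exactly and is asserted as an invariant.

**Surface area** triangulates the height landscape: corner heights are
means of adjacent in-mask pixel-center heights, each pixel quad
contributes two triangles, and the one-pixel dilation ring around the
mask contributes only its *excess* area over a flat quad. The ring term
captures the descent of the surface to the background at the cell edge
without adding anything for flat surroundings: a globally flat field
yields exactly the projected area, zero heights yield exactly the
projected area, and a digitized hemisphere (R = 10 µm) measures within
0.2% of 2πR² at 0.05 µm/px (within ~1.2% at 0.1 µm/px). Pure
mask-clipped corner averaging without the ring term underestimates the
hemisphere by 6–9%, which is why the skirt is part of the estimator.

**Height moments** are population moments over mask pixels; kurtosis is
non-excess (normal → 3). Constant heights give variance 0 with
skewness/kurtosis flagged NaN.

**Shape.** The perimeter traces the Moore (8-connected, clockwise)
boundary chain and sums corner-corrected step weights — 0.948 axial,
1.343 diagonal (Kulpa). Raw 1/√2 weights overestimate a digital circle's
circumference by ~6%, pushing disk circularity to 0.91; the corrected
weights keep digital circles within ~1% and disk circularity ≥ 0.95. A
Crofton estimator is available via `perimeter_estimator="crofton"`.
Circularity is min(1, 4πA/P²); eccentricity is √(1 − λ₂/λ₁) of the
second-central-moment ellipse (cross-checked against
`skimage.regionprops`); the complexity score is
(hull − area)/hull with the convex hull taken over boundary pixel
centers (scipy Qhull; clipped at 0 because the hull of centers can fall
just inside the pixel-count area for convex shapes); sphericity is the
dimensionless π^{1/3}(6V)^{2/3}/SA. A 1-pixel mask takes the degenerate
path: eccentricity 0, complexity 0, perimeter = one pixel outline.

## Statistics

**Wilcoxon signed-rank** (paired, two-sided). Zero differences are
dropped before ranking (Wilcoxon's convention; Pratt's available).
|d| are ranked with average ranks for ties; W⁺ is the positive-rank sum.
For effective n ≤ 25 the exact null distribution is enumerated by
dynamic programming over the (doubled, integer) rank lattice —
equivalent to the full 2ⁿ enumeration, verified against it to 10⁻¹² —
with p = min(1, 2·min(P(W ≤ w), P(W ≥ w))). Above the threshold, a
normal approximation with tie correction (−Σ(t³−t)/48 in the variance)
and a 0.5 continuity correction is used; its empirical size at α = 0.05
is 5.3% over 2,000 null replicates of 50 pairs. Summary rows report mean
difference, SEM = sd(d)/√n, W⁺, p, and a significance flag at α = 0.05.
No multiple-testing correction is applied by default (features are
reported per row); Benjamini–Hochberg sits behind a flag that also
annotates the output.

**Mann–Kendall tau-b.** S = Σ_{i<j} sign(x_j − x_i);
tau_b = S/√((D−T_x)(D−T_t)) with tie corrections (T_t = 0 for an ordered
series); variance with tie correction and a continuity correction of 1.
A strictly monotone series of 7 points gives tau = ±1 with p ≈ 0.0027.
Trends are computed on per-timepoint cohort means by default (the
aggregate-curve reading of a temporal analysis); a per-cell mode exists.

**Rayleigh bubble energy.** E = (4/3)π R³ Δp, reported in nJ. Δp
defaults to 101,325 − 2,339 Pa (1 atm minus the saturation vapor
pressure of water at 20 °C) and is configurable, because the driving
pressure assumed by any given published estimate is rarely stated. For
R = 21 µm this gives 3.84 nJ.

## Synthetic data

**Phantom cells.** A cell is a cosine cap h = H·cos(πr/2R) (finite rim
slope — a raised-cosine profile has zero rim slope and an unsegmentably
shallow skirt) plus n tapered radial ridges at equal angles: each branch
runs from 0.5R to 0.5R + L, its height falling linearly from the dome
height at the root to zero at the tip, with a cosine cross-profile whose
half-width shrinks by 80% along the branch. The truth mask is the exact
support; truth features are computed on a noiseless 4×-supersampled
rendering, giving a numeric ground truth independent of the native
discretization. Complexity grows monotonically as branches are added
(0 → 0.68 for 0 → 6 branches at default geometry).

**Rendering.** The forward model is the fringe equation above with
φ = 2π·p·Δn·h/λ, bias 1, modulation depth 0.8, optional Gaussian
intensity noise and linear illumination tilt. Defaults chosen once for
the synthetic protocol: diagonal carrier (0.25, 0.25) cycles/px
(maximal side-lobe separation) and 0.25 µm/px sampling — a 20×/0.4 NA
system with a standard ~5 µm camera pixel. Under these conditions the
full optical round trip recovers phantom heights with RMS error ≈ 1% of
peak, and the end-to-end pipeline (12 phantoms, one frame) recovers
truth volume to ~0.3% and projected area to ~2% mean absolute percent
error in ~6 s.

**Cohorts.** The fast (feature-space) generator draws, per cell, a
lognormal heterogeneity factor (sd 0.3, mean-centred) per core feature,
constant across time; each record multiplies baseline × effect ×
a lognormal measurement factor (sd 0.05, mean-centred). Baselines are
control-cohort-scale values (volume ≈ 3,055 µm³, projected area ≈
1,125 µm², etc.). The shock-response model applies, at +10 min, an
immediate compaction + circularization (surface area ×0.873, perimeter
×0.846, projected area ×0.851, circularity ×1.15, volume ×1.115, height
variance ×1.49) and then interpolates log-linearly in time to the +2 h
multipliers (partial recovery: volume ×0.985, surface area ×0.957,
circularity ×1.20). Because the per-cell factor cancels from cohort
means, the mean series moves by the effect curve ± measurement noise
/√n; at n ≈ 200 the ~2% per-step trend dominates the ~0.35% standard
error, so the post-shock mean series is strictly monotone and tau-b
reaches ±1 essentially surely, for any seed. The control model is the
identity: over a 2 h window, typically ≥ 15 of 16 features test
non-significant. Ratio features (SA/V, SA/dry-mass, PA/V,
perimeter/area, sphericity) are recomputed from their components per
record, never drawn independently. The timepoint grid merges the two
imaging schedules: −20, −1, +10, +30, +50, +70, +90, +110, +120 min.

The full (image-space) generator writes multi-page TIFF frames with
cells tiled on a grid (16 px border margin), ImageJ-dialect box CSVs,
truth-feature CSVs and a manifest, so the pipeline runs on it exactly as
on real data. The shock response maps onto geometry as branch retraction
(branch length × perimeter-effect³) and body swelling (height ×
volume/area effect); image-space effect sizes are qualitative, not
calibrated to the feature-space multipliers.

What the synthetic data does *not* emulate: optical aberrations and
flat-field error, shot/read noise statistics, cell-to-cell contact,
debris, focus drift, and real astrocyte texture. Passing the end-to-end
checks therefore demonstrates correctness of the algorithms under the
stated imaging model, not segmentation robustness on real micrographs.

## Problem sizes and determinism

Default test and acceptance workloads are sized for a laptop-class
single core: 12-cell image cohorts, 204-cell feature cohorts, 2,000-
replicate null calibrations, 50-field residue sweeps. Every stochastic
component draws from a `numpy.random.default_rng` seeded explicitly;
pipelines are bit-reproducible given (config, seed), and the run
directory records a config hash that must match on re-runs unless
forced.

## Known limitations

* Branch cuts are rasterized pixel chains; pathological residue
  configurations can isolate regions, which are then filled by
  nearest-neighbour continuation and reported, not silently accepted.
* The quantized median threshold cannot separate structures whose
  height differs by less than range/4095 of the crop.
* Feature-space and image-space cohort modes are calibrated
  independently; only the feature-space mode carries the quantitative
  effect multipliers.
* Sphericity is reported dimensionless; conventions differ between
  tools, and values are only comparable within one convention.
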