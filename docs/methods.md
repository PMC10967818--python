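# Methods

## Scope

`opdcyto` implements the computational side of a label-free neutrophil
subtyping assay: interferogram → OPD map → single-cell features → H/L
classification → cohort comparison. Because no raw image data are
publicly available for this assay, the package ships a synthetic phantom
generator whose defaults encode the study conditions; all quantitative
guarantees in the test suite are statements about that generator plus the
algorithms, not about any particular instrument.

## Phantom model

A cell is a disk of radius `r` (default from the drawn area,
`r = sqrt(S_C/π)` ≈ 5.6 µm) with a plateau-with-cosine-rim thickness
profile: constant for ρ ≤ 0.8 r, falling as `½(1+cos)` to zero at ρ = r.
The profile is C¹ at the rim, which keeps the phantom's spectrum compact
(important for honest round-trip testing), and matches the pancake-like
appearance of neutrophils settled in a flow chamber. On top of it:

* **nucleus** — `round` (offset disk, 0.45 r), `banded` (disks along a
  240° arc) or `lobed` (k offset disks, default 3); the nuclear region is
  multiplied by the class OPD contrast: < 1 for H cells (decondensed
  chromatin is optically thin), > 1 for L cells. Class/morphology
  combinations that contradict this are rejected.
* **vesicles** (H cells only) — Gaussian bumps of radius ~0.5 µm placed
  in the cytoplasmic plateau, amplitude 150 nm before rescaling,
  modelling ROS-containing granules with locally high OPD.

The whole profile is smoothed with a σ = 2.5 px Gaussian (≈ 220 nm at the
0.0867 µm/px object pitch — about the diffraction-limited PSF of a
60×/1.42 objective at 630 nm), masked to exactly zero outside the cell,
and finally rescaled by one global factor so that the integrated dry mass
`pitch²·ΣOPD/α` equals the requested target exactly. All relative
morphology statements (nucleus dimmer/brighter than cytoplasm, vesicles
above the cytoplasmic mean) are invariant under that rescale.

### Cohort calibration

Per-cell features are drawn from truncated normals (truncation at 0)
with the reported per-class means: area 100/98 µm², perimeter 54/51 µm,
⟨OPD⟩ 120/200 nm, dry mass 59/96 pg for H/L. Intra-class dispersions are
not reported anywhere, so SDs default to 15% of the mean and are
exposed in `CohortParams`. The four features are drawn independently;
real features are correlated (dry mass is literally S_C·⟨OPD⟩/α), which
makes the synthetic classes somewhat *more* separable than the real
ones — synthetic classifier accuracies land near 98% where the reported
real-data accuracies are 88–90%. Passing tests therefore demonstrate
algorithmic correctness under the stated means, not real-data effect
sizes. Mixing weights default to 20% H (healthy-donor-like "BBD") and
4% H (high-risk-"MDS"-like). Rendered cohorts take the drawn area and
dry mass as geometry/mass targets; perimeter and ⟨OPD⟩ then follow from
the rendered shape rather than the drawn values.

All randomness flows from explicit integer seeds; drawing and rendering
are bit-reproducible.

## Interferogram synthesis

`I = a(1 + v·cos(2π f·r + 2π·OPD/λ))`, a = 110 counts, visibility
v = 0.8, quantized to 8 bits, by default embedded in the full
1024 × 1280 camera raster (5.2 µm pixels, 60× magnification, λ = 630 nm).
Optional additive Gaussian intensity noise with SD expressed as a
fraction of `a`. The carrier defaults to (0.2, 0.2) cycles/px
(3.5 px/fringe at 45°, |f| ≈ 0.283): it must leave room between the +1
order and DC for the demodulation window (below), and a 5 px/fringe
carrier was measurably too slow — the admissible window then clips the
cell's own spatial band and the round-trip error grows several-fold.

## Reconstruction

1. Subtract the mean and apply a Tukey border taper (8% per edge):
   the raster is not periodic and an untapered carrier leaks Dirichlet
   tails across the whole spectrum.
2. FFT; multiply by a circular raised-cosine window (flat inner 60%,
   cosine taper to the rim) centred on the carrier. Default radius
   0.8·|f|: at 0.5·|f| the window truncates the phase-gradient sidebands
   of steep high-OPD rims (≈2 nm residual at an 800 nm peak); 0.8·|f|
   brings that below 1.5 nm while the taper still keeps the narrow DC
   order out. The carrier is taken from the config or estimated as the
   half-plane spectral argmax with parabolic sub-bin refinement.
3. Inverse FFT and demodulate by `exp(−2πi f·r)` — exact for non-integer
   carriers.
4. Unwrap the phase. Default: reliability-sorting unwrapping
   (scikit-image); alternative: DCT/Poisson least-squares, recentred by
   the circular mean offset. Pixels with fringe amplitude below 0.2× the
   median (the taper frame) are excluded from unwrapping and reported as
   zero OPD. Both unwrappers are congruence-restored so output − input
   is an exact multiple of 2π.
5. Convert `OPD = φ·λ/2π` (nm) and flatten the background: a
   total-degree-2 polynomial surface is least-squares fitted to
   background pixels and subtracted, with MAD-based outlier rejection.
   When no cell mask is supplied, the background is found by iterative
   sigma-clipping: plane fits (a plane cannot cup into a cell even when
   the cell covers half the raster) with positive residuals beyond
   4 robust σ clipped — the noise scale is estimated from the lower
   residual side only, because the cell contaminates the upper side —
   then one final fit at the requested order.

Measured round-trip fidelity on default phantoms (in-cell RMSE, 8-bit
quantized): 0.2–0.7 nm noise-free, < 2 nm at 1% intensity noise,
~1.5 nm at an 800 nm OPD peak; a full camera frame reconstructs in a few
seconds.

## Morphometry

Segmentation: `OPD > 40 nm` (far below the 120–200 nm cell means, above
reconstruction noise; Otsu-free simplicity is deliberate), dilated by a
2 px disk, largest connected component kept. The 3D features are
computed over the dilated mask; the near-zero rim pixels picked up by
dilation dilute ⟨OPD⟩ slightly, which is accepted and shared by both
classes. Area = pixel count × pitch²; perimeter by the weighted
chain-length estimator (diagonal-corrected; ≈ +5% bias on smooth disks)
or the Crofton estimator (near-unbiased on disks), selectable. Dry mass
in pg via `M = S_C·(⟨OPD⟩/1000)/α`, α = 0.19 µm³/pg.

## Classification

"The threshold where the two CDFs intersect" is ill-posed literally: the
CDFs of stochastically ordered samples only meet at the extremes. The
operational reading is the crossing of the H *survival* curve with the L
CDF, i.e. the minimizer of the balanced misclassification rate
`½[P̂(H ≥ t) + P̂(L < t)]`, evaluated on every gap between adjacent order
statistics of the pooled sample; a tied minimizing interval returns its
midpoint. Orientation is fixed — H below the threshold — and exact ties
classify as L (conservative toward the majority class). The logistic
model standardizes features per training split (pg and nm scales differ
by ~10³), uses unregularized maximum likelihood, stratified 5-fold CV
with a fixed shuffle seed, and reports the fold-mean accuracy; the
deployed coefficients are refit on all data with their scaler stored in
the model JSON.

## Cohort analysis

The perimeter gate keeps cells within the [5th, 95th] percentile band of
an explicitly supplied reference distribution (the sorted-cell table),
using linear-interpolation percentiles; bounds are inclusive. Group
comparison pools counts across a group's samples (the pooled fraction is
identically the cell-count-weighted mean of per-sample fractions, which
are also reported) and applies the pooled-variance two-proportion z test,
two-sided. Per-feature comparisons use the two-sample t test — Welch by
default, pooled available. No multiple-testing correction is applied:
the design has single planned comparisons.

## Pipeline

One flat `PipelineConfig` holds every tunable; YAML round-trips
losslessly and unknown keys are rejected. The default run is
feature-level (cells as drawn feature rows; seconds for the full
575/481-cell study); `render=True` pushes every cell through
phantom → interferogram → reconstruction → segmentation, at a few
hundred ms per cell, and is exercised in the tests at reduced counts.
Problem sizes in the test suite (e.g. 500 simulated cohort pairs for the
power check, 200 replicates for the significance-pattern check, 10⁴
draws for calibration bounds) were chosen as the smallest sizes at which
the corresponding binomial/SE bounds are meaningful. The manifest
records the config snapshot, package version, per-stage cell counts and
timestamps; feature tables and results are byte-identical across runs
with equal config and seed (timestamps live only in the manifest).

## Known limitations

* Feature draws are independent within a class; the algebraic coupling
  M = S_C·⟨OPD⟩/α holds only for rendered phantoms, not drawn tables
  (the reported class means are internally inconsistent with the product
  relation anyway — mean of products ≠ product of means).
* The phantom nucleus/vesicle geometry is parametric and stylized; no
  fluorescence channels, no motion blur, no multi-cell scenes, no
  touching-cell splitting.
* The optical model omits the physical grating/4f relay and the 6 nm
  source bandwidth; the interferogram is an ideal two-beam cosine.
* A dry-mass-only threshold misassigns a few percent of L cells under
  the default overlap, so observed H fractions in mixed cohorts sit
  above the mixing weight; the two-feature logistic reduces but does not
  remove this. Group-level significance is unaffected.
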