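# Methods

This note documents the models, procedures and numerical choices behind
`patchcascade`, and what the synthetic-data tests do and do not establish.

## Synthetic cohorts

The generator produces cohorts of gray-matter-density-like volumes with the
statistical structure the patch-sampling analysis assumes of spatially
normalized data, and nothing more:

* **Template.** A fixed smooth pseudo-anatomy shared by all subjects: a
  broad central ellipsoidal mass plus six low-frequency Gaussian bumps at
  fixed fractional positions, smoothed with a Gaussian of FWHM
  `background_smoothness_mm` (default 9 mm at full size) and normalized to
  peak 1. The template is drawn from a fixed internal seed so the "anatomy"
  is identical across cohorts; only subject-level randomness varies with
  the cohort seed. Per-subject misalignment is modeled as a random
  sub-voxel translation (amplitude ≤ 1 voxel, trilinear interpolation) —
  the residual error one expects after nonlinear spatial normalization.
* **Atrophy.** Each configured site is a sphere (center voxel, radius in
  voxels) inside which disease-class volumes are multiplied by (1 − δ),
  with a 2-voxel linear soft edge; δ ∈ [0, 1] is the fractional intensity
  reduction. Multiplicative loss mimics modulated density reduction without
  committing to anatomy. A configurable fraction of disease subjects has
  the *first* listed site spared, modeling patients whose primary region is
  preserved.
* **Noise.** Independent per-voxel additive Gaussian noise (default SD
  0.05 intensity units) applied after atrophy; intensities are clipped to
  [0, 1 + 5·noise_sd] since density maps are nonnegative.

Default site placement is a mirrored pair at fixed fractional coordinates
(on the standard 121×145×121 grid: centers (42, 62, 42)/(78, 62, 42),
radius 8 voxels, δ = 0.3) — medial-temporal-like in location only. No
quantitative calibration of δ to real disease effect sizes is claimed or
attempted; δ is a free simulation parameter.

**What passing tests show.** That the pipeline recovers planted signal in
the stated direction: site-covering patch conditions beat site-excluding
ones, zero-δ cohorts score at chance, accuracy is nondecreasing in δ. They
do **not** show that any architecture or patch layout would achieve any
particular accuracy on real MRI: the synthetic anatomy has no tissue
boundaries, no scanner or site effects, no registration failures, and a
single-site signal far simpler than diffuse disease pathology.

## Preprocessing

Two operations on already-normalized volumes: a centered bounding-box crop
(margins split evenly, left margin floored when odd; `origin_offset`
accumulates crop provenance) and separable Gaussian smoothing with
per-axis sigma `fwhm_mm / (voxel_size_mm · 2√(2 ln 2))`, reflected
boundaries. Reflection keeps a constant volume constant and conserves
total intensity (the unit-impulse response is verified against a dense
convolution oracle in the tests). Whether the original bounding box was
centered or data-driven is not knowable from the design alone; centered is
the default, and a tightest-nonzero-box variant can be had by cropping to
the mask's extents.

## Patch geometry

Start offsets along each axis are evenly spaced with endpoint anchoring:
`offset_i = round_half_down(i · (extent − patch_len)/(count − 1))`, first
at 0, last flush with the volume. This is the unique reproducible layout
consistent with "overlapping patches covering the whole volume"; coverage
is audited voxel-by-voxel, and infeasible (count, size) pairs are
rejected. Counts are explicit configuration: published totals that do not
factor into per-axis covering counts (e.g. 28 patches of 32³ or 72 of 24³
on a 91×115×91 grid, where minimal covering grids have 36 and 80) can be
planned with coverage checking disabled plus an optional filter that drops
patches whose nonzero-voxel fraction falls below a threshold (default 0 —
no dropping). ROI patches are centered on configured coordinates (floored
on odd margins) and clamped into bounds; no anatomical atlas is bundled,
so hippocampus-like coordinates are supplied by the caller.

The Monte-Carlo mean pairwise distance draws continuous-uniform point
pairs over the physical box (sides = voxels × voxel size) — not voxel
centers — which makes the estimate exactly linear in voxel size and
reproduces 0.661707·a for a cube of side a. Sampling is chunked (10⁶
pairs per block) to bound memory at the standard 10⁷-pair runs; the
standard error is reported alongside the mean.

## Architecture and numerics

Pooling uses ceil rounding (same-padded pooling): floor rounding would map
91 → 30 in the first subject-level block and contradict the published
31×39×31, so the convention is forced by arithmetic; the same arithmetic
forces a single input channel. Dropout ("first two FC layers") is placed
after the FC1 and FC2 activations. The L2 strength is unspecified in the
design and defaults to 1e-4 (configurable). The patch subnetwork's own
dense head exists only for patch-level pretraining; fusion consumes the
flattened Conv4 features and discards the head.

The execution backend is a numpy engine implementing exactly the declared
layer set: same-padded stride-1 convolution via im2col, block max-pooling
with −∞ padding for ceil rounding, inverted dropout, He-initialized
float32 weights, softmax cross-entropy with per-sample class weights
(w_c = N/(2·N_c)), L2 decay on conv/dense kernels only, and Adam
(β₁ = 0.9, β₂ = 0.999, ε = 1e-8). Gradients are verified against central
finite differences; the built model's parameter arrays match the closed
form layer by layer; traced tensor shapes match the spec propagation.
Early stopping monitors the validation loss (validation accuracy is a
configurable alternative), counts epochs without strict improvement, stops
at the configured patience (default 20), and restores the best-validation
checkpoint.

Determinism: every random draw — template bumps, subject jitter and noise,
split permutations, weight init, batch order, dropout masks — descends
from explicit seeds via `SeedSequence`; per-subnet seeds derive from
(experiment seed, repetition, patch index), so one global seed fixes the
entire experiment.

## Evaluation protocol

Splits use largest-remainder apportionment of the 70/10/20 fractions
within each class (ties by train < val < test order); with 187/229
subjects per class this yields (131, 19, 37) and (160, 23, 46). Matched
undersampling is greedy in ascending disease-subject id, each keeping the
unused control with minimal mean voxelwise absolute intensity difference,
without replacement — deterministic, exact balance whenever controls are
the majority, and not claimed to be an optimal assignment. The decision
threshold on the disease-class probability is 0.5; AUC is the rank
(Mann–Whitney) statistic with ties counted ½.

The repeated-measures ANOVA uses the standard within-subject
decomposition (conditions tested against the subject × condition
interaction), Mauchly's W from orthonormal contrasts with the first-order
chi-square approximation, and the Greenhouse–Geisser epsilon applied to
both degrees of freedom when Mauchly's p < 0.05. Tukey post hoc pairs use
the studentized-range distribution on the same within-subject error term.
All conditions inside one repetition see identical splits and identical
balanced test sets — the pairing that the within-subject analysis
requires. "Training set reduced by half" means a random stratified half of
the training subjects per repetition, validation and test untouched.

## Size profiles

The full-size profile mirrors the design exactly: 121×145×121 volumes
cropped to 91×115×91 at 1.5 mm, channels 8/16/32/64, dense heads
1024/128/2 and 2048/512/2, Adam 1e-4, batch 24, dropout 0.5, 300
subject-level / 200 patch-level epochs, patience 20, 20 repetitions.
Training it is a GPU-scale undertaking and is not exercised by the tests.

The desk profile — the package's own choice of problem sizes for CPU runs
— shrinks everything proportionally: 30×38×30 volumes (test fixtures go
down to 18×22×18 and 24×30×24), 16³ patches (the smallest the four
pooling stages admit), channels 4/8/8/16, dense heads of tens of units,
learning rate 1e-3, batch 8, ~25–30 epochs with patience ~6, 5 seeds or
repetitions. The acceptance tests run the direction/null/monotonicity
probes at this scale in under a minute total.

## Known limitations

* The synthetic anatomy is a smooth blob, not a brain; conclusions about
  relative merits of patch layouts on real data do not follow.
* The numpy engine is single-threaded-BLAS-bound and intended for
  desk-scale experiments; it implements only the layer set these
  architectures need.
* Mauchly's p uses the first-order chi-square approximation (the W and
  chi-square statistics match pingouin exactly; p agrees to a few
  percent, which only matters within a hair of the 0.05 gate).
* The hippocampus ROI coordinates and margins are caller-supplied; none
  are bundled.
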