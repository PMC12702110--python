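# Methods

`cdtikit` evaluates cardiac diffusion tensor imaging (cDTI) acquisition
protocols — how many diffusion-encoding directions (ND), how many repetitions
(NR), and how much low-b data to acquire — entirely on synthetic data with
known ground truth. This note documents the models, the conventions, the
tunable parameters, and the limits of what the synthetic experiments show.

## Diffusion-encoding scheme design

A scheme is an ordered set of unit gradient directions at one b-value.
Because diffusion encoding is antipodally symmetric, directions are points on
the projective sphere; schemes are generated by minimizing the symmetrized
Coulomb energy

    E = sum_{i<j} 1/|d_i - d_j| + 1/|d_i + d_j|

with projected gradient descent from a seeded random start (default 10,000
iterations, backtracking step control; deterministic per seed).

Schemes are scored by the condition number of the N×6 second-moment
transformation matrix with rows `(gx², gy², gz², 2gxgy, 2gxgz, 2gygz)`. The
matrix deliberately excludes the b-value and the log-S0 intercept: the
condition number is a property of the direction geometry alone, and this
6-column form reproduces the standard published values — 2.00 for the
6-direction dual-gradient scheme and sqrt(5/2) ≈ 1.5811 for the icosahedral
scheme, which is the 6-direction optimum. Our 30-direction repulsion schemes
converge to 1.58–1.59.

One empirical subtlety: sqrt(5/2) is *not* a floor for condition-number-
optimized subsets with N > 6. Sequential windows selected by minimizing the
condition number can reach ≈ 1.54, slightly below the icosahedral value,
because the 6-column basis weights the diagonal and off-diagonal deviatoric
modes differently and a non-uniform design can balance them. The package
asserts the sqrt(5/2) floor only for energy-optimized (near-uniform) sets.

### Incremental ordering

The 61-direction master scheme is ordered for incremental sampling: a greedy
pass appends, at each step, the direction that minimizes the energy of the
prefix; a deterministic repair pass then swaps elements wherever a prefix's
condition number exceeds 2.0, choosing the swap that most reduces the running
maximum. The repair permutes the order only — the direction set is unchanged
— and leaves every prefix of length ≥ 6 with condition number below ≈ 2.0.

### Sequential (circular) subsampling

`best_circular_subsample` enumerates every start index of a wrapping window
of the requested length and returns the start minimizing the condition
number (smallest index wins ties). Wrapping is used for windows past the last
index; without wrapping the late start positions would have no valid window.
The study's four nested schemes (6/10/18/30 directions) are windows of the
61-direction master; the 6/10/18 windows are constrained to lie inside the
30-direction window so that every plan's volumes exist in the reference
session (the deepest plans need 20 repetitions per 6-direction stratum =
8 from the 6-window shell + 12 from the 30-window shell).

## Acquisition plans

A plan pairs a high-b shell (b = 500 s/mm²) with a low-b shell (b = 50 s/mm²,
three orthogonal directions) and per-direction repetition counts. The study
grid sets NA_b500 ∈ {30, 60, 90, 120} and NA_b50 = NA_b500 / {10, 5, 3, 2},
over six direction schemes: 96 plans, plus the 720-volume reference session
(24×3 low-b + 12×30 + 8×6 + 20×6 + 4×30 high-b volumes). Nominal time is
NA_all × TR with TR = 3 s (three R-R intervals at 60 bpm; configurable).
Remainders in NA/ND splits go to randomly chosen distinct directions, so
per-direction counts differ by at most one.

## The left-ventricle phantom

A single short-axis slice: an annulus (default endo/epi radii 11.5/29.9 mm,
2.3 mm voxels, 64² grid ≈ 460 myocardial voxels). Per voxel:

* transmural depth `d = (r_epi − r)/(r_epi − r_endo)` ∈ [0, 1];
* helix angle linear in depth, +60° (endo) to −60° (epi) — the conventional
  healthy transmural profile; configurable;
* sheetlet angle of constant magnitude 33° whose sign alternates across four
  azimuthal sectors, so signed E2A averages to ≈ 0 over the slice while
  |E2A| stays at 33° — reproducing the cancellation seen when signed sheetlet
  angles are averaged over regions of opposite polarity;
* a diffusion tensor with MD 1.46×10⁻³ mm²/s, FA 0.35, and eigenvalue shape
  λ2/λ3 = 1.55, assembled in the local cylindrical frame. Eigenvalues are
  solved numerically from (MD, FA, λ2/λ3) to |FA error| < 1e-8; for fixed
  λ2/λ3 > 1 there is a positive minimum attainable FA (0.228 at ratio 1.55),
  below which the request is rejected.

Metric conventions (fixed constants of this package): the cylindrical frame
is radial-outward / circumferential (counter-clockwise from base) /
longitudinal (slice normal). HA is the angle of e1's projection in the
circumferential–longitudinal plane, positive toward longitudinal, in
(−90°, 90°]. For E2A, e1's wall-tangent projection is flipped to non-negative
circumferential component and rotated 90° in-plane to give the cross-myocyte
direction; E2A is the angle of e2's projection in the cross-myocyte/radial
plane, positive toward radial, in (−90°, 90°]. All angles are invariant to
eigenvector sign flips. Construction (`tensor_from_orientation`) inverts
these definitions exactly, so phantom ground truth round-trips through the
metric code to 1e-4° (and the noiseless end-to-end pipeline to 1e-6°).

## Signal simulation and corruption model

Noiseless signal: `S = S0 exp(−b gᵀDg)` (monoexponential tensor
representation). Corruption layers, each seeded and independently togglable:

* **Rician noise** — `sqrt((S+ε1)² + ε2²)`, ε ~ N(0, σ²) i.i.d. per voxel and
  volume, with σ = (mean noiseless myocardial b500 signal) / SNR_target.
  Default SNR_target 9.6, the magnitude SNR typical of motion-compensated
  spin-echo cDTI at 3 T. No spatial noise correlation (simplification).
* **Per-direction bias** — one multiplicative lognormal factor
  exp(N(0, 0.03)) per direction stratum, emulating direction-specific image
  quality (eddy-current) effects. The 3% scale is a design choice: large
  enough to penalize 6-direction schemes that lack redundancy, small against
  the ~10% Rician noise.
* **Outlier volumes** — each volume is attenuated by a uniform factor in
  [0.3, 0.7] with probability 0.05, emulating motion-induced signal loss;
  injected flags are recorded so detection sensitivity can be scored.

The per-repetition SNR estimator (mean/SD over repetitions, averaged over
directions then voxels) is itself biased upward at small repetition counts
(×1.38 at 4 repetitions, ×1.07 at 12, from the sampling distribution of
1/SD); checks against the target use ≥ 12 repetitions. What the simulator
does **not** model: EPI distortion, B0/susceptibility structure, motion
warps, partial volume, spatially correlated physiological noise. Passing
tests therefore demonstrate correctness of the estimation machinery and the
*direction* of protocol effects, not in vivo effect magnitudes.

## Tensor fitting

The log-linear model `ln S = ln S0 − b gᵀDg` is fitted per voxel:

* **LLS** — ordinary least squares on log-signals (closed form).
* **WLS** — weights = squared predicted signals (from the LLS iterate), two
  reweighting passes; the standard heteroscedasticity correction.
* **Robust** — IRLS with combined weight = WLS weight × Geman–McClure weight
  `1/(1+(z/c)²)²` on MAD-standardized log-residuals (scale = 1.4826·MAD,
  c = 3), iterated until the largest tensor-element change < 1e-8 or 50
  iterations. Volumes with final M-weight < 0.1 are flagged as outliers.
  With 10% of volumes attenuated ×0.3–0.7 at SNR 9.6 and 160 volumes, this
  recovers injected outliers with sensitivity > 0.8 and roughly halves the
  tensor RMS error relative to WLS.

Non-positive signals are clamped to `1e-6 × per-voxel max` before the log
(flagged, never dropped); fitted tensors are kept raw, with negative
eigenvalues clipped to zero only inside metric computation (preventing
FA > 1). The b = 50 volumes are ordinary weighted rows of the design — the
protocol has no b = 0.

A measured null result worth recording: at SNR 9.6 with this b = 50/500
protocol, LLS and WLS mean-MD biases are identical to ~1e-10 mm²/s (paired
Monte-Carlo, 1000 realizations). The log transform of Rician magnitude data
is unbiased to O(SNR⁻⁴) — E[ln M] ≈ ln S down to SNR ≈ 5 — so rectification
bias, and hence the WLS advantage, only appears near the noise floor, which
this protocol never reaches. WLS is retained as the standard initialization
of the robust fit, not for a measurable bias correction at these conditions.

## Bootknife resampling

Each direction × shell is a stratum. One bootknife sample removes one
uniformly chosen image per stratum, then draws the requested count with
replacement from the remainder; the removal corrects the plain bootstrap's
small-sample variance underestimation (verified: SD of a 12-member stratum
mean matches σ/√12 within 10% over 500 samples). Requested counts come from
the plan (low-b counts are split across the three orthogonal directions by
the same max-difference-1 rule, an assumption since published protocols
rarely state the low-b split). The removal and the draws are applied per
stratum per sample. Each stratum consumes an independent substream keyed by
(seed, sample index, CRC32 of the stratum id), so adding or removing strata
never perturbs the draws of the others. Requesting more repetitions than a
stack holds is an error naming the stratum, never silent over-sampling.

## Scoring and statistics

Accuracy = per-voxel RMSD between bootstrap samples and the full-reference
map; precision = per-voxel SD across samples (precision ≡ SD⁻²). HA and E2A
are axial (period 180°): differences are wrapped to (−90°, 90°] and SDs are
taken about the doubled-angle circular mean. Wrapping matters near ±90° —
a plain SD of angles clustered across the boundary is ~50× too large — and
published pipelines rarely state their handling, so the unwrapped variant is
also available (`sd_map(..., wrapped=False)`). ROI aggregation averages over
masked voxels, with optional exclusion of azimuth sectors (12 equal wedges
about the LV center by default; a septal-style ROI is two contiguous wedges —
a stand-in for AHA segments 8–9, which need anatomical landmarks the phantom
lacks). Scheme comparisons use paired t-tests across replicates (independent
phantom noise realizations standing in for subjects) with Bonferroni–Holm
correction; confidence intervals of pooled-sample means use the normal
approximation.

## Experiment orchestration

`run_experiment` simulates one reference session per replicate and draws
every plan's bootknife samples from that same session — subsampled plans are
therefore not independent of the reference or of each other, intentionally
mirroring a single-scan subsampling design. Everything derives from explicit
seeds; rerunning a config reproduces outputs exactly, and the manifest
records the config hash and sizes.

## Problem sizes used in the test suite

The heavier synthetic experiments run at reduced scale, chosen as the
smallest sizes at which the checked effects are statistically stable: the
scheme-ordering experiment uses a 32² phantom (≈ 116 voxels, radii scaled to
5.75/14.95 mm), 100 bootstrap samples, and 5 replicates; the SD-halving
check uses 200 samples; noiseless round-trips and parameter-recovery checks
use the full 64² phantom. At these sizes the ND = 30 vs ND = 6 orderings
and the low-b trends reproduce with comfortable margins (e.g. ~14% lower MD
RMSD and ~22% lower FA RMSD for ND = 30 at matched 8-minute scan time).

## Known limitations

* The 61-direction master scheme is a stand-in generated by this package;
  published coordinate tables for the historical schemes are not included,
  so condition numbers match published values to ~±0.05, not digit-exact.
* Single 2D slice; slice thickness is metadata only.
* Corruption magnitudes (bias 3%, outlier rate 5%, attenuation 0.3–0.7) are
  design choices calibrated to be plausible, not fitted to any dataset.
* Volunteer-level effect sizes (e.g. 48% RMSD reductions) are not
  reproducible from synthetic data; only directions and rough magnitudes of
  protocol effects are.
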