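# cdtikit

Cardiac diffusion tensor imaging (cDTI) protocol design and evaluation.

In vivo cDTI of the myocardium is slow and noisy: motion-compensated spin-echo
acquisitions at 3 T reach magnitude SNR of only ~10 at b = 500 s/mm², and
every extra diffusion-encoding direction (ND) or repetition (NR) costs scan
time. Protocol designers must therefore decide how to spend a fixed time
budget — more directions, more repetitions, or more low-b volumes — and how
to quantify what each choice buys in the accuracy and precision of the
clinical metrics: mean diffusivity (MD), fractional anisotropy (FA), helix
angle (HA), and sheetlet angle (E2A). `cdtikit` is a toolkit for making that
trade-off quantitatively, aimed at MR physicists and methods researchers.

It provides, as composable library modules with a thin CLI on top:

* **`schemes`** — electrostatic-repulsion direction-set generation
  (antipodally symmetrized, incremental orderings), condition-number scoring
  of the N×6 encoding matrix, sequential circular subsampling, and the
  two-shell (b = 50/500 s/mm²) acquisition-plan algebra
  (`NA_all = NA_b50 + NA_b500`, nominal time = NA_all × TR).
* **`phantom`** — a digital short-axis left-ventricle slice with known
  ground-truth tensors (transmural ±60° helix angle, sector-alternating
  sheetlet angle, MD 1.46×10⁻³ mm²/s, FA 0.35) and a DWI simulator with
  Rician noise, per-direction bias, and motion-outlier volumes.
* **`tensorfit`** — log-linear, weighted, and robust (Geman–McClure IRLS)
  tensor estimation with outlier flagging and signal prediction.
* **`cardiometrics`** — MD, FA, HA, E2A in a cylindrical LV coordinate
  system, with documented sign and wrapping conventions.
* **`bootstrap`** — the repetition *bootknife*: a stratified bootstrap that
  removes one random image per direction stratum before resampling with
  replacement, correcting small-sample variance underestimation.
* **`evaluate`** — accuracy (RMSD vs the full-reference fit) and precision
  (SD across bootstrap samples, precision ≡ SD⁻²), axial-angle wrapping, ROI
  aggregation with sector exclusion, paired t-tests with Bonferroni–Holm
  correction.
* **`pipeline`** — seeded, manifest-tracked experiments over the 96-plan
  study grid (6 direction schemes × 4 high-b × 4 low-b volume counts) plus a
  720-volume reference session.

See `docs/methods.md` for the models, conventions, and limitations.

## Worked example

```python
import numpy as np
from cdtikit import schemes, phantom, tensorfit, cardiometrics

# design: 61-direction incremental scheme, best sequential 30-window
master = schemes.generate_incremental_scheme(61, seed=0)
start, cn = schemes.best_circular_subsample(master, 30)
print(f"best 30-direction window starts at index {start}, condition number {cn:.3f}")

# an 8-minute plan: 120 high-b volumes, low-b at one third of that
des = schemes.circular_window(master, start, 30, name="inc30")
plan = schemes.build_plan(des, na_b500=120, b50_divisor=3)
print(f"plan {plan.name}: NA_b50={plan.na_b50}, NA_b500={plan.na_b500}, "
      f"NA_all={plan.na_all}, nominal time {plan.nominal_time_s/60:.0f} min")

# simulate at SNR 9.6 with 5% outlier volumes, fit robustly, map the metrics
lv = phantom.make_lv_phantom()
noise = phantom.NoiseModel(snr_b500=9.6, outlier_prob=0.05)
stack = phantom.simulate_dwi(lv, plan, s0=100.0, noise=noise, seed=1)
design = tensorfit.design_matrix(stack.bvals, stack.bvecs)
fit = tensorfit.fit_robust(stack.volume_signals(lv.mask), design)
maps = cardiometrics.compute_metric_maps(fit.tensors, lv.masked_frames())
print(f"median MD {np.median(maps.md)*1e3:.3f} x10^-3 mm^2/s (truth 1.460), "
      f"median FA {np.median(maps.fa):.3f} (truth 0.350)")
```

prints

```
best 30-direction window starts at index 35, condition number 1.566
plan inc30_120_40: NA_b50=40, NA_b500=120, NA_all=160, nominal time 8 min
median MD 1.461 x10^-3 mm^2/s (truth 1.460), median FA 0.351 (truth 0.350)
```

The condition number (ratio of extreme singular values of the encoding
matrix) is the figure of merit for noise propagation into the tensor — the
classic dual-gradient 6-direction scheme sits at 2.00, the icosahedral
optimum at √(5/2) ≈ 1.581, and a well-optimized 30-direction set near 1.59.
The fitted medians land on the phantom's ground truth because at NA_all = 160
and SNR 9.6 the robust fit recovers MD to a median error below 2% and FA
below 5%; six of the 160 volumes were injected as motion outliers, and the
robust fit's per-volume weights flagged five of them (the sixth was mildly
attenuated).

For a full protocol comparison across plans (bootknife resampling, RMSD/SD
scoring, paired tests), see `cdtikit.pipeline.ExperimentConfig` /
`run_experiment`, or the CLI:

```sh
cdtikit design --nd 30 --source incremental61 --seed 0 --out scheme.json
cdtikit plan --des inc30 --nab500 120 --divisor 3 --out plan.json
cdtikit simulate --plan plan.json --snr 9.6 --seed 1 --out dwi
cdtikit fit --dwi dwi --mask dwi_mask.nii.gz --method robust --out fit
cdtikit run --config experiment.yaml
```

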