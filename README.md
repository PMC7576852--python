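# liftucm

Uncontrolled-manifold (UCM) analysis of muscle-mode variability in
repetitive lifting, from raw surface EMG and motion capture to
group-level statistics — with a synthetic-data generator that plants
known ground truth through every stage.

## The problem

When a person lifts a load over and over, the trial-to-trial variability
of their muscle coordination is not all equivalent: some of it leaves the
task outcome (here, the pelvis and trunk positions) unchanged, and some
of it perturbs it. The UCM framework splits the inter-repetition
variability of muscle-mode activations into those two parts. With muscle
modes extracted by non-negative matrix factorization (`EMG ≈ W H`, W the
muscle weights, H the temporal activations, n = 3 modes) and a Jacobian
`J` (d = 2 outcomes) estimated at each 1% of the movement cycle by
regressing mean-free displacement fluctuations on mean-free activation
fluctuations `ΔH`, the variance decomposition is

    GEV  = trace(null(J)ᵀ · C · null(J)) / (n − d)
    NGEV = trace(orth(Jᵀ)ᵀ · C · orth(Jᵀ)) / d
    IMA  = log(GEV / NGEV)

where `C` is the covariance of `ΔH` across repetitions. GEV is
goal-equivalent variance (per null-space DOF), NGEV is non-goal-equivalent
variance (per row-space DOF), and a positive index of motor abundance
(IMA) means coordination variability predominantly leaves the movement
goal invariant.

The package is for movement scientists who want this analysis as a
tested, reusable pipeline: EMG conditioning (40 Hz spectral high-pass for
cardiac artifacts, rectification, 5 Hz zero-lag envelope, per-set
amplitude normalization), marker processing (6 Hz zero-lag filtering,
foot-anchored virtual frame, 10%-of-peak-velocity phase segmentation,
100-point time normalization), per-phase NMF with the VAF > 90% /
increment ≤ 3% mode-number rule, the per-1%-cycle UCM decomposition with
early/late epoch summaries, and two inference branches: penalized-spline
activation curves with Bonferroni-adjusted contrast-cycle-difference
(CCD) bands, and linear mixed models on epoch-averaged IMA/log GEV/log
NGEV with Benjamini–Hochberg–Yekutieli adjustment and estimated-
marginal-means contrasts.

## Worked example

Generate one synthetic participant at the study conditions (20
repetitions, 14 muscles, 3 planted modes) and run the full analysis
against the planted reference weights:

```python
import numpy as np
from liftucm import SynthConfig, generate_dataset, analyze_dataset, PipelineParams
from liftucm.modes import flag_contributing_muscles

ds = generate_dataset(SynthConfig(seed=1))
analysis = analyze_dataset(ds.emg, ds.markers,
                           PipelineParams(seed=1, nmf_restarts=10),
                           reference_W=ds.truth.W_true)
dec = analysis.modes["lift"]
print("retained modes (lift):", dec.k_retained)
print("VAF curve (%):", np.round(dec.vaf_curve, 1))
flags = flag_contributing_muscles(dec.W)
print("contributing muscles, mode 1:",
      [m for m, f in zip(dec.labels, flags[:, 0]) if f])
print(analysis.epochs.round(3).to_string(index=False))
print("planted IMA:", round(ds.truth.ima_true, 3))
```

prints

```
retained modes (lift): 3
VAF curve (%): [47.4 75.3 99.7 99.8]
contributing muscles, mode 1: ['TA', 'VL', 'ST', 'Longis', 'BicepsB']
segment phase epoch   ima  log_gev  log_ngev  n_excluded
 pelvis  lift early 0.488   -5.894    -6.382           0
 pelvis  lift  late 0.573   -5.936    -6.509           0
  trunk  lift early 0.479   -5.899    -6.377           0
  trunk  lift  late 0.569   -5.938    -6.507           0
 pelvis lower early 0.868   -5.721    -6.589           0
 pelvis lower  late 0.982   -5.596    -6.578           0
 trunk  lower early 0.857   -5.726    -6.583           0
 trunk  lower  late 0.977   -5.597    -6.575           0
planted IMA: 0.693
```

The VAF rule retains the 3 planted modes (the third mode lifts VAF from
75% to 99.7%, and a fourth adds only 0.1 points). Five muscles exceed
the 0.071 contribution threshold on mode 1. The epoch table is the input
to the mixed-model stage: per segment, phase and epoch, the mean IMA and
the log-variances. The epoch IMA values scatter around the planted
log(GEV/NGEV) = 0.693, as expected at 20 repetitions (single points have
one null-space degree of freedom; see `docs/methods.md`).

The same pipeline is available from the shell:

```sh
liftucm all --seed 1 --out-dir out/          # simulate -> ... -> ucm
liftucm infer --h-table h.csv --epoch-table e.csv --out-dir out/
```

All outputs are delimited text (plus a JSON ground-truth sidecar), each
embedding the configuration hash.

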