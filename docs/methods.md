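# Methods

`liftucm` implements an uncontrolled-manifold (UCM) analysis of muscle-mode
variability during repetitive lifting, together with a ground-truth
synthetic-data generator that makes every stage of the pipeline testable.
This note documents the models, the numerical choices, and what the
synthetic conditions do and do not establish about real recordings.

## Signal conditioning

**EMG.** The cardiac artifact is removed in the frequency domain: the
signal is Fourier-transformed, every bin with |f| < 40 Hz (including DC)
is zeroed on both sides of the spectrum, and the signal is transformed
back. This makes the operation an exact orthogonal projection (applying
it twice equals applying it once), and any artifact whose energy lies
strictly below 40 Hz is removed up to spectral leakage. The conditioned
signal is full-wave rectified and low-pass filtered with a zero-lag
(forward–backward) 4th-order Butterworth at 5 Hz; the design order refers
to the underlying filter, so the effective attenuation is squared and the
phase lag cancels. Negative undershoot after filtering is clipped to zero
because the envelopes feed a non-negative factorization. Each muscle is
normalized by the mean over repetitions of its per-repetition envelope
maximum, computed over the full repetition (lift onset to lower offset)
within a set; the maxima are taken from the envelope, not the rectified
signal. A 50 Hz notch is available but off by default.

**Kinematics.** Marker trajectories are low-passed with a zero-lag
4th-order Butterworth at 6 Hz. A task-aligned virtual frame is anchored
to the feet: origin at the floor projection of the mid-point of the
calcaneus markers, anterior axis toward the floor projection of the
mid-point of the first-metatarsophalangeal markers, vertical axis equal
to the laboratory vertical; the lateral axis completes a right-handed
triad. Pelvis and trunk displacements are the anterior–posterior and
vertical coordinates, in this frame, of a pelvis landmark and of the
right acromion marker. The pelvis landmark is taken from a dedicated
channel when present; otherwise the centroid of the four pelvis markers
is used as a documented approximation (the anthropometric pelvis model
that would define the landmark exactly is not reproducible here).

**Segmentation.** A lifting (lowering) phase is the contiguous region
where the acromion's positive (negative) vertical velocity stays at or
above 10% of the set's peak positive (negative) velocity. Threshold
regions separated by gaps shorter than 40 ms are merged (guarding against
single-sample dips from noise at the crossing) and regions shorter than
200 ms are discarded. Phases are paired per repetition; each lift must
precede its lower. Segmented windows are time-normalized to 100 points by
piecewise-linear interpolation (endpoints preserved); the peak reference
is per set.

## Muscle modes

Per participant and per phase, the normalized envelope cycles are
concatenated repetition-major into an `n_muscles x (100 * n_reps)` matrix
and factorized as `X ~ W H` with non-negative matrix factorization
(squared Frobenius loss, coordinate descent, seeded random
initialization, best of 20 restarts by default, tolerance 1e-6, at most
2000 iterations). Columns of `W` are rescaled to sum to one, with the
inverse scale absorbed into the rows of `H`, leaving the reconstruction
unchanged. VAF(k) = 100·(1 − ‖X − W H‖²_F / ‖X‖²_F). The retained mode
number is the smallest k with VAF(k) > 90% whose increment to k+1 is at
most 3 percentage points (the increment condition is vacuous at the
muscle count); the incremental selector stops as soon as the rule is
satisfied. Mode correspondence across participants uses greedy assignment
without replacement on the Pearson correlations of the `W` columns
against a reference participant (ties break toward the lowest reference
index); for k ≤ 4 the greedy assignment is verified against exhaustive
search in the tests. A muscle is flagged as contributing to a mode when
its weight strictly exceeds the uniform share 1/n_muscles (0.071 for 14
muscles). Fitting is per phase; a pooled-phase fit is a one-line change
(concatenate both phases first).

## UCM decomposition

At each of the 100 cycle points the across-repetition mean is removed
from the mode activations (`dH`, reps × n, n = 3) and from the
displacement components (`dDisp`, reps × 2). The Jacobian is estimated by
no-intercept least squares of each displacement component on `dH` (both
sides are mean-free, so an intercept is redundant; it can be enabled as a
diagnostic and estimates ≈ 0). A rank-deficient `dH` raises rather than
silently using a pseudo-inverse. With `C` the sample covariance of `dH`
(denominator reps − 1) and orthonormal bases `N` of null(J) and `R` of
range(Jᵀ) obtained by singular value decomposition (relative rank
tolerance 1e-10):

    GEV  = trace(Nᵀ C N) / (n − d)      goal-equivalent variance per DOF
    NGEV = trace(Rᵀ C R) / d            non-goal-equivalent variance per DOF
    IMA  = ln(GEV / NGEV)               index of motor abundance

Both quantities are basis-independent (verified by the rotation-invariance
and trace-conservation identities: (n−d)·GEV + d·NGEV = trace(C)). The
log is natural; base 10 is a trivial rescaling. Nonpositive or undefined
variances propagate as NaN, never ±inf; epoch averages exclude NaN points
with an explicit count and carry a warning flag when more than 20% of an
epoch is excluded. Epochs are the first (early) and last (late) 50 cycle
points; IMA is averaged as-is, GEV and NGEV are averaged on the log scale.

## Group-level inference

**Activation curves.** Per-subject mean H curves are modelled additively:
an unpenalized intercept per group × phase cell, a cell-specific smooth
cycle effect built from 15 cubic B-spline basis functions (evenly spaced
knots) constrained to be orthogonal to the cell intercept, with a
second-order difference penalty and a single smoothing parameter chosen
by generalized cross-validation on a 25-point log grid (a fixed-λ
override exists for deterministic tests); and subject intercepts treated
as ridge-penalized random effects. The random-intercept ridge is set from
a moment (within/between subject) variance decomposition, so the
coefficient covariance — and hence every contrast band — includes the
between-subject variance component. The contrast-cycle-difference (CCD)
between two groups in a phase is the difference of predicted cell curves
with the band δ̂ ± t_{1−α/(2g)}(df)·√var(δ̂), Bonferroni-adjusted over the
g = 6 pairwise group comparisons and pointwise in the cycle; df defaults
to the number of subjects minus one (47 for 48 subjects). A point is
significant when the band excludes zero. Under a null simulation the
pointwise family-wise error over the six comparisons is conservative
(≪ α), as expected from Bonferroni plus penalization shrinkage.

**Epoch summaries.** IMA, log GEV and log NGEV per subject × segment ×
phase × epoch are fitted with a linear mixed model (statsmodels MixedLM,
REML): fixed effects group, phase, epoch and their three two-way
interactions in sum-to-zero coding, plus a random subject intercept.
Each of the six effects gets a Wald χ² test on its coefficient block
(likelihood-ratio tests would be a straightforward alternative; Wald is
the default), and the six p-values are adjusted with the
Benjamini–Hochberg–Yekutieli step-up under arbitrary dependence
(c(m) = Σ 1/i; c(6) = 2.45). Pairwise estimated-marginal-means contrasts
(model-implied cell means averaged over the other factors; in a balanced
design these equal raw cell means) are gated on a significant adjusted
effect involving the factor, with a force override.

## The synthetic generator

One synthetic participant performs `n_reps` = 20 lift–lower repetitions
(lift 1.1 s, lower 1.2 s, 0.3 s pauses, defaults near the task's group
means), recorded as 14-channel EMG at 1000 Hz and six marker trajectories
at 250 Hz. Latent structure: 3 activation templates per phase (Gaussian
bursts over a 0.04 tonic baseline), block-structured muscle weights
(every muscle dominated by one mode, small cross-loadings), a random
full-row-rank 2×3 Jacobian, and a planted covariance `C_true` built as
`Q diag(v) Qᵀ` over stacked null/row-space bases so that the requested
GEV and NGEV per DOF hold exactly. Per-repetition activations are the
template plus mode fluctuations with per-point covariance `C_true`;
displacement fluctuations are `J_true · δ` plus a small residual noise,
added to smooth base trajectories. EMG channels are the envelope times a
band-limited (40–450 Hz) noise carrier, times a multiplicative amplitude
noise (coefficient of variation 0.05 by default), plus a cardiac-like
pulse train whose harmonics all lie below 40 Hz.

Four design choices exist specifically to make the planted truth
recoverable, and they are the main ways the synthetic data idealize real
recordings:

1. **Band-limited fluctuations.** δ is drawn white across cycle points
   and then band-limited (default 4.5 Hz, below the 5 Hz envelope
   cutoff), exactly rescaled so the per-point covariance remains
   `C_true`. Fluctuations faster than the envelope filter would be
   planted but physically unrecoverable by the pipeline's own
   definitions. White-per-point δ remains available via configuration.
2. **Repetition-periodic stochastic texture.** The carrier and the
   amplitude noise repeat exactly once per repetition period, so their
   rectification ripple is identical in every repetition and cancels from
   the mean-free fluctuations: the inter-repetition variability is then
   exactly the planted δ (plus displacement noise). Real EMG noise is not
   periodic; in real data the measured covariance carries an additional
   noise floor that this generator deliberately excludes from the
   inter-repetition channel.
3. **Self-consistent coordinates.** Weights and templates are rescaled
   from a noiseless probe so every channel's per-repetition envelope
   maximum is one; the pipeline's amplitude normalization is then a
   near-identity and `W_true`/`C_true` live in the coordinates the
   pipeline measures. Identifiability of the factorization (low baseline,
   anchored weights) is likewise a planted property: with heavily
   overlapping synergies NMF recovers the subspace but not the planted
   axes, and UCM quantities in obliquely transformed coordinates differ
   from the planted ones. Passing recovery tests therefore demonstrates
   pipeline correctness, not that NMF coordinates are identifiable in
   arbitrary real data.
4. **Repetition-invariant phase windows.** The synthetic acromion
   velocity is a sin² hump on a 0.35-of-peak shoulder: the 10%-of-peak
   crossing sits on a step edge, so detected windows are identical across
   repetitions. Rep-to-rep window jitter of even ±1 sample aliases the
   steep base trajectory into the mean-free displacement fluctuations and
   dominates the planted signal — the same artifact one should expect in
   real data when segmentation jitters. The trunk vertical fluctuation is
   cosine-tapered to zero within ±20 samples of each phase edge for the
   same reason. The stored cycle bounds are produced by applying the
   pipeline's own threshold rule to the generated velocity, so they are
   exact at motion-capture resolution by construction; the 6 Hz marker
   filter widens the detected windows by a constant −5/+4 samples,
   identically in every repetition, which the repetition-wise analysis is
   insensitive to.

Planted variance levels default to GEV 4e-3 / NGEV 2e-3 in activation
units where channel envelope maxima are one (trial-to-trial activation
s.d. ≈ 5% of peak, plausible for metronome-paced lifting) and are chosen
jointly with the 0.04 baseline so Gaussian fluctuations essentially never
clip at zero (clip fraction < 1e-3, reported in the truth record).
Group-level cohorts apply effects additively on the activation templates
and multiplicatively on the planted variance levels. Two light-weight
generators (`generate_h_table`, `generate_epoch_table`) simulate directly
at the level of the statistical models for calibration and power checks
of the inference stage without the cost of full signal synthesis.

## Problem sizes used in the shipped checks

Parameter-recovery checks run at the study scale (20 repetitions, 14
muscles, 100-point cycles). The motor-abundance recovery check uses 99
replicates (33 per planted IMA level in {−1, 0, 1}, base variance level
2e-3, NMF restarted 3 times at fixed k = 3); the observed pooled median
absolute error is ≈ 0.08. The mode-number rule check uses 10 replicate
seeds with 10 NMF restarts per k. The CCD null calibration uses 200
replicates of 24 subjects × 50 cycle points; Monte-Carlo checks of the
projection formulas use 1e6 Gaussian samples. `scripts/acceptance.py`
recomputes the same quantities at moderately reduced replicate counts
(24 recovery replicates, 60 null replicates, 2e5 Monte-Carlo samples).

## Known limitations

- The regression-residual variance at the Jacobian stage is not included
  in the variance decomposition; only the fitted subspaces are used.
- Motor-equivalence (trajectory-deviation) variants and cost-weighted UCM
  are out of scope.
- The epoch mixed model assumes one value per subject × segment × phase ×
  epoch; heavily missing designs are rejected rather than imputed.
- The GAM branch fits a single shared smoothing parameter across cells
  and assumes i.i.d. within-curve residuals; autocorrelated residuals
  make the CCD bands approximate (conservative in the shipped null
  calibration).
- At 20 repetitions the per-point GEV estimate has one degree-of-freedom
  in the null space; single-point IMA values are noisy by construction
  and only epoch or cycle averages are interpretable.
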