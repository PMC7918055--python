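# Methods

This note documents the models and procedures implemented in `emg2kin`,
the choices made where the design was genuinely open, and what the
synthetic experiments do and do not demonstrate.

## Decoding problem and pipeline

The decoder estimates 3-D hand position (cm) at a future horizon
Δ ∈ {50 … 300} ms from six channels of surface EMG alone, with no joint
model. The pipeline per trial:

1. **Conditioning.** Per EMG channel: least-squares linear detrend (DC
   offset and slow drift), median-filter despiking (default kernel 5
   samples = 5 ms at 1 kHz; the kernel is configurable), full-wave
   rectification, and a second-order Butterworth low-pass at 2 Hz giving
   the linear envelope. The 60 Hz position stream is linearly interpolated
   to 1 kHz and low-pass filtered the same way — interpolation corners lie
   far above 2 Hz, so the interpolant choice is immaterial; position is
   filtered after resampling. Filtering is zero-phase (forward–backward)
   because the analysis is offline; a causal single-pass mode exists for
   latency-realistic experiments. Zero-phase filtering of a rectified
   signal can produce negative ripple of order 1e-3, so envelopes are
   clipped at zero.
2. **Features.** Overlapping windows (100 ms window, 50 ms step by
   default) of the envelope; the working feature set is RMS and
   integrated EMG per channel (12 columns). All seven classic time-domain
   statistics (MAV, VAR, RMS, WL, IEMG, SSI, SSC) are implemented with
   their standard definitions, since the acronyms alone do not fix
   formulas; "slope sign integral" is read as the simple square integral
   Σx², the common reading in this acronym family. Features are computed
   on the envelope (the conditioned signal the pipeline produces), with a
   raw-signal option for ablation. The 50 ms step matches the horizon
   grid so that horizon shifts are whole numbers of steps.
3. **Alignment.** The target of a window ending at time *t* is the
   position sample at *t + Δ*; rows whose target falls past the end of a
   recording are dropped. The horizon is applied independently of the
   window length.
4. **Regression.** The recurrent fuzzy neural network described next.
5. **Evaluation.** Per-cycle segments, five-fold cross-validation,
   CC/NRMSE per axis and as three-axis means.

## Recurrent fuzzy neural network

Four layers: input pass-through; Gaussian fuzzification
`a_ij = exp(−(x_i − m_ij)²/σ_ij²)`; a rule layer combining memberships by
product (fuzzy AND) into a spatial firing strength `s_j = Π_i a_ij`,
followed by a per-rule internal feedback
`u_j(t) = λ_j s_j(t) + (1 − λ_j) u_j(t−1)` with λ_j ∈ [0, 1]; and a
defuzzification layer `y_o = Σ_j u_j w_jo / Σ_j u_j`. Each rule owns one
Gaussian per input; λ is indexed per rule and the recurrence uses only the
rule's own past state. The recurrent state starts at zero at every
sequence (segment) boundary.

**Normalization.** Inputs and outputs are min–max normalized to [0, 1]
using training-set extrema stored in the model; Gaussian memberships need
bounded operands, and metrics are computed on denormalized outputs. A
zero range (constant dimension) is replaced by 1 so the dimension
normalizes to a constant 0 and denormalizes exactly.

**Structure learning.** Initial rules come from seeded k-means on the
normalized inputs: centers at cluster means, widths proportional to
per-dimension cluster standard deviations (floored at 5% of the
normalized range), output weights at cluster-mean targets, λ = 0.5.
Widths are scaled by κ = √n_inputs: the product AND multiplies one
membership per input, so without compensation the firing of a typical
point collapses exponentially with input count (≈ e⁻¹² for 12 features),
and thresholds on firing strength lose meaning. With the κ scaling, a
point one cluster-SD away in every dimension fires at e⁻¹ regardless of
dimensionality. During training a rule is added wherever no existing rule
fires above the add threshold (new widths from the distance to the
nearest center, same κ calibration; weights from the current prediction),
and rules whose epoch-mean firing falls below the prune threshold are
removed at epoch boundaries, never below one rule.

**Parameter learning.** Per-sample gradient descent on
E = ½ Σ_o (y_o − ŷ_o)² in the normalized domain, with separate rates for
centers, widths, recurrent parameters and weights. The state one step
back, u(t−1), is treated as a constant in the gradient (depth-1
truncation): the update rules are per-iteration, as in real-time
learning; backpropagation through time is deliberately out of scope.
After every update λ is clipped to [0, 1] and σ floored at σ_min. If the
total activation underflows (< 1e-12) the previous output is held and the
rule base is repaired at that input, since the weighted average is
undefined at zero activation.

**Defaults** (all configurable): 10 initial rules, all four learning
rates 0.01, 50 epochs, σ_min = 1e-3, add threshold 0.1, prune threshold
1e-4. These were fixed from convergence behaviour on the synthetic tasks
and from the teacher-system experiments; none are critical within a
factor of a few.

## Synthetic data generator

The generator emulates a tabletop reaching study: two tasks — a
pick-and-pour motion in a 10 × 45 × 50 cm workspace and an obstacle path
in 20 × 30 × 20 cm — at quick (~3 s/cycle) and slow (~5 s/cycle) speeds,
5 cycles per trial separated by 3 s rest breaks, 9 trials per
task × speed (36 recordings), EMG at 1000 Hz and position at 60 Hz.

**Trajectories** are piecewise minimum-jerk (quintic) segments through
task waypoints. Interior waypoints carry finite-difference (Catmull-Rom)
velocities so the hand flows through via-points without stopping; a
rest-to-rest primitive would bring the velocity to zero at every
waypoint, collapsing the EMG drivers to baseline several times per cycle
— a stop-and-go artifact real reaching does not show. Segment durations
are proportional to inter-waypoint distance. Each cycle's waypoints are
perturbed by seeded Gaussian jitter (1% of the workspace extent per axis,
capped at 2%) so repetitions are similar but not identical; positions are
clipped to the workspace box.

**EMG** is generated as amplitude-modulated noise: channel activation is
`baseline + M · d(t + lead)`, where the drivers d are the rectified
per-axis velocities plus overall speed (K = 4, the minimal set that makes
six channels informative about three axes), M is a seeded 6 × 4 gain
matrix, and the lead is the electromechanical delay (default 75 ms, the
midpoint of the physiological 50–100 ms range; values outside that range
are rejected). The activation multiplies a Gaussian carrier band-passed
to 20–450 Hz (standard surface-EMG bandwidth) and normalized to unit mean
absolute value — so the 2 Hz envelope of the rectified signal is an
unbiased estimate of the activation — plus white sensor noise
(SD 0.05). The default calibration (baseline 0.3, gains uniform on
[0.01, 0.06] per cm/s) makes movement bursts several times the resting
tone, as in real recordings where resting muscle is nearly silent.

**What the generator does not emulate:** motor-unit physiology
(Hill-type dynamics, recruitment), powerline and motion artifacts,
electrode shift, fatigue and other non-stationarities, subject-to-subject
variability beyond seeds, and measurement noise of the motion tracker.
Decoding scores on synthetic data therefore demonstrate that the pipeline
recovers kinematics whenever the envelope–kinematics coupling it assumes
is present — they are not a claim about accuracy on real recordings.
Because EMG amplitude here is proportional to hand speed with task-shared
gains, the small-workspace obstacle task has intrinsically lower
signal-to-noise (slower hands, weaker modulation) and is the hardest
condition — an informational ceiling of this generator design, whereas in
real data muscle drive does not scale down with workspace size in the
same way.

## Evaluation protocol

From each conditioned recording, one fixed-length segment per movement
cycle is cut: 7 s for quick and 9 s for slow motion, starting 0.5 s before
the cycle onset, covering preparation, movement and rest. Cycles are
randomly partitioned (seeded) into five folds; the model is trained on
four and tested on one, with the recurrent state reset at every segment.
NRMSE divides the RMSE by the *actual* series' range. Metrics are
computed per test segment and averaged across segments within a fold
(robust to a single bad segment); a pooled mode that concatenates
segments first is available behind a flag. Conditions (speeds, tasks) are
compared by a classic pooled-variance two-sample t-test across fold
scores, with Welch's variant as an option. The horizon sweep
cross-validates at each Δ from 50 to 300 ms in 50 ms steps; with a 75 ms
generative lead, error is flat through ~200 ms and rises by 300 ms, since
transitions from rest to movement cannot be anticipated further ahead
than the electromechanical lead.

Reduced problem sizes are used for the shipped analyses (3 trials per
condition, i.e. 15 cycles per condition, five-fold CV); these were chosen
so the whole analysis reruns comfortably on a laptop-class single core
while leaving the protocol itself — segmentation, folds, horizons —
unchanged.

## Numerical notes and edge cases

- Memberships and firing strengths lie in (0, 1]; recurrent states are
  convex combinations and remain in [0, 1]; normalized outputs are convex
  combinations of rule weights.
- Gradients avoid division by memberships (the σ/m chain uses
  `g_s · s_j` directly), so underflowing memberships cannot produce
  non-finite gradients; non-finite gradients abort with diagnostics.
- The NRMSE of a constant actual series and the CC of a zero-variance
  series are undefined and raise a named error rather than returning NaN.
- A t-test between two identical constant samples returns (0, 1); a
  degenerate-variance comparison between unequal constants raises.
- Determinism: all randomness flows from explicit integer seeds (master
  seeds are split with `numpy.random.SeedSequence`); identical seeds give
  bit-identical recordings, fits and reports.

## Known limitations

- Gradient truncation at depth 1 means λ is trained against a biased
  estimate of its long-run effect; λ values should be read as effective
  smoothing constants, not identified dynamics.
- Online rule addition is order-dependent (earlier samples shape the rule
  base seen by later ones); two shufflings of the same training data can
  yield different rule counts with similar accuracy.
- The strict prediction model has no access to position history at test
  time; it cannot outperform the information actually present in the EMG
  lead, so horizons far beyond ~100 ms rely on movement regularity.
- Per-segment CC on short segments is a noisy statistic; comparisons
  between conditions should use the provided t-tests across folds, not
  single-fold differences.
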