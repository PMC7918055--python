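# emg2kin

Continuous decoding of 3-D hand position from surface electromyography
(EMG), for offline myoelectric-interface research. The package implements a
complete pipeline — signal conditioning, windowed time-domain feature
extraction, a recurrent fuzzy neural network (RFNN) regressor, and
cross-validated evaluation across prediction horizons — together with a
synthetic generator of synchronized EMG + kinematics recordings, so every
stage can be developed and tested without human-subject data.

## The problem

Muscle electrical activity precedes mechanical tension by roughly
50–100 ms (the electromechanical delay). A decoder that maps the EMG
feature vector at time *t* to the hand position at *t + Δ* can therefore
predict near-future motion — useful as an intention channel in
human–robot collaboration, where only the arm's endpoint matters and no
joint-angle model is wanted. The pipeline here is a strict prediction
model,

    φ(t + Δ) = ψ(f_EMG(t)),    Δ ∈ {50, 100, …, 300} ms,

with `f_EMG` the 12-dimensional feature vector (6 channels × {RMS, IEMG})
computed over overlapping 100 ms windows of the 2 Hz linear envelope.

## The model

The RFNN has four layers. Inputs are min–max normalized; layer 2 fuzzifies
each input *i* against each rule *j* with a Gaussian membership
`exp(−(x_i − m_ij)² / σ_ij²)`; layer 3 combines a rule's memberships with a
product (fuzzy AND) into a firing strength `s_j` and passes it through a
per-rule internal feedback

    u_j(t) = λ_j s_j(t) + (1 − λ_j) u_j(t−1),   λ_j ∈ [0, 1],

which gives the network memory of past activation; layer 4 defuzzifies
with the activation-weighted average `y_o = Σ_j u_j w_jo / Σ_j u_j`.
Structure is initialised by k-means clustering (one rule per cluster) and
adapted online by firing-strength–based rule addition and pruning; all
parameters (m, σ, λ, w) are trained by per-sample gradient descent on the
squared error. Performance is reported per axis and as three-axis means of
the Pearson correlation coefficient (CC) and the range-normalized RMSE
(NRMSE).

## Worked example

```python
import emg2kin as ek

cfg = ek.ExperimentConfig(tasks=("Task_1",), speeds=("quick",),
                          trials_per_condition=3, master_seed=1)
recordings = ek.generate_experiment(cfg)          # synchronized EMG + motion

segments = []
for rec in recordings:                            # envelope + 1 kHz position
    segments.extend(ek.segment_cycles(ek.preprocess_recording(rec)))

reports = ek.cross_validate(                      # features -> RFNN -> metrics
    segments, ek.FeatureSpec(), ek.LearningConfig(seed=1),
    horizon_ms=250.0, seed=1,
)
print(ek.summarize_reports(reports).round(3).to_string(index=False))
```

Output:

```
 cc_x  cc_y  cc_z  cc_mean  nrmse_x  nrmse_y  nrmse_z  nrmse_mean fold  horizon_ms
0.738 0.909 0.897    0.848    0.160    0.138    0.140       0.146    0       250.0
0.738 0.934 0.889    0.853    0.167    0.118    0.146       0.143    1       250.0
0.748 0.921 0.894    0.854    0.158    0.129    0.147       0.145    2       250.0
0.796 0.913 0.919    0.876    0.156    0.137    0.135       0.143    3       250.0
0.713 0.866 0.835    0.805    0.217    0.156    0.180       0.185    4       250.0
0.747 0.909 0.887    0.847    0.172    0.136    0.149       0.152 mean       250.0
```

Each row is one cross-validation fold: the RFNN was trained on four fifths
of the movement cycles and tested on the held-out fifth. A mean CC of 0.85
means the decoded trajectories track the actual hand path closely 250 ms
ahead of the EMG; an NRMSE of 0.15 means the RMS error is ~15% of each
axis's movement range.

The same pipeline is scriptable from the shell:

```sh
emg2kin simulate --out data/ --seed 42
emg2kin evaluate --data data/ --horizon-ms 250 --folds 5 --seed 7
emg2kin sweep-horizon --data data/ --seed 7
emg2kin run --out results/ --seed 7        # end-to-end in one call
```

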