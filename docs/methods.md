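# Methods

## Task and data model

One *fraction* is a treatment session's worth of synchronized traces at a
fixed sampling rate (25 Hz throughout): positions of 1-3 external optical
markers on the chest/abdomen and of the internal tumor, each along the
superior-inferior (SI), anterior-posterior (AP) and left-right (LR) axes,
in millimetres. Sample indices are 1-based in documentation and reports
(`t = 1..t_end`); time is implicit, sample *i* at `(i-1)/rate` seconds.

The supervised arrangement: the recording is split at `t_s` into a
training segment (samples `1..t_s`) and a test segment; a stride-1 sliding
window of `t_delay` samples over all marker channels predicts the
3-vector tumor position `t_ahead` samples after the window ends. A
segment of length L yields `L − t_delay − t_ahead + 1` pairs, the last
pair's target being the segment's final sample. Pair construction is
identical on train and test, and no input window extends past
`target − t_ahead` — the windowing-level causality contract, asserted
exactly in tests. The default protocol leaves the final 30 s as test
(with the 210 s default fraction: 4500 training samples / 750 test) and
uses a 400 ms ahead time, i.e. 10 samples.

All markers and directions are stacked as `C = 3 × n_markers` input
channels of one window, and a single model emits the (SI, AP, LR) tumor
position jointly; per-direction numbers are slices of the joint output. A
per-direction model is not provided as a separate mode — restricting
`output_dim` and target columns achieves it, but the joint head is the
default because the marker channels inform all three directions at once.

Channels are z-scored per channel with statistics from the training
segment only (constant channels get scale clamped to 1). The models are
scale-sensitive and mm-scale inputs slow Adam convergence; the
normalization is inverted before any error is reported, so all RMSEs are
in mm.

## Models

**TCN.** `n` residual levels; level `l` uses dilation `2^(l-1)` (dilation
1 at the lowest level, doubling upward). Each level applies
`convs_per_block` (default 2) dilated causal convolutions — left
zero-padding `(k−1)·d` keeps every hidden layer at the input window's
length, and the output at time *t* reads no input later than *t* — each
followed by a ReLU and optional dropout (default 0; never used in the
shipped experiments). With residual connections enabled the level output
is `Activation(X + F(X))`, with a 1×1 projection on the skip path when
channel counts differ; disabling them (`use_residual=False`) is the
ablation mode. The prediction is a linear readout of the last time step's
features. The receptive field is
`1 + convs_per_block·(k−1)·(2^n − 1)` samples — 497 for the selected
n=5, k=9, far beyond the selected 15-sample window, so the padded zeros
fill the unused history; both the closed form and an input-probe
measurement of the assembled network are tested against each other.

**LSTM baseline.** A stacked vanilla LSTM (no peepholes, no dropout)
consuming the window step by step from zero states — windows are
independent, matching the windowed protocol — with a linear readout of
the top layer's final hidden state. Forget-gate biases are initialized
to 1 (standard practice; the gate equations themselves are the textbook
logistic/tanh updates and are tested against a scalar oracle).

Both models are NumPy implementations with hand-written backpropagation;
weights are drawn fan-in-scaled from the config seed, so inference and
training are bit-reproducible.

## Training and tuning

Mean-squared-error cost on normalized channels, minimized by Adam with
decay rates (0.9, 0.999) and epsilon 1e-8; the learning rate is the tuned
quantity. Training stops at the cost threshold (default 0, i.e. never) or
the maximum iteration count, whichever is first; minibatches (default 64)
are drawn in shuffled epochs from the training-options seed. A non-finite
cost raises a training error carrying the iteration index.

Grid search enumerates the **full factorial product** of four axes per
model — TCN: layers {4..8}, filter size {1,3,5,7,9}, input window
{5,10,15,20,25} samples, learning rate {1e-4,1e-3,5e-3,1e-2,0.1} (625
points); LSTM: layers {1..5}, learning rate as above, hidden units
{10,50,100,150,200,250}, input window as above (750 points as listed,
even though 5×5×5×5 would be 625 — the hidden-units axis genuinely has
six options). Each point is scored by validation 3D RMSE with a temporal
holdout — the last 20% of the training segment, never shuffled into
training and never touching a parameter update — averaged over the tuning
fractions (5 of 69 in the reference protocol); ties break toward the
smaller model, then the lower learning rate. A diverging point scores
+inf rather than aborting the search. The shipped defaults are the
selected values: TCN n=5, k=9, window 15, lr 0.001; LSTM 2 layers, 200
hidden units, window 20, lr 0.01.

## Evaluation

Per-direction RMSE and 3D RMSE over the evaluable test range
`t_start = t_s + t_delay + t_ahead` to `t_end`;
`RMSE_3D² = RMSE_SI² + RMSE_AP² + RMSE_LR²` holds exactly and is asserted.
Product-moment correlation per direction (NaN with a warning on constant
traces). The **no-prediction baseline** represents the uncompensated
system: its reported position at *t* is the true tumor position at
`t − t_ahead`, evaluated over the same range — pure latency error; for a
sine of amplitude A and period τ lagged by δ this gives
`A·√2·|sin(πδ/τ)|`, which the implementation reproduces to float
precision. Improvement is `100·(1 − model/baseline)` percent. Paired
model comparisons use the two-sided Wilcoxon signed-rank test (zero
differences dropped, ties mid-ranked; exact null for n ≤ 25, normal
approximation with continuity correction above), which matches an
exhaustive sign-enumeration oracle for n ≤ 10. Reports round RMSE to
2 decimals (mm) and reductions to whole percent; cohort aggregates are
unweighted means over fractions.

Experiment drivers retrain per condition: model comparison (TCN / LSTM /
baseline), ahead-time sweep (ms converted to samples via the sampling
rate), marker subsets (each of the 7 non-empty subsets, input channels
`3·|subset|`), and TCN ablations (filter-size sweep, residual toggle).

## Synthetic respiratory motion

The generator emulates the statistical structure the method assumes. The
latent breathing waveform over one cycle of unit depth is
`b(s) = sin(πs)^(2p)`, `s ∈ [0,1)` — zero at the cycle boundaries
(end-exhale), one at peak inhale; `p` (default 2) flattens the exhale
plateau and sharpens the inhale, a standard respiratory-motion form. Each
cycle draws its own period (uniform ±5% of τ = 4 s) and depth (±8%).
The tumor trace in direction k is `A_k·b(t) + drift_k·t/60 + ε` with
SI-dominant amplitudes (10, 4, 3) mm, drift (1.0, 0.4, 0.3) mm/min and
sensor noise SD 0.15 mm; marker m, direction k is
`G[m,k]·b(t − lag_m) + ε` with gains of a few mm and mechanical lags
(0.04, 0.12, 0.20) s. One seeded generator per call; a cohort draws
per-fraction period/amplitude/drift perturbations from a master seed.

What this does *not* emulate: irregular breathing (coughs, apnea, shifts
in breathing pattern), marker-specific physiology — every marker observes
the *same* latent waveform, so with noise and lags removed each marker
channel is an exact affine function of the tumor SI channel (asserted as
the easiest learnable case) — and any imaging/acquisition artifacts.
Consequently, passing synthetic tests shows the pipeline learns the
external-internal mapping and beats the latency baseline under realistic
quasi-periodicity; it does not certify clinical accuracy, and one
documented consequence is that additional markers add almost no
*information* here (see Limitations).

## Desk-scale study conditions

The reference protocol (210 s fractions, 4500-pair training sets, the
selected n=5/k=9/32-channel TCN, 200-unit LSTM, 2000 iterations) is the
package default. The test suite and `scripts/acceptance.py` run a reduced
configuration chosen once for single-CPU runs: 80 s fractions (60 s train
/ 20 s test), a TCN with n=4, k=5, 16 channels, an LSTM with 2×32 units,
and 600 Adam iterations at lr 0.002 — the point where training cost has
plateaued on these fractions, so the end-to-end checks compare *trained*
models, with ten generator/init seeds per stochastic claim. Under these
conditions the trained TCN's cohort-mean 3D RMSE is roughly a third of
the no-prediction baseline's at 400 ms ahead, errors grow with ahead time
(160 → 400 → 600 ms), and removing residual connections degrades the
cohort mean (deep non-residual stacks occasionally collapse to constant
outputs — the stabilization residuals exist to provide).

## Numerical choices and degenerate inputs

Normalizer scales below 1e-12 clamp to 1. Correlation on a constant trace
returns NaN with a warning rather than raising. Percent reduction against
a zero baseline and a Wilcoxon test with all-zero differences raise a
degenerate-statistic error. Grid-search ties break deterministically
(score, then parameter count, then learning rate). Checkpoints store the
config plus named parameter arrays and reproduce inference bit-exactly.
Trace files serialize floats with 17 significant digits so write/read
round trips are bit-exact.

## Known limitations

- The networks are NumPy with explicit backprop: fine at desk scale,
  not GPU-class; the full 625-point grid search with real training is
  hours, not minutes.
- With the generator's single shared latent waveform, marker subsets
  differ mainly through lag and 0.15 mm sensor noise on multi-mm gains.
  One marker is measurably worse than three, but the two-vs-three margin
  sits at the sub-0.05 mm level — at converged training the three-marker
  model can even trail the two-marker average slightly, because three
  extra affine-redundant channels buy overfitting variance, not
  information. Multi-marker gains of the kind seen on clinical cohorts
  require markers that carry partially independent motion components.
- The no-prediction baseline is defined as the t_ahead-lagged truth — the
  natural model of an uncompensated gating system; other definitions
  (e.g. last-seen-position hold) would shift baseline numbers.
- Real CyberKnife log formats are not parsed; recordings must be
  converted to the documented trace-file dialect.
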