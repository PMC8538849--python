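# Methods

This note records the model, the conventions chosen where a published
description names a quantity without fully specifying its algorithm,
and what the synthetic generators do and do not emulate.

## Classifier

The classifier is a densely connected feed-forward network over the 137
raw feature measurements, retained in their native units:

* **Batch normalization** of each input feature,
  `z = γ·(x − mean)/√(var + ε) + β`, with trainable γ, β per feature.
  Batch statistics are used during training; inference uses running
  statistics tracked as an exponential moving average (momentum 0.99).
  ε = 10⁻³.  These two constants are implementation choices; results
  are insensitive to them at desk scale.
* **Hidden dense layers** (at most three), ReLU activation, with
  inverted dropout (rate 0.3 by default) after each hidden layer during
  training only, so inference needs no rescaling.  Dropout is never
  applied to the output layer.
* **Softmax output** over the fixed class order (N, AF, O, X).
  Predictions take the arg-max probability; exact ties resolve to the
  lowest class index (deterministic and documented rather than random).

Training minimizes weighted categorical cross-entropy (class weights
≥ 0, summing to 1) by mini-batch Adam (β₁ = 0.9, β₂ = 0.999, default
learning rate 0.001, default batch 128), from uniform random initial
weights in ±0.05 and zero biases, all seeded.  Gradients are analytic
(plain NumPy backpropagation, including through the BN scale/shift) and
are verified in the test suite against central finite differences to
10⁻⁵ relative.  Early stopping monitors the validation loss when a
validation set is supplied (else the inference-mode training loss) and
stops after 10 epochs (configurable) without improvement; the parameter
snapshot with minimal monitored loss is returned.  True-class
probabilities are floored at 10⁻¹² in the loss, with a warning.

The trainable-parameter count of a topology with D dense layers and
`NodesBN` inputs is `2·NodesBN + Σ_{i=1..D} Nodes_i·(Nodes_{i−1}+1)`;
the package treats this closed form as authoritative and asserts it
equals the literal number of scalars in an instantiated model.

## Importance framework

`connection_weights` computes the signed path-sum importance
`W1·W2·…·WD` (shape features × classes); shallower nets simply drop the
absent factors.  `case_weights_importance` inserts
`diag(α_l)` factors with `α_l` the Boolean ReLU activation masks of one
input, evaluated in inference mode (dropout off, running BN statistics)
— importance describes the deployed predictor, not a training-time
snapshot.  For inputs with no pre-activation exactly at zero this
equals the Jacobian of the logits with respect to the BN outputs, which
the suite checks by finite differences.  `global_weights_importance`
replaces the masks by their per-neuron medians over a dataset; with an
even sample count the median of a Boolean can be 0.5, which is kept (a
standard median, no tie rule imposed).  Signs are preserved and nothing
is rescaled: a positive value means high feature values push toward the
class.  `relative_feature_importance` normalizes each class column by
its maximum absolute entry (an all-zero column is left zero with a
warning).  `case_feature_importance` multiplies each row by the
sample's BN output, the local receptive field.  `rank_by_cum_gwi`
aggregates mean absolute global importance over however many trained
models are supplied (e.g. all folds of repeated cross-validation) and
sums over classes; ties break toward the lower feature index.

## Feature conventions

Coordinates are 0-based sample indices, intervals in milliseconds,
segment windows half-open.  Ratios with zero denominators (SD1/SD2,
RRrat, curvature ratios, percent-of-mean) are reported missing, never
±inf.  Missing features are imputed as 0 after being recorded in a
missing mask — the BN layer re-centers inputs, and the mask is retained
for audit.

Where the feature list names a quantity whose full algorithm is not
public, the package fixes an explicit, versioned convention:

* **QRS detection** — band-pass (5–18 Hz) / derivative / squaring /
  150 ms moving-window integration with an adaptive threshold and
  200 ms refractory period, refined to the raw-signal extremum.  The
  noise-correction flag (feature 1) trips when the detected rate leaves
  [20, 300] bpm or any 4 s stretch holds no beat.
* **Average beat** — sample-wise mean on a [−250, +450] ms window
  around R over beats whose peak absolute amplitude lies inside
  meanAmp ± stdAmp (a zero-width band rejects nothing).  Note the rule
  rejects ~32% of beats when amplitudes are Gaussian; that is the
  stated rule, not a defect.
* **Delineation** — Q/S as local minima flanking R (with an onset-based
  fallback for monophasic wide complexes), J where the post-S slope
  settles below 5% of the QRS slope maximum, T as the largest
  baseline deviation in [+150, +430] ms with T-end at 15% decay, P as
  the largest positive deflection in [−250 ms, Q−10 ms].  Fiducial
  ordering is enforced; offenders are dropped to missing.
* **Beat typing** — a beat is ventricular when its maximal normalized
  cross-correlation against the average beat (lag ±50 ms) falls below
  0.8; a simple, auditable proxy for a morphology classifier.
* **AF%** — logistic map 100/(1+exp(−(6·f + 1.5·r − 2.5))) of the
  fraction f of |dRR| > 50 ms and the Poincaré ratio r = SD1/SD2
  (clamped at 3); a perfectly regular rhythm sits at the minimum.
* **PNN50 (min⁻¹)** — count of |dRR| > 50 ms divided by the total |dRR|
  sum expressed in minutes (the count-per-total-duration alternative
  was rejected as inconsistent with the stated normalization);
  PNN50% is the plain count proportion.
* **Complexity** (ECG and TQ) — Lempel–Ziv (1976) phrase count of the
  median-binarized signal, normalized by n/log₂n.
* **Leakage** — per TQ segment, the residual power fraction after
  subtracting the least-squares sinusoid at the segment's dominant
  frequency; **period T** is the inverse of that frequency.
* **Regularity index** — band power within ±0.75 Hz of the dominant
  3–15 Hz peak divided by total band power.
* **Spectral width/area** — on the Hann periodogram (zero-padded to
  4096 points, Δf ≈ 0.073 Hz) normalized to its 3–15 Hz maximum: width
  is the enclosing span of frequencies meeting the level (0.2/0.4/0.6/
  0.8); area integrates the power in excess of the level.
* **Curvature** — |z″|/(1+z′²)^{3/2} on the average beat with the
  sample index as abscissa, maximized within each wave's window.
* **P-wave presence** — positive average-beat deflection in the P
  window exceeding 0.05 mV and 5% of the QRS amplitude.
* **SpecWidth/SpecArea ordering** — level-major blocks (Mean/Min/Max/
  Std within each level), matching names like `MinSpecWidth_08`.

These conventions implement the documented semantics of each feature;
bit-exact agreement with any historical implementation is a non-goal.

## Evaluation

Challenge F1 is the unweighted mean of the N/AF/O per-class F1 (the
Noise class is excluded for its small prevalence); per-class accuracy
uses the one-vs-rest 2×2 reduction.  Because no single convention pins
down a "total" precision/recall, the report emits three labeled
aggregates (macro over 4, macro over the 3 rhythm classes,
support-weighted) and treats none as canonical.  Stratified k-fold
deals each class round-robin after a seeded shuffle, so per-class fold
sizes differ by at most one with larger folds first — the deterministic
remainder pattern that makes fold contents reproducible.  The pooled
(summed over folds) confusion matrix is the primary cross-validation
report; per-fold scores are also kept.  The architecture grid takes
hidden widths from {1, 2, 4, ..., 1024} (eleven choices, including
256), non-increasing across hidden layers, up to four dense layers —
364 topologies.  The class-weight grid steps the first three weights by
0.05 in [0, 0.5] with the fourth as the complement, also restricted to
[0, 0.5]; 891 settings.  The published optimal weights
(0.23, 0.25, 0.3, 0.22) are an average over a high-performing region
and are handled as an override, not a grid point.

## Synthetic generators

The ECG generator composes each beat from Gaussian bumps (P, Q, R, S,
T), places beats by a per-class RR process — near-constant RR with CV
0.03 and P-waves for N; i.i.d. log-normal RR with CV 0.25 (≥ 0.15
enforced), no P deflection and an additive sinusoidal 4–10 Hz f-wave
(default 0.1 mV at 6 Hz) for AF; premature wide P-less ventricular
beats in bigeminy/trigeminy/random patterns for O; baseline wander
(0.33 Hz) plus band-limited EMG noise at twice the QRS amplitude for X —
then band-passes to 0.5–40 Hz and clips to ±5 mV, the recording
conditions of hand-held single-lead devices (300 Hz sampling, 9–61 s
strips).  Ground-truth beat and P-wave positions are returned.  The
defaults above *are* the study conditions of the desk-scale experiments.

What the generator does not emulate: real P/QRS/T morphology variation
between subjects, atrial flutter and other specific arrhythmias beyond
the four coarse classes, electrode-motion artifact structure,
multi-lead signals.  Passing tests therefore demonstrate that the
pipeline implements its stated semantics and that the importance
machinery recovers planted structure — not clinical-grade accuracy on
real recordings, which requires the external database
(`scripts/run_challenge2017.py` documents that protocol).

The feature-table generator draws class-conditional Gaussians with
per-class mean shifts on chosen columns; the recovery experiments use
four planted columns at a 2-SD shift with 500 rows per class, a regime
where the signal is learnable but individual columns still overlap.

## Problem sizes and numerical choices

The test suite trains compact nets (hidden widths 32-16 and below, ≤
2000 rows, ≤ 100 epochs) — sizes chosen so the full experiment suite,
including ten seeds of the recovery study, completes in well under a
minute on one CPU while leaving the statistical conclusions unchanged.
Oracle checks use ≤ 5-neuron layers where explicit path enumeration is
exact.  Tolerances: path-sum vs enumeration 10⁻¹⁰ absolute; masked path
sum vs finite-difference Jacobian 10⁻⁴ relative; analytic gradients vs
central differences 10⁻⁵ relative.

## Known limitations

* The delineation heuristics target the synthetic beat families; exotic
  real-world morphologies (notched T, biphasic P) may delineate poorly
  and fall back to missing values.
* The beat-typing rule is correlation-only; fusion beats and aberrantly
  conducted supraventricular beats are beyond its vocabulary.
* Training is single-threaded NumPy: adequate for hundreds of epochs on
  thousands of rows, not for large-scale sweeps.
* WFDB containers are not read; ECG input is the 2-column CSV form
  (convert externally if needed).
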