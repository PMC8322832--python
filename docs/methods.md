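# Methods

This note documents the models, parameter choices, and numerical decisions
behind qrsnet, and what the synthetic-data tests do and do not demonstrate
about real ECG.

## Signal model and the synthetic generator

Each synthetic beat is a sum of five Gaussian bumps — P, Q, R, S, T — with
per-wave amplitude (mV), center offset relative to R (s), and width (s).
One beat occupies one RR interval; R sits 0.30 s after beat onset. Because
the bumps are analytic, the ground-truth fiducial of each wave is known
exactly: the stored truth index is the extremum of the *rendered* beat
within one wave-width of the analytic center (overlapping neighbors can
shift the summed trace's extremum by a sample or two; for a zero-amplitude
wave such as the absent Vpb P wave, the analytic center is kept).

The five presets encode the morphological signatures the classifier must
separate: Lbbb and Vpb have widened QRS complexes (R widths 0.035 s and
0.045 s vs 0.018 s for normal), Rbbb a deep S (−0.55 mV), Vpb an absent P,
and Apb a small P with a shortened preceding RR. Premature classes (Vpb,
Apb) shorten the preceding beat's RR by a factor 0.7 so the heart-rate
feature discriminates. The default beat cycle (Lbbb, Vpb, Nb, Apb, Rbbb,
repeated) places each premature beat after a long-RR conducted beat, the
way ectopy interrupts an otherwise regular rhythm.

Two generator-level constraints matter for the detector and are deliberate
design requirements rather than tuning:

* **Every effective RR interval exceeds the 215-sample detection window**
  (0.63–0.92 s, i.e. 65–95 beats/min; the shortened pre-ectopic intervals
  bottom out at 0.63 s). The discrete wavelet transform is shift-variant,
  and the cubic `e11` product amplifies that: the enhanced peak height of
  identical beats varies by more than an order of magnitude with dyadic
  grid phase. Two R peaks sharing one threshold window would therefore
  often lose the weaker one; one beat per window removes that failure mode
  at physiologic heart rates.
* **T peaks lie within 200 ms of their R** (0.180–0.195 s, a short but
  plausible QT at these rates). A T wave's residual band-3–5 energy can
  win a threshold window that contains no R; placing it inside the
  detector's refractory gap means such a candidate merges into its beat
  instead of surfacing as a false detection.

Noise is additive: a baseline-wander sinusoid (default 0.1 mV at 0.3 Hz),
Gaussian white noise (default SD 0.02 mV), and an optional 50/60 Hz
powerline sinusoid (off by default). All randomness flows through one
explicit integer seed. What the generator does *not* emulate: beat-to-beat
morphology variability, respiration modulation, electrode motion
artifacts, non-stationary noise, fusion/aberrant beats, or multi-lead
structure. Passing tests on these records therefore demonstrate the
*internal consistency* of the pipeline — correct algebra, correct
thresholds, correct bookkeeping — not field performance on clinical
recordings.

## Denoising

8-level DWT, basis `sym2` by default (any of haar, bior2.6, db4/6/8,
sym2/4/6/8 is accepted), symmetric boundary extension (a configurable
knob; the transform remains linear and perfectly reconstructing under it).
Denoising zeroes d1, d2 (high-frequency noise above ~45 Hz at 360 Hz
sampling) and the level-8 approximation (content below ~0.7 Hz, i.e.
baseline drift), then reconstructs; output length always equals input
length. Note the approximation-zeroing also removes the trace's DC
component — harmless for AC-coupled clinical recordings, but it means a
densely packed synthetic record with positive-dominant beats loses a
constant offset; restoration tests therefore use sparse beats whose DC is
negligible.

Filter metrics: MSE is the mean squared sample difference. The SNR is
reported as the dimensionless power ratio filtered/reference by default
("closer to 1, the better"), with a conventional dB mode
(10·log10(Σref²/Σ(ref−filtered)²)) as an alternative, since the ratio
definition alone does not distinguish distortion from noise retention.

## Detection and localization

The enhancement `e1 = d3+d4+d5`, `e2 = d4·(2d3+d5)`, `e11 = e1·e2` uses
single-band reconstructions of the detail levels 3–5 (each obtained by
inverse-transforming with all other bands zeroed, so the arrays are
sample-aligned with the input). Thresholding: non-overlapping 215-sample
windows (step = width); candidates are local maxima of the full trace with
positive value at or above 60% of their window's maximum; candidates
closer than 72 samples (200 ms) merge, keeping the larger. Local maxima
are computed once over the whole trace rather than per window segment so
that a window boundary cutting a decaying slope cannot fabricate an edge
maximum.

Each accepted `e11` peak is refined to the raw-signal maximum within ±60
samples. The product transform can displace its extremum by up to ~50
samples for wide QRS complexes, so the radius must comfortably exceed that
shift while staying below the minimum RR interval; within the window the R
deflection dominates every other wave, so the argmax is the R peak.

P/Q/S/T are located in fixed physiologic windows relative to the refined
R: Q = minimum in (R−100 ms, R); S = minimum in (R, R+100 ms]; P = maximum
in (R−200 ms, Q); T = maximum in (S+50 ms, S+450 ms). Windows clip at
record edges; beats with an empty window, an ordering violation
(p < q < r < s < t must hold), or a duplicate refined R are dropped and
logged. Detection scoring matches detected to true R indices greedily,
one-to-one, within ±54 samples (150 ms, the common QRS benchmark
tolerance).

## Features and dataset assembly

The 16-vector per beat: the ten absolute peak-to-peak time differences
(PQ … ST) in seconds, the five peak amplitudes in mV as read from the
(filtered) signal, and H = 60/RR_prev beats/min from the preceding RR
interval (the following interval for a record's first beat) so premature
beats perturb H. Beat segmentation, where needed, cuts 99 samples before
and 200 after R (~0.83 s at 360 Hz).

Dataset protocol: the first 30 beats of each of the five classes, in
record order; the first 15 of each class form the 75-row training table
and the last 15 the 75-row test table (consecutive halves — the two-group
split is taken as consecutive rather than interleaved). Normalization maps
each feature's training min/max to [−1, +1]; the identical affine map is
applied to test rows, which are then clipped to [−1, 1] because the
network declares fixed input ranges; constant features map to 0. The
pipeline simulates two margin beats per class beyond the 30 so a rare
dropped beat cannot starve the selection.

## PCA

Eigendecomposition of the covariance of the mean-centered training rows
(no per-feature rescaling — inputs are already in [−1, 1]; a switch
exists). Components are sorted by decreasing eigenvalue with a
deterministic sign convention (largest-magnitude loading positive).
`select_dim(a)` returns the smallest k whose cumulative variance fraction
strictly exceeds a; thresholds of interest are 0.85 and 0.99. One model is
fitted on the pooled training rows of all classes and applied to both
splits, avoiding leakage and per-class transform mismatch. On the default
synthetic features the 99% threshold typically selects k = 7 and the 85%
threshold k = 3.

## Network and training

Architecture 16–5–1 (input width tracks the PCA dimension when reduction
is on): tanh-sigmoid hidden layer, linear output, net input Wa − θ. The
binary sigmoid (f = 1/(1+e⁻ˣ), f′ = f(1−f)) is available as an option.
The single linear output regresses the class id; prediction rounds
half-away-from-zero and clips into [1, 5].

Gradients are derived from E = ½Σ(t−z)² by backpropagation and verified
against central finite differences (the standard check, at 10⁻⁶ relative
tolerance with a unit floor). Thresholds enter the net input with a minus
sign, so ∂E/∂θ = +(t−z)f′(net) at the output; all parameters descend their
gradient.

Training is batch (not per-sample) gradient descent on the dataset MSE
with momentum 0.9 and an adaptive learning rate: ×1.05 after an epoch that
lowers the MSE, ×0.7 — with the step rejected and momentum reset — after
an epoch that raises it by more than 4% (the classical defaults of this
training style). Defaults: up to 100 000 epochs, goal MSE 2·10⁻⁴, initial
rate 3·10⁻⁴. A single learning rate serves both layers. Initial weights
and thresholds are uniform in [−1, 1] from an explicit seed. Non-finite
loss raises a divergence error naming the epoch. On the synthetic 75-row
training tables the goal is typically reached within a few thousand
epochs; tests and the acceptance script cap fine-tuning at 20 000 epochs,
which the problem sizes used here never exhaust in practice.

## Particle swarm optimization

Particles live in the flattened parameter space of the network (91
dimensions for 16–5–1). Velocity update per particle and dimension:
V ← k·[wV + c1·r1·(P_i − X) + c2·r2·(P_g − X)], X ← X + V, with one
uniform draw per term per dimension, elementwise clamping to ±vmax, and
the constriction factor k = 2/|2 − φ − √(φ² − 4φ)|, φ = c1+c2 ≥ 4. With
the default c1 = 2.5, c2 = 2.7 the formula gives k ≈ 0.351. Inertia w
decreases linearly wmax → wmin (0.95 → 0.10) over the iteration budget —
the schedule itself is a package choice, as only the bounds are standard.
Positions initialize uniform in [−1, 1], velocities at zero. Fitness of a
position is the MSE of the unflattened network's raw (unrounded) outputs
on an evaluation set; by default that set is a validation split carved
from the last 20% of the training rows, not the final test set, to avoid
leakage (evaluating on the test table is possible explicitly for fidelity
runs). The swarm's best position seeds backpropagation fine-tuning.
Swarm defaults are 75 particles and 100 iterations with early stop below
fitness 10⁻⁴; tests and the acceptance script scale the swarm to 20
particles and 30 iterations, which suffices at these problem sizes.

## Pipeline and reproducibility

A master seed is split into per-stage sub-seeds via
`numpy.random.SeedSequence.spawn` (noise, network init, swarm), so a stage
can be re-run in isolation with the stream it saw inside the full run.
Reports are pure JSON with a versioned key set; the confusion matrix rows
are actual classes, columns predicted, and the reported accuracy always
equals the matrix trace over its total. Identical configuration and seed
produce byte-identical reports.

## Known limitations

* The detector's per-window relative threshold presumes at most one beat
  per 215-sample window; sustained tachycardia above ~100 beats/min at
  360 Hz violates that and would require a shorter window.
* Localization windows are fixed physiologic constants; extreme QT or PR
  intervals outside those windows mislocate waves.
* The classifier regresses class ids on a single output, so class
  confusion is biased toward adjacent ids; a one-hot output head would
  remove that ordering artifact but is outside the present scope.
* WFDB support covers headers, format 16 (read/write), format 212 (read),
  and the two-byte annotation stream — the subset the MIT-BIH arrhythmia
  layout needs — not the full format family.
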