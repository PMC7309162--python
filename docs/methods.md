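# Methods

This note documents the models, the synthetic-data generator, the numerical
choices and the known limitations of `patchlead`. Everything quantitative
stated here is computed by the test suite or by `scripts/acceptance.py`.

## Reconstruction models

**Least squares.** For each subject the 12 target leads are modeled as an
affine function of the 3 patch channels, `y_j(t) = α_j · x(t) + β_j`, one
independent regression per lead (the stacked per-lead fits reproduce the
single multivariate optimum exactly). The solve is done on centered data via
`numpy.linalg.lstsq`, which gives pseudoinverse (minimum-norm) semantics on
rank-deficient designs — those produce a warning, not an error. The
intercept β is included: the patch and target channels have no common
hardware reference, so a free offset per lead is the safe parameterization.
An optional ridge penalty exists behind a config flag and defaults to zero.

**LSTM.** One network per target lead (12 networks total, fully
independent): three stacked LSTM layers, 50 hidden units each, over
windows of 250 samples (1 s at 250 Hz) of the 3 patch channels; a
per-timestep output stage `ŷ_t = w_h·h_t + w_x·x_t + b` maps the top
hidden state *and the raw input channels* to one sample of the target
lead. The direct input term matters: the dominant part of the patch→lead
map is (near-)linear, and routing it straight to the output lets the
network represent that part exactly and generalize to beat morphologies
never seen in training (ventricular ectopy) instead of replaying the
training rhythm. The recurrent layers model what the affine map cannot:
saturation-type nonlinearity and context.

The cell is the standard form — gates `i, f, o = σ(·)`, candidate
`g = tanh(·)`, state `c_t = f⊙c_{t−1} + i⊙g`, output `h_t = o⊙tanh(c_t)`
— with distinct input and recurrent weight matrices and biases per gate.
The memory-carry property (`f→1, i→0 ⇒ c_t = c_{t−1}`), a hand-evaluated
scalar step, and finite-difference gradient checks pin the implementation
down in the test suite.

Training minimizes the per-sample mean squared error over sliding windows
(step 1 sample = 4 ms) with Adam (lr 0.001), batch 50, 500 epochs, shuffled
each epoch with a seeded generator; weight init is seeded uniform fan-in
with the forget bias raised to +1. Inputs and targets are z-normalized per
channel with statistics frozen on the training segment. Full-signal
reconstruction slides the window over the input, predicts 250 samples per
position, and averages all predictions covering each output sample (the
uniform average is the lowest-variance unbiased combiner of the overlapping
estimates), then inverts the normalization.

### Scaled training profile

The full protocol (hidden 50, step 1 → 1001 windows, 500 epochs) costs on
the order of 10^12 floating-point operations per lead model and is meant
for overnight-style runs; it remains the package default. The test suite
and the acceptance script use a scaled profile chosen by budget arithmetic:
**hidden 24, window step 8 (126 training windows from the 5-s segment),
batch 42, Adam lr 0.01, 40 epochs** (80 for the ectopic-generalization
check). The learning rate is raised because the scaled run takes ~120
optimizer steps where the full protocol takes ~10,000. Model-comparison
checks use four representative leads (II, aVF, V2, V5 — two frontal, two
precordial); the ectopic check uses II and aVF. All properties asserted
(ordering of methods, generalization thresholds) are unchanged by the
scaling; absolute CC/RMSE values at full scale will be modestly better.

## Synthetic paired recordings

The generator produces both channel groups from one cardiac dipole
trajectory `d(t) ∈ R³`, which is what makes reduced-lead reconstruction
physically possible in the first place.

**Dipole.** Each beat is a sum of Gaussian waves (P, Q, R, S, T) over a
cyclic phase with R at mid-cycle; wave timing is specified in seconds
(PR 160 ms, QRS 95 ms at rest) so P and QRS durations are rate-independent,
while the T wave shortens with √RR and its offset is clamped to 47% of the
cycle after R. Every fiducial is analytic — onset/offset at wave center
± 3 widths — giving exact per-beat ground truth for scoring the
delineator. The wave amplitude vectors give the P, QRS and T loops
distinct 3-D directions (mean QRS axis ≈ 45°); together with a seeded
per-beat axis wobble (4° s.d. random rotation emulating respiratory
modulation) the 5-s training segment excites all three dipole dimensions,
as real recordings do. RR intervals carry multiplicative Gaussian jitter
(3% default). Beats whose R peak falls within 250 ms of the record end are
neither rendered nor listed in ground truth (truncation makes them
undetectable in principle).

**Lead fields.** The 12 standard rows satisfy the Einthoven and Goldberger
identities by construction (III = II − I, aVR = −(I+II)/2, …); the
precordial rows rotate from right-anterior (V1) to left-lateral (V6) with
decreasing z weight. The three patch rows are bipolar, frontal-dominated,
with their z column scaled by κ (default 0.3) to emulate the patch's weak
view of horizontal components; they are linearly independent for any
κ > 0, so with a linear torso the 12 leads are an exact affine function of
the patch — the least-squares model's correctness condition, asserted in
the tests.

**Nonlinearity and noise.** An optional memoryless saturation
`g(u) = (1−λ)u + λ·s₀·tanh(u/s₀)` (s₀ = 400 μV) is applied to all leads
after projection; λ = 0 is exactly linear, λ = 0.3 is the condition used
for the LSTM-vs-LR comparison. White noise (5 μV RMS default) and sinusoidal
baseline wander (30 μV at 0.25 Hz, random phase per lead) are added last.
A config seed fully determines the output.

**Pathologies.** Injected as morphology edits so each printed criterion is
met or missed by a controlled margin: wide QRS scales the Q/R/S offsets
and widths by a common factor so the analytic duration equals the requested
milliseconds exactly; ST elevation/depression adds a plateau along a fixed
dipole direction normalized so lead II sees exactly the requested
millivolts, spanning S offset to T offset with 20-ms cosine ramps (the
whole ST–T complex shifts, as ischemic deviation does, keeping the J+80 ms
measurement point on the plateau); pathologic Q sets the Q amplitude to a
fraction of R (and widens Q past the 40-ms duration arm of the criterion,
so detection hinges on depth); T inversion negates the T vector; ectopic
beats substitute a fixed ventricular morphology (no P, 140-ms QRS, rotated
axis, inverted T).

**What the generator does not emulate.** Torso inhomogeneity and electrode
placement variation; atrial arrhythmia; motion and electrode artifacts;
pathologies that alter conduction sequence rather than wave shape. Passing
tests therefore show the pipeline's internal consistency and its behavior
under the stated signal model — not clinical performance, which the
original study measured on 60 subjects whose recordings are not public.

## Preprocessing

Zero-phase 4th-order Butterworth band-pass, default 0.05–100 Hz (the
classic 150-Hz diagnostic corner exceeds the 125-Hz Nyquist at 250 Hz;
100 Hz is the nearest admissible digital corner). Forward–backward
filtering keeps the ST segment phase-true. The 10-s recording splits into
5 s fit / 5 s test, ground-truth beats assigned by the segment containing
their R peak. Windowing is half-open, 0-based, step 1 by default.

## Delineation

R detection is the Pan–Tompkins chain on lead II: 5–15 Hz band-pass,
derivative, squaring, 150-ms moving-window integration, adaptive dual
thresholds (SPKI/NPKI) with a 200-ms refractory period and RR-based
search-back, then refinement to the band-passed extremum.

Wave boundaries use a relative-slope rule: scanning outward from a wave
peak, the boundary is where |slope| falls below 3e⁻⁴ ≈ 0.055 of that
wave's own maximum slope — for a Gaussian wave this lands exactly at
center ± 3 widths, the same convention the generator's ground truth uses,
with sub-sample interpolation of the crossing. A per-lead noise floor
(≈3σ of the baseline slope, estimated from the 20th percentile of |slope|)
keeps noise from postponing the crossing. Q and S are opposite-polarity
extrema within ±60 ms of R; P is the largest deflection in
[R−300, R−80] ms; T in [J+80 ms, R+min(600 ms, 0.7·RR)], its offset scan
bounded away from the next beat's P wave. Interval fiducials are fused
across leads by the median (the generator gives every lead identical true
wave timing, so the median is the unbiased robust fuse; min/max fusion
tracks the worst single-lead tail under noise). Waves that cannot be
located clear a validity flag instead of raising.

Parameters: PR = P onset→QRS onset, QRS = onset→offset, QT = QRS onset→
T offset; amplitudes measured against the mean of the 40-ms PR segment
before QRS onset; QRS total voltage = Σ over leads (|R| + max(|Q|,|S|));
frontal axis = atan2 of the net QRS areas in aVF and I; per-recording
values are medians over beats.

## Diagnostic criteria

All thresholds inclusive and overridable: wide QRS ≥ 120 ms; ST
elevation/depression ≥ 0.1 mV at J+80 ms against the PR baseline
(lead aVR excluded, as in standard practice — it mirrors the other leads);
pathologic Q ≥ 25% of R and ≥ 40 ms; T inversion = negative T peak in any
of V4–V6 (30 μV polarity floor); LVH by Sokolow–Lyon,
S(V1) + max(R(V5), R(V6)) ≥ 3.5 mV. A recording is labelled positive for a
finding when the criterion holds in at least half of its evaluable beats.

## Evaluation

CC is the Pearson correlation over the full held-out segment per lead;
RMSE in μV; the "mean" row is the unweighted mean over the 12 leads.
Sensitivity = TP/(TP+FN), specificity = TN/(TN+FP), displayed as whole
percentages with full precision retained internally.

## Numerical and reproducibility notes

* Training arithmetic is float32 (explicit cell math, BLAS matmuls);
  gradient checks run in float64. Fixed seed + single-threaded execution
  reproduces loss histories to 1e−6 and pipeline report files to the byte.
* A single pipeline seed fans out to fixed per-stage seeds, so stages are
  independently reproducible.
* Degenerate inputs fail loudly and specifically: constant signals are an
  error for CC, an empty result for R detection, a cleared validity flag
  for delineation; a reconstruction too poor to delineate is reported as
  missing in the pipeline output rather than aborting the run.

## Known limitations

* Precordial leads (V1–V3 especially) depend on amplifying the patch's
  κ-attenuated horizontal components; with noise this is the error-dominant
  part of both models — the patch geometry's intrinsic limitation, visible
  here as higher precordial RMSE.
* At heart rates above ~110 bpm the clamped T wave encroaches on the
  J+80 ms point, degrading ST measurement — also true of real ECGs.
* The delineator is tuned for resting, low-noise signals; it makes no
  claim on ambulatory data.
* The scaled LSTM profile trades absolute accuracy for runtime; full-scale
  defaults recover the remaining margin but take hours per subject on one
  CPU, consistent with the personalized-training cost this class of method
  is known for.
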