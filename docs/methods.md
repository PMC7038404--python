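# Methods

## The estimation problem

A force platform measures the ground reaction force (GRF) of a jump landing
directly but confines measurement to the laboratory. Body-worn inertial
sensors travel with the athlete, and during ground contact a segment's
acceleration beyond gravity is mechanically coupled to the GRF
(a = (F − mg)/m), while during flight the plate force is identically zero
but segment accelerations are not. `grfest` exploits exactly this structure:
phase first, force second.

## Model

Let aᵢ(t) ∈ ℝ³ be the acceleration of sensor i at sample t (units of g,
100 Hz) and y(t) the plate GRF in body weights (BW).

**Labels.** ground(t) ⇔ y(t) ≥ 0.05 BW. The boundary value itself is
assigned *ground*: the choice is conservative toward load detection, and the
boundary has measure zero in continuous force data.

**Classifier.** An SVM with Gaussian kernel
k(u, v) = exp(−γ‖u − v‖²) over the feature vector of per-sensor magnitudes
(‖a₁‖, …, ‖a_m‖). The training protocol takes an equal number of samples
per (subject, jump-type) cell — the minimum cell count — concatenates,
shuffles with a seeded RNG, and keeps the first 500 points for training and
the first 200 held-out-subject points for testing. Box constraint C and
kernel width γ are unspecified by the protocol itself; they are selected by
the prescribed five-fold cross-validation over a small logarithmic grid
(C ∈ {0.1, 1, 10, 100}, γ ∈ {scale, 0.1, 1, 10}), configurable in
`ClassifierSpec`.

**Regressors.** One feed-forward network per phase: tanh hidden units,
linear output, hidden-layer widths between 1 and 35 (flight: exactly one
hidden layer; ground: one or two). Inputs are a single time point's features
— no history — so prediction is strictly pointwise. Architecture is chosen
by exhaustively training every candidate width (optionally strided, full
space 35 candidates for flight and 35 + 35² = 1,260 for ground) and taking
the lowest validation RMSE, ties broken toward fewer total neurons.

**Gating.** At inference each sample is classified from magnitudes and
routed to the matching network; outputs are concatenated with no smoothing
across the phase switch (an optional median filter exists, default off).
Peak GRF is the maximum of the estimate restricted to ground-classified
samples; multi-jump recordings are split at flight intervals and a peak
reported per landing. Deployment has no plate, so the restriction uses
predicted phase; validation code can switch to plate-derived labels.

## Training choices

The optimiser, epoch budget and stopping rule of the original protocol are
unrecorded. These networks are small (≤ ~1,300 weights), so we train with
L-BFGS on standardized inputs, tolerance 1e-7, max 500 iterations, from
seeded random initial weights. L-BFGS has no per-iteration early-stop hook;
instead every `GRFNetwork` holds back a seeded validation split (15 %) whose
RMSE is the model-selection score of the architecture search — that is where
the protocol's "early stopping on held-back data" does its work. Whether the
regression inputs were tri-axial components or magnitudes is also
unrecorded; both conventions are implemented (`feature_convention`), with
components the default because they retain directional information the
magnitude discards.

## Evaluation protocol

RMSE (BW) and Pearson's r are computed per trial over the whole activity
curve — flight and ground together — then averaged across trials and folds
(a pooled mode is available; pooled-vs-averaged is not specified by the
protocol, averaging is the default). Cross-validation is subject-level:
leave-two-out enumerates all C(n,2) held-out pairs (91 folds at n = 14),
leave-one-out all n singletons (23 at n = 23). The sensor-subset sweep
trains a full combined model for every non-empty subset of the six
placements × every fold × every landing type (63 × 91 × 2 = 11,466 fits at
full scale) and ranks subsets by mean combined RMSE, ties broken by higher
mean r and then fewer sensors — the parsimony tie-break reflects the
field preference for a single sacrum sensor among near-equal performers.
Peak-GRF agreement is summarised by Bland–Altman analysis with differences
taken plate − model and limits of agreement mean ± 1.96 SD (SD with n − 1).

## Synthetic data

No instrumented cohort is distributable, so the simulator generates the
statistical structure the pipeline assumes:

- **GRF waveform** (per trial, continuous-time, evaluated on both the
  2000 Hz plate grid and the 100 Hz sensor grid): quiet stance at 1 BW →
  half-sine countermovement dip to 0.65 BW over 0.4 s → push-off burst
  (amplitude drawn U(0.5, 0.65), peak ≤ 1.15 BW) → flight window of exactly
  zero force, duration U(0.30, 0.50) s snapped to the sensor grid → landing
  impact rising in 0.05 s to a peak drawn from the landing type's normal —
  unilateral N(2.35, 0.38²) BW, bilateral N(3.13, 0.72²) BW, truncated below
  at 1.2 BW — falling back over 0.10 s → damped-cosine settle. Ground-phase
  force is clamped at ≥ 0.05 BW so the labeling rule reproduces the phase
  series exactly while flight force is exactly zero.
- **Sensors**: sacrum vertical acceleration is grf − 1 on the ground and −1
  (free fall) in flight; thoracic/thigh/shin channels are amplitude-scaled,
  lag-shifted copies with extra noise and a flight-phase limb-swing
  sinusoid so limb acceleration stays nonzero while airborne; unilateral
  landings load the left limb 15 % harder than the right. Independent
  Gaussian noise per axis, default SD 0.05 g — chosen once as a realistic
  level for skin-mounted IMUs including soft-tissue artefact.
- **Subjects**: mass drawn from N(54.7, 3.3²) kg; flight duration and jump
  cadence are configurable guesses (no reference values exist for them).
- **Raw-file fixtures**: per-sensor CSVs (ISO-8601 timestamps, 3 accel
  columns, 100 Hz) and a 2000 Hz plate CSV in newtons (force =
  grf_bw × mass × 9.81); optional per-sensor clock offsets emulate the
  between-sensor synchronisation fault of the original hardware.

What the simulator does **not** model: segment rigid-body kinematics, task
variety (every trial is one countermovement jump), gyroscope/magnetometer
channels, soft-mat filtering of the plate signal, multi-modal noise. The
accel→GRF coupling is exactly linear by construction, so synthetic
performance bounds are optimistic: passing tests demonstrate that the
pipeline recovers the structure it assumes, not field accuracy on human
data. One genuine difficulty survives, however: ground samples whose
magnitude crosses the flight band (|grf − 1| ≈ 1 g, i.e. grf ≈ 2 BW on the
impact ramp) are ambiguous to a magnitude-only pointwise classifier, which
is the same misclassification mode the original system exhibits.

## Ingest chain

Plate records are decimated 2000 → 100 Hz with a polyphase FIR anti-alias
filter (line-padded edges keep the stance plateau flat); naive subsampling
would alias the broadband landing impact. Normalisation divides by
mass × 9.81 m/s². Clock synchronisation is automated: since the sensor
magnitude tracks |grf_bw − 1|, the offset is the lag maximising the demeaned
cross-correlation between magnitude and that reference within a bounded
window (default ± 5 s) — equivalently, minimising the sum of squared
residuals of the mean-matched signals. The estimate fails loudly when the
global optimum falls outside the window, and flags low confidence when the
peak is not distinct (< 2× the 95th percentile of the background). A manual
per-sensor override is available. The sacrum file is mandatory (it anchors
synchronisation quality control); other sensors may be absent with an
explicit flag. Collation snaps all streams to a common 100 Hz grid
referenced to the plate record's start.

## Numerical and degenerate-input conventions

- Timestamps are half-open sample grids; sample i covers [i/rate,
  (i+1)/rate). Segment boundaries in the simulator are nudged by 1 ns so
  float jitter cannot misassign a boundary sample.
- Gravity is fixed at 9.81 m/s².
- Zero-variance inputs: synchronisation raises "unsynchronizable"; Pearson r
  raises rather than returning NaN.
- One-class training sets (all-flight or all-ground) are rejected with a
  clear error; peak extraction with no ground-classified sample raises
  rather than returning a silent zero.
- All stochastic steps (simulation, point-set shuffling, CV splits, weight
  initialisation) are driven by explicit integer seeds; identical seed and
  configuration give bit-identical output.

## Problem sizes used in the shipped experiments

The packaged test-suite experiments run the identical protocol at reduced
scale, chosen as the package's own defaults: the held-out-accuracy
experiment uses 14 subjects × 3 jumps with architecture-search candidates
{1, 4, 8} (flight) and single-layer {1, 4, 8} (ground); the noise-robustness
sweep uses 4 subjects × 2 jumps at noise SD {0, 0.05, 0.2, 0.5} g × 3 seeds
with fixed (4,)/(8,) networks; the subset-sweep bookkeeping is verified by a
dry-run enumeration at full scale (11,466 cells) and by real fits on a
2-sensor, 3-subject study. The full-scale search remains available through
the same entry points.

## Known limitations

- Synthetic-only validation; absolute accuracies do not transfer to humans.
- The pointwise magnitude-only classifier cannot disambiguate the impact
  ramp's flight-band crossing; a temporal model could, but pointwise
  operation is a deliberate design constraint.
- Peak agreement inherits classifier errors: a misrouted impact peak caps
  the estimated peak (the imbalanced-training pathology of small cohorts).
- The simulator's sensor transforms are fixed constants, not learned from
  motion capture.
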