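# Methods

## Scope and model overview

`respmark` addresses marker-placement optimization for respiratory-motion
surrogacy: given time-synchronized displacement traces of nine candidate
external markers and one internal reference point, decide which skin sites
best support a correlation model for patient geometrical setup. The
left–right axis is excluded throughout — thoracic surface points barely
move laterally — so every trace is (AP, SI) only, in mm, relative to the
end-exhale baseline.

The four stages are: synthetic session generation, CCA/PCA marker scoring
and selection, ANFIS correlation modelling, and RMSE-based evaluation.

## Breathing simulator

Real phantom or 4D-CT marker data is not distributable, so all pipeline
stages run on a parametric simulator whose *statistical structure* mimics
the real setting: border markers track the internal point almost
perfectly, midline markers weakly, lateral middle markers strongly but
inconsistently.

**Waveform.** One breathing cycle is the raised sine power
w(t) = sin^(2k)(πt/T), a standard surrogate for the asymmetric respiratory
cycle: w = 0 at end-exhale (cycle start), w = 1 at end-inhale (T/2), and
larger k lengthens the exhale dwell. Default k = 2. Respiration is
strictly periodic in each session; cycle-to-cycle amplitude/period drift
within a session is *not* modelled (see Limitations).

**Sessions.** A session is controlled by a breathing-cycle spec (chest-wall
AP expansion in cm, diaphragm SI excursion in cm, period in s; period
restricted to [2, 10] s), the sampling interval (default 25 ms), and a
duration (default 60 s). Five preset cycle specs spanning 0.5–1.3 cm chest
expansion, 1.2–2.2 cm diaphragm excursion and 4–6 s periods define the
default study; `simulate_study` cycles through them, one per session, with
per-session seeds derived from one master seed.

**Markers.** Marker AP = gain × chest amplitude × w(t − lag) + drift +
white Gaussian noise; SI likewise from the diaphragm amplitude. Session-
to-session variability has two mechanisms:

* *lognormal gain jitter* (sd 0.10 by default), one multiplicative draw
  per marker per session — models day-to-day placement/physique scaling.
  Note this alone cannot change a marker's correlation with the reference
  (Pearson r is scale-invariant);
* *phase jitter*, a per-session Gaussian offset of the marker's lag —
  models variable chest/abdomen phase relationships, and is what makes a
  marker's correlation fluctuate between sessions.

Default presets: border markers M1, M3, M7, M9 have high gains and 0.3 mm
noise (per-session correlation ≈ 0.99 with negligible SD); midline markers
M2, M5, M8 have low gains and 1.6 mm noise (correlation ≈ 0.6–0.7);
lateral middle markers M4, M6 have the highest gains but 0.55 s phase
jitter (high mean, cross-session SD well above the selection ceiling).
The internal reference point is diaphragm-dominated (SI gain 1.0, AP 0.8)
with 0.1 mm noise. These are presets chosen once to emulate the target
ordinal structure — border > midline in amplitude and correlation — not
measured ground truth; reported amplitude/frequency figures from tracking
devices are in device-specific arbitrary units and are deliberately not
reproduced numerically.

## Marker scoring and selection

**CCA score.** For each (marker, session) pair the score is the first
canonical correlation between X = marker (AP, SI) and Y = reference
(AP, SI), computed as the largest singular value of
Cxx^(−1/2) Cxy Cyy^(−1/2). This is the tightest notion of "how well can
any linear readout of this marker track any linear readout of the
reference"; it is affine-invariant and dominates every single-channel
Pearson correlation. Rank-deficient within-set covariances are
ridge-regularized with a warning rather than failing. A constant channel
is a degenerate-input error.

**PCA score.** Each trace is collapsed to its first principal component
(mean-centred, unscaled channels — both are mm, so no standardization);
the score is |Pearson r| between the marker's and the reference's PC1
signals. The PC1 sign is fixed to correlate positively with the
largest-variance channel, making the score stable under channel
reflections. The PC1 explained-variance fraction is carried along and a
coverage gate (strictly > 90% by default) flags markers whose
mono-dimensional reduction would lose more than a small amount of data;
the gate is a diagnostic, not the selector.

**Selection rule.** Scores are aggregated across sessions into mean ±
population SD per marker (values are sorted before summation so the
aggregate is bit-identical under session permutations). A marker is
selected iff mean ≥ τ_corr AND SD ≤ τ_sd. The thresholds are not dictated
by theory; the defaults 0.95 / 0.25 are the loosest round values that
reproduce the published selection outcome on the published per-marker
summary statistics (admitting the border markers, rejecting the lateral
middle markers on SD alone and the midline markers on mean). Both
comparisons are inclusive; the coverage gate is strict. An empty selection
warns rather than raises.

Whether the upstream study pooled sessions or averaged per patient is not
documented; we score per session and aggregate afterwards, which keeps the
SD column meaningful for the variability criterion.

## ANFIS correlation model

One model per output axis (AP, SI) — per-axis modelling is standard
correlation-model practice and keeps consequents linear in mm. The input
vector is the concatenated (AP, SI) samples of the selected markers at one
time instant; no temporal lags are used (training data is synchronized
sample-wise).

* **Structure.** One rule per fuzzy cluster (default 3). Premises are
  Gaussian per dimension, combined with the product t-norm; consequents
  are first-order linear; defuzzification is the firing-strength-weighted
  average. With single-conjunction rules and weighted-average output, the
  OR/implication/aggregation choices of the classic Sugeno table
  (probabilistic OR, sum aggregation) are no-ops and are not implemented
  separately.
* **Initialization.** Fuzzy c-means (fuzzifier m = 2, tolerance 1e-5) on
  the training inputs; rule j's center in dimension k is the cluster
  center, sigma the membership-weighted standard deviation around it
  (floored at 1e-6 with a warning for zero-spread dimensions). Consequents
  start from one global least-squares fit.
* **Hybrid training.** Each epoch solves all consequents jointly by least
  squares on the firing-weighted regressors (this step provably cannot
  raise the training RMSE; a singular system falls back to a small ridge
  with a warning), then takes one gradient step on premise centers and
  sigmas. A step that raises the RMSE by more than 10% is retried with a
  halved learning rate (persistently), up to 8 halvings, else reverted.
  Default 50 epochs, learning rate 0.01.
* **Numerical safeguards.** Firing strengths are computed in log space; if
  every rule underflows (input far outside all premises) the prediction
  falls back to the nearest rule's consequent with a warning. FCM restarts
  (max 5, reseeded) on cluster collapse.

Rule count, epochs and split fraction have no documented counterparts in
the study being emulated; the defaults here are implementation choices
validated by the recovery tests (a known 2-rule generator is recovered to
within 2× the noise floor, sin(x) is fitted below 0.05 RMSE with 5 rules).

## Evaluation

RMSE = √(mean((A − P)²)) per axis, in mm. Cross-axis summaries use the
root of the mean of the per-axis mean squared errors. Evaluation is
honest about generalization: sessions are split into contiguous train /
held-out blocks (floor(0.7 n) training sessions by default) and all
reported RMSEs are test-session errors; within-session block splitting
(70/30, contiguous to respect serial correlation) is available for
single-session work.

`compare_modes` runs the full pipeline for six marker subsets — the
CCA-selected and PCA-selected sets, all nine markers, and the three
regions — and ranks modes by combined RMSE. `importance_degree` ranks the
three regions ascending by RMSE (rank 1 = most important placement
region), ties broken lexicographically so rankings are deterministic. A
selection that comes back empty under unusual criteria falls back to the
single best-mean marker so the comparison stays defined.

## Reproducibility

Every stochastic component is seeded; per-stage seeds are derived from one
master seed as crc32(stage name) XOR master, folded below 2³¹, so stages
can be re-run independently. All artifacts are plain CSV/YAML/JSON with
locale-independent `%.10g` floats (round-trip error < 1e-9). The pipeline
manifest records config, derived seeds, outputs and timings.

Default problem sizes: the acceptance computation uses five 60 s sessions
at 25 ms (2400 samples each) with 15 training epochs; the test suite runs
the same pipeline at 20 s / 50 ms with 8 epochs, which preserves every
qualitative outcome while keeping the suite fast enough to run on every
change. The 20-seed ordering checks use the reduced size.

## What passing tests do and do not show

The simulator reproduces the *ordinal* structure of the real problem —
which regions correlate, how selection separates them, that selected ≈
all-markers ≪ middle in RMSE — so end-to-end tests validate the method's
logic, not its clinical numbers. Real patient data differs in ways the
simulator does not model: cycle-to-cycle amplitude and period variability,
baseline drift of the internal point relative to the skin, hysteresis
(different inhale/exhale paths), cardiac contamination, and non-Gaussian
measurement noise. Absolute RMSEs in mm reported on synthetic sessions
therefore characterize the pipeline, not expected clinical accuracy.

## Known limitations

* Strictly periodic within-session breathing; no hysteresis or irregular
  breathing patterns.
* The phase-jitter mechanism is a minimal stand-in for all sources of
  inter-session correlation change.
* PCA/CCA scoring assumes linear marker–reference coupling; a marker
  nonlinearly coupled to the reference would be under-scored by both
  algorithms (the ANFIS stage, by contrast, is nonlinear).
* Selection thresholds are calibrated to reproduce one published outcome;
  other cohorts may need different τ values.
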