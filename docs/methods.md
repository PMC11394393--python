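# Methods

`hemoinfer` detects internal hemorrhage, and estimates its rate, from a single
noninvasively measurable signal: hematocrit (HCT, σ), sampled once per minute
as a continuous pulse-co-oximetry-style trend.  The difficulty is that σ falls
both when the patient bleeds and when the patient is resuscitated with fluids,
so a raw HCT drop cannot distinguish hemorrhage from harmless hemodilution.
Both detectors here resolve the ambiguity the same way: they know the
administered fluid rate u(t), predict the hemodilution that u alone would
cause, and attribute the unexplained remainder to bleeding.

## Plant: lumped-parameter blood-volume kinetics

States (liters): x1, the change in blood volume (BV) from its pre-insult value
VB0; x2, the target BV change toward which transcapillary fluid exchange
drives x1 at rate k (1/min); and VR, the red-blood-cell (RBC) volume.  With
resuscitation rate u and hemorrhage rate h (L/min):

    ẋ1 = −k·x1 + k·x2 − h + u
    ẋ2 = −h/(1+αh) + u/(1+αu)
    V̇R = −h·σ,        σ = VR / (VB0 + x1)

αu is the fraction of infused fluid ultimately shifted to the interstitium
(1/(1+αu) of it expands BV); αh is the fraction of hemorrhaged volume
eventually recouped from the interstitium.  Hemorrhage removes whole blood, so
RBCs leave in proportion to the current hematocrit and are never replenished —
hence σ is non-increasing whenever h > 0, and with h ≡ 0 the exact dilution
identity (σ0−σ)/σ = x1/VB0 holds (both are tested).

Integration is fixed-step RK4 at 0.05 min; halving the step changes terminal
states by < 1e−6 L.  A run ends at the first sampling instant with > 25% BV
loss or σ < 0.10 (a detection after either limit is "too late to save"), or at
a hard cap of 480 min.  Scenarios apply a 10-min zero-input settling period
followed by constant u and h.

## Luenberger observer (LO)

The linear subsystem (x1, x2) is augmented with the hemorrhage rate as a
slowly varying third state, and driven by the output

    y = (σ0 − σm)/σm,

which equals x1/VB0 exactly when h ≡ 0.  Under hemorrhage the neglected
h-driven output term biases the observer, and the final-value theorem puts the
asymptotic signature at x̂3 ≤ −αh·H for constant H: the signature is a
one-sided witness of bleeding, and −x̂3/αh an upper bound on its rate.  Both
statements are asymptotic, so the property tests scope them to hemorrhages
slow enough (≤ 0.03 L/min at u = 0) that the run outlasts the observer.

The observer gain is designed by pole placement on the nominal
(population-average) model.  Default poles are (−0.06, −0.05, −0.04) 1/min.
This choice is deliberate and matters: y amplifies absolute HCT noise by
σ0/σm², so an aggressive gain turns 1% sensor noise into signature excursions
an order of magnitude larger than the smallest hemorrhage signal
(αh·0.01 ≈ 0.02 L/min).  With |l3| ≈ 0.018 at the default poles the
no-hemorrhage signature noise floor sits well below that signal, while the
slowest time constant (25 min) remains short against typical run lengths.
The asymptote itself is gain-independent, so slowing the observer costs
detection latency, not detectability.

The observer advances once per measurement with 0.25-min RK4 sub-steps,
holding the newest sample (zero-order hold).  ZOH sampling leaves a
half-sample lag bias (for a state ramping at rate r, e1 → r·dt/2, i.e. x̂3
floor ≈ 8e−4 L/min on matched noise-free runs); the convergence tests assert
against that analytic floor rather than zero.

## Extended Kalman filter (EKF)

The nonlinear 4-state model augments the plant with x3 = h (random walk) and
x4 = VR, measured through σ = x4/(x1+VB0).  Process noise is not tuned: it is
propagated parametric uncertainty, Qw = Jθ·Qθ·Jθᵀ, where Jθ = ∂f/∂θ,
θ = (VB0, αu, αh, k), and Qθ is the population covariance the virtual patients
are actually drawn from (a matched prior).  The measurement variance Qv is the
known sensor noise variance of the scenario (floor 1e−8 for noise-free runs).
Prediction integrates the mean and the Lyapunov equation
Ṗ = FP + PFᵀ + Qw jointly (RK4, 0.25-min sub-steps); correction uses the
Joseph form, which keeps P positive semidefinite to 1e−10 across the grid.

Initialization: x̂ = (0, 0, 0, σm·V̄B0), P0 = diag(0.1², 0.1², 0.02², 0.1²).
Two structural points:

* The x3 row of Jθ is identically zero — the random-walk state receives *no*
  parametric process noise, only a 1e−10 floor.  Consequently P33 can only
  shrink, and it shrinks fast: running the filter through the settling period
  collapses P33 ~150-fold before anything happens, after which the filter is
  frozen in its belief that x3 ≈ 0 and cannot track the hemorrhage step.
  Both estimators therefore start at scenario onset, where the settling
  period has done its job (quiescent plant) and the prior is intact.  For
  constant-rate scenarios the filter then behaves like recursive least
  squares: it locks onto H and the estimate *smooths* as evidence
  accumulates, which is what makes the end-of-run rate error small.  The
  tested alternative — adding an explicit random-walk intensity
  (q33 ≈ 1e−5 L²/min³) — tracks steps from a cold covariance but roughly
  triples the late-run rate error at 1% noise, and is not the default.
* At the origin with u = 0, Jθ = 0 entirely; the q_floor exists so P cannot
  collapse to exactly singular there.

Twin-experiment recovery (matched parameters, no noise): |x̂3 − H|/H < 2% at
run end for H ∈ {0.01, 0.05, 0.1} L/min with grid-typical resuscitation
(u = 0.5·H).  With u = 0 the H = 0.1 run ends ~21 min after onset and the
filter reaches only ~7% error — recovery is evidence-limited, not broken.

## Virtual-patient generator

The population is an explicit synthetic stand-in (the study conditions the
harness defines): θ is multivariate lognormal, moment-matched so the sample
mean and covariance reproduce θ̄ = (5.0 L, 0.5, 2.0, 0.1/min) and a diagonal
Qθ at 15% coefficient of variation; σ0 ~ U(0.35, 0.45).  Lognormality
guarantees positivity without rejection; the empirical covariance of 1e5
draws matches Qθ within 5% relative Frobenius error.  The EKF's Qθ equals the
generating covariance unless overridden, keeping twin experiments clean.
Everything is overridable from the `population:` YAML block.

## Detection

Thresholds come from hemorrhage-free calibration: a dedicated cohort runs
every scenario with h forced to zero, and the threshold is the envelope of
what no-hemorrhage physiology plus sensor noise plus patient mismatch can
make the signature do.  Two choices here are load-bearing:

* **Thresholds are curves in time, not scalars.**  The signature spread grows
  enormously over a run (late in heavily diluted runs, σ → 0.10 and the LO
  output amplifies noise by σ0/σ²).  A scalar extreme is owned entirely by
  that late phase — at 1% noise it sits near −2 L/min, two orders beyond any
  hemorrhage signal, and the LO never fires.  The pointwise-in-time extreme
  over the calibration runs still alive at each sample is tight early and
  loose late, which is what makes early detection possible at all.
* **Calibration is per noise level.**  A deployed detector knows its sensor's
  noise specification — the same knowledge that sets Qv — so each noise level
  is evaluated against the envelope of its own calibration runs.  A pooled
  threshold would let the 3%-noise extremes disable the 0–1% evaluations.

Detection requires the signature *strictly* beyond the threshold (the
envelope is itself attainable by no-hemorrhage runs; this only matters in the
noise-free matched limit, where it yields exactly zero false positives) in
more than 50% of the samples of the trailing 10-min window [t−10, t), with no
declaration before one full window has elapsed past onset.  The naive
comparator declares at the first sample with σm ≤ 0.9·σ0, unwindowed.  The
corrected metrics follow the stricter positive notion: some declaration must
start a condition streak that holds to the end of the run (a later sustained
declaration counts even when the first one was transient).

## Evaluation harness

Grid: hemorrhage 0.01–0.10 L/min (step 0.01) × resuscitation 10–190% of H
(step 20%) × noise {0, 1, 2, 3}% — 400 scenarios — plus a hemorrhage-free
twin of each carrying the same absolute u: 800 per patient; 100 patients is
the full-scale protocol (80,000 runs).  Per run and detector: confusion class
(uncorrected and corrected), normalized detection time
NDT = t_detect / min(t_25%BV, t_10%HCT), and for hemorrhage runs the
normalized absolute rate error NAE = mean |Ĥ − H| / H over the final 10% of
the run (EKF: x̂3; LO: the upper bound max(0, −x̂3/αh)).  Scores are computed
per patient over that patient's runs, then summarized as cohort mean ± SD;
detector contrasts use paired t-tests with Bonferroni correction (m = 3,
cutoff p < 0.05/3 ≈ 0.016).  All randomness fans out from one master seed via
counter-based sub-seeds (cohort tag, patient, scenario), so any subset of the
grid reproduces independently.

The engine vectorizes plant and estimators across runs in lock-step (the
same broadcastable step functions serve single-run and batch paths); a
full-grid 20-patient evaluation with calibration runs in a few minutes on one
core.  Reported problem sizes in the shipped tests and acceptance script are
20 evaluation + 20 calibration patients at 1% noise (and a 10-patient reduced
grid for the noise scan), scaled from the 100-patient protocol.

## What the stand-in population does and does not show

The synthetic population reproduces the *mechanics* of the study — dilution
confounding, threshold calibration, windowed detection, rate recovery — but
not the tail behavior of the original animal-derived generator, and several
cohort-level numbers shift accordingly:

* False alarms are rare here.  A lognormal 15%-CV population almost never
  produces an evaluation patient outside the calibration envelope, so
  specificity ≈ 1 and F1 of both sequential detectors lands near 0.95 —
  *above* the reference levels (0.80/0.76) that were produced by a population
  with specificity near 0.5.  Corrected F1 ≥ 0.9 for the EKF, and EKF above
  LO on corrected F1, do reproduce.
* EKF rate-error quartiles land near 8/13/19% rather than ≤3/7/12%: NAE is
  dominated by the nominal-filter parameter-mismatch bias, i.e. directly by
  the population CV.
* The naive detector is the *fastest* detector here (NDT ≈ 0.1): resuscitation
  speeds its 10%-drop trigger while extending the survival limits, and the
  windowed detectors carry a built-in ≥ 10-min latency.  Its weakness is
  precision (specificity ≈ 0 — it fires on every sufficiently resuscitated
  hemorrhage-free run), not speed.
* F1 is not monotone in noise at this cohort scale: at 0% noise the
  calibration envelope is a pure mismatch envelope, and an evaluation patient
  outside it false-alarms *persistently*; noise widens the envelope faster
  than it degrades recall.  This is a finite-cohort extreme-value effect,
  strongest for small calibration cohorts.

Within-patient mechanics (plant identities, observer bound, Jacobians, PSD
covariance, twin recovery, grid accounting) are population-independent and
hold exactly at their stated tolerances.

## Numerical choices and degenerate inputs

Plant RK4 step 0.05 min; estimator sub-steps 0.25 min (observer eigenvalues
≤ 0.06/min make the sub-step error ~1e−9, verified by halving); measurement
interval 1 min.  Measured σ is clipped to (0.001, 0.999) so ratios stay
defined.  Noise is absolute ("1% HCT" = 0.01 in fraction units; a relative
interpretation is available via `add_measurement_noise(relative=True)`).
Ties: if both stop rules fire at the same sample the BV rule is recorded.
0/0 scores (e.g. precision with no declarations) are reported as missing and
excluded from cohort means, never coerced to 0.  Zero-variance paired t-tests
short-circuit (identical → not significant; constant nonzero difference →
significant, flagged degenerate).  k = 0 makes the augmented pair
unobservable and gain design raises an error rather than returning a stale
gain.

## Known limitations

Single-compartment volume kinetics (no Starling multi-compartment exchange,
no heart-rate/blood-pressure channel); constant-rate scenarios only (the
engine's fast path assumes step inputs; `simulate()` accepts arbitrary
piecewise-constant profiles); thresholds are population-level, not
personalized; the hemorrhage state is a random walk with zero drive, so the
EKF is tuned for sustained bleeds, not intermittent ones; and all
cohort-level scores inherit the stand-in population caveat above.
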