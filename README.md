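# hemoinfer

Sequential-inference detection of internal hemorrhage from continuous
hematocrit monitoring — a Luenberger observer and an extended Kalman filter on
a lumped-parameter blood-volume-kinetics model, plus the in-silico trial
harness (virtual patients, scenario grid, threshold calibration, detection and
rate-estimation metrics) used to evaluate them.

## The problem

Internal bleeding is hard to catch early: vital signs compensate, and the one
continuously measurable signal that does respond — hematocrit (HCT, σ) — falls
for two reasons at once.  Hemorrhage dilutes the blood as the interstitium
refills lost volume, but so does ordinary fluid resuscitation.  A clinician
infusing fluids therefore cannot read a falling HCT as bleeding.  Both
algorithms here exploit what the naive reading ignores: the fluid dose u(t) is
*known*.  Each predicts the hemodilution that u alone would cause on a
population-average patient model and turns the unexplained remainder into a
hemorrhage signature.

## The model and the two estimators

Blood-volume kinetics (states in liters; k in 1/min; σ the measured HCT):

    ẋ1 = −k·x1 + k·x2 − h + u          x1: blood-volume change from VB0
    ẋ2 = −h/(1+αh) + u/(1+αu)          x2: target volume change
    V̇R = −h·σ,   σ = VR/(VB0 + x1)     VR: red-cell volume

* **LO** — augments the linear (x1, x2) subsystem with the hemorrhage rate as
  a slowly varying state x3 and observes y = (σ0−σ)/σ, which equals x1/VB0
  exactly when h = 0.  Under a constant hemorrhage H the neglected h-driven
  output term drives the estimate to x̂3 ≤ −αh·H (final-value theorem), so a
  sufficiently negative x̂3 flags bleeding and −x̂3/αh bounds its rate.
* **EKF** — filters the full nonlinear 4-state model (x3 = h as a random
  walk, x4 = VR) with process noise propagated from population parameter
  uncertainty, Qw = Jθ·Qθ·Jθᵀ.  Its x̂3 *is* the hemorrhage-rate estimate.

Detection declares when the signature stays beyond a calibrated threshold in
more than half of the trailing 10-minute window.  Thresholds are the envelope
of everything hemorrhage-free physiology can do: per noise level and per time
point, the extreme signature across a calibration cohort run under
resuscitation alone.  A naive comparator (σ ≤ 0.9·σ0) is scored alongside.

## Worked example

`python examples/single_run_detection.py` — one virtual patient bleeding at
0.03 L/min while receiving 0.015 L/min of fluids, 1% HCT sensor noise:

```
scenario: hemorrhage 0.03 L/min, resuscitation 0.015 L/min, 1% HCT noise
  lo     detected:    69 min after onset   (run ends 230 min, hct10)
  ekf    detected:    30 min after onset   (run ends 230 min, hct10)
  naive  detected:    21 min after onset   (run ends 230 min, hct10)
EKF hemorrhage-rate error over the final 10% of the run: 0.5% of the true 0.03 L/min
```

All three detectors fire long before the run's survival limit (230 min, when
HCT crosses 10%).  The naive rule is quick here but is also the detector that
fires on *every* sufficiently resuscitated patient who is not bleeding at all
— the cohort evaluation below is what separates them.  The EKF additionally
reads the bleeding rate to half a percent on this matched patient.

`python examples/calibrate_and_evaluate.py` runs the full protocol at reduced
scale: threshold calibration on hemorrhage-free runs of one cohort, then a
hemorrhage/resuscitation grid with hemorrhage-free twins on a disjoint cohort,
reporting per-patient F1, corrected F1, precision/recall/specificity and
normalized detection time per detector, with Bonferroni-corrected paired
t-tests.  `examples/hemorrhage_rate_estimation.py` and
`examples/virtual_patients.py` show rate recovery and the population model.

A thin CLI wraps the same library surface:

```bash
hemoinfer calibrate --config cfg.yaml --out results/thresholds.json
hemoinfer evaluate  --config cfg.yaml --out-dir results/
hemoinfer report    --metrics results/metrics.json
```

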