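"""Detect an internal hemorrhage in a single monitored patient.

Simulates one virtual patient bleeding at 0.03 L/min while receiving fluids at
0.015 L/min, with 1% HCT sensor noise, then runs the Luenberger observer, the
extended Kalman filter and the naive 10%-HCT-drop rule side by side.
"""

import numpy as np

from hemoinfer import (
    DetectionConfig,
    EKFConfig,
    LOConfig,
    PopulationModel,
    nominal_patient,
    run_scenario,
)
from hemoinfer.evaluation import Scenario

pop = PopulationModel.from_cv()
patient = nominal_patient(pop)
lo_cfg = LOConfig(params_nominal=patient)
ekf_cfg = EKFConfig(params_nominal=patient, q_theta=pop.q_theta, q_v=1e-4)

# illustrative fixed thresholds; the evaluation harness calibrates these on
# hemorrhage-free runs (see calibrate_and_evaluate.py)
det_cfg = DetectionConfig(x3_lo_threshold=-0.05, x3_ekf_threshold=0.02)

scenario = Scenario(H=0.03, u_frac=0.5, noise_level=0.01, with_hemorrhage=True)
results = run_scenario(patient, scenario, lo_cfg, ekf_cfg, det_cfg, seed=42)

print(f"scenario: hemorrhage {scenario.H} L/min, resuscitation "
      f"{scenario.u_rate} L/min, {100 * scenario.noise_level:g}% HCT noise")
for name, r in results.items():
    when = "never" if r.detect_time is None else f"{r.detect_time:5.0f} min after onset"
    print(f"  {name:<6} detected: {when}   (run ends {r.stop_time:.0f} min, {r.stop_reason})")
print(f"EKF hemorrhage-rate error over the final 10% of the run: "
      f"{100 * results['ekf'].nae:.1f}% of the true 0.03 L/min")
# The two model-based detectors flag the bleed from the mismatch between
# administered fluids and measured hemodilution; the naive rule only reacts
# once HCT has fallen 10%, and reacts identically to harmless dilution.
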