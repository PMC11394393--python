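"""Sample virtual patients and watch one hemodilute.

The virtual-patient generator draws blood-volume-kinetics parameters from a
moment-matched multivariate lognormal population; each draw is one patient the
estimators have never seen.  The trajectory below shows the measured signal the
whole package lives on: hematocrit falling under combined hemorrhage and
resuscitation.
"""

import numpy as np

from hemoinfer import InputSignal, PopulationModel, sample_patients, simulate

pop = PopulationModel.from_cv()  # VB0 5 L, alpha_u 0.5, alpha_h 2, k 0.1/min, 15% CV
patients = sample_patients(pop, 5, seed=3)

print(f"{'VB0 [L]':>8} {'alpha_u':>8} {'alpha_h':>8} {'k [1/min]':>10} {'HCT0':>6}")
for p in patients:
    print(f"{p.vb0:8.2f} {p.alpha_u:8.3f} {p.alpha_h:8.3f} {p.k:10.4f} {p.sigma0:6.3f}")

p = patients[0]
traj = simulate(p, InputSignal.step(u=0.015, h=0.03), t_max=480.0)
traj = traj.with_noise(0.01, seed=7)
print(f"\npatient 0 under 0.03 L/min hemorrhage + 0.015 L/min fluids:")
for t in (0, 30, 60, 120, traj.times[-1]):
    i = np.searchsorted(traj.times, t)
    print(f"  t={traj.times[i]:5.0f} min  BV={p.vb0 + traj.x1[i]:5.2f} L  "
          f"HCT={traj.sigma[i]:.3f} (measured {traj.sigma_meas[i]:.3f})")
print(f"run stopped by rule: {traj.stop_reason} "
      f"(>25% blood volume lost or HCT < 10%)")
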