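"""Ingrowth of the short-lived radon progeny in a closed parcel of air.

Starting from 1 Bq m⁻³ of pure radon (0.477 atoms cm⁻³) with no progeny,
the Bateman solution shows how ²¹⁸Po approaches its parent's activity
within ~20 minutes while ²¹⁴Pb and ²¹⁴Bi need a few hours.
"""

import numpy as np

from rnaero import bateman_ingrowth

times_min = np.array([0, 5, 15, 30, 60, 120, 240])
traj = bateman_ingrowth(1.0, times_min * 60.0)

print(f"{'t/min':>6} {'A_Rn':>8} {'A_Po218':>8} {'A_Pb214':>8} {'A_Bi214':>8}   (Bq m^-3)")
for i, t in enumerate(times_min):
    print(f"{t:>6} {traj.activity['Rn-222'][i]:8.4f} {traj.activity['Po-218'][i]:8.4f} "
          f"{traj.activity['Pb-214'][i]:8.4f} {traj.activity['Bi-214'][i]:8.4f}")

print("\nEach column rises toward the radon activity (secular equilibrium);")
print("the ordering of the rise times mirrors the nuclide half-lives")
print("(3.05 min, 26.8 min, 19.7 min behind a 26.8 min bottleneck).")
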