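"""Calcium coding of stimulus intensity.

Sustained stimulation at increasing external drive modulates the
frequency (f_Ca) and amplitude (A_Ca) of astrocytic calcium spikes,
which the vasculature reads out as a graded BOLD amplitude.  A coarse
grid keeps the run short; the full analysis uses a denser one.
"""

import numpy as np

from nvcsim.analysis import coding_curve
from nvcsim.params import SimulationConfig

config = SimulationConfig()
grid = np.array([3.0, 4.0, 5.0, 6.5, 8.0])
cc = coding_curve(grid, config, duration=60.0, threshold=2.43, seed=0)

print(cc.table[["nu_ext", "nu_e", "f_Ca", "A_Ca",
                "bold_peak"]].to_string(index=False,
                                        float_format="%.3f"))
if cc.log_fit:
    A, x0, B, r2 = cc.log_fit
    print(f"log fit f_Ca = A ln((nu_e - x0)/B): A={A:.3f}, x0={x0:.2f}, "
          f"B={B:.3f} (R^2={r2:.3f})")
print("-> above the ~2.4 Hz activation threshold both spike frequency "
      "and amplitude grow monotonically with the drive; frequency "
      "carries most of the information transmitted to the BOLD "
      "amplitude.")
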