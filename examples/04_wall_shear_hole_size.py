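"""Hole-size trade-off: smaller side holes carry less flux at higher shear.

Solves the two ends of the side-hole diameter sweep (DSH = 1.1 mm and
0.4 mm at Ds = 1 mm), compares the wall-shear-stress distributions at SH1
with a rank-sum test, and prints the headline ratios.  ~1 minute.
"""

import numpy as np

from stentflow import postprocess as post
from stentflow.workbench import CaseConfig, run_case

cases = {dsh: run_case(CaseConfig(DSH=dsh, Ds=1.0)) for dsh in (1.1, 0.4)}

for dsh, res in cases.items():
    r1 = res.rows[res.rows.sh_index == 1].iloc[0]
    print(f"DSH = {dsh} mm: SH1 flux {r1.Q_SH:+.3f} mm^2/s, "
          f"median tau {r1.tau_median:.2e} Pa "
          f"(IQR {r1.tau_q1:.2e} .. {r1.tau_q3:.2e})")

incs, decs = [], []
for idx in (1, 8):
    hi = cases[0.4].rows[cases[0.4].rows.sh_index == idx].iloc[0]
    lo = cases[1.1].rows[cases[1.1].rows.sh_index == idx].iloc[0]
    incs.append((hi.tau_median / lo.tau_median - 1) * 100)
    decs.append((1 - abs(hi.Q_SH) / abs(lo.Q_SH)) * 100)
print(f"\nDSH 1.1 -> 0.4 mm at the end holes (SH1, SH8):")
print(f"  median wall shear: +{np.mean(incs):.0f}%")
print(f"  flux magnitude:    -{np.mean(decs):.0f}%")

fluid = cases[1.1].config.fluid()
samples = {}
for dsh, res in cases.items():
    sh1 = res.flow.mesh.domain.stent.side_holes[0]
    samples[dsh] = post.sh_wall_shear(res.flow, sh1, fluid).samples
p = post.rank_sum_compare(samples[1.1], samples[0.4])
print(f"  rank-sum p-value for the SH1 shear distributions: {p:.1e}")
print("\n=> shrinking the holes concentrates the same exchange through a")
print("   narrower channel: less flux but a significantly higher shear")
print("   level on the hole walls, which discourages encrustation there.")
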