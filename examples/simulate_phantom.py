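"""Build one synthetic beating-heart cine and check volumes against the
closed-form oracle.

The phantom's chamber volumes follow V(t) = (4/3)π a b c̄ (1 + α sin(...)),
so voxel-counted truth masks can be validated exactly.
"""

import numpy as np

from cardiomorph import phantom, mechanics

params = phantom.preset(4, pitch=4.0, frames=20)  # 4-dpf heart, fast profile
totals = []
for k in range(params.frames_per_cycle):
    truth = phantom.make_truth(params, k)
    totals.append(mechanics.mask_volume(truth.lumen()))
    if k < 3:
        t = params.frame_time(k)
        v_analytic = phantom.analytic_chamber_volume(
            params.ventricle, t, params.period, include_trabeculation=True
        )
        v_voxel = mechanics.mask_volume(truth, label=2)
        print(
            f"frame {k}: ventricle voxel {v_voxel:.4g} vs closed form "
            f"{v_analytic:.4g} um3 ({100 * (v_voxel / v_analytic - 1):+.2f}%)"
        )

print(f"\ncycle-mean total lumen: {np.mean(totals):.4g} um3")
print("(~9.5e5 um3 is the scale of a 4-dpf zebrafish heart; the small excess")
print(" over the two-ellipsoid closed form is the canal plus trabeculation)")
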