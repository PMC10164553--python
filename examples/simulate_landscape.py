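"""Simulate a lifetime landscape and quantify its Goldilocks peak.

Builds the reference two-state model in relative units (k_u = 1,
k_f = 0.2 t_rel^-1 [Mg2+]_rel^-1, midpoint at 1 [Mg2+]_rel, n = 4.1),
evaluates the lifetime curve, and reports the peak's position, intensity,
half-height width and area.
"""

import numpy as np

from goldilocks import (
    CleavageRates,
    FoldingTwoState,
    ModelSpec,
    goldilocks_peaks,
    lifetime_curve,
    peak_area,
    peak_width_half_height,
)

spec = ModelSpec(
    states=2,
    folding=FoldingTwoState(K_D=1.0, n=4.1),
    rates=CleavageRates(k_u=1.0, k_f=0.2),
    units="relative",
)

curve = lifetime_curve(np.geomspace(0.1, 10, 200), spec)
print(f"lifetime at 0.1 Mg_rel: {curve.lifetime[0]:.3f} t_rel (unfolded, dilute Mg2+)")
print(f"lifetime at 10  Mg_rel: {curve.lifetime[-1]:.3f} t_rel (folded, Mg2+ excess)")

(peak,) = goldilocks_peaks(spec)
width = peak_width_half_height(spec, peak)
area = peak_area(spec, peak)
print(f"\nGoldilocks peak at {peak.maximum.mg:.3f} Mg_rel, "
      f"lifetime {peak.maximum.lifetime:.3f} t_rel")
print(f"preceding minimum at {peak.preceding_minimum.mg:.3f} Mg_rel, "
      f"lifetime {peak.preceding_minimum.lifetime:.3f} t_rel")
print(f"intensity {peak.intensity:.3f}  (max/min lifetime ratio: the fold-"
      "protection the RNA gains by sitting on the peak)")
print(f"half-height width {width:.3f} Mg_rel, area above flank chord {area:.3f}")
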