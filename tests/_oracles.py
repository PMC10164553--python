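"""Independent brute-force oracles shared by the test suite."""

import numpy as np


def brute_force_extrema(spec, window, num=1_000_000):
    """Independent dense-grid oracle for lifetime extrema.

    Evaluates the lifetime pointwise on a log grid and reads interior
    turning points off the finite-difference sign pattern; shares no code
    path with the analytic root-finding in goldilocks.landscape.
    """
    from goldilocks.models import lifetime

    mg = np.geomspace(window[0], window[1], num)
    y = lifetime(mg, spec)
    sign = np.sign(np.diff(y))
    out = []
    for j in np.nonzero(np.diff(sign) != 0)[0]:
        kind = "maximum" if sign[j] > 0 else "minimum"
        out.append((kind, mg[j + 1], y[j + 1]))
    return out
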