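"""Duschinsky consistency gate for hybrid harmonic/anharmonic force fields.

A high-level harmonic description can be paired with a cheaper anharmonic
force field only when the two sets of normal modes match: every row and
column of J = (L_high)^T L_low must have exactly one squared element > 0.9.
Two modes mixed by 10 degrees pass (cos^2 10 = 0.970); 20 degrees fail
(cos^2 20 = 0.883).
"""

import math

import numpy as np

from gvpt2 import check_correspondence, duschinsky

rng = np.random.default_rng(0)
L_high, _ = np.linalg.qr(rng.normal(0, 1, (9, 9)))
L_high = L_high[:, :3]

for deg in (10.0, 20.0):
    th = math.radians(deg)
    L_low = L_high.copy()
    L_low[:, 0] = math.cos(th) * L_high[:, 0] + math.sin(th) * L_high[:, 1]
    L_low[:, 1] = -math.sin(th) * L_high[:, 0] + math.cos(th) * L_high[:, 1]
    res = duschinsky(L_high, L_low)
    rep = check_correspondence(res, threshold=0.9)
    print(f"{deg:4.0f} deg mixing: max row overlap^2 = "
          f"{res.max_sq_row.min():.4f} -> {'PASS' if rep.passed else 'FAIL'}")
    if not rep.passed:
        print(f"          offending modes: rows {rep.offending_rows}")
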