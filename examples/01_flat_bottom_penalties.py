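"""Shape of the flat-bottom restraint penalty and its tail.

Builds a single distance restraint with the default parameters
(A = 5 kcal/mol, sigma = 1 A, kappa = 0.01) and prints the penalty and its
slope at increasing violations.  The well is zero inside the bounds, rises
quartically through a ~1 A thick wall, and then flattens to an asymptotically
linear tail of slope A*kappa — badly violated restraints pull gently instead
of tearing the structure apart.
"""

import numpy as np

from ravmd import v_dist, v_dist_deriv

lower, upper = 3.0, 5.0
print(f"restraint window [{lower}, {upper}] A, A=5 kcal/mol, sigma=1 A, kappa=0.01")
print(f"{'d (A)':>8} {'V (kcal/mol)':>14} {'dV/dd':>10}")
for d in [3.5, 5.0, 5.5, 6.0, 7.0, 10.0, 25.0, 55.0]:
    v = v_dist(d, lower, upper)
    g = v_dist_deriv(d, lower, upper)
    print(f"{d:8.1f} {v:14.4f} {g:10.4f}")
print()
print("inside the window the penalty and force vanish; far outside, the slope")
print(f"approaches A*kappa = {5 * 0.01:.2f} kcal/(mol A), the gentle linear tail.")
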