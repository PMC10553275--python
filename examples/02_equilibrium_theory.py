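"""Scan the closed-form equilibrium across the enhancement factor.

For each r the stationary state falls on one of three branches: defectors
only (rho_D = lam/eta), Lambert-W coexistence, or cooperators only
(rho_C = lam/(eta - (r-1)c)).  The branch boundary on the low-r side is the
cooperation onset r* = (lam/eta)/(1 - exp(-lam/eta)), which depends only on
the ratio of basal inflow to metabolic rate.
"""

import numpy as np

from ecoflow import (
    cooperation_threshold,
    equilibrium_densities,
    zero_lambda_threshold,
)

lam, eta, c = 0.6, 0.4, 0.1

r_star = cooperation_threshold(lam, eta)
print(f"cooperation onset r* = {r_star:.5f}  (lam/eta = {lam/eta})")
print(f"zero-inflow threshold 1 + eta/c = {zero_lambda_threshold(eta, c)}")
print()
print(" r     branch   rho_C    rho_D    total")
for r in np.arange(1.2, 5.01, 0.4):
    sol = equilibrium_densities(lam, eta, r, c)
    print(f"{r:4.1f}   {sol.branch.value:>4}    {sol.rho_C:6.3f}  "
          f"{sol.rho_D:6.3f}  {sol.rho:6.3f}")

# Below r* the cooperator column is zero; above it, cooperators carry an
# ever larger share of a total density that rises with r because the
# cooperative surplus (r-1)c*rho_C acts as extra resource inflow.
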