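"""Evaluate the two apoptosis hazard curves at their landmark points.

The decision layer eliminates cells through two stochastic routes: a
logistic hazard driven by local crowding (density-dependent apoptosis) and a
Hill hazard driven by the fraction of a cell's boundary in heterotypic
contact (contact-dependent apoptosis). Both are per-simulation-step
probabilities.
"""

import numpy as np

import cellcompete as cc

per_type, _ = cc.convert_params()
p = per_type["A"]

print("density-dependent apoptosis, P(rho) = p_max / (1 + exp(-beta(rho-rho_half)))")
print(f"  saturation (rho >> rho_half): {cc.p_apoptosis_density(10.0, p):.6f}"
      "   <- ceiling probability per step under extreme crowding")
print(f"  at the midpoint rho_half:     {cc.p_apoptosis_density(p.rho_half, p):.6f}"
      "   <- half the ceiling, by construction")
print(f"  in an uncrowded tissue:       {cc.p_apoptosis_density(0.0, p):.6f}"
      "   <- baseline death rate never reaches zero")

print()
print("contact-dependent apoptosis, P(p_AB) = p_max p_AB^n / (S^n + p_AB^n)")
print(f"  no heterotypic contact:  {cc.p_apoptosis_contact(0.0, p):.6f}")
print(f"  fully surrounded (p_AB=1): {cc.p_apoptosis_contact(1.0, p):.6f}"
      "  <- the fitted midpoint S=1.35 lies above 1, so even full"
      " heterotypic contact stays below half-maximum")
for n in (1.8, 3.6, 7.2):
    v = cc.p_apoptosis_contact(p.steepness_S, p.with_overrides(hill_n=n))
    print(f"  at p_AB = S with Hill n={n}: {v:.6f}  <- invariant in n")

print()
print("typical interface cell (p_AB ~ 0.4):",
      f"{cc.p_apoptosis_contact(0.4, p):.2e} per step ->",
      f"mean lifetime ~{1 / cc.p_apoptosis_contact(0.4, p):.0f} steps;",
      "boundary cells turn over within a cell cycle (~225 steps).")
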