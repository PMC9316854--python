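"""Analytic layer: infusion thresholds, CAR-T fate and equilibria.

The eradication threshold phi_CART is the constant CAR-T infusion rate
above which the tumor-free state is globally attracting; below phi_prstnc
the tumor provably persists.  The CAR-T mitosis rate rho_T against
mu_A*mu_T/mu_d decides whether a single infusion washes out or persists.
"""

import cllcart as cc

p = cc.ModelParameters()
print(f"eradication threshold phi_CART:  {cc.eradication_dose_threshold(p):,.0f} cells/day")
print(f"with chemo pressure mu_TC=0.02:  "
      f"{cc.eradication_dose_threshold(p.evolve(mu_TC=0.02)):,.0f} cells/day")
thr, fate = cc.cart_fate_threshold(p)
print(f"CAR-T fate threshold mu_A*mu_T/mu_d = {thr:.4g}; "
      f"rho_T = {p.rho_T:.4g} -> {fate}")

eq = {e["name"]: e for e in cc.equilibria(p)}
A, Ad = eq["no_treatment"]["A"], eq["no_treatment"]["Ad"]
print(f"untreated tumor burden: A* = {A:.4g} cells "
      f"({A / 5e6:,.0f} cells/uL), dead fraction {Ad / A:.2%}")

point = cc.coexistence_equilibrium(p)
print("coexistence point (persistence regime): "
      f"A*={point[0]:.5g}, Ad*={point[1]:.5g}, T*={point[2]:.6g}")
print("  -> a residual ~1e4-cell CAR-T population coexists with a large tumor")

lams = cc.jacobian_eigenvalues(p, "no_treatment")
print("eigenvalues at the untreated point:",
      ", ".join(f"{l.real:+.4g}{l.imag:+.4g}j" for l in lams))
print("  -> the positive third eigenvalue is the CAR-T persistence direction")
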