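"""Dose-response laws: from a chlorambucil dose in mg to a kill rate in 1/day.

Walks the full pharmacokinetic chain for the standard 0.4 mg/kg dose in an
80 kg patient, then evaluates the CAR-T efficacy law for a trial-derived
rate combination.
"""

import cllcart as cc

dose_mg = cc.weight_based_dose(80.0, 0.4)
molecules = cc.mg_to_molecules(dose_mg)
kappa = cc.blood_concentration(dose_mg)  # mg per litre over 5 L of blood
mu_AC = cc.chlorambucil_cytotoxicity(kappa)
mu_C = cc.half_life_to_decay_rate(0.0625)

print(f"dose:                {dose_mg:.0f} mg  ({molecules:.6e} molecules)")
print(f"blood concentration: {kappa:.1f} mg/L")
print(f"kill rate mu_AC:     {mu_AC:.4f} /day  (fraction of tumor killed per day)")
print(f"drug decay mu_C:     {mu_C:.3f} /day   (half-life 1.5 h)")

alpha_T = cc.cart_cytotoxicity(rho_T=2.786e-8, mu_T=1 / 30, rho_A=1 / 60)
print(f"CAR-T efficacy alpha_T: {alpha_T:.4g} /cell/day "
      "(per-cell kill rate at low mitosis/exhaustion pressure)")
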