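"""Growth metrics, mass correction, Q10 and factorial aerobic scope.

Shows the organism-level arithmetic: specific growth rate and condition
factor per fish, fold changes per treatment, and how metabolic rates
measured on different-sized fish are rescaled to a common reference
mass before temperature comparisons.
"""

import gillscale as g

# growth: a fish growing from 2.62 g to 203.43 g over 240 days
iv = g.GrowthInterval("fish-1", t1_days=0, t2_days=240, m1_g=2.62, m2_g=203.43)
sgr = g.specific_growth_rate(iv)
print(f"SGR = {sgr:.3f} %/day  (100 x delta-ln mass per day)")
print(f"fold change = {g.fold_change(203.43, 2.62):.1f}x over the experiment")
print(f"condition factor K = {g.condition_factor(203.43, 26.0):.3f} "
      "(relative plumpness at 26 cm fork length)")
print()

# mass correction: a 48 g fish's RMR rescaled to the 24 g reference
# using the temperature-specific allometric slope b = 0.872
rmr_48g = 3.0
rmr_mc = g.mass_correct(rmr_48g, mass_g=48.0, b=0.872)
print(f"RMR 3.0 mg O2/h at 48 g -> {rmr_mc:.3f} mg O2/h at 24 g "
      "(MR_mc = MR x (M_ref/M)^b)")

# Q10: temperature sensitivity of the mass-corrected rate
q = g.q10(r1=1.0, r2=1.32, t1_c=15.0, t2_c=20.0)
print(f"Q10 = {q:.3f} for a 32% rate increase over 5 degC")

# FAS: aerobic ceiling relative to maintenance, both mass-corrected
fas = g.factorial_aerobic_scope(mmr_mc=6.0, rmr_mc=2.0)
print(f"FAS = {fas:.1f} (mass-corrected MMR / mass-corrected RMR)")
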