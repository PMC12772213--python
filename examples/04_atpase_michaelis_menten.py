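"""Steady-state ATPase from NADH-coupled progress curves.

Simulates noisy linear absorbance decays over a thin-filament titration,
converts each slope to a per-head hydrolysis rate via the NADH extinction
coefficient, and fits the Michaelis-Menten curve with a bootstrap CI.
"""

import trapcycle as tc

concs = [0.0, 1.25, 2.5, 5.0, 10.0, 20.0, 40.0, 60.0]  # µM thin filaments
heads = 0.1  # µM myosin heads
curves = tc.simulate_atpase_progress(vmax=2.35, km=7.65, tf_concs=concs,
                                     heads=heads, noise_sd=0.003, seed=4)
rates = [tc.nadh_slope_to_rate(c, heads=heads) for c in curves]
print("per-head rates (1/s):",
      " ".join(f"{r:.2f}" for r in rates))

fit = tc.fit_michaelis_menten(concs, rates, n_boot=500, seed=9)
print(f"Vmax = {fit.vmax:.2f} /s (95% CI {fit.vmax_ci[0]:.2f}-"
      f"{fit.vmax_ci[1]:.2f}); generative 2.35")
print(f"Km   = {fit.km:.1f} uM (95% CI {fit.km_ci[0]:.1f}-"
      f"{fit.km_ci[1]:.1f}); generative 7.65")
print("the doubled Vmax relative to wild type (1.20 /s) reflects more "
      "available heads, not faster individual cycling")
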