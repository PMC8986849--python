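"""Measure a binding constant from a PRE solvent-reporter titration.

Simulates bulk-chloroform R1 readings while titrating guest into a fixed
0.5 mM paramagnetic host solution (true log Ka = 3.68), then fits the 1:1
isotherm for Ka, log Ka and the binding free energy.
"""

from prenmr import fit_titration
from prenmr.synthetic import default_ground_truth, simulate_titration

gt = default_ground_truth(seed=7, noise_sigma=0.01)
points = simulate_titration(gt)

print("guest (mM)   reporter R1 (s^-1)")
for p in points:
    print(f"  {1e3 * p.guest_total:8.3f}   {p.reporter_R1_obs:6.3f}")

fit = fit_titration(points, mc_draws=500, seed=0)
print(f"\nlog Ka = {fit.logKa:.2f} +- {fit.stderr_logKa:.2f} "
      f"(Monte-Carlo: +- {fit.mc_stderr_logKa:.2f})")
print(f"Ka     = {fit.Ka:.0f} M^-1")
print(f"dG     = {fit.dG:.2f} kcal/mol at {fit.temperature:.2f} K")
print(f"R_empty = {fit.R_empty:.2f}, R_sat = {fit.R_sat:.2f} s^-1")
print("\nThe reporter rate falls as guest displaces chloroform from the "
      "paramagnetic cavity; the midpoint of the drop fixes Ka.")
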