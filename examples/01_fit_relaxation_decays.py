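"""Fit inversion-recovery and CPMG decay curves to mono-exponentials.

Builds two noiseless decay series with known T1/T2, fits them, and shows the
paramagnetic transverse-relaxation enhancement a bound paramagnetic host
produces on a free guest signal.
"""

import numpy as np

from prenmr import DecaySeries, fit_cpmg_decay, fit_inversion_recovery

# inversion recovery: I(t) = I_inf * (1 - B exp(-t/T1)), T1 = 1.0 s
t = np.geomspace(0.01, 5.0, 10)
ir = DecaySeries("guest-only", "inversion_recovery", tuple(t),
                 tuple(1.0 - 2.0 * np.exp(-t / 1.0)), temperature=293.15,
                 field=500.0, signal_label="meta-H")
fit = fit_inversion_recovery(ir)
print(f"T1 = {fit.time_constant:.4f} s  ->  R1 = {fit.rate:.3f} s^-1 "
      f"(inversion factor B = {fit.inversion_factor:.2f})")

# CPMG decays without and with the paramagnetic host present
for label, t2 in [("free guest", 1.66), ("guest + 9 mol% Mn host", 0.10)]:
    td = np.geomspace(0.005, 3 * t2, 10)
    s = DecaySeries(label, "cpmg", tuple(td), tuple(np.exp(-td / t2)),
                    temperature=293.15, field=500.0, signal_label="meta-H")
    f = fit_cpmg_decay(s)
    print(f"{label:>24s}: T2 = {f.time_constant:.3f} s, R2 = {f.rate:.2f} s^-1")

print("\nThe ~16x faster transverse relaxation with the host present is the "
      "exchange-driven paramagnetic relaxation enhancement (PRE).")
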