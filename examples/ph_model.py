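"""Predict the pH of CO2-saturated WPI solutions and invert for a target.

Dissolved CO2 acts as a pressure-tunable acid: pH falls logarithmically with
CO2 pressure and shifts with protein concentration (buffering).
"""
from wheyfrac import f_of_c, ph_at, ph_rounded, pressure_for_ph

for C in (5, 10):
    for P in (5.5, 8.3, 31.0):
        print(f"C = {C:2d} wt%, P = {P:5.1f} MPa -> "
              f"pH {ph_at(P, C):.3f} (reported as {ph_rounded(P, C):.1f})")
# Each line is the equilibrium pH the reactor reaches at that pressure and
# concentration; the 1-dp value is the experiment-table convention.

print(f"\nconcentration term f(10 wt%) = {f_of_c(10):.4f} pH units")

target = 4.7
P = pressure_for_ph(target, C_wpi=5)
print(f"to reach pH {target} at 5 wt%: operate at {P:.2f} MPa")
# The closed-form inversion of the pH correlation -- useful to pick the CO2
# pressure that hits the isoelectric window of alpha-lactalbumin.
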