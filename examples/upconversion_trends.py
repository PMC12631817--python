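"""Steady-state upconversion trends of core-shell-shell Yb/Er nanoparticles.

Sweeps the rate-equation model over core sensitizer doping, excitation power
and inert-shell thickness, and prints the trends a brightness-optimization
campaign cares about: the S-shaped doping curve, the softening power slope,
the red/green balance, and shell-thickness saturation.
"""

import numpy as np
from dataclasses import replace

from uspt import photophysics as pp

par = pp.DEFAULT_RATE_PARAMS
arch = pp.DEFAULT_ARCHITECTURE

doping = pp.doping_sweep(par, np.linspace(0.0, 0.9, 10))
print("Total brightness vs core Yb fraction (x_Er = 0.1, 11.6 kW/cm^2):")
print(doping[["x_yb", "total", "rg_ratio"]].round(3).to_string(index=False))
gain = doping["total"].iloc[-1] / doping["total"].iloc[0]
print(f"-> alloy core (x_Yb=0.9) is {gain:.1f}x brighter than the Yb-free core;")
print("   the second difference changes sign along the curve (the S shape).\n")

grid = np.geomspace(0.69, 21.7, 8)
for x in (0.0, 0.9):
    sweep = pp.power_sweep(replace(arch, core_yb_fraction=x), par, grid)
    print(f"x_Yb={x:.1f}: low-decade log-log slope = {sweep.slope_total:.3f}")
print("-> higher sensitizer doping saturates earlier (smaller slope).\n")

shell = pp.shell_sweep(par)
print("Brightness vs inert shell thickness (surface quenching screened):")
print(shell[["t_inert_nm", "total", "rg_ratio"]].round(3).to_string(index=False))
last_gain = shell["total"].iloc[-1] / shell["total"].iloc[-2] - 1
print(f"-> saturating: the last step (5.4 -> 6.8 nm) adds only {100*last_gain:.1f}%.")
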