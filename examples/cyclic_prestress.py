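"""Prestress relaxation of a viscoelastic patch under cyclic stretch.

A patch is prestretched when applied to the beating heart and then cycled at
the heart rate.  A viscoelastic network lets the prestress relax away while
the oscillatory response settles to a steady state; this script simulates
that protocol (75 % prestrain + 25 % cycles at 4 Hz) and reports when the
per-cycle peak stress converges.
"""

import numpy as np

from gelstrain import (
    Formulation,
    cycles_to_convergence,
    default_calibration,
    formulation_to_modes,
    simulate_stress,
)

spectrum = formulation_to_modes(Formulation(15.0, 0.2), default_calibration())

frequency, n_cycles, spc = 4.0, 100, 100
t = np.arange(n_cycles * spc + 1) / (spc * frequency)
strain = 0.75 + 0.25 * 0.5 * (1 - np.cos(2 * np.pi * frequency * t))
stress = simulate_stress(spectrum, t, strain)

result = cycles_to_convergence(stress[1:], spc, tolerance=0.01)
first_peak = np.abs(stress[1 : spc + 1]).max()
last_peak = np.abs(stress[-spc:]).max()
print(f"peak stress, first cycle: {first_peak:8.1f} Pa")
print(f"peak stress, last cycle:  {last_peak:8.1f} Pa")
print(f"converged (1% tolerance): {result.converged} at cycle {result.cycle}")
print(
    "\nThe initial peak carries the full prestress; the dynamic bonds dissipate"
    "\nit within a few relaxation times, leaving only the steady cyclic load."
)
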