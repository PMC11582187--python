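"""Fit a two-mode Prony series to a noisy stress-relaxation record.

A dynamic-bond network with two boronate chemistries relaxes as the sum of
two exponentials.  The fit recovers both mode stiffnesses and times from a
50 s record with 1 % instrument noise, and reports the weight-averaged
characteristic relaxation time.
"""

from gelstrain import (
    MaxwellMode,
    MaxwellSpectrum,
    fit_relaxation,
    generate_relaxation_curve,
)

truth = MaxwellSpectrum([MaxwellMode(800.0, 10.0), MaxwellMode(200.0, 0.5)])
curve = generate_relaxation_curve(truth, t_max=50.0, noise_cv=0.01, seed=3)
fit = fit_relaxation(curve, n_modes=2)

print("true modes:   (800.0 Pa, 10.000 s), (200.0 Pa, 0.500 s)")
print(
    "fitted modes: "
    + ", ".join(
        f"({m.modulus_weight:.1f} Pa, {m.relaxation_time:.3f} s)" for m in fit.spectrum.modes
    )
)
print(f"characteristic time: {fit.characteristic_time:.3f} s "
      f"(true {(800 * 10 + 200 * 0.5) / 1000:.3f} s)")
print(f"residual 2-norm:     {fit.residual_norm:.2f} Pa")
print(
    "\nThe characteristic time is the stiffness-weighted mean of the mode times;"
    "\nit shortens as the fast-exchanging PBA bond population grows."
)
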