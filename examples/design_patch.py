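"""Select a heart-rate-matched hydrogel recipe for a rat and a pig heart.

A patch works with the beating heart when its gel-point frequency (where
G' = G'') sits inside the heart-rate band and its gel-point modulus suits
the wall it reinforces.  The matcher picks the recipe from the calibrated
design points and reports the predicted gel point.
"""

from gelstrain import HeartSpec, default_calibration, match_formulation

calibration = default_calibration()

for heart in (
    HeartSpec(
        myocardial_modulus=5000.0,  # Pa
        wall_thickness=2.0,  # mm
        graft_thickness=0.3,  # mm
        heart_rate_band=(3.5, 4.5),  # Hz, rat
        species="rat",
    ),
    HeartSpec(
        myocardial_modulus=5000.0,
        wall_thickness=9.0,
        graft_thickness=1.0,
        heart_rate_band=(1.0, 1.5),  # Hz, pig
        species="pig",
    ),
):
    result = match_formulation(heart, calibration)
    gp = result.predicted_gel_point
    print(
        f"{heart.species}: {result.formulation.gtn_wt_percent:.0f} wt% gelatin, "
        f"FPBA fraction {result.formulation.fpba_fraction:.1f} -> "
        f"gel point {gp.frequency:.2f} Hz, {gp.modulus / 1000:.2f} kPa "
        f"(inside {heart.heart_rate_band[0]}-{heart.heart_rate_band[1]} Hz band: "
        f"{result.within_band})"
    )

print(
    "\nThe gel-point frequency is set by the FPBA:(FPBA+PBA) bond ratio and the"
    "\nmodulus by the gelatin weight fraction; the two handles are independent."
)
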