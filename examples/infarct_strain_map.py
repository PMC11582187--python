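"""Map segmental circumferential strain of a beating LV with an infarct.

A synthetic short-axis cine carries a 90-degree noncontractile arc with a
15-degree transition rim on each side.  The
24-segment analysis recovers the per-segment strain, and the adjacent-segment
strain differential peaks at the infarct border, where the wall strain
gradient (and rupture risk) is largest.
"""

import numpy as np

from gelstrain import (
    LVPhantomSpec,
    ZoneLabels,
    analyze_cine,
    generate_lv_cycle,
    max_peak_strain_differential,
    zone_mean_strain,
)

spec = LVPhantomSpec(
    infarct_span=90.0, transition_width=15.0, point_noise_sd=0.02, seed=42
)
cine, truth = generate_lv_cycle(spec)
strain_map = analyze_cine(cine)

print("per-segment end-systolic strain (percent, negative = contraction):")
print(np.array2string(strain_map.peak_strains, precision=1, max_line_width=78))

diffs = strain_map.differentials.copy()
diffs[strain_map.reference_frame_index] = -np.inf
frame, boundary = np.unravel_index(np.argmax(diffs), diffs.shape)
print(f"\nmax peak strain differential: {max_peak_strain_differential(strain_map):.1f} %")
print(
    f"at boundary {boundary}; the infarct-edge boundaries are "
    f"{truth.border_boundaries}, and with a transition rim the sharpest jump"
    " sits one boundary outside the scar edge"
)

# zone summary from the generator geometry: segments 3-8 are infarcted
labels = ZoneLabels(
    tuple(
        "infarct" if 3 <= k <= 8 else ("border" if k in (2, 9) else "remote")
        for k in range(24)
    )
)
means = zone_mean_strain(strain_map.peak_strains, labels)
for zone, value in means.items():
    print(f"mean strain, {zone:7s}: {value:6.1f} %")
print(
    "\nHealthy wall contracts ~-20 %, the scar barely moves, and the largest"
    "\nstrain jump sits on the scar border - the target a viscoelastic patch"
    "\nis designed to smooth."
)
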