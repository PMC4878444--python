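"""Depth-to-energy conversion with the Bragg-Kleeman range model.

Fits R = alpha * E^p to the embedded CSDA water-range table, then looks up
the beam energy whose Bragg peak depth is closest to a few water-equivalent
depths of clinical interest.
"""

import protonarc as pa

table = pa.build_range_table()
print(f"Bragg-Kleeman fit: R = {table.alpha:.6f} * E^{table.p:.4f}  (R in cm, E in MeV)")

for depth in (5.0, 9.0, 16.0, 26.0):
    lk = pa.energy_for_depth(depth, table)
    back = table.range_for_energy(lk.energy_mev)
    print(
        f"depth {depth:5.1f} cm -> {lk.energy_mev:5.0f} MeV "
        f"(model range {back:5.2f} cm, flag={lk.flag})"
    )
# Each depth maps to the 1 MeV grid energy whose range is nearest; depths
# outside the 50-250 MeV range interval would be clamped and flagged.
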