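"""Convert graticule readings to millimetres, including chained readings.

The on-screen instrument is a 10-unit grid spanning 0.8 mm at measurement
zoom (0.08 mm per unit). Cells that migrate past the grid are re-anchored:
the grid is relocated and prior spans are summed.
"""

import chemosim as cs

grid = cs.GridSpec(field_width_mm=0.8)
print(f"one grid unit        : {grid.mm_per_unit:.2f} mm")

reading = cs.grids_to_mm(5.5, 0.8)
print(f"5.5 grid units       : {reading:.2f} mm  (the worked measurement example)")

total = cs.chained_measure([0.8, 0.8], 2.5, 0.8)
print(f"2 relocations + 2.5  : {total:.2f} mm  (0.8 + 0.8 + 0.2)")
print()
print("Fractional readings are allowed, and any partition of a distance into")
print("anchor hops plus a residual reading recovers the same total exactly.")
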