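"""Run one virtual under-agarose assay: control cells vs fMLP.

Loads 200 healthy cells into the central well, diluent on the left, fMLP on
the right, runs the standard 2-hour virtual incubation and measures both
migration fronts plus the chemotactic-function indicators.
"""

import chemosim as cs
from chemosim.engine import RunSettings

layout = cs.WellLayout(
    left_reagent=cs.get_reagent("diluent"),
    right_reagent=cs.get_reagent("fMLP"),
    center_sample=cs.make_sample("control"),
)
plate = cs.load_plate(layout, n_cells=200, seed=7)
end, traj = cs.run(plate, RunSettings(seed=8))

result = cs.measure_run(end)
print(f"random front   : {result.random_mm:.3f} mm   (toward the diluent)")
print(f"directed front : {result.directed_mm:.3f} mm   (toward fMLP)")

metrics = cs.chemotaxis_metrics(traj, side="right")
print(f"cell ratio     : {metrics['cell_ratio']:.2f}  (fraction displaced > 0.1 mm)")
print(f"chemotaxis idx : {metrics['index']:.1f}   (directed / random front)")
print(f"max speed      : {metrics['max_speed_um_min']:.1f} um/min")
print()
print("A healthy population reads ~0.44 mm toward the attractant after 2 h —")
print("about 5.5 units on the 0.08 mm/unit measurement grid — and only a few")
print("hundredths of a millimetre of random migration toward the diluent.")
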