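"""Classify a patient with a two-agonist receptor defect.

Runs the full 5-agonist panel for a patient defective to fMLP and C5a,
validates the control, and asks for a mechanism suggestion. Defects to two
different agonists point away from a single-receptor loss and toward a
global migration defect (the leukocyte-adhesion-deficiency pattern).
"""

import chemosim as cs
from chemosim.engine import RunSettings
from chemosim.reference import Interpretation, validate_control

ranges = {
    name: cs.build_reference_ranges(name, n_sims=60, seed=11 + i)
    for i, name in enumerate(cs.CHEMOATTRACTANTS)
}

patient = cs.make_sample("patient", {"fMLP": 0.3, "C5a": 0.3}, label="patient_1")
control = cs.make_sample("control")


def assay(sample, reagent, seed):
    layout = cs.WellLayout(
        cs.get_reagent("diluent"), cs.get_reagent(reagent), sample
    )
    plate = cs.load_plate(layout, 200, seed=seed)
    end, _ = cs.run(plate, RunSettings(seed=seed + 1), record_trajectories=False)
    return cs.measure_run(end)


c_result = assay(control, "fMLP", seed=100)
control_valid = validate_control(
    c_result, ranges["fMLP"]["directed"], ranges["fMLP"]["random"]
)
print(f"control: directed {c_result.directed_mm:.3f} mm -> valid = {control_valid}")

panel = {
    name: assay(patient, name, seed=300 + 2 * i)
    for i, name in enumerate(cs.CHEMOATTRACTANTS)
}
call = Interpretation.from_panel(
    "patient_1",
    panel,
    {name: ranges[name]["directed"] for name in cs.CHEMOATTRACTANTS},
    control_valid,
)
for name, status in call.per_reagent_status.items():
    print(f"  {name:5s}: {panel[name].directed_mm:.3f} mm -> {status}")
print(f"mechanism hint: {call.mechanism_hint}")
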