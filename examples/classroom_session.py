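"""Generate and run a small classroom session (3 students).

Each student gets a healthy control and two patient samples, each tested
against a single chemoattractant. The session builds reference ranges,
simulates every assay, classifies the results and writes the instructor
answer key alongside the student-facing table.
"""

import tempfile

import chemosim as cs

assignments = cs.generate_session(3, seed=42)
ranges = cs.build_session_ranges(n_sims=60, seed=43)
session = cs.run_session(assignments, ranges=ranges)

print(session.results.to_string(index=False))
print()
for interp in session.interpretations:
    if "patient" in interp.sample:
        print(f"{interp.sample}: {interp.mechanism_hint}")

with tempfile.TemporaryDirectory() as out:
    paths = cs.write_session_outputs(out, assignments, session)
    print()
    print("session artefacts:", ", ".join(p.name for p in paths.values()))
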