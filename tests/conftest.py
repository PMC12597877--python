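"""Shared fixtures: small layouts plus session-scoped Monte-Carlo products.

The expensive Monte-Carlo artefacts (control-front batches, a 200-student
session) are computed once per test session and shared by every test that
needs population-level statistics.
"""

import pytest

import chemosim as cs
from chemosim.reference import simulate_control_fronts


@pytest.fixture
def control_layout():
    return cs.WellLayout(
        left_reagent=cs.get_reagent("diluent"),
        right_reagent=cs.get_reagent("fMLP"),
        center_sample=cs.make_sample("control"),
    )


@pytest.fixture
def diluent_layout():
    """Diluent on both sides: a purely random-migration plate."""
    return cs.WellLayout(
        left_reagent=cs.get_reagent("diluent"),
        right_reagent=cs.get_reagent("diluent"),
        center_sample=cs.make_sample("control"),
    )


@pytest.fixture(scope="session")
def anchor_fronts():
    """50 seeded default control assays against fMLP: (random, directed) mm."""
    return simulate_control_fronts("fMLP", 50, seed=1213)


@pytest.fixture(scope="session")
def classroom():
    """A 200-student session with default pool and 150-sim reference ranges."""
    assignments = cs.generate_session(200, seed=321)
    ranges = cs.build_session_ranges(n_sims=150, seed=322)
    result = cs.run_session(assignments, ranges=ranges)
    return {"assignments": assignments, "ranges": ranges, "result": result}
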