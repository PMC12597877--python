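"""Simulation-derived reference ranges and clinical interpretation.

The assay has no external normal values: the "in-house" reference interval
for each chemoattractant (and for random migration) is generated by Monte
Carlo — many seeded virtual assays of healthy control cells — and summarised
as mean ± 2·SD, the standard clinical reference-interval convention (~95%
coverage under approximate normality). Interpretation is gated on control
validity: an out-of-range control invalidates the whole run and every patient
call becomes indeterminate.
"""

from __future__ import annotations

from dataclasses import dataclass
from types import MappingProxyType
from typing import Mapping, Optional

import numpy as np

from .catalog import (
    DEFAULT_N_CELLS,
    SampleProfile,
    WellLayout,
    get_reagent,
    make_sample,
)
from .engine import RunSettings, simulate_endpoints
from .graticule import MigrationResult, _front_from_axial

__all__ = [
    "STATUS_NORMAL",
    "STATUS_REDUCED",
    "STATUS_ELEVATED",
    "STATUS_INDETERMINATE",
    "ReferenceRange",
    "Interpretation",
    "simulate_control_fronts",
    "build_reference_range",
    "build_reference_ranges",
    "validate_control",
    "interpret_patient",
    "suggest_mechanism",
]

STATUS_NORMAL = "normal"
STATUS_REDUCED = "reduced"
STATUS_ELEVATED = "elevated"
STATUS_INDETERMINATE = "indeterminate"

HINT_NONE = "none"
HINT_RECEPTOR = "receptor_specific"
HINT_GLOBAL = "global_migration_defect"
HINT_INDETERMINATE = "indeterminate"

#: Minimum Monte-Carlo sample size for a stable interval.
MIN_REFERENCE_SIMS = 30


def child_seeds(seed: int, n: int) -> np.ndarray:
    """Derive ``n`` independent 31-bit child seeds from one root seed."""
    state = np.random.SeedSequence(int(seed)).generate_state(n, dtype=np.uint64)
    return (state >> np.uint64(33)).astype(np.int64)


@dataclass(frozen=True)
class ReferenceRange:
    """A mean ± 2·SD normal interval for one reagent and migration mode."""

    reagent: str
    mode: str  # "directed" | "random"
    lower_mm: float
    upper_mm: float
    n_sims: int
    seed: int
    method: str = "mean ± 2·SD"

    def __post_init__(self) -> None:
        if self.mode not in ("directed", "random"):
            raise ValueError("mode must be 'directed' or 'random'")
        if self.lower_mm > self.upper_mm:
            raise ValueError("lower bound exceeds upper bound")

    def contains(self, value_mm: float) -> bool:
        """Closed-interval membership (boundary values are in range)."""
        return self.lower_mm <= value_mm <= self.upper_mm

    def to_dict(self) -> dict:
        return {
            "reagent": self.reagent,
            "mode": self.mode,
            "lower_mm": self.lower_mm,
            "upper_mm": self.upper_mm,
            "n_sims": self.n_sims,
            "seed": self.seed,
            "method": self.method,
        }


def _control_layout(reagent_name: str, control: Optional[SampleProfile]) -> WellLayout:
    reagent = get_reagent(reagent_name)
    if not reagent.is_chemoattractant:
        raise ValueError("reference ranges are built against a chemoattractant")
    return WellLayout(
        left_reagent=get_reagent("diluent"),
        right_reagent=reagent,
        center_sample=control or make_sample("control"),
    )


def simulate_control_fronts(
    reagent: str,
    n_sims: int,
    seed: int,
    *,
    control: Optional[SampleProfile] = None,
    settings: Optional[RunSettings] = None,
    n_cells: int = DEFAULT_N_CELLS,
) -> np.ndarray:
    """Fronts from ``n_sims`` seeded healthy-control assays.

    Returns an (n_sims, 2) array of (random_mm, directed_mm); deterministic
    given ``seed``. Runs are batched through the vectorized endpoint
    simulator, which reproduces per-run results bit for bit.
    """
    layout = _control_layout(reagent, control)
    base = settings or RunSettings()
    seeds = child_seeds(seed, 2 * int(n_sims)).reshape(-1, 2)
    tasks = [(layout, int(ps), int(rs)) for ps, rs in seeds]
    endpoints = simulate_endpoints(tasks, base, n_cells)
    out = np.empty((int(n_sims), 2))
    radius = layout.well_radius_mm
    for i in range(int(n_sims)):
        x = endpoints[i, :, 0]
        out[i] = (
            _front_from_axial(x, "left", radius),
            _front_from_axial(x, "right", radius),
        )
    return out


def build_reference_range(
    reagent: str,
    mode: str,
    n_sims: int,
    seed: int,
    *,
    settings: Optional[RunSettings] = None,
    n_cells: int = DEFAULT_N_CELLS,
) -> ReferenceRange:
    """Monte-Carlo mean ± 2·SD reference interval for one reagent and mode."""
    if n_sims < MIN_REFERENCE_SIMS:
        raise ValueError(
            f"n_sims must be >= {MIN_REFERENCE_SIMS} for a stable interval"
        )
    fronts = simulate_control_fronts(
        reagent, n_sims, seed, settings=settings, n_cells=n_cells
    )
    col = 1 if mode == "directed" else 0
    if mode not in ("directed", "random"):
        raise ValueError("mode must be 'directed' or 'random'")
    values = fronts[:, col]
    mean = float(values.mean())
    sd = float(values.std(ddof=1))
    return ReferenceRange(
        reagent=get_reagent(reagent).name,
        mode=mode,
        lower_mm=mean - 2.0 * sd,
        upper_mm=mean + 2.0 * sd,
        n_sims=int(n_sims),
        seed=int(seed),
    )


def build_reference_ranges(
    reagent: str,
    n_sims: int,
    seed: int,
    *,
    settings: Optional[RunSettings] = None,
    n_cells: int = DEFAULT_N_CELLS,
) -> dict[str, ReferenceRange]:
    """Both directed and random intervals from one shared batch of control sims."""
    if n_sims < MIN_REFERENCE_SIMS:
        raise ValueError(
            f"n_sims must be >= {MIN_REFERENCE_SIMS} for a stable interval"
        )
    fronts = simulate_control_fronts(
        reagent, n_sims, seed, settings=settings, n_cells=n_cells
    )
    name = get_reagent(reagent).name
    ranges = {}
    for mode, col in (("random", 0), ("directed", 1)):
        values = fronts[:, col]
        mean = float(values.mean())
        sd = float(values.std(ddof=1))
        ranges[mode] = ReferenceRange(
            reagent=name,
            mode=mode,
            lower_mm=mean - 2.0 * sd,
            upper_mm=mean + 2.0 * sd,
            n_sims=int(n_sims),
            seed=int(seed),
        )
    return ranges


def _check_match(result: MigrationResult, rng: ReferenceRange) -> None:
    if get_reagent(result.reagent).name != rng.reagent:
        raise ValueError(
            f"result tested {result.reagent} but range is for {rng.reagent}"
        )


def validate_control(
    control_result: MigrationResult,
    range_directed: ReferenceRange,
    range_random: ReferenceRange,
) -> bool:
    """True iff the control's directed and random fronts both lie in range.

    A control outside either interval (below or above) invalidates the assay:
    no patient result run alongside it can be interpreted.
    """
    if range_directed.mode != "directed" or range_random.mode != "random":
        raise ValueError("ranges must be (directed, random) in that order")
    _check_match(control_result, range_directed)
    _check_match(control_result, range_random)
    return range_directed.contains(control_result.directed_mm) and (
        range_random.contains(control_result.random_mm)
    )


def interpret_patient(
    patient_result: MigrationResult,
    reference: ReferenceRange,
    control_valid: bool,
) -> str:
    """Classify one patient measurement against a reference interval.

    Indeterminate whenever the control failed QC; otherwise below the lower
    bound is ``reduced``, above the upper bound is ``elevated`` (still a valid
    result, not a deficiency) and inside the closed interval is ``normal``.
    """
    _check_match(patient_result, reference)
    if not control_valid:
        return STATUS_INDETERMINATE
    value = (
        patient_result.directed_mm
        if reference.mode == "directed"
        else patient_result.random_mm
    )
    if value < reference.lower_mm:
        return STATUS_REDUCED
    if value > reference.upper_mm:
        return STATUS_ELEVATED
    return STATUS_NORMAL


def suggest_mechanism(per_reagent_status: Mapping[str, str]) -> str:
    """Suggest a defect mechanism from a panel of per-agonist statuses.

    Reduced migration toward exactly one chemoattractant points at a
    receptor-specific defect; toward two or more at a global migration defect
    (the leukocyte-adhesion-deficiency pattern, since independent receptor
    losses are unlikely to co-occur). Any indeterminate status poisons the
    call.
    """
    statuses = list(per_reagent_status.values())
    if any(s == STATUS_INDETERMINATE for s in statuses):
        return HINT_INDETERMINATE
    n_reduced = sum(s == STATUS_REDUCED for s in statuses)
    if n_reduced == 0:
        return HINT_NONE
    if n_reduced == 1:
        return HINT_RECEPTOR
    return HINT_GLOBAL


@dataclass(frozen=True)
class Interpretation:
    """The clinical call for one sample: per-agonist statuses plus mechanism."""

    sample: str
    per_reagent_status: Mapping[str, str]
    control_valid: bool
    mechanism_hint: str

    def __post_init__(self) -> None:
        statuses = dict(self.per_reagent_status)
        if not self.control_valid:
            if any(s != STATUS_INDETERMINATE for s in statuses.values()) or (
                self.mechanism_hint != HINT_INDETERMINATE
            ):
                raise ValueError(
                    "an invalid control forces every status and the mechanism "
                    "hint to indeterminate"
                )
        object.__setattr__(self, "per_reagent_status", MappingProxyType(statuses))

    @classmethod
    def from_panel(
        cls,
        sample: str,
        results: Mapping[str, MigrationResult],
        ranges: Mapping[str, ReferenceRange],
        control_valid: bool,
    ) -> "Interpretation":
        """Build a call from per-reagent directed results and matching ranges."""
        statuses = {
            name: interpret_patient(res, ranges[name], control_valid)
            for name, res in results.items()
        }
        return cls(
            sample=sample,
            per_reagent_status=statuses,
            control_valid=control_valid,
            mechanism_hint=suggest_mechanism(statuses),
        )

    def to_dict(self) -> dict:
        return {
            "sample": self.sample,
            "per_reagent_status": dict(self.per_reagent_status),
            "control_valid": self.control_valid,
            "mechanism_hint": self.mechanism_hint,
        }
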