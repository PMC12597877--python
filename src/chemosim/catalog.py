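"""Reagents, cell-sample profiles, and the 3-well plate of the under-agarose assay.

The virtual plate mirrors the classical under-agarose chemotaxis setup: three
collinear wells cut into agar, cells loaded into the central well only, a
diluent (vehicle) in one side well and a chemoattractant in the other. After a
2-hour virtual incubation the distance migrated toward each side well
quantifies random (diluent side) and directed (attractant side) migration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Mapping

import numpy as np

__all__ = [
    "CHEMOATTRACTANTS",
    "DILUENT",
    "Reagent",
    "SampleProfile",
    "WellLayout",
    "CellAgent",
    "PlateState",
    "UnknownReagentError",
    "LayoutError",
    "reagent_catalog",
    "get_reagent",
    "make_sample",
    "load_plate",
]

DILUENT = "diluent"
#: The five chemoattractants offered by the assay, in menu order.
CHEMOATTRACTANTS = ("fMLP", "PMA", "LPS", "C5a", "LTB4")

#: Default well geometry: 2.4 mm-diameter wells, 5.0 mm center-to-center.
DEFAULT_WELL_RADIUS_MM = 1.2
DEFAULT_WELL_SPACING_MM = 5.0
#: Default number of cells loaded into the central well.
DEFAULT_N_CELLS = 200

#: Default motility of a healthy neutrophil population (μm/min).
DEFAULT_MOTILITY_UM_MIN = 10.0
#: Default directional persistence (per-step probability of keeping heading).
DEFAULT_PERSISTENCE = 0.85


class UnknownReagentError(KeyError):
    """Raised when a reagent name does not resolve in the catalog."""


class LayoutError(ValueError):
    """Raised when a plate layout violates the assay's loading rules."""


@dataclass(frozen=True)
class Reagent:
    """A well-loadable substance: the diluent or one of 5 chemoattractants.

    ``potency`` scales the chemotactic bias a healthy cell experiences in the
    reagent's gradient; the diluent carries no signal (potency 0). All
    chemoattractants are supplied at a single fixed working concentration.
    """

    name: str
    is_chemoattractant: bool
    potency: float = 0.0
    concentration_label: str = ""

    def __post_init__(self) -> None:
        if self.potency < 0:
            raise ValueError("reagent potency must be >= 0")
        if self.is_chemoattractant != (self.potency > 0):
            raise ValueError("potency > 0 exactly for chemoattractants")


def _build_catalog() -> tuple[Reagent, ...]:
    entries = [Reagent(DILUENT, False, 0.0, "vehicle only")]
    labels = {
        "fMLP": "100 nM",
        "PMA": "50 ng/mL",
        "LPS": "1 µg/mL",
        "C5a": "10 nM",
        "LTB4": "100 nM",
    }
    for name in CHEMOATTRACTANTS:
        # Single tested concentration; no relative potency data exists, so all
        # chemoattractants share unit potency.
        entries.append(Reagent(name, True, 1.0, labels[name]))
    return tuple(entries)


_CATALOG = _build_catalog()
_BY_LOWER = {r.name.lower(): r for r in _CATALOG}


def reagent_catalog() -> tuple[Reagent, ...]:
    """Return the fixed 6-entry reagent catalog (diluent + 5 chemoattractants)."""
    return _CATALOG


def get_reagent(name: str) -> Reagent:
    """Look up a catalog reagent by name (case-insensitive)."""
    try:
        return _BY_LOWER[str(name).lower()]
    except KeyError:
        valid = ", ".join(r.name for r in _CATALOG)
        raise UnknownReagentError(
            f"unknown reagent {name!r}; valid choices: {valid}"
        ) from None


@dataclass(frozen=True)
class SampleProfile:
    """A control or patient neutrophil population.

    ``sensitivity`` maps chemoattractant names to multipliers in [0, 1.5]
    applied to the chemotactic bias (the defect model: reduced receptor
    function lowers the multiplier). ``random_motility_multiplier`` scales
    the cell's speed everywhere on the plate, modelling machinery-level
    (adhesion-type) migration defects such as leukocyte adhesion deficiency.
    A control is the identity profile.
    """

    label: str
    kind: str  # "control" | "patient"
    motility: float = DEFAULT_MOTILITY_UM_MIN
    persistence: float = DEFAULT_PERSISTENCE
    sensitivity: Mapping[str, float] = field(default_factory=dict)
    random_motility_multiplier: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("control", "patient"):
            raise ValueError("kind must be 'control' or 'patient'")
        if not self.motility > 0:
            raise ValueError("motility must be > 0 µm/min")
        if not 0.0 <= self.persistence < 1.0:
            raise ValueError("persistence must lie in [0, 1)")
        if self.random_motility_multiplier < 0:
            raise ValueError("random_motility_multiplier must be >= 0")
        sens = dict(self.sensitivity)
        for key, mult in sens.items():
            reagent = get_reagent(key)
            if not reagent.is_chemoattractant:
                raise ValueError("diluent cannot carry a sensitivity multiplier")
            if not 0.0 <= mult <= 1.5:
                raise ValueError(
                    f"sensitivity multiplier for {key} must lie in [0, 1.5]"
                )
            if key != reagent.name:
                # normalize case to canonical catalog names
                sens[reagent.name] = sens.pop(key)
        if self.kind == "control":
            if any(m != 1.0 for m in sens.values()) or (
                self.random_motility_multiplier != 1.0
            ):
                raise ValueError("a control profile has all multipliers equal to 1")
        object.__setattr__(self, "sensitivity", MappingProxyType(sens))

    def sensitivity_to(self, reagent_name: str) -> float:
        """Multiplier for one chemoattractant; unspecified reagents default to 1."""
        name = get_reagent(reagent_name).name
        return float(self.sensitivity.get(name, 1.0))

    @property
    def defective_reagents(self) -> tuple[str, ...]:
        """Chemoattractants with sensitivity < 1, in catalog order."""
        return tuple(
            n for n in CHEMOATTRACTANTS if self.sensitivity.get(n, 1.0) < 1.0
        )


def make_sample(
    kind: str,
    defect_spec: Mapping[str, float] | None = None,
    *,
    label: str | None = None,
    motility: float = DEFAULT_MOTILITY_UM_MIN,
    persistence: float = DEFAULT_PERSISTENCE,
    random_motility_multiplier: float = 1.0,
) -> SampleProfile:
    """Construct a control or patient sample profile.

    Controls take an empty ``defect_spec`` and are the identity profile.
    Patients apply the requested per-chemoattractant multipliers; any reagent
    not named keeps sensitivity 1.
    """
    defects = dict(defect_spec or {})
    if kind == "control" and (defects or random_motility_multiplier != 1.0):
        raise ValueError("control samples cannot carry defects")
    return SampleProfile(
        label=label or kind,
        kind=kind,
        motility=motility,
        persistence=persistence,
        sensitivity=defects,
        random_motility_multiplier=random_motility_multiplier,
    )


@dataclass(frozen=True)
class WellLayout:
    """Three collinear, evenly spaced wells; cells only ever in the center.

    The migration axis is x, with the origin at the central well center and
    +x toward the right well.
    """

    left_reagent: Reagent
    right_reagent: Reagent
    center_sample: SampleProfile
    well_spacing_mm: float = DEFAULT_WELL_SPACING_MM
    well_radius_mm: float = DEFAULT_WELL_RADIUS_MM

    def __post_init__(self) -> None:
        for side, obj in (("left", self.left_reagent), ("right", self.right_reagent)):
            if isinstance(obj, SampleProfile):
                raise LayoutError(
                    f"cell sample assigned to the {side} well: the cells must "
                    "always be in the central well"
                )
            if not isinstance(obj, Reagent):
                raise LayoutError(f"{side} well must be loaded with a catalog Reagent")
        if not isinstance(self.center_sample, SampleProfile):
            raise LayoutError("the central well takes a SampleProfile, not a reagent")
        if not self.well_spacing_mm > 0 or not self.well_radius_mm > 0:
            raise LayoutError("well spacing and radius must be positive")
        if self.well_spacing_mm <= 2 * self.well_radius_mm:
            raise LayoutError("wells overlap: spacing must exceed the well diameter")

    @property
    def half_width_mm(self) -> float:
        """Half-extent of the simulated plate region along x."""
        return self.well_spacing_mm + 2 * self.well_radius_mm

    @property
    def half_height_mm(self) -> float:
        return self.well_spacing_mm

    def side_reagent(self, side: str) -> Reagent:
        if side == "left":
            return self.left_reagent
        if side == "right":
            return self.right_reagent
        raise ValueError("side must be 'left' or 'right'")

    def directed_side(self) -> str:
        """The side carrying the chemoattractant in a standard layout.

        Raises :class:`LayoutError` unless exactly one side well holds a
        chemoattractant (the other the diluent), which is the measurable
        random-vs-directed configuration.
        """
        left = self.left_reagent.is_chemoattractant
        right = self.right_reagent.is_chemoattractant
        if left == right:
            raise LayoutError(
                "standard assay needs exactly one chemoattractant side well"
            )
        return "right" if right else "left"


@dataclass(frozen=True)
class CellAgent:
    """One simulated neutrophil: plate-frame position (mm), heading (rad), speed (μm/min)."""

    position: tuple[float, float]
    heading: float
    speed: float


@dataclass
class PlateState:
    """Full state of one virtual assay: layout, agents and the virtual clock.

    Agent state is stored as arrays (positions in mm, headings in rad, last
    per-step speeds in μm/min); the :attr:`agents` property exposes the
    per-cell view.
    """

    layout: WellLayout
    positions: np.ndarray  # (n, 2) mm
    headings: np.ndarray  # (n,) rad
    speeds: np.ndarray  # (n,) μm/min
    virtual_time_s: float
    seed: int

    @property
    def n_agents(self) -> int:
        return int(self.positions.shape[0])

    @property
    def agents(self) -> list[CellAgent]:
        return [
            CellAgent((float(x), float(y)), float(h), float(s))
            for (x, y), h, s in zip(self.positions, self.headings, self.speeds)
        ]

    def copy(self) -> "PlateState":
        return PlateState(
            layout=self.layout,
            positions=self.positions.copy(),
            headings=self.headings.copy(),
            speeds=self.speeds.copy(),
            virtual_time_s=self.virtual_time_s,
            seed=self.seed,
        )


def load_plate(layout: WellLayout, n_cells: int = DEFAULT_N_CELLS, seed: int = 0) -> PlateState:
    """Seed cells uniformly in the central well disk ("Spawn").

    Deterministic given ``seed``. Each agent consumes a contiguous block of
    the placement stream, so loading more cells never reshuffles the first
    ones.
    """
    if not isinstance(layout, WellLayout):
        raise LayoutError("load_plate requires a WellLayout")
    n_cells = int(n_cells)
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rng = np.random.Generator(np.random.Philox(key=int(seed)))
    draws = rng.random((n_cells, 3))  # per-agent rows: radius, angle, heading
    r = layout.well_radius_mm * np.sqrt(draws[:, 0])
    phi = 2.0 * math.pi * draws[:, 1]
    positions = np.column_stack([r * np.cos(phi), r * np.sin(phi)])
    headings = (2.0 * draws[:, 2] - 1.0) * math.pi
    return PlateState(
        layout=layout,
        positions=positions,
        headings=headings,
        speeds=np.zeros(n_cells),
        virtual_time_s=0.0,
        seed=int(seed),
    )
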