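"""The measurement instrument: a zoomable 10×10 grid and derived metrics.

Distances are read exactly as in the on-screen assay: the graticule spans a
known physical field width (0.8 mm at the standard measurement zoom, so one
grid unit is 0.08 mm), readings may be fractional, and migration beyond one
grid span is measured by chaining grid relocations anchored on marked cells.
The migrated population's leading front is the 95th percentile of axial
displacement beyond the central well edge.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .catalog import PlateState
from .engine import TrajectorySet

__all__ = [
    "GridSpec",
    "Measurement",
    "MigrationResult",
    "grids_to_mm",
    "chained_measure",
    "leading_front",
    "chemotaxis_metrics",
    "measure_run",
]

#: Field width (mm) spanned by the 10-unit grid at the measurement zoom.
DEFAULT_FIELD_WIDTH_MM = 0.8
#: Percentile of axial displacement defining the migrated population's front.
FRONT_PERCENTILE = 95.0
#: Net axial displacement (mm) above which a cell counts as having migrated.
CELL_RATIO_THRESHOLD_MM = 0.1


@dataclass(frozen=True)
class GridSpec:
    """Placement and zoom of the overlaid 10×10 measurement grid."""

    center_x_mm: float = 0.0
    center_y_mm: float = 0.0
    field_width_mm: float = DEFAULT_FIELD_WIDTH_MM
    units: int = 10

    def __post_init__(self) -> None:
        if self.field_width_mm <= 0:
            raise ValueError("field width must be positive")
        if self.units != 10:
            raise ValueError("the graticule is a fixed 10-unit grid")

    @property
    def mm_per_unit(self) -> float:
        return self.field_width_mm / self.units


@dataclass(frozen=True)
class Measurement:
    """One graticule reading, possibly chained across grid relocations."""

    grids: float
    anchor_offsets_mm: tuple[float, ...] = ()
    field_width_mm: float = DEFAULT_FIELD_WIDTH_MM

    def __post_init__(self) -> None:
        if self.grids < 0:
            raise ValueError("grid reading cannot be negative")
        if any(a < 0 for a in self.anchor_offsets_mm):
            raise ValueError("anchor offsets cannot be negative")
        object.__setattr__(
            self, "anchor_offsets_mm", tuple(float(a) for a in self.anchor_offsets_mm)
        )

    @property
    def total_mm(self) -> float:
        return chained_measure(self.anchor_offsets_mm, self.grids, self.field_width_mm)


@dataclass(frozen=True)
class MigrationResult:
    """Measured fronts (mm) for one sample/chemoattractant pairing."""

    sample: str
    reagent: str
    random_mm: float
    directed_mm: float

    def __post_init__(self) -> None:
        if self.random_mm < 0 or self.directed_mm < 0:
            raise ValueError("migration distances cannot be negative")


def grids_to_mm(grids: float, field_width_mm: float = DEFAULT_FIELD_WIDTH_MM) -> float:
    """Convert a (possibly fractional) grid reading to millimetres, exactly."""
    if grids < 0:
        raise ValueError("grid reading cannot be negative")
    if field_width_mm <= 0:
        raise ValueError("field width must be positive")
    return grids * field_width_mm / 10.0


def chained_measure(
    anchor_offsets_mm: Iterable[float],
    grids: float,
    field_width_mm: float = DEFAULT_FIELD_WIDTH_MM,
) -> float:
    """Total distance: prior grid-relocation offsets plus the residual reading."""
    offsets = [float(a) for a in anchor_offsets_mm]
    if any(a < 0 for a in offsets):
        raise ValueError("anchor offsets cannot be negative")
    return sum(offsets) + grids_to_mm(grids, field_width_mm)


def _front_from_axial(x: np.ndarray, side: str, well_radius_mm: float) -> float:
    if side not in ("left", "right"):
        raise ValueError("side must be 'left' or 'right'")
    axial = x if side == "right" else -x
    disp = axial - well_radius_mm
    moved = disp[disp > 0]
    if moved.size == 0:
        return 0.0
    # empirical (inverted-CDF) percentile: the sorted value at ceil(q·n)
    return float(np.quantile(moved, FRONT_PERCENTILE / 100.0, method="inverted_cdf"))


def leading_front(end_state: PlateState, side: str) -> float:
    """Front distance (mm) of the population migrated toward ``side``.

    Axial displacement is measured from the central well edge; the front is
    the 95th percentile over agents with positive displacement toward that
    side, or 0 if none migrated past the edge.
    """
    if end_state.n_agents == 0:
        raise ValueError("no agents on plate")
    return _front_from_axial(
        end_state.positions[:, 0], side, end_state.layout.well_radius_mm
    )


def measure_run(end_state: PlateState) -> MigrationResult:
    """Measure both fronts of a completed standard run (diluent vs attractant)."""
    layout = end_state.layout
    directed_side = layout.directed_side()
    random_side = "left" if directed_side == "right" else "right"
    return MigrationResult(
        sample=layout.center_sample.label,
        reagent=layout.side_reagent(directed_side).name,
        random_mm=leading_front(end_state, random_side),
        directed_mm=leading_front(end_state, directed_side),
    )


def chemotaxis_metrics(
    trajectories: TrajectorySet,
    side: str,
    *,
    ratio_threshold_mm: float = CELL_RATIO_THRESHOLD_MM,
) -> dict:
    """Chemotactic-function indicators from one run's trajectories.

    Returns ``distance_mm`` (leading front toward the directed ``side``),
    ``cell_ratio`` (fraction of agents whose net axial displacement toward
    that side exceeds ``ratio_threshold_mm``), ``index`` (directed front /
    opposite-side random front; NaN when the random front is zero) and
    ``max_speed_um_min`` (largest single-step speed of any agent).
    """
    if side not in ("left", "right"):
        raise ValueError("side must be 'left' or 'right'")
    pos = trajectories.positions
    radius = trajectories.well_radius_mm
    sign = 1.0 if side == "right" else -1.0
    other = "left" if side == "right" else "right"

    final_x = pos[:, -1, 0]
    distance = _front_from_axial(final_x, side, radius)
    random_front = _front_from_axial(final_x, other, radius)

    net_axial = sign * (pos[:, -1, 0] - pos[:, 0, 0])
    cell_ratio = float(np.mean(net_axial > ratio_threshold_mm))

    index = distance / random_front if random_front > 0 else math.nan

    if pos.shape[1] > 1:
        step_mm = np.linalg.norm(np.diff(pos, axis=1), axis=2)
        max_speed = float(step_mm.max() * 60000.0 / trajectories.dt_s)
    else:
        max_speed = 0.0
    return {
        "distance_mm": distance,
        "cell_ratio": cell_ratio,
        "index": index,
        "max_speed_um_min": max_speed,
    }
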