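"""Chemoattractant gradient along the migration axis and the resulting bias.

The under-agarose assay is treated over its 2-hour window as a quasi-static
linear gradient: normalized concentration 0 at the central well center rising
linearly to 1 at the inner edge of the chemoattractant well. The gradient acts
only inside that corridor — cells that wander to the diluent side of the plate
feel no pull, which is what makes the diluent-side readout a genuine
random-migration measurement.
"""

from __future__ import annotations

from dataclasses import dataclass

from .catalog import Reagent, SampleProfile, WellLayout, get_reagent

__all__ = ["GradientModel", "concentration_at", "gradient_weight", "chemotactic_bias"]


@dataclass(frozen=True)
class GradientModel:
    """Static linear gradient from the central well toward one source well.

    ``source_x_mm`` is the attractant well center; ``zero_x_mm`` the central
    well center; concentration is normalized to ``amplitude`` (default 1) at
    the source well's inner edge. ``bounds_mm`` are the plate extents along x.
    """

    source_x_mm: float
    zero_x_mm: float = 0.0
    amplitude: float = 1.0
    shape: str = "linear_static"
    source_well_radius_mm: float = 1.2
    bounds_mm: tuple[float, float] = (-7.4, 7.4)

    def __post_init__(self) -> None:
        if self.shape != "linear_static":
            raise ValueError(f"unsupported gradient shape {self.shape!r}")
        if self.source_x_mm == self.zero_x_mm:
            raise ValueError("source and zero positions coincide")

    @classmethod
    def from_layout(cls, layout: WellLayout, side: str) -> "GradientModel":
        sign = 1.0 if side == "right" else -1.0
        half = layout.half_width_mm
        return cls(
            source_x_mm=sign * layout.well_spacing_mm,
            zero_x_mm=0.0,
            source_well_radius_mm=layout.well_radius_mm,
            bounds_mm=(-half, half),
        )

    @property
    def source_edge_x_mm(self) -> float:
        """Inner edge of the source well (where concentration reaches 1)."""
        sign = 1.0 if self.source_x_mm > self.zero_x_mm else -1.0
        return self.source_x_mm - sign * self.source_well_radius_mm


def concentration_at(model: GradientModel, x_mm: float) -> float:
    """Normalized concentration at plate position ``x_mm``, clamped to [0, amplitude]."""
    lo, hi = model.bounds_mm
    if not lo <= x_mm <= hi:
        raise ValueError(f"x = {x_mm} mm outside plate bounds [{lo}, {hi}]")
    span = model.source_edge_x_mm - model.zero_x_mm
    frac = (x_mm - model.zero_x_mm) / span
    return model.amplitude * min(1.0, max(0.0, frac))


def gradient_weight(model: GradientModel, x_mm: float) -> float:
    """Local normalized gradient magnitude: 1 inside the corridor, else 0.

    The corridor runs from the central well center to the source well's inner
    edge; a linear static gradient has constant slope there and none outside.
    """
    lo, hi = sorted((model.zero_x_mm, model.source_edge_x_mm))
    return 1.0 if lo <= x_mm <= hi else 0.0


def chemotactic_bias(
    sample: SampleProfile,
    reagent: Reagent | str,
    model: GradientModel,
    x_mm: float,
) -> float:
    """Dimensionless chemotactic bias κ felt by ``sample`` at ``x_mm``.

    κ = potency(reagent) × sensitivity(sample, reagent) × gradient_weight(x);
    zero for the diluent everywhere. κ scales the deterministic pull the walk
    model applies toward the attractant well.
    """
    if isinstance(reagent, str):
        reagent = get_reagent(reagent)
    if not reagent.is_chemoattractant:
        return 0.0
    return (
        reagent.potency
        * sample.sensitivity_to(reagent.name)
        * gradient_weight(model, x_mm)
    )
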