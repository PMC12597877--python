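"""Biased persistent random walk engine for the virtual chemotaxis assay.

Each cell performs a persistent random walk: at every 10-second step it keeps
its heading with probability equal to the sample's persistence (otherwise it
re-orients uniformly), receives wrapped-normal angular jitter, and — inside a
chemoattractant corridor — a deterministic pull rotating the heading toward
the attractant well with strength proportional to the chemotactic bias κ.
Step length is the sample's motility with multiplicative lognormal noise.

Time acceleration (1×, 60×, 300×) changes only how fast virtual time is meant
to play out on a wall clock; it never enters the physics, so endpoints are
bit-identical across acceleration levels for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .catalog import PlateState, WellLayout, load_plate

__all__ = [
    "RunSettings",
    "TrajectorySet",
    "StateError",
    "step",
    "run",
    "simulate_endpoints",
]

#: Allowed time-acceleration factors (wall-clock pacing only).
ACCELERATION_LEVELS = (1, 60, 300)

#: Standard deviation of per-step lognormal speed noise.
SIGMA_SPEED = 0.2
#: Standard deviation (rad) of per-step wrapped-normal heading jitter.
SIGMA_TURN = 0.2
#: Rotation (rad per step at κ = 1) of the pull toward the attractant well.
BIAS_GAIN = 0.162
#: Hard cap on instantaneous speed, as a multiple of base motility.
MAX_SPEED_FACTOR = 2.0

_TWO_PI = 2.0 * math.pi


class StateError(RuntimeError):
    """Raised when the engine is asked to advance an invalid plate state."""


@dataclass(frozen=True)
class RunSettings:
    """Integration settings for one virtual assay run.

    ``duration_virtual_s`` defaults to the standard 2-hour incubation;
    ``acceleration`` must be one of 1, 60 or 300 and affects wall-clock pacing
    only. ``seed`` drives every stochastic element of the walk.
    """

    duration_virtual_s: float = 7200.0
    dt_s: float = 10.0
    acceleration: int = 60
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt_s <= 0:
            raise ValueError("dt_s must be positive")
        if self.duration_virtual_s < 0:
            raise ValueError("duration cannot be negative")
        if self.acceleration not in ACCELERATION_LEVELS:
            raise ValueError(
                f"acceleration must be one of {ACCELERATION_LEVELS}"
            )
        steps = self.duration_virtual_s / self.dt_s
        if abs(steps - round(steps)) > 1e-9:
            raise ValueError("duration must be a whole number of dt steps")

    @property
    def n_steps(self) -> int:
        return int(round(self.duration_virtual_s / self.dt_s))

    @property
    def wall_clock_s(self) -> float:
        """Wall-clock playback time implied by the acceleration factor."""
        return self.duration_virtual_s / self.acceleration


@dataclass
class TrajectorySet:
    """Time-ordered positions of every agent over one run.

    ``positions`` has shape (n_agents, n_steps + 1, 2) in mm; row 0 of each
    agent is its spawn position inside the central well.
    """

    times_s: np.ndarray
    positions: np.ndarray
    sample_label: str
    left_reagent: str
    right_reagent: str
    settings: RunSettings
    well_radius_mm: float

    @property
    def n_agents(self) -> int:
        return int(self.positions.shape[0])

    @property
    def dt_s(self) -> float:
        return float(self.settings.dt_s)

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format dump with columns agent_id, t_s, x_mm, y_mm."""
        n, t, _ = self.positions.shape
        return pd.DataFrame(
            {
                "agent_id": np.repeat(np.arange(n), t),
                "t_s": np.tile(self.times_s, n),
                "x_mm": self.positions[:, :, 0].ravel(),
                "y_mm": self.positions[:, :, 1].ravel(),
            }
        )

    @classmethod
    def from_dataframe(
        cls,
        frame: pd.DataFrame,
        *,
        sample_label: str = "",
        left_reagent: str = "diluent",
        right_reagent: str = "",
        well_radius_mm: float = 1.2,
        settings: Optional[RunSettings] = None,
    ) -> "TrajectorySet":
        frame = frame.sort_values(["agent_id", "t_s"])
        times = np.sort(frame["t_s"].unique()).astype(float)
        n = frame["agent_id"].nunique()
        if len(frame) != n * len(times):
            raise ValueError("trajectory table is ragged: unequal lengths per agent")
        pos = frame[["x_mm", "y_mm"]].to_numpy(float).reshape(n, len(times), 2)
        if settings is None:
            dt = float(times[1] - times[0]) if len(times) > 1 else 10.0
            settings = RunSettings(duration_virtual_s=dt * (len(times) - 1), dt_s=dt)
        return cls(times, pos, sample_label, left_reagent, right_reagent,
                   settings, well_radius_mm)


def _side_scales(layout: WellLayout) -> tuple[float, float]:
    """Per-side bias scale: potency × sample sensitivity (0 for diluent)."""
    sample = layout.center_sample
    scales = []
    for reagent in (layout.left_reagent, layout.right_reagent):
        if reagent.is_chemoattractant:
            scales.append(reagent.potency * sample.sensitivity_to(reagent.name))
        else:
            scales.append(0.0)
    return scales[0], scales[1]


def _advance(
    positions: np.ndarray,
    headings: np.ndarray,
    u_keep: np.ndarray,
    u_head: np.ndarray,
    z_turn: np.ndarray,
    z_speed: np.ndarray,
    *,
    scale_left: float,
    scale_right: float,
    motility: float,
    random_mult: float,
    persistence: float,
    dt_s: float,
    spacing: float,
    radius: float,
    half_w: float,
    half_h: float,
) -> np.ndarray:
    """One in-place walk step over all agents; returns per-agent speeds (μm/min)."""
    x = positions[:, 0]
    corridor = np.abs(x) <= (spacing - radius)
    right_side = x >= 0.0
    kappa = np.where(right_side, scale_right, scale_left) * corridor
    target = np.where(right_side, 0.0, math.pi)

    redraw = u_keep >= persistence
    np.copyto(headings, (2.0 * u_head - 1.0) * math.pi, where=redraw)
    headings += SIGMA_TURN * z_turn
    headings += BIAS_GAIN * kappa * np.sin(target - headings)
    np.mod(headings + math.pi, _TWO_PI, out=headings)
    headings -= math.pi

    mult = np.exp(SIGMA_SPEED * z_speed - 0.5 * SIGMA_SPEED**2)
    np.clip(mult, 0.0, MAX_SPEED_FACTOR, out=mult)
    # the motility multiplier models machinery-level (adhesion-type) speed
    # loss and therefore applies everywhere, gradient or not
    speeds = motility * random_mult * mult
    step_mm = speeds * (dt_s / 60000.0)  # μm/min over dt seconds → mm

    new_x = x + step_mm * np.cos(headings)
    new_y = positions[:, 1] + step_mm * np.sin(headings)
    # cells never enter a side well they did not start in
    blocked = ((new_x - spacing) ** 2 + new_y**2 < radius**2) | (
        (new_x + spacing) ** 2 + new_y**2 < radius**2
    )
    np.copyto(new_x, x, where=blocked)
    np.copyto(new_y, positions[:, 1], where=blocked)
    np.clip(new_x, -half_w, half_w, out=new_x)
    np.clip(new_y, -half_h, half_h, out=new_y)
    positions[:, 0] = new_x
    positions[:, 1] = new_y
    return speeds


def _kernel_kwargs(layout: WellLayout, dt_s: float) -> dict:
    sample = layout.center_sample
    scale_left, scale_right = _side_scales(layout)
    return dict(
        scale_left=scale_left,
        scale_right=scale_right,
        motility=sample.motility,
        random_mult=sample.random_motility_multiplier,
        persistence=sample.persistence,
        dt_s=dt_s,
        spacing=layout.well_spacing_mm,
        radius=layout.well_radius_mm,
        half_w=layout.half_width_mm,
        half_h=layout.half_height_mm,
    )


def _draw_noise(
    rng: np.random.Generator, n_agents: int, n_steps: int
) -> tuple[np.ndarray, np.ndarray]:
    """Uniform (keep/re-orient) and normal (turn/speed) noise blocks.

    Both arrays are agent-major, so each agent owns a contiguous block of the
    stream and growing the agent count only appends new blocks.
    """
    raw = rng.random((n_agents, n_steps, 2))
    z = rng.standard_normal((n_agents, n_steps, 2))
    return raw, z


def step(state: PlateState, dt_s: float, rng: np.random.Generator) -> PlateState:
    """Advance a plate by one time step, drawing this step's noise from ``rng``."""
    if not isinstance(state, PlateState):
        raise StateError("step requires a loaded PlateState")
    if dt_s <= 0:
        raise ValueError("dt_s must be positive")
    out = state.copy()
    raw, z = _draw_noise(rng, state.n_agents, 1)
    out.speeds = _advance(
        out.positions,
        out.headings,
        raw[:, 0, 0],
        raw[:, 0, 1],
        z[:, 0, 0],
        z[:, 0, 1],
        **_kernel_kwargs(state.layout, dt_s),
    )
    out.virtual_time_s = state.virtual_time_s + dt_s
    return out


def run(
    plate: PlateState,
    settings: RunSettings,
    record_trajectories: bool = True,
) -> tuple[PlateState, Optional[TrajectorySet]]:
    """Run the full virtual incubation; deterministic given ``settings.seed``.

    Noise is pre-drawn from a counter-based stream with one contiguous block
    per agent, so changing the agent count never reshuffles the walks of
    existing agents. Returns the end state and, unless disabled, the full
    trajectory set.
    """
    if not isinstance(plate, PlateState):
        raise StateError("run requires a plate produced by load_plate")
    if plate.n_agents < 1:
        raise StateError("plate has no loaded cells")
    n_steps = settings.n_steps
    state = plate.copy()
    kw = _kernel_kwargs(plate.layout, settings.dt_s)

    traj = None
    if record_trajectories:
        traj_pos = np.empty((plate.n_agents, n_steps + 1, 2))
        traj_pos[:, 0, :] = state.positions

    if n_steps:
        rng = np.random.Generator(np.random.Philox(key=int(settings.seed)))
        raw, z = _draw_noise(rng, plate.n_agents, n_steps)
        for t in range(n_steps):
            state.speeds = _advance(
                state.positions,
                state.headings,
                raw[:, t, 0],
                raw[:, t, 1],
                z[:, t, 0],
                z[:, t, 1],
                **kw,
            )
            if record_trajectories:
                traj_pos[:, t + 1, :] = state.positions
    state.virtual_time_s = plate.virtual_time_s + settings.duration_virtual_s

    if record_trajectories:
        times = plate.virtual_time_s + settings.dt_s * np.arange(n_steps + 1)
        traj = TrajectorySet(
            times_s=times,
            positions=traj_pos,
            sample_label=plate.layout.center_sample.label,
            left_reagent=plate.layout.left_reagent.name,
            right_reagent=plate.layout.right_reagent.name,
            settings=settings,
            well_radius_mm=plate.layout.well_radius_mm,
        )
    return state, traj


def simulate_endpoints(
    tasks,
    settings: RunSettings,
    n_cells: int,
    chunk_size: int = 25,
) -> np.ndarray:
    """End positions for many assays at once, bit-identical to per-run ``run``.

    ``tasks`` is a sequence of ``(layout, plate_seed, run_seed)`` triples; all
    layouts must share the same well geometry. Agents of several runs are
    stacked into one array and advanced together — every per-agent update is
    elementwise, and each run draws its own placement and noise streams, so
    the result equals running each task through :func:`run` individually.
    Returns an (n_tasks, n_cells, 2) array of final positions in mm.
    """
    tasks = list(tasks)
    if not tasks:
        return np.empty((0, n_cells, 2))
    geom = (tasks[0][0].well_spacing_mm, tasks[0][0].well_radius_mm)
    for layout, _, _ in tasks:
        if (layout.well_spacing_mm, layout.well_radius_mm) != geom:
            raise ValueError("batched runs must share well geometry")
    n_steps = settings.n_steps
    out = np.empty((len(tasks), n_cells, 2))

    for start in range(0, len(tasks), chunk_size):
        chunk = tasks[start : start + chunk_size]
        m = len(chunk)
        pos = np.empty((m * n_cells, 2))
        head = np.empty(m * n_cells)
        scale_left = np.empty(m * n_cells)
        scale_right = np.empty(m * n_cells)
        motility = np.empty(m * n_cells)
        random_mult = np.empty(m * n_cells)
        persistence = np.empty(m * n_cells)
        raw = np.empty((m * n_cells, n_steps, 2)) if n_steps else None
        z = np.empty((m * n_cells, n_steps, 2)) if n_steps else None

        for j, (layout, plate_seed, run_seed) in enumerate(chunk):
            sl = slice(j * n_cells, (j + 1) * n_cells)
            plate = load_plate(layout, n_cells=n_cells, seed=int(plate_seed))
            pos[sl] = plate.positions
            head[sl] = plate.headings
            sample = layout.center_sample
            s_left, s_right = _side_scales(layout)
            scale_left[sl] = s_left
            scale_right[sl] = s_right
            motility[sl] = sample.motility
            random_mult[sl] = sample.random_motility_multiplier
            persistence[sl] = sample.persistence
            if n_steps:
                rng = np.random.Generator(np.random.Philox(key=int(run_seed)))
                raw[sl], z[sl] = _draw_noise(rng, n_cells, n_steps)

        layout0 = chunk[0][0]
        for t in range(n_steps):
            _advance(
                pos,
                head,
                raw[:, t, 0],
                raw[:, t, 1],
                z[:, t, 0],
                z[:, t, 1],
                scale_left=scale_left,
                scale_right=scale_right,
                motility=motility,
                random_mult=random_mult,
                persistence=persistence,
                dt_s=settings.dt_s,
                spacing=layout0.well_spacing_mm,
                radius=layout0.well_radius_mm,
                half_w=layout0.half_width_mm,
                half_h=layout0.half_height_mm,
            )
        out[start : start + m] = pos.reshape(m, n_cells, 2)
    return out
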