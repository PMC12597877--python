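"""Classroom-session generation and the end-to-end assay pipeline.

A session assigns every student one healthy control and two patient samples,
each tested against a single chemoattractant at the standard concentration.
Patient defect profiles are drawn from a pool spanning the two mechanism
classes the assay can resolve (global migration defects and receptor-specific
defects); patients are deliberately assigned an agonist they are defective
to, so their directed migration lands below the normal reference range.
Running a session simulates every assay, measures both fronts, gates
interpretation on control validity, and emits the student-facing results
table together with an instructor answer key.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .catalog import (
    CHEMOATTRACTANTS,
    DEFAULT_N_CELLS,
    SampleProfile,
    WellLayout,
    get_reagent,
    make_sample,
)
from .engine import RunSettings, simulate_endpoints
from .graticule import MigrationResult, _front_from_axial
from .reference import (
    HINT_INDETERMINATE,
    HINT_NONE,
    Interpretation,
    ReferenceRange,
    STATUS_INDETERMINATE,
    STATUS_NORMAL,
    build_reference_ranges,
    child_seeds,
    interpret_patient,
    validate_control,
)

__all__ = [
    "DefectTemplate",
    "DEFAULT_DEFECT_POOL",
    "SessionAssignment",
    "SessionResult",
    "generate_session",
    "build_session_ranges",
    "run_session",
    "write_session_outputs",
    "load_assay_config",
]

log = logging.getLogger("chemosim")

RESULT_COLUMNS = ("student_id", "sample", "reagent", "random_mm", "directed_mm", "status")


@dataclass(frozen=True)
class DefectTemplate:
    """A reusable patient defect specification for the session generator."""

    name: str
    defects: Mapping[str, float]
    random_motility_multiplier: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "defects", dict(self.defects))

    @property
    def defective_reagents(self) -> tuple[str, ...]:
        return tuple(n for n in CHEMOATTRACTANTS if self.defects.get(n, 1.0) < 1.0)

    @property
    def true_class(self) -> str:
        """Mechanism class implied by the defect pattern (the answer-key label)."""
        n = len(self.defective_reagents)
        if n == 0:
            return HINT_NONE
        return "receptor_specific" if n == 1 else "global_migration_defect"

    def make(self, label: str) -> SampleProfile:
        return make_sample(
            "patient",
            self.defects,
            label=label,
            random_motility_multiplier=self.random_motility_multiplier,
        )


def _global(mult: float) -> dict[str, float]:
    return {name: mult for name in CHEMOATTRACTANTS}


#: Shipped patient defect pool: two global (adhesion-type) severities, a
#: two-agonist receptor pair, and a single-agonist receptor defect.
DEFAULT_DEFECT_POOL: tuple[DefectTemplate, ...] = (
    DefectTemplate("global_severe", _global(0.3), random_motility_multiplier=0.3),
    DefectTemplate("global_moderate", _global(0.5), random_motility_multiplier=0.5),
    DefectTemplate("receptor_pair_fMLP_C5a", {"fMLP": 0.3, "C5a": 0.3}),
    DefectTemplate("receptor_single_LTB4", {"LTB4": 0.2}),
)


@dataclass(frozen=True)
class SessionAssignment:
    """One student's bench: a control plus two patients, one agonist each."""

    student_id: str
    samples: tuple[SampleProfile, ...]
    reagent_per_sample: Mapping[str, str]
    seed: int
    templates: Mapping[str, DefectTemplate] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.samples) != 3:
            raise ValueError("a session assignment holds exactly 3 samples")
        kinds = [s.kind for s in self.samples]
        if kinds.count("control") != 1 or kinds.count("patient") != 2:
            raise ValueError("assignment must be 1 control + 2 patients")
        reagents = dict(self.reagent_per_sample)
        for sample in self.samples:
            name = reagents.get(sample.label)
            if name is None:
                raise ValueError(f"sample {sample.label!r} has no assigned reagent")
            if not get_reagent(name).is_chemoattractant:
                raise ValueError("assigned reagents must be chemoattractants")
        object.__setattr__(self, "reagent_per_sample", reagents)
        object.__setattr__(self, "templates", dict(self.templates))

    @property
    def control(self) -> SampleProfile:
        return next(s for s in self.samples if s.kind == "control")

    @property
    def patients(self) -> tuple[SampleProfile, ...]:
        return tuple(s for s in self.samples if s.kind == "patient")

    def to_dict(self) -> dict:
        return {
            "student_id": self.student_id,
            "seed": int(self.seed),
            "samples": [
                {
                    "label": s.label,
                    "kind": s.kind,
                    "reagent": self.reagent_per_sample[s.label],
                }
                for s in self.samples
            ],
        }


def generate_session(
    n_students: int,
    defect_pool: Sequence[DefectTemplate] = DEFAULT_DEFECT_POOL,
    seed: int = 0,
) -> list[SessionAssignment]:
    """Deterministically allocate samples and agonists to ``n_students``.

    Each patient draws a defect template from the pool and is assigned one of
    its defective agonists uniformly at random; the control draws uniformly
    from all five chemoattractants. Per-student seeds are split from the
    session seed, so rerunning one student never perturbs another.
    """
    if n_students < 1:
        raise ValueError("n_students must be >= 1")
    pool = list(defect_pool)
    if not pool:
        raise ValueError("defect_pool must not be empty")
    student_seeds = child_seeds(seed, n_students)
    assignments = []
    for i, s_seed in enumerate(student_seeds):
        rng = np.random.Generator(np.random.Philox(key=int(s_seed)))
        sid = f"S{i + 1:03d}"
        control = make_sample("control", label="control")
        reagents = {"control": CHEMOATTRACTANTS[rng.integers(len(CHEMOATTRACTANTS))]}
        templates: dict[str, DefectTemplate] = {}
        patients = []
        if len(pool) >= 2:
            picks = rng.choice(len(pool), size=2, replace=False)
        else:
            picks = [0, 0]
        for j, pick in enumerate(picks, start=1):
            template = pool[int(pick)]
            label = f"patient_{j}"
            patients.append(template.make(label))
            templates[label] = template
            candidates = template.defective_reagents or CHEMOATTRACTANTS
            reagents[label] = candidates[rng.integers(len(candidates))]
        assignments.append(
            SessionAssignment(
                student_id=sid,
                samples=(control, *patients),
                reagent_per_sample=reagents,
                seed=int(s_seed),
                templates=templates,
            )
        )
    return assignments


def build_session_ranges(
    n_sims: int = 100,
    seed: int = 0,
    *,
    reagents: Sequence[str] = CHEMOATTRACTANTS,
    settings: Optional[RunSettings] = None,
    n_cells: int = DEFAULT_N_CELLS,
) -> dict[str, dict[str, ReferenceRange]]:
    """Reference ranges (both modes) for every requested chemoattractant."""
    seeds = child_seeds(seed, len(reagents))
    return {
        name: build_reference_ranges(
            name, n_sims, int(s), settings=settings, n_cells=n_cells
        )
        for name, s in zip(reagents, seeds)
    }


@dataclass
class SessionResult:
    """Everything one simulated session produces."""

    results: pd.DataFrame
    interpretations: list[Interpretation]
    answer_key: dict
    ranges: dict[str, dict[str, ReferenceRange]]


def _assay_layout(sample: SampleProfile, reagent_name: str) -> WellLayout:
    return WellLayout(
        left_reagent=get_reagent("diluent"),
        right_reagent=get_reagent(reagent_name),
        center_sample=sample,
    )


def run_session(
    assignments: Sequence[SessionAssignment],
    engine_settings: Optional[RunSettings] = None,
    ranges: Optional[dict[str, dict[str, ReferenceRange]]] = None,
    *,
    n_cells: int = DEFAULT_N_CELLS,
    panel: bool = True,
) -> SessionResult:
    """Simulate every assay of a session and interpret the results.

    For the student-facing table each sample is measured against its assigned
    agonist only. With ``panel=True`` (default) every patient is additionally
    worked up against the full 5-agonist panel, which is what lets the
    mechanism suggestion distinguish a receptor-specific from a global
    defect. Requires reference ranges for every reagent to be interpreted;
    missing ranges raise before any simulation starts.
    """
    settings = engine_settings or RunSettings()
    if ranges is None:
        raise ValueError("reference ranges must be built before running a session")
    needed = set()
    for a in assignments:
        needed.update(a.reagent_per_sample.values())
    if panel:
        needed.update(CHEMOATTRACTANTS)
    missing = sorted(
        name
        for name in needed
        if name not in ranges
        or "directed" not in ranges[name]
        or "random" not in ranges[name]
    )
    if missing:
        raise ValueError(f"missing reference ranges for: {', '.join(missing)}")

    # first pass: enumerate every assay with its split seeds, then batch-run
    panel_reagents = CHEMOATTRACTANTS if panel else ()
    tasks: list[tuple[WellLayout, int, int]] = []
    task_meta: list[tuple[str, str, str]] = []  # (student_id, sample_label, reagent)
    for assignment in assignments:
        n_assays = 1 + sum(
            max(len(panel_reagents), 1) for _ in assignment.patients
        )
        seeds = child_seeds(assignment.seed, 2 * n_assays).reshape(-1, 2)
        cursor = 0
        control = assignment.control
        control_reagent = assignment.reagent_per_sample[control.label]
        tasks.append(
            (
                _assay_layout(control, control_reagent),
                int(seeds[cursor, 0]),
                int(seeds[cursor, 1]),
            )
        )
        task_meta.append((assignment.student_id, control.label, control_reagent))
        cursor += 1
        for patient in assignment.patients:
            assigned = assignment.reagent_per_sample[patient.label]
            for reagent_name in panel_reagents or (assigned,):
                tasks.append(
                    (
                        _assay_layout(patient, reagent_name),
                        int(seeds[cursor, 0]),
                        int(seeds[cursor, 1]),
                    )
                )
                task_meta.append((assignment.student_id, patient.label, reagent_name))
                cursor += 1

    endpoints = simulate_endpoints(tasks, settings, n_cells)
    radius = tasks[0][0].well_radius_mm if tasks else 0.0
    measured: dict[tuple[str, str, str], MigrationResult] = {}
    for (student_id, label, reagent_name), (layout, _, run_seed), xy in zip(
        task_meta, tasks, endpoints
    ):
        result = MigrationResult(
            sample=label,
            reagent=reagent_name,
            random_mm=_front_from_axial(xy[:, 0], "left", radius),
            directed_mm=_front_from_axial(xy[:, 0], "right", radius),
        )
        measured[(student_id, label, reagent_name)] = result
        log.info(
            "assay student=%s sample=%s reagent=%s seed=%d random=%.3f directed=%.3f",
            student_id, label, reagent_name, run_seed,
            result.random_mm, result.directed_mm,
        )

    rows = []
    interpretations: list[Interpretation] = []
    answer_key: dict = {}
    directed_ranges = {
        name: ranges[name]["directed"] for name in ranges
    }

    for assignment in assignments:
        control = assignment.control
        control_reagent = assignment.reagent_per_sample[control.label]
        c_result = measured[(assignment.student_id, control.label, control_reagent)]
        control_valid = validate_control(
            c_result,
            ranges[control_reagent]["directed"],
            ranges[control_reagent]["random"],
        )
        rows.append(
            (
                assignment.student_id,
                control.label,
                control_reagent,
                round(c_result.random_mm, 3),
                round(c_result.directed_mm, 3),
                "normal" if control_valid else "invalid",
            )
        )
        interpretations.append(
            Interpretation(
                sample=f"{assignment.student_id}/{control.label}",
                per_reagent_status={
                    control_reagent: STATUS_NORMAL
                    if control_valid
                    else STATUS_INDETERMINATE
                },
                control_valid=control_valid,
                mechanism_hint=HINT_NONE if control_valid else HINT_INDETERMINATE,
            )
        )

        key_entry: dict = {
            "control": {"template": None, "true_class": HINT_NONE},
        }
        for patient in assignment.patients:
            assigned = assignment.reagent_per_sample[patient.label]
            reagent_list = panel_reagents or (assigned,)
            results = {
                reagent_name: measured[
                    (assignment.student_id, patient.label, reagent_name)
                ]
                for reagent_name in reagent_list
            }
            assigned_result = results[assigned]
            rows.append(
                (
                    assignment.student_id,
                    patient.label,
                    assigned,
                    round(assigned_result.random_mm, 3),
                    round(assigned_result.directed_mm, 3),
                    interpret_patient(
                        assigned_result, directed_ranges[assigned], control_valid
                    ),
                )
            )
            interpretations.append(
                Interpretation.from_panel(
                    f"{assignment.student_id}/{patient.label}",
                    results,
                    directed_ranges,
                    control_valid,
                )
            )
            template = assignment.templates.get(patient.label)
            key_entry[patient.label] = {
                "template": template.name if template else None,
                "defects": dict(template.defects) if template else dict(patient.sensitivity),
                "random_motility_multiplier": patient.random_motility_multiplier,
                "true_class": template.true_class if template else None,
                "assigned_reagent": assigned,
            }
        answer_key[assignment.student_id] = key_entry

    results_df = pd.DataFrame(rows, columns=list(RESULT_COLUMNS))
    return SessionResult(
        results=results_df,
        interpretations=interpretations,
        answer_key=answer_key,
        ranges=ranges,
    )


def write_session_outputs(
    out_dir: str | Path,
    assignments: Sequence[SessionAssignment],
    result: SessionResult,
) -> dict[str, Path]:
    """Write assignments, results, interpretations, answer key and ranges."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "assignments": out / "assignments.json",
        "results": out / "results.csv",
        "interpretations": out / "interpretations.json",
        "answer_key": out / "answer_key.json",
        "ranges": out / "ranges.json",
    }
    paths["assignments"].write_text(
        json.dumps([a.to_dict() for a in assignments], indent=2)
    )
    result.results.to_csv(paths["results"], index=False)
    paths["interpretations"].write_text(
        json.dumps([i.to_dict() for i in result.interpretations], indent=2)
    )
    paths["answer_key"].write_text(json.dumps(result.answer_key, indent=2))
    paths["ranges"].write_text(
        json.dumps(
            {
                reagent: {mode: r.to_dict() for mode, r in modes.items()}
                for reagent, modes in result.ranges.items()
            },
            indent=2,
        )
    )
    return paths


def load_assay_config(path: str | Path) -> dict:
    """Read a plate/assay configuration from YAML or JSON.

    Recognised keys: ``left``, ``right`` (reagent names), ``sample``
    ("control" or "patient"), ``defects`` (map reagent → multiplier),
    ``random_motility_multiplier``, ``n_cells``, ``seed``, ``duration_s``,
    ``dt_s``, ``acceleration``. Returns a dict with a built ``layout``,
    ``n_cells``, ``seed`` and ``settings``.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValueError("assay config must be a mapping")
    kind = raw.get("sample", "control")
    sample = make_sample(
        kind,
        raw.get("defects") or {},
        label=raw.get("label", kind),
        random_motility_multiplier=float(raw.get("random_motility_multiplier", 1.0)),
    )
    layout = WellLayout(
        left_reagent=get_reagent(raw.get("left", "diluent")),
        right_reagent=get_reagent(raw.get("right", "fMLP")),
        center_sample=sample,
    )
    settings = RunSettings(
        duration_virtual_s=float(raw.get("duration_s", 7200.0)),
        dt_s=float(raw.get("dt_s", 10.0)),
        acceleration=int(raw.get("acceleration", 60)),
        seed=int(raw.get("seed", 0)),
    )
    return {
        "layout": layout,
        "n_cells": int(raw.get("n_cells", DEFAULT_N_CELLS)),
        "seed": int(raw.get("seed", 0)),
        "settings": settings,
    }
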