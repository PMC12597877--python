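# Methods

## The virtual assay

The simulator reproduces the under-agarose chemotaxis protocol as a
deterministic, seed-driven computation. A plate holds three collinear wells
on the migration axis (x): the central well receives the cell sample, one
side well the diluent, the other a chemoattractant. After a 2-hour virtual
incubation the distance migrated past the central well edge is measured
toward each side: the diluent side reads random migration (chemokinesis),
the attractant side directed migration (chemotaxis).

**Geometry.** Wells are 2.4 mm in diameter (radius 1.2 mm) with 5.0 mm
center-to-center spacing, leaving a 2.6 mm agar gap between well edges so a
healthy 2-h directed front (~0.44 mm) stays well inside the corridor. The
simulated plate region spans ±7.4 mm along x. Cells spawn uniformly over
the central well disk and are reflected-clamped at the plate bounds; they
may not enter a side well.

## Walk model

Each cell follows a biased persistent random walk integrated at Δt = 10 s
(720 steps per assay). Per step and agent:

1. **Persistence**: with probability 1 − p the heading is redrawn uniformly
   on (−π, π]; with probability p it is kept. p = 0 therefore gives an
   isotropic random walk whose mean squared displacement is exactly linear
   in time (a property the test suite checks), and larger p lengthens the
   directional correlation time (≈ Δt / (1 − p)).
2. **Jitter**: wrapped-normal angular noise, σ_turn = 0.2 rad.
3. **Chemotactic pull**: Δθ = g · κ · sin(θ\* − θ), rotating the heading
   toward the attractant well with gain g = 0.162 rad per step at κ = 1.
   The bias κ = potency × sensitivity × w(x), where w(x) is the normalized
   gradient magnitude.
4. **Step**: position advances by speed · Δt along the new heading. Speed is
   motility × random_motility_multiplier × a lognormal factor
   (σ_speed = 0.2, unit mean, clipped at 2× so no cell ever exceeds twice
   its base motility).

**Gradient.** The chemoattractant field is static and linear: concentration
0 at the central well center rising to 1 at the attractant well's inner
edge, clamped outside. Its gradient weight w(x) is 1 inside that corridor
and 0 elsewhere — in particular on the diluent half of the plate — so
diluent-side migration is unbiased by construction. A quasi-static linear
gradient is the conventional treatment of the under-agarose geometry over a
2-hour window; the `shape` field of `GradientModel` leaves room for a
diffusive profile later.

**Defect model.** A sample profile carries a per-agonist `sensitivity`
multiplier in [0, 1.5] acting on κ (receptor-level defects) and a
`random_motility_multiplier` acting on speed everywhere (machinery-level,
adhesion-type defects). The speed multiplier is deliberately global rather
than gradient-gated: an adhesion-deficient cell is slow whether or not it
senses attractant, and a gradient-gated version lets global-defect patients
move at full speed inside the corridor, collapsing the separation between
patients and the healthy reference band. Controls are the identity profile
(all multipliers 1), so a patient constructed with sensitivity 1.0
reproduces control statistics exactly under matched seeds.

**Time acceleration.** The 1×/60×/300× levels map virtual time to wall-clock
pacing for interactive playback only; they are accepted, recorded and never
enter the physics, so end states are bit-identical across levels for a
fixed seed.

**Randomness.** Every run draws from a counter-based Philox stream keyed by
its seed, with one contiguous noise block per agent: enlarging the cell
count appends new blocks without reshuffling existing agents' walks.
Batched execution (many assays stacked into one array) performs the same
elementwise arithmetic and is bit-identical to running each assay alone.
Seeds split hierarchically (session → student → assay → plate/run) via
`SeedSequence`, so rerunning one student never perturbs another.

## Calibration

Defaults: motility 10 μm/min, persistence 0.85, bias gain 0.162, 200 cells
per well. These were calibrated jointly so that, at the standard 2-h
incubation, a healthy control's mean directed front is 0.44 mm — the
assay's printed measurement anchor (5.5 grid units at 0.08 mm/unit) — while
keeping the control front's run-to-run SD near 0.05 mm. The effective
axial drift this implies, ≈ 3.7 μm/min, is well below the instantaneous
cell speed because the heading wanders. Random-side fronts average
0.05–0.07 mm; a larger random front (e.g. ~0.2 mm) would require a longer
diffusion length that inflates the directed-front variance and erodes the
patient/control separation the course design depends on, so the smaller
value is the package's deliberate trade-off. Fronts are insensitive to the
integration step near Δt = 10 s.

## Measurement

The graticule is a 10-unit grid spanning `field_width_mm` (0.8 mm at the
standard measurement zoom, hence 0.08 mm per unit); readings may be
fractional, conversion is exact multiplication, and distances beyond one
grid span are measured by summing anchored grid relocations — any partition
of a distance into relocations plus a residual reading reproduces the total
exactly.

The **leading front** is the 95th percentile (empirical, inverted-CDF) of
axial displacement beyond the central well edge among cells that crossed
it, or 0 if none did. The 95th percentile tracks the migrated population
band rather than the single furthest straggler; which cells constitute
"the front" is not fixed by the assay itself, so this choice is a
documented convention, checked in tests against a brute-force sorted
percentile. Derived indicators: chemotaxis distance (the directed front),
cell ratio (fraction of cells with net axial displacement > 0.1 mm, one
order below the healthy front), chemotaxis index (directed / random front,
reported as NaN when the random front is 0), and maximum speed (largest
single-step displacement rate over all cells).

## Reference ranges and interpretation

Reference intervals are mean ± 2·SD of the front over n ≥ 30 seeded
healthy-control assays (default 100–150 per reagent for sessions; 1000 for
the coverage check), the standard clinical reference-interval convention;
empirical coverage of fresh control draws is ≈ 95%. Intervals are closed at
the bounds to avoid knife-edge flapping under float noise.

A control is **valid** iff both its directed and random fronts lie inside
their intervals; an out-of-range control in either direction invalidates
the assay (the symmetric QC convention), and every patient call becomes
*indeterminate* — no other status can leak past an invalid control.
With a valid control, a patient front below the lower bound is *reduced*,
above the upper bound *elevated* (a valid, non-deficient result), otherwise
*normal*. Mechanism suggestion from a per-agonist panel: exactly one
reduced agonist → receptor-specific defect; two or more → global migration
defect (independent receptor losses are unlikely to co-occur); any
indeterminate entry poisons the call.

Because validity gates on two ±2·SD intervals jointly, a true control
passes QC ≈ 91% of the time; this is an inherent property of the
convention, so end-to-end recovery statistics are quoted conditional on a
valid control.

## Classroom sessions

`generate_session` allocates each student one control plus two patients
drawn from a defect pool. The shipped pool spans the mechanisms the assay
can resolve: global 0.3× and 0.5× (sensitivity and speed), a two-agonist
receptor pair (fMLP/C5a at 0.3), and a single-agonist receptor defect
(LTB4 at 0.2). Patients are assigned an agonist drawn from their defective
set — the course design intends patient results to fall below the normal
range — while controls draw uniformly from all five chemoattractants.
`run_session` measures each sample against its assigned agonist for the
student-facing table and additionally works each patient up against the
full 5-agonist panel, which is what makes receptor-specific and global
defects distinguishable; it emits the results CSV (distances in mm to
3 decimals), interpretation JSON, reference-range JSON and an instructor
answer key recording each patient's true template and defect class.

## What the simulation does and does not emulate

The generator reproduces the *structure* of the bench assay — seeded
population migration, graticule measurement, reference-interval logic,
control gating — under idealized conditions: a static linear gradient, no
cell–cell interaction or exclusion, no chemoattractant degradation or
receptor saturation, identical potency for all five agonists at their
single tested concentration, and homogeneous cell populations within a
sample. Passing tests therefore demonstrate internal consistency and the
published calibration anchors, not quantitative agreement with any real
patient population; real assays add donor variability, temperature and
reagent-quality effects that are deliberately out of scope.

## Problem sizes

Statistical tests and the acceptance script use 50 runs for the
directed-front anchor, 1000 + 1000 runs for interval coverage, and a
200-student session (≈ 2200 assays) for design-fidelity and recovery
rates — sizes at which the measured rates are stable to ~1–2 percentage
points.
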