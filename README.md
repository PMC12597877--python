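# chemosim

A headless, scriptable simulator of the **under-agarose neutrophil
chemotaxis assay** — the classical clinical test in which neutrophils placed
in a central well of an agar plate migrate beneath the gel toward a
chemoattractant-filled side well, and the distance travelled after a 2-hour
incubation quantifies chemotactic function.

The package is aimed at immunology educators and computational biologists
who need a reproducible, seed-driven stand-in for the bench assay: it
simulates control and patient neutrophil populations migrating toward five
common chemoattractants (fMLP, PMA, LPS, C5a, LTB4), measures migration with
the same graticule arithmetic used at the microscope, generates in-house
reference ranges by Monte Carlo, and interprets patient results against them
with proper control-validity gating.

## The model

Each cell is an agent performing a **biased persistent random walk**, the
standard formalism for leukocyte migration. At every step (Δt = 10 s
virtual) the heading θ is kept with probability *p* (the persistence,
default 0.85) or redrawn uniformly, receives wrapped-normal jitter
(σ = 0.2 rad), and is rotated toward the attractant well by

> Δθ = g · κ · sin(θ\* − θ),  κ = potency × sensitivity × gradient weight

where θ\* points at the attractant well, g = 0.162 rad is the bias gain and
κ is the chemotactic bias. The gradient is static and linear, acting only in
the corridor between the central well and the attractant well, so migration
toward the opposite (diluent) well is genuinely unbiased — that side reads
**random migration**, the attractant side reads **directed migration**.
Step length is motility (default 10 μm/min) × a lognormal noise factor
(σ = 0.2) × the sample's motility multiplier.

Patient defects are multiplicative: a **receptor-specific defect** lowers
the sensitivity to one agonist; a **global (adhesion-type) defect** — the
leukocyte-adhesion-deficiency pattern — lowers both the sensitivity to every
agonist and the cell's speed everywhere.

Measurements reproduce the on-screen instrument: a 10-unit graticule
spanning 0.8 mm at measurement zoom (0.08 mm per unit; a reading of
5.5 grids is 0.44 mm), with chained grid relocations for longer paths. The
population's **leading front** is the 95th percentile of axial displacement
beyond the central well edge. Default engine parameters are calibrated so a
healthy control's 2-h directed front averages 0.44 mm.

Reference ranges are **mean ± 2·SD** over seeded healthy-control
simulations. Interpretation is gated: if the control's directed or random
front falls outside its range the assay is invalid and every patient call is
*indeterminate*; otherwise patient fronts classify as *reduced*, *normal* or
*elevated*, and the per-agonist pattern yields a mechanism suggestion
(one reduced agonist → receptor-specific; two or more → global defect).

## Worked example

```bash
python examples/run_single_assay.py
```

```
random front   : 0.025 mm   (toward the diluent)
directed front : 0.479 mm   (toward fMLP)
cell ratio     : 0.62  (fraction displaced > 0.1 mm)
chemotaxis idx : 18.8   (directed / random front)
max speed      : 20.0 um/min
```

One seeded 2-h assay of 200 healthy cells against fMLP: the directed front
sits near the 0.44 mm calibration anchor (≈ 5.5 units on the 0.08 mm grid)
while random migration toward the diluent is a few hundredths of a
millimetre. Other scripts in `examples/` demonstrate graticule arithmetic,
reference-range construction, a full 5-agonist patient work-up and a
3-student classroom session.

The same workflows are available from the shell:

```bash
chemosim run --config assay.yaml --out out/
chemosim refrange --reagent fMLP --n 1000 --seed 7
chemosim session --n-students 70 --seed 42 --out session/
```

A classroom session allocates each student one healthy control and two
patient samples (one chemoattractant each), simulates every assay, and
writes `results.csv`, `interpretations.json`, `ranges.json` and an
instructor `answer_key.json`.

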