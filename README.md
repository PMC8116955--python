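# oncolattice

Agent-based simulation of the renal-cell-carcinoma (RCC) tumor
microenvironment on a 3D lattice, built to study the **obesity paradox**:
the clinical observation that obese RCC patients (BMI ≥ 30 kg/m²) often
respond better to immunotherapy than lean patients, even though obesity is
itself a risk factor.

The package is for computational-biology researchers who want to run and
extend desk-scale *in silico* immunotherapy experiments: batch runs of a
stochastic tumor–immune model under lean vs. obese initial conditions, with
outcome tallies, per-category kill attribution, and full seed-level
reproducibility.

## The model

Thirteen immune-cell agent categories (naive/helper/cytotoxic/regulatory T
cells, conventional and plasmacytoid dendritic cells, M1/M2 macrophages,
mast cells, NK cells, neutrophils) and RCC tumor-cell agents occupy a cubic
multi-occupancy grid with a blood vessel along one axis. Signalling is
reduced to a 13-channel **effect field**: each agent may emit a signed
integer on named channels (e.g. *Tumor Growth*, *Natural Killer Cell Kill
Rate*); an agent reading the field sums all emissions within a radius
r = 30 μm of its block plus the environment's global vector, and the
aggregate e rescales the base probability of the event the channel governs:

    p = clamp( p0 · (1 + α·e), 0, 1 ),  α = 0.1

Tumor cells duplicate with probability `p0·g·b`, where `g = 2` under a
non-negative *Tumor Growth* effect (1.25 otherwise) and `b = 2` with blood
access; a positive *Tumor Apoptosis* aggregate e kills with probability
`κ·e` (κ = 0.02). A tumor cell near the vessel can trigger **angiogenesis**,
laying a path of blood voxels; blood access then propagates through
contiguous (26-adjacent) tumor cells by breadth-first search. Naive T cells
carry 8-bit receptors and are activated by bit-string complementarity
against the run's tumor antigen (the classic Celada–Seiden mechanism,
threshold 6 complementary bits).

Obesity (BMI ≥ 30) switches on four global leptin-driven channels
(impaired NK cytotoxicity, suppressed Treg differentiation, macrophage
polarization shifted toward M1), changes the initial NK : mast : pDC
proportions, and adds extra T/DC/M1 agents representing the inflamed
perinephric fat.

A run ends in one of three outcomes: **remission** (no tumor cells left),
**proliferation** (tumor count reaches a limit), or **inconclusive** (tick
limit passed).

## Worked example

One lean verification run from the command line:

```bash
$ oncolattice run --preset phase1-lean --seed 3 --out out/
outcome: proliferation at tick 31 (seed 3)
  cell_counts: out/cell_counts.csv
  kill_counts: out/kill_counts.csv
  outcome: out/outcome.csv
```

With seed 3 the tumor (appearing at tick 10, therapy at tick 15) outgrows
the immune response and reaches the 2000-cell proliferation limit at
tick 31. The three CSVs hold the per-tick census by category, the
cumulative kills by eliminator (NK, cytotoxic T, M1, cDC, pDC, apoptosis),
and the outcome record; every file carries the seed, so the run can be
repeated bit-identically.

The same experiment as a two-arm batch from Python:

```python
import dataclasses
from oncolattice import preset, run

for arm, offset in (("lean", 0), ("obese", 1_000_000)):
    results = [
        run(dataclasses.replace(preset(f"phase1-{arm}"), seed=offset + i, run_number=i))
        for i in range(30)
    ]
    n_rem = sum(r.outcome == "REMISSION" for r in results)
    print(arm, "remissions:", n_rem, "/ 30")
```

Shipped presets: `phase1-lean` / `phase1-obese` (verification protocol:
volume 1e-4 mL, tumor at tick 10, therapy at tick 15, the
(20, 5, 5) vs (0, 15, 15) NK : mast : pDC patterns, 50 obese extras) and
`phase2-lean` / `phase2-obese` (validation protocol: volume 1e-5 mL,
literature/immunohistochemistry-derived densities, tumor mass present and
therapy starting at tick 0).

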