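# Methods

## Model overview

The simulator is a discrete-time, on-lattice agent-based model of the RCC
tumor microenvironment. Space is a cube of side `round(V^(1/3)·10⁴ / s)`
blocks for a simulated volume `V` (mL) and block size `s` (μm); blocks are
multi-occupancy and agents cannot leave the cube. A straight line of blood
voxels along the x axis at mid-height represents the pre-existing vessel.
Fat voxels (count proportional to BMI − 18.5, placed on the outer shell)
are purely graphical/quantitative and host no behaviour.

Time advances in abstract ticks. Within a tick the phases are fixed:

1. **Effect snapshot.** Every emitting agent contributes its emission
   vector at its start-of-tick position; aggregates are computed once per
   receiver, so the immune phase is order-independent except for contested
   kills (resolved by the RNG-shuffled action order). Effects are only
   collected from the therapy-start tick onward; before it the field —
   including the obese global vector — is inert.
2. **Immune phase** (from the therapy-start tick): agents act in shuffled
   order, each perceiving, moving one Chebyshev step, and acting per its
   category (kill / phagocytose / activate / differentiate / switch /
   proliferate / recruit).
3. **Tumor phase** (from the tumor-appearance tick): apoptosis is evaluated
   before duplication; duplicates occupy a uniform block of the closed
   26-neighbourhood.
4. **Angiogenesis**: at most one attempt per tick among tumor cells within
   50 μm of a vessel voxel; on success a discrete line of blood voxels
   (per-axis sign stepping to the nearest vessel voxel, ties lexicographic)
   joins the cell to the vessel, permanently flagging it angiogenic.
5. **Blood access**: breadth-first search over the spatial hash of tumor
   blocks (same-block or 26-adjacent contiguity), seeded at angiogenic
   cells.
6. **Census**: per-category counts and cumulative kills by eliminator are
   recorded; the run ends at the first tick classified as remission
   (0 tumor cells), proliferation (count ≥ limit), or inconclusive
   (tick > limit), with that precedence.

All randomness flows from a single PCG64 generator seeded by the run seed,
so a configuration determines its trajectory bit-for-bit.

## Effect field

Thirteen signed-integer channels connect agents. Aggregation is a
componentwise sum over emissions within a Euclidean radius (default 30 μm,
between block centers) plus the environment's global vector, which
participates everywhere. An aggregate `e` modulates a base probability as
`clamp(p₀(1+αe), 0, 1)` with sensitivity α = 0.1, chosen so the obese
global magnitude of 5 is a ±50 % modulation — a strong but not saturating
influence. The two threshold-type channels (tumor and cytotoxic-T
apoptosis) instead map a positive aggregate to `min(κe, 1)` with κ = 0.02
and are inert at e ≤ 0. Which channels each category emits is config data
(default magnitude 1 per listed channel): regulatory T cells suppress
cytotoxic activation/kill/proliferation and promote cytotoxic-T apoptosis;
M2 macrophages promote angiogenesis, tumor growth, and M1→M2 conversion;
helper-1 cells promote tumor apoptosis and cytotoxic proliferation; cDC and
M1 promote cytotoxic activation; pDC and mast cells promote angiogenesis.
The per-category combinations are the least-constrained part of the model
and are deliberately user-overridable.

## Perception and movement

Movement follows interaction-as-perception: an agent that perceives a
compatible target takes one Chebyshev step toward it per tick (per-axis
sign of the difference); otherwise it random-walks over the closed
neighbourhood. The movement-perception radius defaults to effectively
unbounded (10 000 μm): at desk-scale volumes a finite ~100 μm sensing
radius turns every run into an initial-placement lottery in which army
composition is irrelevant, and none of the population-level contrasts the
model exists to study can emerge; unbounded sensing makes battles
strength-decided. The radius remains a configuration parameter for users
who want to study localized sensing. Helper-2 attraction is the one relay:
a helper-2 that itself perceives the tumor mass hands the tumor centroid to
cytotoxic T cells near it as their movement target for the tick.

Contact interactions (kills, phagocytosis) require co-location or
26-adjacency. Kill ties (several adjacent victims) resolve to the nearest
victim, then lowest id, for determinism.

## Activation and differentiation

Naive T cells carry 8-bit receptors; one 8-bit tumor antigen is drawn per
run. A cDC (any naive kind) or M1 macrophage (CD4 naives) attempts to
activate its closest naive cell each tick: activation requires ≥ 6
complementary bits, succeeding with base probability 0.5 / 0.8 / 1.0 at
6 / 7 / 8 bits, modulated for CD8 naives by the cytotoxic-activation
channel. Activated CD4 naives become helper-1 or helper-2 with equal
probability; activated CD8 naives become cytotoxic in place, while failed
CD8 attempts recycle the cell to a fresh random receptor and position
(conserving the naive pool). CD4 naives independently convert to
regulatory T cells at a base rate per tick, modulated by the
(leptin-suppressed, in obese runs) regulatory-differentiation channel.
Helper and pDC/mast agents recruit new cDC / M1 / NK agents onto a uniform
face of the cube whenever the tumor exists and therapy has started; the
behaviour table states recruitment without a perception precondition, so
none is imposed.

## BMI and the two arms

Obesity is a cutoff at BMI 30. Obese runs differ from lean runs in exactly
four ways: (i) the global effect vector gains NK-kill −m, Treg
differentiation −m, M2-mutation +m, M1-mutation −m with magnitude m = 5;
(ii) under the verification protocol the NK : mast : pDC pool (total 30)
shifts from (20, 5, 5) to (0, 15, 15), conserving the total; (iii) 50
extra perinephric-fat agents are placed uniformly at random, with types
drawn uniformly from the conventional T lineage (CD4 naive / helper-1 /
helper-2 / CD8 naive / cytotoxic), cDC, and M1. Regulatory T cells are
excluded from the extras: the obese adipose infiltrate is dominated by
effector T cells, DCs and M1 macrophages, and leptin signalling
suppresses Treg differentiation — including Tregs would invert the very
effect the extras represent; (iv) under the validation protocol the obese
density column is used directly (+25 % for most types, truncated; directly
measured values for pDC, mast and NK).

Initial counts are `floor(density × volume)` in exact rational arithmetic
(truncation, not rounding, is what the shipped tables encode). The
verification protocol ships the test densities with the dendritic-cell
count pinned to 4 (the table's density column would give 8; both readings
are available). The areal→volumetric conversion
`cells/mm³ = cells/mm² / diameter(mm)` is provided for deriving densities
from section counts. For the measured obese ratios the package defaults to
the textual +21 % (pDC) and −33 % (NK) ratios, while the validation presets
carry the measured obese column verbatim (the two derivations disagree;
both are exposed).

## Parameters

| parameter | default | units | note |
|---|---|---|---|
| block size | 20 | μm | one large-cell diameter; grid side 23 (phase 1), 11 (phase 2) |
| effect radius | 30 | μm | local signalling |
| movement perception radius | 10 000 | μm | effectively unbounded; configurable |
| first tumor cell distance | 50 | μm | from the vessel |
| angiogenesis proximity | 50 | μm | vessel distance enabling an attempt |
| obese effect magnitude | 5 | – | ±50 % modulation at α = 0.1 |
| perinephric extras | 50 | agents | obese verification runs |
| proportion difference | 20 | agents | NK→mast/pDC shift between arms |
| α (modulation) | 0.1 | – | linear clamped multiplier |
| κ (apoptosis slope) | 0.02 | – | threshold channels |
| mild growth factor | 1.25 | – | negative growth effect |
| access boost | 2 | – | blood-access duplication multiplier |
| max ticks / tumor limit | 500 / 2000 | – | outcome thresholds |
| base duplication | 0.14 | /tick | see calibration below |
| base kill / phagocytosis | 0.6 / 0.3 | /attempt | NK & cytotoxic / DC & M1 |
| base proliferation | 0.02 | /tick | cytotoxic & helper T |
| base switch | 0.01 | /tick | macrophage phenotype |
| base Treg differentiation | 0.05 | /tick | CD4 naive |
| base recruitment | 0.3 | /tick | pDC/mast/helper spawning |
| base angiogenesis | 0.5 | /attempt | |

**Calibration.** The tick has no physical duration (the nominal tumor
growth rate in cm/year cannot be converted without a cell-size/time
mapping, so it is carried as metadata only), and the per-event base
probabilities are free constants. The defaults above were therefore
calibrated once, as a set, to the qualitative regime the verification
experiment is designed to exhibit: the tumor establishes itself between appearance
(tick 10) and therapy (tick 15) and can win or lose; all three outcomes
occur; lean kill attribution is NK-led with cytotoxic T cells second;
obese attribution is cytotoxic-T-led; and the obese arm shows a limited
remission advantage. Under these defaults the measured per-run remission
probability is ≈ 0.80 (lean) vs ≈ 0.86 (obese) over 300 runs per arm.
They were not tuned to any numeric target — none exists — and the
directional batch properties in the test suite are expected to hold with
high probability, not certainty, per replicate.

## Synthetic data and fixtures

There are no external datasets: every input is either a shipped density
table (shipped as presets) or generated. Test fixtures are tiny
deterministic configurations (`make_fixture`): a guaranteed-kill 1-NK/1-
tumor layout, a two-clump blood-access case with a flood-fill-verified
expected set, a shortened verification run, and a side-10 mini-run used for
conservation checks. What passing tests show is internal consistency and
reproduction of the tabulated initialization arithmetic and qualitative
batch contrasts — not fidelity to any real patient data: the model has no cell
lifetimes, no pharmacokinetics, no molecular signalling, and an abstract
clock.

## Numerical and design choices

- Exact `Fraction` arithmetic for density→count truncation (float rounding
  would lose table cells like 6 000 000 × 10⁻⁵ = 60); decimal
  interpretation of user-supplied ratios (1.21 means 121/100).
- Distances are Euclidean between block centers; adjacency is the
  26-neighbourhood plus same-block (multi-occupancy contact).
- Perception ties break on lowest agent id; vessel-path target ties break
  lexicographically; both for seed-stable determinism.
- One angiogenesis success per tick at most; repeated successes extend the
  vasculature but do not stack the growth boost.
- Outcome precedence is remission > proliferation > inconclusive, and no
  outcome is evaluated before the tumor exists.
- The conservation identity (cells created = living + killed + apoptosed)
  is tracked per tick and enforced in the test suite.

## Known limitations

- The per-category emission table is reconstructed from channel semantics
  rather than measured per-agent values; it is config data precisely
  because it is uncertain.
- The immune system cannot attack vessels; more angiogenic seeds simply
  make access more robust.
- Batch-level contrasts between arms are modest relative to run-to-run
  variance; single batches of ~100 runs per arm can show the reversed sign,
  which is why the shipped experiment pools three meta-replicates.
- No metastasis, no cell lifetimes, no drug PK/PD; the validation-phase
  protocol is included as presets but is a starting point rather than a
  calibrated patient model.
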