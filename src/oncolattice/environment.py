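"""The cubic simulation environment and its BMI-dependent initialization.

The environment is a cube of multi-occupancy grid blocks holding a straight
blood vessel, decorative perinephric-fat voxels, and the initial immune
roster.  Initial agent counts derive from cellular densities (cells/mL)
multiplied by the simulated volume and truncated to integers.  Obesity
(BMI >= 30 kg/m^2) changes the initial composition (+25% for most immune
types, directly measured values for pDC/mast/NK, a shifted NK:mast:pDC
proportion in the verification protocol, extra fat-resident agents) and
switches on four global leptin-driven effect channels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Mapping, Optional

import numpy as np

from .agents import AgentCategory, BioAgent, random_receptor, RECEPTOR_CATEGORIES
from .effects import effect_vector, zero_effects
from .tumor import TumorCell

# Canonical immune cell-type names (density-table row names).
IMMUNE_TYPES: tuple[str, ...] = (
    "Cytotoxic T Cells",
    "Neutrophils",
    "Mast Cells",
    "Regulatory T Cells",
    "Plasmacytoid Dendritic Cells",
    "Dendritic Cells",
    "M1 Macrophages",
    "M2 Macrophages",
    "Natural Killer Cells",
    "CD4+ Naive T Cells",
    "CD8+ Naive T Cells",
    "Helper Type 1 Cells",
    "Helper Type 2 Cells",
)

TYPE_TO_CATEGORY: dict[str, AgentCategory] = {
    "Cytotoxic T Cells": AgentCategory.CD8_CYTOTOXIC,
    "Neutrophils": AgentCategory.NEUTROPHIL,
    "Mast Cells": AgentCategory.MAST,
    "Regulatory T Cells": AgentCategory.TREG,
    "Plasmacytoid Dendritic Cells": AgentCategory.PDC,
    "Dendritic Cells": AgentCategory.CDC,
    "M1 Macrophages": AgentCategory.M1,
    "M2 Macrophages": AgentCategory.M2,
    "Natural Killer Cells": AgentCategory.NK,
    "CD4+ Naive T Cells": AgentCategory.CD4_NAIVE,
    "CD8+ Naive T Cells": AgentCategory.CD8_NAIVE,
    "Helper Type 1 Cells": AgentCategory.CD4_HELPER1,
    "Helper Type 2 Cells": AgentCategory.CD4_HELPER2,
}

OBESE_BMI_CUTOFF = 30.0

# Cell types whose obese density is the lean density + 25%; the remaining
# types are either measured directly (pDC, mast, NK) or unchanged.
DEFAULT_INCREASED_TYPES: frozenset[str] = frozenset(
    {
        "Cytotoxic T Cells",
        "Regulatory T Cells",
        "Dendritic Cells",
        "M1 Macrophages",
        "Helper Type 2 Cells",
    }
)
# Directly measured obese/lean density ratios (+21% pDC, -33% NK).
DEFAULT_SPECIAL_RATIOS: dict[str, float] = {
    "Plasmacytoid Dendritic Cells": 1.21,
    "Natural Killer Cells": 0.67,
}

# Types eligible as perinephric-fat extra agents in obese runs: the
# conventional T-cell family, conventional dendritic cells, and M1
# macrophages.  Regulatory T cells are excluded: the obese adipose
# infiltrate is dominated by effector T cells / DCs / M1, and leptin
# signalling suppresses Treg differentiation in the obese environment.
PERINEPHRIC_CATEGORIES: tuple[AgentCategory, ...] = (
    AgentCategory.CD4_NAIVE,
    AgentCategory.CD4_HELPER1,
    AgentCategory.CD4_HELPER2,
    AgentCategory.CD8_NAIVE,
    AgentCategory.CD8_CYTOTOXIC,
    AgentCategory.CDC,
    AgentCategory.M1,
)


def validate_density_table(densities: Mapping[str, float]) -> dict[str, float]:
    missing = set(IMMUNE_TYPES) - set(densities)
    unknown = set(densities) - set(IMMUNE_TYPES)
    if missing or unknown:
        raise ValueError(f"bad density table: missing={sorted(missing)} unknown={sorted(unknown)}")
    bad = {k: v for k, v in densities.items() if v < 0}
    if bad:
        raise ValueError(f"densities must be >= 0: {bad}")
    return dict(densities)


@dataclass
class Environment:
    """The cubic lattice with its vessel, fat voxels, and global effects."""

    side: int
    block_size: float  # micrometres per block edge
    bmi: float
    vessel_voxels: set[tuple[int, int, int]] = field(default_factory=set)
    fat_voxels: set[tuple[int, int, int]] = field(default_factory=set)
    global_effects: np.ndarray = field(default_factory=zero_effects)

    def __post_init__(self) -> None:
        if self.side < 2:
            raise ValueError("cube side must be >= 2 blocks")

    @property
    def obese(self) -> bool:
        return self.bmi >= OBESE_BMI_CUTOFF

    def contains(self, position) -> bool:
        return all(0 <= int(c) < self.side for c in position)

    def occupancy(self, agents) -> dict[tuple[int, int, int], set[int]]:
        """Block -> agent-id sets for the given roster (multi-occupancy)."""
        occ: dict[tuple[int, int, int], set[int]] = {}
        for a in agents:
            occ.setdefault(tuple(a.position), set()).add(a.id)
        return occ


def grid_side_from_volume(volume_ml: float, block_size_um: float) -> int:
    """Cube side in blocks for a simulated volume in mL.

    1 mL = 1 cm^3, so the cube edge is ``volume**(1/3) * 1e4`` micrometres;
    the side is that edge divided by the block size, rounded, floored at 2.
    """
    if volume_ml <= 0:
        raise ValueError("volume must be positive")
    if block_size_um <= 0:
        raise ValueError("block size must be positive")
    edge_um = volume_ml ** (1.0 / 3.0) * 1e4
    return max(2, round(edge_um / block_size_um))


def density_to_count(density_per_ml: float, volume_ml: float) -> int:
    """Agents for a cellular density: ``floor(density * volume)``.

    Truncation, not rounding, and exact rational arithmetic so that values
    like 6,000,000 * 1e-5 do not fall below an integer through float error.
    """
    if density_per_ml < 0:
        raise ValueError("density must be >= 0")
    if volume_ml <= 0:
        raise ValueError("volume must be positive")
    return math.floor(Fraction(density_per_ml) * Fraction(volume_ml))


def erdag_convert(areal_density_per_mm2: float, cell_diameter_mm: float) -> float:
    """Areal (cells/mm^2) to volumetric (cells/mm^3) density conversion.

    ``cells/mm^3 = cells/mm^2 * (1 / diameter in mm)``; multiply by 1e3 for
    cells/mL.
    """
    if cell_diameter_mm <= 0:
        raise ValueError("cell diameter must be positive")
    return areal_density_per_mm2 / cell_diameter_mm


def apply_obesity_adjustments(
    lean: Mapping[str, float],
    increase_fraction: float = 0.25,
    increased_types: frozenset[str] | set[str] = DEFAULT_INCREASED_TYPES,
    special_ratios: Mapping[str, float] = DEFAULT_SPECIAL_RATIOS,
) -> dict[str, float]:
    """Obese density table from a lean one.

    Types in ``increased_types`` gain ``increase_fraction`` (default +25%);
    types in ``special_ratios`` are scaled by their measured obese/lean
    ratio; everything else is unchanged.  All products are truncated.
    """
    if increase_fraction < 0:
        raise ValueError("increase fraction must be >= 0")
    lean = validate_density_table(lean)
    for name in set(increased_types) | set(special_ratios):
        if name not in lean:
            raise ValueError(f"unknown cell type: {name}")
    obese = dict(lean)
    # Fractions and ratios are user-supplied decimals; interpret them
    # decimally (via str) so e.g. x1.21 of a round number is not truncated
    # a unit low by binary float representation.
    for name in increased_types:
        obese[name] = float(
            math.floor(Fraction(lean[name]) * (1 + Fraction(str(increase_fraction))))
        )
    for name, ratio in special_ratios.items():
        obese[name] = float(math.floor(Fraction(lean[name]) * Fraction(str(ratio))))
    return obese


def phase1_proportion_counts(
    total_nk_mast_pdc: int, proportion_difference: int, obese: bool
) -> tuple[int, int, int]:
    """NK / mast / pDC counts under the verification-phase proportion rule.

    The lean pattern is ``(d, (total-d)/2, (total-d)/2)`` with
    ``d = proportion_difference``; the obese pattern shifts ``d`` NK agents
    into mast and pDC, split evenly (NK floored at 0).  The combined total
    is identical between the two arms.  With total 30 and d 20 this is the
    canonical (20, 5, 5) lean / (0, 15, 15) obese instance.
    """
    d = proportion_difference
    if d % 2 != 0:
        raise ValueError("proportion difference must be even (split between mast and pDC)")
    if d < 0 or d > total_nk_mast_pdc:
        raise ValueError("proportion difference must be in [0, total]")
    if (total_nk_mast_pdc - d) % 2 != 0:
        raise ValueError("total minus difference must split evenly between mast and pDC")
    base_nk = d
    base_other = (total_nk_mast_pdc - d) // 2
    if not obese:
        return (base_nk, base_other, base_other)
    return (max(base_nk - d, 0), base_other + d // 2, base_other + d // 2)


def obese_global_effects(magnitude: int) -> np.ndarray:
    """Leptin-driven global channels active when BMI >= 30.

    NK cytotoxicity and regulatory-T differentiation are impaired
    (negative); M2->M1 macrophage switching is promoted while M1->M2
    switching is equally suppressed.
    """
    return effect_vector(
        {
            "Natural Killer Cell Kill Rate": -magnitude,
            "Regulatory T Differentiation": -magnitude,
            "M2 Macrophage Mutation": magnitude,
            "M1 Macrophage Mutation": -magnitude,
        }
    )


def initial_counts(config) -> dict[str, int]:
    """Initial immune-agent count per cell type for a configuration.

    Starts from ``density_to_count`` over the density table, applies any
    per-type count overrides, then (verification phase only) replaces the
    NK / mast / pDC counts with the proportion-rule pattern.
    """
    densities = validate_density_table(config.densities)
    counts = {name: density_to_count(densities[name], config.volume) for name in IMMUNE_TYPES}
    for name, count in (config.count_overrides or {}).items():
        if name not in counts:
            raise ValueError(f"unknown cell type in count override: {name}")
        counts[name] = int(count)
    if config.phase == 1:
        obese = config.bmi >= OBESE_BMI_CUTOFF
        nk, mast, pdc = phase1_proportion_counts(
            config.nk_mast_pdc_total, config.proportion_difference, obese
        )
        counts["Natural Killer Cells"] = nk
        counts["Mast Cells"] = mast
        counts["Plasmacytoid Dendritic Cells"] = pdc
    return counts


def _lay_vessel(side: int) -> set[tuple[int, int, int]]:
    # Straight line of blood voxels along the x axis at mid-height of the cube.
    mid = side // 2
    return {(x, mid, mid) for x in range(side)}


def _lay_fat(side: int, bmi: float, rng: np.random.Generator) -> set[tuple[int, int, int]]:
    # Decorative fat voxels on the outermost shell, count scaling with BMI
    # above the underweight threshold.
    n = int(round(20.0 * max(bmi - 18.5, 0.0)))
    shell = [
        (x, y, z)
        for x in range(side)
        for y in range(side)
        for z in range(side)
        if 0 in (x, y, z) or side - 1 in (x, y, z)
    ]
    idx = rng.choice(len(shell), size=min(n, len(shell)), replace=False)
    return {shell[i] for i in np.atleast_1d(idx)}


def first_tumor_position(env: Environment, distance_um: float) -> tuple[int, int, int]:
    """Deterministic seed position for the first tumor cell.

    Offset perpendicular to the vessel, at the configured distance (in
    micrometres, rounded to blocks) from the vessel's midpoint.
    """
    mid = env.side // 2
    offset = max(1, round(distance_um / env.block_size))
    y = min(mid + offset, env.side - 1)
    return (mid, y, mid)


def _clump_positions(
    seed: tuple[int, int, int], n: int, side: int
) -> list[tuple[int, int, int]]:
    # Compact contiguous clump: breadth-first fill of the 26-neighbourhood
    # around the seed, multi-occupancy second pass if the ball saturates.
    from collections import deque

    out: list[tuple[int, int, int]] = []
    seen = {seed}
    queue = deque([seed])
    while queue and len(out) < n:
        pos = queue.popleft()
        out.append(pos)
        x, y, z = pos
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dz in (-1, 0, 1):
                    nb = (x + dx, y + dy, z + dz)
                    if nb not in seen and all(0 <= c < side for c in nb):
                        seen.add(nb)
                        queue.append(nb)
    while len(out) < n:  # grid smaller than the clump: stack multi-occupancy
        out.append(out[len(out) % max(len(out), 1)])
    return out[:n]


def initialize_environment(
    config, rng: np.random.Generator
) -> tuple[Environment, list[BioAgent], list[TumorCell]]:
    """Build the environment, immune roster and initial tumor for a run.

    Immune agents are placed uniformly at random.  In the verification
    phase (phase 1) the tumor list is empty — the engine inserts the single
    first cell at the configured appearance tick and distance from the
    vessel.  In the validation phase (phase 2) the tumor mass is already
    present at tick 0 as a contiguous clump.  Obese runs additionally place
    the perinephric-fat extra agents and enable the global leptin effects.
    """
    side = grid_side_from_volume(config.volume, config.block_size)
    env = Environment(side=side, block_size=config.block_size, bmi=config.bmi)
    env.vessel_voxels = _lay_vessel(side)
    env.fat_voxels = _lay_fat(side, config.bmi, rng)
    if env.obese:
        env.global_effects = obese_global_effects(config.obese_effect_magnitude)

    counts = initial_counts(config)
    total = sum(counts.values()) + (config.perinephric_extra if env.obese else 0)
    if total > config.max_occupancy * side**3:
        raise ValueError(
            f"{total} agents exceed grid capacity ({config.max_occupancy} per block, side {side})"
        )

    roster: list[BioAgent] = []
    next_id = 0
    for name in IMMUNE_TYPES:
        category = TYPE_TO_CATEGORY[name]
        for _ in range(counts[name]):
            pos = tuple(int(v) for v in rng.integers(0, side, size=3))
            receptor = random_receptor(rng) if category in RECEPTOR_CATEGORIES else None
            roster.append(BioAgent(next_id, category, pos, receptor=receptor))
            next_id += 1
    if env.obese and config.perinephric_extra > 0:
        for _ in range(config.perinephric_extra):
            category = PERINEPHRIC_CATEGORIES[int(rng.integers(0, len(PERINEPHRIC_CATEGORIES)))]
            pos = tuple(int(v) for v in rng.integers(0, side, size=3))
            receptor = random_receptor(rng) if category in RECEPTOR_CATEGORIES else None
            roster.append(BioAgent(next_id, category, pos, receptor=receptor))
            next_id += 1

    tumor: list[TumorCell] = []
    if config.phase == 2:
        n_tumor = density_to_count(config.tumor_density, config.volume)
        seed_pos = first_tumor_position(env, config.first_cell_distance)
        for i, pos in enumerate(_clump_positions(seed_pos, n_tumor, side)):
            tumor.append(TumorCell(id=i, position=pos))
    return env, roster, tumor
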