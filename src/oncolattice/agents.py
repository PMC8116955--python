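"""Immune-cell agent categories and their per-tick behaviours.

Thirteen immune cell categories (plus the tumor cell and the decorative
blood voxel agent) populate the lattice.  Movement follows the
interaction-as-perception paradigm: an agent that perceives a compatible
target moves one Chebyshev step toward it per tick; otherwise it random
walks.  Naive T cells carry an 8-bit antigen receptor and are activated by
bit-string complementarity against the run's tumor antigen, the mechanism
of classic bit-string immune simulators (Celada-Seiden).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum
from typing import Optional, Sequence

import numpy as np

from .effects import modulate_rate, apoptosis_probability, DEFAULT_ALPHA, DEFAULT_KAPPA

RECEPTOR_BITS = 8
# Minimum number of complementary bit positions for an activation attempt
# to have any chance of success, and the success base probability at each
# admissible complementarity (affinity steps).
COMPLEMENT_THRESHOLD = 6
BASE_ACTIVATION_PROB = {6: 0.5, 7: 0.8, 8: 1.0}


class AgentCategory(str, Enum):
    CD4_NAIVE = "CD4_NAIVE"
    CD4_HELPER1 = "CD4_HELPER1"
    CD4_HELPER2 = "CD4_HELPER2"
    CD8_NAIVE = "CD8_NAIVE"
    CD8_CYTOTOXIC = "CD8_CYTOTOXIC"
    TREG = "TREG"
    CDC = "CDC"
    PDC = "PDC"
    M1 = "M1"
    M2 = "M2"
    MAST = "MAST"
    NK = "NK"
    NEUTROPHIL = "NEUTROPHIL"
    RCC_TUMOR = "RCC_TUMOR"
    BLOOD = "BLOOD"


IMMUNE_CATEGORIES: tuple[AgentCategory, ...] = tuple(
    c for c in AgentCategory if c not in (AgentCategory.RCC_TUMOR, AgentCategory.BLOOD)
)
# Categories whose receptor field must be present (naive T cells only).
RECEPTOR_CATEGORIES = (AgentCategory.CD4_NAIVE, AgentCategory.CD8_NAIVE)
# Categories that may appear on a kill record, plus the apoptosis tag.
KILLER_CATEGORIES = (
    AgentCategory.NK,
    AgentCategory.CD8_CYTOTOXIC,
    AgentCategory.M1,
    AgentCategory.CDC,
    AgentCategory.PDC,
)
APOPTOSIS = "APOPTOSIS"


@dataclass
class BioAgent:
    """One immune or tumor cell on the grid."""

    id: int
    category: AgentCategory
    position: tuple[int, int, int]
    receptor: Optional[str] = None
    alive: bool = True

    def __post_init__(self) -> None:
        if self.category in RECEPTOR_CATEGORIES:
            if self.receptor is None or len(self.receptor) != RECEPTOR_BITS:
                raise ValueError(
                    f"{self.category.value} requires an {RECEPTOR_BITS}-bit receptor"
                )
        elif self.receptor is not None:
            raise ValueError(f"{self.category.value} must not carry a receptor")


@dataclass(frozen=True)
class KillRecord:
    """Attribution of one eliminated tumor cell."""

    killer: str  # killer category name, or APOPTOSIS
    tick: int
    victim_id: int


def random_receptor(rng: np.random.Generator) -> str:
    return "".join(str(b) for b in rng.integers(0, 2, size=RECEPTOR_BITS))


def complementarity(receptor: str, antigen: str) -> int:
    """Number of complementary (differing) bit positions between strings."""
    if len(receptor) != RECEPTOR_BITS or len(antigen) != RECEPTOR_BITS:
        raise ValueError(f"receptor and antigen must be {RECEPTOR_BITS} bits")
    return sum(1 for r, a in zip(receptor, antigen) if r != a)


def chebyshev(a: Sequence[int], b: Sequence[int]) -> int:
    return int(max(abs(int(x) - int(y)) for x, y in zip(a, b)))


def euclidean_um(a: Sequence[int], b: Sequence[int], block_size: float) -> float:
    d = (np.asarray(a, dtype=np.float64) - np.asarray(b, dtype=np.float64)) * block_size
    return float(np.sqrt(np.dot(d, d)))


def perceive_nearest(
    agent: BioAgent,
    candidates: Sequence[BioAgent],
    perception_radius: float,
    block_size: float,
) -> Optional[BioAgent]:
    """The in-range candidate at minimal Euclidean distance.

    Ties are broken by lowest candidate id so that perception is
    deterministic under a fixed seed.  Returns ``None`` when no candidate
    lies within ``perception_radius`` micrometres.
    """
    best: Optional[BioAgent] = None
    best_key: tuple[float, int] | None = None
    for cand in candidates:
        dist = euclidean_um(agent.position, cand.position, block_size)
        if dist <= perception_radius:
            key = (dist, cand.id)
            if best_key is None or key < best_key:
                best, best_key = cand, key
    return best


def move_toward(
    position: Sequence[int], target: Sequence[int], side: int
) -> tuple[int, int, int]:
    """One Chebyshev step from ``position`` toward ``target``.

    Each coordinate moves by the sign of its difference, so the Chebyshev
    distance to the target strictly decreases unless it is already 0.  The
    result is always inside the cube.
    """
    pos = np.asarray(position, dtype=np.int64)
    tgt = np.asarray(target, dtype=np.int64)
    if np.any(pos < 0) or np.any(pos >= side) or np.any(tgt < 0) or np.any(tgt >= side):
        raise ValueError("positions must lie inside the cube")
    new = np.clip(pos + np.sign(tgt - pos), 0, side - 1)
    return (int(new[0]), int(new[1]), int(new[2]))


def random_step(
    position: Sequence[int], side: int, rng: np.random.Generator
) -> tuple[int, int, int]:
    """Uniform step to one of the 27 blocks of the closed neighbourhood."""
    new = np.clip(
        np.asarray(position, dtype=np.int64) + rng.integers(-1, 2, size=3), 0, side - 1
    )
    return (int(new[0]), int(new[1]), int(new[2]))


def attempt_antigen_recognition(
    receptor: str,
    antigen: str,
    activation_effect: int,
    rng: np.random.Generator,
    threshold: int = COMPLEMENT_THRESHOLD,
    alpha: float = DEFAULT_ALPHA,
) -> bool:
    """Bit-string activation of a naive T cell against the tumor antigen.

    Succeeds only when the number of complementary bits reaches
    ``threshold``; the per-attempt success probability then grows with the
    affinity (0.5 / 0.8 / 1.0 at 6 / 7 / 8 complementary bits) and is
    modulated by the activation effect channel.
    """
    c = complementarity(receptor, antigen)
    if c < threshold:
        return False
    base = BASE_ACTIVATION_PROB.get(c, 1.0)
    return bool(rng.random() < modulate_rate(base, activation_effect, alpha))


def differentiate_cd4(agent: BioAgent, rng: np.random.Generator) -> AgentCategory:
    """Post-activation fate of a CD4+ naive T cell: helper 1 or 2, 50/50."""
    if agent.category is not AgentCategory.CD4_NAIVE:
        raise ValueError(f"expected CD4_NAIVE, got {agent.category.value}")
    return AgentCategory.CD4_HELPER1 if rng.random() < 0.5 else AgentCategory.CD4_HELPER2


def treg_differentiation(
    agent: BioAgent,
    treg_effect: int,
    base_rate: float,
    rng: np.random.Generator,
    alpha: float = DEFAULT_ALPHA,
) -> bool:
    """Whether a CD4+ naive T cell converts to a regulatory T cell this tick.

    In obese runs the global Regulatory T Differentiation channel is
    negative (leptin suppression), lowering the conversion probability.
    """
    if agent.category is not AgentCategory.CD4_NAIVE:
        raise ValueError(f"expected CD4_NAIVE, got {agent.category.value}")
    return bool(rng.random() < modulate_rate(base_rate, treg_effect, alpha))


def phenotype_switch(
    agent: BioAgent,
    mutation_effect: int,
    base_rate: float,
    rng: np.random.Generator,
    alpha: float = DEFAULT_ALPHA,
) -> AgentCategory:
    """Macrophage M1 <-> M2 phenotype switch.

    M1 agents read the M1 Macrophage Mutation channel (their rate of
    becoming M2), M2 agents the M2 channel (their rate of becoming M1);
    the caller supplies the matching aggregated value.  Returns the
    (possibly unchanged) category.
    """
    if agent.category not in (AgentCategory.M1, AgentCategory.M2):
        raise ValueError(f"expected a macrophage, got {agent.category.value}")
    if rng.random() < modulate_rate(base_rate, mutation_effect, alpha):
        return AgentCategory.M2 if agent.category is AgentCategory.M1 else AgentCategory.M1
    return agent.category


def _attempt_contact_elimination(
    attacker: BioAgent,
    victim: BioAgent,
    effect: int,
    base: float,
    tick: int,
    rng: np.random.Generator,
    alpha: float,
) -> Optional[KillRecord]:
    # The victim may be a BioAgent of the tumor category or a TumorCell.
    if getattr(victim, "category", AgentCategory.RCC_TUMOR) is not AgentCategory.RCC_TUMOR:
        raise ValueError("victim must be an RCC tumor cell")
    if chebyshev(attacker.position, victim.position) > 1:
        raise ValueError("victim must be co-located or 26-adjacent to the attacker")
    if rng.random() < modulate_rate(base, effect, alpha):
        victim.alive = False
        return KillRecord(attacker.category.value, tick, victim.id)
    return None


def attempt_kill(
    killer: BioAgent,
    victim: BioAgent,
    kill_effect: int,
    base_kill: float,
    rng: np.random.Generator,
    tick: int = 0,
    alpha: float = DEFAULT_ALPHA,
) -> Optional[KillRecord]:
    """Contact kill attempt by an NK or CD8+ cytotoxic T cell."""
    if killer.category not in (AgentCategory.NK, AgentCategory.CD8_CYTOTOXIC):
        raise ValueError(f"{killer.category.value} cannot attempt a cytotoxic kill")
    return _attempt_contact_elimination(killer, victim, kill_effect, base_kill, tick, rng, alpha)


def attempt_phagocytosis(
    dc: BioAgent,
    victim: BioAgent,
    phago_effect: int,
    base: float,
    rng: np.random.Generator,
    tick: int = 0,
    alpha: float = DEFAULT_ALPHA,
) -> Optional[KillRecord]:
    """Contact phagocytosis attempt by a (plasmacytoid) dendritic cell."""
    if dc.category not in (AgentCategory.CDC, AgentCategory.PDC):
        raise ValueError(f"{dc.category.value} cannot attempt phagocytosis")
    return _attempt_contact_elimination(dc, victim, phago_effect, base, tick, rng, alpha)


def proliferate(
    agent: BioAgent,
    proliferation_effect: int,
    base: float,
    rng: np.random.Generator,
    side: int,
    new_id: int,
    alpha: float = DEFAULT_ALPHA,
) -> Optional[BioAgent]:
    """Duplication attempt of a cytotoxic or helper T cell.

    On success the copy appears in a uniformly chosen block of the closed
    26-neighbourhood (multi-occupancy permits the parent's own block),
    clipped to the cube.
    """
    if agent.category not in (
        AgentCategory.CD8_CYTOTOXIC,
        AgentCategory.CD4_HELPER1,
        AgentCategory.CD4_HELPER2,
    ):
        raise ValueError(f"{agent.category.value} does not proliferate")
    if not 0.0 <= base <= 1.0:
        raise ValueError("base probability must be in [0, 1]")
    if rng.random() < modulate_rate(base, proliferation_effect, alpha):
        return BioAgent(new_id, agent.category, random_step(agent.position, side, rng))
    return None


def spawn_at_edge(
    side: int, category: AgentCategory, rng: np.random.Generator, new_id: int
) -> BioAgent:
    """New agent recruited from outside, on a uniform face of the cube.

    Only NK, conventional DC and M1 macrophage agents are recruited this
    way (by pDC, helper/mast, and helper agents respectively).
    """
    if category not in (AgentCategory.NK, AgentCategory.CDC, AgentCategory.M1):
        raise ValueError(f"{category.value} is not recruited at the edge")
    axis = int(rng.integers(0, 3))
    face = int(rng.integers(0, 2)) * (side - 1)
    pos = [int(v) for v in rng.integers(0, side, size=3)]
    pos[axis] = face
    return BioAgent(new_id, category, (pos[0], pos[1], pos[2]))


def cytotoxic_apoptosis(
    agent: BioAgent,
    apoptosis_effect: int,
    rng: np.random.Generator,
    kappa: float = DEFAULT_KAPPA,
) -> bool:
    """Whether a CD8+ cytotoxic T cell survives this tick's apoptosis check."""
    if agent.category is not AgentCategory.CD8_CYTOTOXIC:
        raise ValueError(f"expected CD8_CYTOTOXIC, got {agent.category.value}")
    if rng.random() < apoptosis_probability(apoptosis_effect, kappa):
        agent.alive = False
    return agent.alive


def cd8_naive_recycle(
    agent: BioAgent,
    activated: bool,
    side: int,
    rng: np.random.Generator,
    new_id: int,
) -> BioAgent:
    """Resolve a CD8+ naive activation attempt.

    Success turns the agent into a CD8+ cytotoxic T cell in place.  Failure
    removes it and recreates a fresh naive cell with a new random receptor
    at a uniformly random position distinct from the old one, conserving the
    naive count.
    """
    if agent.category is not AgentCategory.CD8_NAIVE:
        raise ValueError(f"expected CD8_NAIVE, got {agent.category.value}")
    if activated:
        agent.category = AgentCategory.CD8_CYTOTOXIC
        agent.receptor = None
        return agent
    agent.alive = False
    while True:
        pos = tuple(int(v) for v in rng.integers(0, side, size=3))
        if pos != agent.position or side == 1:
            break
    return BioAgent(new_id, AgentCategory.CD8_NAIVE, pos, receptor=random_receptor(rng))
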