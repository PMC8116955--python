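"""Per-tick scheduler, run configuration, presets, and outcome classification.

A run advances in discrete ticks.  Within a tick the phases are fixed:

1. snapshot all effect emissions (plus the global vector) and aggregate
   them at every agent's start-of-tick position, so the immune phase is
   order-independent except for contested kills;
2. from the therapy-start tick onward, immune agents act in RNG-shuffled
   order (perceive -> move -> act);
3. tumor cells act (apoptosis first, then duplication) from the tumor
   appearance tick onward;
4. one angiogenesis attempt;
5. blood access is recomputed by breadth-first search;
6. the per-tick census and cumulative kill counts are recorded.

Before the therapy-start tick the immune agents do not act at all, which
models the window between tumor appearance and the start of immunotherapy.
A run ends at the first tick whose tumor count triggers an outcome:
remission (0 tumor cells), proliferation (count reaches the limit), or
inconclusive (tick limit passed), in that precedence.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree

from . import agents as ag
from .agents import AgentCategory, BioAgent, KillRecord, APOPTOSIS
from .effects import (
    CHANNEL_INDEX,
    N_CHANNELS,
    aggregate_effects_batch,
    emission_table_to_vectors,
    zero_effects,
)
from .environment import (
    Environment,
    OBESE_BMI_CUTOFF,
    first_tumor_position,
    initialize_environment,
    validate_density_table,
)
from .tumor import TumorCell, compute_blood_access, try_angiogenesis

OUTCOMES = ("REMISSION", "PROLIFERATION", "INCONCLUSIVE")

# Verification-phase (Table-style) lean densities, cells/mL.
PHASE1_DENSITIES: dict[str, float] = {
    "Cytotoxic T Cells": 80_000,
    "Neutrophils": 40_000,
    "Mast Cells": 40_000,
    "Regulatory T Cells": 40_000,
    "Plasmacytoid Dendritic Cells": 40_000,
    "Dendritic Cells": 80_000,
    "M1 Macrophages": 40_000,
    "M2 Macrophages": 40_000,
    "Natural Killer Cells": 160_000,
    "CD4+ Naive T Cells": 80_000,
    "CD8+ Naive T Cells": 80_000,
    "Helper Type 1 Cells": 40_000,
    "Helper Type 2 Cells": 40_000,
}

# Validation-phase densities, cells/mL (lean column and obese column).
PHASE2_LEAN_DENSITIES: dict[str, float] = {
    "Cytotoxic T Cells": 6_000_000,
    "Neutrophils": 21_716_150,
    "Mast Cells": 266_667,
    "Regulatory T Cells": 142_800,
    "Plasmacytoid Dendritic Cells": 1_173_850,
    "Dendritic Cells": 1_173_850,
    "M1 Macrophages": 4_360_000,
    "M2 Macrophages": 6_540_000,
    "Natural Killer Cells": 3_271_430,
    "CD4+ Naive T Cells": 4_905_000,
    "CD8+ Naive T Cells": 6_000_000,
    "Helper Type 1 Cells": 2_452_500,
    "Helper Type 2 Cells": 2_452_500,
}
PHASE2_OBESE_DENSITIES: dict[str, float] = {
    "Cytotoxic T Cells": 7_500_000,
    "Neutrophils": 21_716_150,
    "Mast Cells": 600_000,
    "Regulatory T Cells": 178_500,
    "Plasmacytoid Dendritic Cells": 1_190_003,
    "Dendritic Cells": 1_467_312,
    "M1 Macrophages": 5_450_000,
    "M2 Macrophages": 6_540_000,
    "Natural Killer Cells": 1_090_480,
    "CD4+ Naive T Cells": 4_905_000,
    "CD8+ Naive T Cells": 6_000_000,
    "Helper Type 1 Cells": 2_452_500,
    "Helper Type 2 Cells": 3_065_625,
}


@dataclass
class SimulationConfig:
    """Every parameter of a single run.

    Base event probabilities are per-tick and uncalibrated against wall
    time (the tick is abstract); they are exposed so that users can explore
    regimes.  ``growth_rate_cm_per_year`` is recorded as metadata only: no
    cell-size/tick-duration calibration is available to convert it into a
    per-tick duplication probability.
    """

    # Geometry and patient
    volume: float = 1e-4                  # simulated volume, mL
    block_size: float = 20.0              # block edge, micrometres (~one large cell)
    bmi: float = 22.0                     # kg/m^2; obese at >= 30
    # Initial composition
    densities: dict[str, float] = field(default_factory=lambda: dict(PHASE1_DENSITIES))
    count_overrides: dict[str, int] = field(default_factory=dict)
    phase: int = 1                        # 1 = verification, 2 = validation
    tumor_density: float = 2.5e7          # cells/mL, phase-2 initial tumor mass
    nk_mast_pdc_total: int = 30           # phase-1 NK+mast+pDC pool
    proportion_difference: int = 20       # phase-1 NK shift between arms
    perinephric_extra: int = 50           # obese-only extra T/DC/M1 agents
    # Schedule
    tumor_appearance_tick: int = 10
    therapy_start_tick: int = 15
    max_ticks: int = 500
    tumor_limit: int = 2000
    # Space scales (micrometres)
    first_cell_distance: float = 50.0
    effect_radius: float = 30.0
    # Movement perception is effectively unbounded at desk-scale volumes:
    # an agent that perceives a compatible target moves toward it wherever
    # it is, which is the interaction-as-perception paradigm.  Set a small
    # value to restrict sensing to a local neighbourhood.
    movement_perception_radius: float = 10_000.0
    angio_proximity: float = 50.0
    # Effect-field constants
    obese_effect_magnitude: int = 5
    alpha: float = 0.1                    # probability-modulation sensitivity
    kappa: float = 0.02                   # apoptosis-channel slope
    mild_growth_factor: float = 1.25
    access_boost: float = 2.0
    emission_table: Optional[dict[str, dict[str, int]]] = None
    # Base per-tick event probabilities.  The tick is abstract, so these
    # cannot be calibrated against wall time; they were chosen, once, so
    # that the verification protocol realises its intended qualitative
    # regime: the tumor establishes itself between its appearance and the
    # therapy tick, all three outcomes occur, lean kill attribution is
    # NK-led and obese kill attribution is led by cytotoxic T cells.
    base_duplication: float = 0.14
    base_kill: float = 0.6
    base_phagocytosis: float = 0.3
    base_proliferation: float = 0.02
    base_switch: float = 0.01
    base_treg_differentiation: float = 0.05
    base_angiogenesis: float = 0.5
    base_spawn: float = 0.3
    # Capacity guard for initial placement
    max_occupancy: int = 4
    # Metadata
    growth_rate_cm_per_year: float = 0.80
    seed: int = 0
    run_number: int = 0

    def validate(self) -> "SimulationConfig":
        if not 0 <= self.therapy_start_tick < self.max_ticks:
            raise ValueError("need max_ticks > therapy_start_tick >= 0")
        if self.tumor_appearance_tick < 0:
            raise ValueError("tumor_appearance_tick must be >= 0")
        if self.tumor_limit <= 0:
            raise ValueError("tumor_limit must be positive")
        if not 18.5 <= self.bmi <= 40.0:
            raise ValueError("BMI must be in [18.5, 40.0]")
        if self.volume <= 0 or self.block_size <= 0:
            raise ValueError("volume and block_size must be positive")
        if self.phase not in (1, 2):
            raise ValueError("phase must be 1 or 2")
        for name in (
            "base_duplication", "base_kill", "base_phagocytosis", "base_proliferation",
            "base_switch", "base_treg_differentiation", "base_angiogenesis", "base_spawn",
        ):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be a probability in [0, 1], got {p}")
        validate_density_table(self.densities)
        return self

    @property
    def obese(self) -> bool:
        return self.bmi >= OBESE_BMI_CUTOFF

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "SimulationConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown configuration fields: {sorted(unknown)}")
        return cls(**data).validate()


def preset(name: str, **overrides) -> SimulationConfig:
    """One of the shipped study configurations.

    ``phase1-lean`` / ``phase1-obese``: the verification protocol (volume
    1e-4 mL, tumor appearing at tick 10, therapy at tick 15, the NK:mast:pDC
    proportion rule, 50 perinephric extras in the obese arm).
    ``phase2-lean`` / ``phase2-obese``: the validation protocol (volume
    1e-5 mL, measured densities, tumor mass present and therapy starting
    at tick 0).
    """
    registry = {
        "phase1-lean": dict(
            phase=1, volume=1e-4, bmi=22.0,
            densities=dict(PHASE1_DENSITIES),
            count_overrides={"Dendritic Cells": 4},
            tumor_appearance_tick=10, therapy_start_tick=15,
        ),
        "phase1-obese": dict(
            phase=1, volume=1e-4, bmi=35.0,
            densities=dict(PHASE1_DENSITIES),
            count_overrides={"Dendritic Cells": 4},
            tumor_appearance_tick=10, therapy_start_tick=15,
        ),
        "phase2-lean": dict(
            phase=2, volume=1e-5, bmi=22.0,
            densities=dict(PHASE2_LEAN_DENSITIES),
            tumor_appearance_tick=0, therapy_start_tick=0,
            perinephric_extra=0,
        ),
        "phase2-obese": dict(
            phase=2, volume=1e-5, bmi=35.0,
            densities=dict(PHASE2_OBESE_DENSITIES),
            tumor_appearance_tick=0, therapy_start_tick=0,
            perinephric_extra=0,
        ),
    }
    if name not in registry:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(registry)}")
    params = dict(registry[name])
    params.update(overrides)
    return SimulationConfig(**params).validate()


def preset_names() -> list[str]:
    return ["phase1-lean", "phase1-obese", "phase2-lean", "phase2-obese"]


@dataclass
class RunResult:
    """Outcome and per-tick series of one run, with seed/run provenance."""

    outcome: str
    final_tick: int
    seed: int
    run_number: int
    cell_counts: dict[str, list[int]]  # category name -> one count per tick
    kill_counts: dict[str, list[int]]  # killer name -> cumulative kills per tick
    tumor_created: list[int]           # cumulative tumor cells ever created, per tick
    total_tumor_created: int

    def final_cell_counts(self) -> dict[str, int]:
        return {k: v[-1] for k, v in self.cell_counts.items()}

    def final_kill_counts(self) -> dict[str, int]:
        return {k: v[-1] for k, v in self.kill_counts.items()}


def classify_outcome(tumor_count: int, tick: int, config: SimulationConfig) -> Optional[str]:
    """Outcome label for the current census, or ``None`` to continue.

    Not evaluated before the tumor exists.  Precedence: remission (tumor
    eliminated) over proliferation (count at or past the limit) over
    inconclusive (tick limit passed).
    """
    if tick < config.tumor_appearance_tick:
        return None
    if tumor_count == 0:
        return "REMISSION"
    if tumor_count >= config.tumor_limit:
        return "PROLIFERATION"
    if tick > config.max_ticks:
        return "INCONCLUSIVE"
    return None


_HUNTERS = (AgentCategory.NK, AgentCategory.CD8_CYTOTOXIC, AgentCategory.CDC, AgentCategory.M1)
_MASS_SEEKERS = (
    AgentCategory.TREG,
    AgentCategory.CD4_HELPER1,
    AgentCategory.CD4_HELPER2,
    AgentCategory.MAST,
)


class Simulation:
    """Mutable state of one run; :func:`run` is the one-shot driver."""

    def __init__(self, config: SimulationConfig):
        self.config = config.validate()
        self.rng = np.random.default_rng(config.seed)
        self.env, self.roster, self.tumor = initialize_environment(config, self.rng)
        # One tumor antigen bit string per run; naive receptors are matched
        # against it by complementarity.
        self.antigen = ag.random_receptor(self.rng)
        self._next_agent_id = (max((a.id for a in self.roster), default=-1)) + 1
        self._next_tumor_id = len(self.tumor)
        self.total_tumor_created = len(self.tumor)
        self.kills: dict[str, int] = {c.value: 0 for c in ag.KILLER_CATEGORIES}
        self.kills[APOPTOSIS] = 0
        self.kill_records: list[KillRecord] = []
        self.cell_counts: dict[str, list[int]] = {c.value: [] for c in AgentCategory}
        self.kill_counts: dict[str, list[int]] = {k: [] for k in self.kills}
        self.tumor_created_series: list[int] = []
        self._emission_vectors = emission_table_to_vectors(config.emission_table)
        self._tick_global = zero_effects()

    # -- helpers -------------------------------------------------------

    def _new_agent_id(self) -> int:
        self._next_agent_id += 1
        return self._next_agent_id - 1

    def _spawn(self, category: AgentCategory) -> None:
        self.roster.append(
            ag.spawn_at_edge(self.env.side, category, self.rng, self._new_agent_id())
        )

    def _tumor_block_hash(self) -> dict[tuple[int, int, int], list[TumorCell]]:
        hash_: dict[tuple[int, int, int], list[TumorCell]] = {}
        for c in self.tumor:
            if c.alive:
                hash_.setdefault(c.position, []).append(c)
        return hash_

    def _adjacent_victim(
        self, position: tuple[int, int, int], block_hash
    ) -> Optional[TumorCell]:
        # Nearest living tumor cell in the closed 26-neighbourhood,
        # ties broken by lowest id.
        best = None
        best_key = None
        x, y, z = position
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dz in (-1, 0, 1):
                    for cell in block_hash.get((x + dx, y + dy, z + dz), ()):
                        if not cell.alive:
                            continue
                        d = ag.euclidean_um(position, cell.position, self.env.block_size)
                        key = (d, cell.id)
                        if best_key is None or key < best_key:
                            best, best_key = cell, key
        return best

    def _record_kill(self, record: KillRecord) -> None:
        self.kills[record.killer] += 1
        self.kill_records.append(record)

    def _aggregates(
        self, positions: np.ndarray, emitters_pos, emitters_vec, global_vector=None
    ) -> np.ndarray:
        return aggregate_effects_batch(
            emitters_pos,
            emitters_vec,
            positions,
            self.config.effect_radius,
            self.env.block_size,
            self._tick_global if global_vector is None else global_vector,
        )

    # -- one tick ------------------------------------------------------

    def step(self, tick: int) -> None:
        cfg = self.config
        immune = [a for a in self.roster if a.alive]

        # Phase 1: snapshot emissions and aggregate at start-of-tick positions.
        # Effects are only collected once the immunotherapy has started;
        # before that tick the field (including the environment's global
        # vector) is inert and the tumor grows under zero effects.
        epos, evec = [], []
        if tick >= cfg.therapy_start_tick:
            for a in immune:
                vec = self._emission_vectors.get(a.category.value)
                if vec is not None:
                    epos.append(a.position)
                    evec.append(vec)
        emitters_pos = np.asarray(epos, dtype=np.int64).reshape(-1, 3)
        emitters_vec = np.asarray(evec, dtype=np.int64).reshape(-1, N_CHANNELS)
        self._tick_global = (
            self.env.global_effects if tick >= cfg.therapy_start_tick else zero_effects()
        )
        immune_pos = np.asarray([a.position for a in immune], dtype=np.int64).reshape(-1, 3)
        agg = self._aggregates(immune_pos, emitters_pos, emitters_vec)

        living_tumor = [c for c in self.tumor if c.alive]
        tumor_tree = None
        tumor_snapshot_pos = None
        if living_tumor:
            tumor_snapshot_pos = np.asarray(
                [c.position for c in living_tumor], dtype=np.float64
            )
            tumor_tree = cKDTree(tumor_snapshot_pos)
        # Helper-2 agents that themselves perceive the tumor mass relay its
        # location to cytotoxic T cells near them (the attraction behaviour).
        helper2_pos = [
            a.position
            for a in immune
            if a.category is AgentCategory.CD4_HELPER2
            and tumor_tree is not None
            and float(tumor_tree.query(np.asarray(a.position, dtype=np.float64))[0])
            * self.env.block_size
            <= cfg.movement_perception_radius
        ]

        # Nearest-tumor perception for every immune agent, from the snapshot.
        if tumor_tree is not None and len(immune) > 0:
            near_d, near_i = tumor_tree.query(immune_pos.astype(np.float64))
            near_d = np.atleast_1d(near_d) * self.env.block_size
            near_i = np.atleast_1d(near_i)
        else:
            near_d = np.full(len(immune), np.inf)
            near_i = np.zeros(len(immune), dtype=int)

        # Phase 2: immune agents act (therapy gate).
        if tick >= cfg.therapy_start_tick and immune:
            block_hash = self._tumor_block_hash()
            centroid = None
            if tumor_snapshot_pos is not None:
                centroid = tuple(
                    int(v) for v in np.clip(
                        np.round(tumor_snapshot_pos.mean(axis=0)), 0, self.env.side - 1
                    )
                )
            for i in self.rng.permutation(len(immune)):
                agent = immune[int(i)]
                if not agent.alive:
                    continue
                self._act(agent, agg[int(i)], float(near_d[int(i)]),
                          tumor_snapshot_pos, int(near_i[int(i)]),
                          helper2_pos, centroid, block_hash, immune, tick,
                          (emitters_pos, emitters_vec))

        # Phase 3: tumor dynamics.
        if cfg.phase == 1 and tick == cfg.tumor_appearance_tick:
            pos = first_tumor_position(self.env, cfg.first_cell_distance)
            self.tumor.append(TumorCell(id=self._next_tumor_id, position=pos))
            self._next_tumor_id += 1
            self.total_tumor_created += 1
        if tick >= cfg.tumor_appearance_tick:
            self._tumor_phase(emitters_pos, emitters_vec, tick)

        # Phase 4: one angiogenesis attempt.
        self._angiogenesis(emitters_pos, emitters_vec)

        # Phase 5: blood access by BFS from angiogenic cells.
        access = compute_blood_access(self.tumor)
        for c in self.tumor:
            c.has_blood_access = c.angiogenic or (c.id in access)

        # Phase 6: census.
        self.roster = [a for a in self.roster if a.alive]
        self.tumor = [c for c in self.tumor if c.alive]
        counts = {c.value: 0 for c in AgentCategory}
        for a in self.roster:
            counts[a.category.value] += 1
        counts[AgentCategory.RCC_TUMOR.value] = len(self.tumor)
        counts[AgentCategory.BLOOD.value] = len(self.env.vessel_voxels)
        for name, series in self.cell_counts.items():
            series.append(counts[name])
        for name, series in self.kill_counts.items():
            series.append(self.kills[name])
        self.tumor_created_series.append(self.total_tumor_created)

    # -- per-category behaviour ---------------------------------------

    def _act(self, agent, eff, near_dist, tumor_pos, near_idx,
             helper2_pos, centroid, block_hash, immune, tick, emitters) -> None:
        cfg = self.config
        cat = agent.category
        side = self.env.side
        perceives = near_dist <= cfg.movement_perception_radius
        target = (
            tuple(int(v) for v in tumor_pos[near_idx]) if (perceives and tumor_pos is not None)
            else None
        )

        if cat is AgentCategory.NEUTROPHIL:
            return  # dummy agents: no action, no effects

        if cat in (AgentCategory.NK, AgentCategory.CD8_CYTOTOXIC):
            if cat is AgentCategory.CD8_CYTOTOXIC:
                if not ag.cytotoxic_apoptosis(
                    agent, int(eff[CHANNEL_INDEX["Cytotoxic T Cell Apoptosis"]]),
                    self.rng, cfg.kappa,
                ):
                    return
                if target is None and centroid is not None and helper2_pos:
                    # Helper-2 attraction: cytotoxic T cells near a helper 2
                    # acquire the tumor centroid as target this tick.
                    for hp in helper2_pos:
                        if ag.euclidean_um(agent.position, hp, self.env.block_size) \
                                <= cfg.movement_perception_radius:
                            target = centroid
                            break
            if target is not None:
                agent.position = ag.move_toward(agent.position, target, side)
            else:
                agent.position = ag.random_step(agent.position, side, self.rng)
            victim = self._adjacent_victim(agent.position, block_hash)
            if victim is not None:
                channel = (
                    "Natural Killer Cell Kill Rate" if cat is AgentCategory.NK
                    else "Cytotoxic T Cell Kill Rate"
                )
                record = ag.attempt_kill(
                    agent, victim, int(eff[CHANNEL_INDEX[channel]]),
                    cfg.base_kill, self.rng, tick, cfg.alpha,
                )
                if record is not None:
                    block_hash[victim.position].remove(victim)
                    self._record_kill(record)
            if cat is AgentCategory.CD8_CYTOTOXIC:
                child = ag.proliferate(
                    agent, int(eff[CHANNEL_INDEX["Cytotoxic T Cell Proliferation"]]),
                    cfg.base_proliferation, self.rng, side, self._next_agent_id,
                    cfg.alpha,
                )
                if child is not None:
                    child.id = self._new_agent_id()
                    self.roster.append(child)
            return

        if cat in (AgentCategory.CDC, AgentCategory.M1):
            if target is not None:
                agent.position = ag.move_toward(agent.position, target, side)
            else:
                agent.position = ag.random_step(agent.position, side, self.rng)
            victim = self._adjacent_victim(agent.position, block_hash)
            if victim is not None:
                if cat is AgentCategory.CDC:
                    record = ag.attempt_phagocytosis(
                        agent, victim,
                        int(eff[CHANNEL_INDEX["Dendritic Cell Phagocytosis"]]),
                        cfg.base_phagocytosis, self.rng, tick, cfg.alpha,
                    )
                else:
                    # M1 phagocytosis has no dedicated channel; unmodulated.
                    record = ag._attempt_contact_elimination(
                        agent, victim, 0, cfg.base_phagocytosis, tick, self.rng, cfg.alpha
                    )
                if record is not None:
                    block_hash[victim.position].remove(victim)
                    self._record_kill(record)
            self._try_activate_naive(agent, cat, immune, emitters)
            if cat is AgentCategory.M1:
                agent.category = ag.phenotype_switch(
                    agent, int(eff[CHANNEL_INDEX["M1 Macrophage Mutation"]]),
                    cfg.base_switch, self.rng, cfg.alpha,
                )
            return

        if cat is AgentCategory.M2:
            agent.category = ag.phenotype_switch(
                agent, int(eff[CHANNEL_INDEX["M2 Macrophage Mutation"]]),
                cfg.base_switch, self.rng, cfg.alpha,
            )
            agent.position = ag.random_step(agent.position, side, self.rng)
            return

        if cat in _MASS_SEEKERS:
            if target is not None:
                agent.position = ag.move_toward(agent.position, target, side)
            else:
                agent.position = ag.random_step(agent.position, side, self.rng)
            # Recruiting new agents at the edge requires only that the tumor
            # mass exists (the therapy gate already applies to this phase).
            if centroid is not None:
                if cat is AgentCategory.CD4_HELPER1:
                    if self.rng.random() < cfg.base_spawn:
                        self._spawn(AgentCategory.CDC)
                    if self.rng.random() < cfg.base_spawn:
                        self._spawn(AgentCategory.M1)
                elif cat is AgentCategory.CD4_HELPER2:
                    if self.rng.random() < cfg.base_spawn:
                        self._spawn(AgentCategory.M1)
                elif cat is AgentCategory.MAST:
                    if self.rng.random() < cfg.base_spawn:
                        self._spawn(AgentCategory.CDC)
            if cat in (AgentCategory.CD4_HELPER1, AgentCategory.CD4_HELPER2):
                effect = (
                    int(eff[CHANNEL_INDEX["Helper 1 T Proliferation"]])
                    if cat is AgentCategory.CD4_HELPER1 else 0
                )
                child = ag.proliferate(
                    agent, effect, cfg.base_proliferation, self.rng, side,
                    self._next_agent_id, cfg.alpha,
                )
                if child is not None:
                    child.id = self._new_agent_id()
                    self.roster.append(child)
            return

        if cat is AgentCategory.PDC:
            agent.position = ag.random_step(agent.position, side, self.rng)
            if centroid is not None and self.rng.random() < cfg.base_spawn:
                self._spawn(AgentCategory.NK)
            return

        if cat is AgentCategory.CD4_NAIVE:
            if ag.treg_differentiation(
                agent, int(eff[CHANNEL_INDEX["Regulatory T Differentiation"]]),
                cfg.base_treg_differentiation, self.rng, cfg.alpha,
            ):
                agent.category = AgentCategory.TREG
                agent.receptor = None
            else:
                agent.position = ag.random_step(agent.position, side, self.rng)
            return

        if cat is AgentCategory.CD8_NAIVE:
            agent.position = ag.random_step(agent.position, side, self.rng)
            return

    def _try_activate_naive(self, activator, cat, immune, emitters) -> None:
        """cDC / M1 agents try to activate the closest naive T cell.

        Conventional DCs target either naive kind; M1 macrophages target
        CD4 naives.  The attempt uses bit-string recognition against the
        run's tumor antigen, modulated (CD8 only) by the Cytotoxic T Cell
        Activation channel aggregated at the naive cell's position.
        """
        cfg = self.config
        kinds = (
            (AgentCategory.CD4_NAIVE, AgentCategory.CD8_NAIVE)
            if cat is AgentCategory.CDC else (AgentCategory.CD4_NAIVE,)
        )
        naives = [a for a in immune if a.alive and a.category in kinds]
        chosen = ag.perceive_nearest(
            activator, naives, cfg.movement_perception_radius, self.env.block_size
        )
        if chosen is None:
            return
        if chosen.category is AgentCategory.CD8_NAIVE:
            # Aggregated at the naive cell's position, from the tick's
            # start-of-tick emission snapshot.
            effect = int(
                self._aggregates(
                    np.asarray([chosen.position], dtype=np.int64), *emitters
                )[0][CHANNEL_INDEX["Cytotoxic T Cell Activation"]]
            )
        else:
            effect = 0
        activated = ag.attempt_antigen_recognition(
            chosen.receptor, self.antigen, effect, self.rng, alpha=cfg.alpha
        )
        if chosen.category is AgentCategory.CD4_NAIVE:
            if activated:
                chosen.category = ag.differentiate_cd4(chosen, self.rng)
                chosen.receptor = None
        else:
            replacement = ag.cd8_naive_recycle(
                chosen, activated, self.env.side, self.rng, self._next_agent_id
            )
            if replacement is not chosen:
                self._next_agent_id += 1
                self.roster.append(replacement)

    # -- tumor and vasculature phases ---------------------------------

    def _tumor_phase(self, emitters_pos, emitters_vec, tick) -> None:
        cfg = self.config
        living = [c for c in self.tumor if c.alive]
        if not living:
            return
        positions = np.asarray([c.position for c in living], dtype=np.int64)
        agg = self._aggregates(positions, emitters_pos, emitters_vec)
        apo_eff = agg[:, CHANNEL_INDEX["Tumor Apoptosis"]]
        growth_eff = agg[:, CHANNEL_INDEX["Tumor Growth"]]

        # Apoptosis first: only a positive aggregated effect can kill.
        p_apo = np.clip(cfg.kappa * np.maximum(apo_eff, 0), 0.0, 1.0)
        apoptose = self.rng.random(len(living)) < p_apo
        for cell, dies in zip(living, apoptose):
            if dies:
                cell.alive = False
                self._record_kill(KillRecord(APOPTOSIS, tick, cell.id))

        # Survivors may duplicate; doubled chance at non-negative growth
        # effect, mild improvement otherwise, boosted again by blood access.
        survivors = [c for c, dies in zip(living, apoptose) if not dies]
        if not survivors:
            return
        factor = np.where(
            growth_eff[~apoptose] >= 0, 2.0, cfg.mild_growth_factor
        )
        boost = np.asarray(
            [cfg.access_boost if c.has_blood_access else 1.0 for c in survivors]
        )
        p_dup = np.clip(cfg.base_duplication * factor * boost, 0.0, 1.0)
        duplicate = self.rng.random(len(survivors)) < p_dup
        n_new = int(duplicate.sum())
        if n_new == 0:
            return
        parents = np.asarray(
            [c.position for c, d in zip(survivors, duplicate) if d], dtype=np.int64
        )
        offsets = self.rng.integers(-1, 2, size=(n_new, 3))
        children = np.clip(parents + offsets, 0, self.env.side - 1)
        for row in children:
            self.tumor.append(
                TumorCell(id=self._next_tumor_id, position=(int(row[0]), int(row[1]), int(row[2])))
            )
            self._next_tumor_id += 1
            self.total_tumor_created += 1

    def _angiogenesis(self, emitters_pos, emitters_vec) -> None:
        cfg = self.config
        living = [c for c in self.tumor if c.alive]
        if not living:
            return
        # The angiogenesis channel concerns the tumor as a whole: aggregate
        # it at the tumor centroid.
        centroid = np.clip(
            np.round(np.asarray([c.position for c in living]).mean(axis=0)),
            0, self.env.side - 1,
        ).astype(np.int64)
        angio_eff = int(
            self._aggregates(centroid[None, :], emitters_pos, emitters_vec)[0][
                CHANNEL_INDEX["Angiogenesis"]
            ]
        )
        result = try_angiogenesis(
            living, self.env.vessel_voxels, angio_eff, cfg.angio_proximity,
            cfg.base_angiogenesis, self.rng, self.env.block_size, cfg.alpha,
        )
        if result is not None:
            _, path = result
            self.env.vessel_voxels.update(path.voxels)

    # -- driver --------------------------------------------------------

    def run(self) -> RunResult:
        tick = 0
        while True:
            self.step(tick)
            outcome = classify_outcome(len(self.tumor), tick, self.config)
            if outcome is not None:
                return RunResult(
                    outcome=outcome,
                    final_tick=tick,
                    seed=self.config.seed,
                    run_number=self.config.run_number,
                    cell_counts=self.cell_counts,
                    kill_counts=self.kill_counts,
                    tumor_created=self.tumor_created_series,
                    total_tumor_created=self.total_tumor_created,
                )
            tick += 1


def run(config: SimulationConfig) -> RunResult:
    """Execute one full run; bit-identical for identical configurations."""
    return Simulation(config).run()
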