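"""Per-category agent behaviours: perception, movement, activation, kills."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from oncolattice.agents import (
    AgentCategory,
    BioAgent,
    attempt_antigen_recognition,
    attempt_kill,
    attempt_phagocytosis,
    cd8_naive_recycle,
    chebyshev,
    complementarity,
    cytotoxic_apoptosis,
    differentiate_cd4,
    move_toward,
    perceive_nearest,
    phenotype_switch,
    proliferate,
    random_receptor,
    random_step,
    spawn_at_edge,
    treg_differentiation,
)
from oncolattice.tumor import TumorCell


def _agent(id=0, category=AgentCategory.NK, position=(0, 0, 0), receptor=None):
    return BioAgent(id, category, position, receptor=receptor)


class TestBioAgent:
    def test_naive_t_cells_require_8_bit_receptor(self):
        with pytest.raises(ValueError):
            _agent(category=AgentCategory.CD4_NAIVE)
        with pytest.raises(ValueError):
            _agent(category=AgentCategory.CD8_NAIVE, receptor="0101")
        ok = _agent(category=AgentCategory.CD8_NAIVE, receptor="01010101")
        assert ok.receptor == "01010101"

    def test_non_naive_categories_reject_receptors(self):
        with pytest.raises(ValueError):
            _agent(category=AgentCategory.NK, receptor="01010101")


class TestPerception:
    def test_empty_candidates(self):
        assert perceive_nearest(_agent(), [], 100, 10) is None

    def test_in_range_candidate_found(self):
        cand = _agent(id=1, position=(4, 0, 0))  # 40 um away at 10 um blocks
        assert perceive_nearest(_agent(), [cand], 100, 10) is cand

    def test_out_of_range_ignored(self):
        cand = _agent(id=1, position=(11, 0, 0))
        assert perceive_nearest(_agent(), [cand], 100, 10) is None

    def test_tie_broken_by_lowest_id(self):
        a = _agent(id=7, position=(3, 0, 0))
        b = _agent(id=3, position=(0, 3, 0))
        assert perceive_nearest(_agent(), [a, b], 100, 10).id == 3


class TestMovement:
    @pytest.mark.parametrize(
        "pos,target,expected",
        [
            ((5, 5, 5), (5, 5, 5), (5, 5, 5)),
            ((0, 0, 0), (3, 0, 0), (1, 0, 0)),
            ((2, 9, 4), (0, 0, 9), (1, 8, 5)),  # per-axis sign rule
        ],
    )
    def test_one_chebyshev_step(self, pos, target, expected):
        assert move_toward(pos, target, side=10) == expected

    def test_outside_cube_raises(self):
        with pytest.raises(ValueError):
            move_toward((0, 0, 0), (10, 0, 0), side=10)

    @given(
        st.tuples(*[st.integers(0, 9)] * 3),
        st.tuples(*[st.integers(0, 9)] * 3),
    )
    def test_chebyshev_distance_never_increases(self, pos, target):
        new = move_toward(pos, target, side=10)
        d0, d1 = chebyshev(pos, target), chebyshev(new, target)
        assert all(0 <= c < 10 for c in new)
        if d0 > 0:
            assert d1 == d0 - 1
        else:
            assert new == pos

    def test_random_step_stays_inside(self, rng):
        pos = (0, 9, 5)
        for _ in range(50):
            pos = random_step(pos, 10, rng)
            assert all(0 <= c < 10 for c in pos)


class TestAntigenRecognition:
    def test_full_complement_always_activates(self, rng):
        assert attempt_antigen_recognition("00000000", "11111111", 0, rng)

    def test_below_threshold_never_activates(self, rng):
        for _ in range(100):
            assert not attempt_antigen_recognition("01010101", "01010101", 0, rng)

    def test_bad_length_raises(self, rng):
        with pytest.raises(ValueError):
            attempt_antigen_recognition("0101", "01010101", 0, rng)

    def test_six_bit_complement_activates_at_half_rate(self, rng):
        receptor, antigen = "00000000", "11111100"  # c = 6
        assert complementarity(receptor, antigen) == 6
        hits = sum(
            attempt_antigen_recognition(receptor, antigen, 0, rng) for _ in range(10_000)
        )
        assert 0.48 <= hits / 10_000 <= 0.52

    def test_positive_activation_effect_raises_rate(self, rng):
        receptor, antigen = "00000000", "11111100"
        hits = sum(
            attempt_antigen_recognition(receptor, antigen, 5, rng) for _ in range(10_000)
        )
        assert 0.72 <= hits / 10_000 <= 0.78  # 0.5 * 1.5


class TestDifferentiation:
    def test_cd4_differentiation_is_balanced(self, rng):
        agent = _agent(category=AgentCategory.CD4_NAIVE, receptor="00001111")
        outcomes = [differentiate_cd4(agent, rng) for _ in range(10_000)]
        frac = outcomes.count(AgentCategory.CD4_HELPER1) / len(outcomes)
        assert 0.48 <= frac <= 0.52
        assert AgentCategory.CD4_NAIVE not in outcomes

    def test_cd4_differentiation_reproducible_under_seed(self):
        agent = _agent(category=AgentCategory.CD4_NAIVE, receptor="00001111")
        a = differentiate_cd4(agent, np.random.default_rng(99))
        b = differentiate_cd4(agent, np.random.default_rng(99))
        assert a == b

    def test_wrong_category_raises(self, rng):
        with pytest.raises(ValueError):
            differentiate_cd4(_agent(category=AgentCategory.NK), rng)

    def test_treg_conversion_blocked_by_strong_suppression(self, rng):
        agent = _agent(category=AgentCategory.CD4_NAIVE, receptor="00001111")
        # effect -20 at alpha 0.1 drives the multiplier to below zero
        assert not any(
            treg_differentiation(agent, -20, 0.02, rng) for _ in range(200)
        )


class TestPhenotypeSwitch:
    def test_wrong_category_raises(self, rng):
        with pytest.raises(ValueError):
            phenotype_switch(_agent(category=AgentCategory.NK), 0, 0.01, rng)

    def test_switch_directions(self, rng):
        m1 = _agent(category=AgentCategory.M1)
        m2 = _agent(category=AgentCategory.M2)
        # certain switch at base rate 1
        assert phenotype_switch(m1, 0, 1.0, rng) is AgentCategory.M2
        assert phenotype_switch(m2, 0, 1.0, rng) is AgentCategory.M1
        # impossible switch at base rate 0
        assert phenotype_switch(m1, 0, 0.0, rng) is AgentCategory.M1


class TestKillAttempts:
    def test_non_adjacent_victim_raises(self, rng):
        killer = _agent(category=AgentCategory.NK, position=(0, 0, 0))
        victim = TumorCell(id=9, position=(3, 0, 0))
        with pytest.raises(ValueError):
            attempt_kill(killer, victim, 0, 0.5, rng)

    def test_certain_kill_emits_record_with_killer_category(self, rng):
        killer = _agent(id=4, category=AgentCategory.CD8_CYTOTOXIC, position=(1, 1, 1))
        victim = TumorCell(id=9, position=(1, 1, 2))
        record = attempt_kill(killer, victim, 0, 1.0, rng, tick=5)
        assert record is not None
        assert record.killer == "CD8_CYTOTOXIC"
        assert record.victim_id == 9
        assert record.tick == 5
        assert not victim.alive

    def test_strong_negative_effect_clamps_to_no_kill(self, rng):
        killer = _agent(category=AgentCategory.NK, position=(0, 0, 0))
        for _ in range(100):
            victim = TumorCell(id=1, position=(0, 0, 1))
            assert attempt_kill(killer, victim, -50, 0.5, rng) is None
            assert victim.alive

    def test_non_killer_category_rejected(self, rng):
        with pytest.raises(ValueError):
            attempt_kill(
                _agent(category=AgentCategory.MAST), TumorCell(1, (0, 0, 0)), 0, 0.5, rng
            )

    def test_phagocytosis_mirrors_kill_contract(self, rng):
        dc = _agent(category=AgentCategory.CDC, position=(2, 2, 2))
        victim = TumorCell(id=3, position=(2, 2, 2))  # same block counts as contact
        record = attempt_phagocytosis(dc, victim, 0, 1.0, rng)
        assert record is not None and record.killer == "CDC"
        with pytest.raises(ValueError):
            attempt_phagocytosis(dc, TumorCell(4, (9, 9, 9)), 0, 1.0, rng)


class TestProliferation:
    def test_zero_base_never_proliferates(self, rng):
        agent = _agent(category=AgentCategory.CD8_CYTOTOXIC, position=(5, 5, 5))
        assert all(
            proliferate(agent, 50, 0.0, rng, 10, new_id=1) is None for _ in range(100)
        )

    def test_proliferation_rate_concentrates_at_base(self, rng):
        agent = _agent(category=AgentCategory.CD4_HELPER1, position=(5, 5, 5))
        n = 10_000
        children = sum(
            proliferate(agent, 0, 0.05, rng, 10, new_id=1) is not None for _ in range(n)
        )
        assert 0.045 <= children / n <= 0.055

    def test_child_placed_in_closed_neighbourhood(self, rng):
        agent = _agent(category=AgentCategory.CD8_CYTOTOXIC, position=(0, 0, 0))
        for _ in range(100):
            child = proliferate(agent, 0, 1.0, rng, 10, new_id=2)
            assert child is not None
            assert chebyshev(child.position, agent.position) <= 1
            assert all(0 <= c < 10 for c in child.position)

    def test_non_proliferating_category_rejected(self, rng):
        with pytest.raises(ValueError):
            proliferate(_agent(category=AgentCategory.NK), 0, 0.5, rng, 10, new_id=1)


class TestEdgeSpawning:
    def test_spawn_lies_on_a_face(self, rng):
        for _ in range(50):
            agent = spawn_at_edge(12, AgentCategory.NK, rng, new_id=0)
            assert any(c in (0, 11) for c in agent.position)

    def test_all_six_faces_reached(self, rng):
        faces = set()
        for _ in range(1000):
            x, y, z = spawn_at_edge(12, AgentCategory.CDC, rng, new_id=0).position
            for axis, c in enumerate((x, y, z)):
                if c == 0:
                    faces.add((axis, 0))
                if c == 11:
                    faces.add((axis, 1))
        assert len(faces) == 6

    def test_non_recruited_category_rejected(self, rng):
        with pytest.raises(ValueError):
            spawn_at_edge(12, AgentCategory.NEUTROPHIL, rng, new_id=0)


class TestCytotoxicApoptosisAndRecycle:
    def test_nonpositive_effect_always_survives(self, rng):
        agent = _agent(category=AgentCategory.CD8_CYTOTOXIC)
        assert all(cytotoxic_apoptosis(agent, e, rng) for e in (0, -5) for _ in range(100))

    def test_large_effect_is_certain_death(self, rng):
        agent = _agent(category=AgentCategory.CD8_CYTOTOXIC)
        assert not cytotoxic_apoptosis(agent, 100, rng)
        assert not agent.alive

    def test_successful_recycle_becomes_cytotoxic_in_place(self, rng):
        agent = _agent(category=AgentCategory.CD8_NAIVE, position=(3, 3, 3), receptor="11110000")
        out = cd8_naive_recycle(agent, True, 10, rng, new_id=99)
        assert out is agent
        assert agent.category is AgentCategory.CD8_CYTOTOXIC
        assert agent.position == (3, 3, 3)
        assert agent.receptor is None

    def test_failed_recycle_conserves_naive_count(self, rng):
        agent = _agent(id=1, category=AgentCategory.CD8_NAIVE, position=(3, 3, 3), receptor="11110000")
        fresh = cd8_naive_recycle(agent, False, 10, rng, new_id=99)
        assert not agent.alive
        assert fresh.category is AgentCategory.CD8_NAIVE
        assert fresh.id == 99
        assert fresh.position != (3, 3, 3)
        assert len(fresh.receptor) == 8

    def test_failed_recycle_reproducible_under_seed(self):
        def recycle():
            agent = _agent(
                id=1, category=AgentCategory.CD8_NAIVE, position=(3, 3, 3), receptor="11110000"
            )
            return cd8_naive_recycle(agent, False, 10, np.random.default_rng(5), new_id=2)

        a, b = recycle(), recycle()
        assert a.position == b.position and a.receptor == b.receptor


def test_random_receptor_is_8_bits(rng):
    r = random_receptor(rng)
    assert len(r) == 8 and set(r) <= {"0", "1"}
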