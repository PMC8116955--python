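"""Grid construction, density arithmetic, and BMI-dependent initialization."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, strategies as st

from oncolattice.agents import AgentCategory
from oncolattice.effects import CHANNEL_INDEX
from oncolattice.engine import SimulationConfig, preset
from oncolattice.environment import (
    IMMUNE_TYPES,
    apply_obesity_adjustments,
    density_to_count,
    erdag_convert,
    grid_side_from_volume,
    initial_counts,
    initialize_environment,
    obese_global_effects,
    phase1_proportion_counts,
    validate_density_table,
)


class TestGridSide:
    def test_validation_volume_side(self):
        # 1e-5 mL -> 215.44 um edge -> 22 blocks of 10 um
        assert grid_side_from_volume(1e-5, 10.0) == 22

    def test_minimum_side_floor(self):
        assert grid_side_from_volume(1.0, 10_000.0) == 2

    def test_cube_root_scaling(self):
        # 8e-6 mL -> 200 um edge -> side 20; x8 volume doubles the side
        assert grid_side_from_volume(8e-6, 10.0) == 20
        assert grid_side_from_volume(6.4e-5, 10.0) == 2 * grid_side_from_volume(8e-6, 10.0)

    def test_nonpositive_volume_raises(self):
        with pytest.raises(ValueError):
            grid_side_from_volume(0.0, 10.0)


class TestDensityToCount:
    @pytest.mark.parametrize(
        "density,volume,expected",
        [
            (160_000, 1e-4, 16),     # NK, verification table
            (3_271_430, 1e-5, 32),   # NK lean, validation table (32.71 truncates)
            (1_090_480, 1e-5, 10),   # NK obese, validation table
            (142_800, 1e-5, 1),      # Treg lean (1.428 truncates)
            (6_000_000, 1e-5, 60),   # cytotoxic T lean
            (21_716_150, 1e-5, 217), # neutrophils
            (0, 1e-4, 0),
        ],
    )
    def test_tabulated_cells(self, density, volume, expected):
        assert density_to_count(density, volume) == expected

    @given(
        st.integers(0, 10**8),
        st.sampled_from([1e-6, 1e-5, 1e-4, 1e-3, 2.5e-5, 7e-6]),
    )
    def test_truncation_matches_exact_rational_oracle(self, density, volume):
        exact = Fraction(density) * Fraction(volume)  # float volume taken exactly
        assert density_to_count(density, volume) == math.floor(exact)


class TestErdagConversion:
    def test_identity_at_unit_diameter(self):
        assert erdag_convert(123.0, 1.0) == 123.0

    def test_linear_in_areal_density(self):
        assert erdag_convert(84.0, 0.014) * 2 == erdag_convert(168.0, 0.014)

    def test_recovers_validation_cytotoxic_density(self):
        # 84 cells/mm^2 at 14 um cell diameter -> 6,000 cells/mm^3 = 6e6 cells/mL
        volumetric = erdag_convert(84.0, 0.014)
        assert volumetric == pytest.approx(6000.0)
        assert volumetric * 1e3 == pytest.approx(6_000_000.0)

    def test_nonpositive_diameter_raises(self):
        with pytest.raises(ValueError):
            erdag_convert(84.0, 0.0)


class TestObesityAdjustments:
    def test_quarter_increase_matches_tabulated_cells(self):
        lean = {name: 0.0 for name in IMMUNE_TYPES}
        lean.update(
            {
                "Cytotoxic T Cells": 6_000_000,
                "Dendritic Cells": 1_173_850,
                "Neutrophils": 21_716_150,
                "Regulatory T Cells": 142_800,
            }
        )
        obese = apply_obesity_adjustments(lean, special_ratios={})
        assert obese["Cytotoxic T Cells"] == 7_500_000
        assert obese["Dendritic Cells"] == 1_467_312  # 1,467,312.5 truncates
        assert obese["Regulatory T Cells"] == 178_500
        assert obese["Neutrophils"] == 21_716_150  # not in the increased set

    def test_measured_ratios_take_precedence(self):
        lean = {name: 1_000_000.0 for name in IMMUNE_TYPES}
        obese = apply_obesity_adjustments(lean)
        assert obese["Plasmacytoid Dendritic Cells"] == 1_210_000  # +21%
        assert obese["Natural Killer Cells"] == 670_000  # -33%

    def test_unknown_type_raises(self):
        lean = {name: 0.0 for name in IMMUNE_TYPES}
        with pytest.raises(ValueError):
            apply_obesity_adjustments(lean, increased_types={"Basophils"})


class TestPhase1Proportions:
    def test_lean_and_obese_patterns(self):
        assert phase1_proportion_counts(30, 20, obese=False) == (20, 5, 5)
        assert phase1_proportion_counts(30, 20, obese=True) == (0, 15, 15)

    def test_zero_difference_makes_arms_identical(self):
        assert phase1_proportion_counts(30, 0, False) == phase1_proportion_counts(30, 0, True)

    def test_totals_match_between_arms(self):
        for d in (0, 2, 10, 20):
            lean = phase1_proportion_counts(30, d, False)
            obese = phase1_proportion_counts(30, d, True)
            assert sum(lean) == sum(obese) == 30

    def test_odd_difference_rejected(self):
        with pytest.raises(ValueError):
            phase1_proportion_counts(30, 15, False)


class TestDensityTableValidation:
    def test_missing_and_negative_entries_rejected(self):
        with pytest.raises(ValueError):
            validate_density_table({"Mast Cells": 1.0})
        bad = {name: 1.0 for name in IMMUNE_TYPES}
        bad["Mast Cells"] = -1.0
        with pytest.raises(ValueError):
            validate_density_table(bad)


class TestInitialCounts:
    def test_verification_preset_applies_proportion_rule(self):
        config = preset("phase1-lean")
        counts = initial_counts(config)
        # the density alone gives 16 NK; the proportion rule restates the pool
        assert density_to_count(config.densities["Natural Killer Cells"], config.volume) == 16
        assert counts["Natural Killer Cells"] == 20
        assert counts["Mast Cells"] == 5
        assert counts["Plasmacytoid Dendritic Cells"] == 5
        assert counts["Dendritic Cells"] == 4  # tabulated count override

    def test_nk_mast_pdc_pool_equal_between_arms(self):
        lean = initial_counts(preset("phase1-lean"))
        obese = initial_counts(preset("phase1-obese"))
        pool = ("Natural Killer Cells", "Mast Cells", "Plasmacytoid Dendritic Cells")
        assert sum(lean[k] for k in pool) == sum(obese[k] for k in pool)
        assert sum(lean.values()) == sum(obese.values())

    def test_validation_presets_reproduce_tabulated_counts(self):
        lean = initial_counts(preset("phase2-lean"))
        obese = initial_counts(preset("phase2-obese"))
        assert lean["Cytotoxic T Cells"] == 60 and obese["Cytotoxic T Cells"] == 75
        assert lean["Natural Killer Cells"] == 32 and obese["Natural Killer Cells"] == 10
        assert lean["Neutrophils"] == 217 == obese["Neutrophils"]
        assert lean["Helper Type 2 Cells"] == 24 and obese["Helper Type 2 Cells"] == 30


class TestGlobalEffects:
    def test_obese_vector_has_exactly_four_channels(self):
        vec = obese_global_effects(5)
        nonzero = {name for name, i in CHANNEL_INDEX.items() if vec[i] != 0}
        assert nonzero == {
            "Natural Killer Cell Kill Rate",
            "Regulatory T Differentiation",
            "M2 Macrophage Mutation",
            "M1 Macrophage Mutation",
        }
        assert vec[CHANNEL_INDEX["M2 Macrophage Mutation"]] == 5
        assert vec[CHANNEL_INDEX["M1 Macrophage Mutation"]] == -5
        assert vec[CHANNEL_INDEX["Natural Killer Cell Kill Rate"]] == -5


class TestInitializeEnvironment:
    def test_lean_environment_has_zero_global_effects(self, rng):
        env, roster, tumor = initialize_environment(preset("phase1-lean"), rng)
        assert not env.obese
        assert not env.global_effects.any()
        assert tumor == []  # phase 1: the tumor appears later

    def test_obese_run_adds_exactly_the_perinephric_extras(self):
        lean_cfg, obese_cfg = preset("phase1-lean"), preset("phase1-obese")
        _, lean_roster, _ = initialize_environment(lean_cfg, np.random.default_rng(0))
        _, obese_roster, _ = initialize_environment(obese_cfg, np.random.default_rng(0))
        assert len(obese_roster) == len(lean_roster) + obese_cfg.perinephric_extra

    def test_same_seed_reproduces_the_roster(self):
        config = preset("phase1-obese")
        _, r1, _ = initialize_environment(config, np.random.default_rng(3))
        _, r2, _ = initialize_environment(config, np.random.default_rng(3))
        assert [(a.category, a.position, a.receptor) for a in r1] == [
            (a.category, a.position, a.receptor) for a in r2
        ]

    def test_all_agents_and_voxels_inside_cube(self, rng):
        env, roster, tumor = initialize_environment(preset("phase2-obese"), rng)
        assert all(env.contains(a.position) for a in roster)
        assert all(env.contains(v) for v in env.vessel_voxels | env.fat_voxels)
        assert all(env.contains(c.position) for c in tumor)
        assert len(tumor) == 250  # 2.5e7 cells/mL x 1e-5 mL

    def test_phase2_tumor_clump_is_contiguous(self, rng):
        from oncolattice.tumor import compute_blood_access

        _, _, tumor = initialize_environment(preset("phase2-lean"), rng)
        tumor[0].angiogenic = True
        assert compute_blood_access(tumor) == {c.id for c in tumor}

    def test_capacity_guard(self):
        config = preset("phase2-lean", max_occupancy=0)
        with pytest.raises(ValueError):
            initialize_environment(config, np.random.default_rng(0))
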