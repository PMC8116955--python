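"""CSV output streams, batch experiments, sweeps, summaries, and fixtures.

Each run produces three CSV streams: the per-tick cell census, the per-tick
cumulative kill counts by eliminator, and a single-record outcome file.
Every file carries the run's random seed and run number as '#'-prefixed
metadata lines, so any run can be repeated exactly.  Batch experiments
execute many seeded runs (optionally over a Cartesian parameter sweep) and
combine the per-run outcomes into one CSV; summaries tally outcomes and
average kill attribution and final censuses per experimental arm.
"""

from __future__ import annotations

import dataclasses
import io
import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .agents import AgentCategory, APOPTOSIS, KILLER_CATEGORIES
from .engine import RunResult, SimulationConfig, preset, run
from .environment import IMMUNE_TYPES

# Seed policy: run seeds are base_seed + run_index, with a distinct offset
# for the obese arm so the two arms of an experiment never share seeds.
OBESE_ARM_OFFSET = 1_000_000


def _write_with_metadata(df: pd.DataFrame, result: RunResult, path) -> None:
    buf = io.StringIO()
    buf.write(f"# seed = {result.seed}\n# run_number = {result.run_number}\n")
    df.to_csv(buf, index=False)
    Path(path).write_text(buf.getvalue())


def read_csv_with_metadata(path) -> tuple[pd.DataFrame, dict[str, int]]:
    """Read one of the output streams back, returning (frame, metadata)."""
    meta: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line.lstrip("#").partition("=")
            meta[key.strip()] = int(value)
    return pd.read_csv(path, comment="#"), meta


def write_cell_counts_csv(result: RunResult, path) -> None:
    """Per-tick number of agents by category: one row per tick."""
    df = pd.DataFrame({"tick": range(result.final_tick + 1)} | result.cell_counts)
    _write_with_metadata(df, result, path)


def write_kill_counts_csv(result: RunResult, path) -> None:
    """Per-tick cumulative tumor eliminations by killer category."""
    df = pd.DataFrame({"tick": range(result.final_tick + 1)} | result.kill_counts)
    _write_with_metadata(df, result, path)


def write_outcome_csv(result: RunResult, path) -> None:
    """Single-record outcome file for one run."""
    df = pd.DataFrame(
        [
            {
                "outcome": result.outcome.lower(),
                "final_tick": result.final_tick,
                "seed": result.seed,
                "run_number": result.run_number,
            }
        ]
    )
    _write_with_metadata(df, result, path)


def write_run(result: RunResult, out_dir) -> dict[str, Path]:
    """Write the three streams of one run into a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "cell_counts": out / "cell_counts.csv",
        "kill_counts": out / "kill_counts.csv",
        "outcome": out / "outcome.csv",
    }
    write_cell_counts_csv(result, paths["cell_counts"])
    write_kill_counts_csv(result, paths["kill_counts"])
    write_outcome_csv(result, paths["outcome"])
    return paths


@dataclass
class BatchSpec:
    """A batch experiment: repeated seeded runs of one base configuration.

    ``sweep`` maps configuration field names to value lists; the batch runs
    every combination in the Cartesian product, ``runs`` times each.  Each
    run receives its own seed (``base_seed`` + run index, offset for the
    obese arm) and run number.
    """

    base_config: SimulationConfig
    runs: int = 101
    base_seed: int = 0
    sweep: dict[str, list] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.runs < 1:
            raise ValueError("a batch needs at least one run")
        known = {f.name for f in dataclasses.fields(SimulationConfig)}
        unknown = set(self.sweep) - known
        if unknown:
            raise ValueError(f"sweep over unknown parameters: {sorted(unknown)}")

    def seed_for(self, run_index: int) -> int:
        offset = OBESE_ARM_OFFSET if self.base_config.obese else 0
        return self.base_seed + offset + run_index


def _combined_row(result: RunResult, config: SimulationConfig, swept: dict) -> dict:
    row = {
        "run_number": result.run_number,
        "seed": result.seed,
        "arm": "obese" if config.obese else "lean",
        **swept,
        "outcome": result.outcome.lower(),
        "final_tick": result.final_tick,
        "final_tumor_cells": result.cell_counts[AgentCategory.RCC_TUMOR.value][-1],
        "tumor_cells_created": result.total_tumor_created,
    }
    for killer, series in result.kill_counts.items():
        row[f"kills_{killer}"] = series[-1]
    return row


def batch_run(
    spec: BatchSpec, out_dir=None, progress: bool = False
) -> tuple[list[RunResult], pd.DataFrame]:
    """Execute a batch (sequentially), returning results and the combined table.

    When ``out_dir`` is given, writes ``batch_combined.csv`` there plus each
    run's CSV triple under ``run_<number>/``.
    """
    combos = (
        [dict(zip(spec.sweep, values)) for values in itertools.product(*spec.sweep.values())]
        if spec.sweep
        else [{}]
    )
    results: list[RunResult] = []
    rows: list[dict] = []
    run_number = 0
    for combo in combos:
        for i in range(spec.runs):
            config = dataclasses.replace(
                spec.base_config, **combo, seed=spec.seed_for(run_number),
                run_number=run_number,
            )
            result = run(config)
            results.append(result)
            rows.append(_combined_row(result, config, combo))
            if out_dir is not None:
                write_run(result, Path(out_dir) / f"run_{run_number}")
            if progress:
                print(f"run {run_number}: {result.outcome.lower()} at tick {result.final_tick}")
            run_number += 1
    combined = pd.DataFrame(rows)
    if out_dir is not None:
        Path(out_dir).mkdir(parents=True, exist_ok=True)
        combined.to_csv(Path(out_dir) / "batch_combined.csv", index=False)
    return results, combined


KILLER_NAMES = tuple(c.value for c in KILLER_CATEGORIES) + (APOPTOSIS,)


@dataclass
class BatchSummary:
    """Per-arm outcome tallies, mean kill attribution, and final censuses."""

    outcome_tallies: dict[str, dict[str, int]]
    mean_kills: dict[str, dict[str, float]]
    mean_final_counts: dict[str, dict[str, float]]
    percent_proportions: dict[str, dict[str, float]]


def summarize_batch(results_by_arm: Mapping[str, Sequence[RunResult]]) -> BatchSummary:
    """Summary statistics over one or more experimental arms.

    Invariant to the ordering of runs within an arm; every arm must contain
    at least one run.
    """
    tallies: dict[str, dict[str, int]] = {}
    mean_kills: dict[str, dict[str, float]] = {}
    mean_counts: dict[str, dict[str, float]] = {}
    proportions: dict[str, dict[str, float]] = {}
    for arm, results in results_by_arm.items():
        if not results:
            raise ValueError(f"arm {arm!r} has no runs")
        tally = {"remission": 0, "proliferation": 0, "inconclusive": 0}
        for r in results:
            tally[r.outcome.lower()] += 1
        tallies[arm] = tally
        mean_kills[arm] = {
            killer: float(np.mean([r.kill_counts[killer][-1] for r in results]))
            for killer in KILLER_NAMES
        }
        immune_cats = [c.value for c in AgentCategory if c is not AgentCategory.BLOOD]
        mean_counts[arm] = {
            cat: float(np.mean([r.cell_counts[cat][-1] for r in results]))
            for cat in immune_cats
        }
        total = sum(mean_counts[arm].values())
        proportions[arm] = {
            cat: (100.0 * v / total if total > 0 else 0.0)
            for cat, v in mean_counts[arm].items()
        }
    return BatchSummary(tallies, mean_kills, mean_counts, proportions)


# ---------------------------------------------------------------------------
# Test fixtures: tiny deterministic configurations (grid side <= 12).

def _zero_densities() -> dict[str, float]:
    return {name: 0.0 for name in IMMUNE_TYPES}


def make_fixture(name: str) -> tuple[SimulationConfig, dict]:
    """Micro-configurations for tests and demonstrations.

    Returns ``(config, layout)``; ``layout`` may list agents/tumor cells to
    inject manually (category, position pairs) plus expected values.
    """
    if name == "one-nk-one-tumor-adjacent":
        # A certain kill: one NK next to one tumor cell, base kill 1.
        config = SimulationConfig(
            volume=5.12e-7,  # 80 um edge -> side 8 at 10 um blocks
            block_size=10.0,
            densities=_zero_densities(),
            nk_mast_pdc_total=0,
            proportion_difference=0,
            phase=1,
            tumor_appearance_tick=0,
            therapy_start_tick=0,
            max_ticks=50,
            tumor_limit=100,
            base_kill=1.0,
            base_duplication=0.0,
            first_cell_distance=20.0,
            seed=7,
        )
        layout = {
            "agents": [("NK", (4, 7, 4))],
            "expected_outcome": "REMISSION",
        }
        return config, layout
    if name == "two-clump-bfs":
        # Two tumor clumps separated by more than one block; only the clump
        # holding the angiogenic seed has blood access.
        config = SimulationConfig(
            volume=1.728e-6,  # 120 um edge -> side 12 at 10 um blocks
            block_size=10.0,
            densities=_zero_densities(),
            nk_mast_pdc_total=0,
            proportion_difference=0,
            phase=1,
            max_ticks=20,
            seed=11,
        )
        clump_a = [(1, 1, 1), (2, 1, 1), (2, 2, 2), (3, 2, 2)]
        clump_b = [(8, 8, 8), (9, 8, 8), (9, 9, 9)]
        layout = {
            "tumor": clump_a + clump_b,
            "angiogenic_index": 0,  # the (1,1,1) cell triggered angiogenesis
            "expected_access_indices": list(range(len(clump_a))),
        }
        return config, layout
    if name == "phase1-lean-mini":
        # The verification-phase lean arm, shortened for tests; the
        # NK:mast:pDC pattern is the canonical (20, 5, 5).
        config = preset("phase1-lean", max_ticks=60, seed=3)
        layout = {"expected_nk_mast_pdc": (20, 5, 5)}
        return config, layout
    if name == "mini-run":
        # A small but complete run: a handful of hunters against a growing
        # tumor on a side-10 grid, used for conservation checks.
        densities = _zero_densities()
        densities["Natural Killer Cells"] = 6e6      # 6 agents at 1e-6 mL
        densities["Cytotoxic T Cells"] = 4e6
        densities["Dendritic Cells"] = 2e6
        densities["M2 Macrophages"] = 3e6
        densities["Helper Type 1 Cells"] = 2e6
        config = SimulationConfig(
            volume=1e-6,  # 100 um edge -> side 10 at 10 um blocks
            block_size=10.0,
            densities=densities,
            nk_mast_pdc_total=0,
            proportion_difference=0,
            phase=1,
            tumor_appearance_tick=2,
            therapy_start_tick=4,
            max_ticks=40,
            tumor_limit=60,
            seed=5,
        )
        return config, {}
    raise KeyError(f"unknown fixture {name!r}")


def fixture_names() -> list[str]:
    return ["one-nk-one-tumor-adjacent", "two-clump-bfs", "phase1-lean-mini", "mini-run"]
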