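"""Tumor-cell dynamics, angiogenesis, and blood-access computation.

Tumor cells duplicate stochastically (at a doubled rate under a
non-negative Tumor Growth effect, and faster again with blood access) and
may undergo apoptosis when the Tumor Apoptosis channel is positive.  A cell
close enough to the blood vessel can trigger angiogenesis, laying an
uninterrupted path of blood voxels back to the vessel; the triggering cell
is permanently considered to have blood access, and every tumor cell
connected to such a cell through a chain of contiguous (same-block or
26-adjacent) tumor cells inherits access.  Access is recomputed every tick
by a breadth-first search seeded at the angiogenic cells.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .effects import (
    apoptosis_probability,
    modulate_rate,
    tumor_growth_factor,
    DEFAULT_ALPHA,
    DEFAULT_KAPPA,
)

# Default blood-access duplication boost and vessel proximity (micrometres)
# required for an angiogenesis attempt; the proximity reuses the scale of
# the first-tumor-cell distance from the vessel.
DEFAULT_ACCESS_BOOST = 2.0
DEFAULT_ANGIO_PROXIMITY_UM = 50.0


@dataclass
class TumorCell:
    id: int
    position: tuple[int, int, int]
    angiogenic: bool = False        # this cell triggered angiogenesis
    has_blood_access: bool = False  # recomputed each tick; implied by angiogenic
    alive: bool = True


@dataclass(frozen=True)
class VesselPath:
    """Ordered blood-voxel coordinates from a tumor cell to the vessel.

    Consecutive voxels are 26-adjacent; the first voxel is 26-adjacent to
    the originating cell and the last is 26-adjacent to (or on) the
    pre-existing vessel.  May be empty when the cell already touches the
    vessel.
    """

    voxels: tuple[tuple[int, int, int], ...] = field(default_factory=tuple)


def _chebyshev(a: Sequence[int], b: Sequence[int]) -> int:
    return int(max(abs(int(x) - int(y)) for x, y in zip(a, b)))


def tumor_step(
    cell: TumorCell,
    growth_effect: int,
    apoptosis_effect: int,
    base_dup: float,
    has_access: bool,
    rng: np.random.Generator,
    side: int,
    access_boost: float = DEFAULT_ACCESS_BOOST,
    mild_factor: float = 1.25,
    kappa: float = DEFAULT_KAPPA,
) -> tuple[str, Optional[tuple[int, int, int]]]:
    """One tick of a single tumor cell: apoptosis first, then duplication.

    Returns ``("apoptose", None)``, ``("duplicate", position)`` with the
    duplicate's block (uniform over the closed 26-neighbourhood, clipped to
    the cube), or ``("none", None)``.
    """
    if not 0.0 <= base_dup <= 1.0:
        raise ValueError("base duplication probability must be in [0, 1]")
    if rng.random() < apoptosis_probability(apoptosis_effect, kappa):
        cell.alive = False
        return ("apoptose", None)
    p = base_dup * tumor_growth_factor(growth_effect, mild_factor)
    if has_access:
        p *= access_boost
    if rng.random() < min(p, 1.0):
        new = np.clip(
            np.asarray(cell.position, dtype=np.int64) + rng.integers(-1, 2, size=3),
            0,
            side - 1,
        )
        return ("duplicate", (int(new[0]), int(new[1]), int(new[2])))
    return ("none", None)


def build_vessel_path(
    from_position: Sequence[int], vessel_voxels: Iterable[tuple[int, int, int]]
) -> VesselPath:
    """Discrete line of blood voxels from a tumor cell to the vessel.

    Steps per-axis by the sign of the remaining difference (a
    diagonal-permitting discrete line) toward the nearest vessel voxel by
    Euclidean distance, ties broken by lexicographic coordinate order.  The
    returned path excludes both endpoints.
    """
    voxels = sorted(set(map(tuple, vessel_voxels)))
    if not voxels:
        raise ValueError("vessel is empty")
    start = np.asarray(from_position, dtype=np.int64)
    arr = np.asarray(voxels, dtype=np.int64)
    d2 = np.sum((arr - start) ** 2, axis=1)
    target = arr[int(np.argmin(d2))]  # sorted order makes ties lexicographic
    path: list[tuple[int, int, int]] = []
    cur = start.copy()
    while True:
        cur = cur + np.sign(target - cur)
        if np.array_equal(cur, target):
            break
        path.append((int(cur[0]), int(cur[1]), int(cur[2])))
    return VesselPath(tuple(path))


def try_angiogenesis(
    cells: Sequence[TumorCell],
    vessel_voxels: set[tuple[int, int, int]],
    angio_effect: int,
    proximity: float,
    base_angio: float,
    rng: np.random.Generator,
    block_size: float,
    alpha: float = DEFAULT_ALPHA,
) -> Optional[tuple[int, VesselPath]]:
    """One per-tick angiogenesis attempt.

    Among the living tumor cells within ``proximity`` micrometres of any
    vessel voxel, one uniformly chosen candidate triggers with probability
    ``modulate_rate(base_angio, angio_effect)``.  On success the candidate's
    angiogenic flag is set and the connecting vessel path is returned.
    Angiogenesis may succeed many times over a run (once per tick at most);
    repeated successes do not further boost tumor growth.
    """
    if proximity < 0:
        raise ValueError("proximity must be >= 0")
    living = [c for c in cells if c.alive]
    if not living or not vessel_voxels:
        return None
    varr = np.asarray(sorted(vessel_voxels), dtype=np.float64)
    candidates = []
    for c in living:
        d = (varr - np.asarray(c.position, dtype=np.float64)) * block_size
        if float(np.sqrt(np.min(np.einsum("ij,ij->i", d, d)))) <= proximity:
            candidates.append(c)
    if not candidates:
        return None
    chosen = candidates[int(rng.integers(0, len(candidates)))]
    if rng.random() < modulate_rate(base_angio, angio_effect, alpha):
        chosen.angiogenic = True
        chosen.has_blood_access = True
        return (chosen.id, build_vessel_path(chosen.position, vessel_voxels))
    return None


def compute_blood_access(cells: Sequence[TumorCell]) -> set[int]:
    """Ids of tumor cells connected to an angiogenesis-triggering cell.

    Access propagates through chains of contiguous tumor cells (same block
    or 26-adjacent), found by a breadth-first search over a spatial hash of
    occupied blocks, seeded at the angiogenic cells.
    """
    living = [c for c in cells if c.alive]
    by_block: dict[tuple[int, int, int], list[TumorCell]] = {}
    for c in living:
        by_block.setdefault(c.position, []).append(c)
    accessible: set[int] = set()
    visited_blocks: set[tuple[int, int, int]] = set()
    queue: deque[tuple[int, int, int]] = deque()
    for c in living:
        if c.angiogenic and c.position not in visited_blocks:
            visited_blocks.add(c.position)
            queue.append(c.position)
    while queue:
        bx, by, bz = queue.popleft()
        for cell in by_block[(bx, by, bz)]:
            accessible.add(cell.id)
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dz in (-1, 0, 1):
                    nb = (bx + dx, by + dy, bz + dz)
                    if nb in by_block and nb not in visited_blocks:
                        visited_blocks.add(nb)
                        queue.append(nb)
    return accessible
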