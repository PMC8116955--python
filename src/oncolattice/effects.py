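"""Signed-integer effect channels and their aggregation on the lattice.

Cell agents communicate through 13 named "effect" channels.  Each agent
(and, in obese runs, the environment itself) can emit a signed integer on
any channel; an agent reading the field sums, componentwise, every emission
whose source lies within a fixed signalling radius of its own block, plus
the environment's global vector.  The aggregated integers then rescale the
base probabilities of the events they govern (kill attempts, duplication,
phenotype switches, ...).

Positive values promote the event, negative values suppress it, and zero is
the additive identity, so an agent that emits nothing is indistinguishable
from one emitting an all-zero vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

# The 13 effect channels, in registry order.  The angiogenesis channel is
# sometimes called "Tumor Angiogenesis" in prose; it is the same channel.
CHANNELS: tuple[str, ...] = (
    "Angiogenesis",
    "Cytotoxic T Cell Activation",
    "Cytotoxic T Cell Apoptosis",
    "Cytotoxic T Cell Kill Rate",
    "Cytotoxic T Cell Proliferation",
    "Dendritic Cell Phagocytosis",
    "M1 Macrophage Mutation",
    "M2 Macrophage Mutation",
    "Natural Killer Cell Kill Rate",
    "Regulatory T Differentiation",
    "Helper 1 T Proliferation",
    "Tumor Apoptosis",
    "Tumor Growth",
)
N_CHANNELS = len(CHANNELS)
CHANNEL_INDEX: dict[str, int] = {name: i for i, name in enumerate(CHANNELS)}

# Default probability-modulation sensitivity: an aggregated effect of e
# multiplies a base probability by (1 + ALPHA * e).  With the obese global
# magnitude of 5 this is a +/-50% modulation.
DEFAULT_ALPHA = 0.1
# Default slope of the threshold-type apoptosis channels: a positive effect
# e kills with probability KAPPA * e (clamped to 1).
DEFAULT_KAPPA = 0.02
# Default signalling radius in micrometres.
DEFAULT_EFFECT_RADIUS_UM = 30.0


def zero_effects() -> np.ndarray:
    """The all-zero effect vector (additive identity)."""
    return np.zeros(N_CHANNELS, dtype=np.int64)


def effect_vector(values: Mapping[str, int] | None = None) -> np.ndarray:
    """Build an effect vector from a ``{channel name: value}`` mapping.

    Unknown channel names raise ``KeyError``; omitted channels are 0.
    """
    vec = zero_effects()
    if values:
        for name, value in values.items():
            vec[CHANNEL_INDEX[name]] = int(value)
    return vec


def as_mapping(vec: np.ndarray) -> dict[str, int]:
    """Inverse of :func:`effect_vector`, keeping zero entries."""
    return {name: int(vec[i]) for i, name in enumerate(CHANNELS)}


@dataclass(frozen=True)
class EffectEmission:
    """An effect vector emitted from a source block of the grid."""

    position: tuple[int, int, int]
    vector: np.ndarray = field(default_factory=zero_effects)


def aggregate_effects(
    emissions: Iterable[EffectEmission],
    center: Sequence[int],
    radius: float = DEFAULT_EFFECT_RADIUS_UM,
    block_size: float = 10.0,
    global_vector: np.ndarray | None = None,
    side: int | None = None,
) -> np.ndarray:
    """Sum every emission within ``radius`` micrometres of ``center``.

    Distances are Euclidean between block centers, with positions scaled by
    ``block_size``; an emission in the center's own block is always at
    distance 0 and therefore always included.  The environment's
    ``global_vector`` participates regardless of position.

    Parameters
    ----------
    side
        When given, ``center`` is validated to lie inside the cube
        ``[0, side)``^3 and a ``ValueError`` is raised otherwise.
    """
    if radius < 0:
        raise ValueError(f"radius must be >= 0, got {radius}")
    if block_size <= 0:
        raise ValueError(f"block_size must be > 0, got {block_size}")
    center_arr = np.asarray(center, dtype=np.int64)
    if side is not None and (np.any(center_arr < 0) or np.any(center_arr >= side)):
        raise ValueError(f"center {tuple(center_arr)} outside cube of side {side}")
    total = zero_effects() if global_vector is None else global_vector.astype(np.int64).copy()
    for emission in emissions:
        delta = (np.asarray(emission.position, dtype=np.float64) - center_arr) * block_size
        if float(np.sqrt(np.dot(delta, delta))) <= radius:
            total = total + emission.vector
    return total


def aggregate_effects_batch(
    emitter_positions: np.ndarray,
    emitter_vectors: np.ndarray,
    receiver_positions: np.ndarray,
    radius: float,
    block_size: float,
    global_vector: np.ndarray,
) -> np.ndarray:
    """Vectorised form of :func:`aggregate_effects` for many receivers.

    ``emitter_positions``: (m, 3) int, ``emitter_vectors``: (m, 13) int,
    ``receiver_positions``: (n, 3) int.  Returns an (n, 13) array where row i
    is the aggregate at receiver i.  Equivalent, row by row, to calling
    :func:`aggregate_effects` with the same inputs.
    """
    n = receiver_positions.shape[0]
    out = np.broadcast_to(global_vector, (n, N_CHANNELS)).copy()
    if emitter_positions.shape[0] == 0 or n == 0:
        return out
    diff = (
        receiver_positions[:, None, :].astype(np.float64)
        - emitter_positions[None, :, :].astype(np.float64)
    ) * block_size
    within = np.einsum("nmk,nmk->nm", diff, diff) <= radius * radius + 1e-9
    out += within.astype(np.int64) @ emitter_vectors
    return out


def modulate_rate(
    base_probability: float, effect_value: int, alpha: float = DEFAULT_ALPHA
) -> float:
    """Rescale a base probability by an aggregated effect value.

    Returns ``clamp(base * (1 + alpha * effect), 0, 1)``: linear in the
    effect, monotone nondecreasing, and the identity at effect 0.
    """
    if not 0.0 <= base_probability <= 1.0:
        raise ValueError(f"base probability must be in [0, 1], got {base_probability}")
    return float(np.clip(base_probability * (1.0 + alpha * effect_value), 0.0, 1.0))


def tumor_growth_factor(effect_value: int, mild_factor: float = 1.25) -> float:
    """Duplication-chance multiplier from the Tumor Growth channel.

    The chance of duplicating is doubled for a non-negative effect and only
    mildly improved (``mild_factor``) for a negative one.
    """
    return 2.0 if effect_value >= 0 else mild_factor


def apoptosis_probability(effect_value: int, kappa: float = DEFAULT_KAPPA) -> float:
    """Death probability from a threshold-type apoptosis channel.

    Only a strictly positive effect enables apoptosis; the probability then
    grows linearly (slope ``kappa``) until clamped at 1.
    """
    if effect_value <= 0:
        return 0.0
    return float(min(kappa * effect_value, 1.0))


# Per-category emission table: which channels each agent category emits, at
# the default magnitude 1 per channel.  Signs follow the channel semantics
# (e.g. regulatory T cells suppress cytotoxic activity, M2 macrophages
# promote angiogenesis and tumor growth).  User-overridable through the
# simulation configuration.
DEFAULT_EMISSION_TABLE: dict[str, dict[str, int]] = {
    "TREG": {
        "Cytotoxic T Cell Activation": -1,
        "Cytotoxic T Cell Kill Rate": -1,
        "Cytotoxic T Cell Proliferation": -1,
        "Cytotoxic T Cell Apoptosis": 1,
        "Helper 1 T Proliferation": -1,
    },
    "M1": {
        "M2 Macrophage Mutation": 1,
        "Cytotoxic T Cell Activation": 1,
    },
    "M2": {
        "Angiogenesis": 1,
        "Tumor Growth": 1,
        "M1 Macrophage Mutation": 1,
    },
    "CD4_HELPER1": {
        "Tumor Apoptosis": 1,
        "Cytotoxic T Cell Proliferation": 1,
    },
    "CD4_HELPER2": {
        "Cytotoxic T Cell Proliferation": 1,
        "Helper 1 T Proliferation": 1,
    },
    "CDC": {
        "Cytotoxic T Cell Activation": 1,
    },
    "PDC": {
        "Angiogenesis": 1,
    },
    "MAST": {
        "Angiogenesis": 1,
    },
}


def emission_table_to_vectors(
    table: Mapping[str, Mapping[str, int]] | None = None,
) -> dict[str, np.ndarray]:
    """Compile a ``{category: {channel: value}}`` table to effect vectors."""
    table = DEFAULT_EMISSION_TABLE if table is None else table
    return {category: effect_vector(channels) for category, channels in table.items()}
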