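"""Domain types and initial-array construction for the limbal ring model.

The limbal epithelium is modelled as a one-dimensional closed (circular)
array of stem cells belonging to two functionally equivalent populations,
"blue" (label 1) and "white" (label 0), mirroring the two cell populations
of a LacZ-mosaic mouse.  Each cell has exactly two neighbours.  Initial
arrays are built either with cells placed individually at random
("random arrays", one cell per coherent clone) or as randomly ordered
monochrome groups of ``clone_size`` cells ("clumped arrays", modelling
multicellular coherent clones).

Arrays are constructed at the *exact* target composition: the number of
blue cells (or blue groups) is fixed to the rounded target and the
arrangement is a uniformly random circular permutation of that fixed
composition.  This is the distribution obtained by rejection-sampling
independent draws until the target percentage is hit exactly, without
wasting draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "ConfigError",
    "RingState",
    "SimConfig",
    "init_random",
    "init_clumped",
    "initial_state",
]


class ConfigError(ValueError):
    """Raised when a simulation configuration is invalid."""


def _round_half_away(x: float) -> int:
    """Round to nearest integer, ties away from zero (x is non-negative here)."""
    return int(math.floor(x + 0.5))


@dataclass
class RingState:
    """A circular array of living stem cells plus the fate of the original positions.

    Attributes
    ----------
    labels
        Population label (1 = blue, 0 = white) of each *living* cell, in
        circular order.  May be empty if every cell has been lost.
    alive_mask
        Boolean array over the original generation-0 positions (fixed length
        ``n0``); ``True`` where the original lineage position still holds a
        living cell.  The circular order of ``labels`` is the order of the
        ``True`` positions.
    """

    labels: np.ndarray
    alive_mask: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int8)
        self.alive_mask = np.asarray(self.alive_mask, dtype=bool)
        if self.labels.size != int(self.alive_mask.sum()):
            raise ValueError(
                "labels length must equal the number of living positions "
                f"({self.labels.size} != {int(self.alive_mask.sum())})"
            )

    @property
    def n_living(self) -> int:
        return int(self.labels.size)

    @property
    def n_original(self) -> int:
        return int(self.alive_mask.size)

    @property
    def n_blue(self) -> int:
        return int(self.labels.sum())

    @property
    def is_mosaic(self) -> bool:
        """True when both populations are present on the ring."""
        return 0 < self.n_blue < self.n_living

    def copy(self) -> "RingState":
        return RingState(self.labels.copy(), self.alive_mask.copy())


@dataclass(frozen=True)
class SimConfig:
    """The set-up parameters of one simulation.

    Parameters
    ----------
    n_cells
        Number of stem cells in the ring at generation 0 (G0).
    generations
        Number of division iterations to simulate after G0.
    p_blue
        Initial proportion of blue (positive) cells, in [0, 1].
    clone_size
        Cells per coherent clone, ``k``.  1 gives a random array; larger
        values give clumped arrays of monochrome groups of ``k``.  Must
        divide ``n_cells``.
    p_replace
        Per-cell, per-generation probability of being replaced by a copy of
        a neighbouring cell.
    p_loss
        Per-cell, per-generation probability of being lost (not replaced).
    replicates
        Number of repeat simulations in an ensemble (default 20).
    seed
        Master seed; every random draw is reproducible from it.
    """

    n_cells: int
    generations: int
    p_blue: float = 0.5
    clone_size: int = 1
    p_replace: float = 0.0
    p_loss: float = 0.0
    replicates: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells <= 0:
            raise ConfigError(f"n_cells must be positive, got {self.n_cells}")
        if self.generations < 0:
            raise ConfigError(f"generations must be >= 0, got {self.generations}")
        for name in ("p_blue", "p_replace", "p_loss"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.clone_size <= 0:
            raise ConfigError(f"clone_size must be positive, got {self.clone_size}")
        if self.n_cells % self.clone_size != 0:
            raise ConfigError(
                f"clone_size ({self.clone_size}) must divide n_cells ({self.n_cells})"
            )
        if self.replicates <= 0:
            raise ConfigError(f"replicates must be positive, got {self.replicates}")

    @property
    def n_groups(self) -> int:
        return self.n_cells // self.clone_size

    @property
    def n_blue_groups(self) -> int:
        """Target number of blue coherent clones at G0 (nearest integer)."""
        return _round_half_away(self.n_groups * self.p_blue)

    def with_seed(self, seed: int) -> "SimConfig":
        return replace(self, seed=seed)


def init_random(n: int, p_blue: float, rng: np.random.Generator) -> RingState:
    """Build a random array: ``round(n * p_blue)`` blue cells, uniformly shuffled.

    The arrangement is a uniformly random circular permutation of the exact
    composition, so the target percentage of blue cells is met in every draw.
    """
    if n <= 0:
        raise ConfigError(f"array size must be positive, got {n}")
    if not 0.0 <= p_blue <= 1.0:
        raise ConfigError(f"p_blue must be in [0, 1], got {p_blue}")
    b = _round_half_away(n * p_blue)
    labels = np.zeros(n, dtype=np.int8)
    labels[:b] = 1
    rng.shuffle(labels)
    return RingState(labels, np.ones(n, dtype=bool))


def init_clumped(n: int, p_blue: float, k: int, rng: np.random.Generator) -> RingState:
    """Build a clumped array of ``n // k`` monochrome groups of ``k`` cells.

    ``round(n * p_blue / k)`` groups are blue and the group colour order is a
    uniformly random permutation, so every maximal same-colour run at G0 has a
    length that is a multiple of ``k``.
    """
    if n <= 0:
        raise ConfigError(f"array size must be positive, got {n}")
    if k <= 0 or n % k != 0:
        raise ConfigError(f"clone_size ({k}) must divide n_cells ({n})")
    groups = n // k
    gb = _round_half_away(groups * p_blue)
    group_labels = np.zeros(groups, dtype=np.int8)
    group_labels[:gb] = 1
    rng.shuffle(group_labels)
    return RingState(np.repeat(group_labels, k), np.ones(n, dtype=bool))


def initial_state(config: SimConfig, rng: np.random.Generator) -> RingState:
    """Build the G0 state for a configuration (random if k == 1, else clumped)."""
    if config.clone_size == 1:
        return init_random(config.n_cells, config.p_blue, rng)
    return init_clumped(config.n_cells, config.p_blue, config.clone_size, rng)
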