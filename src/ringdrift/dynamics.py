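"""Per-generation stochastic update rules and the simulation loop.

Each generation applies, to every living cell independently:

* **replacement** — with probability ``p_replace`` the cell's label is
  overwritten by the pre-update label of one of its two ring neighbours
  (left or right with equal probability).  The update is synchronous: all
  cells read the configuration as it stood at the start of the generation.
  A replacement draw may copy a neighbour of the same colour; this is a
  no-op on the labels but still counts as a replacement event.  The number
  of living cells never changes under replacement.
* **loss** — with probability ``p_loss`` the cell is removed and not
  replaced.  Survivors close ranks, preserving circular order, and the
  removed cell's original position is marked lost for good.

Within a generation, replacement is applied before loss; at the per-cell
probabilities studied here the ordering effect is second-order.  Random
draws are consumed in a fixed, documented order (replacement uniforms, then
neighbour directions, then loss uniforms; a sub-step with probability 0
consumes no draws), so a trace is fully reproducible from its
configuration and seed.

Degenerate rings: on a 2-cell ring both neighbours of a cell are the other
cell; on a 1-cell ring replacement is a no-op (the cell has no neighbour
but itself).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .ring import RingState, SimConfig, initial_state
from .stats import GenerationSummary, summarize

__all__ = [
    "LOST",
    "SimulationTrace",
    "step_replacement",
    "step_loss",
    "step_generation",
    "run_simulation",
    "replicate_rng",
]

logger = logging.getLogger(__name__)

#: Sentinel for a lost cell in the (original position x generation) state matrix.
LOST: int = -1


@dataclass
class SimulationTrace:
    """One replicate: the full state history plus per-generation summaries.

    ``states`` has one row per original G0 position and one column per
    generation (G0 included), with values 1 (blue), 0 (white) or
    :data:`LOST` (-1).  Lost entries are absorbing along each row.
    """

    config: SimConfig
    states: np.ndarray
    summaries: list[GenerationSummary]

    @property
    def n_generations(self) -> int:
        """Number of simulated division iterations (columns minus the G0 column)."""
        return self.states.shape[1] - 1

    def series(self, field: str) -> list:
        """Per-generation values of one summary field (e.g. ``"corrected_stripes"``)."""
        return [getattr(s, field) for s in self.summaries]

    @property
    def final_state(self) -> GenerationSummary:
        return self.summaries[-1]


def step_replacement(
    state: RingState, r: float, rng: np.random.Generator
) -> RingState:
    """Synchronous neighbour-replacement pass over all living cells."""
    labels = state.labels
    m = labels.size
    if m == 0:
        raise ValueError("replacement step requires a non-empty ring")
    if r == 0.0 or m == 1:
        return state.copy()
    replaced = rng.random(m) < r
    # one direction draw per cell keeps the stream layout independent of r
    directions = rng.integers(0, 2, size=m) * 2 - 1
    sources = (np.arange(m) + directions) % m
    new_labels = labels.copy()
    new_labels[replaced] = labels[sources[replaced]]
    return RingState(new_labels, state.alive_mask.copy())


def step_loss(state: RingState, q: float, rng: np.random.Generator) -> RingState:
    """Remove each living cell independently with probability ``q``.

    Survivors keep their circular order; removed cells' original positions
    are switched off in the alive mask.
    """
    m = state.labels.size
    if q == 0.0 or m == 0:
        return state.copy()
    survives = rng.random(m) >= q
    alive_mask = state.alive_mask.copy()
    alive_positions = np.flatnonzero(alive_mask)
    alive_mask[alive_positions[~survives]] = False
    return RingState(state.labels[survives], alive_mask)


def step_generation(
    state: RingState, config: SimConfig, rng: np.random.Generator
) -> RingState:
    """Advance the ring by one generation: replacement, then loss."""
    if config.p_replace > 0.0 and state.labels.size > 0:
        state = step_replacement(state, config.p_replace, rng)
    if config.p_loss > 0.0:
        state = step_loss(state, config.p_loss, rng)
    return state


def replicate_rng(seed: int, replicate: int) -> np.random.Generator:
    """Independent, reproducible random stream for replicate ``replicate``."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(replicate,))
    )


def _record_column(out: np.ndarray, state: RingState, column: int) -> None:
    out[:, column] = LOST
    out[state.alive_mask, column] = state.labels


def run_simulation(
    config: SimConfig, rng: np.random.Generator | None = None
) -> SimulationTrace:
    """Run one replicate from G0 through ``config.generations`` generations.

    With ``rng=None`` the stream is built from ``config.seed`` (replicate 0's
    stream), so identical configurations give bit-identical traces.
    """
    if rng is None:
        rng = replicate_rng(config.seed, 0)
    state = initial_state(config, rng)
    n0 = config.n_cells
    states = np.empty((n0, config.generations + 1), dtype=np.int8)
    _record_column(states, state, 0)
    summaries = [summarize(state, 0)]
    for g in range(1, config.generations + 1):
        state = step_generation(state, config, rng)
        _record_column(states, state, g)
        summaries.append(summarize(state, g))
    logger.debug(
        "trace complete: n=%d G=%d final living=%d mosaic=%s",
        n0,
        config.generations,
        summaries[-1].n_total,
        summaries[-1].mosaic,
    )
    return SimulationTrace(config=config, states=states, summaries=summaries)
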