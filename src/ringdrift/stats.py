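"""Per-generation stripe statistics and half-life estimation.

A *patch* (coherent-clone run) is an uninterrupted circular sequence of
contiguous same-population cells; every patch on the stem-cell ring is
assumed to map one-to-one onto a radial stripe in the corneal epithelium,
so patch counts are reported as stripe numbers.

The *uncorrected* stripe number is the total count of blue plus white
patches.  Because adjacent coherent clones of the same population merge
into one visible patch, the observed patch count underestimates the number
of coherent clones.  With ``p`` the observed proportion of blue cells, a
blue patch contains on average ``1/(1-p)`` adjacent blue coherent clones
(and a white patch ``1/p`` white clones), so the *corrected* stripe number

    corrected = blue_patches / (1 - p) + white_patches / p

estimates the total number of coherent clones.  On a mosaic ring, where
blue and white patch counts are equal, this reduces to
``uncorrected / (2 p (1 - p))``.

Statistics that cannot be computed are represented by ``None``: when one
population has been lost the percentage of blue cells is recorded as 0 or
100 and the uncorrected stripe number as 1, but the corrected stripe number
is not calculated; when every cell has been lost no statistic is calculated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .ring import RingState

__all__ = [
    "GenerationSummary",
    "HalfLife",
    "count_patches",
    "corrected_stripe_number",
    "summarize",
    "half_life",
    "half_life_from_table",
]

#: Column order of a tabulated summary (one row per generation).
SUMMARY_COLUMNS = [
    "generation",
    "n_total",
    "n_blue",
    "n_white",
    "pct_blue",
    "blue_patches",
    "white_patches",
    "uncorrected_stripes",
    "correction_factor",
    "corrected_stripes",
    "mosaic_flag",
    "n_lost_cumulative",
]


@dataclass(frozen=True)
class GenerationSummary:
    """Summary statistics of the ring at one generation.

    ``pct_blue``, ``uncorrected_stripes`` and ``corrected_stripes`` are
    ``None`` when undefined (see module docstring).  ``correction_factor``
    is ``1 / (2 p (1 - p))`` on a mosaic ring, else ``None``.
    """

    generation: int
    n_total: int
    n_blue: int
    blue_patches: int
    white_patches: int
    pct_blue: Optional[float]
    uncorrected_stripes: Optional[int]
    corrected_stripes: Optional[float]
    mosaic: bool
    n_lost_cumulative: int

    @property
    def n_white(self) -> int:
        return self.n_total - self.n_blue

    @property
    def correction_applicable(self) -> bool:
        return self.corrected_stripes is not None

    @property
    def correction_factor(self) -> Optional[float]:
        if not self.mosaic:
            return None
        p = self.n_blue / self.n_total
        return 1.0 / (2.0 * p * (1.0 - p))

    def as_row(self) -> dict:
        return {
            "generation": self.generation,
            "n_total": self.n_total,
            "n_blue": self.n_blue,
            "n_white": self.n_white,
            "pct_blue": self.pct_blue,
            "blue_patches": self.blue_patches,
            "white_patches": self.white_patches,
            "uncorrected_stripes": self.uncorrected_stripes,
            "correction_factor": self.correction_factor,
            "corrected_stripes": self.corrected_stripes,
            "mosaic_flag": int(self.mosaic),
            "n_lost_cumulative": self.n_lost_cumulative,
        }


@dataclass(frozen=True)
class HalfLife:
    """First generation at which a tracked series falls to half or below its G0 value.

    ``value`` is ``None`` when the threshold is never reached within the
    series.  ``basis`` names the tracked series (e.g. ``"corrected"``,
    ``"uncorrected"``, ``"n_cells"``); ``mode`` distinguishes the half-life
    of an ensemble-mean series (``"ensemble-mean"``) from a per-replicate
    half-life (``"per-replicate"``).
    """

    value: Optional[int]
    basis: str = "corrected"
    mode: str = "ensemble-mean"

    @property
    def reached(self) -> bool:
        return self.value is not None


def count_patches(state: Union[RingState, np.ndarray]) -> tuple[int, int]:
    """Count circular same-colour runs, returned as (blue_patches, white_patches).

    A monochrome ring is a single patch of its colour; an empty ring has no
    patches.  On any mosaic ring the two counts are equal (patches alternate
    around the circle), so the total is even.
    """
    labels = state.labels if isinstance(state, RingState) else np.asarray(state)
    m = labels.size
    if m == 0:
        return (0, 0)
    boundaries = int((labels != np.roll(labels, 1)).sum())
    if boundaries == 0:
        return (1, 0) if labels[0] == 1 else (0, 1)
    return (boundaries // 2, boundaries // 2)


def corrected_stripe_number(
    blue_patches: int, white_patches: int, p: float
) -> Optional[float]:
    """Correct observed patch counts for random same-colour adjacency.

    ``p`` is the proportion of blue cells observed at the same generation as
    the patch counts.  Returns ``blue_patches/(1-p) + white_patches/p`` for
    ``0 < p < 1``; ``None`` when one population is absent (``p`` is 0 or 1),
    where the correction is not calculated.
    """
    if blue_patches < 0 or white_patches < 0:
        raise ValueError("patch counts must be non-negative")
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"proportion p must be in [0, 1], got {p}")
    if p == 0.0 or p == 1.0:
        return None
    return blue_patches / (1.0 - p) + white_patches / p


def summarize(state: RingState, generation: int) -> GenerationSummary:
    """Compute the full per-generation summary of a ring state."""
    m = state.n_living
    n_blue = state.n_blue
    n_lost = state.n_original - m
    if m == 0:
        return GenerationSummary(
            generation=generation,
            n_total=0,
            n_blue=0,
            blue_patches=0,
            white_patches=0,
            pct_blue=None,
            uncorrected_stripes=None,
            corrected_stripes=None,
            mosaic=False,
            n_lost_cumulative=n_lost,
        )
    p = n_blue / m
    bp, wp = count_patches(state)
    return GenerationSummary(
        generation=generation,
        n_total=m,
        n_blue=n_blue,
        blue_patches=bp,
        white_patches=wp,
        pct_blue=100.0 * p,
        uncorrected_stripes=bp + wp,
        corrected_stripes=corrected_stripe_number(bp, wp, p),
        mosaic=state.is_mosaic,
        n_lost_cumulative=n_lost,
    )


def half_life(
    series: Sequence[Optional[float]],
    basis: str = "corrected",
    mode: str = "ensemble-mean",
) -> HalfLife:
    """First index ``t >= 1`` with ``series[t] <= series[0] / 2``.

    Undefined (``None``/NaN) entries cannot trigger the threshold and are
    skipped.  Returns a :class:`HalfLife` with ``value=None`` if the series
    never falls to half its starting value.
    """
    vals = list(series)
    if len(vals) == 0:
        raise ValueError("series must be non-empty")
    g0 = vals[0]
    if g0 is None or (isinstance(g0, float) and np.isnan(g0)) or g0 <= 0:
        raise ValueError("series[0] must be defined and > 0")
    threshold = g0 / 2.0
    for t in range(1, len(vals)):
        v = vals[t]
        if v is None or (isinstance(v, float) and np.isnan(v)):
            continue
        if v <= threshold:
            return HalfLife(value=t, basis=basis, mode=mode)
    return HalfLife(value=None, basis=basis, mode=mode)


def half_life_from_table(
    table: Union[str, "pd.DataFrame"],
    value_column: str,
    generation_column: Optional[str] = None,
    basis: str = "corrected",
) -> HalfLife:
    """Half-life of a longitudinal series stored in a table or CSV file.

    The table needs a value column and, optionally, a generation/age column;
    rows are sorted by the generation column when given, otherwise taken in
    file order with the first row as the baseline.  The returned ``value``
    is the generation label of the first row at or below half the baseline
    (an index when no generation column is given).
    """
    df = pd.read_csv(table) if isinstance(table, str) else table.copy()
    if generation_column is not None:
        df = df.sort_values(generation_column)
    values = [None if pd.isna(v) else float(v) for v in df[value_column]]
    hl = half_life(values, basis=basis, mode="ensemble-mean")
    if hl.value is not None and generation_column is not None:
        gen = df[generation_column].iloc[hl.value]
        return HalfLife(value=int(gen), basis=basis, mode="ensemble-mean")
    return hl
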