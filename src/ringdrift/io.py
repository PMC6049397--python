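"""CSV persistence and raster export of simulation traces.

A trace is stored as three text files sharing one path prefix:

* ``<prefix>.states.csv`` — the state matrix, one row per original G0
  position, one column per generation (header ``G0..Gn``); values 1 (blue),
  0 (white) or -1 (lost).
* ``<prefix>.summary.csv`` — one row per generation with the 12 summary
  columns (generation, n_total, n_blue, n_white, pct_blue, blue_patches,
  white_patches, uncorrected_stripes, correction_factor, corrected_stripes,
  mosaic_flag, n_lost_cumulative).  Undefined statistics are written as
  empty fields, never 0 or NaN.
* ``<prefix>.config.txt`` — the set-up parameters as flat ``key = value``
  lines mirroring the CLI flag names.

The CSV dialect is fixed (comma separator, dot decimal, UTF-8, header row)
so outputs diff cleanly across platforms, and a round trip through
:func:`write_trace` / :func:`read_trace` is lossless.

Raster export draws one column per generation, as the original display did:
blue and white cells in ring order, lost cells black.  Three display modes
handle lost cells: ``compact`` drops them and stretches the survivors to
the full column height, ``inline`` blacks them out at their original
positions, and ``grouped`` collects them into a single black block at the
bottom of the column.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd
from PIL import Image

from .dynamics import LOST, SimulationTrace
from .ensemble import EnsembleResult
from .ring import SimConfig
from .stats import SUMMARY_COLUMNS, GenerationSummary

__all__ = [
    "write_trace",
    "read_trace",
    "write_ensemble",
    "render_raster",
    "RASTER_MODES",
]

logger = logging.getLogger(__name__)

RASTER_MODES = ("compact", "inline", "grouped")

# display colours (RGB): blue cells, white cells, lost cells
_BLUE = (0, 90, 200)
_WHITE = (255, 255, 255)
_BLACK = (0, 0, 0)

_CONFIG_KEYS = {
    "cells": ("n_cells", int),
    "generations": ("generations", int),
    "p-blue": ("p_blue", float),
    "clone-size": ("clone_size", int),
    "p-replace": ("p_replace", float),
    "p-loss": ("p_loss", float),
    "replicates": ("replicates", int),
    "seed": ("seed", int),
}


def _fmt(value) -> str:
    return "" if value is None else repr(value) if isinstance(value, float) else str(value)


def write_trace(trace: SimulationTrace, prefix: Union[str, Path]) -> list[Path]:
    """Write the state matrix, summary table and configuration of one trace.

    ``prefix`` is a path prefix; the three files are written next to it.
    Returns the written paths.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = []
    try:
        states_path = prefix.with_suffix(prefix.suffix + ".states.csv")
        header = ",".join(f"G{g}" for g in range(trace.states.shape[1]))
        np.savetxt(states_path, trace.states, fmt="%d", delimiter=",",
                   header=header, comments="", encoding="utf-8")
        paths.append(states_path)

        summary_path = prefix.with_suffix(prefix.suffix + ".summary.csv")
        rows = [s.as_row() for s in trace.summaries]
        with open(summary_path, "w", encoding="utf-8", newline="") as fh:
            fh.write(",".join(SUMMARY_COLUMNS) + "\n")
            for row in rows:
                fh.write(",".join(_fmt(row[c]) for c in SUMMARY_COLUMNS) + "\n")
        paths.append(summary_path)

        config_path = prefix.with_suffix(prefix.suffix + ".config.txt")
        with open(config_path, "w", encoding="utf-8") as fh:
            for flag, (field, _) in _CONFIG_KEYS.items():
                fh.write(f"{flag} = {getattr(trace.config, field)}\n")
        paths.append(config_path)
    except OSError as exc:
        raise OSError(f"failed writing trace files at prefix {prefix}: {exc}") from exc
    logger.info("trace written: %s", ", ".join(str(p) for p in paths))
    return paths


def read_trace(prefix: Union[str, Path]) -> SimulationTrace:
    """Read back a trace written by :func:`write_trace` (exact round trip)."""
    prefix = Path(prefix)
    config_kwargs = {}
    for line in prefix.with_suffix(prefix.suffix + ".config.txt").read_text().splitlines():
        if not line.strip():
            continue
        key, _, value = line.partition("=")
        field, cast = _CONFIG_KEYS[key.strip()]
        config_kwargs[field] = cast(value.strip())
    config = SimConfig(**config_kwargs)

    states = np.loadtxt(
        prefix.with_suffix(prefix.suffix + ".states.csv"),
        dtype=np.int8, delimiter=",", skiprows=1, ndmin=2,
    )
    df = pd.read_csv(
        prefix.with_suffix(prefix.suffix + ".summary.csv"),
        float_precision="round_trip",
    )
    summaries = []
    for _, row in df.iterrows():
        summaries.append(
            GenerationSummary(
                generation=int(row["generation"]),
                n_total=int(row["n_total"]),
                n_blue=int(row["n_blue"]),
                blue_patches=int(row["blue_patches"]),
                white_patches=int(row["white_patches"]),
                pct_blue=None if pd.isna(row["pct_blue"]) else float(row["pct_blue"]),
                uncorrected_stripes=(
                    None if pd.isna(row["uncorrected_stripes"])
                    else int(row["uncorrected_stripes"])
                ),
                corrected_stripes=(
                    None if pd.isna(row["corrected_stripes"])
                    else float(row["corrected_stripes"])
                ),
                mosaic=bool(int(row["mosaic_flag"])),
                n_lost_cumulative=int(row["n_lost_cumulative"]),
            )
        )
    return SimulationTrace(config=config, states=states, summaries=summaries)


def write_ensemble(result: EnsembleResult, prefix: Union[str, Path]) -> list[Path]:
    """Write an ensemble's per-generation table and survival table as CSV."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    per_gen_path = prefix.with_suffix(prefix.suffix + ".per_generation.csv")
    result.per_generation.to_csv(per_gen_path, index=False)
    survival_path = prefix.with_suffix(prefix.suffix + ".survival.csv")
    result.survival.to_frame().to_csv(survival_path, index=False)
    logger.info("ensemble written: %s, %s", per_gen_path, survival_path)
    return [per_gen_path, survival_path]


def _column_pixels(column: np.ndarray, mode: str, n0: int) -> np.ndarray:
    """RGB pixel stack (length n0) for one generation column of the state matrix."""
    lut = {1: _BLUE, 0: _WHITE, LOST: _BLACK}
    if mode == "inline":
        return np.array([lut[int(v)] for v in column], dtype=np.uint8)
    living = column[column != LOST]
    if mode == "grouped":
        pixels = [lut[int(v)] for v in living]
        pixels += [_BLACK] * (n0 - len(pixels))
        return np.array(pixels, dtype=np.uint8)
    if mode == "compact":
        m = living.size
        if m == 0:
            return np.tile(np.array(_BLACK, dtype=np.uint8), (n0, 1))
        # stretch the living cells to fill the full column height
        idx = np.floor(np.arange(n0) * m / n0).astype(int)
        return np.array([lut[int(v)] for v in living[idx]], dtype=np.uint8)
    raise ValueError(f"unknown raster mode {mode!r}; expected one of {RASTER_MODES}")


def render_raster(
    trace: SimulationTrace,
    mode: str,
    destination: Union[str, Path],
    scale: int = 4,
) -> Path:
    """Render a trace as a PNG: one column per generation, one row per cell.

    ``scale`` enlarges each cell to a ``scale x scale`` pixel block with
    nearest-neighbour sampling, keeping cell boundaries crisp.
    """
    if mode not in RASTER_MODES:
        raise ValueError(f"unknown raster mode {mode!r}; expected one of {RASTER_MODES}")
    if trace.states.size == 0:
        raise ValueError("cannot render an empty trace")
    n0, n_cols = trace.states.shape
    img = np.empty((n0, n_cols, 3), dtype=np.uint8)
    for g in range(n_cols):
        img[:, g, :] = _column_pixels(trace.states[:, g], mode, n0)
    destination = Path(destination)
    destination.parent.mkdir(parents=True, exist_ok=True)
    image = Image.fromarray(img, mode="RGB")
    if scale != 1:
        image = image.resize((n_cols * scale, n0 * scale), Image.NEAREST)
    image.save(destination, format="PNG")
    logger.info("raster (%s mode) written: %s", mode, destination)
    return destination
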