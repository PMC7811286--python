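"""Cellular-automaton invasion simulator on binary suitability grids.

The automaton is deterministic and monotone: a cell, once occupied, stays
occupied, and at each time step every suitable cell within a generalized
Moore neighborhood (Chebyshev radius ``d``) of an occupied cell becomes
occupied. Its steady state is therefore exactly the union of connected
components — under radius-``d`` adjacency — of suitable cells containing
the seeds.

A scenario sweep varies the binarization threshold level E and the
connectivity radius d, and aggregates the runs into a per-cell percentage
of scenarios in which the cell was reached.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_dilation

from .calibration import BinaryMap, binarize
from .raster import RasterGrid

__all__ = ["SimulationConfig", "step", "simulate", "sweep", "default_e_levels"]

DEFAULT_D_LIST = (1, 2, 4, 8, 10, 12)


def default_e_levels(n: int = 10, lo: float = 0.03, hi: float = 0.10) -> np.ndarray:
    """Equidistant threshold levels, by default 10 from 3% to 10%."""
    return np.linspace(lo, hi, n)


@dataclass
class SimulationConfig:
    d: int
    steps: int = 200
    threshold_E: float | None = None

    def __post_init__(self):
        if self.d < 1 or int(self.d) != self.d:
            raise ValueError("d must be a positive integer radius")
        if self.steps < 1:
            raise ValueError("steps must be >= 1")


def _as_bool(arr) -> np.ndarray:
    return np.asarray(arr).astype(bool)


def step(occupied: np.ndarray, suitable: np.ndarray, d: int) -> np.ndarray:
    """One time step: occupied cells colonize suitable cells within
    Chebyshev distance d. Occupation never recedes."""
    occupied = _as_bool(occupied)
    suitable = _as_bool(suitable)
    if occupied.shape != suitable.shape:
        raise ValueError("occupied and suitable grids differ in shape")
    footprint = np.ones((2 * d + 1, 2 * d + 1), dtype=bool)
    reachable = binary_dilation(occupied, structure=footprint)
    return occupied | (reachable & suitable)


def simulate(
    suitable: BinaryMap | np.ndarray,
    seeds,
    config: SimulationConfig,
) -> tuple[np.ndarray, int]:
    """Run the automaton to its step cap or fixed point.

    ``seeds`` is an iterable of (row, col) cells; seeds on unsuitable
    cells are dropped with a warning. Returns ``(occupied, n_steps)``
    where ``n_steps`` is the step at which the state stopped changing
    (or ``config.steps`` if the cap was hit first).
    """
    suit = _as_bool(suitable.values if isinstance(suitable, BinaryMap) else suitable)
    occupied = np.zeros_like(suit)
    dropped = 0
    for r, c in seeds:
        if suit[r, c]:
            occupied[r, c] = True
        else:
            dropped += 1
    if dropped:
        warnings.warn(f"{dropped} seed(s) on unsuitable cells were dropped")
    if not occupied.any():
        raise ValueError("no seeds fall on suitable cells")
    n_steps = 0
    for t in range(1, config.steps + 1):
        new = step(occupied, suit, config.d)
        if np.array_equal(new, occupied):
            break
        occupied = new
        n_steps = t
    return occupied, n_steps


def sweep(
    continuous_model: RasterGrid,
    calibration_suitabilities,
    seeds,
    d_list=DEFAULT_D_LIST,
    e_levels=None,
    steps: int = 200,
) -> tuple[RasterGrid, list[dict]]:
    """Scenario sweep over threshold levels and connectivity radii.

    For each (E, d) the continuous layer is binarized at the modified
    least-presence threshold for E and the automaton run from the seeds.
    Returns the occupancy layer (percent of scenarios reaching each cell)
    and a per-scenario log.
    """
    if e_levels is None:
        e_levels = default_e_levels()
    d_list = list(d_list)
    e_levels = list(np.atleast_1d(e_levels))
    if not d_list or not e_levels:
        raise ValueError("d_list and e_levels must be nonempty")
    counts = np.zeros(continuous_model.shape, dtype=int)
    log = []
    for E in e_levels:
        bmap = binarize(continuous_model, calibration_suitabilities, E=E)
        for d in d_list:
            occupied, n_steps = simulate(bmap, seeds, SimulationConfig(d=d, steps=steps, threshold_E=E))
            counts += occupied
            log.append(
                {
                    "E": float(E),
                    "d": int(d),
                    "threshold": bmap.threshold,
                    "convergence_step": n_steps,
                    "cells_occupied": int(occupied.sum()),
                }
            )
    pct = 100.0 * counts / (len(d_list) * len(e_levels))
    return continuous_model.copy_with(pct, nodata=-1.0), log
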