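"""Mobility-oriented parity (MOP): extrapolation-risk screening.

When a model calibrated on one region is transferred elsewhere, cells
whose environments have no analogue in the calibration cloud carry
extrapolation risk. MOP scores each projection cell by its mean Euclidean
distance (on range-standardized variables) to the nearest fraction of
reference cells, rescaled to a [0, 1] similarity; cells with any variable
outside the reference range are flagged as strict extrapolation and can
be trimmed out of binary suitability maps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .calibration import BinaryMap
from .raster import EnvStack, RasterGrid

__all__ = ["MOPResult", "mop", "trim"]


@dataclass
class MOPResult:
    similarity: RasterGrid  # 1 = identical to reference cloud, 0 = most dissimilar
    strict_mask: RasterGrid  # 1 = at least one variable outside reference range


def mop(
    reference: EnvStack,
    reference_mask: RasterGrid,
    projection: EnvStack,
    p_nearest: float = 0.05,
    subsample_cap: int = 10_000,
    seed: int = 0,
) -> MOPResult:
    """MOP similarity of projection cells to the calibration cloud.

    Per projection cell: the mean distance to the nearest
    ``ceil(p_nearest * N_ref)`` reference cells, on variables
    standardized by the reference range; similarity is
    ``1 - distance / max(distance)`` over defined projection cells.
    References beyond ``subsample_cap`` cells are subsampled (seeded).
    """
    if reference.names != projection.names:
        raise ValueError(
            f"variable mismatch: {reference.names} vs {projection.names}"
        )
    if not (0 < p_nearest <= 1):
        raise ValueError("p_nearest must be in (0, 1]")
    ref_sel = np.asarray(reference_mask.values) == 1
    if not ref_sel.any():
        raise ValueError("reference mask selects no cells")
    R = reference.to_matrix(ref_sel)
    if R.shape[0] > subsample_cap:
        rng = np.random.default_rng(seed)
        R = R[rng.choice(R.shape[0], size=subsample_cap, replace=False)]
    lo = R.min(axis=0)
    hi = R.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)

    template = projection.template
    bad = projection.nodata_mask()
    P = projection.to_matrix()

    strict = ((P < lo) | (P > hi)).any(axis=1)
    strict[bad.ravel()] = False

    n_near = int(np.ceil(p_nearest * R.shape[0]))
    Rz = (R - lo) / span
    Pz = (P - lo) / span
    D = cdist(Pz, Rz)
    part = np.partition(D, n_near - 1, axis=1)[:, :n_near]
    mean_near = part.mean(axis=1)
    mean_near[bad.ravel()] = np.nan
    dmax = np.nanmax(mean_near)
    if not np.isfinite(dmax) or dmax == 0:
        sim = np.where(np.isnan(mean_near), np.nan, 1.0)
    else:
        sim = 1.0 - mean_near / dmax

    sim_grid = sim.reshape(template.shape).astype(float)
    sim_grid[bad] = template.nodata
    strict_grid = strict.reshape(template.shape).astype(np.uint8)
    return MOPResult(
        similarity=template.copy_with(sim_grid),
        strict_mask=template.copy_with(strict_grid, nodata=255),
    )


def trim(binary_map: BinaryMap, mop_result: MOPResult) -> BinaryMap:
    """Delete strict-extrapolation cells from a binary suitability map."""
    if not binary_map.grid.same_geometry(mop_result.strict_mask):
        raise ValueError("binary map and MOP result geometries differ")
    vals = binary_map.grid.values.astype(np.uint8).copy()
    vals[np.asarray(mop_result.strict_mask.values) == 1] = 0
    return BinaryMap(
        grid=binary_map.grid.copy_with(vals),
        threshold=binary_map.threshold,
        E=binary_map.E,
    )
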