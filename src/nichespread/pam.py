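"""Presence-absence matrix (PAM) on a coarse grid and species richness.

Multi-species occurrence points are binned into grid cells (half-open
[west, east) x [south, north) intervals); the PAM records which species
occur in which cell, and richness is its row sum mapped back onto the
grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .occurrences import OccurrenceSet
from .raster import RasterGrid

__all__ = ["PresenceAbsenceMatrix", "build_pam", "richness"]


@dataclass
class PresenceAbsenceMatrix:
    grid: RasterGrid  # geometry template; values unused
    species_names: list[str]
    matrix: np.ndarray  # sites x species, binary
    site_index: dict[tuple[int, int], int]  # (row, col) -> matrix row
    n_dropped: int = 0

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for (r, c), i in self.site_index.items():
            lon, lat = self.grid.cell_center(r, c)
            rows.append([r, c, float(lon), float(lat), *self.matrix[i]])
        return pd.DataFrame(
            rows, columns=["row", "col", "lon", "lat", *self.species_names]
        )


def build_pam(
    occ: OccurrenceSet,
    cell_size: float = 1.0,
    extent: tuple[float, float, float, float] | None = None,
) -> PresenceAbsenceMatrix:
    """Bin occurrences of all species into cells of ``cell_size`` degrees.

    ``extent`` is (west, south, east, north); default is the tight
    cell-aligned bounding box of the records. Records outside the extent
    are dropped (count logged on the result).
    """
    if len(occ) == 0:
        raise ValueError("empty occurrence set")
    lons, lats = occ.lons, occ.lats
    if extent is None:
        west = np.floor(lons.min() / cell_size) * cell_size
        south = np.floor(lats.min() / cell_size) * cell_size
        east = np.ceil(np.nextafter(lons.max(), np.inf) / cell_size) * cell_size
        north = np.ceil(np.nextafter(lats.max(), np.inf) / cell_size) * cell_size
    else:
        west, south, east, north = extent
    n_cols = int(round((east - west) / cell_size))
    n_rows = int(round((north - south) / cell_size))
    grid = RasterGrid(
        n_rows=n_rows,
        n_cols=n_cols,
        origin_lon=west,
        origin_lat=north,
        cell_size=cell_size,
        values=np.zeros((n_rows, n_cols)),
    )
    species = sorted(occ.df["species"].unique())
    sp_index = {s: j for j, s in enumerate(species)}
    site_index: dict[tuple[int, int], int] = {}
    cells: list[list[int]] = []
    n_dropped = 0
    for sp, lon, lat in zip(occ.df["species"], lons, lats):
        if not (west <= lon < east and south < lat <= north):
            n_dropped += 1
            continue
        rc = grid.index_of(lon, lat)
        if rc not in site_index:
            site_index[rc] = len(cells)
            cells.append([0] * len(species))
        cells[site_index[rc]][sp_index[sp]] = 1
    matrix = np.asarray(cells, dtype=int) if cells else np.zeros((0, len(species)), dtype=int)
    return PresenceAbsenceMatrix(
        grid=grid,
        species_names=species,
        matrix=matrix,
        site_index=site_index,
        n_dropped=n_dropped,
    )


def richness(pam: PresenceAbsenceMatrix) -> RasterGrid:
    """Per-cell species count; cells with no records are 0."""
    vals = np.zeros(pam.grid.shape, dtype=int)
    if pam.matrix.size:
        sums = pam.matrix.sum(axis=1)
        for rc, i in pam.site_index.items():
            vals[rc] = sums[i]
    return pam.grid.copy_with(vals, nodata=-1)
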