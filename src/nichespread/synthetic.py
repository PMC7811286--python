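"""Seeded virtual-species generator.

Produces every input the modelling pipeline needs — spatially
autocorrelated environmental surfaces, a known ("true") suitability
function, country polygons, biased occurrence samples, and an invasion
fixture with a known dispersal-bridging radius — so that the whole
pipeline can be exercised and checked against ground truth.

The default landscape emulates the shape of the real problem at desk
scale: a 60 x 60 grid of 10-arcminute (1/6 degree) cells spanning a
10 x 10 degree mid-latitude window, three environmental variables, a
unimodal (logistic-quadratic) response producing a species with moderate
prevalence, uneven per-country sampling effort, and a handful of
independent records in an "invaded" corner of the landscape.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .occurrences import OccurrenceSet
from .raster import EnvStack, RasterGrid

__all__ = [
    "VirtualSpecies",
    "generate_env",
    "true_response",
    "make_countries",
    "country_of_points",
    "sample_occurrences",
    "make_virtual_species",
    "make_invasion_fixture",
]

#: default grid geometry: 10' cells over a 10 x 10 degree window
DEFAULT_GEOM = dict(origin_lon=100.0, origin_lat=45.0, cell_size=1.0 / 6.0)
SPECIES = "Vespa virtualis"


@dataclass
class VirtualSpecies:
    env: EnvStack
    true_suitability: RasterGrid
    response_params: dict
    countries: dict[str, object]
    occurrences: OccurrenceSet
    invasion_records: OccurrenceSet
    seed: int
    #: minimum Moore radius at which disconnected suitable patches join
    #: (only set by the invasion fixture)
    bridging_radius: int | None = None
    extras: dict = field(default_factory=dict)


def _template(n_rows: int, n_cols: int, **geom) -> RasterGrid:
    g = {**DEFAULT_GEOM, **geom}
    return RasterGrid(
        n_rows=n_rows,
        n_cols=n_cols,
        origin_lon=g["origin_lon"],
        origin_lat=g["origin_lat"],
        cell_size=g["cell_size"],
        values=np.zeros((n_rows, n_cols)),
    )


def generate_env(
    seed: int,
    n_rows: int = 60,
    n_cols: int = 60,
    n_vars: int = 3,
    smoothness: float = 6.0,
    **geom,
) -> EnvStack:
    """Spatially autocorrelated standardized surfaces, one per variable.

    Each layer is a seeded mixture of low-frequency sinusoids plus
    Gaussian-smoothed white noise (length scale ``smoothness`` in cells),
    standardized to mean 0 / sd 1 over the grid. Deterministic per seed.
    """
    if n_rows < 8 or n_cols < 8:
        raise ValueError("grid must be at least 8 x 8")
    if n_vars < 2:
        raise ValueError("need at least 2 variables")
    rng = np.random.default_rng(seed)
    template = _template(n_rows, n_cols, **geom)
    rr, cc = np.meshgrid(
        np.linspace(0, 1, n_rows), np.linspace(0, 1, n_cols), indexing="ij"
    )
    layers = {}
    for j in range(n_vars):
        surf = np.zeros((n_rows, n_cols))
        for _ in range(3):
            fr, fc = rng.uniform(0.5, 2.5, size=2)
            pr, pc = rng.uniform(0, 2 * np.pi, size=2)
            amp = rng.uniform(0.5, 1.5)
            surf += amp * np.sin(2 * np.pi * fr * rr + pr) * np.cos(2 * np.pi * fc * cc + pc)
        noise = rng.standard_normal((n_rows, n_cols))
        if smoothness > 0:
            noise = gaussian_filter(noise, sigma=smoothness, mode="reflect")
        nsd = noise.std()
        if nsd > 0:
            surf += noise / nsd
        surf = (surf - surf.mean()) / surf.std()
        layers[f"env{j + 1}"] = template.copy_with(surf)
    return EnvStack(layers)


def true_response(env: EnvStack, params: dict) -> RasterGrid:
    """True suitability: logistic(sum_j a_j x_j + b_j x_j^2 + c).

    ``params`` maps each variable name to ``(a, b)`` plus an
    ``"intercept"`` entry c. Negative b gives a unimodal response with
    optimum at x = -a / (2 b).
    """
    template = env.template
    missing = [v for v in env.names if v not in params]
    if missing:
        raise ValueError(f"missing response coefficients for {missing}")
    eta = np.full(template.shape, float(params.get("intercept", 0.0)))
    for name in env.names:
        a, b = params[name]
        x = env[name].values.astype(float)
        eta += a * x + b * x**2
    suit = 1.0 / (1.0 + np.exp(-eta))
    return template.copy_with(suit)


def make_countries(
    template: RasterGrid, n_countries: int = 5, seed: int = 0
) -> dict[str, object]:
    """Seeded Voronoi partition of the grid extent into country polygons."""
    from shapely.geometry import MultiPoint, Point, box
    from shapely.ops import voronoi_diagram

    rng = np.random.default_rng(seed)
    west, south, east, north = template.bounds
    sites = np.column_stack(
        [rng.uniform(west, east, n_countries), rng.uniform(south, north, n_countries)]
    )
    bbox = box(west, south, east, north)
    cells = voronoi_diagram(MultiPoint([tuple(s) for s in sites]), envelope=bbox)
    countries: dict[str, object] = {}
    for geom in cells.geoms:
        clipped = geom.intersection(bbox)
        if clipped.is_empty:
            continue
        # assign the polygon to the site it contains
        dists = [clipped.distance(Point(*s)) for s in sites]
        code = f"C{int(np.argmin(dists)) + 1}"
        countries[code] = clipped
    return countries


def country_of_points(countries: dict[str, object], lons, lats) -> list[str | None]:
    """Country code containing each point (None if at sea / outside)."""
    from shapely.geometry import Point
    from shapely.prepared import prep

    prepared = [(code, prep(geom)) for code, geom in countries.items()]
    out = []
    for lon, lat in zip(np.atleast_1d(lons), np.atleast_1d(lats)):
        hit = None
        for code, pgeom in prepared:
            if pgeom.covers(Point(float(lon), float(lat))):
                hit = code
                break
        out.append(hit)
    return out


def sample_occurrences(
    truth: RasterGrid,
    n: int,
    bias: dict[str, float] | None = None,
    countries: dict[str, object] | None = None,
    seed: int = 0,
    role: str = "calibration",
    species: str = SPECIES,
) -> OccurrenceSet:
    """Sample occurrence points proportional to truth x country bias.

    Cells are drawn with replacement with probability proportional to
    true suitability times the sampling weight of the country containing
    the cell center; each point is then jittered uniformly within its
    cell so sub-cell geometry (e.g. distance thinning) is exercised.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    vals = truth.values.astype(float).copy()
    vals[truth.nodata_mask()] = 0.0
    weights = vals.ravel().copy()
    clon, clat = truth.cell_centers()
    if bias:
        if countries is None:
            raise ValueError("bias requires country polygons")
        codes = country_of_points(countries, clon.ravel(), clat.ravel())
        w = np.array([bias.get(c, 0.0) if c else 0.0 for c in codes])
        weights *= w
    total = weights.sum()
    if total <= 0:
        raise ValueError("all sampling weights are zero")
    idx = rng.choice(weights.size, size=n, replace=True, p=weights / total)
    rows, cols = np.unravel_index(idx, truth.shape)
    cs = truth.cell_size
    lons = truth.origin_lon + (cols + rng.uniform(0, 1, n)) * cs
    lats = truth.origin_lat - (rows + rng.uniform(0, 1, n)) * cs
    codes = (
        country_of_points(countries, lons, lats) if countries else [None] * n
    )
    df = pd.DataFrame(
        {
            "species": species,
            "lon": lons,
            "lat": lats,
            "country": codes,
            "role": role,
        }
    )
    return OccurrenceSet(df, [f"sample_occurrences(n={n}, seed={seed})"])


DEFAULT_RESPONSE = {
    "env1": (0.0, -2.0),
    "env2": (0.5, -1.5),
    "env3": (0.0, 0.0),  # nuisance variable, no effect on truth
    "intercept": 1.5,
}

DEFAULT_BIAS = {"C1": 10.0, "C2": 1.0, "C3": 1.0, "C4": 2.0, "C5": 1.0}


def make_virtual_species(
    seed: int,
    n_rows: int = 60,
    n_cols: int = 60,
    n_vars: int = 3,
    n_occurrences: int = 200,
    n_invasion: int = 5,
    response: dict | None = None,
    bias: dict | None = None,
) -> VirtualSpecies:
    """Default virtual species: 3 variables on a 60 x 60 grid, unimodal
    truth, 200 biased occurrence samples, 5 independent records placed in
    high-suitability cells."""
    rng = np.random.default_rng(seed)
    env = generate_env(seed, n_rows, n_cols, n_vars)
    params = dict(response or DEFAULT_RESPONSE)
    for name in env.names:
        params.setdefault(name, (0.0, 0.0))
    truth = true_response(env, params)
    countries = make_countries(env.template, n_countries=5, seed=seed + 1)
    occ = sample_occurrences(
        truth,
        n_occurrences,
        bias=dict(bias or DEFAULT_BIAS),
        countries=countries,
        seed=seed + 2,
    )
    # independent records: jittered points in distinct high-truth cells
    flat = truth.values.ravel()
    top = np.argsort(flat)[::-1][: max(n_invasion * 4, n_invasion)]
    pick = rng.choice(top, size=n_invasion, replace=False)
    rows, cols = np.unravel_index(pick, truth.shape)
    cs = truth.cell_size
    inv_df = pd.DataFrame(
        {
            "species": SPECIES,
            "lon": truth.origin_lon + (cols + 0.5) * cs,
            "lat": truth.origin_lat - (rows + 0.5) * cs,
            "country": country_of_points(
                countries,
                truth.origin_lon + (cols + 0.5) * cs,
                truth.origin_lat - (rows + 0.5) * cs,
            ),
            "role": "independent",
        }
    )
    return VirtualSpecies(
        env=env,
        true_suitability=truth,
        response_params=params,
        countries=countries,
        occurrences=occ,
        invasion_records=OccurrenceSet(inv_df, ["invasion records (synthetic)"]),
        seed=seed,
    )


def make_invasion_fixture(seed: int = 0) -> VirtualSpecies:
    """Two-patch landscape with a known dispersal bridging radius.

    True suitability is high inside two rectangular patches separated by
    a 3-cell-wide unsuitable channel: the patches' nearest suitable cells
    are 4 columns apart, so the automaton bridges the gap iff the Moore
    radius d >= 4 (``bridging_radius`` on the result). Independent
    invasion records sit in the western patch.
    """
    n_rows = n_cols = 40
    template = _template(n_rows, n_cols)
    rng = np.random.default_rng(seed)

    patch = np.zeros((n_rows, n_cols), dtype=bool)
    patch[10:30, 5:15] = True  # western patch
    patch[10:30, 18:28] = True  # eastern patch; gap columns 15-17
    bridging_radius = 4

    # env1 drives the niche: optimum value 0 inside patches, hostile 3 outside
    env1 = np.where(patch, 0.0, 3.0) + 0.05 * rng.standard_normal((n_rows, n_cols))
    env2 = gaussian_filter(rng.standard_normal((n_rows, n_cols)), sigma=4)
    env2 = (env2 - env2.mean()) / env2.std()
    env = EnvStack(
        {
            "env1": template.copy_with(env1),
            "env2": template.copy_with(env2),
        }
    )
    params = {"env1": (0.0, -3.0), "env2": (0.0, 0.0), "intercept": 2.5}
    truth = true_response(env, params)
    countries = make_countries(template, n_countries=3, seed=seed + 1)
    occ = sample_occurrences(truth, 60, seed=seed + 2, countries=countries)

    # invasion seeds inside the western patch
    rows = np.array([15, 20, 25])
    cols = np.array([8, 10, 12])
    cs = template.cell_size
    inv_df = pd.DataFrame(
        {
            "species": SPECIES,
            "lon": template.origin_lon + (cols + 0.5) * cs,
            "lat": template.origin_lat - (rows + 0.5) * cs,
            "country": country_of_points(
                countries,
                template.origin_lon + (cols + 0.5) * cs,
                template.origin_lat - (rows + 0.5) * cs,
            ),
            "role": "independent",
        }
    )
    return VirtualSpecies(
        env=env,
        true_suitability=truth,
        response_params=params,
        countries=countries,
        occurrences=occ,
        invasion_records=OccurrenceSet(inv_df, ["invasion records (synthetic)"]),
        seed=seed,
        bridging_radius=bridging_radius,
        extras={"patch_mask": patch, "seed_cells": list(zip(rows, cols))},
    )
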