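"""Occurrence records: cleaning and spatial/country-density thinning.

An :class:`OccurrenceSet` wraps a pandas DataFrame with the columns
``species, lon, lat, country, role`` (role is ``calibration`` or
``independent``) plus a provenance log of the filters applied to it.

Two thinning schemes prepare calibration data:

* distance thinning — drop records closer than a minimum great-circle
  distance (e.g. 50 km) to any already-kept record, to damp spatial
  autocorrelation;
* country-density thinning — subsample heavily surveyed countries down to
  explicit per-country target counts, to damp reporting bias.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .raster import haversine_km

__all__ = ["OccurrenceSet", "clean", "thin_distance", "thin_country_density"]

COLUMNS = ["species", "lon", "lat", "country", "role"]
ROLES = {"calibration", "independent"}

#: coordinate rounding used for duplicate detection (~0.1 m)
_DUP_DECIMALS = 6


@dataclass
class OccurrenceSet:
    """Ordered point records with a provenance log."""

    df: pd.DataFrame
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self):
        missing = [c for c in COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"occurrence table missing columns: {missing}")
        bad_role = set(self.df["role"].dropna()) - ROLES
        if bad_role:
            raise ValueError(f"unknown roles: {sorted(bad_role)}")
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def lons(self) -> np.ndarray:
        return self.df["lon"].to_numpy(dtype=float)

    @property
    def lats(self) -> np.ndarray:
        return self.df["lat"].to_numpy(dtype=float)

    def with_df(self, df: pd.DataFrame, note: str | None = None) -> "OccurrenceSet":
        prov = list(self.provenance)
        if note:
            prov.append(note)
        return OccurrenceSet(df.reset_index(drop=True), prov)

    def select_role(self, role: str) -> "OccurrenceSet":
        return self.with_df(self.df[self.df["role"] == role])

    # -- I/O --------------------------------------------------------------
    @classmethod
    def from_csv(cls, path) -> "OccurrenceSet":
        df = pd.read_csv(path)
        return cls(df[COLUMNS] if set(COLUMNS) <= set(df.columns) else df)

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)


def clean(occ: OccurrenceSet, countries: dict[str, object]) -> OccurrenceSet:
    """Remove unusable records.

    Drops, in order: records with missing coordinates or coordinates
    outside valid lon/lat bounds; exact duplicates of
    ``(species, lon, lat)`` after rounding coordinates to 6 decimals;
    records falling in no country polygon (at sea); records whose declared
    country disagrees with the polygon that contains them. Records with no
    declared country are kept if they fall inside any polygon.

    ``countries`` maps country code -> shapely geometry. The operation is
    idempotent and logs per-rule removal counts in the provenance.
    """
    from shapely.geometry import Point
    from shapely.prepared import prep

    if not countries:
        raise ValueError("clean requires a non-empty country polygon set")
    df = occ.df.copy()
    df["lon"] = pd.to_numeric(df["lon"], errors="coerce")
    df["lat"] = pd.to_numeric(df["lat"], errors="coerce")
    n0 = len(df)

    coords_ok = (
        df["lon"].notna()
        & df["lat"].notna()
        & df["lon"].between(-180, 180)
        & df["lat"].between(-90, 90)
    )
    df = df[coords_ok]
    n_missing = n0 - len(df)

    key = pd.DataFrame(
        {
            "species": df["species"],
            "lon_r": df["lon"].round(_DUP_DECIMALS),
            "lat_r": df["lat"].round(_DUP_DECIMALS),
        }
    )
    dup = key.duplicated()
    df = df[~dup.to_numpy()]
    n_dup = int(dup.sum())

    prepared = {code: prep(geom) for code, geom in countries.items()}
    located = []
    for lon, lat in zip(df["lon"], df["lat"]):
        pt = Point(float(lon), float(lat))
        hit = None
        for code, pgeom in prepared.items():
            if pgeom.covers(pt):
                hit = code
                break
        located.append(hit)
    located = pd.Series(located, index=df.index, dtype=object)
    at_sea = located.isna()
    declared = df["country"]
    mismatch = (~at_sea) & declared.notna() & (declared != located)
    n_sea = int(at_sea.sum())
    n_mismatch = int(mismatch.sum())
    df = df[~(at_sea | mismatch).to_numpy()]

    note = (
        f"clean: removed {n_missing} missing/out-of-range, {n_dup} duplicates, "
        f"{n_sea} at sea, {n_mismatch} country mismatches; {len(df)} retained"
    )
    return occ.with_df(df, note)


def thin_distance(occ: OccurrenceSet, min_km: float, seed: int) -> OccurrenceSet:
    """Greedy distance thinning.

    Records are visited in a seed-shuffled order; each is kept iff it lies
    at least ``min_km`` (great circle) from every record kept before it.
    The output therefore has all pairwise distances >= ``min_km`` and is
    maximal under its visit order. Output preserves the input row order.
    """
    if min_km <= 0:
        raise ValueError("min_km must be positive")
    n = len(occ)
    if n <= 1:
        return occ.with_df(occ.df, f"thin_distance(min_km={min_km}): {n} retained")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    lons, lats = occ.lons, occ.lats
    kept: list[int] = []
    for i in order:
        if not kept:
            kept.append(i)
            continue
        d = haversine_km(lons[kept], lats[kept], lons[i], lats[i])
        if np.all(d >= min_km):
            kept.append(i)
    kept_sorted = sorted(kept)
    note = f"thin_distance(min_km={min_km}): {len(kept_sorted)} of {n} retained"
    return occ.with_df(occ.df.iloc[kept_sorted], note)


def thin_country_density(
    occ: OccurrenceSet, targets: dict[str, int], seed: int
) -> OccurrenceSet:
    """Subsample listed countries down to target record counts.

    Countries not listed are untouched. A uniform random subsample
    (without replacement, seeded) of exactly ``targets[country]`` records
    is retained per listed country; asking for more records than exist is
    an error.
    """
    rng = np.random.default_rng(seed)
    df = occ.df
    keep = np.ones(len(df), dtype=bool)
    for country in sorted(targets):
        target = targets[country]
        idx = np.flatnonzero((df["country"] == country).to_numpy())
        if target > idx.size:
            raise ValueError(
                f"country {country!r} has {idx.size} records, cannot keep {target}"
            )
        drop = rng.choice(idx, size=idx.size - target, replace=False)
        keep[drop] = False
    note = (
        "thin_country_density("
        + ", ".join(f"{c}->{targets[c]}" for c in sorted(targets))
        + f"): {int(keep.sum())} of {len(df)} retained"
    )
    return occ.with_df(df[keep], note)
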