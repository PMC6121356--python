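"""Built-environment covariates per neighbourhood buffer.

For each dwelling and buffer radius: population density (persons/km^2,
apportioning parcel populations by intersected area), land-use mix (Shannon
entropy of commercial/office/residential area shares, normalized to [0,1]),
street intersection density (degree->=3 nodes per km^2), counts of shops,
recreation facilities and bus stops in the closed disk, and Euclidean
distance to the nearest rail station (not capped at the radius).

Also provides z-score standardization of continuous predictors (sample SD,
n-1) with stored means/SDs, and variance-inflation-factor screening.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from shapely.geometry import Point
from shapely.strtree import STRtree

from .city import CityScene, Dwelling, LAND_USE_TYPES
from .errors import DomainError

__all__ = [
    "CovariateVector",
    "StandardizedDesign",
    "entropy_landuse_mix",
    "buffer_covariates",
    "compute_covariates",
    "vif",
    "standardize",
]

CONTINUOUS_COVARIATES = [
    "population_density",
    "landuse_mix",
    "intersection_density",
    "n_shops",
    "n_recreation",
    "n_bus_stops",
    "dist_mtr",
]


@dataclass(frozen=True)
class CovariateVector:
    dwelling_id: int
    radius: float
    population_density: float  # persons per km^2
    landuse_mix: float  # normalized entropy in [0, 1]
    intersection_density: float  # intersections per km^2
    n_shops: int
    n_recreation: int
    n_bus_stops: int
    dist_mtr: float  # meters to nearest rail station


def entropy_landuse_mix(proportions: Sequence[float]) -> float:
    """Normalized Shannon entropy of land-use area shares.

    -sum(p ln p) / ln(k) with 0*ln 0 = 0; equals 0 for a single use and 1
    for an even mix.  Proportions must be nonnegative and sum to 1.
    """
    p = np.asarray(proportions, dtype=float)
    if (p < 0).any():
        raise DomainError("proportions must be nonnegative")
    if abs(p.sum() - 1.0) > 1e-9:
        raise DomainError("proportions must sum to 1")
    nz = p[p > 0]
    if len(p) < 2:
        return 0.0
    return float(-(nz * np.log(nz)).sum() / np.log(len(p)))


class _CityIndex:
    """Cached spatial indexes over a city's amenities, parcels and nodes."""

    def __init__(self, city: CityScene):
        self.city = city
        self.amenity_trees = {
            k: (cKDTree(v) if len(v) else None) for k, v in city.amenities.items()
        }
        inter = city.intersections()
        self.intersection_tree = cKDTree(inter) if len(inter) else None
        self.n_intersections = len(inter)
        self.parcel_geoms = [p.geometry for p in city.parcels]
        self.parcel_tree = STRtree(self.parcel_geoms)

    def count_within(self, kind: str, center, radius: float) -> int:
        tree = self.amenity_trees.get(kind)
        if tree is None:
            return 0
        return len(tree.query_ball_point(np.asarray(center, dtype=float), r=radius))


_INDEX_CACHE: dict[int, _CityIndex] = {}


def _index_for(city: CityScene) -> _CityIndex:
    key = id(city)
    if key not in _INDEX_CACHE:
        _INDEX_CACHE.clear()  # hold at most one city's indexes
        _INDEX_CACHE[key] = _CityIndex(city)
    return _INDEX_CACHE[key]


def buffer_covariates(
    dwelling: Dwelling, city: CityScene, radius: float
) -> CovariateVector:
    """Covariates in the closed Euclidean disk around one dwelling."""
    idx = _index_for(city)
    center = (dwelling.x, dwelling.y)
    if not city.contains(center):
        raise DomainError("dwelling outside city extent")
    disk = Point(center).buffer(radius, quad_segs=64)
    disk_area_km2 = np.pi * radius**2 / 1e6

    n_shops = idx.count_within("shops", center, radius)
    n_rec = idx.count_within("recreation_facilities", center, radius)
    n_bus = idx.count_within("bus_stops", center, radius)

    stations = city.amenities.get("rail_stations", np.empty((0, 2)))
    if len(stations):
        dist_mtr = float(
            np.min(np.linalg.norm(stations - np.asarray(center), axis=1))
        )
    else:
        dist_mtr = float("inf")

    if idx.intersection_tree is not None:
        n_inter = len(idx.intersection_tree.query_ball_point(np.asarray(center), r=radius))
    else:
        n_inter = 0

    areas = dict.fromkeys(LAND_USE_TYPES, 0.0)
    pop = 0.0
    for j in idx.parcel_tree.query(disk):
        parcel = city.parcels[int(j)]
        inter = idx.parcel_geoms[int(j)].intersection(disk)
        if inter.is_empty:
            continue
        a = inter.area
        areas[parcel.land_use] += a
        pop += parcel.population * (a / parcel.area)

    total_area = sum(areas.values())
    if total_area > 0:
        shares = [areas[t] / total_area for t in LAND_USE_TYPES]
        mix = entropy_landuse_mix(shares)
    else:
        mix = 0.0

    return CovariateVector(
        dwelling_id=dwelling.id,
        radius=float(radius),
        population_density=pop / disk_area_km2,
        landuse_mix=mix,
        intersection_density=n_inter / disk_area_km2,
        n_shops=n_shops,
        n_recreation=n_rec,
        n_bus_stops=n_bus,
        dist_mtr=dist_mtr,
    )


def compute_covariates(
    city: CityScene,
    dwellings: Sequence[Dwelling],
    radii: Sequence[float] = (400.0, 800.0),
) -> pd.DataFrame:
    """Covariate table, one row per dwelling x radius.

    Computed once per unique dwelling location (co-located estate dwellings
    share their buffer) and broadcast to dwelling ids.
    """
    locs: dict[tuple[float, float], list[Dwelling]] = {}
    for d in dwellings:
        locs.setdefault((round(d.x, 2), round(d.y, 2)), []).append(d)
    rows = []
    for (_, _), ds in locs.items():
        rep = ds[0]
        for radius in radii:
            cv = buffer_covariates(rep, city, radius)
            for d in ds:
                rows.append(
                    {
                        "dwelling_id": d.id,
                        "radius": float(radius),
                        "population_density": cv.population_density,
                        "landuse_mix": cv.landuse_mix,
                        "intersection_density": cv.intersection_density,
                        "n_shops": cv.n_shops,
                        "n_recreation": cv.n_recreation,
                        "n_bus_stops": cv.n_bus_stops,
                        "dist_mtr": cv.dist_mtr,
                    }
                )
    return (
        pd.DataFrame(rows)
        .sort_values(["dwelling_id", "radius"])
        .reset_index(drop=True)
    )


def vif(design: pd.DataFrame | np.ndarray) -> pd.Series:
    """Variance inflation factor per predictor.

    VIF_k = 1 / (1 - R^2_k), with R^2_k from an intercept-included least
    squares regression of predictor k on all the others.  A perfectly
    collinear column yields ``inf``.
    """
    X = pd.DataFrame(design)
    if X.shape[1] < 2:
        raise DomainError("need at least 2 predictors")
    if X.shape[0] <= X.shape[1]:
        raise DomainError("need more rows than predictors")
    out = {}
    arr = X.to_numpy(dtype=float)
    n = arr.shape[0]
    for k, name in enumerate(X.columns):
        y = arr[:, k]
        others = np.delete(arr, k, axis=1)
        A = np.column_stack([np.ones(n), others])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        resid = y - A @ coef
        ss_tot = ((y - y.mean()) ** 2).sum()
        if ss_tot == 0:
            out[name] = float("inf")
            continue
        r2 = 1.0 - (resid**2).sum() / ss_tot
        out[name] = float("inf") if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out, name="vif")


@dataclass
class StandardizedDesign:
    """Z-scored continuous predictors with the means/SDs used (sample SD, n-1)."""

    frame: pd.DataFrame
    means: pd.Series
    sds: pd.Series

    def inverse(self, column: str, z: np.ndarray) -> np.ndarray:
        return np.asarray(z) * self.sds[column] + self.means[column]


def standardize(
    design: pd.DataFrame, columns: Sequence[str] | None = None
) -> StandardizedDesign:
    """Z-score the given (default: all numeric) columns on the analysis sample.

    Uses sample SD (ddof=1).  Raises on zero-variance columns, naming them.
    """
    cols = list(columns) if columns is not None else list(design.columns)
    out = design.copy()
    means = {}
    sds = {}
    for c in cols:
        col = design[c].to_numpy(dtype=float)
        mu = col.mean()
        sd = col.std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            raise DomainError(f"zero-variance column cannot be standardized: {c!r}")
        out[c] = (col - mu) / sd
        means[c] = mu
        sds[c] = sd
    return StandardizedDesign(
        frame=out, means=pd.Series(means), sds=pd.Series(sds)
    )
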