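"""Synthetic planar city generation.

A :class:`CityScene` supplies every geographic input the exposure pipeline
consumes: a connected street network, land-use parcels (commercial / office /
residential) with population weights, amenity point sets (shops, recreation
facilities, bus stops, rail stations), a space-filling partition into "street
blocks" (the clustering unit of the multilevel models), and a spatially
autocorrelated vegetation field in [0, 1] giving the local expected greenery
density.

All geometry is planar, in meters, with no geodesy: every distance of interest
is sub-kilometre, so circular neighbourhood buffers are Euclidean disks.
Generation is fully deterministic for a fixed ``(config, seed)`` pair.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.spatial import cKDTree
from shapely.geometry import MultiPoint, Point, box, mapping
from shapely.ops import voronoi_diagram

from .errors import ConfigurationError

__all__ = [
    "CityConfig",
    "CityScene",
    "Dwelling",
    "VegetationField",
    "Parcel",
    "generate_city",
    "place_dwellings",
    "dwellings_to_csv",
]

LAND_USE_TYPES = ("commercial", "office", "residential")


@dataclass(frozen=True)
class CityConfig:
    """Tunable knobs of the synthetic city.

    Defaults describe a dense 9 km x 9 km district: ~160 m street grid with
    jitter and diagonal connectors, 300 street blocks (of which roughly 200
    can host dwellings once the 800 m boundary margin is respected), amenity
    counts chosen so that 400/800 m buffers hold a handful to a few dozen of
    each amenity, and a vegetation field with a 300 m correlation length so
    greenness clusters at the same spatial scale as the neighbourhood
    buffers.  ``dwelling_margin`` keeps estates far enough from the boundary
    that no buffer is clipped, as for dwellings embedded in a continuous
    city.
    """

    width: float = 9000.0
    height: float = 9000.0
    street_spacing: float = 160.0
    street_jitter: float = 0.22  # node displacement, fraction of spacing
    diagonal_fraction: float = 0.08  # share of grid cells gaining a diagonal
    n_blocks: int = 300
    n_shops: int = 1500
    n_recreation: int = 450
    n_bus_stops: int = 1250
    n_rail_stations: int = 30
    dwelling_margin: float = 820.0  # estates stay this far from the boundary
    parcel_size: float = 200.0
    veg_correlation_length: float = 300.0
    veg_mean: float = 0.25
    veg_sd: float = 0.12
    field_resolution: float = 25.0

    def validate(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ConfigurationError("city extent must be positive")
        if self.street_spacing <= 0:
            raise ConfigurationError("street spacing must be positive")
        if self.street_spacing >= min(self.width, self.height):
            raise ConfigurationError(
                "street spacing leaves no streets inside the extent"
            )
        if self.n_blocks < 1:
            raise ConfigurationError("need at least one street block")
        for name in ("n_shops", "n_recreation", "n_bus_stops", "n_rail_stations"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.veg_correlation_length <= 0 or self.field_resolution <= 0:
            raise ConfigurationError("vegetation field scales must be positive")


class VegetationField:
    """Scalar greenery-density field on a regular grid, bilinearly interpolated.

    Built as a Gaussian-filtered white-noise field rescaled to mean
    ``veg_mean`` and SD ``veg_sd`` then clipped to [0, 1]; the filter width
    sets the spatial correlation length, which induces the clustering of
    greenness that makes 400 m and 800 m buffer means differ but correlate.
    """

    def __init__(self, values: np.ndarray, resolution: float):
        self.values = np.asarray(values, dtype=float)
        self.resolution = float(resolution)

    def __call__(self, xy: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(xy, dtype=float))
        gx = pts[:, 0] / self.resolution
        gy = pts[:, 1] / self.resolution
        ny, nx_ = self.values.shape
        gx = np.clip(gx, 0.0, nx_ - 1.0 - 1e-9)
        gy = np.clip(gy, 0.0, ny - 1.0 - 1e-9)
        x0 = np.floor(gx).astype(int)
        y0 = np.floor(gy).astype(int)
        fx = gx - x0
        fy = gy - y0
        v = (
            self.values[y0, x0] * (1 - fx) * (1 - fy)
            + self.values[y0, x0 + 1] * fx * (1 - fy)
            + self.values[y0 + 1, x0] * (1 - fx) * fy
            + self.values[y0 + 1, x0 + 1] * fx * fy
        )
        return v if np.asarray(xy).ndim == 2 else float(v[0])


@dataclass(frozen=True)
class Parcel:
    """A rectangular land-use parcel with a population weight (persons)."""

    id: int
    land_use: str
    x0: float
    y0: float
    x1: float
    y1: float
    population: float

    @property
    def area(self) -> float:
        return (self.x1 - self.x0) * (self.y1 - self.y0)

    @property
    def geometry(self):
        return box(self.x0, self.y0, self.x1, self.y1)


@dataclass
class CityScene:
    """The full synthetic geography (see module docstring)."""

    config: CityConfig
    seed: int
    network: nx.Graph
    parcels: list[Parcel]
    amenities: dict[str, np.ndarray]  # name -> (k, 2) coordinates
    block_seeds: np.ndarray  # (n_blocks, 2)
    block_polygons: list  # shapely Polygons, index == block id
    vegetation_field: VegetationField

    def __post_init__(self):
        self._block_tree = cKDTree(self.block_seeds)

    @property
    def extent(self):
        return box(0.0, 0.0, self.config.width, self.config.height)

    def contains(self, xy: Sequence[float]) -> bool:
        x, y = float(xy[0]), float(xy[1])
        return 0.0 <= x <= self.config.width and 0.0 <= y <= self.config.height

    def block_of(self, xy: np.ndarray) -> np.ndarray:
        """Block id(s) by nearest block seed (a.e. identical to the Voronoi
        polygon containing the point)."""
        pts = np.atleast_2d(np.asarray(xy, dtype=float))
        _, idx = self._block_tree.query(pts)
        return idx if np.asarray(xy).ndim == 2 else int(idx[0])

    def node_positions(self) -> np.ndarray:
        return np.array([self.network.nodes[n]["pos"] for n in self.network.nodes])

    def intersections(self) -> np.ndarray:
        """Coordinates of street intersections (nodes of degree >= 3)."""
        pos = [
            self.network.nodes[n]["pos"]
            for n in self.network.nodes
            if self.network.degree[n] >= 3
        ]
        return np.array(pos) if pos else np.empty((0, 2))

    # -- serialization ----------------------------------------------------

    def to_geojson(self, out_dir: str | Path) -> None:
        """One GeoJSON FeatureCollection per layer plus a JSON sidecar."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)

        streets = {
            "type": "FeatureCollection",
            "features": [
                {
                    "type": "Feature",
                    "geometry": {
                        "type": "LineString",
                        "coordinates": [
                            list(self.network.nodes[u]["pos"]),
                            list(self.network.nodes[v]["pos"]),
                        ],
                    },
                    "properties": {"length": self.network.edges[u, v]["length"]},
                }
                for u, v in self.network.edges
            ],
        }
        parcels = {
            "type": "FeatureCollection",
            "features": [
                {
                    "type": "Feature",
                    "geometry": mapping(p.geometry),
                    "properties": {
                        "id": p.id,
                        "land_use": p.land_use,
                        "population": p.population,
                    },
                }
                for p in self.parcels
            ],
        }
        amenities = {
            "type": "FeatureCollection",
            "features": [
                {
                    "type": "Feature",
                    "geometry": {"type": "Point", "coordinates": [float(x), float(y)]},
                    "properties": {"kind": kind},
                }
                for kind, pts in self.amenities.items()
                for x, y in pts
            ],
        }
        blocks = {
            "type": "FeatureCollection",
            "features": [
                {
                    "type": "Feature",
                    "geometry": mapping(poly),
                    "properties": {"block_id": i},
                }
                for i, poly in enumerate(self.block_polygons)
            ],
        }
        for name, fc in [
            ("streets", streets),
            ("parcels", parcels),
            ("amenities", amenities),
            ("blocks", blocks),
        ]:
            (out / f"{name}.geojson").write_text(json.dumps(fc))
        sidecar = {"seed": self.seed, "config": asdict(self.config)}
        (out / "city.json").write_text(json.dumps(sidecar, indent=2))


@dataclass(frozen=True)
class Dwelling:
    """A geocoded dwelling location assigned to exactly one street block.

    Dwellings are pinned to shared estate points — public-housing towers share
    a geocoded address — so many dwellings coincide, which is exactly the
    within-block clustering the random intercept absorbs.
    """

    id: int
    x: float
    y: float
    block_id: int
    estate_id: int


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def _build_network(cfg: CityConfig, rng: np.random.Generator) -> nx.Graph:
    nx_cols = int(np.floor(cfg.width / cfg.street_spacing)) + 1
    ny_rows = int(np.floor(cfg.height / cfg.street_spacing)) + 1
    xs = np.linspace(0.0, cfg.width, nx_cols)
    ys = np.linspace(0.0, cfg.height, ny_rows)
    jit = cfg.street_jitter * cfg.street_spacing
    g = nx.Graph()
    pos = {}
    for j, y in enumerate(ys):
        for i, x in enumerate(xs):
            dx = rng.uniform(-jit, jit) if 0 < i < nx_cols - 1 else 0.0
            dy = rng.uniform(-jit, jit) if 0 < j < ny_rows - 1 else 0.0
            pos[(i, j)] = (float(x + dx), float(y + dy))
    for (i, j), p in pos.items():
        g.add_node((i, j), pos=p)

    def _add(u, v):
        pu, pv = pos[u], pos[v]
        g.add_edge(u, v, length=float(np.hypot(pu[0] - pv[0], pu[1] - pv[1])))

    for j in range(ny_rows):
        for i in range(nx_cols):
            if i + 1 < nx_cols:
                _add((i, j), (i + 1, j))
            if j + 1 < ny_rows:
                _add((i, j), (i, j + 1))
    # diagonal connectors over a random subset of cells
    for j in range(ny_rows - 1):
        for i in range(nx_cols - 1):
            if rng.random() < cfg.diagonal_fraction:
                if rng.random() < 0.5:
                    _add((i, j), (i + 1, j + 1))
                else:
                    _add((i + 1, j), (i, j + 1))
    return g


def _build_field(cfg: CityConfig, rng: np.random.Generator) -> VegetationField:
    res = cfg.field_resolution
    nx_ = int(np.ceil(cfg.width / res)) + 1
    ny_ = int(np.ceil(cfg.height / res)) + 1
    noise = rng.standard_normal((ny_, nx_))
    smooth = gaussian_filter(noise, sigma=cfg.veg_correlation_length / res, mode="reflect")
    smooth = (smooth - smooth.mean()) / smooth.std()
    values = np.clip(cfg.veg_mean + cfg.veg_sd * smooth, 0.0, 1.0)
    return VegetationField(values, res)


def _build_blocks(cfg: CityConfig, rng: np.random.Generator):
    seeds = rng.uniform(
        [0.02 * cfg.width, 0.02 * cfg.height],
        [0.98 * cfg.width, 0.98 * cfg.height],
        size=(cfg.n_blocks, 2),
    )
    env = box(0.0, 0.0, cfg.width, cfg.height)
    cells = voronoi_diagram(MultiPoint([Point(p) for p in seeds]), envelope=env)
    polys = [None] * cfg.n_blocks
    tree = cKDTree(seeds)
    for cell in cells.geoms:
        clipped = cell.intersection(env)
        if clipped.is_empty:
            continue
        _, idx = tree.query(np.asarray(clipped.representative_point().coords[0]))
        polys[int(idx)] = clipped
    return seeds, polys


def _build_parcels(
    cfg: CityConfig, stations: np.ndarray, rng: np.random.Generator
) -> list[Parcel]:
    size = cfg.parcel_size
    ncx = max(1, int(round(cfg.width / size)))
    ncy = max(1, int(round(cfg.height / size)))
    sx, sy = cfg.width / ncx, cfg.height / ncy
    stat_tree = cKDTree(stations) if len(stations) else None
    parcels = []
    pid = 0
    for j in range(ncy):
        for i in range(ncx):
            cx, cy = (i + 0.5) * sx, (j + 0.5) * sy
            d = stat_tree.query([cx, cy])[0] if stat_tree is not None else 1e9
            # commercial clusters mildly around rail stations; offices are
            # scattered (decentralized commercial centres)
            p_comm = 0.12 * np.exp(-d / 350.0) + 0.16
            p_off = 0.12
            u = rng.random()
            # heavy-tailed tower populations; commercial/office parcels are
            # mixed-use (flats above podium shops), so they keep a sizable
            # residential population rather than dropping to zero
            base_pop = float(rng.lognormal(mean=6.6, sigma=1.0))
            if u < p_comm:
                land_use = "commercial"
                popw = 0.6 * base_pop
            elif u < p_comm + p_off:
                land_use = "office"
                popw = 0.35 * base_pop
            else:
                land_use = "residential"
                popw = base_pop
            parcels.append(
                Parcel(pid, land_use, i * sx, j * sy, (i + 1) * sx, (j + 1) * sy, popw)
            )
            pid += 1
    return parcels


def _place_amenities(
    cfg: CityConfig,
    network: nx.Graph,
    parcels: list[Parcel],
    stations: np.ndarray,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    def _uniform(n):
        return rng.uniform([0, 0], [cfg.width, cfg.height], size=(n, 2))

    # shops concentrate in commercial parcels, with a uniform background
    comm = [p for p in parcels if p.land_use == "commercial"]
    shops = []
    for _ in range(cfg.n_shops):
        if comm and rng.random() < 0.3:
            p = comm[rng.integers(len(comm))]
            shops.append(
                [rng.uniform(p.x0, p.x1), rng.uniform(p.y0, p.y1)]
            )
        else:
            shops.append(list(_uniform(1)[0]))
    shops = np.array(shops) if shops else np.empty((0, 2))

    # bus stops sit on street edges
    edges = list(network.edges)
    stops = []
    for _ in range(cfg.n_bus_stops):
        u, v = edges[rng.integers(len(edges))]
        t = rng.random()
        pu = np.array(network.nodes[u]["pos"])
        pv = np.array(network.nodes[v]["pos"])
        stops.append(pu + t * (pv - pu))
    stops = np.array(stops) if stops else np.empty((0, 2))

    recreation = _uniform(cfg.n_recreation) if cfg.n_recreation else np.empty((0, 2))
    return {
        "shops": shops,
        "recreation_facilities": recreation,
        "bus_stops": stops,
        "rail_stations": stations,
    }


def _place_stations(cfg: CityConfig, rng: np.random.Generator) -> np.ndarray:
    """Spread rail stations with a simple farthest-point thinning."""
    if cfg.n_rail_stations == 0:
        return np.empty((0, 2))
    candidates = rng.uniform(
        [0.1 * cfg.width, 0.1 * cfg.height],
        [0.9 * cfg.width, 0.9 * cfg.height],
        size=(max(cfg.n_rail_stations * 20, 20), 2),
    )
    chosen = [candidates[0]]
    for _ in range(cfg.n_rail_stations - 1):
        d = np.min(
            np.linalg.norm(candidates[:, None, :] - np.array(chosen)[None], axis=2),
            axis=1,
        )
        chosen.append(candidates[int(np.argmax(d))])
    return np.array(chosen)


def generate_city(config: CityConfig | None = None, seed: int = 0) -> CityScene:
    """Build a reproducible synthetic city.

    Deterministic for fixed ``(config, seed)``.  Raises
    :class:`ConfigurationError` on degenerate configs.
    """
    cfg = config or CityConfig()
    cfg.validate()
    root = np.random.SeedSequence([int(seed), 0x6C17])
    r_net, r_field, r_blocks, r_parcels, r_amen, r_stat = (
        np.random.default_rng(s) for s in root.spawn(6)
    )
    network = _build_network(cfg, r_net)
    field_ = _build_field(cfg, r_field)
    seeds, polys = _build_blocks(cfg, r_blocks)
    stations = _place_stations(cfg, r_stat)
    parcels = _build_parcels(cfg, stations, r_parcels)
    amenities = _place_amenities(cfg, network, parcels, stations, r_amen)
    return CityScene(
        config=cfg,
        seed=int(seed),
        network=network,
        parcels=parcels,
        amenities=amenities,
        block_seeds=seeds,
        block_polygons=polys,
        vegetation_field=field_,
    )


def place_dwellings(
    city: CityScene,
    n: int,
    seed: int = 0,
    n_blocks: int | None = None,
    estates_per_block: tuple[int, int] = (1, 3),
) -> list[Dwelling]:
    """Place ``n`` dwellings clustered into housing estates.

    Estates are pinned near street-network nodes (so every dwelling is within
    400 m of a street segment) and at least ``dwelling_margin`` from the
    extent boundary (so no buffer is clipped); each occupied block hosts 1–3
    estates, and dwellings are multinomially allocated over estates with
    Dirichlet weights, emulating towers of very different sizes.
    ``n_blocks`` restricts how many eligible blocks are occupied (default:
    all eligible).
    """
    if n == 0:
        return []
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(np.random.SeedSequence([city.seed, int(seed), 0xD3]))
    node_pos = city.node_positions()
    node_block = city.block_of(node_pos)

    m = city.config.dwelling_margin
    interior = (
        (node_pos[:, 0] >= m)
        & (node_pos[:, 0] <= city.config.width - m)
        & (node_pos[:, 1] >= m)
        & (node_pos[:, 1] <= city.config.height - m)
    )
    if not interior.any():
        interior = np.ones(len(node_pos), dtype=bool)  # tiny test cities
    eligible = np.unique(node_block[interior])
    block_ids = eligible
    if n_blocks is not None and n_blocks < len(block_ids):
        block_ids = rng.choice(block_ids, size=n_blocks, replace=False)

    estates = []  # (x, y, block_id)
    for b in block_ids:
        nodes_in = np.flatnonzero((node_block == b) & interior)
        k = int(rng.integers(estates_per_block[0], estates_per_block[1] + 1))
        for _ in range(k):
            base = node_pos[nodes_in[rng.integers(len(nodes_in))]]
            jitter = rng.uniform(-30, 30, size=2)
            x = float(np.clip(base[0] + jitter[0], 0, city.config.width))
            y = float(np.clip(base[1] + jitter[1], 0, city.config.height))
            estates.append((x, y, int(city.block_of(np.array([x, y])))))

    weights = rng.dirichlet(np.ones(len(estates)))
    assignment = rng.choice(len(estates), size=n, p=weights)
    dwellings = [
        Dwelling(
            id=i,
            x=estates[e][0],
            y=estates[e][1],
            block_id=estates[e][2],
            estate_id=int(e),
        )
        for i, e in enumerate(assignment)
    ]
    return dwellings


def dwellings_to_csv(dwellings: Iterable[Dwelling], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["id", "x", "y", "block_id", "estate_id"])
        for d in dwellings:
            w.writerow([d.id, d.x, d.y, d.block_id, d.estate_id])
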