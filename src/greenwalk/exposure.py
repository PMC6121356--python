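"""Green view index exposure assessment.

A dwelling's neighbourhood exposure is the unweighted mean, over street
sampling points inside a circular buffer (400 m and 800 m by default), of the
point-level green view index: the pooled fraction of vegetation pixels over
the four 90-degree views at the point,

    GVI = (sum of vegetation pixels over 4 views) / (sum of all pixels),

an exact integer ratio in [0, 1].  Sampling points are generated along each
street polyline at arc-length multiples of the spacing (50 m), clipped to the
closed Euclidean disk, and deduplicated at shared nodes.

Two exposure backends share this surface:

``field`` mode scores each point by the city's ground-truth vegetation-field
density (the expected vegetation fraction a renderer would produce there);
it is exact, fast, and used for the large cohort runs.  ``rendered`` mode
renders the four views and runs the pluggable segmenter — the full imagery
path — and is used at small scale and for validation; with truth masks in
place of predictions it reproduces ``field``-style ground truth exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .city import CityScene, Dwelling
from .errors import DomainError, MissingExposureError
from .segment import SegmenterConfig, segment_vegetation, VegetationMask
from .streetscape import RenderConfig, TileSet, render_tileset

__all__ = [
    "BufferSpec",
    "SamplingPoint",
    "GreenViewIndex",
    "sample_points",
    "green_view_index",
    "buffer_mean_gvi",
    "CityPointSampler",
    "compute_exposures",
]

DEFAULT_SPACING = 50.0
DEFAULT_RADII = (400.0, 800.0)


@dataclass(frozen=True)
class BufferSpec:
    """A circular (Euclidean-disk) neighbourhood buffer."""

    center: tuple[float, float]
    radius: float

    def __post_init__(self):
        if self.radius <= 0:
            raise DomainError("buffer radius must be positive")


@dataclass(frozen=True)
class SamplingPoint:
    id: int
    x: float
    y: float
    parent_edge: tuple


@dataclass(frozen=True)
class GreenViewIndex:
    """Point-level green view index as an exact pooled pixel ratio."""

    point_id: int
    greenery_pixels: int
    total_pixels: int

    @property
    def value(self) -> float:
        return self.greenery_pixels / self.total_pixels


def _edge_points(network: nx.Graph, spacing: float):
    """Yield (x, y, edge) at arc-length multiples of ``spacing`` per edge,
    including both endpoints when the length is an exact multiple."""
    for u, v, data in network.edges(data=True):
        pu = np.asarray(network.nodes[u]["pos"], dtype=float)
        pv = np.asarray(network.nodes[v]["pos"], dtype=float)
        length = data.get("length", float(np.linalg.norm(pv - pu)))
        n_steps = int(np.floor(length / spacing + 1e-9))
        for k in range(n_steps + 1):
            t = k * spacing / length if length > 0 else 0.0
            p = pu + t * (pv - pu)
            yield float(p[0]), float(p[1]), (u, v)


def _dedupe(points, decimals: int = 2):
    """Drop points that coincide after rounding coordinates to 0.01 m
    (shared nodes appear once)."""
    seen = set()
    out = []
    for x, y, e in points:
        key = (round(x, decimals), round(y, decimals))
        if key in seen:
            continue
        seen.add(key)
        out.append((x, y, e))
    return out


def sample_points(
    network: nx.Graph, buffer: BufferSpec, spacing: float = DEFAULT_SPACING
) -> list[SamplingPoint]:
    """Street-centerline sampling points inside a buffer.

    Points on each edge sit exactly ``spacing`` apart along the edge; a point
    is kept when its Euclidean distance to the buffer center is <= radius
    (closed disk).  Returns an empty list when no street enters the buffer.
    """
    if spacing <= 0:
        raise DomainError("spacing must be positive")
    cx, cy = buffer.center
    r2 = buffer.radius**2
    kept = [
        (x, y, e)
        for x, y, e in _dedupe(_edge_points(network, spacing))
        if (x - cx) ** 2 + (y - cy) ** 2 <= r2
    ]
    return [SamplingPoint(i, x, y, e) for i, (x, y, e) in enumerate(kept)]


def green_view_index(
    ts: TileSet, masks: Sequence[VegetationMask]
) -> GreenViewIndex:
    """Pooled-pixel green view index of a tileset given its four masks.

    Pixels are pooled over the four views before dividing — not a mean of
    per-view ratios, which differs whenever view sizes differ.
    """
    if len(masks) != 4:
        raise DomainError("need exactly 4 masks")
    by_heading = {m.heading: m for m in masks}
    green = 0
    total = 0
    for t in ts.tiles:
        m = by_heading.get(t.heading)
        if m is None or m.mask.shape != t.truth_mask.shape:
            raise DomainError("mask missing or dimensions differ from tile")
        green += int(m.mask.sum())
        total += int(m.mask.size)
    return GreenViewIndex(ts.point_id, green, total)


def buffer_mean_gvi(values: Iterable[float | GreenViewIndex]) -> float:
    """Unweighted arithmetic mean of point-level index values in a buffer."""
    vals = [v.value if isinstance(v, GreenViewIndex) else float(v) for v in values]
    if not vals:
        raise MissingExposureError("buffer contains no scored sampling points")
    return float(np.mean(vals))


class CityPointSampler:
    """Citywide sampling points with fast per-buffer queries.

    Materializes every per-edge sampling point once (the same construction
    :func:`sample_points` applies per buffer), indexes them with a k-d tree,
    and serves buffer queries / exposure means for thousands of dwellings.
    """

    def __init__(self, city: CityScene, spacing: float = DEFAULT_SPACING):
        self.city = city
        self.spacing = float(spacing)
        pts = _dedupe(_edge_points(city.network, self.spacing))
        self.xy = np.array([(x, y) for x, y, _ in pts])
        self.edges = [e for _, _, e in pts]
        self.tree = cKDTree(self.xy)
        self.field_values = city.vegetation_field(self.xy)

    def __len__(self) -> int:
        return len(self.xy)

    def indices_in_buffer(self, center: Sequence[float], radius: float) -> np.ndarray:
        idx = self.tree.query_ball_point(np.asarray(center, dtype=float), r=radius)
        return np.asarray(idx, dtype=int)

    def points_in_buffer(self, buffer: BufferSpec) -> list[SamplingPoint]:
        idx = self.indices_in_buffer(buffer.center, buffer.radius)
        return [
            SamplingPoint(int(i), float(self.xy[i, 0]), float(self.xy[i, 1]), self.edges[i])
            for i in idx
        ]

    def buffer_mean_field(self, center: Sequence[float], radius: float) -> float:
        idx = self.indices_in_buffer(center, radius)
        if len(idx) == 0:
            raise MissingExposureError("buffer contains no sampling points")
        return float(self.field_values[idx].mean())


def _score_point_rendered(
    sampler: CityPointSampler,
    idx: int,
    style: RenderConfig,
    seg_params: SegmenterConfig | None,
    seed: int,
    use_truth_masks: bool,
) -> float:
    ts = render_tileset(
        sampler.xy[idx], sampler.city, style, seed=seed, point_id=int(idx)
    )
    if use_truth_masks:
        masks = [
            VegetationMask(t.point_id, t.heading, t.truth_mask) for t in ts.tiles
        ]
    else:
        masks = [segment_vegetation(t, seg_params) for t in ts.tiles]
    return green_view_index(ts, masks).value


def compute_exposures(
    city: CityScene,
    dwellings: Sequence[Dwelling],
    radii: Sequence[float] = DEFAULT_RADII,
    mode: str = "field",
    spacing: float = DEFAULT_SPACING,
    style: RenderConfig | None = None,
    seg_params: SegmenterConfig | None = None,
    seed: int = 0,
    use_truth_masks: bool = False,
    sampler: CityPointSampler | None = None,
) -> pd.DataFrame:
    """Per-dwelling mean green view index at each buffer radius.

    Returns a DataFrame (dwelling_id, radius, n_points, mean_gvi); dwellings
    whose buffer holds no sampling point get ``n_points = 0`` and NaN and are
    excluded downstream (the count is the caller's exclusion log).  Exposure
    is computed once per unique dwelling location and broadcast — co-located
    dwellings (towers of one estate) share their neighbourhood by construction.

    ``mode='field'`` scores points by ground-truth vegetation density;
    ``mode='rendered'`` runs the full render+segment imagery path (use for
    small n), optionally with truth masks substituted for predictions.
    """
    if mode not in ("field", "rendered"):
        raise ValueError("mode must be 'field' or 'rendered'")
    sampler = sampler or CityPointSampler(city, spacing)
    style = style or RenderConfig()

    locs = {}
    for d in dwellings:
        locs.setdefault((round(d.x, 2), round(d.y, 2)), []).append(d.id)

    point_cache: dict[int, float] = {}

    def _point_value(i: int) -> float:
        if i not in point_cache:
            point_cache[i] = _score_point_rendered(
                sampler, i, style, seg_params, seed, use_truth_masks
            )
        return point_cache[i]

    rows = []
    for (x, y), ids in locs.items():
        for radius in radii:
            idx = sampler.indices_in_buffer((x, y), radius)
            if len(idx) == 0:
                mean = np.nan
            elif mode == "field":
                mean = float(sampler.field_values[idx].mean())
            else:
                mean = float(np.mean([_point_value(int(i)) for i in idx]))
            for did in ids:
                rows.append((did, radius, len(idx), mean))
    df = pd.DataFrame(rows, columns=["dwelling_id", "radius", "n_points", "mean_gvi"])
    return df.sort_values(["dwelling_id", "radius"]).reset_index(drop=True)
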