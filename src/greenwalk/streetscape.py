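"""Synthetic street-level image tiles with exact ground-truth vegetation masks.

At each street sampling point the pipeline needs four 90-degree-field-of-view
views covering the full panorama (headings 0/90/180/270).  Here those views
are rendered synthetically: sky, buildings and road as backdrop, vegetation
as irregular textured green blobs whose painted pixels define the ground
truth, and — with configurable probability — green-colored *man-made*
confounders (rectilinear, untextured "truck/wall" patches) whose pixels are
NOT vegetation.  The confounders exercise the known failure mode of
color-only greenness extraction, which a shape-aware segmenter must reject.

Rendering is pure: fixed ``(point, city, style, seed)`` reproduces rasters
bit-for-bit.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from matplotlib.colors import hsv_to_rgb  # colorsys-free vectorized conversion

from .city import CityScene
from .errors import DomainError

__all__ = [
    "RenderConfig",
    "ImageTile",
    "TileSet",
    "render_tile",
    "render_tileset",
    "truth_green_fraction",
    "render_validation_corpus",
    "save_tileset",
    "GsvFetcher",
    "SyntheticFetcher",
]

HEADINGS = (0, 90, 180, 270)


@dataclass(frozen=True)
class RenderConfig:
    """Style knobs for the tile renderer.

    ``vegetation_scale`` maps local vegetation-field density to the target
    vegetation pixel fraction of a tile; ``confounder_prob`` is the per-tile
    probability of inserting 1–2 green man-made patches.
    """

    tile_size: int = 256
    vegetation_scale: float = 0.9
    confounder_prob: float = 0.3
    max_confounders: int = 2
    sensor_noise: float = 0.008
    vegetation_texture: float = 0.08  # per-pixel value-channel noise of canopy


@dataclass
class ImageTile:
    """One rendered view: color pixels plus its ground-truth vegetation mask."""

    point_id: int
    heading: int
    pixels: np.ndarray  # (H, W, 3) uint8
    truth_mask: np.ndarray  # (H, W) uint8 in {0, 1}

    def __post_init__(self):
        if self.pixels.shape[:2] != self.truth_mask.shape:
            raise DomainError("pixels and truth_mask dimensions differ")
        if not np.isin(self.truth_mask, (0, 1)).all():
            raise DomainError("truth_mask must be binary")


@dataclass
class TileSet:
    """The four views at one sampling point, one per compass heading."""

    point_id: int
    tiles: tuple[ImageTile, ImageTile, ImageTile, ImageTile]

    def __post_init__(self):
        if tuple(sorted(t.heading for t in self.tiles)) != HEADINGS:
            raise DomainError("tileset must cover headings 0/90/180/270 exactly")


def _paint_vegetation(
    canvas: np.ndarray,
    truth: np.ndarray,
    target_fraction: float,
    style: RenderConfig,
    rng: np.random.Generator,
) -> None:
    """Add irregular textured green blobs until coverage reaches the target."""
    h, w = truth.shape
    total = h * w
    yy, xx = np.mgrid[0:h, 0:w]
    attempts = 0
    while truth.sum() / total < target_fraction and attempts < 400:
        attempts += 1
        cx = rng.uniform(0, w)
        cy = rng.uniform(0.05 * h, 0.92 * h)
        r = rng.uniform(0.06, 0.28) * min(h, w)
        ar = rng.uniform(0.6, 1.6)
        # ragged ellipse: radial threshold perturbed by smooth noise
        dist = np.sqrt(((xx - cx) / r) ** 2 + ((yy - cy) / (r * ar)) ** 2)
        rough = rng.standard_normal((h // 8 + 2, w // 8 + 2))
        rough = np.kron(rough, np.ones((8, 8)))[:h, :w]
        blob = dist + 0.25 * rough < 1.0
        if not blob.any():
            continue
        hue = rng.uniform(0.24, 0.38)
        sat = rng.uniform(0.5, 0.85)
        val = rng.uniform(0.35, 0.65)
        nb = int(blob.sum())
        vals = np.clip(val + style.vegetation_texture * rng.standard_normal(nb), 0.05, 1.0)
        hsv = np.stack(
            [np.full(nb, hue), np.full(nb, sat), vals], axis=-1
        )
        canvas[blob] = hsv_to_rgb(hsv)
        truth[blob] = 1


def _paint_confounders(
    canvas: np.ndarray,
    truth: np.ndarray,
    style: RenderConfig,
    rng: np.random.Generator,
) -> None:
    """Green rectilinear untextured patches (trucks, painted walls): truth 0."""
    h, w = truth.shape
    n = int(rng.integers(1, style.max_confounders + 1))
    for _ in range(n):
        cw = int(rng.uniform(0.10, 0.30) * w)
        ch = int(rng.uniform(0.10, 0.28) * h)
        x0 = int(rng.uniform(0, w - cw))
        y0 = int(rng.uniform(0.25 * h, h - ch))
        hue = rng.uniform(0.25, 0.36)
        color = hsv_to_rgb([hue, rng.uniform(0.5, 0.8), rng.uniform(0.4, 0.6)])
        canvas[y0 : y0 + ch, x0 : x0 + cw] = color
        truth[y0 : y0 + ch, x0 : x0 + cw] = 0  # occludes any vegetation behind


def render_tile(
    target_fraction: float,
    style: RenderConfig,
    rng: np.random.Generator,
    point_id: int = 0,
    heading: int = 0,
    with_confounder: bool | None = None,
) -> ImageTile:
    """Render one tile aiming at a given ground-truth vegetation fraction.

    ``with_confounder=None`` draws per-tile with ``style.confounder_prob``;
    True/False force the choice (used by fixtures).
    """
    s = style.tile_size
    canvas = np.empty((s, s, 3), dtype=float)

    # sky with a vertical gradient
    sky_h = int(rng.uniform(0.38, 0.50) * s)
    t = np.linspace(0.0, 1.0, sky_h)[:, None, None]
    top = np.array([0.45, 0.62, 0.92])
    horizon = np.array([0.75, 0.83, 0.95])
    canvas[:sky_h] = top + (horizon - top) * t

    # road band at the bottom
    road_y = int(0.75 * s)
    canvas[sky_h:road_y] = np.array([0.72, 0.70, 0.66])  # distant facade strip
    canvas[road_y:] = np.array([0.33, 0.33, 0.35])

    # a few buildings between skyline and road line
    for _ in range(int(rng.integers(2, 6))):
        bw = int(rng.uniform(0.10, 0.30) * s)
        x0 = int(rng.uniform(0, s - bw))
        y0 = int(rng.uniform(0.15, 0.50) * s)
        g = rng.uniform(0.40, 0.65)
        tint = rng.uniform(-0.05, 0.05)
        canvas[y0:road_y, x0 : x0 + bw] = np.array([g + tint, g, g - tint * 0.5])

    truth = np.zeros((s, s), dtype=np.uint8)
    tf = float(np.clip(target_fraction, 0.0, 0.95))
    if tf > 0:
        _paint_vegetation(canvas, truth, tf, style, rng)

    draw_conf = (
        rng.random() < style.confounder_prob if with_confounder is None else with_confounder
    )
    if draw_conf:
        _paint_confounders(canvas, truth, style, rng)

    canvas += style.sensor_noise * rng.standard_normal(canvas.shape)
    pixels = (np.clip(canvas, 0.0, 1.0) * 255).round().astype(np.uint8)
    return ImageTile(point_id=point_id, heading=heading, pixels=pixels, truth_mask=truth)


def render_tileset(
    point: Sequence[float],
    city: CityScene,
    style: RenderConfig | None = None,
    seed: int = 0,
    point_id: int = 0,
) -> TileSet:
    """Render the four 90-degree views at a street sampling point.

    The expected ground-truth vegetation fraction of the tileset scales with
    the city's vegetation field at the point.
    """
    style = style or RenderConfig()
    if not city.contains(point):
        raise DomainError(f"point {tuple(point)} outside city extent")
    density = float(city.vegetation_field(np.asarray(point, dtype=float)))
    target = density * style.vegetation_scale
    tiles = []
    for hi, heading in enumerate(HEADINGS):
        rng = np.random.default_rng(
            np.random.SeedSequence([int(seed), int(point_id), hi, 0x5CE])
        )
        # mild per-heading variation around the local density
        tf = np.clip(target * rng.uniform(0.7, 1.3), 0.0, 0.95)
        tiles.append(render_tile(tf, style, rng, point_id=point_id, heading=heading))
    return TileSet(point_id=point_id, tiles=tuple(tiles))


def truth_green_fraction(ts: TileSet) -> float:
    """Pooled ground-truth vegetation fraction: sum of vegetation pixels over
    the four views divided by the sum of their pixel counts."""
    green = sum(int(t.truth_mask.sum()) for t in ts.tiles)
    total = sum(t.truth_mask.size for t in ts.tiles)
    return green / total


def render_validation_corpus(
    n_images: int = 50,
    style: RenderConfig | None = None,
    seed: int = 0,
    fraction_range: tuple[float, float] = (0.02, 0.70),
) -> list[ImageTile]:
    """Render single tiles spanning the vegetation-fraction range, the corpus
    used to validate the segmenter against ground truth (expert-mask role)."""
    style = style or RenderConfig()
    lo, hi = fraction_range
    targets = np.linspace(lo, hi, n_images)
    tiles = []
    for i, tf in enumerate(targets):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), i, 0xA1]))
        tiles.append(render_tile(float(tf), style, rng, point_id=i, heading=0))
    return tiles


def save_tileset(ts: TileSet, out_dir: str | Path, manifest: str | Path | None = None):
    """Write tiles and truth masks as PNG plus an optional manifest CSV row set."""
    from PIL import Image

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for t in ts.tiles:
        img_path = out / f"tile_{ts.point_id}_{t.heading}.png"
        msk_path = out / f"mask_{ts.point_id}_{t.heading}.png"
        Image.fromarray(t.pixels).save(img_path)
        Image.fromarray(t.truth_mask * 255).save(msk_path)
        rows.append((ts.point_id, t.heading, str(img_path), str(msk_path)))
    if manifest is not None:
        new = not Path(manifest).exists()
        with open(manifest, "a", newline="") as fh:
            w = csv.writer(fh)
            if new:
                w.writerow(["point_id", "heading", "image", "truth_mask"])
            w.writerows(rows)
    return rows


class GsvFetcher:
    """Interface where a live street-imagery client would plug in.

    A real implementation would retrieve four 90-degree-FOV panorama crops
    per point and return a :class:`TileSet` (without ground-truth masks).
    Not implemented here; see :class:`SyntheticFetcher` for the synthetic
    stand-in used throughout.
    """

    def fetch(self, point_id: int, point: Sequence[float]) -> TileSet:
        raise NotImplementedError(
            "live street-imagery retrieval is out of scope; use SyntheticFetcher"
        )


class SyntheticFetcher(GsvFetcher):
    """Fetcher backed by the synthetic renderer (same output contract)."""

    def __init__(self, city: CityScene, style: RenderConfig | None = None, seed: int = 0):
        self.city = city
        self.style = style or RenderConfig()
        self.seed = int(seed)

    def fetch(self, point_id: int, point: Sequence[float]) -> TileSet:
        return render_tileset(
            point, self.city, self.style, seed=self.seed, point_id=point_id
        )
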