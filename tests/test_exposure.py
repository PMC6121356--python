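import networkx as nx
import numpy as np
import pytest

from greenwalk.city import Dwelling
from greenwalk.errors import DomainError, MissingExposureError
from greenwalk.exposure import (
    BufferSpec,
    CityPointSampler,
    buffer_mean_gvi,
    compute_exposures,
    green_view_index,
    sample_points,
)
from greenwalk.segment import VegetationMask
from greenwalk.streetscape import HEADINGS, ImageTile, RenderConfig, TileSet, render_tileset, truth_green_fraction


def _line_network(length=200.0):
    g = nx.Graph()
    g.add_node(0, pos=(0.0, 0.0))
    g.add_node(1, pos=(length, 0.0))
    g.add_edge(0, 1, length=length)
    return g


def test_straight_segment_point_arithmetic():
    g = _line_network(200.0)
    pts = sample_points(g, BufferSpec((100.0, 0.0), 500.0), spacing=50.0)
    xs = sorted(p.x for p in pts)
    assert xs == [0.0, 50.0, 100.0, 150.0, 200.0]


def test_buffer_far_from_streets_is_empty():
    g = _line_network(200.0)
    assert sample_points(g, BufferSpec((100.0, 5000.0), 100.0)) == []


def test_point_count_monotone_in_radius(city):
    sampler = CityPointSampler(city)
    center = (city.config.width / 2, city.config.height / 2)
    counts = [len(sampler.indices_in_buffer(center, r)) for r in (200, 400, 800, 1600)]
    assert counts == sorted(counts)


def test_sampler_matches_per_buffer_sampling(city):
    sampler = CityPointSampler(city)
    buf = BufferSpec((city.config.width / 2, city.config.height / 2), 400.0)
    direct = {(round(p.x, 2), round(p.y, 2)) for p in sample_points(city.network, buf)}
    via_tree = {
        (round(p.x, 2), round(p.y, 2)) for p in sampler.points_in_buffer(buf)
    }
    assert direct == via_tree


def _tileset_with_masks(mask_counts, size=100):
    tiles = []
    masks = []
    for h, n in zip(HEADINGS, mask_counts):
        pixels = np.zeros((size, size, 3), dtype=np.uint8)
        tiles.append(ImageTile(1, h, pixels, np.zeros((size, size), dtype=np.uint8)))
        m = np.zeros((size, size), dtype=np.uint8)
        m.flat[:n] = 1
        masks.append(VegetationMask(1, h, m))
    return TileSet(1, tuple(tiles)), masks


def test_green_view_index_pooled_ratio():
    ts, masks = _tileset_with_masks((1000, 2000, 0, 1000))
    g = green_view_index(ts, masks)
    assert (g.greenery_pixels, g.total_pixels) == (4000, 40000)
    assert g.value == 0.1


def test_green_view_index_zero_masks():
    ts, masks = _tileset_with_masks((0, 0, 0, 0))
    assert green_view_index(ts, masks).value == 0.0


def test_green_view_index_dimension_mismatch():
    ts, masks = _tileset_with_masks((10, 10, 10, 10))
    masks[0] = VegetationMask(1, masks[0].heading, np.zeros((3, 3), dtype=np.uint8))
    with pytest.raises(DomainError):
        green_view_index(ts, masks)


def test_pooled_ratio_differs_from_mean_of_ratios():
    """With unequal view sizes the pooled value is not the per-view mean."""
    big = np.zeros((100, 100), dtype=np.uint8)
    small = np.zeros((10, 10), dtype=np.uint8)
    small[:] = 1  # tiny view fully green
    tiles = tuple(
        ImageTile(0, h, np.zeros(m.shape + (3,), dtype=np.uint8), np.zeros_like(m))
        for h, m in zip(HEADINGS, (big, big, big, small))
    )
    masks = [
        VegetationMask(0, h, m)
        for h, m in zip(HEADINGS, (big, big, big, small))
    ]
    pooled = green_view_index(TileSet(0, tiles), masks).value
    per_view_mean = np.mean([0.0, 0.0, 0.0, 1.0])
    assert pooled == 100 / 30100
    assert pooled != per_view_mean


def test_buffer_mean_is_unweighted():
    assert buffer_mean_gvi([0.2, 0.4]) == pytest.approx(0.3)
    assert buffer_mean_gvi([0.7]) == 0.7
    assert buffer_mean_gvi([0.42] * 9) == pytest.approx(0.42)
    with pytest.raises(MissingExposureError):
        buffer_mean_gvi([])


def test_buffer_mean_within_point_range(city):
    sampler = CityPointSampler(city)
    center = (city.config.width / 2, city.config.height / 2)
    idx = sampler.indices_in_buffer(center, 400)
    vals = sampler.field_values[idx]
    mean = sampler.buffer_mean_field(center, 400)
    assert vals.min() <= mean <= vals.max()


def test_truth_mask_pipeline_equals_truth_fraction_mean(city):
    """End-to-end oracle: with truth masks substituted for predictions the
    buffer mean equals the mean ground-truth fraction of the same tilesets."""
    d = Dwelling(0, city.config.width / 2, city.config.height / 2, 0, 0)
    style = RenderConfig(tile_size=32)
    sampler = CityPointSampler(city)
    table = compute_exposures(
        city, [d], radii=[150.0], mode="rendered", style=style,
        seed=13, use_truth_masks=True, sampler=sampler,
    )
    idx = sampler.indices_in_buffer((d.x, d.y), 150.0)
    assert len(idx) > 0
    expected = np.mean(
        [
            truth_green_fraction(
                render_tileset(sampler.xy[i], city, style, seed=13, point_id=int(i))
            )
            for i in idx
        ]
    )
    assert table["mean_gvi"].iloc[0] == pytest.approx(expected, abs=1e-12)
    assert table["n_points"].iloc[0] == len(idx)


def test_two_buffer_means_positively_correlated(city, dwellings):
    table = compute_exposures(city, dwellings[:200], radii=(400.0, 800.0))
    wide = table.pivot(index="dwelling_id", columns="radius", values="mean_gvi").dropna()
    r = np.corrcoef(wide[400.0], wide[800.0])[0, 1]
    assert r > 0.5


def test_empty_buffer_flagged_not_fatal(city):
    # a dwelling in a corner of a sparse custom network can have no points
    d = Dwelling(7, 10.0, 10.0, 0, 0)
    table = compute_exposures(city, [d], radii=[5.0])
    assert table["n_points"].iloc[0] == 0
    assert np.isnan(table["mean_gvi"].iloc[0])
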