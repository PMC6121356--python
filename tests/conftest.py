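import pytest

from greenwalk.city import CityConfig, generate_city, place_dwellings


@pytest.fixture(scope="session")
def small_config():
    """A compact city: fast to generate, still has all layers."""
    return CityConfig(
        width=2600.0,
        height=2600.0,
        street_spacing=150.0,
        n_blocks=40,
        n_shops=120,
        n_recreation=40,
        n_bus_stops=100,
        n_rail_stations=4,
        dwelling_margin=820.0,
    )


@pytest.fixture(scope="session")
def city(small_config):
    return generate_city(small_config, seed=11)


@pytest.fixture(scope="session")
def dwellings(city):
    return place_dwellings(city, 600, seed=3)
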