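import pytest

from berryflux import AggregateGeometry, MediumProperties, ModelParams


@pytest.fixture(scope="session")
def medium24() -> MediumProperties:
    """Seawater at the warm-measurement condition: 24 C, S 35."""
    return MediumProperties.for_conditions(temperature_c=24.0, salinity=35.0)


@pytest.fixture(scope="session")
def sphere_geometry() -> AggregateGeometry:
    """A 1.7 mm ESD aggregate with the ESD-implied volume."""
    return AggregateGeometry(esd_mm=1.7)


@pytest.fixture(scope="session")
def table_geometry() -> AggregateGeometry:
    """The budget-table convention: ESD 1.7 mm, working volume 2.8 mm^3."""
    return AggregateGeometry(esd_mm=1.7, volume_mm3=2.8)


@pytest.fixture(scope="session")
def default_model() -> ModelParams:
    return ModelParams()
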