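"""Shared fixtures: small deterministic synthetic inputs."""

import numpy as np
import pytest

from specularcue import (
    DEFAULT_GRID,
    IlluminantGeneratorParams,
    ReflectanceGeneratorParams,
    SceneConfig,
    Spectrum,
    generate_illuminant_pair,
    generate_reflectance_library,
)


@pytest.fixture(scope="session")
def illuminant_pair():
    return generate_illuminant_pair(IlluminantGeneratorParams(seed=7))


@pytest.fixture(scope="session")
def library():
    return generate_reflectance_library(ReflectanceGeneratorParams(size=150, seed=11))


@pytest.fixture(scope="session")
def big_library():
    return generate_reflectance_library(ReflectanceGeneratorParams(size=300, seed=13))


@pytest.fixture(scope="session")
def small_config():
    return SceneConfig(image_size=96)


@pytest.fixture()
def flat_illuminant():
    return Spectrum(DEFAULT_GRID, np.ones(DEFAULT_GRID.size), role="illuminant",
                    name="flat")


@pytest.fixture()
def gray_reflectance():
    return Spectrum(DEFAULT_GRID, np.full(DEFAULT_GRID.size, 0.5),
                    role="reflectance", name="gray")
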