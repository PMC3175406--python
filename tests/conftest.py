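import dataclasses

import numpy as np
import pytest

from paleodiet.sources import (
    HominidCondition,
    MixturePoint,
    SourceName,
    SourceSignature,
    build_geometry,
)
from paleodiet.synthetic import FoodwebParams, generate_foodweb


@pytest.fixture(scope="session")
def default_params() -> FoodwebParams:
    return FoodwebParams(seed=42)


@pytest.fixture(scope="session")
def foodweb(default_params):
    """Default synthetic dataset (records, truth) at seed 42."""
    return generate_foodweb(default_params)


@pytest.fixture(scope="session")
def noise_free_foodweb(default_params):
    params = dataclasses.replace(
        default_params, noise_sd=(0.0, 0.0), hominid_noise_sd=(0.0, 0.0)
    )
    return params, generate_foodweb(params)


def random_geometry(rng: np.random.Generator, min_proportion: float = 0.15):
    """A well-conditioned mixing geometry with an interior mixture.

    Vertices jitter around the typical food-web layout (fish high δ¹⁵N,
    meat high δ¹³C, plants low on both axes); the mixture is placed at a
    known proportion vector with every component >= min_proportion.
    Returns (geometry, true_proportions).
    """
    fish = np.array([-20.5, 12.0]) + rng.normal(0, [0.4, 0.8])
    meat = np.array([-19.0, 5.5]) + rng.normal(0, [0.3, 0.5])
    plants = np.array([-22.5, 1.5]) + rng.normal(0, [0.5, 0.8])
    p = rng.dirichlet([3.0, 3.0, 3.0])
    p = (1 - 3 * min_proportion) * p + min_proportion  # floor each component
    mix = p[0] * fish + p[1] * meat + p[2] * plants
    srcs = [
        SourceSignature(name, float(v[0]), 0.3, float(v[1]), 0.3)
        for name, v in zip(
            (SourceName.FISH, SourceName.MEAT, SourceName.PLANTS),
            (fish, meat, plants),
        )
    ]
    geometry = build_geometry(
        *srcs,
        MixturePoint(float(mix[0]), float(mix[1]), n_hominids=1),
        mode="average",
    )
    return geometry, p
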