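"""Shared fixtures: small rendered scenes and planted count matrices.

Everything is generated programmatically at test time; session scope keeps
the heavier objects shared across test modules.
"""

from __future__ import annotations

import numpy as np
import pytest

from fitsel import synthetic_data as syn


def small_scene_config(seed: int, **overrides) -> syn.SmfishSceneConfig:
    """A compact 36-cell scene with the default (resolvable) spot density."""
    kwargs = dict(image_shape=(700, 700, 3), n_cells=36, cell_radius=40.0,
                  spots_per_cell_mean=6.0, spot_sigma=1.1, seed=seed)
    kwargs.update(overrides)
    return syn.SmfishSceneConfig(**kwargs)


@pytest.fixture(scope="session")
def small_scene() -> syn.SmfishScene:
    return syn.render_smfish_scene(small_scene_config(seed=11))


@pytest.fixture(scope="session")
def default_counts() -> syn.CountMatrix:
    return syn.gen_count_matrix(syn.SyntheticCountsConfig(seed=1))


@pytest.fixture(scope="session")
def population():
    return syn.gen_population(syn.PopulationConfig(n_neurons=5000, seed=7))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
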