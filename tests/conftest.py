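import numpy as np
import pandas as pd
import pytest

from canopyweb import (
    HerbivoreOccurrence,
    PlotDataset,
    SyntheticConfig,
    TreeRecord,
    generate_forest,
    pool_plots,
    prune_dataset,
)


@pytest.fixture
def toy_dataset() -> PlotDataset:
    """Two plots, four trees, hand-written occurrences."""
    trees = [
        TreeRecord("T1", "P1", "Ficus alba", "Moraceae", 10.0),
        TreeRecord("T2", "P1", "Ficus alba", "Moraceae", 30.0),
        TreeRecord("T3", "P1", "Macaranga sp1", "Euphorbiaceae", 20.0),
        TreeRecord("T4", "P2", "Ficus alba", "Moraceae", 40.0),
    ]
    occ = [
        HerbivoreOccurrence("T1", "M1", 2),
        HerbivoreOccurrence("T2", "M1", 2),
        HerbivoreOccurrence("T2", "M2", 1),
        HerbivoreOccurrence("T3", "M2", 3),
        HerbivoreOccurrence("T4", "M3", 5),
    ]
    return PlotDataset.from_records(trees, occ)


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    """A scaled-down forest: quick to simulate, still multi-plot/multi-family."""
    return SyntheticConfig(
        n_plots=4,
        n_tree_species=20,
        n_herbivore_species=30,
        n_families=6,
        stems_per_plot_mean=40,
        stems_per_plot_sd=8,
        foliage_per_plot_mean=800,
        foliage_per_plot_sd=120,
        herbivores_per_plot_mean=250,
        herbivores_per_plot_sd=80,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_forest(small_config):
    return generate_forest(small_config)


@pytest.fixture(scope="session")
def small_pooled(small_forest):
    return pool_plots(prune_dataset(small_forest))


def random_matrix(rng: np.random.Generator, shape=(4, 6), max_count=9) -> np.ndarray:
    """Random quantitative matrix without all-zero rows/columns."""
    while True:
        a = rng.integers(0, max_count + 1, size=shape) * (rng.random(shape) < 0.6)
        if (a.sum(axis=0) > 0).all() and (a.sum(axis=1) > 0).all():
            return a.astype(float)
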