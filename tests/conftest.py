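import numpy as np
import pandas as pd
import pytest

from patchtraits import SpeciesGrid, StudyTables


def make_grid(array, plot_id="p1", **kw) -> SpeciesGrid:
    return SpeciesGrid(plot_id=plot_id, values=np.asarray(array, dtype=int), **kw)


def random_tables(seed=0, n_plots=6, n_species=5, n_traits=3, n_metrics=3) -> StudyTables:
    """Small random but valid study tables (positive abundances everywhere
    needed, no constant columns)."""
    rng = np.random.default_rng(seed)
    plots = [f"p{i}" for i in range(n_plots)]
    species = [f"s{i}" for i in range(n_species)]
    L = pd.DataFrame(
        rng.poisson(5, size=(n_plots, n_species)) + 1, index=plots, columns=species
    )
    R = pd.DataFrame(
        rng.normal(size=(n_plots, n_metrics)),
        index=plots,
        columns=[f"m{i}" for i in range(n_metrics)],
    )
    Q = pd.DataFrame(
        rng.normal(size=(n_species, n_traits)),
        index=species,
        columns=[f"t{i}" for i in range(n_traits)],
    )
    cov = pd.DataFrame(
        {
            "terrain_age_class": rng.choice(["ta1", "ta2", "ta3"], size=n_plots),
            "cobble_class": rng.choice(["ts1", "ts2", "ts3"], size=n_plots),
        },
        index=plots,
    )
    return StudyTables.from_frames(R, L, Q, cov)


@pytest.fixture
def small_tables() -> StudyTables:
    return random_tables(seed=42)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
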