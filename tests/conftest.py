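import logging

import numpy as np
import pandas as pd
import pytest

from parknest import CommunityMatrix, SiteAttributes
from parknest.synthetic import SyntheticSpec, generate_community, generate_traits


@pytest.fixture(autouse=True)
def _quiet_logs(caplog):
    # keep expected-warning spam (empty-row drops etc.) out of test output
    logging.getLogger("parknest").setLevel(logging.ERROR)
    yield


def make_matrix(cells, species=None, sites=None) -> CommunityMatrix:
    cells = np.asarray(cells)
    species = species or [f"sp{i}" for i in range(cells.shape[0])]
    sites = sites or [f"site{j}" for j in range(cells.shape[1])]
    return CommunityMatrix(pd.DataFrame(cells, index=species, columns=sites))


@pytest.fixture
def perfect_nested():
    return make_matrix([[1, 1, 1], [1, 1, 0], [1, 0, 0]])


@pytest.fixture
def group_table():
    return pd.DataFrame(
        {
            "is_passerine": [True, True, False, True, False],
            "is_resident": [True, False, True, True, True],
            "diet_guild": [
                "insectivorous",
                "insectivorous",
                "omnivorous",
                "granivorous",
                "omnivorous",
            ],
            "is_waterbird": [False, False, False, False, True],
        },
        index=[f"sp{i}" for i in range(5)],
    )


@pytest.fixture(scope="session")
def study_scale():
    """Synthetic community at the default study scale (17 parks, 95 species)."""
    spec = SyntheticSpec(seed=11)
    m, areas, groups = generate_community(spec)
    traits = generate_traits(spec.n_species, spec.trait_corr, seed=spec.seed)
    return m, areas, groups, traits


@pytest.fixture(scope="session")
def small_community():
    """Small, fast community for pipeline/null-model tests."""
    spec = SyntheticSpec(n_species=24, n_sites=8, theta=0.5, seed=5)
    m, areas, groups = generate_community(spec)
    traits = generate_traits(spec.n_species, spec.trait_corr, seed=spec.seed)
    return m, areas, groups, traits


@pytest.fixture
def areas_for():
    def _areas(m, values=None):
        values = values if values is not None else np.geomspace(200, 5, m.n_sites)
        return SiteAttributes(pd.Series(values, index=m.site_ids))

    return _areas
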