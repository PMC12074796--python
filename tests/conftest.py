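import numpy as np
import pandas as pd
import pytest

from reefstab.dataprep import WINDOW, CommunityMatrix


@pytest.fixture
def two_species_matrix():
    """The 2-species, 3-year community used in the hand-derived oracles."""
    return np.array([[1.0, 2.0, 3.0], [3.0, 1.0, 2.0]])


@pytest.fixture
def toy_traits():
    """Four species with simple length-weight coefficients."""
    return pd.DataFrame(
        {
            "species_id": ["a", "b", "c", "d"],
            "max_length": [10.0, 20.0, 40.0, 80.0],
            "growth_coeff": [0.8, 0.5, 0.3, 0.2],
            "trophic_level": [2.2, 3.0, 3.5, 4.2],
            "max_depth": [10.0, 20.0, 30.0, 50.0],
            "lw_a": [0.01, 0.01, 0.02, 0.01],
            "lw_b": [3.0, 3.0, 3.0, 3.1],
        }
    )


def make_matrix(site_id, series_by_species, surveyed_years):
    """Build a CommunityMatrix directly from per-species year -> value dicts."""
    years = sorted(surveyed_years)
    bio = pd.DataFrame(
        {y: [series_by_species[sp].get(y, 0.0) for sp in series_by_species] for y in years},
        index=list(series_by_species),
    )
    flags = pd.DataFrame("observed", index=bio.index, columns=bio.columns)
    return CommunityMatrix(site_id, bio.astype(float), flags, tuple(years))


@pytest.fixture
def make_community_matrix():
    return make_matrix


@pytest.fixture
def full_window():
    return list(WINDOW)
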