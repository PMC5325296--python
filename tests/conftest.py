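import numpy as np
import pandas as pd
import pytest

from riparia.io import CommunityMatrix, LandscapeTable, COVER_CLASSES


def community_from(array, samples_per_site=20, sites=None, species=None) -> CommunityMatrix:
    arr = np.asarray(array)
    sites = sites or [f"S{i+1}" for i in range(arr.shape[0])]
    species = species or [f"sp{j+1}" for j in range(arr.shape[1])]
    return CommunityMatrix(
        pd.DataFrame(arr, index=sites, columns=species), samples_per_site=samples_per_site
    )


def landscape_from(columns: dict, sites=None) -> LandscapeTable:
    """Build a LandscapeTable from non-cover columns, padding covers to 100%."""
    n = len(next(iter(columns.values())))
    sites = sites or [f"S{i+1}" for i in range(n)]
    df = pd.DataFrame(columns, index=sites)
    given = [c for c in COVER_CLASSES if c in df.columns]
    rest = [c for c in COVER_CLASSES if c not in df.columns]
    remainder = 100.0 - (df[given].sum(axis=1) if given else 0.0)
    for i, c in enumerate(rest):
        df[c] = remainder / len(rest) if len(rest) else 0.0
    return LandscapeTable(df)


@pytest.fixture
def toy_community() -> CommunityMatrix:
    return community_from(
        [[8, 1, 1, 0], [2, 0, 2, 4], [0, 2, 2, 4]],
        sites=["A", "B", "C"],
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20261001)
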