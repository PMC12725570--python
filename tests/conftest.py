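"""Shared fixtures: tiny hand-built networks and seeded random trees."""

import numpy as np
import pandas as pd
import pytest

from fcnflow.network import RiverNetwork


def make_reach_frame(
    downstream: list,
    lengths=None,
    areas=None,
    huc12=None,
    ecoregion=None,
    ids=None,
    **extra,
) -> pd.DataFrame:
    """Build a reach table from a downstream-pointer list (None = terminus)."""
    n = len(downstream)
    if ids is None:
        ids = [f"R{i:04d}" for i in range(n)]
    df = pd.DataFrame(
        {
            "reach_id": ids,
            "downstream_id": [None if d is None else ids[d] for d in downstream],
            "length_km": lengths if lengths is not None else np.ones(n),
            "drainage_area_km2": areas if areas is not None else np.ones(n) * 10.0,
            "ecoregion_id": ecoregion if ecoregion is not None else ["E0"] * n,
            "huc12_id": huc12 if huc12 is not None else ["H0"] * n,
        }
    )
    for k, v in extra.items():
        df[k] = v
    return df


def random_tree(n: int, seed: int, n_outlets: int = 1) -> RiverNetwork:
    """Random recursive in-forest with monotone accumulated drainage areas."""
    rng = np.random.default_rng(seed)
    downstream = [None] * n_outlets + [int(rng.integers(0, i)) for i in range(n_outlets, n)]
    local = rng.uniform(0.5, 5.0, n)
    acc = local.copy()
    for i in range(n - 1, n_outlets - 1, -1):
        acc[downstream[i]] += acc[i]
    lengths = rng.uniform(0.2, 8.0, n)
    return RiverNetwork(make_reach_frame(downstream, lengths=lengths, areas=acc))


@pytest.fixture
def chain3() -> RiverNetwork:
    """A → B → C (C is the terminus)."""
    df = make_reach_frame(
        [1, 2, None], lengths=[1.0, 2.0, 3.0], areas=[1.0, 3.0, 10.0],
        ids=["A", "B", "C"],
    )
    return RiverNetwork(df)


@pytest.fixture
def seven_reach_tree() -> RiverNetwork:
    """Binary-ish tree with outlet R0000 and six upstream reaches."""
    #      5 6
    #     3   4
    #      1 2
    #       0
    return RiverNetwork(
        make_reach_frame(
            [None, 0, 0, 1, 2, 3, 3],
            areas=[70, 40, 20, 30, 10, 10, 10],
        )
    )


@pytest.fixture(scope="session")
def small_synth():
    """A modest synthetic bundle shared by read-only tests."""
    from fcnflow.synth import SynthConfig, generate_dataset

    cfg = SynthConfig(
        n_reaches=600, n_outlets=6, n_waterfalls=8, n_dams=25,
        n_species=20, n_huc12=120, seed=42,
    )
    return generate_dataset(cfg)
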