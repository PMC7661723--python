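import numpy as np
import pandas as pd
import pytest

import reprogramome as rp


@pytest.fixture(scope="session")
def default_sim():
    """Default planted simulation (seed 7): counts + truth table."""
    spec = rp.SimSpec(seed=7)
    counts, truth = rp.simulate(spec)
    return spec, counts, truth


@pytest.fixture(scope="session")
def default_run(default_sim):
    """Full pipeline fit of the default simulation."""
    _, counts, truth = default_sim
    results = rp.ReprogramomeModel(counts).fit()
    return counts, truth, results


def make_counts(data: dict, groups: dict, times: dict | None = None) -> rp.CountMatrix:
    """Small count matrix from a dict of sample -> counts and sample -> group."""
    counts = pd.DataFrame(data)
    counts.index = [f"G{i}" for i in range(len(counts))]
    times = times or {}
    design = rp.SampleDesign(
        pd.DataFrame(
            {
                "sample": list(data),
                "group": [groups[s] for s in data],
                "time_h": [times.get(s, np.nan) for s in data],
                "replicate": range(1, len(data) + 1),
            }
        )
    )
    return rp.CountMatrix(counts, design)


@pytest.fixture
def toy_counts():
    """3 genes x 4 samples, two groups."""
    return make_counts(
        {
            "a1": [100, 50, 5],
            "a2": [110, 55, 6],
            "b1": [100, 200, 5],
            "b2": [90, 210, 4],
        },
        {"a1": "A", "a2": "A", "b1": "B", "b2": "B"},
    )
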