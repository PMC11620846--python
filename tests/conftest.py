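import numpy as np
import pandas as pd
import pytest

from coexistkit.importance import compute_importance
from coexistkit.io import QuadratRecord
from coexistkit.simulate import SimulationConfig, simulate_community


@pytest.fixture
def toy_records():
    """3 species over 2 plots of 2 quadrats; hand-checkable numbers."""
    return [
        QuadratRecord("p1", "q1", "A", 3, 30.0),
        QuadratRecord("p1", "q1", "B", 1, 10.0),
        QuadratRecord("p1", "q2", "B", 1, 10.0),
        QuadratRecord("p2", "q1", "A", 2, 20.0),
        QuadratRecord("p2", "q2", "C", 4, 40.0),
    ]


@pytest.fixture(scope="session")
def sim_community():
    """One seeded synthetic community with a conserved phylogeny."""
    cfg = SimulationConfig(seed=11, brownian_rate=1.0)
    records, envs, tree, truth = simulate_community(cfg)
    return {"cfg": cfg, "records": records, "envs": envs,
            "tree": tree, "truth": truth}


@pytest.fixture(scope="session")
def sim_iv(sim_community):
    iv = compute_importance(sim_community["records"])
    species = sim_community["truth"]["species"]
    plots = sim_community["truth"]["plots"]
    mat = iv.iv_matrix.reindex(index=species, columns=plots, fill_value=0.0)
    return iv, mat
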