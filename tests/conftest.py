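import numpy as np
import pandas as pd
import pytest

from medsupply.simulate import SimulationConfig, generate_panel
from medsupply.weights import SpatialWeights, knn_weights


@pytest.fixture(scope="session")
def default_panel():
    """One default synthetic panel (41 cities x 13 years) shared across tests."""
    panel, truth = generate_panel(SimulationConfig(seed=1))
    return panel, truth


@pytest.fixture(scope="session")
def default_weights(default_panel):
    panel, _ = default_panel
    geom = panel.drop_duplicates("city_id").sort_values("city_id")
    return knn_weights(geom[["u", "v"]].to_numpy(), ids=geom["city_id"].tolist())


@pytest.fixture
def toy_panel_3x2():
    """Hand-built 3-city x 2-year panel with simple indicator values."""
    return pd.DataFrame(
        {
            "city_id": ["A", "A", "B", "B", "C", "C"],
            "year": [2007, 2008] * 3,
            "u": [0.0, 0.0, 0.5, 0.5, 1.0, 1.0],
            "v": [0.0, 0.0, 1.0, 1.0, 0.0, 0.0],
            "population": [100.0, 110.0, 200.0, 210.0, 150.0, 160.0],
            "institutions": [10.0, 12.0, 15.0, 14.0, 9.0, 11.0],
            "beds": [500.0, 520.0, 900.0, 950.0, 400.0, 450.0],
            "doctors": [50.0, 55.0, 80.0, 82.0, 30.0, 45.0],
            "health_expenditure": [1e4, 1.2e4, 2.5e4, 2.4e4, 0.8e4, 1.1e4],
        }
    )


def random_weights(rng, n):
    """A random symmetric binary adjacency (connected enough for tests)."""
    adj = (rng.uniform(size=(n, n)) < 0.4).astype(float)
    adj = np.maximum(adj, adj.T)
    np.fill_diagonal(adj, 0.0)
    # ensure no islands: link unit i to i+1
    for i in range(n - 1):
        adj[i, i + 1] = adj[i + 1, i] = 1.0
    return SpatialWeights(ids=list(range(n)), matrix=adj).standardize()


def moran_double_loop(x, W):
    """Brute-force global Moran's I: naive double sum."""
    x = np.asarray(x, dtype=float)
    w = W.to_dense()
    n = len(x)
    z = x - x.mean()
    num = sum(w[i, j] * z[i] * z[j] for i in range(n) for j in range(n))
    return n / w.sum() * num / (z @ z)


def local_moran_double_loop(x, W):
    """Brute-force local Moran I_i with population-sd z-scores."""
    x = np.asarray(x, dtype=float)
    w = W.to_dense()
    n = len(x)
    z = (x - x.mean()) / x.std(ddof=0)
    return np.array([z[i] * sum(w[i, j] * z[j] for j in range(n)) for i in range(n)])
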