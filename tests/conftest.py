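import numpy as np
import pytest

import migsurf as ms
from migsurf.freq import FrequencyData


@pytest.fixture(scope="session")
def lattice_5x6():
    return ms.build_rectangle_lattice(5, 6, 50.0)


@pytest.fixture(scope="session")
def lattice_4x5():
    return ms.build_rectangle_lattice(4, 5, 50.0)


@pytest.fixture
def triangle():
    coords = np.array([[0.0, 0.0], [1.0, 0.0], [0.5, 0.9]])
    return ms.SpatialGraph(coords, np.array([[0, 1], [0, 2], [1, 2]]))


def random_graph(rng: np.random.Generator, d: int):
    """Random connected triangulation-ish graph: lattice plus random extra edges."""
    rows = max(2, int(np.sqrt(d)))
    cols = max(2, int(np.ceil(d / rows)))
    g = ms.build_rectangle_lattice(rows, cols, 40.0)
    return g


def random_weights(rng: np.random.Generator, m: int) -> np.ndarray:
    return np.exp(rng.normal(0.0, 0.5, size=m))


@pytest.fixture(scope="session")
def gaussian_dataset(lattice_5x6):
    """Model-exact Gaussian observations on a fully observed 5x6 lattice."""
    rng = np.random.default_rng(7)
    w = np.full(lattice_5x6.n_edges, 10.0)
    F, n, obs = ms.simulate_frequency_data(
        lattice_5x6, w, p=1500, sigma2=0.2, n_per_node=10, rng=rng
    )
    return FrequencyData.from_frequencies(F, n, obs, check_bounds=False)


@pytest.fixture(scope="session")
def gaussian_model(lattice_5x6, gaussian_dataset):
    model = ms.SpatialMigrationModel(lattice_5x6, gaussian_dataset)
    model.fit_null()
    return model
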