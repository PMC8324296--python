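"""Model-faithful synthetic data: GMRF frequencies and binomial genotypes.

The generator draws latent node allele frequencies from the same spatial
GMRF the estimator assumes — f_j ~ N(mu_j 1, mu_j(1-mu_j) L†) with mu_j
uniform on (0.1, 0.9) — and then samples diploid genotypes binomially at
observed nodes.  Three migration scenarios mirror classic study designs on
a rectangular habitat:

* ``homogeneous``  — one shared edge weight (isolation by distance);
* ``barrier``      — 10-fold reduced weights in the central longitude third;
* ``anisotropic``  — 5-fold higher weights on east–west oriented edges.

Sampling designs: ``dense`` (every node observed) or ``random`` (a 20%
random subset of nodes by default).  Because data come from the estimator's
own generative model, recovery targets (weight ratios, selected penalties)
are well defined; an external coalescent engine can be substituted upstream
by providing genotypes directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .grid import SpatialGraph, laplacian

DEG_PER_KM = 1.0 / 111.195  # at the equator; jitter scale only


@dataclass
class Scenario:
    """Ground-truth migration scenario on a rectangular habitat lattice.

    The default ``base_w`` of 10 puts pairwise resistance distances on the
    ~0.01–0.1 scale typical of continuous-range population structure, and
    keeps the Gaussian latent frequencies essentially inside (0, 1) so
    binomial genotype sampling is faithful to the observation model.
    """

    name: str = "homogeneous"
    base_w: float = 10.0
    barrier_factor: float = 0.1
    aniso_factor: float = 5.0
    sampling: str = "dense"          # "dense" | "random"
    sample_fraction: float = 0.2     # used when sampling == "random"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.name not in ("homogeneous", "barrier", "anisotropic"):
            raise ValueError(f"unknown scenario {self.name!r}")
        if self.base_w <= 0 or self.barrier_factor <= 0 or self.aniso_factor <= 0:
            raise ValueError("scenario factors must be positive")
        if self.sampling not in ("dense", "random"):
            raise ValueError("sampling must be 'dense' or 'random'")
        if not 0.0 < self.sample_fraction <= 1.0:
            raise ValueError("sample_fraction must lie in (0, 1]")


def barrier_edge_mask(graph: SpatialGraph) -> np.ndarray:
    """Edges whose midpoint longitude falls in the central third of the habitat."""
    lon = graph.node_coords[:, 0]
    mid = lon[graph.edges].mean(axis=1)
    lo, hi = lon.min(), lon.max()
    third = (hi - lo) / 3.0
    return (mid >= lo + third) & (mid <= hi - third)


def eastwest_edge_mask(graph: SpatialGraph, threshold_deg: float = 30.0) -> np.ndarray:
    """Edges oriented within ``threshold_deg`` of the east–west axis."""
    coords = graph.node_coords
    lat0 = float(coords[:, 1].mean())
    dlon = (coords[graph.edges[:, 1], 0] - coords[graph.edges[:, 0], 0]) * np.cos(
        np.radians(lat0)
    )
    dlat = coords[graph.edges[:, 1], 1] - coords[graph.edges[:, 0], 1]
    angle = np.degrees(np.arctan2(np.abs(dlat), np.abs(dlon)))
    return angle <= threshold_deg


def scenario_weights(graph: SpatialGraph, scenario: Scenario) -> np.ndarray:
    """Ground-truth edge weights for the scenario."""
    w = np.full(graph.n_edges, scenario.base_w, dtype=float)
    if scenario.name == "barrier":
        w[barrier_edge_mask(graph)] *= scenario.barrier_factor
    elif scenario.name == "anisotropic":
        w[eastwest_edge_mask(graph)] *= scenario.aniso_factor
    return w


def gmrf_sqrt(graph: SpatialGraph, w: np.ndarray) -> np.ndarray:
    """d x (d-1) factor H with H H' = L†, from the Laplacian eigendecomposition."""
    L = laplacian(graph, w).toarray()
    evals, evecs = scipy.linalg.eigh(L)
    # connected graph: exactly one (near-)zero eigenvalue, dropped
    return evecs[:, 1:] / np.sqrt(evals[1:])


def simulate_latent_frequencies(
    graph: SpatialGraph,
    w: np.ndarray,
    mu: np.ndarray,
    rng: np.random.Generator,
    clip: tuple[float, float] | None = (0.01, 0.99),
) -> np.ndarray:
    """Draw f_j ~ N(mu_j 1, mu_j(1-mu_j) L†) per SNP, clipped to ``clip``.

    Clipping keeps the Gaussian draws inside (0, 1) so they remain valid
    binomial success probabilities; pass ``clip=None`` for the raw Gaussian
    draws (e.g. when checking the prior-covariance algebra).  Returns a
    d x p matrix.
    """
    H = gmrf_sqrt(graph, w)
    p = len(mu)
    Z = rng.standard_normal((H.shape[1], p))
    f = mu[None, :] + np.sqrt(mu * (1.0 - mu))[None, :] * (H @ Z)
    if clip is not None:
        f = np.clip(f, clip[0], clip[1])
    return f


def observed_nodes(graph: SpatialGraph, scenario: Scenario, rng: np.random.Generator) -> np.ndarray:
    d = graph.n_nodes
    if scenario.sampling == "dense":
        return np.arange(d)
    n_obs = max(3, int(round(scenario.sample_fraction * d)))
    return np.sort(rng.choice(d, size=n_obs, replace=False))


@dataclass
class SimulatedDataset:
    genotypes: np.ndarray          # (n_individuals, p) in {0, 1, 2}
    sample_coords: np.ndarray      # (n_individuals, 2) lon/lat
    node_of_sample: np.ndarray     # true node of each individual
    observed_ids: np.ndarray
    w_true: np.ndarray
    mu_true: np.ndarray
    f_true: np.ndarray             # latent d x p frequencies (clipped)
    scenario: Scenario = field(repr=False, default=None)


def simulate_dataset(
    graph: SpatialGraph,
    scenario: Scenario,
    p: int = 1000,
    n_per_node: int = 10,
    mu_range: tuple[float, float] = (0.1, 0.9),
    clip: tuple[float, float] = (0.01, 0.99),
    coord_jitter_km: float | None = None,
) -> SimulatedDataset:
    """Full generative pipeline: GMRF frequencies -> binomial genotypes.

    Individuals (``n_per_node`` diploids per observed node) get coordinates
    jittered around their node so the nearest-node assignment step is
    exercised; the jitter is small enough never to flip the assignment.
    Fixing ``scenario.seed`` makes the output bit-identical across runs.
    """
    if p < 1 or n_per_node < 1:
        raise ValueError("p and n_per_node must be at least 1")
    rng = np.random.default_rng(scenario.seed)
    w = scenario_weights(graph, scenario)
    obs = observed_nodes(graph, scenario, rng)
    mu = rng.uniform(mu_range[0], mu_range[1], size=p)
    f = simulate_latent_frequencies(graph, w, mu, rng, clip=clip)
    node_of_sample = np.repeat(obs, n_per_node)
    genotypes = rng.binomial(2, f[node_of_sample, :]).astype(float)
    jitter_km = (
        0.05 * (graph.resolution_km or 50.0)
        if coord_jitter_km is None
        else coord_jitter_km
    )
    coords = graph.node_coords[node_of_sample] + rng.normal(
        scale=jitter_km * DEG_PER_KM, size=(len(node_of_sample), 2)
    )
    return SimulatedDataset(
        genotypes=genotypes,
        sample_coords=coords,
        node_of_sample=node_of_sample,
        observed_ids=obs,
        w_true=w,
        mu_true=mu,
        f_true=f,
        scenario=scenario,
    )


def simulate_frequency_data(
    graph: SpatialGraph,
    w: np.ndarray,
    p: int,
    sigma2: float,
    n_per_node: int,
    rng: np.random.Generator,
    observed_ids: np.ndarray | None = None,
    mu_range: tuple[float, float] = (0.1, 0.9),
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Observed node frequencies straight from the Gaussian observation model.

    Skips genotype sampling: F-hat = f_obs + N(0, sigma^2 mu(1-mu)/n), the
    exact model the likelihood assumes, which makes (w0, sigma^2) recovery
    checks well-posed.  No clipping is applied (the Gaussian model places no
    bounds on the observations); build the summaries with
    ``FrequencyData.from_frequencies(..., check_bounds=False)``.
    Returns (F_hat, n, observed_ids).
    """
    obs = np.arange(graph.n_nodes) if observed_ids is None else np.asarray(observed_ids)
    mu = rng.uniform(mu_range[0], mu_range[1], size=p)
    H = gmrf_sqrt(graph, w)
    Z = rng.standard_normal((H.shape[1], p))
    f = mu[None, :] + np.sqrt(mu * (1.0 - mu))[None, :] * (H @ Z)
    noise = rng.standard_normal((len(obs), p)) * np.sqrt(
        sigma2 * mu * (1.0 - mu) / n_per_node
    )
    F_hat = f[obs] + noise
    n = np.full(len(obs), n_per_node, dtype=np.int64)
    return F_hat, n, obs
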