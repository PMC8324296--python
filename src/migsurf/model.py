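"""Spatial GMRF model of allele-frequency covariance with smoothed edge weights.

The model: latent node frequencies follow a Gaussian Markov random field
whose precision is the weighted graph Laplacian L(w); observed node
frequencies add binomial sampling noise, approximated as a homoskedastic
residual variance sigma^2 scaled by mu_j(1 - mu_j) and the node sample
sizes.  After projecting out per-SNP means with an orthonormal contrast
basis C, the rescaled sample covariance follows a Wishart distribution with
scale C (A L† A' + sigma^2 diag(1/n)) C', which yields the negative
log-likelihood

    nll(w, sigma^2) = p * [ tr(M^{ -1} S) + log det M ],
    M = C V C',  S = C Sigma_hat C',  V = A L† A' + sigma^2 diag(1/n).

Edge weights are estimated by minimizing nll plus an adjacent-edge smoothness
penalty (lambda/2) || Delta log(exp(alpha w) - 1) ||^2, which smooths on a
log scale for weights well below 1/alpha and on a linear scale above it.
All Laplacian pseudo-inverse actions go through a grounded sparse/dense
factorization, never a dense d x d pseudo-inverse, so an objective/gradient
evaluation costs O(d o + o^3).
"""

from __future__ import annotations

import logging

import numpy as np
import scipy.linalg
import scipy.optimize
import scipy.sparse as sp

from .freq import FrequencyData, contrast_basis, qc_filter
from .grid import (
    LaplacianSolver,
    SpatialGraph,
    assign_samples,
    build_triangular_grid,
    edge_pair_incidence,
)
from .results import CVResults, MigrationResults, NullResults

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# penalty
# ---------------------------------------------------------------------------

def soft_logmap(w: np.ndarray, alpha: float) -> np.ndarray:
    """g(w) = log(exp(alpha w) - 1), computed stably for all alpha w > 0.

    g(w) ~ log(alpha w) for alpha w << 1 and ~ alpha w for alpha w >> 1,
    which is what interpolates the penalty between log- and linear-scale
    smoothing of the migration surface.
    """
    x = np.asarray(w, dtype=float) * alpha
    if np.any(x <= 0):
        raise ValueError("edge weights must be strictly positive")
    return x + np.log1p(-np.exp(-x))


def _soft_logmap_grad(w: np.ndarray, alpha: float) -> np.ndarray:
    # g'(w) = alpha / (1 - exp(-alpha w))
    return alpha / (-np.expm1(-alpha * np.asarray(w, dtype=float)))


def penalty(w: np.ndarray, lam: float, alpha: float, incidence: sp.spmatrix) -> float:
    """Smoothness penalty (lambda/2) || Delta g(w) ||^2 over adjacent edge pairs."""
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    if lam == 0:
        soft_logmap(w, alpha if alpha > 0 else 1.0)  # still validate positivity
        return 0.0
    diffs = incidence @ soft_logmap(w, alpha)
    return 0.5 * lam * float(diffs @ diffs)


def penalty_grad(
    w: np.ndarray, lam: float, alpha: float, incidence: sp.spmatrix
) -> np.ndarray:
    """Gradient lambda * g'(w) * Delta' Delta g(w) of the smoothness penalty."""
    if lam == 0:
        return np.zeros_like(np.asarray(w, dtype=float))
    g = soft_logmap(w, alpha)
    return lam * _soft_logmap_grad(w, alpha) * (incidence.T @ (incidence @ g))


# ---------------------------------------------------------------------------
# likelihood machinery
# ---------------------------------------------------------------------------

def marginal_covariance(
    graph: SpatialGraph,
    w: np.ndarray,
    sigma2: float,
    n: np.ndarray,
    observed_ids: np.ndarray,
) -> np.ndarray:
    """V = A L† A' + sigma^2 diag(1/n) over the observed nodes.

    Computed through grounded-Laplacian solves on one-hot right-hand sides
    (cost O(d o + o^3)), never a dense pseudo-inverse.
    """
    observed_ids = np.asarray(observed_ids)
    o = len(observed_ids)
    B = np.zeros((graph.n_nodes, o))
    B[observed_ids, np.arange(o)] = 1.0
    Y = LaplacianSolver(graph, w).solve_pinv(B)
    V = Y[observed_ids]
    V = 0.5 * (V + V.T)
    return V + sigma2 * np.diag(1.0 / np.asarray(n, dtype=float))


def _chol_contrast(M: np.ndarray, o_minus_1: int):
    """Cholesky of the contrast-projected covariance, with a logged jitter retry."""
    try:
        return scipy.linalg.cho_factor(M, lower=True, check_finite=False)
    except scipy.linalg.LinAlgError:
        eps = 1e-12 * np.trace(M) / max(o_minus_1, 1)
        logger.warning("contrast covariance not PD; retrying with jitter %.3e", eps)
        try:
            return scipy.linalg.cho_factor(
                M + eps * np.eye(M.shape[0]), lower=True, check_finite=False
            )
        except scipy.linalg.LinAlgError as err:
            raise np.linalg.LinAlgError(
                "contrast-projected covariance is singular; consider a larger "
                "residual-variance lower bound"
            ) from err


class SpatialMigrationModel:
    """Penalized-likelihood model of effective migration on a spatial lattice.

    Parameters
    ----------
    graph : SpatialGraph
        Triangular lattice over the habitat.
    data : FrequencyData
        Observed-node frequency summaries; ``data.observed_ids`` indexes
        graph nodes and defines the assignment used by the likelihood.

    The typical workflow is ``fit_null()`` (homogeneous isolation-by-distance
    fit of the weight scale w0 and residual variance sigma^2), then ``fit``
    or ``fit_regularization_path`` at one or more penalty strengths, and
    ``loocv`` to pick the penalty by held-out prediction error.
    """

    def __init__(self, graph: SpatialGraph, data: FrequencyData):
        if data.observed_ids.max() >= graph.n_nodes:
            raise ValueError("observed node ids exceed graph size")
        self.graph = graph
        self.data = data
        self.o = data.n_observed
        self.p = data.n_snps
        self.C = contrast_basis(self.o)
        self.S = self.C @ data.Sigma_hat @ self.C.T
        self.incidence = edge_pair_incidence(graph)
        self._B = np.zeros((graph.n_nodes, self.o))
        self._B[data.observed_ids, np.arange(self.o)] = 1.0
        self._inv_n = 1.0 / np.asarray(data.n, dtype=float)
        self._null: NullResults | None = None

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_genotypes(
        cls,
        genotypes: np.ndarray,
        sample_coords: np.ndarray,
        graph: SpatialGraph | None = None,
        polygon: np.ndarray | None = None,
        resolution: float | None = None,
        maf_min: float = 0.05,
        miss_max: float = 0.10,
    ) -> "SpatialMigrationModel":
        """Build the model from raw genotypes and sample coordinates.

        Either pass a pre-built ``graph`` or a habitat ``polygon`` plus grid
        ``resolution`` (km).  Genotypes are QC-filtered, samples are attached
        to their nearest lattice node, and node frequencies estimated.
        """
        if graph is None:
            if polygon is None or resolution is None:
                raise ValueError("provide either graph or (polygon, resolution)")
            graph = build_triangular_grid(polygon, resolution)
        G, report = qc_filter(genotypes, maf_min=maf_min, miss_max=miss_max)
        logger.info(
            "QC: retained %d / %d SNPs", report.n_retained, report.n_input
        )
        node_of_sample = assign_samples(sample_coords, graph)
        data = FrequencyData.from_genotypes(G, node_of_sample)
        return cls(graph, data)

    # -- objective / gradient ----------------------------------------------

    def _graph_solve(self, w: np.ndarray) -> np.ndarray:
        """Y = L† A' for the current observed set (d x o)."""
        return LaplacianSolver(self.graph, w).solve_pinv(self._B)

    def neg_loglik(self, w: np.ndarray, sigma2: float) -> float:
        """p * [tr(M^{-1} S) + log det M] with M the contrast-projected covariance."""
        return self._eval(w, sigma2, want_grad=False)[0]

    def _eval(self, w: np.ndarray, sigma2: float, want_grad: bool = True):
        Y = self._graph_solve(w)
        V = Y[self.data.observed_ids]
        V = 0.5 * (V + V.T) + sigma2 * np.diag(self._inv_n)
        M = self.C @ V @ self.C.T
        M = 0.5 * (M + M.T)
        cf = _chol_contrast(M, self.o - 1)
        MinvS = scipy.linalg.cho_solve(cf, self.S, check_finite=False)
        logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
        f = self.p * (np.trace(MinvS) + logdet)
        if not want_grad:
            return f, None
        Minv = scipy.linalg.cho_solve(
            cf, np.eye(self.o - 1), check_finite=False
        )
        G = self.p * (Minv - MinvS @ Minv)
        G = 0.5 * (G + G.T)
        U = Y @ self.C.T                       # d x (o-1)
        Z = U @ G
        ei, ej = self.graph.edges[:, 0], self.graph.edges[:, 1]
        dU = U[ei] - U[ej]
        dZ = Z[ei] - Z[ej]
        grad = -np.einsum("ij,ij->i", dU, dZ)
        return f, grad

    def objective(
        self, w: np.ndarray, sigma2: float, lam: float, alpha: float
    ) -> float:
        return self.neg_loglik(w, sigma2) + penalty(w, lam, alpha, self.incidence)

    def objective_grad(
        self, w: np.ndarray, sigma2: float, lam: float, alpha: float
    ) -> np.ndarray:
        """Analytic gradient of nll + penalty with respect to the edge weights."""
        _, g = self._eval(w, sigma2, want_grad=True)
        return g + penalty_grad(w, lam, alpha, self.incidence)

    # -- null (constant-w) fit ---------------------------------------------

    def fit_null(
        self,
        w0_init: float | None = None,
        sigma2_init: float = 0.5,
        maxiter: int = 1000,
    ) -> NullResults:
        """Homogeneous isolation-by-distance fit of (w0, sigma^2).

        Maximizes the marginal likelihood with a single shared edge weight by
        Nelder-Mead simplex search in log-parameter space.  The estimated
        residual variance is frozen for all subsequent penalized fits, and
        w0 sets both the penalized fit's initialization and the default
        penalty scale alpha = 1 / w0.
        """
        ones = np.ones(self.graph.n_edges)
        if w0_init is None:
            # heuristic: match mean unit-weight resistance to mean genetic distance
            V1 = marginal_covariance(
                self.graph, ones, 0.0, self.data.n, self.data.observed_ids
            )
            dg = np.diag(V1)
            R1 = dg[:, None] + dg[None, :] - 2.0 * V1
            off = ~np.eye(self.o, dtype=bool)
            denom = float(np.mean(self.data.D_hat[off]))
            w0_init = float(np.mean(R1[off])) / denom if denom > 0 else 1.0
            w0_init = max(w0_init, 1e-8)

        def nm_objective(theta: np.ndarray) -> float:
            w0, s2 = np.exp(theta)
            return self.neg_loglik(w0 * ones, s2)

        res = scipy.optimize.minimize(
            nm_objective,
            x0=np.log([w0_init, sigma2_init]),
            method="Nelder-Mead",
            options={"maxiter": maxiter, "xatol": 1e-8, "fatol": 1e-8},
        )
        if not res.success:
            raise RuntimeError(
                f"constant-weight null fit did not converge: {res.message} "
                f"(nit={res.nit}, final objective {res.fun:.6g})"
            )
        w0, s2 = np.exp(res.x)
        null = NullResults(
            w0=float(w0),
            sigma2=float(s2),
            nll=float(res.fun),
            n_iter=int(res.nit),
            converged=True,
            message=str(res.message),
        )
        self._null = null
        return null

    @property
    def null_fit(self) -> NullResults:
        if self._null is None:
            self.fit_null()
        return self._null

    # -- penalized fit ------------------------------------------------------

    def fit(
        self,
        lam: float,
        alpha: float | None = None,
        w_init: np.ndarray | None = None,
        sigma2: float | None = None,
        lower: float | None = None,
        upper: float | None = None,
        gtol: float | None = None,
        maxiter: int = 1000,
        init_label: str = "null",
    ) -> MigrationResults:
        """Box-constrained quasi-Newton (L-BFGS-B) fit of the edge weights.

        Optimization runs on log-weights so positivity is structural; bounds
        default to [1e-6 * w0, +inf).  ``alpha`` defaults to 1 / w0 and
        ``w_init`` to the constant w0 surface, both from :meth:`fit_null`.
        Optimizer failure is reported through ``converged``/``message`` on
        the result, not as an exception.
        """
        null = self.null_fit
        sigma2 = null.sigma2 if sigma2 is None else float(sigma2)
        alpha = 1.0 / null.w0 if alpha is None else float(alpha)
        m = self.graph.n_edges
        w_init = (
            np.full(m, null.w0) if w_init is None else np.asarray(w_init, dtype=float)
        )
        lower = 1e-6 * null.w0 if lower is None else lower
        if np.any(w_init < lower) or (upper is not None and np.any(w_init > upper)):
            raise ValueError("w_init violates the box constraints")
        gtol = 1e-6 * self.p if gtol is None else gtol
        z_bounds = [(np.log(lower), None if upper is None else np.log(upper))] * m
        trace: list[float] = []

        last_f = [np.inf]

        def fun_grad(z: np.ndarray):
            w = np.exp(z)
            f, g_nll = self._eval(w, sigma2, want_grad=True)
            f += penalty(w, lam, alpha, self.incidence)
            g = (g_nll + penalty_grad(w, lam, alpha, self.incidence)) * w
            last_f[0] = f
            return f, g

        def callback(z: np.ndarray) -> None:
            # objective at the accepted iterate (last line-search evaluation)
            trace.append(last_f[0])

        res = scipy.optimize.minimize(
            fun_grad,
            x0=np.log(w_init),
            jac=True,
            method="L-BFGS-B",
            bounds=z_bounds,
            callback=callback,
            options={"maxiter": maxiter, "gtol": gtol, "ftol": 1e-11},
        )
        w_fit = np.exp(res.x)
        # projected gradient: zero where the lower/upper bound is active
        g = np.asarray(res.jac, dtype=float)
        at_lb = (res.x <= z_bounds[0][0] + 1e-12) & (g > 0)
        proj = np.where(at_lb, 0.0, g)
        return MigrationResults(
            w=w_fit,
            lam=float(lam),
            alpha=alpha,
            sigma2=sigma2,
            w0=null.w0,
            objective=float(res.fun),
            objective_trace=np.asarray(trace),
            grad_norm=float(np.max(np.abs(proj))) if m else 0.0,
            converged=bool(res.success),
            message=str(res.message),
            n_iter=int(res.nit),
            init=init_label,
            graph=self.graph,
            model=self,
        )

    def fit_regularization_path(
        self,
        lam_grid: np.ndarray,
        alpha: float | None = None,
        sigma2: float | None = None,
        warm_start: bool = True,
        **fit_kwargs,
    ) -> list[MigrationResults]:
        """Warm-started fits over a descending penalty-strength grid.

        The strongest penalty is fit first from the constant-w0 surface; each
        subsequent fit starts from the previous solution (``warm_start=False``
        restarts every fit from the constant-w0 surface instead, which is
        mainly useful for comparing the two strategies).  A failed fit is
        recorded and the path continues from the last good solution.
        Results are returned in the (descending) grid order.
        """
        lam_grid = np.sort(np.asarray(lam_grid, dtype=float))[::-1]
        null = self.null_fit
        w_start = np.full(self.graph.n_edges, null.w0)
        results: list[MigrationResults] = []
        label = "null"
        for lam in lam_grid:
            try:
                res = self.fit(
                    lam,
                    alpha=alpha,
                    sigma2=sigma2,
                    w_init=w_start,
                    init_label=label,
                    **fit_kwargs,
                )
            except Exception as err:  # keep the path alive past one bad lambda
                logger.warning("fit at lambda=%.4g failed: %s", lam, err)
                res = MigrationResults(
                    w=w_start.copy(),
                    lam=float(lam),
                    alpha=alpha if alpha is not None else 1.0 / null.w0,
                    sigma2=sigma2 if sigma2 is not None else null.sigma2,
                    w0=null.w0,
                    objective=np.nan,
                    objective_trace=np.empty(0),
                    grad_norm=np.nan,
                    converged=False,
                    message=f"fit failed: {err}",
                    n_iter=0,
                    init=label,
                    graph=self.graph,
                    model=self,
                )
            results.append(res)
            if warm_start and res.converged:
                w_start = res.w
                label = f"warm:lam={lam:.4g}"
        return results

    # -- model selection ----------------------------------------------------

    def loocv(
        self,
        lam_grid: np.ndarray | None = None,
        alpha: float | None = None,
        n_folds: int | None = None,
        rng: np.random.Generator | None = None,
        **fit_kwargs,
    ) -> CVResults:
        from .crossval import loocv as _loocv

        return _loocv(
            self, lam_grid=lam_grid, alpha=alpha, n_folds=n_folds, rng=rng,
            **fit_kwargs,
        )


def default_lambda_grid(num: int = 15) -> np.ndarray:
    """Log-spaced penalty grid from 1e-3 to 1e2, descending."""
    return np.logspace(2, -3, num)
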