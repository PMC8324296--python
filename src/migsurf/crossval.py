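"""Penalty selection by leave-one-observed-node-out cross-validation.

Each fold removes one observed node, refits the whole pipeline on the
remaining nodes (its own constant-weight stage, then a warm-started
regularization path over a descending penalty grid), and predicts the
held-out node's allele frequencies from the Gaussian conditional mean under
the fitted spatial covariance.  The penalty strength with the smallest mean
squared prediction error, averaged over SNPs and then over folds, wins.
"""

from __future__ import annotations

import logging

import numpy as np
import scipy.linalg

from .freq import FrequencyData
from .grid import SpatialGraph
from .model import default_lambda_grid, marginal_covariance
from .results import CVResults, MigrationResults

logger = logging.getLogger(__name__)


def conditional_prediction(
    graph: SpatialGraph,
    w: np.ndarray,
    sigma2: float,
    F_train: np.ndarray,
    n_all: np.ndarray,
    observed_all: np.ndarray,
    heldout_pos: np.ndarray,
    mu_train: np.ndarray,
) -> np.ndarray:
    """Gaussian conditional mean of held-out node frequencies given the rest.

    Per SNP j the model is f-hat_j ~ N(mu_j 1, mu_j(1-mu_j) V) with
    V = A L† A' + sigma^2 diag(1/n) over all observed nodes; the conditional
    mean is mu_j + V[val, tr] V[tr, tr]^{-1} (f-hat_tr - mu_j 1).  The SNP
    scale factor mu_j(1-mu_j) cancels between the two covariance blocks.

    ``heldout_pos`` indexes rows of the full observed set; ``F_train`` and
    ``mu_train`` are in the training rows' order.  Returns an
    (n_heldout, p) matrix of predicted frequencies.
    """
    heldout_pos = np.atleast_1d(heldout_pos)
    o = len(observed_all)
    train_pos = np.setdiff1d(np.arange(o), heldout_pos)
    V = marginal_covariance(graph, w, sigma2, n_all, observed_all)
    T = V[np.ix_(train_pos, train_pos)]
    B = V[np.ix_(train_pos, heldout_pos)]
    cf = scipy.linalg.cho_factor(T, lower=True, check_finite=False)
    coef = scipy.linalg.cho_solve(cf, B, check_finite=False)  # (o-h) x h
    resid = F_train - mu_train[None, :]
    return mu_train[None, :] + coef.T @ resid


def predict_heldout(
    fit: MigrationResults, data_full: FrequencyData, heldout_pos: int
) -> np.ndarray:
    """Predict one held-out node's frequencies from a fit that excluded it.

    ``fit`` must come from a model built on ``data_full`` minus the held-out
    row; its training data supplies the mean frequencies and residual
    variance (nothing from the held-out node enters the predictor).
    """
    model = fit.model
    if model is None:
        raise ValueError("fit does not carry its model; cannot predict")
    data_tr = model.data
    if data_full.observed_ids[heldout_pos] in data_tr.observed_ids:
        raise ValueError("held-out node was part of the fit's training data")
    pred = conditional_prediction(
        fit.graph,
        fit.w,
        fit.sigma2,
        data_tr.F_hat,
        data_full.n,
        data_full.observed_ids,
        np.array([heldout_pos]),
        data_tr.mu_hat,
    )
    return pred[0]


def select_lambda(
    lam_grid: np.ndarray, mean_errors: np.ndarray, tie_rtol: float = 1e-3
) -> float:
    """Pick the penalty with minimum mean CV error, ties toward more smoothing.

    Mean errors within ``tie_rtol`` (relative) of the minimum are treated as
    tied: on the flat part of the CV curve the fits differ only by optimizer
    termination noise, orders of magnitude below fold-to-fold sampling
    variability, and the more regularized model is preferred.
    """
    lam_grid = np.asarray(lam_grid, dtype=float)
    mean_errors = np.asarray(mean_errors, dtype=float)
    best = float(np.min(mean_errors))
    tied = mean_errors <= best * (1.0 + tie_rtol)
    return float(np.max(lam_grid[tied]))


def loocv_2d(
    model,
    lam_grid: np.ndarray,
    alpha_grid: np.ndarray,
    **kwargs,
) -> CVResults:
    """Joint (lambda, alpha) search by cross-validating lambda at each alpha.

    Off by default everywhere: fixing alpha = 1/w0 from each fold's own
    constant-weight stage performs well and avoids the two-dimensional
    search cost.  Returns the best alpha's CVResults with ``alpha_star`` set;
    the winning pair minimizes the fold-averaged error, with the same
    near-tie preference for stronger smoothing within each alpha.
    """
    best: CVResults | None = None
    for alpha in np.asarray(alpha_grid, dtype=float):
        cv = loocv(model, lam_grid=lam_grid, alpha=float(alpha), **kwargs)
        cv.alpha_star = float(alpha)
        if best is None or cv.mean_errors.min() < best.mean_errors.min():
            best = cv
    return best


def loocv(
    model,
    lam_grid: np.ndarray | None = None,
    alpha: float | None = None,
    n_folds: int | None = None,
    rng: np.random.Generator | None = None,
    max_invalid_frac: float = 0.1,
    tie_rtol: float = 1e-3,
    **fit_kwargs,
) -> CVResults:
    """Cross-validate the penalty strength by held-out node prediction error.

    Parameters
    ----------
    model : SpatialMigrationModel
        Fitted-data model on the full observed set.
    lam_grid : array, optional
        Penalty strengths; sorted descending internally (default 15 log-spaced
        values from 1e2 down to 1e-3).
    alpha : float, optional
        Penalty scale.  By default each fold uses 1 / w0 from its own
        constant-weight stage, so no full-data quantity reaches a fold.
    n_folds : int, optional
        If given and smaller than o, observed nodes are partitioned at random
        into this many groups (k-fold variant; leave-one-out is the default
        and recommended mode).

    Notes
    -----
    Every fold refits its own constant-weight stage (w0, sigma^2) and runs a
    warm-started regularization path, strongest penalty first.  A fold whose
    fits fail is dropped with a warning as long as fewer than
    ``max_invalid_frac`` of folds fail.
    """
    from .model import SpatialMigrationModel

    data = model.data
    graph = model.graph
    o = data.n_observed
    if o < 3:
        raise ValueError("cross-validation needs at least 3 observed nodes")
    lam_grid = (
        default_lambda_grid() if lam_grid is None else np.asarray(lam_grid, dtype=float)
    )
    lam_grid = np.sort(lam_grid)[::-1]

    if n_folds is None or n_folds >= o:
        fold_nodes = [np.array([k]) for k in range(o)]
    else:
        rng = np.random.default_rng(0) if rng is None else rng
        perm = rng.permutation(o)
        fold_nodes = [np.sort(chunk) for chunk in np.array_split(perm, n_folds)]

    n_fold = len(fold_nodes)
    errors = np.full((n_fold, len(lam_grid)), np.nan)
    n_invalid = 0
    for f, heldout in enumerate(fold_nodes):
        try:
            data_tr, cols = data.drop_nodes(heldout)
            m_tr = SpatialMigrationModel(graph, data_tr)
            m_tr.fit_null()
            path = m_tr.fit_regularization_path(lam_grid, alpha=alpha, **fit_kwargs)
            F_val = data.F_hat[np.ix_(heldout, np.flatnonzero(cols))]
            for i, res in enumerate(path):
                pred = conditional_prediction(
                    graph,
                    res.w,
                    res.sigma2,
                    data_tr.F_hat,
                    data.n,
                    data.observed_ids,
                    heldout,
                    data_tr.mu_hat,
                )
                # mean over SNPs of the squared error, then over held-out nodes
                errors[f, i] = float(np.mean(np.mean((pred - F_val) ** 2, axis=1)))
        except Exception as err:
            n_invalid += 1
            logger.warning("CV fold %d (nodes %s) failed: %s", f, heldout, err)
    if n_invalid and n_invalid / n_fold >= max_invalid_frac:
        raise RuntimeError(
            f"{n_invalid} of {n_fold} CV folds failed; cannot select lambda"
        )
    valid = ~np.isnan(errors).any(axis=1)
    mean_errors = errors[valid].mean(axis=0)
    lam_star = select_lambda(lam_grid, mean_errors, tie_rtol=tie_rtol)
    return CVResults(
        lam_grid=lam_grid,
        errors=errors,
        mean_errors=mean_errors,
        lam_star=lam_star,
        fold_nodes=[fn.tolist() for fn in fold_nodes],
        n_invalid_folds=n_invalid,
    )
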