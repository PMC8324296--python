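"""Allele-frequency summaries consumed by the spatial likelihood.

Genotypes (0/1/2 allele counts, NaN = missing) plus a sample-to-node
assignment are collapsed to per-node frequency estimates F-hat, node sample
sizes n, SNP mean frequencies mu-hat, the variance-rescaled frequency matrix,
and the o x o covariance / genetic-distance summaries the Wishart likelihood
is written in terms of.  The mean frequencies enter everywhere (rescaling,
likelihood, held-out prediction) and are estimated exactly once per dataset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg


class QCError(ValueError):
    pass


@dataclass
class QCReport:
    n_input: int
    n_retained: int
    n_removed_maf: int
    n_removed_missing: int


def qc_filter(
    genotypes: np.ndarray, maf_min: float = 0.05, miss_max: float = 0.10
) -> tuple[np.ndarray, QCReport]:
    """Drop SNPs by minor-allele-frequency and missingness thresholds.

    SNPs are retained when MAF >= ``maf_min`` (boundary kept) and the missing
    fraction is <= ``miss_max``.  Raises :class:`QCError` if nothing survives.
    """
    G = np.asarray(genotypes, dtype=float)
    if G.ndim != 2:
        raise ValueError("genotypes must be a 2-D (individuals x SNPs) matrix")
    n, p = G.shape
    miss = np.isnan(G)
    n_obs = (~miss).sum(axis=0)
    with np.errstate(invalid="ignore"):
        freq = np.nansum(G, axis=0) / np.maximum(2.0 * n_obs, 1.0)
    maf = np.minimum(freq, 1.0 - freq)
    maf_ok = maf >= maf_min
    miss_ok = miss.mean(axis=0) <= miss_max
    keep = maf_ok & miss_ok & (n_obs > 0)
    report = QCReport(
        n_input=p,
        n_retained=int(keep.sum()),
        n_removed_maf=int((~maf_ok).sum()),
        n_removed_missing=int((~miss_ok).sum()),
    )
    if report.n_retained == 0:
        raise QCError("all SNPs removed by QC filters")
    return G[:, keep], report


def estimate_frequencies(
    genotypes: np.ndarray, node_of_sample: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-node allele frequency MLEs f-hat = (allele count) / (2 * non-missing).

    Returns ``(F_hat, n, observed_ids)`` where rows of the o x p matrix
    ``F_hat`` follow the ascending order of ``observed_ids`` and ``n`` counts
    individuals per observed node (the sample-size vector of the observation
    model).  A node with every genotype missing at some SNP gets the
    cross-node mean frequency imputed there, with a warning.
    """
    G = np.asarray(genotypes, dtype=float)
    node_of_sample = np.asarray(node_of_sample)
    if G.shape[0] != node_of_sample.shape[0]:
        raise ValueError("one node assignment per individual is required")
    observed = np.unique(node_of_sample)
    o, p = len(observed), G.shape[1]
    F = np.empty((o, p))
    counts = np.empty(o, dtype=np.int64)
    n_imputed = 0
    for k, node in enumerate(observed):
        block = G[node_of_sample == node]
        counts[k] = block.shape[0]
        n_obs = (~np.isnan(block)).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            F[k] = np.nansum(block, axis=0) / (2.0 * n_obs)
        n_imputed += int((n_obs == 0).sum())
    if n_imputed:
        col_mean = np.nanmean(F, axis=0)
        mask = np.isnan(F)
        F[mask] = np.broadcast_to(col_mean, F.shape)[mask]
        warnings.warn(
            f"{n_imputed} node x SNP cell(s) had no non-missing genotypes; "
            "imputed with the cross-node mean frequency",
            stacklevel=2,
        )
    return F, counts, observed


def contrast_basis(o: int) -> np.ndarray:
    """Deterministic (o-1) x o orthonormal basis orthogonal to the ones vector.

    Helmert sub-matrix; rows are sign-fixed with a positive first nonzero
    entry so the basis is reproducible across platforms.
    """
    if o < 2:
        raise ValueError("need at least 2 observed nodes for contrasts")
    C = scipy.linalg.helmert(o, full=False)
    for i in range(C.shape[0]):
        nz = C[i, np.abs(C[i]) > 1e-12]
        if nz.size and nz[0] < 0:
            C[i] = -C[i]
    return C


@dataclass
class FrequencyData:
    """Frequency summaries at observed nodes.

    Fields follow the observation model: ``F_hat`` (o x p frequencies in
    [0, 1]), ``n`` (individuals per node), ``mu_hat`` (SNP means over nodes),
    ``F_scaled`` (columns divided by sqrt(mu(1-mu))), ``Sigma_hat`` =
    F_scaled F_scaled' / p, and the genetic distance ``D_hat`` with
    D_kl = mean_j (f_k - f_l)^2 / (mu_j (1 - mu_j)).
    """

    F_hat: np.ndarray
    n: np.ndarray
    observed_ids: np.ndarray
    mu_hat: np.ndarray
    F_scaled: np.ndarray
    Sigma_hat: np.ndarray
    D_hat: np.ndarray

    @property
    def n_observed(self) -> int:
        return self.F_hat.shape[0]

    @property
    def n_snps(self) -> int:
        return self.F_hat.shape[1]

    @classmethod
    def from_frequencies(
        cls,
        F_hat: np.ndarray,
        n: np.ndarray,
        observed_ids: np.ndarray,
        check_bounds: bool = True,
    ) -> "FrequencyData":
        """Build all summaries from node frequencies; drops monomorphic SNPs.

        ``check_bounds=False`` admits frequencies outside [0, 1], which occur
        when observations come straight from the Gaussian observation model
        rather than from genotype counts.
        """
        F_hat = np.asarray(F_hat, dtype=float)
        n = np.asarray(n)
        observed_ids = np.asarray(observed_ids)
        if F_hat.ndim != 2 or F_hat.shape[0] != len(n) or len(n) != len(observed_ids):
            raise ValueError("inconsistent F_hat / n / observed_ids shapes")
        if check_bounds and (np.any(F_hat < 0) or np.any(F_hat > 1)):
            raise ValueError("frequencies must lie in [0, 1]")
        if np.any(n < 1):
            raise ValueError("every observed node needs at least one individual")
        mu = F_hat.mean(axis=0)
        poly = (mu > 0.0) & (mu < 1.0)
        if not np.all(poly):
            warnings.warn(
                f"dropping {int((~poly).sum())} SNP(s) monomorphic across "
                "observed nodes (mean frequency 0 or 1)",
                stacklevel=2,
            )
            F_hat = F_hat[:, poly]
            mu = mu[poly]
        if F_hat.shape[1] == 0:
            raise QCError("no polymorphic SNPs left after node assignment")
        F_scaled, Sigma = rescale(F_hat, mu)
        D = genetic_distance_from_covariance(Sigma)
        return cls(F_hat, n, observed_ids, mu, F_scaled, Sigma, D)

    @classmethod
    def from_genotypes(
        cls, genotypes: np.ndarray, node_of_sample: np.ndarray
    ) -> "FrequencyData":
        F, counts, observed = estimate_frequencies(genotypes, node_of_sample)
        return cls.from_frequencies(F, counts, observed)

    def drop_nodes(self, heldout: np.ndarray) -> tuple["FrequencyData", np.ndarray]:
        """Summaries recomputed without the given observed-node rows (CV folds).

        Mean frequencies, rescaling and covariances are re-estimated from the
        remaining rows only, so nothing about the dropped nodes leaks into a
        fold's fit.  Returns the training-rows data plus the boolean mask of
        SNP columns that stay polymorphic (and hence usable) in the fold.
        """
        keep = np.ones(self.n_observed, dtype=bool)
        keep[np.asarray(heldout)] = False
        if keep.sum() < 2:
            raise ValueError("a fold must retain at least 2 observed nodes")
        F_tr = self.F_hat[keep]
        mu = F_tr.mean(axis=0)
        cols = (mu > 0.0) & (mu < 1.0)
        data = FrequencyData.from_frequencies(
            F_tr[:, cols], self.n[keep], self.observed_ids[keep], check_bounds=False
        )
        return data, cols


def rescale(F_hat: np.ndarray, mu_hat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column-rescale by sqrt(mu(1-mu)) and form Sigma_hat = F_s F_s' / p.

    No centering here: per-SNP means are removed later by the contrast
    matrix, which is what keeps the covariance estimate Wishart-compatible.
    """
    mu_hat = np.asarray(mu_hat, dtype=float)
    if np.any(mu_hat <= 0.0) or np.any(mu_hat >= 1.0):
        raise ValueError("monomorphic SNP encountered; filter before rescaling")
    F_scaled = F_hat / np.sqrt(mu_hat * (1.0 - mu_hat))
    p = F_hat.shape[1]
    Sigma = (F_scaled @ F_scaled.T) / p
    return F_scaled, Sigma


def genetic_distance_from_covariance(Sigma: np.ndarray) -> np.ndarray:
    """D_hat = 1 diag(Sigma)' + diag(Sigma) 1' - 2 Sigma (zero diagonal)."""
    dg = np.diag(Sigma)
    D = dg[:, None] + dg[None, :] - 2.0 * Sigma
    np.fill_diagonal(D, 0.0)
    return D
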