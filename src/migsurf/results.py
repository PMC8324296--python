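"""Results containers for null, penalized and cross-validation fits."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Any

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .grid import SpatialGraph


@dataclass
class NullResults:
    """Constant-weight (homogeneous isolation-by-distance) fit.

    ``w0`` is the shared edge weight and ``sigma2`` the residual variance of
    the observation model; both are maximum-likelihood estimates from a
    derivative-free simplex search.
    """

    w0: float
    sigma2: float
    nll: float
    n_iter: int
    converged: bool
    message: str

    def summary(self) -> str:
        lines = [
            "Homogeneous isolation-by-distance fit",
            "=" * 44,
            f"{'edge weight w0':<28}{self.w0:>16.6g}",
            f"{'residual variance sigma^2':<28}{self.sigma2:>16.6g}",
            f"{'negative log-likelihood':<28}{self.nll:>16.6g}",
            f"{'iterations':<28}{self.n_iter:>16d}",
            f"{'converged':<28}{str(self.converged):>16}",
        ]
        return "\n".join(lines)


@dataclass
class MigrationResults:
    """Penalized fit of the migration surface at one penalty strength.

    ``w`` holds the fitted edge weights in the graph's canonical edge order;
    ``log_relative()`` expresses them as log10(w / w0), the scale on which
    migration surfaces are usually drawn (0 = the homogeneous fit).
    """

    w: np.ndarray
    lam: float
    alpha: float
    sigma2: float
    w0: float
    objective: float
    objective_trace: np.ndarray
    grad_norm: float
    converged: bool
    message: str
    n_iter: int
    init: str
    graph: "SpatialGraph"
    model: Any = field(repr=False, default=None)

    def log_relative(self) -> np.ndarray:
        return np.log10(self.w / self.w0)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "node_a": self.graph.edges[:, 0],
                "node_b": self.graph.edges[:, 1],
                "w_fit": self.w,
                "log10_w_rel": self.log_relative(),
            }
        )

    def summary(self) -> str:
        lr = self.log_relative()
        lines = [
            "Effective migration surface fit",
            "=" * 52,
            f"{'edges (m)':<30}{self.graph.n_edges:>20d}",
            f"{'nodes (d)':<30}{self.graph.n_nodes:>20d}",
            f"{'penalty strength lambda':<30}{self.lam:>20.6g}",
            f"{'penalty scale alpha':<30}{self.alpha:>20.6g}",
            f"{'scale w0 (null fit)':<30}{self.w0:>20.6g}",
            f"{'residual variance sigma^2':<30}{self.sigma2:>20.6g}",
            f"{'objective':<30}{self.objective:>20.6g}",
            f"{'projected-gradient norm':<30}{self.grad_norm:>20.3e}",
            f"{'iterations':<30}{self.n_iter:>20d}",
            f"{'initialized from':<30}{self.init:>20}",
            f"{'converged':<30}{str(self.converged):>20}",
            "-" * 52,
            "log10(w / w0) quantiles",
            f"{'  min':<30}{lr.min():>20.4f}",
            f"{'  25%':<30}{np.percentile(lr, 25):>20.4f}",
            f"{'  median':<30}{np.median(lr):>20.4f}",
            f"{'  75%':<30}{np.percentile(lr, 75):>20.4f}",
            f"{'  max':<30}{lr.max():>20.4f}",
        ]
        return "\n".join(lines)

    def plot(self, ax=None, cmap: str = "coolwarm_r", linewidth: float = 2.0):
        """Draw lattice edges colored by log10(w / w0) in lon/lat space."""
        import matplotlib.pyplot as plt
        from matplotlib.collections import LineCollection

        if ax is None:
            _, ax = plt.subplots()
        segs = self.graph.node_coords[self.graph.edges]
        lr = self.log_relative()
        vmax = max(np.abs(lr).max(), 1e-3)
        lc = LineCollection(segs, cmap=cmap, linewidths=linewidth)
        lc.set_array(lr)
        lc.set_clim(-vmax, vmax)
        ax.add_collection(lc)
        ax.autoscale()
        ax.set_xlabel("longitude")
        ax.set_ylabel("latitude")
        return ax


@dataclass
class CVResults:
    """Leave-one-node-out cross-validation over a penalty grid.

    ``errors[f, i]`` is fold f's mean squared held-out frequency prediction
    error at ``lam_grid[i]`` (grid stored descending); ``lam_star`` minimizes
    the fold-averaged error, with ties resolved toward the larger lambda.
    """

    lam_grid: np.ndarray
    errors: np.ndarray
    mean_errors: np.ndarray
    lam_star: float
    fold_nodes: list
    n_invalid_folds: int = 0
    alpha_star: float | None = None  # set when a 2-D (lambda, alpha) search ran

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.errors.T,
            columns=[f"fold_{i}" for i in range(self.errors.shape[0])],
        )
        df.insert(0, "lambda", self.lam_grid)
        df["mean_error"] = self.mean_errors
        return df

    def summary(self) -> str:
        lines = [
            "Leave-one-node-out cross-validation",
            "=" * 44,
            f"{'folds':<26}{self.errors.shape[0]:>18d}",
            f"{'invalid folds':<26}{self.n_invalid_folds:>18d}",
            f"{'selected lambda':<26}{self.lam_star:>18.6g}",
            "-" * 44,
            f"{'lambda':>14}{'mean CV error':>22}",
        ]
        for lam, err in zip(self.lam_grid, self.mean_errors):
            marker = "  <-- selected" if lam == self.lam_star else ""
            lines.append(f"{lam:>14.6g}{err:>22.8g}{marker}")
        return "\n".join(lines)
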