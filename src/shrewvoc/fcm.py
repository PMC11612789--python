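"""Fuzzy c-means soft clustering.

The c-means model assigns every observation a membership value in [0, 1] to
each of ``c`` clusters (rows of the membership matrix sum to 1) instead of a
crisp label.  It minimizes

    J = sum_ik  u_ik^mu * d(x_k, v_i)^2

by alternating the closed-form membership update

    u_ik = 1 / sum_j (d_ik / d_jk)^(2 / (mu - 1))

with the u^mu-weighted centroid update, where ``mu > 1`` is the fuzzifier
(degree of fuzzification) and ``d`` the Euclidean distance.  A point
coincident with a centroid receives membership 1 there.

Written as a statsmodels-style model object: ``FuzzyCMeans(X, ...).fit()``
returns a :class:`FuzzyCMeansResults` carrying centroids, the membership
matrix, the objective trace and hard labels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

__all__ = ["FuzzyCMeans", "FuzzyCMeansResults", "fcm_memberships", "hard_assign"]

logger = logging.getLogger(__name__)


def _pairwise_dist(X: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Euclidean distances, n x c."""
    return np.sqrt(np.maximum(
        ((X[:, None, :] - C[None, :, :]) ** 2).sum(axis=2), 0.0))


def fcm_memberships(X: np.ndarray, centroids: np.ndarray,
                    fuzzifier: float = 2.0) -> np.ndarray:
    """Closed-form membership matrix for fixed centroids.

    ``u_ik = [sum_j (d_ik / d_jk)^(2/(mu-1))]^(-1)``; a point at zero
    distance from a centroid gets membership 1 there (split equally if it
    coincides with several).
    """
    d = _pairwise_dist(np.asarray(X, float), np.asarray(centroids, float))
    n, c = d.shape
    U = np.zeros((n, c))
    zero = d <= 0.0
    any_zero = zero.any(axis=1)
    if any_zero.any():
        U[any_zero] = zero[any_zero] / zero[any_zero].sum(axis=1, keepdims=True)
    reg = ~any_zero
    if reg.any():
        p = 2.0 / (fuzzifier - 1.0)
        dr = d[reg]
        # u_ik = 1 / sum_j (d_ik/d_jk)^p, computed stably via reciprocals
        inv = dr ** (-p)
        U[reg] = inv / inv.sum(axis=1, keepdims=True)
    return U


def hard_assign(U: np.ndarray) -> np.ndarray:
    """Row-wise argmax of the membership matrix; ties break toward the
    lowest cluster index and are logged."""
    U = np.asarray(U, float)
    labels = np.argmax(U, axis=1)
    row_max = U[np.arange(len(U)), labels]
    ties = (U == row_max[:, None]).sum(axis=1) > 1
    if ties.any():
        logger.info("hard_assign: %d tied row(s) broken toward the lowest "
                    "cluster index (rows %s)", int(ties.sum()),
                    np.where(ties)[0][:20].tolist())
    return labels


class FuzzyCMeans:
    """Fuzzy c-means model for a data matrix.

    Parameters
    ----------
    endog : array, n x d
        Observations to cluster.
    n_clusters : int
        Number of clusters ``c`` (>= 2; ``n > c`` required).
    fuzzifier : float
        Degree of fuzzification ``mu`` (> 1); 2 is the repertoire-analysis
        setting.
    max_iter, tol :
        Stop after ``max_iter`` sweeps or when the largest membership change
        drops below ``tol``.
    """

    def __init__(self, endog: np.ndarray, n_clusters: int = 3,
                 fuzzifier: float = 2.0, max_iter: int = 100,
                 tol: float = 1e-6):
        X = np.asarray(endog, dtype=float)
        if X.ndim != 2:
            raise ValueError("endog must be a 2-D matrix")
        if n_clusters < 2:
            raise ValueError("n_clusters must be >= 2")
        if X.shape[0] <= n_clusters:
            raise ValueError(
                f"need more points ({X.shape[0]}) than clusters ({n_clusters})")
        if fuzzifier <= 1.0:
            raise ValueError("fuzzifier must exceed 1")
        if np.ptp(X, axis=0).max() == 0.0:
            raise ValueError("all points are identical; clustering undefined")
        self.endog = X
        self.n_clusters = n_clusters
        self.fuzzifier = fuzzifier
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, seed: int | np.random.Generator = 0) -> "FuzzyCMeansResults":
        X, c, mu = self.endog, self.n_clusters, self.fuzzifier
        rng = seed if isinstance(seed, np.random.Generator) \
            else np.random.default_rng(seed)
        # initialize centroids on c distinct data points
        distinct = np.unique(X, axis=0)
        if distinct.shape[0] < c:
            raise ValueError("fewer distinct points than clusters")
        idx = rng.choice(distinct.shape[0], size=c, replace=False)
        C = distinct[idx].copy()
        U = fcm_memberships(X, C, mu)
        trace: list[float] = []
        converged = False
        for it in range(self.max_iter):
            Um = U ** mu
            C = (Um.T @ X) / Um.sum(axis=0)[:, None]
            U_new = fcm_memberships(X, C, mu)
            d2 = _pairwise_dist(X, C) ** 2
            trace.append(float((U_new ** mu * d2).sum()))
            delta = float(np.abs(U_new - U).max())
            U = U_new
            if delta < self.tol:
                converged = True
                break
        return FuzzyCMeansResults(
            model=self, centroids=C, membership=U,
            objective_trace=np.asarray(trace), n_iter=len(trace),
            converged=converged)


@dataclass
class FuzzyCMeansResults:
    """Fitted fuzzy c-means clustering."""

    model: FuzzyCMeans
    centroids: np.ndarray
    membership: np.ndarray
    objective_trace: np.ndarray
    n_iter: int
    converged: bool
    _labels: np.ndarray | None = field(default=None, repr=False)

    @property
    def hard_labels(self) -> np.ndarray:
        if self._labels is None:
            self._labels = hard_assign(self.membership)
        return self._labels

    @property
    def objective(self) -> float:
        return float(self.objective_trace[-1])

    def summary(self) -> str:
        counts = np.bincount(self.hard_labels, minlength=self.model.n_clusters)
        lines = [
            "Fuzzy c-means clustering",
            f"  clusters: {self.model.n_clusters}   fuzzifier: {self.model.fuzzifier}",
            f"  iterations: {self.n_iter} (converged: {self.converged})",
            f"  final objective: {self.objective:.6g}",
            "  cluster sizes (hard labels): "
            + ", ".join(f"c{i}={n}" for i, n in enumerate(counts)),
        ]
        return "\n".join(lines)
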