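"""Repertoire clustering: standardization, 2-D embedding, soft clustering.

``RepertoireModel`` is the statsmodels-style entry point: build it from the
per-call feature table, call :meth:`~RepertoireModel.fit`, and receive a
:class:`RepertoireResults` carrying the UMAP embedding, the fuzzy c-means
membership matrix, typicality coefficients/categories and the final
call-type labels, with a ``summary()`` table.

Clustering consumes the nine parameters available for all calls
(standardized z-scores), reduced to two dimensions by UMAP as a
pre-processing step; a flag allows clustering the standardized feature
matrix directly instead of the embedding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fcm import FuzzyCMeans, FuzzyCMeansResults
from .features import ALL_CALLS_PARAMS
from .gradation import (assign_call_types, categorize_typicality,
                        compute_thresholds, infer_cluster_roles,
                        typicality_coefficients)

__all__ = ["zscore_standardize", "embed_2d", "Embedding",
           "RepertoireModel", "RepertoireResults"]


def zscore_standardize(X: np.ndarray | pd.DataFrame,
                       ddof: int = 0) -> np.ndarray | pd.DataFrame:
    """Z-score standardization (population-SD convention by default).

    Each column ends up with mean 0 and SD 1; a constant column is rejected
    with its name (or index) in the message.
    """
    values = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) \
        else np.asarray(X, dtype=float)
    if values.ndim != 2 or values.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 rows")
    if not np.isfinite(values).all():
        raise ValueError("non-finite values in feature matrix")
    sd = values.std(axis=0, ddof=ddof)
    const = np.where(sd == 0.0)[0]
    if len(const):
        names = (list(np.asarray(X.columns)[const]) if isinstance(X, pd.DataFrame)
                 else const.tolist())
        raise ValueError(f"constant column(s) cannot be standardized: {names}")
    Z = (values - values.mean(axis=0)) / sd
    if isinstance(X, pd.DataFrame):
        return pd.DataFrame(Z, index=X.index, columns=X.columns)
    return Z


@dataclass
class Embedding:
    """2-D UMAP coordinates plus the parameters that produced them."""

    coords: np.ndarray
    n_neighbors: int
    min_dist: float
    seed: int

    def __post_init__(self) -> None:
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError("embedding must be n x 2")
        if not np.isfinite(self.coords).all():
            raise ValueError("non-finite embedding coordinates")


def embed_2d(Z: np.ndarray, n_neighbors: int = 15, min_dist: float = 0.1,
             seed: int = 0) -> Embedding:
    """UMAP 2-D embedding of the standardized feature matrix.

    A fixed seed gives reproducible coordinates (UMAP then runs
    single-threaded).  Requires at least ``n_neighbors + 1`` rows.
    """
    import umap  # deferred: umap-learn import is slow

    Z = np.asarray(Z, dtype=float)
    if Z.shape[0] < n_neighbors + 1:
        raise ValueError(
            f"need at least n_neighbors + 1 = {n_neighbors + 1} rows, "
            f"got {Z.shape[0]}")
    reducer = umap.UMAP(n_components=2, n_neighbors=n_neighbors,
                        min_dist=min_dist, random_state=seed)
    coords = reducer.fit_transform(Z)
    return Embedding(coords=np.asarray(coords, dtype=float),
                     n_neighbors=n_neighbors, min_dist=min_dist, seed=seed)


class RepertoireModel:
    """Soft-clustering model of a vocal-repertoire feature table.

    Parameters
    ----------
    features : DataFrame
        Per-call feature table with at least the nine all-calls parameters
        plus ``call_id``.
    n_clusters, fuzzifier, max_iter, tol :
        Fuzzy c-means settings (defaults: c=3, mu=2, 100 iterations).
    n_neighbors, min_dist :
        UMAP hyperparameters.
    cluster_space : 'features' | 'embedding'
        Whether c-means consumes the standardized 9-column matrix (default)
        or the 2-D UMAP embedding.  The embedding is always computed for
        visualization; clustering it directly is fragile because UMAP's
        inter-island distances are not meaningful.
    typicality_method, fixed_thresholds :
        Typicality-threshold computation (empirical terciles by default).
    """

    def __init__(self, features: pd.DataFrame, n_clusters: int = 3,
                 fuzzifier: float = 2.0, max_iter: int = 100, tol: float = 1e-6,
                 n_neighbors: int = 15, min_dist: float = 0.1,
                 cluster_space: str = "features",
                 typicality_method: str = "tercile",
                 fixed_thresholds: tuple[float, float] | None = None):
        missing = [c for c in ALL_CALLS_PARAMS if c not in features.columns]
        if missing:
            raise ValueError(f"feature table lacks required columns: {missing}")
        if cluster_space not in ("embedding", "features"):
            raise ValueError("cluster_space must be 'embedding' or 'features'")
        self.features = features.reset_index(drop=True)
        self.n_clusters = n_clusters
        self.fuzzifier = fuzzifier
        self.max_iter = max_iter
        self.tol = tol
        self.n_neighbors = n_neighbors
        self.min_dist = min_dist
        self.cluster_space = cluster_space
        self.typicality_method = typicality_method
        self.fixed_thresholds = fixed_thresholds

    @classmethod
    def from_csv(cls, path, **kwargs) -> "RepertoireModel":
        return cls(pd.read_csv(path, comment="#"), **kwargs)

    def fit(self, seed: int = 0) -> "RepertoireResults":
        Z = zscore_standardize(self.features[ALL_CALLS_PARAMS])
        embedding = embed_2d(Z.to_numpy(), n_neighbors=self.n_neighbors,
                             min_dist=self.min_dist, seed=seed)
        points = embedding.coords if self.cluster_space == "embedding" \
            else Z.to_numpy()
        fcm = FuzzyCMeans(points, n_clusters=self.n_clusters,
                          fuzzifier=self.fuzzifier, max_iter=self.max_iter,
                          tol=self.tol).fit(seed=seed)
        coeffs = typicality_coefficients(fcm.membership)
        thresholds = compute_thresholds(coeffs, method=self.typicality_method,
                                        fixed=self.fixed_thresholds)
        categories = categorize_typicality(coeffs, thresholds)

        per_call = self.features.copy()
        per_call["umap1"] = embedding.coords[:, 0]
        per_call["umap2"] = embedding.coords[:, 1]
        for k in range(self.n_clusters):
            per_call[f"u{k + 1}"] = fcm.membership[:, k]
        per_call["hard_label"] = fcm.hard_labels
        per_call["typicality_coefficient"] = coeffs
        per_call["typicality_category"] = categories
        roles = infer_cluster_roles(per_call)
        per_call["call_type"] = assign_call_types(
            fcm.hard_labels, roles, per_call["voiced_percentage"].to_numpy())
        return RepertoireResults(model=self, embedding=embedding,
                                 clustering=fcm, thresholds=thresholds,
                                 cluster_roles=roles, per_call=per_call,
                                 seed=seed)


@dataclass
class RepertoireResults:
    """Fitted repertoire analysis: embedding, memberships, typicality and
    call-type labels, one row per call in :attr:`per_call`."""

    model: RepertoireModel
    embedding: Embedding
    clustering: FuzzyCMeansResults
    thresholds: tuple[float, float]
    cluster_roles: dict[int, str]
    per_call: pd.DataFrame
    seed: int

    @property
    def membership(self) -> np.ndarray:
        return self.clustering.membership

    @property
    def hard_labels(self) -> np.ndarray:
        return self.clustering.hard_labels

    @property
    def call_types(self) -> pd.Series:
        return self.per_call["call_type"]

    def cluster_summary(self) -> pd.DataFrame:
        g = self.per_call.groupby("hard_label")
        out = g.agg(n_calls=("call_id", "count"),
                    mean_voiced=("voiced_percentage", "mean"),
                    mean_duration=("duration", "mean"),
                    mean_typicality=("typicality_coefficient", "mean"))
        out["role"] = [self.cluster_roles[int(i)] for i in out.index]
        return out

    def summary(self) -> str:
        lo, hi = self.thresholds
        lines = [
            "Vocal repertoire soft clustering",
            "=" * 48,
            f"calls: {len(self.per_call)}   clusters: {self.model.n_clusters} "
            f"(mu={self.model.fuzzifier}, space={self.model.cluster_space})",
            f"typicality thresholds: atypical < {lo:.3f} < neither < {hi:.3f} < typical",
            "",
            self.cluster_summary().to_string(
                float_format=lambda v: f"{v:.3f}"),
            "",
            "call types: " + ", ".join(
                f"{t}={n}" for t, n in
                self.per_call["call_type"].value_counts().items()),
            "typicality: " + ", ".join(
                f"{t}={n}" for t, n in
                self.per_call["typicality_category"].value_counts().items()),
        ]
        return "\n".join(lines)

    def plot_embedding(self, ax=None, color_by: str = "call_type"):
        """Scatter the 2-D embedding coloured by call type (or any per-call
        column)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 5))
        for value, grp in self.per_call.groupby(color_by):
            ax.scatter(grp["umap1"], grp["umap2"], s=8, label=str(value))
        ax.set_xlabel("UMAP1")
        ax.set_ylabel("UMAP2")
        ax.legend(fontsize=8)
        return ax
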