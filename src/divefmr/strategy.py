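"""Foraging-strategy classification.

Trips are described by a vector of fine-scale diving variables, reduced by a
correlation-matrix PCA, grouped by Ward hierarchical clustering on the
retained component scores, and new trips are assigned to a strategy by linear
discriminant analysis on those scores. An animal with several trips gets the
dominant (modal) strategy across them.

Cluster naming follows the water column: the cluster with the deepest mean
diving is "deep", the rest "mixed" (a third occupied cluster, if any, is
"shallow"). The fitted model serializes to a JSON document for reuse across
deployments.
"""

from __future__ import annotations

import json
import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

__all__ = ["StrategyModel", "StrategyAssignment", "fit_strategy_model", "predict_strategy", "dominant_strategy"]

_CLUSTER_NAMES_BY_DEPTH_RANK = ["deep", "mixed", "shallow"]


@dataclass
class StrategyAssignment:
    trip_id: str
    strategy: str
    pc_scores: np.ndarray
    posterior: dict[str, float]


@dataclass
class StrategyModel:
    variable_names: list[str]
    center: np.ndarray
    scale: np.ndarray
    pca_loadings: np.ndarray  # variables x components (unit-norm eigenvectors)
    explained_variance: np.ndarray  # proportion per retained component
    n_components_kept: int
    cluster_labels: list[str]  # strategy per training trip
    strategy_names: list[str]
    _lda: LinearDiscriminantAnalysis = field(repr=False, default=None)

    @property
    def lda_coefficients(self) -> np.ndarray:
        return self._lda.coef_

    def transform(self, table: pd.DataFrame) -> np.ndarray:
        """Standardize with the training parameters and project to PC scores."""
        missing = [v for v in self.variable_names if v not in table.columns]
        if missing:
            raise KeyError(f"missing strategy variables: {missing}")
        x = table[self.variable_names].to_numpy(dtype=float)
        z = (x - self.center) / self.scale
        return z @ self.pca_loadings

    def to_json(self, path: str | Path) -> None:
        doc = {
            "variable_names": self.variable_names,
            "center": self.center.tolist(),
            "scale": self.scale.tolist(),
            "pca_loadings": self.pca_loadings.tolist(),
            "explained_variance": self.explained_variance.tolist(),
            "n_components_kept": self.n_components_kept,
            "cluster_labels": self.cluster_labels,
            "strategy_names": self.strategy_names,
            "lda": {
                "coef": self._lda.coef_.tolist(),
                "intercept": self._lda.intercept_.tolist(),
                "classes": list(self._lda.classes_),
                "means": self._lda.means_.tolist(),
            },
        }
        Path(path).write_text(json.dumps(doc, indent=1))


def _kaiser_components(eigvals: np.ndarray) -> int:
    return max(2, int(np.sum(eigvals > 1.0)))


def fit_strategy_model(
    trips: pd.DataFrame,
    n_components: int | None = None,
    k_clusters: int = 3,
    min_cluster_size: int = 2,
) -> StrategyModel:
    """Fit PCA + Ward clustering + LDA on a trips x variables table.

    Variables are standardized (correlation-matrix PCA); by default components
    with eigenvalue > 1 are retained (at least 2). Ward-linkage hierarchical
    clustering on the retained scores is cut at ``k_clusters``; clusters
    smaller than ``min_cluster_size`` are merged into the nearest occupied
    cluster, so fewer occupied strategies than ``k_clusters`` is permitted.
    Constant variables are dropped with a warning.
    """
    if len(trips) < k_clusters:
        raise ValueError("need at least k_clusters trips")
    trips = trips.copy()
    variable_names = [c for c in trips.columns if np.issubdtype(trips[c].dtype, np.number)]
    if trips[variable_names].isna().all().any():
        raise ValueError("a strategy variable is all-missing")
    x = trips[variable_names].to_numpy(dtype=float)
    scale = x.std(axis=0, ddof=1)
    constant = scale == 0
    if np.any(constant):
        dropped = [v for v, c in zip(variable_names, constant) if c]
        warnings.warn(f"dropping constant variables: {dropped}")
        variable_names = [v for v, c in zip(variable_names, constant) if not c]
        x = trips[variable_names].to_numpy(dtype=float)
        scale = x.std(axis=0, ddof=1)
    center = x.mean(axis=0)
    z = (x - center) / scale

    # correlation-matrix PCA via SVD of the standardized data
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    eigvals = s**2 / (len(z) - 1)
    var_prop = eigvals / eigvals.sum()
    k = n_components if n_components is not None else _kaiser_components(eigvals)
    k = min(k, len(variable_names))
    loadings = vt[:k].T
    # sign convention: largest-magnitude loading in each component positive
    signs = np.sign(loadings[np.abs(loadings).argmax(axis=0), np.arange(k)])
    loadings = loadings * signs
    scores = z @ loadings

    cluster_idx = fcluster(linkage(scores, method="ward"), k_clusters, criterion="maxclust")
    # merge undersized clusters into the nearest occupied centroid
    counts = Counter(cluster_idx)
    small = [c for c, n in counts.items() if n < min_cluster_size]
    if small and len(counts) > len(small):
        big = [c for c in counts if c not in small]
        centroids = {c: scores[cluster_idx == c].mean(axis=0) for c in big}
        for c in small:
            for i in np.flatnonzero(cluster_idx == c):
                cluster_idx[i] = min(
                    centroids, key=lambda b: np.linalg.norm(scores[i] - centroids[b])
                )

    # name occupied clusters by mean depth-like signal: use the first variable
    # whose name mentions depth, falling back to PC1
    depth_vars = [v for v in variable_names if "depth" in v and "cv" not in v]
    occupied = sorted(set(cluster_idx))
    if depth_vars:
        depth_signal = trips[depth_vars].to_numpy(dtype=float).mean(axis=1)
    else:
        depth_signal = scores[:, 0]
    rank = sorted(occupied, key=lambda c: -np.nanmean(depth_signal[cluster_idx == c]))
    names = {
        c: _CLUSTER_NAMES_BY_DEPTH_RANK[i] if i < 3 else f"cluster{i}"
        for i, c in enumerate(rank)
    }
    labels = [names[c] for c in cluster_idx]

    if len(set(labels)) < 2:
        raise ValueError(
            "clustering collapsed to a single occupied strategy; lower "
            "min_cluster_size or provide more heterogeneous trips"
        )
    lda = LinearDiscriminantAnalysis(priors=np.full(len(set(labels)), 1 / len(set(labels))))
    lda.fit(scores, labels)

    return StrategyModel(
        variable_names=variable_names,
        center=center,
        scale=scale,
        pca_loadings=loadings,
        explained_variance=var_prop[:k],
        n_components_kept=k,
        cluster_labels=labels,
        strategy_names=sorted(set(labels)),
        _lda=lda,
    )


def predict_strategy(
    model: StrategyModel, trip_vars: Mapping[str, float] | pd.DataFrame, trip_id: str = "?"
) -> StrategyAssignment:
    """Assign one trip to a strategy via the fitted LDA on its PC scores."""
    if isinstance(trip_vars, Mapping):
        missing = [v for v in model.variable_names if v not in trip_vars]
        if missing:
            raise KeyError(f"trip {trip_id}: missing variables {missing}")
        row = pd.DataFrame([{v: trip_vars[v] for v in model.variable_names}])
    else:
        row = trip_vars
    scores = model.transform(row)
    z = (row[model.variable_names].to_numpy(dtype=float) - model.center) / model.scale
    if np.any(np.abs(z) > 6):
        warnings.warn(f"trip {trip_id}: variable(s) far outside the training range")
    proba = model._lda.predict_proba(scores)[0]
    classes = list(model._lda.classes_)
    posterior = {c: float(p) for c, p in zip(classes, proba)}
    label = classes[int(np.argmax(proba))]
    return StrategyAssignment(
        trip_id=trip_id, strategy=label, pc_scores=scores[0], posterior=posterior
    )


def dominant_strategy(assignments: Sequence[StrategyAssignment]) -> str:
    """Modal strategy across an animal's trips.

    Ties break first by higher mean posterior probability for the tied
    strategy, then lexicographically.
    """
    if not assignments:
        raise ValueError("need at least one assignment")
    counts = Counter(a.strategy for a in assignments)
    top = max(counts.values())
    tied = sorted(c for c, n in counts.items() if n == top)
    if len(tied) == 1:
        return tied[0]
    mean_post = {
        c: np.mean([a.posterior.get(c, 0.0) for a in assignments if a.strategy == c])
        for c in tied
    }
    best = max(mean_post.values())
    return sorted(c for c, p in mean_post.items() if p == best)[0]
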