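"""Cluster model for predicting subcortical targets from cellular features.

Cells with identified targets define clusters (by default POm, Sp5C, and a
merged SC/Pons cluster). Each cluster is summarized by its sample mean and
covariance; a query cell's distance to cluster i is the Mahalanobis distance
d_i — its distance to the cluster center in units of the cluster's standard
deviation. The cell is assigned to the nearest cluster, and the confidence of
assignment to cluster k is

    P(k) = p_k / sum_i p_i,    p_i = 1 - F(d_i^2, DOF)

where F is the chi-squared cumulative distribution function and DOF the
dimension of the feature space: p_i is the probability of finding a cluster-i
member at least as far out as d_i, under a Gaussian cluster model.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2

__all__ = [
    "FeatureSpaceSpec",
    "ClusterModel",
    "ClassificationResult",
    "DEFAULT_MERGE_MAP",
    "feature_matrix",
    "fit_clusters",
    "mahalanobis",
    "classify",
    "evaluate_cohort",
    "loo_confidences",
]

#: SC and Pons projectors form a single cluster by default: their somata,
#: ongoing rates and sustained responses are the most alike of the four groups.
DEFAULT_MERGE_MAP: dict[str, str] = {
    "POm": "POm",
    "Sp5C": "Sp5C",
    "SC": "SC/Pons",
    "Pons": "SC/Pons",
}


@dataclass(frozen=True)
class FeatureSpaceSpec:
    """Ordered feature names plus an optional cohort-level z-scoring flag."""

    features: tuple[str, ...]
    standardize: bool = False

    def __post_init__(self) -> None:
        if len(self.features) < 1:
            raise ValueError("need at least one feature")

    @property
    def dof(self) -> int:
        return len(self.features)


def feature_matrix(table: pd.DataFrame, spec: FeatureSpaceSpec) -> np.ndarray:
    """Extract the spec's feature columns (optionally z-scored cohort-wise).

    Standardization is off by default: Mahalanobis distances are already
    per-cluster scale-aware, so z-scoring only matters for comparing raw
    distances across feature spaces.
    """
    X = table[list(spec.features)].to_numpy(dtype=float)
    if spec.standardize:
        sd = X.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=0)) / sd
    return X


@dataclass
class Cluster:
    label: str
    mean: np.ndarray
    cov: np.ndarray
    n: int
    diagonal_fallback: bool = False

    def inv_cov(self) -> np.ndarray:
        try:
            return np.linalg.inv(self.cov)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - ridge should prevent
            raise np.linalg.LinAlgError(
                f"covariance of cluster {self.label!r} singular despite ridge"
            ) from exc


@dataclass
class ClusterModel:
    clusters: list[Cluster]
    dof: int
    ridge: float

    @property
    def labels(self) -> list[str]:
        return [c.label for c in self.clusters]

    def to_json(self, path) -> None:
        payload = {
            "dof": self.dof,
            "ridge": self.ridge,
            "clusters": [
                {
                    "label": c.label,
                    "n": c.n,
                    "mean": c.mean.tolist(),
                    "cov": c.cov.tolist(),
                    "diagonal_fallback": c.diagonal_fallback,
                }
                for c in self.clusters
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "ClusterModel":
        with open(path) as fh:
            payload = json.load(fh)
        clusters = [
            Cluster(
                label=c["label"],
                mean=np.asarray(c["mean"]),
                cov=np.asarray(c["cov"]),
                n=c["n"],
                diagonal_fallback=c.get("diagonal_fallback", False),
            )
            for c in payload["clusters"]
        ]
        return cls(clusters=clusters, dof=payload["dof"], ridge=payload["ridge"])


@dataclass
class ClassificationResult:
    labels: list[str]
    distances: np.ndarray       # d_i, SD units
    p_values: np.ndarray        # p_i = 1 - F(d_i^2, DOF)
    confidences: np.ndarray     # P(k), sums to 1
    assigned: str
    tie: bool = False
    underflow: bool = False

    @property
    def assigned_confidence(self) -> float:
        return float(self.confidences[self.labels.index(self.assigned)])


def fit_clusters(
    features: np.ndarray | pd.DataFrame,
    labels: Sequence[str],
    merge_map: Mapping[str, str] | None = None,
    ridge: float = 1e-6,
) -> ClusterModel:
    """Per-cluster sample mean and covariance (denominator n-1) with ridge.

    Labels are first mapped through ``merge_map`` (default merges SC and Pons).
    A ridge of ``ridge * trace(C)/DOF`` is added to the covariance diagonal;
    clusters with fewer than DOF+1 members get a diagonal covariance built
    from per-feature sample variances (with a warning), since their full
    sample covariance is rank-deficient.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim != 2:
        raise ValueError("features must be a 2D (cells x features) array")
    merge_map = dict(DEFAULT_MERGE_MAP if merge_map is None else merge_map)
    merged = [merge_map.get(l, l) for l in labels]
    dof = X.shape[1]

    clusters: list[Cluster] = []
    for lab in sorted(set(merged), key=merged.index):
        pts = X[[i for i, l in enumerate(merged) if l == lab]]
        if len(pts) < 2:
            raise ValueError(f"cluster {lab!r} has fewer than 2 cells")
        mean = pts.mean(axis=0)
        fallback = len(pts) < dof + 1
        if fallback:
            warnings.warn(
                f"cluster {lab!r}: n={len(pts)} < DOF+1={dof + 1}; "
                "using diagonal covariance",
                stacklevel=2,
            )
            cov = np.diag(pts.var(axis=0, ddof=1))
        else:
            cov = np.atleast_2d(np.cov(pts, rowvar=False, ddof=1))
        tr = np.trace(cov)
        eps = ridge * (tr / dof if tr > 0 else 1.0)
        cov = cov + eps * np.eye(dof)
        clusters.append(Cluster(label=lab, mean=mean, cov=cov, n=len(pts), diagonal_fallback=fallback))
    return ClusterModel(clusters=clusters, dof=dof, ridge=ridge)


def mahalanobis(x: np.ndarray, cluster: Cluster) -> float:
    """d = sqrt((x - mu)^T C^-1 (x - mu)); 0 at the cluster mean."""
    diff = np.asarray(x, dtype=float) - cluster.mean
    d2 = float(diff @ cluster.inv_cov() @ diff)
    return float(np.sqrt(max(d2, 0.0)))


def classify(x: np.ndarray, model: ClusterModel) -> ClassificationResult:
    """Assign to the nearest cluster; chi-squared confidences P(k).

    Ties in distance go to the lowest cluster index (flagged). If every p_i
    underflows to zero, the assigned cluster gets confidence 1 (flagged).
    """
    x = np.asarray(x, dtype=float)
    if x.shape != (model.dof,):
        raise ValueError(f"expected feature vector of dimension {model.dof}, got {x.shape}")
    d = np.array([mahalanobis(x, c) for c in model.clusters])
    p = chi2.sf(d**2, df=model.dof)
    assigned_idx = int(np.argmin(d))
    tie = bool(np.sum(d == d[assigned_idx]) > 1)
    total = p.sum()
    underflow = total == 0.0
    if underflow:
        conf = np.zeros_like(p)
        conf[assigned_idx] = 1.0
    else:
        conf = p / total
    return ClassificationResult(
        labels=model.labels,
        distances=d,
        p_values=p,
        confidences=conf,
        assigned=model.labels[assigned_idx],
        tie=tie,
        underflow=underflow,
    )


def evaluate_cohort(
    features: np.ndarray | pd.DataFrame,
    labels: Sequence[str],
    merge_map: Mapping[str, str] | None = None,
    is_dual: Sequence[bool] | None = None,
    leave_one_out: bool = False,
    ridge: float = 1e-6,
) -> pd.DataFrame:
    """Classify every cell of a labeled cohort.

    Dual-target cells (``is_dual``) are excluded from cluster fitting and
    scored as held-out queries. With ``leave_one_out`` each single-target
    cell is also scored against clusters fit without it.

    Returns a per-cell table with the true (merged) label, assignment,
    distances and confidences; ``correct`` compares against the merged label.
    """
    X = np.asarray(features, dtype=float)
    merge_map = dict(DEFAULT_MERGE_MAP if merge_map is None else merge_map)
    merged = np.array([merge_map.get(l, l) for l in labels])
    dual = np.asarray(is_dual, dtype=bool) if is_dual is not None else np.zeros(len(X), bool)
    train_idx = np.flatnonzero(~dual)

    rows = []
    base_model: ClusterModel | None = None
    if not leave_one_out or np.any(dual):
        base_model = fit_clusters(X[train_idx], merged[train_idx].tolist(), merge_map, ridge)
    for i in range(len(X)):
        if leave_one_out and not dual[i]:
            keep = train_idx[train_idx != i]
            model = fit_clusters(X[keep], merged[keep].tolist(), merge_map, ridge)
        else:
            model = base_model
        res = classify(X[i], model)
        row = {
            "cell": i,
            "true_label": merged[i],
            "assigned": res.assigned,
            "correct": res.assigned == merged[i],
            "confidence": res.assigned_confidence,
            "is_dual": bool(dual[i]),
        }
        for lab, dist, conf in zip(res.labels, res.distances, res.confidences):
            row[f"d_{lab}"] = dist
            row[f"P_{lab}"] = conf
        rows.append(row)
    return pd.DataFrame(rows)


def loo_confidences(
    features: np.ndarray | pd.DataFrame,
    labels: Sequence[str],
    merge_map: Mapping[str, str] | None = None,
    ridge: float = 1e-6,
) -> tuple[float, float]:
    """(mean assignment confidence, accuracy) under leave-one-out evaluation."""
    table = evaluate_cohort(
        features, labels, merge_map=merge_map, leave_one_out=True, ridge=ridge
    )
    return float(table["confidence"].mean()), float(table["correct"].mean())
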