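"""Evaluation statistics for proportion estimates and proportion-based clustering.

The four scalar metrics compare a vector of predicted values against a
vector of true values (typically one cell type across profiles, or one
profile across cell types):

* ``pcc`` — Pearson's correlation coefficient.
* ``ccc`` — Lin's concordance correlation coefficient, which penalises
  deviation from the identity line and not only non-linearity; it equals
  the PCC multiplied by a bias-correction factor in [0, 1].
* ``rmse`` — root mean squared error.
* ``jsd`` — Jensen–Shannon divergence between two composition vectors,
  with base-2 logarithms so it lies in [0, 1].

``cluster_spots`` groups spots by their predicted composition with
k-means, so that tissue regions can be delineated from deconvolution
output alone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import rel_entr
from sklearn.cluster import KMeans

__all__ = [
    "pcc",
    "ccc",
    "rmse",
    "jsd",
    "MetricVector",
    "metric_vector",
    "ClusterAssignment",
    "cluster_spots",
]


def pcc(x, y) -> float:
    """Pearson correlation coefficient between two equal-length vectors.

    Returns NaN (with a warning) when either vector has zero variance,
    since the coefficient is undefined there.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < 2:
        raise ValueError("pcc requires vectors of length >= 2")
    if np.var(x) == 0.0 or np.var(y) == 0.0:
        warnings.warn("pcc undefined for zero-variance input; returning NaN",
                      RuntimeWarning, stacklevel=2)
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def ccc(x, y) -> float:
    """Lin's concordance correlation coefficient.

    Uses population (1/n) moments:

        ccc = 2 cov(x, y) / (var(x) + var(y) + (mean(x) - mean(y))^2)

    Two identical constant vectors are perfectly concordant and return 1
    by convention; distinct constant vectors fall through to the formula
    (pure location-shift penalty).
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < 2:
        raise ValueError("ccc requires vectors of length >= 2")
    mx, my = x.mean(), y.mean()
    vx, vy = np.var(x), np.var(y)
    cov = np.mean((x - mx) * (y - my))
    denom = vx + vy + (mx - my) ** 2
    if denom == 0.0:
        # both constant and equal
        return 1.0
    return float(2.0 * cov / denom)


def rmse(x, y) -> float:
    """Root mean squared difference between two equal-length vectors."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    return float(np.sqrt(np.mean((x - y) ** 2)))


def jsd(p, q) -> float:
    """Jensen–Shannon divergence between two composition vectors.

    Base-2 logarithms, so the result lies in [0, 1]; 0·log 0 is taken as
    0. Inputs must be non-negative and are renormalised to sum to 1.
    """
    p = np.asarray(p, dtype=float).ravel()
    q = np.asarray(q, dtype=float).ravel()
    if p.size != q.size:
        raise ValueError(f"length mismatch: {p.size} vs {q.size}")
    if (p < 0).any() or (q < 0).any():
        raise ValueError("jsd inputs must be non-negative")
    sp, sq = p.sum(), q.sum()
    if sp <= 0 or sq <= 0:
        raise ValueError("jsd inputs must have positive mass")
    p = p / sp
    q = q / sq
    m = 0.5 * (p + q)
    # rel_entr uses natural logs and handles 0·log0 = 0
    kl_pm = rel_entr(p, m).sum()
    kl_qm = rel_entr(q, m).sum()
    return float(0.5 * (kl_pm + kl_qm) / np.log(2.0))


@dataclass
class MetricVector:
    """The four metrics evaluated on one pair of vectors."""

    pcc: float
    ccc: float
    rmse: float
    jsd: float


def metric_vector(x, y) -> MetricVector:
    """Compute all four metrics on one (truth, prediction) vector pair.

    JSD treats the two vectors as compositions (renormalised); the other
    three compare them entrywise.
    """
    return MetricVector(pcc=pcc(x, y), ccc=ccc(x, y), rmse=rmse(x, y),
                        jsd=jsd(np.abs(x), np.abs(y)))


@dataclass
class ClusterAssignment:
    """k-means grouping of spots in cell-type-proportion space."""

    labels: np.ndarray
    n_clusters: int
    method: str = "kmeans"
    seed: int = 0
    inertia: float = field(default=float("nan"))


def cluster_spots(props, n_clusters: int, seed: int = 0,
                  n_restarts: int = 10) -> ClusterAssignment:
    """Cluster spots by their proportion vectors with Euclidean k-means.

    Runs ``n_restarts`` initialisations and keeps the lowest-inertia
    solution; deterministic for a fixed ``seed``.
    """
    props = np.asarray(props, dtype=float)
    if props.ndim != 2:
        raise ValueError("props must be a spots x types matrix")
    n_spots = props.shape[0]
    if n_clusters >= n_spots:
        raise ValueError(
            f"n_clusters ({n_clusters}) must be smaller than the number of "
            f"spots ({n_spots})")
    if n_clusters < 2:
        raise ValueError("n_clusters must be >= 2")
    km = KMeans(n_clusters=n_clusters, n_init=n_restarts, random_state=seed)
    labels = km.fit_predict(props)
    return ClusterAssignment(labels=labels, n_clusters=n_clusters,
                             method="kmeans", seed=seed,
                             inertia=float(km.inertia_))
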