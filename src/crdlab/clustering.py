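"""Behavioral clustering of 10-round action vectors.

Individual game play (one 10-element integer action sequence per player
per game, Game 1 and Game 2 pooled) is clustered with K-means on the raw,
unscaled vectors — all coordinates share units (ECoins per round), and
standardizing would distort the fair-share anchor at 2.  The number of
clusters is chosen by the elbow rule, formalized as the k maximizing the
second difference (discrete curvature) of the inertia curve.  Clusters are
then named by where their centroids sit relative to the per-round fair
share of 2 ECoins: *early* contributors start above 2 and end below it,
*high*/*fair*/*low* contributors sit above / at / below 2 throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from sklearn.cluster import KMeans

__all__ = [
    "ClusterResult",
    "ElbowResult",
    "cluster_actions",
    "select_k_elbow",
    "name_clusters",
    "label_behaviors",
]

FAIR_SHARE = 2.0  # per-round fair contribution (endowment/2 over 10 rounds)


@dataclass(frozen=True)
class ClusterResult:
    assignments: np.ndarray  # cluster index per vector
    centroids: np.ndarray    # (k, rounds)
    inertia: float


@dataclass(frozen=True)
class ElbowResult:
    k: int
    inertia: dict[int, float]  # the full curve, for inspection


def _as_matrix(vectors) -> np.ndarray:
    X = np.asarray(vectors, dtype=float)
    if X.ndim != 2:
        raise ValueError(f"expected a 2-D array of action vectors, got {X.shape}")
    return X


def cluster_actions(vectors, k: int, seed: Optional[int] = None,
                    n_init: int = 10) -> ClusterResult:
    """K-means (Lloyd) on raw action vectors, best of ``n_init`` inits."""
    X = _as_matrix(vectors)
    n_distinct = np.unique(X, axis=0).shape[0]
    if n_distinct < k:
        raise ValueError(
            f"need at least k={k} distinct vectors, found {n_distinct}"
        )
    km = KMeans(n_clusters=k, n_init=n_init, init="random",
                algorithm="lloyd", random_state=seed)
    assignments = km.fit_predict(X)
    return ClusterResult(assignments=assignments, centroids=km.cluster_centers_,
                         inertia=float(km.inertia_))


def select_k_elbow(vectors, k_range: Sequence[int] = range(1, 9),
                   seed: Optional[int] = None, n_init: int = 10) -> ElbowResult:
    """Elbow selection: the knee of the log-inertia curve.

    The within-cluster sum of squares is computed for every k in
    ``k_range`` and the selected k is the one whose log-inertia lies
    farthest *below* the chord joining the curve's endpoints (the
    standard knee/elbow construction); endpoints are not eligible.  The
    log scale makes the rule invariant to the overall inertia scale, so
    an elbow between clusters of modest separation is not drowned out by
    one very distant cluster, which would dominate raw differences.  If
    the inertia is already (numerically) zero at the smallest k — e.g.
    all vectors identical — that smallest k is returned.
    """
    ks = sorted(set(int(k) for k in k_range))
    if len(ks) < 3:
        raise ValueError("k_range must contain at least 3 values")
    X = _as_matrix(vectors)
    n_distinct = np.unique(X, axis=0).shape[0]
    inertia: dict[int, float] = {}
    for k in ks:
        if k > n_distinct:
            inertia[k] = 0.0
            continue
        inertia[k] = cluster_actions(X, k, seed=seed, n_init=n_init).inertia
    if inertia[ks[0]] <= 1e-12:
        return ElbowResult(k=ks[0], inertia=inertia)
    floor = 1e-12  # zero inertia (perfect separation) stays finite on the log scale
    log_i = {k: np.log(max(v, floor)) for k, v in inertia.items()}
    k_lo, k_hi = ks[0], ks[-1]
    slope = (log_i[k_hi] - log_i[k_lo]) / (k_hi - k_lo)
    below_chord = {
        k: (log_i[k_lo] + slope * (k - k_lo)) - log_i[k] for k in ks[1:-1]
    }
    best = max(below_chord, key=below_chord.get)
    return ElbowResult(k=best, inertia=inertia)


def name_clusters(centroids, delta: float = 1.0, eps: float = 0.5,
                  fair_share: float = FAIR_SHARE) -> list[str]:
    """Name centroids as early / high / fair / low contributors.

    A centroid is *early* if its rounds 1–5 mean exceeds the fair share,
    its rounds 6–10 mean falls below it, and the drop exceeds ``delta``.
    Otherwise it is *high* / *low* when its overall mean is more than
    ``eps`` above / below the fair share, and *fair* in between.
    Duplicate names are permitted (the caller may flag them).
    """
    C = _as_matrix(centroids)
    half = C.shape[1] // 2
    labels = []
    for c in C:
        m = c.mean()
        first, second = c[:half].mean(), c[half:].mean()
        if (first - second) > delta and first > fair_share and second < fair_share:
            labels.append("early")
        elif m > fair_share + eps:
            labels.append("high")
        elif m < fair_share - eps:
            labels.append("low")
        else:
            labels.append("fair")
    return labels


def label_behaviors(vectors, k: int = 4, seed: Optional[int] = None,
                    n_init: int = 10, delta: float = 1.0,
                    eps: float = 0.5) -> tuple[np.ndarray, ClusterResult, list[str]]:
    """Cluster action vectors and name each one's cluster.

    Returns (per-vector labels, the raw cluster result, per-centroid names).
    """
    result = cluster_actions(vectors, k, seed=seed, n_init=n_init)
    names = name_clusters(result.centroids, delta=delta, eps=eps)
    labels = np.array([names[i] for i in result.assignments])
    return labels, result, names
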